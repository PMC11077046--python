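"""Why mate bridging matters: peak centering in antibody-enrichment data.

In m6A-seq, ~150-nt immunoprecipitated fragments are sequenced ~40 nt from
each end. Counting only the sequenced stretches gives a coverage dip over the
methylated base and often splits one true peak in two; bridging the mates
restores the full-insert coverage with its apex on the site. We simulate 200
genes, each with one methylated DRACH, and compare the two processing modes
on the same molecules.
"""

import numpy as np
import txpileup as tp

cfg = tp.SimConfig(seed=60, n_chroms=4, chrom_length=80_000, n_genes=200,
                   exons_per_gene=(1, 2), exon_length=(200, 350))
genome = tp.make_genome(cfg)
models = tp.make_annotation(genome, cfg)
sites = {}
for m in models:
    c = m.tx_length // 2
    tp.plant_motif(genome, m, c)  # GGACT, a DRACH with the A at center
    sites[m.gene_id] = c

rng = np.random.default_rng(61)
paired, single = tp.enriched_library(models, sites, n_fragments=150,
                                     insert_length=150, read_length=40, rng=rng)
tb = tp.make_table(paired, models, mode="cov")
ts = tp.make_table(single, models, mode="cov")
pk_paired = tp.call_peaks(tb, smooth_w=1, min_cov=30, min_gap=50)
pk_single = tp.call_peaks(ts, smooth_w=1, min_cov=30, min_gap=50)

hit_p = sum(sites[r.gene] == r.txcoor for r in pk_paired.itertuples())
hit_s = sum(sites[r.gene] == r.txcoor for r in pk_single.itertuples())
print(f"paired (bridged): {hit_p}/{len(pk_paired)} peaks exactly on the methylated A "
      f"({hit_p / len(pk_paired):.1%})")
print(f"single-end:       {hit_s}/{len(pk_single)} peaks exactly on the methylated A "
      f"({hit_s / len(pk_single):.1%})")
print("-> single-end mode calls more peaks, but far fewer sit on the true site;")
print("   bridging the 70 unsequenced nucleotides between mates fixes the apex.")
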