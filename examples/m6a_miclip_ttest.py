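"""miCLIP-style m6A detection: replicate t-tests plus DRACH motif context.

Antibody crosslinks at methylated adenosines truncate reverse transcription,
so wild-type libraries show elevated startRatio_1bpDS at m6A sites while
methyltransferase-knockout libraries do not. We simulate 2 WT and 2 KO
replicates, unify their tables, t-test every position, and keep putative
sites with mean difference > 0.05, p < 0.01, at adenines.
"""

import tempfile, os
import txpileup as tp

tmp = tempfile.mkdtemp()
base = tp.SimConfig(seed=40, n_genes=4, fragments_per_gene=1500, error_rate=0.0)
genome = tp.make_genome(base)
models = tp.make_annotation(genome, base)

# put the methylated A on a planted DRACH so the motif annotation is meaningful
gene = models[0].gene_id
site = models[0].tx_length // 2
tp.plant_motif(genome, models[0], site)  # GGACT with the A at `site`


def replicate(seed, stop_prob):
    cfg = tp.SimConfig(seed=seed, n_genes=4, fragments_per_gene=1500, error_rate=0.0)
    sam = os.path.join(tmp, f"rep{seed}.sam")
    tp.simulate_library(models, genome, cfg,
                        [tp.ModSiteSpec(gene, site, "rt_stop", stop_prob)], sam_path=sam)
    frags, _ = tp.assign_to_transcripts(tp.load_alignments(sam), models)
    return tp.add_start_ratio_1bp_ds(tp.make_table(frags, models, genome=genome))


wt = [replicate(s, 0.6) for s in (41, 42)]
ko = [replicate(s, 0.02) for s in (43, 44)]
tables = tp.unify_tables(wt + ko)
res = tp.row_ttests(tables[:2], tables[2:], "startRatio_1bpDS")

merged = tables[0][["chrom", "gencoor", "strand", "gene", "txcoor", "refSeq"]].copy()
merged["mean_diff"] = res["mean_diff"]
merged["p_value"] = res["p_value"]
tp.add_motif_presence(merged, "DRACH", models=models, genome=genome)
tp.call_sites(merged, [("mean_diff", ">", 0.05), ("p_value", "<", 0.01),
                       ("refSeq", "==", "A")])

hits = merged[merged["putative_site"]]
print(f"positions tested: {len(merged)}; putative m6A sites: {len(hits)}")
for r in hits.itertuples():
    in_drach = "in DRACH" if getattr(r, "motif_DRACH") else "no motif"
    print(f"  {r.gene}:{r.txcoor}  diff={r.mean_diff:.3f}  p={r.p_value:.2e}  ({in_drach})")
print(f"injected site was {gene}:{site} (WT stop 0.6 vs KO 0.02, planted DRACH)")
print("-> diff estimates the WT-specific truncation excess; the motif flag shows")
print("   the called site sits in the expected m6A sequence context.")
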