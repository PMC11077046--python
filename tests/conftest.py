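import numpy as np
import pytest

import txpileup as tp


@pytest.fixture
def two_exon_plus():
    return tp.TranscriptModel("geneA", "chr1", "+", ((100, 150), (200, 260)), (120, 230))


@pytest.fixture
def two_exon_minus():
    return tp.TranscriptModel("geneB", "chr1", "-", ((100, 150), (200, 260)))


@pytest.fixture(scope="session")
def sim_library(tmp_path_factory):
    """Small mixed-strand multi-exon paired-end library with truth record."""
    d = tmp_path_factory.mktemp("simlib")
    cfg = tp.SimConfig(seed=11, n_genes=6, fragments_per_gene=200)
    genome = tp.make_genome(cfg, d / "genome.fa")
    models = tp.make_annotation(genome, cfg, d / "annotation.bed")
    truth = tp.simulate_library(models, genome, cfg, sam_path=d / "reads.sam",
                                truth_path=d / "truth.tsv")
    return {
        "dir": d, "config": cfg, "genome": genome, "models": models, "truth": truth,
        "sam": d / "reads.sam", "bed": d / "annotation.bed", "fasta": d / "genome.fa",
    }


def brute_force_table(fragments_by_gene, models, genome=None, mode="covNuc"):
    """Independent per-position oracle: scan every fragment at every position."""
    import pandas as pd

    rows = []
    for model in models:
        frags = fragments_by_gene.get(model.gene_id, [])
        if not frags:
            continue
        seq = tp.transcript_sequence(model, genome) if genome is not None else None
        for p in range(1, model.tx_length + 1):
            row = {
                "chrom": model.chrom,
                "gencoor": model.tx_to_genomic(p),
                "strand": model.strand,
                "gene": model.gene_id,
                "txcoor": p,
            }
            if mode in ("nucFreq", "covNuc"):
                row["refSeq"] = seq[p - 1] if seq else "."
            # one scan over every fragment for this position
            cov = start = end = 0
            base_counts = dict.fromkeys("ACGTN-", 0)
            for f in frags:
                if f.tx_start <= p <= f.tx_end:
                    cov += 1
                    if f.tx_start == p:
                        start += 1
                    if f.tx_end == p:
                        end += 1
                    b = f.calls.get(p)
                    if b is not None:
                        base_counts[b] += 1
            if mode in ("cov", "covNuc"):
                row["cov"], row["start_5p"], row["end_3p"] = cov, start, end
            if mode in ("nucFreq", "covNuc"):
                for base, col in zip("ACGTN-", ["A", "C", "G", "T", "N", "del"]):
                    row[col] = base_counts[base]
            rows.append(row)
    return pd.DataFrame(rows)


def random_fragments(models, n_per_gene, seed):
    rng = np.random.default_rng(seed)
    out = {}
    for m in models:
        L = m.tx_length
        frags = []
        for _ in range(n_per_gene):
            a = int(rng.integers(1, L + 1))
            b = min(L, a + int(rng.integers(0, 200)))
            calls = {}
            for p in range(a, min(b, a + 40) + 1):
                calls[p] = "ACGTN-"[int(rng.integers(6))]
            frags.append(tp.TxFragment(m.gene_id, a, b, calls))
        out[m.gene_id] = frags
    return out
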