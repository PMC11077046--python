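"""Synthetic genomes, annotations and aligned read libraries with known truth.

The generator emulates the inputs of RT-based epitranscriptomic experiments:
a small multi-chromosome genome, multi-exon genes on both strands with CDS
annotations, and paired-end fragment libraries carrying injected modification
effects —

- ``rt_stop``  : with a given probability a fragment reading through the site
  is truncated so its new 5' end sits one nucleotide downstream (s+1), the
  signature of CMC-pseudouridine adducts and miCLIP crosslinks;
- ``misinc``   : the molecule carries a substituted base at the site
  (e.g. C→T for ac4C after NaCNBH3 reduction), read by both mates;
- ``cleavage`` : the fragment is split at the site, producing a read end at s
  and a read start at s+1.

Reads are emitted pre-aligned as coordinate-sorted SAM written directly from
the truth (correct chrom, pos, M/N CIGAR across junctions, pair flags), so
conversion is testable in isolation from any aligner. Everything is
deterministic under ``SimConfig.seed``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .annotation import TranscriptModel, reverse_complement, transcript_sequence

__all__ = [
    "SimConfig",
    "ModSiteSpec",
    "make_genome",
    "make_annotation",
    "simulate_library",
    "enriched_library",
    "plant_motif",
]

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Declarative description of a synthetic study.

    Fragment lengths are normal(mean, sd) truncated to [min, max] and to the
    transcript; mates are the terminal ``read_length`` bases of each fragment
    end; per-base sequencing errors are applied after modification effects.
    """

    seed: int = 1
    n_chroms: int = 2
    chrom_length: int = 20_000
    n_genes: int = 10
    exons_per_gene: tuple[int, int] = (1, 3)
    exon_length: tuple[int, int] = (100, 300)
    intron_length: tuple[int, int] = (50, 500)
    strand_mix: float = 0.5
    fragment_mean: float = 150.0
    fragment_sd: float = 30.0
    fragment_min: int = 50
    fragment_max: int = 400
    read_length: int = 40
    fragments_per_gene: int = 500
    error_rate: float = 0.001

    def __post_init__(self) -> None:
        if self.read_length > self.fragment_max:
            raise ValueError("read_length exceeds maximum fragment length")
        for name in ("chrom_length", "n_genes", "fragment_min", "fragment_max", "read_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class ModSiteSpec:
    """One injected modification effect at a transcript position."""

    gene_id: str
    tx_pos: int
    effect: str  # rt_stop | misinc | cleavage
    prob: float = 1.0
    from_base: Optional[str] = None
    to_base: Optional[str] = None

    def __post_init__(self) -> None:
        if self.effect not in ("rt_stop", "misinc", "cleavage"):
            raise ValueError(f"unknown effect {self.effect!r}")
        if not 0.0 <= self.prob <= 1.0:
            raise ValueError("prob must be in [0, 1]")
        if self.effect == "misinc" and (self.from_base is None or self.to_base is None):
            raise ValueError("misinc requires from_base and to_base")


def _write_fasta(genome: dict[str, str], path: str | os.PathLike, width: int = 60) -> None:
    with open(path, "w") as out:
        for name, seq in genome.items():
            out.write(f">{name}\n")
            for i in range(0, len(seq), width):
                out.write(seq[i : i + width] + "\n")


def make_genome(
    config: SimConfig, fasta_path: Optional[str | os.PathLike] = None
) -> dict[str, str]:
    """Uniform-random A/C/G/T chromosomes; optionally written as FASTA."""
    rng = np.random.default_rng([config.seed, 0])
    genome = {
        f"chr{i + 1}": "".join(rng.choice(_BASES, size=config.chrom_length))
        for i in range(config.n_chroms)
    }
    if fasta_path is not None:
        _write_fasta(genome, fasta_path)
    return genome


def _bed12_line(m: TranscriptModel) -> str:
    start = m.exons[0][0]
    end = m.exons[-1][1]
    sizes = ",".join(str(e - s) for s, e in m.exons)
    offs = ",".join(str(s - start) for s, _ in m.exons)
    thick = m.cds if m.cds is not None else (start, start)
    return "\t".join(
        str(x)
        for x in (
            m.chrom, start, end, m.gene_id, 0, m.strand,
            thick[0], thick[1], 0, len(m.exons), sizes, offs,
        )
    )


def write_bed(models: Iterable[TranscriptModel], path: str | os.PathLike) -> None:
    with open(path, "w") as out:
        for m in models:
            out.write(_bed12_line(m) + "\n")


def make_annotation(
    genome: dict[str, str],
    config: SimConfig,
    bed_path: Optional[str | os.PathLike] = None,
) -> list[TranscriptModel]:
    """Non-overlapping genes on both strands with CDS and nonempty UTRs.

    Genes are laid out left to right per chromosome (round-robin) with a gap
    between neighbours; raises when the genome cannot host the request.
    """
    rng = np.random.default_rng([config.seed, 1])
    chroms = list(genome)
    cursors = {c: 50 for c in chroms}
    gap = 100
    models: list[TranscriptModel] = []
    for i in range(config.n_genes):
        n_ex = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        ex_lens = rng.integers(config.exon_length[0], config.exon_length[1] + 1, size=n_ex)
        in_lens = rng.integers(config.intron_length[0], config.intron_length[1] + 1,
                               size=max(0, n_ex - 1))
        span = int(ex_lens.sum() + in_lens.sum())
        strand = "+" if rng.random() < config.strand_mix else "-"
        placed = False
        for c in chroms[i % len(chroms):] + chroms[: i % len(chroms)]:
            if cursors[c] + span <= len(genome[c]) - 50:
                start = cursors[c]
                cursors[c] = start + span + gap
                exons = []
                g = start
                for j, ln in enumerate(ex_lens):
                    exons.append((g, g + int(ln)))
                    if j < n_ex - 1:
                        g = g + int(ln) + int(in_lens[j])
                L = int(ex_lens.sum())
                cds = None
                if L >= 30:
                    u5 = max(1, round(L * 0.15))
                    u3 = max(1, round(L * 0.15))
                    model = TranscriptModel(f"gene{i + 1:03d}", c, strand, tuple(exons))
                    if strand == "+":
                        cds = (model.tx_to_genomic(u5 + 1) - 1, model.tx_to_genomic(L - u3))
                    else:
                        cds = (model.tx_to_genomic(L - u3) - 1, model.tx_to_genomic(u5 + 1))
                models.append(TranscriptModel(f"gene{i + 1:03d}", c, strand, tuple(exons), cds))
                placed = True
                break
        if not placed:
            raise ValueError(f"genome too small to place gene {i + 1} (span {span})")
    if bed_path is not None:
        write_bed(models, bed_path)
    return models


# ---------------------------------------------------------------------------
# library simulation


def _cigar_and_pos(gpos_sorted: np.ndarray) -> tuple[int, str]:
    """1-based POS and M/N CIGAR from ascending genomic positions."""
    pos = int(gpos_sorted[0])
    parts = []
    run = 1
    for prev, cur in zip(gpos_sorted[:-1], gpos_sorted[1:]):
        if cur == prev + 1:
            run += 1
        else:
            parts.append(f"{run}M{int(cur - prev - 1)}N")
            run = 1
    parts.append(f"{run}M")
    return pos, "".join(parts)


def _apply_errors(seq: list[str], rng: np.random.Generator, rate: float) -> None:
    if rate <= 0:
        return
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    for i in hits:
        alt = [b for b in "ACGT" if b != seq[i]]
        seq[i] = alt[int(rng.integers(3))]


def simulate_library(
    models: list[TranscriptModel],
    genome: dict[str, str],
    config: SimConfig,
    mod_sites: Iterable[ModSiteSpec] = (),
    paired: bool = True,
    sam_path: str | os.PathLike = "reads.sam",
    truth_path: Optional[str | os.PathLike] = None,
) -> pd.DataFrame:
    """Draw fragments per gene, apply modification effects, write sorted SAM.

    Returns the truth record: one row per emitted fragment with its transcript
    span and the effects applied. With ``paired`` the two mates are written as
    a proper pair; otherwise each mate becomes an independent unpaired record
    (note the read2-derived records are then antisense to the gene).
    """
    rng = np.random.default_rng([config.seed, 2])
    by_id = {m.gene_id: m for m in models}
    sites_by_gene: dict[str, dict[str, list[ModSiteSpec]]] = {}
    for spec in mod_sites:
        if spec.gene_id not in by_id:
            raise ValueError(f"mod site references unknown gene {spec.gene_id!r}")
        model = by_id[spec.gene_id]
        if not 1 <= spec.tx_pos <= model.tx_length:
            raise ValueError(f"mod site position {spec.tx_pos} outside {spec.gene_id}")
        if spec.effect == "misinc":
            base = transcript_sequence(model, genome)[spec.tx_pos - 1]
            if base != spec.from_base.upper():
                raise ValueError(
                    f"{spec.gene_id}:{spec.tx_pos} is {base}, not {spec.from_base}"
                )
        sites_by_gene.setdefault(spec.gene_id, {}).setdefault(spec.effect, []).append(spec)

    chrom_order = {c: i for i, c in enumerate(genome)}
    records: list[tuple[int, int, str, str]] = []  # (chrom_idx, pos, name, line)
    truth_rows: list[dict[str, object]] = []
    RL = config.read_length

    for model in models:
        L = model.tx_length
        tseq = transcript_sequence(model, genome)
        gsites = sites_by_gene.get(model.gene_id, {})
        n = config.fragments_per_gene
        lens = np.clip(
            np.rint(rng.normal(config.fragment_mean, config.fragment_sd, size=n)),
            config.fragment_min,
            config.fragment_max,
        ).astype(np.int64)
        starts = rng.integers(1, L + 1, size=n)
        ends = np.minimum(starts + lens - 1, L)

        effects: list[list[str]] = [[] for _ in range(n)]
        for spec in sorted(gsites.get("rt_stop", []), key=lambda s: s.tx_pos):
            s = spec.tx_pos
            mask = (starts <= s) & (s < ends) & (rng.random(n) < spec.prob)
            starts[mask] = s + 1
            for i in np.flatnonzero(mask):
                effects[i].append(f"rt_stop@{s}")

        # split fragments at cleavage sites, then mis-substitute per molecule
        frags: list[tuple[int, int, list[str]]] = []
        cleav = sorted(gsites.get("cleavage", []), key=lambda s: s.tx_pos)
        for i in range(n):
            parts = [(int(starts[i]), int(ends[i]), list(effects[i]))]
            for spec in cleav:
                s = spec.tx_pos
                new_parts = []
                for a, b, eff in parts:
                    if a <= s < b and rng.random() < spec.prob:
                        new_parts.append((a, s, eff + [f"cleavage@{s}"]))
                        new_parts.append((s + 1, b, eff + [f"cleavage@{s}"]))
                    else:
                        new_parts.append((a, b, eff))
                parts = new_parts
            frags.extend(parts)

        for fi, (a, b, eff) in enumerate(frags):
            name = f"{model.gene_id}.{fi}"
            mods: dict[int, str] = {}
            for spec in gsites.get("misinc", []):
                s = spec.tx_pos
                if a <= s <= b and rng.random() < spec.prob:
                    mods[s] = spec.to_base.upper()
                    eff = eff + [f"misinc@{s}"]
            truth_rows.append(
                {"gene": model.gene_id, "fragment": name, "tx_start": a, "tx_end": b,
                 "effects": ";".join(eff)}
            )
            r1 = (a, min(a + RL - 1, b))
            r2 = (max(a, b - RL + 1), b)
            mates = [r1, r2]
            mate_recs = []
            for mi, (ma, mb) in enumerate(mates):
                seq = [mods.get(t, tseq[t - 1]) for t in range(ma, mb + 1)]
                _apply_errors(seq, rng, config.error_rate)
                gpos = model.tx_to_genomic_array(np.arange(ma, mb + 1))
                order = np.argsort(gpos)
                gsorted = gpos[order]
                pos, cigar = _cigar_and_pos(gsorted)
                tx_seq_str = "".join(seq)
                sam_seq = tx_seq_str if model.strand == "+" else reverse_complement(tx_seq_str)
                mate_recs.append((pos, cigar, sam_seq, int(gsorted[-1])))
            # flags: read1 aligns on the gene strand, read2 on the opposite (FR)
            if paired:
                span_lo = min(r[0] for r in mate_recs)
                span_hi = max(r[3] for r in mate_recs)
                tlen_abs = span_hi - span_lo + 1
                plus = model.strand == "+"
                flags = (99, 147) if plus else (83, 163)
                for mi, (pos, cigar, sam_seq, _end) in enumerate(mate_recs):
                    other = mate_recs[1 - mi]
                    if pos < other[0] or (pos == other[0] and mi == 0):
                        tlen = tlen_abs
                    else:
                        tlen = -tlen_abs
                    line = "\t".join(
                        [name, str(flags[mi]), model.chrom, str(pos), "60", cigar,
                         "=", str(other[0]), str(tlen), sam_seq, "I" * len(sam_seq)]
                    )
                    records.append((chrom_order[model.chrom], pos, f"{name}/{mi + 1}", line))
            else:
                for mi, (pos, cigar, sam_seq, _end) in enumerate(mate_recs):
                    plus_aln = (model.strand == "+") == (mi == 0)
                    flag = 0 if plus_aln else 16
                    line = "\t".join(
                        [f"{name}/{mi + 1}", str(flag), model.chrom, str(pos), "60", cigar,
                         "*", "0", "0", sam_seq, "I" * len(sam_seq)]
                    )
                    records.append((chrom_order[model.chrom], pos, f"{name}/{mi + 1}", line))

    records.sort(key=lambda r: (r[0], r[1], r[2]))
    with open(sam_path, "w") as out:
        out.write("@HD\tVN:1.6\tSO:coordinate\n")
        for c, seq in genome.items():
            out.write(f"@SQ\tSN:{c}\tLN:{len(seq)}\n")
        for _, _, _, line in records:
            out.write(line + "\n")

    truth = pd.DataFrame(truth_rows, columns=["gene", "fragment", "tx_start", "tx_end", "effects"])
    if truth_path is not None:
        truth.to_csv(truth_path, sep="\t", index=False)
    return truth


def plant_motif(
    genome: dict[str, str],
    model: TranscriptModel,
    tx_pos: int,
    motif: str = "GGACT",
    center: int = 3,
) -> None:
    """Overwrite the genome so the transcript carries ``motif`` centered at tx_pos.

    ``center`` is the 1-based position of the focal base within the motif
    (default: the A of GGACT, a DRACH instance). Handles strand: for
    minus-strand models the complementary bases are written to the plus
    genomic strand. Mutates ``genome`` in place.
    """
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    for i, base in enumerate(motif.upper()):
        t = tx_pos - center + 1 + i
        if not 1 <= t <= model.tx_length:
            raise ValueError("motif window leaves the transcript")
        g = model.tx_to_genomic(t)
        b = base if model.strand == "+" else comp[base]
        seq = genome[model.chrom]
        genome[model.chrom] = seq[: g - 1] + b + seq[g:]


def enriched_library(
    models: list[TranscriptModel],
    site_by_gene: dict[str, int],
    n_fragments: int,
    insert_length: int,
    read_length: int,
    rng: np.random.Generator,
):
    """Antibody-enrichment (m6A-seq style) fragment library in transcript space.

    Every fragment of a gene contains that gene's site, with the site placed
    uniformly along the insert — the idealization of immunoprecipitating
    fragments that carry a methylated base. Returns two fragment mappings over
    the same molecules: ``paired`` (one bridged fragment per molecule) and
    ``single`` (the two terminal ``read_length`` mates as separate fragments),
    so the two processing modes can be compared on identical data.
    """
    from .conversion import TxFragment

    paired: dict[str, list[TxFragment]] = {}
    single: dict[str, list[TxFragment]] = {}
    for m in models:
        s = site_by_gene.get(m.gene_id)
        if s is None:
            continue
        L = m.tx_length
        offs = rng.integers(0, insert_length, size=n_fragments)
        starts = np.clip(s - offs, 1, None)
        ends = np.minimum(starts + insert_length - 1, L)
        p_list, s_list = [], []
        for a, b in zip(starts, ends):
            a, b = int(a), int(b)
            p_list.append(TxFragment(m.gene_id, a, b))
            s_list.append(TxFragment(m.gene_id, a, min(a + read_length - 1, b)))
            s_list.append(TxFragment(m.gene_id, max(a, b - read_length + 1), b))
        paired[m.gene_id] = p_list
        single[m.gene_id] = s_list
    return paired, single
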