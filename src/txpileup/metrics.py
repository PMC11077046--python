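"""Per-position derived metrics appended to a per-nucleotide table.

These are the detection statistics of RT-based epitranscriptomic assays:

- ``startRatio`` — read-starts over coverage; spikes one nucleotide downstream
  of an RT-blocking adduct (CMC-pseudouridine, antibody crosslinks).
- ``startRatio_1bpDS`` — startRatio shifted one position downstream so the
  signal lands *on* the modified base.
- ``misincRate`` / ``MR_<X>to<Y>`` — misincorporation rates; e.g. the C→T rate
  is the ac4C-seq read-out after NaCNBH3 reduction.
- treated-minus-control differences of any of the above (SRD_1bpDS, MRD_CtoT).
- IUPAC motif presence (e.g. DRACH around m6A), gene-region labels, and
  thresholded putative-site calls.

Metrics are ratios in [0, 1] or NaN (never a division error); differences lie
in [-1, 1]. All functions append column(s) to the given table in place and
return it, so calls chain.
"""

from __future__ import annotations

import math
import re
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .annotation import TranscriptModel, transcript_sequence

__all__ = [
    "add_start_ratio",
    "add_start_ratio_1bp_ds",
    "add_misinc_rate",
    "add_misinc_rate_specific",
    "add_diff",
    "add_motif_presence",
    "add_gene_region",
    "call_sites",
    "IUPAC",
]

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def _require(table: pd.DataFrame, cols: Sequence[str]) -> None:
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise KeyError(f"table lacks required column(s): {missing}")


def _ratio(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    out = np.full(len(num), np.nan)
    ok = den > 0
    out[ok] = num[ok] / den[ok]
    return out


def add_start_ratio(table: pd.DataFrame) -> pd.DataFrame:
    """start_5p / cov per position; NaN where coverage is zero."""
    _require(table, ["cov", "start_5p"])
    table["startRatio"] = _ratio(
        table["start_5p"].to_numpy(float), table["cov"].to_numpy(float)
    )
    return table


def add_start_ratio_1bp_ds(table: pd.DataFrame) -> pd.DataFrame:
    """startRatio of position i+1 reported at position i (within each gene).

    The last position of each gene has no downstream neighbour and is NaN.
    """
    _require(table, ["cov", "start_5p", "gene"])
    sr = pd.Series(
        _ratio(table["start_5p"].to_numpy(float), table["cov"].to_numpy(float)),
        index=table.index,
    )
    table["startRatio_1bpDS"] = sr.groupby(table["gene"], sort=False).shift(-1)
    return table


def _match_mask(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """(denominator over ACGT calls, count of calls matching refSeq)."""
    den = sum(table[b].to_numpy(float) for b in "ACGT")
    ref = table["refSeq"].to_numpy(object)
    matched = np.zeros(len(table))
    for b in "ACGT":
        matched += np.where(ref == b, table[b].to_numpy(float), 0.0)
    return den, matched


def add_misinc_rate(table: pd.DataFrame, include_del: bool = False) -> pd.DataFrame:
    """Fraction of A/C/G/T calls differing from the reference base.

    N calls and deletions are excluded; ``include_del`` adds deletions to both
    numerator and denominator (for cleavage-style chemistries). NaN where the
    denominator is zero or the reference base is not A/C/G/T.
    """
    _require(table, ["refSeq"] + list("ACGT"))
    den, matched = _match_mask(table)
    mis = den - matched
    if include_del:
        mis = mis + table["del"].to_numpy(float)
        den = den + table["del"].to_numpy(float)
    rate = _ratio(mis, den)
    ref = table["refSeq"].to_numpy(object)
    rate[~np.isin(ref, list("ACGT"))] = np.nan
    table["misincRate"] = rate
    return table


def add_misinc_rate_specific(
    table: pd.DataFrame, from_base: str, to_base: str
) -> pd.DataFrame:
    """Specific misincorporation rate, e.g. MR_CtoT = T calls / ACGT calls at C.

    NaN everywhere the reference base differs from ``from_base``.
    """
    from_base, to_base = from_base.upper(), to_base.upper()
    if from_base == to_base:
        raise ValueError("from_base and to_base must differ")
    for b in (from_base, to_base):
        if b not in "ACGT":
            raise ValueError(f"invalid base {b!r}")
    _require(table, ["refSeq"] + list("ACGT"))
    den = sum(table[b].to_numpy(float) for b in "ACGT")
    rate = _ratio(table[to_base].to_numpy(float), den)
    rate[table["refSeq"].to_numpy(object) != from_base] = np.nan
    table[f"MR_{from_base}to{to_base}"] = rate
    return table


def add_diff(
    table_a: pd.DataFrame, table_b: pd.DataFrame, column: str, out_name: str
) -> pd.DataFrame:
    """Append ``out_name`` = a.column - b.column to table_a (tables unified).

    NaN propagates. Raises if the tables are not row-aligned on gene/txcoor.
    """
    _require(table_a, [column])
    _require(table_b, [column])
    if len(table_a) != len(table_b) or not (
        (table_a["gene"].to_numpy(object) == table_b["gene"].to_numpy(object)).all()
        and (table_a["txcoor"].to_numpy() == table_b["txcoor"].to_numpy()).all()
    ):
        raise ValueError("tables are not aligned; unify them first")
    table_a[out_name] = table_a[column].to_numpy(float) - table_b[column].to_numpy(float)
    return table_a


def _gene_sequences(
    table: pd.DataFrame,
    models: Optional[list[TranscriptModel]],
    genome: Optional[dict[str, str]],
) -> dict[str, str]:
    genes = table["gene"].unique()
    if models is not None and genome is not None:
        by_id = {m.gene_id: m for m in models}
        return {g: transcript_sequence(by_id[g], genome) for g in genes}
    if "refSeq" in table.columns:
        seqs = {}
        for g, sub in table.groupby("gene", sort=False):
            s = "".join(sub["refSeq"].astype(str))
            if "." in s:
                raise ValueError(
                    f"gene {g}: refSeq column incomplete; provide models and genome"
                )
            seqs[g] = s
        return seqs
    raise ValueError("transcript sequences unavailable: need refSeq column or models+genome")


def add_motif_presence(
    table: pd.DataFrame,
    motif: str,
    models: Optional[list[TranscriptModel]] = None,
    genome: Optional[dict[str, str]] = None,
    center_offset: Optional[int] = None,
) -> pd.DataFrame:
    """Mark positions centered in an IUPAC motif (column ``motif_<MOTIF>``).

    Position p is True iff the transcript window [p-c+1, p-c+len] matches the
    motif, where c = ``center_offset`` (default ceil(len/2), i.e. the motif's
    central letter sits on p). Scanning never crosses gene boundaries.
    """
    motif = motif.upper().replace("U", "T")
    bad = [ch for ch in motif if ch not in IUPAC]
    if bad:
        raise ValueError(f"invalid IUPAC letter(s) {bad} in motif {motif!r}")
    c = center_offset if center_offset is not None else math.ceil(len(motif) / 2)
    pattern = re.compile("(?=(" + "".join(f"[{IUPAC[ch]}]" for ch in motif) + "))")
    seqs = _gene_sequences(table, models, genome)
    col = np.zeros(len(table), dtype=bool)
    offsets = {}
    pos = 0
    for g, sub in table.groupby("gene", sort=False):
        offsets[g] = pos
        pos += len(sub)
    for g, seq in seqs.items():
        base = offsets[g]
        n = (table["gene"] == g).sum()
        for m in pattern.finditer(seq):
            p = m.start() + c  # 1-based center position
            if 1 <= p <= n:
                col[base + p - 1] = True
    table[f"motif_{motif}"] = col
    return table


def add_gene_region(
    table: pd.DataFrame, models: list[TranscriptModel]
) -> pd.DataFrame:
    """Label each position 5'UTR / CDS / 3'UTR (NaN for noncoding genes)."""
    by_id = {m.gene_id: m for m in models}
    out = np.full(len(table), None, dtype=object)
    idx = 0
    for g, sub in table.groupby("gene", sort=False):
        model = by_id[g]
        n = len(sub)
        if model.cds is not None:
            regions = model.regions()
            labels = np.empty(n, dtype=object)
            for name, span in zip(("5'UTR", "CDS", "3'UTR"), regions):
                if span is not None:
                    labels[span[0] - 1 : span[1]] = name
            out[idx : idx + n] = labels
        idx += n
    table["region"] = out
    return table


_COMPARATORS = {
    ">": np.greater,
    ">=": np.greater_equal,
    "<": np.less,
    "<=": np.less_equal,
    "==": lambda a, b: a == b,
    "!=": lambda a, b: a != b,
}


def call_sites(
    table: pd.DataFrame,
    predicates: Sequence[tuple[str, str, object]],
    out_name: str = "putative_site",
) -> pd.DataFrame:
    """Flag rows satisfying every (column, comparator, threshold) predicate.

    Missing values fail predicates (a NaN metric is never a putative site).
    An empty predicate list flags every row.
    """
    mask = np.ones(len(table), dtype=bool)
    for column, comparator, threshold in predicates:
        _require(table, [column])
        if comparator not in _COMPARATORS:
            raise ValueError(f"unknown comparator {comparator!r}")
        series = table[column]
        with np.errstate(invalid="ignore"):
            res = _COMPARATORS[comparator](series.to_numpy(), threshold)
        mask &= np.asarray(res, dtype=bool) & series.notna().to_numpy()
    table[out_name] = mask
    return table
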