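"""Per-nucleotide summary tables (the txDT analog) and their TSV round-trip.

A table has one row per transcript nucleotide of each included gene and
carries both coordinate systems plus up to four read-outs:

- ``cov``      fragments whose (bridged) span covers the position
- ``start_5p`` fragments whose transcript 5' end is at the position
- ``end_3p``   fragments whose transcript 3' end is at the position
- ``A,C,G,T,N,del`` base-call / deletion counts on sequenced positions

Three modes mirror the original summarization family: ``cov`` (coverage,
starts, ends), ``nucFreq`` (base counts only), ``covNuc`` (both).
"""

from __future__ import annotations

import os
import re
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .annotation import TranscriptModel, keyed_models, transcript_sequence
from .conversion import TxFragment

__all__ = ["make_table", "write_table", "read_table", "concat_tables", "CORE_COLUMNS"]

COORD_COLUMNS = ["chrom", "gencoor", "strand", "gene", "txcoor"]
COV_COLUMNS = ["cov", "start_5p", "end_3p"]
NUC_COLUMNS = ["A", "C", "G", "T", "N", "del"]
CORE_COLUMNS = COORD_COLUMNS + ["refSeq"] + COV_COLUMNS + NUC_COLUMNS

MODES = ("cov", "nucFreq", "covNuc")

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4, "-": 5}

# metric columns appended by the metrics module; anything else on read is an error
_KNOWN_METRICS = re.compile(
    r"^(startRatio|startRatio_1bpDS|misincRate|endRatio|region"
    r"|MR_[ACGT]to[ACGT]|SRD_.*|MRD_.*|.*_diff|motif_.*|putative.*|p_value.*|stat_.*)$"
)
_BOOL_PREFIX = re.compile(r"^(motif_|putative)")


def make_table(
    fragments_by_gene: dict[str, list[TxFragment]],
    models: list[TranscriptModel],
    genome: Optional[dict[str, str]] = None,
    mode: str = "covNuc",
    include_empty: bool = False,
) -> pd.DataFrame:
    """Summarize transcript-space fragments into a per-nucleotide table.

    Genes appear in annotation order; rows of a gene are txcoor 1..tx_length.
    Genes with zero fragments are omitted unless ``include_empty``. With a
    genome, nucFreq/covNuc tables carry the reference base (transcript
    orientation) in ``refSeq``; without one the column holds ".".
    """
    if mode not in MODES:
        raise ValueError(f"invalid mode {mode!r}; choose from {MODES}")
    by_key = keyed_models(models)
    unknown = set(fragments_by_gene) - set(by_key)
    if unknown:
        raise KeyError(f"fragments reference unknown gene(s): {sorted(unknown)}")

    chunks: list[pd.DataFrame] = []
    for model in models:
        frags = fragments_by_gene.get(model.gene_id, [])
        if not frags and not include_empty:
            continue
        L = model.tx_length
        txcoor = np.arange(1, L + 1, dtype=np.int64)
        data: dict[str, object] = {
            "chrom": model.chrom,
            "gencoor": model.tx_to_genomic_array(txcoor),
            "strand": model.strand,
            "gene": model.gene_id,
            "txcoor": txcoor,
        }
        if mode in ("nucFreq", "covNuc"):
            if genome is not None:
                data["refSeq"] = list(transcript_sequence(model, genome))
            else:
                data["refSeq"] = "."
        if mode in ("cov", "covNuc"):
            diff = np.zeros(L + 1, dtype=np.int64)
            start = np.zeros(L, dtype=np.int64)
            end = np.zeros(L, dtype=np.int64)
            for f in frags:
                diff[f.tx_start - 1] += 1
                diff[f.tx_end] -= 1
                start[f.tx_start - 1] += 1
                end[f.tx_end - 1] += 1
            data["cov"] = np.cumsum(diff[:L])
            data["start_5p"] = start
            data["end_3p"] = end
        if mode in ("nucFreq", "covNuc"):
            counts = np.zeros((L, 6), dtype=np.int64)
            for f in frags:
                for p, b in f.calls.items():
                    counts[p - 1, _BASE_INDEX[b]] += 1
            for j, col in enumerate(NUC_COLUMNS):
                data[col] = counts[:, j]
        chunks.append(pd.DataFrame(data))
    if not chunks:
        cols = list(COORD_COLUMNS)
        if mode in ("nucFreq", "covNuc"):
            cols.append("refSeq")
        if mode in ("cov", "covNuc"):
            cols += COV_COLUMNS
        if mode in ("nucFreq", "covNuc"):
            cols += NUC_COLUMNS
        return _empty_table(cols)
    return pd.concat(chunks, ignore_index=True)


def _empty_table(cols: list[str]) -> pd.DataFrame:
    out = pd.DataFrame({c: [] for c in cols})
    for c in cols:
        out[c] = out[c].astype(_column_dtype(c))
    return out


def _column_dtype(name: str) -> str:
    if name in ("gencoor", "txcoor") or name in COV_COLUMNS or name in NUC_COLUMNS:
        return "int64"
    if name in ("chrom", "strand", "gene", "refSeq", "region"):
        return "object"
    if _BOOL_PREFIX.match(name):
        return "bool"
    return "float64"


def canonical_order(columns: Iterable[str]) -> list[str]:
    """Core columns in canonical order first, then extras in given order."""
    columns = list(columns)
    core = [c for c in CORE_COLUMNS if c in columns]
    extra = [c for c in columns if c not in CORE_COLUMNS]
    return core + extra


def write_table(table: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a per-nucleotide table as TSV (header, NA for missing, no quoting)."""
    table[canonical_order(table.columns)].to_csv(path, sep="\t", index=False, na_rep="NA")


def read_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read a TSV written by :func:`write_table`; inverse up to column order.

    Column order is normalized to canonical; unknown (non-core, non-metric)
    columns raise.
    """
    df = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)
    for col in df.columns:
        if col not in CORE_COLUMNS and not _KNOWN_METRICS.match(col):
            raise ValueError(f"unknown column {col!r} in {path}")
    df = df[canonical_order(df.columns)]
    if len(df) == 0:
        for c in df.columns:
            df[c] = df[c].astype(_column_dtype(c))
        return df
    for c in df.columns:
        want = _column_dtype(c)
        if want == "bool" and df[c].dtype == object:
            df[c] = df[c].map({"True": True, "False": False})
        elif want == "int64" and df[c].dtype != np.int64:
            df[c] = df[c].astype("int64")
        elif c in ("chrom", "strand", "gene", "refSeq") and df[c].dtype != object:
            df[c] = df[c].astype(str)
    return df


def concat_tables(tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Row-wise concatenation of tables with disjoint gene sets."""
    seen: set[str] = set()
    keep = []
    for t in tables:
        genes = set(t["gene"].unique())
        dup = genes & seen
        if dup:
            raise ValueError(f"gene(s) present in more than one table: {sorted(dup)}")
        seen |= genes
        if len(t):
            keep.append(t)
    if not keep:
        return tables[0].copy() if tables else _empty_table(CORE_COLUMNS)
    return pd.concat(keep, ignore_index=True)
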