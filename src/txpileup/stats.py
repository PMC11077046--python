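"""Multi-sample table alignment, metagene machinery, row-wise tests, peaks.

Row-wise tests operate across replicate per-nucleotide tables that have been
unified (same genes, same row order). The t-test targets continuous metrics
(e.g. startRatio_1bpDS between wild-type and knockout miCLIP libraries); the
binomial likelihood-ratio test targets count ratios (successes over trials,
e.g. read-starts over coverage) with counts pooled within each group.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .annotation import TranscriptModel
from .metrics import _gene_sequences

__all__ = [
    "unify_tables",
    "get_flanks_from_logical",
    "get_metagene_regions",
    "pfm_from_sites",
    "row_ttests",
    "row_binomial_lrt",
    "call_peaks",
    "sample_genes",
]


def _gene_lengths(table: pd.DataFrame) -> dict[str, int]:
    return {g: len(sub) for g, sub in table.groupby("gene", sort=False)}


def unify_tables(tables: list[pd.DataFrame]) -> list[pd.DataFrame]:
    """Restrict every table to the gene intersection, in identical row order.

    Gene order follows the first table. A gene whose row count differs across
    tables indicates an annotation mismatch and raises.
    """
    lens = [_gene_lengths(t) for t in tables]
    common = set(lens[0])
    for ln in lens[1:]:
        common &= set(ln)
    for g in common:
        sizes = {ln[g] for ln in lens}
        if len(sizes) != 1:
            raise ValueError(f"gene {g!r} has differing lengths across tables: {sizes}")
    if not common:
        warnings.warn("unify_tables: empty gene intersection", stacklevel=2)
    order = [g for g in lens[0] if g in common]
    out = []
    for t in tables:
        sub = pd.concat(
            [t[t["gene"] == g] for g in order], ignore_index=True
        ) if order else t.iloc[0:0].reset_index(drop=True)
        out.append(sub)
    return out


def get_flanks_from_logical(
    table: pd.DataFrame, logical_column: str, value_column: str, w: int
) -> pd.DataFrame:
    """Windows of ``value_column`` around every True of ``logical_column``.

    Returns one row per site (index: gene, txcoor of the center), columns
    -w..+w. Windows never cross gene boundaries; out-of-range offsets are NaN.
    """
    rows = []
    index = []
    for g, sub in table.groupby("gene", sort=False):
        vals = sub[value_column].to_numpy(float)
        flags = sub[logical_column].to_numpy(bool)
        n = len(sub)
        for i0 in np.flatnonzero(flags):
            row = np.full(2 * w + 1, np.nan)
            lo, hi = max(0, i0 - w), min(n, i0 + w + 1)
            row[lo - i0 + w : hi - i0 + w] = vals[lo:hi]
            rows.append(row)
            index.append((g, int(sub["txcoor"].iloc[i0])))
    mat = np.vstack(rows) if rows else np.empty((0, 2 * w + 1))
    return pd.DataFrame(
        mat,
        columns=list(range(-w, w + 1)),
        index=pd.MultiIndex.from_tuples(index, names=["gene", "txcoor"])
        if index
        else pd.MultiIndex.from_arrays([[], []], names=["gene", "txcoor"]),
    )


def get_metagene_regions(
    table: pd.DataFrame,
    value_column: str,
    bins: tuple[int, int, int] = (10, 30, 10),
    aggregate: str = "mean",
    models: Optional[list[TranscriptModel]] = None,
) -> pd.DataFrame:
    """Genes x bins matrix over 5'UTR / CDS / 3'UTR, each region binned per gene.

    Needs a ``region`` column (from :func:`~txpileup.metrics.add_gene_region`)
    or ``models``. Each region of each gene is split into its bin count by
    equal-width position intervals; a cell is the mean (or sum) of
    ``value_column`` over the bin's positions, NaN when the bin is empty
    (region shorter than the bin count). Genes without CDS are skipped.
    """
    if aggregate not in ("mean", "sum"):
        raise ValueError("aggregate must be 'mean' or 'sum'")
    if "region" not in table.columns:
        if models is None:
            raise ValueError("need a region column or models")
        from .metrics import add_gene_region

        table = add_gene_region(table.copy(), models)
    b5, bc, b3 = bins
    region_names = ("5'UTR", "CDS", "3'UTR")
    columns = (
        [f"utr5_{i+1}" for i in range(b5)]
        + [f"cds_{i+1}" for i in range(bc)]
        + [f"utr3_{i+1}" for i in range(b3)]
    )
    agg = np.nanmean if aggregate == "mean" else np.nansum
    rows, genes = [], []
    for g, sub in table.groupby("gene", sort=False):
        reg = sub["region"].to_numpy(object)
        if not (reg == "CDS").any():
            continue
        vals = sub[value_column].to_numpy(float)
        cells: list[float] = []
        for name, b in zip(region_names, (b5, bc, b3)):
            idx = np.flatnonzero(reg == name)
            for chunk in np.array_split(idx, b):
                cells.append(float(agg(vals[chunk])) if len(chunk) else np.nan)
        rows.append(cells)
        genes.append(g)
    mat = np.vstack(rows) if rows else np.empty((0, b5 + bc + b3))
    return pd.DataFrame(mat, columns=columns, index=pd.Index(genes, name="gene"))


def pfm_from_sites(
    table: pd.DataFrame,
    sites: Sequence[tuple[str, int]],
    w: int,
    models: Optional[list[TranscriptModel]] = None,
    genome: Optional[dict[str, str]] = None,
) -> pd.DataFrame:
    """Position frequency matrix (rows A,C,G,T; columns -w..+w) over sites.

    ``sites`` are (gene, txcoor) pairs; sequences come from the table's
    refSeq column or from models+genome. Offsets falling outside a transcript
    contribute nothing, so each column sums to the number of sites for which
    that offset is in range.
    """
    seqs = _gene_sequences(table, models, genome)
    counts = np.zeros((4, 2 * w + 1), dtype=np.int64)
    base_row = {"A": 0, "C": 1, "G": 2, "T": 3}
    for gene, center in sites:
        seq = seqs[gene]
        for off in range(-w, w + 1):
            p = center + off
            if 1 <= p <= len(seq):
                b = seq[p - 1]
                if b in base_row:
                    counts[base_row[b], off + w] += 1
    return pd.DataFrame(counts, index=list("ACGT"), columns=list(range(-w, w + 1)))


def _stack(tables: list[pd.DataFrame], column: str) -> np.ndarray:
    return np.vstack([t[column].to_numpy(float) for t in tables])


def _check_alignment(tables: list[pd.DataFrame]) -> pd.DataFrame:
    first = tables[0]
    for t in tables[1:]:
        if len(t) != len(first) or not (
            (t["gene"].to_numpy(object) == first["gene"].to_numpy(object)).all()
            and (t["txcoor"].to_numpy() == first["txcoor"].to_numpy()).all()
        ):
            raise ValueError("replicate tables are not unified")
    return first


def row_ttests(
    tables_group1: list[pd.DataFrame],
    tables_group2: list[pd.DataFrame],
    value_column: str,
    variance: str = "pooled",
) -> pd.DataFrame:
    """Row-wise two-sample t-tests on ``value_column`` across replicates.

    Returns gene, txcoor, per-group n, mean difference (group1 - group2),
    t statistic, degrees of freedom and the two-sided p-value. Rows where any
    replicate is missing get NaN results. Zero pooled variance yields t = 0,
    p = 1 when the means agree and t = ±inf, p = 0 when they differ.
    """
    if variance not in ("pooled", "welch"):
        raise ValueError("variance must be 'pooled' or 'welch'")
    if len(tables_group1) < 2 or len(tables_group2) < 2:
        raise ValueError("each group needs at least 2 replicate tables")
    first = _check_alignment(tables_group1 + tables_group2)
    x1 = _stack(tables_group1, value_column)
    x2 = _stack(tables_group2, value_column)
    n1, n2 = x1.shape[0], x2.shape[0]
    ok = ~(np.isnan(x1).any(axis=0) | np.isnan(x2).any(axis=0))
    m1, m2 = x1.mean(axis=0), x2.mean(axis=0)
    v1, v2 = x1.var(axis=0, ddof=1), x2.var(axis=0, ddof=1)
    diff = m1 - m2
    with np.errstate(divide="ignore", invalid="ignore"):
        if variance == "pooled":
            sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
            se = np.sqrt(sp2 * (1 / n1 + 1 / n2))
            df = np.full(len(diff), float(n1 + n2 - 2))
        else:
            se = np.sqrt(v1 / n1 + v2 / n2)
            df = (v1 / n1 + v2 / n2) ** 2 / (
                (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
            )
        t = diff / se
    zero_se = se == 0
    t[zero_se & (diff == 0)] = 0.0
    t[zero_se & (diff > 0)] = np.inf
    t[zero_se & (diff < 0)] = -np.inf
    df[zero_se] = float(n1 + n2 - 2)
    with np.errstate(invalid="ignore"):
        p = 2 * sps.t.sf(np.abs(t), df)
    p[zero_se & (diff == 0)] = 1.0
    p[zero_se & (diff != 0)] = 0.0
    for arr in (diff, t, df, p):
        arr[~ok] = np.nan
    return pd.DataFrame(
        {
            "gene": first["gene"].to_numpy(object),
            "txcoor": first["txcoor"].to_numpy(),
            "n1": n1,
            "n2": n2,
            "mean_diff": diff,
            "statistic": t,
            "df": df,
            "p_value": p,
        }
    )


def _binom_ll(k: np.ndarray, n: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Binomial log-likelihood kernel with the 0*log(0) == 0 convention."""
    ll = np.zeros(len(k))
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = k * np.log(p)
        t2 = (n - k) * np.log1p(-p)
    ll += np.where(k > 0, t1, 0.0)
    ll += np.where(n - k > 0, t2, 0.0)
    return ll


def row_binomial_lrt(
    tables_group1: list[pd.DataFrame],
    tables_group2: list[pd.DataFrame],
    successes_column: str,
    trials_column: str,
) -> pd.DataFrame:
    """Row-wise binomial likelihood-ratio tests on pooled group counts.

    Successes and trials are summed across replicates within each group;
    the statistic is 2*(ll at per-group proportions - ll at the pooled
    proportion), compared to chi-square with 1 df. Rows with zero trials in
    either group are NaN.
    """
    first = _check_alignment(tables_group1 + tables_group2)
    k1 = _stack(tables_group1, successes_column).sum(axis=0)
    n1 = _stack(tables_group1, trials_column).sum(axis=0)
    k2 = _stack(tables_group2, successes_column).sum(axis=0)
    n2 = _stack(tables_group2, trials_column).sum(axis=0)
    if ((k1 > n1) | (k2 > n2)).any():
        raise ValueError("successes exceed trials at some rows")
    ok = (n1 > 0) & (n2 > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p1 = np.where(n1 > 0, k1 / np.where(n1 > 0, n1, 1), 0.0)
        p2 = np.where(n2 > 0, k2 / np.where(n2 > 0, n2, 1), 0.0)
        p0 = (k1 + k2) / np.where(n1 + n2 > 0, n1 + n2, 1)
    stat = 2 * (
        _binom_ll(k1, n1, p1)
        + _binom_ll(k2, n2, p2)
        - _binom_ll(k1, n1, p0)
        - _binom_ll(k2, n2, p0)
    )
    stat = np.maximum(stat, 0.0)  # clip tiny negative rounding
    p = sps.chi2.sf(stat, df=1)
    diff = p1 - p2
    for arr in (stat, p, diff):
        arr[~ok] = np.nan
    return pd.DataFrame(
        {
            "gene": first["gene"].to_numpy(object),
            "txcoor": first["txcoor"].to_numpy(),
            "k1": k1,
            "n1": n1,
            "k2": k2,
            "n2": n2,
            "prop_diff": diff,
            "statistic": stat,
            "p_value": p,
        }
    )


def adjust_bh(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (NaN-aware)."""
    p = np.asarray(p, dtype=float)
    out = np.full(len(p), np.nan)
    ok = ~np.isnan(p)
    ps = p[ok]
    m = len(ps)
    order = np.argsort(ps)
    ranked = ps[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(ranked, 1.0)
    out[ok] = adj
    return out


def _smooth(x: np.ndarray, w: int) -> np.ndarray:
    """Centered moving average of full width w, truncated at the edges."""
    if w <= 1:
        return x.astype(float)
    kernel = np.ones(w)
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones(len(x)), kernel, mode="same")
    return num / den


def call_peaks(
    table: pd.DataFrame,
    cov_column: str = "cov",
    smooth_w: int = 1,
    min_cov: float = 1.0,
    min_gap: int = 1,
) -> pd.DataFrame:
    """Simple per-gene coverage peak caller.

    Coverage is smoothed with a centered moving average of width ``smooth_w``
    (edge-truncated); candidates are strict local maxima of the smoothed
    profile with value >= ``min_cov`` (an equal-valued plateau flanked by
    strictly lower values counts once, at its center; an entirely flat
    profile has none); candidates closer than ``min_gap`` are merged keeping
    the highest (leftmost on ties). Returns columns gene, txcoor (peak
    center), height (smoothed value at the center).
    """
    out_gene, out_pos, out_height = [], [], []
    for g, sub in table.groupby("gene", sort=False):
        x = sub[cov_column].to_numpy(float)
        s = _smooth(x, smooth_w)
        n = len(s)
        if n == 0:
            continue
        if n == 1:
            cand = [0] if s[0] >= min_cov else []
        else:
            # runs of equal smoothed value; a run is a (plateau) local maximum
            # when every existing flank is strictly lower — an entirely flat
            # profile has no flanks and yields no peak
            cand = []
            i = 0
            while i < n:
                j = i
                while j + 1 < n and s[j + 1] == s[i]:
                    j += 1
                flanks = []
                if i > 0:
                    flanks.append(s[i - 1])
                if j < n - 1:
                    flanks.append(s[j + 1])
                if flanks and all(f < s[i] for f in flanks) and s[i] >= min_cov:
                    cand.append((i + j) // 2)
                i = j + 1
        # non-maximum suppression within min_gap (highest wins, leftmost on ties)
        cand.sort(key=lambda i: (-s[i], i))
        kept: list[int] = []
        for i in cand:
            if all(abs(i - j) >= min_gap for j in kept):
                kept.append(i)
        for i in sorted(kept):
            out_gene.append(g)
            out_pos.append(int(sub["txcoor"].iloc[i]))
            out_height.append(float(s[i]))
    return pd.DataFrame({"gene": out_gene, "txcoor": out_pos, "height": out_height})


def sample_genes(table: pd.DataFrame, n: int, seed: int) -> pd.DataFrame:
    """Rows of ``n`` genes drawn without replacement (deterministic per seed)."""
    genes = list(dict.fromkeys(table["gene"]))
    if n > len(genes):
        raise ValueError(f"requested {n} genes but table has {len(genes)}")
    rng = np.random.default_rng(seed)
    chosen = set(rng.choice(np.array(genes, dtype=object), size=n, replace=False))
    return table[table["gene"].isin(chosen)].reset_index(drop=True)
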