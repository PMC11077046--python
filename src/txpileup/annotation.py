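"""Transcript models, BED12/BED6 and FASTA loading, and coordinate conversion.

A :class:`TranscriptModel` is one gene (or isoform) record: an ordered set of
exon blocks on one strand of one chromosome, optionally with a CDS span. It is
the unit of genomic<->transcriptomic coordinate conversion used throughout the
package.

Coordinate conventions
----------------------
BED input is 0-based half-open (the standard). Everything exposed by the API
— transcript coordinates, genomic coordinates in tables, conversion functions —
is 1-based inclusive, matching SAM. Transcript coordinate 1 is the transcript
5' end, so for minus-strand genes it maps to the *highest* exonic genomic
coordinate.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Optional

import numpy as np
import pysam

__all__ = [
    "TranscriptModel",
    "Regions",
    "load_bed",
    "load_genome",
    "transcript_sequence",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (case preserved, N self-complementary)."""
    return seq.translate(_COMPLEMENT)[::-1]


class Regions(NamedTuple):
    """Transcript-coordinate spans (1-based inclusive) of the three gene regions.

    Each entry is ``(start, end)`` or ``None`` when the region is empty.
    """

    utr5: Optional[tuple[int, int]]
    cds: Optional[tuple[int, int]]
    utr3: Optional[tuple[int, int]]


@dataclass(eq=False)
class TranscriptModel:
    """One gene/isoform: strand, ordered exon blocks and an optional CDS.

    Parameters
    ----------
    gene_id
        Name from the BED ``name`` column (made unique by the loader when
        duplicated).
    chrom
        Chromosome name.
    strand
        ``"+"`` or ``"-"``.
    exons
        Genomic intervals, 0-based half-open, ascending and pairwise disjoint.
    cds
        Optional genomic ``(thickStart, thickEnd)`` interval, 0-based
        half-open, contained in the exon union. ``None`` for noncoding models.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds: Optional[tuple[int, int]] = None

    # derived arrays for fast conversion
    _starts: np.ndarray = field(init=False, repr=False)
    _ends: np.ndarray = field(init=False, repr=False)
    _cum: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-', got {self.strand!r}")
        if not self.exons:
            raise ValueError(f"{self.gene_id}: no exons")
        exons = tuple((int(s), int(e)) for s, e in self.exons)
        prev_end = -1
        for s, e in exons:
            if s < 0 or e <= s:
                raise ValueError(f"{self.gene_id}: invalid exon ({s}, {e})")
            if s < prev_end:
                raise ValueError(f"{self.gene_id}: exons unsorted or overlapping at ({s}, {e})")
            prev_end = e
        self.exons = exons
        self._starts = np.fromiter((s for s, _ in exons), dtype=np.int64, count=len(exons))
        self._ends = np.fromiter((e for _, e in exons), dtype=np.int64, count=len(exons))
        widths = self._ends - self._starts
        self._cum = np.concatenate(([0], np.cumsum(widths)))
        if self.cds is not None:
            cs, ce = int(self.cds[0]), int(self.cds[1])
            if ce <= cs:
                raise ValueError(f"{self.gene_id}: empty/inverted CDS ({cs}, {ce})")
            if not (self._is_exonic0(cs) and self._is_exonic0(ce - 1)):
                raise ValueError(f"{self.gene_id}: CDS ({cs}, {ce}) not contained in exons")
            self.cds = (cs, ce)

    # -- basic properties ------------------------------------------------

    @property
    def tx_length(self) -> int:
        """Transcript length: sum of exon widths."""
        return int(self._cum[-1])

    @property
    def genomic_span(self) -> tuple[int, int]:
        """0-based half-open genomic interval covered by the exon union."""
        return int(self._starts[0]), int(self._ends[-1])

    def _is_exonic0(self, g0: int) -> bool:
        i = int(np.searchsorted(self._starts, g0, side="right")) - 1
        return i >= 0 and g0 < self._ends[i]

    def is_intron(self, g0_start: int, g0_end: int) -> bool:
        """True iff [g0_start, g0_end) (0-based) is exactly an intron between adjacent exons."""
        i = int(np.searchsorted(self._ends, g0_start))
        return (
            i < len(self.exons) - 1
            and self._ends[i] == g0_start
            and self._starts[i + 1] == g0_end
        )

    # -- coordinate conversion -------------------------------------------

    def genomic_to_tx(self, gpos: int) -> Optional[int]:
        """Map a 1-based genomic coordinate to a 1-based transcript coordinate.

        Returns ``None`` for intronic or out-of-gene positions.
        """
        g0 = gpos - 1
        i = int(np.searchsorted(self._starts, g0, side="right")) - 1
        if i < 0 or g0 >= self._ends[i]:
            return None
        plus = int(self._cum[i]) + (g0 - int(self._starts[i])) + 1
        return plus if self.strand == "+" else self.tx_length - plus + 1

    def genomic_to_tx_array(self, gpos: np.ndarray) -> np.ndarray:
        """Vectorized :meth:`genomic_to_tx`; non-exonic positions map to 0."""
        g0 = np.asarray(gpos, dtype=np.int64) - 1
        i = np.searchsorted(self._starts, g0, side="right") - 1
        ok = (i >= 0) & (g0 < self._ends[np.clip(i, 0, None)])
        i = np.clip(i, 0, None)
        plus = self._cum[i] + (g0 - self._starts[i]) + 1
        if self.strand == "-":
            plus = self.tx_length - plus + 1
        return np.where(ok, plus, 0)

    def tx_to_genomic(self, tpos: int) -> int:
        """Map a 1-based transcript coordinate to its 1-based genomic coordinate."""
        if not 1 <= tpos <= self.tx_length:
            raise ValueError(
                f"{self.gene_id}: transcript position {tpos} outside [1, {self.tx_length}]"
            )
        plus = tpos if self.strand == "+" else self.tx_length - tpos + 1
        i = int(np.searchsorted(self._cum, plus - 1, side="right")) - 1
        return int(self._starts[i]) + (plus - 1 - int(self._cum[i])) + 1

    def tx_to_genomic_array(self, tpos: np.ndarray) -> np.ndarray:
        """Vectorized :meth:`tx_to_genomic` (all inputs must be in range)."""
        tpos = np.asarray(tpos, dtype=np.int64)
        if tpos.size and (tpos.min() < 1 or tpos.max() > self.tx_length):
            raise ValueError(f"{self.gene_id}: transcript positions out of range")
        plus = tpos if self.strand == "+" else self.tx_length - tpos + 1
        i = np.searchsorted(self._cum, plus - 1, side="right") - 1
        return self._starts[i] + (plus - 1 - self._cum[i]) + 1

    def regions(self) -> Regions:
        """5'UTR / CDS / 3'UTR transcript-coordinate intervals.

        Raises
        ------
        ValueError
            If the model has no CDS (noncoding).
        """
        if self.cds is None:
            raise ValueError(f"{self.gene_id}: noncoding model has no CDS regions")
        cs, ce = self.cds
        a = self.genomic_to_tx(cs + 1)  # first CDS base, 1-based genomic cs+1
        b = self.genomic_to_tx(ce)  # last CDS base
        assert a is not None and b is not None
        lo, hi = (a, b) if a <= b else (b, a)
        utr5 = (1, lo - 1) if lo > 1 else None
        utr3 = (hi + 1, self.tx_length) if hi < self.tx_length else None
        return Regions(utr5, (lo, hi), utr3)


def tx_regions(model: TranscriptModel) -> Regions:
    """Functional alias for :meth:`TranscriptModel.regions`."""
    return model.regions()


# ---------------------------------------------------------------------------
# BED parsing


def _parse_bed_line(fields: list[str], lineno: int) -> TranscriptModel:
    chrom = fields[0]
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError as exc:
        raise ValueError(f"BED line {lineno}: non-integer chromStart/chromEnd") from exc
    if start > end:
        raise ValueError(f"BED line {lineno}: chromStart {start} > chromEnd {end}")
    name = fields[3]
    strand = fields[5]
    if strand not in ("+", "-"):
        raise ValueError(f"BED line {lineno}: strand must be '+' or '-', got {strand!r}")
    if len(fields) == 6:
        return TranscriptModel(name, chrom, strand, ((start, end),), None)
    thick_start, thick_end = int(fields[6]), int(fields[7])
    block_count = int(fields[9])
    sizes = [int(x) for x in fields[10].rstrip(",").split(",") if x != ""]
    offsets = [int(x) for x in fields[11].rstrip(",").split(",") if x != ""]
    if len(sizes) != block_count or len(offsets) != block_count:
        raise ValueError(
            f"BED line {lineno}: blockCount {block_count} disagrees with "
            f"blockSizes/blockStarts lengths ({len(sizes)}/{len(offsets)})"
        )
    exons = tuple((start + off, start + off + size) for off, size in zip(offsets, sizes))
    cds = None if thick_start == thick_end else (thick_start, thick_end)
    try:
        return TranscriptModel(name, chrom, strand, exons, cds)
    except ValueError as exc:
        raise ValueError(f"BED line {lineno}: {exc}") from exc


def load_bed(path: str | os.PathLike) -> list[TranscriptModel]:
    """Load a BED12 (or BED6) annotation into transcript models, in file order.

    BED6 records are promoted to single-exon models without CDS;
    ``thickStart == thickEnd`` means no CDS. Duplicate names get a ``#k``
    suffix (second occurrence onward) so every model has a unique ``gene_id``.
    """
    models: list[TranscriptModel] = []
    seen: dict[str, int] = {}
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) not in (6, 12):
                raise ValueError(
                    f"BED line {lineno}: expected 6 or 12 tab-separated fields, got {len(fields)}"
                )
            model = _parse_bed_line(fields, lineno)
            n = seen.get(model.gene_id, 0) + 1
            seen[model.gene_id] = n
            if n > 1:
                model.gene_id = f"{model.gene_id}#{n}"
            models.append(model)
    return models


# ---------------------------------------------------------------------------
# FASTA


def load_genome(path: str | os.PathLike) -> dict[str, str]:
    """Load a FASTA genome into ``{chrom: sequence}``.

    Sequences are uppercased and U is converted to T. Duplicate record ids and
    empty files are errors.
    """
    genome: dict[str, str] = {}
    with pysam.FastxFile(str(path)) as fx:
        for rec in fx:
            if rec.name in genome:
                raise ValueError(f"duplicate FASTA record id {rec.name!r}")
            genome[rec.name] = rec.sequence.upper().replace("U", "T")
    if not genome:
        raise ValueError(f"no FASTA records found in {path}")
    return genome


def transcript_sequence(model: TranscriptModel, genome: dict[str, str]) -> str:
    """Transcript sequence, 5'->3' in transcript orientation.

    Exon sequences are concatenated in genomic order; minus-strand models
    return the reverse complement of that concatenation.
    """
    if model.chrom not in genome:
        raise KeyError(f"{model.gene_id}: chromosome {model.chrom!r} not in genome")
    chrom_seq = genome[model.chrom]
    if model.genomic_span[1] > len(chrom_seq):
        raise ValueError(
            f"{model.gene_id}: exon end {model.genomic_span[1]} exceeds "
            f"{model.chrom} length {len(chrom_seq)}"
        )
    plus = "".join(chrom_seq[s:e] for s, e in model.exons)
    return plus if model.strand == "+" else reverse_complement(plus)


def keyed_models(models: Iterable[TranscriptModel]) -> dict[str, TranscriptModel]:
    """Index models by gene_id, insisting on uniqueness."""
    out: dict[str, TranscriptModel] = {}
    for m in models:
        if m.gene_id in out:
            raise ValueError(f"duplicate gene_id {m.gene_id!r} among models")
        out[m.gene_id] = m
    return out
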