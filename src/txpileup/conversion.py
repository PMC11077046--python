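"""Genomic alignments -> transcript-space fragments, with paired-end bridging.

The conversion step filters alignments for strand and gene-structure
compatibility (every aligned block inside the exon union, every N gap exactly
an annotated intron), merges read1/read2 of a pair into one *bridged* fragment
spanning from the start of read1 to the end of read2, and re-expresses the
result in 1-based transcript coordinates.

The inter-mate gap of a bridged fragment carries no base calls, but the
fragment span covers it — that is the central paired-end semantics: a mate
pair informs about the whole insert, including its unsequenced middle.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pysam

from .annotation import TranscriptModel

__all__ = [
    "AlignedSegmentView",
    "ConversionOptions",
    "TxFragment",
    "DiscardReport",
    "load_alignments",
    "segment_to_tx",
    "fragment_from_pair",
    "fragment_from_segment",
    "assign_to_transcripts",
]

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N", "-": "-"}
_CIGAR_OPS = "MIDNSHP=X"


@dataclass
class AlignedSegmentView:
    """Minimal view of one aligned SAM/BAM record.

    ``cigar`` uses op letters from {M, I, D, N, S, H} ('=' and 'X' are
    normalized to M). ``pos`` is the 1-based leftmost aligned genomic
    coordinate; ``seq`` includes soft-clipped bases (as in SAM) or is ``None``.
    """

    query_name: str
    chrom: str
    strand: str  # alignment strand of this record
    pos: int
    cigar: list[tuple[str, int]]
    seq: Optional[str]
    is_read1: bool = False
    is_read2: bool = False
    is_paired: bool = False
    mapq: int = 60

    @classmethod
    def from_pysam(cls, aln: "pysam.AlignedSegment") -> "AlignedSegmentView":
        cigar = []
        for code, length in aln.cigartuples or []:
            op = _CIGAR_OPS[code]
            if op in "=X":
                op = "M"
            if op != "H":  # hard clips consume nothing we track
                cigar.append((op, length))
        return cls(
            query_name=aln.query_name,
            chrom=aln.reference_name,
            strand="-" if aln.is_reverse else "+",
            pos=aln.reference_start + 1,
            cigar=cigar,
            seq=aln.query_sequence,
            is_read1=aln.is_read1,
            is_read2=aln.is_read2,
            is_paired=aln.is_paired,
            mapq=aln.mapping_quality,
        )

    @property
    def fragment_strand(self) -> str:
        """Implied fragment strand under an FR library layout.

        read1 (or an unpaired read) aligns on the fragment strand; read2 on
        the opposite one.
        """
        if self.is_read2:
            return "-" if self.strand == "+" else "+"
        return self.strand

    def genomic_end(self) -> int:
        """1-based inclusive rightmost aligned genomic coordinate."""
        g = self.pos - 1
        for op, ln in self.cigar:
            if op in "MDN":
                g += ln
        return g


@dataclass
class ConversionOptions:
    """Knobs of the conversion step.

    strand_mode
        Required relation of the fragment strand to the model strand:
        ``"same"`` (default, FR layout on the annotated strand),
        ``"opposite"``, or ``"ignore"``.
    max_fragment
        Bridged spans longer than this (nt) are discarded — guards against
        chimeric pairs.
    min_mapq
        Records below this mapping quality are dropped at load time.
    paired
        When True, mate pairs are bridged; pairs with exactly one usable mate
        are discarded. When False every record is its own fragment
        (single-end processing, also used for long reads).
    """

    strand_mode: str = "same"
    max_fragment: int = 1000
    min_mapq: int = 0
    paired: bool = True

    def __post_init__(self) -> None:
        if self.strand_mode not in ("same", "opposite", "ignore"):
            raise ValueError(f"invalid strand_mode {self.strand_mode!r}")


@dataclass
class TxFragment:
    """One sequencing fragment in transcript coordinates.

    ``calls`` maps transcript position -> base call in {A,C,G,T,N,-}; only
    sequenced (or deleted) positions are present, so an inter-mate gap has no
    entries even though it lies within [tx_start, tx_end].
    """

    gene_id: str
    tx_start: int
    tx_end: int
    calls: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 1 <= self.tx_start <= self.tx_end:
            raise ValueError(f"invalid fragment span [{self.tx_start}, {self.tx_end}]")

    def validate(self, model: TranscriptModel) -> None:
        if self.tx_end > model.tx_length:
            raise ValueError(f"fragment end {self.tx_end} beyond {model.gene_id}")
        for p in self.calls:
            if not self.tx_start <= p <= self.tx_end:
                raise ValueError(f"call at {p} outside span [{self.tx_start}, {self.tx_end}]")


@dataclass
class DiscardReport:
    """Counts of mate groups by outcome of transcript assignment."""

    assigned: int = 0
    strand: int = 0
    structure: int = 0
    span_length: int = 0
    off_annotation: int = 0
    half_pair: int = 0

    @property
    def total_discarded(self) -> int:
        return self.strand + self.structure + self.span_length + self.off_annotation + self.half_pair

    def as_dict(self) -> dict[str, int]:
        return {
            "assigned": self.assigned,
            "strand": self.strand,
            "structure": self.structure,
            "span_length": self.span_length,
            "off_annotation": self.off_annotation,
            "half_pair": self.half_pair,
        }


def load_alignments(
    path: str | os.PathLike,
    region: Optional[str] = None,
    min_mapq: int = 0,
) -> dict[str, list[AlignedSegmentView]]:
    """Load SAM/BAM records grouped by query name.

    Unmapped, secondary and supplementary records are excluded; groups keep
    mate pairing (read1 before read2). ``region`` restricts to one chromosome
    by name (sequential scan, no index needed).
    """
    groups: dict[str, list[AlignedSegmentView]] = {}
    with pysam.AlignmentFile(str(path), check_sq=False) as bam:
        for aln in bam:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            if region is not None and aln.reference_name != region:
                continue
            if aln.mapping_quality < min_mapq:
                continue
            groups.setdefault(aln.query_name, []).append(AlignedSegmentView.from_pysam(aln))
    for segs in groups.values():
        segs.sort(key=lambda s: (s.is_read2, s.pos))
    return groups


def segment_to_tx(
    seg: AlignedSegmentView, model: TranscriptModel
) -> Optional[tuple[int, int, dict[int, str]]]:
    """Express one aligned record in transcript coordinates of ``model``.

    Returns ``(tx_start, tx_end, calls)`` or ``None`` when the alignment is
    incompatible with the gene structure: any M/D block outside the exon
    union, or any N gap that is not exactly an annotated intron. M positions
    carry the read base (complemented for minus-strand models), D positions
    carry "-"; S and I consume read bases but produce no transcript position.
    """
    g = seg.pos - 1  # 0-based genomic cursor
    r = 0  # read cursor
    blocks: list[tuple[int, int, Optional[int]]] = []  # (g0_start, length, read_offset or None)
    for op, ln in seg.cigar:
        if op == "S" or op == "I":
            r += ln
        elif op == "M":
            blocks.append((g, ln, r))
            g += ln
            r += ln
        elif op == "D":
            blocks.append((g, ln, None))
            g += ln
        elif op == "N":
            if not model.is_intron(g, g + ln):
                return None
            g += ln
        else:  # pragma: no cover - H filtered out, P unused
            continue
    if not blocks:
        return None

    minus = model.strand == "-"
    calls: dict[int, str] = {}
    n_pos = 0
    tx_min, tx_max = None, None
    for g0, ln, roff in blocks:
        txs = model.genomic_to_tx_array(np.arange(g0 + 1, g0 + ln + 1))
        if (txs == 0).any():
            return None  # block leaves the exon union
        lo, hi = int(txs.min()), int(txs.max())
        tx_min = lo if tx_min is None else min(tx_min, lo)
        tx_max = hi if tx_max is None else max(tx_max, hi)
        n_pos += ln
        if roff is None:
            for t in txs:
                calls[int(t)] = "-"
        else:
            sub = seg.seq[roff : roff + ln].upper() if seg.seq else "N" * ln
            for t, b in zip(txs, sub):
                b = b if b in "ACGT" else "N"
                calls[int(t)] = _COMP[b] if minus else b
    # exact junction concordance + exonic blocks imply a contiguous tx interval
    if tx_max - tx_min + 1 != n_pos:
        return None
    return tx_min, tx_max, calls


def _strand_ok(frag_strand: str, model: TranscriptModel, opts: ConversionOptions) -> bool:
    if opts.strand_mode == "ignore":
        return True
    same = frag_strand == model.strand
    return same if opts.strand_mode == "same" else not same


def fragment_from_pair(
    seg1: AlignedSegmentView,
    seg2: AlignedSegmentView,
    model: TranscriptModel,
    opts: ConversionOptions = ConversionOptions(),
) -> Optional[TxFragment]:
    """Bridge a mate pair into one transcript-space fragment.

    Returns ``None`` on strand mismatch, structural incompatibility of either
    mate, mates on different chromosomes, or a merged span longer than
    ``opts.max_fragment``. Where the mates overlap, agreeing calls are kept
    once; disagreements become N.
    """
    if seg1.chrom != seg2.chrom or seg1.chrom != model.chrom:
        return None
    read1 = seg1 if seg1.is_read1 or not seg2.is_read1 else seg2
    if not _strand_ok(read1.fragment_strand, model, opts):
        return None
    a = segment_to_tx(seg1, model)
    b = segment_to_tx(seg2, model)
    if a is None or b is None:
        return None
    s1, e1, c1 = a
    s2, e2, c2 = b
    tx_start, tx_end = min(s1, s2), max(e1, e2)
    if tx_end - tx_start + 1 > opts.max_fragment:
        return None
    calls = dict(c1)
    for p, base in c2.items():
        prev = calls.get(p)
        if prev is None:
            calls[p] = base
        elif prev != base:
            calls[p] = "N"
    return TxFragment(model.gene_id, tx_start, tx_end, calls)


def fragment_from_segment(
    seg: AlignedSegmentView,
    model: TranscriptModel,
    opts: ConversionOptions = ConversionOptions(),
) -> Optional[TxFragment]:
    """Single-end conversion: one record becomes one fragment."""
    if seg.chrom != model.chrom:
        return None
    if not _strand_ok(seg.fragment_strand, model, opts):
        return None
    res = segment_to_tx(seg, model)
    if res is None:
        return None
    s, e, calls = res
    if e - s + 1 > opts.max_fragment:
        return None
    return TxFragment(model.gene_id, s, e, calls)


def _group_span(segs: list[AlignedSegmentView]) -> tuple[str, int, int]:
    chrom = segs[0].chrom
    lo = min(s.pos for s in segs)
    hi = max(s.genomic_end() for s in segs)
    return chrom, lo, hi


def assign_to_transcripts(
    groups: dict[str, list[AlignedSegmentView]] | Iterable[list[AlignedSegmentView]],
    models: list[TranscriptModel],
    opts: ConversionOptions = ConversionOptions(),
) -> tuple[dict[str, list[TxFragment]], DiscardReport]:
    """Assign mate groups to every compatible transcript model.

    A group compatible with k models yields k fragments (one per model, in
    annotation order). The discard report counts groups assigned to no model,
    by the furthest stage they reached on any candidate model
    (span_length > structure > strand > off_annotation).
    """
    if not models:
        raise ValueError("empty model list")
    by_chrom: dict[str, list[TranscriptModel]] = {}
    for m in models:
        by_chrom.setdefault(m.chrom, []).append(m)

    fragments: dict[str, list[TxFragment]] = {m.gene_id: [] for m in models}
    report = DiscardReport()
    group_iter = groups.values() if isinstance(groups, dict) else groups

    def convert_units(segs: list[AlignedSegmentView]) -> list[list[AlignedSegmentView]]:
        # units of conversion: mate pairs in paired mode, single records otherwise
        if not opts.paired:
            return [[s] for s in segs]
        r1 = [s for s in segs if not s.is_read2]
        r2 = [s for s in segs if s.is_read2]
        if len(segs) == 2 and len(r1) == 1 and len(r2) == 1:
            return [segs]
        units = []
        for s in segs:
            if s.is_paired:
                units.append([])  # half pair: unusable in paired mode
            else:
                units.append([s])
        return units

    # discard ranks: higher means the unit got further before failing
    RANK = {"off_annotation": 0, "strand": 1, "structure": 2, "span_length": 3}

    for segs in group_iter:
        for unit in convert_units(segs):
            if not unit:
                report.half_pair += 1
                continue
            chrom, lo, hi = _group_span(unit)
            best: Optional[str] = None
            hit = False
            for model in by_chrom.get(chrom, []):
                ms, me = model.genomic_span
                if hi <= ms or lo > me:  # 1-based [lo,hi] vs 0-based [ms,me)
                    continue
                reason = None
                if len(unit) == 2:
                    frag = fragment_from_pair(unit[0], unit[1], model, opts)
                else:
                    frag = fragment_from_segment(unit[0], model, opts)
                if frag is not None:
                    fragments[model.gene_id].append(frag)
                    hit = True
                    continue
                # re-derive the failure stage for reporting
                read1 = next((s for s in unit if not s.is_read2), unit[0])
                if not _strand_ok(read1.fragment_strand, model, opts):
                    reason = "strand"
                elif any(segment_to_tx(s, model) is None for s in unit):
                    reason = "structure"
                else:
                    reason = "span_length"
                if best is None or RANK[reason] > RANK[best]:
                    best = reason
            if hit:
                report.assigned += 1
            elif best is None:
                report.off_annotation += 1
            else:
                setattr(report, best, getattr(report, best) + 1)
    return fragments, report
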