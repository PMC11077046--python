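# Methods

## Processing model

A transcript model is one BED record: ordered, disjoint exon blocks on one
strand of one chromosome, optionally with a CDS (thickStart/thickEnd). BED6
records are promoted to single-block BED12 without CDS; `thickStart ==
thickEnd` means noncoding; CDS containment in the exon union is validated at
construction, and overlapping blocks within a record are rejected rather than
merged (malformed annotations should fail loudly). BED input is 0-based
half-open; every coordinate exposed by the API and the tables is 1-based
inclusive, matching SAM, with transcript coordinate 1 at the 5' end (for
minus-strand genes this is the highest exonic genomic coordinate).

An alignment is compatible with a model when every M/D block lies inside the
exon union and every N gap coincides *exactly* with an intron implied by
adjacent exons (containment alone is not accepted: a read skipping a
non-annotated interval is evidence against the isoform). M positions carry
the read base, complemented into transcript orientation for minus-strand
models; D positions carry "-"; soft clips and insertions consume read bases
but produce no transcript position, because table rows are reference
nucleotides. Under these rules a compatible alignment always occupies a
contiguous transcript interval, which is asserted.

Pairs are bridged: the fragment spans min(tx starts)..max(tx ends), its calls
are the union of the mates' calls, and positions covered by both mates keep
agreeing calls once and become N on disagreement — overlap disagreement is
sequencer error of unknowable side, and N excludes the position from
misincorporation numerators and denominators rather than arbitrating.
Fragment strand follows an FR library layout: read1 (or an unpaired record)
aligns on the fragment strand, read2 opposite; `strand_mode` then demands
same/opposite/any relation to the model strand. This FR rule is also applied
per record in single-end processing mode, so read2-derived records remain
usable when a paired library is deliberately processed unbridged. Merged
spans longer than `max_fragment` (default 1000 nt; CLI `-r`) are discarded as
likely chimeras. Pairs with exactly one usable mate are discarded in paired
mode rather than demoted, keeping coverage semantics uniform; the discard
report counts strand / structure / span-length / off-annotation / half-pair
outcomes, attributing each unassigned group to the furthest stage it reached
on any candidate model. A group compatible with k overlapping models yields
one fragment per model. Reads are never deduplicated; there is no UMI
handling.

The pileup step is exact integer bookkeeping. Coverage counts fragments whose
span covers the row; start_5p/end_3p count fragment termini; A/C/G/T/N/del
count calls. Three invariants hold by construction and are tested: cov(1) =
start_5p(1); cov(i) = cov(i−1) + start_5p(i) − end_3p(i−1); per gene,
Σstart_5p = Σend_3p = fragment count. Bridged-gap positions increment only
coverage — that is the point of bridging.

## Metrics and statistics

All ratio metrics are in [0, 1] or missing (zero denominators and
non-applicable rows give NaN, never an error); differences are in [−1, 1] or
missing, and NaN propagates. SR_1bpDS at i is startRatio evaluated at i+1 —
i.e. the downstream coverage is the denominator — because the statistic is a
shift of the ratio, and the shift never crosses gene boundaries (the last row
of each gene is NaN). Misincorporation denominators exclude N and deletions;
an `include_del` flag adds deletions to numerator and denominator for
cleavage-style chemistries. Motif scanning uses the 15-letter IUPAC DNA
alphabet (U normalized to T on load) with overlapping matches; position p is
flagged when the window centered per `center_offset` (default: the middle
letter, so DRACH flags the A) matches. Putative-site calling is a conjunction
of (column, comparator, threshold) predicates in which missing values always
fail.

Row-wise tests operate across unified replicate tables (gene intersection,
identical row order; unification refuses genes whose lengths differ, which
indicates an annotation mismatch). The t-test defaults to pooled variance
(Welch by flag); rows with any missing replicate are missing; zero pooled
variance gives t = 0, p = 1 on equal means and t = ±inf, p = 0 otherwise.
The count-ratio test is a self-implemented binomial likelihood-ratio test:
successes and trials are pooled within each group, the statistic is twice the
log-likelihood gap between per-group and pooled proportions with the
0·log 0 = 0 convention, referred to chi-square with 1 df. A negative-binomial
GLM would additionally model biological overdispersion of the replicate
counts; the binomial LRT was chosen as the self-contained member of the same
family, and its null calibration is verified empirically. Raw p-values are
reported; Benjamini–Hochberg adjustment is available but off by default since
the downstream thresholds here act on raw p.

Metagene matrices bin each gene's 5'UTR/CDS/3'UTR into fixed per-region bin
counts by equal-width position intervals (`numpy.array_split` semantics);
bins of regions shorter than the bin count are missing, and noncoding genes
are skipped. Flank windows never cross gene boundaries (out-of-range offsets
are missing).

The peak caller is deliberately plain plumbing: centered moving-average
smoothing of chosen width (edge-truncated), candidate = strict local maximum
of the smoothed profile at or above `min_cov` — an equal-valued plateau
flanked by strictly lower values counts once at its center, and an entirely
flat profile has no peaks — followed by non-maximum suppression within
`min_gap`, highest first, leftmost on ties. Its absolute peak counts are not
comparable to any published pipeline; it exists to quantify the *relative*
effect of mate bridging on peak centering.

## Simulator

The generator emulates the study conditions end to end: uniform-random
A/C/G/T genomes over a few chromosomes; non-overlapping genes on both strands
with 1–3 exons (exon 100–300 nt, intron 50–500 nt by default) and CDS with
nonempty UTRs where length permits (15% of the transcript per UTR); fragments
with uniform start positions and normal(150, 30) lengths truncated to
[50, 400] and to the transcript; 40-nt mates from each fragment end;
per-base sequencing error 0.001 applied after modification effects. Injected
effects model the assay chemistries: `rt_stop` moves a fragment's 5' end to
site+1 with the given probability (cDNA-start space, one nucleotide
downstream of the adduct), `misinc` substitutes the molecule's base at the
site so both mates read it, `cleavage` splits the fragment into an end at s
and a start at s+1. Reads are emitted pre-aligned as coordinate-sorted SAM
written directly from the truth (correct chrom/pos, M/N CIGAR across
junctions, FR pair flags), which removes any aligner from the test loop and
makes the SAM byte-deterministic under the seed. An antibody-enrichment
builder (`enriched_library`) additionally produces m6A-seq-style libraries in
which every fragment contains its gene's site at a uniform offset, returned
in both bridged and split-mate form over the same molecules.

What the simulator does **not** model: coverage/GC bias, duplicates, quality
scores, alignment error, indel realignment ambiguity, isoform mixtures,
overdispersed biological replication. Passing recovery tests therefore shows
the pipeline's bookkeeping and estimators are correct under the stated
generative model, not that real libraries are free of these nuisances.

## Problem sizes and numerical choices

The test suite and the acceptance script run on deliberately compact
configurations chosen to keep every check exact or tightly bounded: oracle
equivalence on 10 genes × 1000 paired fragments (exact integer equality
against a brute-force per-position scan), effect-size recovery at 2000
fragments per gene (bands ±0.05 for SRD at 0.78 and ±0.03 for MRD at 0.30,
about three binomial standard errors at the realized per-site coverage),
null calibration over 5000 positions (p < 0.05 fraction in [0.03, 0.07]),
and the bridging-vs-single peak comparison over 200 genes × 150 fragments.
Sub-seeds for independent simulation stages are derived deterministically
from the single user seed.

Other conventions: FASTA sequences are uppercased with U→T on load; base
calls outside ACGT become N; table TSVs use "NA" for missing, "." for an
unavailable refSeq, and a fixed canonical column order (files with shuffled
columns are normalized on read, unknown columns are rejected); duplicate BED
names get a "#k" suffix so per-gene table blocks stay unambiguous; `cov`-mode
tables omit refSeq and base-count columns entirely rather than emitting
placeholders.

## Known limitations

Single-threaded by design; the computation is decomposable per gene, so
callers can shard the model list if needed. Long reads are handled as
single-end spliced alignments only. The CLI `-r`/`-m` flags are interpreted
as max merged-fragment length and min fragments per gene. No genome-space
pileup output, no GTF/GFF parsing, no isoform quantification, and plotting is
out of scope — every plot's data (start/end/coverage tables, flank matrices,
metagene matrices, PFMs, volcano inputs) is produced as plain tables instead.
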