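# txpileup

Nucleotide-resolution analysis of RNA-seq data in transcript space, with
proper handling of paired-end mates.

Many RNA biology assays encode their signal not in read *counts* per gene but
in per-nucleotide "read-outs" of the alignments: where reads start, where they
end, which base they report, and where they carry deletions. RT-stop
chemistries (Pseudo-seq/CMC for pseudouridine, miCLIP crosslinks for m6A)
produce pile-ups of cDNA starts one nucleotide downstream of the modified
base; misincorporation chemistries (ac4C-seq) produce specific mismatches;
cleavage-based protocols produce coordinated read ends and starts. txpileup
converts genomically aligned reads (SAM/BAM) plus a BED12/BED6 transcriptome
annotation (and optionally a FASTA genome) into one table with a row per
transcript nucleotide carrying both coordinate systems and all four
read-outs, then provides the derived metrics and statistics these assays use.

Two things distinguish the processing model:

- **Transcript space.** Reads are mapped genome-wide (avoiding annotation
  bias), then filtered for strand and exon-structure compatibility and
  re-expressed in transcript coordinates, where splice junctions disappear
  and positions are biologically contiguous.
- **Mate bridging.** A proper pair is treated as one fragment from the start
  of read1 to the end of read2. The unsequenced inter-mate gap counts toward
  coverage (the molecule demonstrably spans it) while contributing no base
  calls. For a 150-nt insert sequenced 40 nt from each end, this recovers
  evidence across 70 nucleotides that single-end accounting discards.

## The table and its metrics

For gene g with transcript length L the table holds rows (g, txcoor = 1..L)
with columns `chrom, gencoor, strand, gene, txcoor, refSeq, cov, start_5p,
end_3p, A, C, G, T, N, del`. Derived per-position statistics:

- startRatio(i) = start_5p(i) / cov(i), and its 1-bp-downstream shift
  SR_1bpDS(i) = startRatio(i+1) — the RT-stop read-out, reported *on* the
  modified base;
- SRD_1bpDS = SR_1bpDS(treated) − SR_1bpDS(control);
- misincRate(i) = mismatching ACGT calls / all ACGT calls, and the specific
  MR_XtoY (e.g. MR_CtoT = T calls / ACGT calls at reference-C positions),
  with MRD_CtoT the treated-minus-control difference;
- IUPAC motif presence (e.g. DRACH), gene-region labels (5'UTR/CDS/3'UTR),
  and thresholded putative-site calls.

Group comparisons run row-wise across unified replicate tables: two-sample
t-tests (pooled or Welch) for continuous metrics and a binomial
likelihood-ratio test for count ratios, plus flank windows, metagene
matrices, sequence PFMs and a simple coverage peak caller.

A first-class simulator generates random genomes, multi-exon annotations on
both strands, and pre-aligned paired-end libraries with injected RT-stop,
misincorporation and cleavage effects of known probability, so the whole
pipeline is testable against ground truth without any external data.

## Worked example

`examples/pseudouridine_rt_stop.py` simulates a CMC-treated library (RT-stop
probability 0.8 at one site) against a mock control (0.02), builds both
tables, and scores every position:

```
highest SRD_1bpDS: 0.777 at gene001:200
injected site was  gene001:200 with stop probability 0.8 vs 0.02
```

The top-scoring position is exactly the injected site, and the score
estimates the excess stopping fraction 0.8 − 0.02 = 0.78. The other examples
cover replicate t-testing with DRACH context (`m6a_miclip_ttest.py`), C→T
misincorporation calling (`ac4c_misincorporation.py`), and the effect of mate
bridging on peak centering (`paired_bridging_peaks.py`).

The same pipeline is available from the shell:

```sh
txpileup pileup -b reads.bam -g genes.bed -f genome.fa \
    -p TRUE -d covNuc -r 300 -m 0 -o table.tsv
```

where `-p` bridges mates, `-d` picks the summary (cov / nucFreq / covNuc),
`-r` discards merged fragments longer than the limit and `-m` drops genes
with fewer assigned fragments. `txpileup simulate / metrics / peaks / test`
cover the simulator, metric columns, peak calling and row-wise tests.

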