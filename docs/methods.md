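# Methods

## The problem

RelE is a bacterial type-II toxin: it enters the empty ribosomal A site and
cleaves the mRNA after the second nucleotide of the A-site codon.  Ribosome
profiling of cells overexpressing RelE (or of lysates digested with purified
RelE) therefore yields footprints whose 3' ends report the ribosome's
position at single-nucleotide — in fact sub-codon — resolution, something
the standard MNase protocol cannot do.  Two signatures dominate such data:

1. **5' polarity in vivo.** Repeated cycles of cleavage, rescue of the
   stalled ribosome (tmRNA/ArfA) and re-initiation on the surviving 5'
   fragment concentrate ribosome and mRNA density toward the 5' ends of
   genes and of polycistronic operons.
2. **Reading frame.** RelE 3' ends fall predominantly on the second
   nucleotide of the A-site codon; codons ending in C (NNC) are cut one
   nucleotide later.  Shifting NNC-codon density from the third to the
   second sub-codon position ("NNC shift") sharpens the frame signal enough
   to detect programmed frameshifts, e.g. the +1 shift at codon 28 of a
   prfB-like gene.

`relprof` implements both the analyses (density, metagene, operon
statistics, frame tools, specificity profiling) and a synthetic-footprint
simulator that embodies the cleavage/rescue/initiation model, so every
analysis is testable against ground truth without external data.

## Coordinate conventions

Internal coordinates are 0-based half-open; GFF3 output is 1-based
inclusive; SAM follows its standard.  "Offset +4 from the start codon"
means the 0-based transcript offset 4 (the 5th nucleotide).  Footprint
records carry 5'/3' ends as genomic, 0-based, inclusive positions in
transcript orientation.  Sub-codon positions are numbered 1/2/3 (offsets
0/1/2 within the codon).

## The simulator

**Transcriptome.** A single synthetic contig carries `n_genes` ORFs (ATG,
random sense codons from a configurable usage table — uniform over the 61
by default — and a stop), grouped into operons laid out 5'→3' on either
strand with 150 nt intergenic spacers and 80 nt intra-operon gaps; each
transcript has 30 nt 5' and 90 nt 3' UTRs.  The optional frameshift gene
places an in-frame stop at codon `c` (default 28) with an open shifted
frame (≥ 50 sense codons) beginning at nt `3(c−1)+1` for a +1 shift
(`3(c−1)−1` for −1).  Shifted-frame codons carry no C at their 2nd or 3rd
position, so RelE products downstream of the shift stay at the annotated
third sub-codon position and are not NNC-shifted away — the clean
transition the prfB construct is meant to exhibit.

**Nuclease geometry.** RelE: 3' end at A-site first nt + `delta_rele`
(default 1, i.e. after the 2nd nt); NNC codons cut after the 3rd nt with
probability `p_nnc` (default 1); optional uniform mis-cleavage
`p_miscleave` (default 0) places the end uniformly within the A-site codon.
MNase: 3' boundary at A-site first nt + `delta_mnase` (default 12), with
optional Gaussian jitter, and the cut repositioned to the nearest site
(≤ 3 nt) whose downstream base is A/T with probability `p_cut_before_AT`
(0.8 by default; `None` disables repositioning entirely, which the
geometry-closure tests use).  The 5' end is always MNase-trimmed
`five_prime_offset` = 20 nt upstream of the A-site first nt, chosen so
footprint lengths (RelE ≈ 22 nt, MNase ≈ 33 nt) sit inside the cloning
windows (20–40 nt in vivo, 10–40 in vitro) and differ by
`delta_mnase − delta_rele` = 11 nt.  These defaults reproduce the +4/+15
start-codon and +12 stop-codon metagene peaks.

**Sequence preference as sampling weight.** RelE prefers C at −1 and G at
+1 of its cut.  Each candidate footprint receives a multiplicative weight
(`w_minus1_C`, `w_plus1_G`, both 3 by default; magnitudes are a package
choice — large enough to make the bias matrices visibly asymmetric) and the
emitted library is a resample, with replacement, of candidates proportional
to weight — sequencing from a fragment pool whose abundances reflect
cleavage propensity.  Cut positions are never moved by the preference, so
A-site geometry is exact in every read; the preference shows up as which
contexts are over-represented.  A consequence worth knowing: quantities
defined "per codon occurrence" (frame fractions, heatmap rows) are
re-weighted by context under the default weights; closed-form checks
against codon usage are made with neutral weights.

**Occupied A sites.** A fraction `p_occupied_Asite` of ribosomes carries a
stably bound A-site factor (tRNA at a SecM-like arrest, release factor at a
TnaC-like stop).  These block RelE with probability `p_block_occupied`
(default 1) and are digested with MNase geometry instead — the simulator
analogue of the pause-site exception.

**Dynamics.** The in vivo model is an exact event-driven (Gillespie)
simulation per mRNA copy of a transcription unit (all cistrons of an
operon share one message).  Channels, all exponential: initiation at a
cistron's start codon (rate `k_init` = 0.2 /s per mRNA, allowed when the
first 10 codons are clear and the cistron survives upstream of any cut),
elongation by one codon (`k_elong` = 10 codons/s, under a 10-codon steric
exclusion), RelE cleavage of an unoccupied A site (`k_cleave`, order 0.3 /s
when induced), which truncates the message at the cut and stalls the
ribosome, and rescue (`k_rescue` = 0.5 /s), which removes a stalled
ribosome.  Every cistron downstream of the 5'-most cut leaves the initiable
pool; ribosomes already past the cut finish on the released fragment.  A
ribosome decoding a stop codon is released by its next elongation event; on
the frameshift gene a ribosome reaching the shift site moves ±1 nt instead.
IN_VITRO mode freezes initiation and elongation and returns the supplied
occupancy unchanged (invariant under `sim_time`), modelling
chloramphenicol-arrested lysates.

The model has no mRNA synthesis or decay, so at a fixed late observation
time every message ends fully truncated and empty — there is no steady
state with reads.  Two observation designs are used.  For polarity and
no-cleavage controls, all copies are observed at a fixed age past one
traversal time (the no-cleavage steady state is flat, ratio ≈ 1).  For
operon-gradient analyses, `age_mixture=True` draws each copy's age
uniformly from [0, `sim_time`], modelling continuous transcription during
the induction window; the resulting mixture of young (fully covered) and
old (5'-truncated) messages produces the graded decline of treated/control
ratios along operon positions.

**RNA-seq.** Alkaline-hydrolysis fragments are uniform over transcripts
(gene choice proportional to configured abundance, lengths uniform in
40–60 nt) with no sequence bias at either end; they serve as the
no-bias and no-frame control.

## Analyses

* **Density**: every accepted read increments the genomic position of its
  3'-most nucleotide on its strand.  Gene coverage below 0.1 reads/codon
  (strict) excludes a gene from the averaged analyses.
* **Metagene**: per gene, the density over a window around the start or
  stop codon's first nucleotide is normalised by its own window mean
  (default; a raw mode exists) and genes ≥ 1000 nt are averaged with equal
  weight.  Peak ties resolve toward 5' with a warning.
* **Polarity**: per-gene mean density over codons 1–100 divided by the
  mean from codon 151 on, with a 0.5-read pseudocount in the tail.
* **Operons**: monocistronic operons are dropped; an operon whose per-gene
  RNA-seq density varies more than 5-fold (strict, max/min of per-nt
  means) is dropped; genes under 1 rpkm are dropped.  Survivors get
  treated/control per-nt density ratios binned by operon position
  (1, 2, 3, 4, ≥5).  The rank-sum test uses midranks, exact enumeration
  for n₁+n₂ ≤ 12 and otherwise a normal approximation with tie-corrected
  variance and continuity correction; two-sided p = 2·min(P≤, P≥), capped
  at 1.
* **Frames**: 3' ends mapped to sub-codon positions over CDS interiors
  (first/last 30 nt excluded, no coverage threshold) or over 3' UTRs (90 nt
  past the stop, truncated at the next CDS, frame continued from the ORF).
  A-site attribution inverts the geometry: RelE position-2 ends map to
  their codon, position-3 ends only on NNC codons (else ambiguous, dropped
  from the heatmap with the fraction reported); MNase ends map 12 nt back.
  The NNC shift moves density from the 3rd to the 2nd nucleotide of every
  CDS codon ending in C (genome-wide by default; a gene subset can be
  given) and conserves totals exactly.
* **Frameshift scan**: per-codon counts of ends at positions 1/2/3; binary
  segmentation maximising the two-segment multinomial likelihood ratio.
  Splits tied because boundary codons carry no reads resolve to the middle
  of the tied run.  A call needs ≥ 50 reads on the gene, a score above 30,
  and a change in the dominant position (2→3 ⇒ +1, 2→1 ⇒ −1).  The
  threshold sits far above the null scan maximum (a maximum of ~2-df
  likelihood-ratio statistics, tail ≈ 18–22 at the 99th percentile) and is
  verified by a zero-false-call test on 100 no-shift simulations.
* **Specificity**: base frequencies at −2..+2 around the cut (−1 = last
  footprint base, +1 = first base past it), against a background of
  coverage-weighted transcribed sequence (whole-genome by flag);
  enrichment = frequency / background, NaN-flagged where the background is
  empty.  ORF position bias counts bases per sub-codon position over all
  CDS codons.

## What the simulator does and does not emulate

It reproduces the statistical structure the analyses assume: cut-site
geometry and its sequence modulation, occupied-A-site blocking, 5'
polarity from cleavage/rescue/initiation, polycistronic depletion,
uniform RNA-seq, cloning-window length filters, and a programmed
frameshift.  It does not model rRNA/tRNA contamination, sequencing errors,
cloning/ligation bias, mRNA synthesis/decay kinetics (beyond the age
mixture), codon-specific elongation rates, or realistic genome
composition.  Passing tests therefore demonstrate the correctness and
calibration of the analysis code under the model's assumptions, not
biological conclusions about any real library.

## Numerical and design choices

* One RNG stream per simulation; seeds are mandatory and all randomness in
  the pipeline flows from a single seed, making summary JSON byte-stable.
* Steric exclusion of 10 codons ≈ one footprint; initiation requires the
  first 10 codons clear.
* Degenerate inputs: empty read sets give empty histograms and
  NaN-flagged frame summaries; genes too short for polarity windows are
  skipped with a log message; a flat metagene reports its 5'-most offset
  with a warning.
* Problem sizes in the test-suite and acceptance runs (50-gene
  transcriptomes, a few hundred footprints per gene, 20-seed replicate
  sets) were chosen as the smallest sizes at which the statistical checks
  have comfortable power.

## Known limitations

* The dynamics observes mRNA copies independently; ribosome and RelE pools
  are implicitly unlimited.
* Downstream-fragment translation is simplified: runners finish their
  cistron, but subsequent cleavage of runner-bearing fragments does not
  create new trackable fragments.
* The frameshift scan models a single change point; multiple shifts in one
  gene would be reported as the strongest split only.
* With the default context weights, sub-codon fractions are
  context-re-weighted (see above); quantitative frame comparisons across
  libraries should use matched weight settings.
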