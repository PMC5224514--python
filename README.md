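# relprof

Ribosome-profiling analysis of RelE-mediated mRNA cleavage, with a
synthetic-footprint simulator.

RelE is a bacterial toxin–antitoxin endonuclease that binds the empty
ribosomal A site and cleaves the mRNA after the **second nucleotide of the
A-site codon**.  Footprint libraries produced under RelE (in vivo
overexpression, or purified RelE added to lysates) therefore encode the
ribosome's position — and its reading frame — in the 3' ends of reads, at a
precision that MNase-only protocols cannot reach.  `relprof` is for
computational biologists who want to analyse such libraries, or to test
analysis code against a simulator with known ground truth:

* **3'-end density maps** (`assign_3prime_density`) and equal-weighted
  **metagene profiles** (`metagene`, `peak_offset`): a RelE library peaks
  at offset +4 from the first nucleotide of the start codon (cut after the
  2nd nt of the A-site codon 2), an MNase library at +15 (ribosome 3'
  boundary), and +12 downstream of stop codons at termination.
* **5'-polarity statistics** (`polarity_ratio`) and **operon-position
  ratios** with a Mann–Whitney rank-sum test (`define_single_TUs`,
  `position_ratios`, `rank_sum_test`): cleavage/rescue/re-initiation cycles
  enrich ribosomes at the 5' ends of genes and of polycistronic messages.
* **Sub-codon reading-frame tools** (`subcodon_fractions`,
  `codon_heatmap`, `nnc_shift`): RelE 3' ends sit mostly on sub-codon
  position 2; codons ending in C (NNC) are cut one nucleotide later, and
  the NNC shift moves that density back, sharpening the frame signal.
* **Frameshift detection** (`frameshift_scan`): a multinomial
  likelihood-ratio change point on the per-codon frame composition detects
  programmed frameshifts such as the +1 shift at codon 28 of a prfB-like
  gene.
* **Nuclease specificity** (`end_bias`, `orf_position_bias`): MNase cuts
  preferentially before A/T; RelE prefers C at −1 and G at +1 of its cut.
* **A simulator** (`generate_transcriptome`, `simulate_dynamics`,
  `place_ribosomes`, `digest`, `emit_reads`, `simulate_rnaseq`) that writes
  FASTA/GFF3/operon-TSV/SAM plus per-read truth tables, and embodies the
  kinetic model (initiation, elongation with steric exclusion, A-site
  cleavage that truncates the message, ribosome rescue) as an exact
  stochastic simulation.

## Worked example

The bundled demo simulates one transcriptome (24 genes in 5 operons, the
last gene carrying a +1 frameshift at codon 28) and five libraries — RelE
and MNase digests of the same frozen lysate, an in vivo RelE library under
full cleavage/rescue/initiation dynamics, a wild-type control and uniform
RNA-seq — then runs every analysis stage on the emitted SAM files:

```bash
relprof report --outdir demo --seed 5
# or: python -m relprof.cli report --outdir demo --seed 5
```

`demo/summary.json` then contains (abridged):

```json
"start_peaks": {"rele_invitro": 4, "mnase_invitro": 15},
"stop_peaks":  {"rele_invitro": 1, "mnase_invitro": 12},
"polarity": {
  "rele_invivo": {"median_ratio": 244.37, "n_genes": 18},
  "wt_invivo":   {"median_ratio": 0.77,   "n_genes": 23}},
"operon": {"bin_medians": {"1": 2.84, "2": 0.65, "3": 0.0, "4": 0.29, "5": 0.0},
           "rank_sum": {"U": 25.0, "p": 0.00794}},
"frame_fractions": {"before_shift": [0.0, 0.600, 0.400],
                    "after_shift":  [0.0, 0.984, 0.016]},
"frameshift_calls": [{"gene_id": "gene0024", "codon_index": 28, "direction": 1}]
```

Reading this: the RelE start peak at +4 versus MNase at +15 shows the 3'
ends are RelE-generated A-site cuts, not ribosome boundaries; the stop
peaks (+1 vs +12) say the same at termination.  The in vivo cleavage
library is massively 5'-polarised (head/tail median ratio ≫ 1) while the
control is ≈ 1, and the treated/control ratio falls with operon position
(median 2.84 at position 1 versus 0 at position ≥5; rank-sum p ≈ 0.008).
Before correction 60% of RelE 3' ends sit on sub-codon position 2 and 40%
on position 3; the NNC shift moves the position-3 ends that come from
C-ending A-site codons, leaving 98% on position 2.  On that corrected
track the change-point scan recovers the +1 frameshift at codon 28 of the
construct and calls nothing anywhere else.

Per-stage subcommands (`simulate`, `density`, `metagene`, `operon`,
`frame`, `specificity`) expose the same analyses on any SAM/FASTA/GFF3
inputs; see `relprof --help`.

## Layout

```
src/relprof/
  transcriptome.py   synthetic genomes, operons, frameshift constructs
  nucleases.py       MNase / RelE cut-site models
  dynamics.py        cleavage/rescue/initiation stochastic simulation
  digest.py          footprint generation, SAM/FASTQ emission, RNA-seq
  io.py              FASTA/GFF3/SAM readers, BedGraph writer
  density.py         3'-end tracks, gene stats, metagenes, polarity
  operons.py         single-TU filter, position ratios, rank-sum test
  frames.py          sub-codon fractions, NNC shift, heatmap, frameshift scan
  specificity.py     end-bias matrices, ORF composition, length histograms
  pipeline.py, cli.py  orchestration and command line
docs/methods.md      model, parameters, assumptions, limitations
```
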