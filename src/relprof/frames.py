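"""Sub-codon reading-frame analysis, NNC-shift correction and frameshift
detection.

With RelE-generated 3' ends, footprint ends fall predominantly after the
second nucleotide of the A-site codon, so the distribution of ends over
sub-codon positions 1/2/3 reads out the ribosome's frame.  Codons ending in
C (NNC) are cleaved after their third nucleotide instead; the NNC shift
moves that density back one nucleotide, sharpening the frame signal.  A
change in the dominant sub-codon position along a gene reveals a
programmed frameshift; the change point is located by binary segmentation
with a multinomial likelihood-ratio score.

Sub-codon positions are numbered 1/2/3 = offsets 0/1/2 within the codon.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .density import DensityTrack
from .transcriptome import SENSE_CODONS, GeneModel, gene_cds_seq

log = logging.getLogger(__name__)


@dataclass
class FrameSummary:
    """Fractions of 3' ends at sub-codon positions 1/2/3 over a region set."""

    f1: float
    f2: float
    f3: float
    region: str
    n_reads: int

    @property
    def defined(self) -> bool:
        return self.n_reads > 0

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.f1, self.f2, self.f3)


def _frame_counts_cds(track: DensityTrack, gene: GeneModel, exclude_end_nt: int) -> np.ndarray:
    v = track.gene_vector(gene)
    lo, hi = exclude_end_nt, gene.cds_len - exclude_end_nt
    counts = np.zeros(3, dtype=np.int64)
    if hi <= lo:
        return counts
    w = v[lo:hi]
    idx = (np.arange(lo, hi)) % 3
    for k in range(3):
        counts[k] = w[idx == k].sum()
    return counts


def _occupied_mask(annotation, contig_lengths: dict[str, int]) -> dict[str, np.ndarray]:
    occ = {c: np.zeros(n, dtype=bool) for c, n in contig_lengths.items()}
    for g in annotation:
        occ[g.contig][g.start : g.end] = True
    return occ


def subcodon_fractions(
    track: DensityTrack,
    annotation,
    exclude_end_nt: int = 30,
    region: str = "CDS_interior",
    utr3_len: int = 90,
) -> FrameSummary:
    """Fractions of read 3' ends at sub-codon positions 1/2/3.

    ``CDS_interior`` uses every coding sequence with no coverage threshold,
    excluding the first and last ``exclude_end_nt`` nt of each ORF.
    ``UTR3`` uses up to ``utr3_len`` nt downstream of each stop codon
    (truncated at the next annotated CDS), with the frame of reference
    continued from the preceding ORF.
    """
    if region not in ("CDS_interior", "UTR3"):
        raise ValueError("region must be CDS_interior or UTR3")
    counts = np.zeros(3, dtype=np.int64)
    if region == "CDS_interior":
        for gene in annotation:
            counts += _frame_counts_cds(track, gene, exclude_end_nt)
    else:
        lengths = {
            c: arr.size for (c, s), arr in track.counts.items() if s == "+"
        }
        occ = _occupied_mask(annotation, lengths)
        for gene in annotation:
            arr = track.counts[(gene.contig, gene.strand)]
            occ_c = occ[gene.contig]
            for t in range(gene.cds_len, gene.cds_len + utr3_len):
                pos = gene.start + t if gene.strand == "+" else gene.end - 1 - t
                if not 0 <= pos < arr.size or occ_c[pos]:
                    break
                counts[t % 3] += arr[pos]
    n = int(counts.sum())
    if n == 0:
        log.warning("subcodon_fractions: no reads in region %s", region)
        return FrameSummary(float("nan"), float("nan"), float("nan"), region, 0)
    f = counts / n
    return FrameSummary(float(f[0]), float(f[1]), float(f[2]), region, n)


def asite_codon_from_3prime(
    end_t: int, cds_seq: str, library_type: str
) -> tuple[int | None, str]:
    """Invert 3'-end geometry to the A-site codon index (1-based).

    ``end_t`` is the transcript-orientation CDS offset of the footprint's
    3'-most nucleotide.  RelE: ends at sub-codon position 2 place the A-site
    codon around them; ends at position 3 are assigned to their own codon
    only when it ends in C (the NNC rule), otherwise flagged ``ambiguous``.
    MNase: the A-site codon first nt sits 12 nt upstream of the end.
    Returns ``(codon_index, flag)`` with flag in {"ok", "ambiguous",
    "out_of_range"}.
    """
    library_type = library_type.upper()
    n = len(cds_seq)
    if library_type == "RELE":
        if not 0 <= end_t < n:
            return None, "out_of_range"
        sub = end_t % 3  # 0-based position within codon
        if sub == 1:
            return end_t // 3 + 1, "ok"
        if sub == 2 and cds_seq[end_t] == "C":
            return end_t // 3 + 1, "ok"
        return None, "ambiguous"
    if library_type == "MNASE":
        a_first = end_t - 12
        if a_first < 0 or end_t >= n + 12:
            return None, "out_of_range"
        return a_first // 3 + 1, "ok"
    raise ValueError("library_type must be RELE or MNASE")


@dataclass
class CodonHeatmap:
    """Per-sense-codon occupancy fractions over sub-codon positions 1-3."""

    fractions: pd.DataFrame  # 61 x 3, rows sum to 1 where counted
    counts: pd.DataFrame
    ambiguous_fraction: float
    zero_rows: list[str]


def codon_heatmap(
    track: DensityTrack, annotation, genome: dict[str, str], library_type: str = "RELE"
) -> CodonHeatmap:
    """A-site codon x sub-codon-position occupancy for a RelE library.

    Reads are attributed to A-site codons by inverting cleavage geometry;
    ambiguous ends (position-3 ends on non-NNC codons, position-1 ends) are
    dropped and their fraction reported.
    """
    counts = {c: np.zeros(3, dtype=np.int64) for c in SENSE_CODONS}
    ambiguous = 0
    total = 0
    for gene in annotation:
        seq = gene_cds_seq(genome, gene)
        v = track.gene_vector(gene)
        for t in np.flatnonzero(v):
            c = int(v[t])
            total += c
            codon_idx, flag = asite_codon_from_3prime(int(t), seq, library_type)
            if flag != "ok":
                ambiguous += c
                continue
            codon = seq[3 * (codon_idx - 1) : 3 * codon_idx]
            if codon not in counts:  # stop codon in A site: not a sense row
                ambiguous += c
                continue
            sub = int(t) - 3 * (codon_idx - 1)
            counts[codon][sub] += c
    cdf = pd.DataFrame(counts, index=[1, 2, 3]).T
    row_sums = cdf.sum(axis=1)
    zero_rows = list(cdf.index[row_sums == 0])
    frac = cdf.div(row_sums.replace(0, np.nan), axis=0)
    return CodonHeatmap(
        fractions=frac,
        counts=cdf,
        ambiguous_fraction=ambiguous / total if total else float("nan"),
        zero_rows=zero_rows,
    )


def nnc_shift(
    track: DensityTrack, annotation, genome: dict[str, str], genes: list[str] | None = None
) -> DensityTrack:
    """Move 3'-end density from the 3rd to the 2nd nucleotide of every CDS
    codon ending in C.  Total density is conserved; all other positions are
    untouched.  ``genes`` restricts the correction to a subset (genome-wide
    by default)."""
    new = track.copy()
    gene_set = annotation if genes is None else [annotation.gene(g) for g in genes]
    for gene in gene_set:
        seq = gene_cds_seq(genome, gene)
        arr = new.counts[(gene.contig, gene.strand)]
        for k in range(gene.n_codons):
            if seq[3 * k + 2] != "C":
                continue
            t3 = 3 * k + 2
            p3 = gene.start + t3 if gene.strand == "+" else gene.end - 1 - t3
            p2 = p3 + (-1 if gene.strand == "+" else 1)
            if arr[p3]:
                arr[p2] += arr[p3]
                arr[p3] = 0
    return new


@dataclass
class FrameshiftCall:
    gene_id: str
    codon_index: int  # 1-based first codon of the downstream segment
    frame_before: int  # dominant sub-codon position (1-3) upstream
    frame_after: int
    direction: int  # +1 or -1
    score: float


def _multinomial_ll(x: np.ndarray) -> float:
    n = x.sum()
    if n == 0:
        return 0.0
    nz = x[x > 0]
    return float((nz * np.log(nz / n)).sum())


def frameshift_scan(
    track: DensityTrack,
    gene: GeneModel,
    genome: dict[str, str],
    min_reads: int = 50,
    min_score: float = 30.0,
    min_segment_codons: int = 3,
    nnc_shifted: bool = True,
) -> FrameshiftCall | None:
    """Scan one gene for a change in dominant sub-codon position.

    Per-codon counts of 3' ends at positions 1/2/3 are split at every
    candidate codon; the split maximising the multinomial likelihood-ratio
    between the two segments is the change point.  A call is emitted when
    the score exceeds ``min_score`` (calibrated on no-shift simulations)
    and the gene carries at least ``min_reads`` ends.  The direction maps
    the dominant-position change (2 -> 3 is +1; 2 -> 1 is -1).
    """
    if not nnc_shifted:
        log.warning("frameshift_scan: track not NNC-shifted; frame signal degraded")
    v = track.gene_vector(gene)
    n_total = int(v.sum())
    if n_total < min_reads:
        log.info("%s: %d reads < %d; no frameshift scan", gene.gene_id, n_total, min_reads)
        return None
    n_cod = gene.n_codons
    per_codon = v[: 3 * n_cod].reshape(n_cod, 3)
    cum = np.vstack([np.zeros(3, dtype=np.int64), np.cumsum(per_codon, axis=0)])
    total = cum[-1]
    ll_all = _multinomial_ll(total.astype(float))
    candidates = np.arange(min_segment_codons, n_cod - min_segment_codons + 1)
    if candidates.size == 0:
        return None
    scores = np.empty(candidates.size)
    for j, c in enumerate(candidates):
        up = cum[c].astype(float)
        down = (total - cum[c]).astype(float)
        scores[j] = 2.0 * (_multinomial_ll(up) + _multinomial_ll(down) - ll_all)
    best_score = scores.max()
    if best_score < min_score:
        return None
    # read-free codons at the boundary tie neighbouring splits exactly;
    # take the middle of the tied run
    tied = np.flatnonzero(scores >= best_score - 1e-9)
    run = [tied[0]]
    for t in tied[1:]:
        if t == run[-1] + 1:
            run.append(t)
        else:
            break
    best_c = int(candidates[run[len(run) // 2]])
    up = cum[best_c]
    down = total - cum[best_c]
    frame_before = int(np.argmax(up)) + 1
    frame_after = int(np.argmax(down)) + 1
    delta = (frame_after - frame_before) % 3
    if delta == 0:
        return None  # dominant frame unchanged: not a frameshift signature
    direction = 1 if delta == 1 else -1
    return FrameshiftCall(
        gene_id=gene.gene_id,
        codon_index=best_c + 1,
        frame_before=frame_before,
        frame_after=frame_after,
        direction=direction,
        score=float(best_score),
    )
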