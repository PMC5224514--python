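"""3'-end density tracks, gene-level statistics and metagene profiles.

Ribosome occupancy is credited to the genomic position of each footprint's
3'-most nucleotide, per strand.  Metagene profiles are equal-weighted
averages across genes aligned at their start or stop codon: each gene's
window is (by default) normalised by its own mean before averaging so that
deep genes do not dominate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .transcriptome import GeneModel

log = logging.getLogger(__name__)


class DensityTrack:
    """Per-contig, per-strand counts of read 3' ends at each nucleotide."""

    def __init__(self, contig_lengths: dict[str, int], label: str = ""):
        self.label = label
        self.counts: dict[tuple[str, str], np.ndarray] = {
            (c, s): np.zeros(n, dtype=np.int64)
            for c, n in contig_lengths.items()
            for s in "+-"
        }

    @property
    def total(self) -> int:
        return int(sum(a.sum() for a in self.counts.values()))

    def add_end(self, contig: str, strand: str, pos: int, n: int = 1) -> None:
        self.counts[(contig, strand)][pos] += n

    def gene_positions(self, gene: GeneModel, lo: int, hi: int) -> np.ndarray:
        """Genomic positions of transcript offsets [lo, hi) for ``gene``."""
        if gene.strand == "+":
            return np.arange(gene.start + lo, gene.start + hi)
        return np.arange(gene.end - 1 - lo, gene.end - 1 - hi, -1)

    def gene_vector(self, gene: GeneModel, lo: int = 0, hi: int | None = None) -> np.ndarray:
        """Counts over transcript offsets [lo, hi) in transcript orientation
        (offset 0 = first nt of the start codon)."""
        if hi is None:
            hi = gene.cds_len
        pos = self.gene_positions(gene, lo, hi)
        arr = self.counts[(gene.contig, gene.strand)]
        if pos.min() < 0 or pos.max() >= arr.size:
            raise IndexError(f"{gene.gene_id}: window [{lo},{hi}) outside contig")
        return arr[pos]

    def copy(self) -> "DensityTrack":
        new = DensityTrack({}, label=self.label)
        new.counts = {k: v.copy() for k, v in self.counts.items()}
        return new


def assign_3prime_density(
    reads, contig_lengths: dict[str, int] | dict[str, str], label: str = ""
) -> DensityTrack:
    """Build a 3'-end density track from reads.

    Accepts :class:`~relprof.io.SimpleRead`-like objects (``start``/``end``
    half-open, ``strand``) or :class:`~relprof.digest.FootprintRecord`
    (which carries the 3' end explicitly).  Forward reads [s, e) increment
    position e-1 on '+'; reverse reads increment position s on '-'.
    """
    lengths = {
        c: (len(v) if isinstance(v, str) else int(v)) for c, v in contig_lengths.items()
    }
    track = DensityTrack(lengths, label=label)
    for r in reads:
        if hasattr(r, "three_prime"):
            track.add_end(r.contig, r.strand, r.three_prime)
        elif r.strand == "+":
            track.add_end(r.contig, "+", r.end - 1)
        else:
            track.add_end(r.contig, "-", r.start)
    return track


def gene_stats(
    track: DensityTrack,
    annotation,
    min_reads_per_codon: float = 0.1,
    min_rpkm: float | None = None,
) -> pd.DataFrame:
    """Per-gene 3'-end counts inside the CDS with the coverage filter.

    A gene is kept unless its density is strictly below
    ``min_reads_per_codon`` (and, when given, ``min_rpkm``).  Exclusion
    reasons are recorded per gene.
    """
    lib_total = track.total
    rows = []
    for gene in annotation:
        total = int(track.gene_vector(gene).sum())
        n_codons = gene.n_codons
        rpc = total / n_codons
        rpkm = (
            total / (gene.cds_len / 1000.0) / (lib_total / 1e6) if lib_total else 0.0
        )
        reason = ""
        if rpc < min_reads_per_codon:
            reason = f"reads_per_codon {rpc:.4g} < {min_reads_per_codon}"
        elif min_rpkm is not None and rpkm < min_rpkm:
            reason = f"rpkm {rpkm:.4g} < {min_rpkm}"
        rows.append(
            {
                "gene_id": gene.gene_id,
                "total": total,
                "reads_per_codon": rpc,
                "rpkm": rpkm,
                "kept": reason == "",
                "exclusion_reason": reason,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class MetageneProfile:
    offsets: np.ndarray  # transcript-orientation offsets from the anchor
    mean_density: np.ndarray
    n_genes: int
    anchor: str  # START | STOP
    normalization: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"offset": self.offsets, "mean_density": self.mean_density, "n_genes": self.n_genes}
        )


def metagene(
    track: DensityTrack,
    annotation,
    anchor: str = "START",
    offsets: tuple[int, int] = (-50, 100),
    min_gene_len: int = 1000,
    normalization: str = "mean",
) -> MetageneProfile:
    """Equal-weighted average 3'-end density around start or stop codons.

    ``offsets`` is the inclusive window [-L, +R] relative to the first
    nucleotide of the anchor codon.  Genes shorter than ``min_gene_len`` nt
    of CDS are excluded; each gene's window is divided by its own mean
    (``normalization='mean'``) before the unweighted average, or averaged
    raw (``'raw'``).
    """
    anchor = anchor.upper()
    if anchor not in ("START", "STOP"):
        raise ValueError("anchor must be START or STOP")
    if normalization not in ("mean", "raw"):
        raise ValueError("normalization must be 'mean' or 'raw'")
    lo, hi = offsets
    if hi < lo:
        raise ValueError("offset window is empty")
    rows = []
    for gene in annotation:
        if gene.cds_len < min_gene_len:
            continue
        a = 0 if anchor == "START" else gene.cds_len - 3
        try:
            v = track.gene_vector(gene, a + lo, a + hi + 1).astype(float)
        except IndexError:
            log.warning("%s: metagene window outside contig; skipped", gene.gene_id)
            continue
        if normalization == "mean":
            m = v.mean()
            if m == 0:
                continue
            v = v / m
        rows.append(v)
    if not rows:
        raise ValueError("no qualifying genes for metagene")
    mat = np.vstack(rows)
    return MetageneProfile(
        offsets=np.arange(lo, hi + 1),
        mean_density=mat.mean(axis=0),
        n_genes=mat.shape[0],
        anchor=anchor,
        normalization=normalization,
    )


def peak_offset(
    profile: MetageneProfile, search_window: tuple[int, int] | None = None
) -> int:
    """Offset of the maximum average density; ties resolve toward 5'."""
    lo, hi = search_window if search_window is not None else (
        int(profile.offsets[0]),
        int(profile.offsets[-1]),
    )
    mask = (profile.offsets >= lo) & (profile.offsets <= hi)
    if not mask.any():
        raise ValueError("empty search window")
    offs = profile.offsets[mask]
    vals = profile.mean_density[mask]
    best = int(offs[np.argmax(vals)])
    if (vals == vals.max()).sum() > 1:
        log.warning("peak_offset: tie in window [%d, %d]; reporting 5'-most", lo, hi)
    return best


def polarity_ratio(
    track: DensityTrack,
    annotation,
    head_codons: int = 100,
    tail_from_codon: int = 151,
    pseudocount: float = 0.5,
) -> tuple[pd.DataFrame, dict]:
    """Per-gene ratio of mean 3'-end density over the first ``head_codons``
    codons to the mean from ``tail_from_codon`` onward (a 5'-polarity
    score).  ``pseudocount`` reads are added to the tail to avoid division
    by zero.  Genes too short for both windows are skipped.
    """
    rows = []
    for gene in annotation:
        n_cod = gene.n_codons
        if n_cod < tail_from_codon + 10:
            log.info("%s: too short for polarity windows; skipped", gene.gene_id)
            continue
        v = track.gene_vector(gene).astype(float)
        head = v[: 3 * head_codons].sum() / (3 * head_codons)
        tail_nt = v[3 * (tail_from_codon - 1) :]
        tail = (tail_nt.sum() + pseudocount) / tail_nt.size
        rows.append({"gene_id": gene.gene_id, "head": head, "tail": tail, "ratio": head / tail})
    df = pd.DataFrame(rows)
    summary = {
        "n_genes": len(df),
        "mean_ratio": float(df["ratio"].mean()) if len(df) else float("nan"),
        "median_ratio": float(df["ratio"].median()) if len(df) else float("nan"),
    }
    return df, summary
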