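"""Nuclease digestion of ribosome snapshots and read emission.

Each ribosome in a snapshot defines one candidate footprint.  The 3' end
comes from RelE geometry (cut after the 2nd nt of the A-site codon; after
the 3rd for NNC codons) in a RelE library, or from the MNase boundary (+12
from the A-site codon first nt) otherwise; ribosomes with a stably occupied
A site block RelE and fall back to MNase geometry.  The 5' end is always
MNase-trimmed at the ribosome's upstream boundary.  RelE's preference for C
at -1 and G at +1 of the cut enters as a multiplicative cleavage-propensity
weight: the emitted library is a resample (with replacement) of candidate
footprints proportional to this weight, mimicking sequencing from a
fragment pool whose abundances reflect cleavage efficiency.  Cut positions
themselves are never moved by the preference, so A-site geometry stays
exact.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .dynamics import RibosomeSnapshot
from .nucleases import MNaseModel, RelEModel
from .transcriptome import SyntheticTranscriptome

_AT = frozenset("AT")
_GC = frozenset("GC")


@dataclass
class FootprintRecord:
    """One aligned footprint; ends are genomic, 0-based, inclusive, with
    ``five_prime``/``three_prime`` in transcript orientation (on '-' strand
    the 3' end has the smaller genomic coordinate)."""

    contig: str
    strand: str
    five_prime: int
    three_prime: int
    nuclease: str  # tag of the 3'-end-generating enzyme: MNASE | RELE | RNASEQ
    gene_id: str
    asite_nt: int | None = None  # truth: CDS offset of the A-site codon first nt
    truncated: bool = False

    @property
    def length(self) -> int:
        return abs(self.three_prime - self.five_prime) + 1

    @property
    def start(self) -> int:
        """Leftmost genomic coordinate (0-based)."""
        return min(self.five_prime, self.three_prime)

    @property
    def end(self) -> int:
        """Exclusive rightmost genomic coordinate."""
        return max(self.five_prime, self.three_prime) + 1


def _mnase_cut(
    tx: SyntheticTranscriptome,
    gene,
    geometric: int,
    model: MNaseModel,
    rng: np.random.Generator,
    lo: int,
    hi: int,
) -> tuple[int, bool]:
    """Realised MNase cut: offset ``e`` such that the cut sits between
    transcript offsets ``e`` and ``e+1``, plus a flag marking clipping at a
    transcript/fragment boundary.  With probability ``p_cut_before_AT`` the
    base at ``e+1`` is A/T, otherwise C/G, choosing the candidate nearest
    the geometric boundary (ties toward 5')."""
    e = geometric
    if model.boundary_jitter_sd > 0:
        e += int(round(rng.normal(0.0, model.boundary_jitter_sd)))
    clipped = e < lo or e > hi
    e = max(lo, min(hi, e))
    if model.p_cut_before_AT is None:
        return e, clipped
    want = _AT if rng.random() < model.p_cut_before_AT else _GC
    for d in range(model.max_reposition + 1):
        for cand in ((e - d, e + d) if d else (e,)):
            if lo <= cand <= hi and tx.transcript_nt(gene, cand + 1) in want:
                return cand, clipped
    return e, clipped


def digest(
    snapshots: list[RibosomeSnapshot],
    tx: SyntheticTranscriptome,
    rele: RelEModel | None = None,
    mnase: MNaseModel | None = None,
    rng: np.random.Generator | int | None = None,
    n_reads: int | None = None,
) -> list[FootprintRecord]:
    """Digest the ribosomes in ``snapshots`` into a footprint library.

    ``rele=None`` gives an MNase-only library (3' ends at the ribosome
    boundary); otherwise 3' ends come from RelE except where the A site is
    occupied.  For a RelE library the returned records are a weighted
    resample (with replacement, size ``n_reads`` or the ribosome count) of
    the candidates, weight = sequence-context cleavage propensity.
    Footprints reaching past the transcript (or past an in vivo cleavage
    truncation) are clipped and flagged.
    """
    if mnase is None:
        mnase = MNaseModel()
    rng = np.random.default_rng(rng)
    out: list[FootprintRecord] = []
    weights: list[float] = []
    for snap in snapshots:
        gene = tx.gene(snap.gene_id)
        t_lo, t_hi = tx.transcript_bounds(gene)
        avail_end = (
            t_hi - 1
            if snap.truncation_nt is None
            else snap.truncation_nt - 1
        )
        for rib in snap.ribosomes:
            a = rib.asite_nt
            rib_avail = avail_end if a <= avail_end else t_hi - 1
            truncated = False
            use_rele = rele is not None and not (
                rib.a_site_occupied and rng.random() < rele.p_block_occupied
            )
            w = 1.0
            if use_rele:
                tag = "RELE"
                if rele.p_miscleave > 0 and rng.random() < rele.p_miscleave:
                    end = a + int(rng.integers(3))
                else:
                    codon = "".join(tx.transcript_nt(gene, a + k) for k in range(3))
                    if codon.endswith("C") and rng.random() < rele.p_nnc:
                        end = a + 2
                    else:
                        end = a + rele.delta_rele
                # cleavage propensity from the context at the fixed cut site
                if tx.transcript_nt(gene, end) == "C":
                    w *= rele.w_minus1_C
                if end + 1 < t_hi and tx.transcript_nt(gene, end + 1) == "G":
                    w *= rele.w_plus1_G
            else:
                tag = "MNASE"
                end, _ = _mnase_cut(
                    tx, gene, a + mnase.delta_mnase, mnase, rng, a, t_hi - 2
                )
            if end > rib_avail:
                end = rib_avail
                truncated = True
            cut5, clipped5 = _mnase_cut(
                tx, gene, a - mnase.five_prime_offset - 1, mnase, rng, t_lo - 1, a - 3
            )
            five = cut5 + 1
            truncated = truncated or clipped5
            if a > avail_end and snap.truncation_nt is not None:
                # ribosome on the released downstream fragment: the fragment
                # begins at the cleavage cut
                five = max(five, snap.truncation_nt)
            if end < five:
                continue
            out.append(
                FootprintRecord(
                    contig=gene.contig,
                    strand=gene.strand,
                    five_prime=tx.to_genomic(gene, five),
                    three_prime=tx.to_genomic(gene, end),
                    nuclease=tag,
                    gene_id=gene.gene_id,
                    asite_nt=a,
                    truncated=truncated,
                )
            )
            weights.append(w)
    if rele is None and n_reads is None:
        return out
    if not out:
        return out
    p = np.asarray(weights) / np.sum(weights)
    size = len(out) if n_reads is None else n_reads
    idx = rng.choice(len(out), size=size, replace=True, p=p)
    return [out[i] for i in idx]


def emit_reads(
    footprints: list[FootprintRecord],
    window: tuple[int, int],
    sam_path: str | Path,
    genome: dict[str, str],
    fastq_path: str | Path | None = None,
    drop_truncated: bool = False,
) -> int:
    """Write footprints inside the length ``window`` (inclusive) to SAM.

    Returns the number of records emitted.  Sequences are taken from the
    genome; reverse-strand reads are stored reverse-complemented with flag 16
    per the SAM convention.
    """
    import pysam

    from .transcriptome import revcomp

    wmin, wmax = window
    if wmin > wmax:
        raise ValueError("window min must be <= max")
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": name, "LN": len(seq)} for name, seq in genome.items()],
    }
    tids = {name: i for i, name in enumerate(genome)}
    n = 0
    fq = open(fastq_path, "w") if fastq_path is not None else None
    try:
        with pysam.AlignmentFile(str(sam_path), "w", header=header) as sam:
            for i, fp in enumerate(footprints):
                if not wmin <= fp.length <= wmax:
                    continue
                if drop_truncated and fp.truncated:
                    continue
                seq = genome[fp.contig][fp.start : fp.end]
                if fp.strand == "-":
                    seq = revcomp(seq)
                rec = pysam.AlignedSegment()
                rec.query_name = f"{fp.gene_id}.{fp.nuclease}.{i}"
                rec.query_sequence = seq
                rec.flag = 16 if fp.strand == "-" else 0
                rec.reference_id = tids[fp.contig]
                rec.reference_start = fp.start
                rec.mapping_quality = 42
                rec.cigarstring = f"{fp.length}M"
                rec.query_qualities = pysam.qualitystring_to_array("I" * fp.length)
                sam.write(rec)
                if fq is not None:
                    fq.write(f"@{rec.query_name}\n{seq}\n+\n{'I' * fp.length}\n")
                n += 1
    finally:
        if fq is not None:
            fq.close()
    return n


def write_truth_table(footprints: list[FootprintRecord], path: str | Path) -> None:
    """Per-read ground truth (true A-site offset and generating nuclease)."""
    import pandas as pd

    pd.DataFrame(
        {
            "gene_id": [f.gene_id for f in footprints],
            "asite_nt": [f.asite_nt for f in footprints],
            "asite_codon": [
                None if f.asite_nt is None else f.asite_nt // 3 + 1 for f in footprints
            ],
            "nuclease": [f.nuclease for f in footprints],
            "five_prime": [f.five_prime for f in footprints],
            "three_prime": [f.three_prime for f in footprints],
            "truncated": [f.truncated for f in footprints],
        }
    ).to_csv(path, sep="\t", index=False)


def simulate_rnaseq(
    tx: SyntheticTranscriptome,
    abundance: dict[str, float] | None = None,
    fragment_window: tuple[int, int] = (40, 60),
    n_reads: int = 10000,
    rng_seed: int | None = None,
) -> list[FootprintRecord]:
    """Uniform alkaline-hydrolysis RNA-seq fragments over transcripts.

    Fragment start positions are uniform over each transcript (UTRs
    included) and lengths uniform in ``fragment_window``; there is no
    sequence bias at either end.  Gene choice is proportional to
    ``abundance`` (uniform by default).
    """
    rng = np.random.default_rng(rng_seed)
    genes = tx.genes
    if abundance is None:
        w = np.ones(len(genes))
    else:
        w = np.array([abundance.get(g.gene_id, 0.0) for g in genes], dtype=float)
        if (w < 0).any():
            raise ValueError("abundances must be >= 0")
    if w.sum() <= 0:
        raise ValueError("all-zero abundances")
    p = w / w.sum()
    wmin, wmax = fragment_window
    gidx = rng.choice(len(genes), size=n_reads, p=p)
    lens = rng.integers(wmin, wmax + 1, size=n_reads)
    out: list[FootprintRecord] = []
    for gi, L in zip(gidx, lens):
        gene = genes[gi]
        t_lo, t_hi = tx.transcript_bounds(gene)
        if t_hi - t_lo < L:
            continue
        s = int(rng.integers(t_lo, t_hi - L + 1))
        out.append(
            FootprintRecord(
                contig=gene.contig,
                strand=gene.strand,
                five_prime=tx.to_genomic(gene, s),
                three_prime=tx.to_genomic(gene, s + int(L) - 1),
                nuclease="RNASEQ",
                gene_id=gene.gene_id,
            )
        )
    return out
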