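"""Nuclease sequence specificity from footprint 3' ends.

The base composition around the realised cut (positions -2..+2, where -1 is
the footprint's last nucleotide and +1 the first base past the cut) is
compared against a background composition to expose enzyme preference:
MNase cuts preferentially before A/T, RelE prefers C at -1 and G at +1.
The default background is the composition of the transcribed regions
weighted by per-gene read counts, since footprints sample expressed
sequence; a whole-genome background is available by flag.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .transcriptome import _COMPLEMENT, gene_cds_seq

log = logging.getLogger(__name__)

_BASES = ["A", "C", "G", "T"]


@dataclass
class EndBiasMatrix:
    """Base frequencies around footprint 3' ends with background enrichment."""

    frequencies: pd.DataFrame  # index: positions -flank..+flank (no 0); columns ACGT
    background: pd.Series
    enrichment: pd.DataFrame  # frequency / background; NaN where background is 0
    n_reads: int
    n_skipped: int


def _composition(seq_counter: Counter) -> pd.Series:
    total = sum(seq_counter[b] for b in _BASES)
    return pd.Series({b: seq_counter[b] / total if total else np.nan for b in _BASES})


def end_bias(
    reads,
    genome: dict[str, str],
    annotation=None,
    flank: int = 2,
    background: str = "coverage",
) -> EndBiasMatrix:
    """Base frequencies at positions -flank..+flank around read 3' ends.

    ``background='coverage'`` weights each gene's CDS composition by its
    read count (requires ``annotation``); ``'genome'`` uses the whole
    genome.  Reads whose context would run off the contig are skipped and
    counted.
    """
    positions = [p for p in range(-flank, flank + 1) if p != 0]
    freq = {p: Counter() for p in positions}
    gene_reads: Counter = Counter()
    n = n_skip = 0
    for r in reads:
        e = r.three_prime if hasattr(r, "three_prime") else (
            r.end - 1 if r.strand == "+" else r.start
        )
        seq = genome[r.contig]
        try:
            ctx = {}
            for p in positions:
                if r.strand == "+":
                    g = e + p + 1 if p < 0 else e + p
                    base = seq[g] if g >= 0 else None
                else:
                    g = e - (p + 1) if p < 0 else e - p
                    base = seq[g].translate(_COMPLEMENT) if g >= 0 else None
                if base is None:
                    raise IndexError
                ctx[p] = base
        except IndexError:
            n_skip += 1
            continue
        for p, base in ctx.items():
            freq[p][base] += 1
        gid = getattr(r, "gene_id", None)
        if gid is not None:
            gene_reads[gid] += 1
        n += 1

    if background == "genome":
        bg_counter = Counter()
        for seq in genome.values():
            bg_counter.update(seq)
    elif background == "coverage":
        if annotation is None:
            raise ValueError("coverage background requires an annotation")
        bg_counter = Counter()
        for gene in annotation:
            w = gene_reads.get(gene.gene_id, 1)
            comp = Counter(gene_cds_seq(genome, gene))
            for b in _BASES:
                bg_counter[b] += w * comp[b]
    else:
        raise ValueError("background must be 'coverage' or 'genome'")

    fdf = pd.DataFrame(
        {p: _composition(freq[p]) for p in positions}
    ).T.reindex(columns=_BASES)
    bg = _composition(bg_counter)
    enr = fdf.divide(bg.replace(0, np.nan), axis=1)
    if (bg == 0).any():
        log.warning("end_bias: background lacks some bases; enrichment flagged NaN")
    return EndBiasMatrix(
        frequencies=fdf, background=bg, enrichment=enr, n_reads=n, n_skipped=n_skip
    )


def orf_position_bias(genome: dict[str, str], annotation) -> pd.DataFrame:
    """Base frequencies at sub-codon positions 1/2/3 over all annotated CDS
    codons (rows: positions, columns: A/C/G/T; each row sums to 1)."""
    counters = [Counter(), Counter(), Counter()]
    for gene in annotation:
        seq = gene_cds_seq(genome, gene)
        for k in range(3):
            counters[k].update(seq[k::3])
    return pd.DataFrame(
        {f"position_{k + 1}": _composition(counters[k]) for k in range(3)}
    ).T.reindex(columns=_BASES)


def length_histogram(reads) -> tuple[pd.Series, float]:
    """Footprint-length histogram and median length."""
    lengths = [r.length if hasattr(r, "length") else r.end - r.start for r in reads]
    if not lengths:
        return pd.Series(dtype=np.int64, name="count"), float("nan")
    ser = pd.Series(Counter(lengths), name="count").sort_index()
    return ser, float(np.median(lengths))


def per_gene_correlation(
    track_a, track_b, annotation, min_reads: int = 10
) -> dict:
    """Correlation of per-gene 3'-end counts between two libraries.

    Genes must pass ``min_reads`` in both tracks.  Returns the Pearson
    correlation of log counts and the Spearman rank correlation.
    """
    rows = []
    for gene in annotation:
        a = int(track_a.gene_vector(gene).sum())
        b = int(track_b.gene_vector(gene).sum())
        if a >= min_reads and b >= min_reads:
            rows.append((a, b))
    if len(rows) < 3:
        raise ValueError("fewer than 3 genes pass min_reads in both libraries")
    arr = np.array(rows, dtype=float)
    r_log = float(stats.pearsonr(np.log(arr[:, 0]), np.log(arr[:, 1]))[0])
    r_rank = float(stats.spearmanr(arr[:, 0], arr[:, 1])[0])
    return {"n_genes": len(rows), "pearson_log": r_log, "spearman": r_rank}
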