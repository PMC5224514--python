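"""Operon-level 5' polarity: single transcription units, per-gene
treated/control density ratios binned by operon position, and a
Mann-Whitney rank-sum test for distribution differences.

A "single transcription unit" is a polycistronic operon whose genes show
uniform RNA-seq coverage (within a configurable fold range), so that
position within the operon — not promoter structure — explains any
systematic ribosome-density gradient.
"""

from __future__ import annotations

import logging
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

log = logging.getLogger(__name__)


def _per_nt_density(track, gene) -> float:
    return float(track.gene_vector(gene).sum()) / gene.cds_len


def define_single_TUs(
    annotation,
    rnaseq_track,
    ribo_track=None,
    max_fold: float = 5.0,
    min_rpkm: float = 1.0,
    stat: str = "mean",
) -> pd.DataFrame:
    """Filter to genes inside uniformly covered polycistronic operons.

    Monocistronic operons are dropped; an operon is dropped when the ratio
    of its highest to lowest per-gene RNA-seq density exceeds ``max_fold``
    (strictly); genes below ``min_rpkm`` in the RNA-seq (and, if supplied,
    Ribo-seq) library are dropped individually.  ``stat`` selects mean or
    median per-nt density for the fold test.
    """
    if stat not in ("mean", "median"):
        raise ValueError("stat must be 'mean' or 'median'")
    rna_total = rnaseq_track.total
    ribo_total = ribo_track.total if ribo_track is not None else None
    rows = []
    for op_id, grp in annotation.operons.groupby("operon_id", sort=True):
        if len(grp) < 2:
            continue  # monocistronic: excluded
        genes = [annotation.gene(g) for g in grp.sort_values("position")["gene_id"]]
        if stat == "mean":
            dens = [_per_nt_density(rnaseq_track, g) for g in genes]
        else:
            dens = [float(np.median(rnaseq_track.gene_vector(g))) for g in genes]
        if min(dens) <= 0 or max(dens) / min(dens) > max_fold:
            log.info("operon %s: RNA-seq density varies > %g-fold; excluded", op_id, max_fold)
            continue
        for g, pos in zip(genes, grp.sort_values("position")["position"]):
            rpkm_rna = (
                track_rpkm(rnaseq_track, g, rna_total) if rna_total else 0.0
            )
            if rpkm_rna < min_rpkm:
                continue
            if ribo_total:
                if track_rpkm(ribo_track, g, ribo_total) < min_rpkm:
                    continue
            rows.append({"gene_id": g.gene_id, "operon_id": op_id, "position": int(pos)})
    return pd.DataFrame(rows, columns=["gene_id", "operon_id", "position"])


def track_rpkm(track, gene, lib_total: int | None = None) -> float:
    total = lib_total if lib_total is not None else track.total
    if total == 0:
        return 0.0
    return float(track.gene_vector(gene).sum()) / (gene.cds_len / 1000.0) / (total / 1e6)


def position_ratios(
    treated_track,
    control_track,
    tu_genes: pd.DataFrame,
    annotation,
    max_bin: int = 5,
) -> pd.DataFrame:
    """Per-gene treated/control per-nt density ratios with operon-position
    bins (1, 2, ..., >= ``max_bin``).  Genes with zero control density are
    excluded with a log message."""
    rows = []
    for _, rec in tu_genes.iterrows():
        gene = annotation.gene(rec["gene_id"])
        num = _per_nt_density(treated_track, gene)
        den = _per_nt_density(control_track, gene)
        if den == 0:
            log.info("%s: zero control density; excluded from ratios", gene.gene_id)
            continue
        pos = int(rec["position"])
        rows.append(
            {
                "gene_id": gene.gene_id,
                "operon_id": rec["operon_id"],
                "position": pos,
                "bin": min(pos, max_bin),
                "ratio": num / den,
            }
        )
    return pd.DataFrame(rows, columns=["gene_id", "operon_id", "position", "bin", "ratio"])


def rank_sum_test(sample_a, sample_b, method: str = "auto") -> tuple[float, float]:
    """Two-sided Mann-Whitney rank-sum test.

    Returns ``(U, p)`` where U counts pairs (a, b) with a > b (midranks for
    ties).  Small samples (n_a + n_b <= 12) are handled by exact
    enumeration of all rank assignments; larger ones by the normal
    approximation with tie-corrected variance and continuity correction.
    ``method`` forces a branch ("exact" / "normal") for cross-validation.
    """
    if method not in ("auto", "exact", "normal"):
        raise ValueError("method must be auto, exact or normal")
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0

    if method == "exact" or (method == "auto" and n1 + n2 <= 12):
        n = n1 + n2
        us = np.array(
            [
                sum(ranks[list(idx)]) - n1 * (n1 + 1) / 2.0
                for idx in combinations(range(n), n1)
            ]
        )
        total = comb(n, n1)
        eps = 1e-9
        p_le = np.count_nonzero(us <= u_obs + eps) / total
        p_ge = np.count_nonzero(us >= u_obs - eps) / total
        return float(u_obs), float(min(1.0, 2.0 * min(p_le, p_ge)))

    mean_u = n1 * n2 / 2.0
    n = n1 + n2
    _, t = np.unique(pooled, return_counts=True)
    tie_term = (t**3 - t).sum() / (n * (n - 1))
    var_u = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if var_u <= 0:
        return float(u_obs), 1.0
    diff = u_obs - mean_u
    cc = 0.5 if diff != 0 else 0.0
    z = (diff - np.sign(diff) * cc) / np.sqrt(var_u)
    return float(u_obs), float(min(1.0, 2.0 * norm.sf(abs(z))))
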