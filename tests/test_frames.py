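"""Sub-codon frame readout, NNC shift, A-site inversion, frameshift scan."""

import numpy as np
import pytest

import relprof as rp
from relprof.frames import asite_codon_from_3prime
from relprof.transcriptome import SENSE_CODONS


def _track(tx):
    return rp.DensityTrack({c: len(s) for c, s in tx.genome.items()})


def nnc_fraction_of_elongating_codons(tx, genes):
    n = nnc = 0
    for g in genes:
        seq = tx.cds_seq(g)
        for k in range(2, g.n_codons - 2):
            n += 1
            nnc += seq[3 * k + 2] == "C"
    return nnc / n


def test_subcodon_mapping_trivial_case(tx):
    g = rp.GeneModel("t", "synChr", "+", 300, 1500, None, None)
    track = _track(tx)
    for k in range(20, 40):
        track.add_end("synChr", "+", 300 + 3 * k + 1)  # 2nd nt of each codon
    fs = rp.subcodon_fractions(track, rp.AnnotationSet(genes=[g]))
    assert fs.as_tuple() == (0.0, 1.0, 0.0)
    assert fs.n_reads == 20


def test_end_exclusion_window(tx):
    g = rp.GeneModel("t", "synChr", "+", 300, 1500, None, None)
    track = _track(tx)
    track.add_end("synChr", "+", 300 + 10)  # within the first 30 nt: excluded
    track.add_end("synChr", "+", 300 + g.cds_len - 5)  # final 30 nt: excluded
    track.add_end("synChr", "+", 300 + 61)
    fs = rp.subcodon_fractions(track, rp.AnnotationSet(genes=[g]), exclude_end_nt=30)
    assert fs.n_reads == 1
    fs0 = rp.subcodon_fractions(track, rp.AnnotationSet(genes=[g]), exclude_end_nt=0)
    assert fs0.n_reads == 3


def test_rele_library_frame_signal_and_nnc_closed_form(tx, plain_genes):
    """With p_nnc=1 and neutral context weights, f2 > f3 > f1 and f3 equals
    the NNC fraction among decoded codons (closed form from codon usage)."""
    snaps = rp.place_ribosomes(
        tx, n_per_gene=2000, rng=13, genes=[g.gene_id for g in plain_genes]
    )
    rele = rp.RelEModel(p_nnc=1.0, w_minus1_C=1.0, w_plus1_G=1.0)
    fp = rp.digest(snaps, tx, rele=rele, mnase=rp.MNaseModel(), rng=14)
    track = rp.assign_3prime_density(fp, tx.genome)
    fs = rp.subcodon_fractions(track, plain_genes)
    assert fs.f2 > fs.f3 > fs.f1
    expected = nnc_fraction_of_elongating_codons(tx, plain_genes)
    se = np.sqrt(expected * (1 - expected) / fs.n_reads)
    assert abs(fs.f3 - expected) < 4 * se + 0.01


def test_utr3_reads_show_no_frame(tx, ann):
    reads = rp.simulate_rnaseq(tx, n_reads=60000, rng_seed=15)
    track = rp.assign_3prime_density(reads, tx.genome)
    fs = rp.subcodon_fractions(track, ann, region="UTR3")
    assert fs.n_reads > 1000
    assert max(fs.as_tuple()) - min(fs.as_tuple()) < 0.05


def test_asite_inversion_examples():
    seq = "ATG" + "GAT" * 20 + "TAA"  # no NNC codons
    assert asite_codon_from_3prime(4, seq, "RELE") == (2, "ok")
    # MNase end 12 nt downstream of the stop codon's first nt -> stop in A site
    stop_first = len(seq) - 3
    idx, flag = asite_codon_from_3prime(stop_first + 12, seq, "MNASE")
    assert (idx, flag) == (len(seq) // 3, "ok")
    # position-3 end on a non-C-ending codon is ambiguous
    assert asite_codon_from_3prime(5, seq, "RELE") == (None, "ambiguous")
    assert asite_codon_from_3prime(-1, seq, "RELE") == (None, "out_of_range")
    seq_c = "ATG" + "GAC" * 20 + "TAA"
    assert asite_codon_from_3prime(5, seq_c, "RELE") == (2, "ok")


def test_asite_inversion_matches_truth_table(tx, plain_genes):
    """Geometry inversion recovers the true A-site codon for every
    unambiguous RelE read (jitter 0) and every MNase read."""
    snaps = rp.place_ribosomes(
        tx, n_per_gene=300, rng=16, genes=[g.gene_id for g in plain_genes]
    )
    mn = rp.MNaseModel(p_cut_before_AT=None)
    for rele, lib in ((rp.RelEModel(), "RELE"), (None, "MNASE")):
        fps = rp.digest(snaps, tx, rele=rele, mnase=mn, rng=17)
        checked = 0
        for f in fps:
            if f.nuclease != lib or f.truncated:
                continue
            gene = tx.gene(f.gene_id)
            end_t = tx.to_transcript(gene, f.three_prime)
            idx, flag = asite_codon_from_3prime(end_t, tx.cds_seq(gene), lib)
            if flag == "ok":
                assert idx == f.asite_nt // 3 + 1
                checked += 1
        assert checked > 1000


def test_nnc_shift_worked_examples_and_conservation(tx):
    # gene with a known NNC codon: ATG GAC ... -> codon 2 = GAC
    target = None
    for g in tx.genes:
        seq = tx.cds_seq(g)
        for k in range(2, g.n_codons - 1):
            if seq[3 * k + 2] == "C":
                target = (g, k)
                break
        if target:
            break
    g, k = target
    ann1 = rp.AnnotationSet(genes=[g])
    track = _track(tx)
    p3 = 3 * k + 2
    for t, n in ((p3, 5),):
        track.add_end("synChr", g.strand, tx.to_genomic(g, t), n=n)
    shifted = rp.nnc_shift(track, ann1, tx.genome)
    v = shifted.gene_vector(g)
    assert v[3 * k + 1] == 5 and v[3 * k + 2] == 0
    assert shifted.total == track.total
    # non-NNC codon untouched
    g2 = g
    seq = tx.cds_seq(g2)
    k2 = next(k for k in range(2, g2.n_codons - 1) if seq[3 * k + 2] != "C")
    track2 = _track(tx)
    track2.add_end("synChr", g2.strand, tx.to_genomic(g2, 3 * k2 + 2), n=5)
    shifted2 = rp.nnc_shift(track2, ann1, tx.genome)
    assert np.array_equal(shifted2.gene_vector(g2), track2.gene_vector(g2))


def test_nnc_shift_conserves_and_never_decreases_f2(tx, plain_genes, rele_track):
    shifted = rp.nnc_shift(rele_track, plain_genes, tx.genome)
    assert shifted.total == rele_track.total
    before = rp.subcodon_fractions(rele_track, plain_genes)
    after = rp.subcodon_fractions(shifted, plain_genes)
    assert after.f2 >= before.f2


def test_f2_recovery_under_uniform_miscleavage(tx, plain_genes):
    """With 10% uniform mis-cleavage and p_nnc=1, the NNC shift restores
    f2 = 0.9 + 0.1/3 + (0.1/3)q, with q the NNC codon fraction (mis-cleaved
    position-3 ends on NNC codons are shifted too)."""
    snaps = rp.place_ribosomes(
        tx, n_per_gene=2500, rng=18, genes=[g.gene_id for g in plain_genes]
    )
    rele = rp.RelEModel(p_nnc=1.0, p_miscleave=0.1, w_minus1_C=1.0, w_plus1_G=1.0)
    fp = rp.digest(snaps, tx, rele=rele, mnase=rp.MNaseModel(), rng=19)
    track = rp.assign_3prime_density(fp, tx.genome)
    shifted = rp.nnc_shift(track, plain_genes, tx.genome)
    fs = rp.subcodon_fractions(shifted, plain_genes)
    q = nnc_fraction_of_elongating_codons(tx, plain_genes)
    expected = 0.9 + 0.1 / 3 + 0.1 / 3 * q
    se = np.sqrt(expected * (1 - expected) / fs.n_reads)
    assert abs(fs.f2 - expected) < 3 * se + 0.01


def test_codon_heatmap_nnc_pattern(tx, plain_genes, rele_track):
    heat = rp.codon_heatmap(rele_track, plain_genes, tx.genome)
    argmax = heat.fractions.idxmax(axis=1)
    for codon in SENSE_CODONS:
        if codon in heat.zero_rows:
            continue
        if heat.counts.loc[codon].sum() < 50:
            continue
        assert argmax[codon] == (3 if codon.endswith("C") else 2)


def test_codon_heatmap_p_nnc_zero_all_position_two(tx, plain_genes):
    snaps = rp.place_ribosomes(
        tx, n_per_gene=500, rng=20, genes=[g.gene_id for g in plain_genes]
    )
    fp = rp.digest(snaps, tx, rele=rp.RelEModel(p_nnc=0.0), mnase=rp.MNaseModel(), rng=21)
    track = rp.assign_3prime_density(fp, tx.genome)
    heat = rp.codon_heatmap(track, plain_genes, tx.genome)
    argmax = heat.fractions.idxmax(axis=1)
    for codon in SENSE_CODONS:
        if codon not in heat.zero_rows and heat.counts.loc[codon].sum() >= 30:
            assert argmax[codon] == 2


def _frameshift_track(tx, ann, gene, n_ribosomes, seed):
    snaps = rp.place_ribosomes(tx, n_per_gene=n_ribosomes, rng=seed, genes=[gene.gene_id])
    fp = rp.digest(
        snaps, tx, rele=rp.RelEModel(), mnase=rp.MNaseModel(), rng=seed + 10_000
    )
    track = rp.assign_3prime_density(fp, tx.genome)
    return rp.nnc_shift(track, ann, tx.genome)


def test_frameshift_scan_recovers_plus_one_at_codon_28(tx, ann):
    gene = next(g for g in tx.genes if g.frameshift is not None)
    hits = 0
    for seed in range(10):
        shifted = _frameshift_track(tx, ann, gene, 500, seed)
        call = rp.frameshift_scan(shifted, gene, tx.genome)
        assert call is not None
        if abs(call.codon_index - 28) <= 1 and call.direction == 1:
            hits += 1
    assert hits >= 9


def test_frameshift_scan_minus_one_direction(tx):
    fs = rp.FrameshiftSpec(codon_index=40, direction=-1)
    tx2 = rp.generate_transcriptome(n_genes=3, rng_seed=9, frameshift_spec=fs)
    ann2 = rp.AnnotationSet(genes=tx2.genes)
    gene = next(g for g in tx2.genes if g.frameshift is not None)
    hits = 0
    for seed in range(10):
        snaps = rp.place_ribosomes(tx2, n_per_gene=500, rng=seed, genes=[gene.gene_id])
        fp = rp.digest(snaps, tx2, rele=rp.RelEModel(), mnase=rp.MNaseModel(), rng=seed)
        shifted = rp.nnc_shift(rp.assign_3prime_density(fp, tx2.genome), ann2, tx2.genome)
        call = rp.frameshift_scan(shifted, gene, tx2.genome)
        if call and abs(call.codon_index - 40) <= 1 and call.direction == -1:
            hits += 1
    assert hits >= 9


def test_frameshift_scan_silent_on_no_shift_gene_and_low_coverage(tx, ann, plain_genes):
    gene = list(plain_genes)[0]
    shifted = _frameshift_track(tx, ann, gene, 500, 3)
    assert rp.frameshift_scan(shifted, gene, tx.genome) is None
    sparse = _frameshift_track(tx, ann, gene, 10, 4)
    assert rp.frameshift_scan(sparse, gene, tx.genome, min_reads=50) is None
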