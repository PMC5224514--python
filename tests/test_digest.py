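"""Cut-site geometry, occupied-A-site blocking, read emission and RNA-seq."""

import numpy as np
import pysam
import pytest

import relprof as rp
from relprof.dynamics import Ribosome, RibosomeSnapshot


def _single(tx, gene, asite_nt, occupied=False):
    return [
        RibosomeSnapshot(
            gene_id=gene.gene_id,
            ribosomes=[Ribosome(asite_nt=asite_nt, a_site_occupied=occupied)],
        )
    ]


@pytest.fixture(scope="module")
def plus_gene(tx):
    return next(g for g in tx.genes if g.strand == "+" and g.frameshift is None)


def _end_offset(tx, gene, fp):
    return tx.to_transcript(gene, fp.three_prime)


def test_initiating_ribosome_rele_end_at_plus4(tx, plus_gene):
    """Initiation complex: codon 2 in the A site; RelE cuts after its 2nd nt,
    4 nt downstream of the start codon's first nt (offset 4, 0-based)."""
    snaps = _single(tx, plus_gene, 3)
    fp = rp.digest(snaps, tx, rele=rp.RelEModel(p_nnc=0.0), mnase=rp.MNaseModel(), rng=0)
    assert len(fp) == 1 and fp[0].nuclease == "RELE"
    assert _end_offset(tx, plus_gene, fp[0]) == 4


def test_initiating_ribosome_mnase_end_at_plus15(tx, plus_gene):
    mn = rp.MNaseModel(p_cut_before_AT=None, boundary_jitter_sd=0.0)
    fp = rp.digest(_single(tx, plus_gene, 3), tx, rele=None, mnase=mn, rng=0)
    assert _end_offset(tx, plus_gene, fp[0]) == 15


def test_terminating_ribosome_mnase_end_at_stop_plus12(tx, plus_gene):
    mn = rp.MNaseModel(p_cut_before_AT=None)
    a = plus_gene.cds_len - 3  # stop codon in the A site
    fp = rp.digest(_single(tx, plus_gene, a), tx, rele=None, mnase=mn, rng=0)
    assert _end_offset(tx, plus_gene, fp[0]) - (plus_gene.cds_len - 3) == 12


def test_nnc_codon_cut_after_third_nt(tx):
    """An A-site codon ending in C is cut after its 3rd nt when p_nnc = 1."""
    for gene in tx.genes:
        if gene.frameshift is not None:
            continue
        seq = tx.cds_seq(gene)
        for k in range(2, gene.n_codons - 2):
            if seq[3 * k : 3 * k + 3].endswith("C"):
                fp = rp.digest(
                    _single(tx, gene, 3 * k), tx,
                    rele=rp.RelEModel(p_nnc=1.0), mnase=rp.MNaseModel(), rng=0,
                )
                assert _end_offset(tx, gene, fp[0]) == 3 * k + 2
                return
    pytest.skip("no NNC codon found")


def test_occupied_a_site_blocks_rele_and_falls_back_to_mnase(tx, plus_gene):
    mn = rp.MNaseModel(p_cut_before_AT=None)
    fp = rp.digest(
        _single(tx, plus_gene, 60, occupied=True), tx,
        rele=rp.RelEModel(p_block_occupied=1.0), mnase=mn, rng=0,
    )
    assert fp[0].nuclease == "MNASE"
    assert _end_offset(tx, plus_gene, fp[0]) == 60 + 12


def test_geometry_closure_both_strands(tx, snapshots):
    """With jitter 0, no sequence repositioning and default deltas, every
    MNase 3' end sits at A-site+12 and every non-NNC RelE end at A-site+1,
    in transcript coordinates on either strand."""
    mn = rp.MNaseModel(p_cut_before_AT=None, boundary_jitter_sd=0.0)
    fp_m = rp.digest(snapshots, tx, rele=None, mnase=mn, rng=1)
    for f in fp_m:
        gene = tx.gene(f.gene_id)
        if not f.truncated:
            assert tx.to_transcript(gene, f.three_prime) - f.asite_nt == 12
    fp_r = rp.digest(snapshots, tx, rele=rp.RelEModel(p_nnc=0.0), mnase=mn, rng=2)
    for f in fp_r:
        if f.nuclease != "RELE":
            continue
        gene = tx.gene(f.gene_id)
        assert tx.to_transcript(gene, f.three_prime) - f.asite_nt == 1


def test_generalized_deltas_shift_ends_accordingly(tx, plus_gene):
    for delta in (2, 5):
        fp = rp.digest(
            _single(tx, plus_gene, 30), tx,
            rele=rp.RelEModel(delta_rele=delta, p_nnc=0.0), mnase=rp.MNaseModel(), rng=0,
        )
        assert _end_offset(tx, plus_gene, fp[0]) == 30 + delta
    for delta in (9, 14):
        fp = rp.digest(
            _single(tx, plus_gene, 30), tx,
            rele=None, mnase=rp.MNaseModel(delta_mnase=delta, p_cut_before_AT=None),
            rng=0,
        )
        assert _end_offset(tx, plus_gene, fp[0]) == 30 + delta


def test_footprint_near_cut_is_truncated_and_flagged(tx, plus_gene):
    snap = RibosomeSnapshot(
        gene_id=plus_gene.gene_id,
        ribosomes=[Ribosome(asite_nt=30, stalled=True)],
        truncation_nt=32,  # mRNA cut just past the A-site codon's 2nd nt
    )
    mn = rp.MNaseModel(p_cut_before_AT=None)
    fp = rp.digest([snap], tx, rele=None, mnase=mn, rng=0)
    assert fp[0].truncated
    assert tx.to_transcript(plus_gene, fp[0].three_prime) == 31


def test_rele_footprints_shorter_than_mnase_by_delta_difference(tx, snapshots):
    mn = rp.MNaseModel(p_cut_before_AT=None)
    fp_r = rp.digest(snapshots, tx, rele=rp.RelEModel(p_nnc=0.0), mnase=mn, rng=3)
    fp_m = rp.digest(snapshots, tx, rele=None, mnase=mn, rng=4)
    _, med_r = rp.length_histogram([f for f in fp_r if f.nuclease == "RELE"])
    _, med_m = rp.length_histogram(fp_m)
    assert med_m - med_r == 11  # delta_mnase - delta_rele


def test_emit_reads_window_boundaries(tx, tmp_path):
    gene = tx.genes[0]
    fps = []
    for L in (9, 10, 40, 41):
        t5 = 50
        fps.append(
            rp.FootprintRecord(
                contig=gene.contig,
                strand="+",
                five_prime=t5,
                three_prime=t5 + L - 1,
                nuclease="RELE",
                gene_id=gene.gene_id,
            )
        )
    sam = tmp_path / "w.sam"
    assert rp.emit_reads(fps, (10, 40), sam, tx.genome) == 2


def test_emit_reads_empty_and_reverse_conventions(tx, tmp_path):
    sam = tmp_path / "e.sam"
    assert rp.emit_reads([], (10, 40), sam, tx.genome) == 0
    with pysam.AlignmentFile(str(sam), check_sq=False) as fh:
        assert list(fh) == []
    rev = rp.FootprintRecord(
        contig=tx.genes[0].contig, strand="-",
        five_prime=129, three_prime=100,  # 3' end genomically leftmost
        nuclease="MNASE", gene_id=tx.genes[0].gene_id,
    )
    sam2 = tmp_path / "r.sam"
    rp.emit_reads([rev], (10, 40), sam2, tx.genome)
    with pysam.AlignmentFile(str(sam2)) as fh:
        rec = next(iter(fh))
    assert rec.flag == 16
    assert rec.reference_start == 100
    assert rec.reference_end == 130


def test_emit_reads_deterministic(tx, rele_footprints, tmp_path):
    p1, p2 = tmp_path / "a.sam", tmp_path / "b.sam"
    rp.emit_reads(rele_footprints, (10, 40), p1, tx.genome)
    rp.emit_reads(rele_footprints, (10, 40), p2, tx.genome)
    assert p1.read_bytes() == p2.read_bytes()


def test_rnaseq_coverage_flat_and_unbiased(tx, ann):
    reads = rp.simulate_rnaseq(tx, n_reads=60000, rng_seed=7)
    track = rp.assign_3prime_density(reads, tx.genome)
    gene = tx.genes[0]
    v = track.gene_vector(gene).astype(float)
    # 3'-end coverage is flat over the CDS interior (30-nt bins beat shot noise)
    inner = v[60 : 60 + 30 * ((v.size - 120) // 30)]
    binned = inner.reshape(-1, 30).sum(axis=1)
    assert binned.std() / binned.mean() < 0.3
    bias = rp.end_bias(reads, tx.genome, ann)
    assert np.nanmax(np.abs(bias.enrichment.values - 1)) < 0.08


def test_rnaseq_determinism_and_zero_abundance_error(tx):
    r1 = rp.simulate_rnaseq(tx, n_reads=500, rng_seed=3)
    r2 = rp.simulate_rnaseq(tx, n_reads=500, rng_seed=3)
    assert [(f.five_prime, f.three_prime) for f in r1] == [
        (f.five_prime, f.three_prime) for f in r2
    ]
    with pytest.raises(ValueError):
        rp.simulate_rnaseq(tx, abundance={g.gene_id: 0.0 for g in tx.genes})
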