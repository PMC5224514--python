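import numpy as np
import pandas as pd
import pytest

import relprof as rp


def operon_table(tx) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"operon_id": f"op{i + 1:03d}", "gene_id": gid, "position": p + 1}
            for i, op in enumerate(tx.operons)
            for p, gid in enumerate(op)
        ]
    )


@pytest.fixture(scope="session")
def tx():
    """Mid-sized transcriptome with a prfB-like +1 frameshift gene (the last)."""
    return rp.generate_transcriptome(
        n_genes=20, rng_seed=2, frameshift_spec=rp.FrameshiftSpec(codon_index=28)
    )


@pytest.fixture(scope="session")
def ann(tx):
    return rp.AnnotationSet(genes=tx.genes, operons=operon_table(tx))


@pytest.fixture(scope="session")
def plain_genes(tx, ann):
    """Annotation restricted to the genes without a frameshift."""
    return rp.AnnotationSet(genes=[g for g in tx.genes if g.frameshift is None])


@pytest.fixture(scope="session")
def snapshots(tx):
    """Static occupancy with initiation and termination complexes."""
    return rp.place_ribosomes(
        tx, n_per_gene=400, f_initiation=0.2, f_termination=0.1, rng=3
    )


@pytest.fixture(scope="session")
def rele_footprints(tx, snapshots):
    return rp.digest(snapshots, tx, rele=rp.RelEModel(), mnase=rp.MNaseModel(), rng=4)


@pytest.fixture(scope="session")
def mnase_footprints(tx, snapshots):
    return rp.digest(snapshots, tx, rele=None, mnase=rp.MNaseModel(), rng=5)


@pytest.fixture(scope="session")
def rele_track(tx, rele_footprints):
    return rp.assign_3prime_density(rele_footprints, tx.genome, label="rele")


@pytest.fixture(scope="session")
def mnase_track(tx, mnase_footprints):
    return rp.assign_3prime_density(mnase_footprints, tx.genome, label="mnase")
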