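import numpy as np
import pytest

import mirword as mw


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def reporter_oligos():
    """The two bundled PDGFRA 3'UTR reporter oligonucleotides."""
    return mw.read_fasta(mw.PDGFRA_REPORTER_FASTA)


@pytest.fixture(scope="session")
def small_planted_fixture():
    """A small planted-motif dataset reused across enrichment tests:
    300 UTRs, 20% carriers of CACTGCC, triplicate expression with a
    1-log-unit carrier down-shift."""
    rng = np.random.default_rng(7)
    utrs, carriers = mw.generate_utrs(
        G=300, length_range=(100, 300), f=0.2, rng=rng
    )
    matrix, design = mw.generate_overexpression(
        carriers, delta=1.0, sigma=1.0,
        gene_ids=[u.gene_id for u in utrs], rng=rng,
    )
    result = mw.fit_moderated_t(mw.normalize(matrix), design)
    ranked = mw.rank_genes(result)
    return dict(
        utrs=utrs, carriers=carriers, matrix=matrix, design=design,
        result=result, ranked=ranked,
    )


def random_dna(rng, length, p=(0.25, 0.25, 0.25, 0.25)):
    return "".join(rng.choice(list("ACGT"), size=length, p=p))
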