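import numpy as np
import pytest

import rumiphage as rp


@pytest.fixture(scope="session")
def small_catalog():
    """5 planted species x 3 members at 2% within / ~75% between divergence."""
    return rp.simulate_catalog(
        n_species=5,
        members_per_species=3,
        genome_len=(1000, 2000),
        within_div=0.02,
        between_div=0.25,
        seed=42,
    )


@pytest.fixture(scope="session")
def mag_community(small_catalog):
    genomes, _, _ = small_catalog
    mags, planted, genus_table = rp.simulate_mag_set(genomes, n_mags=6, seed=7)
    return genomes, mags, planted, genus_table


@pytest.fixture
def rng():
    return np.random.default_rng(123)


def make_hit(
    query_id="q",
    subject_id="s",
    pct_identity=95.0,
    aln_length=1000,
    q_start=1,
    q_end=1000,
    s_start=1,
    s_end=1000,
    mismatches=0,
    gap_opens=0,
    evalue=1e-30,
    bitscore=500.0,
):
    """AlignmentHit factory with benign defaults for filter/interval tests."""
    return rp.AlignmentHit(
        query_id=query_id,
        subject_id=subject_id,
        pct_identity=pct_identity,
        aln_length=aln_length,
        mismatches=mismatches,
        gap_opens=gap_opens,
        q_start=q_start,
        q_end=q_end,
        s_start=s_start,
        s_end=s_end,
        evalue=evalue,
        bitscore=bitscore,
    )
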