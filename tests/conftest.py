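import pytest

import mhcdoc as m


@pytest.fixture(scope="session")
def pool():
    """The study-scale pool: 21 classical + 4 co-amplified non-classical
    alleles, classical alleles at least 3 substitutions apart."""
    return m.make_allele_pool(21, 4, min_pairwise_substitutions=3, seed=1)


@pytest.fixture(scope="session")
def nonclassical_ids(pool):
    return [a.id for a in pool.nonclassical]


def amplicon_study(pool, genotypes, platform, seed, profile=None):
    """Simulate -> tally -> singleton/length filter -> correct -> genotype,
    at the amplicon level (no file emission)."""
    from mhcdoc.preprocess import (
        drop_singletons,
        length_filter,
        table_from_simulated,
    )

    profile = profile or m.ErrorProfile.default(platform)
    design = m.make_run_design(sorted(genotypes), platform, seed)
    amplicons = m.simulate_run(design, pool, genotypes, profile)
    table = length_filter(drop_singletons(table_from_simulated(amplicons, platform)))
    corrected, decisions = m.correct_table(table)
    calls, profiles = m.genotype_table(corrected)
    return amplicons, table, corrected, decisions, calls


def truth_sequences(pool, genotype):
    return frozenset(pool[i].sequence for i in genotype)
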