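import pytest

from degoverlap import (
    ExperimentSpec, SharedBlock, SimulationDesign, make_universe,
)


@pytest.fixture(scope="session")
def small_universe():
    return make_universe(1000, seed=0)


@pytest.fixture(scope="session")
def tiny_universe():
    return make_universe(10, seed=0)


def paper_pair_design(seed=0):
    """Two experiments at the study's reported scale with concordant planted
    cores (61 over/over, 53 under/under) and no discordant core."""
    return SimulationDesign(
        N=20_000,
        experiments=(
            ExperimentSpec("pmliv", n_over=1687, n_under=1027),
            ExperimentSpec("sifoxm1", n_over=800, n_under=900),
        ),
        shared_blocks=(
            SharedBlock(("pmliv", "sifoxm1"), ("over", "over"), 61),
            SharedBlock(("pmliv", "sifoxm1"), ("under", "under"), 53),
        ),
        seed=seed,
    )


def paper_triple_design(seed=0):
    """Three experiments with pairwise and triple planted cores sized like
    the study's reported double (61/53, 367/388) and triple (23/28)
    overlaps; 18 dual-direction genes on the third experiment."""
    return SimulationDesign(
        N=20_000,
        experiments=(
            ExperimentSpec("pmliv", n_over=1687, n_under=1027),
            ExperimentSpec("sifoxm1", n_over=800, n_under=900),
            ExperimentSpec("foxo3", n_over=1200, n_under=1400),
        ),
        shared_blocks=(
            # triple cores (subsets of both pairwise overlaps)
            SharedBlock(("pmliv", "sifoxm1", "foxo3"), ("over",) * 3, 23),
            SharedBlock(("pmliv", "sifoxm1", "foxo3"), ("under",) * 3, 28),
            # pairwise-only remainders: 61-23, 53-28, 367-23, 388-28
            SharedBlock(("pmliv", "sifoxm1"), ("over", "over"), 38),
            SharedBlock(("pmliv", "sifoxm1"), ("under", "under"), 25),
            SharedBlock(("pmliv", "foxo3"), ("over", "over"), 344),
            SharedBlock(("pmliv", "foxo3"), ("under", "under"), 360),
        ),
        dual_direction_count=18,
        dual_direction_experiment="foxo3",
        seed=seed,
    )


@pytest.fixture(scope="session")
def pair_design():
    return paper_pair_design()


@pytest.fixture(scope="session")
def triple_design():
    return paper_triple_design()
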