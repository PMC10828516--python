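import pytest

from epihybrid.simulate import (
    MarkerMapSpec,
    default_planted_qtl,
    simulate_epiril_pedigree,
    simulate_marker_map,
    simulate_regions,
    simulate_trio_methylomes,
)


@pytest.fixture(scope="session")
def skeleton():
    """Default 144-marker, 5-chromosome map skeleton."""
    return simulate_marker_map(MarkerMapSpec())


@pytest.fixture(scope="session")
def epimap(skeleton):
    """169-line epiRIL panel on the default map."""
    return simulate_epiril_pedigree(skeleton, 169, seed=11)


@pytest.fixture(scope="session")
def regions(skeleton):
    return simulate_regions(skeleton, seed=11)


@pytest.fixture(scope="session")
def trio_states(epimap, regions):
    """Trio methylomes with fully penetrant planted QTL and no call noise."""
    planted = default_planted_qtl(epimap, regions, penetrance=1.0)
    return simulate_trio_methylomes(
        epimap, regions, planted, state_noise=0.0, hybrid_noise=0.0, seed=11
    ), planted
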