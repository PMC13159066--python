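import pytest

import ivdmet as m


@pytest.fixture(scope="session")
def params():
    return m.load_reference_kinetics()


@pytest.fixture(scope="session")
def coarse_grid():
    return m.build_grid(m.DiscGeometry(), 60, 40)


@pytest.fixture(scope="session")
def medium_grid():
    return m.build_grid(m.DiscGeometry(), 120, 80)


@pytest.fixture(scope="session")
def fine_grid():
    return m.build_grid(m.DiscGeometry(), 240, 160)


@pytest.fixture(scope="session")
def scenario_solutions(params, fine_grid):
    """All four preset scenarios solved on the reporting grid."""
    return {
        name: m.solve_steady_state(fine_grid, sc, params)
        for name, sc in m.PRESET_SCENARIOS.items()
    }
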