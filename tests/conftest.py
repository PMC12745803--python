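import numpy as np
import pytest
from hypothesis import settings

import grnca as g

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rule54_pair() -> g.LandscapePair:
    """The detailed-analysis landscape pair: rule 54 on the 4-vs-6 spaced ICs."""
    ic_a = g.manual_spaced_ic(22, 4)
    ic_b = g.manual_spaced_ic(22, 6)
    return g.LandscapePair(
        mode="ic_switch",
        target_a=g.generate_target(54, ic_a, 21),
        target_b=g.generate_target(54, ic_b, 21),
    )


@pytest.fixture(scope="session")
def small_dev() -> g.DevelopmentConfig:
    return g.DevelopmentConfig(n_genes=4, n_cells=6, n_rows=5)


@pytest.fixture(scope="session")
def static_traces_500(rule54_pair):
    """Three 500-generation static runs at popsize 100 (shared, expensive)."""
    traces = {}
    for seed in (0, 1, 2):
        cfg = g.EvolutionConfig(
            popsize=100, mu=10, generations=500, season_length=300,
            seed=seed, snapshot_count=5,
        )
        traces[seed] = g.run_static(cfg, rule54_pair.target_a)
    return traces
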