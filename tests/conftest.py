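"""Shared fixtures for the test suite (numeric oracles live in oracles.py)."""

import pytest

import nutrisim as ns


@pytest.fixture(scope="session")
def high_profile():
    return ns.make_country(ns.ARCHETYPES["high_burden"], seed=1)


@pytest.fixture(scope="session")
def low_profile():
    return ns.make_country(ns.ARCHETYPES["low_burden"], seed=2)


@pytest.fixture(scope="session")
def nigeria():
    return ns.nigeria_fixture()


@pytest.fixture(scope="session")
def world6():
    return ns.make_world(6, seed=0)


@pytest.fixture(scope="session")
def none_strategy():
    return ns.get_strategy("none")


@pytest.fixture(scope="session")
def paris_strategy():
    return ns.get_strategy("paris")


@pytest.fixture(scope="session")
def pooled_strategy_runs(world6):
    """Pooled attributable DALYs for key strategies over a small seed bank.

    Computed once per session and reused by the acceptance tests that need
    full paired runs (Paris near-linearity, strategy ordering).
    """
    seeds = range(10)
    n = 10_000
    strategies = {name: ns.get_strategy(name)
                  for name in ("none", "paris", "combined_public_health")}
    pooled = {name: 0.0 for name in strategies}
    for profile in world6:
        for seed in seeds:
            for name, strat in strategies.items():
                res = ns.run_paired(profile, strategy=strat, n=n, seed=seed)
                pooled[name] += res.attributable_dalys()
    return pooled
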