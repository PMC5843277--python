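"""Bayesian t-test suite: simulators, Cohen's d, squared-difference
distance, the JZS reference Bayes factor, and ABC parameter recovery."""

import numpy as np
import pytest

from abcinfer import ABCParameterEstimation
from abcinfer.examples import ttest


def test_h0_has_no_mean_difference(rng):
    data = ttest.simulate("H0", 50_000, 50_000, rng)
    d = ttest.cohens_d(data)
    assert d == pytest.approx(0.0, abs=0.02)


def test_h1_recovers_generating_effect_size(rng):
    data = ttest.simulate("H1", 100_000, 100_000, rng, d=0.5)
    assert ttest.cohens_d(data) == pytest.approx(0.5, abs=0.02)


def test_h1_with_zero_effect_matches_h0_distribution():
    d0 = ttest.cohens_d(ttest.simulate("H0", 200, 200, np.random.default_rng(3)))
    d1 = ttest.cohens_d(ttest.simulate("H1", 200, 200, np.random.default_rng(3), d=0.0))
    assert d0 == d1  # identical draws, identical effect


def test_h1_requires_effect_size(rng):
    with pytest.raises(ValueError, match="requires an effect size"):
        ttest.simulate("H1", 10, 10, rng)


def test_cohens_d_direct_formula():
    data = ttest.two_group_array([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
    assert ttest.cohens_d(data) == pytest.approx(-1.0)


def test_cohens_d_location_invariant(rng):
    g1, g2 = rng.normal(size=20), rng.normal(size=25)
    base = ttest.cohens_d(ttest.two_group_array(g1, g2))
    shifted = ttest.cohens_d(ttest.two_group_array(g1 + 7.5, g2 + 7.5))
    assert shifted == pytest.approx(base)


def test_cohens_d_identical_groups_is_zero_and_degenerate_rejected():
    g = np.array([1.0, 2.0, 3.0])
    assert ttest.cohens_d(ttest.two_group_array(g, g)) == 0.0
    with pytest.raises(ValueError, match="pooled variance"):
        ttest.cohens_d(ttest.two_group_array([1.0, 1.0], [1.0, 1.0]))


@pytest.mark.parametrize(
    "a,b,expected", [(0.5, 0.3, 0.04), (1.7, 1.7, 0.0), (-1.0, 2.0, 9.0)]
)
def test_squared_difference_values(a, b, expected):
    assert ttest.squared_difference(a, b) == pytest.approx(expected)
    assert ttest.squared_difference(b, a) == ttest.squared_difference(a, b)


def test_batch_simulators_match_summary_distribution(rng):
    """The fused per-model simulators must reproduce the distribution of
    Cohen's d obtained from the per-dataset simulator path."""
    suite = ttest.suite(20, 20)
    h1 = suite.models[1]
    d = np.full(4000, 0.4)
    batch = h1.simulate_summaries({"d": d}, 4000, rng)[:, 0]
    loop = np.array(
        [ttest.cohens_d(ttest.simulate("H1", 20, 20, rng, d=0.4)) for _ in range(2000)]
    )
    assert batch.mean() == pytest.approx(loop.mean(), abs=0.02)
    assert batch.std() == pytest.approx(loop.std(), abs=0.03)


# ---------------------------------------------------------------------------
# JZS default Bayes factor oracle
# ---------------------------------------------------------------------------


def test_jzs_lower_limit_printed_values():
    assert np.log(ttest.jzs_bf10(0.0, 25, 25)) == pytest.approx(-1.26, abs=0.02)
    assert np.log(ttest.jzs_bf10(0.0, 100, 100)) == pytest.approx(-1.87, abs=0.02)


def test_jzs_increases_with_observed_effect():
    bfs = [ttest.jzs_bf10(d, 25, 25) for d in (0.0, 0.3, 0.6, 1.0)]
    assert np.all(np.diff(bfs) > 0)


def test_jzs_validates_inputs():
    with pytest.raises(ValueError):
        ttest.jzs_bf10(0.0, 1, 25)
    with pytest.raises(ValueError):
        ttest.jzs_bf10(0.0, 25, 25, scale=0.0)


# ---------------------------------------------------------------------------
# ABC effect-size recovery
# ---------------------------------------------------------------------------


def test_abc_posterior_recovers_known_effect_size():
    """Data simulated at d = 0.5 (100 per group): the ABC posterior mean of
    d concentrates near the empirical effect size, and across replicate
    datasets near the generating value."""
    suite = ttest.suite(100, 100)
    post_means, d_hats = [], []
    for seed in range(5):
        rng = np.random.default_rng(1000 + seed)
        data = ttest.simulate("H1", 100, 100, rng, d=0.5)
        d_hats.append(ttest.cohens_d(data))
        est = ABCParameterEstimation.from_data(data, suite)
        res = est.fit(model="H1", n_simulations=100_000, percentile=1, seed=seed)
        post_means.append(float(res.draws["d"].mean()))
    for pm, dh in zip(post_means, d_hats):
        assert pm == pytest.approx(dh, abs=0.1)
    assert np.mean(post_means) == pytest.approx(0.5, abs=0.15)
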