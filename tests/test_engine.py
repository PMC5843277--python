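"""Engine primitives: MAD scaling, thresholds, acceptance, posterior and
Bayes-factor arithmetic, reference-table construction."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from abcinfer import (
    ABCSettings,
    ModelSet,
    ModelSpec,
    Prior,
    ReferenceTable,
    bayes_factor_matrix,
    build_reference_table,
    estimate_posterior,
    generate_pseudo_observed,
    mad_scaled_euclidean,
    mad_scales,
    model_posterior,
    reject,
    select_epsilon,
)
from abcinfer.engine import ModelPosterior


def brute_force_mad(values):
    med = sorted(values)[len(values) // 2] if len(values) % 2 else (
        sorted(values)[len(values) // 2 - 1] + sorted(values)[len(values) // 2]
    ) / 2
    dev = sorted(abs(v - med) for v in values)
    n = len(dev)
    return dev[n // 2] if n % 2 else (dev[n // 2 - 1] + dev[n // 2]) / 2


# ---------------------------------------------------------------------------
# MAD scales and scaled Euclidean distance
# ---------------------------------------------------------------------------


def test_mad_of_small_sequence_matches_brute_force():
    values = [1, 2, 3, 4, 5]
    assert brute_force_mad(values) == 1
    assert mad_scales(np.array(values)[:, None])[0] == 1


def test_zero_mad_dimension_gets_unit_scale():
    scales = mad_scales(np.array([[4.0], [4.0], [4.0]]))
    assert scales[0] == 1.0


@given(
    st.lists(st.integers(-10_000, 10_000), min_size=2, max_size=30),
    st.integers(-10_000, 10_000),
)
def test_mad_translation_invariant(values, shift):
    # integer-valued summaries keep the float arithmetic exact
    base = mad_scales(np.asarray(values, dtype=float)[:, None])[0]
    shifted = mad_scales((np.asarray(values, dtype=float) + shift)[:, None])[0]
    assert shifted == base


@pytest.mark.parametrize(
    "s_sim,s_obs,scales,expected",
    [
        ([3.0], [0.0], [1.0], 3.0),
        ([3.0, 4.0], [0.0, 0.0], [1.0, 1.0], 5.0),
        ([1.5, -2.0], [1.5, -2.0], [2.0, 3.0], 0.0),
    ],
)
def test_scaled_euclidean_values(s_sim, s_obs, scales, expected):
    assert mad_scaled_euclidean(
        np.array(s_sim), np.array(s_obs), np.array(scales)
    ) == pytest.approx(expected)


def test_scaled_euclidean_symmetric_and_rejects_mismatch(rng):
    a, b = rng.normal(size=4), rng.normal(size=4)
    scales = np.ones(4)
    assert mad_scaled_euclidean(a, b, scales) == pytest.approx(
        mad_scaled_euclidean(b, a, scales)
    )
    with pytest.raises(ValueError, match="length mismatch"):
        mad_scaled_euclidean(a, b[:3], scales[:3])


# ---------------------------------------------------------------------------
# epsilon selection and rejection
# ---------------------------------------------------------------------------


def test_nearest_rank_percentile_accepts_exact_share():
    distances = np.arange(1.0, 101.0)
    eps = select_epsilon(distances, 5)
    assert eps == 5.0
    assert int(np.sum(distances <= eps)) == 5


def test_epsilon_degenerate_and_full_percentile(rng):
    assert select_epsilon([3.0, 3.0, 3.0], 50) == 3.0
    d = rng.exponential(size=57)
    assert select_epsilon(d, 100) == d.max()


def test_select_epsilon_validates_input():
    with pytest.raises(ValueError):
        select_epsilon([], 5)
    with pytest.raises(ValueError):
        select_epsilon([1.0], 0)


def _toy_table(distances, model_indices=None, params=None):
    n = len(distances)
    idx = model_indices if model_indices is not None else np.zeros(n, dtype=int)
    return ReferenceTable(
        idx, np.zeros((n, 1)), params or {}, np.asarray(distances, dtype=float)
    )


def test_reject_filters_by_distance_preserving_order():
    table = _toy_table([1.0, 2.0, 3.0])
    kept = reject(table, 2.0)
    np.testing.assert_array_equal(kept.distances, [1.0, 2.0])
    assert len(reject(table, np.inf)) == 3
    assert len(reject(table, 0.0)) == 0
    with pytest.raises(ValueError):
        reject(table, -1.0)


# ---------------------------------------------------------------------------
# posterior model probabilities and Bayes factors
# ---------------------------------------------------------------------------


def _two_models(p=(0.5, 0.5)):
    return ModelSet(
        [
            ModelSpec("m1", prior_probability=p[0]),
            ModelSpec("m2", prior_probability=p[1]),
        ]
    )


def test_posterior_raw_and_normalized_fractions():
    settings = ABCSettings(n_simulations=1000, percentile=10)
    accepted = _toy_table([0.0] * 100, np.array([0] * 75 + [1] * 25))
    post = model_posterior(accepted, settings, _two_models())
    np.testing.assert_allclose(post.raw_fraction, [0.075, 0.025])
    np.testing.assert_allclose(post.probabilities, [0.75, 0.25])


def test_posterior_with_one_empty_model_and_single_model():
    settings = ABCSettings(n_simulations=100)
    post = model_posterior(
        _toy_table([0.0] * 50, np.zeros(50, dtype=int)), settings, _two_models()
    )
    np.testing.assert_allclose(post.probabilities, [1.0, 0.0])
    single = ModelSet([ModelSpec("only")])
    post1 = model_posterior(_toy_table([0.0] * 7), settings, single)
    np.testing.assert_allclose(post1.probabilities, [1.0])


def test_zero_total_acceptance_is_an_error():
    with pytest.raises(ValueError, match="threshold is too strict"):
        ModelPosterior(["a", "b"], np.array([0, 0]), 100)


def test_bf_ratio_with_equal_priors():
    post = ModelPosterior(["m1", "m2"], np.array([75, 25]), 1000)
    bf = bayes_factor_matrix(post, _two_models())
    assert bf["m1", "m2"] == pytest.approx(3.0)
    assert bf["m2", "m1"] == pytest.approx(1 / 3)
    np.testing.assert_allclose(np.diag(bf.values), 1.0)


def test_bf_uses_prior_odds():
    # same acceptance, unequal model priors: prior odds must divide out
    post = ModelPosterior(["m1", "m2"], np.array([60, 30]), 1000)
    bf = bayes_factor_matrix(post, _two_models(p=(2 / 3, 1 / 3)))
    assert bf["m1", "m2"] == pytest.approx((60 / 30) * ((1 / 3) / (2 / 3)))


def test_bf_cap_on_zero_acceptance():
    post = ModelPosterior(["m1", "m2"], np.array([120, 0]), 1000)
    bf = bayes_factor_matrix(post, _two_models(), cap=10_000)
    assert bf["m1", "m2"] == 10_000.0
    assert np.log(bf["m1", "m2"]) == pytest.approx(9.21, abs=0.005)
    assert bf["m2", "m1"] == 1 / 10_000.0
    assert bf.capped[0, 1] and bf.capped[1, 0]


def test_bf_reciprocity_for_uncapped_cells(rng):
    counts = rng.integers(1, 200, size=3)
    post = ModelPosterior(["a", "b", "c"], counts, 10_000)
    models = ModelSet([ModelSpec("a"), ModelSpec("b"), ModelSpec("c")])
    bf = bayes_factor_matrix(post, models)
    for i in range(3):
        for j in range(3):
            if not bf.capped[i, j]:
                assert bf.values[i, j] * bf.values[j, i] == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# reference-table construction
# ---------------------------------------------------------------------------


def _mean_suite():
    """One-parameter toy: mu ~ N(0,1), data = 5 draws of N(mu, 1), summary = mean."""

    def sim(params, rng):
        return rng.normal(params["mu"], 1.0, size=5)

    model = ModelSpec("m", priors={"mu": Prior("normal", loc=0, scale=1)}, simulate=sim)
    return ModelSet([model])


def test_table_has_n_rows_and_nonnegative_distances():
    settings = ABCSettings(n_simulations=300, percentile=10, seed=1)
    table = build_reference_table(
        _mean_suite(), np.array([0.0]), settings, summary_fn=np.mean
    )
    assert table.n_rows == 300
    assert table.k == 1
    assert np.all(table.distances >= 0)
    assert table.parameter_names == ["mu"]


def test_model_index_draws_follow_prior_probabilities():
    def sim(params, rng):
        return np.array([1.0])

    models = ModelSet([ModelSpec("a", simulate=sim), ModelSpec("b", simulate=sim)])
    counts = []
    for seed in range(20):
        settings = ABCSettings(n_simulations=100, seed=seed)
        table = build_reference_table(models, np.array([1.0]), settings, summary_fn=np.mean)
        counts.append(int(np.sum(table.model_indices == 0)))
    # each count ~ Binomial(100, 0.5); pooled over 20 seeds ~ Binomial(2000, 0.5)
    p = stats.binomtest(int(np.sum(counts)), 2000, 0.5).pvalue
    assert p > 1e-4


def test_constant_simulator_equal_to_observed_gives_zero_distances():
    def sim(params, rng):
        return np.array([2.0, 2.0])

    models = ModelSet([ModelSpec("const", simulate=sim)])
    settings = ABCSettings(n_simulations=50, seed=0)
    table = build_reference_table(models, np.array([2.0]), settings, summary_fn=np.mean)
    np.testing.assert_array_equal(table.distances, 0.0)


def test_simulator_shape_mismatch_is_reported():
    def sim(params, rng):
        return np.ones(3)

    models = ModelSet([ModelSpec("bad", simulate=sim)])
    settings = ABCSettings(n_simulations=5, seed=0)
    with pytest.raises(ValueError, match="shape"):
        build_reference_table(
            models,
            np.array([1.0]),
            settings,
            summary_fn=np.mean,
            observed_shape=(4,),
        )


def test_identical_seed_gives_bit_identical_table():
    settings = ABCSettings(n_simulations=200, seed=42)
    kwargs = dict(summary_fn=np.mean)
    t1 = build_reference_table(_mean_suite(), np.array([0.3]), settings, **kwargs)
    t2 = build_reference_table(_mean_suite(), np.array([0.3]), settings, **kwargs)
    assert t1.equals(t2)


def test_prior_model_probabilities_recovered_at_infinite_epsilon():
    def sim(params, rng):
        return rng.normal(size=4)

    models = ModelSet(
        [
            ModelSpec("a", simulate=sim, prior_probability=0.7),
            ModelSpec("b", simulate=sim, prior_probability=0.3),
        ]
    )
    settings = ABCSettings(n_simulations=20_000, epsilon=np.inf, seed=3)
    table = build_reference_table(models, np.array([0.0]), settings, summary_fn=np.mean)
    accepted = reject(table, np.inf)
    post = model_posterior(accepted, settings, models)
    # binomial MC error: sd = sqrt(0.7*0.3/20000) ~ 0.0032
    np.testing.assert_allclose(post.probabilities, [0.7, 0.3], atol=0.015)


# ---------------------------------------------------------------------------
# parameter posterior and pseudo-observed data
# ---------------------------------------------------------------------------


def test_posterior_sample_summary_arithmetic():
    table = _toy_table(
        [0.0, 0.0, 0.0], params={"theta": np.array([1.0, 2.0, 3.0])}
    )
    sample = estimate_posterior(table, 0, epsilon=0.0)
    s = sample.summary()
    assert s.loc["theta", "mean"] == pytest.approx(2.0)
    assert s.loc["theta", "median"] == pytest.approx(2.0)
    q = s.loc["theta", ["q2.5%", "q25%", "q75%", "q97.5%"]].to_numpy(dtype=float)
    assert np.all(np.diff(q) >= 0)


def test_empty_acceptance_raises():
    table = _toy_table([5.0, 6.0], params={"theta": np.array([1.0, 2.0])})
    with pytest.raises(ValueError, match="threshold is too strict"):
        estimate_posterior(table, 0, epsilon=1.0)


def test_pseudo_observed_data_reproducible_and_validated():
    model = _mean_suite()[0]
    d1 = generate_pseudo_observed(model, {"mu": 1.0}, seed=5)
    d2 = generate_pseudo_observed(model, {"mu": 1.0}, seed=5)
    np.testing.assert_array_equal(d1, d2)
    assert d1.shape == (5,)
    with pytest.raises(ValueError, match="do not match"):
        generate_pseudo_observed(model, {"sigma": 1.0}, seed=5)
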