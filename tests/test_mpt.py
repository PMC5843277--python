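"""Multinomial-processing-tree models: design bookkeeping, tree
probabilities, binomial simulation, and prior structure."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from abcinfer.examples import mpt


def params_from_values(values):
    return dict(zip(mpt.parameter_names(), values))


def find_cell(condition=None, prime=None, gender=None, target=None):
    design = mpt.MPTDesign()
    for cell in design.cells:
        if (
            (condition is None or cell.condition == condition)
            and (prime is None or cell.prime == prime)
            and (gender is None or cell.gender == gender)
            and (target is None or cell.target == target)
        ):
            return cell
    raise LookupError


def test_design_has_16_cells_and_11_parameters():
    design = mpt.MPTDesign()
    assert design.n_cells == 16
    names = mpt.parameter_names()
    assert len(names) == 11
    assert sum(n.startswith("A_") for n in names) == 8
    assert sum(n.startswith("C_") for n in names) == 2
    assert names[-1] == "G"
    for model in mpt.suite().models:
        assert len(model.parameter_names) == 11


def test_stereotype_consistency_rule():
    assert find_cell(prime="black", target="gun").stereotype_consistent_correct
    assert find_cell(prime="white", target="tool").stereotype_consistent_correct
    assert not find_cell(prime="black", target="tool").stereotype_consistent_correct
    assert not find_cell(prime="white", target="gun").stereotype_consistent_correct


def test_pd_perfect_control_always_correct():
    params = params_from_values([0.3] * 8 + [1.0, 1.0] + [0.4])
    probs = mpt.cell_probabilities("process_dissociation", params, mpt.MPTDesign())
    np.testing.assert_allclose(probs, 1.0)


def test_pd_pure_automaticity_on_consistent_and_inconsistent_cells():
    # C = 0, A = 1: the automatic stereotype response decides everything
    params = params_from_values([1.0] * 8 + [0.0, 0.0] + [0.5])
    p_gun = mpt.cell_probability(
        "process_dissociation", params, find_cell(prime="black", target="gun")
    )
    p_tool = mpt.cell_probability(
        "process_dissociation", params, find_cell(prime="black", target="tool")
    )
    assert p_gun == pytest.approx(1.0)
    assert p_tool == pytest.approx(0.0)


def test_pd_tree_arithmetic():
    # C=0.5, A=0.2, G=0.5 on a black-prime gun cell:
    # 0.5 + 0.5 * (0.2 + 0.8 * 0.5) = 0.8
    params = params_from_values([0.2] * 8 + [0.5, 0.5] + [0.5])
    p = mpt.cell_probability(
        "process_dissociation", params, find_cell(prime="black", target="gun")
    )
    assert p == pytest.approx(0.8)


def test_stroop_reverses_process_order():
    # A=1 forces the stereotype response regardless of C under Stroop
    params = params_from_values([1.0] * 8 + [1.0, 1.0] + [0.5])
    p = mpt.cell_probability("stroop", params, find_cell(prime="black", target="tool"))
    assert p == pytest.approx(0.0)
    # ... whereas the PD tree answers correctly through control first
    p_pd = mpt.cell_probability(
        "process_dissociation", params, find_cell(prime="black", target="tool")
    )
    assert p_pd == pytest.approx(1.0)


@given(st.lists(st.floats(0, 1), min_size=11, max_size=11))
def test_cell_probabilities_stay_in_unit_interval(values):
    params = params_from_values(values)
    for model in mpt.MODEL_NAMES:
        probs = mpt.cell_probabilities(model, params, mpt.MPTDesign())
        assert probs.shape == (16,)
        assert np.all(probs >= 0) and np.all(probs <= 1)


def test_out_of_range_parameters_rejected():
    params = params_from_values([0.5] * 10 + [1.5])
    with pytest.raises(ValueError, match="out of"):
        mpt.cell_probabilities("stroop", params, mpt.MPTDesign())


def test_simulated_counts_bounded_and_degenerate_tree_all_correct(rng):
    design = mpt.MPTDesign(trials_per_cell=30)
    params = params_from_values([0.3] * 8 + [1.0, 1.0] + [0.5])
    counts = mpt.simulate_counts("process_dissociation", params, design, rng)
    np.testing.assert_array_equal(counts, 30)
    random_params = params_from_values(rng.uniform(size=11))
    counts = mpt.simulate_counts("stroop", random_params, design, rng)
    assert np.all(counts >= 0) and np.all(counts <= 30)


def test_empirical_proportions_concentrate_on_cell_probabilities(rng):
    design = mpt.MPTDesign(trials_per_cell=10_000)
    params = params_from_values(rng.uniform(size=11))
    probs = mpt.cell_probabilities("process_dissociation", params, design)
    counts = mpt.simulate_counts("process_dissociation", params, design, rng)
    np.testing.assert_allclose(counts / design.trials_per_cell, probs, atol=0.02)


def test_fitting_and_recovery_prior_families():
    fit = mpt.default_priors()
    gen = mpt.recovery_priors()
    assert fit["A_private_white_female"].params == {"alpha": 2.0, "beta": 10.0}
    assert fit["C_public"].params == {"alpha": 3.0, "beta": 3.0}
    assert fit["G"].params == {"alpha": 10.0, "beta": 10.0}
    assert gen["C_public"].params == {"alpha": 60.0, "beta": 40.0}
    assert gen["G"].params == {"alpha": 50.0, "beta": 50.0}


def test_batch_summaries_match_per_dataset_path(rng):
    design = mpt.MPTDesign()
    suite = mpt.suite(design)
    model = suite.models[0]
    values = rng.uniform(0.2, 0.8, size=11)
    params_batch = {n: np.full(2000, v) for n, v in zip(mpt.parameter_names(), values)}
    batch = model.simulate_summaries(params_batch, 2000, rng)
    assert batch.shape == (2000, 16)
    expected = mpt.cell_probabilities(
        "process_dissociation", params_from_values(values), design
    )
    np.testing.assert_allclose(batch.mean(axis=0), expected, atol=0.03)
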