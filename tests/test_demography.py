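import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from macroburden import (CohortGrid, DomainError, ShapeError, ValidationError,
                         counterfactual_participation, counterfactual_population,
                         delta_labor_approx, effective_labor, informal_care_deduction,
                         morbidity_ratio, project_population, split_mortality)
from macroburden.demography import _cohort_survival_product


# ---------------------------------------------------------------------------
# mortality split

@pytest.mark.parametrize("sigma,sigma_r,expected", [
    (0.02, 0.005, 1 - 0.98 / 0.995),
    (0.03, 0.0, 0.03),
    (0.01, 0.01, 0.0),
])
def test_split_mortality_values(sigma, sigma_r, expected):
    assert split_mortality(sigma, sigma_r) == pytest.approx(expected, abs=1e-15)


def test_split_mortality_rejects_excess_cause_specific():
    with pytest.raises(DomainError):
        split_mortality(0.01, 0.02)


@settings(deadline=None, max_examples=200)
@given(
    sigma=st.floats(0.0, 0.99),
    frac=st.floats(0.0, 1.0),
)
def test_split_mortality_round_trip(sigma, frac):
    """Recombining the split factors reproduces total survival to 1e-12."""
    sigma_r = sigma * frac
    other = split_mortality(sigma, sigma_r)
    assert (1 - sigma_r) * (1 - other) == pytest.approx(1 - sigma, abs=1e-12)


# ---------------------------------------------------------------------------
# population projection

def test_project_population_single_cohort_hand_recursion():
    mortality = np.full((3, 1, 1), 0.1)
    grid = project_population(np.array([[100.0]]), mortality, 0.0)
    assert grid.counts[:, 0, 0] == pytest.approx([100.0, 90.0, 81.0])


def test_project_population_conserves_under_zero_mortality():
    n0 = np.array([[10.0], [20.0], [30.0], [40.0]])
    mortality = np.zeros((4, 4, 1))
    grid = project_population(n0, mortality, 10.0)
    totals = grid.totals()
    assert totals == pytest.approx(100.0 + 10.0 * np.arange(4))


def test_project_population_shape_error():
    with pytest.raises(ShapeError):
        project_population(np.ones((2, 1)), np.zeros((3, 4, 1)), 0.0)


def test_counterfactual_dominates_status_quo(toy):
    sq = toy.population_grid()
    cf = counterfactual_population(sq, toy.diabetes_mortality,
                                   all_cause_mortality=toy.all_cause_mortality)
    assert np.all(cf.counts >= sq.counts - 1e-12)


def test_counterfactual_product_equals_direct_recursion(toy, synth_small):
    """The accumulated-survival correction reproduces an independent forward
    recursion under the split other-cause mortality, including the closed
    terminal age group."""
    for inp in (toy, synth_small):
        other = split_mortality(inp.all_cause_mortality, inp.diabetes_mortality)
        births = inp.population[:, 0, :]
        direct = project_population(inp.population[0], other, births,
                                    label="counterfactual")
        via_product = counterfactual_population(
            inp.population_grid(), inp.diabetes_mortality,
            all_cause_mortality=inp.all_cause_mortality)
        np.testing.assert_allclose(via_product.counts, direct.counts, rtol=1e-9)


def test_counterfactual_two_year_divisor_arithmetic():
    """Two years of cause-specific mortality 0.005 imply a divisor 0.995**2."""
    sigma_r = np.full((3, 3, 1), 0.005)
    n = CohortGrid(np.ones((3, 3, 1)))
    nbar = counterfactual_population(n, sigma_r)
    assert nbar.counts[2, 2, 0] == pytest.approx(1.0 / 0.990025, rel=1e-12)


def test_counterfactual_identity_when_no_disease_mortality(toy):
    nbar = counterfactual_population(toy.population_grid(),
                                     np.zeros_like(toy.diabetes_mortality),
                                     all_cause_mortality=toy.all_cause_mortality)
    np.testing.assert_allclose(nbar.counts, toy.population, rtol=1e-12)


def test_cohort_survival_product_respects_min_t_a():
    rates = np.full((4, 4, 1), 0.1)
    D = _cohort_survival_product(rates)
    # cell (3, 2): min(t, a) = 2 history terms
    assert D[3, 2, 0] == pytest.approx(0.9 ** 2)
    assert D[0, 3, 0] == 1.0 and D[3, 0, 0] == 1.0


# ---------------------------------------------------------------------------
# morbidity ratio and participation

@pytest.mark.parametrize("yld,yll,expected", [
    (2.0, 4.0, 0.5), (0.0, 0.0, 0.0), (9.0, 3.0, 3.0),
])
def test_morbidity_ratio_values(yld, yll, expected):
    assert morbidity_ratio(yld, yll) == pytest.approx(expected)


def test_morbidity_ratio_caps_zero_deaths_cells():
    assert morbidity_ratio(5.0, 0.0, cap=10.0) == 10.0
    with pytest.raises(DomainError):
        morbidity_ratio(-1.0, 1.0)


def test_counterfactual_participation_single_step():
    sigma_r = np.zeros((2, 2, 1))
    sigma_r[0, 0, 0] = 0.01
    xi = np.zeros((2, 2))
    xi[0, 0] = 2.0
    part = np.full((2, 2, 1), 0.8)
    lbar = counterfactual_participation(part, sigma_r, xi, p=1.0)
    assert lbar[1, 1, 0] == pytest.approx(0.8 / 0.98, rel=1e-12)
    assert lbar[0, 0, 0] == 0.8  # base year untouched


def test_counterfactual_participation_no_disease_is_identity(synth_small):
    xi = morbidity_ratio(synth_small.yld, synth_small.yll)
    lbar = counterfactual_participation(synth_small.participation,
                                        np.zeros_like(synth_small.diabetes_mortality),
                                        xi)
    np.testing.assert_array_equal(lbar, synth_small.participation)


def test_counterfactual_participation_p_zero_keeps_only_current_term():
    """With p = 0 the survivor weight kills every lagged (tau >= 1) term."""
    sigma_r = np.full((3, 3, 1), 0.01)
    xi = np.full((3, 3), 2.0)
    part = np.full((3, 3, 1), 0.5)
    lbar = counterfactual_participation(part, sigma_r, xi, p=0.0)
    # cell (2,2) has two history terms but only tau=0 survives p**tau
    assert lbar[2, 2, 0] == pytest.approx(0.5 / (1 - 0.01 * 2.0), rel=1e-12)


def test_counterfactual_participation_dominates(synth_small):
    xi = morbidity_ratio(synth_small.yld, synth_small.yll)
    lbar = counterfactual_participation(synth_small.participation,
                                        synth_small.diabetes_mortality, xi)
    assert np.all(lbar >= synth_small.participation - 1e-15)
    assert np.all(lbar <= 1.0)


# ---------------------------------------------------------------------------
# informal care and effective labor

def test_informal_care_unit_loss_per_patient():
    ded = informal_care_deduction(np.array([1.0]), 4.0, 35.9, np.array([1.0]))
    assert round(float(ded.sum()), 2) == 0.11


def test_informal_care_scales_with_hours_and_patients():
    ded = informal_care_deduction(np.array([100.0]), 8.3, 35.9, np.array([1.0]))
    assert ded.sum() == pytest.approx(100 * 8.3 / 35.9)
    assert informal_care_deduction(np.array([50.0]), 0.0, 35.9,
                                   np.array([1.0])).sum() == 0.0


def test_informal_care_weight_validation_and_clipping():
    with pytest.raises(ValidationError):
        informal_care_deduction(np.array([1.0]), 4.0, 35.9, np.array([0.5, 0.4]))
    ded = informal_care_deduction(np.array([100.0]), 4.0, 35.9,
                                  np.array([0.5, 0.5]),
                                  available=np.array([1.0, 100.0]))
    assert ded[0] == 1.0  # clipped to available labor


def test_effective_labor_values_and_floor():
    grid = CohortGrid(np.full((1, 3, 1), 1000.0))
    part = np.full((1, 3, 1), 0.8)
    informal = np.array([[10.0, 0.0, 900.0]])
    L = effective_labor(grid, part, informal)
    assert L[0, 0, 0] == pytest.approx(790.0)
    assert L[0, 1, 0] == pytest.approx(800.0)
    assert L[0, 2, 0] == 0.0  # floored
    assert np.all(effective_labor(grid, np.zeros((1, 3, 1))) == 0.0)


# ---------------------------------------------------------------------------
# closed-form labor gain

def test_delta_labor_single_term_arithmetic():
    part = np.full((2, 2, 1), 0.8)
    n = np.full((2, 2, 1), 1000.0)
    sigma_r = np.zeros((2, 2, 1))
    sigma_r[0, 0, 0] = 0.01
    xi = np.zeros((2, 2))
    xi[0, 0] = 2.0
    dL = delta_labor_approx(part, n, sigma_r, xi, p=1.0, rho=1.0)
    assert dL[1, 1, 0] == pytest.approx(24.0, rel=1e-12)
    assert np.all(delta_labor_approx(part, n, sigma_r, xi, rho=0.0) == 0.0)
    with pytest.raises(DomainError):
        delta_labor_approx(part, n, sigma_r, xi, rho=1.5)


def test_delta_labor_linear_in_rho_and_monotone():
    part = np.full((3, 3, 1), 0.7)
    n = np.full((3, 3, 1), 500.0)
    sigma_r = np.full((3, 3, 1), 0.01)
    xi = np.full((3, 3), 1.5)
    full = delta_labor_approx(part, n, sigma_r, xi)
    half = delta_labor_approx(part, n, sigma_r, xi, rho=0.5)
    np.testing.assert_allclose(half, 0.5 * full, rtol=1e-12)
    more_sigma = delta_labor_approx(part, n, sigma_r * 2, xi)
    more_xi = delta_labor_approx(part, n, sigma_r, xi * 2)
    assert np.all(more_sigma >= full) and np.all(more_xi >= full)


def test_delta_labor_matches_exact_two_path_difference(synth_small):
    """At low cause-specific mortality (<= 0.005) the closed form tracks the
    exact two-scenario labor difference within 5% on single-lineage cohort
    cells (the closed form does not model the pooled terminal group)."""
    inp = synth_small.replace(
        diabetes_mortality=np.minimum(synth_small.diabetes_mortality, 0.005))
    xi = morbidity_ratio(inp.yld, inp.yll)
    nbar = counterfactual_population(inp.population_grid(), inp.diabetes_mortality,
                                     all_cause_mortality=inp.all_cause_mortality)
    lbar = counterfactual_participation(inp.participation, inp.diabetes_mortality, xi)
    exact = (lbar * nbar.counts - inp.participation * inp.population)[:, :-1, :].sum()
    approx = delta_labor_approx(inp.participation, inp.population,
                                inp.diabetes_mortality, xi)[:, :-1, :].sum()
    assert exact > 0
    assert abs(approx - exact) / exact < 0.05
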