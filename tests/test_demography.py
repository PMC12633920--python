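import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from secularsim import (
    DemographyParams,
    apply_mortality,
    attempt_reproduction_all,
    death_probability,
    form_marriages,
    initial_wellbeing,
    reproduction_probability,
    wb_age_delta,
    wb_insecurity_delta,
)
from secularsim.config import DEFAULT_MORTALITY_CURVE

from conftest import make_society


@pytest.fixture
def params():
    return DemographyParams()


class TestAgeDelta:
    def test_threshold_value_is_intercept(self, params):
        assert wb_age_delta(params.wb_age_threshold, params) == pytest.approx(
            params.wb_intercept_C
        )

    def test_age_100_is_minus_three_c(self, params):
        assert wb_age_delta(100.0, params) == pytest.approx(
            -3.0 * params.wb_intercept_C
        )

    def test_zero_crossing_in_loss_regime(self, params):
        # delta = 0 at u = (1/4)^(1/Exp2)
        thr = params.wb_age_threshold
        u_star = 0.25 ** (1.0 / params.wb_exp_loss)
        age_star = thr + u_star * (100.0 - thr)
        assert wb_age_delta(age_star, params) == pytest.approx(0.0, abs=1e-12)

    def test_young_agents_gain_most(self, params):
        deltas = wb_age_delta(np.arange(0, 101), params)
        assert deltas[0] == deltas.max()
        assert np.all(np.diff(deltas) <= 1e-12)  # monotone non-increasing


class TestInsecurityDelta:
    def test_endpoints(self, params):
        assert wb_insecurity_delta(0.0, params) == pytest.approx(params.wb_max_inc)
        assert wb_insecurity_delta(params.wb_insec_threshold, params) == pytest.approx(
            0.0
        )
        assert wb_insecurity_delta(1.0, params) == pytest.approx(-0.25)

    def test_linear_interpolation_in_loss_branch(self, params):
        # halfway between (0.1, 0) and (1, -0.25)
        assert wb_insecurity_delta(0.55, params) == pytest.approx(-0.125)

    def test_continuous_and_monotone(self, params):
        ins = np.linspace(0, 1, 1001)
        d = wb_insecurity_delta(ins, params)
        assert np.all(np.diff(d) <= 1e-12)
        assert np.max(np.abs(np.diff(d))) < 0.01  # no jump at the threshold

    def test_domain_error(self, params):
        with pytest.raises(ValueError):
            wb_insecurity_delta(1.2, params)

    def test_printed_variant_grows_with_insecurity(self, params):
        printed = params.model_copy(update={"eq3_as_printed": True})
        assert wb_insecurity_delta(0.05, printed) > wb_insecurity_delta(0.0, printed)


class TestInsecurityDeltaProperty:
    @settings(max_examples=80, derandomize=True, deadline=None)
    @given(
        ins=st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
        max_inc=st.floats(min_value=0.0, max_value=0.3),
        thr=st.floats(min_value=0.01, max_value=0.9),
    )
    def test_sign_respects_threshold(self, ins, max_inc, thr):
        """Gain below the threshold, loss above it, for any parameters."""
        params = DemographyParams(wb_max_inc=max_inc, wb_insec_threshold=thr)
        delta = float(wb_insecurity_delta(ins, params))
        if ins < thr:
            assert delta >= 0.0
        elif ins > thr:
            assert delta <= 0.0
        else:
            assert delta == pytest.approx(0.0, abs=1e-12)


class TestCurves:
    def test_initial_wellbeing_bounds_and_shape(self):
        wb = initial_wellbeing(np.arange(0, 101))
        assert np.all((wb >= 0) & (wb <= 1))
        assert initial_wellbeing(20) > initial_wellbeing(90)

    def test_constant_user_curve(self):
        assert initial_wellbeing(37, curve=[0.8]) == pytest.approx(0.8)

    def test_initial_wellbeing_age_domain(self):
        with pytest.raises(ValueError):
            initial_wellbeing(120)

    def test_death_probability_monotone_with_fig_shape(self):
        wb = np.linspace(0, 1, 101)
        p = death_probability(wb)
        assert np.all((p >= 0) & (p <= 1))
        assert np.all(np.diff(p) <= 1e-12)
        assert p[0] >= 0.9
        assert p[-1] <= 0.02
        assert death_probability(0.2) >= death_probability(0.8)


class TestReproductionProbability:
    def test_midpoint(self, params):
        a = params.rep_mid_threshold
        # choose wb/ins so the weighted mean lands exactly on a
        assert reproduction_probability(a, a, params) == pytest.approx(0.5)

    def test_weighted_average(self, params):
        # x = (0.6 * 1 + 0.2 * 0.5) / 1.5
        x = (0.6 + 0.1) / 1.5
        expected = 1.0 / (
            1.0 + np.exp(-params.rep_curve_shape * (x - params.rep_mid_threshold))
        )
        assert reproduction_probability(0.6, 0.2, params) == pytest.approx(expected)
        assert x == pytest.approx(0.46667, abs=1e-4)

    def test_steep_curve_limit(self, params):
        steep = params.model_copy(update={"rep_curve_shape": 1e4})
        assert reproduction_probability(0.9, 0.9, steep) > 0.999

    def test_monotone_in_both_inputs(self, params):
        p0 = reproduction_probability(0.4, 0.2, params)
        assert reproduction_probability(0.5, 0.2, params) > p0
        assert reproduction_probability(0.4, 0.4, params) > p0


class TestMortality:
    def test_certain_death_empties_society(self, params):
        soc = make_society(n=40)
        deadly = params.model_copy(update={"mortality_curve": [1.0]})
        apply_mortality(soc, deadly, seed=1)
        assert soc.size == 0

    def test_widowing(self, params):
        soc = make_society(n=4, ages=[30, 30, 30, 30])
        soc.partner[:] = [1, 0, 3, 2]
        # kill agents 0 and 2 deterministically via wellbeing
        soc.wellbeing[:] = [0.0, 1.0, 0.0, 1.0]
        curve = [-1.0, 1.0]  # p = 1 - wb
        apply_mortality(soc, params.model_copy(update={"mortality_curve": curve}), 5)
        assert soc.size == 2
        assert np.all(soc.partner == -1)

    def test_high_wellbeing_mortality_is_rare(self, params):
        soc = make_society(n=2000)
        soc.wellbeing[:] = 1.0
        deaths = apply_mortality(soc, params, seed=3)
        assert deaths <= 0.02 * 2000

    def test_matches_bernoulli_oracle_distribution(self, params):
        """Deaths agree with independent Bernoulli draws per agent."""
        reps = 200
        base = make_society(n=1000, seed=11)
        wb = base.wellbeing.copy()
        rng = np.random.default_rng(99)
        wb[:] = rng.random(1000)
        p = death_probability(wb, DEFAULT_MORTALITY_CURVE)
        observed = np.empty(reps)
        for r in range(reps):
            soc = make_society(n=1000, seed=11)
            soc.wellbeing[:] = wb
            observed[r] = apply_mortality(soc, params, seed=1000 + r)
        mu = p.sum()
        sigma = np.sqrt((p * (1 - p)).sum())
        # mean of 200 replicates within 4 standard errors of the oracle mean
        assert abs(observed.mean() - mu) < 4 * sigma / np.sqrt(reps)
        # spread compatible with the Poisson-binomial oracle (chi-square-ish)
        assert 0.5 * sigma < observed.std(ddof=1) < 1.5 * sigma


class TestMarriage:
    def test_compatible_pair_marries(self, params):
        soc = make_society(n=2, ages=[20, 24])
        soc.gender[:] = [0, 1]
        form_marriages(soc, params.model_copy(update={"marriage_age_diff": 5.0}), 1)
        assert soc.partner[0] == 1 and soc.partner[1] == 0

    def test_underage_never_matched(self, params):
        soc = make_society(n=2, ages=[14, 20])
        soc.gender[:] = [0, 1]
        form_marriages(soc, params, 1)
        assert np.all(soc.partner == -1)

    def test_age_gap_respected_and_married_untouched(self, params):
        soc = make_society(n=4, ages=[20, 60, 25, 27])
        soc.gender[:] = [0, 1, 0, 1]
        soc.partner[2] = 3
        soc.partner[3] = 2
        form_marriages(soc, params.model_copy(update={"marriage_age_diff": 5.0}), 2)
        assert soc.partner[0] == -1 and soc.partner[1] == -1  # 40-year gap
        assert soc.partner[2] == 3 and soc.partner[3] == 2

    def test_reciprocity_on_random_population(self, params):
        soc = make_society(n=300, seed=7)
        form_marriages(soc, params, 3)
        married = np.nonzero(soc.partner >= 0)[0]
        assert len(married) > 0
        for i in married:
            assert soc.partner[soc.partner[i]] == i
            assert soc.gender[soc.partner[i]] != soc.gender[i]
            assert abs(soc.age[soc.partner[i]] - soc.age[i]) <= params.marriage_age_diff


class TestReproduction:
    def _couple(self, wb_f=0.8, wb_m=0.6, age_f=30):
        soc = make_society(n=2, ages=[age_f, 32])
        soc.gender[:] = [0, 1]
        soc.partner[:] = [1, 0]
        soc.wellbeing[:] = [wb_f, wb_m]
        return soc

    def test_wellbeing_cost_and_conservation(self, params):
        soc = self._couple()
        certain = params.model_copy(
            update={"rep_cost": 0.05, "rep_curve_shape": 1e6, "rep_mid_threshold": 0.01}
        )
        off = attempt_reproduction_all(soc, certain, seed=1)
        assert off["n"] == 1
        assert soc.wellbeing[0] == pytest.approx(0.76)
        assert soc.wellbeing[1] == pytest.approx(0.57)
        assert off["wellbeing"][0] == pytest.approx(0.04 + 0.03)

    def test_offspring_inherits_one_parent_triple(self, params):
        soc = self._couple()
        soc.religiosity[:] = [0.9, 0.2]
        soc.insecurity[:] = [0.7, 0.1]
        soc.sensitivity[:] = [0.6, 0.3]
        soc.anxiety[:] = soc.insecurity * soc.sensitivity
        certain = params.model_copy(
            update={"rep_curve_shape": 1e6, "rep_mid_threshold": 0.01}
        )
        off = attempt_reproduction_all(soc, certain, seed=4)
        triple = (off["religiosity"][0], off["insecurity"][0], off["sensitivity"][0])
        assert triple in [(0.9, 0.7, 0.6), (0.2, 0.1, 0.3)]

    def test_unmarried_or_out_of_range_female_never_reproduces(self, params):
        certain = params.model_copy(
            update={"rep_curve_shape": 1e6, "rep_mid_threshold": 0.01}
        )
        single = make_society(n=2, ages=[30, 32])
        single.gender[:] = [0, 1]
        assert attempt_reproduction_all(single, certain, seed=1)["n"] == 0
        older = self._couple(age_f=50)
        assert attempt_reproduction_all(older, certain, seed=1)["n"] == 0

    def test_at_most_one_birth_per_female(self, params):
        soc = self._couple()
        certain = params.model_copy(
            update={"rep_curve_shape": 1e6, "rep_mid_threshold": 0.01}
        )
        off = attempt_reproduction_all(soc, certain, seed=2)
        assert off["n"] == 1
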