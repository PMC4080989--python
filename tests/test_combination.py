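"""Chou-Talalay CI arithmetic, classification and Loewe consistency."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from atptca.combination import (
    ADDITIVE,
    ANTAGONISM,
    NOT_ESTIMABLE,
    SYNERGY,
    CombinationDesign,
    ci_report,
    classify_ci,
    combination_index,
    combo_components_at_effect,
)
from atptca.dose_response import analyze_profile
from atptca.plate import DoseSeries
from atptca.simulate import DrugResponseModel, loewe_mixture_inhibition
from tests.conftest import hill_profile, make_profile


def loewe_isobole_components(model_a, model_b, ratio, effect_pct):
    """Independent oracle: solve the Loewe equation t/ratio_a/DA + ... = 1
    along the fixed-ratio ray dA = t, dB = t/ratio for the ray position
    giving the stated effect, returning the component doses."""
    da_eq = model_a.dose_for(effect_pct)
    db_eq = model_b.dose_for(effect_pct)

    def g(t):
        return t / da_eq + (t / ratio) / db_eq - 1.0

    t_star = brentq(g, 1e-12, 1e6)
    return t_star, t_star / ratio


def mixture_profile(model_a, model_b, design, rho=1.0, condition=None):
    """Noiseless combination profile on the design's A-component axis."""
    ca = np.asarray(design.drug_a.concentrations)
    cb = np.asarray(design.drug_b.concentrations)
    inh = [loewe_mixture_inhibition(a, b, model_a, model_b, rho) for a, b in zip(ca, cb)]
    return make_profile(inh, series=design.axis, condition=condition or design.label)


class TestCombinationDesign:
    def test_fixed_ratio_from_paired_series(self):
        design = CombinationDesign(DoseSeries.from_tdc("A", 2.0), DoseSeries.from_tdc("B", 1.0))
        assert design.ratio == pytest.approx(2.0)
        assert design.label == "A+B"

    def test_unequal_ratio_rejected(self):
        a = DoseSeries.from_tdc("A", 1.0)
        bad = DoseSeries("B", (2.0, 1.0, 0.5, 0.25, 0.125, 0.0625), 1.0)
        # corrupting one step breaks the constant-ratio invariant
        with pytest.raises(ValueError):
            CombinationDesign(a, DoseSeries("B", tuple(
                c * (1.1 if i == 3 else 1.0) for i, c in enumerate(bad.concentrations)
            ), 1.0))


class TestCombinationIndex:
    def test_sham_half_doses_give_unity(self):
        assert combination_index(0.5, 0.5, 1.0, 1.0, alpha=0) == pytest.approx(1.0)

    def test_quarter_doses(self):
        assert combination_index(0.25, 0.25, 1.0, 1.0, alpha=0) == pytest.approx(0.5)
        assert combination_index(0.25, 0.25, 1.0, 1.0, alpha=1) == pytest.approx(0.5625)

    def test_relabel_symmetry_and_alpha_ordering(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            da, db, sa, sb = rng.uniform(0.01, 5.0, 4)
            ci0 = combination_index(da, db, sa, sb, alpha=0)
            assert combination_index(db, da, sb, sa, alpha=0) == pytest.approx(ci0)
            assert combination_index(da, db, sa, sb, alpha=1) >= ci0

    @pytest.mark.parametrize("bad", [0.0, -1.0, float("nan"), float("inf")])
    def test_nonpositive_doses_rejected(self, bad):
        with pytest.raises(ValueError):
            combination_index(bad, 0.5, 1.0, 1.0)

    def test_alpha_must_be_binary(self):
        with pytest.raises(ValueError):
            combination_index(0.5, 0.5, 1.0, 1.0, alpha=2)


class TestClassifyCI:
    @pytest.mark.parametrize(
        "ci,expected",
        [
            (0.23, SYNERGY),
            (0.79999, SYNERGY),
            (0.8, ADDITIVE),  # boundary assigned to additive
            (1.0, ADDITIVE),
            (1.2, ADDITIVE),  # boundary assigned to additive
            (1.20001, ANTAGONISM),
            (1.33, ANTAGONISM),
        ],
    )
    def test_thresholds(self, ci, expected):
        assert classify_ci(ci) == expected

    @given(st.floats(0.001, 10.0))
    @settings(max_examples=200)
    def test_classification_total_and_consistent(self, ci):
        cls = classify_ci(ci)
        assert cls == (SYNERGY if ci < 0.8 else ANTAGONISM if ci > 1.2 else ADDITIVE)


class TestComboComponents:
    def test_equal_ratio_split(self):
        a = DoseSeries.from_tdc("A", 1.0)
        design = CombinationDesign(a, DoseSeries.from_tdc("B", 1.0))
        prof = make_profile([90, 80, 70, 50, 30, 10], series=a, condition="A+B")
        comp = combo_components_at_effect(prof, design, 0.5)
        assert comp.dose_a == pytest.approx(0.25)
        assert comp.dose_b == pytest.approx(0.25)

    def test_two_to_one_ratio_split(self):
        design = CombinationDesign(DoseSeries.from_tdc("A", 1.0),
                                   DoseSeries.from_tdc("B", 0.5))
        prof = make_profile([90, 50, 40, 30, 20, 10], series=design.axis, condition="A+B")
        comp = combo_components_at_effect(prof, design, 0.5)
        assert comp.dose_a == pytest.approx(1.0)
        assert comp.dose_b == pytest.approx(0.5)

    def test_censored_crossing_not_estimable(self):
        design = CombinationDesign(DoseSeries.from_tdc("A", 1.0),
                                   DoseSeries.from_tdc("B", 1.0))
        prof = make_profile([40, 35, 30, 20, 10, 5], series=design.axis, condition="A+B")
        comp = combo_components_at_effect(prof, design, 0.5)
        assert not comp.estimable and comp.dose_a is None

    def test_loewe_additive_mixture_matches_isobole_oracle(self):
        """Component doses at the 50% crossing of a simulated additive
        mixture reproduce the analytic Loewe isobole point within 1%."""
        a = DoseSeries.from_tdc("A", 1.0)
        b = DoseSeries.from_tdc("B", 1.0)
        design = CombinationDesign(a, b)
        model_a = DrugResponseModel("L", "A", 100.0, 0.6, 1.4)
        model_b = DrugResponseModel("L", "B", 100.0, 0.3, 1.4)
        prof = mixture_profile(model_a, model_b, design)
        comp = combo_components_at_effect(prof, design, 0.5)
        da_oracle, db_oracle = loewe_isobole_components(model_a, model_b, design.ratio, 50.0)
        assert comp.dose_a == pytest.approx(da_oracle, rel=0.01)
        assert comp.dose_b == pytest.approx(db_oracle, rel=0.01)


class TestCIReport:
    def _selfcombo(self, ec50, h=1.0, imax=100.0):
        series = DoseSeries.from_tdc("X", 1.0)
        design = CombinationDesign(series, series)
        model = DrugResponseModel("L", "X", imax, ec50, h)
        single = analyze_profile(hill_profile(imax, ec50, h, series=series, condition="X"))
        combo = analyze_profile(mixture_profile(model, model, design, condition="X+X"))
        return single, combo, design

    def test_sham_self_combination_is_additive_unity(self):
        """A drug combined with itself at half-dose components has CI = 1 at
        both effect levels (Loewe ground truth)."""
        single, combo, design = self._selfcombo(ec50=0.18)
        ci50, ci90 = ci_report(single, single, combo, design, alpha=0)
        assert ci50.ci == pytest.approx(1.0, abs=1e-6)
        assert ci90.ci == pytest.approx(1.0, abs=1e-6)
        assert ci50.classification == ADDITIVE

    def test_potency_shifted_mixture_recovers_ci_quarter(self):
        """rho = 0.25 ground truth comes back as CI50 ~ 0.25: the analytic
        dose-shift construction, cross-checked by the isobole solver."""
        series = DoseSeries.from_tdc("X", 1.0)
        design = CombinationDesign(series, series)
        model = DrugResponseModel("L", "X", 100.0, 1.0, 1.0)
        single = analyze_profile(hill_profile(100.0, 1.0, 1.0, series=series, condition="X"))
        combo = analyze_profile(mixture_profile(model, model, design, rho=0.25, condition="X+X"))
        ci50, _ = ci_report(single, single, combo, design, alpha=0)
        assert ci50.ci == pytest.approx(0.25, abs=0.03)
        assert ci50.classification == SYNERGY
        # oracle: additive isobole components, scaled by rho
        da_add, _ = loewe_isobole_components(model, model, 1.0, 50.0)
        assert ci50.dose_a_combo == pytest.approx(0.25 * da_add, rel=0.05)

    def test_flat_single_agent_censors_both_levels(self):
        series = DoseSeries.from_tdc("X", 1.0)
        design = CombinationDesign(series, series)
        single_a = analyze_profile(hill_profile(100.0, 0.18, 1.0, series=series))
        single_b = analyze_profile(make_profile([30] * 6, series=series, condition="flat"))
        combo = analyze_profile(hill_profile(100.0, 0.1, 1.0, series=series, condition="X+X"))
        for res in ci_report(single_a, single_b, combo, design, alpha=0):
            assert res.ci is None
            assert res.classification == NOT_ESTIMABLE

    def test_effect_levels_censor_independently(self):
        # partial single agents reach 50% but never 90%: CI50 exists, CI90 not
        series = DoseSeries.from_tdc("X", 1.0)
        design = CombinationDesign(series, series)
        single = analyze_profile(hill_profile(70.0, 0.18, 1.5, series=series))
        model = DrugResponseModel("L", "X", 70.0, 0.18, 1.5)
        combo = analyze_profile(mixture_profile(model, model, design, condition="X+X"))
        ci50, ci90 = ci_report(single, single, combo, design, alpha=0)
        assert ci50.ci is not None
        assert ci90.ci is None and ci90.classification == NOT_ESTIMABLE


class TestLoeweConsistency:
    def test_equal_shape_pairs_near_unity_unequal_bounded(self):
        """Noiseless Loewe-additive pairs measured through the pipeline:
        equal-shape pairs give CI50 in [0.95, 1.05]; unequal-slope pairs stay
        within +-0.15 of unity (interpolation error only, since the simulated
        mixture sits exactly on the Loewe isobole)."""
        rng = np.random.default_rng(20260919)
        series = DoseSeries.from_tdc("A", 1.0)
        design = CombinationDesign(series, DoseSeries.from_tdc("B", 1.0))
        n_equal = n_unequal = 0
        for _ in range(80):
            imax = rng.uniform(90, 100)
            h = rng.uniform(1.0, 3.0)
            e_a, e_b = np.exp(rng.uniform(np.log(0.15), np.log(1.5), 2))
            equal_shape = rng.random() < 0.5
            h_b = h if equal_shape else rng.uniform(0.5, 3.0)
            model_a = DrugResponseModel("L", "A", imax, float(e_a), h)
            model_b = DrugResponseModel("L", "B", imax, float(e_b), h_b)
            single_a = analyze_profile(hill_profile(imax, e_a, h, series=series, condition="A"))
            single_b = analyze_profile(hill_profile(imax, e_b, h_b,
                                                    series=design.drug_b, condition="B"))
            combo = analyze_profile(mixture_profile(model_a, model_b, design))
            ci50, _ = ci_report(single_a, single_b, combo, design, alpha=0)
            if ci50.ci is None:
                continue  # crossing outside the tested window; CI undefined
            if equal_shape:
                n_equal += 1
                assert 0.95 <= ci50.ci <= 1.05
            else:
                n_unequal += 1
                assert abs(ci50.ci - 1.0) <= 0.15
        assert n_equal >= 20 and n_unequal >= 20
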