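"""Virtual-trial plumbing and the clinical-calibration fit."""

import numpy as np
import pytest

from bgqsp import pharmacology as ph
from bgqsp import trials as tr
from bgqsp.coupling import default_table
from bgqsp.pathology import healthy_state, pd_state


def records(values, n=100):
    return [tr.ClinicalRecord(f"r{i}", "UPDRS-III", v, n)
            for i, v in enumerate(values)]


class TestLinearCalibration:
    def test_exact_line_recovered(self):
        """5 points on clinical = 2*b/g - 1: slope/intercept exact, R^2 = 1."""
        bg = [0.5, 1.0, 1.5, 2.0, 3.0]
        fit = tr.fit_linear_calibration(bg, records([2 * b - 1 for b in bg]))
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(-1.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_constant_clinical_zero_slope(self):
        fit = tr.fit_linear_calibration([1.0, 2.0, 3.0], records([5.0] * 3))
        assert fit.slope == 0.0
        assert fit.r_squared == 0.0

    def test_too_few_records_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            tr.fit_linear_calibration([1.0, 2.0], records([1.0, 2.0]))

    def test_zero_bg_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            tr.fit_linear_calibration([1.0, 1.0, 1.0], records([1, 2, 3]))

    def test_weights_matter(self):
        """A heavily weighted outlier pulls the weighted fit."""
        bg = [1.0, 2.0, 3.0, 4.0]
        recs = records([1.0, 2.0, 3.0, 10.0])
        recs[-1].n_patients = 10000
        fit_w = tr.fit_linear_calibration(bg, recs)
        recs[-1].n_patients = 1
        fit_u = tr.fit_linear_calibration(bg, recs)
        assert fit_w.slope != pytest.approx(fit_u.slope)

    def test_placebo_normalization_shift_invariance(self):
        """Subtracting a constant from every b/g leaves R^2 unchanged."""
        rng = np.random.default_rng(0)
        bg = rng.uniform(1.0, 3.0, 8)
        recs = records(list(2.0 * bg - 1.0 + rng.normal(0, 0.3, 8)))
        r2a = tr.fit_linear_calibration(bg, recs).r_squared
        r2b = tr.fit_linear_calibration(bg - bg[0], recs).r_squared
        assert r2a == pytest.approx(r2b, rel=1e-9)


class TestConditionMultipliers:
    def test_healthy_without_drugs_is_neutral(self):
        mult, folds = tr.condition_multipliers(healthy_state())
        assert all(v == pytest.approx(1.0) for v in mult.values())
        assert folds == {}

    def test_pd_structural_factors_present(self):
        mult, _ = tr.condition_multipliers(pd_state(0.8))
        assert mult[("GPe", "mGluR")] < 1.0
        assert mult[("STN", "gpe_GABA")] > 1.0

    def test_a2a_antagonist_amplifies_d2_ka_coupling_only_with_signal(self):
        from bgqsp.fixtures import archetype_drugs

        a2a = [d for d in archetype_drugs() if d.name == "a2a_blocker_syn"][0]
        pd = pd_state(0.8)
        reg = ph.Regimen(arms=[(a2a, 40.0)], da_release_fold=2.0)
        m_ld, _ = tr.condition_multipliers(pd, ph.Regimen(da_release_fold=2.0))
        m_both, _ = tr.condition_multipliers(pd, reg)
        key = ("MSN_D2", "K_A")
        # L-DOPA raises D2 activation, moving the K_A multiplier away from
        # unity in the direction of the gain sign; A2A blockade amplifies
        # that displacement
        assert m_ld[key] != 1.0
        assert np.sign(m_both[key] - 1.0) == np.sign(m_ld[key] - 1.0)
        assert abs(m_both[key] - 1.0) > abs(m_ld[key] - 1.0)


class TestVirtualTrial:
    def test_placebo_arm_deterministic(self, graph):
        arm = tr.TrialArm(ph.Regimen(), pd_state(0.8), n_seeds=3, label="pbo")
        a = tr.run_virtual_trial(arm, graph=graph, base_seed=5, duration=400.0)
        b = tr.run_virtual_trial(arm, graph=graph, base_seed=5, duration=400.0)
        assert a.mean == b.mean
        assert np.array_equal(a.values, b.values)

    def test_arm_label_in_diagnostics(self, graph):
        bad = tr.TrialArm(ph.Regimen(), pd_state(0.5),
                          n_seeds=3, label="broken-arm")
        # corrupt the regimen after construction to exercise the error path
        bad.regimen.da_release_fold = -1.0
        with pytest.raises(Exception, match="broken-arm"):
            tr.run_virtual_trial(bad, graph=graph, duration=400.0)

    def test_minimum_seed_count_enforced(self):
        with pytest.raises(ValueError, match="n_seeds"):
            tr.TrialArm(ph.Regimen(), pd_state(0.5), n_seeds=2)


class TestOptimizeCouplings:
    def test_requires_more_conditions_than_parameters(self):
        arm = tr.TrialArm(ph.Regimen(), pd_state(0.5), n_seeds=3)
        pairs = [(arm, rec) for rec in records([1.0] * 3)]
        with pytest.raises(ValueError, match="more conditions"):
            tr.optimize_couplings(default_table(), pairs, seed=0)

    def test_single_gain_smoke_improves_or_matches(self, graph):
        """1-D calibration on a tiny synthetic table runs deterministically
        and logs its evaluations."""
        from bgqsp.fixtures import archetype_drugs

        d2 = [d for d in archetype_drugs() if d.name == "d2_blocker_syn"][0]
        pd = pd_state(0.6)
        arms = [
            tr.TrialArm(ph.Regimen(), pd, 3, "pbo"),
            tr.TrialArm(ph.Regimen(arms=[(d2, 4.0)]), pd, 3, "lo"),
            tr.TrialArm(ph.Regimen(arms=[(d2, 16.0)]), pd, 3, "hi"),
        ]
        cache = tr._ArmCache(arms, graph, 0, 400.0, 150.0)
        truth = default_table().scaled({"d2_msn_ka": 1.3})
        bg = cache.bg_vector(truth)
        recs = records(list(2.0 * bg - 1.0))
        table, info = tr.optimize_couplings(
            default_table(), list(zip(arms, recs)), seed=1, graph=graph,
            maxfev=8, duration=400.0, transient=150.0,
            params=("d2_msn_ka",))
        assert info["evaluations"]
        assert 0.0 <= info["r_squared"] <= 1.0
        assert info["n_simulations"] > 0
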