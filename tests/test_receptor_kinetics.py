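"""Competitive occupancy, activation, dopamine dynamics and the PET mapping."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

from bgqsp import receptor_kinetics as rk


def lig(name, ki, eff=1.0, conc=0.0, receptor="D1", role="drug"):
    return rk.Ligand(name, {receptor: ki}, {receptor: eff}, conc, role)


class TestCompetitiveOccupancy:
    def test_half_maximal_at_ki(self):
        occ = rk.competitive_occupancy([lig("a", 10.0, conc=10.0)], "D1")
        assert occ["a"] == pytest.approx(0.5)

    def test_zero_concentrations_give_zero_occupancy(self):
        ligs = [lig("a", 10.0), lig("b", 3.0)]
        occ = rk.competitive_occupancy(ligs, "D1")
        assert all(v == 0.0 for v in occ.values())

    def test_two_ligands_at_their_ki_occupy_one_third_each(self):
        ligs = [lig("a", 10.0, conc=10.0), lig("b", 3.0, conc=3.0)]
        occ = rk.competitive_occupancy(ligs, "D1")
        assert occ["a"] == pytest.approx(1.0 / 3.0)
        assert occ["b"] == pytest.approx(1.0 / 3.0)

    def test_missing_affinity_raises(self):
        with pytest.raises(KeyError):
            rk.competitive_occupancy([lig("a", 10.0, receptor="D1")], "5HT2A")

    def test_negative_concentration_raises(self):
        with pytest.raises(ValueError):
            rk.Ligand("a", {"D1": 1.0}, {}, -1.0)

    @settings(max_examples=50, deadline=None)
    @given(
        concs=st.lists(st.floats(0.0, 1e4), min_size=1, max_size=4),
        kis=st.lists(st.floats(1e-2, 1e4), min_size=4, max_size=4),
        scale=st.floats(1e-3, 1e3),
    )
    def test_scale_invariance(self, concs, kis, scale):
        """Multiplying every C and Ki by one factor leaves occupancy fixed."""
        ligs = [lig(f"l{i}", k, conc=c)
                for i, (c, k) in enumerate(zip(concs, kis))]
        scaled = [lig(f"l{i}", k * scale, conc=c * scale)
                  for i, (c, k) in enumerate(zip(concs, kis))]
        occ = rk.competitive_occupancy(ligs, "D1")
        occ2 = rk.competitive_occupancy(scaled, "D1")
        for name in occ:
            assert occ[name] == pytest.approx(occ2[name], rel=1e-9, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_mass_action_equilibrium_solver(self, seed):
        """Independent oracle: solve the receptor-conservation fixed point for
        trace receptor density and compare bound fractions."""
        rng = np.random.default_rng(seed)
        concs = rng.uniform(0.1, 500.0, 3)
        kis = rng.uniform(0.5, 200.0, 3)
        ligs = [lig(f"l{i}", kis[i], conc=concs[i]) for i in range(3)]

        def free_receptor(r):
            # r = fraction of receptors free; bound_i = r * C_i / K_i
            return r * (1.0 + np.sum(concs / kis)) - 1.0

        r_free = brentq(free_receptor, 0.0, 1.0, xtol=1e-15)
        expected = {f"l{i}": r_free * concs[i] / kis[i] for i in range(3)}
        occ = rk.competitive_occupancy(ligs, "D1")
        for name in occ:
            assert occ[name] == pytest.approx(expected[name], abs=1e-9)

    def test_d2_pools_combined_by_high_affinity_fraction(self):
        """An agonist binds the low-affinity pool 100x more weakly, so total
        occupancy interpolates between the pool occupancies."""
        agonist = rk.Ligand("ag", {"D2": 10.0}, {"D2": 1.0}, 10.0)
        occ_75 = rk.competitive_occupancy([agonist], "D2", 0.75)["ag"]
        occ_hi = rk.competitive_occupancy([agonist], "D2", 1.0)["ag"]
        assert occ_hi == pytest.approx(0.5)
        lo_pool = (10.0 / 1000.0) / (1.0 + 10.0 / 1000.0)
        assert occ_75 == pytest.approx(0.75 * 0.5 + 0.25 * lo_pool)

    def test_antagonist_binds_both_pools_equally(self):
        antag = rk.Ligand("an", {"D2": 10.0}, {}, 10.0)
        assert rk.competitive_occupancy([antag], "D2", 0.75)["an"] == \
            pytest.approx(0.5)


class TestReceptorActivation:
    def test_full_agonist_at_half_occupancy(self):
        l = lig("a", 10.0, eff=1.0, conc=10.0)
        occ = rk.competitive_occupancy([l], "D1")
        assert rk.receptor_activation(occ, [l], "D1") == pytest.approx(0.5)

    def test_pure_antagonist_contributes_nothing(self):
        l = lig("a", 10.0, eff=0.0, conc=1e6)
        occ = rk.competitive_occupancy([l], "D1")
        assert rk.receptor_activation(occ, [l], "D1") == 0.0

    def test_partial_agonist_with_antagonist(self):
        """Partial agonist (eff 0.4) at occupancy 0.5 plus an antagonist at
        occupancy 0.3 -> activation 0.20."""
        part = lig("p", 1.0, eff=0.4)
        ant = lig("q", 1.0, eff=0.0)
        occ = {"p": 0.5, "q": 0.3}
        assert rk.receptor_activation(occ, [part, ant], "D1") == \
            pytest.approx(0.20)


class TestDopamineTimecourse:
    def test_single_release_decays_with_half_life(self):
        state = rk.DopamineSynapseState(firing_rate=0.0, half_life=50.0)
        trace = rk.simulate_da_timecourse(state, 200.0, seed=0, initial=100.0)
        assert trace[50] / trace[0] == pytest.approx(0.5, rel=0.02)

    def test_no_firing_no_da(self):
        state = rk.DopamineSynapseState(firing_rate=0.0)
        trace = rk.simulate_da_timecourse(state, 500.0, seed=0)
        assert np.all(trace == 0.0)

    def test_trace_nonnegative(self):
        state = rk.DopamineSynapseState()
        assert np.all(rk.simulate_da_timecourse(state, 5000.0, seed=3) >= 0)

    def test_long_run_mean_matches_closed_form(self):
        """Steady state of linear clearance: quantum * rate * half_life/ln2,
        within Monte-Carlo error pooled over three seeds of 100 s each."""
        state = rk.DopamineSynapseState()
        means = [rk.simulate_da_timecourse(state, 100_000.0, seed=s)[1000:].mean()
                 for s in (1, 2, 3)]
        expected = (state.quantum * state.firing_rate
                    * state.half_life / rk.LN2 / 1000.0)
        assert np.mean(means) == pytest.approx(expected, rel=0.05)

    def test_nonpositive_half_life_rejected(self):
        with pytest.raises(ValueError):
            rk.DopamineSynapseState(half_life=0.0)


def _tracer(receptor="D2"):
    return rk.Ligand("tracer", {receptor: 1.0}, {}, 0.0, role="tracer")


class TestTracerDisplacement:
    def test_identical_states_displace_nothing(self):
        h = rk.DopamineSynapseState()
        assert rk.tracer_displacement(h, h, _tracer(), "D2") == \
            pytest.approx(0.0, abs=1e-9)

    def test_displacement_monotone_in_release(self):
        h = rk.DopamineSynapseState()
        disp = [rk.tracer_displacement(h, h.scaled(r), _tracer(), "D2")
                for r in np.linspace(1.0, 4.0, 8)]
        assert np.all(np.diff(disp) > 0)

    def test_slower_clearance_displaces_dat_tracer(self):
        """DAT downregulation (longer half-life) raises free DA and displaces
        a DAT tracer even at fixed release."""
        h = rk.DopamineSynapseState(half_life=50.0)
        slow = rk.DopamineSynapseState(half_life=100.0)
        d = rk.tracer_displacement(h, slow, _tracer("DAT"), "DAT")
        assert d > 0

    def test_non_tracer_rejected(self):
        h = rk.DopamineSynapseState()
        with pytest.raises(ValueError):
            rk.tracer_displacement(h, h, lig("drug", 1.0, receptor="D2"), "D2")


class TestPlaceboMapping:
    def test_zero_displacement_is_unit_fold(self):
        assert rk.release_change_from_displacement(0.0, rk.D2_TRACER) == 1.0

    def test_acute_anchor(self):
        """23% D2-antagonist-tracer displacement -> +120% release."""
        fold = rk.release_change_from_displacement(23.0, rk.D2_TRACER)
        assert 100.0 * (fold - 1.0) == pytest.approx(120.0, abs=0.1)

    def test_chronic_anchor(self):
        """11% DAT-tracer displacement -> +40% release."""
        fold = rk.release_change_from_displacement(11.0, rk.DAT_TRACER)
        assert 100.0 * (fold - 1.0) == pytest.approx(40.0, abs=0.1)

    @pytest.mark.parametrize("tracer_class", [rk.D2_TRACER, rk.DAT_TRACER])
    def test_roundtrip_identity(self, tracer_class):
        """displacement(release(d)) == d across the invertible range."""
        for d in [2.0, 8.0, 15.0, 30.0]:
            fold = rk.release_change_from_displacement(d, tracer_class)
            back = rk.displacement_from_release(fold, tracer_class)
            assert back == pytest.approx(d, abs=1e-6)

    def test_out_of_range_displacement_names_maximum(self):
        with pytest.raises(ValueError, match="attainable maximum"):
            rk.release_change_from_displacement(99.9, rk.DAT_TRACER)

    def test_autoreceptor_makes_da_sublinear_in_release(self):
        """Doubling release raises steady-state free DA less than 2-fold."""
        assert 1.0 < rk.da_fold(2.0) < 2.0
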