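"""Dose -> concentration -> per-receptor activation changes."""

import numpy as np
import pytest

from bgqsp import pharmacology as ph
from bgqsp import receptor_kinetics as rk
from bgqsp.coupling import default_table
from bgqsp.pathology import healthy_state, pd_state, schizophrenia_state


@pytest.fixture
def prami():
    """D2-preferring agonist anchored at 0.125 mg -> 10% D2-tracer reduction."""
    return ph.DrugSpec(
        "d2_agonist_syn",
        ligands=[rk.Ligand("d2_agonist_syn",
                           {"D2": 3.9, "D2S": 3.9, "D3": 0.5},
                           {"D2": 0.8, "D2S": 1.0, "D3": 1.0})],
        pk_anchor=ph.PKAnchor(0.125, 10.0, rk.D2_TRACER),
    )


@pytest.fixture
def d2_blocker():
    return ph.DrugSpec(
        "d2_blocker_syn",
        ligands=[rk.Ligand("d2_blocker_syn", {"D2": 1.0, "D2S": 1.0}, {})],
        engagement=ph.Engagement("D2", 0.6, 10.0),
    )


class TestDoseToConcentration:
    def test_zero_dose_zero_concentration(self, prami):
        assert ph.dose_to_concentration(prami, 0.0)["d2_agonist_syn"] == 0.0

    def test_linear_pharmacokinetics(self, prami):
        c1 = ph.dose_to_concentration(prami, 0.5)["d2_agonist_syn"]
        c2 = ph.dose_to_concentration(prami, 1.0)["d2_agonist_syn"]
        assert c2 == pytest.approx(2.0 * c1)

    def test_anchor_reproduced_through_displacement_model(self, prami):
        """The anchored dose reproduces the anchored tracer displacement to
        half a percentage point when run back through the imaging model."""
        disp = ph.drug_tracer_displacement(prami, 0.125)
        assert disp == pytest.approx(10.0, abs=0.5)

    def test_double_dose_displacement_near_doubling(self, prami):
        """At low occupancy the competition model is near-linear: twice the
        anchored dose displaces close to twice the anchored amount."""
        disp = ph.drug_tracer_displacement(prami, 0.25)
        assert 15.0 < disp < 22.0

    def test_unanchored_drug_flagged(self, d2_blocker):
        assert not d2_blocker.calibrated

    def test_anchor_unattainable_raises(self):
        with pytest.raises(ValueError, match="anchor"):
            bad = ph.DrugSpec(
                "bad", ligands=[rk.Ligand("bad", {"5HT2A": 1.0}, {})],
                pk_anchor=ph.PKAnchor(1.0, 50.0, rk.D2_TRACER))
            ph.pk_slope(bad)

    def test_metabolite_scales_with_parent(self, prami):
        drug = ph.DrugSpec(
            "parent", ligands=[
                rk.Ligand("parent", {"D2": 5.0}, {"D2": 1.0}),
                rk.Ligand("metab", {"D2": 50.0}, {"D2": 0.5},
                          role="metabolite"),
            ],
            pk_anchor=ph.PKAnchor(1.0, 20.0, rk.D2_TRACER),
            metabolite_ratios={"metab": 0.3},
        )
        conc = ph.dose_to_concentration(drug, 2.0)
        assert conc["metab"] == pytest.approx(0.3 * conc["parent"])


class TestActivationDelta:
    def test_empty_regimen_all_zero(self):
        delta = ph.activation_delta_vector(ph.Regimen(), schizophrenia_state())
        assert max(abs(v) for v in delta.values()) == 0.0

    def test_zero_affinity_drug_gives_zero_vector(self):
        inert = ph.DrugSpec(
            "inert", ligands=[rk.Ligand("inert", {"DAT": 5.0}, {})],
            engagement=ph.Engagement("DAT", 0.5, 1.0))
        delta = ph.activation_delta_vector(
            ph.Regimen(arms=[(inert, 1e4)]), healthy_state())
        table_receptors = default_table().receptors()
        assert all(delta[r] == pytest.approx(0.0, abs=1e-9)
                   for r in table_receptors if not r.startswith("D2"))

    def test_saturating_d2_antagonist_cancels_baseline(self, d2_blocker):
        sz = schizophrenia_state()
        base = ph.baseline_activation("D2", sz)
        delta = ph.activation_delta_vector(
            ph.Regimen(arms=[(d2_blocker, 1e5)]), sz)
        assert delta["D2"] == pytest.approx(-base, abs=0.05)

    def test_d1_agonist_on_depleted_state_positive_bounded(self):
        d1 = ph.DrugSpec(
            "d1ag", ligands=[rk.Ligand("d1ag", {"D1": 30.0}, {"D1": 1.0})],
            engagement=ph.Engagement("D1", 0.6, 10.0))
        pd = pd_state(0.9)
        base = ph.baseline_activation("D1", pd)
        delta = ph.activation_delta_vector(ph.Regimen(arms=[(d1, 40.0)]), pd)
        assert 0.0 < delta["D1"] <= 1.0 - base + 1e-9

    def test_monotone_dose_response_single_target_agonist(self):
        d1 = ph.DrugSpec(
            "d1ag", ligands=[rk.Ligand("d1ag", {"D1": 30.0}, {"D1": 1.0})],
            engagement=ph.Engagement("D1", 0.6, 10.0))
        pd = pd_state(0.8)
        deltas = [
            ph.activation_delta_vector(ph.Regimen(arms=[(d1, dose)]), pd)["D1"]
            for dose in [0.0, 5.0, 20.0, 80.0]
        ]
        assert np.all(np.diff(deltas) >= -1e-12)

    def test_unknown_receptor_warned_and_ignored(self, caplog):
        odd = ph.DrugSpec(
            "odd", ligands=[rk.Ligand("odd", {"SIGMA1": 5.0, "D1": 20.0},
                                      {"D1": 1.0})],
            engagement=ph.Engagement("D1", 0.5, 1.0))
        with caplog.at_level("WARNING", logger="bgqsp.pharmacology"):
            ph.activation_delta_vector(ph.Regimen(arms=[(odd, 1.0)]),
                                       healthy_state())
        assert any("SIGMA1" in rec.message for rec in caplog.records)

    def test_ldopa_comedication_raises_da_receptor_activation(self):
        pd = pd_state(0.8)
        delta = ph.activation_delta_vector(
            ph.Regimen(da_release_fold=2.0), pd)
        assert delta["D1"] > 0 and delta["D2"] > 0


class TestA2ACoupling:
    def test_gain_anchors(self):
        assert ph.a2a_coupling_gain(0.0) == 1.0
        assert ph.a2a_coupling_gain(0.90) == pytest.approx(1.65)

    def test_linear_interpolation(self):
        assert ph.a2a_coupling_gain(0.45) == pytest.approx(1.325)

    def test_clipped_below_at_one(self):
        assert ph.a2a_coupling_gain(1e-12) >= 1.0

    def test_out_of_range_occupancy_rejected(self):
        with pytest.raises(ValueError):
            ph.a2a_coupling_gain(1.5)

    def test_regimen_occupancy_competes_with_adenosine(self):
        a2a = ph.DrugSpec(
            "a2ab", ligands=[rk.Ligand("a2ab", {"A2A": 10.0}, {})],
            engagement=ph.Engagement("A2A", 0.9, 40.0))
        occ = ph.regimen_a2a_occupancy(
            ph.Regimen(arms=[(a2a, 40.0)]), healthy_state())
        assert 0.5 < occ < 1.0
        assert ph.regimen_a2a_occupancy(ph.Regimen(), healthy_state()) == 0.0
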