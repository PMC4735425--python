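"""Receptor-activation -> conductance coupling: the pharmacology-to-physiology bridge.

Each :class:`CouplingRule` maps a change in the activation of one receptor to a
multiplicative modulation of one membrane-channel or synaptic maximal
conductance on one cell population, through a signed linear gain:

    multiplier(population, target) = clip(1 + sum_rules k * delta_activation,
                                          lo, hi)

Rules acting on the same (population, target) compose additively inside the
clip.  Rules that share physical meaning (e.g. the D2 effect on cortical
glutamate release onto both MSN types, via both AMPA and NMDA) share a single
named gain parameter; the seven parameters adjusted during clinical
calibration are listed in :data:`CALIBRATED7`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "CouplingRule",
    "CouplingTable",
    "apply_modulation",
    "default_table",
    "CALIBRATED7",
    "KNOWN_RECEPTORS",
]

KNOWN_RECEPTORS = frozenset({
    "D1", "D2", "D2S", "D3",
    "5HT1A", "5HT1B", "5HT2A", "5HT4",
    "M1", "M2", "nACh", "alpha",
    "A2A", "DAT", "NMDA", "AMPA", "GABA_A", "mGluR23",
})

#: Channel targets understood by the circuit, per population.
CHANNEL_TARGETS = {
    "MSN_D1": {"K_ir", "K_A"},
    "MSN_D2": {"K_ir", "K_A"},
    "Pyr": {"HVA", "Na_p", "K_dr", "K_Ca", "leak"},
    "BC": {"K_dr", "leak"},
    "TC": {"Ih", "K_leak"},
    "Re": {"leak", "K_leak"},
    "STN": set(),
    "GPe": set(),
    "GPi": set(),
}

#: Synaptic (projection) targets understood by the circuit, per postsynaptic
#: population.  A multiplier on such a target scales the gmax of that afferent
#: projection; presynaptic release modulation is represented the same way.
SYNAPTIC_TARGETS = {
    "MSN_D1": {"ctx_AMPA", "ctx_NMDA"},
    "MSN_D2": {"ctx_AMPA", "ctx_NMDA"},
    "Pyr": {"ee_AMPA", "ee_NMDA", "bc_GABA", "tc_AMPA", "tc_NMDA"},
    "BC": {"pyr_AMPA"},
    "STN": {"hyperdirect_AMPA", "gpe_GABA"},
    "GPe": {"stn_AMPA", "msn_GABA", "mGluR"},
    "GPi": {"msn_GABA", "stn_AMPA"},
    "TC": {"gpi_GABA", "re_GABA"},
    "Re": {"tc_AMPA"},
}

#: The seven gain parameters adjusted during the clinical calibration.
CALIBRATED7 = (
    "d1_msn_kir",    # D1 effect on D1+ MSN via K_ir
    "d2_msn_ka",     # D2 effect on D2+ MSN via A-type K+
    "d2_ctx_glu",    # D2 effect on all MSN via cortical AMPA/NMDA gmax
    "ht2a_pyr",      # 5-HT2A effect on Pyr via HVA and persistent Na+
    "ht4_pyr",       # 5-HT4 effect on Pyr via K_dr and K_Ca
    "m1_pyr_kdr",    # M1 effect on Pyr via K_dr
    "d1_pyr_ee",     # D1 effect on Pyr via recurrent e-e AMPA/NMDA gmax
)

DEFAULT_BOUNDS = (0.2, 3.0)


@dataclass(frozen=True)
class CouplingRule:
    """One receptor -> conductance coupling with a signed linear gain."""

    receptor: str
    population: str
    target: str
    gain: float
    lo: float = DEFAULT_BOUNDS[0]
    hi: float = DEFAULT_BOUNDS[1]
    param: str = ""

    def __post_init__(self):
        if self.receptor not in KNOWN_RECEPTORS:
            raise ValueError(f"unknown receptor {self.receptor!r}")
        pop = self.population
        ok = (self.target in CHANNEL_TARGETS.get(pop, set())
              or self.target in SYNAPTIC_TARGETS.get(pop, set()))
        if not ok:
            raise ValueError(
                f"unknown target {self.target!r} for population {pop!r}"
            )
        if not 0.0 < self.lo <= 1.0 <= self.hi:
            raise ValueError(f"bounds must satisfy 0 < lo <= 1 <= hi, got "
                             f"[{self.lo}, {self.hi}]")
        if not self.param:
            object.__setattr__(
                self, "param",
                f"{self.receptor.lower()}_{pop.lower()}_{self.target.lower()}",
            )


@dataclass
class CouplingTable:
    """The full receptor->conductance gain map, including the calibrated seven."""

    rules: list = field(default_factory=list)
    calibrated7: tuple = CALIBRATED7

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        params = {r.param for r in self.rules}
        missing = [p for p in self.calibrated7 if p not in params]
        if missing:
            raise ValueError(f"calibrated parameters missing from table: {missing}")
        if len(set(self.calibrated7)) != len(self.calibrated7):
            raise ValueError("calibrated7 parameters must be unique")

    # -- gain-parameter interface ------------------------------------------
    def gains(self, params: Iterable[str] | None = None) -> dict:
        """Current gain per named parameter (calibrated seven by default)."""
        params = tuple(params) if params is not None else self.calibrated7
        out = {}
        for p in params:
            vals = {r.gain for r in self.rules if r.param == p}
            if not vals:
                raise KeyError(f"no rule with param {p!r}")
            if len(vals) > 1:
                raise ValueError(f"rules sharing param {p!r} have diverging gains")
            out[p] = vals.pop()
        return out

    def with_gains(self, gains: Mapping[str, float]) -> "CouplingTable":
        """New table with the given named gains replaced."""
        rules = [
            replace(r, gain=float(gains[r.param])) if r.param in gains else r
            for r in self.rules
        ]
        return CouplingTable(rules, self.calibrated7)

    def scaled(self, param_scale: Mapping[str, float]) -> "CouplingTable":
        """New table with gains of the named parameters multiplied (used for
        the adenosine A2A amplification of the D2->K_A coupling)."""
        rules = [
            replace(r, gain=r.gain * param_scale.get(r.param, 1.0))
            for r in self.rules
        ]
        return CouplingTable(rules, self.calibrated7)

    def receptors(self) -> set:
        return {r.receptor for r in self.rules}

    # -- serialization ------------------------------------------------------
    def to_csv(self, path) -> None:
        df = pd.DataFrame(
            [
                dict(param=r.param, receptor=r.receptor, population=r.population,
                     target=r.target, gain=repr(r.gain), lo=repr(r.lo),
                     hi=repr(r.hi))
                for r in self.rules
            ]
        )
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, calibrated7: tuple = CALIBRATED7) -> "CouplingTable":
        df = pd.read_csv(path, dtype=str)
        required = {"param", "receptor", "population", "target", "gain", "lo", "hi"}
        if not required.issubset(df.columns):
            raise ValueError(
                f"coupling table missing columns {sorted(required - set(df.columns))}"
            )
        rules = [
            CouplingRule(
                receptor=row.receptor, population=row.population,
                target=row.target, gain=float(row.gain), lo=float(row.lo),
                hi=float(row.hi), param=row.param,
            )
            for row in df.itertuples()
        ]
        return cls(rules, calibrated7)


def apply_modulation(table: CouplingTable, delta: Mapping) -> dict:
    """Conductance multipliers from an activation-change vector.

    ``delta`` maps receptor -> change of activation (signed fraction); a key
    ``(receptor, population)`` overrides the per-receptor value for that
    population.  Returns map (population, target) -> multiplier, clipped into
    the rule bounds so the resulting conductance is always positive.
    """
    acc: dict = {}
    bounds: dict = {}
    for r in table.rules:
        d = delta.get((r.receptor, r.population), delta.get(r.receptor, 0.0))
        key = (r.population, r.target)
        acc[key] = acc.get(key, 0.0) + r.gain * d
        lo, hi = bounds.get(key, (r.lo, r.hi))
        bounds[key] = (min(lo, r.lo), max(hi, r.hi))
    out = {}
    for key, s in acc.items():
        lo, hi = bounds[key]
        out[key] = min(max(1.0 + s, lo), hi)
    return out


def default_table() -> CouplingTable:
    """The coupling rules stated in the model description, with the calibrated
    seven at their healthy-calibration gains and the remaining couplings at
    modest literature-signed defaults."""
    R = CouplingRule
    rules = [
        # --- the calibrated seven -----------------------------------------
        R("D1", "MSN_D1", "K_ir", -0.8, param="d1_msn_kir"),
        R("D2", "MSN_D2", "K_A", -1.6, param="d2_msn_ka"),
        R("D2", "MSN_D1", "ctx_AMPA", -0.3, param="d2_ctx_glu"),
        R("D2", "MSN_D1", "ctx_NMDA", -0.3, param="d2_ctx_glu"),
        R("D2", "MSN_D2", "ctx_AMPA", -0.3, param="d2_ctx_glu"),
        R("D2", "MSN_D2", "ctx_NMDA", -0.3, param="d2_ctx_glu"),
        R("5HT2A", "Pyr", "HVA", +0.8, param="ht2a_pyr"),
        R("5HT2A", "Pyr", "Na_p", +0.8, param="ht2a_pyr"),
        R("5HT4", "Pyr", "K_dr", -0.6, param="ht4_pyr"),
        R("5HT4", "Pyr", "K_Ca", -0.6, param="ht4_pyr"),
        R("M1", "Pyr", "K_dr", -0.5, param="m1_pyr_kdr"),
        R("D1", "Pyr", "ee_AMPA", +0.4, param="d1_pyr_ee"),
        R("D1", "Pyr", "ee_NMDA", +0.4, param="d1_pyr_ee"),
        # --- remaining couplings from the model description ---------------
        # muscarinic M2: more Ih in thalamocortical cells, more leak in
        # reticular cells; 5-HT2A acts the same way on the thalamus
        R("M2", "TC", "Ih", +0.5, param="m2_tc_ih"),
        R("M2", "Re", "leak", +0.5, param="m2_re_leak"),
        R("5HT2A", "TC", "Ih", +2.0, param="ht2a_tc_ih"),
        R("5HT2A", "Re", "leak", +1.2, param="ht2a_re_leak"),
        # M1 also couples to the pyramidal leak conductance
        R("M1", "Pyr", "leak", -0.3, param="m1_pyr_leak"),
        # adrenergic: K+ conductance at interneuron somata up (less GABA
        # excitability); regulates glutamatergic but not GABAergic synapses
        R("alpha", "BC", "K_dr", +0.5, param="alpha_bc_kdr"),
        R("alpha", "Pyr", "ee_AMPA", -0.3, param="alpha_pyr_glu"),
        # nicotinic: enhances GABA neurotransmission and glutamate release
        R("nACh", "Pyr", "bc_GABA", +0.3, param="nach_gaba"),
        R("nACh", "Pyr", "ee_AMPA", +0.3, param="nach_glu"),
        R("nACh", "Pyr", "ee_NMDA", +0.3, param="nach_glu"),
        R("nACh", "BC", "pyr_AMPA", +0.3, param="nach_glu_bc"),
        # pallidal serotonin receptors shape excitation/inhibition at the STN
        R("5HT1B", "STN", "hyperdirect_AMPA", -0.5, param="ht1b_stn_glu"),
        R("5HT1A", "GPe", "stn_AMPA", -0.4, param="ht1a_gpe_glu"),
    ]
    return CouplingTable(rules)
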