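"""Competitive multi-ligand receptor occupancy, activation, and synaptic dopamine dynamics.

This module implements the receptor-competition synapse at the bottom of the
pharmacology chain: equilibrium competitive binding between neurotransmitter,
parent drug, active metabolite and PET tracer at a shared receptor; activation
as efficacy-weighted occupancy; a stochastic impulse-release/first-order
clearance model of synaptic dopamine; and the tracer-displacement model used
to anchor target engagement to human PET imaging, together with its inverse
(observed displacement -> fold change of presynaptic dopamine release).

Binding is treated as equilibrium competition (no association/dissociation
kinetics): all readouts downstream consume occupancy and activation fractions
only.  D2-family receptors are modelled as a mixture of a high- and a
low-affinity sub-pool; agonists (efficacy > 0, including dopamine itself) see
the listed Ki against the high-affinity pool and a conventional 100x weaker Ki
against the low-affinity pool, while neutral antagonists and tracers bind both
pools with the same Ki.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "Ligand",
    "ReceptorPool",
    "DopamineSynapseState",
    "competitive_occupancy",
    "receptor_activation",
    "simulate_da_timecourse",
    "steady_state_free_da",
    "da_fold",
    "tracer_displacement",
    "displacement_from_release",
    "release_change_from_displacement",
    "placebo_anchor_constants",
    "dopamine_ligand",
    "D2_TRACER",
    "DAT_TRACER",
]

LN2 = math.log(2.0)

#: Receptors carrying a high/low affinity two-state mixture (D2-like family).
D2_FAMILY = frozenset({"D2", "D2S"})

#: Ratio between low- and high-affinity state Ki for agonists at D2-family
#: receptors (conventional two-state ratio; the text manipulates only the
#: high-affinity fraction).
LOW_AFFINITY_RATIO = 100.0

#: Default fraction of D2 receptors in the agonist-high-affinity state under
#: normal dopamine release.
DEFAULT_HIGH_AFFINITY_FRACTION = 0.75

#: Tracer classes used for PET anchoring.
D2_TRACER = "D2-antagonist-tracer"
DAT_TRACER = "DAT-tracer"

# --- humanized dopamine synapse defaults -----------------------------------
# Stand-ins for the companion synapse calibration: chosen so the healthy
# steady-state free dopamine is ~30 nM at 4 Hz tonic firing with a 50 ms
# half-life and 50% maximal autoreceptor feedback.
DA_QUANTUM_NM = 150.0          # nM added to the free pool per release event
DA_TONIC_RATE_HZ = 4.0         # presynaptic tonic firing rate
DA_HALF_LIFE_MS = 50.0         # healthy synaptic clearance half-life
AUTORECEPTOR_GAIN = 0.5        # f_auto: release *= (1 - f_auto * act_D2S)

#: Functional affinities (Ki, nM) of dopamine at its receptors.  D2-family
#: entries are the high-affinity-state Ki.  These set baseline activation
#: levels in the network chain; the PET-imaging displacement model uses its
#: own anchored constants (see ``placebo_anchor_constants``).
DA_AFFINITIES = {
    "D1": 3.0,
    "D2": 8.0,
    "D2S": 10.0,
    "D3": 8.0,
}

#: Release-fold anchors for the placebo PET mapping: a 23% displacement of a
#: D2-antagonist tracer corresponds to +120% release (acute), an 11%
#: displacement of a DAT tracer to +40% release (chronic).
ANCHORS = {D2_TRACER: (23.0, 2.2), DAT_TRACER: (11.0, 1.4)}


@dataclass
class Ligand:
    """A binding species: neurotransmitter, drug, active metabolite or tracer.

    Parameters
    ----------
    name:
        Identifier.
    affinities:
        Map receptor -> Ki in nM (all > 0).
    efficacies:
        Map receptor -> intrinsic efficacy in [0, 1] (0 = neutral antagonist,
        1 = full agonist).  Receptors absent from the map are treated as
        efficacy 0.
    concentration:
        Free synaptic concentration in nM (>= 0).
    role:
        One of ``neurotransmitter``, ``drug``, ``metabolite``, ``tracer``.
    """

    name: str
    affinities: dict = field(default_factory=dict)
    efficacies: dict = field(default_factory=dict)
    concentration: float = 0.0
    role: str = "drug"

    def __post_init__(self):
        if self.role not in ("neurotransmitter", "drug", "metabolite", "tracer"):
            raise ValueError(f"unknown ligand role {self.role!r} for {self.name}")
        for rec, ki in self.affinities.items():
            if not ki > 0:
                raise ValueError(f"{self.name}: Ki at {rec} must be > 0, got {ki}")
        for rec, eff in self.efficacies.items():
            if not 0.0 <= eff <= 1.0:
                raise ValueError(
                    f"{self.name}: efficacy at {rec} must be in [0,1], got {eff}"
                )
        if self.concentration < 0:
            raise ValueError(
                f"{self.name}: concentration must be >= 0, got {self.concentration}"
            )

    def efficacy(self, receptor: str) -> float:
        return float(self.efficacies.get(receptor, 0.0))

    def ki(self, receptor: str) -> float:
        try:
            return float(self.affinities[receptor])
        except KeyError:
            raise KeyError(
                f"ligand {self.name!r} has no affinity for receptor {receptor!r}"
            ) from None

    def is_agonist_at(self, receptor: str) -> bool:
        """Agonist-like ligands prefer the high-affinity state of D2-family
        receptors; neutral antagonists and tracers do not discriminate."""
        return self.efficacy(receptor) > 0.0 and self.role != "tracer"

    def with_concentration(self, concentration: float) -> "Ligand":
        return Ligand(
            self.name, dict(self.affinities), dict(self.efficacies),
            concentration, self.role,
        )


@dataclass
class ReceptorPool:
    """A postsynaptic receptor population."""

    receptor: str
    high_affinity_fraction: float = DEFAULT_HIGH_AFFINITY_FRACTION
    baseline_activation: float = 0.0

    def __post_init__(self):
        for name in ("high_affinity_fraction", "baseline_activation"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")


@dataclass
class DopamineSynapseState:
    """Presynaptic/clearance parameterization of the striatal DA synapse.

    ``release_scale`` is the fold of normal per-event release (1 = healthy);
    ``half_life`` the synaptic clearance half-life in ms.
    """

    release_scale: float = 1.0
    firing_rate: float = DA_TONIC_RATE_HZ
    half_life: float = DA_HALF_LIFE_MS
    baseline_free_da: float | None = None
    high_affinity_fraction: float = DEFAULT_HIGH_AFFINITY_FRACTION
    quantum: float = DA_QUANTUM_NM

    def __post_init__(self):
        if not self.half_life > 0:
            raise ValueError(f"half_life must be > 0, got {self.half_life}")
        if self.release_scale < 0:
            raise ValueError(f"release_scale must be >= 0, got {self.release_scale}")

    def scaled(self, release_fold: float = 1.0, **overrides) -> "DopamineSynapseState":
        """Copy of this state with release multiplied by ``release_fold``."""
        kw = dict(
            release_scale=self.release_scale * release_fold,
            firing_rate=self.firing_rate,
            half_life=self.half_life,
            high_affinity_fraction=self.high_affinity_fraction,
            quantum=self.quantum,
        )
        kw.update(overrides)
        return DopamineSynapseState(**kw)


def _pool_occupancy(loads: Sequence[float]) -> list[float]:
    total = 1.0 + sum(loads)
    return [x / total for x in loads]


def competitive_occupancy(
    ligands: Sequence[Ligand],
    receptor: str,
    high_affinity_fraction: float = DEFAULT_HIGH_AFFINITY_FRACTION,
) -> dict:
    """Equilibrium competitive occupancy of ``receptor`` by every ligand.

    occupancy_i = (C_i/K_i) / (1 + sum_j C_j/K_j)

    For D2-family receptors the competition is solved separately in the high-
    and low-affinity sub-pools (agonist Ki applies to the high-affinity pool,
    a ``LOW_AFFINITY_RATIO``-fold weaker Ki to the low pool; antagonists and
    tracers use the listed Ki in both) and combined by
    ``high_affinity_fraction`` weighting.

    Returns a map ligand name -> occupancy fraction.  Occupancies are >= 0 and
    sum to <= 1.
    """
    for lig in ligands:
        if lig.concentration < 0:
            raise ValueError(f"{lig.name}: negative concentration")
        lig.ki(receptor)  # raises KeyError if missing

    if receptor in D2_FAMILY:
        f = float(high_affinity_fraction)
        if not 0.0 <= f <= 1.0:
            raise ValueError("high_affinity_fraction must be in [0,1]")
        hi_loads, lo_loads = [], []
        for lig in ligands:
            ki = lig.ki(receptor)
            c = lig.concentration
            if lig.is_agonist_at(receptor):
                hi_loads.append(c / ki)
                lo_loads.append(c / (ki * LOW_AFFINITY_RATIO))
            else:
                hi_loads.append(c / ki)
                lo_loads.append(c / ki)
        occ_hi = _pool_occupancy(hi_loads)
        occ_lo = _pool_occupancy(lo_loads)
        return {
            lig.name: f * oh + (1.0 - f) * ol
            for lig, oh, ol in zip(ligands, occ_hi, occ_lo)
        }

    loads = [lig.concentration / lig.ki(receptor) for lig in ligands]
    occ = _pool_occupancy(loads)
    return {lig.name: o for lig, o in zip(ligands, occ)}


def receptor_activation(
    occupancies: Mapping[str, float],
    ligands: Sequence[Ligand],
    receptor: str,
) -> float:
    """Activation fraction: efficacy-weighted sum of ligand occupancies."""
    by_name = {lig.name: lig for lig in ligands}
    act = 0.0
    for name, occ in occupancies.items():
        act += occ * by_name[name].efficacy(receptor)
    return min(max(act, 0.0), 1.0)


def activation_at(
    ligands: Sequence[Ligand],
    receptor: str,
    high_affinity_fraction: float = DEFAULT_HIGH_AFFINITY_FRACTION,
) -> float:
    """Convenience: occupancy + activation in one call."""
    occ = competitive_occupancy(ligands, receptor, high_affinity_fraction)
    return receptor_activation(occ, ligands, receptor)


def dopamine_ligand(concentration: float) -> Ligand:
    """Dopamine at its functional affinities (full agonist everywhere it binds)."""
    return Ligand(
        "dopamine",
        affinities=dict(DA_AFFINITIES),
        efficacies={r: 1.0 for r in DA_AFFINITIES},
        concentration=concentration,
        role="neurotransmitter",
    )


# ---------------------------------------------------------------------------
# Dopamine dynamics
# ---------------------------------------------------------------------------

def simulate_da_timecourse(
    state: DopamineSynapseState,
    duration: float,
    seed: int,
    dt: float = 1.0,
    initial: float = 0.0,
) -> np.ndarray:
    """Stochastic free-dopamine trace (nM per ``dt`` ms time step).

    Release events are drawn from a seeded Poisson process at
    ``state.firing_rate``; each event adds ``quantum * release_scale`` to the
    free pool, which is cleared first-order with rate ln2/half_life.
    """
    if not duration > 0:
        raise ValueError("duration must be > 0")
    if not state.half_life > 0:
        raise ValueError("half_life must be > 0")
    rng = np.random.default_rng(seed)
    n = int(round(duration / dt))
    decay = math.exp(-LN2 * dt / state.half_life)
    events = rng.poisson(state.firing_rate * dt / 1000.0, size=n)
    trace = np.empty(n)
    c = float(initial)
    q = state.quantum * state.release_scale
    for i in range(n):
        c = c * decay + q * events[i]
        trace[i] = c
    return trace


def _autoreceptor_activation(
    da: float,
    state: DopamineSynapseState,
    extra_ligands: Sequence[Ligand] = (),
) -> float:
    ligs = [dopamine_ligand(da)]
    ligs += [l for l in extra_ligands if "D2S" in l.affinities]
    return activation_at(ligs, "D2S", state.high_affinity_fraction)


def steady_state_free_da(
    state: DopamineSynapseState,
    extra_ligands: Sequence[Ligand] = (),
    f_auto: float = AUTORECEPTOR_GAIN,
) -> float:
    """Self-consistent steady-state free dopamine (nM).

    Solves  DA = Q * release_scale * (1 - f_auto * act_D2S(DA)) * rate * tau
    with tau = half_life/ln2, where act_D2S includes competition from any
    D2S-binding drug in ``extra_ligands`` (autoreceptor agonists suppress,
    antagonists enhance, release).
    """
    tau_s = state.half_life / LN2 / 1000.0
    drive = state.quantum * state.release_scale * state.firing_rate * tau_s
    if drive == 0.0:
        return 0.0

    def resid(da: float) -> float:
        act = _autoreceptor_activation(da, state, extra_ligands)
        return drive * (1.0 - f_auto * act) - da

    hi = drive  # feedback only reduces release; DA <= drive
    lo = drive * (1.0 - f_auto)
    return float(brentq(resid, lo * 0.5, hi * 1.001))


def da_fold(
    release_fold: float,
    baseline: DopamineSynapseState | None = None,
    extra_ligands: Sequence[Ligand] = (),
) -> float:
    """Fold change of steady-state free DA for a fold change of release.

    Autoreceptor feedback makes this sub-linear: doubling release raises
    steady-state free dopamine by less than 2-fold.
    """
    base = baseline or DopamineSynapseState()
    da0 = steady_state_free_da(base)
    da1 = steady_state_free_da(base.scaled(release_fold), extra_ligands)
    return da1 / da0


# ---------------------------------------------------------------------------
# Tracer displacement and the placebo mapping
# ---------------------------------------------------------------------------

def _d2_tracer_specific_binding(x: float, f_high: float) -> float:
    """Relative specific binding of a trace-dose D2-antagonist tracer against
    dopamine load ``x`` = DA / Ki(high pool).  The tracer binds both affinity
    sub-pools equally; dopamine sees the low pool 100x more weakly."""
    return f_high / (1.0 + x) + (1.0 - f_high) / (1.0 + x / LOW_AFFINITY_RATIO)


def _dat_tracer_specific_binding(x: float) -> float:
    """Relative specific binding of a trace-dose DAT tracer against dopamine
    load ``x`` = DA / K(DAT): single-site competition at the transporter."""
    return 1.0 / (1.0 + x)


def _displacement_for_fold(m: float, x_base: float, tracer_class: str,
                           f_high: float) -> float:
    """Percent displacement when free DA changes by fold ``m`` from a baseline
    dopamine load ``x_base`` (anchored, dimensionless)."""
    if tracer_class == D2_TRACER:
        b0 = _d2_tracer_specific_binding(x_base, f_high)
        b1 = _d2_tracer_specific_binding(m * x_base, f_high)
    elif tracer_class == DAT_TRACER:
        b0 = _dat_tracer_specific_binding(x_base)
        b1 = _dat_tracer_specific_binding(m * x_base)
    else:
        raise ValueError(f"unknown tracer class {tracer_class!r}")
    if b0 <= 0.0:
        raise ValueError("zero baseline tracer occupancy")
    return 100.0 * (1.0 - b1 / b0)


@lru_cache(maxsize=None)
def placebo_anchor_constants() -> dict:
    """One-time anchoring of the displacement->release mapping.

    Two dimensionless constants — the baseline dopamine load relative to the
    D2-tracer Ki, and relative to the DAT-tracer sensitivity — are solved so
    that the release-fold anchors reproduce the observed PET displacements:
    +120% release (fold 2.2) -> 23% D2-antagonist-tracer displacement and
    +40% release (fold 1.4) -> 11% DAT-tracer displacement.  The solved
    constants are cached for the process; ``scripts/anchor_placebo.py``
    reports them.
    """
    healthy = DopamineSynapseState()
    f_high = healthy.high_affinity_fraction
    out = {}
    for cls, key in ((D2_TRACER, "x_d2"), (DAT_TRACER, "x_dat")):
        disp_target, fold = ANCHORS[cls]
        m = da_fold(fold, healthy)

        def resid(log_x, m=m, cls=cls, disp_target=disp_target):
            return _displacement_for_fold(m, math.exp(log_x), cls, f_high) - disp_target

        out[key] = math.exp(brentq(resid, math.log(1e-4), math.log(1e4)))
        out[key.replace("x_", "fold_")] = fold
    return out


def _x_base_for(tracer_class: str) -> float:
    consts = placebo_anchor_constants()
    return consts["x_d2"] if tracer_class == D2_TRACER else consts["x_dat"]


def _tracer_class_for(tracer: Ligand, receptor: str) -> str:
    if receptor == "DAT":
        return DAT_TRACER
    return D2_TRACER


def tracer_displacement(
    baseline: DopamineSynapseState,
    challenge: DopamineSynapseState,
    tracer: Ligand,
    receptor: str = "D2",
    extra_ligands: Sequence[Ligand] = (),
) -> float:
    """Percent reduction in specific tracer binding between two synapse states.

    The free-dopamine level of each state is computed self-consistently
    (autoreceptor feedback included); the tracer, at trace dose, competes with
    dopamine at ``receptor`` using the anchored imaging constants.  Returns
    100 * (1 - occ_tracer(challenge)/occ_tracer(baseline)); 0 when the states
    are identical, positive when the challenge raises free dopamine.
    """
    if tracer.role != "tracer":
        raise ValueError(f"{tracer.name} is not a tracer (role={tracer.role!r})")
    tracer.ki(receptor)  # must bind the receptor
    cls = _tracer_class_for(tracer, receptor)
    x_base = _x_base_for(cls)
    da0 = steady_state_free_da(baseline)
    da1 = steady_state_free_da(challenge, extra_ligands)
    if da0 <= 0.0:
        raise ValueError("zero baseline dopamine: tracer displacement undefined")
    m = da1 / da0
    f_high = baseline.high_affinity_fraction
    return _displacement_for_fold(m, x_base, cls, f_high)


def displacement_from_release(
    release_fold: float,
    tracer_class: str = D2_TRACER,
    baseline: DopamineSynapseState | None = None,
) -> float:
    """Percent tracer displacement produced by a fold change of DA release."""
    base = baseline or DopamineSynapseState()
    m = da_fold(release_fold, base)
    return _displacement_for_fold(
        m, _x_base_for(tracer_class), tracer_class, base.high_affinity_fraction
    )


def release_change_from_displacement(
    displacement: float,
    tracer_class: str = D2_TRACER,
    baseline: DopamineSynapseState | None = None,
    fold_max: float = 100.0,
) -> float:
    """Invert the tracer-displacement model: displacement % -> release fold.

    0% displacement maps to fold 1.0.  By construction of the one-time
    anchoring, a 23% D2-antagonist-tracer displacement maps to fold 2.2
    (+120% release) and an 11% DAT-tracer displacement to fold 1.4 (+40%).
    """
    if displacement < 0:
        raise ValueError("displacement must be >= 0")
    if displacement == 0:
        return 1.0
    base = baseline or DopamineSynapseState()
    d_max = displacement_from_release(fold_max, tracer_class, base)
    if displacement >= d_max:
        raise ValueError(
            f"displacement {displacement:.3g}% outside the invertible range; "
            f"attainable maximum is {d_max:.3g}% at release fold {fold_max:g}"
        )

    def resid(r: float) -> float:
        return displacement_from_release(r, tracer_class, base) - displacement

    return float(brentq(resid, 1.0, fold_max, xtol=1e-10))
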