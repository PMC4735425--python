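"""Drug-dose regimens -> per-receptor activation changes under a disease state.

A :class:`DrugSpec` bundles the ligands a drug contributes to the synapse
(parent plus optional active metabolites), an optional PET anchoring point
(dose, observed tracer displacement, tracer class) that pins its intrasynaptic
concentration scale, and optional non-competitive mechanism components (a
presynaptic dopamine release fold for MAO-B-inhibitor-like activity, a
serotonin half-life fold for SERT inhibition, and direct ionotropic
conductance folds for NMDA/AMPA modulators).  Pharmacokinetics are linear:
concentration is proportional to dose, with the slope solved once from the
anchor through the receptor-competition model.  Drugs without an anchor
declare an explicit target-engagement point and are flagged uncalibrated.

:func:`activation_delta_vector` evaluates, for every receptor the coupling
table listens to, the activation with and without the drugs of a regimen —
both under the same disease-state neurotransmitter dynamics — and returns the
difference.  Comedication expressed as a dopamine release fold (L-DOPA,
MAO-B inhibition) enters through the dopamine synapse, not as a ligand.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from scipy.optimize import brentq

from . import receptor_kinetics as rk
from .coupling import KNOWN_RECEPTORS, CouplingTable, default_table
from .pathology import DiseaseState, healthy_state

__all__ = [
    "DrugSpec",
    "PKAnchor",
    "Engagement",
    "Regimen",
    "dose_to_concentration",
    "activation_delta_vector",
    "disease_delta_vector",
    "baseline_activation",
    "a2a_coupling_gain",
    "regimen_a2a_occupancy",
    "transmitter_ligands",
]

log = logging.getLogger(__name__)

#: A2A coupling-gain anchors: no occupancy -> x1.0; 90% occupancy (the maximal
#: tracer displacement reported for A2A antagonists) -> x1.65 on the D2->K_A
#: coupling parameter.
A2A_GAIN_AT_FULL_ANCHOR = 0.65
A2A_OCC_ANCHOR = 0.90

#: Baseline free concentrations (nM) and affinities of the non-dopamine
#: transmitters.  These set healthy baseline activations in the mid range so
#: both agonists and antagonists have room to move them; they are synthetic
#: calibration stand-ins, not measured constants.
TRANSMITTER_TONES = {
    "serotonin": dict(
        concentration=10.0,
        affinities={"5HT1A": 8.0, "5HT1B": 12.0, "5HT2A": 15.0, "5HT4": 20.0},
    ),
    "acetylcholine": dict(
        concentration=50.0,
        affinities={"M1": 40.0, "M2": 35.0, "nACh": 80.0},
    ),
    "norepinephrine": dict(
        concentration=20.0,
        affinities={"alpha": 25.0},
    ),
    "adenosine": dict(
        concentration=100.0,
        affinities={"A2A": 120.0},
    ),
    "glutamate": dict(
        concentration=1000.0,
        affinities={"NMDA": 2000.0, "AMPA": 2000.0, "mGluR23": 3000.0},
    ),
    "gaba": dict(
        concentration=1000.0,
        affinities={"GABA_A": 2000.0},
    ),
}

SEROTONIN_RECEPTORS = frozenset({"5HT1A", "5HT1B", "5HT2A", "5HT4"})
DA_RECEPTORS = frozenset({"D1", "D2", "D2S", "D3"})


@dataclass(frozen=True)
class PKAnchor:
    """PET anchoring point: at ``dose`` mg, the drug displaces ``displacement``
    percent of the tracer class's specific binding."""

    dose: float
    displacement: float
    tracer_class: str = rk.D2_TRACER

    def __post_init__(self):
        if not 0.0 < self.displacement < 100.0:
            raise ValueError("anchor displacement must be in (0, 100)")
        if not self.dose > 0:
            raise ValueError("anchor dose must be > 0")


@dataclass(frozen=True)
class Engagement:
    """Explicit target-engagement declaration for drugs without a PET anchor:
    ``occupancy`` at ``receptor`` when given at ``dose`` mg.  Flagged as
    uncalibrated; during clinical calibration these are the per-drug scalars
    optimized within biological ranges."""

    receptor: str
    occupancy: float
    dose: float

    def __post_init__(self):
        if not 0.0 < self.occupancy < 1.0:
            raise ValueError("engagement occupancy must be in (0, 1)")
        if not self.dose > 0:
            raise ValueError("engagement dose must be > 0")


@dataclass
class DrugSpec:
    """A drug: ligand templates plus optional non-competitive mechanisms."""

    name: str
    ligands: list = field(default_factory=list)
    pk_anchor: PKAnchor | None = None
    engagement: Engagement | None = None
    metabolite_ratios: dict = field(default_factory=dict)  # ligand name -> molar ratio
    release_fold_slope: float = 0.0       # DA release fold = 1 + slope * dose
    ht_half_life_slope: float = 0.0       # 5-HT half-life fold = 1 + slope * dose
    conductance_slopes: dict = field(default_factory=dict)  # e.g. {"NMDA": -0.01}
    dose_unit: str = "mg"

    def __post_init__(self):
        has_mechanism = (self.ligands or self.release_fold_slope
                         or self.ht_half_life_slope or self.conductance_slopes)
        if not has_mechanism:
            raise ValueError(f"{self.name}: drug declares no mechanism")
        if self.ligands and self.pk_anchor is None and self.engagement is None:
            raise ValueError(
                f"{self.name}: ligand-carrying drugs need a pk_anchor or an "
                f"explicit target-engagement declaration"
            )

    @property
    def calibrated(self) -> bool:
        """True when the concentration scale is pinned by a PET anchor."""
        return self.pk_anchor is not None

    def release_fold(self, dose: float) -> float:
        return max(1.0 + self.release_fold_slope * dose, 0.0)

    def ht_half_life_fold(self, dose: float) -> float:
        return max(1.0 + self.ht_half_life_slope * dose, 1e-3)

    def conductance_folds(self, dose: float) -> dict:
        return {
            t: max(1.0 + s * dose, 0.05)
            for t, s in self.conductance_slopes.items()
        }


@dataclass
class Regimen:
    """Drug-dose arms plus comedication.

    ``da_release_fold`` expresses L-DOPA / MAO-B comedication directly as a
    multiplicative increase of presynaptic dopamine release (2.0 = doubling).
    """

    arms: list = field(default_factory=list)   # list of (DrugSpec, dose)
    da_release_fold: float = 1.0

    def __post_init__(self):
        for drug, dose in self.arms:
            if dose < 0:
                raise ValueError(f"{drug.name}: dose must be >= 0")
        if self.da_release_fold < 0:
            raise ValueError("da_release_fold must be >= 0")

    def total_release_fold(self) -> float:
        fold = self.da_release_fold
        for drug, dose in self.arms:
            fold *= drug.release_fold(dose)
        return fold

    def total_ht_fold(self) -> float:
        fold = 1.0
        for drug, dose in self.arms:
            fold *= drug.ht_half_life_fold(dose)
        return fold

    def total_conductance_folds(self) -> dict:
        folds: dict = {}
        for drug, dose in self.arms:
            for t, f in drug.conductance_folds(dose).items():
                folds[t] = folds.get(t, 1.0) * f
        return folds


# ---------------------------------------------------------------------------
# Dose -> concentration
# ---------------------------------------------------------------------------

def _imaging_displacement_by_drug(
    loads_hi: float, loads_lo: float, x_base: float, f_high: float,
    tracer_class: str,
) -> float:
    """Percent displacement of a trace-dose tracer by competing drug loads
    (dimensionless C/Ki) at the anchored imaging synapse."""
    if tracer_class == rk.D2_TRACER:
        b0 = (f_high / (1.0 + x_base)
              + (1.0 - f_high) / (1.0 + x_base / rk.LOW_AFFINITY_RATIO))
        b1 = (f_high / (1.0 + x_base + loads_hi)
              + (1.0 - f_high) / (1.0 + x_base / rk.LOW_AFFINITY_RATIO + loads_lo))
    elif tracer_class == rk.DAT_TRACER:
        b0 = 1.0 / (1.0 + x_base)
        b1 = 1.0 / (1.0 + x_base + loads_hi)
    else:
        raise ValueError(f"unknown tracer class {tracer_class!r}")
    return 100.0 * (1.0 - b1 / b0)


def _anchor_receptor(tracer_class: str) -> str:
    return "DAT" if tracer_class == rk.DAT_TRACER else "D2"


def _drug_loads(drug: DrugSpec, parent_conc: float, receptor: str):
    """Total high/low-pool competitive loads of a drug's ligands at ``receptor``
    for a given parent concentration (metabolites scale by molar ratio)."""
    hi = lo = 0.0
    for lig in drug.ligands:
        if receptor not in lig.affinities:
            continue
        ratio = drug.metabolite_ratios.get(lig.name, 1.0)
        c = parent_conc * ratio
        ki = lig.affinities[receptor]
        if lig.is_agonist_at(receptor):
            hi += c / ki
            lo += c / (ki * rk.LOW_AFFINITY_RATIO)
        else:
            hi += c / ki
            lo += c / ki
    return hi, lo


def pk_slope(drug: DrugSpec) -> float:
    """Linear-PK slope (nM parent concentration per mg) for a drug.

    Anchored drugs: solved so the anchor dose reproduces the anchored tracer
    displacement through the receptor-competition model.  Unanchored drugs:
    from the declared target-engagement point (plain occupancy at the stated
    receptor), logged as uncalibrated.
    """
    if drug.pk_anchor is not None:
        anchor = drug.pk_anchor
        receptor = _anchor_receptor(anchor.tracer_class)
        x_base = rk._x_base_for(anchor.tracer_class)
        f_high = rk.DEFAULT_HIGH_AFFINITY_FRACTION
        hi1, lo1 = _drug_loads(drug, 1.0, receptor)
        if hi1 == 0.0 and lo1 == 0.0:
            raise ValueError(
                f"{drug.name}: no ligand binds {receptor}; anchor unattainable"
            )

        def resid(log_c: float) -> float:
            c = math.exp(log_c)
            return _imaging_displacement_by_drug(
                hi1 * c, lo1 * c, x_base, f_high, anchor.tracer_class
            ) - anchor.displacement

        lo_b, hi_b = math.log(1e-9), math.log(1e9)
        if resid(hi_b) < 0:
            raise ValueError(
                f"{drug.name}: anchor displacement {anchor.displacement}% "
                f"unattainable through the competition model"
            )
        c_star = math.exp(brentq(resid, lo_b, hi_b, xtol=1e-12))
        return c_star / anchor.dose

    if drug.engagement is not None:
        eng = drug.engagement
        kis = [l.affinities[eng.receptor] for l in drug.ligands
               if eng.receptor in l.affinities]
        if not kis:
            raise ValueError(
                f"{drug.name}: no ligand binds {eng.receptor} for engagement"
            )
        c_star = min(kis) * eng.occupancy / (1.0 - eng.occupancy)
        log.info("drug %s: uncalibrated target engagement (%.0f%% at %s, "
                 "%g %s)", drug.name, 100 * eng.occupancy, eng.receptor,
                 eng.dose, drug.dose_unit)
        return c_star / eng.dose

    return 0.0  # pure mechanism drug (no ligands)


def drug_tracer_displacement(drug: DrugSpec, dose: float,
                             tracer_class: str = rk.D2_TRACER) -> float:
    """Percent tracer displacement produced by a drug at a dose, through the
    anchored imaging competition model (the inverse of the PK anchoring)."""
    receptor = _anchor_receptor(tracer_class)
    conc = dose_to_concentration(drug, dose)
    parent = drug.ligands[0].name if drug.ligands else None
    if parent is None:
        return 0.0
    hi, lo = _drug_loads(drug, conc[parent], receptor)
    return _imaging_displacement_by_drug(
        hi, lo, rk._x_base_for(tracer_class),
        rk.DEFAULT_HIGH_AFFINITY_FRACTION, tracer_class)


def dose_to_concentration(drug: DrugSpec, dose: float) -> dict:
    """Free synaptic concentration (nM) of each of the drug's ligands at
    ``dose`` mg, under the linear-pharmacokinetics assumption."""
    if dose < 0:
        raise ValueError("dose must be >= 0")
    slope = pk_slope(drug)
    out = {}
    for lig in drug.ligands:
        ratio = drug.metabolite_ratios.get(lig.name, 1.0)
        out[lig.name] = slope * dose * ratio
    return out


def regimen_ligands(regimen: Regimen) -> list:
    """All drug/metabolite ligands of a regimen at their dosed concentrations."""
    ligs = []
    for drug, dose in regimen.arms:
        concs = dose_to_concentration(drug, dose)
        for lig in drug.ligands:
            ligs.append(lig.with_concentration(concs[lig.name]))
    return ligs


# ---------------------------------------------------------------------------
# Activation under a disease state
# ---------------------------------------------------------------------------

def transmitter_ligands(
    disease: DiseaseState,
    da_release_fold: float = 1.0,
    ht_fold: float = 1.0,
    drug_ligands: Sequence = (),
) -> list:
    """Endogenous transmitter ligands at their disease-state concentrations.

    Dopamine is solved self-consistently from the disease dopamine synapse
    (release fold applied, D2S-binding drugs competing at the autoreceptor);
    the serotonin concentration scales with the 5-HT half-life fold.
    """
    syn = disease.da_synapse().scaled(da_release_fold)
    da = rk.steady_state_free_da(syn, extra_ligands=list(drug_ligands))
    ligs = [rk.dopamine_ligand(da)]
    for name, spec in TRANSMITTER_TONES.items():
        conc = spec["concentration"]
        if name == "serotonin":
            conc = conc * ht_fold
        ligs.append(rk.Ligand(
            name,
            affinities=dict(spec["affinities"]),
            efficacies={r: 1.0 for r in spec["affinities"]},
            concentration=conc,
            role="neurotransmitter",
        ))
    return ligs


def _activation(
    receptor: str,
    disease: DiseaseState,
    transmitters: Sequence,
    drug_ligands: Sequence = (),
) -> float:
    ligs = [l for l in transmitters if receptor in l.affinities]
    ligs += [l for l in drug_ligands if receptor in l.affinities]
    if not ligs:
        return 0.0
    act = rk.activation_at(ligs, receptor, disease.d2_high_affinity)
    if receptor in SEROTONIN_RECEPTORS:
        act *= disease.serotonin_tone_factor(receptor)
    return min(max(act, 0.0), 1.0)


def baseline_activation(receptor: str, disease: DiseaseState | None = None) -> float:
    """Drug-free activation of ``receptor`` under a disease overlay."""
    disease = disease or healthy_state()
    return _activation(receptor, disease, transmitter_ligands(disease))


def activation_delta_vector(
    regimen: Regimen,
    disease: DiseaseState,
    table: CouplingTable | None = None,
) -> dict:
    """Per-receptor activation change of a regimen vs. the drug-free disease
    baseline (both evaluated under the same disease-state dynamics).

    Returns a map receptor -> signed delta in [-1, 1] covering every receptor
    the coupling table listens to.  Drug affinities for receptors outside the
    known set are warned about and ignored.
    """
    table = table or default_table()
    drug_ligs = regimen_ligands(regimen)
    for lig in drug_ligs:
        unknown = set(lig.affinities) - KNOWN_RECEPTORS
        if unknown:
            log.warning("ligand %s references unknown receptors %s; ignored",
                        lig.name, sorted(unknown))

    receptors = sorted(table.receptors() | {"D2S"})
    base_trans = transmitter_ligands(disease)
    drug_trans = transmitter_ligands(
        disease,
        da_release_fold=regimen.total_release_fold(),
        ht_fold=regimen.total_ht_fold(),
        drug_ligands=drug_ligs,
    )
    delta = {}
    for rec in receptors:
        act0 = _activation(rec, disease, base_trans)
        act1 = _activation(rec, disease, drug_trans, drug_ligs)
        delta[rec] = act1 - act0
    return delta


def disease_delta_vector(
    disease: DiseaseState,
    table: CouplingTable | None = None,
    reference: DiseaseState | None = None,
) -> dict:
    """Per-receptor activation change of a drug-free disease overlay relative
    to the healthy reference — the pathology's own contribution to the
    conductance modulation."""
    table = table or default_table()
    reference = reference or healthy_state()
    receptors = sorted(table.receptors() | {"D2S"})
    ref_trans = transmitter_ligands(reference)
    dis_trans = transmitter_ligands(disease)
    return {
        rec: (_activation(rec, disease, dis_trans)
              - _activation(rec, reference, ref_trans))
        for rec in receptors
    }


# ---------------------------------------------------------------------------
# Adenosine A2A co-regulation of the D2 -> K_A coupling
# ---------------------------------------------------------------------------

def a2a_coupling_gain(a2a_occupancy: float) -> float:
    """Multiplier on the D2->K_A coupling parameter for a given A2A-antagonist
    occupancy: linear with gain(0) = 1.0 and gain(0.90) = 1.65, clipped below
    at 1.0."""
    if not 0.0 <= a2a_occupancy <= 1.0:
        raise ValueError("occupancy must be in [0,1]")
    return max(1.0, 1.0 + (A2A_GAIN_AT_FULL_ANCHOR / A2A_OCC_ANCHOR) * a2a_occupancy)


def regimen_a2a_occupancy(regimen: Regimen, disease: DiseaseState) -> float:
    """Total A2A occupancy by the regimen's drug ligands, in competition with
    endogenous adenosine."""
    drug_ligs = [l for l in regimen_ligands(regimen) if "A2A" in l.affinities]
    if not drug_ligs:
        return 0.0
    trans = [l for l in transmitter_ligands(disease) if "A2A" in l.affinities]
    occ = rk.competitive_occupancy(trans + drug_ligs, "A2A")
    return sum(occ[l.name] for l in drug_ligs)
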