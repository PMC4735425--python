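"""Synthetic drug libraries, disease configs and clinical tables with known truth.

Everything here is synthetic: affinities are drawn from plausible ranges
(0.1-1000 nM) and labelled as such — no real-drug constants are asserted
beyond the PET-anchored pramipexole-like and A2A engagement points used as
anchoring examples.  The archetype set covers one intervention class per
mechanism studied with the platform: a pure D2 antagonist, a D2-preferring
(autoreceptor-biased) agonist, a D1 agonist, a 5-HT2A antagonist, a
SERT-like serotonin half-life extender, an A2A antagonist, an NMDA
conductance reducer, and an M1 anticholinergic.

The clinical-table generator runs the full model at known "true" coupling
gains and emits clinical changes on a known line plus Gaussian noise, so the
calibration workflow can be validated as a parameter-recovery experiment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import pharmacology as ph
from . import receptor_kinetics as rk
from .coupling import CouplingTable, default_table
from .pathology import DiseaseState, pd_state, schizophrenia_state
from .trials import TrialArm, ClinicalRecord, _ArmCache

__all__ = [
    "SyntheticStudySpec",
    "archetype_drugs",
    "make_drug_library",
    "validate_library",
    "make_trial_arms",
    "make_clinical_table",
]

LIBRARY_COLUMNS = ("name", "role", "receptor", "Ki_nM", "efficacy")


@dataclass
class SyntheticStudySpec:
    """Ground-truth description of a synthetic calibration study."""

    n_drugs: int = 8
    receptors_per_drug: int = 2
    true_gain_factors: dict = field(default_factory=dict)  # param -> factor
    true_slope: float = 2.0
    true_intercept: float = -1.0
    noise_sd: float = 0.0
    n_seeds: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise SD must be >= 0")


def archetype_drugs() -> list:
    """The synthetic archetype drugs, one per intervention class."""
    L = rk.Ligand
    drugs = [
        ph.DrugSpec(
            "d2_blocker_syn",
            ligands=[L("d2_blocker_syn", {"D2": 2.0, "D2S": 2.0, "D3": 5.0}, {})],
            pk_anchor=ph.PKAnchor(2.0, 60.0, rk.D2_TRACER),
        ),
        ph.DrugSpec(
            # D2-preferring agonist with the FLB457-style anchoring point
            "d2_agonist_syn",
            ligands=[L("d2_agonist_syn",
                       {"D2": 3.9, "D2S": 3.9, "D3": 0.5},
                       {"D2": 0.8, "D2S": 1.0, "D3": 1.0})],
            pk_anchor=ph.PKAnchor(0.125, 10.0, rk.D2_TRACER),
        ),
        ph.DrugSpec(
            "d1_agonist_syn",
            ligands=[L("d1_agonist_syn", {"D1": 30.0}, {"D1": 1.0})],
            engagement=ph.Engagement("D1", 0.60, 10.0),
        ),
        ph.DrugSpec(
            "ht2a_blocker_syn",
            ligands=[L("ht2a_blocker_syn", {"5HT2A": 5.0}, {})],
            engagement=ph.Engagement("5HT2A", 0.70, 20.0),
        ),
        ph.DrugSpec(
            # SERT inhibition modelled as a serotonin half-life extension
            "sert_blocker_syn",
            ht_half_life_slope=0.02,   # fold 1.4 at 20 mg
        ),
        ph.DrugSpec(
            "a2a_blocker_syn",
            ligands=[L("a2a_blocker_syn", {"A2A": 10.0}, {})],
            engagement=ph.Engagement("A2A", 0.90, 40.0),
        ),
        ph.DrugSpec(
            "nmda_reducer_syn",
            conductance_slopes={"NMDA_cortical": -0.005},   # -5% cortical gNMDA at 10 mg
        ),
        ph.DrugSpec(
            "m1_blocker_syn",
            ligands=[L("m1_blocker_syn", {"M1": 8.0, "M2": 40.0}, {})],
            engagement=ph.Engagement("M1", 0.65, 5.0),
        ),
    ]
    return drugs


def make_drug_library(n_extra: int = 0, seed: int = 0, path=None) -> pd.DataFrame:
    """Drug-library table: archetypes plus optional random filler drugs.

    One row per (ligand, receptor) with columns name, role, receptor, Ki_nM,
    efficacy.  Ki values fall in 0.1-1000 nM; efficacies are 0 (neutral
    antagonist), 1 (full agonist) or a partial value in 0.2-0.8.
    Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for drug in archetype_drugs():
        for lig in drug.ligands:
            for rec, ki in sorted(lig.affinities.items()):
                rows.append(dict(name=lig.name, role=lig.role, receptor=rec,
                                 Ki_nM=float(ki),
                                 efficacy=float(lig.efficacies.get(rec, 0.0))))
    receptors = sorted({"D1", "D2", "D2S", "D3", "5HT1A", "5HT1B", "5HT2A",
                        "5HT4", "M1", "M2", "nACh", "alpha", "A2A"})
    for i in range(n_extra):
        name = f"random_drug_{i:02d}_syn"
        hit = rng.choice(receptors, size=rng.integers(1, 4), replace=False)
        for rec in sorted(hit):
            ki = float(np.round(10 ** rng.uniform(-1, 3), 3))
            eff = float(rng.choice([0.0, np.round(rng.uniform(0.2, 0.8), 2), 1.0]))
            rows.append(dict(name=name, role="drug", receptor=rec,
                             Ki_nM=ki, efficacy=eff))
    df = pd.DataFrame(rows, columns=list(LIBRARY_COLUMNS))
    validate_library(df)
    if path is not None:
        df.to_csv(path, index=False)
    return df


def validate_library(df: pd.DataFrame) -> None:
    """Schema check for a drug-library table."""
    missing = set(LIBRARY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"drug library missing columns {sorted(missing)}")
    if not (df["Ki_nM"] > 0).all():
        raise ValueError("all Ki values must be > 0")
    if not df["efficacy"].between(0, 1).all():
        raise ValueError("all efficacies must be in [0, 1]")
    if not df["role"].isin(["neurotransmitter", "drug", "metabolite",
                            "tracer"]).all():
        raise ValueError("invalid ligand role in library")


def make_trial_arms(
    disease: DiseaseState | None = None,
    n_seeds: int = 3,
    dose_scale: float = 1.0,
) -> list:
    """A standard panel of virtual-trial arms over the drug archetypes.

    Per-drug low and high doses plus an untreated arm: enough conditions to
    identify the seven coupling gains.
    """
    disease = disease if disease is not None else schizophrenia_state()
    drugs = {d.name: d for d in archetype_drugs()}
    doses = [
        ("d2_blocker_syn", 2.0), ("d2_blocker_syn", 8.0),
        ("d2_agonist_syn", 0.25), ("d2_agonist_syn", 1.0),
        ("d1_agonist_syn", 10.0), ("d1_agonist_syn", 40.0),
        ("ht2a_blocker_syn", 20.0), ("ht2a_blocker_syn", 60.0),
        ("sert_blocker_syn", 20.0),
        ("a2a_blocker_syn", 40.0),
        ("nmda_reducer_syn", 10.0),
        ("m1_blocker_syn", 5.0),
    ]
    arms = [TrialArm(ph.Regimen(), disease, n_seeds, "untreated")]
    for name, dose in doses:
        reg = ph.Regimen(arms=[(drugs[name], dose * dose_scale)])
        arms.append(TrialArm(reg, disease, n_seeds, f"{name}@{dose*dose_scale:g}"))
    return arms


def make_clinical_table(
    spec: SyntheticStudySpec,
    arms=None,
    table: CouplingTable | None = None,
    graph=None,
    duration: float = 800.0,
    transient: float = 250.0,
    path=None,
):
    """Synthetic clinical outcomes generated by the model itself.

    The model is run at the "true" coupling gains (the default table scaled
    by ``spec.true_gain_factors``); each arm's clinical change is
    true_slope * b/g + true_intercept + N(0, noise_sd).  Returns
    (records, truth) where truth stores the generating parameters and the
    noise-free b/g values for recovery tests.
    """
    from .circuit import build_network

    rng = np.random.default_rng(spec.seed)
    table = table or default_table()
    true_table = table.scaled(spec.true_gain_factors)
    arms = arms if arms is not None else make_trial_arms(n_seeds=spec.n_seeds)
    graph = graph or build_network(1)
    cache = _ArmCache(arms, graph, spec.seed, duration, transient)
    bg = cache.bg_vector(true_table)
    noise = rng.normal(0.0, spec.noise_sd, size=len(arms))
    records = []
    for i, arm in enumerate(arms):
        change = spec.true_slope * bg[i] + spec.true_intercept + noise[i]
        records.append(ClinicalRecord(arm.label, "UPDRS-III", float(change),
                                      n_patients=100))
    truth = dict(
        true_gain_factors=dict(spec.true_gain_factors),
        true_slope=spec.true_slope, true_intercept=spec.true_intercept,
        noise_sd=spec.noise_sd, bg=bg.tolist(),
        labels=[a.label for a in arms],
    )
    if path is not None:
        pd.DataFrame(
            [dict(label=r.label, scale=r.scale, observed_change=r.observed_change,
                  n_patients=r.n_patients) for r in records]
        ).to_csv(path, index=False)
    return records, truth
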