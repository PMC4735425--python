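"""Disease-state configurations as parameter overlays on the healthy model.

Parkinsonian pathology is a general decrease of presynaptic dopamine release
(substantia-nigra cell death) together with three compensatory/pathological
changes: upregulation of the high-affinity D2 receptor fraction (75% at normal
release, 100% when release falls to 5% of normal), DAT downregulation
lengthening the synaptic dopamine half-life (50 ms at normal release, 70 ms as
release approaches 0), and loss of bidirectional plasticity at the MSN-GPe /
GPe-STN boundary.  Reduced serotonergic raphe tone modifies the activation of
all 5-HT receptors.  The hyperdopaminergic state used for the antipsychotic
side-effect calibration raises striatal release above normal.

Both compensation curves are linear between their printed endpoints; linearity
is the minimal assumption and is isolated here for replacement.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .receptor_kinetics import DopamineSynapseState

__all__ = [
    "DiseaseState",
    "high_affinity_fraction",
    "dat_half_life",
    "healthy_state",
    "pd_state",
    "schizophrenia_state",
]

SEROTONIN_RECEPTORS = ("5HT1A", "5HT1B", "5HT2A", "5HT4")

#: Endpoints of the compensation curves.
HIGH_AFFINITY_NORMAL = 0.75
HIGH_AFFINITY_MAX = 1.00
HIGH_AFFINITY_FLOOR_RELEASE = 0.05   # release fold at which the fraction hits 1.0
DAT_HALF_LIFE_NORMAL_MS = 50.0
DAT_HALF_LIFE_MAX_MS = 70.0

#: Default PD overlay magnitudes at full depletion (scaled linearly with
#: depletion so that depletion 0 is exactly the healthy overlay).
PD_MSN_GPE_COUPLING_LOSS = 0.5   # mGluR slow-current gain at MSN->GPe, -50%
PD_GPE_STN_COUPLING_GAIN = 0.2   # compensatory GABA gmax at GPe->STN, +20%
PD_SEROTONIN_TONE_LOSS = 0.2     # uniform -20% activation of 5-HT receptors

SCHIZOPHRENIA_RELEASE_SCALE = 1.4


def high_affinity_fraction(release_scale: float) -> float:
    """Fraction of D2 receptors in the agonist-high-affinity state.

    0.75 at normal release (1.0), 1.00 when release is limited to 5% of
    normal, linear in between; clipped to [0.75, 1.0].
    """
    span = 1.0 - HIGH_AFFINITY_FLOOR_RELEASE
    t = (1.0 - release_scale) / span
    t = min(max(t, 0.0), 1.0)
    return HIGH_AFFINITY_NORMAL + (HIGH_AFFINITY_MAX - HIGH_AFFINITY_NORMAL) * t


def dat_half_life(release_scale: float) -> float:
    """Synaptic dopamine half-life (ms) under DAT downregulation.

    50 ms at normal release, 70 ms as release approaches its theoretical limit
    of 0, linear in between.
    """
    t = min(max(1.0 - release_scale, 0.0), 1.0)
    return DAT_HALF_LIFE_NORMAL_MS + (DAT_HALF_LIFE_MAX_MS - DAT_HALF_LIFE_NORMAL_MS) * t


@dataclass
class DiseaseState:
    """Pathology + compensation overlay on the healthy model."""

    condition: str = "healthy"
    depletion: float = 0.0
    release_scale: float = 1.0
    d2_high_affinity: float = HIGH_AFFINITY_NORMAL
    dat_half_life: float = DAT_HALF_LIFE_NORMAL_MS
    msn_gpe_coupling: float = 1.0
    gpe_stn_coupling: float = 1.0
    serotonin_tone: dict = field(default_factory=dict)

    def __post_init__(self):
        if not 0.0 <= self.depletion <= 1.0:
            raise ValueError(f"depletion must be in [0,1], got {self.depletion}")
        if not HIGH_AFFINITY_NORMAL <= self.d2_high_affinity <= HIGH_AFFINITY_MAX:
            raise ValueError(
                f"d2_high_affinity must be in [{HIGH_AFFINITY_NORMAL}, "
                f"{HIGH_AFFINITY_MAX}], got {self.d2_high_affinity}"
            )
        if not (DAT_HALF_LIFE_NORMAL_MS <= self.dat_half_life
                <= DAT_HALF_LIFE_MAX_MS):
            raise ValueError(
                f"dat_half_life must be in [{DAT_HALF_LIFE_NORMAL_MS}, "
                f"{DAT_HALF_LIFE_MAX_MS}] ms, got {self.dat_half_life}"
            )

    def da_synapse(self) -> DopamineSynapseState:
        """The striatal dopamine synapse under this overlay."""
        return DopamineSynapseState(
            release_scale=self.release_scale,
            half_life=self.dat_half_life,
            high_affinity_fraction=self.d2_high_affinity,
        )

    def serotonin_tone_factor(self, receptor: str) -> float:
        return float(self.serotonin_tone.get(receptor, 1.0))

    def with_release_fold(self, fold: float) -> "DiseaseState":
        """Overlay with presynaptic DA release multiplied (L-DOPA / MAO-B /
        placebo surge); compensation parameters stay at their disease values."""
        return replace(self, release_scale=self.release_scale * fold)


def healthy_state() -> DiseaseState:
    return DiseaseState()


def pd_state(depletion: float) -> DiseaseState:
    """Parkinsonian overlay at the given fraction of lost DA release.

    Release is scaled to 1 - depletion; the D2 high-affinity fraction and the
    DA half-life follow their compensation curves.  The plasticity overlays
    grow quadratically with depletion and the serotonin overlay ramps in
    beyond 50% depletion: both emerge late in the disease, so the mild-to-
    moderate range stays close to the healthy operating point (depletion 0 is
    exactly the healthy overlay).
    """
    if not 0.0 <= depletion <= 1.0:
        raise ValueError(f"depletion must be in [0,1], got {depletion}")
    release = 1.0 - depletion
    # raphe involvement emerges late in the disease: the 5-HT tone overlay
    # ramps in only beyond 50% depletion, reaching the full loss at 100%
    late = max(0.0, (depletion - 0.5) / 0.5)
    tone = 1.0 - PD_SEROTONIN_TONE_LOSS * late
    return DiseaseState(
        condition="parkinson",
        depletion=depletion,
        release_scale=release,
        d2_high_affinity=high_affinity_fraction(release),
        dat_half_life=dat_half_life(release),
        msn_gpe_coupling=1.0 - PD_MSN_GPE_COUPLING_LOSS * depletion ** 2,
        gpe_stn_coupling=1.0 + PD_GPE_STN_COUPLING_GAIN * depletion ** 2,
        serotonin_tone={r: tone for r in SEROTONIN_RECEPTORS},
    )


def schizophrenia_state(release_scale: float = SCHIZOPHRENIA_RELEASE_SCALE) -> DiseaseState:
    """Hyperdopaminergic overlay (elevated striatal release) used for the
    antipsychotic motor-side-effect calibration."""
    if not release_scale > 1.0:
        raise ValueError("schizophrenia overlay requires release_scale > 1")
    return DiseaseState(
        condition="schizophrenia",
        depletion=0.0,
        release_scale=release_scale,
        d2_high_affinity=high_affinity_fraction(release_scale),
        dat_half_life=dat_half_life(release_scale),
    )
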