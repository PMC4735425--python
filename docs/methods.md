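# Methods

`bgqsp` is a quantitative systems pharmacology (QSP) platform for hypokinetic
motor symptoms: it couples a competitive receptor-pharmacology layer to a
conductance-based spiking model of the closed
cortico-striatal-thalamo-cortical motor loop, reads out the ratio of beta
(12-50 Hz) to gamma (60-100 Hz) power of a field-potential proxy as an
in-silico motor biomarker, and calibrates that biomarker linearly against
clinical-scale changes.  This note documents the model, its assumptions, the
free parameters, and the choices made where the design was genuinely open.

## 1. Receptor competition layer

Binding is equilibrium competitive binding in the trace-receptor limit:

    occupancy_i = (C_i / K_i) / (1 + sum_j C_j / K_j)

over every ligand j (neurotransmitter, parent drug, active metabolite,
tracer) present at a receptor, with activation the efficacy-weighted
occupancy sum.  No association/dissociation kinetics are modelled: every
downstream readout consumes steady-state occupancy and activation fractions.

D2-family receptors (`D2`, presynaptic `D2S`) are a mixture of a high- and a
low-affinity sub-pool combined by the high-affinity fraction (0.75 under
normal dopamine release).  Agonists — including dopamine — see their listed
Ki against the high-affinity pool and a conventional 100x weaker Ki against
the low pool; neutral antagonists and tracers bind both pools equally.

### Dopamine synapse

Free dopamine follows impulse release (quantum x release_scale per
presynaptic event, seeded Poisson at the tonic rate) with first-order
clearance at rate ln2 / half_life; its steady state is

    DA = Q * release_scale * (1 - f_auto * act_D2S(DA)) * rate * half_life/ln2

solved self-consistently (the D2S autoreceptor term makes free dopamine
sub-linear in release: doubling release raises it less than 2-fold).
Defaults — quantum 150 nM, tonic rate 4 Hz, half-life 50 ms, f_auto 0.5 —
are stand-ins for a companion synapse calibration that is not part of this
package; they place healthy free dopamine near 30 nM.  The functional
dopamine affinities (D1 3 nM, D2-high 8 nM, D2S 10 nM) are *effective*
constants chosen so that baseline D1/D2 activation stays nearly flat under
depletion until the compensation mechanisms saturate (see §4); they are not
literature binding constants.

### PET tracer displacement and the placebo mapping

Tracer displacement is modelled at an anchored *imaging* synapse that is
deliberately separate from the functional affinities above: the only free
constants are the baseline dopamine load relative to the D2-antagonist-tracer
Ki and relative to the DAT-tracer sensitivity.  These two scalars are solved
once (`scripts/anchor_placebo.py`, re-solved lazily at run time) so that the
release-fold anchors reproduce the clinically observed placebo displacements:
+120% release -> 23% D2-antagonist-tracer displacement (acute) and +40%
release -> 11% DAT-tracer displacement (chronic).
`release_change_from_displacement` inverts the forward model by a monotone
root-find; the mapping is exact at the anchors by construction and smooth in
between.  Drug PK anchoring uses the same imaging synapse: the linear-PK
slope (nM per mg) of an anchored drug is solved so its anchor dose reproduces
the anchored displacement.  Drugs without an imaging anchor declare an
explicit target-engagement point and are flagged uncalibrated.

## 2. Circuit model

Every compartment obeys the Hodgkin-Huxley current balance
C dV/dt = -sum g_a (V - E_a) + I_ex.  Cell models: STN, GPe and GPi are
Rubin-Terman-lineage single-compartment cells (Na, K_dr, Ca_T, Ca_L, AHP,
leak); TC and Re carry a low-threshold Ca current, TC additionally Ih, K_A
and a K leak; MSNs are two compartments with the inwardly rectifying K_ir and
the A-type K_A on the dendrite as the dopamine-modulation targets; pyramidal
cells are two compartments with persistent Na, high-voltage-activated Ca and
K_Ca as serotonergic targets; basket cells are fast-spiking single
compartments.  All constants live in `src/bgqsp/data/circuit_params.yaml`
with provenance comments; bias currents, noise magnitudes and synaptic
weights were set during the healthy-state calibration and frozen.

Wiring follows the printed in-degree rules exactly (16 cells per pallidal
nucleus in two groups of eight wired within-group; STN <- 3 GPe;
GPe <- 3 GPe + 3 STN; GPi <- 1 GPe + 1 STN; every TC <- all 8 GPi of its
group; 4 TC, 4 Re; 40 Pyr, 20 BC with 60% of BCs projecting to Pyr and the
remaining eight forming the interneuron microcircuit; hyperdirect Pyr -> STN;
Pyr -> both MSN types).  Striatal afferents are the only cross-group
connections.  Axonal delays are uniform per projection (1-5 ms for most
projections; the pallido-subthalamic loop uses 6-12 ms and the intracortical
loop 1-2 ms — the paper is silent on delays, and these choices place the
loop resonances in their physiological bands).

Synapses are difference-of-exponentials conductances
g(t) = <g> N (exp(-t/t_decay) - exp(-t/t_rise)), normalized so <g> is the
peak; NMDA carries a sigmoidal Mg-block factor evaluated at the step's
starting voltage.  mGluR at the MSN->GPe projection is a slow (20/200 ms)
depolarizing conductance whose gain is the Parkinsonian plasticity target.
Background bombardment is an Ornstein-Uhlenbeck conductance pair per cell
(tau 2 ms excitatory / 10 ms inhibitory), applied to the dendrite of
two-compartment cells.

### Integration

States advance with a two-stage second-order (Heun) step at dt = 0.025 ms;
synaptic and noise conductances are aggregated per compartment as (G, G*E)
pairs and held fixed within a step, so both stages see consistent synaptic
input.  A first-order scheme (exponential-Euler gating with a forward
voltage update) was tried first and abandoned: its phase drift on a
tonically firing cell (~0.15 ms per period) violates the integrator accuracy
contract of spike times within 0.5 ms of a tiny-step Runge-Kutta reference
over 500 ms; the Heun step meets it with a ~0.2 ms worst-case offset.
Spikes are upward threshold crossings at -20 mV with re-arming below -30 mV.
Identical (configuration, seed) runs are bit-identical.

## 3. Pharmacology-to-physiology coupling

Receptor-activation changes map to multiplicative conductance modulations
through signed linear gains, composed additively and clipped into
[0.2, 3.0] so conductances stay positive:

    multiplier = clip(1 + sum_rules k * delta_activation, 0.2, 3.0)

The delta applied to the circuit is the total shift from the
healthy-calibrated reference: pathology shift (disease baseline vs healthy)
plus drug shift (disease + drugs vs disease baseline), both evaluated through
the same receptor-competition dynamics.  The seven clinically calibrated
gains are D1->MSN_D1 K_ir, D2->MSN_D2 K_A, D2->cortical glutamate onto both
MSN types (AMPA+NMDA, presynaptic release expressed as a gmax multiplier —
indistinguishable from postsynaptic scaling at this resolution),
5-HT2A->Pyr (HVA, Na_p), 5-HT4->Pyr (K_dr, K_Ca), M1->Pyr K_dr and
D1->Pyr e-e AMPA/NMDA.  The remaining text-derived rules (M2 and 5-HT2A on
thalamic Ih/leak, adrenergic on interneuron K and glutamatergic synapses,
nicotinic enhancement of GABA and glutamate, pallidal 5-HT1A/1B on STN
excitation) carry literature-signed default gains; the signs and magnitudes
of the serotonergic couplings are calibration targets, not fixed constants.
Adenosine A2A-antagonist occupancy multiplies the D2->K_A gain linearly
(x1.0 at zero occupancy, x1.65 at the 90% maximal-displacement anchor).

L-DOPA and MAO-B inhibition are multiplicative increases of presynaptic
dopamine release, not ligands; SERT inhibition is a serotonin half-life fold
(concentration scales proportionally); ionotropic modulators (NMDA/AMPA
conductance reducers) are global folds on the corresponding synapse kind.
Multi-mechanism drugs combine a ligand set with a release-fold component in
one specification.

## 4. Disease states

Parkinsonian pathology: release_scale = 1 - depletion, with compensation
curves linear between their printed endpoints — the D2 high-affinity
fraction rises from 75% at normal release to 100% at 5% of normal, the
dopamine half-life from 50 ms to 70 ms as release approaches 0 (linearity is
the minimal assumption and both curves are isolated in one place).  The
plasticity overlays scale with depletion: mGluR gain at MSN->GPe falls to
-50% and the compensatory GPe->STN GABA rises to +20% at full depletion.
The serotonergic-tone overlay (uniform -20% activation of the 5-HT receptors
at full depletion) ramps in only beyond 50% depletion, reflecting the late
raphe involvement in the disease; all overlay magnitudes are
config-overridable.  The interaction of depletion with the compensation
curves makes baseline D1/D2 activation nearly flat up to ~60-70% depletion
with substantial (>20%) declines only beyond ~80% — the nonlinearity that
lets clinical symptoms emerge only after most nigral neurons are lost.
The hyperdopaminergic overlay used for the antipsychotic side-effect
calibration raises striatal release to 1.4x normal.

## 5. Readout

The field-potential proxy is the summed synaptic current onto pyramidal
cells (their number dominates the dipole); background OU currents are not
included in the proxy.  PSDs use Welch's method with 1 s Hann windows and
50% overlap (single full-length window on shorter traces) after discarding
the initial transient; band powers are Riemann sums of PSD bins so a
partition of [0, Nyquist] reproduces the trace variance (Parseval).  Beta
uses the operationally widened 12-50 Hz band (less variable on 2.5 s
simulations than the textbook 10-40 Hz), gamma 60-100 Hz, with an optional
30-45 Hz low-gamma band.  The readout is named after the STN because the
clinical biomarker is the STN LFP beta/gamma ratio; the simulated proxy is
cortical (pyramidal synaptic currents) per the model's dipole assumption,
and the naming discrepancy is deliberate and documented.

Reported b/g for a condition is the mean over several seeds with SD: single
2.5 s runs carry substantial estimator variance (between-seed coefficient of
variation ~0.3 at 1.5 s, ~0.2 at 4 s), driven by slow state wandering of the
small (148-cell) network.  Tests and virtual trials therefore always
average over seed panels, and directional claims are tested statistically
(paired one-sided tests or pooled regressions over the seed panels).

## 6. Virtual trials and clinical calibration

A trial arm = regimen + disease overlay + seed panel, run through
pharmacology -> coupling -> circuit -> readout.  Clinical calibration is a
patient-count-weighted least-squares fit of observed placebo-normalized
clinical changes (UPDRS-III points, EPS fraction or OFF-time hours — all
three scales share the same weighted linear link) on the arm-level b/g; the
placebo module maps the PET-anchored acute (+120%) and chronic (+40%)
release surges through the same chain and the fitted slope (the intercept
cancels under placebo normalization).

Coupling-gain optimization is a seeded derivative-free search over
multiplicative factors on the seven gains maximizing the weighted R^2:
Nelder-Mead with restarts by default, plus a coordinate-refinement mode used
at reduced simulation sizes, which exploits the fact that an arm is only
re-simulated when a varied gain actually changes its multiplier vector.
Because the reference clinical databases are not distributed with the
package, calibration is validated as a parameter-recovery experiment on
synthetic clinical tables generated by the model itself at known gains
(see `bgqsp.fixtures`): noise-free tables must be re-fit almost perfectly,
noisy tables must generalize to held-out seed panels, and permuted labels
must collapse the attainable R^2.

## 7. Synthetic data

`bgqsp.fixtures` generates everything needed to exercise the platform
without any external data: a schema-validated drug library (plausible Ki in
0.1-1000 nM; efficacies 0, partial, or 1) containing one archetype per
intervention class — pure D2 antagonist, autoreceptor-preferring D2 agonist
with the 0.125 mg -> 10% / 0.25 mg -> 20% imaging anchor, D1 agonist,
5-HT2A antagonist, SERT-like half-life extender, A2A antagonist, NMDA
conductance reducer, M1 anticholinergic — plus random filler drugs, trial
arm panels, and clinical tables on a known line with configurable noise.
All fixtures are seed-deterministic, and every affinity is labelled
synthetic.  What passing recovery tests show is that the calibration
machinery identifies coupling gains *when the generating model is the
platform itself*; they do not establish fidelity to real clinical data,
which would require the unavailable trial databases.

## 8. Numerical and statistical choices

* dt = 0.025 ms (contract: <= 0.05 ms); halving dt changes the healthy b/g
  by less than the seed-to-seed spread.
* Root-finds (anchoring, displacement inversion, PK slopes) use bracketed
  Brent iterations with ~1e-10 tolerances; anchored quantities are exact at
  their anchors by construction.
* Ties/degenerate inputs: zero gamma power raises (degenerate trace); zero
  model-b/g variance and constant clinical outcomes are explicit error or
  zero-slope paths in the calibration fit.
* All randomness (wiring choice, delays, OU paths, Poisson release, seed
  panels, optimizer restarts) descends from caller-provided integer seeds.

## 9. Known limitations

* The 148-cell network is a caricature of basal-ganglia anatomy: subregional
  structure, conduction heterogeneity and cell diversity are absent, and the
  biomarker's estimator variance across seeds is large, so small
  pharmacological contrasts (a few percent of b/g) are at the edge of
  statistical resolution for practical seed panels.
* Channel constants for the thalamic and cortical cells are tuned reductions,
  not transcriptions of a single published set.
* The PET imaging synapse is anchored, not mechanistic: no kinetic tracer
  modelling (BPnd, reference-tissue models), no spatial diffusion, no
  region-specific transporter densities.
* Pharmacokinetics are linear and steady-state; no absorption/elimination
  dynamics, protein binding, or brain penetration.
* Receptor desensitization, second-messenger kinetics and time-evolving
  neurodegeneration are out of scope.
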