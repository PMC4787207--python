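# Methods

`striatosim` simulates dopamine (DA) volume transmission in a small
striatal volume and asks how postsynaptic signaling adapts — and eventually
fails — as the nigrostriatal innervation is progressively destroyed. This
note records the model, its parameters, the numerical choices, and the
design decisions taken where the problem was genuinely open.

## Model overview

The simulated tissue is a periodic cubic lattice, by default (60 µm)³ at
2 µm voxel resolution. DA terminals (release/uptake sites) occupy points of
this volume; the extracellular DA concentration field C(x, t) evolves by

1. **quantal release** — each spike of each neuron gives every terminal of
   that neuron an independent chance `p_release · s(C_ar)` of releasing one
   vesicle of `quantum` molecules, where `s` is the autoreceptor
   suppression factor (below);
2. **diffusion** — explicit 7-point finite differences with the
   tortuosity-corrected coefficient D_eff;
3. **Michaelis–Menten reuptake** — per-voxel Vmax proportional to the local
   terminal count, normalized so the volume average at the intact reference
   density equals `vmax_total`;
4. **nonspecific clearance** — first order at rate `k_ns` (catabolism,
   uptake into non-DA elements);
5. optional **amphetamine efflux** — a continuous, transporter-mediated
   leak per surviving terminal.

Because terminals are simultaneously the sources and the sinks of DA,
uniformly removing them leaves the tonic balance point unchanged (*passive
stabilization*) while slowing every transient — which is what attenuates
burst- and pause-evoked (phasic) signals under denervation.

Probe readouts are converted to D1/D2 receptor occupancy by Hill isotherms
(a kinetic binding mode exists as an alternative), and occupancy is
transduced by the two-parameter postsynaptic abstraction: per pathway a
threshold θ (set homeostatically to the mean binding under tonic firing)
and a gain g (set inversely proportional to the phasic-evoked activity),
with

    r_D1 = g₁ · max(0, occ_D1 − θ₁)        (Gs cascade, above threshold)
    r_D2 = g₂ · max(0, θ₂ − occ_D2)        (Gi/o cascade, below threshold)

## Default parameters

| parameter | default | units | note |
|---|---|---|---|
| D_eff | 322 | µm²/s | 763 µm²/s free, tortuosity λ=1.54 |
| α (ECS fraction) | 0.21 | – | |
| Vmax (intact) | 4 | µM/s | DAT uptake at reference density |
| Km | 0.2 | µM | |
| quantum | 3000 | molecules | per vesicle |
| p_release | 0.06 | – | per spike per terminal |
| k_ns | 322/70² ≈ 0.066 | 1/s | see "void calibration" |
| terminal density | 0.1 | 1/µm³ | intact reference |
| mean firing rate | 4 | Hz | tonic and phasic |
| burst | 20 Hz × 0.3 s | | regular ISIs within burst |
| pause | 0 Hz × 1.2 s | | paired 1:1 with bursts |
| event rate | 0.25 | 1/s | Poisson pair placement |
| autoreceptor | EC50 40 nM, h=2, max 0.5, τ=0.3 s | | release-probability feedback |
| D2 EC50 | 10 | nM | high-affinity |
| D1 EC50 | 300 | nM | low-affinity; see calibration |
| intact neuron count | 100 | | arbors overlapping the volume |

With these values the closed-form tonic balance gives ≈27 nM extracellular
DA; simulated probe means land within a few percent of it.

The burst/pause microstructure is deliberately minimal: one 0.3 s, 20 Hz
burst adds (20−4)·0.3 = 4.8 expected spikes and one 1.2 s pause removes
4·1.2 = 4.8, so paired events keep the long-run mean at 4 Hz for any event
rate. For unbalanced configurations the pause-event frequency is adjusted
by the rate-balance identity instead. Bursts are synchronized across
neurons (shared epoch schedule); within-burst spikes are regular with a
random phase per neuron. The published description constrains the burst
rate only loosely ("~20 Hz", while a quoted typical burst raises the rate
by 15 Hz, i.e. 19 Hz); 20 Hz is used.

## Denervation and its statistics

Two degradation modes are provided. *Coherent (microscale)* loss removes
terminals uniformly; in the experiments layer this is interpreted as
**neuron loss**: the volume is driven by `round(100·(1−f))` neurons, each
keeping its sparse in-volume terminal complement. This matters for the
baseline statistics. Baseline fluctuations at a probe are shot noise from
per-spike multi-terminal release bunches with relaxation time ∝ 1/density;
with neuron-loss scaling the bunch amplitude is density-independent while
the bunch rate scales with density, so variance ∝ rate·τ is invariant —
passive stabilization holds for the SD as well as the mean. (Holding the
neuron count fixed while thinning terminals would shrink bunch amplitudes
and make the baseline SD fall as √density, which is not what is observed
in denervated tissue.)

Probes report the mean concentration over a 12-µm-radius sphere, emulating
the sampling volume of an extracellular measurement. A bare single-voxel
point measure is available (`probe_radius=0`) but carries quantal shot
noise proportional to terminal density at millisecond timescales; no point
measure can exhibit a denervation-invariant SD, so the regional average is
the default readout.

*Mesoscale* loss removes whole spherical axonal arbors (each covering 2.7%
of the reference volume — the lattice itself at desk scale, giving 5000
arbors a mean point-overlap of ≈135, inside the anatomical 100–200 range).
Removing arbors creates *voids*: connected regions with no terminal within
a 4 µm reach radius. The reach matters: at 0.8 terminals/voxel roughly 45%
of voxels are empty by Poisson chance — above the site-percolation
threshold — so raw empty-voxel connectivity would label the entire intact
lattice one giant "void". The reach-based definition (seed where no
terminal lies within 4 µm, then grow the region back by the same radius)
detects nothing in intact maps and recovers carved test geometries to
voxel accuracy.

## Void steady state and the k_ns calibration

Inside a void there is neither release nor DAT uptake; DA is set by
diffusive influx against nonspecific clearance, D_eff∇²C = k_ns·C. On a
sphere of radius R with fixed boundary concentration the solution is

    C(r) = C_R (R/r) · sinh(r/λ)/sinh(R/λ),  λ = √(D_eff/k_ns),

with center value C_R·(R/λ)/sinh(R/λ). `k_ns` is **calibrated**, not
measured: k_ns = D_eff/λ² with λ = 70 µm places the center of a 500-µm
void at 20% of the surrounding tonic level. Sensitivity: the center
fraction is x/sinh(x) with x = R/λ, so ±10% on λ moves the 500-µm figure
between roughly 14% and 27%. Inside innervated tissue the same k_ns is
negligible (<1% effect on the intact tonic mean; ~4% at 90% denervation).
A general 3-D finite-difference mode solves the same equation on arbitrary
void masks and agrees with the closed form within 2% at 5 µm resolution.

The desk lattice (60 µm, periodic) cannot contain a >500 µm void; a void
regime on the lattice is therefore represented by complete arbor loss —
the simulated volume is the deep interior of an extensive void, where
distally sourced DA is essentially absent — and the finite-void boundary
physics lives in the dedicated solver.

## Transduction calibration (one-time, frozen)

The breakdown-of-compensation analysis needs two operationalizations the
source material defines only qualitatively, both calibrated once against
the stated anchor — compensated-D2 breakdown in the 70±10% denervation
band with restoration to at least 50% — and then frozen:

* **Aberrant activation.** The aberrant index of a pathway is the fraction
  of tonic-firing time its response exceeds 0.2 × the intact
  *event-evoked* reference (mean response during bursts for D1, during
  pauses for D2). Event-evoked references are used because phasic-*epoch*
  means are diluted by the background time between events — with the
  diluted reference the criterion sits inside the bulk of baseline
  fluctuations and even intact tissue indexes ~0.3. Breakdown at a
  denervation level is declared when the index exceeds its seed-matched
  intact value by more than 0.035 (the excess form pairs out each seed's
  shared schedule statistics; a 30-s phasic half contains only ~8
  Poisson-placed events, so absolute per-seed indices are noisy), or when
  the phasic/tonic contrast (mP−mT)/(mP+mT) falls below 0.2.
* **Receptor EC50s.** Only the ordering EC50_D2 ≪ tonic baseline ≪ EC50_D1
  is constrained by the source; 10 nM and 300 nM are used. 300 nM (rather
  than the ~1 µM low-affinity binding constant) reflects the coupling of
  occupancy to the functional cascade and lets burst-evoked D1 excursions
  clear the baseline fluctuation scale.

With these frozen values the 5-seed full-scale sweep puts first breakdown
at 80% denervation and restoration (phasic D2 within 10% of intact,
criterion untriggered) at 70%.

The autoreceptor multiplier s = 1 − 0.5·C²/(C²+40²) acts on a low-pass
filtered copy of local DA (τ = 0.3 s): feedback sets the tonic operating
point (the steady state, and hence the closed-form balance, is unchanged)
but lags sub-second bursts instead of clamping them. With instantaneous
feedback, 0.3-s bursts saturate at ~125 nM; with the lag they reach the
~300 nM range typical of striatal burst transients.

## Drug interventions (qualitative anchors)

* **l-dopa**: vesicular quantum ×2. Acute = transduction kept at the
  pre-drug (denervated, adapted) state; chronic = thresholds and gains
  recalibrated on the post-drug signal. In intact tissue the tonic D2
  binding shifts by ~13%; raw DA rises more (~85%), since the synthesis
  regulation that would cap it presynaptically is outside the model scope.
* **low-dose uptake inhibition** (cocaine/methylphenidate range):
  competitive, Km ×3.
* **high-dose amphetamine**: vesicular quench 1.0 (no action-potential
  release), effective Km ×30 (transporter reversal ≈ no net reuptake), and
  continuous efflux of 250 molecules/s per surviving terminal. Intact
  tissue then reaches ~0.3 µM within seconds; a lesioned hemisphere rises
  proportionally to its surviving innervation and saturates lower because
  nonspecific clearance breaks the release/uptake cancellation. These
  values are qualitative and were fixed once so that the amphetamine
  rotation phenomenology (below) is reproduced.

## Rotation prediction

Each hemisphere drives locomotion on its contralateral side: the D1 (Gs)
cascade excites the direct/Go pathway, while the below-threshold D2 cascade
r_D2 is the indirect/NoGo readout — DA acting on D2 receptors suppresses
it. The locomotor drive of a hemisphere is

    L = ⟨r_D1⟩/ref_D1 − ⟨r_D2⟩/ref_D2,

means over the whole schedule, each normalized by the intact drug-free
overall mean of the same pathway, so the intact resting hemisphere sits at
L ≈ 0 (activation levels compared on a shared scale). The predicted
rotation follows the hemisphere with the larger drive; differences below
10% of the total activation magnitude count as no net rotation. Drug-free
coherent lesions are evaluated in the chronically adapted state; void
lesions have no phasic signal at the probe, their gain adaptation is
undefined (flagged uncompensable), and they are evaluated pre-adaptation.

This reproduces the six-panel unilateral-lesion table: no rotation for
drug-free lesions of any regime; contraversive rotation for a low-coherent
lesion under low-dose uptake inhibition; ipsiversive rotation for an acute
high-coherent lesion under amphetamine, canceling to none once adaptation
is fully developed; ipsiversive rotation for an extensive (void) lesion
under amphetamine. A related sensitivity analysis (`uptake_quench_dose`)
shows the uptake-inhibition dose needed to quench phasic D2 signaling is
lower in partially denervated tissue than intact — the basis of the
methylphenidate-sensitivity prediction for subclinical disease.

## Numerics

* Explicit Euler diffusion with a hard CFL guard dt ≤ h²/(6·D_eff)
  (2.07 ms at the defaults; dt = 1 ms is used). Negative concentrations
  anywhere abort the run.
* A quantum is deposited as a Gaussian of fixed physical width
  σ = 2 µm (normalized on the truncated 2σ kernel) rather than into a
  single voxel: the point source is below grid resolution, and a
  grid-independent kernel keeps the transient DAT saturation — and with it
  the tonic balance — stable under refinement (2 µm → 1 µm changes the
  tonic mean by <1%; time-step halving by ~2%).
* Mass is accounted exactly: released + effluxed − uptaken − cleared equals
  the change in total field DA to 10⁻⁸ relative per run, and pure diffusion
  conserves mass to 10⁻¹⁰ over 10⁴ steps.
* Reproducibility: a single master seed fans out into counter-based
  substreams (per-neuron background, epoch schedule, terminal placement,
  release draws), so runs are bit-for-bit reproducible and adding neurons
  never reshuffles existing trains.

## Problem sizes

Full-scale runs use the (60 µm)³ lattice, a 64 s schedule (32 s tonic then
32 s phasic), dt = 1 ms, 100 intact neurons and 4 regional probes; sweeps
use 5 seeds. The statistical test suite runs the same pipeline on a
(40 µm)³ lattice with a 24 s schedule (10 seeds for the passive-
stabilization equivalence tests, TOST at α = 0.01 with a 15% margin) and
2 seeds at full scale for the breakdown sweep; these sizes give
comfortably reproducible statistics for every directional claim tested.

## What the synthetic data does and does not capture

All inputs are generated: spike trains are homogeneous Poisson with
idealized, fully synchronized rectangular bursts and silent pauses;
innervation is spatially uniform (or uniform spheres of arbors) with no
patch/matrix structure, no axonal morphology, and no sprouting; surviving
neurons are unaltered by disease; receptor pools neither desensitize nor
switch affinity states; the intracellular cascade is a memoryless
rectifier; adaptation is quasi-static (instant recalibration between
conditions). Passing tests therefore demonstrate the *mechanisms* —
passive stabilization, phasic attenuation, gain-compensation breakdown,
void diffusion limits, drug direction-of-effect — under these idealized
conditions; they do not validate quantitative predictions for real tissue,
where synthesis regulation, heterogeneous innervation and slower
adaptation dynamics would modify the numbers.

## Known limitations

* The breakdown level depends on the frozen criterion constants; the model
  produces a gradual deterioration, and any sharp "threshold" is a
  property of the criterion as much as of the physics.
* Somatodendritic autoreceptor feedback on firing rate is not enabled by
  default (only release-probability feedback is).
* Desk-scale voids are represented by complete local denervation; the
  partial DA levels at void boundaries appear only in the dedicated
  steady-state solver.
* Drug anchors are qualitative; doses map to parameter multipliers, not to
  mg/kg.
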