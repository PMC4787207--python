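"""In-silico experiments: denervation sweeps, drug challenges, rotation.

Every condition follows the same pipeline: build an innervation map, degrade
it, drive it with a mixed tonic→phasic spike schedule, simulate the dopamine
field, convert probe concentrations to D1/D2 occupancies, and transduce them
with homeostatically calibrated thresholds and gains.  Conditions are paired
by seed (the intact reference for a seed uses the same spike trains and the
same terminal placement) so comparisons across denervation levels are
low-variance.

Denervation seeds are reused across levels of a sweep, which makes removal
*progressive*: the terminals lost at 50% are a subset of those lost at 70%.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import (
    AmphetamineSpec,
    ConfigError,
    InterventionSpec,
    RunConfig,
    TransductionConfig,
)
from .dopamine_field import ConcentrationTrace, default_probes, simulate
from .innervation import (
    TerminalMap,
    build_mesoscale,
    build_microscale,
    denervate_arbors,
    denervate_uniform,
    find_voids,
)
from .receptors import OccupancyTrace, occupancy_equilibrium
from .spike_trains import SpikeTrainSet, generate, make_schedule
from .transduction import (
    ResponseSummary,
    ResponseTrace,
    TransductionState,
    calibrate_gain,
    calibrate_thresholds,
    d1_response,
    summarize,
)

__all__ = [
    "ExperimentSummary",
    "RotationPrediction",
    "SignalRun",
    "run_signal",
    "evaluate_condition",
    "denervation_sweep",
    "sweep_table",
    "breakdown_level",
    "restoration_level",
    "ldopa_experiment",
    "hemisphere_experiment",
    "rotation_predictor",
    "rotation_table",
    "uptake_quench_dose",
]

# Desk-scale lesion regimes for the hemisphere comparison.  The void regime
# removes every arbor: the simulated volume then stands for the deep
# interior of an extensive (>500 µm) void, where distally sourced dopamine
# is essentially absent (the boundary physics of finite voids is covered by
# the dedicated steady-state solver).
REGIME_FRACTIONS = {"low_coherent": 0.6, "high_coherent": 0.85}
VOID_ARBOR_FRACTION = 1.0
VOID_N_ARBORS = 200

# Standard drug specifications (qualitative anchors, see docs/methods.md).
DRUGS: Dict[str, Optional[InterventionSpec]] = {
    "none": None,
    "ldopa": InterventionSpec(ldopa_quantum_scale=2.0),
    "uptake": InterventionSpec(uptake_km_scale=3.0),
    "amph": InterventionSpec(amphetamine=AmphetamineSpec()),
}


@dataclass
class SignalRun:
    """One simulated condition: map, trains, dopamine trace, occupancy."""

    tmap: TerminalMap
    trains: SpikeTrainSet
    trace: ConcentrationTrace
    occ: OccupancyTrace
    denervation: float
    intervention: str = "none"

    def da_summary(self, burn_in: float = 2.0) -> Dict[str, float]:
        return self.trace.summary(burn_in)


@dataclass
class ExperimentSummary:
    """Per-condition record: dopamine statistics + transduction readouts."""

    label: str
    denervation: float
    intervention: str
    compensation: str  # uncompensated | compensated | acute_drug | chronic_drug
    da_mean_tonic: float
    da_sd_tonic: float
    da_mean_phasic: float
    da_sd_phasic: float
    response: ResponseSummary
    state: TransductionState
    overall_mean_d1: float = 0.0
    overall_mean_d2: float = 0.0


@dataclass(frozen=True)
class RotationPrediction:
    direction: str  # ipsiversive | contraversive | none
    drive_lesioned: float
    drive_intact: float


def _mixed_schedule(duration: float):
    return make_schedule(duration, duration / 2.0)


def build_map(
    cfg: RunConfig,
    denervation: float,
    seed: int,
    mode: str = "uniform",
) -> TerminalMap:
    """Intact microscale (or mesoscale) map degraded to ``denervation``."""
    if mode == "uniform":
        tmap = build_microscale(cfg.lattice, cfg.experiment.terminal_density, seed)
        if denervation > 0:
            tmap = denervate_uniform(tmap, denervation, seed)
        return tmap
    if mode == "arbor":
        arbors, tmap = build_mesoscale(
            cfg.lattice, VOID_N_ARBORS, 0.027, cfg.experiment.terminal_density, seed
        )
        if denervation > 0:
            tmap = denervate_arbors(arbors, tmap, denervation, seed)
        return tmap
    raise ConfigError(f"unknown map mode {mode!r}")


def run_signal(
    cfg: RunConfig,
    *,
    denervation: float = 0.0,
    seed: int = 0,
    intervention: Optional[InterventionSpec] = None,
    tmap: Optional[TerminalMap] = None,
    probes: Optional[np.ndarray] = None,
    probe_radius: Optional[float] = 12.0,
    intervention_label: str = "none",
) -> SignalRun:
    """Simulate one condition under the mixed tonic→phasic schedule."""
    ex = cfg.experiment
    if tmap is None:
        tmap = build_map(cfg, denervation, seed)
    sched = _mixed_schedule(ex.duration)
    firing = cfg.firing.model_copy(update={"mode": "phasic"})
    # Denervation is neuron loss: the box is driven by proportionally fewer
    # neurons, each keeping its (sparse) complement of in-volume terminals.
    # This is what keeps baseline fluctuations — per-spike release bunches
    # with density-independent amplitude but density-scaled rate and
    # density-inverse decay time — invariant under coherent denervation.
    n_eff = max(1, int(round(ex.n_neurons * (1.0 - denervation))))
    trains = generate(n_eff, sched, firing, seed)
    if probes is None:
        probes = default_probes(cfg.lattice, ex.n_probes)
    trace = simulate(
        trains,
        tmap,
        cfg.kinetics,
        intervention=intervention,
        probes=probes,
        probe_radius=probe_radius,
        dt=ex.dt,
        seed=seed,
    )
    occ = occupancy_equilibrium(trace, cfg.receptors)
    return SignalRun(tmap, trains, trace, occ, denervation, intervention_label)


def _summarize_run(
    run: SignalRun,
    resp: ResponseTrace,
    state: TransductionState,
    intact_ref: Optional[ResponseSummary],
    cfg: RunConfig,
    label: str,
    compensation: str,
) -> ExperimentSummary:
    tc = cfg.transduction
    da = run.da_summary(tc.burn_in)
    rs = summarize(resp, intact_ref, tc)
    mask = run.occ.times >= tc.burn_in
    return ExperimentSummary(
        label=label,
        denervation=run.denervation,
        intervention=run.intervention,
        compensation=compensation,
        da_mean_tonic=da.get("mean_tonic", float("nan")),
        da_sd_tonic=da.get("sd_tonic", float("nan")),
        da_mean_phasic=da.get("mean_phasic", float("nan")),
        da_sd_phasic=da.get("sd_phasic", float("nan")),
        response=rs,
        state=state,
        overall_mean_d1=float(resp.r_d1[mask].mean()),
        overall_mean_d2=float(resp.r_d2[mask].mean()),
    )


def evaluate_condition(
    run: SignalRun,
    cfg: RunConfig,
    intact_ref: Optional[ResponseSummary] = None,
    label: str = "",
) -> Tuple[ExperimentSummary, ExperimentSummary, ResponseSummary]:
    """Uncompensated and gain-compensated summaries for one condition.

    Thresholds are always recalibrated to the condition's own tonic baseline
    (quasi-static homeostasis).  When ``intact_ref`` is None the condition is
    its own reference (the intact case), making its gain 1 by construction.
    Returns (uncompensated, compensated, intact_reference_used).
    """
    tc = cfg.transduction
    th1, th2 = calibrate_thresholds(run.occ, tc)
    state0 = TransductionState(th1, th2, 1.0, 1.0, provenance="intact")
    resp0 = d1_response(run.occ, state0)
    if intact_ref is None:
        intact_ref = summarize(resp0, None, tc)
    sum0 = _summarize_run(run, resp0, state0, intact_ref, cfg, label or "uncompensated", "uncompensated")
    state1 = calibrate_gain(resp0, intact_ref, state0, tc)
    resp1 = d1_response(run.occ, state1)
    sum1 = _summarize_run(run, resp1, state1, intact_ref, cfg, label or "compensated", "compensated")
    return sum0, sum1, intact_ref


def denervation_sweep(
    cfg: RunConfig,
    levels: Optional[Sequence[float]] = None,
    seeds: Optional[Sequence[int]] = None,
) -> List[Dict]:
    """Run the denervation sweep; one record per (level, seed).

    Each record carries the uncompensated and compensated summaries plus the
    seed-matched intact reference.
    """
    ex = cfg.experiment
    if levels is None:
        levels = ex.levels
    if seeds is None:
        seeds = [cfg.master_seed + i for i in range(ex.n_seeds)]
    for lv in levels:
        if not 0.0 <= lv <= 1.0:
            raise ConfigError(f"denervation level {lv} outside [0, 1]")
    # The intact reference is pooled across seeds: a single seed's phasic
    # half contains only a handful of burst/pause events, so per-seed
    # references are noisy and would leak that noise into every relative
    # metric of the sweep.
    intact_runs = {seed: run_signal(cfg, denervation=0.0, seed=seed) for seed in seeds}
    refs = [evaluate_condition(run, cfg)[2] for run in intact_runs.values()]
    intact_ref = ResponseSummary(
        **{
            f: float(np.mean([getattr(r, f) for r in refs]))
            for f in (
                "mean_d1_tonic", "mean_d1_phasic", "mean_d2_tonic", "mean_d2_phasic",
                "mean_d1_burst", "mean_d2_pause",
            )
        }
    )
    records: List[Dict] = []
    for seed in seeds:
        for lv in levels:
            run = (
                intact_runs[seed]
                if lv == 0.0
                else run_signal(cfg, denervation=lv, seed=seed)
            )
            try:
                sum0, sum1, _ = evaluate_condition(
                    run, cfg, intact_ref, label=f"denervation={lv:.2f}"
                )
            except ConfigError as e:
                raise ConfigError(f"denervation level {lv}, seed {seed}: {e}") from e
            records.append(
                {
                    "level": lv,
                    "seed": seed,
                    "uncompensated": sum0,
                    "compensated": sum1,
                    "intact_ref": intact_ref,
                }
            )
    return records


def sweep_table(records: List[Dict]) -> pd.DataFrame:
    """Tidy table: one row per condition × compensation × pathway × epoch."""
    rows = []
    for rec in records:
        for comp in ("uncompensated", "compensated"):
            s: ExperimentSummary = rec[comp]
            for pathway in ("d1", "d2"):
                for epoch in ("tonic", "phasic"):
                    rows.append(
                        {
                            "level": rec["level"],
                            "seed": rec["seed"],
                            "compensation": comp,
                            "pathway": pathway,
                            "epoch": epoch,
                            "mean_response": getattr(s.response, f"mean_{pathway}_{epoch}"),
                            "da_mean": s.da_mean_tonic if epoch == "tonic" else s.da_mean_phasic,
                            "da_sd": s.da_sd_tonic if epoch == "tonic" else s.da_sd_phasic,
                            "aberrant_index": getattr(s.response, f"aberrant_index_{pathway}"),
                            "contrast": getattr(s.response, f"contrast_{pathway}"),
                            "gain": getattr(s.state, f"gain_{pathway}"),
                            "threshold": getattr(s.state, f"theta_{pathway}"),
                        }
                    )
    return pd.DataFrame(rows)


def _level_means(records: List[Dict]) -> Dict[float, Dict[str, float]]:
    out: Dict[float, Dict[str, float]] = {}
    levels = sorted({r["level"] for r in records})
    # seed-matched intact indices: the excess over these pairs out the
    # common baseline statistics of each seed's schedule
    intact = {
        r["seed"]: r["compensated"].response.aberrant_index_d2
        for r in records
        if r["level"] == 0.0
    }
    intact_d1 = {
        r["seed"]: r["compensated"].response.aberrant_index_d1
        for r in records
        if r["level"] == 0.0
    }
    for lv in levels:
        recs = [r for r in records if r["level"] == lv]
        comp = [r["compensated"] for r in recs]
        refs = [r["intact_ref"] for r in recs]
        out[lv] = {
            "contrast_d2": float(np.mean([c.response.contrast_d2 for c in comp])),
            "aberrant_d2": float(np.mean([c.response.aberrant_index_d2 for c in comp])),
            "aberrant_d1": float(np.mean([c.response.aberrant_index_d1 for c in comp])),
            "excess_d2": float(
                np.mean(
                    [
                        r["compensated"].response.aberrant_index_d2
                        - intact.get(r["seed"], 0.0)
                        for r in recs
                    ]
                )
            ),
            "excess_d1": float(
                np.mean(
                    [
                        r["compensated"].response.aberrant_index_d1
                        - intact_d1.get(r["seed"], 0.0)
                        for r in recs
                    ]
                )
            ),
            "phasic_d2_ratio": float(
                np.mean(
                    [
                        c.response.mean_d2_phasic / ref.mean_d2_phasic
                        for c, ref in zip(comp, refs)
                        if ref.mean_d2_phasic > 0
                    ]
                )
            ),
            "gain_d2": float(np.mean([c.state.gain_d2 for c in comp])),
        }
    return out


def _triggered(m: Dict[str, float], tc: TransductionConfig) -> bool:
    return m["contrast_d2"] < tc.contrast_lost or m["excess_d2"] > tc.aberrant_threshold


def breakdown_level(records: List[Dict], tc: TransductionConfig) -> Optional[float]:
    """Smallest denervation level whose seed-mean compensated-D2 metrics meet
    the breakdown criterion (contrast lost, or aberrant-index excess over the
    seed-matched intact condition above threshold)."""
    means = _level_means(records)
    for lv in sorted(means):
        if lv > 0 and _triggered(means[lv], tc):
            return lv
    return None


def restoration_level(records: List[Dict], tc: TransductionConfig) -> Optional[float]:
    """Largest level where compensation restores phasic D2 to within 10% of
    intact without triggering the breakdown criterion."""
    means = _level_means(records)
    best = None
    for lv in sorted(means):
        m = means[lv]
        restored = abs(m["phasic_d2_ratio"] - 1.0) <= 0.10
        if restored and not _triggered(m, tc):
            best = lv
    return best


def ldopa_experiment(
    cfg: RunConfig,
    denervation: float = 0.85,
    mode: str = "acute",
    seed: int = 0,
    drug: Optional[InterventionSpec] = None,
) -> Dict[str, ExperimentSummary]:
    """Paired pre/post l-dopa condition at a given denervation.

    Pre-drug transduction is the compensated (adapted) denervated state.
    ``mode="acute"`` keeps pre-drug thresholds and gains; ``mode="chronic"``
    recalibrates both on the post-drug signal.
    """
    if mode not in ("acute", "chronic"):
        raise ConfigError(f"unknown l-dopa mode {mode!r}")
    drug = drug or DRUGS["ldopa"]
    tc = cfg.transduction

    intact_run = run_signal(cfg, denervation=0.0, seed=seed)
    _, _, intact_ref = evaluate_condition(intact_run, cfg)

    pre_run = run_signal(cfg, denervation=denervation, seed=seed)
    _, pre_sum, _ = evaluate_condition(pre_run, cfg, intact_ref, label="pre-drug")

    post_run = run_signal(
        cfg,
        denervation=denervation,
        seed=seed,
        tmap=pre_run.tmap,
        intervention=drug,
        intervention_label="ldopa",
    )
    if mode == "acute":
        post_state = replace(pre_sum.state, provenance="acute_drug")
        post_resp = d1_response(post_run.occ, post_state)
        post_sum = _summarize_run(
            post_run, post_resp, post_state, intact_ref, cfg, "post-drug", "acute_drug"
        )
    else:
        th1, th2 = calibrate_thresholds(post_run.occ, tc)
        st0 = TransductionState(th1, th2, 1.0, 1.0, provenance="chronic_drug")
        resp0 = d1_response(post_run.occ, st0)
        post_state = replace(
            calibrate_gain(resp0, intact_ref, st0, tc), provenance="chronic_drug"
        )
        post_resp = d1_response(post_run.occ, post_state)
        post_sum = _summarize_run(
            post_run, post_resp, post_state, intact_ref, cfg, "post-drug", "chronic_drug"
        )
    return {"pre": pre_sum, "post": post_sum, "intact_ref_phasic_d2": intact_ref.mean_d2_phasic}


def _void_probes(tmap: TerminalMap, n_probes: int) -> np.ndarray:
    """Probe voxels nearest the centroid of the largest terminal-free void."""
    voids = find_voids(tmap, min_equiv_diameter=3 * tmap.lattice.voxel_size)
    if not voids:
        raise ConfigError("void regime requested but no voids present in lesioned map")
    v = voids[0]
    centroid = v.voxel_indices.mean(axis=0)
    d = np.linalg.norm(v.voxel_indices - centroid, axis=1)
    order = np.argsort(d)
    return v.voxel_indices[order[:n_probes]].astype(np.int64)


def hemisphere_experiment(
    cfg: RunConfig,
    regime: str,
    drug: str = "none",
    compensated: bool = True,
    seed: int = 0,
    lesion_fraction: Optional[float] = None,
    intact_pre: Optional[SignalRun] = None,
) -> Tuple[ExperimentSummary, ExperimentSummary, ResponseSummary]:
    """Paired lesioned/intact hemisphere summaries under a shared schedule.

    Regimes: ``low_coherent`` (<70% uniform), ``high_coherent`` (≥70%
    uniform) and ``void`` (whole-arbor loss; probes sit inside the largest
    void).  The drug is applied acutely on top of the (optionally)
    adaptation-compensated lesioned state.  Returns
    (lesioned, intact, intact drug-free reference).
    """
    if regime not in ("low_coherent", "high_coherent", "void"):
        raise ConfigError(f"unknown regime {regime!r}")
    if drug not in DRUGS:
        raise ConfigError(f"unknown drug {drug!r}")
    if lesion_fraction is not None:
        if regime == "low_coherent" and lesion_fraction >= 0.7:
            raise ConfigError("low_coherent regime requires fraction < 0.7")
        if regime == "high_coherent" and lesion_fraction < 0.7:
            raise ConfigError("high_coherent regime requires fraction >= 0.7")
    spec = DRUGS[drug]
    tc = cfg.transduction

    les_probe_radius = 12.0
    if regime == "void":
        frac = lesion_fraction if lesion_fraction is not None else VOID_ARBOR_FRACTION
        les_map = build_map(cfg, frac, seed, mode="arbor")
        les_probes = _void_probes(les_map, cfg.experiment.n_probes)
        # probes must sample inside the void, not across its boundary
        les_probe_radius = min(12.0, 2 * cfg.lattice.voxel_size)
    else:
        frac = lesion_fraction if lesion_fraction is not None else REGIME_FRACTIONS[regime]
        les_map = build_map(cfg, frac, seed, mode="uniform")
        les_probes = None

    # drug-free runs establish the adapted transduction state per hemisphere
    if intact_pre is None:
        intact_pre = run_signal(cfg, denervation=0.0, seed=seed)
    _, _, intact_ref = evaluate_condition(intact_pre, cfg)
    intact_state = TransductionState(
        *calibrate_thresholds(intact_pre.occ, tc), 1.0, 1.0, provenance="intact"
    )

    les_pre = run_signal(
        cfg, denervation=frac, seed=seed, tmap=les_map, probes=les_probes,
        probe_radius=les_probe_radius,
    )
    th1, th2 = calibrate_thresholds(les_pre.occ, tc)
    les_state = TransductionState(th1, th2, 1.0, 1.0, provenance="intact")
    if compensated:
        resp0 = d1_response(les_pre.occ, les_state)
        les_state = calibrate_gain(resp0, intact_ref, les_state, tc)

    if spec is None:
        les_run, intact_run = les_pre, intact_pre
    else:
        les_run = run_signal(
            cfg, denervation=frac, seed=seed, tmap=les_map, probes=les_probes,
            probe_radius=les_probe_radius, intervention=spec, intervention_label=drug,
        )
        intact_run = run_signal(
            cfg, denervation=0.0, seed=seed, tmap=intact_pre.tmap,
            intervention=spec, intervention_label=drug,
        )

    comp_label = "compensated" if compensated else "uncompensated"
    les_resp = d1_response(les_run.occ, les_state)
    les_sum = _summarize_run(
        les_run, les_resp, les_state, intact_ref, cfg, f"lesioned/{regime}/{drug}", comp_label
    )
    int_resp = d1_response(intact_run.occ, intact_state)
    int_sum = _summarize_run(
        intact_run, int_resp, intact_state, intact_ref, cfg, f"intact/{drug}", "uncompensated"
    )
    return les_sum, int_sum, intact_ref


def rotation_predictor(
    lesioned: ExperimentSummary,
    intact: ExperimentSummary,
    intact_ref: ResponseSummary,
    tolerance: float = 0.1,
) -> RotationPrediction:
    """Predict rotation direction from per-hemisphere locomotor drives.

    Each hemisphere drives locomotion on the contralateral body side.  D1
    (Gs) cascade activation excites the direct (Go) pathway; the D2 (Gi/o)
    cascade read out here is the indirect (NoGo) pathway's disinhibition
    signal, so dopamine acting on D2 receptors *suppresses* it.  The drive is

        L = <r_d1>/ref_d1 − <r_d2>/ref_d2

    with means over the whole schedule, each normalized by the intact
    drug-free overall mean of the same pathway — the intact resting
    hemisphere is thereby the zero point of the drive scale, as when
    activation levels are compared on a shared color scale.  The hemisphere
    with the larger drive wins; a drive difference below ``tolerance`` of
    the total activation magnitude gives no net rotation.
    """
    ref1 = 0.5 * (intact_ref.mean_d1_tonic + intact_ref.mean_d1_phasic) or 1.0
    ref2 = 0.5 * (intact_ref.mean_d2_tonic + intact_ref.mean_d2_phasic) or 1.0
    n1l = lesioned.overall_mean_d1 / ref1
    n2l = lesioned.overall_mean_d2 / ref2
    n1i = intact.overall_mean_d1 / ref1
    n2i = intact.overall_mean_d2 / ref2
    l_les = n1l - n2l
    l_int = n1i - n2i
    scale = max(abs(l_les), abs(l_int), 0.5 * (n1l + n2l + n1i + n2i), 1e-12)
    delta = (l_les - l_int) / scale
    if delta > tolerance:
        direction = "contraversive"
    elif delta < -tolerance:
        direction = "ipsiversive"
    else:
        direction = "none"
    return RotationPrediction(direction, l_les, l_int)


def rotation_table(cfg: RunConfig, seed: int = 0, tolerance: float = 0.1) -> Dict[str, str]:
    """Predicted rotation direction for the canonical lesion × drug cases.

    Cases: drug-free low-coherent, high-coherent and void lesions;
    low-coherent + low-dose uptake inhibition; high-coherent + amphetamine,
    acute and after full adaptation; void + amphetamine.
    """
    # Drug-free coherent lesions are evaluated in the chronically adapted
    # (compensated) state; the void lesion has no phasic signal at the
    # probe, so its gain adaptation is undefined (uncompensable) and it is
    # evaluated pre-adaptation.
    panels = {
        "low_drugfree": ("low_coherent", "none", True),
        "high_drugfree": ("high_coherent", "none", True),
        "void_drugfree": ("void", "none", False),
        "low_uptake": ("low_coherent", "uptake", True),
        "high_amph_acute": ("high_coherent", "amph", False),
        "high_amph_adapted": ("high_coherent", "amph", True),
        "void_amph": ("void", "amph", False),
    }
    out: Dict[str, str] = {}
    intact_pre = run_signal(cfg, denervation=0.0, seed=seed)
    for name, (regime, drug, comp) in panels.items():
        les, intact, ref = hemisphere_experiment(
            cfg, regime, drug, comp, seed, intact_pre=intact_pre
        )
        out[name] = rotation_predictor(les, intact, ref, tolerance).direction
    return out


def uptake_quench_dose(
    cfg: RunConfig,
    denervation: float,
    km_scales: Sequence[float] = (1.5, 2.0, 3.0, 4.0, 6.0),
    seed: int = 0,
    quench_fraction: float = 0.25,
) -> Optional[float]:
    """Smallest uptake-inhibition dose (Km multiplier) that quenches phasic
    D2 signaling at a given denervation.

    The lesion is adaptation-compensated; the drug acts acutely.  "Quenched"
    means the phasic-epoch D2 response falls below ``quench_fraction`` of its
    drug-free value in the same condition.  Used for the methylphenidate
    sensitivity analysis: partially denervated tissue should quench at lower
    doses than intact tissue.
    """
    tc = cfg.transduction
    intact_run = run_signal(cfg, denervation=0.0, seed=seed)
    _, _, intact_ref = evaluate_condition(intact_run, cfg)
    pre = run_signal(cfg, denervation=denervation, seed=seed)
    th1, th2 = calibrate_thresholds(pre.occ, tc)
    state = TransductionState(th1, th2, 1.0, 1.0)
    state = calibrate_gain(d1_response(pre.occ, state), intact_ref, state, tc)
    base = d1_response(pre.occ, state).epoch_mean("d2", "phasic", tc.burn_in)
    if base <= 0:
        return None
    for scale in sorted(km_scales):
        run = run_signal(
            cfg,
            denervation=denervation,
            seed=seed,
            tmap=pre.tmap,
            intervention=InterventionSpec(uptake_km_scale=scale),
            intervention_label="uptake",
        )
        resp = d1_response(run.occ, state)
        if resp.epoch_mean("d2", "phasic", tc.burn_in) < quench_fraction * base:
            return scale
    return None
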