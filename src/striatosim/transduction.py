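"""Threshold/gain transduction of receptor occupancy into pathway activation.

The postsynaptic abstraction has two parameters per pathway:

* threshold θ — the occupancy at which the cascade engages, set
  homeostatically to the mean binding during tonic firing;
* gain g — the amplification of deviations from threshold, set inversely
  proportional to the activity evoked by phasic firing (so a weakened phasic
  signal is amplified back to its intact level).

The Gs-coupled D1 cascade responds above threshold,
r_d1 = g·max(0, occ − θ); the Gi/o-coupled D2 cascade responds below it,
r_d2 = g·max(0, θ − occ) (dips in occupancy — pauses — disinhibit the
cascade).  Compensation raises the gain as denervation attenuates phasic
amplitude; beyond a point the amplified baseline fluctuations activate the
cascade during plain tonic firing (aberrant activation) and the
phasic/tonic contrast collapses.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np

from .config import ConfigError, TransductionConfig
from .receptors import OccupancyTrace

__all__ = [
    "TransductionState",
    "ResponseTrace",
    "ResponseSummary",
    "calibrate_thresholds",
    "calibrate_gain",
    "d1_response",
    "d2_response",
    "aberrant_index",
    "contrast",
    "summarize",
]


@dataclass(frozen=True)
class TransductionState:
    theta_d1: float
    theta_d2: float
    gain_d1: float = 1.0
    gain_d2: float = 1.0
    provenance: str = "intact"
    uncompensable_d1: bool = False
    uncompensable_d2: bool = False

    def __post_init__(self):
        for th in (self.theta_d1, self.theta_d2):
            if not 0.0 <= th <= 1.0:
                raise ConfigError("thresholds must lie in [0, 1]")
        if self.gain_d1 < 0 or self.gain_d2 < 0:
            raise ConfigError("gains must be non-negative")


@dataclass
class ResponseTrace:
    """Pathway activation r(t) per probe, shape (t, p); arbitrary units."""

    times: np.ndarray
    r_d1: np.ndarray
    r_d2: np.ndarray
    mode_schedule: List[Tuple[float, float, str]] = field(default_factory=list)
    epochs: List[Tuple[float, float, str]] = field(default_factory=list)

    def epoch_mask(self, mode: str, burn_in: float = 0.0) -> np.ndarray:
        m = np.zeros(len(self.times), dtype=bool)
        for a, b, mode_i in self.mode_schedule:
            if mode_i == mode:
                m |= (self.times >= a + burn_in) & (self.times < b)
        return m

    def event_mask(self, kind: str) -> np.ndarray:
        """Time mask of fine schedule epochs ('burst' or 'pause')."""
        m = np.zeros(len(self.times), dtype=bool)
        for a, b, k in self.epochs:
            if k == kind:
                m |= (self.times >= a) & (self.times < b)
        return m

    def event_mean(self, pathway: str, kind: str) -> Optional[float]:
        r = self.r_d1 if pathway == "d1" else self.r_d2
        m = self.event_mask(kind)
        if not m.any():
            return None
        return float(r[m].mean())

    def epoch_mean(self, pathway: str, mode: str, burn_in: float = 0.0) -> float:
        r = self.r_d1 if pathway == "d1" else self.r_d2
        m = self.epoch_mask(mode, burn_in)
        if not m.any():
            raise ConfigError(f"no {mode} samples in trace")
        return float(r[m].mean())


@dataclass(frozen=True)
class ResponseSummary:
    """Per-epoch pathway means plus the aberration/contrast metrics.

    ``mean_d1_burst`` and ``mean_d2_pause`` are event-evoked means over the
    epochs that actually carry each pathway's functional signal (bursts for
    D1, pauses for D2), undiluted by the background time between events.
    """

    mean_d1_tonic: float
    mean_d1_phasic: float
    mean_d2_tonic: float
    mean_d2_phasic: float
    mean_d1_burst: float = 0.0
    mean_d2_pause: float = 0.0
    aberrant_index_d1: float = 0.0
    aberrant_index_d2: float = 0.0
    contrast_d1: float = 0.0
    contrast_d2: float = 0.0


def d1_response(occ: OccupancyTrace, state: TransductionState) -> ResponseTrace:
    """Above-threshold rectified-linear D1 (Gs) cascade activation."""
    r1 = state.gain_d1 * np.maximum(0.0, occ.occ_d1 - state.theta_d1)
    r2 = state.gain_d2 * np.maximum(0.0, state.theta_d2 - occ.occ_d2)
    return ResponseTrace(occ.times, r1, r2, list(occ.mode_schedule), list(occ.epochs))


def d2_response(occ: OccupancyTrace, state: TransductionState) -> ResponseTrace:
    """Below-threshold rectified-linear D2 (Gi/o) cascade activation.

    Provided as a named counterpart to :func:`d1_response`; both cascades are
    evaluated on the shared trace and returned together.
    """
    return d1_response(occ, state)


def calibrate_thresholds(
    reference_occ: OccupancyTrace,
    cfg: Optional[TransductionConfig] = None,
) -> Tuple[float, float]:
    """Thresholds = mean occupancy per receptor during tonic firing.

    The reference trace must contain at least ``cfg.min_reference`` seconds of
    tonic-mode samples after burn-in.
    """
    cfg = cfg or TransductionConfig()
    m = reference_occ.epoch_mask("tonic", cfg.burn_in)
    if len(reference_occ.times) > 1:
        dt = float(np.median(np.diff(reference_occ.times)))
    else:
        dt = 0.0
    covered = m.sum() * dt
    if covered + 1e-9 < cfg.min_reference:
        raise ConfigError(
            f"tonic reference covers {covered:.1f}s after burn-in; "
            f"need >= {cfg.min_reference:.1f}s"
        )
    return float(reference_occ.occ_d1[m].mean()), float(reference_occ.occ_d2[m].mean())


def calibrate_gain(
    condition_response: ResponseTrace,
    intact_reference: ResponseSummary,
    state: TransductionState,
    cfg: Optional[TransductionConfig] = None,
) -> TransductionState:
    """Rescale gains so the phasic-epoch means match the intact reference.

    ``condition_response`` must already be computed with ``state``.  A pathway
    whose phasic-evoked response is zero cannot be compensated: its gain is
    capped at ``cfg.gain_cap`` and the state is flagged uncompensable.
    Idempotent: recalibrating an already-compensated state leaves it fixed.
    """
    cfg = cfg or TransductionConfig()
    burn = cfg.burn_in
    updates: Dict[str, object] = {}
    for pathway, ref in (("d1", intact_reference.mean_d1_phasic), ("d2", intact_reference.mean_d2_phasic)):
        cur = condition_response.epoch_mean(pathway, "phasic", burn)
        g_old = getattr(state, f"gain_{pathway}")
        if cur <= 0.0:
            updates[f"gain_{pathway}"] = cfg.gain_cap
            updates[f"uncompensable_{pathway}"] = True
            continue
        g_new = g_old * ref / cur
        if g_new > cfg.gain_cap:
            g_new = cfg.gain_cap
            updates[f"uncompensable_{pathway}"] = True
        updates[f"gain_{pathway}"] = g_new
    updates["provenance"] = "compensated"
    return replace(state, **updates)


def aberrant_index(
    resp: ResponseTrace,
    intact_ref: ResponseSummary,
    pathway: str,
    cfg: Optional[TransductionConfig] = None,
) -> float:
    """Fraction of tonic-firing time the response exceeds the criterion.

    The criterion is ``cfg.aberrant_criterion`` × the intact phasic-epoch
    mean of the same pathway; 0 means the cascade is never driven by
    baseline fluctuations.
    """
    cfg = cfg or TransductionConfig()
    m = resp.epoch_mask("tonic", cfg.burn_in)
    if not m.any():
        raise ConfigError("aberrant_index requires tonic-firing samples")
    r = (resp.r_d1 if pathway == "d1" else resp.r_d2)[m]
    # the reference scale is the intact event-evoked response (bursts carry
    # the D1 signal, pauses the D2 signal); the phasic-epoch mean is the
    # fallback when no fine event schedule is available
    if pathway == "d1":
        ref = intact_ref.mean_d1_burst or intact_ref.mean_d1_phasic
    else:
        ref = intact_ref.mean_d2_pause or intact_ref.mean_d2_phasic
    crit = cfg.aberrant_criterion * ref
    return float((r > crit).mean())


def contrast(resp: ResponseTrace, pathway: str, cfg: Optional[TransductionConfig] = None) -> float:
    """(mean_P − mean_T)/(mean_P + mean_T); 1 = fully phasic-specific."""
    cfg = cfg or TransductionConfig()
    mp = resp.epoch_mean(pathway, "phasic", cfg.burn_in)
    mt = resp.epoch_mean(pathway, "tonic", cfg.burn_in)
    if mp + mt == 0.0:
        return 0.0
    return (mp - mt) / (mp + mt)


def summarize(
    resp: ResponseTrace,
    intact_ref: Optional[ResponseSummary] = None,
    cfg: Optional[TransductionConfig] = None,
) -> ResponseSummary:
    """Epoch means plus, when an intact reference is given, the aberration
    indices and contrasts."""
    cfg = cfg or TransductionConfig()
    b = cfg.burn_in
    means = {
        f"mean_{p}_{m}": resp.epoch_mean(p, m, b)
        for p in ("d1", "d2")
        for m in ("tonic", "phasic")
        if resp.epoch_mask(m, b).any()
    }
    for p in ("d1", "d2"):
        means.setdefault(f"mean_{p}_tonic", 0.0)
        means.setdefault(f"mean_{p}_phasic", 0.0)
    means["mean_d1_burst"] = resp.event_mean("d1", "burst") or 0.0
    means["mean_d2_pause"] = resp.event_mean("d2", "pause") or 0.0
    extras = {}
    if intact_ref is not None:
        has_t = resp.epoch_mask("tonic", b).any()
        has_p = resp.epoch_mask("phasic", b).any()
        if has_t:
            extras["aberrant_index_d1"] = aberrant_index(resp, intact_ref, "d1", cfg)
            extras["aberrant_index_d2"] = aberrant_index(resp, intact_ref, "d2", cfg)
        if has_t and has_p:
            extras["contrast_d1"] = contrast(resp, "d1", cfg)
            extras["contrast_d2"] = contrast(resp, "d2", cfg)
    return ResponseSummary(**means, **extras)
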