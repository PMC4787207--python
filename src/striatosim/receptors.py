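"""Dopamine receptor occupancy from concentration traces.

D2-like receptors are the high-affinity species (EC50 ~ 10 nM, occupied by
the tonic baseline); D1-like receptors are low-affinity (EC50 ~ 1 µM,
recruited mainly by phasic bursts).  Equilibrium mode applies the Hill
binding isotherm sample-by-sample; kinetic mode integrates the two-state
binding ODE and relaxes to the same isotherm for fast rates.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Tuple

import numpy as np

from .config import ConfigError, ReceptorParams
from .dopamine_field import ConcentrationTrace

__all__ = ["OccupancyTrace", "occupancy_equilibrium", "occupancy_kinetic", "hill"]


@dataclass
class OccupancyTrace:
    """D1/D2 occupancy per time sample and probe, shape (t, p)."""

    times: np.ndarray
    occ_d1: np.ndarray
    occ_d2: np.ndarray
    mode_schedule: List[Tuple[float, float, str]] = field(default_factory=list)
    epochs: List[Tuple[float, float, str]] = field(default_factory=list)

    def epoch_mask(self, mode: str, burn_in: float = 0.0) -> np.ndarray:
        m = np.zeros(len(self.times), dtype=bool)
        for a, b, mode_i in self.mode_schedule:
            if mode_i == mode:
                m |= (self.times >= a + burn_in) & (self.times < b)
        return m


def hill(c: np.ndarray, ec50: float, n: float) -> np.ndarray:
    """Hill occupancy C^n / (C^n + EC50^n), safe at C = 0."""
    c = np.asarray(c, dtype=float)
    ch = np.power(np.maximum(c, 0.0), n)
    return ch / (ch + ec50 ** n)


def occupancy_equilibrium(trace: ConcentrationTrace, params: ReceptorParams) -> OccupancyTrace:
    """Instantaneous-equilibrium binding readout of a concentration trace.

    Occupancy is computed per probe (a probe is a point measure standing in
    for one postsynaptic neuron's receptor pool); downstream statistics are
    averaged across probes only after any nonlinear step.
    """
    c = trace.values
    return OccupancyTrace(
        times=trace.times,
        occ_d1=hill(c, params.ec50_d1, params.hill),
        occ_d2=hill(c, params.ec50_d2, params.hill),
        mode_schedule=list(trace.mode_schedule),
        epochs=list(trace.epochs),
    )


def occupancy_kinetic(trace: ConcentrationTrace, params: ReceptorParams) -> OccupancyTrace:
    """Integrate d(occ)/dt = k_on·C·(1−occ) − k_off·occ per receptor.

    Receptor affinity is k_off/k_on per species: the supplied k_off is used
    for both receptors and k_on is derived from each EC50 so that the kinetic
    fixed point matches the equilibrium isotherm (hill = 1).
    """
    if params.k_on is None or params.k_off is None:
        raise ConfigError("kinetic mode requires k_on and k_off")
    t = trace.times
    if len(t) < 2:
        raise ConfigError("kinetic mode needs at least two samples")
    dt = float(np.diff(t).mean())
    if not np.allclose(np.diff(t), dt, rtol=1e-6, atol=1e-9):
        raise ConfigError("kinetic mode requires uniformly spaced samples")
    if dt > 0.1 / params.k_off:
        raise ConfigError(
            f"sample interval {dt:g}s too coarse for k_off={params.k_off:g}/s "
            "(need dt <= 0.1/k_off)"
        )
    c = trace.values
    occ = {}
    for name, ec50 in (("d1", params.ec50_d1), ("d2", params.ec50_d2)):
        k_off = params.k_off
        k_on = k_off / ec50
        o = np.empty_like(c)
        o[0] = hill(c[:1], ec50, 1.0)[0]
        for i in range(1, len(c)):
            o[i] = o[i - 1] + dt * (k_on * c[i - 1] * (1 - o[i - 1]) - k_off * o[i - 1])
        occ[name] = np.clip(o, 0.0, 1.0)
    return OccupancyTrace(
        times=t,
        occ_d1=occ["d1"],
        occ_d2=occ["d2"],
        mode_schedule=list(trace.mode_schedule),
        epochs=list(trace.epochs),
    )
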