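"""Extracellular dopamine dynamics on the lattice.

The update per time step dt is, in order:

1. quantal release — every spike of every neuron gives each of that neuron's
   terminals an independent chance ``p_release × s(C_local)`` to release one
   vesicle into its voxel, where s is the autoreceptor suppression factor;
2. explicit (forward-Euler) diffusion with periodic boundaries;
3. Michaelis–Menten reuptake, with per-voxel Vmax proportional to the local
   terminal count and normalized so that at the intact reference density the
   volume-average equals ``vmax_total``;
4. first-order nonspecific clearance at rate ``k_ns``;
5. optional continuous amphetamine efflux per surviving terminal.

Because terminals are simultaneously the sources (release) and the sinks
(reuptake) of dopamine, uniformly removing them leaves the tonic balance
point unchanged — passive stabilization — while slowing all transients, which
is what attenuates phasic signaling under denervation.

The scheme is explicit, so dt must satisfy the CFL-type stability bound
dt ≤ h²/(6 D_eff); ``simulate`` refuses to run otherwise.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import numba
from scipy.optimize import brentq

from .config import ConfigError, InterventionSpec, KineticParams, Lattice
from .innervation import TerminalMap
from .spike_trains import SpikeTrainSet

__all__ = [
    "ConcentrationTrace",
    "simulate",
    "analytic_tonic_mean",
    "void_steady_state",
    "apply_intervention",
    "default_probes",
    "cfl_bound",
]


@dataclass
class ConcentrationTrace:
    """Extracellular dopamine time series at probe voxels (nM)."""

    probe_voxels: np.ndarray  # (p, 3) int voxel indices
    times: np.ndarray  # (t,) s
    values: np.ndarray  # (t, p) nM
    mode_schedule: List[Tuple[float, float, str]] = field(default_factory=list)
    epochs: List[Tuple[float, float, str]] = field(default_factory=list)
    mass_balance: Dict[str, float] = field(default_factory=dict)
    final_field: Optional[np.ndarray] = None

    def epoch_mask(self, mode: str, burn_in: float = 0.0) -> np.ndarray:
        """Boolean time mask for a firing mode ('tonic' or 'phasic').

        ``burn_in`` discards the first seconds of each mode interval so that
        statistics are not contaminated by the transient after a switch.
        """
        m = np.zeros(len(self.times), dtype=bool)
        for a, b, mode_i in self.mode_schedule:
            if mode_i == mode:
                m |= (self.times >= a + burn_in) & (self.times < b)
        return m

    def summary(self, burn_in: float = 0.0) -> Dict[str, float]:
        """Per-mode mean and temporal SD, averaged across probes."""
        out: Dict[str, float] = {}
        for mode in ("tonic", "phasic"):
            m = self.epoch_mask(mode, burn_in)
            if not m.any():
                continue
            v = self.values[m]
            out[f"mean_{mode}"] = float(v.mean())
            out[f"sd_{mode}"] = float(v.std(axis=0).mean())
        return out


def cfl_bound(lattice: Lattice, params: KineticParams) -> float:
    """Largest stable explicit time step: h² / (6 D_eff)."""
    return lattice.voxel_size ** 2 / (6.0 * params.d_eff)


@numba.njit(cache=True, fastmath=True)
def _step(c, out, car, ar_fac, dcoef, vmax_dt, km, kns_dt):  # pragma: no cover - jitted
    nz, ny, nx = c.shape
    uptaken = 0.0
    cleared = 0.0
    for i in range(nz):
        im = nz - 1 if i == 0 else i - 1
        ip = 0 if i == nz - 1 else i + 1
        for j in range(ny):
            jm = ny - 1 if j == 0 else j - 1
            jp = 0 if j == ny - 1 else j + 1
            for k in range(nx):
                kmi = nx - 1 if k == 0 else k - 1
                kp = 0 if k == nx - 1 else k + 1
                cc = c[i, j, k]
                lap = (
                    c[im, j, k]
                    + c[ip, j, k]
                    + c[i, jm, k]
                    + c[i, jp, k]
                    + c[i, j, kmi]
                    + c[i, j, kp]
                    - 6.0 * cc
                )
                cn = cc + dcoef * lap
                u = vmax_dt[i, j, k] * cn / (cn + km)
                cn -= u
                uptaken += u
                cl = kns_dt * cn
                cn -= cl
                cleared += cl
                out[i, j, k] = cn
                if ar_fac > 0.0:
                    car[i, j, k] += ar_fac * (cn - car[i, j, k])
    return uptaken, cleared


def default_probes(lattice: Lattice, n_probes: int = 4) -> np.ndarray:
    """Evenly spaced probe voxels along the main diagonal."""
    shape = np.asarray(lattice.shape)
    fracs = (np.arange(n_probes) + 0.5) / n_probes
    return (fracs[:, None] * shape[None, :]).astype(np.int64)


def _probe_regions(probes: np.ndarray, lattice: Lattice, radius) -> np.ndarray:
    """Flat voxel indices of each probe's sampling sphere, shape (p, K).

    ``radius=None`` selects the whole lattice (volume-average readout).
    """
    shape = lattice.shape
    if radius is None:
        return np.tile(np.arange(int(np.prod(shape))), (len(probes), 1))
    if radius <= 0:
        return np.ravel_multi_index((probes[:, 0], probes[:, 1], probes[:, 2]), shape)[:, None]
    h = lattice.voxel_size
    if 2 * radius >= min(lattice.extent):
        raise ConfigError("probe_radius too large for the lattice")
    rad = int(np.floor(radius / h))
    off = np.arange(-rad, rad + 1)
    oz, oy, ox = np.meshgrid(off, off, off, indexing="ij")
    offsets = np.stack([oz.ravel(), oy.ravel(), ox.ravel()], axis=1)
    inside = np.sum(offsets ** 2, axis=1) * h ** 2 <= radius ** 2
    offsets = offsets[inside]
    nbr = (probes[:, None, :] + offsets[None, :, :]) % np.asarray(shape)
    return np.ravel_multi_index((nbr[..., 0], nbr[..., 1], nbr[..., 2]), shape)


def _spikes_by_step(trains: SpikeTrainSet, dt: float, n_steps: int) -> Dict[int, np.ndarray]:
    """step index -> array of neuron ids spiking during that step."""
    steps: List[np.ndarray] = []
    neurons: List[np.ndarray] = []
    for i, t in enumerate(trains.spikes):
        s = np.floor(t / dt).astype(np.int64)
        s = s[s < n_steps]
        steps.append(s)
        neurons.append(np.full(len(s), i, dtype=np.int64))
    if not steps:
        return {}
    allsteps = np.concatenate(steps)
    allneurons = np.concatenate(neurons)
    order = np.argsort(allsteps, kind="stable")
    allsteps = allsteps[order]
    allneurons = allneurons[order]
    out: Dict[int, np.ndarray] = {}
    uniq, idx = np.unique(allsteps, return_index=True)
    bounds = np.append(idx, len(allsteps))
    for u, a, b in zip(uniq, bounds[:-1], bounds[1:]):
        out[int(u)] = allneurons[a:b]
    return out


def simulate(
    trains: SpikeTrainSet,
    tmap: TerminalMap,
    params: KineticParams,
    *,
    intervention: Optional[InterventionSpec] = None,
    probes: Optional[np.ndarray] = None,
    duration: Optional[float] = None,
    dt: float = 1e-3,
    seed: int = 0,
    initial: Optional[float | np.ndarray] = None,
    record_every: int = 1,
    probe_radius: Optional[float] = 12.0,
    keep_field: bool = False,
) -> ConcentrationTrace:
    """Run the volume-transmission simulation and record probe concentrations.

    ``initial`` seeds the field (nM); by default the analytic tonic balance
    point is used so recordings start near steady state.  ``record_every``
    subsamples the stored trace (dynamics always advance at ``dt``).

    Each probe reports the mean concentration over a sphere of
    ``probe_radius`` µm around its voxel (periodic wrap), emulating the
    sampling volume of an extracellular measurement; ``probe_radius=0``
    gives a bare single-voxel point measure and ``probe_radius=None`` the
    whole-volume average.  The averaging scale matters: point measures
    carry quantal shot noise proportional to terminal density, and a
    regional sphere still loses slow release transients by diffusion once
    the uptake screening length outgrows it, so passive stabilization of
    the baseline SD holds exactly only for averages over scales beyond the
    screening length (the volume readout).
    """
    lattice = tmap.lattice
    if intervention is not None:
        params = apply_intervention(params, intervention)
    bound = cfl_bound(lattice, params)
    if dt > bound * (1 + 1e-12):
        raise ConfigError(
            f"dt={dt:g} s violates the explicit-diffusion stability bound "
            f"dt <= h^2/(6 D_eff) = {bound:g} s"
        )
    if duration is None:
        duration = trains.duration
    if duration > trains.duration + 1e-9:
        raise ConfigError("simulation duration exceeds spike-train duration")
    n_steps = int(round(duration / dt))

    shape = lattice.shape
    counts = tmap.counts().astype(np.float64)
    # per-terminal Vmax normalized to the intact reference density
    intact_per_voxel = tmap.intact_density * lattice.voxel_volume
    if intact_per_voxel > 0:
        vmax = params.vmax_nM * counts / intact_per_voxel
    else:
        vmax = np.zeros(shape)

    if initial is None:
        # start at the tonic balance point so recordings begin near steady
        # state; the empirical pooled rate stands in for the nominal one.
        # A sourceless (fully denervated) map has no balance point: it
        # represents the deep interior of an extensive void, where dopamine
        # is essentially absent.
        if tmap.n_terminals == 0:
            c0 = 0.0
        else:
            rate = trains.n_spikes() / (trains.duration * trains.n_neurons) if trains.duration > 0 else 0.0
            try:
                c0 = analytic_tonic_mean(params, firing_rate=rate, density=tmap.intact_density)
            except ConfigError:
                c0 = 0.0
        c = np.full(shape, c0, dtype=np.float64)
    elif np.isscalar(initial):
        c = np.full(shape, float(initial), dtype=np.float64)
    else:
        c = np.array(initial, dtype=np.float64)
        if c.shape != shape:
            raise ConfigError("initial field shape does not match lattice")
    out = np.empty_like(c)

    # terminal bookkeeping
    n_term = tmap.n_terminals
    if n_term:
        vidx = tmap.voxel_indices()
        term_flat = np.ravel_multi_index((vidx[:, 0], vidx[:, 1], vidx[:, 2]), shape)
    else:
        term_flat = np.empty(0, dtype=np.int64)
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(20,)))
    # assign terminals to neurons uniformly at random (or by arbor parity when
    # arbors are present, keeping whole arbors on one neuron)
    if n_term:
        if tmap.arbor_id is not None:
            owner = tmap.arbor_id % trains.n_neurons
        else:
            owner = rng.integers(0, trains.n_neurons, size=n_term)
        order = np.argsort(owner, kind="stable")
        sorted_terms = term_flat[order]
        owner_sorted = owner[order]
        starts = np.searchsorted(owner_sorted, np.arange(trains.n_neurons + 1))
        terms_of = [sorted_terms[starts[i]:starts[i + 1]] for i in range(trains.n_neurons)]
    else:
        terms_of = [np.empty(0, dtype=np.int64) for _ in range(trains.n_neurons)]

    q_c = params.quantum_conc(lattice.voxel_volume)
    spikes = _spikes_by_step(trains, dt, n_steps)

    # A quantum is deposited with a fixed physical Gaussian width rather than
    # into a single voxel: the sub-voxel point source is below grid
    # resolution, and a grid-independent kernel keeps the local saturation of
    # uptake (and hence the tonic balance) stable under grid refinement.
    if params.release_sigma > 0 and n_term:
        h = lattice.voxel_size
        rad = max(1, int(np.ceil(2.0 * params.release_sigma / h)))
        off = np.arange(-rad, rad + 1)
        oz, oy, ox = np.meshgrid(off, off, off, indexing="ij")
        offsets = np.stack([oz.ravel(), oy.ravel(), ox.ravel()], axis=1)
        kernel_w = np.exp(
            -0.5 * (np.sum(offsets ** 2, axis=1) * h ** 2) / params.release_sigma ** 2
        )
        kernel_w /= kernel_w.sum()
        nbr = (vidx[:, None, :] + offsets[None, :, :]) % np.asarray(shape)
        term_nbr = np.ravel_multi_index((nbr[..., 0], nbr[..., 1], nbr[..., 2]), shape)
    elif n_term:
        term_nbr = term_flat[:, None]
        kernel_w = np.ones(1)
    else:
        term_nbr = np.empty((0, 1), dtype=np.int64)
        kernel_w = np.ones(1)
    if n_term:
        nbr_of = [term_nbr[order][starts[i]:starts[i + 1]] for i in range(trains.n_neurons)]
    else:
        nbr_of = [term_nbr for _ in range(trains.n_neurons)]
    deposit = q_c * kernel_w

    ar = params.autoreceptor
    # autoreceptors sense a low-pass-filtered copy of local DA: feedback
    # develops over ~tau and therefore lags sub-second bursts instead of
    # clamping them instantaneously
    ar_fac = dt / ar.tau if (ar.enabled and ar.tau > 0) else 0.0
    car = c.copy() if ar_fac > 0 else c
    dcoef = params.d_eff * dt / lattice.voxel_size ** 2
    vmax_dt = vmax * dt
    km = params.km_nM
    kns_dt = params.k_ns * dt

    if probes is None:
        probes = default_probes(lattice)
    probes = np.atleast_2d(np.asarray(probes, dtype=np.int64))
    probe_flat = _probe_regions(probes, lattice, probe_radius)  # (p, K)

    n_rec = (n_steps + record_every - 1) // record_every
    times = np.empty(n_rec)
    values = np.empty((n_rec, len(probe_flat)))

    efflux_field = None
    if params.efflux_rate > 0 and n_term:
        per_mol = params.molecule_conc(lattice.voxel_volume)
        eff = np.zeros(int(np.prod(shape)))
        np.add.at(eff, term_flat, dt * params.efflux_rate * per_mol)
        efflux_field = eff.reshape(shape)

    released = 0.0
    uptaken = 0.0
    cleared = 0.0
    effluxed = 0.0
    total0 = float(c.sum())

    cflat = c.reshape(-1)
    carflat = car.reshape(-1)
    rec = 0
    for step in range(n_steps):
        neurons = spikes.get(step)
        if neurons is not None:
            for nid in neurons:
                tf = terms_of[nid]
                if len(tf) == 0:
                    continue
                p = params.p_release
                if ar.enabled and ar.max_suppression > 0:
                    cl = carflat[tf]
                    ch = cl ** ar.hill
                    p = p * (1.0 - ar.max_suppression * ch / (ch + ar.ec50 ** ar.hill))
                rel = np.nonzero(rng.random(len(tf)) < p)[0]
                if len(rel):
                    idx = nbr_of[nid][rel]
                    np.add.at(cflat, idx.ravel(), np.tile(deposit, len(rel)))
                    released += q_c * len(rel)
        if efflux_field is not None:
            c += efflux_field
            effluxed += float(efflux_field.sum())
        u, cl_ = _step(c, out, car, ar_fac, dcoef, vmax_dt, km, kns_dt)
        uptaken += u
        cleared += cl_
        c, out = out, c
        cflat = c.reshape(-1)
        if ar_fac == 0.0:
            carflat = cflat
        if step % record_every == 0:
            times[rec] = (step + 1) * dt
            values[rec] = cflat[probe_flat].mean(axis=1)
            rec += 1
        if step % 1000 == 999 and c.min() < 0:
            raise ConfigError("negative concentration encountered: scheme failure")
    if n_steps and c.min() < 0:
        raise ConfigError("negative concentration encountered: scheme failure")

    mass = {
        "released": released,
        "uptaken": uptaken,
        "cleared": cleared,
        "effluxed": effluxed,
        "delta_total": float(c.sum()) - total0,
    }
    return ConcentrationTrace(
        probe_voxels=probes,
        times=times[:rec],
        values=values[:rec],
        mode_schedule=list(trains.mode_schedule),
        epochs=[(e.start, e.end, e.kind) for e in trains.schedule],
        mass_balance=mass,
        final_field=c.copy() if keep_field else None,
    )


def analytic_tonic_mean(
    params: KineticParams, firing_rate: float = 4.0, density: float = 0.1
) -> float:
    """Closed-form tonic balance concentration (nM).

    Solves, per unit volume,

        rate · p_release · s(C) · quantum · density / (N_A · α)
            = Vmax_total · (density/density) · C / (C + Km)

    The terminal density multiplies both sides and cancels: the tonic mean is
    invariant to coherent denervation (passive stabilization).  Returns 0 for
    zero release; raises if release flux exceeds uptake capacity even at full
    autoreceptor suppression (no steady state).
    """
    if firing_rate < 0:
        raise ConfigError("firing_rate must be non-negative")
    if firing_rate == 0 or params.p_release == 0 or params.quantum == 0:
        return 0.0
    if params.vmax_total <= 0:
        raise ConfigError("vmax_total must be positive for a tonic steady state")
    per_molecule = params.molecule_conc(1.0)  # nM per (molecule/µm³)
    # volumetric release flux at the reference density; the *actual* density
    # scales release and uptake identically and cancels, so `density` here is
    # the intact calibration density at which vmax_total is defined
    flux = firing_rate * params.p_release * params.quantum * per_molecule * density

    ar = params.autoreceptor

    def supp(c: float) -> float:
        if not ar.enabled or ar.max_suppression == 0:
            return 1.0
        ch = c ** ar.hill
        return 1.0 - ar.max_suppression * ch / (ch + ar.ec50 ** ar.hill)

    vmax = params.vmax_nM
    km = params.km_nM
    s_min = 1.0 - (ar.max_suppression if ar.enabled else 0.0)
    if flux * s_min >= vmax:
        raise ConfigError(
            "release flux exceeds uptake capacity: no tonic steady state "
            f"(flux {flux * s_min:.1f} nM/s >= Vmax {vmax:.1f} nM/s)"
        )

    def balance(c: float) -> float:
        return flux * supp(c) - vmax * c / (c + km)

    hi = km * flux * s_min / (vmax - flux * s_min) + km  # generous upper bracket
    lo = 0.0
    while balance(hi) > 0:
        hi *= 2.0
    return float(brentq(balance, lo, hi, xtol=1e-9, rtol=1e-12))


def void_steady_state(
    radius: float,
    params: KineticParams,
    boundary_conc: float = 1.0,
    *,
    mode: str = "analytic",
    n_radial: int = 400,
    voxel: float = 5.0,
) -> Tuple[np.ndarray, np.ndarray, float]:
    """Steady-state dopamine profile inside a spherical terminal-free void.

    Solves D_eff ∇²C = k_ns C on a sphere of radius R with C(R) fixed.  The
    closed form is C(r) = C_R (R/r) sinh(r/λ)/sinh(R/λ), λ = sqrt(D_eff/k_ns),
    with center value C_R (R/λ)/sinh(R/λ).  ``mode="numeric"`` solves the
    same problem by 3-D finite differences on a cubic grid with the sphere
    carved out (the general machinery for arbitrary void masks) and must
    agree with the closed form to ~(voxel/λ)² relative accuracy.

    Returns (r, C(r), C_center).
    """
    if radius <= 0:
        raise ConfigError("void radius must be positive")
    if params.k_ns <= 0:
        raise ConfigError("k_ns must be positive for a void steady state")
    lam = np.sqrt(params.d_eff / params.k_ns)
    r = np.linspace(0.0, radius, n_radial)
    x = radius / lam
    with np.errstate(invalid="ignore", divide="ignore"):
        prof = boundary_conc * (radius / r) * np.sinh(r / lam) / np.sinh(x)
    center = boundary_conc * x / np.sinh(x)
    prof[0] = center
    if mode == "analytic":
        return r, prof, float(center)
    if mode != "numeric":
        raise ConfigError(f"unknown void solver mode {mode!r}")

    # 3-D finite-difference solve on a cube enclosing the sphere
    from scipy.sparse import coo_matrix
    from scipy.sparse.linalg import cg

    h = voxel
    n = int(np.ceil(2 * radius / h)) + 3
    grid = (np.arange(n) + 0.5) * h - n * h / 2.0
    zz, yy, xx = np.meshgrid(grid, grid, grid, indexing="ij")
    rr = np.sqrt(xx ** 2 + yy ** 2 + zz ** 2)
    inside = rr < radius
    nunk = int(inside.sum())
    idx = -np.ones((n + 2, n + 2, n + 2), dtype=np.int64)  # padded with outside
    idx[1:-1, 1:-1, 1:-1][inside] = np.arange(nunk)
    core = idx[1:-1, 1:-1, 1:-1]
    dcoef = params.d_eff / h ** 2

    rows = [np.arange(nunk)]
    cols = [np.arange(nunk)]
    vals = [np.full(nunk, params.k_ns + 6.0 * dcoef)]
    rhs = np.zeros(nunk)
    shifts = [
        idx[:-2, 1:-1, 1:-1], idx[2:, 1:-1, 1:-1],
        idx[1:-1, :-2, 1:-1], idx[1:-1, 2:, 1:-1],
        idx[1:-1, 1:-1, :-2], idx[1:-1, 1:-1, 2:],
    ]
    me = core[inside]
    for nb_arr in shifts:
        nb = nb_arr[inside]
        linked = nb >= 0
        rows.append(me[linked])
        cols.append(nb[linked])
        vals.append(np.full(linked.sum(), -dcoef))
        # neighbors outside the void hold the boundary concentration
        np.add.at(rhs, me[~linked], dcoef * boundary_conc)
    mat = coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(nunk, nunk),
    ).tocsr()
    sol, info = cg(mat, rhs, rtol=1e-10, maxiter=20000)
    if info != 0:
        raise ConfigError(f"void solver failed to converge (info={info})")

    # radial average of the numeric solution
    nbins = min(n_radial, n)
    bins = np.linspace(0, radius, nbins + 1)
    rin = rr[inside]
    which = np.clip(np.digitize(rin, bins) - 1, 0, nbins - 1)
    prof_num = np.full(nbins, np.nan)
    for bi in range(nbins):
        m = which == bi
        if m.any():
            prof_num[bi] = sol[m].mean()
    r_num = 0.5 * (bins[:-1] + bins[1:])
    near = rin <= max(h, radius / 20)
    c_center = float(sol[near].mean()) if near.any() else float(sol[np.argmin(rin)])
    good = ~np.isnan(prof_num)
    return r_num[good], prof_num[good], c_center


def apply_intervention(params: KineticParams, spec: InterventionSpec) -> KineticParams:
    """Return kinetics modified by a drug intervention.

    l-dopa scales the vesicular quantum; uptake inhibition scales Km
    (competitive); amphetamine quenches vesicular release, blocks uptake
    (Km multiplier) and switches on continuous transporter-mediated efflux.
    """
    upd: Dict[str, float] = {}
    if spec.ldopa_quantum_scale != 1.0:
        upd["quantum"] = params.quantum * spec.ldopa_quantum_scale
    km = params.km * spec.uptake_km_scale
    if spec.amphetamine is not None:
        a = spec.amphetamine
        upd["p_release"] = params.p_release * (1.0 - a.vesicular_quench)
        km = km * a.uptake_block
        upd["efflux_rate"] = a.efflux_rate
    if km != params.km:
        upd["km"] = km
    if not upd:
        return params
    return params.model_copy(update=upd)
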