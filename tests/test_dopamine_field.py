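"""Dopamine field: conservation, oracles, stability, interventions."""
import numpy as np
import pytest

import striatosim as ss
from striatosim.config import ConfigError


@pytest.fixture(scope="module")
def kin():
    return ss.KineticParams()


class TestConservationAndStability:
    def test_pure_diffusion_conserves_mass(self, fast_cfg):
        # release, uptake and clearance off; periodic boundaries: the total
        # dopamine must be conserved to roundoff over 10^4 steps
        lat = fast_cfg.lattice
        kin = ss.KineticParams(vmax_total=0.0, k_ns=0.0, p_release=0.0)
        tmap = ss.TerminalMap(lattice=lat, positions=np.empty((0, 3)), intact_density=0.0)
        trains = ss.SpikeTrainSet(1, 10.0, [np.empty(0)], mode_schedule=[(0.0, 10.0, "tonic")])
        rng = np.random.default_rng(0)
        init = rng.random(lat.shape) * 100.0
        trace = ss.simulate(trains, tmap, kin, dt=1e-3, seed=0, initial=init, keep_field=True)
        assert trace.final_field.sum() == pytest.approx(init.sum(), rel=1e-10)

    def test_cfl_violation_raises_naming_bound(self, fast_cfg, intact_map):
        trains = ss.generate_tonic(2, 1.0, fast_cfg.firing, seed=0)
        with pytest.raises(ConfigError, match="stability bound"):
            ss.simulate(trains, intact_map, fast_cfg.kinetics, dt=5e-3, seed=0)

    def test_mass_accounting_closes(self, fast_cfg, tonic_trace):
        m = tonic_trace.mass_balance
        lhs = m["released"] + m["effluxed"] - m["uptaken"] - m["cleared"]
        scale = max(abs(m["released"]), 1.0)
        assert lhs == pytest.approx(m["delta_total"], abs=1e-8 * scale)

    def test_bitwise_seed_reproducibility(self, fast_cfg, intact_map):
        trains = ss.generate_tonic(20, 3.0, fast_cfg.firing, seed=5)
        a = ss.simulate(trains, intact_map, fast_cfg.kinetics, dt=1e-3, seed=5)
        b = ss.simulate(trains, intact_map, fast_cfg.kinetics, dt=1e-3, seed=5)
        np.testing.assert_array_equal(a.values, b.values)


class TestTonicOracle:
    def test_zero_rate_gives_zero(self, kin):
        assert ss.analytic_tonic_mean(kin, firing_rate=0.0) == 0.0

    def test_density_invariance(self, kin):
        # passive stabilization in closed form: scaling the terminal density
        # with per-terminal release and uptake fixed (vmax_total tracks
        # density) leaves the balance point unchanged
        a = ss.analytic_tonic_mean(kin, density=0.1)
        scaled = kin.model_copy(update={"vmax_total": kin.vmax_total * 0.1})
        b = ss.analytic_tonic_mean(scaled, density=0.01)
        assert a == pytest.approx(b, rel=1e-9)

    def test_no_steady_state_detected(self):
        kin = ss.KineticParams(vmax_total=0.01, p_release=1.0, quantum=30000)
        with pytest.raises(ConfigError, match="no tonic steady state"):
            ss.analytic_tonic_mean(kin)

    def test_simulation_matches_analytic_within_10pct(self, fast_cfg, tonic_trace, kin):
        analytic = ss.analytic_tonic_mean(kin, firing_rate=4.0, density=0.1)
        sim = tonic_trace.summary(burn_in=4.0)["mean_tonic"]
        assert sim == pytest.approx(analytic, rel=0.10)

    def test_nonspecific_clearance_negligible_in_intact_tissue(self, kin):
        with_ns = ss.analytic_tonic_mean(kin)
        without = ss.analytic_tonic_mean(kin.model_copy(update={"k_ns": 0.0}))
        assert abs(with_ns - without) / without < 0.03


class TestVoidSteadyState:
    def test_closed_form_center_fraction_500um(self, kin):
        # R = 250 µm, lambda = 70 µm: center/boundary = x/sinh(x), x = 25/7
        _, _, center = ss.void_steady_state(250.0, kin, boundary_conc=1.0)
        x = 250.0 / np.sqrt(kin.d_eff / kin.k_ns)
        assert center == pytest.approx(x / np.sinh(x), rel=1e-9)
        assert center == pytest.approx(0.201, abs=0.001)

    def test_small_void_approaches_boundary_value(self, kin):
        _, _, center = ss.void_steady_state(1.0, kin, boundary_conc=1.0)
        assert center == pytest.approx(1.0, abs=1e-3)

    def test_center_fraction_decreases_with_radius(self, kin):
        fr = [ss.void_steady_state(r, kin)[2] for r in (50, 150, 250, 400)]
        assert all(a > b for a, b in zip(fr, fr[1:]))

    def test_numeric_solver_matches_closed_form(self, kin):
        r_a, prof_a, c_a = ss.void_steady_state(250.0, kin, mode="analytic")
        r_n, prof_n, c_n = ss.void_steady_state(250.0, kin, mode="numeric", voxel=5.0)
        assert c_n == pytest.approx(c_a, rel=0.02)
        interp = np.interp(r_n, r_a, prof_a)
        assert np.max(np.abs(prof_n - interp) / interp) < 0.02

    def test_invalid_inputs_rejected(self, kin):
        with pytest.raises(ConfigError):
            ss.void_steady_state(-1.0, kin)
        with pytest.raises(ConfigError):
            ss.void_steady_state(10.0, kin.model_copy(update={"k_ns": 0.0}))


class TestInterventions:
    def test_identity_spec_is_noop(self, kin):
        out = ss.apply_intervention(kin, ss.InterventionSpec())
        assert out == kin

    def test_ldopa_scales_quantum(self, kin):
        out = ss.apply_intervention(kin, ss.InterventionSpec(ldopa_quantum_scale=2.0))
        assert out.quantum == 2 * kin.quantum
        assert out.quantum_conc(8.0) == pytest.approx(2 * kin.quantum_conc(8.0))

    def test_uptake_inhibition_scales_km(self, kin):
        out = ss.apply_intervention(kin, ss.InterventionSpec(uptake_km_scale=3.0))
        assert out.km == pytest.approx(3 * kin.km)

    def test_amphetamine_transform(self, kin):
        spec = ss.InterventionSpec(
            amphetamine=ss.AmphetamineSpec(efflux_rate=100.0, vesicular_quench=1.0, uptake_block=10.0)
        )
        out = ss.apply_intervention(kin, spec)
        assert out.p_release == 0.0
        assert out.km == pytest.approx(10 * kin.km)
        assert out.efflux_rate == 100.0

    def test_amphetamine_rise_rate_tracks_innervation(self, fast_cfg):
        # efflux-driven concentration rise is proportional to surviving
        # terminals: the 50%-denervated map rises at half the intact rate
        lat = fast_cfg.lattice
        spec = ss.InterventionSpec(amphetamine=ss.AmphetamineSpec(efflux_rate=400.0))
        trains = ss.SpikeTrainSet(1, 2.0, [np.empty(0)], mode_schedule=[(0.0, 2.0, "tonic")])
        rates = []
        for lv in (0.0, 0.5):
            tmap = ss.build_microscale(lat, 0.1, seed=3)
            if lv:
                tmap = ss.denervate_uniform(tmap, lv, seed=3)
            tr = ss.simulate(
                trains, tmap, fast_cfg.kinetics, intervention=spec,
                dt=1e-3, seed=3, initial=0.0,
            )
            sel = tr.times <= 0.25  # early window, before uptake balances
            slope = np.polyfit(tr.times[sel], tr.values[sel].mean(axis=1), 1)[0]
            rates.append(slope)
        assert rates[1] / rates[0] == pytest.approx(0.5, abs=0.1)


class TestDenervationInvariance:
    """Passive stabilization inside the simulator itself."""

    def test_tonic_mean_invariant_to_90pct_denervation(self, fast_cfg):
        lat = fast_cfg.lattice
        means = []
        for lv, n in ((0.0, 100), (0.9, 10)):
            tmap = ss.build_microscale(lat, 0.1, seed=9)
            if lv:
                tmap = ss.denervate_uniform(tmap, lv, seed=9)
            trains = ss.generate_tonic(n, 16.0, fast_cfg.firing, seed=9)
            tr = ss.simulate(trains, tmap, fast_cfg.kinetics, dt=1e-3, seed=9)
            means.append(tr.summary(3.0)["mean_tonic"])
        assert means[1] == pytest.approx(means[0], rel=0.10)

    def test_grid_refinement_stability(self, fast_cfg):
        # halving the voxel changes the tonic mean by < 5%; the two runs use
        # the same terminal positions but independent release realizations,
        # so the run must be long enough for the time-average to settle
        means = []
        tmap2 = ss.build_microscale(ss.Lattice(extent=(24.0, 24.0, 24.0)), 0.1, seed=11)
        trains = ss.generate_tonic(40, 24.0, fast_cfg.firing, seed=11)
        # same dt on both grids (valid under both CFL bounds) so the
        # comparison isolates spatial refinement
        for h in (2.0, 1.0):
            lat = ss.Lattice(extent=(24.0, 24.0, 24.0), voxel_size=h)
            tmap = ss.TerminalMap(lattice=lat, positions=tmap2.positions, intact_density=0.1)
            tr = ss.simulate(trains, tmap, fast_cfg.kinetics, dt=5e-4, seed=11,
                             probe_radius=8.0)
            means.append(tr.summary(3.0)["mean_tonic"])
        assert means[1] == pytest.approx(means[0], rel=0.05)
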