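"""Experiment orchestration on a desk-scale lattice.

These tests run the full pipeline (map → trains → field → occupancy →
transduction) on a (40 µm)³ lattice with a 24 s schedule; statistical
assertions are directional or carry generous tolerances accordingly.
"""
import numpy as np
import pytest

import striatosim as ss
from striatosim.config import ConfigError
from striatosim import experiments as ex
from striatosim.transduction import ResponseSummary


@pytest.fixture(scope="module")
def sweep_records(fast_cfg):
    levels = [0.0, 0.5, 0.75, 0.97]
    return ex.denervation_sweep(fast_cfg, levels=levels, seeds=[1, 2])


class TestSweep:
    def test_tonic_da_mean_flat_across_levels(self, sweep_records):
        means = {}
        for r in sweep_records:
            means.setdefault(r["level"], []).append(r["compensated"].da_mean_tonic)
        base = np.mean(means[0.0])
        for lv in (0.5, 0.75):
            assert np.mean(means[lv]) == pytest.approx(base, rel=0.10)

    def test_phasic_da_sd_strictly_decreasing(self, sweep_records):
        sds = {}
        for r in sweep_records:
            sds.setdefault(r["level"], []).append(r["compensated"].da_sd_phasic)
        seq = [np.mean(sds[lv]) for lv in (0.0, 0.5, 0.75, 0.97)]
        assert all(a > b for a, b in zip(seq, seq[1:]))

    def test_uncompensated_phasic_response_decreases(self, sweep_records):
        resp = {}
        for r in sweep_records:
            resp.setdefault(r["level"], []).append(
                r["uncompensated"].response.mean_d2_phasic
            )
        seq = [np.mean(resp[lv]) for lv in (0.0, 0.5, 0.75, 0.97)]
        assert seq[0] > seq[1] > seq[2] > seq[3]

    def test_gain_nondecreasing_with_denervation(self, sweep_records):
        gains = {}
        for r in sweep_records:
            gains.setdefault(r["level"], []).append(r["compensated"].state.gain_d2)
        seq = [np.mean(gains[lv]) for lv in (0.0, 0.5, 0.75, 0.97)]
        assert all(b >= a - 1e-9 for a, b in zip(seq, seq[1:]))

    def test_compensation_restores_phasic_d2(self, sweep_records):
        for r in sweep_records:
            if r["level"] <= 0.5:
                c = r["compensated"]
                assert c.response.mean_d2_phasic == pytest.approx(
                    r["intact_ref"].mean_d2_phasic, rel=0.10
                )

    def test_tidy_table_schema(self, sweep_records):
        df = ex.sweep_table(sweep_records)
        assert {"level", "seed", "compensation", "pathway", "epoch", "mean_response", "gain"} <= set(df.columns)
        assert len(df) == len(sweep_records) * 2 * 2 * 2

    def test_bad_level_rejected(self, fast_cfg):
        with pytest.raises(ConfigError):
            ex.denervation_sweep(fast_cfg, levels=[1.5], seeds=[1])


class TestPauseSkewing:
    def test_short_pauses_attenuate_more_than_long(self, fast_cfg):
        """With denervation, slow dopamine decay means short pauses no longer
        reach the D2 threshold while long pauses still evoke full responses."""
        responses = {}
        for pd in (0.4, 2.0):
            firing = ss.FiringConfig(
                mode="phasic", pause_duration=pd,
                burst_duration=0.3,
                event_rate=0.2,
                burst_rate=4.0 + 4.0 * pd / 0.3,  # keep pairs balanced
            )
            cfg = fast_cfg.model_copy(update={"firing": firing})
            for lv in (0.0, 0.75):
                run = ex.run_signal(cfg, denervation=lv, seed=3)
                th1, th2 = ss.calibrate_thresholds(run.occ, cfg.transduction)
                st = ss.TransductionState(th1, th2)
                resp = ss.d1_response(run.occ, st)
                responses[(pd, lv)] = resp.event_mean("d2", "pause")
        short_ratio = responses[(0.4, 0.75)] / responses[(0.4, 0.0)]
        long_ratio = responses[(2.0, 0.75)] / responses[(2.0, 0.0)]
        assert short_ratio < long_ratio


class TestRotation:
    def _summary(self, d1, d2):
        rs = ResponseSummary(0, 0, 0, 0)
        return ex.ExperimentSummary(
            label="x", denervation=0, intervention="none", compensation="uncompensated",
            da_mean_tonic=0, da_sd_tonic=0, da_mean_phasic=0, da_sd_phasic=0,
            response=rs, state=ss.TransductionState(0.5, 0.5),
            overall_mean_d1=d1, overall_mean_d2=d2,
        )

    @pytest.fixture()
    def ref(self):
        return ResponseSummary(0, 1.0, 0, 1.0)

    def test_identical_summaries_give_none(self, ref):
        a = self._summary(0.5, 0.5)
        b = self._summary(0.5, 0.5)
        assert ex.rotation_predictor(a, b, ref).direction == "none"

    def test_swap_symmetry(self, ref):
        les = self._summary(1.0, 0.1)
        intact = self._summary(0.5, 0.5)
        fwd = ex.rotation_predictor(les, intact, ref)
        rev = ex.rotation_predictor(intact, les, ref)
        assert fwd.direction == "contraversive" and rev.direction == "ipsiversive"
        assert fwd.drive_lesioned == rev.drive_intact

    def test_d2_activation_opposes_locomotion(self, ref):
        # the hemisphere whose indirect-pathway (below-threshold D2) cascade
        # is silenced drives contralateral locomotion
        les = self._summary(0.5, 0.0)
        intact = self._summary(0.5, 0.5)
        assert ex.rotation_predictor(les, intact, ref).direction == "contraversive"

    def test_regime_fraction_mismatch_rejected(self, fast_cfg):
        with pytest.raises(ConfigError, match="regime"):
            ex.hemisphere_experiment(fast_cfg, "low_coherent", lesion_fraction=0.9)
        with pytest.raises(ConfigError, match="regime"):
            ex.hemisphere_experiment(fast_cfg, "high_coherent", lesion_fraction=0.3)


class TestBreakdownHelpers:
    def _record(self, level, seed, excess, contrast=0.8, ratio=1.0):
        rs = ResponseSummary(
            0.0, 0.1, 0.0, 0.2, aberrant_index_d2=excess, contrast_d2=contrast
        )
        summ = ex.ExperimentSummary(
            label="x", denervation=level, intervention="none", compensation="compensated",
            da_mean_tonic=0, da_sd_tonic=0, da_mean_phasic=0, da_sd_phasic=0,
            response=rs, state=ss.TransductionState(0.5, 0.5),
        )
        ref = ResponseSummary(0.0, 0.1, 0.0, 0.2 / ratio)
        return {"level": level, "seed": seed, "uncompensated": summ, "compensated": summ, "intact_ref": ref}

    def test_first_triggering_level_found(self):
        tc = ss.TransductionConfig()
        recs = [
            self._record(0.0, 1, 0.00),
            self._record(0.5, 1, 0.01),
            self._record(0.7, 1, 0.06),
            self._record(0.9, 1, 0.30),
        ]
        assert ex.breakdown_level(recs, tc) == 0.7
        assert ex.restoration_level(recs, tc) == 0.5

    def test_no_trigger_returns_none(self):
        tc = ss.TransductionConfig()
        recs = [self._record(lv, 1, 0.0) for lv in (0.0, 0.5)]
        assert ex.breakdown_level(recs, tc) is None


class TestUptakeInhibitionSensitivity:
    def test_quench_dose_lower_when_denervated(self, fast_cfg):
        """Partially denervated (compensated) tissue loses phasic D2
        signaling at a lower uptake-inhibition dose than intact tissue —
        the basis of the methylphenidate-sensitivity prediction."""
        doses = (2.0, 3.0, 6.0)
        intact = ex.uptake_quench_dose(fast_cfg, 0.0, km_scales=doses, seed=2)
        denerv = ex.uptake_quench_dose(fast_cfg, 0.6, km_scales=doses, seed=2)
        assert denerv is not None
        assert intact is None or denerv < intact
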