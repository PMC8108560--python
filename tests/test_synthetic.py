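import numpy as np
import pytest

from sleeptes import (
    HypnogramModel,
    OscComponent,
    StageSignalModel,
    build_schedule,
    inject_tes_artifact,
    simulate_hypnogram,
    simulate_recording,
    synthesize_epoch,
    welch_band_power,
)
from sleeptes.hypnogram import STAGES, stage_code
from sleeptes.spectral import WelchSpec

from conftest import STAGING_MONTAGE


class TestHypnogramModel:
    def test_identity_matrix_is_absorbing(self):
        model = HypnogramModel(transition_matrix=np.eye(5), initial_stage="W")
        hyp = simulate_hypnogram(model, 100, seed=0)
        assert hyp.stage_names() == ["W"] * 100

    def test_non_stochastic_rows_rejected(self):
        bad = np.eye(5)
        bad[2, 2] = 0.5
        with pytest.raises(ValueError, match="stochastic"):
            HypnogramModel(transition_matrix=bad)

    def test_determinism(self, hyp_model):
        a = simulate_hypnogram(hyp_model, 200, seed=42)
        b = simulate_hypnogram(hyp_model, 200, seed=42)
        assert a == b

    def test_stage_proportions_match_stationary_distribution(self, hyp_model):
        """Empirical stage mix over 50 nights sits within 3 SE of the
        chain's stationary distribution (eigen-decomposition oracle)."""
        pi = hyp_model.stationary_distribution()
        n_epochs, n_seeds = 960, 50
        counts = np.zeros(5)
        for seed in range(n_seeds):
            hyp = simulate_hypnogram(hyp_model, n_epochs, seed=seed)
            counts += np.bincount(hyp.labels, minlength=5)
        frac = counts / counts.sum()
        # effective SE inflated by the chain's autocorrelation; bound it by
        # the per-night SD of stage fractions across the 50 independent nights
        per_night = np.array([
            np.bincount(simulate_hypnogram(hyp_model, n_epochs, seed=1000 + s).labels,
                        minlength=5) / n_epochs
            for s in range(n_seeds)
        ])
        se = per_night.std(axis=0, ddof=1) / np.sqrt(n_seeds)
        assert np.all(np.abs(frac - pi) < 3 * se + 0.01)

    def test_n3_boost_raises_paired_n3_time(self):
        base = HypnogramModel()
        boosted = HypnogramModel(n3_boost=1.3, boost_onset_epoch=0)
        diffs = []
        for seed in range(20):
            a = simulate_hypnogram(boosted, 960, seed=seed)
            b = simulate_hypnogram(base, 960, seed=seed)
            diffs.append((a.labels == 3).sum() - (b.labels == 3).sum())
        assert np.mean(diffs) > 0

    def test_boost_rows_renormalized(self):
        m = HypnogramModel(n3_boost=1.5)
        P = m.boosted_matrix()
        assert np.allclose(P.sum(axis=1), 1.0)
        assert np.all(P[:, 3] >= m.transition_matrix[:, 3])


class TestSynthesizeEpoch:
    def test_zero_amplitudes_give_zero_block(self):
        silent = StageSignalModel(
            components={s: [] for s in STAGES},
            noise_rms={s: 0.0 for s in STAGES},
            emg_rms={s: 0.0 for s in STAGES},
            eog_components={},
            ref_noise_rms=0.0,
            validate=False,
        )
        block = synthesize_epoch("N2", silent, 4, 64.0, seed=0)
        assert block.shape == (4, 1920)
        assert np.all(block == 0.0)

    def test_unknown_stage_rejected(self, signal_model):
        with pytest.raises(ValueError, match="unknown"):
            synthesize_epoch("N4", signal_model, 2, 64.0, seed=0)

    def test_n3_dominates_sw_band(self, signal_model):
        sw = WelchSpec()  # 0.5-1 Hz
        n3 = synthesize_epoch("N3", signal_model, 1, 64.0, seed=3)
        n2 = synthesize_epoch("N2", signal_model, 1, 64.0, seed=3)
        assert welch_band_power(n3[0], 64.0, sw) > welch_band_power(n2[0], 64.0, sw)

    def test_n2_dominates_spindle_band(self, signal_model):
        spindle = WelchSpec(band=(11.0, 16.0))
        n3 = synthesize_epoch("N3", signal_model, 1, 64.0, seed=3)
        n2 = synthesize_epoch("N2", signal_model, 1, 64.0, seed=3)
        assert welch_band_power(n2[0], 64.0, spindle) > welch_band_power(n3[0], 64.0, spindle)

    def test_spectral_separation_over_stages(self, signal_model):
        """Averaged over 20 epochs/stage, slow-wave power orders
        N3 > N2 > {W, REM}."""
        sw = WelchSpec()
        mean_power = {}
        for stage in ("N3", "N2", "W", "REM"):
            vals = [
                welch_band_power(
                    synthesize_epoch(stage, signal_model, 1, 64.0, [9, k])[0],
                    64.0, sw)
                for k in range(20)
            ]
            mean_power[stage] = np.mean(vals)
        assert mean_power["N3"] > mean_power["N2"]
        assert mean_power["N2"] > mean_power["W"]
        assert mean_power["N2"] > mean_power["REM"]

    def test_model_validation_enforces_n3_dominance(self):
        comps = {s: [] for s in STAGES}
        comps["N3"] = [OscComponent(0.5, 1.0, 60.0)]
        comps["N2"] = [OscComponent(0.5, 1.0, 80.0)]  # N2 louder than N3
        with pytest.raises(ValueError, match="largest slow-wave"):
            StageSignalModel(components={**StageSignalModel().components, **comps})

    def test_so_peak_amplitude_above_scoring_criterion(self):
        comps = dict(StageSignalModel().components)
        comps["N3"] = [OscComponent(0.5, 1.0, 40.0)]  # peak 57 uV: too small
        with pytest.raises(ValueError, match="75"):
            StageSignalModel(components=comps)


class TestSimulateRecording:
    def test_length_arithmetic(self, signal_model):
        from sleeptes.hypnogram import Hypnogram

        hyp = Hypnogram.from_stages(["W"] * 10)
        rec = simulate_recording(hyp, signal_model,
                                 montage=("A", "B", "C", "D", "E", "F"),
                                 rate=64.0, seed=0)
        assert rec.data.shape == (6, 19200)

    def test_determinism_bit_identical(self, signal_model, hyp_model):
        hyp = simulate_hypnogram(hyp_model, 12, seed=2)
        a = simulate_recording(hyp, signal_model, montage=STAGING_MONTAGE, seed=2)
        b = simulate_recording(hyp, signal_model, montage=STAGING_MONTAGE, seed=2)
        assert np.array_equal(a.data, b.data)

    def test_stim_blocks_dominate_amplitude(self, signal_model, hyp_model):
        hyp = simulate_hypnogram(hyp_model, 80, seed=3)
        sched = build_schedule(60.0, "stim")
        rec = simulate_recording(hyp, signal_model, montage=STAGING_MONTAGE,
                                 schedule=sched, seed=3)
        rate = rec.rate
        inside = rec.data[:, int(60 * rate):int(360 * rate)]
        outside = rec.data[:, : int(60 * rate)]
        assert np.abs(inside).max() >= 10 * np.abs(outside).max()

    def test_sham_schedule_leaves_signal_untouched(self, signal_model, hyp_model):
        hyp = simulate_hypnogram(hyp_model, 80, seed=3)
        sham = build_schedule(60.0, "sham")
        with_sched = simulate_recording(hyp, signal_model, montage=STAGING_MONTAGE,
                                        schedule=sham, seed=3)
        without = simulate_recording(hyp, signal_model, montage=STAGING_MONTAGE, seed=3)
        assert np.array_equal(with_sched.data, without.data)

    def test_schedule_past_end_rejected(self, signal_model, hyp_model):
        hyp = simulate_hypnogram(hyp_model, 30, seed=1)
        sched = build_schedule(600.0)
        with pytest.raises(ValueError, match="past"):
            simulate_recording(hyp, signal_model, montage=STAGING_MONTAGE,
                               schedule=sched, seed=1)


class TestInjectArtifact:
    def _quiet_record(self, seconds=2100, rate=64.0):
        from sleeptes.psg_io import PSGRecord

        rng = np.random.default_rng(0)
        data = rng.normal(0, 10, (2, int(seconds * rate)))
        return PSGRecord(data, rate, ["C3", "C4"])

    def test_empty_block_list_is_identity(self):
        from sleeptes.protocol import StimSchedule

        rec = self._quiet_record(100)
        sched = StimSchedule("stim", [], [])
        out = inject_tes_artifact(rec, sched)
        assert np.array_equal(out.data, rec.data)

    def test_exact_sample_count_altered(self):
        from sleeptes.protocol import StimSchedule

        rec = self._quiet_record(600)
        sched = StimSchedule("stim", [(60.0, 360.0)], [])
        out = inject_tes_artifact(rec, sched, artifact_uv=5000.0)
        changed = out.data != rec.data
        # a 0.5 Hz sine has zeros every 1 s; those samples are unchanged
        n_changed = changed.sum(axis=1)
        expected = 300 * 64
        assert np.all(n_changed >= expected - 301) and np.all(n_changed <= expected)
        assert np.all(~changed[:, : 60 * 64])

    def test_artifact_power_concentrated_at_half_hertz(self):
        from sleeptes.protocol import StimSchedule

        rec = self._quiet_record(900)
        sched = StimSchedule("stim", [(100.0, 400.0)], [])
        out = inject_tes_artifact(rec, sched)
        spec = WelchSpec()  # slow-wave band contains the 0.5 Hz artifact line
        inside = welch_band_power(out.data[0, 100 * 64:400 * 64], 64.0, spec)
        outside = welch_band_power(out.data[0, 400 * 64:700 * 64], 64.0, spec)
        assert inside > 100 * outside

    def test_requires_stim_condition(self):
        from sleeptes.protocol import StimSchedule

        rec = self._quiet_record(600)
        sched = StimSchedule("sham", [(60.0, 360.0)], [])
        with pytest.raises(ValueError, match="stim"):
            inject_tes_artifact(rec, sched)
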