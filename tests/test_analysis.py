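"""ECochG chain: cancellation, extraction, filtering, onset, SP/CAP
metrics, intensity series, adaptation, survival recovery."""

import numpy as np
import pytest

from ecochg import analysis as ana
from ecochg import synthesis as syn
from ecochg.waveform import Waveform


def _wave(samples, t0=80, si=25.0, **meta):
    return Waveform(np.asarray(samples, dtype=float), si, t0, meta)


class TestCancellation:
    def test_antisymmetric_cancellation_is_exact(self):
        rng = np.random.default_rng(0)
        s = rng.normal(size=512)
        m = rng.normal(size=512)
        cond = _wave(s + m)
        rar = _wave(s - m)
        out = ana.cancel_cm(cond, rar)
        assert np.max(np.abs(out.samples - s)) <= 1e-12

    def test_identical_inputs_pass_through(self):
        w = _wave(np.sin(np.linspace(0, 6, 256)))
        out = ana.cancel_cm(w, w)
        assert np.array_equal(out.samples, w.samples)

    def test_misaligned_inputs_rejected(self):
        a = _wave(np.zeros(100))
        b = Waveform(np.zeros(100), 25.0, 81)
        with pytest.raises(ValueError, match="t0_index"):
            ana.cancel_cm(a, b)

    def test_session_cancellation_removes_cm_band(self, click_pair):
        cond, rar = click_pair(120.0)
        out = ana.cancel_cm(cond, rar)
        assert ana.band_power(out, 1500, 3000) < \
            0.01 * ana.band_power(cond, 1500, 3000)


class TestCMExtraction:
    def test_recovers_generator_cm(self, click_pair, noiseless_cfg,
                                   normal_phenotype):
        cond, rar = click_pair(120.0)
        mean = ana.cancel_cm(cond, rar)
        cm = ana.extract_cm(cond, mean)
        comp = syn.component_waveforms(
            normal_phenotype, syn.StimulusSpec(120.0, "condensation"),
            noiseless_cfg)
        assert np.max(np.abs(cm.samples - comp["cm"])) <= 1e-12

    def test_equal_polarities_give_zero_cm(self):
        w = _wave(np.sin(np.linspace(0, 6, 256)))
        cm = ana.extract_cm(w, ana.cancel_cm(w, w))
        assert np.allclose(cm.samples, 0.0)

    def test_cm_amplitude_invariant_to_survival(self, noiseless_cfg,
                                                click_pair):
        amps = []
        for s in (1.0, 0.4):
            ph = syn.SubjectPhenotype.synaptopathy(s)
            cond, rar = click_pair(120.0, ph)
            cm = ana.extract_cm(cond, ana.cancel_cm(cond, rar))
            amps.append(np.ptp(cm.samples))
        assert amps[0] == pytest.approx(amps[1], abs=1e-9)


class TestResidualCMLowpass:
    def test_dc_passes_unchanged(self):
        w = _wave(np.full(1024, 3.0))
        out = ana.lowpass_residual_cm(w)
        assert np.allclose(out.samples, 3.0, rtol=0.01)

    def test_4khz_attenuated_12_3_db(self):
        # |H(f)| = 1/sqrt(1 + (f/fc)^4): one octave above a 2 kHz cutoff
        # means 1/sqrt(17) = -12.3 dB.
        fs = 40000.0
        n = 4000
        t = np.arange(n) / fs
        tone = np.sin(2 * np.pi * 4000.0 * t)
        out = ana.lowpass_residual_cm(Waveform(tone, 1e6 / fs, 0))
        mid = slice(n // 4, 3 * n // 4)
        att_db = 20 * np.log10(np.std(out.samples[mid]) / np.std(tone[mid]))
        assert att_db == pytest.approx(-12.3, abs=0.5)

    def test_zero_phase_preserves_trough_time(self):
        t = np.linspace(-5, 10, 600)
        pulse = -np.exp(-((t - 1.5) ** 2) / 0.5)
        w = Waveform(pulse, 25.0, 200)
        out = ana.lowpass_residual_cm(w)
        assert abs(np.argmin(out.samples) - np.argmin(pulse)) <= 1

    def test_cutoff_at_nyquist_rejected(self):
        w = _wave(np.zeros(256), si=250.0)   # fs = 4 kHz
        with pytest.raises(ValueError, match="Nyquist"):
            ana.lowpass_residual_cm(w, cutoff_hz=2000.0)

    def test_applied_only_when_cm_band_prominent(self):
        fs = 40000.0
        t = np.arange(2048) / fs
        clean = _wave(np.sin(2 * np.pi * 500.0 * t), si=25.0)
        contaminated = _wave(np.sin(2 * np.pi * 500.0 * t)
                             + 0.8 * np.sin(2 * np.pi * 2000.0 * t),
                             si=25.0)
        assert ana.lowpass_if_needed(clean) is clean
        assert ana.lowpass_if_needed(contaminated) is not contaminated


class TestCMOnset:
    def test_ramp_start_detected_within_one_sample(self, noiseless_cfg,
                                                   normal_phenotype):
        comp = syn.component_waveforms(
            normal_phenotype, syn.StimulusSpec(120.0, "condensation"),
            noiseless_cfg)
        shift = 12    # 0.3 ms at 25 us
        shifted = np.concatenate([np.zeros(shift), comp["cm"][:-shift]])
        onset = ana.detect_cm_onset(_wave(shifted, t0=comp["t0_index"]))
        assert onset == pytest.approx(0.3, abs=0.0251)   # one 25 us sample

    def test_flat_trace_reports_absent(self):
        assert ana.detect_cm_onset(_wave(np.zeros(800), t0=400)) is None

    def test_onset_robust_to_noise(self, noiseless_cfg, normal_phenotype):
        # CM amplitude 20 sigma: onset shift < 0.1 ms in >= 95/100 seeds.
        comp = syn.component_waveforms(
            normal_phenotype, syn.StimulusSpec(120.0, "condensation"),
            noiseless_cfg)
        cm0 = comp["cm"]
        sigma = np.max(np.abs(cm0)) / 20.0
        base = ana.detect_cm_onset(_wave(cm0, t0=comp["t0_index"]))
        rng = np.random.default_rng(42)
        hits = 0
        for _ in range(100):
            noisy = _wave(cm0 + rng.normal(0, sigma, len(cm0)),
                          t0=comp["t0_index"])
            hits += abs(ana.detect_cm_onset(noisy) - base) < 0.1
        assert hits >= 95


class TestPotentialMetrics:
    def test_noiseless_metrics_match_generator_truth(self, click_pair,
                                                     noiseless_cfg,
                                                     normal_phenotype):
        cond, rar = click_pair(120.0)
        mean = ana.cancel_cm(cond, rar)
        onset = ana.detect_cm_onset(ana.extract_cm(cond, mean))
        m = ana.measure_potentials(mean, onset)
        comp = syn.component_waveforms(
            normal_phenotype, syn.StimulusSpec(120.0, "condensation"),
            noiseless_cfg)
        truth = comp["sp"] + comp["cap"]
        t = comp["t_ms"]
        # CAP: global negative extremum of the noiseless SP+CAP sum
        i_trough = np.argmin(truth)
        assert m.cap_latency_ms == pytest.approx(t[i_trough] - onset,
                                                 abs=0.025)
        assert m.cap_amplitude_uv == pytest.approx(-truth[i_trough],
                                                   abs=1e-6)
        # SP: the leading local minimum of the sum inside the deflection
        start = np.flatnonzero(truth < 0.02 * truth[i_trough])[0]
        seg = truth[start:i_trough]
        i_sp = start + 1 + np.flatnonzero(
            (seg[1:-1] <= seg[:-2]) & (seg[1:-1] <= seg[2:]))[0]
        assert m.sp_latency_ms == pytest.approx(t[i_sp] - onset, abs=0.025)
        assert m.sp_amplitude_uv == pytest.approx(-truth[i_sp], abs=1e-6)

    def test_all_zero_trace_flags_absent(self):
        m = ana.measure_potentials(_wave(np.zeros(800), t0=200), 0.0)
        assert m.sp_absent and m.cap_absent

    def test_constant_offset_leaves_metrics_unchanged(self, click_pair):
        cond, rar = click_pair(120.0)
        mean = ana.cancel_cm(cond, rar)
        onset = ana.detect_cm_onset(ana.extract_cm(cond, mean))
        m0 = ana.measure_potentials(mean, onset)
        m1 = ana.measure_potentials(mean.copy_with(mean.samples + 17.3),
                                    onset)
        assert m1.sp_latency_ms == m0.sp_latency_ms
        assert m1.cap_latency_ms == m0.cap_latency_ms
        assert m1.cap_amplitude_uv == pytest.approx(m0.cap_amplitude_uv,
                                                    abs=1e-9)
        assert m1.duration_ms == m0.duration_ms

    def test_duration_covers_sp_to_cap_span(self, measured_metrics):
        m, _ = measured_metrics(120.0)
        assert m.duration_ms >= m.cap_latency_ms - m.sp_latency_ms


class TestIntensitySeries:
    def test_noiseless_normal_latency_monotone(self, normal_phenotype):
        cfg = syn.GeneratorConfig(noise_sd_uv=0.0, trials_per_polarity=1)
        sess = syn.synthesize_session(normal_phenotype, cfg,
                                      train_levels=())
        metrics, thr = ana.intensity_series(sess)
        levels = [m.level_pe_spl for m in metrics]
        assert levels == sorted(levels, reverse=True)
        lats = [m.cap_latency_ms for m in metrics]
        assert np.all(np.diff(lats) >= 0)     # 120 dB first -> increasing
        assert thr == 60.0

    def test_synaptopathy_attenuates_and_raises_threshold(self):
        # amplitudes lower at every level; CAP threshold higher on average
        thr_normal, thr_syn = [], []
        for seed in range(5):
            amps = {}
            for s in (1.0, 0.4):
                ph = syn.SubjectPhenotype.synaptopathy(s) if s < 1.0 \
                    else syn.SubjectPhenotype.normal()
                sess = syn.synthesize_session(
                    ph, syn.GeneratorConfig(rng_seed=seed),
                    train_levels=())
                metrics, thr = ana.intensity_series(sess)
                amps[s] = {m.level_pe_spl: m.cap_amplitude_uv
                           for m in metrics if not m.cap_absent}
                (thr_normal if s == 1.0 else thr_syn).append(thr)
            for level in amps[0.4]:
                if level in amps[1.0]:
                    assert amps[0.4][level] < amps[1.0][level]
        assert np.mean(thr_syn) > np.mean(thr_normal)

    def test_single_level_session(self, normal_phenotype):
        cfg = syn.GeneratorConfig(noise_sd_uv=0.0, trials_per_polarity=1)
        sess = syn.synthesize_session(normal_phenotype, cfg,
                                      levels=(100,), train_levels=())
        metrics, thr = ana.intensity_series(sess)
        assert len(metrics) == 1
        assert thr == 100.0


class TestAdaptation:
    def _profile(self, rho, level=120.0):
        ph = syn.SubjectPhenotype(adaptation_floor=rho)
        cfg = syn.GeneratorConfig(noise_sd_uv=0.0, trials_per_polarity=1)
        spec = lambda pol: syn.StimulusSpec(level, pol,
                                            train=syn.TrainSpec())
        tc = syn.synthesize_train_recording(ph, spec("condensation"), cfg)
        tr = syn.synthesize_train_recording(ph, spec("rarefaction"), cfg)
        return ana.analyze_train(tc, tr), \
            syn.adaptation_amplitudes(ph, cfg)

    def test_no_adaptation_profile_flat(self):
        prof, _ = self._profile(1.0)
        assert np.allclose(prof.normalized, 1.0, atol=0.03)

    def test_profile_recovers_generator_rule(self):
        prof, rule = self._profile(0.6)
        assert np.max(np.abs(prof.normalized - rule) / rule) < 0.05

    def test_position_one_exactly_unity(self):
        prof, _ = self._profile(0.6)
        assert prof.normalized[0] == 1.0

    def test_absent_cap_at_position_one_is_error(self):
        flat = [_wave(np.zeros(116), t0=0) for _ in range(11)]
        with pytest.raises(ValueError, match="position 1"):
            ana.adaptation_profile(flat)

    def test_synaptopathy_adaptation_matches_normal(self):
        # the attenuation pattern is survival-independent: loss of synapses
        # scales the CAP but leaves the train dynamics intact
        prof_n, _ = self._profile(0.5)
        ph = syn.SubjectPhenotype.synaptopathy(0.5, adaptation_floor=0.5)
        cfg = syn.GeneratorConfig(noise_sd_uv=0.0, trials_per_polarity=1)
        tc = syn.synthesize_train_recording(
            ph, syn.StimulusSpec(120.0, "condensation",
                                 train=syn.TrainSpec()), cfg)
        tr = syn.synthesize_train_recording(
            ph, syn.StimulusSpec(120.0, "rarefaction",
                                 train=syn.TrainSpec()), cfg)
        prof_s = ana.analyze_train(tc, tr)
        assert np.allclose(prof_s.normalized, prof_n.normalized, atol=0.05)


class TestSurvivalRecovery:
    def test_noiseless_inversion_is_sharp(self):
        for s in (0.4, 0.7, 1.0):
            amp = syn.cap_amplitude_uv(120.0, s, 1.0 - s)
            assert syn.estimate_synaptic_survival(amp, 120.0) == \
                pytest.approx(s, abs=0.01)

    def test_zero_amplitude_maps_to_zero(self):
        assert syn.estimate_synaptic_survival(0.0, 120.0) == 0.0
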