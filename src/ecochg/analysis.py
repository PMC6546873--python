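"""Electrocochleography processing chain.

Implements the standard promontory-recording analysis for click-evoked
cochlear potentials:

1. **CM cancellation** -- averaging the responses to condensation and
   rarefaction clicks cancels the polarity-following cochlear microphonic
   and leaves the compound action potential with the superimposed summating
   potential.
2. **CM extraction** -- subtracting that mean from the condensation average
   recovers the CM itself.
3. **Residual-CM low-pass** -- a zero-phase 2 kHz low-pass with a
   12 dB/octave (second-order Butterworth) magnitude response attenuates
   incompletely cancelled CM at high stimulus levels.
4. **SP/CAP metrics** -- latencies are referenced to CM onset; amplitudes to
   the mean of the 1 ms baseline preceding CM onset.  The SP is taken at the
   initial negative deflection arising from baseline, the CAP at the maximum
   negative potential, and the response duration runs from the initial
   negative deflection to the return to baseline.
5. **Intensity series and adaptation profiles** across the 120-60 dB click
   series and the high-rate click-train paradigm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import synthesis
from .waveform import TrialSet, Waveform, average_trials, check_aligned


@dataclass
class ECochGMetrics:
    """SP/CAP/CM measurements for one averaged response at one level.

    Latencies are in ms relative to CM onset; amplitudes are positive
    magnitudes (in uV) of negative deflections measured against the 1 ms
    pre-CM baseline.
    """

    level_pe_spl: float | None = None
    cm_amplitude_uv: float | None = None     # peak-to-peak of extracted CM
    sp_latency_ms: float | None = None
    sp_amplitude_uv: float | None = None
    cap_latency_ms: float | None = None
    cap_amplitude_uv: float | None = None
    duration_ms: float | None = None
    sp_absent: bool = False
    cap_absent: bool = False
    flags: list = field(default_factory=list)


@dataclass
class AdaptationProfile:
    """Normalized CAP amplitude per click position in the train paradigm.

    ``normalized[0]`` (position 1, the initial click) is exactly 1.
    """

    positions: np.ndarray
    normalized: np.ndarray
    raw_uv: np.ndarray
    level_pe_spl: float | None = None


# ---------------------------------------------------------------------------
# Linear-algebraic steps

def cancel_cm(cond_avg: Waveform, rar_avg: Waveform) -> Waveform:
    """Point-wise mean of the condensation and rarefaction averages.

    The CM inverts with click polarity and cancels; the polarity-invariant
    SP and CAP survive.
    """
    check_aligned(cond_avg, rar_avg)
    return cond_avg.copy_with(0.5 * (cond_avg.samples + rar_avg.samples),
                              derivation="cm_cancelled")


def extract_cm(cond_avg: Waveform, mean_waveform: Waveform) -> Waveform:
    """Subtract the polarity mean from the condensation average -> CM."""
    check_aligned(cond_avg, mean_waveform)
    return cond_avg.copy_with(cond_avg.samples - mean_waveform.samples,
                              derivation="cm")


def band_power(w: Waveform, f_lo_hz: float, f_hi_hz: float) -> float:
    """Total spectral power (uV^2) in a frequency band, via the rFFT."""
    n = len(w.samples)
    spec = np.fft.rfft(w.samples)
    freqs = np.fft.rfftfreq(n, d=w.sampling_interval_us * 1e-6)
    mask = (freqs >= f_lo_hz) & (freqs <= f_hi_hz)
    power = np.abs(spec) ** 2 / n
    return float(power[mask].sum())


def lowpass_residual_cm(w: Waveform, cutoff_hz: float = 2000.0) -> Waveform:
    """Zero-phase low-pass with a second-order Butterworth magnitude.

    The filter is applied in the frequency domain as the real magnitude
    response ``|H(f)| = 1 / sqrt(1 + (f/fc)^4)`` (12 dB/octave asymptote),
    which is zero-phase by construction and therefore does not bias the
    SP/CAP latencies.
    """
    fs = 1e6 / w.sampling_interval_us
    if cutoff_hz >= fs / 2.0:
        raise ValueError(f"cutoff {cutoff_hz} Hz is at or above the "
                         f"Nyquist frequency {fs / 2:.0f} Hz")
    n = len(w.samples)
    spec = np.fft.rfft(w.samples)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    gain = 1.0 / np.sqrt(1.0 + (freqs / cutoff_hz) ** 4)
    return w.copy_with(np.fft.irfft(spec * gain, n),
                       lowpass_cutoff_hz=cutoff_hz)


def lowpass_if_needed(w: Waveform, cutoff_hz: float = 2000.0,
                      band=(1500.0, 3000.0),
                      band_fraction_threshold: float = 0.05) -> Waveform:
    """Apply the residual-CM low-pass only where needed.

    The filter runs only when the power in the CM band (1.5-3 kHz by
    default) exceeds ``band_fraction_threshold`` of the total power, i.e.
    when cancellation left an appreciable CM residue.
    """
    total = band_power(w, 0.0, 1e6 / w.sampling_interval_us / 2.0)
    if total <= 0:
        return w
    if band_power(w, *band) / total > band_fraction_threshold:
        return lowpass_residual_cm(w, cutoff_hz)
    return w


# ---------------------------------------------------------------------------
# CM onset

def detect_cm_onset(cm: Waveform, sd_multiple: float = 3.0,
                    min_consecutive: int = 3,
                    floor_fraction: float = 0.005) -> float | None:
    """Earliest time (ms) at which the CM rises sustainedly out of the noise.

    The criterion is ``|cm| > sd_multiple * SD(pre-stimulus baseline)`` for
    at least ``min_consecutive`` consecutive samples; a small floor
    (``floor_fraction`` of the absolute peak) keeps the rule meaningful on
    noiseless traces.  The onset is then traced back from the crossing to
    the last sample still inside one baseline SD, so the reported time marks
    where the rise began rather than where it cleared the detection band.
    Returns ``None`` when no crossing exists (CM absent).
    """
    if cm.t0_index * cm.sampling_interval_us < 1000.0:
        raise ValueError("detect_cm_onset needs >= 1 ms of pre-stimulus "
                         "baseline")
    v = cm.samples
    baseline_sd = float(np.std(v[:cm.t0_index]))
    peak = float(np.max(np.abs(v)))
    if peak == 0.0:
        return None
    thresh = max(sd_multiple * baseline_sd, floor_fraction * peak)
    above = np.abs(v) > thresh
    above[:cm.t0_index] = False
    run, i_cross = 0, None
    for i in range(cm.t0_index, len(v)):
        run = run + 1 if above[i] else 0
        if run >= min_consecutive:
            i_cross = i - min_consecutive + 1
            break
    if i_cross is None:
        return None
    back_level = max(baseline_sd, floor_fraction * peak / 2.0)
    i_on = i_cross
    while i_on > 0 and abs(v[i_on - 1]) > back_level:
        i_on -= 1
    return cm.index_to_time(i_on)


# ---------------------------------------------------------------------------
# SP / CAP measurement

def _sustained_run(mask: np.ndarray, start: int, n_sustain: int) -> int | None:
    """First index >= start opening a run of n_sustain True samples."""
    run = 0
    for i in range(start, len(mask)):
        run = run + 1 if mask[i] else 0
        if run >= n_sustain:
            return i - n_sustain + 1
    return None


def measure_potentials(sp_cap: Waveform, cm_onset_ms: float,
                       sd_multiple: float = 2.0,
                       sustain_ms: float = 0.2,
                       floor_fraction: float = 0.02) -> ECochGMetrics:
    """SP/CAP latency, amplitude and duration of a CM-cancelled waveform.

    * baseline = mean over the 1 ms preceding CM onset; its SD (with a
      noiseless floor of ``floor_fraction`` of the peak deflection) sets the
      detection band ``baseline +/- thresh``.
    * SP onset = first departure below ``baseline - thresh`` sustained for
      ``sustain_ms``; the SP point itself is the first local minimum after
      that onset or, failing one, the flattest point (smallest |dV/dt|)
      before the CAP trough -- the conventional SP "shoulder".
    * CAP = global negative extremum after SP onset (ties to earlier).
    * duration = SP onset to the first sustained return inside the baseline
      band after the CAP trough.

    All latencies are relative to ``cm_onset_ms``.  Traces without a
    sustained negative deflection come back flagged absent.
    """
    v = sp_cap.samples
    si_ms = sp_cap.sampling_interval_us / 1000.0
    i_on = sp_cap.time_to_index(cm_onset_ms)
    i_bl0 = sp_cap.time_to_index(cm_onset_ms - 1.0)
    if i_bl0 < 0 or i_on <= i_bl0:
        raise ValueError("baseline window (1 ms before CM onset) falls "
                         "outside the record")
    baseline = float(np.mean(v[i_bl0:i_on]))
    bl_sd = float(np.std(v[i_bl0:i_on]))
    peak_dev = float(np.max(np.abs(v[i_on:] - baseline))) if i_on < len(v) \
        else 0.0
    thresh = max(sd_multiple * bl_sd, floor_fraction * peak_dev)
    n_sus = max(1, int(round(sustain_ms / si_ms)))

    metrics = ECochGMetrics(level_pe_spl=sp_cap.meta.get("level_pe_spl"))
    if peak_dev == 0.0 or thresh == 0.0:
        metrics.sp_absent = metrics.cap_absent = True
        metrics.flags.append("no_response")
        return metrics

    below = v < baseline - thresh
    i_sp_onset = _sustained_run(below, i_on, n_sus)
    if i_sp_onset is None:
        metrics.sp_absent = metrics.cap_absent = True
        metrics.flags.append("no_negative_deflection")
        return metrics

    i_cap = i_sp_onset + int(np.argmin(v[i_sp_onset:]))
    metrics.cap_latency_ms = sp_cap.index_to_time(i_cap) - cm_onset_ms
    metrics.cap_amplitude_uv = baseline - float(v[i_cap])

    # SP point: first local minimum between deflection onset and CAP trough,
    # else the leading shoulder -- a local slope maximum (descent pause)
    # followed by renewed descent into the CAP.
    i_sp = i_sp_onset
    if i_cap - i_sp_onset >= 3:
        seg = v[i_sp_onset:i_cap + 1]
        local_min = np.flatnonzero((seg[1:-1] <= seg[:-2])
                                   & (seg[1:-1] <= seg[2:]))
        if len(local_min):
            i_sp = i_sp_onset + 1 + int(local_min[0])
        else:
            dv = np.gradient(seg)
            inner = dv[1:-1]
            shoulders = np.flatnonzero((inner[1:-1] >= inner[:-2])
                                       & (inner[1:-1] >= inner[2:]))
            for s in shoulders:
                k = s + 2          # index into dv
                if np.min(dv[k:]) < dv[k]:   # descent resumes afterwards
                    i_sp = i_sp_onset + k
                    break
    metrics.sp_latency_ms = sp_cap.index_to_time(i_sp) - cm_onset_ms
    metrics.sp_amplitude_uv = baseline - float(v[i_sp])

    inside = np.abs(v - baseline) < thresh
    i_ret = _sustained_run(inside, i_cap, n_sus)
    if i_ret is None:
        metrics.duration_ms = sp_cap.index_to_time(len(v) - 1) \
            - sp_cap.index_to_time(i_sp_onset)
        metrics.flags.append("no_return_to_baseline")
    else:
        metrics.duration_ms = sp_cap.index_to_time(i_ret) \
            - sp_cap.index_to_time(i_sp_onset)
    return metrics


# ---------------------------------------------------------------------------
# Session-level analyses

def analyze_level(cond: TrialSet, rar: TrialSet,
                  apply_lowpass: str = "auto") -> ECochGMetrics:
    """Full chain for one intensity: average, cancel, extract, measure.

    ``apply_lowpass`` is ``"auto"`` (only when the residual CM band power
    warrants it), ``"always"`` or ``"never"``.
    """
    cond_avg = average_trials(cond)
    rar_avg = average_trials(rar)
    mean = cancel_cm(cond_avg, rar_avg)
    cm = extract_cm(cond_avg, mean)
    onset = detect_cm_onset(cm)
    if apply_lowpass == "always":
        mean = lowpass_residual_cm(mean)
    elif apply_lowpass == "auto":
        mean = lowpass_if_needed(mean)
    if onset is None:
        m = ECochGMetrics(level_pe_spl=cond.level_pe_spl)
        m.sp_absent = m.cap_absent = True
        m.flags.append("cm_absent")
        return m
    metrics = measure_potentials(mean, onset)
    metrics.level_pe_spl = cond.level_pe_spl
    metrics.cm_amplitude_uv = float(np.ptp(cm.samples))
    return metrics


def intensity_series(session, apply_lowpass: str = "auto"):
    """Metrics per level of a session plus the CAP threshold.

    Returns ``(metrics_list, threshold)`` where the threshold is the lowest
    level with a detected CAP (``None`` when no level has one).  Missing
    responses are flagged, never interpolated.
    """
    metrics = []
    for level in sorted(session.singles, reverse=True):
        pols = session.singles[level]
        metrics.append(analyze_level(pols["condensation"],
                                     pols["rarefaction"], apply_lowpass))
    detected = [m.level_pe_spl for m in metrics if not m.cap_absent]
    threshold = min(detected) if detected else None
    return metrics, threshold


def adaptation_profile(train_epochs, local_ref_ms: float = 0.2,
                       level_pe_spl: float | None = None
                       ) -> AdaptationProfile:
    """Normalized CAP amplitude versus click position in the train.

    ``train_epochs`` are the 11 per-click epochs cut from the averaged,
    CM-cancelled train response (averaging across sequence repetitions
    happens before normalization).  Within each ISI-bounded window the CAP
    amplitude is the trough magnitude relative to a local reference taken
    over the last ``local_ref_ms`` of the window -- the level just before
    the next click, where every response sits at the same phase of its own
    recovery, so the overlap carried over from the preceding click cancels
    in the ratio.  Amplitudes are normalized to the initial click
    (position 1); an undetectable CAP at position 1 is an error.
    """
    raw = []
    for ep in train_epochs:
        n_ref = max(1, int(round(local_ref_ms * 1000.0
                                 / ep.sampling_interval_us)))
        v = ep.samples[ep.t0_index:]
        ref = float(np.mean(v[-n_ref:]))
        raw.append(ref - float(np.min(v)))
    raw = np.asarray(raw)
    if raw[0] <= 0:
        raise ValueError("CAP absent at train position 1; adaptation "
                         "profile undefined")
    return AdaptationProfile(np.arange(1, len(raw) + 1), raw / raw[0], raw,
                             level_pe_spl)


def analyze_train(cond: TrialSet, rar: TrialSet, window=(0.0, 2.9),
                  template_span_ms: float = 12.0) -> AdaptationProfile:
    """Adaptation profile from a pair of train trial sets.

    Averages each polarity, cancels the CM, then measures the CAP trough at
    each of the 11 click positions.  Because the 2.9 ms inter-click interval
    is shorter than the response duration, consecutive responses overlap;
    the initial click, however, is followed by a silent lead gap and its
    response is uncontaminated.  That isolated response serves as a per-ear
    template: walking through the train, each already-measured click's
    scaled template is subtracted from the record before the next position
    is measured, so every amplitude is read from an overlap-free residual.
    Amplitudes are normalized to the initial click.
    """
    cond_avg = average_trials(cond)
    rar_avg = average_trials(rar)
    mean = cancel_cm(cond_avg, rar_avg)
    onsets = cond.meta.get("onsets_ms")
    if onsets is None:
        onsets = synthesis.make_click_sequence(
            synthesis.StimulusSpec(train=synthesis.TrainSpec()))

    si_ms = mean.sampling_interval_us / 1000.0
    baseline = float(np.mean(mean.samples[:mean.t0_index])) \
        if mean.t0_index > 0 else 0.0
    residual = mean.samples - baseline

    # isolated lead-click response -> template (clipped to the lead gap)
    if len(onsets) > 1:
        span = min(template_span_ms, onsets[1] - onsets[0])
    else:
        span = template_span_ms
    i0 = mean.time_to_index(onsets[0])
    n_tpl = int(round(span / si_ms))
    template = residual[i0:i0 + n_tpl].copy()

    # the CAP peak lag comes from the isolated template; per-position
    # troughs are read in a narrow band around it so the non-adapting SP
    # cannot masquerade as the CAP when the train amplitudes shrink
    n_lo = int(round(window[0] / si_ms))
    n_hi = int(round(window[1] / si_ms))
    i_lag = int(np.argmin(template[n_lo:n_hi])) + n_lo
    half_band = max(1, int(round(0.3 / si_ms)))
    lo = max(n_lo, i_lag - half_band)
    hi = min(n_hi, i_lag + half_band + 1)
    raw = []
    for onset in onsets:
        i_on = mean.time_to_index(onset)
        amp = -float(residual[i_on + lo:i_on + hi].min())
        raw.append(amp)
        if raw[0] <= 0:
            raise ValueError("CAP absent at train position 1; adaptation "
                             "profile undefined")
        scale = amp / raw[0]
        stop = min(i_on + n_tpl, len(residual))
        residual[i_on:stop] -= scale * template[:stop - i_on]
    raw = np.asarray(raw)
    return AdaptationProfile(np.arange(1, len(raw) + 1), raw / raw[0], raw,
                             cond.level_pe_spl)


def metrics_to_frame(metrics, ear: str | None = None):
    """Tidy table of an intensity series (one row per level)."""
    import pandas as pd

    rows = []
    for m in metrics:
        rows.append({
            "ear": ear, "level_pe_spl": m.level_pe_spl,
            "cm_amplitude_uv": m.cm_amplitude_uv,
            "sp_latency_ms": m.sp_latency_ms,
            "sp_amplitude_uv": m.sp_amplitude_uv,
            "cap_latency_ms": m.cap_latency_ms,
            "cap_amplitude_uv": m.cap_amplitude_uv,
            "duration_ms": m.duration_ms,
            "flags": ";".join(
                (["sp_absent"] if m.sp_absent else [])
                + (["cap_absent"] if m.cap_absent else []) + m.flags),
        })
    return pd.DataFrame(rows)
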