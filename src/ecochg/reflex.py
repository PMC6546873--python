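"""Middle-ear acoustic reflex metrics.

The immittance trace evoked by a 300 ms tone is averaged over five stimuli;
the response onset is the first sustained deviation from the pre-stimulus
baseline, and the peak latency is the time of the maximum negative
deflection relative to that onset.  A reflex is absent when no response is
found at intensities up to 110 dB HL.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .waveform import TrialSet, Waveform, average_trials

REFLEX_ABSENT_LIMIT_DB_HL = 110.0


@dataclass
class ReflexMetrics:
    freq_hz: float | None = None
    onset_ms: float | None = None
    peak_latency_ms: float | None = None   # relative to response onset
    peak_amplitude: float | None = None    # magnitude, arbitrary units
    n_averaged: int = 0
    absent: bool = False
    flags: list = field(default_factory=list)


def average_reflex(traces) -> Waveform:
    """Point-wise mean of reflex traces (five per waveform by convention).

    A count other than five raises a warning but the average proceeds with
    whatever was given.
    """
    traces = list(traces)
    if len(traces) != 5:
        warnings.warn(f"expected 5 reflex traces per waveform, got "
                      f"{len(traces)}; averaging anyway", stacklevel=2)
    ts = TrialSet(np.vstack([t.samples for t in traces]),
                  traces[0].sampling_interval_us, traces[0].t0_index,
                  meta=dict(traces[0].meta))
    for t in traces[1:]:
        if len(t) != ts.n_samples or t.t0_index != ts.t0_index:
            raise ValueError("reflex traces are not aligned")
    return average_trials(ts)


def measure_reflex(avg: Waveform, sd_multiple: float = 2.0,
                   sustain_ms: float = 5.0,
                   floor_fraction: float = 0.01) -> ReflexMetrics:
    """Onset and peak latency of an averaged immittance trace.

    * baseline mean and SD come from the pre-stimulus stretch (>= 50 ms
      required);
    * onset = first deviation beyond ``baseline +/- sd_multiple * SD``
      sustained for ``sustain_ms`` (a floor of ``floor_fraction`` of the
      peak deviation keeps the rule defined on noiseless traces);
    * peak latency = time of the maximum negative deflection minus onset.

    A trace with no sustained deviation is reported absent.
    """
    si_ms = avg.sampling_interval_us / 1000.0
    if avg.t0_index * si_ms < 50.0:
        raise ValueError("measure_reflex needs >= 50 ms of pre-stimulus "
                         "baseline")
    v = avg.samples
    baseline = float(np.mean(v[:avg.t0_index]))
    sd = float(np.std(v[:avg.t0_index]))
    peak_dev = float(np.max(np.abs(v[avg.t0_index:] - baseline)))
    metrics = ReflexMetrics(freq_hz=avg.meta.get("tone_freq_hz"),
                            n_averaged=avg.meta.get("n_averaged", 1))
    if peak_dev == 0.0:
        metrics.absent = True
        metrics.flags.append("flat_trace")
        return metrics
    thresh = max(sd_multiple * sd, floor_fraction * peak_dev)
    outside = np.abs(v - baseline) > thresh
    outside[:avg.t0_index] = False
    n_sus = max(1, int(round(sustain_ms / si_ms)))
    run, i_onset = 0, None
    for i in range(avg.t0_index, len(v)):
        run = run + 1 if outside[i] else 0
        if run >= n_sus:
            i_onset = i - n_sus + 1
            break
    if i_onset is None:
        metrics.absent = True
        metrics.flags.append("no_deviation")
        return metrics
    i_peak = i_onset + int(np.argmin(v[i_onset:]))
    metrics.onset_ms = avg.index_to_time(i_onset)
    metrics.peak_latency_ms = avg.index_to_time(i_peak) - metrics.onset_ms
    metrics.peak_amplitude = baseline - float(v[i_peak])
    return metrics


def reflex_threshold(levels_db_hl, responses,
                     absent_limit_db_hl: float = REFLEX_ABSENT_LIMIT_DB_HL
                     ) -> float | None:
    """Lowest level (dB HL) with a detected reflex.

    ``responses`` holds one truthy/falsy detection flag per tested level
    (levels sorted ascending).  Returns ``None`` -- reflex absent -- when no
    response was found at any level up to the absence limit (110 dB HL).
    """
    levels = list(levels_db_hl)
    if sorted(levels) != levels:
        raise ValueError("levels must be sorted ascending")
    for level, detected in zip(levels, responses):
        if detected:
            return float(level)
    return None
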