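"""Waveform containers, interchange I/O, trial averaging and epoching.

Evoked-potential recordings are represented as uniformly sampled voltage
traces (microvolts) with an explicit stimulus-onset sample.  Collections of
repeated trials share one time axis and are stored as a 2-D array.

The on-disk interchange format is plain text: a tab-separated table whose
first column is ``time_ms`` and whose remaining columns hold one trial each,
accompanied by a JSON sidecar (``<path>.json``) that records the sampling
interval, stimulus alignment and free-form acquisition metadata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


class FormatError(ValueError):
    """Raised when an interchange file and its sidecar disagree."""


@dataclass
class Waveform:
    """A uniformly sampled voltage trace with a stimulus-time reference.

    Parameters
    ----------
    samples:
        Voltages in microvolts.
    sampling_interval_us:
        Sampling interval in microseconds (25 us for the click-evoked
        cochlear recordings this package targets).
    t0_index:
        Index of the stimulus (click or tone) onset sample.  Sample ``i``
        occurs at ``(i - t0_index) * sampling_interval_us / 1000`` ms.
    meta:
        Free-form metadata mapping.
    """

    samples: np.ndarray
    sampling_interval_us: float
    t0_index: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if self.sampling_interval_us <= 0:
            raise ValueError("sampling_interval_us must be positive")
        if not (0 <= self.t0_index < len(self.samples)):
            raise ValueError("t0_index must lie within the record")

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def times_ms(self) -> np.ndarray:
        """Time axis in ms, zero at the stimulus onset sample."""
        idx = np.arange(len(self.samples)) - self.t0_index
        return idx * (self.sampling_interval_us / 1000.0)

    def time_to_index(self, t_ms: float) -> int:
        """Map a time in ms to the nearest sample index (ties to earlier)."""
        x = self.t0_index + t_ms * 1000.0 / self.sampling_interval_us
        return int(np.ceil(x - 0.5))

    def index_to_time(self, i: int) -> float:
        return (i - self.t0_index) * self.sampling_interval_us / 1000.0

    def copy_with(self, samples: np.ndarray, **meta) -> "Waveform":
        merged = dict(self.meta)
        merged.update(meta)
        return Waveform(np.asarray(samples, dtype=float),
                        self.sampling_interval_us, self.t0_index, merged)


@dataclass
class TrialSet:
    """Repeated trials sharing one time axis.

    ``data`` has shape ``(n_trials, n_samples)``; all trials share
    ``sampling_interval_us`` and ``t0_index``.
    """

    data: np.ndarray
    sampling_interval_us: float
    t0_index: int = 0
    polarity: str | None = None
    level_pe_spl: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (n_trials, n_samples)")
        if self.data.shape[0] < 1:
            raise ValueError("a TrialSet needs at least one trial")
        if self.sampling_interval_us <= 0:
            raise ValueError("sampling_interval_us must be positive")
        if not (0 <= self.t0_index < self.data.shape[1]):
            raise ValueError("t0_index must lie within the record")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def times_ms(self) -> np.ndarray:
        idx = np.arange(self.n_samples) - self.t0_index
        return idx * (self.sampling_interval_us / 1000.0)

    def trial(self, i: int) -> Waveform:
        return Waveform(self.data[i], self.sampling_interval_us,
                        self.t0_index, dict(self.meta))


def check_aligned(a, b) -> None:
    """Raise if two waveforms/trial sets do not share a time axis."""
    na = len(a.samples) if isinstance(a, Waveform) else a.n_samples
    nb = len(b.samples) if isinstance(b, Waveform) else b.n_samples
    if na != nb:
        raise ValueError(f"length mismatch: {na} vs {nb} samples")
    if not np.isclose(a.sampling_interval_us, b.sampling_interval_us):
        raise ValueError("sampling_interval_us mismatch")
    if a.t0_index != b.t0_index:
        raise ValueError("t0_index mismatch")


def average_trials(ts: TrialSet) -> Waveform:
    """Point-wise arithmetic mean across trials.

    The number of averaged trials is recorded in ``meta['n_averaged']``.
    """
    if ts.n_trials < 1:
        raise ValueError("cannot average an empty trial set")
    meta = dict(ts.meta)
    meta.update(n_averaged=ts.n_trials, polarity=ts.polarity,
                level_pe_spl=ts.level_pe_spl)
    return Waveform(ts.data.mean(axis=0), ts.sampling_interval_us,
                    ts.t0_index, meta)


def write_trialset(ts: TrialSet, path: str | Path) -> None:
    """Write a trial set as a TSV table plus a JSON sidecar.

    Column 1 is ``time_ms``; remaining columns are one per trial.  The
    sidecar ``<path>.json`` holds sampling interval, alignment, trial count
    and any metadata (polarity, level, paradigm, seed, phenotype ...).
    Values are printed with 12 significant digits so a round trip preserves
    microvolt values to well below 1e-9.
    """
    path = Path(path)
    header = "time_ms\t" + "\t".join(
        f"trial_{i + 1:04d}" for i in range(ts.n_trials))
    table = np.column_stack([ts.times_ms, ts.data.T])
    np.savetxt(path, table, fmt="%.12g", delimiter="\t",
               header=header, comments="")
    sidecar = {
        "sampling_interval_us": ts.sampling_interval_us,
        "t0_index": int(ts.t0_index),
        "n_trials": int(ts.n_trials),
        "polarity": ts.polarity,
        "level_pe_spl": ts.level_pe_spl,
        "meta": _jsonable(ts.meta),
    }
    Path(f"{path}.json").write_text(json.dumps(sidecar, indent=1))


def read_trialset(path: str | Path) -> TrialSet:
    """Read a trial set written by :func:`write_trialset`.

    Raises :class:`FormatError` naming the offending field when the sidecar
    and the table disagree (trial count, sampling interval).
    """
    path = Path(path)
    sidecar_path = Path(f"{path}.json")
    if not sidecar_path.exists():
        raise FormatError(f"missing sidecar {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    table = np.loadtxt(path, delimiter="\t", skiprows=1, ndmin=2)
    n_cols = table.shape[1] - 1
    if n_cols != sidecar["n_trials"]:
        raise FormatError(
            f"field 'n_trials': sidecar says {sidecar['n_trials']} trials "
            f"but file has {n_cols} trial columns")
    times = table[:, 0]
    si_ms = sidecar["sampling_interval_us"] / 1000.0
    t0 = sidecar["t0_index"]
    expected = (np.arange(len(times)) - t0) * si_ms
    if np.max(np.abs(times - expected)) > 1e-6:
        raise FormatError(
            "field 'sampling_interval_us': time column inconsistent with "
            "sidecar sampling interval / t0_index")
    return TrialSet(table[:, 1:].T, sidecar["sampling_interval_us"],
                    t0, sidecar.get("polarity"),
                    sidecar.get("level_pe_spl"), sidecar.get("meta", {}))


def read_onsets(path: str | Path) -> list[float]:
    """Read a stimulus-onset list: one time in ms per line."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(float(line))
    return out


def epoch_by_onsets(continuous: Waveform, onsets_ms, window) -> list[Waveform]:
    """Cut one epoch per stimulus onset out of a continuous record.

    Parameters
    ----------
    continuous:
        The source record; onset times are relative to its ``t0_index``.
    onsets_ms:
        Stimulus onset times in ms.
    window:
        ``(pre_ms, post_ms)`` extent around each onset.  Each epoch spans
        ``[onset - pre_ms, onset + post_ms)`` (post-exclusive), so epochs cut
        at abutting windows concatenate back to the source segment exactly.

    Each returned epoch carries its own ``t0_index`` at the click onset.
    Overlapping windows are allowed.  A window extending beyond the record
    raises ``ValueError`` naming the offending onset.
    """
    pre_ms, post_ms = window
    si = continuous.sampling_interval_us
    n_pre = int(round(pre_ms * 1000.0 / si))
    n_post = int(round(post_ms * 1000.0 / si))
    epochs = []
    for onset in onsets_ms:
        center = continuous.time_to_index(onset)
        start, stop = center - n_pre, center + n_post
        if start < 0 or stop > len(continuous.samples):
            raise ValueError(
                f"epoch window ({pre_ms}, {post_ms}) ms around onset "
                f"{onset} ms exceeds the record bounds")
        epochs.append(Waveform(continuous.samples[start:stop], si, n_pre,
                               {**continuous.meta, "onset_ms": onset}))
    return epochs


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
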