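"""Forward simulation of click-evoked cochlear potentials.

This module generates the raw material the analysis chain consumes:
condensation/rarefaction click-evoked electrocochleographic epochs, click
trains for adaptation measurements, middle-ear-reflex immittance traces and
per-ear clinical tables (audiogram + brainstem-response latencies).

The generative model encodes the physiology of cochlear synaptopathy
("hidden hearing loss") as three independent dials:

* ``ohc_gain`` scales the cochlear microphonic (CM), the outer-hair-cell
  receptor potential that follows stimulus polarity.  Synaptopathy leaves
  it untouched.
* ``synaptic_survival`` (s) scales the summating potential (SP) and the
  compound action potential (CAP), both of which shrink when inner-hair-cell
  synapses are lost.
* ``fast_fiber_loss`` preferentially removes the short-latency fiber
  population from the CAP latency density, delaying and broadening the CAP
  without touching the CM -- the electrophysiological signature that
  separates synaptopathy from simple cochlear (outer-hair-cell) loss.

Each epoch is CM(t) + SP(t) + CAP(t) + white Gaussian noise.  The CM is a
2 kHz carrier (center of the 1.5-3 kHz spectral band of click-evoked CMs)
with raised-cosine ramps whose sign flips between condensation and
rarefaction clicks.  The SP is a polarity-invariant initial negative
deflection.  The CAP is the convolution of a damped-sinusoid single-fiber
unit response with a two-component Gamma latency density (fast + slow
fibers).  Amplitudes follow a logistic function of click level and
latencies shift linearly with level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import stats as sps

from .waveform import TrialSet, Waveform

# ---------------------------------------------------------------------------
# Generator constants (conventions of this simulator, not measured values)

CM_CARRIER_HZ = 2000.0      # center of the 1.5-3 kHz CM energy band
CM_RAMP_MS = 0.25           # raised-cosine onset/offset ramp; CM onset = ramp start
CM_PLATEAU_MS = 4.0
CM_PEAK_UV = 2.4            # half peak-to-peak at 120 dB, full OHC gain

SP_PEAK_UV = 3.8
SP_GAMMA_SHAPE = 8.0
SP_MODE_MS = 0.5            # SP bump mode at 120 dB

CAP_PEAK_UV = 12.0
CAP_UNIT_PERIOD_MS = 1.0    # damped-sinusoid unit response
CAP_UNIT_DECAY_MS = 0.5
CAP_GAMMA_SHAPE = 8.0
CAP_FAST_MEAN_MS = 1.6      # fast-fiber latency density mean at 120 dB
CAP_SLOW_MEAN_MS = 2.4
CAP_FAST_WEIGHT = 0.75      # fraction of fibers in the fast pool when intact

LEVEL_MIDPOINT_DB = {"cm": 85.0, "sp": 90.0, "cap": 90.0}
LEVEL_SLOPE_DB = {"cm": 12.0, "sp": 10.0, "cap": 10.0}
LATENCY_SLOPE_MS_PER_DB = 0.015   # latency growth per dB below 120

ECOCHG_LEVELS_DB = (120, 110, 100, 90, 80, 70, 60)
TRAIN_LEVELS_DB = (120, 110, 100, 90)
ECOCHG_NHL_OFFSET_DB = 30.0   # 120 dB p.e. SPL == 90 dB nHL for these clicks
ABR_NHL_OFFSET_DB = 35.0      # 125 dB p.e. SPL == 90 dB nHL for ABR clicks

AUDIOGRAM_FREQS_HZ = (250, 500, 1000, 2000, 4000, 8000)
REFLEX_FREQS_HZ = (500, 1000, 2000, 4000)
REFLEX_TONE_MS = 300.0
REFLEX_RAMP_MS = 18.0


# ---------------------------------------------------------------------------
# Domain types

@dataclass
class SubjectPhenotype:
    """Generative parameters of one simulated ear.

    All fractions live in [0, 1].  ``adaptation_floor`` is the steady-state
    CAP fraction reached during high-rate click trains (position-wise
    amplitude ``rho + (1 - rho) * exp(-(k-1)/tau)``).
    ``threshold_shift_db`` maps audiometric frequency (Hz) to dB HL added to
    the normal hearing threshold.
    """

    ohc_gain: float = 1.0
    synaptic_survival: float = 1.0
    fast_fiber_loss: float = 0.0
    adaptation_floor: float = 0.5
    threshold_shift_db: dict = field(default_factory=dict)
    label: str = "normal"

    def __post_init__(self) -> None:
        for name in ("ohc_gain", "synaptic_survival", "fast_fiber_loss"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not 0.0 < self.adaptation_floor <= 1.0:
            raise ValueError("adaptation_floor must lie in (0, 1]")
        if self.label == "normal" and (
                self.ohc_gain != 1.0 or self.synaptic_survival != 1.0
                or self.fast_fiber_loss != 0.0):
            raise ValueError("a 'normal' phenotype must have ohc_gain=1, "
                             "synaptic_survival=1, fast_fiber_loss=0")
        if self.label == "synaptopathy" and self.ohc_gain != 1.0:
            raise ValueError("synaptopathy preserves OHC function: "
                             "ohc_gain must be 1")

    @classmethod
    def normal(cls) -> "SubjectPhenotype":
        return cls()

    @classmethod
    def synaptopathy(cls, survival: float,
                     fast_fiber_loss: float | None = None,
                     adaptation_floor: float = 0.5) -> "SubjectPhenotype":
        """Synapse loss with preserved OHCs and unchanged thresholds.

        By default the fast (short-latency, low-spontaneous-rate) fiber pool
        is depleted in proportion to the synapse loss
        (``fast_fiber_loss = 1 - survival``), which delays and broadens the
        CAP as the survival fraction falls.
        """
        if fast_fiber_loss is None:
            fast_fiber_loss = 1.0 - survival
        return cls(ohc_gain=1.0, synaptic_survival=survival,
                   fast_fiber_loss=fast_fiber_loss,
                   adaptation_floor=adaptation_floor, label="synaptopathy")

    @classmethod
    def cochlear_loss(cls, ohc_gain: float,
                      threshold_shift_db: dict | None = None
                      ) -> "SubjectPhenotype":
        """Outer-hair-cell loss: attenuated CM, elevated thresholds,
        SP/CAP reduced through the loss of amplification, but no neural
        delay or broadening."""
        if threshold_shift_db is None:
            shift = round(40.0 * (1.0 - ohc_gain))
            threshold_shift_db = {f: shift for f in AUDIOGRAM_FREQS_HZ}
        return cls(ohc_gain=ohc_gain, synaptic_survival=1.0,
                   fast_fiber_loss=0.0, threshold_shift_db=threshold_shift_db,
                   label="cochlear_loss")


@dataclass
class TrainSpec:
    """High-rate click-train paradigm: an initial click, a silent lead gap,
    then a rapid train, the whole sequence repeated periodically."""

    lead_gap_ms: float = 15.0
    train_isi_ms: float = 2.9
    clicks_in_train: int = 10
    sequence_period_ms: float = 191.0


@dataclass
class StimulusSpec:
    level_pe_spl: float = 120.0
    polarity: str = "condensation"
    click_duration_ms: float = 0.1
    train: TrainSpec | None = None
    nhl_offset_db: float = ECOCHG_NHL_OFFSET_DB

    def __post_init__(self) -> None:
        if self.polarity not in ("condensation", "rarefaction"):
            raise ValueError(f"unknown polarity {self.polarity!r}")

    @property
    def level_nhl(self) -> float:
        return self.level_pe_spl - self.nhl_offset_db


@dataclass
class GeneratorConfig:
    sampling_interval_us: float = 25.0
    epoch_pre_ms: float = 5.0
    epoch_post_ms: float = 12.0
    trials_per_polarity: int = 500
    noise_sd_uv: float = 10.0
    adaptation_tau_positions: float = 2.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_interval_us <= 0:
            raise ValueError("sampling_interval_us must be positive")
        if self.trials_per_polarity < 1:
            raise ValueError("trials_per_polarity must be >= 1")


@dataclass
class Session:
    """All recordings simulated for one ear: single-click trial sets for the
    full intensity series and click-train trial sets for adaptation."""

    singles: dict          # level -> polarity -> TrialSet
    trains: dict           # level -> polarity -> TrialSet
    phenotype: SubjectPhenotype
    cfg: GeneratorConfig


# ---------------------------------------------------------------------------
# Stimulus timing

def make_click_sequence(spec: StimulusSpec) -> list[float]:
    """Click onset times (ms) of one stimulus sequence.

    With a train: the initial click at 0, the second after the lead gap and
    the rest at the train inter-stimulus interval; all onsets fall inside one
    sequence period.  Without a train: a single onset at 0.
    """
    if spec.train is None:
        return [0.0]
    tr = spec.train
    onsets = [0.0] + [tr.lead_gap_ms + k * tr.train_isi_ms
                      for k in range(tr.clicks_in_train)]
    if onsets[-1] >= tr.sequence_period_ms:
        raise ValueError("click train does not fit in one sequence period")
    return onsets


def _check_level(level: float) -> None:
    if not 60.0 <= level <= 120.0:
        raise ValueError(
            f"click level {level} dB p.e. SPL outside the calibrated "
            f"60-120 dB range")


# ---------------------------------------------------------------------------
# Component amplitude / latency functions

def _logistic(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def _level_gain(level: float, which: str) -> float:
    return _logistic((level - LEVEL_MIDPOINT_DB[which])
                     / LEVEL_SLOPE_DB[which])


def _latency_shift_ms(level: float) -> float:
    return LATENCY_SLOPE_MS_PER_DB * (120.0 - level)


def cm_amplitude_uv(level: float, ohc_gain: float = 1.0) -> float:
    """CM carrier amplitude (half peak-to-peak) at a given click level."""
    _check_level(level)
    return CM_PEAK_UV * _level_gain(level, "cm") * ohc_gain


def sp_amplitude_uv(level: float, survival: float = 1.0,
                    ohc_gain: float = 1.0) -> float:
    """SP trough magnitude.  Scales with synaptic survival; OHC loss acts
    as an effective level attenuation."""
    _check_level(level)
    eff = level - 40.0 * (1.0 - ohc_gain)
    return SP_PEAK_UV * _level_gain(max(eff, 0.0), "sp") * survival


@lru_cache(maxsize=256)
def _cap_kernel(level: float, fast_fiber_loss: float,
                si_us: float) -> tuple:
    """Unit-amplitude CAP shape (trough calibrated against the intact-fiber
    mixture at the same level) on a t >= 0 grid.  Cached per level/loss."""
    dt_ms = si_us / 1000.0
    t = np.arange(0.0, 12.0, dt_ms)
    shift = _latency_shift_ms(level)

    def density(loss: float) -> np.ndarray:
        wf = CAP_FAST_WEIGHT * (1.0 - loss)
        ws = 1.0 - CAP_FAST_WEIGHT
        fast = sps.gamma.pdf(t, CAP_GAMMA_SHAPE,
                             scale=(CAP_FAST_MEAN_MS + shift) / CAP_GAMMA_SHAPE)
        slow = sps.gamma.pdf(t, CAP_GAMMA_SHAPE,
                             scale=(CAP_SLOW_MEAN_MS + shift) / CAP_GAMMA_SHAPE)
        return wf * fast + ws * slow

    unit_t = np.arange(0.0, 6.0, dt_ms)
    unit = -np.sin(2.0 * np.pi * unit_t / CAP_UNIT_PERIOD_MS) * \
        np.exp(-unit_t / CAP_UNIT_DECAY_MS)

    raw = np.convolve(density(fast_fiber_loss), unit)[:len(t)] * dt_ms
    ref = np.convolve(density(0.0), unit)[:len(t)] * dt_ms
    return raw / abs(ref.min()), t


def cap_amplitude_uv(level: float, survival: float = 1.0,
                     fast_fiber_loss: float = 0.0, ohc_gain: float = 1.0,
                     si_us: float = 25.0) -> float:
    """Expected CAP trough magnitude for a noiseless epoch.

    This is the forward amplitude model the survival estimator inverts:
    a logistic level function scaled by the survival fraction and reduced
    further by the shape change that fast-fiber loss induces.
    """
    _check_level(level)
    shape, _ = _cap_kernel(level, fast_fiber_loss, si_us)
    eff = level - 40.0 * (1.0 - ohc_gain)
    return CAP_PEAK_UV * _level_gain(max(eff, 0.0), "cap") * survival * \
        abs(shape.min())


def estimate_synaptic_survival(measured_cap_uv: float, level: float,
                               coupled_fast_loss: bool = True,
                               si_us: float = 25.0) -> float:
    """Invert the forward CAP amplitude model to recover synaptic survival.

    With ``coupled_fast_loss`` the inversion assumes the synaptopathy
    convention that ``fast_fiber_loss = 1 - survival``.  The returned value
    may exceed 1 slightly when measurement noise pushes the amplitude above
    the intact-ear prediction.
    """
    from scipy.optimize import brentq

    def forward(s: float) -> float:
        loss = max(0.0, 1.0 - s) if coupled_fast_loss else 0.0
        shape, _ = _cap_kernel(level, loss, si_us)
        return CAP_PEAK_UV * _level_gain(level, "cap") * s * abs(shape.min())

    hi = 1.5
    if measured_cap_uv <= 0.0:
        return 0.0
    if measured_cap_uv >= forward(hi):
        return hi
    return brentq(lambda s: forward(s) - measured_cap_uv, 0.0, hi,
                  xtol=1e-6)


# ---------------------------------------------------------------------------
# Epoch synthesis

def component_waveforms(phenotype: SubjectPhenotype, spec: StimulusSpec,
                        cfg: GeneratorConfig) -> dict:
    """Noiseless CM / SP / CAP component arrays on the epoch time grid.

    Returns a dict with keys ``t_ms``, ``cm``, ``sp``, ``cap`` and
    ``t0_index``.  These are the generator's own ground truth, used by the
    analysis oracles.
    """
    _check_level(spec.level_pe_spl)
    dt_ms = cfg.sampling_interval_us / 1000.0
    n_pre = int(round(cfg.epoch_pre_ms / dt_ms))
    n_post = int(round(cfg.epoch_post_ms / dt_ms))
    t = (np.arange(n_pre + n_post) - n_pre) * dt_ms

    cm = _cm_component(t, spec.level_pe_spl, phenotype.ohc_gain)
    if spec.polarity == "rarefaction":
        cm = -cm
    sp = _sp_component(t, spec.level_pe_spl, phenotype)
    cap = _cap_component(t, spec.level_pe_spl, phenotype,
                         cfg.sampling_interval_us)
    return {"t_ms": t, "cm": cm, "sp": sp, "cap": cap, "t0_index": n_pre}


def _cm_component(t: np.ndarray, level: float, ohc_gain: float) -> np.ndarray:
    amp = cm_amplitude_uv(level, ohc_gain)
    total = 2.0 * CM_RAMP_MS + CM_PLATEAU_MS
    env = np.zeros_like(t)
    rise = (t >= 0) & (t < CM_RAMP_MS)
    env[rise] = 0.5 * (1.0 - np.cos(np.pi * t[rise] / CM_RAMP_MS))
    env[(t >= CM_RAMP_MS) & (t < CM_RAMP_MS + CM_PLATEAU_MS)] = 1.0
    fall = (t >= CM_RAMP_MS + CM_PLATEAU_MS) & (t < total)
    env[fall] = 0.5 * (1.0 + np.cos(np.pi * (t[fall] - CM_RAMP_MS
                                             - CM_PLATEAU_MS) / CM_RAMP_MS))
    return amp * env * np.sin(2.0 * np.pi * CM_CARRIER_HZ * t / 1000.0)


def _sp_component(t: np.ndarray, level: float,
                  ph: SubjectPhenotype) -> np.ndarray:
    amp = sp_amplitude_uv(level, ph.synaptic_survival, ph.ohc_gain)
    mode = SP_MODE_MS + _latency_shift_ms(level)
    scale = mode / (SP_GAMMA_SHAPE - 1.0)
    shape = np.where(t > 0, sps.gamma.pdf(np.maximum(t, 0.0),
                                          SP_GAMMA_SHAPE, scale=scale), 0.0)
    peak = sps.gamma.pdf(mode, SP_GAMMA_SHAPE, scale=scale)
    return -amp * shape / peak


def _cap_component(t: np.ndarray, level: float, ph: SubjectPhenotype,
                   si_us: float) -> np.ndarray:
    shape, t_pos = _cap_kernel(level, ph.fast_fiber_loss, si_us)
    eff = level - 40.0 * (1.0 - ph.ohc_gain)
    amp = CAP_PEAK_UV * _level_gain(max(eff, 0.0), "cap") * \
        ph.synaptic_survival
    out = np.zeros_like(t)
    pos = t >= 0
    n = min(pos.sum(), len(shape))
    out[np.flatnonzero(pos)[:n]] = amp * shape[:n]
    return out


def synthesize_trial(phenotype: SubjectPhenotype, spec: StimulusSpec,
                     cfg: GeneratorConfig,
                     rng: np.random.Generator | None = None) -> Waveform:
    """One single-click epoch: CM + SP + CAP + white Gaussian noise."""
    comp = component_waveforms(phenotype, spec, cfg)
    samples = comp["cm"] + comp["sp"] + comp["cap"]
    if cfg.noise_sd_uv > 0:
        if rng is None:
            rng = np.random.default_rng(cfg.rng_seed)
        samples = samples + rng.normal(0.0, cfg.noise_sd_uv, len(samples))
    meta = {"level_pe_spl": spec.level_pe_spl, "polarity": spec.polarity,
            "phenotype": phenotype.label}
    return Waveform(samples, cfg.sampling_interval_us, comp["t0_index"], meta)


def synthesize_trialset(phenotype: SubjectPhenotype, spec: StimulusSpec,
                        cfg: GeneratorConfig,
                        rng: np.random.Generator | None = None) -> TrialSet:
    """A full trial set for one level/polarity (template + per-trial noise)."""
    comp = component_waveforms(phenotype, spec, cfg)
    template = comp["cm"] + comp["sp"] + comp["cap"]
    n = cfg.trials_per_polarity
    if cfg.noise_sd_uv > 0:
        if rng is None:
            rng = np.random.default_rng(cfg.rng_seed)
        data = template[None, :] + rng.normal(
            0.0, cfg.noise_sd_uv, (n, len(template)))
    else:
        data = np.tile(template, (n, 1))
    return TrialSet(data, cfg.sampling_interval_us, comp["t0_index"],
                    spec.polarity, spec.level_pe_spl,
                    {"phenotype": phenotype.label})


def adaptation_amplitudes(phenotype: SubjectPhenotype, cfg: GeneratorConfig,
                          n_positions: int = 11) -> np.ndarray:
    """Per-click CAP amplitude multipliers in a train.

    Position 1 (the initial click) is 1 exactly; later positions decay
    exponentially toward the steady-state floor rho:
    ``rho + (1 - rho) * exp(-(k - 1) / tau)``.
    """
    k = np.arange(1, n_positions + 1, dtype=float)
    rho = phenotype.adaptation_floor
    return rho + (1.0 - rho) * np.exp(-(k - 1.0)
                                      / cfg.adaptation_tau_positions)


def synthesize_train_recording(phenotype: SubjectPhenotype,
                               spec: StimulusSpec, cfg: GeneratorConfig,
                               rng: np.random.Generator | None = None,
                               n_trials: int | None = None) -> TrialSet:
    """Trial set of continuous records covering one click-train sequence.

    Each trial spans from ``epoch_pre_ms`` before the initial click to
    ``epoch_post_ms`` after the last click; CM and SP repeat unattenuated at
    every click while CAP amplitudes follow the adaptation rule.
    """
    if spec.train is None:
        raise ValueError("spec.train must be set for a train recording")
    onsets = make_click_sequence(spec)
    amps = adaptation_amplitudes(phenotype, cfg, len(onsets))
    dt_ms = cfg.sampling_interval_us / 1000.0
    n_pre = int(round(cfg.epoch_pre_ms / dt_ms))
    n_total = n_pre + int(round((onsets[-1] + cfg.epoch_post_ms) / dt_ms))
    t = (np.arange(n_total) - n_pre) * dt_ms

    cm = np.zeros(n_total)
    sp = np.zeros(n_total)
    cap = np.zeros(n_total)
    for onset, a in zip(onsets, amps):
        tt = t - onset
        cm += _cm_component(tt, spec.level_pe_spl, phenotype.ohc_gain)
        sp += _sp_component(tt, spec.level_pe_spl, phenotype)
        cap += a * _cap_component(tt, spec.level_pe_spl, phenotype,
                                  cfg.sampling_interval_us)
    if spec.polarity == "rarefaction":
        cm = -cm
    template = cm + sp + cap

    n = cfg.trials_per_polarity if n_trials is None else n_trials
    if cfg.noise_sd_uv > 0:
        if rng is None:
            rng = np.random.default_rng(cfg.rng_seed)
        data = template[None, :] + rng.normal(0.0, cfg.noise_sd_uv,
                                              (n, n_total))
    else:
        data = np.tile(template, (n, 1))
    return TrialSet(data, cfg.sampling_interval_us, n_pre, spec.polarity,
                    spec.level_pe_spl,
                    {"phenotype": phenotype.label, "onsets_ms": list(onsets)})


def synthesize_session(phenotype: SubjectPhenotype, cfg: GeneratorConfig,
                       levels=ECOCHG_LEVELS_DB,
                       train_levels=TRAIN_LEVELS_DB) -> Session:
    """Simulate a full recording session for one ear.

    Single clicks of both polarities at each level of the intensity series
    (120 down to 60 dB p.e. SPL in 10 dB steps by default) plus click-train
    sequences at the high levels used for adaptation analysis.  The session
    is reproducible: the same ``cfg.rng_seed`` yields identical output.
    """
    root = np.random.default_rng(cfg.rng_seed)
    singles: dict = {}
    for level in levels:
        singles[level] = {}
        for pol in ("condensation", "rarefaction"):
            spec = StimulusSpec(level_pe_spl=level, polarity=pol)
            singles[level][pol] = synthesize_trialset(
                phenotype, spec, cfg, rng=np.random.default_rng(
                    root.integers(2**31)))
    trains: dict = {}
    for level in train_levels:
        trains[level] = {}
        for pol in ("condensation", "rarefaction"):
            spec = StimulusSpec(level_pe_spl=level, polarity=pol,
                                train=TrainSpec())
            trains[level][pol] = synthesize_train_recording(
                phenotype, spec, cfg, rng=np.random.default_rng(
                    root.integers(2**31)))
    return Session(singles, trains, phenotype, cfg)


# ---------------------------------------------------------------------------
# Middle-ear reflex traces

def synthesize_reflex_trace(phenotype: SubjectPhenotype, tone_freq_hz: float,
                            level_above_threshold_db: float = 10.0,
                            amplitude: float = 1.0,
                            noise_sd: float = 0.0,
                            rng: np.random.Generator | None = None,
                            sampling_interval_us: float = 1000.0) -> Waveform:
    """Immittance trace (arbitrary units) evoked by a 300 ms tone.

    The deflection is negative-going and is built from a phasic fast
    component plus a tonic slow component.  Synaptopathy attenuates the fast
    component in proportion to ``fast_fiber_loss`` (the reflex arc is driven
    by rapid low-spontaneous-rate fibers), which delays the peak without
    abolishing the response.  ``amplitude = 0`` produces a flat trace that
    downstream analysis reports as an absent reflex.
    """
    if tone_freq_hz not in REFLEX_FREQS_HZ:
        raise ValueError(f"unsupported reflex tone frequency {tone_freq_hz};"
                         f" expected one of {REFLEX_FREQS_HZ}")
    dt_ms = sampling_interval_us / 1000.0
    pre_ms, post_ms = 100.0, 300.0
    n_pre = int(round(pre_ms / dt_ms))
    n = n_pre + int(round((REFLEX_TONE_MS + post_ms) / dt_ms))
    t = (np.arange(n) - n_pre) * dt_ms

    # tone envelope with raised-cosine rise/fall ramps
    env = np.zeros(n)
    rise = (t >= 0) & (t < REFLEX_RAMP_MS)
    env[rise] = 0.5 * (1 - np.cos(np.pi * t[rise] / REFLEX_RAMP_MS))
    env[(t >= REFLEX_RAMP_MS) & (t < REFLEX_TONE_MS - REFLEX_RAMP_MS)] = 1.0
    fall = (t >= REFLEX_TONE_MS - REFLEX_RAMP_MS) & (t < REFLEX_TONE_MS)
    env[fall] = 0.5 * (1 + np.cos(np.pi * (t[fall] - REFLEX_TONE_MS
                                           + REFLEX_RAMP_MS) / REFLEX_RAMP_MS))

    # phasic (zero-integral) kernels: the fast pathway rises and relaxes
    # quickly, the slow pathway later; mixing them moves the response peak
    # continuously later as the fast component is depleted
    tk = np.arange(0.0, 600.0, dt_ms)
    fast_kernel = np.exp(-tk / 15.0) / 15.0 - np.exp(-tk / 150.0) / 150.0
    slow_kernel = np.exp(-tk / 60.0) / 60.0 - np.exp(-tk / 400.0) / 400.0
    fast = np.convolve(env, fast_kernel)[:n] * dt_ms
    slow = np.convolve(env, slow_kernel)[:n] * dt_ms
    fast /= fast.max()
    slow /= slow.max()

    gain = 1.0 + 0.05 * level_above_threshold_db
    w_fast = 1.2 * (1.0 - phenotype.fast_fiber_loss)
    trace = -amplitude * gain * (w_fast * fast + 0.8 * slow)
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        trace = trace + rng.normal(0.0, noise_sd, n)
    return Waveform(trace, sampling_interval_us, n_pre,
                    {"tone_freq_hz": tone_freq_hz,
                     "tone_duration_ms": REFLEX_TONE_MS,
                     "ramp_ms": REFLEX_RAMP_MS,
                     "phenotype": phenotype.label})


# ---------------------------------------------------------------------------
# Clinical tables

NORMAL_THRESHOLD_DB = 10.0
NORMAL_WAVE_I_MS = 1.55
NORMAL_IP_I_III_MS = 2.25
NORMAL_IP_III_V_MS = 1.85
NORMAL_WAVE_I_UV = 0.30


def synthesize_clinical_tables(phenotypes: list, rng=None,
                               threshold_noise_db: float = 0.0,
                               latency_noise_ms: float = 0.0,
                               amplitude_noise_frac: float = 0.0):
    """Per-ear audiogram and brainstem-response records for a cohort.

    ``phenotypes`` is a list of ``(subject_id, ear, SubjectPhenotype)``.
    Returns ``(audiograms, abr_waves)`` as lists of
    :class:`ecochg.clinical.Audiogram` / :class:`ecochg.clinical.ABRWaves`.

    Synaptopathy leaves thresholds alone but scales the Wave I amplitude by
    the synaptic survival fraction; severe synapse loss (< 30% survival)
    desynchronizes the later waves, which are then flagged absent.
    """
    from .clinical import ABRWaves, Audiogram

    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    audiograms, abrs = [], []
    for subject, ear, ph in phenotypes:
        thr = {}
        for f in AUDIOGRAM_FREQS_HZ:
            base = NORMAL_THRESHOLD_DB + ph.threshold_shift_db.get(f, 0.0)
            if threshold_noise_db > 0:
                base += rng.normal(0.0, threshold_noise_db)
                base = 5.0 * round(base / 5.0)      # audiometer 5 dB steps
            thr[f] = max(base, -10.0)
        audiograms.append(Audiogram(ear=ear, thresholds_db=thr,
                                    subject=subject))

        s = ph.synaptic_survival
        jitter = (lambda sd: rng.normal(0.0, sd)) if latency_noise_ms > 0 \
            else (lambda sd: 0.0)
        wave_i = wave_iii = wave_v = None
        wave_i_uv = None
        if s >= 0.15:
            wave_i = NORMAL_WAVE_I_MS + jitter(latency_noise_ms)
            amp = NORMAL_WAVE_I_UV * s
            if amplitude_noise_frac > 0:
                amp *= max(0.05, 1.0 + rng.normal(0.0, amplitude_noise_frac))
            wave_i_uv = amp
        if s >= 0.30:
            # fast-fiber loss slows neural conduction slightly
            delay = 0.4 * ph.fast_fiber_loss
            wave_iii = NORMAL_WAVE_I_MS + NORMAL_IP_I_III_MS + delay \
                + jitter(latency_noise_ms)
            wave_v = wave_iii + NORMAL_IP_III_V_MS + jitter(latency_noise_ms)
        abrs.append(ABRWaves(ear=ear, wave_i_ms=wave_i, wave_iii_ms=wave_iii,
                             wave_v_ms=wave_v, wave_i_amplitude_uv=wave_i_uv,
                             subject=subject))
    return audiograms, abrs
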