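"""Audiometric, brainstem-response and speech-score computations.

Covers the routine clinical indices used around the electrophysiology:
pure-tone average (PTA) and hearing-loss severity classes, the bilateral
normal-threshold grouping rule, ABR inter-peak intervals and the I-III
abnormality flag, word-list scoring and consonant confusion-matrix scoring.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PTA_FREQS_HZ = (500, 1000, 2000, 4000)
LF_FREQS_HZ = (250, 500, 1000)
HF_FREQS_HZ = (2000, 4000, 8000)

#: Severity bands in dB HL.  The mild band starts at 20 dB: clinical usage
#: groups ears with PTA 20-34 dB with the mild losses, so "normal" covers
#: PTA < 20 dB only.
SEVERITY_BANDS = (
    ("normal", -float("inf"), 20.0),
    ("mild", 20.0, 41.0),
    ("moderate", 41.0, 71.0),
    ("severe", 71.0, 96.0),
    ("profound", 96.0, float("inf")),
)

IP_I_III_UPPER_LIMIT_MS = 2.60

#: The 16-consonant identification set, presented in an a-consonant-a
#: context.  Chance performance is 1/16 (6.25%).
CONSONANTS = ("b", "d", "f", "g", "k", "l", "m", "n",
              "p", "r", "s", "t", "v", "z", "j", "tS")


@dataclass
class Audiogram:
    """Per-ear air-conduction thresholds (dB HL) at the standard octave
    frequencies 250-8000 Hz."""

    ear: str
    thresholds_db: dict
    subject: str | None = None

    def __post_init__(self) -> None:
        for f, v in self.thresholds_db.items():
            if not np.isfinite(v) or v < -10.0:
                raise ValueError(f"threshold at {f} Hz must be finite and "
                                 f">= -10 dB HL, got {v}")


@dataclass
class ABRWaves:
    """Per-ear ABR wave latencies (ms) and Wave I amplitude (uV).

    ``None`` marks an absent (undetectable) wave.  Latencies of present
    waves must be non-decreasing in the order I, III, V.
    """

    ear: str
    wave_i_ms: float | None = None
    wave_iii_ms: float | None = None
    wave_v_ms: float | None = None
    wave_i_amplitude_uv: float | None = None
    subject: str | None = None

    def __post_init__(self) -> None:
        present = [v for v in (self.wave_i_ms, self.wave_iii_ms,
                               self.wave_v_ms) if v is not None]
        if any(b < a for a, b in zip(present, present[1:])):
            raise ValueError("present ABR wave latencies must be ordered "
                             "I <= III <= V")


@dataclass
class SpeechScore:
    condition: str
    n_items: int
    n_correct: int
    percent: float = field(init=False)

    def __post_init__(self) -> None:
        if not 0 <= self.n_correct <= self.n_items:
            raise ValueError("n_correct must lie in [0, n_items]")
        self.percent = 100.0 * self.n_correct / self.n_items


# ---------------------------------------------------------------------------
# Audiometry

def compute_pta(a: Audiogram) -> int:
    """Pure-tone average over 0.5, 1, 2 and 4 kHz, rounded half-up to the
    nearest integer dB."""
    try:
        vals = [a.thresholds_db[f] for f in PTA_FREQS_HZ]
    except KeyError as e:
        raise ValueError(f"audiogram is missing the {e.args[0]} Hz "
                         f"threshold required for the PTA") from e
    mean = sum(vals) / 4.0
    return int(np.floor(mean + 0.5))


def lf_average(a: Audiogram) -> float:
    """Low-frequency average: mean threshold at 250, 500 and 1000 Hz
    (a reporting convention of this package)."""
    return float(np.mean([a.thresholds_db[f] for f in LF_FREQS_HZ]))


def hf_average(a: Audiogram) -> float:
    """High-frequency average: mean threshold at 2, 4 and 8 kHz
    (a reporting convention of this package)."""
    return float(np.mean([a.thresholds_db[f] for f in HF_FREQS_HZ]))


def classify_hearing(pta_db: float) -> str:
    """Severity class for a PTA value (see :data:`SEVERITY_BANDS`)."""
    if not np.isfinite(pta_db):
        raise ValueError("PTA must be finite")
    for name, lo, hi in SEVERITY_BANDS:
        if lo <= pta_db < hi:
            return name
    raise AssertionError("unreachable")


def assign_groups(per_subject_pta: dict) -> dict:
    """Pool subjects by bilateral hearing status.

    ``per_subject_pta`` maps subject id -> (right PTA, left PTA).  Group 1
    holds subjects with normal thresholds bilaterally (both PTAs <= 15 dB);
    every other subject (mild loss in at least one ear) goes to group 2.
    """
    return {subj: 1 if max(ptas) <= 15.0 else 2
            for subj, ptas in per_subject_pta.items()}


# ---------------------------------------------------------------------------
# ABR indices

def interpeak_intervals(w: ABRWaves) -> dict:
    """I-III, III-V and I-V inter-peak intervals (ms, to 0.01).

    An interval whose defining waves include an absent one is ``None``.
    """
    def diff(a, b):
        if a is None or b is None:
            return None
        return round(b - a, 2)

    return {"ip_i_iii": diff(w.wave_i_ms, w.wave_iii_ms),
            "ip_iii_v": diff(w.wave_iii_ms, w.wave_v_ms),
            "ip_i_v": diff(w.wave_i_ms, w.wave_v_ms)}


def flag_ip_abnormal(ip_i_iii_ms: float | None,
                     limit_ms: float = IP_I_III_UPPER_LIMIT_MS
                     ) -> bool | None:
    """True when the I-III interval strictly exceeds the normal upper limit
    (2.60 ms by default); ``None`` propagates missing intervals."""
    if ip_i_iii_ms is None:
        return None
    return ip_i_iii_ms > limit_ms


# ---------------------------------------------------------------------------
# Speech scores

def score_word_list(responses, condition: str = "quiet") -> SpeechScore:
    """Percent of words correctly repeated in one list.

    ``responses`` is a boolean sequence, one entry per presented word
    (10-word lists for articulation curves, 25-word lists for the
    recognition test in noise).
    """
    responses = list(responses)
    return SpeechScore(condition, len(responses),
                       int(sum(bool(r) for r in responses)))


def score_consonant_matrix(pairs, alphabet=CONSONANTS):
    """Score a consonant-identification run and build its confusion matrix.

    ``pairs`` is a sequence of ``(stimulus, response)`` symbols drawn from
    ``alphabet``.  Returns ``(percent_correct, confusion)`` where
    ``confusion`` is a DataFrame with stimulus rows and response columns
    whose row sums equal the presentations per consonant; percent correct
    is ``100 * trace / total``.
    """
    index = {c: i for i, c in enumerate(alphabet)}
    table = np.zeros((len(alphabet), len(alphabet)), dtype=int)
    for stim, resp in pairs:
        if stim not in index or resp not in index:
            bad = stim if stim not in index else resp
            raise ValueError(f"symbol {bad!r} is not in the "
                             f"{len(alphabet)}-consonant set")
        table[index[stim], index[resp]] += 1
    total = table.sum()
    if total == 0:
        raise ValueError("no stimulus/response pairs given")
    percent = 100.0 * np.trace(table) / total
    confusion = pd.DataFrame(table, index=list(alphabet),
                             columns=list(alphabet))
    return percent, confusion


# ---------------------------------------------------------------------------
# Reference clinical table

def load_reference_table() -> pd.DataFrame:
    """Per-ear clinical reference dataset bundled with the package.

    Audiometric, gap-detection and ABR measurements from a ten-member
    family segregating dominant optic atrophy with hidden auditory
    neuropathy (one row per ear; absent responses are ``NaN`` with the
    corresponding ``*_absent`` convention of empty cells in the source
    table).  Used by the test-suite fixtures and as a worked example.
    """
    ref = importlib.resources.files("ecochg.data") / "clinical_reference.tsv"
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t", na_values=["-", "ABS"])
    return df


def abr_from_row(row) -> ABRWaves:
    """Build an :class:`ABRWaves` record from a reference-table row."""
    def val(col):
        v = row[col]
        return None if pd.isna(v) else float(v)

    return ABRWaves(ear=row["ear"], wave_i_ms=val("wave_i_ms"),
                    wave_iii_ms=val("wave_iii_ms"),
                    wave_v_ms=val("wave_v_ms"),
                    subject=str(row["subject"]))
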