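"""Per-second respiratory state classification from capnography-derived measures.

Each monitored second is assigned one of four respiratory states from the
capnography channel — normal breathing, hypopneic hypoventilation (waveform
amplitude deviating more than 10% from the pre-sedation baseline), bradypneic
hypoventilation (capnography-derived respiratory rate below 8 breaths/min) or
apnea (no waveform, or an end-tidal CO2 of 0 mmHg) — with artifact-flagged
seconds (talking, dislodged sampling cannula) marked missing and excluded
from analysis.

The cut-offs live in :data:`RATE_CUTOFF` and :data:`AMPLITUDE_TOLERANCE`
and may be overridden per call; the defaults are the conventional values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Canonical state alphabet, severity-ordered precedence is APNEA >
#: BRADYPNEA > HYPOPNEA > NORMAL when criteria co-occur.
NORMAL = "NORMAL"
HYPOPNEA = "HYPOPNEA"
BRADYPNEA = "BRADYPNEA"
APNEA = "APNEA"
MISSING = "MISSING"

#: States that describe breathing (MISSING excluded).
STATE_ALPHABET = (NORMAL, HYPOPNEA, BRADYPNEA, APNEA)
ALL_CODES = STATE_ALPHABET + (MISSING,)

#: One-letter aliases used in compact textual sequence specs.
SHORT = {"N": NORMAL, "H": HYPOPNEA, "B": BRADYPNEA, "A": APNEA, "M": MISSING}

#: Bradypnea threshold: rate strictly below this is bradypneic (breaths/min).
RATE_CUTOFF = 8.0
#: Hypopnea threshold: |relative amplitude - 1| strictly above this (fraction).
AMPLITUDE_TOLERANCE = 0.10


@dataclass(frozen=True)
class RespiratorySample:
    """One second of monitoring for one patient.

    ``rel_amplitude`` is capnogram waveform amplitude as a fraction of the
    pre-sedation baseline (1.0 = unchanged). ``spo2``, ``pulse_detected``
    and ``tcco2`` are optional side channels not used for state assignment.
    """

    patient_id: str
    t: int
    resp_rate: float
    etco2: float
    rel_amplitude: float
    waveform_present: bool = True
    artifact: bool = False
    spo2: float | None = None
    pulse_detected: bool | None = None
    tcco2: float | None = None


@dataclass
class StateSequence:
    """Ordered per-second respiratory state codes for one patient."""

    patient_id: str
    states: np.ndarray  # dtype object/str, values in ALL_CODES

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=object)
        if self.states.size < 1:
            raise ValueError(f"empty state sequence for patient {self.patient_id}")
        bad = set(self.states) - set(ALL_CODES)
        if bad:
            raise ValueError(f"unknown state codes {sorted(bad)}")

    def __len__(self) -> int:
        return int(self.states.size)

    @property
    def length(self) -> int:
        return len(self)

    def to_intervals(self) -> list[tuple[str, int, int]]:
        """Run-length encode as half-open ``(state, start_s, end_s)`` intervals."""
        s = self.states
        change = np.flatnonzero(s[1:] != s[:-1]) + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [len(s)]])
        return [(str(s[a]), int(a), int(b)) for a, b in zip(starts, ends)]

    @classmethod
    def from_string(cls, patient_id: str, spec: str) -> "StateSequence":
        """Build from a one-letter-per-second string, e.g. ``"NNABM"``."""
        return cls(patient_id, np.array([SHORT[c] for c in spec], dtype=object))


def classify_second(sample: RespiratorySample) -> str:
    """Assign the respiratory state for a single monitored second.

    Precedence: artifact -> MISSING; no waveform or etCO2 = 0 -> APNEA;
    rate < 8 -> BRADYPNEA; amplitude deviating > 10% from baseline ->
    HYPOPNEA; otherwise NORMAL.
    """
    if sample.resp_rate < 0 or sample.etco2 < 0 or sample.rel_amplitude < 0:
        raise ValueError(
            f"negative measurement for patient {sample.patient_id} at t={sample.t}"
        )
    if sample.artifact:
        return MISSING
    if not sample.waveform_present or sample.etco2 == 0.0:
        return APNEA
    if sample.resp_rate < RATE_CUTOFF:
        return BRADYPNEA
    if abs(sample.rel_amplitude - 1.0) > AMPLITUDE_TOLERANCE:
        return HYPOPNEA
    return NORMAL


def classify_frame(
    df: pd.DataFrame,
    rate_cutoff: float = RATE_CUTOFF,
    amplitude_tolerance: float = AMPLITUDE_TOLERANCE,
) -> np.ndarray:
    """Vectorized :func:`classify_second` over a long monitoring table.

    ``df`` needs columns ``resp_rate, etco2, rel_amplitude, waveform_present,
    artifact``. Returns an object array of state codes, one per row.
    """
    for col in ("resp_rate", "etco2", "rel_amplitude"):
        vals = df[col].to_numpy(dtype=float)
        if np.any(vals < 0):
            raise ValueError(f"negative values in column {col!r}")
    rate = df["resp_rate"].to_numpy(dtype=float)
    etco2 = df["etco2"].to_numpy(dtype=float)
    amp = df["rel_amplitude"].to_numpy(dtype=float)
    wave = df["waveform_present"].to_numpy(dtype=bool)
    artifact = df["artifact"].to_numpy(dtype=bool)

    out = np.full(len(df), NORMAL, dtype=object)
    out[np.abs(amp - 1.0) > amplitude_tolerance] = HYPOPNEA
    out[rate < rate_cutoff] = BRADYPNEA
    out[(~wave) | (etco2 == 0.0)] = APNEA
    out[artifact] = MISSING
    return out


def build_sequence(
    samples: pd.DataFrame,
    patient_id: str | None = None,
    **thresholds: float,
) -> StateSequence:
    """Classify one patient's contiguous per-second samples into a sequence.

    ``samples`` is the long monitoring table restricted to one patient;
    ``t`` must start at 0 and increase in steps of 1.
    """
    if patient_id is None:
        ids = samples["patient_id"].unique()
        if len(ids) != 1:
            raise ValueError("samples must belong to a single patient")
        patient_id = str(ids[0])
    t = samples["t"].to_numpy(dtype=int)
    if len(t) == 0:
        raise ValueError(f"no samples for patient {patient_id}")
    if t[0] != 0 or np.any(np.diff(t) != 1):
        raise ValueError(f"samples for patient {patient_id} not contiguous from t=0")
    return StateSequence(patient_id, classify_frame(samples, **thresholds))


def expand_intervals(
    patient_id: str,
    intervals: list[tuple[str, int, int]],
    total_length: int,
    fill: str | None = NORMAL,
) -> StateSequence:
    """Expand half-open ``(state, start_s, end_s)`` intervals to per-second codes.

    Uncovered seconds are filled with ``fill`` (default NORMAL, the convention
    for observer-marked abnormality onsets/offsets on an otherwise normal
    record); pass ``fill=None`` to reject gaps. Overlaps always reject.
    """
    if total_length < 1:
        raise ValueError("total_length must be >= 1")
    covered = np.zeros(total_length, dtype=bool)
    out = np.full(total_length, fill, dtype=object)
    for state, a, b in sorted(intervals, key=lambda iv: iv[1]):
        if state not in ALL_CODES:
            raise ValueError(f"unknown state {state!r}")
        if not (0 <= a < b <= total_length):
            raise ValueError(f"interval ({state}, {a}, {b}) out of bounds")
        if covered[a:b].any():
            raise ValueError(f"overlapping interval ({state}, {a}, {b})")
        covered[a:b] = True
        out[a:b] = state
    if fill is None and not covered.all():
        gap = int(np.flatnonzero(~covered)[0])
        raise ValueError(f"gap at t={gap} and no fill state configured")
    return StateSequence(patient_id, out)


def sequences_from_frame(df: pd.DataFrame, **thresholds: float) -> list[StateSequence]:
    """Split a long monitoring table by patient and classify each."""
    return [
        build_sequence(g, patient_id=str(pid), **thresholds)
        for pid, g in df.groupby("patient_id", sort=True)
    ]
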