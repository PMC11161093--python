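"""Per-animal freezing sessions from auditory aversive conditioning.

A retrieval session is scored in 24 consecutive 30-s time bins (percent
time freezing per bin, 1-based indexing).  The conditioned stimulus (CS)
plays during bins 13-24; the early CS response (bins 13-17) is the
*phasic* component and the late response (bins 18-24) the *sustained*
component.  Bins 1-12 are the pre-CS baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: number of 30-s bins per session
N_BINS = 24
#: 1-based bin ranges for the CS window and its two components
CS_BINS = (13, 24)
PHASIC_BINS = (13, 17)
SUSTAINED_BINS = (18, 24)

SESSIONS = ("Adaptation", "MR1", "MR2", "MR3", "MR4", "MR5", "MR6")
SEXES = ("female", "male")

_BIN_COLUMNS = [f"bin_{i}" for i in range(1, N_BINS + 1)]


class SessionValidationError(ValueError):
    """Raised when a freezing session violates its invariants."""


@dataclass(frozen=True)
class FreezingSession:
    """One animal x one session: 24 per-bin freezing percentages."""

    animal_id: str
    sex: str
    session: str
    bins: tuple[float, ...] = field(repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "bins", tuple(float(b) for b in self.bins))
        validate_session(self)

    def bin(self, i: int) -> float:
        """Freezing in 1-based bin ``i``."""
        if not 1 <= i <= N_BINS:
            raise SessionValidationError(f"bin index {i} outside 1..{N_BINS}")
        return self.bins[i - 1]


def validate_session(session: FreezingSession) -> None:
    if session.sex not in SEXES:
        raise SessionValidationError(
            f"animal {session.animal_id!r}: sex must be one of {SEXES}, got {session.sex!r}"
        )
    if session.session not in SESSIONS:
        raise SessionValidationError(
            f"animal {session.animal_id!r}: unknown session label {session.session!r}"
        )
    if len(session.bins) != N_BINS:
        raise SessionValidationError(
            f"animal {session.animal_id!r}: expected {N_BINS} bins, got {len(session.bins)}"
        )
    for i, v in enumerate(session.bins, start=1):
        if not np.isfinite(v) or not 0.0 <= v <= 100.0:
            raise SessionValidationError(
                f"animal {session.animal_id!r}: bin_{i} value {v!r} outside [0, 100]"
            )


def cs_window(session: FreezingSession) -> np.ndarray:
    """CS-window freezing (bins 13-24) re-indexed so t = 0 is CS onset.

    Returns a length-12 float array; element ``t`` is freezing during
    bin ``13 + t``.
    """
    lo, hi = CS_BINS
    return np.asarray(session.bins[lo - 1 : hi], dtype=float)


def phasic_window(session: FreezingSession) -> np.ndarray:
    """Phasic-component freezing, bins 13-17."""
    lo, hi = PHASIC_BINS
    return np.asarray(session.bins[lo - 1 : hi], dtype=float)


def sustained_window(session: FreezingSession) -> np.ndarray:
    """Sustained-component freezing, bins 18-24."""
    lo, hi = SUSTAINED_BINS
    return np.asarray(session.bins[lo - 1 : hi], dtype=float)


def sessions_to_frame(sessions: Iterable[FreezingSession]) -> pd.DataFrame:
    """Long-format table: one row per animal-session, bin_1..bin_24 columns."""
    rows = [
        {"animal_id": s.animal_id, "sex": s.sex, "session": s.session,
         **dict(zip(_BIN_COLUMNS, s.bins))}
        for s in sessions
    ]
    return pd.DataFrame(rows, columns=["animal_id", "sex", "session", *_BIN_COLUMNS])


def frame_to_sessions(frame: pd.DataFrame) -> list[FreezingSession]:
    missing = [c for c in ("animal_id", "sex", "session", *_BIN_COLUMNS) if c not in frame.columns]
    if missing:
        raise SessionValidationError(f"sessions table is missing columns: {missing}")
    return [
        FreezingSession(
            animal_id=str(row["animal_id"]),
            sex=str(row["sex"]),
            session=str(row["session"]),
            bins=tuple(float(row[c]) for c in _BIN_COLUMNS),
        )
        for _, row in frame.iterrows()
    ]


def read_sessions(path: str | Path) -> list[FreezingSession]:
    """Read a sessions CSV (``animal_id,sex,session,bin_1,...,bin_24``)."""
    return frame_to_sessions(pd.read_csv(path, float_precision="round_trip"))


def write_sessions(sessions: Sequence[FreezingSession], path: str | Path) -> None:
    # %.17g keeps the round trip lossless for float64 freezing values
    sessions_to_frame(sessions).to_csv(path, index=False, float_format="%.17g")
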