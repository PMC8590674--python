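"""Core domain containers shared across the pipeline.

Sleep stages follow the three-class convention of portable sleep testing:
``WAKE``, ``REM`` and ``NREM`` (N1/N2/N3 are not distinguished).  A
*hypnogram* is represented throughout as a 1-D :class:`numpy.ndarray` of
these label strings, one per 30-second epoch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

WAKE = "WAKE"
REM = "REM"
NREM = "NREM"

#: Canonical stage order used for confusion matrices and class indices.
STAGES: tuple[str, str, str] = (WAKE, REM, NREM)

STAGE_TO_INDEX = {s: i for i, s in enumerate(STAGES)}

#: AASM scoring epoch length in seconds.
EPOCH_SECONDS = 30.0

#: Stages counted as sleep for TST/AHI purposes.
SLEEP_STAGES = frozenset({REM, NREM})


def as_hypnogram(labels: Iterable[str]) -> np.ndarray:
    """Coerce an iterable of stage labels into a validated hypnogram array.

    Labels are upper-cased; anything outside {WAKE, REM, NREM} raises
    :class:`ValueError`.
    """
    arr = np.asarray([str(l).upper() for l in labels], dtype="<U4")
    bad = set(arr.tolist()) - set(STAGES)
    if bad:
        raise ValueError(f"unknown sleep stage label(s): {sorted(bad)}")
    return arr


def stages_to_indices(hypnogram: Sequence[str]) -> np.ndarray:
    """Map stage labels to integer class indices (WAKE=0, REM=1, NREM=2)."""
    hyp = as_hypnogram(hypnogram)
    return np.array([STAGE_TO_INDEX[s] for s in hyp], dtype=np.int64)


def is_sleep(hypnogram: Sequence[str]) -> np.ndarray:
    """Boolean mask of epochs scored as sleep (REM or NREM)."""
    hyp = as_hypnogram(hypnogram)
    return np.isin(hyp, [REM, NREM])


@dataclass
class SignalRecord:
    """A multichannel respiratory-effort + activity recording.

    Attributes
    ----------
    thorax, abdomen : ndarray
        RIP belt signals (arbitrary units), same length, uniformly sampled.
    activity : ndarray
        Movement magnitude channel, same length and rate as the belts.
    sample_rate : float
        Common sampling rate in Hz.
    """

    thorax: np.ndarray
    abdomen: np.ndarray
    activity: np.ndarray
    sample_rate: float
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.thorax = np.asarray(self.thorax, dtype=float)
        self.abdomen = np.asarray(self.abdomen, dtype=float)
        self.activity = np.asarray(self.activity, dtype=float)
        n = len(self.thorax)
        if len(self.abdomen) != n or len(self.activity) != n:
            raise ValueError(
                "channel length mismatch: "
                f"thorax={n}, abdomen={len(self.abdomen)}, activity={len(self.activity)}"
            )
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def duration(self) -> float:
        """Recording duration in seconds."""
        return len(self.thorax) / self.sample_rate

    @property
    def n_epochs(self) -> int:
        """Number of complete 30-s epochs covered by the recording."""
        return int(self.duration // EPOCH_SECONDS)


@dataclass(frozen=True)
class RespiratoryEvent:
    """A scored apnea or hypopnea: onset (s), duration (s) and type."""

    start: float
    duration: float
    kind: str  # "apnea" | "hypopnea"

    def __post_init__(self) -> None:
        if self.kind not in ("apnea", "hypopnea"):
            raise ValueError(f"event type must be apnea|hypopnea, got {self.kind!r}")
        if self.duration < 10.0:
            raise ValueError(
                f"respiratory events are at least 10 s long, got {self.duration} s"
            )

    @property
    def end(self) -> float:
        return self.start + self.duration


@dataclass
class RespiratoryEventList:
    """Scored respiratory events within an analysis window.

    Events must be non-overlapping, sorted by onset, and contained in
    ``[0, analysis_duration]``.
    """

    events: list[RespiratoryEvent] = field(default_factory=list)
    analysis_duration: float = 0.0

    def __post_init__(self) -> None:
        self.events = sorted(self.events, key=lambda e: e.start)
        prev_end = -np.inf
        for ev in self.events:
            if ev.start < 0 or ev.end > self.analysis_duration + 1e-9:
                raise ValueError(
                    f"event [{ev.start}, {ev.end}] outside analysis window "
                    f"[0, {self.analysis_duration}]"
                )
            if ev.start < prev_end - 1e-9:
                raise ValueError(f"overlapping events at t={ev.start:.1f} s")
            prev_end = ev.end

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)


@dataclass
class FeatureMatrix:
    """Per-epoch feature vectors: one row per 30-s epoch.

    ``normalized`` records whether per-study median/IQR scaling has been
    applied; re-normalizing a normalized matrix is a contract violation.
    """

    values: np.ndarray
    feature_names: tuple[str, ...]
    epoch_duration: float = EPOCH_SECONDS
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("feature values must be 2-D (epochs x features)")
        self.feature_names = tuple(self.feature_names)
        if self.values.shape[1] != len(self.feature_names):
            raise ValueError(
                f"{self.values.shape[1]} columns but "
                f"{len(self.feature_names)} feature names"
            )
        if self.values.size and not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite entries")

    @property
    def n_epochs(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]
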