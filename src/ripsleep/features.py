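"""Breath detection and per-epoch feature extraction.

The classifier consumes a fixed 14-feature schema per 30-s epoch,
instantiating the feature families that make RIP + actigraphy staging work:
breath amplitude statistics and epoch-to-epoch amplitude change for each
belt, overall epoch signal dispersion, the thoraco-abdominal Pearson
correlation, breathing-rate and breath-duration-variability statistics, and
activity summaries.  Features are normalized per study by subtracting the
column median and dividing by the interquartile range, which removes
subject- and sensor-gain effects without being dragged by movement
artifacts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from sklearn.base import BaseEstimator, TransformerMixin

from .types import EPOCH_SECONDS, FeatureMatrix, SignalRecord

logger = logging.getLogger(__name__)

__all__ = [
    "FEATURE_NAMES",
    "BreathList",
    "detect_breaths",
    "extract_epoch_features",
    "robust_normalize",
    "make_windows",
    "StudyNormalizer",
    "WINDOW_PAST",
    "WINDOW_FUTURE",
    "WINDOW_LENGTH",
]

#: Model input window: 22 past epochs, the current epoch, 2 future epochs.
WINDOW_PAST = 22
WINDOW_FUTURE = 2
WINDOW_LENGTH = WINDOW_PAST + 1 + WINDOW_FUTURE  # 25

#: The fixed 14-column feature schema, in column order.  Respiratory rate is
#: derived from detected breaths (60 / mean breath duration), so a separate
#: mean-duration column would be redundant and is not included.
FEATURE_NAMES: tuple[str, ...] = (
    "thorax_breath_amp_mean",
    "thorax_breath_amp_sd",
    "thorax_signal_sd",
    "thorax_amp_change",
    "abdomen_breath_amp_mean",
    "abdomen_breath_amp_sd",
    "abdomen_signal_sd",
    "abdomen_amp_change",
    "thorabd_correlation",
    "breath_duration_sd",
    "respiratory_rate",
    "activity_mean",
    "activity_sd",
    "activity_max",
)

# Breath-detection constants: respiratory band, minimum breath spacing, and
# peak prominence relative to the signal's robust range.
_BAND_HZ = (0.1, 0.7)
_MIN_BREATH_SPACING_S = 1.5
_PROMINENCE_FRACTION = 0.10


@dataclass
class BreathList:
    """Detected breaths: peak times (s), peak-to-trough amplitudes, and
    peak-to-peak durations (s).  Times are strictly increasing."""

    peak_times: np.ndarray
    amplitudes: np.ndarray
    durations: np.ndarray

    def __post_init__(self) -> None:
        self.peak_times = np.asarray(self.peak_times, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        self.durations = np.asarray(self.durations, dtype=float)
        if not (len(self.peak_times) == len(self.amplitudes) == len(self.durations)):
            raise ValueError("breath arrays must have equal length")
        if len(self.peak_times) > 1 and np.any(np.diff(self.peak_times) <= 0):
            raise ValueError("breath peak times must be strictly increasing")
        if np.any(self.durations <= 0) or np.any(self.amplitudes < 0):
            raise ValueError("breath durations must be positive, amplitudes >= 0")

    def __len__(self) -> int:
        return len(self.peak_times)


def _empty_breaths() -> BreathList:
    return BreathList(np.empty(0), np.empty(0), np.empty(0))


def detect_breaths(signal: np.ndarray, sample_rate: float) -> BreathList:
    """Detect respiratory cycles in a RIP signal.

    The signal is band-passed to the respiratory band (0.1-0.7 Hz, zero
    phase) and inspiratory peaks are picked with a minimum spacing of 1.5 s
    and a prominence of at least 10% of the filtered signal's robust
    (1st-99th percentile) range.  Breath amplitude is peak minus the
    preceding trough; breath duration is the peak-to-peak interval (the
    first breath copies the first interval).
    """
    x = np.asarray(signal, dtype=float)
    if sample_rate <= 0:
        raise ValueError("sample_rate must be positive")
    if x.ndim != 1:
        raise ValueError("signal must be 1-D")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite samples")
    if len(x) < 2.0 * sample_rate:  # shorter than one plausible breath
        return _empty_breaths()

    nyq = sample_rate / 2.0
    hi = min(_BAND_HZ[1], 0.95 * nyq)
    sos = sps.butter(2, [_BAND_HZ[0], hi], btype="band", fs=sample_rate,
                     output="sos")
    filt = sps.sosfiltfilt(sos, x)

    lo_p, hi_p = np.percentile(filt, [1, 99])
    global_range = hi_p - lo_p
    if global_range <= 0:
        return _empty_breaths()

    # The prominence threshold adapts per 30-s segment (10% of the
    # segment's robust range) so breaths survive strong slow amplitude
    # modulation; a global floor keeps near-flat segments from promoting
    # noise wiggles to breaths.
    min_dist = max(int(_MIN_BREATH_SPACING_S * sample_rate), 1)
    seg_len = int(round(30.0 * sample_rate))
    margin = int(round(3.0 * sample_rate))
    floor = 0.02 * global_range
    candidates: list[int] = []
    for start in range(0, len(filt), seg_len):
        stop = min(start + seg_len, len(filt))
        a, b = max(0, start - margin), min(len(filt), stop + margin)
        seg = filt[a:b]
        lo_s, hi_s = np.percentile(seg, [1, 99])
        prom = max(_PROMINENCE_FRACTION * (hi_s - lo_s), floor)
        pk, _ = sps.find_peaks(seg, distance=min_dist, prominence=prom)
        pk = pk + a
        candidates.extend(int(p) for p in pk if start <= p < stop)
    if not candidates:
        return _empty_breaths()
    # re-enforce minimum spacing across segment boundaries
    candidates.sort()
    peaks = [candidates[0]]
    for p in candidates[1:]:
        if p - peaks[-1] >= min_dist:
            peaks.append(p)
        elif filt[p] > filt[peaks[-1]]:
            peaks[-1] = p
    peaks = np.asarray(peaks)

    amplitudes = np.empty(len(peaks))
    for k, p in enumerate(peaks):
        start = peaks[k - 1] if k > 0 else 0
        trough = filt[start:p + 1].min()
        amplitudes[k] = filt[p] - trough
    times = peaks / sample_rate
    if len(peaks) > 1:
        intervals = np.diff(times)
        durations = np.concatenate([[intervals[0]], intervals])
    else:
        durations = np.array([len(x) / sample_rate])
    return BreathList(times, np.maximum(amplitudes, 0.0), durations)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def extract_epoch_features(
    record: SignalRecord, epoch_duration: float = EPOCH_SECONDS
) -> FeatureMatrix:
    """Compute the 14-feature schema for every complete epoch of a record.

    Breaths are detected once per belt over the full recording and assigned
    to epochs by peak time.  Epochs with no detected breaths (apneic or
    flat) get zero for the breath-derived features; the per-study
    normalization later turns that zero into an informative low value.
    A trailing partial epoch is dropped.
    """
    fs = record.sample_rate
    spe = int(round(epoch_duration * fs))
    n_epochs = len(record.thorax) // spe
    if n_epochs == 0:
        return FeatureMatrix(np.empty((0, len(FEATURE_NAMES))), FEATURE_NAMES)

    breaths = {
        "thorax": detect_breaths(record.thorax, fs),
        "abdomen": detect_breaths(record.abdomen, fs),
    }
    epoch_of = {
        belt: np.minimum(
            (bl.peak_times // epoch_duration).astype(int), n_epochs - 1
        )
        for belt, bl in breaths.items()
    }

    values = np.zeros((n_epochs, len(FEATURE_NAMES)))
    col = {name: i for i, name in enumerate(FEATURE_NAMES)}
    n_empty = 0

    for e in range(n_epochs):
        sl = slice(e * spe, (e + 1) * spe)
        th, ab, ac = record.thorax[sl], record.abdomen[sl], record.activity[sl]

        for belt, seg in (("thorax", th), ("abdomen", ab)):
            bl = breaths[belt]
            in_epoch = epoch_of[belt] == e
            amps = bl.amplitudes[in_epoch]
            if len(amps):
                values[e, col[f"{belt}_breath_amp_mean"]] = amps.mean()
                values[e, col[f"{belt}_breath_amp_sd"]] = amps.std()
            else:
                n_empty += 1
            values[e, col[f"{belt}_signal_sd"]] = seg.std()

        values[e, col["thorabd_correlation"]] = _pearson(th, ab)

        bl = breaths["thorax"]
        in_epoch = epoch_of["thorax"] == e
        durs = bl.durations[in_epoch]
        if len(durs):
            values[e, col["breath_duration_sd"]] = durs.std()
            values[e, col["respiratory_rate"]] = 60.0 / durs.mean()

        values[e, col["activity_mean"]] = ac.mean()
        values[e, col["activity_sd"]] = ac.std()
        values[e, col["activity_max"]] = ac.max()

    # amplitude change vs previous epoch (first epoch: 0 by convention)
    for belt in ("thorax", "abdomen"):
        mean_col = values[:, col[f"{belt}_breath_amp_mean"]]
        change = np.zeros(n_epochs)
        if n_epochs > 1:
            change[1:] = np.abs(np.diff(mean_col))
        values[:, col[f"{belt}_amp_change"]] = change

    if n_empty:
        logger.warning(
            "%d epoch/belt segments had no detected breaths; "
            "breath-derived features set to 0", n_empty,
        )
    return FeatureMatrix(values, FEATURE_NAMES)


def robust_normalize(features: FeatureMatrix) -> FeatureMatrix:
    """Per-study robust scaling: ``x' = (x - median(x)) / IQR(x)`` per column.

    Quartiles use linear interpolation; a column with IQR = 0 is centered
    and left at zero (divide by 1) so the output stays finite.  Applying
    this twice is a contract violation and raises.
    """
    if features.normalized:
        raise ValueError("FeatureMatrix is already normalized")
    if features.n_epochs < 2:
        raise ValueError("need >= 2 epochs to normalize")
    x = features.values
    q1, med, q3 = np.percentile(x, [25, 50, 75], axis=0)
    iqr = q3 - q1
    scale = np.where(iqr > 0, iqr, 1.0)
    return FeatureMatrix(
        (x - med) / scale, features.feature_names,
        epoch_duration=features.epoch_duration, normalized=True,
    )


def make_windows(features: FeatureMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Build the model's 25-step input windows, one per epoch.

    The window for target epoch ``i`` covers epochs ``[i-22, i+2]``
    inclusive, with the target at (1-based) position 23.  Record edges are
    replicate-padded (indices clipped to ``[0, n-1]``) so that every epoch
    receives exactly one prediction.

    Returns
    -------
    windows : (n_epochs, 25, n_features) ndarray
    target_indices : (n_epochs,) ndarray
    """
    n = features.n_epochs
    if n == 0:
        return (np.empty((0, WINDOW_LENGTH, features.n_features)),
                np.empty(0, dtype=int))
    offsets = np.arange(-WINDOW_PAST, WINDOW_FUTURE + 1)
    idx = np.clip(np.arange(n)[:, None] + offsets[None, :], 0, n - 1)
    return features.values[idx], np.arange(n)


class StudyNormalizer(TransformerMixin, BaseEstimator):
    """Scikit-learn transformer applying per-study median/IQR scaling.

    Unlike a train-time-fitted scaler, the statistics are recomputed from
    each study passed to :meth:`transform` — the normalization is a
    per-recording operation, mirroring how the staging pipeline is applied
    to a single night at a time.  ``fit`` is a no-op kept for pipeline
    compatibility.
    """

    def fit(self, X, y=None):  # noqa: D102 - sklearn signature
        self.n_features_in_ = np.asarray(X).shape[1]
        return self

    def transform(self, X):
        """Scale each column of ``X`` by its own median and IQR."""
        x = np.asarray(X, dtype=float)
        q1, med, q3 = np.percentile(x, [25, 50, 75], axis=0)
        iqr = q3 - q1
        return (x - med) / np.where(iqr > 0, iqr, 1.0)
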