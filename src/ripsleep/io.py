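"""Readers, writers and the end-to-end pipeline runner.

Signals travel as EDF (European Data Format), hypnograms/events/features as
CSV, reports and model metadata as JSON.  EDF reading goes through MNE;
writing uses a minimal self-contained EDF encoder (16-bit samples, 1-s data
records) because no installed library exposes an EDF writer.

Channel naming in real-world EDFs varies between devices, so the reader
takes a channel map (defaults: ``Thorax``, ``Abdomen``, ``Activity``)
matched case-insensitively against the file's labels.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .types import (
    EPOCH_SECONDS,
    FeatureMatrix,
    RespiratoryEvent,
    RespiratoryEventList,
    SignalRecord,
    as_hypnogram,
)

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_CHANNEL_MAP",
    "write_edf",
    "read_edf",
    "write_hypnogram",
    "read_hypnogram",
    "write_events",
    "read_events",
    "write_features",
    "read_features",
    "run_pipeline",
]

DEFAULT_CHANNEL_MAP = {
    "thorax": "Thorax",
    "abdomen": "Abdomen",
    "activity": "Activity",
}


# --------------------------------------------------------------------------
# EDF
# --------------------------------------------------------------------------

def _edf_field(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def _phys_str(v: float) -> str:
    """Shortest decimal representation of ``v`` fitting EDF's 8-char field."""
    for prec in (7, 6, 5, 4, 3, 2, 1):
        s = f"{v:.{prec}g}"
        if len(s) <= 8:
            return s
    raise ValueError(f"cannot encode physical bound {v!r} in 8 characters")


def write_edf(path: str | Path, record: SignalRecord,
              channel_map: dict[str, str] | None = None) -> None:
    """Write a :class:`SignalRecord` as a 3-channel EDF file.

    Samples are quantized to 16 bits over each channel's physical range
    (EDF's native resolution); data records are 1 s long, so the sample
    rate must be a whole number of Hz.  A trailing partial record is
    dropped.
    """
    cm = channel_map or DEFAULT_CHANNEL_MAP
    fs = record.sample_rate
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sample rate (1-s records)")
    fs = int(round(fs))
    channels = [
        (cm["thorax"], record.thorax),
        (cm["abdomen"], record.abdomen),
        (cm["activity"], record.activity),
    ]
    n_records = len(record.thorax) // fs
    ns = len(channels)

    header = b"".join([
        _edf_field("0", 8),
        _edf_field(record.subject_id or "X X X X", 80),
        _edf_field("Startdate 01-JAN-2000 X X X", 80),
        _edf_field("01.01.00", 8),
        _edf_field("00.00.00", 8),
        _edf_field(256 * (1 + ns), 8),
        _edf_field("", 44),
        _edf_field(n_records, 8),
        _edf_field(1, 8),
        _edf_field(ns, 4),
    ])

    # The header stores the physical range as 8-char decimal strings; use the
    # parsed-back values for quantization so a reader reconstructs exactly.
    phys, phys_s = [], []
    for _, x in channels:
        lo0, hi0 = float(np.min(x)), float(np.max(x))
        pad = 1e-3 * (hi0 - lo0) if hi0 > lo0 else 0.5
        lo_s, hi_s = _phys_str(lo0 - pad), _phys_str(hi0 + pad)
        lo, hi = float(lo_s), float(hi_s)
        if hi <= lo:
            hi_s = _phys_str(lo + 1.0)
            hi = float(hi_s)
        phys.append((lo, hi))
        phys_s.append((lo_s, hi_s))

    fields = []
    fields.append(b"".join(_edf_field(name, 16) for name, _ in channels))
    fields.append(b"".join(_edf_field("RIP belt" if "activ" not in name.lower()
                                      else "accelerometer", 80)
                           for name, _ in channels))
    fields.append(b"".join(_edf_field("au", 8) for _ in channels))
    fields.append(b"".join(_edf_field(lo_s, 8) for lo_s, _ in phys_s))
    fields.append(b"".join(_edf_field(hi_s, 8) for _, hi_s in phys_s))
    fields.append(b"".join(_edf_field(-32768, 8) for _ in channels))
    fields.append(b"".join(_edf_field(32767, 8) for _ in channels))
    fields.append(b"".join(_edf_field("", 80) for _ in channels))
    fields.append(b"".join(_edf_field(fs, 8) for _ in channels))
    fields.append(b"".join(_edf_field("", 32) for _ in channels))
    sig_header = b"".join(fields)

    digital = []
    for (_, x), (lo, hi) in zip(channels, phys):
        scaled = (x[: n_records * fs] - lo) / (hi - lo) * 65535.0 - 32768.0
        digital.append(np.clip(np.round(scaled), -32768, 32767).astype("<i2"))

    with open(path, "wb") as f:
        f.write(header)
        f.write(sig_header)
        for r in range(n_records):
            for d in digital:
                f.write(d[r * fs:(r + 1) * fs].tobytes())


def read_edf(path: str | Path,
             channel_map: dict[str, str] | None = None) -> SignalRecord:
    """Read thoracic RIP, abdominal RIP and activity channels from an EDF.

    Channels are located via ``channel_map`` (case-insensitive label
    match).  Channels recorded at different rates are returned on the
    file's highest sampling rate (lower-rate channels are upsampled by the
    reader).  A missing mapped channel raises with the file's available
    labels listed.
    """
    import mne

    cm = channel_map or DEFAULT_CHANNEL_MAP
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    labels = {name.lower(): name for name in raw.ch_names}
    picked = {}
    for key in ("thorax", "abdomen", "activity"):
        want = cm[key].lower()
        if want not in labels:
            raise ValueError(
                f"channel {cm[key]!r} (for {key}) not found in {path}; "
                f"available channels: {raw.ch_names}"
            )
        picked[key] = raw.get_data(picks=[labels[want]])[0]
    return SignalRecord(
        thorax=picked["thorax"],
        abdomen=picked["abdomen"],
        activity=picked["activity"],
        sample_rate=float(raw.info["sfreq"]),
        subject_id=Path(path).stem,
    )


# --------------------------------------------------------------------------
# CSV formats
# --------------------------------------------------------------------------

def write_hypnogram(hypnogram, path: str | Path) -> None:
    """Write a hypnogram as CSV with columns ``epoch_index,label``."""
    hyp = as_hypnogram(hypnogram)
    pd.DataFrame({"epoch_index": np.arange(len(hyp)), "label": hyp}).to_csv(
        path, index=False
    )


def read_hypnogram(path: str | Path) -> np.ndarray:
    """Read a hypnogram CSV; labels are case-insensitive, epoch indices
    must be contiguous from 0."""
    df = pd.read_csv(path)
    if not {"epoch_index", "label"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns epoch_index,label")
    idx = df["epoch_index"].to_numpy()
    expected = np.arange(len(df))
    if not np.array_equal(idx, expected):
        bad = int(np.flatnonzero(idx != expected)[0])
        raise ValueError(
            f"{path}: epoch_index not contiguous at row {bad} "
            f"(line {bad + 2}): got {idx[bad]}, expected {expected[bad]}"
        )
    try:
        return as_hypnogram(df["label"])
    except ValueError as exc:
        for i, lab in enumerate(df["label"]):
            if str(lab).upper() not in ("WAKE", "REM", "NREM"):
                raise ValueError(
                    f"{path}, line {i + 2}: unknown label {lab!r}"
                ) from exc
        raise


def write_events(events: RespiratoryEventList, path: str | Path) -> None:
    """Write events as CSV ``start_s,duration_s,type`` plus an
    ``analysis_duration_s`` column (constant)."""
    pd.DataFrame({
        "start_s": [e.start for e in events],
        "duration_s": [e.duration for e in events],
        "type": [e.kind for e in events],
        "analysis_duration_s": [events.analysis_duration] * len(events),
    }).to_csv(path, index=False)


def read_events(path: str | Path,
                analysis_duration: float | None = None) -> RespiratoryEventList:
    df = pd.read_csv(path)
    evs = [
        RespiratoryEvent(float(r.start_s), float(r.duration_s), str(r.type))
        for r in df.itertuples()
    ]
    if analysis_duration is None:
        if len(df) and "analysis_duration_s" in df.columns:
            analysis_duration = float(df["analysis_duration_s"].iloc[0])
        else:
            analysis_duration = max((e.end for e in evs), default=0.0)
    return RespiratoryEventList(evs, analysis_duration)


def write_features(features: FeatureMatrix, path: str | Path) -> None:
    """Write a feature matrix as CSV with a feature-name header row."""
    pd.DataFrame(features.values, columns=list(features.feature_names)).to_csv(
        path, index=False
    )


def read_features(path: str | Path, normalized: bool = False) -> FeatureMatrix:
    df = pd.read_csv(path)
    return FeatureMatrix(df.to_numpy(dtype=float), tuple(df.columns),
                         normalized=normalized)


# --------------------------------------------------------------------------
# pipeline
# --------------------------------------------------------------------------

def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _schema_hash(names) -> str:
    return hashlib.sha256("|".join(names).encode()).hexdigest()[:16]


def run_pipeline(config: dict, out_dir: str | Path | None = None) -> Path:
    """Run simulate -> featurize -> train -> predict -> evaluate.

    ``config`` is a plain dict (usually loaded from YAML)::

        seed: 7                      # mandatory; drives every stage
        out: runs/demo               # output directory
        cohort:
          n_subjects: 10
          n_epochs: 240
          ahi_range: [0, 40]
          sample_rate: 25
        split:
          n_test: 3                  # held-out subjects (taken from the end)
        model:
          training_epochs: 5
          n_folds: 5

    Each stage writes its outputs under ``out`` and is skipped when they
    already exist, so a run is resumable from on-disk intermediates.
    Stage durations, seeds, the config hash and the feature-schema hash
    are appended to ``out/pipeline.log``.  Returns the path to
    ``report.json``.
    """
    from .evaluation import evaluate_cohort
    from .features import extract_epoch_features
    from .model import SleepStageClassifier, TrainedModel, predict_hypnogram
    from .simulate import SyntheticStudyConfig, generate_cohort

    if "seed" not in config:
        raise ValueError("pipeline config must specify a seed")
    seed = int(config["seed"])
    out = Path(out_dir or config.get("out", "ripsleep_run"))
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "pipeline.log"
    chash = _config_hash(config)

    def log_stage(stage: str, t0: float, **extra) -> None:
        entry = {"stage": stage, "seconds": round(time.time() - t0, 3),
                 "seed": seed, "config_hash": chash, **extra}
        with open(log_path, "a") as f:
            f.write(json.dumps(entry) + "\n")
        logger.info("pipeline stage %s done in %.1f s", stage, entry["seconds"])

    cohort_cfg = config.get("cohort", {})
    n_subjects = int(cohort_cfg.get("n_subjects", 10))
    n_epochs = int(cohort_cfg.get("n_epochs", 240))
    ahi_range = tuple(cohort_cfg.get("ahi_range", (0.0, 40.0)))
    sample_rate = float(cohort_cfg.get("sample_rate", 25.0))
    n_test = int(config.get("split", {}).get("n_test", max(1, n_subjects // 5)))
    if n_test >= n_subjects:
        raise ValueError("split.n_test must leave at least one training subject")

    subj_ids = [f"S{i:03d}" for i in range(n_subjects)]
    sig_dir, hyp_dir = out / "signals", out / "hypnograms"
    ev_dir, feat_dir = out / "events", out / "features"
    pred_dir = out / "predictions"
    for d in (sig_dir, hyp_dir, ev_dir, feat_dir, pred_dir):
        d.mkdir(exist_ok=True)

    # ---- simulate ----
    t0 = time.time()
    if not all((sig_dir / f"{s}.edf").exists() for s in subj_ids):
        try:
            base = SyntheticStudyConfig(
                n_epochs=n_epochs, sample_rate=sample_rate, seed=seed
            )
            cohort = generate_cohort(n_subjects, ahi_range, base, seed=seed)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage 'simulate' failed: {exc}") from exc
        for sid, (record, hyp, events) in zip(subj_ids, cohort):
            write_edf(sig_dir / f"{sid}.edf", record)
            write_hypnogram(hyp, hyp_dir / f"{sid}.csv")
            write_events(events, ev_dir / f"{sid}.csv")
        log_stage("simulate", t0, n_subjects=n_subjects)

    # ---- featurize ----
    t0 = time.time()
    if not all((feat_dir / f"{s}.csv").exists() for s in subj_ids):
        for sid in subj_ids:
            try:
                record = read_edf(sig_dir / f"{sid}.edf")
                fm = extract_epoch_features(record)
            except Exception as exc:
                raise RuntimeError(
                    f"pipeline stage 'featurize' failed on {sid}: {exc}"
                ) from exc
            write_features(fm, feat_dir / f"{sid}.csv")
        log_stage("featurize", t0)

    train_ids = subj_ids[: n_subjects - n_test]
    test_ids = subj_ids[n_subjects - n_test:]

    # ---- train ----
    model_path = out / "model.zip"
    t0 = time.time()
    if not model_path.exists():
        model_cfg = dict(config.get("model", {}))
        model_cfg.setdefault("seed", seed)
        clf = SleepStageClassifier(**model_cfg)
        feats = [read_features(feat_dir / f"{s}.csv") for s in train_ids]
        hyps = [read_hypnogram(hyp_dir / f"{s}.csv") for s in train_ids]
        try:
            clf.fit(feats, hyps)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage 'train' failed: {exc}") from exc
        clf.model_.save(model_path)
        log_stage("train", t0,
                  schema_hash=_schema_hash(clf.model_.feature_schema),
                  best_val_kappa=clf.cv_log_["best_val_kappa"])

    # ---- predict ----
    t0 = time.time()
    model = TrainedModel.load(model_path)
    if not all((pred_dir / f"{s}.csv").exists() for s in test_ids):
        from .features import robust_normalize

        for sid in test_ids:
            fm = read_features(feat_dir / f"{sid}.csv")
            if _schema_hash(fm.feature_names) != _schema_hash(model.feature_schema):
                raise RuntimeError(
                    f"pipeline stage 'predict' failed on {sid}: feature-schema "
                    "hash mismatch between stored features and model"
                )
            try:
                labels, _ = predict_hypnogram(model, robust_normalize(fm))
            except Exception as exc:
                raise RuntimeError(
                    f"pipeline stage 'predict' failed on {sid}: {exc}"
                ) from exc
            write_hypnogram(labels, pred_dir / f"{sid}.csv")
        log_stage("predict", t0,
                  schema_hash=_schema_hash(model.feature_schema))

    # ---- evaluate ----
    t0 = time.time()
    report_path = out / "report.json"
    cohort_eval = []
    for sid in test_ids:
        ref = read_hypnogram(hyp_dir / f"{sid}.csv")
        pred = read_hypnogram(pred_dir / f"{sid}.csv")
        events = read_events(ev_dir / f"{sid}.csv",
                             analysis_duration=len(ref) * EPOCH_SECONDS)
        duration_min = len(ref) * EPOCH_SECONDS / 60.0
        cohort_eval.append((ref, pred, events, duration_min))
    try:
        report = evaluate_cohort(cohort_eval)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'evaluate' failed: {exc}") from exc
    with open(report_path, "w") as f:
        json.dump(report.to_dict(), f, indent=1, sort_keys=True)
    log_stage("evaluate", t0, n_test=len(test_ids))
    return report_path


def load_config(path: str | Path) -> dict:
    """Load a YAML pipeline configuration."""
    with open(path) as f:
        return yaml.safe_load(f)
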