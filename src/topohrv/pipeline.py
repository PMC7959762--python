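"""End-to-end orchestration: recordings -> windows -> features -> model -> report.

A *recording* is a (subject_id, R-peak times, per-epoch labels) triple.  The
pipeline cleans the beat train, interpolates the IHR, cuts labeled windows,
extracts the 48 persistence statistics per window, balances and trains the
linear SVM on the training recordings, predicts every testing epoch, and
reports the full metric suite (per-class, pooled, per-subject mean +/- sd).
Every artifact carries the configuration for provenance.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import joblib
import numpy as np
import pandas as pd

from .classify import SleepStageClassifier, class_order, task_labels
from .config import PipelineConfig
from .features import FEATURE_NAMES, epoch_features
from .metrics import per_subject_report
from .preprocessing import clean_rpeaks, compute_ihr, extract_windows

logger = logging.getLogger(__name__)

__all__ = [
    "compute_feature_frame",
    "run_pipeline",
    "save_model",
    "load_model",
    "write_features_csv",
    "read_features_csv",
]

_META_COLUMNS = ["subject_id", "epoch_index", "label"]


def compute_feature_frame(recordings, config: PipelineConfig) -> pd.DataFrame:
    """Feature rows (subject, epoch, label + 48 statistics) for recordings."""
    config.validate()
    rows = []
    for subject_id, times, labels in recordings:
        cleaned = clean_rpeaks(
            times, low_ratio=config.median_filter_low,
            high_ratio=config.median_filter_high)
        series = compute_ihr(cleaned, sample_rate=config.sample_rate)
        windows = extract_windows(
            series, labels, cleaned,
            epoch_seconds=config.epoch_seconds,
            window_epochs=config.window_epochs,
            min_beats_per_epoch=config.min_beats_per_epoch,
            subject_id=str(subject_id))
        for w in windows:
            feats = epoch_features(
                w.values, p=config.takens_p, tau=config.takens_tau,
                max_scale=config.vr_max_scale)
            rows.append([w.subject_id, w.epoch_index, w.label, *feats])
        logger.info("subject %s: %d feature rows", subject_id, len(windows))
    return pd.DataFrame(rows, columns=_META_COLUMNS + FEATURE_NAMES)


def _frame_to_task(frame: pd.DataFrame, task: str):
    y, mask = task_labels(frame["label"].to_numpy(), task)
    sub = frame.loc[mask]
    X = sub[FEATURE_NAMES].to_numpy(dtype=float)
    subjects = sub["subject_id"].to_numpy()
    return X, y, subjects


def run_pipeline(config: PipelineConfig, train_recordings, test_recordings,
                 out_dir=None) -> dict:
    """Train on one set of recordings, evaluate on another.

    Returns a report dict with the trained model, feature frames, and the
    full metric suite on the test set; when ``out_dir`` is given, the
    feature tables, model and JSON report are written there with the
    configuration embedded.
    """
    config.validate()
    train_frame = compute_feature_frame(train_recordings, config)
    test_frame = compute_feature_frame(test_recordings, config)
    if train_frame.empty or test_frame.empty:
        raise ValueError("pipeline produced no analysis windows for "
                         f"{'training' if train_frame.empty else 'testing'}")
    X_train, y_train, _ = _frame_to_task(train_frame, config.task)
    X_test, y_test, subj_test = _frame_to_task(test_frame, config.task)

    model = SleepStageClassifier(
        C=config.svm_c, balance=True, random_state=config.seed,
        standardize=config.standardize_features)
    model.fit(X_train, y_train)
    y_pred = model.predict(X_test)
    order = class_order(config.task)
    scores = model.decision_function(X_test) if len(order) == 2 else None
    report = per_subject_report(subj_test, y_test, y_pred, order,
                                scores=scores)
    report["config"] = config.to_dict()
    report["n_train_rows"] = int(len(y_train))
    report["n_train_balanced"] = int(len(model.balanced_indices_))
    report["n_test_rows"] = int(len(y_test))

    result = {
        "report": report,
        "model": model,
        "train_features": train_frame,
        "test_features": test_frame,
        "predictions": y_pred,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_features_csv(out / "train_features.csv", train_frame, config)
        write_features_csv(out / "test_features.csv", test_frame, config)
        save_model(out / "model.joblib", model, config)
        serializable = {k: v for k, v in report.items()}
        with open(out / "report.json", "w") as fh:
            json.dump(serializable, fh, indent=2, default=_jsonify)
            fh.write("\n")
        logger.info("pipeline artifacts written to %s", out)
    return result


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


# ---------------------------------------------------------------------------
# Artifact I/O
# ---------------------------------------------------------------------------

def write_features_csv(path, frame: pd.DataFrame,
                       config: PipelineConfig | None = None) -> None:
    """Feature table as CSV; the config travels in a JSON comment header."""
    with open(path, "w", newline="") as fh:
        if config is not None:
            fh.write("# config: " + json.dumps(config.to_dict()) + "\n")
        frame.to_csv(fh, index=False)


def read_features_csv(path) -> tuple[pd.DataFrame, PipelineConfig | None]:
    with open(path) as fh:
        first = fh.readline()
        config = None
        if first.startswith("# config: "):
            config = PipelineConfig.from_dict(
                json.loads(first[len("# config: "):]))
        else:
            fh.seek(0)
        frame = pd.read_csv(fh, float_precision="round_trip")
    return frame, config


def save_model(path, model: SleepStageClassifier,
               config: PipelineConfig) -> None:
    joblib.dump({"format_version": 1, "model": model,
                 "config": config.to_dict()}, path)


def load_model(path) -> tuple[SleepStageClassifier, PipelineConfig]:
    payload = joblib.load(path)
    if payload.get("format_version") != 1:
        raise ValueError("unrecognized model file format")
    return payload["model"], PipelineConfig.from_dict(payload["config"])
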