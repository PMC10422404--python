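"""Read/write the tabular session-log format.

One session is one wide CSV (columns exactly :data:`gazeload.types.SAMPLE_COLUMNS`,
one row per sample, trials concatenated in order) plus a YAML sidecar
``<name>.meta.yaml`` holding participant/condition metadata and the per-trial
row counts.  Optional 3D fields are empty cells, never zero vectors.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .types import (
    SAMPLE_COLUMNS,
    SchemaError,
    SessionLog,
    Trial,
    ValidationError,
    validate_session,
)

_FLOAT_FORMAT = "%.12g"


def sidecar_path(path: str | Path) -> Path:
    path = Path(path)
    return path.with_suffix(path.suffix + ".meta.yaml") if path.suffix != ".csv" \
        else path.with_name(path.stem + ".meta.yaml")


def write_session_log(log: SessionLog, path: str | Path) -> Path:
    """Serialize a session to CSV + YAML sidecar; returns the CSV path."""
    if not log.trials:
        raise ValidationError("nothing to write: session has no trials")
    validate_session(log)
    path = Path(path)
    frames = []
    trial_meta = []
    for trial in log.trials:
        frames.append(trial.samples[SAMPLE_COLUMNS])
        trial_meta.append(
            {
                "condition": trial.condition,
                "n_samples": int(trial.n_samples),
                "presentation_index": trial.presentation_index,
            }
        )
    pd.concat(frames, ignore_index=True).to_csv(
        path, index=False, float_format=_FLOAT_FORMAT
    )
    meta = {
        "participant_id": log.participant_id,
        "trials": trial_meta,
        **log.metadata,
    }
    with open(sidecar_path(path), "w", encoding="utf-8") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)
    return path


def read_session_log(path: str | Path, dialect: dict | None = None) -> SessionLog:
    """Parse and validate a session CSV written by :func:`write_session_log`.

    Rows with unparseable numerics are rejected (a :class:`SchemaError`), the
    ``-1`` pupil sentinel is preserved untouched, and no interpolation or any
    other transformation happens at read time.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype={"target_label": "string"})
    missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    extra = [c for c in df.columns if c not in SAMPLE_COLUMNS]
    if extra:
        raise SchemaError(f"unexpected column(s): {', '.join(extra)}")
    numeric = [c for c in SAMPLE_COLUMNS if c != "target_label"]
    for col in numeric:
        try:
            df[col] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"unparseable numeric value in column {col}") from exc
    df["target_label"] = df["target_label"].fillna("").astype(str)

    meta_file = sidecar_path(path)
    if not meta_file.exists():
        raise SchemaError(f"missing sidecar metadata file {meta_file.name}")
    with open(meta_file, encoding="utf-8") as fh:
        meta = yaml.safe_load(fh)
    participant = str(meta["participant_id"])
    trials = []
    offset = 0
    for entry in meta["trials"]:
        n = int(entry["n_samples"])
        chunk = df.iloc[offset : offset + n].reset_index(drop=True)
        if len(chunk) != n:
            raise SchemaError(
                f"sidecar declares {n} samples for {entry['condition']} but the "
                f"CSV has only {len(chunk)} rows left"
            )
        pres = entry.get("presentation_index")
        trials.append(
            Trial(
                participant_id=participant,
                condition=str(entry["condition"]),
                samples=chunk,
                presentation_index=None if pres is None else int(pres),
            )
        )
        offset += n
    if offset != len(df):
        raise SchemaError(
            f"CSV has {len(df) - offset} trailing rows not covered by the sidecar"
        )
    extra_meta = {k: v for k, v in meta.items() if k not in ("participant_id", "trials")}
    log = SessionLog(participant_id=participant, trials=trials, metadata=extra_meta)
    validate_session(log)
    return log


def estimate_sample_rate(trial: Trial) -> tuple[float, float]:
    """Mean and SD (ddof=1) of the instantaneous sample rate 1/dt in Hz."""
    t = trial.times
    if len(t) < 3:
        raise ValidationError("need at least 3 samples to estimate a sample rate")
    dt = np.diff(t)
    if np.any(dt == 0):
        raise ValidationError("duplicate timestamps")
    rates = 1.0 / dt
    return float(np.mean(rates)), float(np.std(rates, ddof=1))
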