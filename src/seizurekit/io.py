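"""CSV readers/writers for feature templates, cohorts and result tables.

All files are comma-delimited UTF-8 with Unix newlines and `.` decimals.
Floats are written at full repr precision so every written table re-reads
to an equal in-memory structure.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .features import FEATURE_NAMES, FeatureVector
from .knn import ConfusionMatrix, FeatureTemplate

TEMPLATE_COLUMNS = ("subject_id", *FEATURE_NAMES, "label", "normalized")


def _repr_float(x: float) -> str:
    return repr(float(x))


def _write_csv(df: pd.DataFrame, path: str | Path) -> None:
    # repr-precision floats so written values round-trip bit-exactly
    Path(path).write_text(
        df.to_csv(index=False, lineterminator="\n", float_format=_repr_float),
        encoding="utf-8",
    )


def write_feature_csv(vectors: Sequence[FeatureVector], path: str | Path) -> None:
    """Write feature vectors (a template body) as CSV."""
    df = pd.DataFrame(
        [
            {
                "subject_id": v.subject_id,
                **dict(zip(FEATURE_NAMES, v.values())),
                "label": "" if v.label is None else v.label,
                "normalized": v.normalized,
            }
            for v in vectors
        ],
        columns=list(TEMPLATE_COLUMNS),
    )
    _write_csv(df, path)


def read_feature_csv(path: str | Path) -> list[FeatureVector]:
    """Read feature vectors written by :func:`write_feature_csv`."""
    try:
        df = pd.read_csv(
            path, dtype={"subject_id": str, "label": str},
            float_precision="round_trip",
        )
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed CSV ({exc})") from exc
    missing = set(TEMPLATE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    vectors = []
    for _, row in df.iterrows():
        label = row["label"]
        if pd.isna(label) or label == "":
            label = None
        vectors.append(
            FeatureVector(
                **{name: float(row[name]) for name in FEATURE_NAMES},
                label=label,
                normalized=bool(row["normalized"]),
                subject_id="" if pd.isna(row["subject_id"]) else str(row["subject_id"]),
            )
        )
    return vectors


def write_template_csv(template: FeatureTemplate, path: str | Path) -> None:
    write_feature_csv(template.rows, path)


def read_template_csv(path: str | Path) -> FeatureTemplate:
    return FeatureTemplate(read_feature_csv(path))


def write_cohort_csv(cohort: pd.DataFrame, path: str | Path) -> None:
    """Write an (age, apen) cohort table."""
    _write_csv(cohort[["age", "apen"]], path)


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    if not {"age", "apen"} <= set(df.columns):
        raise ValueError(f"{path}: cohort CSV needs 'age,apen' columns")
    return df[["age", "apen"]].astype(float)


def write_confusion_csv(cm: ConfusionMatrix, path: str | Path) -> None:
    Path(path).write_text(cm.to_frame().to_csv(lineterminator="\n"), encoding="utf-8")


def write_predictions_csv(records: Sequence[dict], path: str | Path) -> None:
    """Predictions as `subject_id,predicted_label,rule,metric,k` rows."""
    df = pd.DataFrame(
        records, columns=["subject_id", "predicted_label", "rule", "metric", "k"]
    )
    _write_csv(df, path)
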