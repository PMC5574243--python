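"""End-to-end orchestration: extract -> normalize -> classify -> level-predict.

The pipeline mirrors the analysis flow: raw epochs are reduced to the
six-feature vectors, min-max normalized, classified against a labeled
training template with the k-NN classifier, and an age-vs-ApEn polynomial
level model is fitted to a cohort, order-selected, and error-analyzed.
Four artifacts are written: features.csv, predictions.csv, model.json and
error_table.csv. Runs are deterministic given the config, so repeated runs
produce byte-identical artifacts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

from .epochs import read_epoch_csv
from .features import ApEnConfig, extract_features, normalize_template
from .io import (
    read_cohort_csv,
    read_template_csv,
    write_feature_csv,
    write_predictions_csv,
    _write_csv,
)
from .knn import KnnConfig, classify
from .regression import (
    PolynomialModel,
    error_table,
    error_table_frame,
    fit_polynomial,
    select_order,
)

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    epochs_dir: str = ""
    template: str = ""
    cohort: str = ""
    out_dir: str = "out"
    apen_m: int = 2
    apen_r: float = 0.2
    apen_r_mode: str = "relative"
    rolloff_fraction: float = 0.85
    zc_threshold: float = 0.0
    k: int = 1
    metric: str = "euclidean"
    rule: str = "nearest_neighbour"
    seed: int = 0
    orders: tuple[int, ...] = (1, 2, 3, 4)
    log_level: str = "INFO"

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Parse a `key = value` config file; unknown keys are rejected."""
        known = {f.name: f.type for f in fields(cls)}
        kwargs = {}
        for lineno, raw in enumerate(
            Path(path).read_text(encoding="utf-8").splitlines(), start=1
        ):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, value = (part.strip() for part in line.split("=", 1))
            if key not in known:
                raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
            kwargs[key] = value
        cfg = cls()
        for key, value in kwargs.items():
            current = getattr(cfg, key)
            if key == "orders":
                setattr(cfg, key, tuple(int(v) for v in value.split(",")))
            elif isinstance(current, int):
                setattr(cfg, key, int(value))
            elif isinstance(current, float):
                setattr(cfg, key, float(value))
            else:
                setattr(cfg, key, value)
        return cfg

    def apen_config(self) -> ApEnConfig:
        return ApEnConfig(m=self.apen_m, r=self.apen_r, r_mode=self.apen_r_mode)

    def knn_config(self) -> KnnConfig:
        return KnnConfig(k=self.k, metric=self.metric, rule=self.rule, seed=self.seed)


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Execute the full analysis; returns the paths of the written artifacts.

    Raises FileNotFoundError / ValueError with a diagnostic naming the
    offending input on any failure.
    """
    logging.basicConfig(level=config.log_level)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    # 1. extract
    epochs_dir = Path(config.epochs_dir)
    if not epochs_dir.is_dir():
        raise FileNotFoundError(f"epochs_dir not found: {epochs_dir}")
    epoch_paths = sorted(epochs_dir.glob("*.csv"))
    if not epoch_paths:
        raise FileNotFoundError(f"no epoch CSVs in {epochs_dir}")
    epochs = [read_epoch_csv(p) for p in epoch_paths]
    vectors = [
        extract_features(
            e, config.apen_config(), config.rolloff_fraction, config.zc_threshold
        )
        for e in epochs
    ]
    log.info("extracted %d feature vectors", len(vectors))

    # 2. normalize
    normalized = normalize_template(vectors)
    artifacts["features"] = out_dir / "features.csv"
    write_feature_csv(normalized, artifacts["features"])

    # 3. classify against the training template
    template_path = Path(config.template)
    if not template_path.is_file():
        raise FileNotFoundError(f"template not found: {template_path}")
    template = read_template_csv(template_path)
    knn_cfg = config.knn_config()
    records = [
        {
            "subject_id": v.subject_id,
            "predicted_label": classify(v, template, knn_cfg),
            "rule": knn_cfg.rule,
            "metric": knn_cfg.metric,
            "k": knn_cfg.k,
        }
        for v in normalized
    ]
    artifacts["predictions"] = out_dir / "predictions.csv"
    write_predictions_csv(records, artifacts["predictions"])
    log.info("classified %d epochs", len(records))

    # 4. level model: fit candidate orders, select, error-analyze
    cohort_path = Path(config.cohort)
    if not cohort_path.is_file():
        raise FileNotFoundError(f"cohort not found: {cohort_path}")
    cohort = read_cohort_csv(cohort_path)
    best_order = select_order(
        config.orders, cohort["age"], cohort["apen"], seed=config.seed
    )
    best = fit_polynomial(cohort["age"], cohort["apen"], best_order)
    artifacts["model"] = out_dir / "model.json"
    best.to_json(artifacts["model"])
    models = [
        PolynomialModel(
            fit_polynomial(cohort["age"], cohort["apen"], k).coefficients,
            source=f"fitted_order{k}",
        )
        for k in config.orders
    ]
    reports = error_table(models, list(zip(cohort["age"], cohort["apen"])))
    artifacts["error_table"] = out_dir / "error_table.csv"
    _write_csv(error_table_frame(reports), artifacts["error_table"])
    log.info(
        "level model: selected order %d over %d cohort rows",
        best_order, len(cohort),
    )
    return artifacts
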