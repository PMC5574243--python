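"""From-scratch k-nearest-neighbour classification of EEG feature vectors.

Four distance measures (Euclidean, cityblock, cosine, correlation), a
cosine-similarity category score, and four decision rules:

* ``nearest_neighbour`` — majority label among the k nearest rows; majority
  ties resolve to the single closest row's label, and equal distances break
  by lowest row index (stable sort).
* ``random_neighbour`` — the label of one of the k nearest drawn uniformly
  with the configured seed.
* ``smallest_neighbour`` — the label of the farthest row *within* the
  k-nearest set (the weakest of the selected neighbours).
* ``similarity_weighted`` — argmax over classes of the summed cosine
  similarity between the query and the k nearest rows of that class.

With k = 1 the first three rules coincide. Distances are computed on
whatever feature scale the template carries; templates are conventionally
min-max normalized first.
"""

from __future__ import annotations

import logging
import zlib
from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .features import FEATURE_NAMES, FeatureVector

log = logging.getLogger(__name__)

METRICS = ("euclidean", "cityblock", "cosine", "correlation")
RULES = (
    "nearest_neighbour",
    "random_neighbour",
    "smallest_neighbour",
    "similarity_weighted",
)


@dataclass(frozen=True)
class KnnConfig:
    k: int = 1
    metric: str = "euclidean"
    rule: str = "nearest_neighbour"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be a positive integer")
        if self.metric not in METRICS:
            raise ValueError(f"metric must be one of {METRICS}, got {self.metric!r}")
        if self.rule not in RULES:
            raise ValueError(f"rule must be one of {RULES}, got {self.rule!r}")


@dataclass
class FeatureTemplate:
    """Labeled table of feature vectors: the k-NN training/testing set."""

    rows: list[FeatureVector]
    feature_names: tuple[str, ...] = FEATURE_NAMES

    def __post_init__(self) -> None:
        if any(r.label is None for r in self.rows):
            raise ValueError("every template row needs a class label")

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def classes(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.rows:
            seen.setdefault(r.label, None)
        return list(seen)

    def matrix(self) -> np.ndarray:
        return np.stack([r.values() for r in self.rows])

    def labels(self) -> list[str]:
        return [r.label for r in self.rows]


def similarity(x: Sequence[float], d_j: Sequence[float]) -> float:
    """Cosine similarity in [-1, 1]; equals 1 - cosine distance."""
    a = np.asarray(x, dtype=float)
    b = np.asarray(d_j, dtype=float)
    if a.shape != b.shape:
        raise ValueError("similarity needs vectors of equal dimension")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(a @ b / (na * nb))


def distance(a: Sequence[float], b: Sequence[float], metric: str) -> float:
    """Distance between two feature vectors under the named metric."""
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.shape != y.shape:
        raise ValueError("distance needs vectors of equal dimension")
    if metric == "euclidean":
        return float(np.sqrt(np.sum((x - y) ** 2)))
    if metric == "cityblock":
        return float(np.sum(np.abs(x - y)))
    if metric == "cosine":
        return 1.0 - similarity(x, y)
    if metric == "correlation":
        xc = x - x.mean()
        yc = y - y.mean()
        nx, ny = np.linalg.norm(xc), np.linalg.norm(yc)
        if nx == 0 or ny == 0:
            raise ValueError("correlation distance undefined for a constant vector")
        return float(1.0 - xc @ yc / (nx * ny))
    raise ValueError(f"unknown metric {metric!r}")


def category_score(
    x: Sequence[float],
    neighbours: Sequence[tuple[Sequence[float], str]],
    c: str,
) -> float:
    """Summed cosine similarity of x to the neighbours labeled c.

    Classification by this pathway assigns the class maximising the score.
    """
    return float(
        sum(similarity(x, vec) for vec, label in neighbours if label == c)
    )


def _k_nearest(
    x: np.ndarray, template: FeatureTemplate, cfg: KnnConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Indices and distances of the k nearest template rows (stable order)."""
    if cfg.k > len(template):
        raise ValueError(f"k={cfg.k} exceeds template size {len(template)}")
    dists = np.array(
        [distance(x, row, cfg.metric) for row in template.matrix()]
    )
    order = np.argsort(dists, kind="stable")[: cfg.k]
    return order, dists[order]


def classify(
    x: Sequence[float] | FeatureVector,
    template: FeatureTemplate,
    cfg: KnnConfig = KnnConfig(),
) -> str:
    """Assign x the class determined by its k nearest template rows."""
    vec = x.values() if isinstance(x, FeatureVector) else np.asarray(x, dtype=float)
    idx, _ = _k_nearest(vec, template, cfg)
    labels = [template.rows[i].label for i in idx]

    if cfg.rule == "nearest_neighbour":
        counts = Counter(labels)
        top = max(counts.values())
        winners = {lab for lab, c in counts.items() if c == top}
        if len(winners) == 1:
            return winners.pop()
        return labels[0]  # tie: the single closest row decides
    if cfg.rule == "random_neighbour":
        # deterministic given (cfg, query): substream keyed on the query bytes
        digest = zlib.crc32(vec.tobytes())
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, digest]))
        return labels[int(rng.integers(len(labels)))]
    if cfg.rule == "smallest_neighbour":
        return labels[-1]  # farthest row within the k-nearest set
    # similarity_weighted: Eq.-style argmax of summed similarity over classes
    neighbours = [(template.rows[i].values(), template.rows[i].label) for i in idx]
    classes = template.classes
    scores = [category_score(vec, neighbours, c) for c in classes]
    return classes[int(np.argmax(scores))]


@dataclass
class ConfusionMatrix:
    labels: list[str]
    counts: np.ndarray  # counts[true, predicted]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.counts) / self.total)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts,
            index=pd.Index(self.labels, name="true"),
            columns=pd.Index(self.labels, name="predicted"),
        )

    def __str__(self) -> str:
        return f"{self.to_frame()}\naccuracy: {self.accuracy:.4f}"


def evaluate(
    template_train: FeatureTemplate,
    template_test: FeatureTemplate,
    cfg: KnnConfig = KnnConfig(),
) -> ConfusionMatrix:
    """Classify every test row against the training template."""
    labels: dict[str, None] = {}
    for lab in template_train.classes + template_test.classes:
        labels.setdefault(lab, None)
    labels = list(labels)
    index = {lab: i for i, lab in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=int)
    for row in template_test.rows:
        pred = classify(row, template_train, cfg)
        counts[index[row.label], index[pred]] += 1
    cm = ConfusionMatrix(labels, counts)
    log.info(
        "k-NN evaluation: k=%d metric=%s rule=%s accuracy=%.4f",
        cfg.k, cfg.metric, cfg.rule, cm.accuracy,
    )
    return cm


def accuracy_grid(
    template_train: FeatureTemplate,
    template_test: FeatureTemplate,
    ks: Sequence[int] = (1, 2, 3),
    metrics: Sequence[str] = METRICS,
    rules: Sequence[str] = ("nearest_neighbour", "random_neighbour", "smallest_neighbour"),
    seed: int = 0,
) -> pd.DataFrame:
    """Accuracy for every (k, metric, rule) combination, long format."""
    records = []
    for k in ks:
        for metric in metrics:
            for rule in rules:
                cfg = KnnConfig(k=k, metric=metric, rule=rule, seed=seed)
                cm = evaluate(template_train, template_test, cfg)
                records.append(
                    {"k": k, "metric": metric, "rule": rule, "accuracy": cm.accuracy}
                )
    return pd.DataFrame.from_records(records)
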