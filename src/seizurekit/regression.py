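"""Polynomial regression of approximate entropy against subject age.

The "level of epilepsy" model: ApEn measured from epileptic EEG rises with
patient age, and a low-order polynomial Y = b0 + b1*x + ... + bk*x^k fitted
by ordinary least squares interpolates that trend. The module fits such
models, evaluates them, and builds the percent-deviation error table used
to choose the fitting order. Published 3rd- and 4th-order reference models
(and their 7th-order residual polynomials) are bundled as constants.

Prediction error follows the convention of the published error table: the
interpreted (predicted) value is first rounded to 3 significant figures,
the deviation 100*|interpreted - actual|/actual is computed in exact
decimal arithmetic, and the percentage is reported to 2 decimals with
half-up rounding.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class PolynomialModel:
    """Coefficients b0..bk in ascending powers, with provenance tag."""

    coefficients: tuple[float, ...]
    source: str = "fitted"

    def __post_init__(self) -> None:
        if len(self.coefficients) < 2:
            raise ValueError("a polynomial model needs order >= 1")
        if not all(np.isfinite(self.coefficients)):
            raise ValueError("coefficients must be finite")
        object.__setattr__(self, "coefficients", tuple(float(c) for c in self.coefficients))

    @property
    def order(self) -> int:
        return len(self.coefficients) - 1

    def __call__(self, age: float) -> float:
        return evaluate_polynomial(self, age)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "order": self.order,
                "coefficients": [repr(c) for c in self.coefficients],
                "source": self.source,
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload + "\n", encoding="utf-8")
        return payload

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "PolynomialModel":
        p = Path(str(text_or_path))
        text = p.read_text(encoding="utf-8") if p.is_file() else str(text_or_path)
        obj = json.loads(text)
        coeffs = tuple(float(c) for c in obj["coefficients"])
        model = cls(coeffs, source=obj.get("source", "fitted"))
        if model.order != obj["order"]:
            raise ValueError("order field disagrees with coefficient count")
        return model


# Published reference models: ApEn as a function of age in years.
PAPER_3RD = PolynomialModel(
    (0.001932, 0.00052903, -1.2915e-05, 1.3277e-07), source="paper_3rd"
)
PAPER_4TH = PolynomialModel(
    (0.0013676, 0.00063605, -1.7628e-05, 2.0511e-07, -3.5815e-10), source="paper_4th"
)
# Residual-vs-age polynomials published alongside the fits (7th order).
PAPER_RES3 = PolynomialModel(
    (0.0032633, -0.0014727, 0.00018623, -1.0201e-05, 2.8173e-07,
     -4.0981e-09, 2.9924e-11, -8.6358e-14),
    source="paper_res3",
)
PAPER_RES4 = PolynomialModel(
    (0.0026987, -0.0013657, 0.00018151, -1.0129e-05, 2.8173e-07,
     -4.0981e-09, 2.9924e-11, -8.6358e-14),
    source="paper_res4",
)

REFERENCE_MODELS = {
    m.source: m for m in (PAPER_3RD, PAPER_4TH, PAPER_RES3, PAPER_RES4)
}


def evaluate_polynomial(model: PolynomialModel, age: float) -> float:
    """Horner evaluation of sum_i b_i * age^i."""
    if not np.isfinite(age):
        raise ValueError("age must be finite")
    acc = 0.0
    for c in reversed(model.coefficients):
        acc = acc * age + c
    return acc


def fit_polynomial(
    ages: Sequence[float],
    apen_values: Sequence[float],
    order: int,
    scaled: bool = False,
) -> PolynomialModel:
    """Ordinary least-squares polynomial fit of ApEn on age.

    Fits on the raw age scale by default so coefficients are directly
    comparable with the published models; ``scaled=True`` fits on a
    centered/scaled domain for conditioning and converts back.
    """
    x = np.asarray(ages, dtype=float)
    y = np.asarray(apen_values, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("ages and apen_values must be equal-length 1-D sequences")
    if order < 1:
        raise ValueError("order must be >= 1")
    n_distinct = np.unique(x).size
    if n_distinct < order + 1:
        raise ValueError(
            f"rank-deficient design: order {order} needs >= {order + 1} distinct "
            f"ages, got {n_distinct}"
        )
    if scaled:
        poly = np.polynomial.Polynomial.fit(x, y, deg=order)
        coeffs = poly.convert().coef
    else:
        coeffs = np.polynomial.polynomial.polyfit(x, y, deg=order)
    return PolynomialModel(tuple(coeffs), source="fitted")


def round_sig(x: float, sig: int = 3) -> float:
    """Round to `sig` significant figures (0 stays 0)."""
    x = float(x)
    if x == 0 or not np.isfinite(x):
        return x
    return float(f"{x:.{sig - 1}e}")


def percent_deviation(
    actual: float,
    interpreted: float,
    sig_figs: Optional[int] = 3,
    decimals: Optional[int] = 2,
) -> float:
    """100 * |interpreted - actual| / actual, error-table convention.

    The interpreted value is rounded to ``sig_figs`` significant figures
    before comparison (matching printed-table precision), the ratio is
    computed in exact decimal arithmetic, and the result is reported to
    ``decimals`` places with half-up rounding. Pass ``sig_figs=None`` /
    ``decimals=None`` for the raw relative deviation.
    """
    actual, interpreted = float(actual), float(interpreted)
    if actual == 0:
        raise ValueError("percent deviation undefined for actual == 0")
    interp = round_sig(interpreted, sig_figs) if sig_figs is not None else interpreted
    dev = (
        abs(Decimal(repr(interp)) - Decimal(repr(actual)))
        / abs(Decimal(repr(actual)))
        * 100
    )
    if decimals is not None:
        dev = dev.quantize(Decimal(1).scaleb(-decimals), rounding=ROUND_HALF_UP)
    return float(dev)


@dataclass(frozen=True)
class PredictionReport:
    """One row of the error table: a model's prediction at one age."""

    model_source: str
    age: float
    interpreted_apen: float  # rounded to table precision
    actual_apen: Optional[float] = None
    percent_dev: Optional[float] = None


def error_table(
    models: Sequence[PolynomialModel],
    test_points: Sequence[tuple[float, Optional[float]]],
    sig_figs: int = 3,
) -> list[PredictionReport]:
    """Prediction-error table: one report per (model, test point)."""
    if not models or not len(test_points):
        raise ValueError("error_table needs at least one model and one point")
    reports = []
    for model in models:
        for age, actual in test_points:
            interp = round_sig(evaluate_polynomial(model, age), sig_figs)
            dev = (
                percent_deviation(actual, interp, sig_figs=sig_figs)
                if actual is not None
                else None
            )
            reports.append(
                PredictionReport(model.source, float(age), interp, actual, dev)
            )
    return reports


def error_table_frame(reports: Sequence[PredictionReport]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "model": r.model_source,
                "age": r.age,
                "actual_apen": r.actual_apen,
                "interpreted_apen": r.interpreted_apen,
                "percent_deviation": r.percent_dev,
            }
            for r in reports
        ]
    )


def select_order(
    candidates: Sequence[int],
    ages: Sequence[float],
    apen_values: Sequence[float],
    seed: int = 0,
    holdout_fraction: float = 0.5,
) -> int:
    """Choose the fitting order by held-out mean relative deviation.

    Splits the cohort with a seeded shuffle, fits each candidate order on the
    training half and scores it on the held-out half with the unrounded
    relative deviation. Orders whose error is within a 1e-6 percentage-point
    slack of the best tie toward the lower order (parsimony).
    """
    if len(candidates) < 2:
        raise ValueError("need at least two candidate orders")
    x = np.asarray(ages, dtype=float)
    y = np.asarray(apen_values, dtype=float)
    if np.any(y == 0):
        raise ValueError("relative deviation undefined at apen == 0")
    rng = np.random.default_rng(seed)
    idx = rng.permutation(x.size)
    n_hold = max(1, int(round(holdout_fraction * x.size)))
    hold, train = idx[:n_hold], idx[n_hold:]
    kmax = max(candidates)
    if np.unique(x[train]).size < kmax + 1:
        raise ValueError(f"too few distinct training ages for order {kmax}")
    errors = {}
    for k in sorted(candidates):
        model = fit_polynomial(x[train], y[train], k)
        preds = np.array([evaluate_polynomial(model, a) for a in x[hold]])
        errors[k] = float(np.mean(np.abs(preds - y[hold]) / np.abs(y[hold])) * 100)
    best = min(errors.values())
    for k in sorted(errors):
        if errors[k] <= best + 1e-6:
            return k
    raise AssertionError("unreachable")
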