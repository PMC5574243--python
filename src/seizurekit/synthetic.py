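"""Seeded synthetic EEG surrogates and cohorts.

No clinical recording ships with the package, so every pipeline stage is
exercised on surrogates that reproduce the two statistical contrasts the
method relies on:

* within an epoch — "epileptic" epochs are rhythmic spike-wave-like
  oscillations (low approximate entropy), "normal" epochs are broadband
  1/f-coloured noise of matched total power (high approximate entropy);
* across a cohort — the ApEn level rises with subject age following a
  known polynomial, observed with additive Gaussian noise.

The spike-wave surrogate (a harmonic stack with a quadratic peak-sharpening
nonlinearity) is a standard stand-in for ictal rhythmicity; no claim of
clinical realism is made. All generators are pure functions of their spec:
one top-level seed expands into stable per-subject substreams, so adding
subjects never perturbs earlier ones.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .epochs import EegEpoch
from .features import ApEnConfig, extract_features, normalize_template
from .knn import FeatureTemplate
from .regression import PolynomialModel, evaluate_polynomial

KINDS = ("normal", "epileptic")


@dataclass(frozen=True)
class EpochSpec:
    """Recipe for one synthetic epoch.

    Defaults emulate a short scalp-EEG window: 2 s at 128 Hz with a 3 Hz
    spike-wave fundamental (the classic ictal discharge rate band).
    """

    kind: str = "epileptic"
    n_samples: int = 256
    sampling_rate: float = 128.0
    base_freq: float = 3.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}")
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if not (self.sampling_rate > 0):
            raise ValueError("sampling_rate must be positive")
        if not (0 < self.base_freq < self.sampling_rate / 2):
            raise ValueError("base_freq must lie below the Nyquist frequency")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for an (age, ApEn) cohort drawn around a known polynomial."""

    ages: tuple[float, ...]
    true_model: PolynomialModel
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        ages = tuple(float(a) for a in self.ages)
        if not ages or any(a <= 0 for a in ages):
            raise ValueError("ages must be non-empty and positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        object.__setattr__(self, "ages", ages)


def _rng(seed: int, *key: int) -> np.random.Generator:
    """Stable substream: same (seed, key) always yields the same stream."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=tuple(key)))


def generate_epoch(spec: EpochSpec, subject_id: str = "") -> EegEpoch:
    """Synthesise one epoch; bit-identical for identical specs."""
    rng = _rng(spec.seed)
    t = np.arange(spec.n_samples) / spec.sampling_rate
    if spec.kind == "epileptic":
        # harmonic stack: fundamental + 2 harmonics, 1/h amplitude fall-off;
        # a seeded phase offset decorrelates subjects drawn with different seeds
        phase = rng.uniform(0.0, 2 * np.pi)
        base = sum(
            np.sin(2 * np.pi * h * spec.base_freq * t + h * phase) / h
            for h in (1, 2, 3)
        )
        # quadratic peak sharpening mimics the spike of a spike-wave complex
        x = np.sign(base) * base**2
    else:
        white = rng.standard_normal(spec.n_samples)
        spectrum = np.fft.rfft(white)
        freqs = np.fft.rfftfreq(spec.n_samples, d=1 / spec.sampling_rate)
        shaping = np.ones_like(freqs)
        shaping[1:] = 1.0 / np.sqrt(freqs[1:])  # 1/f power profile
        shaping[0] = 0.0  # no DC drift
        x = np.fft.irfft(spectrum * shaping, n=spec.n_samples)
    rms = np.sqrt(np.mean(x**2))
    x = x / rms  # unit RMS so the two kinds have matched total power
    if spec.noise_sd > 0:
        x = x + rng.normal(0.0, spec.noise_sd, spec.n_samples)
    return EegEpoch(x, spec.sampling_rate, subject_id=subject_id)


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """(age, apen) pairs: polynomial trend + Gaussian noise, clipped at 0."""
    rng = _rng(spec.seed)
    ages = np.asarray(spec.ages, dtype=float)
    apen = np.array([evaluate_polynomial(spec.true_model, a) for a in ages])
    if spec.noise_sd > 0:
        apen = apen + rng.normal(0.0, spec.noise_sd, ages.size)
    apen = np.clip(apen, 0.0, None)
    return pd.DataFrame({"age": ages, "apen": apen})


def generate_template(
    n_per_class: int,
    class_specs: Mapping[str, EpochSpec],
    apen_cfg: ApEnConfig = ApEnConfig(),
    seed: int = 0,
) -> FeatureTemplate:
    """Labeled, normalized feature template of n_per_class epochs per class.

    Per-subject epoch seeds are derived from (seed, subject index) so the
    template is reproducible and grows stably.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    vectors = []
    subject = 0
    for label, spec in class_specs.items():
        for _ in range(n_per_class):
            subject += 1
            child_seed = int(_rng(seed, subject).integers(0, 2**31 - 1))
            epoch = generate_epoch(
                replace(spec, seed=child_seed), subject_id=f"S{subject}"
            )
            vec = extract_features(epoch, apen_cfg)
            vec.label = label
            vectors.append(vec)
    return FeatureTemplate(normalize_template(vectors))
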