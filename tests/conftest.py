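"""Shared fixtures and independent oracles for the seizurekit suite."""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from seizurekit import EpochSpec

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


def apen_bruteforce(x, m: int, r: float) -> float:
    """Exhaustive O(N^2) approximate entropy, written independently of the
    library implementation: explicit template lists, per-template counting
    of Chebyshev-close matches (self-match included)."""
    x = np.asarray(x, dtype=float)
    n_total = x.size

    def phi(mm: int) -> float:
        templates = np.array([x[i : i + mm] for i in range(n_total - mm + 1)])
        n = len(templates)
        acc = 0.0
        for a in templates:
            count = int(np.sum(np.max(np.abs(templates - a), axis=1) <= r))
            acc += math.log(count / n)
        return acc / n

    return phi(m) - phi(m + 1)


def apen_bruteforce_slow(x, m: int, r: float) -> float:
    """Pure double-loop variant (no vectorisation at all); for tiny N."""
    x = list(map(float, x))
    n_total = len(x)

    def phi(mm: int) -> float:
        templates = [x[i : i + mm] for i in range(n_total - mm + 1)]
        n = len(templates)
        acc = 0.0
        for a in templates:
            count = 0
            for b in templates:
                if max(abs(ai - bi) for ai, bi in zip(a, b)) <= r:
                    count += 1
            acc += math.log(count / n)
        return acc / n

    return phi(m) - phi(m + 1)


@pytest.fixture
def class_specs():
    """Epoch recipes for the two classes at the standard study conditions:
    2 s @ 128 Hz, 3 Hz spike-wave fundamental, noise SD 0.3 (unit-RMS scale)."""
    base = EpochSpec(noise_sd=0.3)
    return {
        "epileptic": dataclasses.replace(base, kind="epileptic"),
        "normal": dataclasses.replace(base, kind="normal"),
    }


@pytest.fixture
def rng():
    return np.random.default_rng(20170813)
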