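"""The six per-epoch seizure features and feature-vector assembly.

Approximate entropy (ApEn) is the headline statistic: it quantifies how
predictable an amplitude sequence is from its own recent history. Rhythmic,
seizure-like activity gives low ApEn; broadband background activity gives
high ApEn. The remaining five features — population standard deviation (SD),
standard error of the mean (SE), modified mean absolute value (MMAV),
spectral roll-off and zero-crossing count (ZC) — summarise amplitude and
spectral shape. Together they form the six-column feature vector that the
k-NN classifier consumes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .epochs import EegEpoch

log = logging.getLogger(__name__)

FEATURE_NAMES = ("apen", "sd", "se", "mmav", "rolloff", "zc")


@dataclass(frozen=True)
class ApEnConfig:
    """Approximate-entropy parameters.

    m is the embedding (template) length; r the similarity tolerance.
    In ``relative`` mode the effective tolerance is ``r`` times the epoch's
    population SD, the conventional parameterisation (m=2, r=0.2·SD is the
    literature-standard default for physiological series).
    """

    m: int = 2
    r: float = 0.2
    r_mode: str = "relative"  # "relative" or "absolute"

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("embedding dimension m must be >= 1")
        if self.r < 0:
            raise ValueError("tolerance r must be >= 0")
        if self.r_mode not in ("relative", "absolute"):
            raise ValueError(f"unknown r_mode {self.r_mode!r}")

    def effective_r(self, epoch: EegEpoch) -> float:
        if self.r_mode == "relative":
            return self.r * standard_deviation(epoch)
        return self.r


@dataclass
class FeatureVector:
    """The six named feature values for one epoch/subject."""

    apen: float
    sd: float
    se: float
    mmav: float
    rolloff: float
    zc: float
    label: Optional[str] = None
    normalized: bool = False
    subject_id: str = ""

    def values(self) -> np.ndarray:
        return np.array(
            [self.apen, self.sd, self.se, self.mmav, self.rolloff, self.zc],
            dtype=float,
        )


def _phi(x: np.ndarray, m: int, r: float) -> float:
    """phi^m(r) = mean over templates of log(fraction of templates within r).

    Template similarity uses the Chebyshev (max-abs) distance and the count
    includes the self-match, so every C_i > 0 and the log is defined.
    """
    templates = sliding_window_view(x, m)  # (N-m+1, m)
    n = templates.shape[0]
    counts = np.empty(n, dtype=float)
    # Chunk the pairwise Chebyshev distances to bound memory at ~2e7 floats.
    step = max(1, int(2e7 / (n * m)))
    for start in range(0, n, step):
        block = templates[start : start + step]
        d = np.abs(block[:, None, :] - templates[None, :, :]).max(axis=2)
        counts[start : start + step] = (d <= r).sum(axis=1)
    return float(np.mean(np.log(counts / n)))


def approximate_entropy(epoch: EegEpoch, cfg: ApEnConfig = ApEnConfig()) -> float:
    """ApEn(m, r) = phi^m(r) - phi^{m+1}(r).

    Low values mean the series is regular/predictable (seizure-like rhythm);
    high values mean irregularity. Non-negative up to floating tolerance
    because self-matches are included in the counts.
    """
    n = epoch.n_samples
    if n < cfg.m + 2:
        raise ValueError(
            f"epoch of {n} samples too short for embedding dimension m={cfg.m}"
        )
    r_eff = cfg.effective_r(epoch)
    return _phi(epoch.samples, cfg.m, r_eff) - _phi(epoch.samples, cfg.m + 1, r_eff)


def standard_deviation(epoch: EegEpoch) -> float:
    """Population standard deviation (divisor N)."""
    return float(np.std(epoch.samples))


def standard_error(epoch: EegEpoch) -> float:
    """Standard error of the mean, SD / sqrt(N)."""
    return standard_deviation(epoch) / math.sqrt(epoch.n_samples)


def mmav(epoch: EegEpoch) -> float:
    """Modified mean absolute value.

    Mean of the rectified samples with weight 1.0 over the central half of
    the window (1-based indices ceil(0.25N) <= n <= floor(0.75N)) and 0.5
    on the edges.
    """
    x = np.abs(epoch.samples)
    n_samp = x.size
    idx = np.arange(1, n_samp + 1)
    lo = math.ceil(0.25 * n_samp)
    hi = math.floor(0.75 * n_samp)
    w = np.where((idx >= lo) & (idx <= hi), 1.0, 0.5)
    return float(np.mean(w * x))


def spectral_rolloff(epoch: EegEpoch, fraction: float = 0.85) -> float:
    """Frequency (Hz) below which `fraction` of the one-sided magnitude
    spectrum is concentrated.

    The spectrum has floor(N/2)+1 bins at frequencies k * rate / N; the
    roll-off is the lowest bin frequency whose cumulative magnitude reaches
    the fraction of the total. A zero spectrum returns 0.0 with a warning.
    """
    if epoch.n_samples < 2:
        raise ValueError("roll-off needs at least 2 samples")
    if not (0 < fraction < 1):
        raise ValueError("fraction must lie in (0, 1)")
    mag = np.abs(np.fft.rfft(epoch.samples))
    total = mag.sum()
    if total == 0:
        log.warning("all-zero spectrum for %r; roll-off set to 0", epoch.subject_id)
        return 0.0
    cum = np.cumsum(mag)
    # tiny relative slack so exact-fraction boundaries are not missed to rounding
    k = int(np.searchsorted(cum, fraction * total * (1 - 1e-12)))
    return k * epoch.sampling_rate / epoch.n_samples


def zero_crossing(epoch: EegEpoch, threshold: float = 0.0) -> int:
    """Count sign changes between consecutive samples whose amplitude jump
    is at least `threshold`.

    Samples exactly zero adopt the sign of the previous nonzero sample
    (leading zeros adopt the first nonzero sign), so touching zero is not
    double-counted.
    """
    if epoch.n_samples < 2:
        raise ValueError("zero crossing needs at least 2 samples")
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    x = epoch.samples
    s = np.sign(x)
    nz = np.flatnonzero(s)
    if nz.size == 0:
        return 0
    # forward-fill zero signs from the previous nonzero sample
    filled_idx = np.maximum.accumulate(
        np.where(s != 0, np.arange(x.size), -1)
    )
    filled_idx[filled_idx < 0] = nz[0]  # leading zeros inherit first nonzero sign
    s = s[filled_idx]
    flips = s[1:] != s[:-1]
    big_enough = np.abs(np.diff(x)) >= threshold
    return int(np.count_nonzero(flips & big_enough))


def extract_features(
    epoch: EegEpoch,
    apen_cfg: ApEnConfig = ApEnConfig(),
    rolloff_fraction: float = 0.85,
    zc_threshold: float = 0.0,
) -> FeatureVector:
    """Compute all six features for one epoch (unnormalized)."""
    out = {}
    steps = {
        "apen": lambda: approximate_entropy(epoch, apen_cfg),
        "sd": lambda: standard_deviation(epoch),
        "se": lambda: standard_error(epoch),
        "mmav": lambda: mmav(epoch),
        "rolloff": lambda: spectral_rolloff(epoch, rolloff_fraction),
        "zc": lambda: float(zero_crossing(epoch, zc_threshold)),
    }
    for name, fn in steps.items():
        try:
            out[name] = fn()
        except Exception:
            log.error("feature %s failed for epoch %r", name, epoch.subject_id)
            raise
    return FeatureVector(**out, subject_id=epoch.subject_id)


def normalize_template(vectors: Sequence[FeatureVector]) -> list[FeatureVector]:
    """Column-wise min-max scaling of a feature collection to [0, 1].

    Constant columns map to 0.5 by convention. Labels and subject ids are
    preserved; the result is idempotent (re-normalizing changes nothing).
    """
    if len(vectors) < 2:
        raise ValueError("normalization needs at least 2 feature vectors")
    mat = np.stack([v.values() for v in vectors])
    if not np.all(np.isfinite(mat)):
        raise ValueError("non-finite feature values cannot be normalized")
    lo = mat.min(axis=0)
    hi = mat.max(axis=0)
    span = hi - lo
    scaled = np.where(span > 0, (mat - lo) / np.where(span > 0, span, 1.0), 0.5)
    out = []
    for vec, row in zip(vectors, scaled):
        fields = dict(zip(FEATURE_NAMES, (float(v) for v in row)))
        out.append(replace(vec, **fields, normalized=True))
    return out
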