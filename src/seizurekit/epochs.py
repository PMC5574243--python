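"""EEG epoch container and plain-text I/O.

An epoch is one fixed-length window of a single-channel EEG recording,
stored as a 1-D amplitude array together with its sampling rate. All
feature extraction in :mod:`seizurekit.features` operates on epochs;
no montage handling, filtering or automatic segmentation is done here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


class CorruptInputError(ValueError):
    """Raised when an epoch contains non-finite samples or malformed text."""


@dataclass(frozen=True)
class EegEpoch:
    """One channel of N time-domain samples at a fixed sampling rate.

    Parameters
    ----------
    samples:
        Amplitude values (conventionally microvolts; units are not enforced).
    sampling_rate:
        Samples per second, strictly positive.
    subject_id:
        Opaque identifier carried through feature tables.
    """

    samples: np.ndarray
    sampling_rate: float
    subject_id: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples, dtype=float)
        if arr.ndim != 1 or arr.size < 1:
            raise ValueError("epoch needs a 1-D array with at least one sample")
        if not np.all(np.isfinite(arr)):
            raise CorruptInputError(
                f"epoch {self.subject_id!r} contains non-finite samples"
            )
        if not (self.sampling_rate > 0):
            raise ValueError("sampling_rate must be positive")
        object.__setattr__(self, "samples", arr)

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def mean(self) -> float:
        return float(self.samples.mean())


def read_epoch_csv(path: str | Path) -> EegEpoch:
    """Read an epoch from its plain-text form.

    Line 1 is ``<subject_id>,<sampling_rate>``; every following non-empty
    line holds one sample. Decimal point, no thousands separators.
    """
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines:
        raise CorruptInputError(f"{path}: empty epoch file")
    head = lines[0].split(",")
    if len(head) != 2:
        raise CorruptInputError(f"{path}:1: expected 'subject_id,sampling_rate'")
    subject_id, rate_str = head[0].strip(), head[1].strip()
    try:
        rate = float(rate_str)
    except ValueError as exc:
        raise CorruptInputError(f"{path}:1: bad sampling rate {rate_str!r}") from exc
    samples = []
    for lineno, line in enumerate(lines[1:], start=2):
        line = line.strip()
        if not line:
            continue
        try:
            samples.append(float(line))
        except ValueError as exc:
            raise CorruptInputError(f"{path}:{lineno}: bad sample {line!r}") from exc
    if not samples:
        raise CorruptInputError(f"{path}: no samples")
    return EegEpoch(np.asarray(samples), rate, subject_id=subject_id)


def write_epoch_csv(epoch: EegEpoch, path: str | Path) -> None:
    """Write an epoch in the format :func:`read_epoch_csv` reads (full repr precision)."""
    path = Path(path)
    body = "\n".join(repr(float(x)) for x in epoch.samples)
    path.write_text(
        f"{epoch.subject_id},{epoch.sampling_rate!r}\n{body}\n", encoding="utf-8"
    )
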