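"""Fixed-width histogramming of voxel-level ADC values.

All ADC values are handled internally on the 10^-6 mm^2/s scale, where the
conventional interval width for whole-lesion ADC histograms is 100. Bins are
half-open, ``[left, right)``, with a value falling exactly on an edge assigned
to the right-hand bin. Both the support and the edge convention are
configuration, not constants: they are properties of :class:`BinningScheme`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .errors import ValidationError

#: Canonical tumor-class order, also the tie-break order for classifiers.
CLASSES = ("PA", "WT", "MT")


@dataclass(frozen=True)
class BinningScheme:
    """A shared, cohort-wide binning grid for ADC histograms.

    Parameters
    ----------
    origin : float
        Left edge of the first bin, in 10^-6 mm^2/s. Default 0.
    width : float
        Bin width, in 10^-6 mm^2/s. Default 100.
    n_bins : int
        Number of bins. The default 40 covers 0-4000, comfortably above
        free-water ADC (~3000).

    Bin ``m`` covers the half-open interval
    ``[origin + m*width, origin + (m+1)*width)``.
    """

    origin: float = 0.0
    width: float = 100.0
    n_bins: int = 40

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValidationError(f"bin width must be positive, got {self.width}")
        if self.n_bins < 1:
            raise ValidationError(f"n_bins must be >= 1, got {self.n_bins}")

    @property
    def upper(self) -> float:
        return self.origin + self.n_bins * self.width

    def edges(self) -> np.ndarray:
        """All ``n_bins + 1`` bin edges."""
        return self.origin + self.width * np.arange(self.n_bins + 1)

    def to_dict(self) -> dict:
        return {"origin": self.origin, "width": self.width, "n_bins": self.n_bins}

    @classmethod
    def from_dict(cls, d: dict) -> "BinningScheme":
        return cls(origin=float(d["origin"]), width=float(d["width"]),
                   n_bins=int(d["n_bins"]))


@dataclass(frozen=True, eq=False)
class Histogram:
    """Binned voxel counts ``O_m`` for one patient under a shared scheme."""

    patient_id: str
    scheme: BinningScheme
    counts: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", counts)
        if counts.shape != (self.scheme.n_bins,):
            raise ValidationError(
                f"counts has shape {counts.shape}, scheme expects ({self.scheme.n_bins},)"
            )
        if np.any(counts < 0):
            raise ValidationError("histogram counts must be non-negative")
        if counts.sum() < 1:
            raise ValidationError("histogram must contain at least one observation")

    @property
    def total(self) -> int:
        """Total observation count ``N`` (the patient's voxel count)."""
        return int(self.counts.sum())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Histogram):
            return NotImplemented
        return (self.patient_id == other.patient_id
                and self.scheme == other.scheme
                and np.array_equal(self.counts, other.counts))

    def __hash__(self) -> int:  # content-based, counts immutable by convention
        return hash((self.patient_id, self.scheme, self.counts.tobytes()))


def bin_values(values: Iterable[float], scheme: BinningScheme,
               overflow_policy: str = "clamp") -> np.ndarray:
    """Assign each value to its half-open bin and return the count vector.

    Values at or above the upper edge of the grid are handled per
    ``overflow_policy``: ``"clamp"`` places them in the last bin (with a
    warning), ``"error"`` rejects the input. Values below ``origin`` are
    always rejected.
    """
    if overflow_policy not in ("clamp", "error"):
        raise ValidationError(f"unknown overflow_policy {overflow_policy!r}")
    v = np.asarray(list(values) if not isinstance(values, np.ndarray) else values,
                   dtype=np.float64)
    if v.size == 0:
        raise ValidationError("cannot bin an empty value list")
    if not np.all(np.isfinite(v)):
        raise ValidationError("values must be finite")
    if np.any(v < scheme.origin):
        raise ValidationError(
            f"value {v.min()} lies below the bin origin {scheme.origin}"
        )
    idx = np.floor((v - scheme.origin) / scheme.width).astype(np.int64)
    over = idx >= scheme.n_bins
    if np.any(over):
        if overflow_policy == "error":
            raise ValidationError(
                f"{int(over.sum())} value(s) at or above the upper edge "
                f"{scheme.upper} with overflow_policy='error'"
            )
        warnings.warn(
            f"{int(over.sum())} value(s) >= {scheme.upper} clamped into the last bin",
            stacklevel=2,
        )
        idx = np.where(over, scheme.n_bins - 1, idx)
    return np.bincount(idx, minlength=scheme.n_bins).astype(np.int64)


def make_histogram(patient_id: str, values: Iterable[float], scheme: BinningScheme,
                   overflow_policy: str = "clamp") -> Histogram:
    """Bin one patient's voxel values into a :class:`Histogram`."""
    return Histogram(patient_id=patient_id, scheme=scheme,
                     counts=bin_values(values, scheme, overflow_policy))


def patient_mean(values: Iterable[float]) -> float:
    """Arithmetic mean of one patient's voxel values."""
    v = np.asarray(list(values) if not isinstance(values, np.ndarray) else values,
                   dtype=np.float64)
    if v.size == 0:
        raise ValidationError("cannot take the mean of an empty value list")
    return float(v.mean())
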