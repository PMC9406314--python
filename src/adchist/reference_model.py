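"""Pooled class reference distributions.

Each tumor class's reference is the empirical probability mass function of
all voxel observations pooled across that class's patients: every voxel is
one observation, so a patient with twice the voxels carries twice the weight.
Additive (Laplace) smoothing with ``alpha`` pseudo-counts per bin keeps the
chi-square statistic finite when a patient occupies a bin the pooled training
data never reached; ``alpha = 0`` reproduces the raw empirical PMF, in which
case a zero-expected bin with observed counts yields an infinite statistic
(deterministically, see :mod:`adchist.chi2_classifier`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .binning import CLASSES, BinningScheme, Histogram
from .errors import ValidationError


@dataclass(frozen=True, eq=False)
class ReferencePMF:
    """Pooled, smoothed empirical PMF ``p_{t,m}`` for one tumor class."""

    tumor_class: str
    scheme: BinningScheme
    probs: np.ndarray = field(repr=False)
    alpha: float = 0.0
    source_patient_ids: frozenset = frozenset()

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=np.float64)
        object.__setattr__(self, "probs", probs)
        object.__setattr__(self, "source_patient_ids",
                           frozenset(self.source_patient_ids))
        if self.tumor_class not in CLASSES:
            raise ValidationError(f"unknown tumor class {self.tumor_class!r}")
        if probs.shape != (self.scheme.n_bins,):
            raise ValidationError(
                f"probs shape {probs.shape} != ({self.scheme.n_bins},)"
            )
        if np.any(probs < 0):
            raise ValidationError("PMF entries must be non-negative")
        if abs(probs.sum() - 1.0) > 1e-12:
            raise ValidationError(f"PMF sums to {probs.sum()!r}, not 1")
        if self.alpha < 0:
            raise ValidationError("alpha must be non-negative")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ReferencePMF):
            return NotImplemented
        return (self.tumor_class == other.tumor_class
                and self.scheme == other.scheme
                and self.alpha == other.alpha
                and self.source_patient_ids == other.source_patient_ids
                and np.array_equal(self.probs, other.probs))

    def to_dict(self) -> dict:
        return {
            "tumor_class": self.tumor_class,
            "scheme": self.scheme.to_dict(),
            "alpha": self.alpha,
            "probs": [float(p) for p in self.probs],
            "source_patient_ids": sorted(self.source_patient_ids),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ReferencePMF":
        return cls(tumor_class=d["tumor_class"],
                   scheme=BinningScheme.from_dict(d["scheme"]),
                   probs=np.asarray(d["probs"], dtype=np.float64),
                   alpha=float(d["alpha"]),
                   source_patient_ids=frozenset(d["source_patient_ids"]))


@dataclass(frozen=True, eq=False)
class ExpectedCounts:
    """Expected per-bin counts ``E_{t,m} = N(i) * p_{t,m}`` for one patient."""

    values: np.ndarray
    patient_total: int

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", values)
        if self.patient_total < 1:
            raise ValidationError("patient_total must be >= 1")
        if abs(values.sum() - self.patient_total) > 1e-9:
            raise ValidationError(
                f"expected counts sum to {values.sum()!r}, not {self.patient_total}"
            )


def fit_reference(histograms: Sequence[Histogram], alpha: float = 0.5,
                  tumor_class: str = "PA") -> ReferencePMF:
    """Pool one class's histograms into a smoothed reference PMF.

    ``p_m = (sum_i O_m(i) + alpha) / (sum_i N(i) + alpha * n_bins)``.
    All histograms must share one binning scheme. Duplicate histograms are
    allowed (bootstrap resamples weight a patient once per draw).
    """
    histograms = list(histograms)
    if not histograms:
        raise ValidationError("cannot fit a reference from zero histograms")
    if alpha < 0:
        raise ValidationError("alpha must be non-negative")
    scheme = histograms[0].scheme
    for h in histograms[1:]:
        if h.scheme != scheme:
            raise ValidationError(
                f"mixed binning schemes: {h.scheme} vs {scheme}"
            )
    pooled = np.zeros(scheme.n_bins, dtype=np.float64)
    total = 0
    for h in histograms:
        pooled += h.counts
        total += h.total
    probs = (pooled + alpha) / (total + alpha * scheme.n_bins)
    probs = probs / probs.sum()  # guard rounding; off by < 1 ulp
    return ReferencePMF(tumor_class=tumor_class, scheme=scheme, probs=probs,
                        alpha=alpha,
                        source_patient_ids=frozenset(h.patient_id
                                                     for h in histograms))


def expected_counts(ref: ReferencePMF, patient_total: int) -> ExpectedCounts:
    """Per-bin expected counts if the patient's voxels followed ``ref``."""
    if patient_total < 1:
        raise ValidationError("patient_total must be >= 1")
    return ExpectedCounts(values=patient_total * ref.probs,
                          patient_total=patient_total)


def fit_all_references(histograms: Sequence[Histogram],
                       true_classes: Mapping[str, str],
                       alpha: float = 0.5,
                       exclude_patient_ids: Iterable[str] = ()) -> dict:
    """Fit one reference per tumor class, honoring an exclusion set.

    ``true_classes`` maps patient_id to class. Exclusion implements the
    cross-validation contract: held-out patients contribute to no reference.
    A class left without patients raises a validation error naming it.
    """
    exclude = frozenset(exclude_patient_ids)
    by_class: dict = {c: [] for c in CLASSES}
    for h in histograms:
        if h.patient_id in exclude:
            continue
        cls = true_classes.get(h.patient_id)
        if cls is None:
            raise ValidationError(f"no class label for patient {h.patient_id!r}")
        by_class[cls].append(h)
    refs = {}
    for c in CLASSES:
        if not by_class[c]:
            raise ValidationError(
                f"class {c} has no remaining patients after exclusion"
            )
        refs[c] = fit_reference(by_class[c], alpha=alpha, tumor_class=c)
    return refs
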