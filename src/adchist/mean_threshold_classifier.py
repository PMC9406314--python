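"""The mean-ADC comparator: Youden-optimal thresholds between MT and each
benign class.

Clinical routine classifies parotid lesions by the lesion's mean ADC against
a cut-point. Because the two common benign entities sit on opposite sides of
the malignant range (PA high, WT low), two separate thresholds are fitted:
MT versus PA and MT versus WT. Each cut maximizes the Youden index
J = sensitivity + specificity - 1 on the fitting data, searching all
midpoints between consecutive distinct observed means (plus ±inf sentinels)
and both orientations (malignant below or above the cut). Orientation is
learned from the data rather than assumed, so the procedure stays total on
resampled training sets that happen to invert the usual ordering.

The three-way rule combining the two thresholds: a patient is MT only if
both thresholds vote MT; otherwise the benign class whose threshold voted
against MT decides, and if both do, the class whose threshold the mean
clears by the larger margin (ties to PA).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .binning import CLASSES
from .errors import StateError, ValidationError

MT_IF_LEQ = "MT_if_leq"
MT_IF_GEQ = "MT_if_geq"

_PAIRS = {"MT_vs_PA": "PA", "MT_vs_WT": "WT"}


@dataclass(frozen=True)
class ThresholdSpec:
    """A fitted cut-point for one MT-versus-benign comparison.

    ``orientation`` says on which side of ``cut`` a mean is called MT;
    ``youden_j`` is the Youden index the cut attains on its fitting data.
    """

    pair: str
    cut: float
    orientation: str
    youden_j: float

    def __post_init__(self) -> None:
        if self.pair not in _PAIRS:
            raise ValidationError(f"unknown pair {self.pair!r}")
        if self.orientation not in (MT_IF_LEQ, MT_IF_GEQ):
            raise ValidationError(f"unknown orientation {self.orientation!r}")

    @property
    def benign_class(self) -> str:
        return _PAIRS[self.pair]

    def votes_mt(self, mean: float) -> bool:
        if self.orientation == MT_IF_LEQ:
            return mean <= self.cut
        return mean >= self.cut

    def benign_margin(self, mean: float) -> float:
        """How far the mean sits beyond the cut on the benign side."""
        if self.orientation == MT_IF_LEQ:
            return mean - self.cut
        return self.cut - mean

    def to_dict(self) -> dict:
        return {"pair": self.pair, "cut": self.cut,
                "orientation": self.orientation, "youden_j": self.youden_j}

    @classmethod
    def from_dict(cls, d: dict) -> "ThresholdSpec":
        return cls(pair=d["pair"], cut=float(d["cut"]),
                   orientation=d["orientation"], youden_j=float(d["youden_j"]))


@dataclass(frozen=True)
class MeanClassifierModel:
    """Both fitted thresholds plus the ids of the patients that fitted them."""

    threshold_mt_pa: ThresholdSpec
    threshold_mt_wt: ThresholdSpec
    source_patient_ids: frozenset = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "source_patient_ids",
                           frozenset(self.source_patient_ids))

    def to_dict(self) -> dict:
        return {"threshold_mt_pa": self.threshold_mt_pa.to_dict(),
                "threshold_mt_wt": self.threshold_mt_wt.to_dict(),
                "source_patient_ids": sorted(self.source_patient_ids)}

    @classmethod
    def from_dict(cls, d: dict) -> "MeanClassifierModel":
        return cls(threshold_mt_pa=ThresholdSpec.from_dict(d["threshold_mt_pa"]),
                   threshold_mt_wt=ThresholdSpec.from_dict(d["threshold_mt_wt"]),
                   source_patient_ids=frozenset(d["source_patient_ids"]))


def candidate_cuts(means_positive: np.ndarray,
                   means_negative: np.ndarray) -> np.ndarray:
    """Midpoints between consecutive distinct pooled means, with ±inf sentinels.

    This grid realizes every achievable confusion matrix, so the maximum of J
    over it equals the maximum over all real cut-points.
    """
    pooled = np.unique(np.concatenate([means_positive, means_negative]))
    mids = (pooled[:-1] + pooled[1:]) / 2.0
    return np.concatenate([[-math.inf], mids, [math.inf]])


def fit_youden_threshold(means_positive: Iterable[float],
                         means_negative: Iterable[float],
                         pair: str = "MT_vs_PA") -> ThresholdSpec:
    """Fit the Youden-maximizing cut between MT (positive) and one benign class.

    Ties in J are broken toward the smaller cut, then toward ``MT_if_leq``,
    so refits on identical data are bit-stable.
    """
    pos = np.asarray(list(means_positive), dtype=np.float64)
    neg = np.asarray(list(means_negative), dtype=np.float64)
    if pos.size == 0 or neg.size == 0:
        raise ValidationError("both classes need at least one mean value")
    cuts = candidate_cuts(pos, neg)
    best: tuple | None = None  # (J, cut, orientation)
    for cut in cuts:
        for orientation in (MT_IF_LEQ, MT_IF_GEQ):
            if orientation == MT_IF_LEQ:
                sens = np.mean(pos <= cut)
                spec = np.mean(neg > cut)
            else:
                sens = np.mean(pos >= cut)
                spec = np.mean(neg < cut)
            j = float(sens + spec - 1.0)
            if best is None or j > best[0]:
                best = (j, float(cut), orientation)
    assert best is not None
    return ThresholdSpec(pair=pair, cut=best[1], orientation=best[2],
                         youden_j=best[0])


def fit_mean_classifier(means: Mapping[str, float],
                        true_classes: Mapping[str, str],
                        exclude_patient_ids: Iterable[str] = (),
                        duplicates: Sequence[str] | None = None,
                        ) -> MeanClassifierModel:
    """Fit both thresholds from per-patient mean ADC values.

    ``means`` maps patient_id to mean ADC; ``true_classes`` maps patient_id
    to class. ``duplicates``, when given, is an explicit training multiset of
    patient ids (bootstrap resamples repeat ids); otherwise every non-excluded
    patient appears once. The MT-vs-PA threshold never sees WT patients and
    vice versa.
    """
    exclude = frozenset(exclude_patient_ids)
    if duplicates is None:
        roster = [pid for pid in means if pid not in exclude]
    else:
        roster = [pid for pid in duplicates if pid not in exclude]
    by_class: dict = {c: [] for c in CLASSES}
    for pid in roster:
        by_class[true_classes[pid]].append(means[pid])
    for c in CLASSES:
        if not by_class[c]:
            raise ValidationError(
                f"class {c} has no remaining patients after exclusion"
            )
    thr_pa = fit_youden_threshold(by_class["MT"], by_class["PA"], pair="MT_vs_PA")
    thr_wt = fit_youden_threshold(by_class["MT"], by_class["WT"], pair="MT_vs_WT")
    return MeanClassifierModel(threshold_mt_pa=thr_pa, threshold_mt_wt=thr_wt,
                               source_patient_ids=frozenset(roster))


def classify_mean(mean: float, model: MeanClassifierModel,
                  candidate_classes: Sequence[str] = CLASSES) -> str:
    """Classify one mean ADC value.

    Pairwise mode (candidates {MT, PA} or {MT, WT}) applies the single
    relevant threshold. Three-way mode combines both thresholds as described
    in the module docstring.
    """
    if model is None or model.threshold_mt_pa is None:  # defensive
        raise StateError("mean classifier model is not fitted")
    candidates = frozenset(candidate_classes)
    if not candidates <= set(CLASSES):
        raise ValidationError(
            f"unknown candidate class(es): {sorted(candidates - set(CLASSES))}"
        )
    if len(candidates) < 2:
        raise ValidationError("need at least two candidate classes")

    if candidates == {"MT", "PA"}:
        thr = model.threshold_mt_pa
        return "MT" if thr.votes_mt(mean) else "PA"
    if candidates == {"MT", "WT"}:
        thr = model.threshold_mt_wt
        return "MT" if thr.votes_mt(mean) else "WT"
    if candidates == {"PA", "WT"}:
        raise ValidationError(
            "no threshold is defined for the PA-versus-WT pair"
        )

    # three-way rule
    pa_votes_mt = model.threshold_mt_pa.votes_mt(mean)
    wt_votes_mt = model.threshold_mt_wt.votes_mt(mean)
    if pa_votes_mt and wt_votes_mt:
        return "MT"
    if pa_votes_mt:          # only the WT threshold vetoed MT
        return "WT"
    if wt_votes_mt:          # only the PA threshold vetoed MT
        return "PA"
    # both benign votes fire: larger clearance beyond its threshold wins
    pa_margin = model.threshold_mt_pa.benign_margin(mean)
    wt_margin = model.threshold_mt_wt.benign_margin(mean)
    return "PA" if pa_margin >= wt_margin else "WT"
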