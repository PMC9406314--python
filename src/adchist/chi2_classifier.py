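"""Chi-square discrepancy classification of ADC histograms.

A patient's binned counts ``O_m`` are compared to the expected counts
``E_{t,m} = N * p_{t,m}`` under each class reference via

    T_t = sum_m (O_m - E_{t,m})^2 / E_{t,m}

and the patient is assigned the class with the smallest statistic. The
statistic is used purely as a discrepancy score — no p-value or
degrees-of-freedom calibration is attached to it.

Zero-expected bins (possible only with smoothing ``alpha = 0``) are handled
deterministically: ``E = 0, O = 0`` contributes nothing; ``E = 0, O > 0``
makes the statistic ``+inf``, which compares larger than every finite value,
and two infinite statistics tie.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .binning import CLASSES, Histogram
from .errors import ValidationError
from .reference_model import ReferencePMF


@dataclass(frozen=True)
class Chi2Classification:
    """Per-class statistics and the argmin decision for one patient.

    ``predicted_class`` attains the minimum of ``statistics`` over
    ``candidate_classes``; exact ties are broken by the fixed class order
    PA < WT < MT and flagged.
    """

    patient_id: str
    statistics: Mapping[str, float]
    predicted_class: str
    candidate_classes: tuple
    tie_flag: bool


def chi2_statistic(histogram: Histogram, ref: ReferencePMF) -> float:
    """The chi-square discrepancy of one histogram against one reference."""
    if histogram.scheme != ref.scheme:
        raise ValidationError(
            f"histogram scheme {histogram.scheme} != reference scheme {ref.scheme}"
        )
    observed = histogram.counts.astype(np.float64)
    expected = histogram.total * ref.probs
    zero_e = expected == 0
    if np.any(zero_e & (observed > 0)):
        return math.inf
    active = ~zero_e
    diff = observed[active] - expected[active]
    return float(np.sum(diff * diff / expected[active]))


def classify(histogram: Histogram, refs: Mapping[str, ReferencePMF],
             candidate_classes: Sequence[str] = CLASSES) -> Chi2Classification:
    """Assign the candidate class whose reference is closest in chi-square.

    ``candidate_classes`` restricts the comparison: the full three-way rule
    uses all classes, while pairwise evaluations (e.g. MT versus PA) compare
    only the named pair, each with its own two-candidate decision.
    """
    candidates = tuple(c for c in CLASSES if c in set(candidate_classes))
    if len(candidates) != len(set(candidate_classes)):
        unknown = set(candidate_classes) - set(CLASSES)
        raise ValidationError(f"unknown candidate class(es): {sorted(unknown)}")
    if len(candidates) < 2:
        raise ValidationError(
            f"need at least two candidate classes, got {candidates}"
        )
    missing = [c for c in candidates if c not in refs]
    if missing:
        raise ValidationError(f"no reference fitted for: {missing}")
    stats = {c: chi2_statistic(histogram, refs[c]) for c in candidates}
    best = min(stats.values())
    winners = [c for c in candidates if stats[c] == best]
    return Chi2Classification(
        patient_id=histogram.patient_id,
        statistics=stats,
        predicted_class=winners[0],
        candidate_classes=candidates,
        tie_flag=len(winners) > 1,
    )
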