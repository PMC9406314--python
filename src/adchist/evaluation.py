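"""Classifier evaluation: confusion matrices, pairwise sensitivity and
specificity, and three cross-validation schemes.

Two evaluation surfaces are provided:

* *apparent* (resubstitution) performance — references and thresholds fitted
  on the full cohort, every patient classified, pairwise MT-versus-benign /
  MT-versus-PA / MT-versus-WT sensitivity and specificity reported. Pairwise
  comparisons use two-candidate decisions; MT-versus-benign uses the full
  three-way rule.
* *predictive* performance — leave-one-out CV, repeated stratified k-fold CV
  and stratified bootstrap with out-of-bag evaluation. Held-out patients
  contribute to no reference or threshold of their own fold (asserted inside
  every loop). All held-out predictions are pooled into one confusion matrix
  (micro-averaging; a macro switch averaging per-repeat metrics is available
  for repeated CV). CV metrics always use the three-way decision.

Folds and bootstrap draws are stratified by class so small classes can never
be emptied by chance; bootstrap iterations whose out-of-bag set is empty are
skipped and counted in the report diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .binning import CLASSES, BinningScheme, Histogram, make_histogram, patient_mean
from .chi2_classifier import classify as chi2_classify
from .data_io import Cohort
from .errors import ValidationError
from .mean_threshold_classifier import classify_mean, fit_mean_classifier
from .reference_model import fit_all_references

PAIRWISE_COMPARISONS = ("MT_vs_benign", "MT_vs_PA", "MT_vs_WT")


@dataclass(frozen=True, eq=False)
class ConfusionMatrix:
    """3x3 counts, rows = true class, columns = predicted, order (PA, WT, MT)."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", counts)
        if counts.shape != (3, 3):
            raise ValidationError(f"confusion matrix must be 3x3, got {counts.shape}")
        if np.any(counts < 0):
            raise ValidationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def trace(self) -> int:
        return int(np.trace(self.counts))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ConfusionMatrix):
            return NotImplemented
        return np.array_equal(self.counts, other.counts)

    def to_dict(self) -> dict:
        return {"order": list(CLASSES),
                "counts": [[int(c) for c in row] for row in self.counts]}

    @classmethod
    def from_dict(cls, d: dict) -> "ConfusionMatrix":
        return cls(counts=np.asarray(d["counts"], dtype=np.int64))


def confusion(true_classes: Sequence[str],
              predicted_classes: Sequence[str]) -> ConfusionMatrix:
    """Tally a confusion matrix from parallel label vectors."""
    if len(true_classes) != len(predicted_classes):
        raise ValidationError(
            f"length mismatch: {len(true_classes)} true vs "
            f"{len(predicted_classes)} predicted"
        )
    if len(true_classes) == 0:
        raise ValidationError("no patients to tally")
    index = {c: i for i, c in enumerate(CLASSES)}
    counts = np.zeros((3, 3), dtype=np.int64)
    for t, p in zip(true_classes, predicted_classes):
        if t not in index or p not in index:
            raise ValidationError(f"unknown label in pair ({t!r}, {p!r})")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts=counts)


def pooled_benign_metrics(cm: ConfusionMatrix) -> tuple:
    """Precision and TPR of the merged benign class (PA and WT as one)."""
    c = cm.counts
    benign = [0, 1]  # PA, WT rows/cols
    tp = int(c[np.ix_(benign, benign)].sum())
    pred_benign = int(c[:, benign].sum())
    true_benign = int(c[benign, :].sum())
    precision = tp / pred_benign if pred_benign else None
    tpr = tp / true_benign if true_benign else None
    return precision, tpr


def metrics_from_confusion(cm: ConfusionMatrix) -> dict:
    """Total accuracy plus per-class and pooled-benign precision / TPR.

    Precision is ``None`` (serialized as null) when a class was never
    predicted — "never predicted" is not the same thing as "always wrong".
    """
    c = cm.counts
    precision: dict = {}
    tpr: dict = {}
    for i, cls in enumerate(CLASSES):
        col = int(c[:, i].sum())
        row = int(c[i, :].sum())
        precision[cls] = int(c[i, i]) / col if col else None
        tpr[cls] = int(c[i, i]) / row if row else None
    precision["PA|WT"], tpr["PA|WT"] = pooled_benign_metrics(cm)
    return {"total_accuracy": cm.trace / cm.total,
            "precision": precision, "tpr": tpr}


def pairwise_sens_spec(true_classes: Sequence[str],
                       predicted_classes: Sequence[str],
                       comparison: str) -> tuple:
    """Sensitivity and specificity with MT as the positive class.

    ``MT_vs_PA`` / ``MT_vs_WT`` consider only patients of those two true
    classes; ``MT_vs_benign`` counts any non-MT prediction as a benign call.
    """
    if comparison not in PAIRWISE_COMPARISONS:
        raise ValidationError(f"unknown comparison {comparison!r}")
    negatives = {"MT_vs_benign": {"PA", "WT"},
                 "MT_vs_PA": {"PA"}, "MT_vs_WT": {"WT"}}[comparison]
    pairs = [(t, p) for t, p in zip(true_classes, predicted_classes)
             if t == "MT" or t in negatives]
    n_pos = sum(1 for t, _ in pairs if t == "MT")
    n_neg = len(pairs) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValidationError(
            f"{comparison}: needs at least one positive and one negative patient"
        )
    tp = sum(1 for t, p in pairs if t == "MT" and p == "MT")
    tn = sum(1 for t, p in pairs if t != "MT" and p != "MT")
    return tp / n_pos, tn / n_neg


# ---------------------------------------------------------------------------
# reports

@dataclass(frozen=True, eq=False)
class MetricsReport:
    """One evaluation's metrics plus the configuration that produced it."""

    scheme: str                 # apparent | loocv | repeated_cv | bootstrap
    method: str                 # histogram | mean
    confusion_matrix: ConfusionMatrix
    total_accuracy: float
    precision: Mapping[str, float | None]
    tpr: Mapping[str, float | None]
    n_evaluated: int
    pairwise: Mapping[str, tuple] | None = None
    diagnostics: Mapping[str, object] = field(default_factory=dict)
    config: Mapping[str, object] = field(default_factory=dict)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MetricsReport):
            return NotImplemented
        return self.to_dict() == other.to_dict()

    def to_dict(self) -> dict:
        pairwise = None
        if self.pairwise is not None:
            pairwise = {k: {"sensitivity": v[0], "specificity": v[1]}
                        for k, v in sorted(self.pairwise.items())}
        return {
            "scheme": self.scheme,
            "method": self.method,
            "n_evaluated": self.n_evaluated,
            "confusion": self.confusion_matrix.to_dict(),
            "total_accuracy": self.total_accuracy,
            "precision": {k: self.precision[k] for k in (*CLASSES, "PA|WT")},
            "tpr": {k: self.tpr[k] for k in (*CLASSES, "PA|WT")},
            "pairwise_sens_spec": pairwise,
            "diagnostics": dict(sorted(self.diagnostics.items())),
            "config": dict(sorted(self.config.items())),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MetricsReport":
        pairwise = None
        if d.get("pairwise_sens_spec") is not None:
            pairwise = {k: (v["sensitivity"], v["specificity"])
                        for k, v in d["pairwise_sens_spec"].items()}
        return cls(scheme=d["scheme"], method=d["method"],
                   confusion_matrix=ConfusionMatrix.from_dict(d["confusion"]),
                   total_accuracy=d["total_accuracy"],
                   precision=d["precision"], tpr=d["tpr"],
                   n_evaluated=d["n_evaluated"], pairwise=pairwise,
                   diagnostics=d.get("diagnostics", {}),
                   config=d.get("config", {}))


def _report(scheme: str, method: str, true: list, pred: list,
            pairwise=None, diagnostics=None, config=None,
            overrides: dict | None = None) -> MetricsReport:
    cm = confusion(true, pred)
    m = metrics_from_confusion(cm)
    if overrides:
        m.update(overrides)
    return MetricsReport(scheme=scheme, method=method, confusion_matrix=cm,
                         total_accuracy=m["total_accuracy"],
                         precision=m["precision"], tpr=m["tpr"],
                         n_evaluated=len(true), pairwise=pairwise,
                         diagnostics=diagnostics or {}, config=config or {})


# ---------------------------------------------------------------------------
# shared evaluation plumbing

@dataclass(frozen=True)
class EvalConfig:
    """Knobs shared by every evaluation: binning, smoothing, overflow."""

    scheme: BinningScheme = BinningScheme()
    alpha: float = 0.5
    overflow_policy: str = "clamp"

    def to_dict(self) -> dict:
        return {"binning": self.scheme.to_dict(), "alpha": self.alpha,
                "overflow_policy": self.overflow_policy}


class _Prepared:
    """Per-patient histograms and means computed once per cohort."""

    def __init__(self, cohort: Cohort, config: EvalConfig):
        self.ids = [s.patient_id for s in cohort]
        self.classes = cohort.true_classes
        self.histograms = {
            s.patient_id: make_histogram(s.patient_id, s.voxels, config.scheme,
                                         config.overflow_policy)
            for s in cohort
        }
        self.means = {s.patient_id: patient_mean(s.voxels) for s in cohort}
        self.by_class = {c: [pid for pid in self.ids if self.classes[pid] == c]
                         for c in CLASSES}

    def fit(self, method: str, config: EvalConfig,
            train_ids: Sequence[str] | None = None,
            exclude: Iterable[str] = ()):
        """Fit the selected classifier on a training roster.

        ``train_ids`` is an explicit multiset (bootstrap); otherwise all
        non-excluded patients, each once.
        """
        exclude = frozenset(exclude)
        if method == "histogram":
            if train_ids is None:
                hists = [self.histograms[pid] for pid in self.ids]
            else:
                hists = [self.histograms[pid] for pid in train_ids]
            return fit_all_references(hists, self.classes, alpha=config.alpha,
                                      exclude_patient_ids=exclude)
        if method == "mean":
            roster = list(self.ids) if train_ids is None else list(train_ids)
            roster = [pid for pid in roster if pid not in exclude]
            return fit_mean_classifier(self.means, self.classes,
                                       duplicates=roster)
        raise ValidationError(f"unknown method {method!r}")

    def predict(self, method: str, model, pid: str,
                candidates: Sequence[str] = CLASSES) -> str:
        if method == "histogram":
            return chi2_classify(self.histograms[pid], model,
                                 candidate_classes=candidates).predicted_class
        return classify_mean(self.means[pid], model,
                             candidate_classes=candidates)


def _model_sources(method: str, model) -> frozenset:
    if method == "histogram":
        ids: set = set()
        for ref in model.values():
            ids |= ref.source_patient_ids
        return frozenset(ids)
    return model.source_patient_ids


# ---------------------------------------------------------------------------
# evaluation schemes

def apparent_metrics(cohort: Cohort, method: str = "histogram",
                     config: EvalConfig | None = None) -> MetricsReport:
    """Resubstitution evaluation: fit on the full cohort, classify everyone.

    Reports the three-way confusion metrics plus Table-3-style pairwise
    sensitivity/specificity, where MT-versus-PA and MT-versus-WT each use
    their own two-candidate decision on the relevant patients only.
    """
    config = config or EvalConfig()
    prep = _Prepared(cohort, config)
    model = prep.fit(method, config)
    true = [prep.classes[pid] for pid in prep.ids]
    pred = [prep.predict(method, model, pid) for pid in prep.ids]

    pairwise = {"MT_vs_benign": pairwise_sens_spec(true, pred, "MT_vs_benign")}
    for comparison, benign in (("MT_vs_PA", "PA"), ("MT_vs_WT", "WT")):
        subset = [pid for pid in prep.ids if prep.classes[pid] in ("MT", benign)]
        sub_true = [prep.classes[pid] for pid in subset]
        sub_pred = [prep.predict(method, model, pid, candidates=("MT", benign))
                    for pid in subset]
        pairwise[comparison] = pairwise_sens_spec(sub_true, sub_pred, comparison)

    return _report("apparent", method, true, pred, pairwise=pairwise,
                   config=config.to_dict())


def loocv(cohort: Cohort, method: str = "histogram",
          config: EvalConfig | None = None) -> MetricsReport:
    """Leave-one-out CV: refit without each patient, classify them three-way."""
    config = config or EvalConfig()
    for c, n in cohort.class_counts.items():
        if n < 2:
            raise ValidationError(f"LOOCV needs >= 2 patients per class; {c} has {n}")
    prep = _Prepared(cohort, config)
    true, pred = [], []
    for pid in prep.ids:
        model = prep.fit(method, config, exclude={pid})
        sources = _model_sources(method, model)
        if pid in sources:
            raise AssertionError(
                f"held-out patient {pid!r} leaked into a fitted model"
            )
        true.append(prep.classes[pid])
        pred.append(prep.predict(method, model, pid))
    return _report("loocv", method, true, pred, config=config.to_dict())


def _stratified_folds(prep: _Prepared, k: int, rng: np.random.Generator) -> list:
    """Deal each class's shuffled patients round-robin over k folds.

    Per-class fold sizes differ by at most one, so every fold keeps every
    class represented whenever the class has at least k patients; with k = n
    each fold is a single patient and the scheme degenerates to LOOCV.
    """
    folds: list = [[] for _ in range(k)]
    position = 0
    for c in CLASSES:
        ids = prep.by_class[c]
        for pid in (ids[j] for j in rng.permutation(len(ids))):
            folds[position % k].append(pid)
            position += 1
    return [f for f in folds if f]


def repeated_kfold(cohort: Cohort, method: str = "histogram",
                   config: EvalConfig | None = None, k: int = 10,
                   repeats: int = 1000, seed: int = 0,
                   aggregate: str = "micro") -> MetricsReport:
    """Repeated stratified k-fold CV, reproducible from ``seed``.

    Each repeat partitions the cohort into k class-stratified folds; each
    fold is classified by models fitted on its complement. All held-out
    predictions across folds and repeats pool into one confusion matrix
    (``aggregate="micro"``); ``"macro"`` instead averages per-repeat metrics,
    skipping repeats where a metric is undefined.
    """
    config = config or EvalConfig()
    if k < 2:
        raise ValidationError(f"k must be >= 2, got {k}")
    if repeats < 1:
        raise ValidationError(f"repeats must be >= 1, got {repeats}")
    if aggregate not in ("micro", "macro"):
        raise ValidationError(f"unknown aggregate {aggregate!r}")
    prep = _Prepared(cohort, config)
    rng = np.random.default_rng(seed)
    true, pred = [], []
    per_repeat: list = []
    skipped_folds = 0
    for _ in range(repeats):
        r_true: list = []
        r_pred: list = []
        for fold in _stratified_folds(prep, k, rng):
            try:
                model = prep.fit(method, config, exclude=set(fold))
            except ValidationError:
                skipped_folds += 1  # a whole class fell into this fold
                continue
            sources = _model_sources(method, model)
            for pid in fold:
                if pid in sources:
                    raise AssertionError(
                        f"held-out patient {pid!r} leaked into a fitted model"
                    )
                r_true.append(prep.classes[pid])
                r_pred.append(prep.predict(method, model, pid))
        true.extend(r_true)
        pred.extend(r_pred)
        if aggregate == "macro" and r_true:
            per_repeat.append(metrics_from_confusion(confusion(r_true, r_pred)))
    diagnostics = {"repeats": repeats, "k": k, "skipped_folds": skipped_folds}
    cfg = {**config.to_dict(), "k": k, "repeats": repeats, "seed": seed,
           "aggregate": aggregate}
    overrides = None
    if aggregate == "macro":
        overrides = _macro_average(per_repeat)
        diagnostics["macro_repeats_used"] = len(per_repeat)
    return _report("repeated_cv", method, true, pred,
                   diagnostics=diagnostics, config=cfg, overrides=overrides)


def _macro_average(per_repeat: list) -> dict:
    """Average per-repeat metrics, ignoring repeats where one is undefined."""
    def avg(values):
        defined = [v for v in values if v is not None]
        return float(np.mean(defined)) if defined else None

    keys = (*CLASSES, "PA|WT")
    return {
        "total_accuracy": avg([m["total_accuracy"] for m in per_repeat]),
        "precision": {key: avg([m["precision"][key] for m in per_repeat])
                      for key in keys},
        "tpr": {key: avg([m["tpr"][key] for m in per_repeat]) for key in keys},
    }


def bootstrap_cv(cohort: Cohort, method: str = "histogram",
                 config: EvalConfig | None = None, iterations: int = 1000,
                 seed: int = 0) -> MetricsReport:
    """Stratified bootstrap with out-of-bag evaluation, reproducible from seed.

    Each iteration draws, within every class, as many patients as the class
    holds, with replacement (so no class can vanish from the training set);
    models are fitted on that multiset and the never-drawn (out-of-bag)
    patients are classified three-way. Iterations with an empty out-of-bag
    set are skipped and counted in the diagnostics.
    """
    config = config or EvalConfig()
    if iterations < 1:
        raise ValidationError(f"iterations must be >= 1, got {iterations}")
    prep = _Prepared(cohort, config)
    rng = np.random.default_rng(seed)
    true, pred = [], []
    skipped_empty_oob = 0
    for _ in range(iterations):
        train: list = []
        for c in CLASSES:
            ids = prep.by_class[c]
            draws = rng.integers(0, len(ids), size=len(ids))
            train.extend(ids[j] for j in draws)
        oob = [pid for pid in prep.ids if pid not in set(train)]
        if not oob:
            skipped_empty_oob += 1
            continue
        model = prep.fit(method, config, train_ids=train)
        sources = _model_sources(method, model)
        for pid in oob:
            if pid in sources:
                raise AssertionError(
                    f"out-of-bag patient {pid!r} leaked into a fitted model"
                )
            true.append(prep.classes[pid])
            pred.append(prep.predict(method, model, pid))
    diagnostics = {"iterations": iterations,
                   "skipped_empty_oob": skipped_empty_oob}
    cfg = {**config.to_dict(), "iterations": iterations, "seed": seed}
    return _report("bootstrap", method, true, pred,
                   diagnostics=diagnostics, config=cfg)
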