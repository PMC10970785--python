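"""Model-robustness battery: specimen-aware cross-validation, permutation
and pseudo-class controls, learning curves, and summary metrics.

Sampling events from one specimen are statistically dependent, so the
default cross-validation splits at the specimen level, stratified by class:
no specimen ever contributes to both sides of a split. "20% leave-out" is
realized as repeated seeded specimen-stratified random splits rather than
exhaustive enumeration. An event-level ("leaky") split mode exists solely
to demonstrate how dependent data inflate cross-validation statistics when
a model is overfitted — the didactic overfitting signature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .classify import CLASSIFIED, classification_statistics
from .pcalda import PCALDAClassifier

__all__ = [
    "specimen_aware_split",
    "event_level_split",
    "leave_p_out_cv",
    "permuted_mixed_model",
    "pseudo_class_control",
    "learning_curve",
    "LearningCurveResult",
    "metrics",
    "MetricsResult",
    "concordance",
    "ValidationReport",
]


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def specimen_aware_split(specimens, labels, holdout_fraction: float = 0.2,
                         seed=0):
    """Split events into train/test with no specimen on both sides.

    Per class, round(fraction * specimens-in-class) specimens (at least 1)
    are held out. Returns (train_idx, test_idx) event-index arrays.
    """
    if not 0.0 < holdout_fraction < 1.0:
        raise ValueError("holdout_fraction must lie in (0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    specimens = np.asarray(specimens)
    labels = np.asarray(labels)
    test_specimens: list = []
    for lab in np.unique(labels):
        specs = np.unique(specimens[labels == lab])
        if specs.size < 2:
            raise ValueError(f"class {lab!r} has a single specimen; "
                             "specimen-aware splitting is impossible")
        n_hold = min(specs.size - 1,
                     max(1, _round_half_up(holdout_fraction * specs.size)))
        test_specimens.extend(rng.choice(specs, size=n_hold, replace=False))
    test_mask = np.isin(specimens, test_specimens)
    return np.flatnonzero(~test_mask), np.flatnonzero(test_mask)


def event_level_split(labels, holdout_fraction: float = 0.2, seed=0):
    """Class-stratified random event split that ignores specimen identity.

    Events of one specimen may land on both sides; use only for didactic
    comparison (overfitting demonstrations), never for validation claims.
    """
    if not 0.0 < holdout_fraction < 1.0:
        raise ValueError("holdout_fraction must lie in (0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    labels = np.asarray(labels)
    test_idx: list[int] = []
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        n_hold = min(idx.size - 1,
                     max(1, _round_half_up(holdout_fraction * idx.size)))
        test_idx.extend(rng.choice(idx, size=n_hold, replace=False))
    test_idx = np.sort(np.array(test_idx, dtype=int))
    train_mask = np.ones(labels.size, dtype=bool)
    train_mask[test_idx] = False
    return np.flatnonzero(train_mask), test_idx


@dataclass
class ValidationReport:
    """Aggregated cross-validation outcome.

    The confusion matrix counts classified events only (truth rows x
    predicted columns); no-calls are reported through unclassified_count
    and the duty cycle.
    """

    classes: list[str]
    confusion_matrix: np.ndarray
    unclassified_count: int
    accuracy: float | None
    per_class_sensitivity: np.ndarray
    per_class_specificity: np.ndarray
    kappa: float | None
    auroc_ovr: np.ndarray | None
    duty_cycle: float
    concordance: float | None
    concordance_per_specimen: dict[str, float]
    fold_assignments: list[dict[str, str]]
    n_events: int
    n_repeats: int
    pc_caps: list[int]
    threshold: float
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "classes": list(self.classes),
            "confusion_matrix": self.confusion_matrix.tolist(),
            "unclassified_count": int(self.unclassified_count),
            "accuracy": self.accuracy,
            "per_class_sensitivity": self.per_class_sensitivity.tolist(),
            "per_class_specificity": self.per_class_specificity.tolist(),
            "kappa": self.kappa,
            "auroc_ovr": None if self.auroc_ovr is None else self.auroc_ovr.tolist(),
            "duty_cycle": self.duty_cycle,
            "concordance": self.concordance,
            "concordance_per_specimen": self.concordance_per_specimen,
            "n_events": int(self.n_events),
            "n_repeats": int(self.n_repeats),
            "pc_caps": [int(c) for c in self.pc_caps],
            "threshold": self.threshold,
            "warnings": list(self.warnings),
        }


def leave_p_out_cv(X, y, specimens, p: float = 0.2, repeats: int = 25,
                   n_pc="fifth", threshold: float = 0.0, seed=0,
                   split_mode: str = "specimen",
                   **model_params) -> ValidationReport:
    """Repeated leave-p-out cross-validation of the PCA-LDA pipeline.

    Each repeat draws a fresh split, fits a model on the training side
    (n_pc resolved there, e.g. the one-fifth rule on the training size) and
    classifies the held-out side with the given posterior threshold
    (threshold 0 classifies every non-outlier event). Results aggregate over
    repeats into one report.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(str)
    specimens = np.asarray(specimens).astype(str)
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    classes = [str(c) for c in np.unique(y)]
    k = len(classes)
    class_to_col = {c: i for i, c in enumerate(classes)}

    counts = np.array([(y == c).sum() for c in classes])
    report_warnings: list[str] = []
    if counts.max() > 1.2 * counts.min():
        msg = ("unbalanced design: per-class event counts differ by more "
               f"than 20% ({dict(zip(classes, counts.tolist()))})")
        report_warnings.append(msg)
        warnings.warn(msg, stacklevel=2)

    confusion = np.zeros((k, k), dtype=int)
    unclassified = 0
    n_attempts = 0
    scores_rows: list[np.ndarray] = []
    scores_truth: list[str] = []
    spec_predictions: dict[str, list[str]] = {}
    fold_assignments: list[dict[str, str]] = []
    pc_caps: list[int] = []

    for _ in range(repeats):
        if split_mode == "specimen":
            train_idx, test_idx = specimen_aware_split(specimens, y, p, rng)
        elif split_mode == "event":
            train_idx, test_idx = event_level_split(y, p, rng)
        else:
            raise ValueError(f"unknown split_mode: {split_mode!r}")
        train_classes = set(y[train_idx])
        if train_classes != set(classes):
            raise ValueError("a training fold is missing a class; "
                             "increase specimens per class or reduce p")
        fold = {}
        for s in np.unique(specimens[train_idx]):
            fold[str(s)] = "train"
        for s in np.unique(specimens[test_idx]):
            fold[str(s)] = "test"
        fold_assignments.append(fold)

        model = PCALDAClassifier(n_pc=n_pc, threshold=threshold, **model_params)
        model.fit(X[train_idx], y[train_idx], specimens=specimens[train_idx])
        pc_caps.append(model.n_pc_)
        preds = model.classify(X[test_idx], event_ids=test_idx,
                               threshold=threshold)
        post = model.predict_proba(X[test_idx])
        model_cols = [class_to_col[str(c)] for c in model.classes_]
        for row, t in zip(post, y[test_idx]):
            full = np.zeros(k)
            full[model_cols] = row
            scores_rows.append(full)
            scores_truth.append(str(t))
        n_attempts += len(test_idx)
        for pred, idx in zip(preds, test_idx):
            truth_c = str(y[idx])
            if pred.status == CLASSIFIED:
                confusion[class_to_col[truth_c],
                          class_to_col[pred.predicted_class]] += 1
                spec_predictions.setdefault(str(specimens[idx]), []).append(
                    pred.predicted_class)
            else:
                unclassified += 1

    n_classified = int(confusion.sum())
    accuracy = float(np.trace(confusion)) / n_classified if n_classified else None
    duty = n_classified / n_attempts if n_attempts else 0.0
    m = metrics(confusion,
                scores=np.vstack(scores_rows) if scores_rows else None,
                truth=scores_truth if scores_truth else None,
                classes=classes, strict=False)
    conc_mean, conc_per_spec = concordance(spec_predictions)
    return ValidationReport(
        classes=classes, confusion_matrix=confusion,
        unclassified_count=unclassified, accuracy=accuracy,
        per_class_sensitivity=m.sensitivity,
        per_class_specificity=m.specificity,
        kappa=m.kappa, auroc_ovr=m.auroc_ovr, duty_cycle=duty,
        concordance=conc_mean, concordance_per_specimen=conc_per_spec,
        fold_assignments=fold_assignments, n_events=int(X.shape[0]),
        n_repeats=repeats, pc_caps=pc_caps, threshold=threshold,
        warnings=report_warnings)


def permuted_mixed_model(labels, seed=0, specimens=None, blocked: bool = False):
    """Mixed-class permutation control labels.

    Each pseudo-class receives an equal share (+-1, remainders assigned by
    seeded draw) of events from every true class, destroying any real class
    structure while preserving class sizes approximately. With
    ``blocked=True`` all events of a specimen move together.
    """
    labels = np.asarray(labels).astype(str)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("permutation control needs >= 2 classes")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    k = classes.size
    pseudo = np.empty(labels.size, dtype=labels.dtype)
    for lab in classes:
        if blocked:
            if specimens is None:
                raise ValueError("blocked permutation requires specimens")
            specimens_arr = np.asarray(specimens).astype(str)
            units = rng.permutation(np.unique(specimens_arr[labels == lab]))
            groups: list[list[int]] = [[] for _ in range(k)]
            for i, unit in enumerate(units):
                groups[i % k].extend(
                    np.flatnonzero((specimens_arr == unit) & (labels == lab)))
            chunks = [np.array(g, dtype=int) for g in groups]
        else:
            idx = rng.permutation(np.flatnonzero(labels == lab))
            base, extra = divmod(idx.size, k)
            sizes = np.full(k, base)
            sizes[:extra] += 1
            chunks = np.split(idx, np.cumsum(sizes)[:-1])
        for target, chunk in zip(rng.permutation(classes), chunks):
            pseudo[chunk] = target
    return pseudo


def pseudo_class_control(n_events: int, k: int, seed=0, prefix: str = "pseudo"):
    """Split one homogeneous class into k near-equal pseudo-classes.

    Returns an array of pseudo labels; CV on the result is the "no real
    structure" chance-level baseline. Requires at least 2 events per
    pseudo-class.
    """
    if k < 2:
        raise ValueError("need k >= 2 pseudo-classes")
    if n_events < 2 * k:
        raise ValueError("need at least 2 events per pseudo-class")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    idx = rng.permutation(n_events)
    base, extra = divmod(n_events, k)
    sizes = np.full(k, base)
    sizes[:extra] += 1
    out = np.empty(n_events, dtype=object)
    for j, chunk in enumerate(np.split(idx, np.cumsum(sizes)[:-1])):
        out[chunk] = f"{prefix}_{j + 1}"
    return out.astype(str)


@dataclass
class LearningCurveResult:
    """Per-usage-fraction CV metrics plus the PC caps actually used."""

    fractions: list[float]
    accuracies: list[float | None]
    pc_caps: list[int]
    specimens_used: list[int]
    saturated: list[bool]
    reports: list[ValidationReport]

    def to_dict(self) -> dict:
        return {"fractions": self.fractions,
                "accuracies": self.accuracies,
                "pc_caps": self.pc_caps,
                "specimens_used": self.specimens_used,
                "saturated": self.saturated}


def learning_curve(X, y, specimens, usage_fractions=None,
                   pc_rule="adaptive_fifth", repeats: int = 5, p: float = 0.2,
                   threshold: float = 0.0, seed=0,
                   split_mode: str = "specimen",
                   subsample_mode: str = "event",
                   saturation_tol: float = 0.02,
                   **model_params) -> LearningCurveResult:
    """Model performance as a function of data usage.

    For each usage fraction a nested, seeded, class-stratified subset of
    the data is drawn and leave-p-out CV runs on it. With
    ``subsample_mode="event"`` (default) sampling events are subsampled
    within every specimen, so all specimens stay represented at low usage
    — the way usage increments behave when a fixed specimen cohort is
    measured less; ``subsample_mode="specimen"`` drops whole specimens
    instead (every fraction must then leave >= 2 specimens per class).
    The ``adaptive_fifth`` rule re-derives the PC cap from each
    training-fold size; ``pc_rule=<int>`` pins the cap (the overfitting
    demonstration). A fraction is flagged saturated when its accuracy
    differs from the previous fraction's by less than ``saturation_tol``.
    """
    if usage_fractions is None:
        usage_fractions = [round(0.1 * i, 1) for i in range(1, 11)]
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(str)
    specimens = np.asarray(specimens).astype(str)
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    # Common random numbers: one CV seed (drawn first) shared by all
    # fractions, so fold draws are matched along the curve and
    # consecutive-fraction differences reflect data usage rather than
    # split resampling noise.
    cv_seed = int(rng.integers(0, 2 ** 31 - 1))

    # One seeded order per class; fractions take growing prefixes (nested).
    order: dict[str, np.ndarray] = {}
    if subsample_mode == "specimen":
        for lab in np.unique(y):
            order[lab] = rng.permutation(np.unique(specimens[y == lab]))
    elif subsample_mode == "event":
        for lab in np.unique(y):
            order[lab] = rng.permutation(np.flatnonzero(y == lab))
    else:
        raise ValueError(f"unknown subsample_mode: {subsample_mode!r}")

    if pc_rule == "adaptive_fifth":
        n_pc_for = lambda: "fifth"  # noqa: E731
    elif isinstance(pc_rule, (int, np.integer)):
        n_pc_for = lambda: int(pc_rule)  # noqa: E731
    else:
        raise ValueError("pc_rule must be 'adaptive_fifth' or an integer cap")

    fractions, accuracies, caps, n_specs, reports = [], [], [], [], []
    for frac in usage_fractions:
        if subsample_mode == "specimen":
            keep: list[str] = []
            for lab, specs in order.items():
                n_use = max(2, _round_half_up(frac * specs.size))
                if n_use > specs.size:
                    raise ValueError(f"fraction {frac} infeasible for class {lab!r}")
                keep.extend(specs[:n_use])
            mask = np.isin(specimens, keep)
        else:
            idx: list[int] = []
            for lab, events in order.items():
                n_use = max(4, _round_half_up(frac * events.size))
                idx.extend(events[:min(n_use, events.size)])
            mask = np.zeros(y.size, dtype=bool)
            mask[idx] = True
        report = leave_p_out_cv(X[mask], y[mask], specimens[mask], p=p,
                                repeats=repeats, n_pc=n_pc_for(),
                                threshold=threshold, seed=cv_seed,
                                split_mode=split_mode, **model_params)
        fractions.append(float(frac))
        accuracies.append(report.accuracy)
        caps.append(max(report.pc_caps))
        n_specs.append(int(np.unique(specimens[mask]).size))
        reports.append(report)

    saturated = [False]
    for prev, curr in zip(accuracies, accuracies[1:]):
        saturated.append(prev is not None and curr is not None
                         and abs(curr - prev) < saturation_tol)
    return LearningCurveResult(fractions=fractions, accuracies=accuracies,
                               pc_caps=caps, specimens_used=n_specs,
                               saturated=saturated, reports=reports)


@dataclass
class MetricsResult:
    sensitivity: np.ndarray
    specificity: np.ndarray
    kappa: float | None
    auroc_ovr: np.ndarray | None


def metrics(confusion_matrix, scores=None, truth=None,
            classes=None, strict: bool = True) -> MetricsResult:
    """Per-class sensitivity/specificity, Cohen's kappa, one-vs-rest AUROC.

    kappa = (p_o - p_e) / (1 - p_e) with chance agreement p_e from the
    row/column marginals; a degenerate matrix with p_e = 1 raises in strict
    mode and yields kappa None otherwise. AUROC per class uses the rank
    statistic on posterior scores with midranks for ties; it needs
    ``scores`` (events x classes) and per-event ``truth``.
    """
    C = np.asarray(confusion_matrix, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1] or C.size == 0:
        raise ValueError("confusion matrix must be square and non-empty")
    k = C.shape[0]
    total = C.sum()
    sens = np.full(k, np.nan)
    spec = np.full(k, np.nan)
    for c in range(k):
        tp = C[c, c]
        fn = C[c].sum() - tp
        fp = C[:, c].sum() - tp
        tn = total - tp - fn - fp
        if tp + fn > 0:
            sens[c] = tp / (tp + fn)
        if tn + fp > 0:
            spec[c] = tn / (tn + fp)
    kappa = None
    if total > 0:
        p_o = np.trace(C) / total
        p_e = float((C.sum(axis=1) * C.sum(axis=0)).sum()) / total ** 2
        if p_e >= 1.0:
            if strict:
                raise ValueError("chance agreement p_e = 1; kappa undefined")
            kappa = None
        else:
            kappa = float((p_o - p_e) / (1.0 - p_e))
    auroc = None
    if scores is not None:
        if truth is None or classes is None:
            raise ValueError("AUROC needs scores, truth and classes")
        scores = np.asarray(scores, dtype=float)
        truth = np.asarray(truth).astype(str)
        auroc = np.full(k, np.nan)
        for c, lab in enumerate(classes):
            pos = truth == str(lab)
            n_pos, n_neg = int(pos.sum()), int((~pos).sum())
            if n_pos == 0 or n_neg == 0:
                continue
            ranks = rankdata(scores[:, c])
            auroc[c] = (ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) \
                / (n_pos * n_neg)
    return MetricsResult(sensitivity=sens, specificity=spec, kappa=kappa,
                         auroc_ovr=auroc)


def concordance(spec_predictions: dict[str, list[str]]):
    """Spatial concordance: per-specimen agreement with the modal call.

    Input maps specimen id to its list of classified predictions; specimens
    with fewer than two classified events are excluded. Returns (dataset
    mean or None, per-specimen dict). Modal ties break toward the
    alphabetically first class.
    """
    per_spec: dict[str, float] = {}
    for spec_id, preds in spec_predictions.items():
        if len(preds) < 2:
            continue
        values, counts = np.unique(np.asarray(preds, dtype=str),
                                   return_counts=True)
        per_spec[str(spec_id)] = float(counts.max() / len(preds))
    mean = float(np.mean(list(per_spec.values()))) if per_spec else None
    return mean, per_spec
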