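"""Cross-validation protocols, metrics and the model-variant harness.

Two protocols are implemented:

* *subject-dependent*: within one subject, trials are partitioned into
  folds (10 by default, each holding out ~10% of trials); windows follow
  their trial so no trial is split across train and test;
* *LOSO* (leave-one-subject-out): one fold per subject, testing on the
  whole held-out subject.

When domain adaptation is on, the source domain is the training windows
and the target domain is the *unlabelled* test-fold windows
(transductive adaptation — test inputs, never test labels, participate
in training).  A leakage audit verifies that no test window's
(subject, trial, start) identity appears on the training side.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .connectivity import ConnectivityTransformer, PSDTransformer
from .model import DomainAdaptiveRCNN
from .preprocessing import LabeledWindows


@dataclass
class Metrics:
    """Binary-classification confusion counts; class 1 is positive."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def acc(self) -> float:
        return (self.tp + self.tn) / max(self.tp + self.tn + self.fp + self.fn, 1)

    @property
    def sn(self) -> float:
        """Sensitivity TP/(TP+FN)."""
        return self.tp / max(self.tp + self.fn, 1)

    @property
    def sp(self) -> float:
        """Specificity TN/(TN+FP)."""
        return self.tn / max(self.tn + self.fp, 1)

    def as_dict(self) -> dict:
        return {"tp": self.tp, "tn": self.tn, "fp": self.fp, "fn": self.fn,
                "acc": self.acc, "sn": self.sn, "sp": self.sp}


def evaluate(y_true: np.ndarray, y_pred: np.ndarray) -> Metrics:
    """Confusion-count metrics with label 1 as the positive class."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) == 0:
        raise ValueError("empty test set")
    if y_true.shape != y_pred.shape:
        raise ValueError("prediction/label length mismatch")
    return Metrics(tp=int(((y_true == 1) & (y_pred == 1)).sum()),
                   tn=int(((y_true == 0) & (y_pred == 0)).sum()),
                   fp=int(((y_true == 0) & (y_pred == 1)).sum()),
                   fn=int(((y_true == 1) & (y_pred == 0)).sum()))


@dataclass
class CVScheme:
    """Fold definitions over trials (subject-dependent) or subjects (LOSO)."""

    kind: str                       # "subject_dependent" | "loso"
    unit: str                       # "trial" | "subject"
    folds: list[np.ndarray]         # held-out unit ids per fold
    seed: int = 0

    def __post_init__(self) -> None:
        flat = np.concatenate(self.folds) if self.folds else np.array([])
        if len(np.unique(flat)) != len(flat):
            raise ValueError("folds must be pairwise disjoint")


def make_subject_dependent_folds(trial_ids, n_folds: int = 10, seed: int = 0) -> CVScheme:
    """Random disjoint trial folds within one subject (default 10 x 10%)."""
    trials = np.unique(np.asarray(trial_ids))
    if len(trials) < n_folds:
        raise ValueError(f"{len(trials)} trials cannot form {n_folds} non-empty folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(trials)
    folds = [np.sort(f) for f in np.array_split(perm, n_folds)]
    return CVScheme(kind="subject_dependent", unit="trial", folds=folds, seed=seed)


def make_loso_folds(subject_ids) -> CVScheme:
    """One fold per subject: test on that subject, train on all others."""
    subjects = np.unique(np.asarray(subject_ids))
    if len(subjects) < 2:
        raise ValueError("leave-one-subject-out needs at least 2 subjects")
    return CVScheme(kind="loso", unit="subject", folds=[np.array([s]) for s in subjects])


def audit_no_leakage(dataset: LabeledWindows, train_idx: np.ndarray,
                     test_idx: np.ndarray) -> None:
    """Raise if any test window identity appears on the training side."""
    if np.intersect1d(train_idx, test_idx).size:
        raise AssertionError("train and test indices overlap")
    train_keys = dataset.select(train_idx).provenance_keys()
    test_keys = dataset.select(test_idx).provenance_keys()
    common = train_keys & test_keys
    if common:
        raise AssertionError(f"leakage: {len(common)} windows appear in both train and test")


def _fold_indices(dataset: LabeledWindows, scheme: CVScheme,
                  fold: np.ndarray, subject=None) -> tuple[np.ndarray, np.ndarray]:
    if scheme.unit == "trial":
        ids = dataset.trial_ids
        scope = np.ones(len(dataset), dtype=bool) if subject is None \
            else dataset.subject_ids == subject
    else:
        ids = dataset.subject_ids
        scope = np.ones(len(dataset), dtype=bool)
    test_mask = scope & np.isin(ids, fold)
    train_mask = scope & ~np.isin(ids, fold)
    return np.flatnonzero(train_mask), np.flatnonzero(test_mask)


def train_fold(features: np.ndarray, dataset: LabeledWindows,
               train_idx: np.ndarray, test_idx: np.ndarray,
               target: str = "valence", domain_adapt: bool = False,
               model_params: dict | None = None, seed: int = 0) -> tuple[Metrics, list[dict]]:
    """Fit one fold and evaluate on its held-out windows.

    The model is re-initialized from ``seed``; with ``domain_adapt`` the
    test-fold windows are passed as the unlabelled target domain.
    """
    audit_no_leakage(dataset, train_idx, test_idx)
    y = dataset.labels(target)
    params = dict(model_params or {})
    params.update(domain_adapt=domain_adapt, random_state=seed)
    clf = DomainAdaptiveRCNN(**params)
    X_target = features[test_idx] if domain_adapt else None
    clf.fit(features[train_idx], y[train_idx], X_target=X_target)
    pred = clf.predict(features[test_idx])
    return evaluate(y[test_idx], pred), clf.history_


def cross_validate(features: np.ndarray, dataset: LabeledWindows, scheme: CVScheme,
                   target: str = "valence", domain_adapt: bool = False,
                   model_params: dict | None = None, seed: int = 0,
                   subject=None) -> list[Metrics]:
    """Run every fold of a CV scheme; returns per-fold metrics."""
    out = []
    for fold in scheme.folds:
        train_idx, test_idx = _fold_indices(dataset, scheme, fold, subject=subject)
        m, _ = train_fold(features, dataset, train_idx, test_idx, target=target,
                          domain_adapt=domain_adapt, model_params=model_params, seed=seed)
        out.append(m)
    return out


#: Full-scale optimization settings per scenario (initial learning rate
#: 1e-4 retained as the documented fallback).
INITIAL_LEARNING_RATE = 1e-4
DEPENDENT_HPARAMS = {"learning_rate": 1e-3, "batch_size": 40, "epochs": 200}
LOSO_HPARAMS = {"learning_rate": 5e-3, "batch_size": 128, "epochs": 150}

#: Model-variant grid: feature family x domain adaptation.
VARIANTS = {
    "RCNN": ("psd", False),
    "DA-RCNN": ("psd", True),
    "BC-RCNN": ("connectivity", False),
    "BC-DA-RCNN": ("connectivity", True),
}


def variant_features(dataset: LabeledWindows, feature_kind: str,
                     measure: str = "plv", order=None,
                     cache: dict | None = None) -> np.ndarray:
    """Windows to model inputs for a variant; optionally memoized."""
    key = (feature_kind, measure)
    if cache is not None and key in cache:
        return cache[key]
    if feature_kind == "psd":
        feats = PSDTransformer(fs=dataset.fs).transform(dataset.windows)
    elif feature_kind == "connectivity":
        feats = ConnectivityTransformer(measure=measure, order=order,
                                        fs=dataset.fs).transform(dataset.windows)
    else:
        raise ValueError(f"unknown feature kind {feature_kind!r}")
    if cache is not None:
        cache[key] = feats
    return feats


def run_variant(variant: str, dataset: LabeledWindows, scheme: CVScheme,
                target: str = "valence", measure: str = "plv", order=None,
                model_params: dict | None = None, seed: int = 0,
                feature_cache: dict | None = None) -> dict:
    """Train and evaluate one model variant over a full CV scheme.

    Returns a dict with per-fold metrics and their mean accuracy /
    sensitivity / specificity, mirroring the ablation table layout.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; pick from {sorted(VARIANTS)}")
    feature_kind, da = VARIANTS[variant]
    feats = variant_features(dataset, feature_kind, measure=measure, order=order,
                             cache=feature_cache)
    metrics = cross_validate(feats, dataset, scheme, target=target, domain_adapt=da,
                             model_params=model_params, seed=seed)
    return {
        "variant": variant,
        "feature": feature_kind if feature_kind == "psd" else measure,
        "domain_adapt": da,
        "folds": [m.as_dict() for m in metrics],
        "acc": float(np.mean([m.acc for m in metrics])),
        "sn": float(np.mean([m.sn for m in metrics])),
        "sp": float(np.mean([m.sp for m in metrics])),
    }
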