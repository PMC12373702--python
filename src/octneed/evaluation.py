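"""Patient-level cross-validation, ROC/AUC and EER operating points.

Evaluation follows the study protocol: repeated (default 5 x) fivefold
cross-validation at patient level, with each fold splitting the cohort
into 64% training, 16% validation and 20% test so that every patient is
tested exactly once per repeat.  Per repeat, the pooled test scores
yield one ROC curve and AUC; results report the mean and standard
deviation of the AUC over repeats plus sensitivity/specificity at the
equal-error-rate (EER) operating point — the threshold where the
false-negative and false-positive rates coincide — and the accuracy at
that threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, NamedTuple, Optional, Sequence

import numpy as np
from sklearn import metrics as _skm
from sklearn.model_selection import KFold, StratifiedKFold

from . import models as _models
from .datasets import CohortDataset

__all__ = [
    "FoldPlan",
    "ROCCurve",
    "EERPoint",
    "CVResult",
    "make_folds",
    "roc_auc",
    "eer_operating_point",
    "accuracy_at_threshold",
    "run_experiment",
]


@dataclass(frozen=True)
class FoldPlan:
    """Patient-id assignments for one round of k-fold cross-validation."""

    folds: tuple  # of dicts with 'train', 'val', 'test' id arrays
    seed: int

    def validate(self, patient_ids: Sequence[str]) -> None:
        """Test sets partition the cohort; roles are disjoint within folds."""
        all_test = np.concatenate([f["test"] for f in self.folds])
        if len(np.unique(all_test)) != len(all_test):
            raise AssertionError("a patient appears in two test folds")
        if set(all_test) != set(patient_ids):
            raise AssertionError("test folds do not cover the cohort")
        for f in self.folds:
            roles = [set(f["train"]), set(f["val"]), set(f["test"])]
            for i in range(3):
                for j in range(i + 1, 3):
                    if roles[i] & roles[j]:
                        raise AssertionError("patient assigned to two roles in a fold")


def make_folds(
    patient_ids: Sequence[str],
    k: int = 5,
    seed: int = 0,
    labels: Optional[Sequence[int]] = None,
    val_fraction: float = 0.2,
) -> FoldPlan:
    """Patient-level k-fold plan with a rotating held-out test set.

    Each patient is tested exactly once; the remaining patients are
    randomly divided into training and validation (by default 64%/16%
    of the cohort for k=5).  With ``labels`` the test split is
    stratified to preserve the class ratio.
    """
    ids = np.asarray(patient_ids)
    if len(ids) < k:
        raise ValueError(f"need at least {k} patients for {k}-fold CV")
    if len(np.unique(ids)) != len(ids):
        raise ValueError("patient ids must be unique")
    rng = np.random.default_rng(seed)
    rs = int(rng.integers(2**31))
    if labels is not None and np.bincount(np.asarray(labels).astype(int)).min() < k:
        warnings.warn("a class has fewer members than folds; dropping stratification",
                      UserWarning, stacklevel=2)
        labels = None
    if labels is not None:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=rs)
        split_iter = splitter.split(ids, np.asarray(labels))
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=rs)
        split_iter = splitter.split(ids)
    folds = []
    for rest_idx, test_idx in split_iter:
        rest = rng.permutation(rest_idx)
        n_val = int(round(val_fraction * len(rest)))
        folds.append({
            "val": ids[np.sort(rest[:n_val])],
            "train": ids[np.sort(rest[n_val:])],
            "test": ids[np.sort(test_idx)],
        })
    plan = FoldPlan(folds=tuple(folds), seed=seed)
    plan.validate(ids)
    return plan


class ROCCurve(NamedTuple):
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray


def roc_auc(scores: Sequence[float], labels: Sequence[int]):
    """ROC curve over all score thresholds and its trapezoidal area.

    The area equals the normalized Mann-Whitney U statistic (probability
    that a random positive outscores a random negative, ties half).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    fpr, tpr, thr = _skm.roc_curve(y, s, drop_intermediate=False)
    return ROCCurve(fpr, tpr, thr), float(_skm.auc(fpr, tpr))


class EERPoint(NamedTuple):
    sensitivity: float
    specificity: float
    threshold: float


def eer_operating_point(curve: ROCCurve) -> EERPoint:
    """Operating point where the false-negative and false-positive rates meet.

    Linear interpolation between ROC vertices when the FNR = FPR crossing
    falls inside a segment; at the crossing sensitivity equals
    specificity.  A degenerate single-threshold curve yields the chance
    point with a warning.
    """
    fpr, tpr, thr = np.asarray(curve.fpr), np.asarray(curve.tpr), np.asarray(curve.thresholds)
    if len(fpr) < 2:
        raise ValueError("degenerate ROC curve")
    if len(fpr) <= 2:
        warnings.warn("all scores identical; EER point is the chance point", UserWarning,
                      stacklevel=2)
    d = (1.0 - tpr) - fpr  # FNR - FPR, monotonically decreasing along the curve
    idx = None
    for i in range(len(d) - 1):
        if d[i] == 0:
            idx = (i, 0.0)
            break
        if d[i] > 0 >= d[i + 1]:
            t = d[i] / (d[i] - d[i + 1])
            idx = (i, t)
            break
    if idx is None:
        i = int(np.argmin(np.abs(d)))
        fp, tp = fpr[i], tpr[i]
        th = thr[i]
    else:
        i, t = idx
        fp = fpr[i] + t * (fpr[i + 1] - fpr[i])
        tp = tpr[i] + t * (tpr[i + 1] - tpr[i])
        lo = thr[i + 1] if not np.isfinite(thr[i]) else thr[i]
        th = lo + t * (thr[i + 1] - lo) if np.isfinite(lo) else thr[i + 1]
    return EERPoint(sensitivity=float(tp), specificity=float(1.0 - fp), threshold=float(th))


def accuracy_at_threshold(scores, labels, threshold: float) -> float:
    """Fraction of correct calls when scores >= threshold are positive."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    return float(np.mean((s >= threshold).astype(int) == y))


@dataclass
class CVResult:
    """Repeated cross-validation outcome in the study's reporting shape."""

    experiment_id: str
    model_kind: str
    mode: str
    aucs: np.ndarray
    pooled_scores: np.ndarray
    pooled_labels: np.ndarray
    eer: EERPoint
    accuracy: float
    n_positive: int
    n_negative: int
    n_excluded: int
    fold_records: list = field(default_factory=list)

    @property
    def auc_mean(self) -> float:
        return float(np.mean(self.aucs))

    @property
    def auc_std(self) -> float:
        return float(np.std(self.aucs))

    @property
    def sensitivity(self) -> float:
        return self.eer.sensitivity

    @property
    def specificity(self) -> float:
        return self.eer.specificity

    def roc(self):
        curve, _ = roc_auc(self.pooled_scores, self.pooled_labels)
        return curve

    def plot_roc(self, ax=None):
        """Pooled ROC curve with the EER diagonal, matplotlib axes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        curve = self.roc()
        ax.plot(curve.fpr, curve.tpr,
                label=f"AUC = {self.auc_mean:.2f} ± {self.auc_std:.2f}")
        ax.plot([0, 1], [1, 0], "k:", lw=0.8)
        ax.plot([0, 1], [0, 1], "k--", lw=0.8)
        ax.set_xlabel("false positive rate")
        ax.set_ylabel("true positive rate")
        ax.legend(loc="lower right")
        return ax

    def summary(self) -> str:
        return "\n".join([
            f"Experiment {self.experiment_id} [{self.model_kind}, {self.mode}] — "
            f"{len(self.aucs)} x fivefold CV",
            f"  AUC      {self.auc_mean:.2f} ± {self.auc_std:.2f}",
            f"  accuracy {self.accuracy:.0%} at the EER operating point",
            f"  sens/spec at EER  {self.sensitivity:.0%} / {self.specificity:.0%}",
            f"  groups: {self.n_positive} positive / {self.n_negative} negative"
            + (f" ({self.n_excluded} excluded: label undefined)" if self.n_excluded else ""),
        ])


def _fit_and_score(model_kind, mode, X, y, tr, va, te, seed, net_config, pretrained, l2):
    if model_kind == "logreg":
        trva = np.concatenate([tr, va])
        if len(np.unique(y[trva])) < 2:
            warnings.warn("single-class training fold; predicting the prior",
                          UserWarning, stacklevel=2)
            return np.full(len(te), float(np.mean(y[trva])))
        res = _models.FluidLogit(X[trva], y[trva], feature_names=None,
                                 class_weight="balanced").fit(l2_strength=l2)
        return res.predict_proba(X[te])
    if model_kind == "cnn":
        cfg = net_config or _models.NetConfig()
        if mode == "transfer":
            if pretrained is None:
                raise ValueError("transfer mode requires pretrained weights")
            res = _models.fine_tune(pretrained, cfg, X[tr], y[tr], X[va], y[va], seed=seed)
        else:
            res = _models.train_from_scratch(cfg, X[tr], y[tr], X[va], y[va], seed=seed)
        return res.predict_proba(X[te])
    raise ValueError(f"unknown model kind {model_kind!r}")


def run_experiment(
    dataset: CohortDataset,
    experiment_id: str,
    model_kind: str = "logreg",
    mode: str = "scratch",
    repeats: int = 5,
    seed: int = 0,
    k: int = 5,
    net_config=None,
    pretrained_weights: Optional[Dict] = None,
    l2_strength: float = 1.0,
) -> CVResult:
    """Repeated fivefold cross-validation of one experiment's endpoint.

    Patients whose label is undefined for the experiment (or whose study
    arm is not analysed in it) are excluded and counted.  Scores are
    pooled per repeat for the AUC; the EER operating point and its
    accuracy are computed on the scores pooled over all repeats.
    """
    defined, y_all = dataset.experiment_labels(experiment_id)
    n_excluded = int((~defined).sum())
    idx = np.flatnonzero(defined)
    if idx.size == 0:
        raise ValueError(f"no patient has a defined label for experiment {experiment_id}")
    ids = dataset.patient_ids[idx]
    y = y_all[idx]
    X = dataset.predictor_matrix("features" if model_kind == "logreg" else "volumes")[idx]
    pos = {pid: i for i, pid in enumerate(ids)}

    ss = np.random.SeedSequence(seed)
    repeat_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(repeats)]
    aucs, fold_records = [], []
    pooled_scores, pooled_labels = [], []
    for r, rseed in enumerate(repeat_seeds):
        plan = make_folds(ids, k=k, seed=rseed, labels=y)
        scores_r = np.full(len(ids), np.nan)
        for f_i, f in enumerate(plan.folds):
            tr = np.array([pos[p] for p in f["train"]])
            va = np.array([pos[p] for p in f["val"]])
            te = np.array([pos[p] for p in f["test"]])
            s = _fit_and_score(model_kind, mode, X, y, tr, va, te,
                               seed=rseed + f_i, net_config=net_config,
                               pretrained=pretrained_weights, l2=l2_strength)
            scores_r[te] = s
            fold_records.append({"repeat": r, "fold": f_i, "test_ids": f["test"],
                                 "scores": s, "labels": y[te]})
        _, auc_r = roc_auc(scores_r, y)
        aucs.append(auc_r)
        pooled_scores.append(scores_r)
        pooled_labels.append(y)
    pooled_scores = np.concatenate(pooled_scores)
    pooled_labels = np.concatenate(pooled_labels)
    curve, _ = roc_auc(pooled_scores, pooled_labels)
    eer = eer_operating_point(curve)
    acc = accuracy_at_threshold(pooled_scores, pooled_labels, eer.threshold)
    return CVResult(
        experiment_id=experiment_id,
        model_kind=model_kind,
        mode=mode,
        aucs=np.asarray(aucs),
        pooled_scores=pooled_scores,
        pooled_labels=pooled_labels,
        eer=eer,
        accuracy=acc,
        n_positive=int(y.sum()),
        n_negative=int(len(y) - y.sum()),
        n_excluded=n_excluded,
        fold_records=fold_records,
    )
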