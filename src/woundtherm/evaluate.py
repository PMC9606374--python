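"""Repeated 70/30 holdout evaluation of the healing classifier.

Each repetition draws a stratified random split of the feature table,
fits PCA on the training rows only, projects both sides to the leading
three principal-component scores, selects and trains the Bayesian-evidence
network on the training scores, and scores both sides.  Sensitivity is the
correct detection rate of UNHEALED wounds (the positive class) and
specificity that of healed wounds.  Aggregates are the mean and SD over
repetitions; the "best" repetition (maximal test sensitivity, ties broken
by specificity) also reports its training-set ROC curve and AUC.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import bnn
from .pca import PCAModel, fit_pca, project
from .texture import FEATURE_NAMES

__all__ = [
    "SplitSpec",
    "PipelineConfig",
    "RepetitionResult",
    "EvaluationReport",
    "split_data",
    "confusion_counts",
    "sensitivity_specificity",
    "roc_curve",
    "auc",
    "run_experiment",
]

LABELS = ("healed", "unhealed")
POSITIVE = "unhealed"


@dataclass(frozen=True)
class SplitSpec:
    train_fraction: float = 0.70
    n_repetitions: int = 20
    stratified: bool = True
    master_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_repetitions < 1:
            raise ValueError("n_repetitions must be >= 1")


@dataclass(frozen=True)
class PipelineConfig:
    """Model settings shared by every repetition."""

    n_components: int = 3
    h_range: tuple[int, ...] = tuple(range(1, 10))
    restarts: int = 5
    alpha0: float = 0.1
    threshold: float = 0.5
    standardize_pca: bool = False


@dataclass
class RepetitionResult:
    rep_index: int
    selected_h: int
    threshold: float
    train_sensitivity: float
    train_specificity: float
    test_sensitivity: float
    test_specificity: float


@dataclass
class EvaluationReport:
    repetitions: list[RepetitionResult]
    mean_train: tuple[float, float]  # (sensitivity, specificity)
    sd_train: tuple[float, float]
    mean_test: tuple[float, float]
    sd_test: tuple[float, float]
    best_rep_index: int
    best_train_roc: list[tuple[float, float]]  # (FPR, TPR) points
    best_train_auc: float
    n_failed: int
    config: dict

    def to_json(self, path: str | Path) -> None:
        doc = {
            "repetitions": [asdict(r) for r in self.repetitions],
            "mean_train": list(self.mean_train),
            "sd_train": list(self.sd_train),
            "mean_test": list(self.mean_test),
            "sd_test": list(self.sd_test),
            "best_rep_index": self.best_rep_index,
            "best_train_roc": [list(p) for p in self.best_train_roc],
            "best_train_auc": self.best_train_auc,
            "n_failed": self.n_failed,
            "config": self.config,
        }
        Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True))


def split_data(
    table: pd.DataFrame, spec: SplitSpec, rep_index: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified random train/test split, seeded by (master_seed, rep_index).

    The per-class test size is ``floor(n_class * (1 - train_fraction))`` —
    with the 47/17 study composition at 70% this yields a 45-row training
    set and a 19-row (14 unhealed / 5 healed) test set.
    """
    if not set(table["label"]) <= set(LABELS):
        raise ValueError("labels must be 'healed'/'unhealed'")
    rng = np.random.default_rng(np.random.SeedSequence([spec.master_seed, rep_index]))
    test_frac = 1.0 - spec.train_fraction
    test_idx: list[int] = []
    if spec.stratified:
        groups = [table.index[table["label"] == lab] for lab in LABELS]
    else:
        groups = [table.index]
    for idx in groups:
        n_test = int(np.floor(len(idx) * test_frac))
        perm = rng.permutation(len(idx))
        test_idx.extend(idx[perm[:n_test]])
    test = table.loc[sorted(test_idx)]
    train = table.drop(index=test_idx).sort_index()
    for part, name in ((train, "training"), (test, "test")):
        if set(part["label"]) != set(LABELS):
            raise ValueError(f"a class is absent from the {name} side")
    return train, test


def confusion_counts(
    true_labels: Sequence[str], pred_labels: Sequence[str], positive: str = POSITIVE
) -> tuple[int, int, int, int]:
    """(TP, FN, TN, FP) with unhealed as the positive class by default."""
    true_labels = list(true_labels)
    pred_labels = list(pred_labels)
    if len(true_labels) == 0:
        raise ValueError("empty label sequences")
    if len(true_labels) != len(pred_labels):
        raise ValueError("label sequences differ in length")
    bad = set(true_labels) | set(pred_labels)
    if not bad <= set(LABELS):
        raise ValueError(f"unknown labels: {bad - set(LABELS)}")
    tp = fn = tn = fp = 0
    for t, p in zip(true_labels, pred_labels):
        if t == positive:
            tp += p == positive
            fn += p != positive
        else:
            tn += p != positive
            fp += p == positive
    return tp, fn, tn, fp


def sensitivity_specificity(
    counts: tuple[int, int, int, int]
) -> tuple[float, float]:
    tp, fn, tn, fp = counts
    if tp + fn == 0 or tn + fp == 0:
        raise ValueError("a class is empty: sensitivity/specificity undefined")
    return tp / (tp + fn), tn / (tn + fp)


def roc_curve(
    probabilities: Sequence[float], true_labels: Sequence[str]
) -> list[tuple[float, float]]:
    """(FPR, TPR) points from threshold +inf down to -inf, (0,0) to (1,1)."""
    y = np.asarray(probabilities, dtype=float)
    t = np.asarray([lab == POSITIVE for lab in true_labels])
    n_pos, n_neg = int(t.sum()), int((~t).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs both classes present")
    order = np.argsort(-y, kind="mergesort")
    points = [(0.0, 0.0)]
    tp = fp = 0
    prev = np.inf
    for k in order:
        if y[k] != prev:
            points.append((fp / n_neg, tp / n_pos))
            prev = y[k]
        if t[k]:
            tp += 1
        else:
            fp += 1
    points.append((fp / n_neg, tp / n_pos))
    # drop the duplicated first point emitted before any count moved
    dedup = [points[0]]
    for pt in points[1:]:
        if pt != dedup[-1]:
            dedup.append(pt)
    if dedup[-1] != (1.0, 1.0):
        dedup.append((1.0, 1.0))
    return dedup


def auc(points: Sequence[tuple[float, float]]) -> float:
    """Trapezoidal area under an ROC polyline."""
    pts = sorted(points)
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    return float(np.trapezoid(y, x))


def _binary_targets(labels: Sequence[str]) -> np.ndarray:
    return np.asarray([1.0 if lab == POSITIVE else 0.0 for lab in labels])


def run_experiment(
    table: pd.DataFrame,
    spec: SplitSpec = SplitSpec(),
    config: PipelineConfig = PipelineConfig(),
) -> EvaluationReport:
    """Repeated-holdout evaluation of the full PCA + network pipeline.

    The held-out rows touch the models only through PCA projection and
    prediction — never fitting — so no information leaks from test to train.
    Failed repetitions are recorded and excluded from the aggregates.
    """
    reps: list[RepetitionResult] = []
    best_roc: list[tuple[float, float]] = []
    best_auc = float("nan")
    best_key: tuple[float, float] | None = None
    best_idx = -1
    n_failed = 0
    rep_rng = np.random.default_rng(np.random.SeedSequence([spec.master_seed, 9999]))

    for rep in range(spec.n_repetitions):
        arch_seed = int(rep_rng.integers(0, 2**31 - 1))
        try:
            train_tab, test_tab = split_data(table, spec, rep)
            Xtr = train_tab[list(FEATURE_NAMES)].to_numpy(dtype=float)
            Xte = test_tab[list(FEATURE_NAMES)].to_numpy(dtype=float)
            model = fit_pca(
                Xtr, standardize=config.standardize_pca, k_selected=config.n_components
            )
            Str = project(model, Xtr, config.n_components)
            Ste = project(model, Xte, config.n_components)
            ttr = _binary_targets(train_tab["label"])
            h, net, _ = bnn.select_architecture(
                Str,
                ttr,
                h_range=config.h_range,
                restarts=config.restarts,
                seed=arch_seed,
                alpha0=config.alpha0,
            )
            pl_tr, prob_tr = bnn.predict(net, Str, config.threshold)
            pl_te, _ = bnn.predict(net, Ste, config.threshold)
            sens_tr, spec_tr = sensitivity_specificity(
                confusion_counts(train_tab["label"], pl_tr)
            )
            sens_te, spec_te = sensitivity_specificity(
                confusion_counts(test_tab["label"], pl_te)
            )
        except (ValueError, FloatingPointError, RuntimeError) as exc:
            warnings.warn(f"repetition {rep} failed: {exc}", stacklevel=2)
            n_failed += 1
            continue
        reps.append(
            RepetitionResult(
                rep_index=rep,
                selected_h=h,
                threshold=config.threshold,
                train_sensitivity=sens_tr,
                train_specificity=spec_tr,
                test_sensitivity=sens_te,
                test_specificity=spec_te,
            )
        )
        key = (sens_te, spec_te)
        if best_key is None or key > best_key:
            best_key = key
            best_idx = rep
            best_roc = roc_curve(prob_tr, list(train_tab["label"]))
            best_auc = auc(best_roc)

    if not reps:
        raise RuntimeError("every repetition failed")

    def agg(vals: list[float]) -> tuple[float, float]:
        a = np.asarray(vals)
        return float(a.mean()), float(a.std(ddof=1)) if a.size > 1 else 0.0

    mean_tr_s, sd_tr_s = agg([r.train_sensitivity for r in reps])
    mean_tr_p, sd_tr_p = agg([r.train_specificity for r in reps])
    mean_te_s, sd_te_s = agg([r.test_sensitivity for r in reps])
    mean_te_p, sd_te_p = agg([r.test_specificity for r in reps])

    return EvaluationReport(
        repetitions=reps,
        mean_train=(mean_tr_s, mean_tr_p),
        sd_train=(sd_tr_s, sd_tr_p),
        mean_test=(mean_te_s, mean_te_p),
        sd_test=(sd_te_s, sd_te_p),
        best_rep_index=best_idx,
        best_train_roc=best_roc,
        best_train_auc=best_auc,
        n_failed=n_failed,
        config={
            "split": asdict(spec),
            "pipeline": {**asdict(config), "h_range": list(config.h_range)},
        },
    )
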