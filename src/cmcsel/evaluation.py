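"""Repeated-holdout evaluation, classification metrics, and feature stability.

The study design is R independent stratified train/test splits (default
R=10, 90/10).  Within each repetition, within-subject normalization is
fitted on the training rows only; the selection algorithms receive the
training split together with a per-subject SMOTE balancer that they apply
to every fit (including each inner CV fold's training part — validation
rows are never augmented), and each tuned classifier is scored on the
untouched test rows.  Across repetitions, a feature selected
in at least a threshold fraction (default 70%) of the repetitions is called
*stable*, and the selection efficiency of an algorithm is

    100 * (number of stable features) / (mean number of selected features),

measuring how robust its selection is to data perturbation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .balancing import WithinSubjectNormalizer, smote_per_subject
from .coherence import FeatureMatrix
from .fesc import ConsensusConfig, fesc_select
from .results import AlgorithmStability, SelectionRun, StabilityReport
from .selectors import lasso_select, pfsfs_select

logger = logging.getLogger(__name__)

DEFAULT_R = 10
DEFAULT_TEST_FRAC = 0.1
DEFAULT_STABILITY_THRESHOLD = 0.7


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion-matrix counts."""

    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be nonnegative")
        if self.total == 0:
            raise ValueError("confusion counts must describe a nonempty test set")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass(frozen=True)
class Metrics:
    """MCE, TPR, TNR and F1; rates are None when their denominator is zero."""

    mce: float
    tpr: float | None
    tnr: float | None
    f1: float | None

    def as_dict(self) -> dict:
        return {"mce": self.mce, "tpr": self.tpr, "tnr": self.tnr, "f1": self.f1}


def confusion_from_predictions(y_true: np.ndarray, y_pred: np.ndarray,
                               positive) -> ConfusionCounts:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    pos_t, pos_p = y_true == positive, y_pred == positive
    return ConfusionCounts(
        TP=int(np.sum(pos_t & pos_p)),
        TN=int(np.sum(~pos_t & ~pos_p)),
        FP=int(np.sum(~pos_t & pos_p)),
        FN=int(np.sum(pos_t & ~pos_p)),
    )


def classification_metrics(c: ConfusionCounts, reciprocal_f1: bool = False) -> Metrics:
    """MCE = (FP+FN)/total, TPR = TP/(TP+FN), TNR = TN/(TN+FP), and F1.

    F1 uses the standard form 2*TP / (2*TP + FP + FN).  ``reciprocal_f1``
    switches to the count-reciprocal variant 2 / (2*TP + FP + FN), kept only
    for comparison with legacy tooling; it is not a rate and is off by
    default.
    """
    mce = (c.FP + c.FN) / c.total
    tpr = tnr = f1 = None
    if c.TP + c.FN > 0:
        tpr = c.TP / (c.TP + c.FN)
    else:
        logger.warning("TPR undefined: no positive examples in the test set")
    if c.TN + c.FP > 0:
        tnr = c.TN / (c.TN + c.FP)
    else:
        logger.warning("TNR undefined: no negative examples in the test set")
    denom = 2 * c.TP + c.FP + c.FN
    if denom > 0:
        f1 = (2.0 if reciprocal_f1 else 2.0 * c.TP) / denom
    return Metrics(mce=mce, tpr=tpr, tnr=tnr, f1=f1)


def repeated_holdout(
    labels: np.ndarray,
    subject_ids: np.ndarray,
    R: int = DEFAULT_R,
    test_frac: float = DEFAULT_TEST_FRAC,
    seed: int = 0,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """R independent stratified train/test splits.

    Stratification is by (subject, class): each stratum contributes
    ``round(test_frac * stratum size)`` rows to the test set of every
    repetition.  A stratum too small to contribute a test row stays whole
    in the training set, with a warning.  Repetition r is seeded
    ``seed + r``, so splits are reproducible and repetition-independent.
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    if not 0.0 < test_frac < 1.0:
        raise ValueError("test_frac must be in (0, 1)")
    labels = np.asarray(labels)
    subject_ids = np.asarray(subject_ids)
    strata = [
        np.flatnonzero((subject_ids == s) & (labels == c))
        for s in np.unique(subject_ids)
        for c in np.unique(labels)
    ]
    splits = []
    for r in range(R):
        rng = np.random.default_rng(seed + r)
        test_idx = []
        for rows in strata:
            if len(rows) == 0:
                continue
            n_test = int(round(test_frac * len(rows)))
            if n_test == 0:
                logger.warning(
                    "stratum of %d rows too small for test_frac=%g; kept in training",
                    len(rows), test_frac,
                )
                continue
            test_idx.append(rng.permutation(rows)[:n_test])
        test = np.sort(np.concatenate(test_idx))
        train = np.setdiff1d(np.arange(len(labels)), test)
        splits.append((train, test))
    return splits


def stability_set(selections: list[np.ndarray], R: int,
                  threshold: float = DEFAULT_STABILITY_THRESHOLD) -> np.ndarray:
    """Columns selected in at least ``ceil(threshold * R)`` of the R selections."""
    if len(selections) != R:
        raise ValueError(f"expected {R} selections, got {len(selections)}")
    need = math.ceil(threshold * R)
    counts: dict[int, int] = {}
    for sel in selections:
        for c in np.unique(np.asarray(sel, dtype=int)):
            counts[c] = counts.get(c, 0) + 1
    return np.asarray(sorted(c for c, n in counts.items() if n >= need), dtype=int)


def selection_efficiency(stable_count: int, mean_selected: float) -> float:
    """Percent of stable features over the mean selected count, to one decimal."""
    if mean_selected <= 0:
        raise ValueError("mean_selected must be positive")
    return round(100.0 * stable_count / mean_selected, 1)


# ------------------------------------------------------------ the driver ---

#: Default algorithm roster.  FeSC variants are named by the initial of the
#: clustering algorithms in the consensus (H hierarchical, S spectral,
#: D DBSCAN) and by the similarity index sigma.
def default_algorithms(svm_c_grid=(1.0, 10.0)) -> dict:
    def cfg(algos, sigma):
        return ConsensusConfig(algorithms=algos, sigma=sigma, svm_c_grid=svm_c_grid)
    return {
        "fesc-sd-0.6": cfg(("spectral", "dbscan"), 0.6),
        "fesc-hd-0.6": cfg(("hierarchical", "dbscan"), 0.6),
        "fesc-hsd-0.6": cfg(("hierarchical", "spectral", "dbscan"), 0.6),
        "pfsfs": "pfsfs",
        "lasso": "lasso",
    }


def _run_algorithm(name: str, spec, values: np.ndarray, labels: np.ndarray,
                   seed: int, subject_ids=None, balancer=None) -> SelectionRun:
    kw = dict(seed=seed, subject_ids=subject_ids, balancer=balancer)
    if isinstance(spec, ConsensusConfig):
        return fesc_select(values, labels, spec, **kw)
    if spec == "pfsfs":
        return pfsfs_select(values, labels, **kw)
    if spec == "lasso":
        return lasso_select(values, labels, **kw)
    raise ValueError(f"unknown algorithm spec for {name!r}: {spec!r}")


def run_study(
    fm: FeatureMatrix,
    algorithms: dict | None = None,
    R: int = DEFAULT_R,
    test_frac: float = DEFAULT_TEST_FRAC,
    seed: int = 0,
    stability_threshold: float = DEFAULT_STABILITY_THRESHOLD,
    smote_k: int = 5,
    positive_class=None,
) -> tuple[StabilityReport, pd.DataFrame]:
    """Run the full repeated-holdout study on a feature matrix.

    Returns the stability report and a tidy per-repetition metrics table
    (columns: algorithm, repetition, metric, value).  The positive class
    for TPR/TNR defaults to the smaller class label (class 1).
    """
    if algorithms is None:
        algorithms = default_algorithms()
    classes = np.unique(fm.labels)
    if len(classes) != 2:
        raise ValueError("the study is a binary classification problem")
    positive = classes[0] if positive_class is None else positive_class

    splits = repeated_holdout(fm.labels, fm.subject_ids, R, test_frac, seed)
    selections: dict[str, list[np.ndarray]] = {name: [] for name in algorithms}
    records = []

    for r, (train, test) in enumerate(splits):
        rep_seed = seed + r
        from dataclasses import replace as _replace
        train_fm = _replace(fm, values=fm.values[train], labels=fm.labels[train],
                            subject_ids=fm.subject_ids[train])
        test_fm = _replace(fm, values=fm.values[test], labels=fm.labels[test],
                           subject_ids=fm.subject_ids[test])
        norm = WithinSubjectNormalizer().fit(train_fm)
        train_fm = norm.transform(train_fm)
        test_fm = norm.transform(test_fm)

        def balancer(values, labels, sids, _fm=train_fm, _seed=rep_seed):
            # SMOTE on a row subset, keeping the matrix layout metadata
            sub = _replace(_fm, values=values, labels=labels,
                           subject_ids=np.asarray(sids))
            bal = smote_per_subject(sub, k_neighbors=smote_k, seed=_seed)
            return bal.values, bal.labels

        for name, spec in algorithms.items():
            run = _run_algorithm(name, spec, train_fm.values, train_fm.labels,
                                 rep_seed, subject_ids=train_fm.subject_ids,
                                 balancer=balancer)
            selections[name].append(run.selected_columns)
            import warnings
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                y_pred = run.model.predict(test_fm.values[:, run.selected_columns])
                y_train_pred = run.model.predict(train_fm.values[:, run.selected_columns])
            cc = confusion_from_predictions(test_fm.labels, y_pred, positive)
            met = classification_metrics(cc)
            train_mce = float(np.mean(y_train_pred != train_fm.labels))
            logger.info("rep %d %s: selected %d, test MCE %.4f",
                        r, name, len(run.selected_columns), met.mce)
            for metric, value in {**met.as_dict(), "train_mce": train_mce,
                                  "n_selected": len(run.selected_columns)}.items():
                records.append({"algorithm": name, "repetition": r,
                                "metric": metric, "value": value})

    tidy = pd.DataFrame.from_records(records)
    algo_stats = {}
    for name in algorithms:
        sel = selections[name]
        counts = [len(s) for s in sel]
        stable = stability_set(sel, R, stability_threshold)
        mean_sel = float(np.mean(counts))
        sub = tidy[tidy.algorithm == name]
        mmean = {m: float(sub[sub.metric == m].value.mean()) for m in sub.metric.unique()}
        mstd = {m: float(sub[sub.metric == m].value.std(ddof=0)) for m in sub.metric.unique()}
        algo_stats[name] = AlgorithmStability(
            algorithm=name,
            selected_counts=counts,
            mean_selected=mean_sel,
            std_selected=float(np.std(counts)),
            stable_features=[int(c) for c in stable],
            selection_efficiency=selection_efficiency(len(stable), mean_sel),
            metrics_mean=mmean,
            metrics_std=mstd,
        )

    report = StabilityReport(
        R=R,
        test_frac=test_frac,
        stability_threshold=stability_threshold,
        seed=seed,
        algorithms=algo_stats,
    )
    return report, tidy
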