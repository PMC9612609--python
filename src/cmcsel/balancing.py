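"""Within-subject normalization and per-subject SMOTE class balancing.

Trial counts per gesture class are typically imbalanced, and coherence
magnitudes differ between subjects.  Both issues are handled per subject:
values are first scaled by the subject's maximum, then the minority class
is oversampled up to the majority count with SMOTE-style interpolation
between nearest same-class neighbours.  Synthetic rows are interpolations
between two real rows of the same subject and class, placed at equally
spaced positions along the connecting segment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .coherence import FeatureMatrix

logger = logging.getLogger(__name__)

DEFAULT_K_NEIGHBORS = 5


@dataclass
class BalancedMatrix(FeatureMatrix):
    """FeatureMatrix whose classes are balanced per subject.

    ``synthetic_mask`` flags the generated rows (False for original data).
    """

    synthetic_mask: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.synthetic_mask is None:
            self.synthetic_mask = np.zeros(self.n_trials, dtype=bool)
        self.synthetic_mask = np.asarray(self.synthetic_mask, dtype=bool)
        if len(self.synthetic_mask) != self.n_trials:
            raise ValueError("synthetic_mask must have one entry per row")


class WithinSubjectNormalizer:
    """Scale each subject's block by its own maximum value.

    ``fit`` learns per-subject maxima (on training rows); ``transform``
    applies them, so held-out rows of a known subject are scaled with the
    training statistic and never leak into it.
    """

    def __init__(self) -> None:
        self.maxima_: dict = {}

    def fit(self, fm: FeatureMatrix) -> "WithinSubjectNormalizer":
        self.maxima_ = {}
        for sid in np.unique(fm.subject_ids):
            block = fm.values[fm.subject_ids == sid]
            m = float(np.max(block))
            if m <= 0.0:
                raise ValueError(f"subject {sid}: all-zero feature block cannot be normalized")
            self.maxima_[sid] = m
        return self

    def transform(self, fm: FeatureMatrix) -> FeatureMatrix:
        if not self.maxima_:
            raise RuntimeError("normalizer must be fitted first")
        values = fm.values.copy()
        for sid in np.unique(fm.subject_ids):
            if sid not in self.maxima_:
                raise KeyError(f"subject {sid} was not seen during fit")
            values[fm.subject_ids == sid] /= self.maxima_[sid]
        return replace(fm, values=values)


def normalize_within_subject(fm: FeatureMatrix) -> FeatureMatrix:
    """Divide each subject's rows by that subject's maximum value (idempotent)."""
    return WithinSubjectNormalizer().fit(fm).transform(fm)


def _interpolate(parent: np.ndarray, neighbor: np.ndarray, count: int) -> np.ndarray:
    # `count` equally spaced points strictly between parent and neighbor
    lam = np.arange(1, count + 1) / (count + 1)
    return parent[None, :] + lam[:, None] * (neighbor - parent)[None, :]


def smote_per_subject(
    fm: FeatureMatrix,
    k_neighbors: int = DEFAULT_K_NEIGHBORS,
    seed: int | np.random.Generator = 0,
) -> BalancedMatrix:
    """Raise each subject's minority class exactly to its majority count.

    For every subject with class counts (n_min, n_maj), the n_maj - n_min
    synthetic rows are distributed round-robin over the minority rows; each
    chosen parent picks one of its ``k_neighbors`` nearest same-class,
    same-subject neighbours at random (seeded) and contributes equally
    spaced interpolations along the segment to that neighbour.  A subject
    with a single minority row cannot be interpolated and is balanced by
    duplication, with a warning.
    """
    if k_neighbors < 1:
        raise ValueError("k_neighbors must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    classes = np.unique(fm.labels)
    if len(classes) != 2:
        raise ValueError(f"expected exactly two classes, got {classes}")

    new_rows, new_labels, new_subjects = [], [], []
    for sid in np.unique(fm.subject_ids):
        sel = fm.subject_ids == sid
        counts = {c: int(np.sum(sel & (fm.labels == c))) for c in classes}
        minority = min(classes, key=lambda c: counts[c])
        need = counts[max(classes, key=lambda c: counts[c])] - counts[minority]
        if need == 0:
            continue
        X = fm.values[sel & (fm.labels == minority)]
        n_min = X.shape[0]
        if n_min == 0:
            raise ValueError(f"subject {sid}: minority class absent, cannot balance")
        if n_min == 1:
            logger.warning(
                "subject %s: single minority sample; balancing by duplication", sid
            )
            synth = np.repeat(X, need, axis=0)
        else:
            k = min(k_neighbors, n_min - 1)
            nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
            _, idx = nn.kneighbors(X)  # first neighbour is the point itself
            per_parent = np.bincount(np.arange(need) % n_min, minlength=n_min)
            chunks = []
            for p in range(n_min):
                if per_parent[p] == 0:
                    continue
                j = idx[p, 1 + rng.integers(k)]
                chunks.append(_interpolate(X[p], X[j], int(per_parent[p])))
            synth = np.concatenate(chunks, axis=0)
        new_rows.append(synth)
        new_labels.append(np.full(need, minority, dtype=fm.labels.dtype))
        new_subjects.append(np.full(need, sid, dtype=fm.subject_ids.dtype))

    if new_rows:
        values = np.concatenate([fm.values] + new_rows, axis=0)
        labels = np.concatenate([fm.labels] + new_labels)
        subjects = np.concatenate([fm.subject_ids] + new_subjects)
        mask = np.concatenate(
            [np.zeros(fm.n_trials, dtype=bool), np.ones(len(values) - fm.n_trials, dtype=bool)]
        )
    else:
        values, labels, subjects = fm.values, fm.labels, fm.subject_ids
        mask = np.zeros(fm.n_trials, dtype=bool)

    return BalancedMatrix(
        values=values,
        labels=labels,
        subject_ids=subjects,
        M=fm.M,
        Q=fm.Q,
        scheme=fm.scheme,
        emg_labels=fm.emg_labels,
        eeg_labels=fm.eeg_labels,
        synthetic_mask=mask,
    )
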