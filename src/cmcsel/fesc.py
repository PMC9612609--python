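"""Feature selection with consensus clustering (FeSC).

Every feature is summarized by two numbers, its mean value over the trials
of each class (pooling).  In that 2-D space, several clustering algorithms
(hierarchical, spectral, DBSCAN) group the features; a consensus step keeps
groups on which at least a fraction ``sigma`` of the algorithms agree and
which contain at least ``nu`` features, and one representative feature (the
member closest to the group mean) is selected per group.  The minimum group
size ``nu`` and the per-algorithm hyperparameters are chosen by an inner
5-fold cross-validation that minimizes the mean classification error (MCE)
of an RBF-kernel SVM trained on the selected features.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from sklearn.cluster import DBSCAN, AgglomerativeClustering, SpectralClustering
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .results import SelectionRun

logger = logging.getLogger(__name__)

ALGORITHM_NAMES = ("hierarchical", "spectral", "dbscan")


@dataclass
class PooledMatrix:
    """Per-feature (class-1 mean, class-2 mean) points.

    Row f holds the mean of feature f over the trials of each class; these
    2-D points are the clustering input.  ``feature_columns`` maps rows back
    to columns of the originating feature matrix.
    """

    points: np.ndarray
    feature_columns: np.ndarray
    class_order: tuple = ()

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.feature_columns = np.asarray(self.feature_columns, dtype=int)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must be (p, 2)")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("pooled points must be finite")


@dataclass(frozen=True)
class ConsensusConfig:
    """Configuration of the consensus step.

    ``sigma`` is the fraction of clustering algorithms that must co-assign
    two features for them to join the same consensus group; the usual
    settings are 0.6 (majority of three, or both of two) and 0.9 (full
    agreement).  ``nu_grid`` lists candidate minimum group sizes, learned by
    the inner CV together with the per-algorithm grids.
    """

    algorithms: tuple[str, ...] = ALGORITHM_NAMES
    sigma: float = 0.6
    nu_grid: tuple[int, ...] = (2, 5, 10, 20)
    n_clusters_grid: tuple[int, ...] = (12, 25, 50, 100, 200, 400)
    dbscan_eps_grid: tuple[float, ...] = (0.04, 0.08)
    dbscan_min_samples_grid: tuple[int, ...] = (2,)
    svm_c_grid: tuple[float, ...] = (1.0, 10.0, 100.0)
    random_state: int = 0

    def __post_init__(self) -> None:
        if len(self.algorithms) < 2:
            raise ValueError("consensus needs at least two clustering algorithms")
        unknown = set(self.algorithms) - set(ALGORITHM_NAMES)
        if unknown:
            raise ValueError(f"unknown clustering algorithms: {sorted(unknown)}")
        if not 0.0 < self.sigma <= 1.0:
            raise ValueError("sigma must be in (0, 1]")
        if any(nu < 1 for nu in self.nu_grid):
            raise ValueError("nu values must be >= 1")

    @property
    def name(self) -> str:
        tag = "".join(a[0] for a in self.algorithms)
        return f"fesc-{tag}-{self.sigma:g}"


def pool_by_class(values: np.ndarray, labels: np.ndarray,
                  feature_columns: np.ndarray | None = None) -> PooledMatrix:
    """Average each feature over the trials of each class (2 points/feature)."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError(f"pooling requires exactly two classes, got {classes}")
    pts = np.column_stack([values[labels == c].mean(axis=0) for c in classes])
    cols = np.arange(values.shape[1]) if feature_columns is None else feature_columns
    return PooledMatrix(points=pts, feature_columns=cols, class_order=tuple(classes.tolist()))


def _clip_n_clusters(k: int, p: int) -> int:
    # keep cluster counts meaningful for small feature sets
    return max(2, min(k, p // 2))


def run_individual_clusterings(
    pooled: PooledMatrix,
    params: dict,
    random_state: int = 0,
) -> dict[str, np.ndarray]:
    """One flat labeling per requested algorithm.

    ``params`` maps an algorithm name to its hyperparameters, e.g.
    ``{"hierarchical": {"n_clusters": 50}, "dbscan": {"eps": 0.05,
    "min_samples": 2}}``.  DBSCAN may label points as noise (-1);
    hierarchical and spectral always assign a cluster.
    """
    pts = pooled.points
    p = pts.shape[0]
    if p < 2:
        raise ValueError("need at least two features to cluster")
    out: dict[str, np.ndarray] = {}
    for name, kw in params.items():
        if name == "hierarchical":
            k = kw["n_clusters"]
            if k > p:
                raise ValueError(f"hierarchical: {k} clusters for {p} points")
            model = AgglomerativeClustering(n_clusters=k, linkage="ward")
            out[name] = model.fit_predict(pts)
        elif name == "spectral":
            k = kw["n_clusters"]
            if k > p:
                raise ValueError(f"spectral: {k} clusters for {p} points")
            model = SpectralClustering(
                n_clusters=k, affinity="rbf", assign_labels="kmeans",
                random_state=random_state, n_init=3,
            )
            import warnings
            with warnings.catch_warnings():
                # eigensolver fallback chatter on near-degenerate affinities
                warnings.simplefilter("ignore")
                out[name] = model.fit_predict(pts)
        elif name == "dbscan":
            model = DBSCAN(eps=kw["eps"], min_samples=kw["min_samples"])
            out[name] = model.fit_predict(pts)
        else:
            raise ValueError(f"unknown clustering algorithm: {name}")
    return out


def co_association(labelings: list[np.ndarray]) -> np.ndarray:
    """Fraction of labelings placing each feature pair in the same non-noise cluster."""
    if not labelings:
        raise ValueError("no labelings given")
    p = len(labelings[0])
    acc = np.zeros((p, p))
    for lab in labelings:
        lab = np.asarray(lab)
        if len(lab) != p:
            raise ValueError("labelings must cover the same feature set")
        same = (lab[:, None] == lab[None, :])
        valid = lab != -1
        same &= valid[:, None] & valid[None, :]
        acc += same
    acc /= len(labelings)
    np.fill_diagonal(acc, 1.0)
    return acc


def consensus_clusters(
    labelings: list[np.ndarray],
    sigma: float,
    nu: int,
) -> list[np.ndarray]:
    """Consensus groups: connected components of the thresholded co-association.

    Pairs with co-association >= ``sigma`` are linked; the consensus groups
    are the connected components of that graph with at least ``nu`` members.
    Features in no retained component are discarded.  Components are
    returned ordered by their smallest member index.
    """
    if not 0.0 < sigma <= 1.0:
        raise ValueError("sigma must be in (0, 1]")
    A = co_association(labelings)
    adj = csr_matrix(A >= sigma)
    n_comp, comp = connected_components(adj, directed=False)
    clusters = []
    for c in range(n_comp):
        members = np.flatnonzero(comp == c)
        if len(members) >= nu:
            clusters.append(members)
    clusters.sort(key=lambda m: int(m[0]))
    return clusters


def select_centroids(clusters: list[np.ndarray], pooled: PooledMatrix) -> np.ndarray:
    """One representative feature per consensus group.

    The representative is the member closest (Euclidean) to the group's
    coordinate mean; ties break to the lowest column index.  Returns the
    selected original feature columns.
    """
    selected = []
    for members in clusters:
        pts = pooled.points[members]
        d = np.linalg.norm(pts - pts.mean(axis=0), axis=1)
        selected.append(members[int(np.argmin(d))])  # argmin is first-wins on ties
    return pooled.feature_columns[np.asarray(sorted(selected), dtype=int)]


def _algo_param_grid(config: ConsensusConfig, p: int) -> list[dict]:
    """All per-algorithm hyperparameter combinations, deterministic order."""
    per_algo = []
    for name in config.algorithms:
        if name in ("hierarchical", "spectral"):
            ks = sorted({_clip_n_clusters(k, p) for k in config.n_clusters_grid})
            per_algo.append([(name, {"n_clusters": k}) for k in ks])
        else:  # dbscan
            per_algo.append([
                (name, {"eps": e, "min_samples": ms})
                for e in config.dbscan_eps_grid
                for ms in config.dbscan_min_samples_grid
            ])
    return [dict(combo) for combo in itertools.product(*per_algo)]


def _svm(C: float, seed: int) -> SVC:
    return SVC(kernel="rbf", C=C, gamma="scale", random_state=seed)


def fesc_select(
    values: np.ndarray,
    labels: np.ndarray,
    config: ConsensusConfig,
    n_folds: int = 5,
    seed: int = 0,
    subject_ids: np.ndarray | None = None,
    balancer=None,
) -> SelectionRun:
    """Full FeSC on a training matrix: tune by nested CV, refit, select.

    For every grid point (per-algorithm hyperparameters x nu x SVM C), an
    inner stratified ``n_folds``-fold CV repeats the whole selection inside
    each fold (pooling and clustering see only the fold's training part)
    and scores an RBF SVM on the held-out part.  The grid point with the
    lowest mean MCE wins (first in grid order on ties); selection and SVM
    are then refitted on the full training matrix.

    ``balancer`` is an optional callable ``(values, labels, subject_ids) ->
    (values, labels)`` (e.g. per-subject SMOTE).  It is applied to each
    inner fold's training part only — validation rows are never augmented,
    so the tuning MCE stays honest — and again to the full matrix for the
    final refit.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    p = values.shape[1]
    combos = _algo_param_grid(config, p)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(values, labels))

    def _fit_data(rows):
        if balancer is None:
            return values[rows], labels[rows]
        sids = None if subject_ids is None else np.asarray(subject_ids)[rows]
        return balancer(values[rows], labels[rows], sids)

    # errs[(combo_idx, nu, C)] -> list of fold MCEs
    errs: dict[tuple[int, int, float], list[float]] = {}
    for tr, va in folds:
        Xb, yb = _fit_data(tr)
        pooled = pool_by_class(Xb, yb)
        label_cache: dict = {}

        def _labels(name, kw):
            key = (name, tuple(sorted(kw.items())))
            if key not in label_cache:
                label_cache[key] = run_individual_clusterings(
                    pooled, {name: kw}, config.random_state)[name]
            return label_cache[key]

        for ci, params in enumerate(combos):
            labs = [_labels(name, params[name]) for name in config.algorithms]
            for nu in config.nu_grid:
                clusters = consensus_clusters(labs, config.sigma, nu)
                if not clusters:
                    for C in config.svm_c_grid:
                        errs.setdefault((ci, nu, C), []).append(np.inf)
                    continue
                cols = select_centroids(clusters, pooled)
                for C in config.svm_c_grid:
                    clf = _svm(C, seed)
                    clf.fit(Xb[:, cols], yb)
                    mce = float(np.mean(clf.predict(values[va][:, cols]) != labels[va]))
                    errs.setdefault((ci, nu, C), []).append(mce)

    keys = [(ci, nu, C) for ci in range(len(combos))
            for nu in config.nu_grid for C in config.svm_c_grid]
    means = {k: float(np.mean(errs[k])) for k in keys}
    best = min(keys, key=lambda k: means[k])
    if not np.isfinite(means[best]):
        raise RuntimeError(
            "consensus was empty for every grid point; widen nu_grid or the "
            "per-algorithm grids"
        )
    ci, nu, C = best

    Xb, yb = _fit_data(np.arange(len(labels)))
    pooled = pool_by_class(Xb, yb)
    labelings = run_individual_clusterings(pooled, combos[ci], config.random_state)
    clusters = consensus_clusters([labelings[n] for n in config.algorithms], config.sigma, nu)
    if not clusters:
        raise RuntimeError("tuned configuration yields an empty consensus on the full split")
    cols = select_centroids(clusters, pooled)
    model = _svm(C, seed).fit(Xb[:, cols], yb)

    return SelectionRun(
        algorithm=config.name,
        selected_columns=np.asarray(cols, dtype=int),
        params={
            "clustering": combos[ci],
            "nu": int(nu),
            "svm_C": float(C),
            "sigma": config.sigma,
        },
        cv_mce=means[best],
        model=model,
    )
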