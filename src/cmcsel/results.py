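"""Result containers shared by the selection algorithms and the evaluation driver."""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np


def _round_sig(x: float, digits: int = 10) -> float:
    if x == 0 or not np.isfinite(x):
        return float(x)
    return float(f"{x:.{digits}g}")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, np.ndarray)):
        return [_jsonable(v) for v in np.asarray(obj).tolist()] if isinstance(obj, np.ndarray) \
            else [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        return _round_sig(float(obj))
    return obj


@dataclass
class SelectionRun:
    """One algorithm's outcome on one training split.

    ``selected_columns`` are column indices into the feature matrix the
    algorithm was trained on; ``model`` is the fitted classifier (not
    serialized).  ``extras`` carries algorithm-specific traces such as the
    SFS error trace or the LASSO CV curve.
    """

    algorithm: str
    selected_columns: np.ndarray
    params: dict
    cv_mce: float
    model: object = None
    extras: dict = field(default_factory=dict)

    def to_dict(self, column_names: list[str] | None = None) -> dict:
        d = {
            "algorithm": self.algorithm,
            "selected_columns": [int(c) for c in self.selected_columns],
            "params": _jsonable(self.params),
            "cv_mce": _round_sig(float(self.cv_mce)),
            "extras": _jsonable(self.extras),
        }
        if column_names is not None:
            d["selected_names"] = [column_names[int(c)] for c in self.selected_columns]
        return d

    def to_json(self, path, column_names: list[str] | None = None) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(column_names), fh, indent=2, sort_keys=True)


@dataclass
class AlgorithmStability:
    """Across-repetition summary for one algorithm."""

    algorithm: str
    selected_counts: list[int]
    mean_selected: float
    std_selected: float
    stable_features: list[int]
    selection_efficiency: float
    metrics_mean: dict
    metrics_std: dict

    def to_dict(self) -> dict:
        return _jsonable(asdict(self))


@dataclass
class StabilityReport:
    """Stability analysis of all algorithms over R repeated holdout splits."""

    R: int
    test_frac: float
    stability_threshold: float
    seed: int
    algorithms: dict  # name -> AlgorithmStability
    roi_percentages: dict = field(default_factory=dict)  # name -> domain -> roi -> pct

    def to_dict(self) -> dict:
        return _jsonable({
            "R": self.R,
            "test_frac": self.test_frac,
            "stability_threshold": self.stability_threshold,
            "seed": self.seed,
            "algorithms": {k: v.to_dict() for k, v in self.algorithms.items()},
            "roi_percentages": self.roi_percentages,
        })

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
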