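"""End-to-end pipeline configuration and orchestration.

``run_pipeline`` chains preprocessing, coherence feature extraction, the
repeated-holdout selection/classification study, the stability analysis
and the ROI aggregation, writing every artifact (plus a manifest with the
fully resolved configuration) under one output directory.  All randomness
derives from the single base seed recorded in the manifest.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import io as _io
from .coherence import DEFAULT_BANDS, build_feature_matrix, concat_feature_matrices
from .evaluation import default_algorithms, run_study
from .fesc import ConsensusConfig
from .preprocessing import preprocess_recording
from .roi import RoiScheme, aggregate_to_rois, map_features_to_domains
from .synthetic import SynthConfig, generate_dataset

logger = logging.getLogger(__name__)

KNOWN_ALGORITHMS = ("fesc-sd-0.6", "fesc-hd-0.6", "fesc-hs-0.6", "fesc-hsd-0.6",
                    "fesc-hsd-0.9", "pfsfs", "lasso")


@dataclass
class PipelineConfig:
    """Validated configuration of a full run.

    ``recordings`` is a list of HDF5 paths, or the literal string
    ``"synthetic"`` to generate the built-in benchmark.  ``algorithms``
    names the selectors to run (see ``KNOWN_ALGORITHMS``).
    """

    recordings: object = "synthetic"
    out_dir: str = "cmcsel-out"
    seed: int = 0
    duration: float = 4.0
    band: tuple[float, float] = (1.5, 80.0)
    notch_hz: float = 50.0
    algorithms: tuple[str, ...] = ("fesc-sd-0.6", "fesc-hd-0.6", "fesc-hsd-0.6",
                                   "pfsfs", "lasso")
    R: int = 10
    test_frac: float = 0.1
    stability_threshold: float = 0.7
    smote_k: int = 5
    roi_scheme: str | None = None  # path to a YAML/JSON scheme, default built-in

    def __post_init__(self) -> None:
        unknown = [a for a in self.algorithms if a not in KNOWN_ALGORITHMS]
        if unknown:
            raise ValueError(
                f"unknown algorithms {unknown}; choose from {KNOWN_ALGORITHMS}"
            )
        if self.R < 1:
            raise ValueError("R must be >= 1")
        if not 0.0 < self.test_frac < 1.0:
            raise ValueError("test_frac must be in (0, 1)")
        if not 0.0 < self.stability_threshold <= 1.0:
            raise ValueError("stability_threshold must be in (0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        allowed = set(cls.__dataclass_fields__)
        unknown = set(data) - allowed
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "algorithms" in data:
            data["algorithms"] = tuple(data["algorithms"])
        if "band" in data:
            data["band"] = tuple(data["band"])
        return cls(**data)


def resolve_algorithms(names, svm_c_grid=(1.0, 10.0)) -> dict:
    """Algorithm names -> specs understood by the evaluation driver."""
    base = default_algorithms(svm_c_grid)
    table = dict(base)
    table["fesc-hs-0.6"] = ConsensusConfig(
        algorithms=("hierarchical", "spectral"), sigma=0.6, svm_c_grid=svm_c_grid)
    table["fesc-hsd-0.9"] = ConsensusConfig(
        algorithms=("hierarchical", "spectral", "dbscan"), sigma=0.9,
        svm_c_grid=svm_c_grid)
    return {n: table[n] for n in names}


def load_recordings(config: PipelineConfig):
    """Recordings per the config: synthetic benchmark or HDF5 files."""
    if config.recordings == "synthetic":
        recs, gt = generate_dataset(SynthConfig(seed=config.seed))
        return recs, gt
    paths = list(config.recordings)
    return [_io.read_recording(p) for p in paths], None


def run_pipeline(config: PipelineConfig):
    """Execute the whole pipeline and write artifacts under ``out_dir``.

    Returns the stability report.  Stages: (synthesize or read) recordings
    -> filter/segment/rectify -> MSC feature matrix -> repeated-holdout
    study with per-repetition balancing -> stability + selection efficiency
    -> ROI aggregation of each algorithm's stable features.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage_times = {}

    def _stage(name):
        logger.info("stage: %s", name)
        stage_times[name] = time.time()

    def _done(name):
        stage_times[name] = round(time.time() - stage_times[name], 2)

    _stage("recordings")
    recs, gt = load_recordings(config)
    if gt is not None:
        with open(out / "ground_truth.json", "w") as fh:
            json.dump(gt.to_dict(), fh, indent=2)
    _done("recordings")

    _stage("features")
    try:
        mats = [
            build_feature_matrix(
                preprocess_recording(r, duration=config.duration, band=config.band,
                                     notch_hz=config.notch_hz),
                DEFAULT_BANDS,
            )
            for r in recs
        ]
    except Exception as e:
        raise RuntimeError(f"feature stage failed: {e}") from e
    fm = concat_feature_matrices(mats)
    _io.write_feature_matrix(out / "features.csv", fm)
    _done("features")

    _stage("study")
    report, tidy = run_study(
        fm,
        algorithms=resolve_algorithms(config.algorithms),
        R=config.R,
        test_frac=config.test_frac,
        seed=config.seed,
        stability_threshold=config.stability_threshold,
        smote_k=config.smote_k,
    )
    tidy.to_csv(out / "metrics.csv", index=False)
    _done("study")

    _stage("roi")
    scheme = RoiScheme.from_file(config.roi_scheme) if config.roi_scheme else RoiScheme()
    for name, st in report.algorithms.items():
        if st.stable_features:
            triples = map_features_to_domains(st.stable_features, fm)
            report.roi_percentages[name] = aggregate_to_rois(triples, scheme)
    report.to_json(out / "stability.json")
    _done("roi")

    manifest = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "n_trials": int(fm.n_trials),
        "n_features": int(fm.n_features),
        "stage_seconds": stage_times,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return report
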