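# cmcsel

**Corticomuscular-coherence feature selection and stability analysis for
EEG-EMG movement classification.**

Minimizing a wearable EEG+EMG monitoring setup (for tele-rehabilitation,
motor training, gesture recognition) requires knowing which few sensors and
frequency bands actually discriminate between movements. `cmcsel` fuses
the two modalities at the sensor level into a single physiologically
interpretable feature — the magnitude-squared coherence (MSC)

```
C(f) = |S_xy(f)|² / (S_xx(f) · S_yy(f))   ∈ [0, 1]
```

between every EMG×EEG channel pair, averaged over K = 11 canonical bands
(δ, θ, α, β₁, β₂, β, γ₁, γ₂, γ₃, γ, full), giving M·Q·K features per
trial (1760 for a 5-muscle × 32-channel montage). It then compares three
feature-selection strategies under a repeated-holdout protocol (R = 10,
90/10):

- **FeSC** — consensus clustering of per-class-pooled features
  (hierarchical + spectral + DBSCAN, co-association threshold σ, minimum
  group size ν learned by nested 5-fold CV), one representative feature
  per consensus group, RBF-SVM classification;
- **pFSFS** — p-value filter (Welch t-test, α = 0.05) → forward
  sequential selection wrapped around QDA;
- **LASSO** — L1 path with λ by 5-fold CV, |β| ranking, incremental
  RBF-SVM refit.

Features selected in ≥ 70% of the repetitions are *stable*, and each
algorithm's **selection efficiency** — `100 · #stable / mean #selected` —
quantifies its robustness to data perturbation. Stable features map back
through the invertible (muscle, channel, band) index onto physiological
regions of interest (low/SMR/full frequencies; Frontal/Centro-parietal/
Occipital scalp; Arm/Forearm/Hand muscles).

A synthetic generator plants band-limited, class-dependent EEG-EMG
coupling (additive on the EEG side, amplitude-modulating on the EMG side
so that it survives rectification) in known channels and bands, so the
whole pipeline is testable end-to-end without any data download.

## Worked example

```python
from cmcsel import (SynthConfig, generate_dataset, preprocess_recording,
                    build_feature_matrix, concat_feature_matrices, run_study,
                    map_features_to_domains, aggregate_to_rois)
from cmcsel.pipeline import resolve_algorithms

recs, truth = generate_dataset(SynthConfig(seed=1))
fm = concat_feature_matrices(
    [build_feature_matrix(preprocess_recording(r)) for r in recs])
print(f"{fm.n_trials} trials x {fm.n_features} features")

report, metrics = run_study(
    fm, algorithms=resolve_algorithms(["fesc-hsd-0.6", "pfsfs"]), R=10, seed=1)
for name, st in report.algorithms.items():
    print(f"{name}: test MCE {st.metrics_mean['mce']:.3f}, "
          f"{len(st.stable_features)} stable / {st.mean_selected:.1f} selected, "
          f"efficiency {st.selection_efficiency:.1f}%")

stable = report.algorithms["pfsfs"].stable_features
print("recovered:", sorted(set(stable) & set(truth.discriminative_columns)))
print("stable features:", map_features_to_domains(stable, fm))
```

prints (about two minutes on one core):

```
200 trials x 176 features
fesc-hsd-0.6: test MCE 0.015, 2 stable / 14.3 selected, efficiency 14.0%
pfsfs: test MCE 0.000, 4 stable / 4.3 selected, efficiency 93.0%
recovered: [35, 47, 149]
stable features: [('AD', 'C3', 'alpha'), ('AD', 'Cz', 'beta1'),
                  ('AD', 'Cz', 'full'), ('FDI', 'C4', 'gamma1')]
```

Reading this: the benchmark plants couplings at (AD, C3, α), (AD, Cz, β₁)
and (FDI, C4, γ₁) — feature columns 35, 47 and 149. Both algorithms
classify the gestures with mean test MCE ≤ 0.015 over ten holdouts, and
pFSFS stably recovers exactly the planted sensor-band combinations (plus
the overlapping full-band echo of the Cz coupling), with 93% of its
selections stable across repetitions. The consensus selector attains
similar error from cluster representatives but stabilizes fewer individual
columns — the trade-off between compactness and stability that the
selection-efficiency index makes visible. All stable features fall in the
Centro-parietal EEG ROI, where the couplings were planted.

The same pipeline runs from the shell:

```sh
cmcsel simulate --out-dir data --seed 1          # HDF5 recordings
cmcsel features data/*.h5 --out features.csv     # MSC feature matrix
cmcsel evaluate features.csv --out-dir results   # study + stability report
cmcsel report results/stability.json             # ROI percentage tables
cmcsel run --out-dir results --seed 1            # all of the above at once
```

## Layout

```
src/cmcsel/
  preprocessing.py   filtering, onset-anchored segmentation, rectification
  coherence.py       Welch cross-spectra, MSC, band averaging, feature matrix
  balancing.py       within-subject normalization, per-subject SMOTE
  fesc.py            pooling, consensus clustering, centroid selection, SVM
  selectors.py       pFSFS and LASSO comparator pipelines
  evaluation.py      repeated holdout, metrics, stability, selection efficiency
  roi.py             feature → (muscle, channel, band) → ROI aggregation
  synthetic.py       coupled-signal generator with ground truth
  manifests.py       published per-subject trial counts (WAY-EEG-GAL)
  io.py              HDF5 recordings, CSV feature matrices, JSON results
  pipeline.py, cli.py
docs/methods.md      the model, estimators, design choices, limitations
```
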