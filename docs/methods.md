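# Methods

## The problem

A minimal EEG+EMG monitoring setup for movement recognition needs to know
*which* sensors and frequency bands actually carry discriminative
information. `cmcsel` addresses this by fusing the two modalities at the
sensor level into a single feature — the magnitude-squared coherence (MSC)
between every EMG×EEG channel pair in canonical frequency bands — and then
comparing three feature-selection strategies on the resulting
high-dimensional matrix, with an explicit analysis of how *stable* each
strategy's selection is when the data are resampled.

## Signal model and preprocessing

Recordings are Q EEG channels and M bipolar EMG channels at a common rate
fs (≥ 2·80 Hz; the reference setting is 500 Hz), with per-trial,
per-EMG-channel annotated contraction onsets and a binary gesture label per
trial. Preprocessing is deliberately light (inputs are assumed
artefact-free):

1. **Band-pass** 1.5–80 Hz, Chebyshev type I of order 86. The filter is
   realized as a cascade of second-order sections and applied
   forward-backward, because an order-86 band-pass in direct form is
   numerically hopeless and zero phase keeps EEG/EMG alignment intact.
   Passband ripple defaults to 0.5 dB (configurable). Forward–backward
   application squares the magnitude response; the residual at a 100 Hz
   probe tone is dominated by float64 round-off through the 22 biquads
   (~1% broadband), not by actual leakage of the tone (design response
   there ≈ 1e-14).
2. **Notch** at the mains frequency, default 50 Hz (configurable for 60 Hz
   grids), an order-2 IIR notch biquad, also zero-phase, quality factor 35
   (−3 dB width ≈ 1.4 Hz).
3. **Segmentation**: one 4 s window per trial, starting at the annotated
   onset (a configurable pre-onset offset exists, default 0). Because each
   EMG channel has its own onset, the EEG is segmented once *per EMG
   channel*, so every EMG×EEG pair is time-aligned on that muscle's
   activation. Windows are half-open sample ranges `[start, start+L)`,
   0-based; trials that do not fit are dropped with a warning.
4. **Rectification and normalization**: EMG windows are full-wave
   rectified; every window (EEG and EMG) is divided by its own area under
   the curve, defined as the trapezoidal integral of |x(t)| over the
   window. This removes per-trial amplitude scale; MSC itself is scale
   invariant, so normalization mainly stabilizes downstream numerics.

## MSC features

For a pair of windows, auto- and cross-spectral densities are estimated by
Welch's method with 0.5 s Hann windows (250 samples at 500 Hz, zero-padded
to a 256-point FFT) at 50% overlap *within* the 4 s window — 15 windows. A
single-window estimate would be identically 1, which is why the estimate
averages over windows inside the trial rather than across trials; a pooled
across-trial estimator (`msc_pooled`) is provided for dataset-level
spectra but is not used for the feature matrix.

MSC is `|Sxy|² / (Sxx·Syy)`, clipped to [0, 1]; zero-power bins return 0
by convention. Estimator facts that the tests encode: the Cauchy–Schwarz
bound holds bin-wise to 1e-9; identical inputs give coherence 1; for
independent noise the estimator is biased upward with mean ≈ 1/W — because
the 50%-overlapped windows are correlated, the measured bias (≈ 0.070)
sits slightly above 1/15 but safely below the disjoint-window ceiling 1/8.

Band averages are taken over K = 11 bands: δ(1.5–4), θ(4–8), α(8–13),
β₁(13–20), β₂(20–30), β(13–30), γ₁(30–45), γ₂(45–60), γ₃(60–80),
γ(30–80), full(1.5–80) Hz. Bands deliberately overlap (β contains β₁ and
β₂). Intervals are half-open `[low, high)` to avoid double-counting shared
edges; the topmost edge (80 Hz) is inclusive. One trial yields M·Q·K
features; the column of (m, q, k) is `((m−1)·Q + (q−1))·K + (k−1)` (band
fastest), an invertible map used later for the physiological read-out.
The full reference montage (M=5, Q=32) gives 1760 features.

## Balancing

Class counts are imbalanced per subject. Within each training split,
values are first normalized within subject (divided by the subject's
maximum, fitted on training rows and applied to that subject's test rows),
then the minority class of each subject is raised *exactly* to the
majority count by SMOTE-style interpolation: synthetic rows are equally
spaced points on the segment between a minority row and one of its k=5
nearest same-class, same-subject neighbours (seeded neighbour choice). A
subject with a single minority row is balanced by duplication, with a
warning. Exact balancing is chosen for determinism; on the published
light-vs-heavy trial manifest it yields 672 rows per class.

Balancing is fitted strictly on training data. This holds at every level:
outer test folds are never augmented, and — one level deeper — the inner
model-selection folds used by the selectors balance only each fold's
training part. Balancing the training matrix before inner folding would
let interpolated rows straddle fold boundaries and make every
configuration's inner error optimistic; with per-fold balancing the inner
CV actually discriminates between hyperparameter settings.

## The three selectors

**FeSC (feature selection with consensus).** Each feature is pooled to a
2-D point (its mean over class-1 trials, its mean over class-2 trials).
Three clustering algorithms — agglomerative (Ward, Euclidean), spectral
(RBF affinity, k-means assignment), and DBSCAN — cluster the p points. A
co-association matrix A holds the fraction of algorithms co-assigning each
pair (DBSCAN noise points never co-assign); pairs with A ≥ σ are linked
and consensus groups are the connected components with at least ν members
(transitive closure accepted). From each group the member closest to the
group's coordinate mean is selected (ties to the lowest column index). σ
is 0.6 ("majority", or "both" for two-algorithm variants) or 0.9 ("full
agreement"); ν and the per-algorithm grids (cluster counts
{12, 25, 50, 100, 200, 400} capped at p/2; DBSCAN eps {0.04, 0.08},
min-samples 2) are chosen by an inner stratified 5-fold CV minimizing the
mean classification error (MCE) of an RBF-kernel SVM (C on a small log
grid) trained on the selected features — the selection itself is repeated
inside each fold. The cluster-count grid spans coarse to fine so the CV
can adapt granularity to p; at small p, fine grids make Ward shred genuine
feature groups. Variants are named by the participating algorithms'
initials (e.g. FeSC-SD-0.6, FeSC-HSD-0.9).

**pFSFS.** A per-feature Welch two-sample t-test removes features with
p > 0.05 (no multiplicity correction — the filter is a coarse screen, as
in its usual usage). Forward sequential selection then greedily adds the
candidate minimizing the 5-fold CV MCE of a QDA classifier, stopping when
the best addition improves MCE by ≤ 1e-6. QDA covariances are shrunk
toward spherical (1e-6), escalating automatically on rank deficiency.

**LASSO.** The L1-penalized least-squares objective
`1/(2N)·Σ(yᵢ − β₀ − xᵢᵀβ)² + λ‖β‖₁` with classes coded y ∈ {0, 1} and
features standardized per training fold; 100 log-spaced penalties from
λ_max down to 1e-4·λ_max; λ* minimizes the 5-fold CV mean squared error.
Nonzero coefficients are ranked by |β| (ties to the lower column), and an
RBF SVM is refitted on growing prefixes of the ranking; the shortest
prefix with minimal CV MCE is the selection. The same seeded fold
partitions are shared by all selectors within a repetition.

## Evaluation, stability, ROIs

The study protocol is R = 10 repeated holdouts: stratified by
(subject, class), 90/10 train/test, repetition r seeded `seed + r`. Each
algorithm selects on the training split and its tuned classifier is scored
on the untouched test rows: MCE = (FP+FN)/total, TPR = TP/(TP+FN),
TNR = TN/(TN+FP), F1 = 2TP/(2TP+FP+FN). The count-reciprocal F1 variant
2/(2TP+FP+FN) exists behind a compatibility flag only; it is not a rate
and is never reported by default. Degenerate rates (empty class in a test
set) are returned as missing with a warning. The positive class is
class 1.

A feature is **stable** if selected in at least 70% of the repetitions
(count ≥ ⌈0.7·R⌉). The **selection efficiency** of an algorithm is
`100 · |stable| / mean(#selected)`, reported to one decimal — high when an
algorithm repeatedly converges on the same small set.

Stable columns are mapped back through the inverse feature index to
(muscle, EEG channel, band) triples and aggregated, per domain
independently, into regions of interest: frequencies into low {δ, θ},
SMR {α, β₁, β₂, β, γ₁, γ₂, γ₃, γ} and full {full}; EEG channels of a
32-channel 10-20 montage into Frontal / Centro-parietal (temporal,
central and parietal merged, since motor control engages all three) /
Occipital; muscles into Arm {AD, BR}, Forearm {CED, FD}, Hand {FDI}. The
channel→ROI table is configuration (YAML/JSON), not code, since montage
conventions vary. Overlapping bands each count once.

## The synthetic benchmark

The generator emulates exactly the structure the method assumes and
nothing more: EEG channels are 1/f background noise; EMG channels are
broadband noise shaped by a burst envelope (raised-cosine ramps) starting
at the annotated onset, with small per-channel onset jitter; couplings are
band-limited shared drives z(t) planted for trials of one class.

Two modelling points matter. First, the EEG receives z additively (scaled
to a gain times the channel's own in-band RMS), but the EMG is
**amplitude-modulated** by the drive, `carrier·(1 + κz)`: rectification
cancels the linear correlation of any symmetric additive component
(E[|z+n| | z] is even in z), whereas it demodulates a modulation — which
is also how a common synaptic drive physiologically modulates motor-unit
activity. An additive-only generator would produce a benchmark on which
the pipeline's own rectification step erases the planted signal. Second,
realism of the feature geometry: each coupling is echoed on a neighbouring
electrode at 0.85 of its gain (volume conduction — real cortical sources
never appear on a single electrode), so discriminative features arrive in
correlated groups as they do in real montages; and couplings are expressed
subject-specifically (subject s expresses coupling s mod C fully, the
others at 0.25 gain), so no single feature classifies every subject and a
selector must recover the whole planted set.

Default benchmark: 4 subjects, 40 vs 10 trials per class per subject (4:1
imbalance to exercise SMOTE), M=2 EMG × Q=8 EEG at 500 Hz (176 features),
three couplings of gain 2.2 in α (AD–C3), β₁ (AD–Cz) and γ₁ (FDI–C4,
class 2), echoed on Cz/C4/P3. A paper-scale preset (M=5, Q=32, 1760
features) exists for layout checks. Everything is reproducible from one
seed; per-subject streams derive from `seed·1009 + subject`.

What passing on this benchmark shows: the pipeline detects genuine
band-limited corticomuscular coupling through filtering, rectification,
normalization, Welch MSC and band averaging, and the selectors recover it
stably under resampling at realistic imbalance. What it does not show:
robustness to artefacts, non-stationarity, electrode impedance drift,
cross-subject transfer, or EMG whose spectrum deviates from the
modulated-noise model — real cohort performance cannot be inferred from
these tests.

## Numerical choices and edge cases

- Zero-AUC (all-zero) segments are hard errors naming trial and channel.
- Zero-power spectral bins give coherence 0 (debug-logged), not errors.
- Centroid and |β| ties break to the lowest column index; grid-search ties
  break to the first grid point in deterministic enumeration order.
- SFS stop tolerance 1e-6 absolute MCE; QDA shrinkage 1e-6 escalating to
  1e-3/1e-1 on singular class covariances.
- A stratum too small to contribute a test row stays whole in training
  (warning); a subject whose minority class has one row balances by
  duplication (warning).
- JSON reports round floats to 10 significant digits, so identical
  configuration and seed reproduce byte-identical artifacts.

## Problem sizes used by the test suite

Unit tests run on tiny instances (1–2 subjects, ≤ 12 trials per class,
M·Q ≤ 4). The end-to-end benchmark in the acceptance tests is the default
generator configuration above with R = 10 repetitions and the FeSC
variants SD/HD/HSD-0.6 plus pFSFS; these sizes are the package's chosen
desk-scale study conditions and complete in a few minutes on one core.
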