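"""Magnitude-squared coherence (MSC) features for EMG x EEG sensor pairs.

For a pair of time-aligned windows x (EMG) and y (EEG), the MSC spectrum is

    C(f) = |Sxy(f)|^2 / (Sxx(f) * Syy(f))        in [0, 1],

with auto/cross spectral densities estimated by Welch averaging over short
Hann windows inside the trial window.  The spectrum is then averaged over a
set of canonical frequency bands, and band means for every (EMG channel,
EEG channel, band) combination form one feature row per trial.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .preprocessing import SegmentBundle

logger = logging.getLogger(__name__)

DEFAULT_WIN_SECONDS = 0.5
DEFAULT_NFFT = 256
DEFAULT_OVERLAP = 0.5


@dataclass(frozen=True)
class BandScheme:
    """Ordered list of (name, low Hz, high Hz) frequency bands.

    Bands are half-open ``[low, high)``; the scheme's topmost edge is
    included so the highest band(s) keep their last bin.  Bands may overlap
    (the broad beta and gamma bands contain their sub-bands by design).
    """

    bands: tuple[tuple[str, float, float], ...]

    def __post_init__(self) -> None:
        for name, low, high in self.bands:
            if not 0.0 < low < high:
                raise ValueError(f"band {name}: need 0 < low < high, got ({low}, {high})")
        names = [b[0] for b in self.bands]
        if len(set(names)) != len(names):
            raise ValueError("band names must be unique")

    @property
    def K(self) -> int:
        return len(self.bands)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(b[0] for b in self.bands)

    @property
    def top_edge(self) -> float:
        return max(b[2] for b in self.bands)

    def index(self, name: str) -> int:
        return self.names.index(name)


#: The 11 canonical bands: delta through gamma sub-bands plus the broad
#: beta, gamma and full-range bands (edges in Hz).
DEFAULT_BANDS = BandScheme((
    ("delta", 1.5, 4.0),
    ("theta", 4.0, 8.0),
    ("alpha", 8.0, 13.0),
    ("beta1", 13.0, 20.0),
    ("beta2", 20.0, 30.0),
    ("beta", 13.0, 30.0),
    ("gamma1", 30.0, 45.0),
    ("gamma2", 45.0, 60.0),
    ("gamma3", 60.0, 80.0),
    ("gamma", 30.0, 80.0),
    ("full", 1.5, 80.0),
))


def _welch_args(fs: float, win_len: float, nfft: int, overlap: float, n_samples: int):
    nperseg = int(round(win_len * fs))
    if nperseg < 2:
        raise ValueError("Welch window shorter than two samples")
    if nperseg > n_samples:
        raise ValueError(
            f"segment of {n_samples} samples is shorter than one "
            f"{win_len} s Welch window ({nperseg} samples)"
        )
    if not 0.0 <= overlap < 1.0:
        raise ValueError("overlap fraction must be in [0, 1)")
    if nfft < nperseg:
        raise ValueError("nfft must be >= window length in samples")
    return dict(
        fs=fs,
        window=signal.get_window("hann", nperseg),
        nperseg=nperseg,
        noverlap=int(nperseg * overlap),
        nfft=nfft,
        detrend=False,
        scaling="density",
    )


def cross_spectra(
    x: np.ndarray,
    y: np.ndarray,
    fs: float,
    win_len: float = DEFAULT_WIN_SECONDS,
    nfft: int = DEFAULT_NFFT,
    overlap: float = DEFAULT_OVERLAP,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Welch auto- and cross-spectral densities of two equal-length windows.

    Returns ``(f, Sxx, Syy, Sxy)`` on the one-sided nfft frequency grid.
    ``x`` and ``y`` may carry leading channel axes (broadcast against each
    other); the last axis is time.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape[-1] != y.shape[-1]:
        raise ValueError("x and y must have the same number of samples")
    kw = _welch_args(fs, win_len, nfft, overlap, x.shape[-1])
    f, sxx = signal.welch(x, **kw)
    _, syy = signal.welch(y, **kw)
    _, sxy = signal.csd(x, y, **kw)
    return f, sxx, syy, sxy


def n_welch_windows(n_samples: int, fs: float, win_len: float = DEFAULT_WIN_SECONDS,
                    overlap: float = DEFAULT_OVERLAP) -> int:
    """Number of Welch windows that fit in a segment (sets the MSC noise bias ~1/W)."""
    nperseg = int(round(win_len * fs))
    step = nperseg - int(nperseg * overlap)
    return 1 + (n_samples - nperseg) // step


def msc(
    x: np.ndarray,
    y: np.ndarray,
    fs: float,
    win_len: float = DEFAULT_WIN_SECONDS,
    nfft: int = DEFAULT_NFFT,
    overlap: float = DEFAULT_OVERLAP,
) -> tuple[np.ndarray, np.ndarray]:
    """Magnitude-squared coherence spectrum of two windows, in [0, 1].

    Bins where either autospectrum vanishes are returned as 0 by convention
    (logged at debug level), never as an error.
    """
    f, sxx, syy, sxy = cross_spectra(x, y, fs, win_len, nfft, overlap)
    denom = sxx * syy
    bad = denom <= 0.0
    if np.any(bad):
        logger.debug("msc: %d zero-power bins returned as coherence 0", int(np.sum(bad)))
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(bad, 0.0, np.abs(sxy) ** 2 / np.where(bad, 1.0, denom))
    return f, np.clip(c, 0.0, 1.0)


def msc_pooled(
    xs: np.ndarray,
    ys: np.ndarray,
    fs: float,
    win_len: float = DEFAULT_WIN_SECONDS,
    nfft: int = DEFAULT_NFFT,
    overlap: float = DEFAULT_OVERLAP,
) -> tuple[np.ndarray, np.ndarray]:
    """Coherence from spectra pooled over a stack of trials (first axis).

    This is the estimator obtained by averaging the auto- and cross-spectra
    across trials before taking the ratio.  It is not used for the per-trial
    feature matrix (a per-trial ratio is) but is exposed for analyses that
    want a single dataset-level coherence spectrum.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.shape != ys.shape or xs.ndim != 2:
        raise ValueError("xs and ys must be equal-shape (n_trials, n_samples) stacks")
    f, sxx, syy, sxy = cross_spectra(xs, ys, fs, win_len, nfft, overlap)
    sxx_m, syy_m, sxy_m = sxx.mean(axis=0), syy.mean(axis=0), sxy.mean(axis=0)
    denom = sxx_m * syy_m
    bad = denom <= 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(bad, 0.0, np.abs(sxy_m) ** 2 / np.where(bad, 1.0, denom))
    return f, np.clip(c, 0.0, 1.0)


def band_average(f: np.ndarray, spectrum: np.ndarray, scheme: BandScheme = DEFAULT_BANDS) -> np.ndarray:
    """Mean of a spectrum over each band of the scheme.

    Bands are half-open ``[low, high)`` except that the scheme's topmost
    edge is inclusive, so adjacent bands never double-count a shared edge
    bin while the highest bands keep their final bin.  A band containing no
    frequency bin is an error.  ``spectrum`` may carry leading axes; the
    last axis is frequency.
    """
    f = np.asarray(f, dtype=float)
    spectrum = np.asarray(spectrum, dtype=float)
    top = scheme.top_edge
    out = np.empty(spectrum.shape[:-1] + (scheme.K,))
    for k, (name, low, high) in enumerate(scheme.bands):
        mask = (f >= low) & ((f < high) | ((high == top) & (f <= high)))
        if not np.any(mask):
            raise ValueError(f"band {name} ({low}, {high}) Hz contains no frequency bin")
        out[..., k] = spectrum[..., mask].mean(axis=-1)
    return out


def feature_index(m: int, q: int, k: int, M: int, Q: int, K: int) -> int:
    """Column of the (EMG m, EEG q, band k) feature; all indices 1-based.

    Band index varies fastest, then the EEG channel, then the EMG channel.
    """
    if not (1 <= m <= M and 1 <= q <= Q and 1 <= k <= K):
        raise IndexError(f"(m={m}, q={q}, k={k}) outside 1..({M}, {Q}, {K})")
    return ((m - 1) * Q + (q - 1)) * K + (k - 1)


def feature_unmap(col: int, M: int, Q: int, K: int) -> tuple[int, int, int]:
    """Inverse of :func:`feature_index`: column -> 1-based (m, q, k)."""
    if not 0 <= col < M * Q * K:
        raise IndexError(f"column {col} outside 0..{M * Q * K - 1}")
    k = col % K
    q = (col // K) % Q
    m = col // (K * Q)
    return m + 1, q + 1, k + 1


@dataclass
class FeatureMatrix:
    """Trials x (M*Q*K) band-averaged MSC values with metadata.

    Columns follow :func:`feature_index`; ``column_names`` renders them as
    ``<muscle>_<channel>_<band>``.  All values lie in [0, 1] before any
    within-subject normalization.
    """

    values: np.ndarray
    labels: np.ndarray
    subject_ids: np.ndarray
    M: int
    Q: int
    scheme: BandScheme
    emg_labels: tuple[str, ...]
    eeg_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels)
        self.subject_ids = np.asarray(self.subject_ids)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (trials x features)")
        p = self.M * self.Q * self.scheme.K
        if self.values.shape[1] != p:
            raise ValueError(f"expected {p} = M*Q*K columns, got {self.values.shape[1]}")
        if len(self.labels) != self.values.shape[0] or len(self.subject_ids) != self.values.shape[0]:
            raise ValueError("labels/subject_ids must match the trial count")

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def K(self) -> int:
        return self.scheme.K

    def feature_index(self, m: int, q: int, k: int) -> int:
        return feature_index(m, q, k, self.M, self.Q, self.K)

    def unmap(self, col: int) -> tuple[int, int, int]:
        return feature_unmap(col, self.M, self.Q, self.K)

    def column_triple(self, col: int) -> tuple[str, str, str]:
        """Column -> (muscle code, EEG channel name, band name)."""
        m, q, k = self.unmap(col)
        return self.emg_labels[m - 1], self.eeg_labels[q - 1], self.scheme.names[k - 1]

    def column_names(self) -> list[str]:
        return ["_".join(self.column_triple(c)) for c in range(self.n_features)]

    def class_counts(self) -> dict:
        vals, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))


def build_feature_matrix(
    bundle: SegmentBundle,
    scheme: BandScheme = DEFAULT_BANDS,
    win_len: float = DEFAULT_WIN_SECONDS,
    nfft: int = DEFAULT_NFFT,
    overlap: float = DEFAULT_OVERLAP,
) -> FeatureMatrix:
    """Per-trial band-averaged MSC for every EMG x EEG pair.

    For trial ``n``, the column of (EMG m, EEG q, band k) holds the band-k
    mean of the MSC between EMG channel m's window and the EEG channel q
    window that was cut at channel m's onset.
    """
    if not bundle.rectified:
        raise ValueError("bundle must be rectified/normalized before feature extraction")
    n, M, Q, K = bundle.n_trials, bundle.n_emg, bundle.n_eeg, scheme.K
    values = np.empty((n, M * Q * K))
    for m in range(M):
        for i in range(n):
            x = bundle.emg_segments[i, m]            # (L,)
            ys = bundle.eeg_segments_by_emg[m, i]    # (Q, L)
            f, c = msc(x[None, :], ys, bundle.fs, win_len, nfft, overlap)  # (Q, F)
            bands = band_average(f, c, scheme)       # (Q, K)
            values[i, m * Q * K:(m + 1) * Q * K] = bands.reshape(-1)
    return FeatureMatrix(
        values=values,
        labels=np.asarray(bundle.trial_classes),
        subject_ids=np.repeat(bundle.subject_id, n),
        M=M,
        Q=Q,
        scheme=scheme,
        emg_labels=bundle.emg_labels,
        eeg_labels=bundle.eeg_labels,
    )


def concat_feature_matrices(mats: list[FeatureMatrix]) -> FeatureMatrix:
    """Stack per-subject feature matrices into one dataset."""
    if not mats:
        raise ValueError("no feature matrices to concatenate")
    first = mats[0]
    for fm in mats[1:]:
        if (fm.M, fm.Q, fm.scheme) != (first.M, first.Q, first.scheme):
            raise ValueError("feature matrices have incompatible layouts")
        if fm.emg_labels != first.emg_labels or fm.eeg_labels != first.eeg_labels:
            raise ValueError("feature matrices have different channel labels")
    from dataclasses import replace
    return replace(
        first,
        values=np.concatenate([fm.values for fm in mats], axis=0),
        labels=np.concatenate([fm.labels for fm in mats]),
        subject_ids=np.concatenate([fm.subject_ids for fm in mats]),
    )
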