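"""Filtering, onset-anchored segmentation, rectification and AUC normalization.

The pipeline assumes artefact-free multichannel EEG+EMG recordings with
per-trial, per-EMG-channel movement-onset annotations.  Processing order is

1. band-pass (Chebyshev-I, zero-phase) and mains notch filtering of every
   channel,
2. cutting one fixed-length window per trial, anchored at each EMG channel's
   own onset (so there is one EEG segmentation per EMG channel),
3. full-wave rectification of the EMG windows and normalization of every
   window (EEG and EMG) by its own area under the curve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

logger = logging.getLogger(__name__)

DEFAULT_BAND = (1.5, 80.0)
DEFAULT_BANDPASS_ORDER = 86
DEFAULT_RIPPLE_DB = 0.5
DEFAULT_NOTCH_HZ = 50.0
DEFAULT_SEGMENT_SECONDS = 4.0


@dataclass
class Recording:
    """One subject's continuous multichannel EEG+EMG acquisition.

    ``eeg`` is (Q, samples) and ``emg`` is (M, samples), both in microvolts
    at a common sampling rate ``fs``.  ``onsets`` is (n_trials, M): each EMG
    channel carries its own annotated contraction onset (seconds) for every
    trial.  ``trial_classes`` holds one label per trial, coded as small
    integers (1 and 2 for a binary problem).
    """

    eeg: np.ndarray
    emg: np.ndarray
    fs: float
    eeg_labels: tuple[str, ...]
    emg_labels: tuple[str, ...]
    onsets: np.ndarray
    trial_classes: np.ndarray
    subject_id: str

    def __post_init__(self) -> None:
        self.eeg = np.asarray(self.eeg, dtype=float)
        self.emg = np.asarray(self.emg, dtype=float)
        self.onsets = np.atleast_2d(np.asarray(self.onsets, dtype=float))
        self.trial_classes = np.asarray(self.trial_classes)
        self.eeg_labels = tuple(self.eeg_labels)
        self.emg_labels = tuple(self.emg_labels)
        if self.eeg.ndim != 2 or self.emg.ndim != 2:
            raise ValueError("eeg and emg must be 2-D (channels x samples)")
        if self.eeg.shape[1] != self.emg.shape[1]:
            raise ValueError("eeg and emg must share the sample count")
        if self.eeg.shape[0] < 1 or self.emg.shape[0] < 1:
            raise ValueError("need at least one EEG and one EMG channel")
        if len(self.eeg_labels) != self.eeg.shape[0]:
            raise ValueError("eeg_labels length does not match channel count")
        if len(self.emg_labels) != self.emg.shape[0]:
            raise ValueError("emg_labels length does not match channel count")
        if self.onsets.shape[1] != self.emg.shape[0]:
            raise ValueError("onsets must provide one column per EMG channel")
        if len(self.trial_classes) != self.onsets.shape[0]:
            raise ValueError("one class label per trial is required")
        if self.fs <= 2 * DEFAULT_BAND[1]:
            raise ValueError(
                f"sampling rate {self.fs} Hz cannot represent the "
                f"{DEFAULT_BAND[1]} Hz upper analysis edge"
            )

    @property
    def n_eeg(self) -> int:
        return self.eeg.shape[0]

    @property
    def n_emg(self) -> int:
        return self.emg.shape[0]

    @property
    def n_trials(self) -> int:
        return self.onsets.shape[0]

    @property
    def duration(self) -> float:
        return self.eeg.shape[1] / self.fs


@dataclass
class SegmentBundle:
    """Per-trial windows cut from a :class:`Recording`.

    ``emg_segments`` is (n_trials, M, L).  ``eeg_segments_by_emg`` is
    (M, n_trials, Q, L): entry ``m`` holds the EEG windows cut at EMG channel
    ``m``'s onsets, so EEG and EMG windows of a pair are time-aligned.
    """

    emg_segments: np.ndarray
    eeg_segments_by_emg: np.ndarray
    fs: float
    duration: float
    trial_classes: np.ndarray
    subject_id: str
    eeg_labels: tuple[str, ...]
    emg_labels: tuple[str, ...]
    excluded_trials: tuple[int, ...] = ()
    rectified: bool = False

    @property
    def n_trials(self) -> int:
        return self.emg_segments.shape[0]

    @property
    def n_emg(self) -> int:
        return self.emg_segments.shape[1]

    @property
    def n_eeg(self) -> int:
        return self.eeg_segments_by_emg.shape[2]

    @property
    def segment_length(self) -> int:
        return self.emg_segments.shape[2]


def _validate_band(fs: float, low: float, high: float) -> None:
    if not (0.0 < low < high < fs / 2.0):
        raise ValueError(
            f"band ({low}, {high}) Hz must satisfy 0 < low < high < fs/2 = {fs / 2}"
        )


def design_bandpass(
    fs: float,
    band: tuple[float, float] = DEFAULT_BAND,
    order: int = DEFAULT_BANDPASS_ORDER,
    ripple_db: float = DEFAULT_RIPPLE_DB,
) -> np.ndarray:
    """Chebyshev type-I band-pass as second-order sections.

    ``order`` is the overall filter order; a band-pass of order ``2n`` comes
    from an ``n``-th order low-pass prototype, hence ``order`` must be even.
    The high nominal order is only numerically viable as an SOS cascade.
    """
    _validate_band(fs, *band)
    if order < 2 or order % 2:
        raise ValueError("band-pass order must be a positive even integer")
    return signal.cheby1(order // 2, ripple_db, band, btype="bandpass", fs=fs, output="sos")


def bandpass_filter(
    x: np.ndarray,
    fs: float,
    band: tuple[float, float] = DEFAULT_BAND,
    order: int = DEFAULT_BANDPASS_ORDER,
    ripple_db: float = DEFAULT_RIPPLE_DB,
    axis: int = -1,
) -> np.ndarray:
    """Zero-phase Chebyshev-I band-pass (forward-backward SOS)."""
    sos = design_bandpass(fs, band, order, ripple_db)
    return signal.sosfiltfilt(sos, np.asarray(x, dtype=float), axis=axis)


def notch_filter(
    x: np.ndarray,
    fs: float,
    f0: float = DEFAULT_NOTCH_HZ,
    order: int = 2,
    quality: float = 35.0,
    axis: int = -1,
) -> np.ndarray:
    """Zero-phase IIR notch at the mains frequency.

    Each second-order stage is a classic direct-form notch biquad; ``order``
    must be an even multiple of 2 and sets the number of cascaded stages.
    ``quality`` controls the -3 dB notch width (f0 / quality).
    """
    if not 0.0 < f0 < fs / 2.0:
        raise ValueError(f"notch frequency {f0} Hz must lie in (0, fs/2)")
    if order < 2 or order % 2:
        raise ValueError("notch order must be a positive even integer")
    b, a = signal.iirnotch(f0, quality, fs=fs)
    y = np.asarray(x, dtype=float)
    for _ in range(order // 2):
        y = signal.filtfilt(b, a, y, axis=axis)
    return y


def filter_recording(
    rec: Recording,
    band: tuple[float, float] = DEFAULT_BAND,
    order: int = DEFAULT_BANDPASS_ORDER,
    ripple_db: float = DEFAULT_RIPPLE_DB,
    notch_hz: float | None = DEFAULT_NOTCH_HZ,
    notch_quality: float = 35.0,
) -> Recording:
    """Apply band-pass + notch to every EEG and EMG channel of a recording."""

    def _proc(sig_mat: np.ndarray) -> np.ndarray:
        y = bandpass_filter(sig_mat, rec.fs, band, order, ripple_db, axis=-1)
        if notch_hz is not None:
            y = notch_filter(y, rec.fs, notch_hz, quality=notch_quality, axis=-1)
        return y

    return replace(rec, eeg=_proc(rec.eeg), emg=_proc(rec.emg))


def segment_trials(
    rec: Recording,
    duration: float = DEFAULT_SEGMENT_SECONDS,
    pre_onset: float = 0.0,
) -> SegmentBundle:
    """Cut one ``duration``-second window per trial per EMG channel.

    Windows are half-open sample ranges ``[start, start+L)`` with
    ``start = round((onset - pre_onset) * fs)``; EEG windows in entry ``m``
    of the bundle use EMG channel ``m``'s onset.  Trials whose window does
    not fit inside the recording (for any channel) are dropped with a
    warning and recorded in ``excluded_trials``.
    """
    L = int(round(duration * rec.fs))
    if L < 1:
        raise ValueError("segment duration must cover at least one sample")
    n_samples = rec.eeg.shape[1]
    starts = np.round((rec.onsets - pre_onset) * rec.fs).astype(int)  # (n, M)

    keep, excluded = [], []
    for n in range(rec.n_trials):
        if np.all((starts[n] >= 0) & (starts[n] + L <= n_samples)):
            keep.append(n)
        else:
            excluded.append(n)
            logger.warning(
                "subject %s: trial %d window [%s, +%d) outside recording; dropped",
                rec.subject_id, n, starts[n].tolist(), L,
            )

    emg_seg = np.empty((len(keep), rec.n_emg, L))
    eeg_seg = np.empty((rec.n_emg, len(keep), rec.n_eeg, L))
    for i, n in enumerate(keep):
        for m in range(rec.n_emg):
            s = starts[n, m]
            emg_seg[i, m] = rec.emg[m, s:s + L]
            eeg_seg[m, i] = rec.eeg[:, s:s + L]

    return SegmentBundle(
        emg_segments=emg_seg,
        eeg_segments_by_emg=eeg_seg,
        fs=rec.fs,
        duration=duration,
        trial_classes=rec.trial_classes[keep],
        subject_id=rec.subject_id,
        eeg_labels=rec.eeg_labels,
        emg_labels=rec.emg_labels,
        excluded_trials=tuple(excluded),
    )


def _auc(seg: np.ndarray, fs: float) -> float:
    # area under the rectified curve, trapezoidal, over time in seconds
    return float(np.trapezoid(np.abs(seg), dx=1.0 / fs))


def rectify_and_normalize(bundle: SegmentBundle) -> SegmentBundle:
    """Full-wave rectify EMG windows; normalize every window by its AUC.

    The AUC of a window is the trapezoidal integral of its absolute value
    over the window (seconds); after this step every EEG and EMG window has
    unit AUC.  An all-zero window is a hard error naming trial and channel.
    """
    emg = np.abs(bundle.emg_segments).copy()
    eeg = bundle.eeg_segments_by_emg.copy()
    fs = bundle.fs

    for n in range(bundle.n_trials):
        for m in range(bundle.n_emg):
            a = _auc(emg[n, m], fs)
            if a <= 0.0:
                raise ValueError(
                    f"zero-AUC EMG segment: subject {bundle.subject_id}, "
                    f"trial {n}, EMG channel {bundle.emg_labels[m]}"
                )
            emg[n, m] /= a
            for q in range(bundle.n_eeg):
                a = _auc(eeg[m, n, q], fs)
                if a <= 0.0:
                    raise ValueError(
                        f"zero-AUC EEG segment: subject {bundle.subject_id}, "
                        f"trial {n}, EMG anchor {bundle.emg_labels[m]}, "
                        f"EEG channel {bundle.eeg_labels[q]}"
                    )
                eeg[m, n, q] /= a

    return replace(bundle, emg_segments=emg, eeg_segments_by_emg=eeg, rectified=True)


def preprocess_recording(
    rec: Recording,
    duration: float = DEFAULT_SEGMENT_SECONDS,
    band: tuple[float, float] = DEFAULT_BAND,
    order: int = DEFAULT_BANDPASS_ORDER,
    ripple_db: float = DEFAULT_RIPPLE_DB,
    notch_hz: float | None = DEFAULT_NOTCH_HZ,
    pre_onset: float = 0.0,
) -> SegmentBundle:
    """Filter -> segment -> rectify+normalize, in one call."""
    filtered = filter_recording(rec, band, order, ripple_db, notch_hz)
    bundle = segment_trials(filtered, duration=duration, pre_onset=pre_onset)
    return rectify_and_normalize(bundle)
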