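"""Synthetic EEG-EMG recordings with planted, class-dependent coherence.

The generator emulates the statistical structure the pipeline assumes: a
band-limited common drive z(t) shared between designated EEG-EMG channel
pairs during movement, visible as magnitude-squared coherence in exactly
one frequency band, for trials of one class only.

The EEG channel receives the drive additively (z scaled against the
channel's own in-band background power), on top of 1/f "pink" background
noise.  The EMG channel is broadband noise shaped by a burst envelope that
starts at the annotated onset; the drive enters *multiplicatively*, as an
amplitude modulation ``carrier * (1 + kappa * z)``.  The multiplicative
route matters: the preprocessing rectifies the EMG, and full-wave
rectification of a symmetric additive component cancels its linear
correlation entirely, whereas rectification demodulates an amplitude
modulation — which is also how a common synaptic drive physiologically
modulates motor-unit activity.

Inter-subject variability is emulated by attenuating, for each subject in
turn, one of the planted couplings: no single feature then separates the
classes for every subject, as in real cohorts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .coherence import DEFAULT_BANDS, BandScheme, feature_index
from .preprocessing import Recording

logger = logging.getLogger(__name__)

DEFAULT_EEG_LABELS = ("F3", "Fz", "F4", "C3", "Cz", "C4", "P3", "O1")
DEFAULT_EMG_LABELS = ("AD", "FDI")


@dataclass(frozen=True)
class Coupling:
    """One planted EEG-EMG coupling.

    ``gain`` is the amplitude of the shared drive relative to the target
    channels' background (EEG: in-band additive SNR; EMG: modulation depth
    is ``emg_mod_depth * gain`` of the config, clipped below 1).

    ``echo_channel`` receives the same drive at ``echo_gain * gain``,
    emulating the volume conduction that spreads any real cortical source
    over neighbouring electrodes; coherence features therefore come in
    correlated groups rather than as isolated columns, as in real montages.
    """

    muscle: str
    channel: str
    band: str
    klass: int
    gain: float
    echo_channel: str | None = None
    echo_gain: float = 0.85

    def __post_init__(self) -> None:
        if self.gain < 0:
            raise ValueError("coupling gain must be nonnegative")
        if not 0.0 <= self.echo_gain <= 1.0:
            raise ValueError("echo_gain must be in [0, 1]")


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for the synthetic benchmark.

    Defaults describe a desk-scale cohort: 4 subjects, 40 vs 10 trials per
    class per subject (a 4:1 imbalance, exercising the SMOTE step), M=2 EMG
    by Q=8 EEG channels at 500 Hz, and three strong couplings planted in
    distinct sensorimotor channels/bands, two active in class 1 and one in
    class 2, each echoed on a neighbouring electrode.

    Inter-subject variability: subject ``s`` expresses coupling ``s mod C``
    at full gain and the remaining couplings at ``subject_attenuation``
    times their gain, so no single feature separates the classes for every
    subject — the selectors must recover the whole planted set.
    """

    n_subjects: int = 4
    trials_per_class: tuple[int, int] = (40, 10)
    fs: float = 500.0
    eeg_labels: tuple[str, ...] = DEFAULT_EEG_LABELS
    emg_labels: tuple[str, ...] = DEFAULT_EMG_LABELS
    couplings: tuple[Coupling, ...] = (
        Coupling("AD", "C3", "alpha", 1, 2.2, echo_channel="Cz"),
        Coupling("AD", "Cz", "beta1", 1, 2.2, echo_channel="C4"),
        Coupling("FDI", "C4", "gamma1", 2, 2.2, echo_channel="P3"),
    )
    scheme: BandScheme = DEFAULT_BANDS
    duration: float = 4.0        # movement / segment length, s
    gap: float = 2.0             # inter-trial silence, s
    lead_in: float = 1.0         # pre-onset time inside a trial slot, s
    onset_jitter: float = 0.02   # max per-channel onset offset, s
    emg_baseline: float = 0.15   # EMG noise amplitude outside bursts
    emg_mod_depth: float = 0.35  # modulation depth per unit coupling gain
    ramp: float = 0.1            # burst envelope ramp, s
    subject_attenuation: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        band_names = set(self.scheme.names)
        for c in self.couplings:
            if c.band not in band_names:
                raise ValueError(f"coupling band {c.band!r} not in the band scheme")
            low, high = [b[1:] for b in self.scheme.bands if b[0] == c.band][0]
            if high > self.fs / 2:
                raise ValueError(f"coupling band {c.band} exceeds the Nyquist rate")
            if c.muscle not in self.emg_labels:
                raise ValueError(f"coupling muscle {c.muscle!r} not among EMG channels")
            if c.channel not in self.eeg_labels:
                raise ValueError(f"coupling channel {c.channel!r} not among EEG channels")
            if c.echo_channel is not None and c.echo_channel not in self.eeg_labels:
                raise ValueError(f"echo channel {c.echo_channel!r} not among EEG channels")
            if c.klass not in (1, 2):
                raise ValueError("coupling class must be 1 or 2")
        if min(self.trials_per_class) < 1 or self.n_subjects < 1:
            raise ValueError("need at least one trial per class and one subject")

    @property
    def M(self) -> int:
        return len(self.emg_labels)

    @property
    def Q(self) -> int:
        return len(self.eeg_labels)

    def band_edges(self, name: str) -> tuple[float, float]:
        for bname, low, high in self.scheme.bands:
            if bname == name:
                return low, high
        raise KeyError(name)


@dataclass
class GroundTruth:
    """Which feature columns carry planted class contrast.

    ``discriminative_columns`` are the (muscle, channel, band) columns of
    the planted couplings under the M*Q*K index map.  ``nominal_contrast``
    is the coupling's two-sided linear-SNR coherence approximation
    (g^2/(1+g^2))^2 — a rough magnitude, not a calibrated prediction.
    """

    discriminative_columns: list[int]
    couplings: tuple[Coupling, ...]
    nominal_contrast: list[float]
    M: int
    Q: int
    K: int
    companion_columns: list[int] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "discriminative_columns": [int(c) for c in self.discriminative_columns],
            "companion_columns": [int(c) for c in self.companion_columns],
            "couplings": [
                {"muscle": c.muscle, "channel": c.channel, "band": c.band,
                 "class": c.klass, "gain": c.gain}
                for c in self.couplings
            ],
            "nominal_contrast": [float(v) for v in self.nominal_contrast],
            "M": self.M, "Q": self.Q, "K": self.K,
        }


def _pink_noise(rng: np.random.Generator, n: int, fs: float) -> np.ndarray:
    """Unit-RMS 1/f-amplitude noise (flat below 1 Hz to bound the variance)."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    shaping = 1.0 / np.sqrt(np.maximum(f, 1.0))
    x = np.fft.irfft(spec * shaping, n=n)
    return x / np.std(x)


def _band_noise(rng: np.random.Generator, n: int, fs: float,
                band: tuple[float, float]) -> np.ndarray:
    """Unit-RMS band-limited Gaussian noise (4th-order Butterworth, zero phase)."""
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    z = signal.sosfiltfilt(sos, rng.standard_normal(n))
    return z / np.std(z)


def _burst_envelope(n: int, fs: float, ramp: float) -> np.ndarray:
    """Unit plateau with raised-cosine ramps at both ends."""
    env = np.ones(n)
    k = min(int(round(ramp * fs)), n // 2)
    if k > 0:
        up = 0.5 * (1 - np.cos(np.pi * np.arange(k) / k))
        env[:k] = up
        env[-k:] = up[::-1]
    return env


def _band_rms(x: np.ndarray, fs: float, band: tuple[float, float]) -> float:
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    return float(np.std(signal.sosfiltfilt(sos, x)))


def generate_recording(config: SynthConfig, subject_index: int) -> Recording:
    """One subject's synthetic recording; deterministic in (seed, subject)."""
    rng = np.random.default_rng(config.seed * 1009 + subject_index)
    fs, M, Q = config.fs, config.M, config.Q
    n1, n2 = config.trials_per_class
    n_trials = n1 + n2
    slot = config.lead_in + config.duration + config.gap
    n_samples = int(round((n_trials * slot + config.gap) * fs))
    L = int(round(config.duration * fs))

    classes = rng.permutation(np.repeat([1, 2], [n1, n2]))

    eeg = np.stack([_pink_noise(rng, n_samples, fs) for _ in range(Q)])
    carriers = np.stack([rng.standard_normal(n_samples) for _ in range(M)])
    emg_env = np.full((M, n_samples), config.emg_baseline)
    emg_mod = np.ones((M, n_samples))

    onsets = np.empty((n_trials, M))
    burst = _burst_envelope(L, fs, config.ramp)

    # subject expresses one coupling fully, the others attenuated
    atten = np.full(len(config.couplings), config.subject_attenuation)
    if config.couplings:
        atten[subject_index % len(config.couplings)] = 1.0

    for n in range(n_trials):
        base = n * slot + config.lead_in
        jit = rng.uniform(-config.onset_jitter, config.onset_jitter, size=M)
        onsets[n] = base + jit
        starts = np.round(onsets[n] * fs).astype(int)
        for m in range(M):
            emg_env[m, starts[m]:starts[m] + L] = burst

        for ci, c in enumerate(config.couplings):
            if c.klass != classes[n]:
                continue
            g = c.gain * atten[ci]
            if g == 0.0:
                continue
            m = config.emg_labels.index(c.muscle)
            band = config.band_edges(c.band)
            s = starts[m]
            z = _band_noise(rng, L, fs, band) * burst
            # EEG: additive, scaled to g times the channel's own in-band RMS
            targets = [(config.eeg_labels.index(c.channel), g)]
            if c.echo_channel is not None:
                targets.append((config.eeg_labels.index(c.echo_channel), g * c.echo_gain))
            for q, gq in targets:
                eeg_rms = _band_rms(eeg[q, s:s + L], fs, band)
                eeg[q, s:s + L] += gq * eeg_rms * z
            # EMG: amplitude modulation of the burst carrier by the drive
            depth = min(config.emg_mod_depth * g, 0.95 / max(np.max(np.abs(z)), 1e-12))
            emg_mod[m, s:s + L] *= 1.0 + depth * z

    emg = carriers * emg_env * emg_mod

    return Recording(
        eeg=eeg,
        emg=emg,
        fs=fs,
        eeg_labels=config.eeg_labels,
        emg_labels=config.emg_labels,
        onsets=onsets,
        trial_classes=classes,
        subject_id=f"S{subject_index + 1:02d}",
    )


def generate_dataset(config: SynthConfig = SynthConfig()
                     ) -> tuple[list[Recording], GroundTruth]:
    """All subjects' recordings plus the planted-feature ground truth."""
    recs = [generate_recording(config, s) for s in range(config.n_subjects)]
    K = config.scheme.K
    cols, companions, contrast = [], [], []
    for c in config.couplings:
        m = config.emg_labels.index(c.muscle) + 1
        k = config.scheme.index(c.band) + 1
        q = config.eeg_labels.index(c.channel) + 1
        cols.append(feature_index(m, q, k, config.M, config.Q, K))
        if c.echo_channel is not None:
            qe = config.eeg_labels.index(c.echo_channel) + 1
            companions.append(feature_index(m, qe, k, config.M, config.Q, K))
        lin = c.gain ** 2 / (1.0 + c.gain ** 2)
        contrast.append(lin ** 2)
    return recs, GroundTruth(
        discriminative_columns=cols,
        couplings=config.couplings,
        nominal_contrast=contrast,
        M=config.M,
        Q=config.Q,
        K=K,
        companion_columns=companions,
    )


def paper_scale_config(seed: int = 0) -> SynthConfig:
    """A 5-muscle x 32-channel preset matching a full acquisition montage."""
    eeg32 = ("Fp1", "Fp2", "AF3", "AF4", "F7", "F3", "Fz", "F4", "F8",
             "FC5", "FC1", "FC2", "FC6", "T7", "C3", "Cz", "C4", "T8",
             "CP5", "CP1", "CP2", "CP6", "P7", "P3", "Pz", "P4", "P8",
             "PO3", "PO4", "O1", "Oz", "O2")
    emg5 = ("AD", "BR", "CED", "FD", "FDI")
    return SynthConfig(
        n_subjects=2,
        trials_per_class=(10, 5),
        eeg_labels=eeg32,
        emg_labels=emg5,
        couplings=(
            Coupling("AD", "C3", "alpha", 1, 2.2, echo_channel="Cz"),
            Coupling("BR", "Cz", "beta1", 1, 2.2, echo_channel="C4"),
            Coupling("FDI", "C4", "gamma1", 2, 2.2, echo_channel="Pz"),
        ),
        seed=seed,
    )
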