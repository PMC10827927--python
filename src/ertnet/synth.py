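"""Labeled synthetic EEG with band- and channel-localized class signatures.

The generator plants exactly the kind of structure the interpretability
analysis is meant to recover: each class adds a narrow-band oscillation
(centre frequency drawn per epoch inside the class band, random phase) on a
small set of target channels, on top of 1/f "pink" background noise shared
by all classes, optional white noise, optional 50 Hz line interference and
optional broadband high-frequency bursts.  A ground-truth manifest records
the planted band and channels per class so recovery can be scored without
consulting the model.

Everything is a deterministic function of the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import EpochSet
from .montage import Montage, get_montage


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class ClassSignature:
    """Band-limited oscillatory code for one class.

    band:
        (low, high) Hz; per-epoch centre frequency is drawn uniformly here.
    target_channels:
        channel names receiving the oscillation (empty = signature-free
        class, i.e. background only).
    amplitude:
        oscillation amplitude in the same units as the unit-variance
        background noise, so amplitude ~ SNR.
    phase_jitter:
        sd (radians) of per-channel phase offsets around the epoch phase.
    """

    band: tuple[float, float] | None
    target_channels: tuple[str, ...] = ()
    amplitude: float = 2.0
    phase_jitter: float = 0.0


@dataclass(frozen=True)
class NoiseSpec:
    pink_amp: float = 1.0
    pink_exponent: float = 1.0
    white_sd: float = 0.3
    line_50hz_amp: float = 0.0
    hf_artifact_amp: float = 0.0


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for one synthetic dataset.

    Defaults produce the 2-class beta-band task used throughout the test
    suite: 32 channels at 128 Hz, 4-s epochs, a 20 Hz (18-22 Hz band)
    signature of amplitude 2 on the temporal-lobe pair T7/T8 against
    unit-variance pink background (amplitude/noise ratio 2), 8 subjects,
    50 epochs per subject per class -> 800 epochs.
    """

    montage: str | list[str] = "deap32"
    sampling_rate: float = 128.0
    epoch_seconds: float = 4.0
    n_subjects: int = 8
    epochs_per_subject_per_class: int = 50
    signatures: dict[str, ClassSignature] = field(default_factory=lambda: {
        "background": ClassSignature(band=None),
        "beta": ClassSignature(band=(18.0, 22.0),
                               target_channels=("T7", "T8"),
                               amplitude=2.0),
    })
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.signatures) < 2:
            raise ConfigError("need at least 2 classes")
        nyq = self.sampling_rate / 2
        for name, sig in self.signatures.items():
            if sig.band is not None and not (0 < sig.band[0] <= sig.band[1] < nyq):
                raise ConfigError(
                    f"class {name!r} band {sig.band} outside (0, {nyq}) Hz")


def pink_noise(n_samples: int, exponent: float = 1.0,
               seed: int | np.random.Generator = 0) -> np.ndarray:
    """Zero-mean 1/f^exponent noise by spectral synthesis, unit variance.

    Amplitudes scale as f^(-exponent/2) so the power spectral density
    follows 1/f^exponent; phases are uniform.
    """
    if n_samples < 2:
        raise ConfigError("need at least 2 samples")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    freqs = np.fft.rfftfreq(n_samples, d=1.0)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-exponent / 2.0)
    phases = rng.uniform(0, 2 * np.pi, len(freqs))
    spectrum = amp * np.exp(1j * phases)
    spectrum[0] = 0.0  # zero mean
    x = np.fft.irfft(spectrum, n=n_samples)
    sd = x.std()
    return x / sd if sd > 0 else x


def _epoch_noise(n_channels: int, n_samples: int, sr: float,
                 noise: NoiseSpec, rng: np.random.Generator) -> np.ndarray:
    out = np.zeros((n_channels, n_samples))
    t = np.arange(n_samples) / sr
    if noise.pink_amp > 0:
        for c in range(n_channels):
            out[c] = noise.pink_amp * pink_noise(n_samples, noise.pink_exponent, rng)
    if noise.white_sd > 0:
        out += rng.normal(0, noise.white_sd, out.shape)
    if noise.line_50hz_amp > 0:
        phase = rng.uniform(0, 2 * np.pi)
        out += noise.line_50hz_amp * np.sin(2 * np.pi * 50.0 * t + phase)
    if noise.hf_artifact_amp > 0:
        # a short broadband (>45 Hz) burst at a random position
        burst_len = max(4, int(0.1 * sr))
        start = rng.integers(0, max(1, n_samples - burst_len))
        burst = rng.normal(0, noise.hf_artifact_amp, (n_channels, burst_len))
        f0 = min(55.0, 0.45 * sr)
        carrier = np.sin(2 * np.pi * f0 * t[:burst_len])
        out[:, start:start + burst_len] += burst * carrier
    return out


def generate(config: SynthConfig) -> tuple[EpochSet, dict]:
    """Generate the labeled EpochSet plus its ground-truth manifest."""
    mont: Montage = get_montage(config.montage)
    n_samples = int(round(config.epoch_seconds * config.sampling_rate))
    class_names = list(config.signatures)
    rng = np.random.default_rng(config.seed)
    t = np.arange(n_samples) / config.sampling_rate

    epochs, labels, subjects = [], [], []
    for s in range(config.n_subjects):
        sid = f"S{s + 1:02d}"
        for k, name in enumerate(class_names):
            sig = config.signatures[name]
            targets = [mont.index(ch) for ch in sig.target_channels]
            for _ in range(config.epochs_per_subject_per_class):
                x = _epoch_noise(mont.n_channels, n_samples,
                                 config.sampling_rate, config.noise, rng)
                if sig.band is not None and targets:
                    f0 = rng.uniform(*sig.band)
                    phase = rng.uniform(0, 2 * np.pi)
                    for c in targets:
                        ph = phase + (rng.normal(0, sig.phase_jitter)
                                      if sig.phase_jitter > 0 else 0.0)
                        x[c] += sig.amplitude * np.sin(2 * np.pi * f0 * t + ph)
                epochs.append(x)
                labels.append(k)
                subjects.append(sid)

    ep = EpochSet(
        epochs=np.stack(epochs),
        labels=np.array(labels),
        label_names=class_names,
        subject_ids=np.array(subjects),
        sampling_rate=config.sampling_rate,
        epoch_seconds=config.epoch_seconds,
        channel_names=list(mont.channel_names),
    )
    manifest = {
        "montage": mont.name,
        "sampling_rate": config.sampling_rate,
        "epoch_seconds": config.epoch_seconds,
        "n_subjects": config.n_subjects,
        "seed": config.seed,
        "classes": {
            name: {
                "band": list(sig.band) if sig.band else None,
                "target_channels": list(sig.target_channels),
                "amplitude": sig.amplitude,
            } for name, sig in config.signatures.items()
        },
        "noise": {
            "pink_amp": config.noise.pink_amp,
            "pink_exponent": config.noise.pink_exponent,
            "white_sd": config.noise.white_sd,
            "line_50hz_amp": config.noise.line_50hz_amp,
            "hf_artifact_amp": config.noise.hf_artifact_amp,
        },
    }
    return ep, manifest
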