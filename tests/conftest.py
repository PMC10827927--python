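import struct

import numpy as np
import pytest

from ertnet import (EEGRecording, ERTNet, ERTNetConfig, ClassSignature,
                    NoiseSpec, SynthConfig, TrainConfig, fit, generate)

#: compact study geometry used by the unit tests: 8 standard channels at
#: 32 Hz, 2-s epochs, alpha-band signature on the occipital pair.
TINY_CHANNELS = ["F3", "F4", "C3", "C4", "P3", "P4", "O1", "O2"]


def tiny_synth_config(seed=0, **overrides):
    base = dict(
        montage=TINY_CHANNELS,
        sampling_rate=32.0,
        epoch_seconds=2.0,
        n_subjects=4,
        epochs_per_subject_per_class=10,
        signatures={
            "background": ClassSignature(band=None),
            "alpha": ClassSignature(band=(8.0, 12.0),
                                    target_channels=("O1", "O2"),
                                    amplitude=4.0),
        },
        noise=NoiseSpec(white_sd=0.3),
        seed=seed,
    )
    base.update(overrides)
    return SynthConfig(**base)


def tiny_model_config(**overrides):
    base = dict(n_channels=8, n_samples=64, n_classes=2, f1=2,
                kernel_length=8, depth=2, pool1=2, pool2=4, n_heads=2,
                dropout=0.25, sep_kernel_length=4)
    base.update(overrides)
    return ERTNetConfig(**base)


@pytest.fixture(scope="session")
def tiny_epochs():
    ep, manifest = generate(tiny_synth_config(seed=7))
    return ep, manifest


@pytest.fixture(scope="session")
def trained_tiny(tiny_epochs):
    """A small ERTNet trained to convergence on the alpha-band task."""
    ep, _ = tiny_epochs
    model = ERTNet(tiny_model_config(), seed=3, dtype=np.float32)
    fit(model, ep, TrainConfig(epochs=20, batch_size=16, learning_rate=5e-3,
                               seed=3, early_stop_patience=None))
    return model


def write_minimal_edf(path, signal, sampling_rate, channel_names,
                      phys_range=1000.0):
    """Write a minimal single-record-per-second EDF file (16-bit).

    Test-only helper: just enough of the European Data Format for a
    round-trip through a standard EDF reader.  ``signal`` is
    [channels, samples] in microvolts; the sampling rate and record count
    must be integers.
    """
    signal = np.asarray(signal, dtype=float)
    n_ch, n_samp = signal.shape
    fs = int(sampling_rate)
    assert fs == sampling_rate and n_samp % fs == 0
    n_records = n_samp // fs

    def pad(text, width):
        s = str(text)[:width]
        return s.ljust(width).encode("ascii")

    hdr = b"".join([
        pad("0", 8), pad("X", 80), pad("test", 80),
        pad("01.01.20", 8), pad("00.00.00", 8),
        pad(256 * (1 + n_ch), 8), pad("", 44),
        pad(n_records, 8), pad(1, 8), pad(n_ch, 4),
    ])
    fields = [
        [pad(name, 16) for name in channel_names],
        [pad("", 80)] * n_ch,
        [pad("uV", 8)] * n_ch,
        [pad(-phys_range, 8)] * n_ch,
        [pad(phys_range, 8)] * n_ch,
        [pad(-32768, 8)] * n_ch,
        [pad(32767, 8)] * n_ch,
        [pad("", 80)] * n_ch,
        [pad(fs, 8)] * n_ch,
        [pad("", 32)] * n_ch,
    ]
    for group in fields:
        hdr += b"".join(group)

    scale = 32767.0 / phys_range
    with open(path, "wb") as fh:
        fh.write(hdr)
        for rec in range(n_records):
            chunk = signal[:, rec * fs:(rec + 1) * fs]
            digital = np.clip(np.round(chunk * scale), -32768, 32767)
            for ch in range(n_ch):
                fh.write(struct.pack(f"<{fs}h", *digital[ch].astype(int)))
    return path


def sine_recording(freq, sampling_rate=200.0, seconds=10.0, n_channels=2):
    t = np.arange(int(seconds * sampling_rate)) / sampling_rate
    sig = np.tile(np.sin(2 * np.pi * freq * t), (n_channels, 1))
    return EEGRecording(sig, sampling_rate,
                        [f"C{i}" for i in range(n_channels)])
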