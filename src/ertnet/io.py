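"""Reading, preprocessing, segmenting and labeling multichannel EEG.

The preprocessing operations mirror the two standard recipes for the
emotion datasets this package targets:

* 128 Hz dimensional-label recordings: band-pass 4-45 Hz, resample to
  128 Hz, cut into non-overlapping 4-s epochs.
* 200 Hz discrete-label recordings: 50 Hz notch, band-pass 1-50 Hz, cut
  into 4-s epochs, resample to 200 Hz, per-channel per-epoch z-score.

All filters are zero-phase windowed-sinc (Hamming) FIR designs, so the
operations are linear and introduce no phase distortion.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps


class MetadataError(ValueError):
    """Required metadata missing or inconsistent."""


class FormatError(ValueError):
    """File contents inconsistent with the declared format."""


class ParameterError(ValueError):
    """Preprocessing parameter outside its valid range."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class EEGRecording:
    """A continuous multichannel EEG signal in microvolts.

    signal is ``[n_channels, n_samples]``; channel order is meaningful and
    must match ``channel_names``.
    """

    signal: np.ndarray
    sampling_rate: float
    channel_names: list[str]
    subject_id: str = "S00"
    trial_id: str = "T00"

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise FormatError("signal must be 2-D [channels, samples]")
        if self.signal.shape[0] != len(self.channel_names):
            raise FormatError(
                f"{self.signal.shape[0]} signal rows but "
                f"{len(self.channel_names)} channel names"
            )
        if not self.sampling_rate > 0:
            raise MetadataError("sampling_rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate


@dataclass
class EpochSet:
    """Fixed-length labeled EEG segments, the training/evaluation currency.

    epochs is ``[n_epochs, n_channels, n_samples]``.  Every epoch carries
    its subject so subject-wise protocols (leave-one-subject-out) can group
    without ambiguity.
    """

    epochs: np.ndarray
    labels: np.ndarray
    label_names: list[str]
    subject_ids: np.ndarray
    sampling_rate: float
    epoch_seconds: float
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.subject_ids = np.asarray(self.subject_ids)
        if self.epochs.ndim != 3:
            raise FormatError("epochs must be 3-D [n, channels, samples]")
        n = self.epochs.shape[0]
        if len(self.labels) != n or len(self.subject_ids) != n:
            raise FormatError("labels/subject_ids length mismatch")
        expected = int(round(self.epoch_seconds * self.sampling_rate))
        if n and self.epochs.shape[2] != expected:
            raise FormatError(
                f"epoch length {self.epochs.shape[2]} != "
                f"round({self.epoch_seconds} s x {self.sampling_rate} Hz)"
            )

    def __len__(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_classes(self) -> int:
        return len(self.label_names)

    def subset(self, idx) -> "EpochSet":
        idx = np.asarray(idx)
        return EpochSet(
            self.epochs[idx], self.labels[idx], list(self.label_names),
            self.subject_ids[idx], self.sampling_rate, self.epoch_seconds,
            list(self.channel_names),
        )


QUADRANT_NAMES = ["HAHV", "LAHV", "HALV", "LALV"]


@dataclass(frozen=True)
class LabelScheme:
    """How per-trial ratings become integer classes.

    ``quadrant4`` splits the valence/arousal plane at ``threshold`` into
    HAHV/LAHV/HALV/LALV; a rating equal to the threshold counts as "high".
    ``binary_valence``/``binary_arousal`` threshold one dimension.
    ``discrete`` passes integer labels through unchanged.
    """

    mode: str = "quadrant4"
    threshold: float = 5.0

    _MODES = ("quadrant4", "binary_valence", "binary_arousal", "discrete")

    def __post_init__(self) -> None:
        if self.mode not in self._MODES:
            raise ParameterError(f"mode must be one of {self._MODES}")


def assign_labels(ratings_or_labels, scheme: LabelScheme):
    """Map ratings (or pass through discrete labels) to (labels, names).

    For dimensional modes the input is a DataFrame (or mapping of arrays)
    with ``valence`` and ``arousal`` columns on the 1-9 rating scale.
    """
    if scheme.mode == "discrete":
        labels = np.asarray(ratings_or_labels, dtype=int)
        names = [str(c) for c in np.unique(labels)]
        remap = {int(c): i for i, c in enumerate(np.unique(labels))}
        return np.array([remap[int(v)] for v in labels]), names

    df = pd.DataFrame(ratings_or_labels)
    for col in ("valence", "arousal"):
        if col not in df:
            raise MetadataError(f"dimensional labels need a {col!r} column")
        vals = df[col].to_numpy(float)
        if np.any((vals < 1) | (vals > 9)):
            raise ParameterError(f"{col} ratings must lie in [1, 9]")
    hi_v = df["valence"].to_numpy(float) >= scheme.threshold
    hi_a = df["arousal"].to_numpy(float) >= scheme.threshold

    if scheme.mode == "binary_valence":
        return hi_v.astype(int), ["LV", "HV"]
    if scheme.mode == "binary_arousal":
        return hi_a.astype(int), ["LA", "HA"]

    labels = np.select(
        [hi_a & hi_v, ~hi_a & hi_v, hi_a & ~hi_v], [0, 1, 2], default=3
    )
    return labels.astype(int), list(QUADRANT_NAMES)


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def load_recording(path, format: str | None = None) -> EEGRecording:
    """Load an EDF file or an array container (.npy + JSON sidecar).

    The sidecar of an array container must provide ``sampling_rate`` and
    ``channel_names``; ``subject_id``/``trial_id`` are optional.
    """
    path = Path(path)
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "array"
    if format == "edf":
        return _load_edf(path)
    if format == "array":
        return _load_array(path)
    raise FormatError(f"unknown format {format!r}")


def _load_edf(path: Path) -> EEGRecording:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    signal = raw.get_data() * 1e6  # volts -> microvolts
    return EEGRecording(
        signal=signal,
        sampling_rate=float(raw.info["sfreq"]),
        channel_names=list(raw.ch_names),
        subject_id=str(raw.info.get("subject_info") or {}).strip() or "S00",
    )


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def _load_array(path: Path) -> EEGRecording:
    if not path.exists():
        raise FileNotFoundError(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise MetadataError(f"missing JSON sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    for key in ("sampling_rate", "channel_names"):
        if key not in meta:
            raise MetadataError(f"sidecar lacks required field {key!r}")
    signal = np.load(path)
    if signal.ndim != 2 or signal.shape[0] != len(meta["channel_names"]):
        raise FormatError(
            f"array shape {signal.shape} inconsistent with "
            f"{len(meta['channel_names'])} channels"
        )
    return EEGRecording(
        signal=signal,
        sampling_rate=float(meta["sampling_rate"]),
        channel_names=list(meta["channel_names"]),
        subject_id=str(meta.get("subject_id", "S00")),
        trial_id=str(meta.get("trial_id", "T00")),
    )


def save_recording(rec: EEGRecording, path) -> Path:
    """Write the array container + sidecar read back by load_recording."""
    path = Path(path)
    np.save(path.with_suffix(".npy"), rec.signal)
    _sidecar_path(path).write_text(json.dumps({
        "sampling_rate": rec.sampling_rate,
        "channel_names": list(rec.channel_names),
        "subject_id": rec.subject_id,
        "trial_id": rec.trial_id,
    }, indent=1))
    return path.with_suffix(".npy")


def save_epochs(ep: EpochSet, directory) -> Path:
    """Persist an EpochSet as epochs.npy + sidecar + labels.csv."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.save(directory / "epochs.npy", ep.epochs)
    (directory / "epochs.json").write_text(json.dumps({
        "sampling_rate": ep.sampling_rate,
        "epoch_seconds": ep.epoch_seconds,
        "channel_names": list(ep.channel_names),
        "label_names": list(ep.label_names),
    }, indent=1))
    pd.DataFrame({
        "subject": ep.subject_ids,
        "trial": np.arange(len(ep)),
        "label": ep.labels,
    }).to_csv(directory / "labels.csv", index=False)
    return directory


def load_epochs(directory) -> EpochSet:
    directory = Path(directory)
    meta = json.loads((directory / "epochs.json").read_text())
    table = pd.read_csv(directory / "labels.csv")
    return EpochSet(
        epochs=np.load(directory / "epochs.npy"),
        labels=table["label"].to_numpy(int),
        label_names=list(meta["label_names"]),
        subject_ids=table["subject"].to_numpy(str),
        sampling_rate=float(meta["sampling_rate"]),
        epoch_seconds=float(meta["epoch_seconds"]),
        channel_names=list(meta["channel_names"]),
    )


def read_labels_csv(path) -> pd.DataFrame:
    """Labels table: subject, trial plus valence/arousal or label columns."""
    df = pd.read_csv(path)
    need = {"subject", "trial"}
    if not need <= set(df.columns):
        raise MetadataError("labels CSV needs subject and trial columns")
    if not ({"valence", "arousal"} <= set(df.columns) or "label" in df.columns):
        raise MetadataError("labels CSV needs valence+arousal or label")
    return df


# ---------------------------------------------------------------------------
# filtering / resampling / segmentation
# ---------------------------------------------------------------------------

def _fir_taps(fs: float, n_samples: int, transition_hz: float = 0.5) -> tuple[int, float]:
    """Hamming-window FIR length for the requested transition width.

    Hamming windows need about 3.3/N cycles of transition, i.e.
    N = 3.3 * fs / transition.  The length is capped at a third of the
    signal so zero-phase (forward-backward) application stays well posed on
    short recordings; the transition widens accordingly.
    """
    taps = int(np.ceil(3.3 * fs / transition_hz))
    cap = max(15, n_samples // 3)
    if taps > cap:
        taps = cap
        transition_hz = 3.3 * fs / taps
    if taps % 2 == 0:
        taps += 1
    return taps, transition_hz


def _zero_phase(signal_2d: np.ndarray, taps: np.ndarray) -> np.ndarray:
    # symmetric (linear-phase) FIR applied once, centred: zero net phase;
    # reflect padding keeps edge transients small on short recordings
    npad = min(len(taps), signal_2d.shape[1] - 1)
    padded = np.pad(signal_2d, ((0, 0), (npad, npad)), mode="reflect")
    out = sps.fftconvolve(padded, taps[None, :], mode="same")
    return out[:, npad:-npad]


def bandpass_filter(rec: EEGRecording, low: float, high: float,
                    kind: str = "fir") -> EEGRecording:
    """Zero-phase FIR band-pass; output length equals input length."""
    if kind != "fir":
        raise ParameterError("only FIR band-pass is supported")
    nyq = rec.sampling_rate / 2
    if not 0 < low < high:
        raise ParameterError("need 0 < low < high")
    if high >= nyq:
        raise ParameterError(f"high cutoff {high} Hz >= Nyquist {nyq} Hz")
    n_taps, _ = _fir_taps(rec.sampling_rate, rec.n_samples)
    taps = sps.firwin(n_taps, [low, high], pass_zero=False,
                      window="hamming", fs=rec.sampling_rate)
    return replace(rec, signal=_zero_phase(rec.signal, taps))


def notch_filter(rec: EEGRecording, freq: float = 50.0,
                 width: float = 4.0) -> EEGRecording:
    """Zero-phase FIR band-stop centred on ``freq`` (line interference)."""
    nyq = rec.sampling_rate / 2
    if freq >= nyq:
        raise ParameterError(f"notch frequency {freq} Hz >= Nyquist {nyq} Hz")
    lo = max(0.5, freq - width)
    hi = min(nyq - 0.5, freq + width)
    n_taps, _ = _fir_taps(rec.sampling_rate, rec.n_samples, transition_hz=1.0)
    taps = sps.firwin(n_taps, [lo, hi], pass_zero=True,
                      window="hamming", fs=rec.sampling_rate)
    return replace(rec, signal=_zero_phase(rec.signal, taps))


def resample(rec: EEGRecording, target_rate: float) -> EEGRecording:
    """Fourier-domain resampling to round(n * target / source) samples."""
    if not target_rate > 0:
        raise ParameterError("target_rate must be positive")
    if target_rate == rec.sampling_rate:
        return replace(rec, signal=rec.signal.copy())
    n_new = int(round(rec.n_samples * target_rate / rec.sampling_rate))
    out = sps.resample(rec.signal, n_new, axis=1)
    return replace(rec, signal=out, sampling_rate=float(target_rate))


def segment_epochs(rec: EEGRecording, epoch_seconds: float = 4.0,
                   overlap: float = 0.0, label: int = 0,
                   label_names: list[str] | None = None) -> EpochSet:
    """Cut non-overlapping (or overlapping) fixed windows; remainder dropped.

    Windows are half-open ``[t, t + epoch_seconds)`` starting at 0.  All
    epochs inherit the recording's subject and the given class label.
    """
    win = int(round(epoch_seconds * rec.sampling_rate))
    if win < 1:
        raise ParameterError("epoch shorter than one sample")
    step = win - int(round(overlap * rec.sampling_rate))
    if step < 1:
        raise ParameterError("overlap leaves a non-positive step")
    n = 0 if rec.n_samples < win else (rec.n_samples - win) // step + 1
    if n == 0:
        warnings.warn("recording shorter than one epoch; empty EpochSet")
        epochs = np.empty((0, rec.n_channels, win))
    else:
        starts = np.arange(n) * step
        epochs = np.stack([rec.signal[:, s:s + win] for s in starts])
    return EpochSet(
        epochs=epochs,
        labels=np.full(n, label, dtype=int),
        label_names=label_names or [str(label)],
        subject_ids=np.full(n, rec.subject_id),
        sampling_rate=rec.sampling_rate,
        epoch_seconds=epoch_seconds,
        channel_names=list(rec.channel_names),
    )


def concatenate_epochs(parts: list[EpochSet]) -> EpochSet:
    if not parts:
        raise ValueError("nothing to concatenate")
    first = parts[0]
    names = first.label_names
    for p in parts[1:]:
        if p.label_names != names and p.n_classes == first.n_classes:
            raise FormatError("inconsistent label names")
    return EpochSet(
        np.concatenate([p.epochs for p in parts]),
        np.concatenate([p.labels for p in parts]),
        list(names),
        np.concatenate([p.subject_ids for p in parts]),
        first.sampling_rate, first.epoch_seconds, list(first.channel_names),
    )


def normalize(ep: EpochSet, mode: str = "zscore_per_channel_per_epoch") -> EpochSet:
    """Per-(epoch, channel) z-score; constant traces map to zeros."""
    if mode != "zscore_per_channel_per_epoch":
        raise ParameterError(f"unknown normalization mode {mode!r}")
    if ep.epochs.shape[-1] < 2:
        raise ParameterError("need at least 2 samples per epoch")
    mean = ep.epochs.mean(axis=2, keepdims=True)
    sd = ep.epochs.std(axis=2, keepdims=True)
    # a trace is constant when its sd vanishes relative to its magnitude
    floor = 1e-12 * (np.abs(ep.epochs).max(axis=2, keepdims=True) + 1.0)
    ok = sd > floor
    out = np.where(ok, (ep.epochs - mean) / np.where(ok, sd, 1.0), 0.0)
    return replace(ep, epochs=out)


def resample_epochs(ep: EpochSet, target_rate: float) -> EpochSet:
    """Fourier resampling applied epoch-wise (post-segmentation recipes)."""
    if not target_rate > 0:
        raise ParameterError("target_rate must be positive")
    if target_rate == ep.sampling_rate or len(ep) == 0:
        return replace(ep, sampling_rate=float(target_rate)) \
            if target_rate != ep.sampling_rate else replace(ep)
    n_new = int(round(ep.epochs.shape[2] * target_rate / ep.sampling_rate))
    out = sps.resample(ep.epochs, n_new, axis=2)
    return replace(ep, epochs=out, sampling_rate=float(target_rate))


# ---------------------------------------------------------------------------
# declarative pipelines
# ---------------------------------------------------------------------------

#: 128 Hz dimensional-label recipe.
DEAP_PIPELINE: list[tuple[str, dict]] = [
    ("bandpass", {"low": 4.0, "high": 45.0}),
    ("resample", {"target_rate": 128.0}),
    ("segment", {"epoch_seconds": 4.0}),
]

#: 200 Hz discrete-label recipe (notch, wide band-pass, segment, resample,
#: per-epoch z-score).
SEEDV_PIPELINE: list[tuple[str, dict]] = [
    ("notch", {"freq": 50.0}),
    ("bandpass", {"low": 1.0, "high": 50.0}),
    ("segment", {"epoch_seconds": 4.0}),
    ("resample", {"target_rate": 200.0}),
    ("normalize", {}),
]

PRESET_PIPELINES = {"deap": DEAP_PIPELINE, "seedv": SEEDV_PIPELINE}

_REC_STEPS = {
    "bandpass": bandpass_filter,
    "notch": notch_filter,
    "resample": resample,
}


def apply_pipeline(rec: EEGRecording, steps, **segment_kwargs):
    """Run an ordered (step_name, kwargs) list on a recording.

    Steps before "segment" operate on the continuous recording; steps after
    operate on the EpochSet.  Returns whatever the last step produces.
    """
    state = rec
    for name, kwargs in steps:
        if isinstance(state, EEGRecording):
            if name == "segment":
                state = segment_epochs(state, **{**kwargs, **segment_kwargs})
            elif name in _REC_STEPS:
                state = _REC_STEPS[name](state, **kwargs)
            else:
                raise ParameterError(f"unknown pipeline step {name!r}")
        else:
            if name == "normalize":
                state = normalize(state, **kwargs)
            elif name == "resample":
                state = resample_epochs(state, **kwargs)
            else:
                raise ParameterError(
                    f"step {name!r} not valid after segmentation")
    return state
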