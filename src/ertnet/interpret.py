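"""Interpretability of a trained model: what each temporal kernel passes
(frequency response and band label), where its spatial kernels look
(topographies), how much each kernel matters (ablation), and whether a
kernel has converged to a Gaussian-like low-pass smoother.

The temporal kernels of the first layer are linear FIR filters (no
activation precedes them), so their discrete-time Fourier transform is an
exact description of what the model extracts from the raw signal.
"""

from __future__ import annotations

import json
import warnings
from contextlib import contextmanager
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize as sopt
from scipy import stats as sstats

from .io import EpochSet
from .model import _SoftmaxClassifier
from .montage import Montage
from .training import FoldResult, evaluate

__all__ = [
    "BAND_EDGES", "KernelSpectrum", "TopoMap", "GaussianFit",
    "kernel_frequency_response", "spatial_topomap", "ablate",
    "ablation_study", "gaussian_fit", "kernel_report",
]

#: canonical EEG rhythm bands (Hz); delta is taken as everything below 4 Hz
#: so near-DC low-pass kernels still receive a label
BAND_EDGES: dict[str, tuple[float, float]] = {
    "delta": (0.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 50.0),
}


@dataclass
class KernelSpectrum:
    kernel_index: int
    frequencies: np.ndarray          # Hz, (0, Nyquist]
    magnitude: np.ndarray
    dominant_frequency: float
    band_label: str
    spectral_flatness: float

    def as_dict(self) -> dict:
        return {
            "kernel_index": self.kernel_index,
            "dominant_frequency": self.dominant_frequency,
            "band_label": self.band_label,
            "spectral_flatness": self.spectral_flatness,
        }


@dataclass
class TopoMap:
    kernel_index: int
    depth_index: int
    weights: np.ndarray              # one weight per channel
    channel_names: list[str]
    coords: np.ndarray               # [C, 2]

    def top_channels(self, n: int = 2) -> list[str]:
        order = np.argsort(-np.abs(self.weights))
        return [self.channel_names[i] for i in order[:n]]


@dataclass
class GaussianFit:
    std: float                       # sigma, in samples
    amplitude: float                 # fitted peak relative to a unit Gaussian
    center: float
    r: float                         # Pearson r kernel vs fitted curve

    @property
    def converged(self) -> bool:
        return np.isfinite(self.r)


def _band_label(dominant: float, flatness: float,
                flatness_threshold: float = 0.5) -> str:
    if flatness > flatness_threshold:
        return "broadband"
    for name, (lo, hi) in BAND_EDGES.items():
        if lo <= dominant < hi:
            return name
    return "broadband"


def kernel_frequency_response(kernel: np.ndarray, sampling_rate: float,
                              n_grid: int = 512) -> KernelSpectrum:
    """Magnitude of the kernel's DTFT on a dense grid up to Nyquist.

    The dominant frequency is the argmax above 0.5 Hz; the band label comes
    from the canonical band edges unless the spectral flatness (geometric /
    arithmetic mean of power) exceeds 0.5, in which case the kernel is
    broadband.
    """
    kernel = np.asarray(kernel, dtype=float).ravel()
    if kernel.size < 2:
        raise ValueError("kernel must have length >= 2")
    n_fft = max(2 * n_grid, 1 << int(np.ceil(np.log2(4 * kernel.size))))
    mag = np.abs(np.fft.rfft(kernel, n_fft))
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / sampling_rate)
    keep = freqs > 0
    freqs, mag = freqs[keep], mag[keep]
    if not np.any(mag > 0):
        warnings.warn("zero kernel: dominant frequency undefined")
        return KernelSpectrum(-1, freqs, mag, float("nan"), "broadband", 1.0)
    power = mag ** 2
    flatness = float(np.exp(np.mean(np.log(power + 1e-300))) /
                     (power.mean() + 1e-300))
    searchable = freqs > 0.5
    dom = float(freqs[searchable][np.argmax(mag[searchable])]) \
        if searchable.any() else float(freqs[np.argmax(mag)])
    # a low-pass kernel whose response only decays from DC "dominates" near 0
    if mag[0] >= mag.max() * 0.999:
        dom = float(freqs[0])
    return KernelSpectrum(-1, freqs, mag, dom,
                          _band_label(dom, flatness), flatness)


def spatial_topomap(model: _SoftmaxClassifier, kernel_index: int,
                    montage: Montage) -> list[TopoMap]:
    """The D depthwise spatial weight vectors attached to one temporal
    kernel, with 2-D electrode coordinates for rendering."""
    w = model.param_dict["spatial.W"].value  # [F1, D, C]
    f1, d, c = w.shape
    if not 0 <= kernel_index < f1:
        raise IndexError(f"kernel index {kernel_index} out of range [0, {f1})")
    if montage.n_channels != c:
        raise ValueError("montage does not match the model's channel count")
    return [
        TopoMap(kernel_index, j, w[kernel_index, j].copy(),
                list(montage.channel_names), montage.coords.copy())
        for j in range(d)
    ]


@contextmanager
def _kernels_silenced(model: _SoftmaxClassifier, indices):
    """Temporarily zero temporal kernels and their first-stage batch-norm
    affine so the ablated branches contribute exactly zero downstream;
    original weights restored on exit."""
    temporal = model.param_dict["temporal.W"]
    bn = model.param_dict
    saved = {
        "temporal.W": temporal.value.copy(),
        "bn1.gamma": bn["bn1.gamma"].value.copy(),
        "bn1.beta": bn["bn1.beta"].value.copy(),
    }
    try:
        for i in indices:
            temporal.value[i, :] = 0.0
            bn["bn1.gamma"].value[i] = 0.0
            bn["bn1.beta"].value[i] = 0.0
        yield model
    finally:
        for name, value in saved.items():
            bn[name].value[...] = value


def ablate(model: _SoftmaxClassifier, kernel_indices, test: EpochSet,
           row_name: str | None = None) -> dict:
    """Evaluate with the given temporal kernels removed (no retraining).

    Removal = zeroing the kernel weights and neutralizing the first batch
    norm's scale/shift for those maps.  The model is restored afterwards.
    An empty index set is the unablated reference row ("None").
    """
    indices = sorted(set(int(i) for i in kernel_indices))
    f1 = model.param_dict["temporal.W"].value.shape[0]
    for i in indices:
        if not 0 <= i < f1:
            raise IndexError(f"kernel index {i} out of range [0, {f1})")
    name = row_name or (", ".join(str(i + 1) for i in indices) or "None")
    with _kernels_silenced(model, indices):
        result: FoldResult = evaluate(model, test)
    row = {"kernels_removed": name, "average_auc": result.auc_macro}
    row.update({f"auc_{k}": v for k, v in result.per_class_auc.items()})
    row["accuracy"] = result.accuracy
    return row


def ablation_study(model: _SoftmaxClassifier, test: EpochSet,
                   groups: list[list[int]] | None = None) -> pd.DataFrame:
    """Singleton ablations for every temporal kernel, optional named
    groups, and the unablated "None" reference row, as one table of
    average and per-class AUC."""
    f1 = model.param_dict["temporal.W"].value.shape[0]
    rows = [ablate(model, [i], test) for i in range(f1)]
    for grp in groups or []:
        rows.append(ablate(model, grp, test))
    rows.append(ablate(model, [], test))
    return pd.DataFrame(rows)


def prune_redundant_kernels(model: _SoftmaxClassifier, data: EpochSet,
                            auc_tolerance: float = 0.01) -> list[int]:
    """Greedily silence temporal kernels the model does not need.

    Trained filter banks are typically redundant: several kernels learn the
    same discriminative band, so removing any single one changes nothing
    and single-kernel ablation understates every kernel's importance.
    This reduces the model to a minimal sufficient filter bank: repeatedly
    remove (permanently, via the ablation mechanism) the kernel whose
    removal costs the least macro AUC on ``data``, as long as AUC stays
    within ``auc_tolerance`` of the unpruned model.  On the reduced model,
    ablation attributes information to the kernels that actually carry it.

    Returns the list of silenced kernel indices (model modified in place).
    """
    f1 = model.param_dict["temporal.W"].value.shape[0]

    def score() -> float:
        r = evaluate(model, data)
        return r.auc_macro if r.auc_macro is not None else r.accuracy / 100.0

    base = score()
    pruned: list[int] = []
    while len(pruned) < f1 - 1:
        candidates = [i for i in range(f1) if i not in pruned]
        scores = {}
        for i in candidates:
            with _kernels_silenced(model, pruned + [i]):
                scores[i] = score()
        best = max(candidates, key=lambda i: scores[i])
        if scores[best] < base - auc_tolerance:
            break
        pruned.append(best)
    # make the pruning permanent
    temporal = model.param_dict["temporal.W"]
    for i in pruned:
        temporal.value[i, :] = 0.0
        model.param_dict["bn1.gamma"].value[i] = 0.0
        model.param_dict["bn1.beta"].value[i] = 0.0
    return pruned


def gaussian_fit(kernel: np.ndarray) -> GaussianFit:
    """Least-squares fit of a * exp(-(t - t0)^2 / (2 sigma^2)).

    sigma is reported in samples; amplitude is the fitted peak a (the scale
    of the matching unit Gaussian); r is the Pearson correlation between
    the kernel and the fitted curve.  Non-convergence yields r = nan.
    """
    kernel = np.asarray(kernel, dtype=float).ravel()
    t = np.arange(kernel.size)
    if kernel.size < 5:
        raise ValueError("kernel must have length >= 5")
    weight = np.abs(kernel)
    t0_init = float((t * weight).sum() / weight.sum()) if weight.sum() > 0 \
        else kernel.size / 2
    a_init = kernel[int(round(t0_init))]
    if a_init == 0:
        a_init = kernel[np.argmax(np.abs(kernel))]
    sigma_init = max(kernel.size / 6.0, 1.0)

    def model_fn(tt, a, t0, sigma):
        return a * np.exp(-((tt - t0) ** 2) / (2 * sigma ** 2))

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = sopt.curve_fit(
                model_fn, t, kernel, p0=[a_init, t0_init, sigma_init],
                bounds=([-np.inf, -kernel.size, 1e-3],
                        [np.inf, 2 * kernel.size, 10 * kernel.size]),
                maxfev=5000)
        fitted = model_fn(t, *popt)
        if np.std(fitted) == 0 or np.std(kernel) == 0:
            r = float("nan")
        else:
            r = float(sstats.pearsonr(kernel, fitted)[0])
        return GaussianFit(std=float(abs(popt[2])), amplitude=float(popt[0]),
                           center=float(popt[1]), r=r)
    except RuntimeError:
        return GaussianFit(std=float("nan"), amplitude=float("nan"),
                           center=float("nan"), r=float("nan"))


def kernel_report(model: _SoftmaxClassifier, sampling_rate: float,
                  montage: Montage, gaussian_r_threshold: float = 0.9
                  ) -> dict:
    """Per temporal kernel: spectrum + band label + Gaussian fit + its D
    spatial topographies, plus a summary separating band-selective kernels
    from Gaussian-like smoothers."""
    temporal = model.param_dict["temporal.W"].value
    f1 = temporal.shape[0]
    kernels = []
    band_selective, gaussian_like = [], []
    for i in range(f1):
        spec = kernel_frequency_response(temporal[i], sampling_rate)
        spec.kernel_index = i
        gfit = gaussian_fit(temporal[i])
        maps = spatial_topomap(model, i, montage)
        if gfit.converged and gfit.r >= gaussian_r_threshold:
            gaussian_like.append(i)
        elif spec.band_label != "broadband":
            band_selective.append(i)
        kernels.append({
            **spec.as_dict(),
            "gaussian_fit": {"std": gfit.std, "amplitude": gfit.amplitude,
                             "center": gfit.center, "r": gfit.r},
            "topomaps": [
                {"depth_index": m.depth_index,
                 "weights": m.weights.tolist(),
                 "top_channels": m.top_channels()} for m in maps],
        })
    return {
        "sampling_rate": sampling_rate,
        "montage": montage.name,
        "n_temporal_kernels": f1,
        "kernels": kernels,
        "summary": {
            "band_selective": band_selective,
            "gaussian_like": gaussian_like,
        },
    }


def save_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=1)
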