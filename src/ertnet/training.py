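"""Training loops, evaluation protocols, statistical comparison and
hyperparameter search.

Protocols follow the common emotion-EEG evaluation designs: segment-level
stratified 10-fold cross-validation and an 8:2 stratified holdout for the
subject-dependent setting, leave-one-subject-out cross-validation (LOSOCV,
dropout 0.25) for the subject-independent setting.  Paired fold accuracies
are compared with the Wilcoxon signed-rank test; paired AUCs on a common
test set with the DeLong test for correlated ROC curves.

Note: segment-level k-fold can place segments of one subject in both train
and test folds.  That mirrors the subject-dependent protocol these datasets
are usually evaluated with; use :func:`losocv` for subject-independent
claims.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats as sstats
from sklearn.metrics import confusion_matrix, roc_auc_score
from sklearn.model_selection import (KFold, LeaveOneGroupOut, StratifiedKFold,
                                     train_test_split)

from .io import EpochSet
from .nn import Adam
from .model import (ERTNet, ERTNetConfig, EXTRACTION_PREFIXES,
                    _SoftmaxClassifier, make_optimizer)

__all__ = [
    "TrainConfig", "FoldResult", "SearchSpace", "fit", "evaluate",
    "kfold_cv", "holdout_split", "losocv", "wilcoxon_signed_rank",
    "delong_auc", "delong_test", "delong_test_multiclass", "transfer_init",
    "hyperparameter_search", "sweep", "DivergenceError", "ProtocolError",
    "TransferError",
]


class DivergenceError(RuntimeError):
    pass


class ProtocolError(ValueError):
    pass


class TransferError(ValueError):
    pass


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings (Adam, categorical cross-entropy)."""

    epochs: int = 100
    batch_size: int = 64
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    weight_decay: float = 0.0
    #: L1 (network-slimming) strength on the first-stage batch-norm scales;
    #: drives redundant temporal-kernel branches to exactly zero so kernel
    #: attribution is sharp.  0 disables.
    kernel_sparsity: float = 0.0
    seed: int = 0
    early_stop_patience: int | None = 10
    validation_fraction: float = 0.1
    #: restrict optimization to parameters whose name starts with one of
    #: these prefixes (e.g. ("head",) to recalibrate only the decision
    #: layer after pruning, or to freeze a transferred extractor).
    trainable_prefixes: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be positive")
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")


@dataclass
class FoldResult:
    """Metrics for one evaluation: accuracy (%), macro one-vs-rest AUC,
    per-class AUC and the K x K confusion matrix (rows = true class)."""

    fold: int
    accuracy: float
    auc_macro: float | None
    per_class_auc: dict[str, float | None]
    confusion: np.ndarray

    def as_dict(self) -> dict:
        return {
            "fold": self.fold,
            "accuracy": self.accuracy,
            "auc_macro": self.auc_macro,
            "per_class_auc": self.per_class_auc,
            "confusion": self.confusion.tolist(),
        }


@dataclass(frozen=True)
class SearchSpace:
    """Inclusive integer ranges for the architecture search."""

    f1: tuple[int, int] = (4, 20)
    kernel_length: tuple[int, int] = (5, 100)
    depth: tuple[int, int] = (1, 5)
    n_heads: tuple[int, int] = (4, 20)


# ---------------------------------------------------------------------------
# fitting and evaluation
# ---------------------------------------------------------------------------

def fit(model: _SoftmaxClassifier, train: EpochSet,
        config: TrainConfig = TrainConfig()) -> dict:
    """Mini-batch Adam on categorical cross-entropy.

    An optional stratified validation slice of the training data drives
    early stopping (patience on validation loss); the best-validation
    weights are restored.  Returns a history dict with per-epoch loss and
    accuracy.
    """
    rng = np.random.default_rng(config.seed)
    x, y = train.epochs, train.labels
    val_x = val_y = None
    if config.early_stop_patience is not None and config.validation_fraction > 0:
        counts = np.bincount(y)
        can_stratify = counts.min() >= 2 and \
            config.validation_fraction * len(y) >= len(counts)
        try:
            tr_idx, va_idx = train_test_split(
                np.arange(len(y)), test_size=config.validation_fraction,
                random_state=config.seed,
                stratify=y if can_stratify else None)
            x, y = train.epochs[tr_idx], train.labels[tr_idx]
            val_x, val_y = train.epochs[va_idx], train.labels[va_idx]
        except ValueError:
            pass

    opt = make_optimizer(model, lr=config.learning_rate)
    if config.trainable_prefixes is not None:
        trainable = [p for p in model.params
                     if p.name.startswith(tuple(config.trainable_prefixes))]
        opt = Adam(trainable, lr=config.learning_rate)
    opt.weight_decay = config.weight_decay
    if config.kernel_sparsity > 0:
        opt.l1_params = [p for p in model.params if p.name == "bn1.gamma"]
        opt.l1_strength = config.kernel_sparsity
    history = {"loss": [], "accuracy": [], "val_loss": []}
    best_val, best_state, patience_left = np.inf, None, config.early_stop_patience
    n = len(y)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses, correct = [], 0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            opt.zero_grad()
            loss, probs = model.loss_and_grad(x[idx], y[idx])
            if not math.isfinite(loss):
                raise DivergenceError(
                    f"non-finite loss at epoch {epoch}, batch {start // config.batch_size}")
            if config.learning_rate > 0:
                opt.step()
            losses.append(loss * len(idx))
            correct += int((probs.argmax(axis=1) == y[idx]).sum())
        history["loss"].append(float(np.sum(losses) / n))
        history["accuracy"].append(correct / n)

        if val_x is not None:
            probs = model.predict_proba(val_x)
            eps = 1e-12
            vloss = float(-np.log(
                probs[np.arange(len(val_y)), val_y] + eps).mean())
            history["val_loss"].append(vloss)
            if vloss < best_val - 1e-6:
                best_val, best_state = vloss, model.state_dict()
                patience_left = config.early_stop_patience
            else:
                patience_left -= 1
                if patience_left <= 0:
                    break
    if best_state is not None:
        model.load_state_dict(best_state)
    return history


def evaluate(model: _SoftmaxClassifier, test: EpochSet,
             fold: int = 0) -> FoldResult:
    """Accuracy from the confusion matrix plus macro one-vs-rest ROC AUC.

    A test set containing a single class has no defined AUC; it is
    reported as None.
    """
    probs = model.predict_proba(test.epochs)
    pred = probs.argmax(axis=1)
    k = test.n_classes
    cm = confusion_matrix(test.labels, pred, labels=np.arange(k))
    acc = 100.0 * np.trace(cm) / len(test)
    per_class: dict[str, float | None] = {}
    present = np.unique(test.labels)
    for j, name in enumerate(test.label_names):
        if j in present and len(present) > 1:
            per_class[name] = float(
                roc_auc_score((test.labels == j).astype(int), probs[:, j]))
        else:
            per_class[name] = None
    defined = [v for v in per_class.values() if v is not None]
    auc_macro = float(np.mean(defined)) if defined else None
    return FoldResult(fold, float(acc), auc_macro, per_class, cm)


def summarize(results: list[FoldResult]) -> dict:
    accs = np.array([r.accuracy for r in results])
    aucs = np.array([r.auc_macro for r in results if r.auc_macro is not None])
    return {
        "accuracy_mean": float(accs.mean()),
        "accuracy_sd": float(accs.std(ddof=1)) if len(accs) > 1 else 0.0,
        "auc_mean": float(aucs.mean()) if len(aucs) else None,
        "auc_sd": float(aucs.std(ddof=1)) if len(aucs) > 1 else None,
        "n_folds": len(results),
    }


def _fresh_model(model_config: ERTNetConfig, seed: int,
                 model_class=ERTNet) -> _SoftmaxClassifier:
    return model_class(model_config, seed=seed)


def kfold_cv(ep: EpochSet, model_config: ERTNetConfig,
             train_config: TrainConfig = TrainConfig(), k: int = 10,
             model_class=ERTNet) -> tuple[list[FoldResult], dict]:
    """Stratified k-fold cross-validation at segment level."""
    if k < 2:
        raise ProtocolError("k-fold needs k >= 2")
    if len(ep) < k:
        raise ProtocolError("fewer epochs than folds")
    counts = np.bincount(ep.labels)
    if counts[counts > 0].min() < k:
        warnings.warn("a class has fewer members than folds; "
                      "falling back to unstratified folds")
        splitter = KFold(n_splits=k, shuffle=True,
                         random_state=train_config.seed)
        splits = splitter.split(ep.epochs)
    else:
        splitter = StratifiedKFold(n_splits=k, shuffle=True,
                                   random_state=train_config.seed)
        splits = splitter.split(ep.epochs, ep.labels)
    results = []
    for i, (tr, te) in enumerate(splits):
        model = _fresh_model(model_config, train_config.seed + i, model_class)
        fit(model, ep.subset(tr), replace(train_config,
                                          seed=train_config.seed + i))
        results.append(evaluate(model, ep.subset(te), fold=i))
    return results, summarize(results)


def holdout_split(ep: EpochSet, ratio: float = 0.8, stratify: bool = True,
                  seed: int = 0) -> tuple[EpochSet, EpochSet]:
    """Seeded stratified train/test split (default 8:2)."""
    if not 0 < ratio < 1:
        raise ProtocolError("ratio must be in (0, 1)")
    tr, te = train_test_split(
        np.arange(len(ep)), train_size=ratio, random_state=seed,
        stratify=ep.labels if stratify else None)
    return ep.subset(np.sort(tr)), ep.subset(np.sort(te))


def losocv(ep: EpochSet, model_config: ERTNetConfig,
           train_config: TrainConfig = TrainConfig(),
           dropout: float = 0.25, model_class=ERTNet
           ) -> tuple[dict[str, FoldResult], dict]:
    """Leave-one-subject-out cross-validation (subject-independent).

    Dropout defaults to the subject-independent setting 0.25.
    """
    subjects = np.unique(ep.subject_ids)
    if len(subjects) < 2:
        raise ProtocolError("LOSOCV needs at least 2 subjects")
    cfg = replace(model_config, dropout=dropout)
    logo = LeaveOneGroupOut()
    per_subject: dict[str, FoldResult] = {}
    for i, (tr, te) in enumerate(
            logo.split(ep.epochs, ep.labels, groups=ep.subject_ids)):
        held_out = str(ep.subject_ids[te][0])
        assert not set(tr) & set(te)
        model = _fresh_model(cfg, train_config.seed + i, model_class)
        fit(model, ep.subset(tr), replace(train_config,
                                          seed=train_config.seed + i))
        per_subject[held_out] = evaluate(model, ep.subset(te), fold=i)
    return per_subject, summarize(list(per_subject.values()))


# ---------------------------------------------------------------------------
# statistics: Wilcoxon signed-rank and DeLong
# ---------------------------------------------------------------------------

def wilcoxon_signed_rank(a, b) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired scores.

    Zero differences are dropped.  For n <= 25 the p-value is exact,
    computed from the full sign-assignment distribution of the rank sum
    (midranks are used for tied magnitudes, so the exact path remains
    valid with ties); beyond that a normal approximation with continuity
    and tie correction is used.  Returns (W, p) with W = min(W+, W-).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = a - b
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return 0.0, 1.0
    ranks = sstats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    w = min(w_plus, w_minus)
    if n <= 25:
        # distribution of W+ over all 2^n sign assignments, via convolution
        # on doubled ranks (midranks may be half-integral)
        doubled = np.round(2 * ranks).astype(int)
        total = doubled.sum()
        dist = np.zeros(total + 1)
        dist[0] = 1.0
        for r in doubled:
            shifted = np.zeros_like(dist)
            shifted[r:] = dist[: len(dist) - r]
            dist = dist + shifted
        dist /= 2.0 ** n
        lo = int(round(2 * w))
        hi = int(round(2 * max(w_plus, w_minus)))
        p = dist[: lo + 1].sum() + dist[hi:].sum()
        return w, float(min(1.0, p))
    mean = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = (tie_counts ** 3 - tie_counts).sum() / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    z = (w - mean + 0.5) / math.sqrt(var)  # continuity correction
    p = 2.0 * sstats.norm.cdf(z)
    return w, float(min(1.0, p))


def _midrank(x: np.ndarray) -> np.ndarray:
    return sstats.rankdata(x, method="average")


def delong_auc(scores: np.ndarray, labels: np.ndarray
               ) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC as the Mann-Whitney statistic plus DeLong structural components.

    Returns (auc, v10, v01): v10 has one entry per positive item, v01 one
    per negative; their empirical variances give the AUC variance.
    """
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ProtocolError("both classes must be present")
    all_ranks = _midrank(np.concatenate([pos, neg]))
    pos_ranks = _midrank(pos)
    neg_ranks = _midrank(neg)
    auc = (all_ranks[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    return float(auc), v10, v01


def delong_test(scores1, scores2, labels) -> tuple[float, float, float, float]:
    """DeLong test for two correlated AUCs on the same binary-labeled items.

    Returns (auc1, auc2, z, p) with a two-sided normal p-value for the
    paired AUC difference.
    """
    labels = np.asarray(labels).astype(int)
    a1, v10_1, v01_1 = delong_auc(np.asarray(scores1, float), labels)
    a2, v10_2, v01_2 = delong_auc(np.asarray(scores2, float), labels)
    m, n = len(v10_1), len(v01_1)
    s10 = np.cov(np.stack([v10_1, v10_2]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.stack([v01_1, v01_2]), ddof=1) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    if var_diff <= 0:
        z = 0.0
        p = 1.0
    else:
        z = (a1 - a2) / math.sqrt(var_diff)
        p = 2.0 * sstats.norm.sf(abs(z))
    return a1, a2, float(z), float(min(1.0, p))


def delong_test_multiclass(probs1: np.ndarray, probs2: np.ndarray,
                           labels: np.ndarray) -> pd.DataFrame:
    """One-vs-rest DeLong per class with Bonferroni-adjusted p-values."""
    labels = np.asarray(labels).astype(int)
    k = probs1.shape[1]
    rows = []
    for j in range(k):
        y = (labels == j).astype(int)
        if y.min() == y.max():
            rows.append({"class": j, "auc1": np.nan, "auc2": np.nan,
                         "z": np.nan, "p": np.nan, "p_bonferroni": np.nan})
            continue
        a1, a2, z, p = delong_test(probs1[:, j], probs2[:, j], y)
        rows.append({"class": j, "auc1": a1, "auc2": a2, "z": z, "p": p,
                     "p_bonferroni": min(1.0, p * k)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# transfer learning and hyperparameter search
# ---------------------------------------------------------------------------

def transfer_init(target: _SoftmaxClassifier,
                  source: _SoftmaxClassifier | str) -> _SoftmaxClassifier:
    """Copy the feature-extraction weights of a tuned source model (e.g. an
    EEGNet baseline) into the target; transformer and head stay fresh.

    Temporal, spatial, separable and batch-norm parameters (including
    running statistics) are copied bit-exactly; mismatching shapes raise a
    TransferError naming the offending layers.
    """
    if isinstance(source, (str, bytes)) or hasattr(source, "__fspath__"):
        source = _SoftmaxClassifier.load(source)
    src_state = source.state_dict()
    tgt = target.param_dict
    bad = []
    to_copy = {}
    for name, value in src_state.items():
        if not name.startswith(EXTRACTION_PREFIXES):
            continue
        if name.endswith((".running_mean", ".running_var")):
            to_copy[name] = value
            continue
        if name not in tgt:
            bad.append(name)
        elif tgt[name].value.shape != value.shape:
            bad.append(f"{name} {value.shape} -> {tgt[name].value.shape}")
        else:
            to_copy[name] = value
    if bad:
        raise TransferError("extraction stacks differ at: " + ", ".join(bad))
    target.load_state_dict(to_copy)
    return target


def hyperparameter_search(space: SearchSpace, ep: EpochSet,
                          base_config: ERTNetConfig,
                          train_config: TrainConfig = TrainConfig(),
                          budget: int = 10, k: int = 3, seed: int = 0
                          ) -> tuple[ERTNetConfig, pd.DataFrame]:
    """Seeded random search over (F1, T, D, heads); F2 = F1 x D throughout.

    Objective is mean k-fold CV accuracy.  Returns the best config and the
    full trial log.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    rng = np.random.default_rng(seed)
    rows, best, best_acc = [], None, -np.inf
    for trial in range(budget):
        f1 = int(rng.integers(space.f1[0], space.f1[1] + 1))
        t = int(rng.integers(space.kernel_length[0],
                             min(space.kernel_length[1],
                                 base_config.n_samples) + 1))
        d = int(rng.integers(space.depth[0], space.depth[1] + 1))
        heads = int(rng.integers(space.n_heads[0], space.n_heads[1] + 1))
        cfg = replace(base_config, f1=f1, kernel_length=t, depth=d,
                      n_heads=heads, f2=None, ff_dim=None)
        _, summary = kfold_cv(ep, cfg, train_config, k=k)
        acc = summary["accuracy_mean"]
        rows.append({"trial": trial, "f1": f1, "kernel_length": t,
                     "depth": d, "n_heads": heads, "f2": cfg.f2,
                     "accuracy_mean": acc})
        if acc > best_acc:
            best_acc, best = acc, cfg
    return best, pd.DataFrame(rows)


def sweep(parameter: str, values, ep: EpochSet, base_config: ERTNetConfig,
          train_config: TrainConfig = TrainConfig(), k: int = 3
          ) -> pd.DataFrame:
    """Accuracy curve over one architecture parameter (kernel_length T or
    n_blocks), one k-fold CV summary per value."""
    if parameter not in ("kernel_length", "n_blocks"):
        raise ValueError("sweep supports kernel_length or n_blocks")
    if len(list(values)) == 0:
        raise ValueError("values must be non-empty")
    rows = []
    for v in values:
        cfg = replace(base_config, **{parameter: int(v)})
        _, summary = kfold_cv(ep, cfg, train_config, k=k)
        rows.append({parameter: int(v), **summary})
    return pd.DataFrame(rows)
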