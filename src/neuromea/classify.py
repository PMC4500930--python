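"""Pattern recognition of activity phenotypes.

A single-layer perceptron (no hidden units: input knots map directly onto
one logistic output node per group) is trained with the resilient
propagation (Rprop) rule on standardized 204-feature vectors.  Recognition
is assessed by cross-validation — leave-one-out by default, as is usual for
small-n MEA cohorts — and a χ² test of the accumulated confusion counts
against chance expectation.

Implementation notes:

* Rprop is the iRprop− variant: per-weight step sizes grow by ``eta_plus``
  while the gradient sign is stable and shrink by ``eta_minus`` on a sign
  change, in which case the gradient is zeroed for that step (no weight
  backtracking).
* Targets are one-hot, outputs logistic, loss is summed cross-entropy, and
  prediction is the arg-max output.
* Standardization (centering/scaling, zero-variance drops, NaN imputation
  by the training mean) is re-fit inside every fold so held-out samples
  never leak into the training statistics.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "PerceptronSpec",
    "RpropSpec",
    "ClassificationResult",
    "Standardizer",
    "standardize",
    "train_perceptron",
    "predict",
    "cross_validate",
    "chi_square_recognition",
]


@dataclass(frozen=True)
class RpropSpec:
    eta_plus: float = 1.2
    eta_minus: float = 0.5
    delta0: float = 0.1
    delta_min: float = 1e-6
    delta_max: float = 50.0

    def __post_init__(self) -> None:
        if not (0.0 < self.eta_minus < 1.0 < self.eta_plus):
            raise ValueError("need 0 < eta_minus < 1 < eta_plus")


@dataclass(frozen=True)
class PerceptronSpec:
    n_inputs: int = 204
    n_outputs: int = 2
    rprop: RpropSpec = field(default_factory=RpropSpec)
    max_epochs: int = 1000
    convergence_tol: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_outputs < 2:
            raise ValueError("need at least two output nodes (groups)")


@dataclass(frozen=True)
class ClassificationResult:
    """Confusion counts and recognition percentages from cross-validation."""

    confusion: np.ndarray  # (true group, predicted group) counts
    group_names: tuple[str, ...]
    chi2_stat: float
    chi2_p: float
    folds: str

    @property
    def recognition_pct(self) -> np.ndarray:
        rows = self.confusion.sum(axis=1, keepdims=True).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return 100.0 * self.confusion / rows

    @property
    def diagonal_accuracy(self) -> float:
        return float(np.trace(self.confusion)) / float(self.confusion.sum())

    def to_frame(self) -> pd.DataFrame:
        """Recognition table: one row per data group, predicted % per group."""
        df = pd.DataFrame(
            self.recognition_pct,
            index=pd.Index(self.group_names, name="data_group"),
            columns=[f"pred_{g}_pct" for g in self.group_names],
        )
        df["n"] = self.confusion.sum(axis=1)
        df["chi2_p"] = self.chi2_p
        return df


# --------------------------------------------------------------------------
# standardization

@dataclass(frozen=True)
class Standardizer:
    """Feature scaler fitted on a training subset only."""

    mean: np.ndarray
    sd: np.ndarray
    kept: np.ndarray  # boolean mask of retained (non-degenerate) columns
    n_imputed: int

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        X = np.where(np.isnan(X), self.mean, X)
        Z = (X - self.mean) / np.where(self.sd > 0, self.sd, 1.0)
        return Z[:, self.kept]


def fit_standardizer(X_train: np.ndarray) -> Standardizer:
    X = np.asarray(X_train, dtype=float)
    if X.size == 0:
        raise ValueError("empty training subset")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(X, axis=0)
        sd = np.nanstd(X, axis=0, ddof=1)
    all_nan = np.all(np.isnan(X), axis=0)
    mean = np.where(all_nan, 0.0, mean)
    sd = np.where(np.isnan(sd), 0.0, sd)
    kept = (sd > 0) & ~all_nan
    n_imputed = int(np.isnan(X).sum())
    return Standardizer(mean=mean, sd=sd, kept=kept, n_imputed=n_imputed)


def standardize(
    X: np.ndarray, reference: np.ndarray | None = None
) -> tuple[np.ndarray, Standardizer]:
    """Center/scale ``X`` by the reference subset's statistics.

    ``reference`` defaults to ``X`` itself.  Zero-variance (or all-missing)
    features are dropped identically for every transformed matrix; missing
    values are imputed by the reference mean (count recorded on the
    returned :class:`Standardizer`).
    """
    ref = X if reference is None else reference
    sc = fit_standardizer(ref)
    return sc.transform(X), sc


# --------------------------------------------------------------------------
# perceptron

def _one_hot(y: np.ndarray, n_classes: int) -> np.ndarray:
    T = np.zeros((y.size, n_classes))
    T[np.arange(y.size), y] = 1.0
    return T


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -30.0, 30.0)))


def train_perceptron(
    X: np.ndarray, y: np.ndarray, spec: PerceptronSpec
) -> np.ndarray:
    """Train the no-hidden-layer perceptron; returns weights ``(D+1, G)``.

    The last weight row is the bias.  Deterministic given ``spec.seed``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("need at least two groups in the training data")
    G = spec.n_outputs
    if classes.max() >= G:
        raise ValueError("label exceeds the number of output nodes")
    n, d = X.shape
    Xb = np.hstack([X, np.ones((n, 1))])
    T = _one_hot(y, G)
    rng = np.random.default_rng(spec.seed)
    W = rng.uniform(-0.1, 0.1, size=(d + 1, G))

    rp = spec.rprop
    delta = np.full_like(W, rp.delta0)
    g_prev = np.zeros_like(W)
    loss_prev = math.inf
    for _epoch in range(spec.max_epochs):
        P = _sigmoid(Xb @ W)
        eps = 1e-12
        loss = -float(np.sum(T * np.log(P + eps) + (1 - T) * np.log(1 - P + eps)))
        if not math.isfinite(loss):
            raise FloatingPointError(
                f"training diverged (loss={loss!r} at epoch {_epoch})"
            )
        if abs(loss_prev - loss) < spec.convergence_tol:
            break
        loss_prev = loss
        g = Xb.T @ (P - T)  # gradient of summed cross-entropy
        sign_prod = g_prev * g
        delta = np.where(
            sign_prod > 0,
            np.minimum(delta * rp.eta_plus, rp.delta_max),
            np.where(sign_prod < 0, np.maximum(delta * rp.eta_minus, rp.delta_min), delta),
        )
        g = np.where(sign_prod < 0, 0.0, g)  # iRprop-: skip step on sign change
        W = W - np.sign(g) * delta
        g_prev = g
    return W


def predict(W: np.ndarray, X: np.ndarray) -> np.ndarray:
    Xb = np.hstack([np.asarray(X, dtype=float), np.ones((len(X), 1))])
    return np.argmax(_sigmoid(Xb @ W), axis=1)


def training_accuracy(W: np.ndarray, X: np.ndarray, y: np.ndarray) -> float:
    return float(np.mean(predict(W, X) == np.asarray(y)))


# --------------------------------------------------------------------------
# cross-validation

def _fold_indices(n: int, y: np.ndarray, k: int | None, rng: np.random.Generator):
    if k is None:  # leave-one-out
        for i in range(n):
            yield np.array([i]), np.delete(np.arange(n), i)
    else:
        perm = rng.permutation(n)
        for fold in np.array_split(perm, k):
            train = np.setdiff1d(np.arange(n), fold)
            yield fold, train


def cross_validate(
    X: np.ndarray,
    labels: Sequence[str],
    spec: PerceptronSpec | None = None,
    k: int | None = None,
    expectation: str = "uniform",
) -> ClassificationResult:
    """Cross-validated recognition of group membership.

    Leave-one-out by default (``k=None``); pass ``k`` for k-fold.  The
    standardizer is re-fit on each fold's training subset.  Per-fold
    training seeds derive deterministically from ``spec.seed``.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    group_names = tuple(sorted(set(labels.tolist())))
    y = np.array([group_names.index(l) for l in labels])
    counts = np.bincount(y, minlength=len(group_names))
    if np.any(counts < 2):
        warnings.warn(
            "a group has fewer than 2 samples; its folds proceed but "
            "recognition for it is unreliable",
            stacklevel=2,
        )
    base = spec or PerceptronSpec()
    rng = np.random.default_rng(base.seed)
    G = len(group_names)
    n_outputs = max(G, base.n_outputs) if base.n_outputs > G else G
    confusion = np.zeros((G, G), dtype=int)
    for f, (test_idx, train_idx) in enumerate(_fold_indices(len(y), y, k, rng)):
        sc = fit_standardizer(X[train_idx])
        Xtr = sc.transform(X[train_idx])
        Xte = sc.transform(X[test_idx])
        fold_spec = PerceptronSpec(
            n_inputs=Xtr.shape[1],
            n_outputs=n_outputs,
            rprop=base.rprop,
            max_epochs=base.max_epochs,
            convergence_tol=base.convergence_tol,
            seed=(base.seed * 100_003 + f) % (2**31 - 1),
        )
        W = train_perceptron(Xtr, y[train_idx], fold_spec)
        # restrict the arg-max to the nodes of observed groups (extra output
        # nodes, if configured, never had a positive target)
        Xteb = np.hstack([Xte, np.ones((len(Xte), 1))])
        pred = np.argmax(_sigmoid(Xteb @ W)[:, :G], axis=1)
        for t, p in zip(y[test_idx], pred):
            confusion[t, p] += 1
    stat, p = chi_square_recognition(confusion, expectation=expectation)
    folds = "leave-one-out" if k is None else f"{k}-fold"
    return ClassificationResult(
        confusion=confusion,
        group_names=group_names,
        chi2_stat=stat,
        chi2_p=p,
        folds=folds,
    )


def chi_square_recognition(
    confusion: np.ndarray | ClassificationResult,
    expectation: str = "uniform",
) -> tuple[float, float]:
    """Goodness-of-fit of confusion counts against chance expectation.

    ``uniform`` spreads each true-group row uniformly over the predicted
    classes (50% per cell for two groups); ``proportional`` uses the
    observed group sizes as the chance profile.  Degrees of freedom are
    rows × (cols − 1); returns ``(statistic, upper-tail p)``.
    """
    if isinstance(confusion, ClassificationResult):
        confusion = confusion.confusion
    obs = np.asarray(confusion, dtype=float)
    rows, cols = obs.shape
    row_sums = obs.sum(axis=1)
    if np.any(row_sums <= 0):
        raise ValueError("a true group has zero observations (expected count 0)")
    if expectation == "uniform":
        exp = np.repeat(row_sums[:, None] / cols, cols, axis=1)
    elif expectation == "proportional":
        col_profile = obs.sum(axis=0) / obs.sum()
        if np.any(col_profile <= 0):
            raise ValueError("a predicted class has zero overall counts")
        exp = row_sums[:, None] * col_profile[None, :]
    else:
        raise ValueError(f"unknown expectation model {expectation!r}")
    stat = float(np.sum((obs - exp) ** 2 / exp))
    df = rows * (cols - 1)
    p = float(sps.chi2.sf(stat, df))
    return stat, p
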