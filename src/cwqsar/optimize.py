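"""Monte-Carlo optimization of correlation weights.

The search maximizes one of two target functions over the weight vector of
the active attributes:

    TF1 = R_TRN + R_iTRN − |R_TRN − R_iTRN| · c
    TF2 = TF1 + w_iic · IIC

R_TRN and R_iTRN are Pearson correlations between observed and calculated
activity on the training and invisible-training subsets; the index of
ideality of correlation (IIC) is the calibration-set correlation damped by
the asymmetry between the mean absolute errors of the negative and positive
residual classes.  The intercept/slope of the one-descriptor regression are
refit on TRN (closed-form least squares) at every evaluation.

The optimizer itself is coordinate-wise stochastic ascent: each epoch
visits every active attribute once in seeded-random order, proposes an
additive uniform perturbation of its weight, and keeps the move whenever
the target function does not decrease.  Everything is deterministic for a
fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .registry import AttributeRegistry
from .smiles import AttributeKey


@dataclass
class OptimizerConfig:
    """Settings of the Monte-Carlo search.

    target              "TF1" or "TF2".
    c                   penalty constant on the |R_TRN − R_iTRN| term (0.1).
    w_iic               weight of the IIC term in TF2 (0.2).
    n_epochs            number of full passes over the active attributes (N*).
    threshold           attribute rarity threshold (T*), kept for provenance.
    seed                RNG seed; same seed ⇒ identical result.
    perturbation_range  half-width of the uniform additive proposal.
    n_probes            number of independent optimizations for interpretation.
    """

    target: str = "TF2"
    c: float = 0.1
    w_iic: float = 0.2
    n_epochs: int = 15
    threshold: int = 1
    seed: int = 0
    perturbation_range: float = 2.0
    n_probes: int = 3

    def __post_init__(self):
        if self.target not in ("TF1", "TF2"):
            raise ValueError("target must be TF1 or TF2")
        if self.n_epochs < 1 or self.n_probes < 1:
            raise ValueError("n_epochs and n_probes must be >= 1")
        if self.perturbation_range <= 0:
            raise ValueError("perturbation_range must be positive")


def tf1(r_trn: float, r_itrn: float, c: float) -> float:
    """Balance-of-correlation target: reward both subsets, penalize their gap."""
    return r_trn + r_itrn - abs(r_trn - r_itrn) * c


def tf2(tf1_value: float, iic_value: float, w_iic: float) -> float:
    return tf1_value + w_iic * iic_value


def iic(deltas, r_cal: float) -> float:
    """Index of ideality of correlation from calibration residuals.

    ``deltas`` are observed − calculated values.  Residuals are split by
    sign (Δ ≥ 0 counts as positive); the damping factor is the ratio of the
    smaller to the larger of the two sign-class mean absolute errors.  An
    empty sign class gives ratio 0; a perfectly zero residual vector is the
    ideal symmetric fit, ratio 1.
    """
    deltas = np.asarray(deltas, dtype=float)
    if deltas.size == 0:
        raise ValueError("calibration set is empty")
    if np.all(deltas == 0):
        return r_cal
    neg = np.abs(deltas[deltas < 0])
    pos = np.abs(deltas[deltas >= 0])
    if neg.size == 0 or pos.size == 0:
        return 0.0
    mae_neg = neg.mean()
    mae_pos = pos.mean()
    lo, hi = min(mae_neg, mae_pos), max(mae_neg, mae_pos)
    ratio = 1.0 if hi == 0 else lo / hi
    return r_cal * ratio


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson r, defined as 0 for a constant input."""
    if x.size < 2:
        return 0.0
    sx = x.std()
    sy = y.std()
    if sx == 0 or sy == 0:
        return 0.0
    return float(((x - x.mean()) * (y - y.mean())).mean() / (sx * sy))


@dataclass
class FitState:
    r_trn: float
    r_itrn: float
    r_cal: float
    iic: float
    tf_value: float
    c0: float
    c1: float
    epoch: int = 0


@dataclass
class OptimizationResult:
    weights: dict[AttributeKey, float]
    state: FitState
    trace: pd.DataFrame = field(repr=False)


class _Evaluator:
    """Target-function evaluation on a fixed dataset/split geometry."""

    def __init__(self, X: np.ndarray, y: np.ndarray, subset: np.ndarray, config: OptimizerConfig):
        self.X = X
        self.y = y
        self.trn = subset == "TRN"
        self.itrn = subset == "iTRN"
        self.cal = subset == "CAL"
        if not (self.trn.any() and self.itrn.any() and self.cal.any()):
            raise ValueError("TRN, iTRN and CAL subsets must all be non-empty")
        if np.ptp(y[self.trn]) == 0:
            raise ValueError("all training activities are equal; correlation undefined")
        self.config = config

    def evaluate(self, dcw: np.ndarray) -> FitState:
        y_trn = self.y[self.trn]
        x_trn = dcw[self.trn]
        # closed-form least squares on TRN
        var = x_trn.var()
        if var == 0:
            c1 = 0.0
            c0 = float(y_trn.mean())
        else:
            c1 = float(((x_trn - x_trn.mean()) * (y_trn - y_trn.mean())).mean() / var)
            c0 = float(y_trn.mean() - c1 * x_trn.mean())
        calc = c0 + c1 * dcw
        r_trn = _pearson(y_trn, calc[self.trn])
        r_itrn = _pearson(self.y[self.itrn], calc[self.itrn])
        r_cal = _pearson(self.y[self.cal], calc[self.cal])
        t1 = tf1(r_trn, r_itrn, self.config.c)
        ic = iic(self.y[self.cal] - calc[self.cal], r_cal)
        tf = t1 if self.config.target == "TF1" else tf2(t1, ic, self.config.w_iic)
        return FitState(r_trn, r_itrn, r_cal, ic, tf, c0, c1)


def optimize(
    registry: AttributeRegistry,
    X: np.ndarray,
    y: np.ndarray,
    subset: np.ndarray,
    config: OptimizerConfig,
    seed: int | None = None,
    log=None,
) -> OptimizationResult:
    """Coordinate-wise stochastic ascent over the active-attribute weights.

    ``X`` is the occurrence-count matrix from
    :meth:`AttributeRegistry.count_matrix` (columns follow
    ``registry.active_keys``), ``y`` the observed activities and ``subset``
    the per-compound split labels.  Returns the final weights, fit state
    and a per-epoch trace.
    """
    keys = registry.active_keys
    if X.shape[1] != len(keys):
        raise ValueError("count matrix does not match the registry's active attributes")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    ev = _Evaluator(X, y, np.asarray(subset), config)

    w = rng.uniform(0.5, 1.5, size=len(keys))
    dcw = X @ w
    state = ev.evaluate(dcw)
    rows = []
    for epoch in range(1, config.n_epochs + 1):
        for j in rng.permutation(len(keys)):
            delta = rng.uniform(-config.perturbation_range, config.perturbation_range)
            dcw_new = dcw + delta * X[:, j]
            cand = ev.evaluate(dcw_new)
            if cand.tf_value >= state.tf_value:
                w[j] += delta
                dcw = dcw_new
                state = cand
        state.epoch = epoch
        rows.append(
            {
                "epoch": epoch,
                "tf": state.tf_value,
                "r_trn": state.r_trn,
                "r_itrn": state.r_itrn,
                "r_cal": state.r_cal,
                "iic": state.iic,
            }
        )
        if log is not None:
            log(
                f"epoch {epoch:3d}  {config.target}={state.tf_value:.4f}  "
                f"r_trn={state.r_trn:.4f} r_itrn={state.r_itrn:.4f} "
                f"r_cal={state.r_cal:.4f} iic={state.iic:.4f}"
            )
    trace = pd.DataFrame(rows)
    return OptimizationResult(dict(zip(keys, w)), state, trace)


def run_probes(
    registry: AttributeRegistry,
    X: np.ndarray,
    y: np.ndarray,
    subset: np.ndarray,
    config: OptimizerConfig,
    log=None,
) -> list[OptimizationResult]:
    """Independent optimizations from seeds seed, seed+1, … seed+n_probes−1."""
    return [
        optimize(registry, X, y, subset, config, seed=config.seed + i, log=log)
        for i in range(config.n_probes)
    ]
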