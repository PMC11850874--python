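"""One-descriptor regression and the external-validation metric battery.

Covers the ordinary least-squares fit of activity on the descriptor, the
> 3·s outlier rule, leave-one-out Q², the external predictivity family
(Q²F1, Q²F2, Q²F3), the concordance correlation coefficient, rm², error
summaries (s, MAE, RMSE, F) and Y-scrambling.

Conventions: R² is the explained-variance form 1 − SSE/SST (it can be
negative for poor external predictions); rm² is computed in the
predicted-on-observed direction; s uses the n − 2 denominator; Q² is
leave-one-out on the set the model was fit to.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .optimize import iic as _iic
from .optimize import _pearson


@dataclass
class RegressionModel:
    """pIC50 = c0 + c1 · DCW, fit by ordinary least squares."""

    c0: float
    c1: float
    se_c0: float
    se_c1: float
    s: float  # residual SD, n-2 denominator
    n: int

    def predict(self, dcw):
        return self.c0 + self.c1 * np.asarray(dcw, dtype=float)

    def equation(self, t: int, n_epochs: int) -> str:
        return (
            f"pIC50 = {self.c0:.4f} (±{self.se_c0:.4f}) + "
            f"{self.c1:.4f} (±{self.se_c1:.4f}) × DCW({t},{n_epochs})"
        )


def fit_regression(dcw, pic50) -> RegressionModel:
    """Least-squares line through (DCW, pIC50); rejects a degenerate design."""
    x = np.asarray(dcw, dtype=float)
    y = np.asarray(pic50, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 points to fit the regression")
    if np.ptp(x) == 0:
        raise ValueError("descriptor is constant; regression is degenerate")
    res = stats.linregress(x, y)
    resid = y - (res.intercept + res.slope * x)
    s = float(np.sqrt((resid**2).sum() / (x.size - 2)))
    return RegressionModel(
        c0=float(res.intercept),
        c1=float(res.slope),
        se_c0=float(res.intercept_stderr),
        se_c1=float(res.stderr),
        s=s,
        n=int(x.size),
    )


def detect_outliers(dcw, pic50, ids, k: float = 3.0):
    """Ids whose residual from the full-data fit exceeds k·s, plus the refit.

    Single pass: fit once on everything, flag, refit once without the
    flagged compounds.
    """
    x = np.asarray(dcw, dtype=float)
    y = np.asarray(pic50, dtype=float)
    model = fit_regression(x, y)
    resid = y - model.predict(x)
    mask = np.abs(resid) > k * model.s
    outliers = [i for i, m in zip(ids, mask) if m]
    refit = fit_regression(x[~mask], y[~mask]) if mask.any() else model
    return outliers, refit


def loo_q2(dcw, pic50) -> float:
    """Leave-one-out cross-validated Q² of the one-descriptor regression.

    Uses the PRESS identity for simple regression: the deleted residual is
    e_i / (1 − h_ii) with leverage h_ii = 1/n + (x_i − x̄)²/Sxx.
    """
    x = np.asarray(dcw, dtype=float)
    y = np.asarray(pic50, dtype=float)
    model = fit_regression(x, y)
    resid = y - model.predict(x)
    sxx = ((x - x.mean()) ** 2).sum()
    h = 1.0 / x.size + (x - x.mean()) ** 2 / sxx
    press = ((resid / (1.0 - h)) ** 2).sum()
    sst = ((y - y.mean()) ** 2).sum()
    return float(1.0 - press / sst)


def ccc(x, y) -> float:
    """Lin's concordance correlation coefficient (biased /n form)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    sxy = ((x - x.mean()) * (y - y.mean())).sum()
    sxx = ((x - x.mean()) ** 2).sum()
    syy = ((y - y.mean()) ** 2).sum()
    return float(2 * sxy / (sxx + syy + n * (x.mean() - y.mean()) ** 2))


def rm2(observed, predicted) -> float:
    """rm² = r²(1 − √(r² − r0²)), predicted regressed on observed.

    r² is the squared Pearson correlation; r0² the through-origin
    coefficient of determination of predicted on observed.
    """
    x = np.asarray(observed, dtype=float)
    y = np.asarray(predicted, dtype=float)
    syy = ((y - y.mean()) ** 2).sum()
    if syy == 0:
        return float("nan")
    r2 = _pearson(x, y) ** 2
    k = (x * y).sum() / (x * x).sum()
    r02 = 1.0 - ((y - k * x) ** 2).sum() / syy
    return float(r2 * (1.0 - np.sqrt(max(r2 - r02, 0.0))))


def compute_metrics(observed, predicted, train_mean: float, train_n: int) -> dict[str, float]:
    """All external/internal statistics for one subset.

    ``train_mean``/``train_n`` are the training-set activity mean and size,
    which enter Q²F1 and Q²F3.  Zero variance in the observed vector makes
    the variance-normalized metrics undefined; they are returned as NaN
    with a ``degenerate`` flag rather than raised.
    """
    obs = np.asarray(observed, dtype=float)
    prd = np.asarray(predicted, dtype=float)
    if obs.size != prd.size or obs.size < 2:
        raise ValueError("observed and predicted must be equal-length vectors of size >= 2")
    n = obs.size
    sse = ((obs - prd) ** 2).sum()
    mae = float(np.abs(obs - prd).mean())
    rmse = float(np.sqrt(sse / n))
    s = float(np.sqrt(sse / (n - 2))) if n > 2 else float("nan")
    sst = ((obs - obs.mean()) ** 2).sum()
    sst_train = ((obs - train_mean) ** 2).sum()
    degenerate = sst == 0
    r = _pearson(obs, prd)
    out = {
        "n": n,
        "r2": float(1.0 - sse / sst) if not degenerate else float("nan"),
        "pearson_r2": r**2,
        "ccc": ccc(obs, prd) if not degenerate else float("nan"),
        "iic": _iic(obs - prd, r),
        "q2_f1": float(1.0 - sse / sst_train) if sst_train > 0 else float("nan"),
        "q2_f2": float(1.0 - sse / sst) if not degenerate else float("nan"),
        "q2_f3": float(1.0 - (sse / n) / (sst_train / train_n)) if sst_train > 0 else float("nan"),
        "rm2": rm2(obs, prd) if not degenerate else float("nan"),
        "mae": mae,
        "rmse": rmse,
        "s": s,
        "f": float((n - 2) * r**2 / (1 - r**2)) if 0 < r**2 < 1 and n > 2 else float("nan"),
        "degenerate": degenerate,
    }
    return out


def c_rp2(r: float, rr2: float) -> float:
    """Y-randomization statistic cRp² = R·√(R² − R̄r²), clipped at 0."""
    return float(r * np.sqrt(max(r**2 - rr2, 0.0)))


def y_scramble(dcw, pic50, n_permutations: int = 100, seed: int = 0) -> float:
    """cRp² from data: R is the Pearson correlation of the genuine fit,
    R̄r² the mean squared correlation over seeded permutations of the
    activity vector."""
    if n_permutations < 10:
        raise ValueError("need at least 10 permutations")
    x = np.asarray(dcw, dtype=float)
    y = np.asarray(pic50, dtype=float)
    rng = np.random.default_rng(seed)
    r = _pearson(x, y)
    rr2 = float(np.mean([_pearson(x, rng.permutation(y)) ** 2 for _ in range(n_permutations)]))
    return c_rp2(r, rr2)


REPORT_COLUMNS = [
    "n", "r2", "ccc", "iic", "q2", "q2_f1", "q2_f2", "q2_f3", "s", "rmse", "mae", "rm2", "c_rp2",
]


def validation_report(frames: dict[str, tuple[np.ndarray, np.ndarray]],
                      n_scramble: int = 100, seed: int = 0) -> pd.DataFrame:
    """One row per subset with the Table-style metric battery.

    ``frames`` maps subset label to (observed, predicted) arrays and must
    contain "TRN".  Q² is leave-one-out for the training set and the
    external (training-mean referenced) form for the other subsets;
    Y-scrambling is reported for the training set.
    """
    obs_trn, prd_trn = frames["TRN"]
    train_mean = float(np.asarray(obs_trn).mean())
    train_n = len(obs_trn)
    rows = {}
    for label, (obs, prd) in frames.items():
        m = compute_metrics(obs, prd, train_mean, train_n)
        if label == "TRN":
            m["q2"] = loo_q2(prd, obs) if np.ptp(prd) > 0 else float("nan")
            m["c_rp2"] = y_scramble(prd, obs, n_scramble, seed)
        else:
            m["q2"] = m["q2_f1"]
            m["c_rp2"] = float("nan")
        rows[label] = m
    df = pd.DataFrame(rows).T
    df.index.name = "subset"
    return df[REPORT_COLUMNS]
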