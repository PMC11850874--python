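"""Model/Results surface for Monte-Carlo correlation-weight QSAR.

:class:`CorrelationWeightQSAR` is built from a compound table (id, SMILES,
pIC50) and a four-way split; :meth:`~CorrelationWeightQSAR.fit` runs one or
more Monte-Carlo probes and returns a :class:`MonteCarloQSARResults`
carrying the fitted correlation weights, the one-descriptor regression with
standard errors, per-subset validation statistics, the applicability-domain
report, promoter classification and a ``summary()`` table.

Typical use::

    model = CorrelationWeightQSAR.from_dataframe(df, seed=1)
    res = model.fit(target="TF2", n_epochs=15, n_probes=3, seed=1)
    print(res.summary())
    res.predict(["O=C(C=Cc1ccc(OC)cc1)c1ccccc1"])
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .domain import DomainReport, build_defect_table, domain_report
from .features import Compound
from .interpret import classify_promoters
from .io import assign_splits
from .metrics import RegressionModel, detect_outliers, fit_regression, validation_report
from .optimize import OptimizationResult, OptimizerConfig, run_probes
from .registry import SUBSETS, AttributeRegistry


class CorrelationWeightQSAR:
    """One-descriptor QSAR whose descriptor is learned by Monte Carlo.

    Parameters
    ----------
    data : DataFrame with columns ``id``, ``smiles``, ``pic50``.
    splits : mapping id -> subset label (TRN/iTRN/CAL/VAL).
    threshold : rarity threshold T — an attribute must occur in at least
        this many training ∪ invisible-training compounds to stay active.
    """

    def __init__(self, data: pd.DataFrame, splits: Mapping[str, str], threshold: int = 1):
        missing = {"id", "smiles", "pic50"} - set(data.columns)
        if missing:
            raise ValueError(f"data is missing columns {sorted(missing)}")
        self.data = data.reset_index(drop=True)
        self.splits = dict(splits)
        unassigned = [i for i in self.data["id"] if i not in self.splits]
        if unassigned:
            raise ValueError(f"{len(unassigned)} compounds have no split assignment")
        self.threshold = threshold
        self.compounds = [
            Compound(row.id, row.smiles, float(row.pic50)).featurize()
            for row in self.data.itertuples()
        ]
        self.registry = AttributeRegistry.build(self.compounds, self.splits, threshold)
        self.X, self.active_keys = self.registry.count_matrix(self.compounds)
        self.y = self.data["pic50"].to_numpy(dtype=float)
        self.subset = np.array([self.splits[c.id] for c in self.compounds])

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        splits: Mapping[str, str] | None = None,
        split_fractions: Sequence[float] = (0.27, 0.27, 0.23, 0.23),
        seed: int = 0,
        threshold: int = 1,
    ) -> "CorrelationWeightQSAR":
        """Build from a compound table, randomly splitting when no split is given."""
        if splits is None:
            splits = assign_splits(list(data["id"]), split_fractions, seed)
        return cls(data, splits, threshold)

    def subset_sizes(self) -> dict[str, int]:
        return {s: int((self.subset == s).sum()) for s in SUBSETS}

    def fit(
        self,
        target: str = "TF2",
        n_epochs: int = 15,
        c: float = 0.1,
        w_iic: float = 0.2,
        perturbation_range: float = 2.0,
        n_probes: int = 3,
        seed: int = 0,
        log=None,
    ) -> "MonteCarloQSARResults":
        """Run ``n_probes`` independent Monte-Carlo optimizations.

        The probe with the highest final target-function value becomes the
        reported model; all probes are kept for promoter classification.
        """
        config = OptimizerConfig(
            target=target,
            c=c,
            w_iic=w_iic,
            n_epochs=n_epochs,
            threshold=self.threshold,
            seed=seed,
            perturbation_range=perturbation_range,
            n_probes=n_probes,
        )
        probes = run_probes(self.registry, self.X, self.y, self.subset, config, log=log)
        return MonteCarloQSARResults(self, config, probes)


class MonteCarloQSARResults:
    """Fit results: correlation weights, regression, diagnostics, reports."""

    def __init__(
        self,
        model: CorrelationWeightQSAR,
        config: OptimizerConfig,
        probes: list[OptimizationResult],
    ):
        self.model = model
        self.config = config
        self.probes = probes
        self.best_index = int(np.argmax([p.state.tf_value for p in probes]))
        best = probes[self.best_index]
        model.registry.set_weights(best.weights)
        self._w = np.array([best.weights[k] for k in model.active_keys])
        self.dcw = model.X @ self._w
        trn = model.subset == "TRN"
        self.regression: RegressionModel = fit_regression(self.dcw[trn], model.y[trn])
        self.fittedvalues = self.regression.predict(self.dcw)
        self.resid = model.y - self.fittedvalues
        self._defect_table = build_defect_table(
            model.registry,
            size_trn=int(trn.sum()),
            size_cal=int((model.subset == "CAL").sum()),
        )

    # ---- core quantities -------------------------------------------------
    @property
    def params(self) -> pd.Series:
        return pd.Series({"c0": self.regression.c0, "c1": self.regression.c1})

    @property
    def bse(self) -> pd.Series:
        return pd.Series({"c0": self.regression.se_c0, "c1": self.regression.se_c1})

    @property
    def trace(self) -> pd.DataFrame:
        return self.probes[self.best_index].trace

    def cw_table(self) -> pd.DataFrame:
        return self.model.registry.to_frame()

    # ---- prediction ------------------------------------------------------
    def compute_dcw(self, smiles: str) -> float:
        return self.model.registry.compute_dcw(Compound("query", smiles)).dcw

    def predict(self, smiles: Sequence[str]) -> np.ndarray:
        """Predicted pIC50 for new SMILES strings."""
        return self.regression.predict([self.compute_dcw(s) for s in smiles])

    # ---- diagnostics -----------------------------------------------------
    def validation(self, n_scramble: int = 100, seed: int = 0) -> pd.DataFrame:
        """Per-subset metric battery (R², CCC, IIC, Q², Q²F1–F3, s, MAE, rm², cRp²)."""
        frames = {}
        for label in SUBSETS:
            mask = self.model.subset == label
            if mask.sum() >= 2:
                frames[label] = (self.model.y[mask], self.fittedvalues[mask])
        return validation_report(frames, n_scramble=n_scramble, seed=seed)

    def outliers(self, k: float = 3.0):
        """Compounds whose full-data residual exceeds k·s (the > 3S rule)."""
        return detect_outliers(self.dcw, self.model.y, list(self.model.data["id"]), k)

    def domain(self) -> DomainReport:
        """Applicability-domain report with the 2 × mean-training-defect rule."""
        return domain_report(self.model.compounds, self.model.splits, self._defect_table)

    def promoters(self) -> pd.DataFrame:
        """Enhancing/reducing promoter classification across probes."""
        return classify_promoters(
            [p.weights for p in self.probes], self.model.registry, self._defect_table
        )

    def scatter_data(self) -> pd.DataFrame:
        """Experimental-vs-calculated table for plotting (id, subset, obs, pred)."""
        return pd.DataFrame(
            {
                "id": self.model.data["id"],
                "subset": self.model.subset,
                "obs": self.model.y,
                "pred": self.fittedvalues,
            }
        )

    def plot_fit(self, ax=None):
        """Scatter of calculated vs experimental pIC50, one marker per subset."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for label, group in self.scatter_data().groupby("subset", sort=False):
            ax.scatter(group["obs"], group["pred"], s=14, label=label)
        lims = [self.model.y.min() - 0.2, self.model.y.max() + 0.2]
        ax.plot(lims, lims, "k--", lw=0.8)
        ax.set_xlabel("experimental pIC50")
        ax.set_ylabel("calculated pIC50")
        ax.legend()
        return ax

    # ---- presentation ----------------------------------------------------
    def summary(self) -> str:
        sizes = self.model.subset_sizes()
        dom = self.domain()
        cov = dom.coverage()
        val = self.validation()
        lines = [
            "Monte-Carlo correlation-weight QSAR results",
            "=" * 60,
            f"target function      {self.config.target}"
            f"  (c={self.config.c}, w_iic={self.config.w_iic})",
            f"threshold T / epochs {self.config.threshold} / {self.config.n_epochs}",
            f"probes               {self.config.n_probes} (best: #{self.best_index + 1})",
            f"active attributes    {len(self.model.active_keys)}"
            f" of {len(self.model.registry.records)}",
            f"subset sizes         "
            + ", ".join(f"{k}={v}" for k, v in sizes.items()),
            "",
            self.regression.equation(self.config.threshold, self.config.n_epochs),
            "",
            "validation metrics:",
            val.round(4).to_string(),
            "",
            f"AD: mean TRN defect {dom.mean_trn_defect:.4f}, "
            f"threshold {dom.threshold:.4f}, "
            "coverage "
            + ", ".join(f"{k}={100 * v:.0f}%" for k, v in cov.items()),
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:
        st = self.probes[self.best_index].state
        return (
            f"<MonteCarloQSARResults {self.config.target} "
            f"tf={st.tf_value:.4f} r_trn={st.r_trn:.4f}>"
        )
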