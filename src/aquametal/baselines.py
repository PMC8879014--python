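"""Comparison model families: three linear regressions and six support
vector regressors, plus the R-ratio comparison against the network models.

Linear families fit Y = a0 + sum_i a_i X_i by ordinary least squares,
Huber-weighted iteratively reweighted least squares (tuning constant
1.345), or bidirectional stepwise selection by AIC.  Kernel families use
epsilon-insensitive support vector regression with box constraint 1,
epsilon = iqr(target)/13.49, polynomial kernels of degree 2 and 3, and
Gaussian kernels at the fine/medium/coarse preset scales sqrt(p)/4,
sqrt(p), 4*sqrt(p) for p = 4 predictors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy.stats import iqr
from sklearn.linear_model import LinearRegression
from sklearn.svm import SVR

from . import metrics

__all__ = [
    "LINEAR_FAMILIES",
    "SVM_FAMILIES",
    "ALL_FAMILIES",
    "BaselineResult",
    "ComparisonReport",
    "fit_baseline",
    "compare",
]

LINEAR_FAMILIES = ("linear", "robust_linear", "stepwise_linear")
SVM_FAMILIES = (
    "svm_linear",
    "svm_quadratic",
    "svm_cubic",
    "svm_fine_gaussian",
    "svm_medium_gaussian",
    "svm_coarse_gaussian",
)
ALL_FAMILIES = LINEAR_FAMILIES + SVM_FAMILIES

_N_PREDICTORS = 4
_GAUSSIAN_SCALES = {
    "svm_fine_gaussian": np.sqrt(_N_PREDICTORS) / 4.0,
    "svm_medium_gaussian": np.sqrt(_N_PREDICTORS),
    "svm_coarse_gaussian": 4.0 * np.sqrt(_N_PREDICTORS),
}


@dataclass
class BaselineResult:
    """One fitted comparison family and its per-partition metrics."""

    family: str
    records: dict[str, metrics.MetricRecord]
    coefficients: dict[str, float] | None    # linear families only
    predict: callable = field(repr=False)

    def r(self, partition: str) -> float:
        return self.records[partition].r


@dataclass(frozen=True)
class ComparisonReport:
    """Per-metal R ratios of the network model over the best baselines."""

    rows: tuple[dict, ...]
    partition: str = "test"

    def row_table(self):
        import pandas as pd

        return pd.DataFrame(list(self.rows))


def _stepwise_ols(x: np.ndarray, y: np.ndarray) -> tuple[object, list[int]]:
    """Bidirectional stepwise OLS guided by AIC; returns (fit, columns)."""
    remaining = list(range(x.shape[1]))
    selected: list[int] = []

    def fit_cols(cols: list[int]):
        design = sm.add_constant(x[:, cols]) if cols else np.ones((len(y), 1))
        return sm.OLS(y, design).fit()

    current = fit_cols(selected)
    improved = True
    while improved:
        improved = False
        # forward step
        candidates = [c for c in remaining if c not in selected]
        trials = [(fit_cols(selected + [c]), c) for c in candidates]
        if trials:
            best_fit, best_c = min(trials, key=lambda t: t[0].aic)
            if best_fit.aic < current.aic - 1e-9:
                selected.append(best_c)
                current = best_fit
                improved = True
        # backward step
        if len(selected) > 1:
            trials = [
                (fit_cols([c for c in selected if c != drop]), drop)
                for drop in selected
            ]
            best_fit, drop = min(trials, key=lambda t: t[0].aic)
            if best_fit.aic < current.aic - 1e-9:
                selected.remove(drop)
                current = best_fit
                improved = True
    return current, selected


def _linear_predictor(family: str, xt: np.ndarray, yt: np.ndarray):
    names = ["a0", "a1", "a2", "a3", "a4"]
    if family == "linear":
        fit = LinearRegression().fit(xt, yt)
        coefs = dict(zip(names, [float(fit.intercept_), *map(float, fit.coef_)]))
        return fit.predict, coefs
    if family == "robust_linear":
        design = sm.add_constant(xt)
        fit = sm.RLM(yt, design, M=sm.robust.norms.HuberT(t=1.345)).fit()
        coefs = dict(zip(names, map(float, fit.params)))
        return (lambda x: fit.predict(sm.add_constant(x, has_constant="add"))), coefs
    # stepwise
    fit, cols = _stepwise_ols(xt, yt)
    coefs = {"a0": float(fit.params[0])}
    coefs.update({f"a{c + 1}": 0.0 for c in range(xt.shape[1])})
    for j, c in enumerate(cols):
        coefs[f"a{c + 1}"] = float(fit.params[j + 1])
    coefs["selected"] = tuple(sorted(cols))

    def predict(x: np.ndarray) -> np.ndarray:
        design = (
            sm.add_constant(x[:, cols], has_constant="add")
            if cols
            else np.ones((len(x), 1))
        )
        return fit.predict(design)

    return predict, coefs


def _svm_predictor(family: str, xt: np.ndarray, yt: np.ndarray):
    eps = float(iqr(yt) / 13.49)
    if eps <= 0:
        eps = 0.1
    common = dict(C=1.0, epsilon=eps)
    if family == "svm_linear":
        model = SVR(kernel="linear", **common)
    elif family == "svm_quadratic":
        model = SVR(kernel="poly", degree=2, coef0=1.0, gamma="scale", **common)
    elif family == "svm_cubic":
        model = SVR(kernel="poly", degree=3, coef0=1.0, gamma="scale", **common)
    else:
        scale = _GAUSSIAN_SCALES[family]
        model = SVR(kernel="rbf", gamma=1.0 / scale**2, **common)
    model.fit(xt, yt)
    return model.predict, None


def fit_baseline(
    family: str,
    x: np.ndarray,
    y: np.ndarray,
    split,
    hn_for_aic: int = 0,
) -> BaselineResult:
    """Fit one family on the training partition and score all partitions."""
    if family not in ALL_FAMILIES:
        raise ValueError(f"unknown baseline family {family!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    xt, yt = x[split.train], y[split.train]
    if family in LINEAR_FAMILIES:
        predict, coefs = _linear_predictor(family, xt, yt)
    else:
        predict, coefs = _svm_predictor(family, xt, yt)

    records = {}
    partitions = {
        "train": split.train,
        "validation": split.validation,
        "test": split.test,
        "all": np.arange(len(y)),
    }
    for name, idx in partitions.items():
        pred = np.asarray(predict(x[idx]), dtype=float)
        m = metrics.mse(y[idx], pred)
        records[name] = metrics.MetricRecord(
            partition=name,
            mse=m,
            r=metrics.pearson_r(y[idx], pred),
            aic=metrics.aic(len(y), m, hn_for_aic),
            kge=metrics.kge(y[idx], pred) if y[idx].mean() != 0 else np.nan,
            n=len(idx),
            k=hn_for_aic,
        )
    return BaselineResult(
        family=family, records=records, coefficients=coefs, predict=predict
    )


def compare(
    nn_r_by_metal: dict[str, float],
    baselines_by_metal: dict[str, list[BaselineResult]],
    partition: str = "test",
) -> ComparisonReport:
    """R ratios of the network models over the best linear / kernel family."""
    if set(nn_r_by_metal) != set(baselines_by_metal):
        raise ValueError("network and baseline metal sets differ")
    rows = []
    for metal, results in baselines_by_metal.items():
        linear = [r for r in results if r.family in LINEAR_FAMILIES]
        svm = [r for r in results if r.family in SVM_FAMILIES]
        if not linear or not svm:
            raise ValueError(f"{metal}: need both linear and SVM baselines")
        best_linear = max(r.r(partition) for r in linear)
        best_svm = max(r.r(partition) for r in svm)
        nn_r = nn_r_by_metal[metal]
        rows.append(
            {
                "metal": metal,
                "nn_r": nn_r,
                "best_linear_r": best_linear,
                "best_svm_r": best_svm,
                "ratio_nn_vs_linear": nn_r / best_linear,
                "ratio_nn_vs_svm": nn_r / best_svm,
            }
        )
    return ComparisonReport(rows=tuple(rows), partition=partition)
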