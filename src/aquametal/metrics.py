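"""Performance measures: MSE, Pearson correlation, AIC, and Kling-Gupta
efficiency.

AIC here is the network-selection form N*ln(MSE) + 2k with k the
hidden-neuron count.  KGE combines correlation R, the variability ratio
VE = sd(predicted)/sd(observed), and the bias ratio
BT = mean(predicted)/mean(observed):

    KGE = 1 - sqrt((R-1)^2 + (VE-1)^2 + (BT-1)^2)

with ideal value 1.  Standard deviations are population (ddof=0).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

__all__ = ["MetricRecord", "mse", "pearson_r", "aic", "kge"]


@dataclass(frozen=True)
class MetricRecord:
    """Metrics of one model on one partition."""

    partition: str        # train | validation | test | all | validation+test
    mse: float            # normalized scale
    r: float
    aic: float
    kge: float
    n: int
    k: int                # hidden-neuron count used in the AIC term
    mse_raw: float | None = None   # natural (mg/L) scale

    def as_dict(self) -> dict:
        return asdict(self)


def _pair(observed, predicted) -> tuple[np.ndarray, np.ndarray]:
    o = np.asarray(observed, dtype=float).ravel()
    p = np.asarray(predicted, dtype=float).ravel()
    if o.size == 0:
        raise ValueError("empty input")
    if o.shape != p.shape:
        raise ValueError("observed/predicted length mismatch")
    return o, p


def mse(observed, predicted) -> float:
    """Mean squared error."""
    o, p = _pair(observed, predicted)
    return float(np.mean((o - p) ** 2))


def pearson_r(observed, predicted) -> float:
    """Product-moment correlation; requires nonzero variance on both sides."""
    o, p = _pair(observed, predicted)
    do, dp = o - o.mean(), p - p.mean()
    so, sp = np.sqrt(np.sum(do**2)), np.sqrt(np.sum(dp**2))
    if so == 0 or sp == 0:
        raise ValueError("pearson_r undefined for zero-variance input")
    return float(np.clip(np.sum(do * dp) / (so * sp), -1.0, 1.0))


def aic(n: int, mse_value: float, k: int) -> float:
    """N*ln(MSE) + 2k; a perfect fit (MSE = 0) yields the -inf sentinel."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if k < 0:
        raise ValueError("k must be >= 0")
    if mse_value < 0:
        raise ValueError("mse must be >= 0")
    if mse_value == 0:
        return float("-inf")
    return float(n * np.log(mse_value) + 2 * k)


def kge(observed, predicted) -> float:
    """Kling-Gupta efficiency; 1 iff R = VE = BT = 1."""
    o, p = _pair(observed, predicted)
    if o.mean() == 0:
        raise ValueError("kge undefined for zero-mean observations")
    if np.std(o) == 0:
        raise ValueError("kge undefined for constant observations")
    r = pearson_r(o, p)
    ve = float(np.std(p) / np.std(o))
    bt = float(p.mean() / o.mean())
    return float(1.0 - np.sqrt((r - 1.0) ** 2 + (ve - 1.0) ** 2 + (bt - 1.0) ** 2))
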