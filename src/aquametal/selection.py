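"""Topology selection: sweep hidden-neuron counts and pick the AIC minimum.

Each candidate 4-HN-1 topology is trained with its own deterministic
substream of the root seed, scored by AIC = N*ln(validation MSE) + 2*HN
with N the full dataset size, and the governing structure is the HN at the
AIC minimum (ties broken toward the smaller HN).
"""

from __future__ import annotations

from dataclasses import dataclass, replace, field

import numpy as np

from . import metrics
from .pso import PSOConfig, TrainedModel, train

__all__ = ["SelectionReport", "select_governing", "sweep"]


@dataclass(frozen=True)
class SelectionReport:
    """Outcome of one hidden-neuron sweep for one metal."""

    rows: tuple[dict, ...]          # each: hn, seed, val_mse, aic
    governing_hn: int
    governing_model: TrainedModel
    metal: str | None = None
    season: str | None = None
    water_type: str | None = None
    aic_u_shaped: bool | None = None   # diagnostic: AIC rises after its minimum

    def row_table(self):
        import pandas as pd

        return pd.DataFrame(list(self.rows))


def select_governing(rows: list[dict]) -> int:
    """Governing HN = argmin AIC; ties broken by the smaller HN."""
    if not rows:
        raise ValueError("empty sweep")
    best = min(rows, key=lambda r: (r["aic"], r["hn"]))
    return int(best["hn"])


def _u_shape_diagnostic(rows: list[dict]) -> bool:
    """Whether AIC increases again after its minimum (logged, not asserted)."""
    aics = [r["aic"] for r in sorted(rows, key=lambda r: r["hn"])]
    i = int(np.argmin(aics))
    return i < len(aics) - 1 and aics[-1] > aics[i]


def sweep(
    x: np.ndarray,
    y: np.ndarray,
    split,
    hn_values,
    pso_config: PSOConfig,
    n_total: int | None = None,
    metal: str | None = None,
    season: str | None = None,
    water_type: str | None = None,
) -> SelectionReport:
    """Train one model per candidate HN and select the AIC minimum.

    ``n_total`` is the N used in the AIC term (defaults to the number of
    rows in ``x``); the MSE in the AIC is the normalized-scale validation
    MSE of the candidate model.
    """
    hn_values = sorted(set(int(h) for h in hn_values))
    if not hn_values:
        raise ValueError("empty hidden-neuron range")
    if any(h < 1 or h > 30 for h in hn_values):
        raise ValueError("hidden-neuron counts must lie in [1, 30]")
    n_total = int(n_total if n_total is not None else len(x))

    rows: list[dict] = []
    models: dict[int, TrainedModel] = {}
    for hn in hn_values:
        sub_seed = int(
            np.random.SeedSequence([pso_config.seed, hn]).generate_state(1)[0]
            % (2**31)
        )
        model = train(x, y, split, hn, replace(pso_config, seed=sub_seed))
        models[hn] = model
        rows.append(
            {
                "hn": hn,
                "seed": sub_seed,
                "val_mse": model.best_val_mse,
                "aic": metrics.aic(n_total, model.best_val_mse, hn),
            }
        )
    governing = select_governing(rows)
    return SelectionReport(
        rows=tuple(rows),
        governing_hn=governing,
        governing_model=models[governing],
        metal=metal,
        season=season,
        water_type=water_type,
        aic_u_shaped=_u_shape_diagnostic(rows),
    )
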