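"""Olden's connection-weight sensitivity analysis.

The signed contribution of input i is the sum over hidden neurons of the
product of its input-to-hidden weight and that neuron's hidden-to-output
weight, c_i = sum_x W_ix * W_xy.  Relative importance is reported as
RI_i = 100 * |c_i| / sum_j |c_j| with the sign of c_i carried alongside,
so the percentages are well-defined even when signed contributions cancel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import NetworkParameters

__all__ = [
    "RelativeImportance",
    "olden_contributions",
    "olden_ri",
    "rank_inputs",
]

INPUT_NAMES = ("temp", "ph", "ec", "tds")


@dataclass(frozen=True)
class RelativeImportance:
    """Per-input Olden importance for one trained model."""

    inputs: tuple[str, ...]
    signed_contributions: np.ndarray   # c_i, one per input
    ri_percent: np.ndarray             # 100*|c_i| / sum|c|
    metal: str | None = None
    season: str | None = None
    water_type: str | None = None

    def as_rows(self) -> list[dict]:
        return [
            {
                "metal": self.metal,
                "season": self.season,
                "water_type": self.water_type,
                "input": name,
                "signed_contribution": float(c),
                "ri_percent": float(ri),
            }
            for name, c, ri in zip(
                self.inputs, self.signed_contributions, self.ri_percent
            )
        ]


def olden_contributions(w_in: np.ndarray, w_out: np.ndarray) -> np.ndarray:
    """Signed per-input contributions c_i = sum_x W_ix * W_xy.

    ``w_in`` is (HN, n_inputs), ``w_out`` is (HN,); works for any input
    count, not just the 4-input production network.
    """
    w_in = np.asarray(w_in, dtype=float)
    w_out = np.asarray(w_out, dtype=float)
    return w_in.T @ w_out


def olden_ri(
    params: NetworkParameters,
    input_names: tuple[str, ...] | None = None,
    **labels,
) -> RelativeImportance:
    """Connection-weight relative importance of each input."""
    contributions = olden_contributions(params.w_in, params.w_out)
    total = np.sum(np.abs(contributions))
    if total == 0:
        raise ValueError(
            "all connection-weight contributions are zero "
            "(e.g. zero output weights); relative importance undefined"
        )
    names = input_names or INPUT_NAMES[: params.w_in.shape[1]]
    if len(names) != params.w_in.shape[1]:
        raise ValueError("input_names length mismatch")
    return RelativeImportance(
        inputs=tuple(names),
        signed_contributions=contributions,
        ri_percent=100.0 * np.abs(contributions) / total,
        **labels,
    )


def rank_inputs(ri: RelativeImportance) -> list[str]:
    """Inputs ordered by |RI| descending; ties keep input order (stable)."""
    order = np.argsort(-ri.ri_percent, kind="stable")
    return [ri.inputs[i] for i in order]
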