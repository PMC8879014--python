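"""Feed-forward 4-HN-1 regression network with tansig hidden units.

The network maps the four normalized physicochemical inputs through a
single hidden layer of HN hyperbolic-tangent (tansig) units to one scalar
output (the normalized metal concentration).  The output unit is linear by
default; a tansig output is available by flag.  All parameters flatten into
a vector of length 6*HN + 1 (4*HN input weights + HN hidden biases + HN
output weights + 1 output bias) so a swarm optimizer can treat the network
as a point in R^(6HN+1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "NetworkParameters",
    "n_parameters",
    "forward",
    "encode",
    "decode",
]

N_INPUTS = 4
MAX_HIDDEN = 30


@dataclass(frozen=True)
class NetworkParameters:
    """Weights and biases of a 4-HN-1 network.

    w_in : (HN, 4) input-to-hidden connection weights
    b_hidden : (HN,) hidden biases
    w_out : (HN,) hidden-to-output connection weights
    b_out : output bias
    """

    w_in: np.ndarray
    b_hidden: np.ndarray
    w_out: np.ndarray
    b_out: float

    def __post_init__(self) -> None:
        w_in = np.asarray(self.w_in, dtype=float)
        hn = w_in.shape[0]
        if not 1 <= hn <= MAX_HIDDEN:
            raise ValueError(f"hidden-neuron count must be in [1, {MAX_HIDDEN}]")
        if w_in.shape != (hn, N_INPUTS):
            raise ValueError(f"w_in must have shape ({hn}, {N_INPUTS})")
        if np.shape(self.b_hidden) != (hn,):
            raise ValueError("b_hidden shape mismatch")
        if np.shape(self.w_out) != (hn,):
            raise ValueError("w_out shape mismatch")
        object.__setattr__(self, "w_in", w_in)
        object.__setattr__(self, "b_hidden", np.asarray(self.b_hidden, float))
        object.__setattr__(self, "w_out", np.asarray(self.w_out, float))
        object.__setattr__(self, "b_out", float(self.b_out))

    @property
    def n_hidden(self) -> int:
        return self.w_in.shape[0]

    def to_json(self) -> dict:
        return {
            "n_hidden": self.n_hidden,
            "w_in": self.w_in.tolist(),
            "b_hidden": self.b_hidden.tolist(),
            "w_out": self.w_out.tolist(),
            "b_out": self.b_out,
        }

    @classmethod
    def from_json(cls, obj: dict) -> "NetworkParameters":
        return cls(
            np.asarray(obj["w_in"], float),
            np.asarray(obj["b_hidden"], float),
            np.asarray(obj["w_out"], float),
            float(obj["b_out"]),
        )


def n_parameters(hn: int) -> int:
    """Flat-vector dimension of a 4-hn-1 network: 6*hn + 1."""
    return (N_INPUTS + 2) * hn + 1


def hidden_activations(params: NetworkParameters, features: np.ndarray) -> np.ndarray:
    """(n, HN) tansig hidden-layer activations; each strictly in (-1, 1)."""
    x = np.atleast_2d(np.asarray(features, dtype=float))
    if x.shape[1] != N_INPUTS:
        raise ValueError(f"expected {N_INPUTS} feature columns, got {x.shape[1]}")
    return np.tanh(x @ params.w_in.T + params.b_hidden)


def forward(
    params: NetworkParameters,
    features: np.ndarray,
    output_activation: str = "linear",
) -> np.ndarray:
    """Network prediction, one scalar per row of ``features``."""
    h = hidden_activations(params, features)
    y = h @ params.w_out + params.b_out
    if output_activation == "tansig":
        y = np.tanh(y)
    elif output_activation != "linear":
        raise ValueError(f"unknown output activation {output_activation!r}")
    return y


def encode(params: NetworkParameters) -> np.ndarray:
    """Flatten parameters: [w_in row-major, b_hidden, w_out, b_out]."""
    return np.concatenate(
        [
            params.w_in.ravel(),
            params.b_hidden,
            params.w_out,
            [params.b_out],
        ]
    )


def decode(vector: np.ndarray, hn: int) -> NetworkParameters:
    """Inverse of :func:`encode` for a given hidden-neuron count."""
    vector = np.asarray(vector, dtype=float)
    expected = n_parameters(hn)
    if vector.shape != (expected,):
        raise ValueError(
            f"flat vector for HN={hn} must have length {expected}, "
            f"got {vector.shape}"
        )
    k = N_INPUTS * hn
    return NetworkParameters(
        w_in=vector[:k].reshape(hn, N_INPUTS),
        b_hidden=vector[k:k + hn],
        w_out=vector[k + hn:k + 2 * hn],
        b_out=float(vector[-1]),
    )


def batch_forward(positions: np.ndarray, hn: int, features: np.ndarray) -> np.ndarray:
    """Predictions of a whole swarm at once.

    positions : (S, 6*hn+1) one flat parameter vector per particle
    features : (n, 4) normalized inputs
    returns (S, n) predictions.
    """
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    if positions.shape[1] != n_parameters(hn):
        raise ValueError("position dimension does not match HN")
    x = np.asarray(features, dtype=float)
    k = N_INPUTS * hn
    s = positions.shape[0]
    w_in = positions[:, :k].reshape(s, hn, N_INPUTS)
    b_h = positions[:, k:k + hn]
    w_out = positions[:, k + hn:k + 2 * hn]
    b_out = positions[:, -1]
    h = np.tanh(np.einsum("shi,ni->snh", w_in, x) + b_h[:, None, :])
    return np.einsum("snh,sh->sn", h, w_out) + b_out[:, None]
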