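"""Fixed-point inference for pretrained models.

The reference format is Q6.10: 16-bit signed fixed point with 6 integer bits
(sign included) and 10 fractional bits, multiply-accumulate in a 32-bit
partial-sum accumulator, results rounded back to 16 bits.  Rounding is
round-to-nearest with ties away from zero; out-of-range values saturate.
The hyperbolic tangent is replaced by a four-segment odd piecewise-linear
approximation (PLA) suitable for shift-and-add hardware.

Models are expressed as a stack of linear layers with elementwise
activations; helpers adapt the shallow modulatory networks.  All quantized
matrix products run on integer arrays, so the arithmetic path is exactly the
fixed-point one (up to the accumulator width emulated in 64-bit storage with
saturation at the 32-bit boundary).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ModNetState, sigmoid as _sigmoid_f


class ConfigurationError(ValueError):
    """A quantization format cannot represent the model at all."""


@dataclass(frozen=True)
class QFormat:
    """Signed fixed-point format: ``total_bits`` wide with ``frac_bits``
    fractional bits (integer part = total - frac, sign included)."""

    total_bits: int = 16
    frac_bits: int = 10
    accumulator_bits: int = 32

    def __post_init__(self):
        if self.frac_bits >= self.total_bits:
            raise ConfigurationError("frac_bits must be < total_bits")
        if self.frac_bits < 0 or self.total_bits < 2:
            raise ConfigurationError("need total_bits >= 2 and frac_bits >= 0")

    @property
    def int_bits(self) -> int:
        return self.total_bits - self.frac_bits

    @property
    def scale(self) -> int:
        return 1 << self.frac_bits

    @property
    def qmin(self) -> int:
        return -(1 << (self.total_bits - 1))

    @property
    def qmax(self) -> int:
        return (1 << (self.total_bits - 1)) - 1

    @property
    def step(self) -> float:
        return 1.0 / self.scale

    @property
    def max_value(self) -> float:
        return self.qmax / self.scale

    @property
    def min_value(self) -> float:
        return self.qmin / self.scale


Q6_10 = QFormat(total_bits=16, frac_bits=10, accumulator_bits=32)


def _round_ties_away(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def quantize_int(x, fmt: QFormat = Q6_10) -> np.ndarray:
    """Integer codes: round(x * 2^frac) with ties away from zero, saturated."""
    q = _round_ties_away(np.asarray(x, dtype=np.float64) * fmt.scale)
    return np.clip(q, fmt.qmin, fmt.qmax).astype(np.int64)


def dequantize(q, fmt: QFormat = Q6_10) -> np.ndarray:
    return np.asarray(q, dtype=np.float64) / fmt.scale


def quantize(x, fmt: QFormat = Q6_10) -> np.ndarray:
    """Nearest representable fixed-point value (idempotent; saturates)."""
    return dequantize(quantize_int(x, fmt), fmt)


def pla_tanh(x):
    """Four-segment odd piecewise-linear approximation of tanh:

        |x| >= 3         -> 1
        1.5 <= |x| < 3   -> 0.06|x| + 0.815
        0.5 <= |x| < 1.5 -> 0.443|x| + 0.24
        otherwise        -> 0.924|x|

    extended to negative inputs by odd symmetry.
    """
    x = np.asarray(x, dtype=np.float64)
    a = np.abs(x)
    mag = np.select(
        [a >= 3.0, a >= 1.5, a >= 0.5],
        [np.ones_like(a), 0.06 * a + 0.815, 0.443 * a + 0.24],
        default=0.924 * a,
    )
    result = np.where(x < 0, -mag, mag)
    return result if result.shape else float(result)


def quantized_matmul(w_int: np.ndarray, x_int: np.ndarray,
                     fmt: QFormat = Q6_10) -> np.ndarray:
    """Integer fixed-point product (n_out, n_in) @ (..., n_in) -> (..., n_out).

    Products of two Q(f)-scaled codes accumulate at scale 2^(2f) in the
    partial-sum accumulator (saturating at ``accumulator_bits``), then round
    back to the working format with ties away from zero.

    The integer path is exact while the accumulator fits 64-bit storage
    (2*frac_bits + log2(n_in) <= 62); wider diagnostic formats fall back to
    float64 accumulation on the dequantized codes, whose rounding error is
    orders of magnitude below those formats' step size.
    """
    n_in = w_int.shape[-1]
    exact = 2 * fmt.frac_bits + int(np.ceil(np.log2(max(n_in, 2)))) + 2 <= 62
    if exact:
        acc = np.asarray(x_int, dtype=np.int64) @ w_int.T.astype(np.int64)
        amax = min((1 << (fmt.accumulator_bits - 1)) - 1, 2**62)
        acc = np.clip(acc, -amax - 1, amax)
        half = 1 << (fmt.frac_bits - 1) if fmt.frac_bits > 0 else 0
        rounded = np.sign(acc) * ((np.abs(acc) + half) >> fmt.frac_bits)
    else:
        accf = (np.asarray(x_int, dtype=np.float64) @
                w_int.T.astype(np.float64)) / fmt.scale
        rounded = _round_ties_away(accf).astype(np.int64)
    return np.clip(rounded, fmt.qmin, fmt.qmax)


# ---------------------------------------------------------------------------
# Layered-model inference
# ---------------------------------------------------------------------------

_ACTIVATIONS = {
    "sigmoid": _sigmoid_f,
    "tanh": np.tanh,
    "pla_tanh": pla_tanh,
    "relu": lambda x: np.maximum(x, 0.0),
    "none": lambda x: x,
}


@dataclass
class LinearModel:
    """A stack of (weight, activation-name) layers; weights are (n_out, n_in)."""

    layers: list[tuple[np.ndarray, str]]

    @classmethod
    def from_modnet(cls, state: ModNetState) -> "LinearModel":
        return cls(layers=[(state.W_proj, "sigmoid"), (state.W, "none")])

    def float_predict(self, X: np.ndarray) -> np.ndarray:
        h = np.asarray(X, dtype=np.float64)
        for W, act in self.layers:
            h = _ACTIVATIONS[act](h @ W.T)
        return h.argmax(axis=-1)

    def float_accuracy(self, X: np.ndarray, y: np.ndarray) -> float:
        return float(np.mean(self.float_predict(X) == y))


def weight_quantization_error(model: LinearModel, fmt: QFormat = Q6_10
                              ) -> list[float]:
    """Per-layer mean relative error of the quantized weight vectors,
    ||W_q - W|| / ||W||."""
    errs = []
    for W, _ in model.layers:
        Wq = quantize(W, fmt)
        denom = np.linalg.norm(W)
        errs.append(float(np.linalg.norm(Wq - W) / denom) if denom else 0.0)
    return errs


def quantized_inference(model: LinearModel, X: np.ndarray, y: np.ndarray,
                        fmt: QFormat = Q6_10, keep_output_float: bool = True
                        ) -> dict:
    """Run the model with quantized weights/inputs and integer accumulation.

    Every hidden layer's matmul runs on integer codes with 32-bit partial sums
    rounded back to the working format; activations are evaluated in float on
    the dequantized pre-activations and requantized (tanh uses its
    piecewise-linear approximation on the fixed-point path).  When
    ``keep_output_float`` is set, the final layer instead runs in floating
    point on the dequantized features with unquantized weights.

    Returns accuracy and the per-layer relative weight quantization error.
    """
    for W, _ in model.layers:
        if np.any(W != 0) and not np.any(quantize(W, fmt) != 0):
            raise ConfigurationError(
                f"format Q{fmt.int_bits}.{fmt.frac_bits} cannot represent any "
                "weight of a layer (all codes are zero)")
    h = np.asarray(X, dtype=np.float64)
    n_layers = len(model.layers)
    for li, (W, act) in enumerate(model.layers):
        last = li == n_layers - 1
        if last and keep_output_float:
            pre = h @ W.T
            h = _ACTIVATIONS[act](pre)
            break
        x_int = quantize_int(h, fmt)
        w_int = quantize_int(W, fmt)
        pre_int = quantized_matmul(w_int, x_int, fmt)
        pre = dequantize(pre_int, fmt)
        act_name = "pla_tanh" if act == "tanh" else act
        h = quantize(_ACTIVATIONS[act_name](pre), fmt)
    accuracy = float(np.mean(h.argmax(axis=-1) == y))
    return {
        "accuracy": accuracy,
        "weight_error": weight_quantization_error(model, fmt),
        "format": fmt,
    }


def precision_sweep(model: LinearModel, X: np.ndarray, y: np.ndarray,
                    bit_list: list[int], int_bits: int = 6,
                    keep_output_float: bool = True) -> dict[int, float]:
    """Accuracy at each total bit width (integer part fixed at ``int_bits``,
    so fractional precision is total - int_bits; output layer left in float
    by default)."""
    if not bit_list:
        raise ValueError("bit_list must not be empty")
    out: dict[int, float] = {}
    for bits in bit_list:
        if bits <= int_bits:
            raise ValueError(f"total bits {bits} must exceed int_bits {int_bits}")
        fmt = QFormat(total_bits=bits, frac_bits=bits - int_bits,
                      accumulator_bits=max(32, 2 * bits + 8))
        out[bits] = quantized_inference(
            model, X, y, fmt, keep_output_float=keep_output_float)["accuracy"]
    return out
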