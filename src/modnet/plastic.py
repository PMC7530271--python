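"""The modulatory-trace plastic readout layer.

Every connection of the readout carries three quantities: a regular weight
w_ij (a lifetime parameter, trained by backpropagation), a plasticity
coefficient delta_ij (lifetime, trained, per-connection), and an episodic
modulatory trace Mod_ij (reset to zero at the start of every episode, updated
by a local plasticity rule at every presentation).  The effective weight is

    W_tot = w_ij + delta_ij * Mod_ij                                   (total)
    x_out = softmax(sum_j W_tot_ij x_in_j [+ clamp bonus])           (forward)
    Mod_ij <- Mod_ij + alpha * x_out_i (x_in_j - x_out_i Mod_ij)       (trace)
    alpha  = gamma * logistic(sum_i x_out_i / n)                     (context)

The trace is an Oja-style running association between inputs and (possibly
label-clamped) outputs: after a clamped support presentation the trace row of
the clamped class moves toward the presented feature vector, which is what
lets a single presentation bind a pattern to a label.  gamma is a single
global trainable scalar regulating the trace rate; the modulatory context
term (the logistic of the mean output) gates how fast new information enters.

All operations run through :mod:`modnet.autodiff`, so episode losses
differentiate through the unrolled trace recursion into w, delta and gamma.
Shapes are batched over episodes: w and delta are (n_out, n_in); x_in is
(B, n_in); Mod is (B, n_out, n_in).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


@dataclass
class PlasticReadout:
    """Trainable state of the plastic layer.

    ``w`` and ``delta`` are per-connection lifetime parameters; ``gamma`` is a
    global scalar.  ``Mod`` is the episodic trace, always re-created at zero by
    :func:`reset_trace` when an episode begins.
    """

    w: Tensor
    delta: Tensor
    gamma: Tensor
    Mod: Tensor
    clamp_bonus: float = 10.0

    @property
    def n_out(self) -> int:
        return self.w.shape[0]

    @property
    def n_in(self) -> int:
        return self.w.shape[1]

    def parameters(self) -> list[Tensor]:
        return [self.w, self.delta, self.gamma]


def make_readout(n_in: int, n_out: int, seed: int = 0,
                 delta_init: float = 0.01, gamma_init: float = 0.02,
                 clamp_bonus: float = 10.0, dtype=np.float64) -> PlasticReadout:
    """Create a readout with small random fixed weights, plasticity
    coefficients at ``delta_init`` (0.01) and trace rate ``gamma_init`` (0.02)."""
    rng = np.random.default_rng(seed)
    limit = 1.0 / np.sqrt(n_in)
    w = ad.parameter(rng.uniform(-limit, limit, (n_out, n_in)), dtype=dtype)
    delta = ad.parameter(np.full((n_out, n_in), delta_init), dtype=dtype)
    gamma = ad.parameter(np.asarray(gamma_init), dtype=dtype)
    Mod = Tensor(np.zeros((1, n_out, n_in), dtype=dtype))
    return PlasticReadout(w=w, delta=delta, gamma=gamma, Mod=Mod,
                          clamp_bonus=clamp_bonus)


def reset_trace(readout: PlasticReadout, batch: int = 1) -> PlasticReadout:
    """Zero the episodic trace (exactly), leaving w, delta and gamma untouched.
    Idempotent; also detaches the trace from any previous episode's graph."""
    dtype = readout.w.data.dtype
    readout.Mod = Tensor(
        np.zeros((batch, readout.n_out, readout.n_in), dtype=dtype))
    return readout


def effective_weight(readout: PlasticReadout) -> Tensor:
    """W_tot = w + delta * Mod, shape (B, n_out, n_in)."""
    B, n_out, n_in = readout.Mod.shape
    return readout.w.reshape(1, n_out, n_in) + \
        readout.delta.reshape(1, n_out, n_in) * readout.Mod


def forward(readout: PlasticReadout, x_in, labels: np.ndarray | None = None
            ) -> tuple[Tensor, Tensor]:
    """One presentation: returns (x_out, logits).

    ``x_in`` is (B, n_in) (a Tensor to backpropagate into the embedding).
    When ``labels`` is given (one int per batch row), a clamp bonus is added to
    the labelled unit's pre-activation before the softmax, steering the output
    toward the correct class while the trace records the association.  Query
    presentations pass no label.  The output is a softmax distribution (sums
    to 1).
    """
    x_in = ad.as_tensor(x_in)
    B = x_in.shape[0]
    W_tot = effective_weight(readout)                       # (B, o, i)
    logits = ad.matmul(W_tot, x_in.reshape(B, readout.n_in, 1)) \
        .reshape(B, readout.n_out)
    if labels is not None:
        bonus = np.zeros((B, readout.n_out), dtype=x_in.data.dtype)
        bonus[np.arange(B), np.asarray(labels)] = readout.clamp_bonus
        logits = logits + Tensor(bonus)
    return ad.softmax(logits), logits


def trace_alpha(readout: PlasticReadout, x_out: Tensor) -> Tensor:
    """Modulatory context term: alpha = gamma * logistic(mean of the outputs).
    One scalar per batch row, shared by every connection; always in (0, gamma)."""
    n = x_out.shape[-1]
    mean_out = x_out.sum(axis=-1, keepdims=True) * (1.0 / n)   # (B, 1)
    return readout.gamma * ad.sigmoid(mean_out)


def trace_update(readout: PlasticReadout, x_in, x_out: Tensor) -> PlasticReadout:
    """Apply the Oja-like trace step once per presentation (after forward, with
    the post-clamp output):

        Mod <- Mod + alpha * x_out_i * (x_in_j - x_out_i * Mod_ij)
    """
    x_in = ad.as_tensor(x_in)
    B, n_out, n_in = readout.Mod.shape
    alpha = trace_alpha(readout, x_out).reshape(B, 1, 1)
    xo = x_out.reshape(B, n_out, 1)
    xi = x_in.reshape(B, 1, n_in)
    readout.Mod = readout.Mod + alpha * (xo * xi - (xo * xo) * readout.Mod)
    return readout
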