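"""The shallow modulatory network (ModNet).

The architecture mirrors the insect mushroom body: inputs (antennal-lobe
projection neurons) are lifted by a *fixed* random projection into a
high-dimensional hidden layer (Kenyon cells), which converges onto a small
output layer (mushroom body output neurons).  Only hidden-to-output weights
learn, through a Hebbian rule whose *rate* is gated by a modulatory layer that
reads the output error — the computational analogue of dopaminergic modulation
of Kenyon-cell -> MBON synapses.

Per sample, with hidden activations x_j and output activations A_i:

    A_i  = sigmoid(sum_j w_ij x_j)                       (standard activation)
    M_i  = sum_j w'_ij e_j                               (modulatory activation)
    dw_ij = sigmoid(M_i / n) * delta_ij                  (gated Hebbian update)
    delta_ij = eta_ij (b1 x_i x_j + b2 (x_j - x_i) + b3) (plasticity term)
    eta_ij = eta_in / (e_i x_i)   clipped, special-cased at zero
    dw'_ij = eta'_ij * scale      sign(eta'_ij) = sign(e_i), |eta'_ij| ~ x_i

where e = onehot(label) - A is the output error.  Training is strictly online
(one sample at a time); the modulatory gate sigmoid(M/n) starts large while the
error is large and decays toward 0.5-ish as learning saturates, which is what
produces the fast early learning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclass
class ModNetConfig:
    """Hyperparameters of the shallow modulatory network.

    The plasticity coefficients default to the benchmark configuration
    (b1, b2, b3) = (0.1, 0.2, 0.001) with the initial adaptive rate eta_in in
    [0.001, 0.01].  ``n_scale`` is the global divisor inside the modulatory
    sigmoid gate (flattens the gate's dynamic range); ``mod_scale`` the tunable
    magnitude of the modulatory-weight update; ``eta_clip`` caps the adaptive
    rate near the e_i*x_i -> 0 singularity (defaults to 10*eta_in).

    ``polarity_rule`` selects how the sign of the adaptive rate eta_ij is set:

    * ``"quotient"`` (default): the sign of eta_in / (e_i x_i), i.e. sign(e_i).
      The error direction drives potentiation/depression; this is the reading
      under which the network actually learns.
    * ``"multiply"``: quotient sign additionally multiplied by
      sign(x_j - x_i) * sign(w_ij).
    * ``"replace"``: sign(x_j - x_i) * sign(w_ij) replaces the quotient sign
      (the activation-difference/weight-polarity reading; retained for study —
      it discards the error direction and does not learn).
    """

    n_in: int
    n_out: int
    n_hidden: int = 1000
    beta1: float = 0.1
    beta2: float = 0.2
    beta3: float = 0.001
    eta_in: float = 0.001
    n_scale: float = 10.0
    mod_scale: float = 0.01
    mod_eta_in: float = 0.001
    eta_clip: float | None = None     # None -> 10 * eta_in
    projection_density: float = 1.0
    epochs: int = 2
    seed: int = 0
    polarity_rule: str = "quotient"

    def __post_init__(self):
        if self.n_hidden < self.n_out:
            raise ValueError("n_hidden must be >= n_out")
        for name in ("eta_in", "mod_eta_in", "n_scale", "mod_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 < self.projection_density <= 1):
            raise ValueError("projection_density must be in (0, 1]")
        if self.polarity_rule not in ("quotient", "multiply", "replace"):
            raise ValueError(f"unknown polarity_rule {self.polarity_rule!r}")
        if self.eta_clip is None:
            self.eta_clip = 10.0 * self.eta_in


@dataclass
class ModNetState:
    """All mutable arrays of a ModNet.  ``W_proj`` is fixed after initialisation."""

    W_proj: np.ndarray   # (n_hidden, n_in), frozen random projection
    W: np.ndarray        # (n_out, n_hidden), trainable standard weights w_ij
    W_mod: np.ndarray    # (n_out, n_out), trainable modulatory weights w'_ij
    eta: np.ndarray      # (n_out, n_hidden), adaptive rates eta_ij
    mod_eta: np.ndarray  # (n_out, n_out), adaptive modulatory rates eta'_ij

    def copy(self) -> "ModNetState":
        return ModNetState(*(a.copy() for a in
                             (self.W_proj, self.W, self.W_mod, self.eta, self.mod_eta)))


def init_state(config: ModNetConfig) -> ModNetState:
    """Initialise a network: sparse uniform[-1,1] random projection (density
    ``projection_density``); trainable weights uniform[-0.1, 0.1]; adaptive
    rates at their initial values."""
    rng = np.random.default_rng(config.seed)
    W_proj = rng.uniform(-1.0, 1.0, size=(config.n_hidden, config.n_in))
    if config.projection_density < 1.0:
        mask = rng.random(W_proj.shape) < config.projection_density
        W_proj *= mask
    W = rng.uniform(-0.1, 0.1, size=(config.n_out, config.n_hidden))
    W_mod = rng.uniform(-0.1, 0.1, size=(config.n_out, config.n_out))
    eta = np.full((config.n_out, config.n_hidden), config.eta_in)
    mod_eta = np.full((config.n_out, config.n_out), config.mod_eta_in)
    return ModNetState(W_proj, W, W_mod, eta, mod_eta)


def forward(state: ModNetState, input_vector: np.ndarray
            ) -> tuple[np.ndarray, np.ndarray]:
    """Hidden and output activations for one input; both sigmoidal, in (0, 1)."""
    x = np.asarray(input_vector, dtype=np.float64)
    if x.shape != (state.W_proj.shape[1],):
        raise ValueError(
            f"input shape {x.shape} does not match n_in={state.W_proj.shape[1]}"
        )
    hidden = sigmoid(state.W_proj @ x)
    output = sigmoid(state.W @ hidden)
    return hidden, output


def modulatory_activation(state: ModNetState, error_vector: np.ndarray) -> np.ndarray:
    """M_i = sum_j w'_ij e_j — the modulatory layer's response to the output error."""
    return state.W_mod @ np.asarray(error_vector, dtype=np.float64)


def plasticity_term(state: ModNetState, hidden: np.ndarray, output: np.ndarray,
                    config: ModNetConfig) -> np.ndarray:
    """delta_ij = eta_ij (b1 x_i x_j + b2 (x_j - x_i) + b3).

    x_i is the postsynaptic (output) activation, x_j the presynaptic (hidden)
    one.  The constant b3 lets a synapse move even with no pre/post activity.
    """
    xi = output[:, None]       # (n_out, 1)
    xj = hidden[None, :]       # (1, n_hidden)
    return state.eta * (config.beta1 * xi * xj + config.beta2 * (xj - xi)
                        + config.beta3)


def _polarity_sign(hidden: np.ndarray, output: np.ndarray, W: np.ndarray) -> np.ndarray:
    """sign(x_j - x_i) * sign(w_ij), with sign(0) = +1."""
    diff = hidden[None, :] - output[:, None]
    s1 = np.where(np.sign(diff) == 0, 1.0, np.sign(diff))
    s2 = np.where(np.sign(W) == 0, 1.0, np.sign(W))
    return s1 * s2


def adapt_learning_rate(state: ModNetState, error: np.ndarray, output: np.ndarray,
                        config: ModNetConfig,
                        hidden: np.ndarray | None = None) -> np.ndarray:
    """Update eta in place: eta_ij = eta_in / (e_i x_i), clipped to eta_clip and
    set to eta_in where e_i or x_i is 0, then sign-adjusted per the configured
    polarity rule.  ``hidden`` is required for the activation-difference
    polarity variants ("multiply"/"replace").  Returns the new eta."""
    if config.polarity_rule != "quotient" and hidden is None:
        raise ValueError("hidden activations required for this polarity rule")
    e = error[:, None]
    x = output[:, None]
    prod = e * x
    nonzero = prod != 0
    with np.errstate(divide="ignore", over="ignore"):
        quotient = np.where(nonzero, config.eta_in / np.where(nonzero, prod, 1.0),
                            config.eta_in)
    magnitude = np.minimum(np.abs(quotient), config.eta_clip)
    qsign = np.where(np.sign(quotient) == 0, 1.0, np.sign(quotient))
    if config.polarity_rule == "quotient":
        sign = np.broadcast_to(qsign, state.eta.shape)
    elif config.polarity_rule == "multiply":
        sign = qsign * _polarity_sign(hidden, output, state.W)
    else:  # replace
        sign = _polarity_sign(hidden, output, state.W)
    state.eta = np.broadcast_to(magnitude, state.eta.shape) * sign
    return state.eta


def adapt_mod_learning_rate(state: ModNetState, error: np.ndarray,
                            output: np.ndarray, config: ModNetConfig) -> np.ndarray:
    """Modulatory-layer rates: sign directly correlated with the error, magnitude
    scaled by the output activation — eta'_ij = sign(e_i) * mod_eta_in * x_i."""
    state.mod_eta = np.broadcast_to(
        np.sign(error)[:, None] * config.mod_eta_in * output[:, None],
        state.mod_eta.shape,
    ).copy()
    return state.mod_eta


def update_standard_weights(state: ModNetState, hidden: np.ndarray,
                            output: np.ndarray, error: np.ndarray,
                            config: ModNetConfig,
                            delta: np.ndarray | None = None) -> np.ndarray:
    """Apply dw_ij = sigmoid(M_i / n) * delta_ij additively; returns the update."""
    M = modulatory_activation(state, error)
    if delta is None:
        delta = plasticity_term(state, hidden, output, config)
    dW = sigmoid(M / config.n_scale)[:, None] * delta
    if not np.all(np.isfinite(dW)):
        bad = np.argwhere(~np.isfinite(dW))[0]
        raise FloatingPointError(
            f"non-finite weight update at (i, j) = {tuple(bad)}; "
            f"|M| max = {np.abs(M).max():.3g}, |delta| max = {np.abs(delta).max():.3g}"
        )
    state.W += dW
    return dW


def update_modulatory_weights(state: ModNetState, error: np.ndarray,
                              output: np.ndarray, config: ModNetConfig) -> np.ndarray:
    """Apply dw'_ij = eta'_ij * scale; zero error leaves W_mod unchanged."""
    adapt_mod_learning_rate(state, error, output, config)
    dW = state.mod_eta * config.mod_scale
    state.W_mod += dW
    return dW


def evaluate(state: ModNetState, features: np.ndarray, labels: np.ndarray) -> float:
    """Classification accuracy by argmax of the output activations."""
    hidden = sigmoid(features @ state.W_proj.T)
    logits = hidden @ state.W.T
    return float(np.mean(logits.argmax(axis=1) == labels))


def train(state: ModNetState, features: np.ndarray, labels: np.ndarray,
          config: ModNetConfig, attention=None, history_every: int = 100
          ) -> tuple[ModNetState, dict]:
    """Online training loop (batch size 1).

    Per sample: forward -> error -> modulatory activation -> rate adaptation ->
    gated Hebbian weight update -> modulatory-weight update.  ``attention`` is an
    optional hook object (see :mod:`modnet.attention`) with ``observe(hidden)``
    called per sample and ``transform_update(state, dW_pending)`` applied to the
    pending standard-weight update.

    ``history`` records, every ``history_every`` samples, the running training
    accuracy and the mean absolute modulatory activation over the window.
    """
    features = np.asarray(features, dtype=np.float64)
    labels = np.asarray(labels)
    if labels.min() < 0 or labels.max() >= config.n_out:
        raise ValueError("labels must lie in [0, n_out)")
    rng = np.random.default_rng(config.seed + 1)
    hist_samples, hist_acc, hist_absM = [], [], []
    window_correct, window_absM, seen = 0, [], 0
    for epoch in range(config.epochs):
        order = rng.permutation(len(features))
        for idx in order:
            x, y = features[idx], labels[idx]
            hidden, output = forward(state, x)
            target = np.zeros(config.n_out)
            target[y] = 1.0
            error = target - output
            M = modulatory_activation(state, error)
            adapt_learning_rate(state, error, output, config, hidden=hidden)
            delta = plasticity_term(state, hidden, output, config)
            gate = sigmoid(M / config.n_scale)[:, None]
            dW = gate * delta
            if attention is not None:
                attention.observe(hidden)
                dW = attention.transform_update(state, dW)
            if not np.all(np.isfinite(dW)):
                raise FloatingPointError("non-finite weight update during training")
            state.W += dW
            if attention is not None:
                attention.enforce_pruned(state)
            update_modulatory_weights(state, error, output, config)
            window_correct += int(output.argmax() == y)
            window_absM.append(np.abs(M).mean())
            seen += 1
            if seen % history_every == 0:
                hist_samples.append(seen)
                hist_acc.append(window_correct / history_every)
                hist_absM.append(float(np.mean(window_absM)))
                window_correct, window_absM = 0, []
    history = {
        "samples": np.array(hist_samples),
        "accuracy": np.array(hist_acc),
        "mean_abs_modulation": np.array(hist_absM),
    }
    if attention is not None:
        history.update(attention.history())
    return state, history
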