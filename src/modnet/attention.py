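"""Region-based attention, activity-driven pruning, and the compartmentalized
two-hidden-layer network.

The hidden layer is divided into contiguous equal regions.  Every
``eval_period`` samples each region's *activity factor* is computed,

    A_k = mean(a_ik) / a_max,

the window-mean activation normalised by the window maximum in that region.
Regions with A_k at or above a threshold have their pending weight updates
scaled by A_k (relatively boosting the most active populations); regions below
it are *inhibited*: their weights are driven toward zero, sign-preserving, and
clamped to exactly zero once they cross it (a pruned connection never
recovers).

The compartmentalized variant adds a second hidden layer whose input
connections are trained by a slow unsupervised covariance rule,

    dw_ij = eta' (x_pre - s1)(x_post - s2) w_ij,

applied every ``n_slow`` samples on window-mean activations, and splits both
hidden layers into compartments that are gated off (outputs forced to zero,
updates skipped) after two consecutive sub-threshold activity evaluations —
mirroring the independently valenced, individually silenceable compartments of
the mushroom-body lobes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import core
from .core import ModNetConfig, ModNetState, sigmoid


class TrainingError(RuntimeError):
    """The network degenerated during training (e.g. every compartment gated)."""


@dataclass
class RegionPartition:
    """Contiguous equal-block partition of a layer's neurons into regions."""

    n_neurons: int
    n_regions: int = 10
    eval_period: int = 100          # samples per activity evaluation window
    activity_threshold: float = 0.1  # regions below this A_k are inhibited
    alpha_init: float = 1.0          # initial fraction of active neurons

    def __post_init__(self):
        if not (1 <= self.n_regions <= self.n_neurons):
            raise ValueError("need 1 <= n_regions <= n_neurons")
        if self.eval_period < 1:
            raise ValueError("eval_period must be >= 1")
        if not (0 < self.alpha_init <= 1):
            raise ValueError("alpha_init must be in (0, 1]")

    @property
    def region_of(self) -> np.ndarray:
        """Region index per neuron."""
        bounds = np.linspace(0, self.n_neurons, self.n_regions + 1).astype(int)
        out = np.empty(self.n_neurons, dtype=np.int64)
        for k in range(self.n_regions):
            out[bounds[k]:bounds[k + 1]] = k
        return out

    def slices(self) -> list[slice]:
        bounds = np.linspace(0, self.n_neurons, self.n_regions + 1).astype(int)
        return [slice(bounds[k], bounds[k + 1]) for k in range(self.n_regions)]


@dataclass
class RegionActivity:
    """Snapshot of one activity evaluation."""

    A: np.ndarray                # (n_regions,) activity factors in [0, 1]
    active: np.ndarray           # (n_regions,) bool, A_k >= threshold
    pruned_fraction: float       # cumulative fraction of pruned connections


def activity_factor(activations: np.ndarray) -> float:
    """A_k = mean(a) / max(a) over a region's window of activations; 0 for an
    all-zero (dead) region."""
    a = np.asarray(activations, dtype=np.float64)
    if a.size == 0:
        raise ValueError("empty region")
    amax = a.max()
    if amax == 0:
        return 0.0
    return float(a.mean() / amax)


def activity_factors(window: np.ndarray, partition: RegionPartition) -> np.ndarray:
    """Per-region activity factors from a (n_samples, n_neurons) window."""
    window = np.atleast_2d(window)
    return np.array([activity_factor(window[:, s]) for s in partition.slices()])


def scale_update(pending: np.ndarray, A: np.ndarray,
                 partition: RegionPartition) -> np.ndarray:
    """Scale a pending (n_out, n_neurons) update columnwise by each region's
    activity factor (the boost reading: active regions keep proportionally more
    of their update).  Never flips an update's sign since A_k >= 0."""
    scaled = pending.copy()
    for k, s in enumerate(partition.slices()):
        scaled[:, s] *= A[k]
    return scaled


def inhibition_step(weights: np.ndarray, A_k: float,
                    pending: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One inhibition step for a sub-threshold region.

    Positive weights decrease by |A_k * dw|, negative ones increase by it, and a
    weight that would cross zero is clamped to exactly 0 and reported pruned.
    Returns (new_weights, newly_pruned_mask).
    """
    step = np.abs(A_k * pending)
    mag = np.abs(weights)
    new_mag = np.maximum(mag - step, 0.0)
    newly_pruned = (mag > 0) & (new_mag == 0)
    return np.sign(weights) * new_mag, newly_pruned


class RegionAttention:
    """Attention hook for the online training loop.

    Accumulates hidden activations; every ``eval_period`` samples recomputes the
    region activity factors.  Pending standard-weight updates are transformed:
    columns of active regions are scaled by A_k, columns of inhibited regions
    receive a sign-preserving decay toward zero instead of their update, and a
    region whose window activity is exactly zero (a dead region — e.g. a gated
    compartment) is pruned outright.
    """

    def __init__(self, partition: RegionPartition, n_out: int,
                 seed: int = 0, literal_sign: bool = False):
        self.partition = partition
        self.literal_sign = literal_sign
        self.A: np.ndarray | None = None
        self._buffer: list[np.ndarray] = []
        self.pruned = np.zeros((n_out, partition.n_neurons), dtype=bool)
        self._samples_seen = 0
        self._hist_samples: list[int] = []
        self._hist_A: list[np.ndarray] = []
        self._hist_pruned: list[float] = []
        if partition.alpha_init < 1.0:
            # sparse initialisation: the complementary fraction of hidden neurons
            # starts disconnected (their outgoing columns are structural zeros)
            rng = np.random.default_rng(seed)
            n = partition.n_neurons
            inactive = rng.choice(n, size=n - int(round(partition.alpha_init * n)),
                                  replace=False)
            self.pruned[:, inactive] = True
        self._init_pruned = self.pruned.copy()

    # -- hook interface ----------------------------------------------------
    def observe(self, hidden: np.ndarray) -> None:
        self._buffer.append(np.asarray(hidden, dtype=np.float64))
        self._samples_seen += 1
        if len(self._buffer) >= self.partition.eval_period:
            window = np.stack(self._buffer)
            self.A = activity_factors(window, self.partition)
            self._buffer = []
            self._hist_samples.append(self._samples_seen)
            self._hist_A.append(self.A.copy())
            self._hist_pruned.append(float(self.pruned.mean()))

    def transform_update(self, state: ModNetState,
                         pending: np.ndarray) -> np.ndarray:
        out = pending.copy()
        if self.A is not None:
            thr = self.partition.activity_threshold
            for k, s in enumerate(self.partition.slices()):
                A_k = self.A[k]
                if A_k == 0.0:
                    # dead region: no activity at all in the window; its
                    # connections carry no information — prune outright
                    out[:, s] = -state.W[:, s]
                    self.pruned[:, s] = True
                elif A_k >= thr:
                    out[:, s] *= -A_k if self.literal_sign else A_k
                else:
                    w = state.W[:, s]
                    new_w, newly = inhibition_step(w, A_k, pending[:, s])
                    out[:, s] = new_w - w
                    self.pruned[:, s] |= newly
        out[self.pruned] = 0.0
        # a pruned weight stays exactly zero: cancel any residual update and,
        # for just-pruned entries, emit the exact step to zero
        out = np.where(self.pruned & (state.W != 0), -state.W, out)
        return out

    def enforce_pruned(self, state: ModNetState) -> None:
        state.W[self.pruned] = 0.0

    def history(self) -> dict:
        return {
            "attention_samples": np.array(self._hist_samples),
            "activity_factors": (np.stack(self._hist_A) if self._hist_A
                                 else np.empty((0, self.partition.n_regions))),
            "pruned_fraction": np.array(self._hist_pruned),
        }

    @property
    def pruned_fraction(self) -> float:
        """Fraction of all connections at zero (structural plus rule-pruned)."""
        return float(self.pruned.mean())

    @property
    def rule_pruned_fraction(self) -> float:
        """Fraction of the initially existing connections that the inhibition
        rule has since driven to zero."""
        exists = ~self._init_pruned
        return float((self.pruned & exists).sum() / max(exists.sum(), 1))

    def snapshot(self) -> RegionActivity:
        A = (self.A if self.A is not None
             else np.zeros(self.partition.n_regions))
        return RegionActivity(
            A=A, active=A >= self.partition.activity_threshold,
            pruned_fraction=self.pruned_fraction,
        )


# ---------------------------------------------------------------------------
# Covariance rule and compartment gating
# ---------------------------------------------------------------------------

def covariance_update(W_local: np.ndarray, pre_acts: np.ndarray,
                      post_acts: np.ndarray, cov_eta: float,
                      s1: float = 0.5, s2: float = 0.5) -> np.ndarray:
    """Slow unsupervised covariance rule, multiplicative in the weight:

        dw_ij = cov_eta * (x_pre_j - s1) * (x_post_i - s2) * w_ij

    for W_local of shape (n_post, n_pre).  Returns the updated matrix (a zero
    weight stays zero).
    """
    pre = np.asarray(pre_acts, dtype=np.float64)
    post = np.asarray(post_acts, dtype=np.float64)
    dW = cov_eta * np.outer(post - s2, pre - s1) * W_local
    return W_local + dW


class CompartmentGater:
    """Masks compartments that stay below the gating threshold for two
    consecutive activity evaluations.  Gating is permanent and idempotent."""

    def __init__(self, n_compartments: int, threshold: float):
        self.threshold = threshold
        self.below_count = np.zeros(n_compartments, dtype=int)
        self.masked = np.zeros(n_compartments, dtype=bool)

    def update(self, A: np.ndarray) -> np.ndarray:
        below = np.asarray(A) < self.threshold
        self.below_count = np.where(below, self.below_count + 1, 0)
        self.masked |= self.below_count >= 2
        if self.masked.all():
            raise TrainingError(
                "all compartments gated off: the network is degenerate"
            )
        return ~self.masked


def gate_compartments(activity_evaluations: np.ndarray,
                      threshold: float) -> np.ndarray:
    """Active mask after a sequence of activity evaluations (rows = evaluations,
    columns = compartments); a compartment is masked once it has been below
    ``threshold`` on two consecutive evaluations."""
    evals = np.atleast_2d(np.asarray(activity_evaluations, dtype=np.float64))
    gater = CompartmentGater(evals.shape[1], threshold)
    active = np.ones(evals.shape[1], dtype=bool)
    for row in evals:
        active = gater.update(row)
    return active


# ---------------------------------------------------------------------------
# Compartmentalized network
# ---------------------------------------------------------------------------

@dataclass
class CompartmentConfig:
    """Configuration of the two-hidden-layer compartmentalized network
    (default sizes 784 x 1000 x 1000 x 10)."""

    n_in: int = 784
    n_hidden1: int = 1000
    n_hidden2: int = 1000
    n_out: int = 10
    n_compartments: int = 10
    s1: float = 0.5
    s2: float = 0.5
    cov_eta: float = 0.01
    n_slow: int = 100               # samples between covariance updates
    gating_threshold: float = 0.1
    eval_period: int = 100
    activity_threshold: float = 0.1
    within_fraction: float = 0.8    # fraction of h1->h2 connections within-compartment
    epochs: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.n_slow < 1 or self.eval_period < 1:
            raise ValueError("periods must be >= 1")
        if self.n_hidden1 % self.n_compartments or self.n_hidden2 % self.n_compartments:
            raise ValueError("hidden sizes must divide evenly into compartments")


class CompartmentalModNet:
    """Input -> fixed random projection -> compartmentalized hidden1 ->
    covariance-trained hidden2 -> modulatory-Hebbian output layer.

    Both hidden layers are split into compartments; compartment-level attention
    (scale/inhibit) shapes the trainable weights, and persistently inactive
    compartments are gated off entirely.
    """

    def __init__(self, config: CompartmentConfig,
                 modnet_config: ModNetConfig | None = None):
        self.config = config
        self.mn = modnet_config or ModNetConfig(
            n_in=config.n_in, n_out=config.n_out, n_hidden=config.n_hidden2,
            seed=config.seed,
        )
        rng = np.random.default_rng(config.seed)
        c = config
        self.W_proj = rng.uniform(-1.0, 1.0, (c.n_hidden1, c.n_in))
        # hidden1 -> hidden2: block-diagonal-dominant so compartments are
        # meaningful units (within_fraction of connections inside the block)
        comp1 = np.repeat(np.arange(c.n_compartments), c.n_hidden1 // c.n_compartments)
        comp2 = np.repeat(np.arange(c.n_compartments), c.n_hidden2 // c.n_compartments)
        within = comp2[:, None] == comp1[None, :]
        f = c.within_fraction
        # keep all within-block entries; keep off-block entries with the
        # probability q that makes within-block connections a `f` fraction
        q = (1 - f) / (f * (c.n_compartments - 1)) if f < 1 else 0.0
        keep = within | (rng.random(within.shape) < q)
        self.W_h = rng.uniform(-0.5, 0.5, (c.n_hidden2, c.n_hidden1)) * keep
        self.W_out = rng.uniform(-0.1, 0.1, (c.n_out, c.n_hidden2))
        self.W_mod = rng.uniform(-0.1, 0.1, (c.n_out, c.n_out))
        self.eta = np.full((c.n_out, c.n_hidden2), self.mn.eta_in)
        self.mod_eta = np.full((c.n_out, c.n_out), self.mn.mod_eta_in)
        self.comp1, self.comp2 = comp1, comp2
        self.active1 = np.ones(c.n_compartments, dtype=bool)
        self.active2 = np.ones(c.n_compartments, dtype=bool)
        self.gater1 = CompartmentGater(c.n_compartments, c.gating_threshold)
        self.gater2 = CompartmentGater(c.n_compartments, c.gating_threshold)
        self._exists_h = keep             # the block-sparse topology itself
        self.pruned_h = np.zeros_like(self.W_h, dtype=bool)
        self.pruned_out = np.zeros_like(self.W_out, dtype=bool)

    # -- inference ---------------------------------------------------------
    def forward(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        h1 = sigmoid(self.W_proj @ x)
        h1 = h1 * self.active1[self.comp1]
        h2 = sigmoid(self.W_h @ h1)
        h2 = h2 * self.active2[self.comp2]
        out = sigmoid(self.W_out @ h2)
        return h1, h2, out

    def evaluate(self, features: np.ndarray, labels: np.ndarray) -> float:
        h1 = sigmoid(features @ self.W_proj.T) * self.active1[self.comp1]
        h2 = sigmoid(h1 @ self.W_h.T) * self.active2[self.comp2]
        logits = h2 @ self.W_out.T
        return float(np.mean(logits.argmax(axis=1) == labels))

    @property
    def pruned_fraction(self) -> float:
        """Fraction of existing connections (h1->h2 topology plus h2->out) that
        the attention/gating rules have driven to exact zero."""
        n_exist = int(self._exists_h.sum()) + self.pruned_out.size
        n_pruned = int((self.pruned_h & self._exists_h).sum()) + int(self.pruned_out.sum())
        return n_pruned / n_exist

    # -- compartment attention helpers --------------------------------------
    def _compartment_A(self, window: np.ndarray, comp: np.ndarray) -> np.ndarray:
        return np.array([
            activity_factor(window[:, comp == k])
            for k in range(self.config.n_compartments)
        ])

    def _attend_out(self, A2: np.ndarray, pending: np.ndarray) -> np.ndarray:
        """Compartment-level scale/inhibit/prune of the pending output update."""
        thr = self.config.activity_threshold
        out = pending.copy()
        for k in range(self.config.n_compartments):
            cols = self.comp2 == k
            if A2[k] == 0.0:
                out[:, cols] = -self.W_out[:, cols]
                self.pruned_out[:, cols] = True
            elif A2[k] >= thr:
                out[:, cols] *= A2[k]
            else:
                new_w, newly = inhibition_step(self.W_out[:, cols], A2[k],
                                               pending[:, cols])
                out[:, cols] = new_w - self.W_out[:, cols]
                self.pruned_out[:, cols] |= newly
        out[self.pruned_out] = 0.0
        out = np.where(self.pruned_out & (self.W_out != 0), -self.W_out, out)
        return out

    def _inhibit_h(self, A1: np.ndarray, A2: np.ndarray) -> None:
        """Inhibit/prune h1->h2 connections of sub-threshold compartments; the
        pending update for the slow weights is the covariance step, so the decay
        magnitude uses the weight's own scale."""
        thr = self.config.activity_threshold
        for k in range(self.config.n_compartments):
            for axis, comp, A in ((1, self.comp1, A1), (0, self.comp2, A2)):
                sel = comp == k
                if A[k] >= thr:
                    continue
                block = self.W_h[:, sel] if axis == 1 else self.W_h[sel, :]
                if A[k] == 0.0:
                    new_block = np.zeros_like(block)
                    newly = block != 0
                else:
                    new_block, newly = inhibition_step(
                        block, A[k], self.config.cov_eta * np.abs(block) + 1e-4
                    )
                if axis == 1:
                    self.W_h[:, sel] = new_block
                    self.pruned_h[:, sel] |= newly
                else:
                    self.W_h[sel, :] = new_block
                    self.pruned_h[sel, :] |= newly
        self.W_h[self.pruned_h] = 0.0

    # -- training ------------------------------------------------------------
    def train(self, features: np.ndarray, labels: np.ndarray,
              history_every: int = 100) -> dict:
        """Online training: the output layer learns per sample by the gated
        Hebbian rule; h1->h2 weights learn by the slow covariance rule every
        ``n_slow`` samples; compartment attention and gating run every
        ``eval_period`` samples."""
        c, mn = self.config, self.mn
        rng = np.random.default_rng(c.seed + 1)
        buf1: list[np.ndarray] = []
        buf2: list[np.ndarray] = []
        A1 = A2 = None
        hist: dict[str, list] = {k: [] for k in (
            "samples", "accuracy", "mean_abs_modulation", "pruned_fraction",
            "activity_h1", "activity_h2", "active_compartments")}
        window_correct, window_absM, seen = 0, [], 0
        shim = ModNetState(self.W_proj, self.W_out, self.W_mod,
                           self.eta, self.mod_eta)
        for epoch in range(c.epochs):
            order = rng.permutation(len(features))
            for idx in order:
                x, y = features[idx], labels[idx]
                h1, h2, output = self.forward(x)
                target = np.zeros(c.n_out)
                target[y] = 1.0
                error = target - output
                M = core.modulatory_activation(shim, error)
                core.adapt_learning_rate(shim, error, output, mn, hidden=h2)
                delta = core.plasticity_term(shim, h2, output, mn)
                pending = sigmoid(M / mn.n_scale)[:, None] * delta
                if A2 is not None:
                    pending = self._attend_out(A2, pending)
                else:
                    pending[self.pruned_out] = 0.0
                self.W_out += pending
                self.W_out[self.pruned_out] = 0.0
                core.update_modulatory_weights(shim, error, output, mn)
                buf1.append(h1)
                buf2.append(h2)
                seen += 1
                if seen % c.n_slow == 0 and buf1:
                    n = min(len(buf1), c.n_slow)
                    pre = np.mean(buf1[-n:], axis=0)
                    post = np.mean(buf2[-n:], axis=0)
                    self.W_h = covariance_update(self.W_h, pre, post,
                                                 c.cov_eta, c.s1, c.s2)
                    self.W_h[self.pruned_h] = 0.0
                if seen % c.eval_period == 0:
                    w1 = np.stack(buf1[-c.eval_period:])
                    w2 = np.stack(buf2[-c.eval_period:])
                    A1 = self._compartment_A(w1, self.comp1)
                    A2 = self._compartment_A(w2, self.comp2)
                    self._inhibit_h(A1, A2)
                    self.active1 = self.gater1.update(A1)
                    self.active2 = self.gater2.update(A2)
                    buf1, buf2 = [], []
                    hist["activity_h1"].append(A1.copy())
                    hist["activity_h2"].append(A2.copy())
                    hist["active_compartments"].append(
                        int(self.active1.sum() + self.active2.sum()))
                window_correct += int(output.argmax() == y)
                window_absM.append(np.abs(M).mean())
                if seen % history_every == 0:
                    hist["samples"].append(seen)
                    hist["accuracy"].append(window_correct / history_every)
                    hist["mean_abs_modulation"].append(float(np.mean(window_absM)))
                    hist["pruned_fraction"].append(self.pruned_fraction)
                    window_correct, window_absM = 0, []
        # rate/modulatory arrays are reassigned inside the shared-state shim
        self.eta, self.mod_eta, self.W_mod = shim.eta, shim.mod_eta, shim.W_mod
        return {k: np.array(v) for k, v in hist.items()}
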