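# Methods

This note documents the models implemented in `modnet`, the choices made
where the underlying learning rules leave room for interpretation, the
synthetic data the package is validated on, and the known limits of both.

## 1. The shallow modulatory network (`modnet.core`)

### Model

The network mirrors the insect mushroom-body circuit: a sensory input layer
(antennal-lobe projection neurons) is expanded by a **fixed random
projection** `W_proj` into a high-dimensional hidden layer (Kenyon cells),
which converges onto a small output layer (mushroom-body output neurons,
MBONs). Only the hidden-to-output weights `W` learn. Their plasticity is
gated by a **modulatory layer** that reads the output error — the
computational counterpart of dopaminergic gating of Kenyon-cell → MBON
synapses.

Per sample, with hidden activations `x_j = sigmoid(W_proj x)` and output
activations `A_i = sigmoid(W x)`:

```
e            = onehot(label) − A                    output error
M_i          = Σ_j w'_ij e_j                        modulatory activation
η_ij         = η_in / (e_i x_i)                    adaptive rate (clipped)
δ_ij         = η_ij (β1 x_i x_j + β2 (x_j − x_i) + β3)   plasticity term
Δw_ij        = sigmoid(M_i / n) · δ_ij              gated Hebbian update
Δw'_ij       = η'_ij · scale                        modulatory-weight update
```

Training is strictly online (batch size 1), with samples reshuffled per
epoch; the default budget is 2 epochs. The history records the running
training accuracy and the mean |M| every 100 samples; on learnable tasks
mean |M| decays as the error shrinks — the network rewards and penalises
hardest early in training.

### Parameters

| parameter | default | meaning |
|---|---|---|
| `n_hidden` | 1000 | Kenyon-cell expansion size |
| `beta1, beta2, beta3` | 0.1, 0.2, 0.001 | correlation, difference and bias terms of the plasticity rule; `beta3` lets silent synapses drift |
| `eta_in` | 0.001 (use 0.001–0.01) | initial adaptive rate |
| `eta_clip` | 10·`eta_in` | cap on the adaptive rate; the quotient η_in/(e_i·x_i) is singular as e_i·x_i → 0 and the rule does not otherwise bound it |
| `n_scale` | 10 | global divisor inside the modulatory sigmoid gate; flattens the gate's dynamic range |
| `mod_scale` | 0.01 | magnitude of the modulatory-weight update |
| `projection_density` | 1.0 | fraction of nonzero entries in the random projection |

### Interpretation choices

The learning rule is stated compactly and several readings are possible;
these are the ones implemented, each with the reasoning:

* **Gate argument `M_i/n`.** The gate's magnitude term is read as a
  *division* of the modulatory activation by a single global scaling
  parameter `n` (default 10), since the division is described as flattening
  the sigmoid's dynamic range. A per-synapse parameter would multiply the
  state by `n_out × n_hidden` for no observed benefit.
* **Rate quotient and its sign (`polarity_rule`).** The magnitude of the
  adaptive rate is `|η_in/(e_i x_i)|`, clipped. For its sign, three options
  are implemented: inherit the quotient's sign, i.e. sign(e_i)
  (**`"quotient"`, the default**); multiply it by
  sign(x_j − x_i)·sign(w_ij) (`"multiply"`); or replace it with that product
  (`"replace"`). The activation-difference/weight-polarity readings discard
  or scramble the error's direction, and networks trained under them stay at
  chance accuracy; under `"quotient"` the error drives potentiation versus
  depression and the network learns a separable 10-class task to >99% in two
  epochs. The default is therefore the only functional reading.
* **Modulatory-weight rate.** sign(η'_ij) = sign(e_i) and
  |η'_ij| = `mod_eta_in`·x_i: the sign correlates directly with the error
  and the magnitude scales with the output activation.
* **Error definition.** e = onehot(label) − A; the label is the one-hot
  target the modulatory layer receives.
* Where `e_i` or `x_i` is exactly 0, η_ij reverts to `η_in`.

## 2. Region attention and compartments (`modnet.attention`)

### Activity factors, scaling, inhibition

The hidden layer is split into `n_regions` contiguous equal blocks. Every
`eval_period` (100) samples, each region's activity factor is

```
A_k = mean(a_ik) / a_max        over the window's activations in region k,
```

0 for an all-zero window. Regions at or above `activity_threshold` have
their pending weight updates scaled by `A_k` (relatively boosting the most
active populations; the literal subtractive form is available behind
`literal_sign=True`). Regions below the threshold are inhibited: each
weight moves toward zero by |A_k·Δw|, is clamped to exactly 0 when it would
cross, and a pruned connection never recovers. A region whose window
activity is exactly zero — possible only for gated or masked neurons, since
sigmoidal units are otherwise never silent — is pruned outright: a
connection from a permanently silent unit carries no information, and the
literal decay rule (scaled by A_k = 0) would otherwise never remove it.

### What the activity factor can and cannot separate

With an i.i.d. random projection the regions are statistically identical,
so their activity factors concentrate tightly (empirically ≈ 0.43–0.55 for
sigmoidal hidden units on the synthetic tasks). Thresholds well below that
band (including the conservative default of 0.1) disable inhibition
entirely; thresholds inside the band prune whichever regions fluctuate
below it. The pruning experiments therefore run at a threshold just under
the band's centre (0.48), where a minority of regions is removed and
accuracy is retained; pushing the threshold to the centre (0.5) removes
half or more of the network and costs accuracy. Because the activity of a
hidden unit does not depend on its *outgoing* weights, rule-driven pruning
converges to the same regions whether the readout starts dense or 50%
disconnected — that initialisation-independence is what the
dense-versus-sparse test checks.

### Compartmentalized variant

`CompartmentalModNet` adds a second hidden layer
(default 784×1000×1000×10). The first hidden layer is a fixed random
projection; the hidden1→hidden2 weights are block-diagonal-dominant (all
within-compartment connections exist; off-block connections are kept with
the probability that makes within-compartment links 80% of the total) and
learn by a slow unsupervised covariance rule on window-mean activations
every `n_slow` (100) samples:

```
Δw_ij = η' (x_pre − s1)(x_post − s2) w_ij,      s1 = s2 = 0.5, η' = 0.01.
```

The rule is multiplicative in `w`, so absent connections stay absent. The
output layer learns by the modulatory Hebbian rule above. Both hidden
layers are split into 10 compartments whose *net* activity factor (the
activity factor of the compartment's pooled activations) drives the same
scale/inhibit logic, and a compartment below the gating threshold on two
consecutive evaluations is gated off permanently: outputs forced to zero,
updates skipped. Gating every compartment raises a `TrainingError`. Gated
compartments subsequently have zero activity and are pruned outright, which
is why the compartmentalized network removes more connections than region
attention alone on matched runs.

## 3. The modulatory-trace readout (`modnet.plastic`)

Each readout connection carries a lifetime weight `w_ij`, a lifetime
plasticity coefficient `δ_ij` (per-connection, initialised to 0.01), and an
episodic trace `Mod_ij` (reset to exactly 0 when an episode starts). One
scalar `γ` (initialised to 0.02) regulates the trace rate. Per
presentation:

```
x_out = softmax([w + δ⊙Mod] x_in + B·onehot(label) if label given)
α     = γ · logistic(Σ_i x_out_i / n_out)
Mod  ← Mod + α · x_out_i (x_in_j − x_out_i Mod_ij)
```

The trace is an Oja-style running association: under constant drive it
converges to `x_in/x_out` (the fixed point checked in the tests), which
bounds it for inputs in [0,1]. `w`, `δ` and `γ` are trained by
backpropagation with the trace recursion inside the differentiation graph,
so episode losses shape how fast and how strongly the trace binds.

Choices where the formulation is open:

* `δ` is **per-connection** (it may be constant or per-connection); the
  per-connection form is what gives the readout its printed parameter count
  (320 + 320 + 1 for 5-way on 64 features).
* `γ` is one global trainable scalar.
* α uses the **post-softmax** outputs, and is one scalar per step shared by
  all connections (the rule provides no per-connection dependence).
* Label clamping adds a bonus `B` (default 10) to the labelled logit before
  the softmax; the trace update uses the post-clamp output, which is what
  lets a single clamped presentation bind a feature vector to its row.
  Queries pass no label.

## 4. The episodic harness (`modnet.fewshot`)

The embedding is the standard few-shot baseline: four modules of 3×3
convolution (64 filters, biases on) → batch normalization (no learnable
affine parameters; batch statistics always) → ReLU → 2×2 max-pool, taking
28×28 single-channel images to a 1×1×64 map. In code the pool is applied
before the ReLU, which is algebraically identical (max commutes with a
monotone function) and cheaper. Total trainable parameters with the 5-way
readout: 640 + 3·36,928 + 320 + 320 + 1 = **112,065**, counted
programmatically from the parameter arrays.

An N-way K-shot episode samples N classes without replacement from the
split, hides their identity behind a random label assignment and a random
per-class rotation from {0°, 90°, 180°, 270°} (rotated variants act as
distinct classes), presents the K·N support images sequentially with label
clamping and trace updates, then scores one query drawn from a support
class (disjoint sample) without a label. Only the query's cross-entropy
enters the objective — the task metric is query classification — and its
gradient unrolls through the whole episode.

The reference schedule is Adam at 3×10⁻⁵ decayed by 2/3 every 100,000
episodes over 500,000 episodes, evaluated on 200 episodes of held-out
classes; the class split keeps ≈94% of classes for training. The
**scaled plan** used throughout the tests keeps the schedule's shape at
desk scale: 20,000 episodes, decay at five evenly spaced milestones, Adam
at 10⁻³ (appropriate for the shorter run), and episodes processed in
batches of 20 (the support/query recursion is stepped synchronously across
the batch; each episode still sees its own trace). Problem sizes for the
validation runs: a glyph bank of 220 classes × 20 samples, 200 training and
20 held-out classes, three seeds. Under these conditions the model reaches
≈89–93% 5-way 1-shot query accuracy, and forcing δ≡0 on the trained model
collapses it to the 20% chance level — the association lives in the trace.

Batch normalization uses the statistics of whatever batch passes through,
including at evaluation (transductive normalization over the episode's
images), a common choice in episodic training that keeps the network
definition free of running-average state.

## 5. Fixed-point inference (`modnet.quantization`)

The working format is Q6.10: 16 bits, 6 integer bits (sign included), 10
fractional. Quantization is round-to-nearest with ties away from zero and
saturation at the format's range; "6 bits for signed integer" is read as
sign + 5 magnitude bits, giving a range of ±32. Matrix products run on
integer codes with products accumulated at scale 2²ᶠ in a 32-bit saturating
partial-sum accumulator and rounded back to the working format. The integer
path is bit-exact while the accumulator fits 64-bit storage
(2f + log₂ n ≤ 62); wider diagnostic formats (e.g. 30 fractional bits) fall
back to float64 accumulation, whose error is orders of magnitude below
those formats' step. tanh on the fixed-point path is replaced by the
four-segment odd piecewise-linear approximation

```
|x| ≥ 3: 1;   1.5 ≤ |x| < 3: 0.06|x| + 0.815;
0.5 ≤ |x| < 1.5: 0.443|x| + 0.24;   otherwise 0.924|x|,
```

(the second branch applied to |x| for consistency with the odd extension),
whose maximum deviation from tanh on [−4, 4] is ≈ 0.079. Activations other
than tanh are evaluated in float on the dequantized pre-activations and
requantized; the output layer can be kept entirely in float, which on
trained models never does worse than quantizing it — the direction of the
observed sensitivity of the output layer to precision. Precision sweeps
hold the 6 integer bits fixed and vary the total width.

## 6. Synthetic data (`modnet.synthetic`)

* **Vector tasks** stand in for flattened image benchmarks: class means are
  random unit directions scaled by `separation` (near-orthogonal in high
  dimension, so pairwise mean distances concentrate at `separation·√2`) and
  samples add isotropic Gaussian noise. `separation` is the single
  difficulty knob: 0 yields an uninformative task (chance-level for any
  classifier), 6 with unit noise yields Bayes accuracy > 0.99 (checked with
  a nearest-class-mean oracle). The validation condition for fast learning
  is 10 classes × 100 dims × 600 samples/class at separation 6.
* **Glyph banks** emulate a handwritten-character corpus's class/sample
  structure: many classes, few samples. Each class prototype is 2–5 random
  quadratic Bézier strokes rasterised at 4× and area-pooled to the target
  size; samples jitter the prototype by rotation ≤10°, translation ≤2 px
  and ≤1% Bernoulli pixel flips. Pixels are in [0, 1] with strokes as the
  high-valued foreground.

What these generators do **not** emulate: real stroke dynamics,
writer-specific style correlations, class imbalance, or the visual
complexity of natural characters. Passing the harness on glyph banks shows
the episodic machinery binds and generalises across novel procedural
classes; it does not by itself establish accuracy on real handwriting, and
the scaled runs' accuracies are not comparable to full-scale results on
real corpora.

## 7. Numerical and engineering notes

* All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); no global RNG state is touched.
* `modnet.autodiff` is a small reverse-mode engine on NumPy arrays written
  for this package: broadcasting arithmetic, batched matmul, conv/pool/
  batch-norm kernels in channels-last layout, softmax and cross-entropy.
  Gradients are validated op-by-op and end-to-end against central finite
  differences (1e-4 relative on an unrolled episode). float64 is used for
  gradient checks, float32 for training throughput.
* `enable_fast_alloc()` raises glibc's mmap/trim thresholds so the many
  multi-megabyte temporaries of reverse-mode training reuse heap pages
  instead of faulting fresh mappings; this is a severalfold speedup on the
  episodic runs and a no-op elsewhere.
* Checkpoints use a small versioned container (JSON header + raw
  little-endian array bytes) because model state includes non-gradient
  state (traces, adaptive rates, activity factors) and the format must
  round-trip byte-identically.
* Area-mean downsampling (e.g. 28×28 → 10×10) uses exact fractional overlap
  weights, so constants are preserved and each output pixel is a convex
  combination of inputs.
* Degenerate inputs: zero-weight forward passes give uniform outputs
  (sigmoid(0) = 0.5, uniform softmax); all-zero images produce finite
  losses; an all-gated compartment network raises rather than silently
  predicting.

## 8. Known limitations

* The shallow rule's default reading (`polarity_rule="quotient"`) is the
  only one found to learn; the alternative polarity readings are retained
  for study but are not useful defaults.
* Region activity factors cannot separate statistically identical regions
  (Section 2), so pruning behaviour depends on placing the threshold
  relative to the empirical activity band; the package default (0.1) is
  conservative and prunes nothing on the synthetic tasks.
* The few-shot results here are desk-scale: a synthetic glyph corpus,
  20,000 episodes and a 28×28/64-filter embedding. Full-scale episodic
  training on a real handwriting corpus is out of scope.
* Quantization-aware training is not implemented; models are trained in
  float and quantized for inference only.
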