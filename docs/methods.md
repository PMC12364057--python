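# Methods

This note documents the models, the synthetic data, the numerical choices,
and the problem sizes used by the test suite and `scripts/acceptance.py`.

## The circuit model

Each neuron is a discrete-time recurrent leaky integrate-and-fire (rLIF)
unit. With decay β, threshold Θ, feedforward weights w, recurrent weights r
and previous-step layer spikes S:

    V' = β V + wᵀ(x + ε) + rᵀ S_prev,   ε ~ N(0, η²) elementwise
    spike (S = 1) and reset V' → 0 when V' ≥ Θ
    V' clamped from below at −2

One step corresponds to 1 ms, so the reset imposes an implicit 1-ms
refractory period. The clamp is applied *after* the reset: the order only
matters when Θ ≤ 0, which no supported configuration uses, but it is fixed
so results are reproducible. Three layers (sensory, reservoir, output)
update in order within a step: the sensory layer sees the current stimulus
image, each downstream layer sees the upstream layer's *current-step*
spikes, and every layer's recurrence uses its own *previous-step* spikes.
Independent Gaussian noise is added to every feedforward input element of
every layer at every step, during training and simulation alike.

Defaults: β = 0.9, Θ = 1.0, η = 0.05, layer sizes 400/200/10 (total 610,
so a 20% recording yields 122 neurons). These are package defaults chosen
to give sparse but nonzero firing at unit-scale stimuli; they are
configurable per layer.

### Training

The circuit is trained to classify the glyph images. Per step, a softmax
over the ten output-neuron membrane voltages is scored against the one-hot
label with cross-entropy, and the per-step losses are summed over the
presentation window (default 25 steps — the presentation length is a free
protocol choice). The Heaviside spike is kept in the forward pass and
replaced by the derivative of a logistic with slope 25 in the backward pass
(value slope/4 at threshold), making backpropagation through time possible.
The surrogate slope defaults to 10: steeper slopes concentrate the
gradient in a vanishing band around the threshold and made training
outcomes depend strongly on the initialization seed, while slope 10
reaches near-perfect accuracy on the 3-class task reliably.
The optimizer is adaptive-moment gradient descent; early stopping triggers
when validation accuracy has not improved for 5 consecutive epochs, and the
best-validation weights are returned. Because the noise makes evaluation
stochastic, accuracy is averaged over repeated presentations (default 5
repeats at desk scale; the full protocol uses 30). Data are split
train/validation/test 60/20/20.

## Glyph stimuli

The stimulus set stands in for a handwritten-digit corpus without any
download. Ten deterministic geometric primitives (bars at several
orientations, ring, disk, upright and diagonal crosses, square outline,
double bar) are rendered at 28×28 with smooth (anti-aliased) stroke edges,
then jittered per sample: rotation N(0, 0.12 rad), translation N(0, 1.5 px)
per axis, stroke width 3 ± 0.4 px, intensity 1 ± 0.12 (clipped). Pixels are
in [0, 1]. The classes are linearly separable to ~98% held-out accuracy
with a multinomial logistic classifier, and a 2-layer VAE embeds them into
a clustered 2-D latent space — the property the control experiments rely
on. The generator makes no attempt to reproduce digit pixel statistics;
what passing tests show is that the *pipeline* (classification training,
latent embedding, latent control) works on clustered image classes, not
that it matches any particular dataset.

## Variational autoencoders

Both the stimulus VAE (sVAE) and the neural VAE (nVAE) use a Gaussian
encoder producing (μ, log σ²) and a decoder with a logistic output so
reconstructions stay in [0, 1] (pixels and filtered spike states both live
there). Latent dimension k = 2 throughout (configurable). The loss is

    L = Σ‖x − dec(z)‖² + α · KL,   KL = −½ Σ (1 + log σ² − μ² − σ²)

with reparameterized sampling during training and the encoder *mean* used
everywhere at forecasting and control time (control needs deterministic
dynamics). α defaults to 1 for the sVAE and 0.01 for the nVAE: smoothed
spike states have far lower variance than image pixels, and with a larger
α the nVAE posterior can collapse (latent standard deviation of order
1e-3), leaving nothing for the dynamics model or the controllers to work
with. The KL term is the standard closed form added as a penalty; it is
zero exactly when μ = 0, σ² = 1. Training uses
minibatch Adam, early stopping with patience 5 on validation loss, and —
on the nVAE path — a per-epoch multiplicative learning-rate decay of 0.99.
Hidden sizes default to 128 (sVAE) and 64 (nVAE); single hidden layer with
tanh activations.

## Latent input sequences

Latent stimulus points are 120 k-means centers of the embedded validation
images, shuffled and split 40/40/40 into train/validation/test center
sets. Each center set is turned into a 1-ms sequence three ways: a step
function holding each center 500 steps, and fast/slow linear interpolation
between consecutive centers over 200/1000 steps per segment. Interpolated
sample j of a segment is c_i + (j/dur)(c_{i+1} − c_i): the next center is
reached at the first sample of the following segment, so a segment
contributes exactly `dur` samples (the worked midpoint value, 0.5 at step
100 of 200, pins this convention; an inclusive-endpoint convention cannot
reproduce it). The default composite sequence concatenates one step pass,
then the fast segments, then the slow segments; the exact composition used
to produce the original 36,800-step protocol sequences is not recoverable,
so the composition here is config-driven.

## Latent dynamics model

Observed spikes are smoothed per neuron with x_{n+1} = ω s_{n+1} +
(1 − ω) x_n, x₀ = s₀, ω = 0.1, keeping states in [0, 1]. The LDM is

    ẑ_{n+1} = A · enc_neural(x_n) + B · enc_stim(u_n)

with 2×2 matrices A and B. The nVAE is pretrained for 20 epochs, then
fine-tuned jointly with A and B under the combined loss
L_nVAE + L_forecast, where the forecast term is the mean squared error of
T_f-step autoregressive latent rollouts seeded at the encoded observation
(sliding windows with stride T_f; the nVAE reconstruction term is applied
at the window starts). The sVAE is frozen — its parameters are never
touched, and the fit works on a *copy* of the supplied nVAE. Early
stopping patience is 5 with learning-rate decay 0.99. A initializes at
0.9·I and B at zero unless overridden.

The identification horizon T_f defaults to 40, deliberately longer than
the 10-step control horizon: the exponential filter contributes a pole at
1 − ω = 0.9 to the observed dynamics, and a 10-step objective is nearly
flat in the distinction between a 0.95 pole and a 1.00 pole, letting the
fit drift to near-unit eigenvalues that wreck long open-loop forecasts.
Forty-step rollouts restore sensitivity to the true decay. This is an
identification-design choice; the controller's horizon is unaffected.

## Ground-truth spiking fixture

The fixture that validates identification and control end to end is a
linear-Gaussian latent system with Bernoulli spiking emissions:

    z' = A_true z + B_true v + ξ,  ξ ~ N(0, 0.02² I)
    s_i ~ Bernoulli(σ(w_i·z + b_i)),  60 neurons, w ~ N(0, 1.2²), b = −1

Defaults, chosen once from the physics of the downstream pipeline:
A_true = [[0.95, 0.03], [0, 0.92]] — eigenvalues 0.95/0.92, slow relative
to the ω = 0.1 filter so the filter pole only weakly contaminates the
identified eigenvalues; B_true = [[0.05, 0.01], [0, 0.05]] — a small input
gain, so unit-scale latent inputs produce unit-scale steady-state latent
displacements (the slow dynamics amplify them by (I − A)⁻¹) and the
default PID gain matrices (proportional entries up to 20) leave the closed
loop stable. Excitation inputs for identification mix 500-step holds with
200- and 1000-step linear ramps between random points in [−1, 1]².

What the fixture does *not* emulate: recurrent spiking interactions,
non-Gaussian noise propagated through network nonlinearities, and
nonlinear latent flow. Passing recovery tests therefore shows the
identification machinery is correct on a system that satisfies its
assumptions, not that a real circuit's manifold is linear.

## Controllers

PID: v = K_P e + K_I (Σ e)·dt + K_D (e − e_prev)/dt at dt = 1 step, with
the current error included in the sum and an unfiltered backward
difference. Default gains K_P = [[20, 20], [5, 20]],
K_I = [[0.9, 0.9], [0.1, 0.1]], K_D = 0.01·ones. No anti-windup by
default; an optional bound on the integral accumulator is available.

MPC: minimize e_Tᵀ S e_T + Σ_{i=1}^{T−1} e_iᵀ Q e_i + Σ_{i=0}^{T−1}
Δv_iᵀ R Δv_i subject to z_{i+1} = A z_i + B v_i, where e_i = z_i − z*_i is
the tracking error against the (possibly time-varying) reference and
Δv_i = v_i − v_{i−1} with v_{−1} the last input actually applied, carried
across receding-horizon iterations. The cost is written in tracking-error
coordinates because a cost on the raw state would regulate to the origin
rather than follow set points. Defaults: T = 10, Q = S = I, R = 0.001·I,
no bounds. In the circuit-in-the-loop pipeline the input search is
additionally bounded to the training latent-input bounding box expanded by
50% of its range per side (configurable, and removable): the learned input
matrix B is only locally valid, and outside the stimulus decoder's
training support its outputs saturate, so an unbounded search can wind up
to implausibly large latent inputs under model mismatch. The exact-model
experiments use no bounds. Since the dynamics are linear and the cost quadratic, the
unconstrained problem condenses to a positive-definite linear system whose
factorization depends only on (A, B, Q, R, S, T) and is precomputed once
per controller; per step only the linear term is rebuilt. With input
bounds the same condensed objective is minimized with L-BFGS-B. Penalizing
the input *increment* makes constant-reference tracking offset-free: any
equilibrium-sustaining input is reachable with zero steady-state increment
cost. Tests verify the solver against an independent stacked KKT quadratic
program with states and inputs as explicit variables.

## Closed loop and experiments

At step n the plant reports z_n (for the circuit: decode v → image,
advance the circuit one step with noise, filter the observed ensemble's
spikes, encode); the controller sees z_n and the reference window
z*_{n+1..n+T} (PID sees only e_n = z*_n − z_n) and returns v_n; the
stimulus presented at step n is exactly the decode of v_n. Set-point
references are the 2-means centroids of the latent test states, each held
500 steps (ordered by first latent coordinate for reproducibility). Arc
references take the chord z0*→zf* as the diameter of a circle — the unique
circle through both points whose two opposite arcs have equal length — and
sample each semicircle uniformly in angle (identical to uniform arc length
for a circle), with the endpoints set exactly. Metrics: per-dimension nMSE
(MSE divided by the reference range max − min; a constant-reference
dimension falls back to plain MSE, a case the protocol never produces) and
per-dimension input RMS. Transients are kept in stored traces and metrics.

## Problem sizes and determinism

Desk-scale defaults used by the acceptance suite and script, chosen to
keep a full run in minutes on one CPU (full-protocol values in
parentheses): 10 control trials per condition (50), 2–3 ensembles per
sweep condition (10), 3 glyph classes × 200 images with a 130/60/10
circuit for the controller comparison (10 digit classes, 400/200/10),
5 accuracy-evaluation repeats (30), 30 k-means centers for the
desk pipeline (120, the default config value). The parameter-recovery
experiment uses the sizes stated with it: 5 seeds × 20,000 steps × 60
neurons. Every random operation draws from a generator seeded via a named
substream of the global seed (CRC-32 of the stage label mixed into a seed
sequence), so any stage can be rerun independently and whole experiments
are byte-reproducible from (config, seed).

## Known limitations

- The latent model is strictly linear; switching or nonlinear latent
  dynamics, time-delay embeddings, and Koopman-style lifts are out of
  scope.
- The nVAE reconstruction term during LDM fine-tuning is applied at
  forecast-window starts only; applying it to every step or to decoded
  forecasts is a plausible variant that was not needed here.
- PID with the default gain matrices can fail badly on learned circuit
  dynamics (large nMSE); this mirrors the reactive controller's known
  sensitivity and is reported, not suppressed.
- State bounds in the MPC problem are not implemented (the experiments use
  none); input bounds are.
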