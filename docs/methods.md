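# Methods

## Model and integration

Networks are continuous-time rate RNNs,

    τ dx = (−x + W_rec r + b_rec + W_in u) dt + √(2τ) σ_rec dξ,
    r = f(x),    z = W_out r + b_out,

discretized by first-order Euler–Maruyama.  With α = dt/τ the per-step
noise is √(2α)·σ_rec·ξ, ξ ~ N(0, I) — the discrete counterpart of the
√(2τ)·σ_rec·dξ diffusion term.  Under this scheme a disconnected unit is a
discrete Ornstein–Uhlenbeck process with stationary variance
σ_rec²·2/(2−α), which the test suite checks against simulation; the same
convention makes the continuum limit dt→0 recover variance σ_rec².

Defaults: dt = 10 ms, τ = 100 ms (α = 0.1), n_rec = 50, σ_rec = 0.05,
rectified-linear transfer (tanh and logistic are available).  These sizes
train in seconds-to-minutes on one CPU core; nothing in the implementation
ties correctness to them.  The initial state x0 is the zero vector and is
not trained.  States are guarded against divergence (non-finite values
raise immediately).

## Constraints by reparameterization

Connectivity masks (`conn_*`, 1 = synapse allowed), trainability masks
(`train_*`, 1 = plastic) and an optional Dale sign vector map raw
parameters to the effective weights used by the dynamics:

* without Dale signs: `W_eff = conn ⊙ W_raw`;
* with Dale signs: `W_rec_eff = conn ⊙ |W_raw| ⊙ s_pre` (and likewise for
  the readout), where `s_pre` is the ±1 sign of the presynaptic (column)
  unit.  The first ⌈dales_ratio·n_rec⌉ units are excitatory.

The sign is attached to the *outgoing* synapses of each unit — "a neuron's
synapses are all excitatory or all inhibitory" binds the presynaptic
index under z = W r.  Input weights are left unsigned; whether Dale's
principle should bind sensory afferents is genuinely underdetermined, and
the unsigned choice keeps the input encoding a free modeling decision.

Enforcing Dale by reparameterization (rather than projecting after each
update) means constraints hold exactly at every iteration and gradients
remain defined: the chain rule through |·| uses sign(W_raw) with
subgradient 0 at 0 (the same convention as the ReLU kink).  Structured
recipes — no-autapse, two-region with Bernoulli inter-region connectivity,
and frozen E↔I synapses — are ordinary mask edits with no special code
path in the dynamics.

## Losses, gradients, optimizers

Losses are mask-weighted means over the whole batch
(Σ mask⊙err / Σ mask), so learning rates are invariant to batch size and
trial length; an all-zero mask yields loss 0 by convention.  Binary
cross-entropy squashes the raw readout through a logistic and clips
probabilities to [1e-7, 1−1e-7]; the gradient is taken exactly through the
clip (zero where clipped) so finite differences agree everywhere.
Regularizers act on the *effective* weights — an L1/L2 penalty on a
forbidden synapse would otherwise pull raw parameters that have no effect
on the dynamics — plus an optional L2 penalty on mean squared rates.

Gradients are computed by explicit reverse-mode differentiation through
the unrolled recurrence (backpropagation through time), including the
chain through the constraint reparameterization.  Noise realizations are
drawn once per iteration and treated as constants (pathwise derivative).
Trainability masks zero the gradients of frozen parameters after BPTT, so
frozen entries are bit-identical across training, not merely close.
Gradient correctness is gated by central finite differences (step 1e-5,
float64, relative error < 1e-4) across sizes, unroll lengths, masks,
Dale/no-Dale, both losses and all regularizers.

Optimizers are plain SGD, Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-8, bias
correction) and RMSProp (decay 0.9, update lr·g/(√v+1e-8)), with optional
global-norm gradient clipping.  Defaults: Adam, lr 1e-3, batch 64,
evaluation every 10 iterations on 128 fresh trials.  Evaluation always
uses freshly sampled trials, never training batches, and draws from
dedicated random streams (a single master seed fans out to named
init/trials/noise/eval streams), so changing the evaluation cadence never
perturbs the training trajectory.

## Tasks and the synthetic-trial generator

Trials are rasterized on the grid t_k = k·dt, T = round(duration/dt); the
time-resolved trial function receives t in ms.  Targets are 0 outside the
response window; masks are 0 while a stimulus is on (the network is
unconstrained there) and 1 during fixation, delays and the response
window, so premature responses are penalized.  Choice = argmax of the
time-averaged output over the response window, ties toward the lowest
channel.

*Perceptual discrimination*: two channels with means (1±c)/2 during the
stimulus (c = coherence) plus i.i.d. Gaussian noise of per-step sd
0.1·√(2τ/dt).  The √(2τ/dt) factor makes the task's information rate
independent of the integration step: halving dt doubles the samples and
raises per-step noise by √2.  With this generator an ideal integrator's
accuracy is Φ(c·√K/(σ√2)) for K stimulus steps — the quantity used below
to place coherences relative to the psychophysical threshold.

*Delayed discrimination*: one channel carrying amplitudes f1 then f2
(normalized by the largest configured frequency, keeping inputs O(1))
separated by a delay; channel 0 is correct iff f1 > f2.  Noiseless by
default — the computational load is the working memory across the delay,
not sensory noise.

*Delayed match-to-category*: one-hot direction inputs during sample and
test epochs, categories as the equal-width partition
category(k) = ⌊k·n_categories/n_directions⌋.  The readout reports the
category of the *test* stimulus (one output channel per category, as in
the category-labelled readout convention); the sample/test match label is
still computed per trial and exposed for match/non-match analyses.  A
match/non-match readout is the documented alternative.

Each trial carries its own `trial_seed`, so any trial is reproducible in
isolation and vectorized assembly is bit-identical to the scripted
time-loop (tested).

What the generator does *not* emulate: temporally correlated sensory
noise, reaction-time (free-response) paradigms, inter-trial dependencies,
and graded (non-binary) reward.  Passing tests therefore demonstrate
correctness of the training and analysis machinery under idealized
stationary stimuli, not fidelity to any particular dataset.

## Curriculum learning

A curriculum is an ordered stage list with one threshold each (default
0.9).  The stage metric (task accuracy unless a custom function is given)
is measured at every evaluation checkpoint on the current stage's task;
the stage advances when the metric *reaches* the threshold (≥ — "reaches
90%" semantics; the alternative strict-exceeds reading differs only on
exact ties).  Completing the last stage stops training, so a single-stage
curriculum is plain training with a stopping criterion.  Optimizer state
persists across stage transitions, matching one continuous training run.
If the iteration budget elapses first, training returns incomplete with a
warning rather than raising.

## The bundled curriculum experiments

`cogrnn.experiments` fixes one set of conditions for the
curriculum-vs-fixed comparison and freezes them:

* Trial schedule: fixation 100 ms, stimulus 900 ms, response 200 ms
  (T = 120).  At 900 ms the ideal integrator reaches ≈ 93% at coherence
  0.1 — the hardest stage sits just above the 90% criterion, as in the
  near-threshold regime the 2AFC paradigm is designed around, while
  coherences 0.3–0.7 are comfortably easy; this ordering is what a
  coherence curriculum presupposes.
* Training: Adam, lr 2e-4, batch 16.  Small batches put low-coherence
  learning in the gradient-noise-limited regime (the batch-averaged
  discriminative gradient component at c = 0.1 is no longer
  mean-dominated), so learning speed genuinely depends on coherence — with
  large batches and a higher learning rate every coherence trains in tens
  of iterations and iterations-to-criterion degenerates to the evaluation
  cadence.  The moderate learning rate spreads learning over hundreds of
  iterations so the comparison is resolvable.
* Criterion measurement: accuracy on 512 fresh trials every 10 iterations
  (binomial sd ≈ 1.3% at the threshold), reducing lucky crossings;
  criterion = 90% accuracy at coherence 0.1; budget 8000 iterations
  (censored runs score the budget).
* Comparison: 10 network pairs, both arms of a pair starting from the
  identical initialization and master seed; one-sided paired Wilcoxon
  sign-rank on iterations-to-criterion (zero differences dropped).

Network size is 40 units for the paired comparison and 50 (the package
default) for the final-accuracy measurement; these desk-scale sizes train
each arm in seconds to a few minutes on one CPU core.

Known sensitivity: with 10 pairs the sign-rank p-value is coarse (all
wins give 2⁻¹⁰ ≈ 0.001; each small reversal roughly doubles it), and
initializations that happen to solve coherence 0.1 near the cadence floor
contribute ties or small reversals bounded by the stage-passage overhead.
The direction of the effect has been stable across runs; its significance
at exactly p < 0.01 is the fragile quantity.

## Analyses

The standalone simulator re-implements the forward recurrence with no
shared code path with the trainer and is held to 1e-12 agreement under a
shared noise stream.  Perturbations: lesioning (rows, columns and readout
of the lesioned units zeroed), additive state pulses over [onset,
onset+duration), and one-shot Gaussian corruption of the effective
recurrent weights.

The psychometric function is a logistic with lapse,
p(choice 1 | c) = λ + (1−2λ)/(1+e^{−k(c−c₀)}), fitted by bounded least
squares to choice fractions over signed coherences (negative = rewards
choice 2); the form is a convention, chosen for its standard
slope/bias/lapse parameterization.  Trial-averaged state traces average
correct trials only, per coherence.  PCA concatenates the per-coherence
averaged traces along time, centers per unit, and decomposes by SVD; it is
cross-checked against an independent covariance eigendecomposition and
scikit-learn.

## Numerical conventions and edge cases

float64 throughout; ReLU and |·| subgradients at 0 are 0; argmax ties
break toward channel 0; an all-zero loss mask gives loss and gradient 0;
probabilities are clipped before logs; weight archives serialize floats
via repr (exact round-trip); the degenerate all-zero random matrix in the
spectral initializer raises rather than dividing by zero.

## Known limitations

No LSTM or spiking/adaptation variants; no reinforcement learning; no
trial-to-trial dependencies; no reaction-time readout; the curriculum
comparison's significance is desk-scale fragile as described above.
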