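# Methods

This note records the scientific and numerical choices behind the
package: what is modeled, what the synthetic generators emulate, which
quantities are tunable, and where the genuinely open design decisions
were settled.

## The calibration loop

A network with one hidden layer of 20 units maps one observed frame
(q = 1) to a parameter proposal λ̂.  The absolute value is the
activation throughout — on the output layer it guarantees the
positivity every calibrated parameter requires, and the subgradient at
the kink is taken as 0 (the minimum-norm element).  Per-parameter
output scales equal the upper ends of the prior box so that unit-scale
activations reach the whole box.

**Uniform prior.**  The posterior construction weighs visited samples
by exp(−J) times the prior, so the prior is implemented through the
initialization: after random weight initialization the output bias is
shifted so that the network's first proposal on the training input
equals a uniform draw from the prior box.  Over repeated
initializations the initial-proposal distribution is then exactly
uniform (the Kolmogorov–Smirnov check in the test suite).  Prior
boxes: β ∈ [0, 1], τ ∈ [1, 30], σ ∈ [0, 1] for SIR;
α ∈ [0, 2.5], β ∈ [0, 8] for Harris–Wilson, with the κ box scaled to
[0, 2·ΣO/ΣW] because κ's natural unit — the value any steady state
pins it to — is ΣO/ΣW, whatever units the user's tables are in.

**Batching.**  The observed series is cut into consecutive
non-overlapping teacher-forced segments: the solver starts from the
observed state at the segment head and integrates B steps.  A trailing
remainder shorter than B is dropped — with the 100-frame SIR series
and B = 90 this yields exactly one optimizer step per epoch; keeping
the tail (frames 90–100, where the epidemic is extinct and I ≈ 0)
would add a second, uninformative batch whose near-zero loss at
arbitrary (β, τ) corrupts the weighted marginals.

**Optimizer.**  Adam at learning rate 0.002, 20 initializations by
default; every optimizer step records one (λ̂, J) sample with its
initialization id.  Initializations derive independent seeds from the
master training seed and can run concurrently; results merge by id.

**Danger zones.**  Parameter proposals entering the solvers are
saturated with a small-slope leak at twice the prior box (hard bounds
would zero the gradient and strand an initialization that momentum
carried past them).  τ is floored at 1: below that the relaxation rate
1/τ leaves the stability region of the unit-step scheme.  The SIR
training solver additionally clamps states hard at ±5 — the drift is
quadratic in the state, so extreme proposals otherwise
double-exponentiate within a few steps; inside the physical simplex
the clamp never engages.  Non-finite losses abort that initialization;
the multi-start driver records the failure and pools the survivors.

## Forward models

Both SDEs use the Stratonovich convention and are discretized with the
Heun predictor–corrector scheme, which is strongly convergent for
Stratonovich integrals and stays differentiable.  Noise increments are
drawn up front as plain arrays, so differentiation treats them as
constants; when the SIR noise amplitude is learned, the gradient flows
through the amplitude only.

**SIR.**  The ±σI∘dW terms share one Wiener increment, so S + I + R
is conserved pathwise and exactly by the scheme (to rounding).  The
solver steps at dt = 1, one step per observation frame, matching the
agent-based model's unit iteration.

**Harris–Wilson.**  Flows are computed as whole-matrix operations;
zero-cost entries (unreachable routes) contribute no flow.  Zone sizes
are floored at 10⁻⁸ after every step.  The noiseless steady state is
found in two stages: integrate the dynamics until the drift is
moderate, then polish with the self-consistency iteration
W ← D(W)/κ.  The two-stage scheme matters when α > 1: zones that lose
the competition decay only algebraically under the dynamics
(dW ≈ −κW² once their demand collapses), while the Picard map sends
them to zero superlinearly and converges exponentially on the
survivors.  Steady-state balance holds to a relative residual below
10⁻⁶ on surviving zones, and the state is ε-invariant (ε only sets the
convergence rate).

**Training loss for steady-state data.**  A single observed frame has
no successor, so it is scored by stationarity: the solver runs 5 steps
of dt = 0.1 from the frame and every visited state is compared against
it.  The half-unit horizon matters quantitatively: a single-dt
residual is O(dt²) and the resulting landscape is so flat (J ~ 10⁻³)
that the optimizer's own step noise washes out the potential's basin
structure; over the longer horizon the loss spans many orders of
magnitude and the exp(−J) weights actually discriminate.  Noisy
replicate frames are scored the same way, one batch per frame; a
transition-scoring mode exists for genuine time-series data.

## Synthetic data

**Diffusive SIR.**  3,000 agents on a periodic 10 × 10 square;
infection radius 0.3, infection probability 0.2, recovery after 14
steps; one randomly placed initial infection; 100 iterations.  Within
a step the order is move → infect → age/recover, with infections
resolved synchronously against the current infected set (new cases do
not transmit in their first step) and one Bernoulli trial per
susceptible per step however many infected neighbors are in range.
Contact search uses a periodic k-d tree, with an all-pairs
torus-metric scan kept as the reference implementation.  The
compartment diffusivities are not identifiable from density curves and
default to 0.02 each, chosen so the infection wave peaks a little past
the midpoint of the series, the regime the reported dynamics imply.  Recovered (β̂, τ̂) depend on
this choice only weakly: the teacher-forced l2 fit lands near
β̂ ≈ 0.25, τ̂ ≈ 13 for every diffusivity between 0 and 0.15, because
even static agents percolate the contact graph at this density.  What
the fit does pin down robustly is the peak-infection time, which the
calibrated ensemble reproduces.

**Harris–Wilson.**  50 origin and 8 destination zones scattered
(Gaussian, SD 0.05) around four fixed town centers near the corners of
the unit square; demands and initial sizes i.i.d. uniform on
[0.1, 1]; convenience weights c = exp(−d / sup d) on Euclidean
distances; true parameters (α, β, κ) = (1.2, 4, 2).  The polycentric
geometry is deliberate: with all zones in one undifferentiated cluster
the size preference α > 1 drives the market to a monopoly (ν ≈ 1) or
to a two-survivor state in which κ = ΣO/ΣW is implied by the surviving
balance equations and (α, β) lie on a continuous zero-loss curve —
both regimes carry no usable parameter information.  Separated towns
keep one center per town alive, giving interior inequality
(ν ≈ 0.3–0.5) and enough independent balance equations for the
discrete two-solution structure.  Every dataset is screened with
automatic reseeding: the inequality must be strictly interior
(0 < ν < 1; numerically monopolized markets are rejected too) and at
least four zones must survive.  The survivor floor is the package's
identifiability contract: k surviving zones supply k − 1 independent
balance constraints on (α, β), so three survivors leave the nontrivial
solution exactly determined at best, with a valley too shallow for the
optimizer to resolve, and two survivors leave a continuous solution
curve.  Noiseless datasets are the
single converged steady state; noisy datasets are four replicate
observations of it under additive centered Gaussian noise of SD σ,
clipped positive.  What the generator does **not** emulate: measured
cost networks with travel-mode structure, heavy-tailed demand
distributions, or dynamics-correlated noise — passing tests show the
method recovers parameters of its own model class, not that any real
market obeys the model.

## Density estimation

Weights are exp(−(J − min J)) (the shift cancels in the normalization
and prevents underflow), normalized over all pooled samples; samples
with non-finite loss get weight zero.  The prior enters through the
initialization scheme rather than as an explicit weight factor, and
every visited sample counts — including proposals that training
carried outside the initial prior box, whose loss was evaluated at the
saturated parameter values actually handed to the solver.  For users
who prefer strict posterior bookkeeping under the uniform-box prior,
``box_restricted_weights`` applies the box as a joint indicator; this
suppresses mass that accumulates where solver guards saturate extreme
excursions, at the cost of departing from the pool-everything
convention the default follows.  Marginals are weighted Gaussian
KDEs on a 500-point grid spanning the sampled range ± 3 bandwidths;
the default bandwidth is Scott's rule with the effective sample size
1/Σw².  The MLE is the grid argmax; expectation and SD are trapezoidal
quadratures.  Peaks are local maxima with prominence above 5% of the
global maximum (an edge mode is kept if its height clears the same
threshold), and each peak's width is measured at half its height with
linear interpolation between grid points — a single detected peak
yields a width SD of exactly 0.  No burn-in is discarded: all visited
samples count.

## Problem sizes and scaling

The SIR experiment runs at full size (20 × 70 epochs, batch 90, about
a minute).  The Harris–Wilson experiments are scaled in epochs — 4,000
(noiseless) and 1,000 (noisy, four batches per epoch) instead of
10,000 — after verifying that every initialization's endpoint is
stationary well before the cut (endpoint movement below 10⁻³ per 500
epochs); the pooled sample count is 80,000 either way.  The acceptance
script (`scripts/acceptance.py`) states the sizes it uses and derives
all seeds from its `--seed` argument.

## Known limitations

* The recovered SIR (β̂, τ̂) split along the β–τ ridge is a property of
  the epidemic curve's shape, which depends on agent-model details
  (diffusivities above all) that density data cannot identify;
  different published fits of the same printed parameters are
  therefore not exactly reproducible from those parameters alone.
* At high data noise the trivial Harris–Wilson solution dominates the
  weighted marginal through transit mass near (1, 0) rather than
  through converged endpoints; with very few initializations the α
  marginal can stay ragged.
* The network's shared hidden layer couples the output coordinates:
  shallow, narrow basins of the potential (the trivial solution under
  noiseless data) can be crossed during the initial adjustment of the
  better-identified coordinates and then appear only as transit mass,
  not as endpoint clusters.
* Learning graph adjacency matrices, Itô-convention noise, and
  real-world (measured) cost networks are out of scope.
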