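# Methods

`nichesync` simulates niche construction as reciprocal free-energy
minimization between two active-inference agents — synthetic songbirds —
coupled only through the songs they exchange. This note documents the
model, the numerics, and the design choices, in enough detail to
reproduce or modify any of them.

## The generative model

Each bird entertains the same two-level hierarchical dynamic model of
birdsong:

- **Top level ("area X")** — a Lorenz system `x⁽²⁾ = (x, y, z)` with
  σ = 10, β = 8/3, ρ = 28 and time constant τ₂ = 2 s. Its output cause
  is a linear read-out of the second state, `v = 0.32 · y⁽²⁾`, giving
  `v ∈ ±8` over the attractor.
- **Song level ("HVC")** — a faster Lorenz system `x⁽¹⁾` with σ = 10,
  β = 8/3, τ₁ = 0.25 s, whose Rayleigh number is modulated by the
  descending cause around a learnable baseline:
  `ρ₁(t) = ρ_base + v(t)`, prior mean ρ_base = 24.
- **Sonogram map** — the song level is voiced as two channels:
  amplitude `a = softplus(0.3 · y⁽¹⁾)` (a.u.) and frequency
  `f = 3500 + 1500 · tanh(60 (z⁽¹⁾ − 24) / 1500)` Hz. The tanh keeps
  the frequency strictly inside the songbird band (2–5 kHz) while
  preserving gradients everywhere; a hard clip would zero the sensory
  gradient whenever the channel saturates and stall inference.

The learnable **order parameter** θ = ρ_base is the bird's "trait": it
sets the chaotic structure of the song. Each agent holds a Gaussian
belief over θ (mean and log-precision), with the prior exposed in the
experiment configuration.

All densities are Gaussian with diagonal, log-parametrized precisions.
The spec-level log-precisions are γ_z = 4 (sonogram), γ_w = 8 (hidden
states), γ_v = 6 (cause read-out), applied per characteristic channel
scale (amplitude 0.5 a.u., frequency 150 Hz, states 10 units, cause
2 units): Π = exp(γ)/scale². Causes additionally carry a zero-mean
shrinkage prior with log-precision γ_vp (−6 in the duet; see
*Precision contexts* below).

## Generalized coordinates and units

States and sensory channels carry derivatives to order 4, causes to
order 2. Nonlinear maps are closed at first order: derivative orders
propagate through the base-point Jacobian. Because the shift of the top
embedded order is identically zero under truncation, flow errors are
defined on orders 0..n−1; with this closure, a state generated by the
model's own flow observing its own output has exactly zero prediction
error — the self-consistency invariant the tests check.

Internally all generalized coordinates are carried in **sample-time
units** (one tick = dt = 1/256 s is one time unit; time constants and
the noise smoothness rescale by 1/dt). In absolute seconds the k-th
derivative of the fast Lorenz grows as ‖J‖ᵏ ≈ 60ᵏ, which makes the
filter both ill-conditioned and unstable; in tick units ‖J‖·dt ≈ 0.2
and derivative magnitudes decay with order. This is a pure units
change — the public model parameters remain in seconds.

Precisions across derivative orders follow the smoothness profile for
noise with Gaussian autocorrelation of width s: the precision of order
k scales as s²ᵏ/(2k−1)!!, with s = 1/128 s (2 ticks). Listening noise
is generated as exactly such a smoothed process, by convolving white
noise with a Gaussian kernel and its derivatives, so the generalized
sensory signal is self-consistent at every order.

## Perception

Expectations μ̃ follow the gradient flow μ̇ = Dμ − κ ∂F/∂μ (κ = 0.5)
where D is the shift operator and F the Laplace free energy, with the
fixed-form posterior covariance held constant (its entropy is treated
as the constant zero, so F = energy − entropy and
F = complexity − accuracy hold by construction; on the static
linear-Gaussian fixture every decomposition term, including the KL
divergence and the log-evidence, is computed from its own closed form).

The integrator is local linearization: one step is
μ ← μ + φ₁(J·dt)·dt·flow(μ), with J = D − κH. Numerical details that
matter:

- **Gradients** are central finite differences of the fused, vectorized
  energy (a single batched evaluation per tick; perturbation 1e-5 of
  each coordinate's scale).
- **Curvature H** is a batched finite-difference Hessian, refreshed
  every 8 ticks and whenever the sensory gain changes. (An analytic
  Gauss–Newton curvature was tried and rejected: it underestimates the
  Lorenz bilinear curvature ~3×, and the exponential-integrator step
  then over-relaxes and diverges.)
- **φ₁ via augmented exponential.** J is nilpotent-dominated and often
  numerically singular; forming J⁻¹(e^{J dt} − I) by a linear solve
  produces garbage steps. φ₁ is instead read off the exponential of the
  block matrix [[J, I], [0, 0]]·dt, which needs no inverse.
- **Backtracking guard.** Local linearization can overshoot the Lorenz
  nonlinearity when errors are large (initial transients, role
  switches). If the full step would raise F by more than 25 nats (an
  absolute margin, invariant to the arbitrary log-determinant constant),
  the corrective part of the step is geometrically damped toward the
  pure prediction step μ + φ₁(D)·D μ, which is always bounded.

## Action and the blanket

Action is the voicing of predictions: the singer emits the sonogram
sample its current song-level expectations predict, carried with its
temporal derivatives (the generalized sample) — this is the only
cross-agent data path, which `audit_blanket` verifies by replaying each
agent in isolation against the recorded blanket states and requiring a
bit-identical trajectory. Relabeling the two agents (with their random
substreams) mirrors the system exactly.

Epochs alternate strictly (2 s sing, 2 s listen). The singer hears
itself noiselessly at full precision — self-audition closes the
action–perception loop that sustains the chaotic song (without it the
filter relaxes onto the Lorenz fixed point). The listener hears the
emission plus smoothed Gaussian noise. In the uncoupled ("singing
alone") condition the listener receives the zero-amplitude sample with
sensory precision attenuated by e⁻⁶: attention withdrawn from an
inaudible partner, so each bird free-runs its own chaotic model instead
of being dragged onto a silent manifold.

Initial expectations are a shared uniform draw on [−8, 8]³ per level
plus a per-agent N(0, 0.1) perturbation, seeded self-consistently with
each agent's flow. Nearby starts are what makes "divergence through
sensitivity to initial conditions" measurable in the uncoupled
condition; independent draws would start the birds at chaos-saturated
distance.

## Learning

Learning is a slow flow on the free energy of the whole epoch — a path
integral, not a per-tick quantity. The per-tick partial ∂F/∂θ is blind
to how the filtered path depends on θ (state inference absorbs
parameter misfits into unobserved states) and it counts the θ-prior
term once per tick. The epoch update therefore:

1. re-filters the epoch's own sensory record at θ ± 2 (the probe is
   fixed at the scale of plausible trait differences; chaotic
   path-to-path variability drowns smaller probes) and differences the
   mean free energies — the profile gradient and curvature;
2. counts the prior once and the data once per tick, gated by the
   epoch's mean sensory gain (attention gates evidence; attenuated
   silence teaches nothing);
3. accrues the positive part of the data curvature into the posterior
   precision (credible intervals never widen), and takes the
   natural-gradient step on prior + data, clipped to the probe's trust
   region.

Singing epochs are excluded: the data were generated by the very
parameter under inference, and this circular self-evidence measurably
anchors θ in place. Agents whose posterior precision exceeds 10³ skip
the replays (their steps are numerically negligible) and fall back to
the per-tick trace — a pure runtime optimization.

## Precision contexts

Two findings shaped the experiment defaults:

- **Level-2 synchrony needs free causes.** With the cause prior weak
  (γ_vp = −6), the listener's top level tracks the singer's through the
  inferred cause, and coupled duets reach identical synchrony.
- **Trait learning needs anchored causes.** With free causes the birds
  converge *behaviourally*: each absorbs the partner's ρ₁ into its
  cause estimate (effective sung ρ₁ values meet in the middle within a
  couple of epochs) and the free energy becomes flat in θ — niche
  states substitute for trait learning. The learning and inheritance
  experiments therefore run with the cause prior anchored (γ_vp = 2)
  for both birds, the precision context in which the trait, not the
  fast states, carries the exchanged information.

This precision-dependence is itself a finding the package exposes:
whether "construction" happens in fast environmental states or in slow
heritable parameters is controlled by the relative precisions.

## Experiments and study conditions

- **Duet** (`nichesync duet`): 8 × 2 s epochs, both birds with
  identical models and precise trait beliefs. Synchrony is scored on
  the second-level expectations: normalized RMS distance from the
  diagonal (identical synchrony) and the R² of the optimal affine map
  from one bird's expectations and their first derivatives to the
  other's (generalized synchrony), headline values on the final quarter
  of ticks. Complementarity is the summed free-energy trace (free
  energies are extensive), lower = more attuned.
- **Precision asymmetry** (`nichesync learning`): teacher prior
  (θ = 24, log-precision 8) vs learner (θ = 30, log-precision 0), with
  the uncoupled control. The learner's θ descends to the teacher's
  value epoch by epoch while its 90% credible interval narrows; the
  teacher barely moves; uncoupled, the gap persists.
- **Niche inheritance** (`nichesync inheritance`): agent B is the
  niche. Across 10 trials of 4 epochs, each trial's organism is drawn
  fresh with a precise trait (θ = 28); the niche's posterior over θ
  becomes its *prior* for the next trial (ecological inheritance: the
  constructed state is what the next organism encounters), and it
  learns slowly (learning scale 0.25, which shrinks the trust region).
  The niche starts at θ = 32 with log-precision 2 — a partially formed
  niche approached from within the chaotic regime (paths through
  ρ₁ ≈ 25 cross the Lorenz chaos boundary and make joint F
  non-monotone in θ). Trial-mean joint free energy then declines
  monotonically (3-seed ensemble mean) as the niche attunes; freezing
  the niche (scale 0) abolishes the trend; doubling the niche's sensory
  precision ("salience") yields lower joint F throughout paired runs.

## What the simulations do and do not show

All inputs are self-generated: the "environment" is another agent with
the same model class, noise is stationary Gaussian, and the only
heritable quantity is a single scalar trait. Passing tests show that
the mechanics — evidence-bound oracles, generalized synchrony through a
shared blanket, precision-asymmetric trait transmission, inheritance of
a constructed prior — behave as the theory prescribes in this minimal
setting. They do not show anything about real acoustic communication,
about model mismatch between organism and niche, or about selection;
the song map is not a syrinx model and the "niche" has no physical
substrate.

Known limitations: sensitivity to initial conditions in the two-level
generator lives mostly in the slow driver (the song level is slaved to
it), so 1e-6 perturbations take tens of seconds to reach unit distance
through the hierarchy — the chaos tests therefore probe the song level
at a verified chaotic operating point. Identifiability of the trait is
intermittent (the profile is locally bumpy at sub-unit scales), which
is why learning uses wide probes and trust-region steps. The
backtracking guard makes perception robust but means the realized flow
is not exactly the nominal gradient flow during violent transients.

## Problem sizes

Default runs used throughout the tests and the acceptance script:
dt = 1/256 s; duets 8 × 2 s epochs (4096 ticks, two agents); synchrony
contrast over 10 seed-paired duets; learning over one seed with both
controls; inheritance over 10 trials × 4 epochs, 3-seed ensembles for
the learning and frozen conditions.
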