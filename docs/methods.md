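# Methods

This note documents the models implemented in `semitdp`, the parameter
choices that matter, the numerical decisions taken where the design was
genuinely open, and what the synthetic fixtures do and do not establish.

## Logical voter ensemble

Voters are pre-trained stochastic classifiers abstracted as per-sample
firing-probability tables (each row a probability vector over the N_C output
neurons); they model the posterior of a trained classifier, and the package
deliberately does not learn them.  Learning acts only on the ensemble→final
weights through the pulse-ITDP rule with shift constant `a = e^5` and
learning rate `η = 0.001`.  The closed-form equilibrium and final-voter
output probabilities assume (i) voters independent given the sample,
(ii) uniform sample presentation, and (iii) a unit-impulse EPSP kernel in
the final voter (only same-tick spikes integrate).

Numerical choices:

* **Initial weights** start at `log(a)/2`; the equilibrium is independent of
  initialisation but trajectories are not, and a mid-range start keeps the
  early depression branch from dominating plots.  A seeded random option
  exists.
* **Divergent equilibria.**  When a (neuron, gate) pair never co-fires the
  equilibrium is −∞; such weights are clipped at a floor of −50 and flagged,
  keeping downstream softmaxes well defined.
* **State enumeration** of the N_C^{N_E} ensemble states is capped at 10^6
  states; beyond the cap the solver raises and the caller must reduce the
  ensemble or estimate by simulation.
* **Presentation schedule.**  Step t presents class `(t−1) mod N_C` and the
  `((t−1) div N_C)`-th sample of that class, wrapping within the class —
  the schedule any finite dataset must cycle.
* All randomness flows through one master generator per run, with one
  derived substream per voter.

## SEM circuit

A winner-take-all circuit of K Poisson neurons with membrane

    u_k(t) = w_k0 + Σ_i w_ki y_i(t) + I(t) + v(t).

The inhibition term is additive and doubly functional: immediately after any
circuit spike it is −A_inh = −3000 (refractory pulse), relaxing with
τ_inh = 5 ms to the resting offset O_inh = −550, which acts as a firing
threshold sized to the typical weighted-evidence sum of a circuit with a few
hundred afferent pixels.  Circuits with far fewer afferents (the final WTA)
get the inhibition shift I_s = 560 − 4·N_E applied as A_inh − I_s,
O_inh + I_s.  With the default geometry this produces the regular burst of
roughly 3–4 spikes per 40 ms presentation that paces all plasticity.

**Firing semantics.**  The circuit as a whole is one inhomogeneous Poisson
process with rate R(t) = Σ_k e^{u_k}; per step of dt = 1 ms it emits at most
one spike with probability 1 − e^{−R·dt}, capped at 0.95, and the spike is
attributed to neuron k with softmax probability q_k = e^{u_k}/R (the
posterior over hidden causes).  This circuit-level sampling is used instead
of independent per-neuron Bernoulli draws because the membrane routinely
sits far above exp-scale: per-neuron draws then all saturate at the cap,
every neuron fires in lockstep and no competition (hence no learning) is
possible, while posterior sampling preserves soft competition at any drive
level and is equivalent in the dt → 0 limit.

**Plasticity.**  All rules are trigger-gated and share the inverse-
exponential potentiation bound `c = e^5`:

* STDP (post-spike triggered, per synapse): `Δw = y_i·c·e^{−w} − 1`,
  fixed point `w* = log(c·y)`.
* Excitability (circuit-spike triggered, all K neurons):
  `Δw_k0 = z_k·e^{−w_k0} − 1`; stationarity gives `w_k0 = log q_k`, so
  converged excitabilities form a prior (Σ e^{w_k0} = 1).
* Variance tracking (per variable): `η ← μ(m2 − m1²)/(1 + e^{−m1})` with
  μ = 0.01, then the moments relax toward the current value at rate η.
  The weight update uses the pre-update η; moments use the recomputed one.
  States start at m1 = w, m2 = w² + 1, η = μ (unit presumed variance, so
  learning starts at the global rate and anneals as the variable settles).

**Initial weights.**  Input (STDP) weights start uniform in [4.5, 5], i.e.
at the potentiation ceiling log c.  This is a deliberate design choice with
two consequences: circuits fire from the very first presentation (STDP is
post-spike-triggered — a silent circuit can never start learning against the
fixed inhibition offset), and unconverged neurons act as novelty detectors —
a neuron that has converged to one class's statistics wins that class but
loses novel classes to still-fresh neurons, which is what recruits one
neuron per hidden class.  Initialisations below the converged weight level
were found to deadlock (no circuit ever fires) or collapse (one neuron wins
every class).  Excitabilities start uniform in [−log K ± 0.5].

**Background noise.**  The optional Ornstein–Uhlenbeck perturbation uses a
20 ms mean-reversion time and 0.5 stationary standard deviation — a mild
decorrelating perturbation.  All acceptance checks run with it disabled;
enabling it changes no qualitative behaviour.

## ITDP layer

Ensemble→final synapses update whenever either presynaptic pathway spikes:
`Δw = h·c·e^{−w} − 1`, where h sums the Gaussian pairing factor
`g(Δt) = e^{−Δt²/2σ²}` (σ² = 1.5×10⁻⁴ s²) over (distal, proximal) spike
pairs.  The biological −20 ms pairing peak is absorbed into an assumed
conduction delay, so the curve peaks at zero lag.  Distal (gating) spikes
gate plasticity only; they never enter the final membrane.

Bookkeeping decisions:

* **Pairing window**: spike buffers keep 5σ ≈ 61 ms of history; discarded
  pairs contribute < e^{−12.5}.
* **Pair counting**: all spikes of a timestep are buffered before the
  step's triggers are processed, and each trigger pairs only against the
  opposite pathway's buffer.  A pair spanning two steps therefore enters h
  exactly once (at its later spike), while a same-step coincident pair is
  visible to both of its triggers — which is precisely what makes
  persistent perfect coincidence satisfy h = 1 per trigger and converge to
  log c, the same fixed point as the logical rule's co-firing branch.
* A distal spike also updates proximal synapses whose buffers are empty
  (depression branch, h = 0), matching the "update on either pathway's
  spike" contract.

## Input pipeline

Binarization at intensity > 200 (of 255); pixels ON in **less than 3%** of
images are disabled (a pixel at exactly 3% is retained — strict reading of
"less than"); 2× supersampling replicates each pixel into a 2×2 block so
that quarter-feature members and the full-feature gating circuit receive
equally many input neurons.  Each surviving pixel is an exclusive ON/OFF
neuron pair; the eligible neuron fires 40 Hz Poisson during the 40 ms
presentation and nothing fires during the 40 ms rest.  Feature selection
draws ⌊|active|/4⌋ distinct pixels per member (sequential weighted draw
without replacement, renormalising after each draw): uniformly at random;
from 2-D normal Gaussians (σ² = 49) whose means are jittered from an even
initial layout under the tabulated (ε, δ) accept constraints, with a
3-pixel forbidden band inside the active region's border; or from stretched
Gaussians (σ_x² = 4, σ_y² = 625) rotating by π/N_E per member.  Member
subsets may overlap; no cross-member de-duplication is performed.
Coordinates are 0-based (row, col) on the supersampled grid.

## Metrics

NCE uses natural logs (the ratio is base-invariant); diversity uses base
N_C as its definition requires, making full agreement 0 and uniform
disagreement 1.  The windowed NCE at time t counts spikes in [T_p, t] with
T_p = t(1 − d/4D), d = min(t, 2D), D = one round's duration — early windows
shed the immature initial output faster, and from t = 2D the window is the
latest half of the run.  Degenerate windows (no spikes, or a single
occupied joint cell) report NaN rather than 0 so burn-in gaps are visible.
Per-presentation winners are the neurons with most spikes in the window;
ties break by earliest last spike, then lowest index.  Test error assigns
each final neuron to the class it fired most for during training; wins by
unassigned (never-firing) neurons count as errors.

The 0 ≤ NCE ≤ 0.5 chance bound holds on the operating family of joint
distributions — uniform class marginal (balanced round-robin presentation)
and uniform firing marginal (exchangeable WTA neurons).  Outside that
family NCE can exceed 0.5 (a constant-firing voter under uniform classes
approaches 1); the bound sweep and the headline supremum therefore sample
marginal-balanced random joints.

## Synthetic fixtures

`make_digits` emulates a small binarized handwritten-digit task: four
distinct stroke prototypes (vertical bar, ring, diagonal, angle) corrupted
by independent pixel flips at rate 0.08 by default.  The flip rate was
chosen once so that quarter-feature SEM members show the heterogeneous,
imperfect performance (windowed NCE roughly 0 – 0.25, with occasional EM
local-optimum trapping) that makes ensemble combination meaningful.  The
fixture reproduces class structure, per-class variability and spatial
locality of evidence; it does **not** reproduce the style variability of
real handwriting, so passing results bound what the architecture does on
well-separated noisy classes, not its error rate on real digit data.
`make_voters` builds logical-model tables whose per-class probability mass
(`discriminability`, from chance 1/N_C to 1) maps monotonically onto NCE.

## Problem sizes used in the automated checks

The analytic-consistency check runs 5×10⁵ learning steps on an N_E = 3,
N_C = 4 instance; output-probability consistency enumerates N_S = 256
states against 4,000 measuring steps per class.  The ensemble-benefit check
trains N_E = 5 with supervised gating (three distal spikes per
presentation, 15 ms apart, first at +5 ms) on 4 × 100 images for 2 rounds,
over 10 seeds, on a 16×16 canvas (supersampled 32×32, ~230 active pixels
per circuit — the regime the fixed inhibition offset is sized for), with
background noise off; it then compares the median final-WTA NCE against the
median ensemble-average NCE.  One seed simulates 64 s of biological time in
roughly 8 s.

## Known limitations

* dt = 1 ms quantises spike timing; the ITDP Gaussian (σ ≈ 12 ms) is wide
  relative to dt, so timing quantisation is benign, but sub-millisecond
  STDP effects are not represented.
* The EPSP traces use two per-neuron exponential accumulators,
  mathematically identical to summing the kernel over spikes but immune to
  history scans.
* Membrane potentials are clamped at +500 before exponentiation (counted
  per circuit); the clamp only engages under pathological parameterisation.
* The automatic gating selection ranks circuits by running windowed NCE at
  a fixed cadence (every 50 presentations) during the first round only;
  the original procedure's manual repeat-and-pick search is replaced by
  seed sweeps.
* Evolutionary feature-subset search, per-member distinct datasets,
  Mexican-hat inhibition and multi-module ITDP chaining are out of scope.
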