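# semitdp

Unsupervised ensemble learning in spiking neural networks, coordinated by
**input-timing-dependent plasticity (ITDP)** — a heterosynaptic rule in which
the pairing of two presynaptic pathways (a proximal classifier pathway and a
distal gating pathway) strengthens the proximal synapse onto a shared target
neuron.

The package is for computational neuroscientists and machine-learning
researchers studying how a mixture-of-experts-style architecture can be
realised with biologically plausible spiking circuits: a population of
**spiking expectation-maximization (SEM)** winner-take-all classifiers learns
hidden input classes by STDP, and a gating network's distal projections let
ITDP learn the weighted combination of their votes — all without labels.

## The model

Two levels of abstraction of the same architecture are implemented and
cross-validated against each other.

**Logical voter ensemble** (`semitdp.logical`).  Discrete-time voters fire
one of N_C neurons per tick from per-sample probability tables.  The weight
from ensemble neuron m to a final voter neuron, gated by gating neuron g,
follows the pulse-ITDP rule

    Δw = a·e^{−w} − 1   if m and g co-fire
    Δw = −1             if exactly one fires
    Δw = 0              otherwise,

whose equilibrium is closed-form: `w* = log a + log[p(m)p(g) / (p(m)+p(g)−p(m)p(g))]`,
and for a whole ensemble `w*_k^{ij} = log a − log[Σ_l(p_m+p_g)/Σ_l p_m p_g − 1]`.
The expected final-voter firing probabilities follow by enumerating all
N_C^{N_E} ensemble firing states.  The stochastic simulation of the same
system converges to these solutions (this is one of the acceptance checks).

**Spiking SEM ensemble** (`semitdp.sem`, `.itdp`, `.runner`).  Each circuit
holds K Poisson neurons with membrane `u_k = w_k0 + Σ_i w_ki y_i + I(t) + v(t)`
(double-exponential EPSPs `y_i`, a shared inhibition pulse `I(t)` enforcing
soft competition and refractoriness, optional Ornstein–Uhlenbeck background
`v(t)`).  A circuit spike samples the softmax posterior over hidden causes;
STDP (`Δw = y·c·e^{−w} − 1`) and spike-triggered excitability plasticity
implement stochastic online EM, with per-variable variance-tracking learning
rates.  Ensemble outputs reach the final WTA through ITDP synapses driven by
the Gaussian spike-pairing curve `g(Δt) = e^{−Δt²/2σ²}`; the gating circuit's
distal spikes enable that plasticity but contribute nothing to the final
membrane.  Images are binarized, occupancy-filtered, supersampled and encoded
by ON/OFF Poisson input pairs; ensemble members receive a quarter of the
pixels each by random, normal-Gaussian or stretched-Gaussian feature
selection.  Performance is measured by normalized conditional entropy
NCE = H(C|F)/H(C,F) (0 = perfect class-exclusive firing, 0.5 = chance) and an
entropy-based ensemble diversity.

## Worked example

Train a five-member spiking ensemble with supervised gating on the built-in
synthetic digit task (four stroke-prototype classes with pixel-flip noise),
then test on unseen samples:

```
$ semitdp test --per-class 40 --rounds 2 --seed 1 --test-per-class 15
training NCE (windowed, t=25.6s):
  member_0     0.1136
  member_1     0.0824
  member_2     0.0870
  member_3     0.2223
  member_4     0.1493
  final        -0.0000
  ensemble avg 0.1309
test error rate (final WTA): 0.000
```

Each `member_j` line is the windowed NCE of one ensemble SEM classifier
(imperfect: between 0.08 and 0.22 here — members see only a quarter of the
pixels and some get trapped in EM local optima).  The ITDP-combined final
WTA reaches NCE 0.000: the weighted vote corrects the members' mistakes.
With frozen weights the trained system classifies unseen noisy samples with
0% error on this easy fixture.

The same comparison with a *learned* (unsupervised) gating circuit and a
parallel STDP-combined final layer:

```
$ semitdp compare-stdp --per-class 30 --rounds 2 --seed 5 --gating unsupervised
  ...
  final        0.1476
  final_stdp   0.4936
  gating       0.2457
  ensemble avg 0.2384
```

— given a moderately performing gating network (NCE 0.25), the ITDP final
layer (0.15) beats both the ensemble average (0.24) and the STDP-only
alternative (0.49).

The closed-form logical model is available through `semitdp analytic` and its
stochastic validation through `semitdp validate`.

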