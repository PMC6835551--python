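# Methods

## Encoding race

All models assume exponentially distributed encoding latencies: stimulus
*x* with rate v_x is encoded by time *t* after onset with probability
1 − e^(−v_x t). The probability that the probe is encoded before the
reference decomposes, at negative SOA (probe first), into the probability
that the probe finishes before the reference even appears plus the Luce
ratio v_p/(v_p+v_r) for the remaining mass; at non-negative SOA only the
discounted Luce term survives. SOA = 0 is assigned to the non-negative
branch; both branches agree there, so the choice is inert. The same
function arises as the CDF of the bilateral-exponential arrival-time
difference, so one implementation serves both the TVA-style (v_p, v_r) and
the λ-style parameter vocabularies.

Rates are stored internally in events/ms so SOAs remain in milliseconds;
reported rates in Hz are exactly 1000× the internal value, converted only
at the I/O boundary. Fitting bounds the rates to [1e−4, 1] events/ms
(0.1–1000 Hz), a wide margin around the 15–131 Hz range plausible for
human observers.

## Indecision-range model

The binary response probability is assembled from three percept classes:
"probe first" iff the probe's arrival leads the reference's by more than δ
ms (the race evaluated at SOA+τ+δ), "reference first" symmetrically
(1 minus the race at SOA+τ−δ), and "simultaneous" for the remainder.
A forced binary response resolves simultaneity percepts to "probe first"
with probability 1 − ξ:

    P("probe first") = P_p1st(SOA+τ+δ) + (1−ξ)·[P_p1st(SOA+τ−δ) − P_p1st(SOA+τ+δ)]

This construction keeps the three percept probabilities a proper
distribution, reduces exactly to the bare race at δ = 0 (where ξ is inert),
puts the plateau at 0.5 for equal rates with neutral ξ = 0.5, and moves the
plateau linearly in ξ independent of the rates — the behaviors that define
the model. δ ≥ 0 and ξ ∈ [0, 1] are enforced; τ is an unconstrained-sign
shift of the SOA axis.

## Encoding-reset model

The reset threshold t₀ (the maximum ineffective exposure duration) varies
trial-by-trial as Normal(t₀, s₀) *without truncation*: a negative draw
simply means the reset never triggers on that trial. A reset occurs iff
|SOA+τ| ≤ t₀_trial, after which both stimuli race from a common start and
the probe wins with the Luce ratio. Marginalizing the normal draw gives the
closed form with mixture weight Φ((SOA+τ+t₀)/s₀) on the early branch and
1 − Φ((SOA+τ−t₀)/s₀) on the late branch. The per-trial simulator implements
exactly these semantics, so it reproduces the untruncated Φ. Where the
common start sits in time affects only latencies, never response
probabilities, so the simulator restarts at the second onset.

s₀ = 0 is handled as the pointwise step-function limit (indicator of
|SOA+τ| ≤ t₀, boundary assigned to "reset"); z-scores that overflow for
subnormal s₀ are mapped through the normal CDF's correct 0/1 limits. At
SOA+τ = 0 both mixture components equal the Luce ratio, making the curve
continuous there with plateau height v_p/(v_p+v_r) — which is why a
vertically displaced plateau requires unequal rates in this model, in
contrast to the indecision model's ξ.

## Synthetic designs

Presets emulate two study layouts. `exp1`: 21 SOAs from −100 to 100 ms in
10 ms steps, 240 repetitions each, 5040 trials — the precision needed for
a plateau spanning only a few SOA steps to be distinguishable from noise.
`exp2_neutral`/`exp2_cued`: the same grid, respectively a grid shifted to
−40…160 ms (the cued probe is perceived earlier, so the curve shifts
right), with the uneven repetition schedule (8, 10, …, 28, …, 12, 8) that
concentrates trials at the informative central SOAs. The printed schedule
has 19 entries for 21 SOAs; the default aligns it to the central 19 and
pads both extremes with the schedule minimum (8), a documented convention
rather than an inference — any schedule can be passed explicitly. The
140 ms cue-to-probe interval is carried as design metadata only: the cue's
effect enters the models solely through τ and rate differences.

Binomial sampling and all simulators draw from one seedable generator per
call; no global random state. Identical seeds give bit-identical data.

What the generator emulates — and does not: it produces ideal binomial
observers of the stated models. Real data add session/block structure,
lapses and key errors (deliberately not modeled: the fitted configurations
omit error parameters), learning and fatigue drifts, and between-participant
heterogeneity. Passing recovery tests therefore show that the pipeline is
correct and that the study scale is informative in principle, not that real
observers satisfy the models.

## Fitting

The likelihood is binomial at the SOA level, with model probabilities
clipped to [1e−9, 1 − 1e−9] in place of lapse parameters. Optimization is
bounded Nelder–Mead (derivative-free, since the curves are smooth but have
branch kinks at SOA+τ = 0 and ±t₀) from `n_starts = 10` Latin-hypercube
starting points, seeded. The optimizer works on the unit cube over the
bounds, with rates mapped on a log10 scale — their bounds span four decades
while plausible values occupy a narrow band, and log spacing makes starts
land usefully. Default bounds: rates [1e−4, 1] events/ms, δ and t₀
[0, 200] ms, s₀ [0, 100] ms, ξ [0, 1], τ [−200, 200] ms.

`fit_model` defaults to freezing τ = 0, the equal-complexity configuration
for basic (uncued) studies: four free parameters for either plateau model,
two for the bare race. Any parameter can be frozen the same way (e.g.
ξ = 0.5). Data with every count at 0 or at n are rejected as degenerate.
BIC uses n = total trials, not the number of SOA levels. Ties in the
multi-start pool resolve to the lowest objective; ties in model comparison
resolve to the fit listed first.

## Model comparison and recovery

ΔBIC is labeled inconclusive below 2, positive from 2 to 10, and strong at
10 and above; only the ≥ 10 rule is the anchored convention, the lower
bands follow the standard Kass–Raftery-style reading. The recovery harness
samples data from a known model, refits the generating class and the bare
race, and reports per-parameter median absolute errors and the fraction of
replicates in which BIC prefers the generating class. Discrimination
*between* the two plateau models is reported but never asserted — their
curves are too similar for BIC to separate reliably at this scale.

At the 5040-trial design, the reset mechanism at (60/40 Hz, t₀ = 15 ms,
s₀ = 18 ms) is detected against the bare race essentially always (measured
100/100 replicates, mean ΔBIC ≈ 38). The equal-rate indecision point
(50/50 Hz, δ = 20 ms, ξ = 0.5) is intrinsically marginal: the expected
log-likelihood advantage over the best simple race is ≈ 12.6 nats, so the
expected ΔBIC after the 2·ln(5040) ≈ 17.05 complexity penalty is only ≈ +10
with an SD of the same size, and the bare race wins in roughly one
replicate in five (measured 80/100 preference). This is a property of the
statistical problem — a 20 ms symmetric plateau at these rates carries
limited information against a 17-point penalty — and not of the optimizer,
whose fitted likelihoods exceed the generating parameters' likelihood in
every replicate. Detecting such plateaus reliably needs either sharper
plateaus, unequal rates, or more trials.

## Problem sizes

The test suite exercises the Monte-Carlo oracles at 10⁵ trials per SOA on
the 21-point grid and the recovery studies at 20 replicates of the full
5040-trial design; both settings were chosen as the package's standard
desk-scale configuration and complete in well under a minute each on a
single core.

## Known limitations

- Binary responses only: no ternary (explicit "simultaneous") response
  fitting, no response times.
- No lapse/error parameters, by design; grossly contaminated data will
  bias the rates instead.
- No standard errors or posterior uncertainty on estimates; the recovery
  harness is the intended way to gauge estimator spread.
- τ as a pure axis shift is a simplification for cued conditions; explicit
  cue-processing models are out of scope.
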