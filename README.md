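# tojrace

Model-based analysis of plateaus in visual temporal-order judgments (TOJs).

In a TOJ task, two targets — a *probe* and a *reference* — appear separated
by a stimulus onset asynchrony (SOA; negative SOA = probe first), and the
observer reports which came first. The proportion of "probe first" responses
over SOA normally traces an S-shaped psychometric function, but with densely
spaced SOAs and many repetitions a flat central *plateau* emerges around the
point of subjective simultaneity. `tojrace` implements and compares the two
process models that can generate such plateaus, for researchers in visual
attention and psychophysics who want to fit them to judgment-count data or
probe their distinguishability by simulation.

## The models

All three models share an exponential encoding race: stimulus *x* is encoded
by time *t* after its onset with probability 1 − e^(−v_x t). The probability
that the probe is encoded first is

    P_p1st(v_p, v_r, SOA) = 1 − e^(−v_p |SOA|) · v_r/(v_p+v_r)   (SOA < 0)
    P_p1st(v_p, v_r, SOA) =     e^(−v_r |SOA|) · v_p/(v_p+v_r)   (SOA ≥ 0)

with v_p/(v_p+v_r) the Luce ratio of a simultaneous race. On top of this:

- **simple** — the bare race (no plateau); free parameters v_p, v_r
  (reported in Hz), optionally a net delay τ.
- **indecision** — arrival-time differences smaller than a half-width δ
  cannot be ordered; the resulting "simultaneous" percepts are resolved to
  "probe first" with probability 1 − ξ. The response probability is
  P_p1st(SOA+τ+δ) + (1−ξ)·[P_p1st(SOA+τ−δ) − P_p1st(SOA+τ+δ)]: a
  post-encoding, decision-level plateau whose height moves with ξ.
- **reset** — if the second onset falls within t₀ ms of the first (t₀ varying
  trial-by-trial with SD s₀), encoding restarts from a common origin and the
  probe wins with the Luce ratio: w·v_p/(v_p+v_r) + (1−w)·P_p1st(SOA+τ), where
  the mixture weight w is Φ((SOA+τ+t₀)/s₀) for SOA+τ ≤ 0 and
  1 − Φ((SOA+τ−t₀)/s₀) otherwise. A pre-encoding plateau with a fully
  deterministic decision rule; its height can leave 0.5 only via v_p ≠ v_r.

The simple race is nested in both plateau models (δ = 0, respectively t₀ = 0,
s₀ → 0). Models are fitted by binomial maximum likelihood (bounded multi-start
Nelder–Mead) and compared by BIC = k·ln(n) − 2·logL with n the total trial
count; BIC differences ≥ 10 are read as strong evidence.

## Worked example

`examples/simulate_fit_compare.py` samples a dense synthetic study (21 SOAs
from −100 to 100 ms, 240 repetitions each, 5040 trials) from the reset model
at v_p = 60 Hz, v_r = 40 Hz, t₀ = 15 ms, s₀ = 18 ms, then fits all three
models with τ frozen at 0 and ranks them:

```
simple      loglik=-1523.023  BIC= 3063.097  {'vp_hz': 43.93, 'vr_hz': 33.467}
indecision  loglik=-1491.839  BIC= 3017.779  {'vp_hz': 63.57, 'vr_hz': 49.273, 'delta': 23.894, 'xi': 0.442}
reset       loglik=-1489.113  BIC= 3012.327  {'vp_hz': 54.458, 'vr_hz': 39.592, 't0': 17.285, 's0': 14.639}

model                 BIC       dBIC
reset            3012.327      0.000 *
indecision       3017.779      5.452
simple           3063.097     50.770
```

The generating parameters are recovered to within a few Hz and ms, and the
bare race is rejected by ΔBIC ≈ 51 — note how it compensates for the missing
plateau by underestimating both rates. The gap between the two plateau
models themselves is small (5.5): their curves are similar, and telling them
apart is the hard part of the scientific problem. `examples/plateau_curves.py`
prints the three curves side by side, and `examples/parameter_recovery.py`
runs a seeded recovery study.

The same pipeline is scriptable from the shell:

```sh
tojrace simulate --config sim.yaml --seed 1 -o data.csv
tojrace fit data.csv --model simple --model indecision --model reset -o fits.json
tojrace compare fits.json -o comparison.json
tojrace recover --config recover.yaml --seed 1 -o recovery.json
```

Judgment data are plain CSV with columns
`participant,condition,soa_ms,n_trials,n_probe_first`; every output artifact
embeds its resolved configuration and seed.

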