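# Methods

This note documents the statistical model behind `vbgnsum`, the synthetic
data-generating process used by the simulation framework, the defaults and
why they were chosen, and the known limitations. Nothing here reports an
empirical number that the test suite or `scripts/acceptance.py` does not
itself compute.

## 1. Estimand and estimator

The estimand is `N_K`, the number of key population members, all of whom
are assumed to attend the venues on the sampling frame (every key member
has a nonzero venue-attendance probability). The estimator is a ratio of
two survey quantities tied together by the bookkeeping identity that ties
counted from the sender side must equal ties counted from the receiver
side. With `y_i` the out-report of non-key frame member `i` (venue-attending
key acquaintances) and `v_j` the visibility of key member `j`
(venue-attending non-key acquaintances who know `j`):

```
Σ_{i∈F∖K} y_i = Σ_{j∈K} v_j      ⟹      N_K = Σ y_i / v̄ .
```

Both sums run over ties between `F∖K` and `K`, which is why the denominator
uses the *non-key* acquaintances of key respondents (`q1 − q2` in the
survey instrument) and the numerator uses only non-key respondents'
out-reports (`q2`). Keeping both sides of the ratio on the same tie set is
what makes the census identity exact; the package follows this operational
rule throughout. (A broader definition of visibility that also counted
in-ties from other key members would mismatch a numerator restricted to
`F∖K` senders and break the identity; we deliberately do not mix the two.)

Venue samples provide only relative inclusion probabilities
`c_i ∝ π_i` (attendance frequency, or any strictly monotone proxy for it).
Both pieces are therefore estimated with the generalized Horvitz–Thompson /
modified Hansen–Hurwitz mean `(Σ x_i/c_i)/(Σ 1/c_i)`, exactly invariant to
rescaling all `c_i`; the numerator total additionally multiplies by an
externally supplied `N_{F∖K}`. The estimate is exactly linear in
`N_{F∖K}`, so a relative error in the supplied count passes through
one-for-one; `EstimateResult.rescale_frame` exposes this algebraically.

**Degenerate cases.** If every sampled key member reports zero visibility,
the ratio is undefined; the package raises `InestimableVisibilityError`
rather than returning zero or infinity, and the simulation driver records
such replicates as failed. A supplied `N_{F∖K} ≤ 0`, empty strata, or
nonpositive `c` are configuration errors.

**Uncertainty.** No design-consistent variance estimator is established
for scale-up estimators; the package deliberately does not pretend to one.
Survey mode offers a respondent-level within-stratum bootstrap (default
1,000 replicates, 2.5/97.5 percentile interval) labelled heuristic: it
captures respondent-level noise, not network-level or frame-count
uncertainty.

## 2. Synthetic populations

`generate_population` builds a frame of `N_F` persons containing `N_K` key
members connected by a bipartite acquaintance tie set between `F∖K` and
`K`. Each non-key member's tie count is drawn with mean
`mean_degree_to_key` (default 3 venue-attending key acquaintances):

* `degree_dispersion = 1` (default): `Binomial(N_K, m/N_K)` — the marginal
  of independent per-pair Bernoulli ties;
* `degree_dispersion > 1`: negative binomial with variance
  `dispersion × mean` — gamma-mixed tie propensities for heavier-tailed
  out-degrees.

Tie partners are assigned uniformly at random among key members, so
in-ties are multinomial over `K`. Because each realised tie increments
exactly one `y_i` and one `v_j`, the out/in identity holds exactly for
every population, not merely in expectation — the structural property all
downstream checks rest on. The tie set is stored as a flat edge list (two
integer arrays); a general graph container would add nothing the
estimators consume.

These defaults are stand-ins chosen to be plausible for venue-intercept
studies, not calibrated to any particular field study: the true degree
distributions of venue-attending populations are study-specific.

## 3. Attendance scenarios

Attendance rates (expected venue visits per reference period) drive sample
inclusion and are assigned per stratum, so the key and non-key strata can
follow different families:

| family | description | rationale |
|---|---|---|
| S1 | all rates equal | degenerate baseline; design collapses to stratified SRS |
| S2 | lognormal(0, σ=1) | right-skewed visit frequency, a tail of regulars |
| S3 | two-point: 80% at rate 1, 20% at rate 10 | clumped "regulars vs. occasionals" |
| S4 | lognormal, rank-correlated ≈ 0.5 with the person's tie count | attendance confounded with network degree (gregarious people both attend more and know more) |

S4 uses a Gaussian copula on jittered ranks with Pearson
`ρ = 2·sin(π·0.5/6)` so the Spearman correlation targets 0.5; key members'
rates track their visibility `v_j`, non-key members' their out-degree
`y_i`. The four families span homogeneous, skewed, clumped, and
degree-confounded inclusion — the qualitative axes a venue design can
plausibly occupy. All rates are positive, and rescaling all of them by a
constant changes neither sampling distributions nor estimates.

## 4. Reporting error

Reporting error is one-directional by assumption: non-members never claim
key-population membership (their in-reports are identically zero), while
ties themselves can be misreported. The model is always applied to the true
network, never compounded.

**False negatives** (`false_negative_rate`): each true tie is independently
invisible with this probability, removing it from *both* the out-report and
the matched in-report — a visibility failure affects both ends of the tie.
Symmetric thinning scales numerator and denominator by the same factor in
expectation, so the estimator is robust to false negatives; the census
ratio remains exactly `N_K`.

**False positives** (`false_positive_rate`): phantom out-ties with no
matching in-report, inflating only the numerator. Mechanism: respondents
misattribute key-population membership to some of their non-key
venue-attending acquaintances, and the chance of misattribution per
eligible acquaintance scales with how prevalent the key population is on
the frame (the more common the group, the more plausible the confusion).
Phantom counts are `Poisson(FPR × pool × N_K/N_F)` per respondent, with
`pool` (default 6) the mean number of venue-attending acquaintances
eligible for misattribution. The resulting relative bias is approximately

```
FPR × pool × (N_K/N_F) / mean_degree_to_key ,
```

increasing in the false-positive rate and, at a fixed rate, increasing in
the key population's share of the frame — small key populations are barely
affected while large ones are overcounted. A simple proportional-inflation
mechanism (phantoms ∝ own out-degree) was considered and rejected: it
makes the bias equal to the FPR for every population size, erasing the
size interaction that is the substantive point of the false-positive
stress test. The `pool` default is a deliberate modelling constant, in the
plausible range for "venue-going acquaintances spoken to in the past
month" in intercept surveys.

## 5. Venue sampling

`draw_sample` models intercept recruitment as sequential draws proportional
to attendance rate, without replacement, until fixed quotas of key and
non-key respondents are met; draws from an already-filled stratum are
discarded, as field teams keep intercepting until quotas close. This is
implemented through the successive-sampling representation: sorting
`u_i = Exp(1)/rate_i` ascending gives the size-biased draw order, and a
size-biased permutation restricted to a stratum is that stratum's own
size-biased permutation, so the two quotas fill independently per stratum.
The two formulations are exactly equivalent; the representation is O(n) in
memory and vectorises.

Each record carries `c_i` = attendance rate — a relative probability only.
Absolute inclusion probabilities under this design are *not* proportional
to rates (without-replacement depletion bends them), which is faithful to
the field situation: the estimator is judged in simulation precisely on
whether the relative-probability approximation is good enough.
`true_inclusion_probs` estimates the absolute probabilities by brute-force
replication, purely as a test oracle, and `gnsum_known_probs` consumes them
as the known-probability benchmark.

Under equal rates the design reduces exactly to stratified simple random
sampling (tested against an independent SRS implementation).

## 6. Simulation study design

One scenario cell = generate `n_networks` populations, dress each with
attendance rates, apply reporting error once per population, draw
`n_samples_per_network` venue samples from each, estimate with the true
`N_{F∖K}`. Summaries:

```
relative bias (%) = 100 (mean estimate − N_K)/N_K
relative SE  (%)  = 100 SD(estimates)/N_K
```

The SD pools all estimates in the cell by default; `se_over =
"network_means"` switches to the SD of per-network means (both readings of
"variability across networks × samples" are defensible; pooling everything
is the more conservative and is the default).

Default grids: frame 20,000; key population ∈ {500, 1000, 5000} (Test A);
key sample ∈ {25, 50, 100} with 400 non-key respondents (Test B; Tests A
and B share the 3×3 cross, read along different axes); the 4×4 attendance
cross at `N_K`=1000, 50 key sampled (Test C); false-positive rate ∈
{0, 0.05, 0.10, 0.25, 0.50} × population size (Test D). Replication
defaults are the package's desk scale, 20 networks × 100 samples per cell
(the per-sample variability that relative SE measures does not shrink with
replication, so the desk scale estimates the same quantity as a larger run,
only with more Monte-Carlo noise on the summary). A full-scale run
(e.g. 100 × 1,000) is a configuration change. All randomness descends from
one integer seed per run through `numpy` seed-sequence spawning; per-cell
seeds are derived deterministically, so any output row is regenerable in
isolation. Identical configuration and seed reproduce populations, samples,
and summaries bit-for-bit.

## 7. What the synthetic world does and does not emulate

It emulates: a frame connected to the key group by a sparse acquaintance
network with controllable mean degree and dispersion; exact out/in tie
bookkeeping; attendance-driven unequal inclusion, including attendance
correlated with degree; quota-based intercept sampling; one-directional
reporting error with matched false-negative bookkeeping and unmatched false
positives.

It does not emulate: explicit venues or venue-day schedules (the venue
layer is collapsed into per-person attendance rates, which is all the
estimator consumes — a two-stage venue-day sampler is an extension point);
ties among key members (irrelevant to the estimator's tie set, which is
bipartite by definition); recall error beyond the two rates; refusal and
nonresponse; repeat-intercept deduplication; geography or multi-city
structure. Passing simulations therefore demonstrate design-consistency
and robustness *within this generative world*, not that any particular
field study satisfies the assumptions — in real data the frame count, the
accuracy of attendance as an inclusion proxy, and transmission error are
the binding concerns.

## 8. Numerical and design choices

* Ratio form: the estimator carries an O(1/n) small-sample ratio bias
  (~`CV²` of the denominator); at the default 50 sampled key members this
  is of order 0.05% and is ignored. Tests on very small strata allow for it
  explicitly.
* Exact invariances (scale in `c`, linearity in `N_{F∖K}`, census
  identity) are tested to 1e-12/1e-9 float tolerance.
* Zero-visibility samples raise; simulation cells record failures in
  `n_failed` and summarise the remaining replicates.
* Key members occupy person ids `0..N_K−1` by construction; samplers and
  estimators never rely on this.
* Population CSV serialisation stores per-person counts, not the edge
  list, so reporting error must be applied before serialising.
* Survey validation rejects, with line numbers: nonpositive attendance,
  negative counts, non-binary status, and key respondents with `q2 > q1`.
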