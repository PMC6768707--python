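# vbgnsum — venue-based generalized network scale-up estimation

`vbgnsum` estimates the size of a **hidden key population** — a group such
as men who have sex with men, female sex workers, or people who inject
drugs, whose size matters for HIV surveillance and program planning but
which no census or registry counts — from **venue-based (time-location)
samples**: surveys that intercept people at the bars, clubs, and other
venues where key population members gather. It is written for
epidemiologists and survey statisticians who already field venue-intercept
studies and want a size estimate out of the same interviews, and it ships
with a replicated simulation framework for stress testing the estimator
before trusting it in the field.

## The estimator

Let `F` be the frame population (everyone who attends the venues on the
frame, size `N_F`) and `K ⊆ F` the key population (size `N_K`, the
estimand). Acquaintance ties between non-key frame members and key members
can be counted from either end:

* the **out-report** `y_i` — how many venue-attending key members person
  `i ∈ F∖K` knows, and
* the **in-report** (visibility) `v_j` — how many venue-attending non-key
  acquaintances know key member `j`.

Both ends count the same ties, so `Σ_i y_i = Σ_j v_j`, and therefore

```
N_K = Σ_i y_i / v̄ ,     v̄ = mean visibility of key members.
```

Venue-based sampling complicates estimating both pieces: inclusion
probabilities are unknown, driven by how often each respondent attends
venues. But attendance frequency is itself observable, so a venue sample is
a *relative probability sample* — each respondent's inclusion probability
is known up to a common constant `c_i ∝ π_i`. Both pieces can then be
estimated with the generalized Horvitz–Thompson (modified Hansen–Hurwitz)
mean, which is invariant to the unknown constant:

```
v̄̂        = Σ_k (v_k/c_k) / Σ_k (1/c_k)          over key respondents
Ŷ_{F∖K→K} = N_{F∖K} · Σ_i (y_i/c_i) / Σ_i (1/c_i)  over non-key respondents

N̂_K = Ŷ_{F∖K→K} / v̄̂
```

where `N_{F∖K}` — the number of venue attenders outside the key population —
is supplied externally (an estimate of the venue-attending population is an
acceptable proxy; error in it propagates exactly linearly). In survey terms,
key respondents contribute `v = q1 − q2` and non-key respondents `y = q2`,
where q1 counts all venue-attending acquaintances and q2 the key-population
ones, with attendance frequency as `c`.

The package also implements the traditional scale-up estimator
(`basic_nsum`) and the known-inclusion-probability Horvitz–Thompson variant
(`gnsum_known_probs`) as benchmarks.

## Worked example

```python
import numpy as np
from vbgnsum import VenueSample, vb_gnsum

sample = VenueSample(
    person_id=np.arange(4),
    is_key=np.array([True, True, False, False]),
    c=np.array([1.0, 2.0, 1.0, 1.0]),     # relative inclusion probabilities
    y=np.array([0, 0, 1, 3]),              # out-reports (non-key respondents)
    v=np.array([2.0, 4.0, np.nan, np.nan]),  # in-report proxies (key respondents)
)
result = vb_gnsum(sample, n_frame_minus_key=10)
```

`examples/01_worked_estimate.py` runs this and prints:

```
numerator  (est. total out-reports to K): 20.0000
denominator (est. mean visibility of K):  2.6667
estimated key population size:            7.5000
with N_F\K misstated by +10%:             8.2500
```

The 10 non-key frame members send an estimated 20 ties into the key
population; each key member absorbs an estimated 8/3 of them, so
`N̂_K = 20/(8/3) = 7.5`. Misstating `N_{F∖K}` by +10% moves the estimate by
exactly +10% — the linear error propagation of the supplied frame count.

`examples/02_survey_mode.py` shows the full survey-file workflow (generate a
synthetic intercept survey, validate and read it, estimate with a heuristic
bootstrap interval), and `examples/03_simulation_study.py` runs a reduced
false-positive stress test. A thin CLI wraps the same calls:

```sh
vbgnsum generate --out survey.csv --seed 3
vbgnsum estimate --survey survey.csv --frame-size 1800 --bootstrap 1000
vbgnsum simulate --test C --out sim_out/
```

## The simulation framework

`vbgnsum.simulate` replays the whole pipeline — synthetic frame population
with an acquaintance network into the key group, attendance-rate
assignment, reporting error, quota-based PPS-by-attendance venue sampling,
estimation — over many networks and samples per scenario cell, reporting
relative bias `100·(mean N̂_K − N_K)/N_K` and relative standard error
`100·SD(N̂_K)/N_K`. Four stress-test grids are built in: key population size
(**A**), key sample size (**B**), a 4×4 cross of attendance-rate
distribution families for key × non-key members (**C**), and increasing
false-positive reporting (**D**). See `docs/methods.md` for the generative
model, scenario families, and default sizes.

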