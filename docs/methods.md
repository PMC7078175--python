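# Methods

## The deposition model

Avian deposition on a searched shoreline segment is estimated per *search
interval* — the `s` days between two consecutive searches.  The forward
model for the carcasses collected at the closing search is

    E[N_C] = E · Σ_{n=0}^{s−1} D_n · P_n

with `D_n` the birds deposited `n` days before the search, `P_n` the
probability a carcass survives `n` days of scavenging and decomposition
(`P_0 = 1`, non-increasing), and `E` the searcher efficiency.  Assuming
constant within-interval deposition (`D_n = D`) and inverting gives the
estimator

    D = (N_C − N_O) / (L · E · Σ_{n=0}^{s−1} P_n)

in birds·km⁻¹·day⁻¹.  The persistence sum runs over exactly `s` lags,
`n = s−1 … 0`: a 4-day Monday→Friday interval uses `P_3 … P_0`, and a
12-day interval uses all 12 tabulated lags.  An interval ending on day `t`
covers deposition days `(t−s, t]`, half-open at the start, so a bird
deposited on the search day itself has lag 0.

`N_O`, the count of "old" carcasses attributed to an earlier interval, is
taken as a validated input column — how old carcasses are recognised in
the field is outside this package's scope.  If relaxed validation ever
lets `N_C − N_O` go negative, the rate is clamped to 0 with a warning,
since negative deposition is physically meaningless.  Rates are stored at
full precision; rounding happens only in reports.

## Parameters

| Parameter | Meaning | Units | Packaged default |
|---|---|---|---|
| `E` | searcher efficiency | probability | beach 0.86, marsh 0.43 |
| `P_n` | persistence at lag `n` | probability | 12-lag beach/marsh curves |
| `s` | search interval | days | data-defined; grids use {1,2,3,4,6,12} |
| `L` | segment length | km | data-defined; simulations use 1 km |
| `D` | deposition rate | birds·km⁻¹·day⁻¹ | simulations use 1 and 10 |
| period | modelled window | days | 12 |
| `n_trials` | Monte Carlo trials per cell | — | 1000 |

The packaged beach/marsh values are the Gulf of Mexico habitat-specific
estimates used in the Deepwater Horizon shoreline assessment; they sit
within the range reported across other spills, so they make a
representative sensitivity baseline.  Persistence curves are tabulated at
integer lags with no interpolation: a lag beyond the tabulated support is
an error, not an extrapolation, because the tables carry exactly the lags
the supported search intervals need (up to 12 days).  The third grid
treatment pairs the marsh persistence curve with `E = 0.70`, the
efficiency gain achievable by searching each segment twice per visit.

## Extrapolation

For each calendar day, the daily rates of qualifying segments (interval
length ≤ a user-chosen maximum) of the same habitat within an
extrapolation area are averaged **unweighted across segments** — the mean
divides by segment count, not shoreline length — and multiplied by the
habitat's total shoreline length in the area.  Daily habitat estimates sum
over areas and days into the final total.  Habitat-days with no qualifying
segment are reported as missing and excluded from the total with a logged
tally rather than imputed as zero: absent search data is not evidence of
absent deposition, and no principled imputation rule exists at this layer.
Per-day averaging pools all qualifying segments regardless of their
interval lengths.

## Monte Carlo simulator

Each deposited bird independently persists to the next search with
probability `P_n` and, if persisting, is independently detected with
probability `E`.  The two stages are drawn separately (as two binomial
thinnings per lag), which is statistically identical to a single draw at
`q_n = E·P_n`; the split mirrors the physical process and lets tests probe
either stage.  Daily deposited counts are deterministic integers, not
Poisson draws — the simulated conditions fix deposition exactly so that
all variability comes from thinning.

Persisting-but-undetected carcasses do **not** carry over into the next
interval's pool.  Carryover would require persistence beyond the tabulated
lag range and a re-detection model that is not available; equivalently,
the simulation assumes old carcasses are perfectly recognised and
excluded, so `N_O = 0` throughout.  A consequence is that per-search
counts are independent across the `K = period/s` searches, which the
analytic variance below relies on — the two modules share the assumption
as a matched pair.

A trial simulates all `K` searches, estimates a rate per search (`N_O =
0`), averages the rates and scales by the period and segment length.  An
experiment runs `n_trials` trials and reports the mean, sample SD
(`n−1` denominator; immaterial at 1000 trials but fixed for
reproducibility) and CV = SD/mean.  Randomness uses one root seed with
per-trial substreams derived from `(seed, trial index)`, so trial results
are order-independent and parallelisable by contract.

## Closed-form oracle

Under the no-carryover assumption the per-search count is a sum of
independent binomials, `N_C ~ Σ_{n=0}^{s−1} Binomial(D, q_n)`, so

    E[total] = D · period
    Var[total] = period² · Σ_n D·q_n(1−q_n) / (K · (E·ΣP)²)

The estimator is exactly unbiased under constant deposition.  The CV
scales as `1/√D` (variance linear, mean linear in `D`), which is why the
low-deposition precision curves sit `√10` above the high-deposition ones.

The bounding patterns concentrate each interval's `s·D` birds at a single
lag, giving expected totals

    first day:  period · D · s · P_{s−1} / ΣP   (underestimate)
    last day:   period · D · s / ΣP             (overestimate)

Searcher efficiency cancels, so bias depends only on the persistence
curve, interval length and deposition magnitude.  At `s = 2` the two error
magnitudes are algebraically equal for any curve (`ΣP = 1 + P_1` makes
both `period·D·(1−P_1)/(1+P_1)`); for `s > 2` with strictly decreasing
persistence the overestimate dominates.  No published algebra exists for
these variances — the derivation is this package's own and is validated
against the simulator (and, for tiny instances, against brute-force
enumeration over every joint per-bird outcome) rather than against printed
formulas.

## Synthetic search records

The generator (`shoredep.io.generate_synthetic_records`) emulates the
simulated study conditions on multiple segments: constant integer
deposition per segment-day, a regular search schedule (an opening search,
then every `s` days over a 12-day period), carcass counts drawn through
the simulator's persistence/detection process, and a paired ground-truth
table of true deposition per segment-day.  It does **not** emulate several
features of real spill data: day-to-day deposition fluctuation (the
packaged consecutive-search counts show real deposition varies strongly
between days), carcass drift between segments, imperfect old-carcass
classification, irregular or missed searches, or uncertainty in `E` and
`P_n` themselves.  Passing recovery tests therefore demonstrates that the
estimator inverts its own generating process without bias — not that real
totals carry no systematic error when those assumptions fail; the bounding
analysis quantifies the worst case for one of them (non-constant
deposition).

## Numerical and design choices

* **Problem sizes.**  Grid experiments default to 1000 trials per cell,
  matching the repeated-trial design the summary statistics describe; the
  enumeration cross-check uses 100,000 replicates of ≤4-bird intervals,
  where the exact distribution is computable.  The end-to-end recovery
  check uses 84 daily-searched 1-km segments (1008 segment-days), enough
  for a 4-standard-error band of about ±1.6 % of the true total.
* **Tie-breaks and degenerate inputs.**  `N_C = 0` yields rate 0, not
  missing; an experiment with fewer than 2 trials has no sample SD and is
  an error; `E·ΣP = 0` cannot arise from validated parameters but raises
  rather than returning infinity.
* **CV under bias.**  The CV is always reported against the *estimate's*
  own mean (σ/x̄), not the true total, so the definition is identical for
  unbiased and bounding experiments.
* **Dates.**  Calendar dates, whole days; interval length is the exact
  date difference (Monday→Friday = 4 days).
* **Missing `N_O`.**  A blank old-count in a record CSV is treated as 0
  with a logged notice, consistent with the simulated conditions in which
  no old carcasses exist.
* **Marsh lags beyond 11 days.**  Whether the marsh curve was ever used
  with lags past `n = 11` is unknowable from the available tables; the
  package refuses longer lags outright.

## Known limitations

* No confidence-interval procedure for the extrapolated total: the
  analytic variance covers a single simulated segment cell, not the
  stratified multi-segment estimator with real search schedules.
* No propagation of uncertainty in `E` and `P_n` (they enter as known
  constants).
* No spatial structure: deposition is homogeneous within a segment and
  segments are independent; drift and refloating are out of scope.
* The bounding analysis brackets, but does not correct, the bias from
  non-constant deposition; a correction would need an observed deposition
  pattern (e.g. from daily-searched sentinel segments).
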