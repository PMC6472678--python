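# Methods

## The agreement index

The Ensemble Outcome Agreement (EOA) index measures, on [0, 1], the
confidence that a multi-model ensemble fulfils a hypothesis H of the form
"aggregated outcome strictly greater (or less) than a threshold". It is
*not* a probability of H: it assigns values near 1 when sub-ensemble
outcomes agree strongly, near 0 when they do not, regardless of why.

For an ensemble of N member outcomes, every non-empty subset (2^N − 1 of
them) is aggregated (median by default; mean available). Three quantities
enter the index:

- **ES**: the smallest size s such that *every* size-s subset aggregate
  fulfils H. If the full-ensemble aggregate fails H, no size qualifies and
  EOA = 0 exactly (the zero rule: individual fulfilling members cannot
  rescue a failing ensemble).
- **AF**: for each size i < ES let my_i be the mean |aggregate − threshold|
  over fulfilling subset aggregates (0 if none) and mn_i over
  non-fulfilling ones (absent if none). With ratios r_i = my_i / mn_i,

      AF = max(1 − (ES − 1) / Σ r_i, 0),   AF := 0 when ES = 1.

- **EOA** = [1 − (ES − AF)/(N+1)] / [1 − 1/(N+1)], classified Low
  [0, 0.25), Medium [0.25, 0.5), High [0.5, 0.75), Very high [0.75, 1),
  Maximum = 1.

Assumptions worth stating: members are treated as exchangeable and equally
credible (no weights, no quality screening, no dependence corrections);
fulfilment is *strict* — a median exactly on the threshold does not fulfil
H, which is what makes the balanced four-value ensemble {−2, −1, +1, +2}
at threshold 0 score exactly 0; the even-length median is the mean of the
two central order statistics.

### Degenerate cases of AF

- A size where *all* subsets fulfil has mn absent; its ratio borrows the
  maximum ratio defined at the other sizes below ES. By minimality of ES,
  size ES−1 always has at least one non-fulfilling subset, so a defined
  ratio normally exists.
- mn defined but exactly 0 (all dissenting aggregates sitting precisely on
  the threshold) is treated like absent, with a warning — the disagreement
  magnitude is zero and the ratio would be infinite.
- If *no* size below ES defines a ratio (the previous case at every size),
  AF is set to 1, the limiting value as the dissent magnitude vanishes.
- Σ r_i = 0 (no fulfilling aggregate below ES has any distance) gives
  AF = 0.

The alternative algebraic grouping AF = max(1 − mean_i r_i, 0) is
implemented behind `af_grouping="mean_ratio"` for audit; it is not the
default because it drives AF to 0 precisely when agreement dominates
(r → ∞), contradicting the index's intent.

### Computation

Subset aggregates are computed from a pre-sorted value array: combinations
of a sorted array are sorted rows, so medians are direct column reads.
ES uses a worst-subset argument — for median and mean, the size-s subset
minimizing the aggregate is the s smallest values (elementwise order
statistic domination) — giving ES in O(N²); full per-size enumeration is
still performed for the distance summaries at sizes below ES, and on
request for all sizes (131071 aggregates at N = 17, ~0.1 s). Tests compare
the optimized path against a deliberately naive pure-Python enumeration.

The sampled estimator draws, per size, `n_samples_per_size` subsets —
exactly (full enumeration) when C(N, i) fits the budget, uniformly without
replacement when combinations can be cheaply enumerated, with replacement
otherwise — and estimates ES as the smallest size with zero sampled
violations. It is deterministic under its mandatory seed and degenerates
to the exhaustive result for small N.

### A known limitation: threshold non-monotonicity

Raising the threshold makes fulfilment strictly harder, so ES is
non-decreasing and the AF = 0 reduction of the index is non-increasing.
The full index, however, is **not** globally monotone in the threshold:
when a subset aggregate crosses from barely-fulfilling to
barely-dissenting, mn at that size collapses toward 0, the ratio my/mn
inflates, and AF — hence EOA — can *rise*, by at most 1/N at constant ES
(if ES increases, the index necessarily falls). Example (verified by
literal enumeration): values {−0.808, −2.841, −0.180}, thresholds
−1.545 → −1.481 give EOA 0.425 → 0.556. Such increases affected roughly
0.8% of steps under dense random threshold ladders in our experiments.
In practice, with thresholds spaced coarsely relative to the ensemble
spread (e.g. 0% vs 10%), the index behaves monotonically; the property
suite asserts the provable facts (ES monotonicity, the 1/N bound, and the
absorbing zero rule).

## Response metrics

Both metrics are percent changes computed per member on 30-year-mean
yields, each member serving as its own denominator:

- adaptation value = 100·(y_adapted − y_unadapted)/y_unadapted at the same
  (ΔT, ΔP, CO2, soil) perturbation;
- recovery value = 100·(y_adapted,perturbed − y_baseline)/y_baseline,
  where the baseline is that member's unperturbed (ΔT = ΔP = 0), unadapted
  run at the baseline CO2 level (360 ppm).

A member with a zero or missing denominator at a cell is dropped from that
cell's ensemble (never imputed) and N is reduced accordingly; cells never
mix options, soils or CO2 levels. Metric values are rounded to 9 decimals
on the percent scale: yields carry far less precision, and without the
rounding a strict fulfilment test at a representable threshold (e.g.
"> 10") would be decided by multiplication-order ulps.

## Surfaces and grids

The default grid is ΔT ∈ {−1..+7} °C by 1 °C × ΔP ∈ {−40..+30}% by 10%
(72 cells); grids are inclusive arithmetic sequences with levels rounded
to exact decimals so cell keys compare reliably. Each non-empty cell of an
EOA surface carries the full-ensemble median response *and* the EOA result
computed from the same per-cell sample; empty cells are written as NA,
never 0, since EOA = 0 is a meaningful value. Outputs are tidy CSV
(`dT,dP,n_members,median_response,ES,AF,EOA,EOA_class`, 6 significant
digits) with a JSON metadata sidecar. The recommendation report is a pure
class filter (class order Low < Medium < High < Very high < Maximum) with
an optional ΔT/ΔP region restriction; any expert judgement beyond the
class filter is out of scope. Plotting (class-banded filled contours) is a
natural extension point but is not implemented; the CSV output is the
interface.

## Synthetic data

Two-level ensembles (`make_known_es_ensemble`): m dissenters at a value
below the threshold, n − m consenters above. Under median aggregation the
worst size-s subset packs min(s, m) dissenters, so when the dissent
magnitude is at least the consent magnitude ES = 2m + 1 (an even split's
median fails the strict test), otherwise ES = 2m. The closed form is
re-verified against exhaustive enumeration every time a fixture is
constructed, so the fixture cannot silently drift from the core it is
meant to test.

Synthetic run tables (`simulate_model_runs`):

    yield = base · soil_factor · co2_factor · (1 + slope_T·ΔT + slope_P·ΔP)
                 · (1 + (effect + bias_m)·[adapted]) · (1 + ε),  clipped at 0.

Defaults (chosen once, as plausible winter-wheat magnitudes): 17 members;
the 72-cell grid; base yield 6000 kg/ha; slope_T = −5%/°C;
slope_P = +0.5% per % precipitation; soils shallow (×0.85) and deep
(×1.0); CO2 levels 447 and 522 ppm with +0.05% yield per ppm above the
360 ppm baseline; adaptation effect +10% of yield; σ_model = 0.03;
σ_resid = 0.02; missingness 0 (set explicitly to emulate options not
simulated by all members — removal is uniform over adapted member–option
pairs, and unadapted/baseline runs are always kept so denominators exist).

Design notes. The adaptation effect multiplies the climate-adjusted yield,
so with zero noise the adaptation value is *exactly* 100·effect at every
cell — the generator's ground truth is recovered without tolerance. The
member bias σ_model perturbs each member's adaptation *response*
(effect_m = effect + bias_m, yield-fraction units): a pure level bias,
additive or multiplicative, cancels out of both response metrics (each
member is its own denominator) and would be unobservable, leaving nothing
for the index to disagree about. Noise is Gaussian on the relative scale —
the simplest structure with the required properties.

What the generator does *not* emulate: crop physiology (phenology,
water stress, CO2 response curves), correlated model errors, non-linear
interaction between adaptation and climate, or structured (non-random)
missingness. Passing tests therefore demonstrate the correctness of the
index and pipeline machinery on data with known structure, not the realism
of any particular agronomic conclusion.

## Problem sizes in the test suite

Oracle-equivalence tests run 500 random ensembles at N ≤ 12 (the naive
enumeration oracle is pure Python); known-ES recovery covers every
(n ≤ 17, m ≤ (n−1)/2) pair exhaustively; the sampled-vs-exhaustive ES
comparison uses 40 seeded replicates of 17-member ensembles at 2000
samples per size; end-to-end pipeline checks use the full 72-cell grid
with 17 members (noiseless) and scaled-down 3×3 grids with 5–9 members
elsewhere. These sizes keep the whole suite in a few seconds while every
code path — including full 131071-subset enumeration — is exercised.
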