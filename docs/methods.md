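# Methods

This note documents the models, numerical choices and known limitations of
`fopsim`. It is written for a reader who wants to understand exactly what
the pipeline computes and what the test suite does and does not establish.

## The replacement simulation

The unit of observation is a 24-hour-recall entry: person *p* consumed
amount *a* (g or mL) of food *f*. Food composition is expressed per 100
basis units (g or mL); grams and millilitres are treated as numerically
interchangeable (density 1) unless a per-food density is supplied, because
criteria are stated per 100 g **or** 100 mL and no density conversion is
implied. Daily intake of nutrient *k* is the sum over entries of
`a/100 × per100_k(f)`; nutrients absent from a food's composition record
contribute nothing to the sum (they remain *missing* at the food level and
are never silently zeroed at load time).

**Classification.** A criteria set assigns each category a list of
thresholds `(nutrient, ≤/≥, limit, denominator)` and an eligibility flag.
Denominators: per-100-basis (profile value as is), per serving
(`value × serving_size/100`), % of energy (`100 × k × g / kcal` with
Atwater factors k = 9 for fats and 4 for sugars), and % of total fat
(`100 × g / total_fat`). Comparators are inclusive; ≥ is reserved for fiber
(the only "more is better" nutrient here). A threshold that cannot be
evaluated — missing nutrient, missing serving size, zero energy or total
fat under a percentage denominator — **fails conservatively** with a logged
reason: a food whose healthfulness cannot be verified never counts as
compliant and is never offered as a replacement. This is the safe direction
for a labeling simulation and reflects that real food databases merge
sources of uneven completeness.

**Replacement map.** For each non-compliant processed food the candidate
set is every compliant processed food of the same category. If empty, the
food is recorded as unreplaced and passes through all scenarios. Otherwise
the candidate minimising |energy density − original's| is chosen, ties
broken by lexicographic food id. Nearest energy density keeps the
scenario-3 correction factor close to 1 and makes the choice fully
deterministic; the rule is pluggable (`candidate_rule`) should a
nutrient-space distance be preferred. The map is global — one replacement
per food, applied to every entry of that food — mirroring product-level
substitution rather than per-occasion substitution.

**Scenarios.** Scenario 1 returns the input unchanged. Scenario 2 swaps
the food id, keeping the amount. Scenario 3 swaps and multiplies the
amount by `ED_original/ED_replacement`, so the entry's energy is conserved
to machine precision; categories in the exempt set (by default
sugar-sweetened beverages, bakery, dairy) are replaced but *not* rescaled —
i.e. they keep their scenario-2 values — because rescaling low-energy-density
beverages and high-volume staples would imply implausibly large consumed
amounts. A zero or missing energy density on either side of a pair makes
the factor undefined; such pairs fall back to factor 1 with a logged
warning. Restricted runs (`restrict_to_categories`) limit replacement to a
category subset and leave all other entries bit-identical.

## Participant exclusions

Filters are applied per person in a fixed documented order — age outside
20–59 y, pregnancy/lactation, BMI < 10 or > 58 kg/m², missing age or BMI —
and finally a single-pass energy filter removing persons outside mean ± 3 SD,
where mean and SD are the *unweighted* moments of daily energy over the pool
surviving the earlier filters. A person failing several rules is counted
once, under the first failing rule. Missing-data checks run before the
energy pass because a record without age or BMI cannot sit in the energy
pool; the energy rule is applied exactly once, not iterated to convergence
(iteration would change the sample in ways no analysis plan specifies). The
audit object records counts per reason and conserves
`initial_n = final_n + Σ exclusions`.

## Survey statistics

**Quantiles.** The weighted quantile is the cumulative-expansion-weight
estimator used by major survey packages: sort the observations, accumulate
normalised weights `F_i`, return the first value with `F_i > p`, and average
the two adjacent order statistics when some `F_i` equals `p` exactly (within
10⁻¹² on the normalised scale). With equal weights this reproduces the
classic textbook quantile (e.g. the mean of the two central values at an
even median split). The definition is deliberately non-interpolating
between unequal weights: a value carrying 99% of the weight *is* the
median, which an interpolating scheme would violate. Quantiles are
monotone in `p` and scale-equivariant; both properties are property-tested.

**Percent change** is `100 × (after − before)/before` on full-precision
weighted medians, rounded to one decimal only for reporting; it is missing
when the reference is zero. Published tables sometimes print percent
changes computed from unrounded medians that cannot be recovered from the
rounded medians printed alongside them; this package always computes from
full precision and its output checker verifies that every percent change in
a figure file is recomputable from the accompanying medians table.

**Scenario contrasts.** For each nutrient, the two scenarios' person
records are stacked and `log(intake + δ)` is regressed on a scenario
indicator by weighted least squares, with cluster-robust (sandwich)
variance at the PSU level within strata and a t reference with
`clusters − 1` degrees of freedom, as survey software reports. Because each
person appears in both scenarios inside the same PSU, the clustering also
absorbs the within-person pairing. The offset δ is half the smallest
positive observed value of that nutrient across both scenarios (recorded in
the output), a standard device for zero-inflated intakes such as trans fat;
note that when a nutrient's distribution sits far from zero, δ is not small
relative to intake and the indicator coefficient is attenuated relative to
the true log-ratio — the p-value, not the coefficient, is the reported
quantity. Identical scenarios make the paired cluster variance exactly
zero; the implementation reports p = 1 in that degenerate case rather than
rounding noise. Significance is two-sided at 0.05 with no multiplicity
correction, matching common practice for these tables. The full
Taylor-linearised survey estimator (and replicate weights) are out of
scope; the cluster-robust sandwich is the documented, swappable stand-in.

## The synthetic-data generator

The generator emulates the *structure* of a national dietary sub-sample,
not any real food supply: it exists so the pipeline's estimates can be
checked against a known truth.

- **Food supply.** 19 categories (16 processed — beverages, dairy, bakery,
  snacks, processed meats, … — plus staples, fruits/vegetables and fresh
  animal foods) with energy shares, energy-density anchors and per-kcal
  nutrient anchors chosen so that a 1900 kcal/day diet lands near familiar
  national intake levels (≈ 90–120 g sugar, ≈ 2000 mg sodium, ≈ 21 g
  fiber). Each category holds 18 foods (a database of 342, comparable to
  the few hundred processed items a real 24HR yields); per-food energy
  density and nutrient densities get small log-normal jitter (σ = 0.12 and
  0.06), with one jitter draw per nutrient group so composition invariants
  (added ≤ total sugar, saturated + trans ≤ total fat) hold by
  construction.
- **Planted compliance.** Within a category, non-compliant foods sit at the
  per-kcal anchor `a` and compliant foods at `a(1−r)` for planted
  reductions `r` (negative for fiber, where compliant foods carry more).
  The generated criteria set puts each defining nutrient's threshold at the
  geometric midpoint `a·ED·√(1−r)` per 100 basis units, and every food is
  rejection-sampled against the actual classification engine until its
  label matches the plant (deterministic anchor fallback after 200 tries),
  so planted labels are exact, not approximate.
- **Recalls.** Every person consumes 4 entries per category, each drawn
  uniformly from the category's foods and supplying an equal split of the
  category's energy share. Fixed per-entry energy makes the category
  energy shares exact and keeps each person's replacement ratio an average
  over many near-independent draws, so its distribution is approximately
  symmetric and the weighted *median* change tracks the closed-form *mean*
  change. Daily energy is log-normal (median 1900 kcal, log-SD 0.43)
  truncated at |z| ≤ 1.8 so that the planted 12 000 kcal outliers are the
  only records outside the ±3 SD exclusion band — this is what makes
  "planted exclusions = filtered set" an exact set equality rather than a
  probabilistic one.
- **Closed-form truth.** Before replacement a replaceable category's
  expected per-kcal density of nutrient *k* is `a(q + (1−q)(1−r))`, where
  `q` is the probability of drawing a non-compliant food; after unexempted
  scenario-3 replacement it is exactly `a(1−r)` (every entry ends on a
  compliant food). The expected population percent change is the
  share-weighted ratio of these densities, computed per nutrient by
  `expected_change`, with unreplaceable processed categories (generated
  all-non-compliant, no candidates) and unprocessed categories contributing
  unchanged densities. Energy's expected change is 0 — scenario 3
  conserves it — which makes the energy row a direct test of the
  correction-factor machinery. The recovery suite runs the full pipeline
  on 10 surveys of 2000 participants and requires agreement within ±2
  percentage points for every nutrient.
- **Survey design.** Log-normal weights (log-SD 0.5) independent of
  intake, 10 strata × 4 PSUs, and standard demographic covariates for
  subgroup summaries. Defaults: 61.1% of foods per replaceable category
  non-compliant, 13 of 16 processed categories replaceable, 5 pregnant +
  2 aberrant-BMI + 3 energy-outlier plants per 2000 participants.

**What passing tests do and do not show.** The generator's recalls are
homogeneous in structure (same categories for everyone, fixed entry
energies, no day-to-day variation, weights independent of diet), its
nutrient distributions are clean log-normals, and compliance separates
perfectly at a single threshold per defining nutrient. Real 24HR data have
none of these properties: skipped categories, correlated food choices,
measurement error, incomplete composition records and weights correlated
with diet. Passing the recovery suite therefore demonstrates that the
*pipeline arithmetic* — classification, matching, rescaling, weighting,
quantiles, contrasts — is correct, not that estimates from real survey data
would carry these uncertainties.

## Numerical and design choices

- Atwater factors fixed at 9 kcal/g (fats) and 4 kcal/g (sugars) for
  %-of-energy thresholds.
- Inclusive comparators (≤/≥); "meeting" a limit includes the boundary.
- The 19-category shipped config applies thresholds to added sugar, the
  26-category one to total sugar, mirroring the two regulatory styles they
  illustrate; their numeric cut-offs are demonstrations only.
- Correction factors are ratios of energy densities and therefore
  independent of consumed amounts; exempt categories are *replaced without
  rescaling* (scenario-2 semantics) rather than left unreplaced, the
  reading consistent with exempting them only from the energy correction.
- Tie-breaks everywhere are total orders (lexicographic ids), so identical
  inputs give byte-identical outputs.
- Problem sizes in the test and acceptance runs — 200 random oracle
  fixtures, 10 recovery surveys of 2000 participants, 1000 null surveys of
  200 persons in 40 clusters — were chosen so the whole suite completes in
  well under a minute while leaving the binomial 99% band for the null
  rejection rate (0.032–0.068 at n = 1000) narrow enough to detect a
  miscalibrated variance estimator.

## Known limitations

- One 24HR per person: no usual-intake (measurement-error) modeling.
- Total replacement: no partial adoption or consumer-behavior model.
- The cluster-robust sandwich approximates, but is not, the full
  survey-design variance estimator; finite-population corrections and
  replicate weights are unsupported.
- Grouped summaries report subgroup medians/IQRs with national contrast
  p-values; per-subgroup contrasts would require subgroup-level
  regressions.
- Real regulatory cut-off tables are not bundled; users supply their own
  criteria configs for real analyses.
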