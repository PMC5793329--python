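# fopsim

Simulation of dietary change under front-of-package (FOP) nutrient-profiling
criteria.

Many countries attach a front-of-package logo to processed foods whose
content of energy, saturated fat, trans fat, sugar, sodium and fiber meets
category-specific cut-offs. A natural policy question is: *if consumers
replaced the non-compliant processed foods in their diet with compliant
foods of the same category, how would population energy and nutrient intake
change?* `fopsim` implements that replacement simulation for 24-hour dietary
recall (24HR) data from complex surveys, for nutrition and public-health
researchers evaluating labeling policy.

## What it computes

Given a food-composition table, a 24HR recall table, a participant table
with survey-design fields, and one or more criteria configurations, the
pipeline:

1. **classifies** every processed food against a declarative criteria set —
   per-category thresholds of the form *nutrient ≤ limit* per 100 g/mL, per
   serving, as % of energy (9 kcal/g for fats, 4 kcal/g for sugars) or as %
   of total fat, with whole categories optionally ineligible for the logo;
2. **filters participants** the way adult 24HR analyses do: age outside
   20–59 y, pregnancy/lactation, BMI < 10 or > 58 kg/m², missing data, and a
   single-pass ±3 SD energy filter;
3. **simulates three scenarios** per criteria set —
   - *scenario 1*: observed intake;
   - *scenario 2*: each non-compliant processed food is replaced by the
     compliant same-category food with the nearest energy density (kcal/100
     g or mL); foods with no compliant candidate stay;
   - *scenario 3*: as scenario 2, but the consumed amount is multiplied by
     the correction factor `ED_original / ED_replacement` so the entry's
     energy is conserved (e.g. 446.86/290.5 = **1.54**), except in exempt
     categories (sugar-sweetened beverages, bakery, dairy) where rescaling
     would imply implausible amounts;
4. **summarises** intakes with survey-weighted medians and interquartile
   ranges (p25–p75), percent changes vs. scenario 1, and contrast p-values
   from weighted linear regression of log-intake on a scenario indicator
   with cluster-robust (PSU-level) variance;
5. optionally restricts the replacement to chosen categories (e.g. only
   sugar-sweetened beverages) and contrasts two criteria sets against each
   other.

A first-class synthetic-data generator (`fopsim.synthetic`) emulates the
whole study — a ~19-category food supply, log-normal daily energy around a
1900 kcal median, strata/PSU weights, planted exclusions, and planted
per-category nutrient reductions with a closed-form expected percent change
— so every stage is testable without access to restricted survey microdata.

## Worked example

```bash
fopsim generate demo --seed 3 --n-participants 2000
cd demo && fopsim run run.yaml
```

The first command writes a complete synthetic fixture (foods.csv,
recalls.csv, participants.csv, criteria.yaml, ground_truth.json, run.yaml);
the second runs the full pipeline into `results/`. The exclusion audit
(`audit.json`) reports

```
initial_n 2000 → final_n 1990
(pregnant_or_lactating 5, bmi_aberrant 2, energy_outlier 3)
```

matching the generator's planted exclusions exactly, and the national
summary table (`table_synthetic-criteria.csv`) contains, for scenarios 1
and 3:

| nutrient | scenario 1 median (p25–p75) | scenario 3 median | change | p |
|---|---|---|---|---|
| energy (kcal) | 1879 (1436–2466) | 1879 | 0.0% | 1.0 |
| saturated fat (g) | 14.8 (11.4–19.4) | 13.1 | −11.3% | <10⁻⁶¹ |
| trans fat (g) | 0.148 (0.111–0.197) | 0.076 | −48.3% | <10⁻⁶⁰ |
| total sugar (g) | 92.8 (70.8–123.9) | 58.7 | −36.8% | <10⁻⁵³ |
| sodium (mg) | 1774 (1361–2328) | 1560 | −12.1% | <10⁻⁶¹ |
| fiber (g) | 21.7 (16.7–28.9) | 22.8 | +5.0% | <10⁻⁴⁹ |

Energy is unchanged because this run rescales every replacement (empty
exempt set): scenario 3 conserves energy by construction, while the
nutrient-per-kcal profile of the diet improves. The percent changes agree
with the generator's closed-form expectations (−11.1, −47.8, −38.1, −13.1,
+4.3) within sampling error. Of 288 processed foods, 68% classify as
non-compliant and 73% of those have a compliant same-category replacement.

The library surface mirrors scikit-learn where the operations are
predict/transform shaped:

```python
from fopsim import ComplianceClassifier, ScenarioReplacer, load_criteria, load_food_db

db = load_food_db("demo/foods.csv")
criteria = load_criteria("demo/criteria.yaml")
clf = ComplianceClassifier(criteria).fit(db)          # per-food compliance
rep = ScenarioReplacer(criteria, scenario=3).fit(db)  # builds replacement map
counterfactual = rep.transform(recalls_frame)         # rewritten 24HR table
```

Two illustrative criteria configs ship with the package
(`fopsim/configs/`): a 19-category set applying limits to *added* sugar,
and a 26-category set applying limits to *total* sugar with sugar-based
categories (soft drinks, jam, honey, chocolate, …) ineligible for the logo.
Their numerical cut-offs are demonstrations, not regulatory values.

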