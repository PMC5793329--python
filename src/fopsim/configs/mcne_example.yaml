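# Illustrative 19-category criteria set in the style of the Mexican Committee
# of Nutrition Experts (MCNE) front-of-package scheme: WHO-aligned structure,
# thresholds on ADDED sugar, all categories eligible for the logo.
# The numerical cut-offs below are approximations for demonstration and
# testing only; they are not the committee's published values.
name: mcne-example
categories:
  - category: soft drinks
    eligible: true
    thresholds:
      - {nutrient: energy, cmp: le, limit: 20, per: per_100_basis}
      - {nutrient: added_sugar, cmp: le, limit: 2.5, per: per_100_basis}
  - category: fruit and vegetable juices
    eligible: true
    thresholds:
      - {nutrient: energy, cmp: le, limit: 50, per: per_100_basis}
      - {nutrient: added_sugar, cmp: le, limit: 2.5, per: per_100_basis}
  - category: dairy drinks
    eligible: true
    thresholds:
      - {nutrient: saturated_fat, cmp: le, limit: 1.4, per: per_100_basis}
      - {nutrient: added_sugar, cmp: le, limit: 5, per: per_100_basis}
      - {nutrient: sodium, cmp: le, limit: 100, per: per_100_basis}
  - category: yogurt and fermented milks
    eligible: true
    thresholds:
      - {nutrient: saturated_fat, cmp: le, limit: 2.4, per: per_100_basis}
      - {nutrient: added_sugar, cmp: le, limit: 7, per: per_100_basis}
  - category: cheese
    eligible: true
    thresholds:
      - {nutrient: saturated_fat, cmp: le, limit: 15, per: per_100_basis}
      - {nutrient: sodium, cmp: le, limit: 900, per: per_100_basis}
  - category: breakfast cereals
    eligible: true
    thresholds:
      - {nutrient: added_sugar, cmp: le, limit: 20, per: per_100_basis}
      - {nutrient: sodium, cmp: le, limit: 400, per: per_100_basis}
      - {nutrient: fiber, cmp: ge, limit: 5, per: per_100_basis}
  - category: cereal bars
    eligible: true
    thresholds:
      - {nutrient: energy, cmp: le, limit: 350, per: per_100_basis}
      - {nutrient: added_sugar, cmp: le, limit: 20, per: per_100_basis}
      - {nutrient: saturated_fat, cmp: le, limit: 10, per: pct_of_energy}
  - category: bread and tortillas
    eligible: true
    thresholds:
      - {nutrient: sodium, cmp: le, limit: 400, per: per_100_basis}
      - {nutrient: added_sugar, cmp: le, limit: 10, per: per_100_basis}
  - category: bakery products
    eligible: true
    thresholds:
      - {nutrient: saturated_fat, cmp: le, limit: 10, per: pct_of_energy}
      - {nutrient: added_sugar, cmp: le, limit: 20, per: per_100_basis}
      - {nutrient: trans_fat, cmp: le, limit: 1.3, per: pct_of_total_fat}
  - category: cookies and biscuits
    eligible: true
    thresholds:
      - {nutrient: saturated_fat, cmp: le, limit: 10, per: pct_of_energy}
      - {nutrient: added_sugar, cmp: le, limit: 20, per: per_100_basis}
  - category: salty snacks
    eligible: true
    thresholds:
      - {nutrient: sodium, cmp: le, limit: 500, per: per_100_basis}
      - {nutrient: saturated_fat, cmp: le, limit: 10, per: pct_of_energy}
      - {nutrient: trans_fat, cmp: le, limit: 1.3, per: pct_of_total_fat}
  - category: candy and confectionery
    eligible: true
    thresholds:
      - {nutrient: energy, cmp: le, limit: 250, per: per_100_basis}
      - {nutrient: added_sugar, cmp: le, limit: 20, per: per_100_basis}
  - category: chocolate products
    eligible: true
    thresholds:
      - {nutrient: added_sugar, cmp: le, limit: 30, per: per_100_basis}
      - {nutrient: saturated_fat, cmp: le, limit: 10, per: per_100_basis}
  - category: jams honey and syrups
    eligible: true
    thresholds:
      - {nutrient: added_sugar, cmp: le, limit: 40, per: per_100_basis}
  - category: processed meats
    eligible: true
    thresholds:
      - {nutrient: sodium, cmp: le, limit: 900, per: per_100_basis}
      - {nutrient: saturated_fat, cmp: le, limit: 13, per: pct_of_energy}
  - category: ready meals and soups
    eligible: true
    thresholds:
      - {nutrient: sodium, cmp: le, limit: 400, per: per_100_basis}
      - {nutrient: saturated_fat, cmp: le, limit: 10, per: pct_of_energy}
  - category: sauces and dressings
    eligible: true
    thresholds:
      - {nutrient: sodium, cmp: le, limit: 750, per: per_100_basis}
      - {nutrient: added_sugar, cmp: le, limit: 10, per: per_100_basis}
  - category: fats and oils
    eligible: true
    thresholds:
      - {nutrient: saturated_fat, cmp: le, limit: 30, per: pct_of_total_fat}
      - {nutrient: trans_fat, cmp: le, limit: 1.3, per: pct_of_total_fat}
  - category: ice cream and frozen desserts
    eligible: true
    thresholds:
      - {nutrient: energy, cmp: le, limit: 250, per: per_100_basis}
      - {nutrient: added_sugar, cmp: le, limit: 20, per: per_100_basis}
      - {nutrient: saturated_fat, cmp: le, limit: 5, per: per_100_basis}
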