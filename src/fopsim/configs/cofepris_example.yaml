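# Illustrative 26-category criteria set in the style of the COFEPRIS
# (Mexican sanitary-risk agency) front-of-package scheme: EU-Pledge-derived
# structure, thresholds on TOTAL sugar, and sugar-based categories (soft
# drinks, jam, jelly, syrup, honey, chocolate products) marked ineligible to
# carry the logo at all.  The numerical cut-offs are approximations for
# demonstration and testing only; they are not the agency's published values.
name: cofepris-example
categories:
  - category: soft drinks
    eligible: false
    thresholds: []
  - category: jam and jelly
    eligible: false
    thresholds: []
  - category: honey
    eligible: false
    thresholds: []
  - category: syrups
    eligible: false
    thresholds: []
  - category: chocolate products
    eligible: false
    thresholds: []
  - category: candy and confectionery
    eligible: true
    thresholds:
      - {nutrient: energy, cmp: le, limit: 170, per: per_serving}
      - {nutrient: total_sugar, cmp: le, limit: 30, per: per_100_basis}
  - category: fruit and vegetable juices
    eligible: true
    thresholds:
      - {nutrient: energy, cmp: le, limit: 70, per: per_100_basis}
      - {nutrient: total_sugar, cmp: le, limit: 13.5, per: per_100_basis}
  - category: dairy drinks
    eligible: true
    thresholds:
      - {nutrient: saturated_fat, cmp: le, limit: 2.6, per: per_100_basis}
      - {nutrient: total_sugar, cmp: le, limit: 13.5, per: per_100_basis}
  - category: yogurt and fermented milks
    eligible: true
    thresholds:
      - {nutrient: saturated_fat, cmp: le, limit: 2.6, per: per_100_basis}
      - {nutrient: total_sugar, cmp: le, limit: 13.5, per: per_100_basis}
  - category: cheese
    eligible: true
    thresholds:
      - {nutrient: saturated_fat, cmp: le, limit: 17, per: per_100_basis}
      - {nutrient: sodium, cmp: le, limit: 1000, per: per_100_basis}
  - category: milk
    eligible: true
    thresholds:
      - {nutrient: saturated_fat, cmp: le, limit: 2.6, per: per_100_basis}
  - category: breakfast cereals
    eligible: true
    thresholds:
      - {nutrient: total_sugar, cmp: le, limit: 30, per: per_100_basis}
      - {nutrient: sodium, cmp: le, limit: 450, per: per_100_basis}
  - category: cereal bars
    eligible: true
    thresholds:
      - {nutrient: energy, cmp: le, limit: 200, per: per_serving}
      - {nutrient: total_sugar, cmp: le, limit: 35, per: per_100_basis}
  - category: bread and tortillas
    eligible: true
    thresholds:
      - {nutrient: sodium, cmp: le, limit: 500, per: per_100_basis}
  - category: bakery products
    eligible: true
    thresholds:
      - {nutrient: saturated_fat, cmp: le, limit: 13, per: pct_of_energy}
      - {nutrient: total_sugar, cmp: le, limit: 35, per: per_100_basis}
  - category: cookies and biscuits
    eligible: true
    thresholds:
      - {nutrient: saturated_fat, cmp: le, limit: 13, per: pct_of_energy}
      - {nutrient: total_sugar, cmp: le, limit: 35, per: per_100_basis}
  - category: salty snacks
    eligible: true
    thresholds:
      - {nutrient: sodium, cmp: le, limit: 670, per: per_100_basis}
      - {nutrient: saturated_fat, cmp: le, limit: 13, per: pct_of_energy}
  - category: processed meats
    eligible: true
    thresholds:
      - {nutrient: sodium, cmp: le, limit: 1100, per: per_100_basis}
  - category: ready meals and soups
    eligible: true
    thresholds:
      - {nutrient: sodium, cmp: le, limit: 500, per: per_100_basis}
      - {nutrient: energy, cmp: le, limit: 425, per: per_serving}
  - category: sauces and dressings
    eligible: true
    thresholds:
      - {nutrient: sodium, cmp: le, limit: 900, per: per_100_basis}
  - category: fats and oils
    eligible: true
    thresholds:
      - {nutrient: saturated_fat, cmp: le, limit: 33, per: pct_of_total_fat}
      - {nutrient: trans_fat, cmp: le, limit: 2, per: pct_of_total_fat}
  - category: ice cream and frozen desserts
    eligible: true
    thresholds:
      - {nutrient: energy, cmp: le, limit: 110, per: per_serving}
      - {nutrient: total_sugar, cmp: le, limit: 25, per: per_100_basis}
  - category: flavored waters
    eligible: true
    thresholds:
      - {nutrient: energy, cmp: le, limit: 20, per: per_100_basis}
      - {nutrient: total_sugar, cmp: le, limit: 4.5, per: per_100_basis}
  - category: nuts and seeds
    eligible: true
    thresholds:
      - {nutrient: sodium, cmp: le, limit: 400, per: per_100_basis}
  - category: canned fruits and vegetables
    eligible: true
    thresholds:
      - {nutrient: total_sugar, cmp: le, limit: 17, per: per_100_basis}
      - {nutrient: sodium, cmp: le, limit: 400, per: per_100_basis}
  - category: instant noodles and pasta
    eligible: true
    thresholds:
      - {nutrient: sodium, cmp: le, limit: 500, per: per_100_basis}
      - {nutrient: saturated_fat, cmp: le, limit: 13, per: pct_of_energy}
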