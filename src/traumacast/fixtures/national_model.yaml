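# Same national scenario, but the two modeled strata (close proximity,
# moderate rockets) are RECOMPUTED from their source groups' carried rates
# via the borrow/average derivation rules, instead of injecting published
# counts.  The four review-backed strata keep their published constants
# (their underlying study data live in external reviews).
name: national-conflict-model
national_population: 9767718
groups:
  - id: direct
    name: Direct exposure to the terrorist attacks
    raw_size: 39664
    data_type: Clinical assessments
    derivation:
      mode: meta
      k: 9
      estimate: {point: 0.32, low: 0.21, high: 0.42}
      counts: {expected: 12564, lower: 8474, upper: 16654}
  - id: proximal
    name: Close proximity to the terrorist attacks
    raw_size: 121061
    data_type: Modeling
    derivation:
      mode: borrow
      sources: [intense_rockets]
  - id: soldiers
    name: Soldiers in combat and support units
    raw_size: 165000
    data_type: Clinical assessments
    reassignments:
      - {count: 20773, to: null}
    derivation:
      mode: meta
      k: 4
      estimate: {point: 0.08, low: 0.01, high: 0.14}
      counts: {expected: 11021, lower: 1494, upper: 20549}
  - id: intense_rockets
    name: Civilians under intense exposure to rocket attacks (<40 km)
    raw_size: 1069011
    data_type: Adjusted probable PTSD
    derivation:
      mode: meta_adjusted
      k: 6
      estimate: {point: 0.10, low: 0.03, high: 0.17}
      counts: {expected: 109088, lower: 33058, upper: 185118}
  - id: moderate_rockets
    name: Civilians under moderate exposure to rocket attacks (40-80 km)
    raw_size: 4960469
    data_type: Modeling
    derivation:
      mode: average
      sources: [intense_rockets, indirect]
  - id: indirect
    name: Indirectly affected communities (>80 km)
    residual: true
    data_type: Clinical assessments
    derivation:
      mode: meta
      k: 5
      estimate: {point: 0.02, low: 0.01, high: 0.03}
      counts: {expected: 70714, lower: 21410, upper: 120019}
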