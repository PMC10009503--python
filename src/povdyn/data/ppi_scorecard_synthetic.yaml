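# Synthetic poverty-likelihood scorecard for testing and simulation.
# This is NOT a published country scorecard: question points and the
# points -> likelihood lookup are invented with the same structure as
# published asset-based scorecards (points sum to 100; likelihood is a
# non-increasing step function of points).
name: synthetic-ppi-scorecard
questions:
  - id: roof_material
    points: [0, 6, 12]
  - id: floor_material
    points: [0, 4, 8]
  - id: cooking_fuel
    points: [0, 5, 10]
  - id: rooms_per_person
    points: [0, 5, 10]
  - id: owns_radio
    points: [0, 8]
  - id: owns_phone
    points: [0, 6, 12]
  - id: owns_bicycle
    points: [0, 10]
  - id: head_education
    points: [0, 4, 8, 12]
  - id: children_in_school
    points: [0, 4, 8]
  - id: land_title
    points: [0, 10]
lookup:
  - {min_points: 0, likelihood: 0.92}
  - {min_points: 10, likelihood: 0.85}
  - {min_points: 20, likelihood: 0.74}
  - {min_points: 30, likelihood: 0.60}
  - {min_points: 40, likelihood: 0.45}
  - {min_points: 50, likelihood: 0.31}
  - {min_points: 60, likelihood: 0.19}
  - {min_points: 70, likelihood: 0.11}
  - {min_points: 80, likelihood: 0.05}
  - {min_points: 90, likelihood: 0.02}
lookup_note: likelihood that a household is below the poverty line given its points
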