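# Declarative knowledge base of fibula-flap reconstruction variants.
#
# A variant is a point in the cross product of the axes below; geometric
# feasibility predicates (by name) prune combinations the engine cannot
# realize.  Numeric bounds are planning conventions and may be overridden
# by the engine configuration.
schema_version: 1

axes:
  donors: [left_fibula, right_fibula]
  pedicle_sides: [left, right]
  skin_islands: [none]          # add 'lateral' when a paddle is harvested

bounds:
  max_segments: 4
  max_segment_length_mm: 40.0
  min_practical_segment_length_mm: 15.0

feasibility:
  # a skin island must sit on the fibula face left free by the medially
  # running vessels, i.e. never on the medial face
  - skin_island_not_medial
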