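# Colony-typical phenology defaults for the satellite fitting mode.
# Representative values for an Adelie-Land-type colony; in satellite mode
# only bp and f are re-estimated, t0 is re-anchored to the local first
# sunrise after midwinter + 27.4 days, and everything else is held fixed.
# Override any entry with a user-supplied YAML of the same shape.
t0: 97.0      # peak arrival, day-of-year (re-anchored per site in satellite mode)
dt0: 6.0      # arrival spread, days
m: 35.0       # courtship duration, days
b: 75.0       # female absence (male incubation), days
db: 9.0       # post-return event spread, days
bp: 3900.0    # breeding pairs (free in satellite mode)
nb: 0.15      # non-breeder ratio
hr: 0.85      # hatching success
f: 0.70       # fledging success (free in satellite mode)
c_max: 3.0    # longest colony stay per trip, days
c_min: 1.5    # shortest colony stay per trip, days
s_max: 12.0   # longest at-sea trip, days
s_min: 8.0    # shortest at-sea trip, days
s_fem: 8.0    # female's first post-hatch trip, days
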