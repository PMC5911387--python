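# Default growth-class thresholds (implementation defaults, overridable).
# Inclusive lower bounds: a value equal to a cutoff takes the higher class.
# The GS cutoffs are the GL cutoffs mapped through the GS-on-GL regression
# line of a reference simulated cohort (default config, seed 0).
labels = -, +, ++, +++, ++++
gl = 0.25, 0.75, 1.25, 1.75
gs = 0.2149, 0.5445, 0.8741, 1.2037
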