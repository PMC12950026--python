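# SYNTHETIC stand-in reference table for the afferent (gain, b) grid search.
# One row per ramp-and-hold trial: the five-velocity battery (0 -> 37 deg at
# 980..96 deg/s) followed by the five-hold-angle battery (240.4 deg/s to
# 60..15 deg).  x_ss_hz is the tonic plateau rate, x_max_hz the phasic peak.
# These numbers are NOT measurements: they are constructed to mimic the
# qualitative phasic-tonic phenomenology of cockroach hair-plate afferents
# (peaks ~150% of plateau, peak growing with ramp speed, plateau growing with
# hold angle, subthreshold plateau at the smallest deflection).  Replace with
# a measured table for quantitative afferent fitting.
trial,x_ss_hz,x_max_hz
v980,100,166
v604,100,152
v352,100,141
v188,100,130
v96,100,118
hold60,128,196
hold46,110,170
hold34,92,144
hold23,66,106
hold15,0,62
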