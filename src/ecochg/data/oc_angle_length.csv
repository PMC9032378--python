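# Angular insertion depth vs. percent organ-of-Corti length from the base.
# Control points interpolated from published averages of human cochlear
# frequency-position anatomy (organ-of-Corti map); editable — replace with a
# subject- or atlas-specific table if available.
angle_deg,percent_length
0,0.0
45,11.0
90,21.0
135,30.0
180,38.0
225,45.0
270,51.5
315,57.5
360,63.0
405,67.2
450,70.5
495,73.2
540,76.5
585,79.0
630,81.5
675,83.5
720,85.5
810,89.0
900,92.0
990,94.5
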