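# Baseline magnet-assisted delivery: 100 nm particles, 1.5 T remanence,
# 20 x 10 cm magnet with its face 5 cm from the tumor center.
# nanoparticle.mobility_scale should be set from
# `magipt calibrate --target-w-half 0.08cm` (see docs/methods.md).
name: magnetic_baseline
magnet.B_rem: 1.5
magnet.length_l: "20 cm"
magnet.height_h: "10 cm"
magnet.distance_d: "5 cm"
nanoparticle.radius_a: "100 nm"
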