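# Conventional intraperitoneal chemotherapy: no magnet (B_rem = 0).
# All other parameters are the shipped tissue/kinetics defaults (SI units);
# boundary.C_outer is the rim drug concentration in mol/m^3 (calibrate with
# `magipt calibrate --target-mean-cf 0.0013`).
name: conventional
magnet.B_rem: 0.0
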