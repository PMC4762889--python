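# Yasso07 decomposition constants: maximum a posteriori point estimate as
# published with the model (global litter-bag + woody-decomposition fit).
# This file is configuration: every operation accepts an alternative set.
#
# Units: alpha_* yr^-1 (reference rates at T = 0 degC, modifier = 1);
# beta1 degC^-1; beta2 degC^-2; gamma m^-1 (annual precipitation in metres);
# size_phi1 cm^-1, size_phi2 cm^-2, size_r dimensionless.
# flow_<i>_<j> is the fraction of decomposed mass of pool i routed to pool j;
# humus_fraction is the fraction of decomposed labile mass routed to H;
# the remainder of each pool's decomposed mass leaves the system as CO2.

alpha_a = 0.66
alpha_w = 4.3
alpha_e = 0.35
alpha_n = 0.22
alpha_h = 0.0033

flow_a_w = 0.32
flow_a_e = 0.01
flow_a_n = 0.035
flow_w_a = 0.48
flow_w_e = 0.005
flow_w_n = 0.01
flow_e_a = 0.93
flow_e_w = 0.01
flow_e_n = 0.02
flow_n_a = 0.34
flow_n_w = 0.01
flow_n_e = 0.016
humus_fraction = 0.04

beta1 = 0.096
beta2 = -0.0014
gamma = -1.21

size_phi1 = -1.71
size_phi2 = 0.86
size_r = -0.306
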