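# Third-trimester human placenta. L0 is the stated 0.3-0.7 m range midpoint
# used in the source analysis (0.5 m); Q0 = 500 ml/min in m^3/s.
species_label = "human-T3"
L0 = 0.5
d0 = 0.004
Q0 = 8.333333333333333e-6
mdot0 = 8.33e-6
mu_b = 4.0e-3
rho_b = 1000.0
D_ox = 1.7e-9
T = 309.15
Rprime_ox = 259.8
rho_ox = 0.0468
alpha_cotyledons = 80
beta_villi = 65
P_input_range = [8.0, 18.0]
P_output_range = [22.0, 37.0]
K_Hill = 0.04
n_Hill = 2.65
C_max = 9.82
C_diss = 0.13
P_artery = 15.7
P_capillary = 28.3
C_bound_artery = 1.647
C_bound_capillary = 4.244
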