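# Mouse placenta, embryonic day 15.5. Q0 = 0.246 ml/min; see mouse-E13.5.toml
# for the v_mean unit note.
species_label = "mouse-E15.5"
L0 = 0.0056
d0 = 0.00046
Q0 = 4.1e-9
mdot0 = 8.76e-6
mu_b = 4.0e-3
rho_b = 1000.0
D_ox = 1.7e-9
T = 309.15
Rprime_ox = 259.8
rho_ox = 0.0468
alpha_cotyledons = 1
beta_villi = 65
v_mean_mms = 25.0
K_Hill = 0.04
n_Hill = 2.65
C_max = 9.82
C_diss = 0.13
P_artery = 15.7
P_capillary = 28.3
C_bound_artery = 1.647
C_bound_capillary = 4.244
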