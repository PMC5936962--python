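"""Total oxygen-transport resistance versus tree depth, and its optimum.

R(N) is a convective term growing linearly in N plus a diffusive term
decaying geometrically, so the landscape is convex with a unique minimum.
With the shipped constants the uncalibrated minimum sits at the grid edge
(the stationary point falls below N = 1); calibrating the diffusive scale by
the factor kappa moves the optimum to the published depth N = 18, which
quantifies the gap instead of hiding it.
"""

from placentox import (
    TransportOptions,
    calibrate_kappa,
    load_preset,
    optimize_N,
    resistance_coefficients,
    total_resistance,
)

human = load_preset("human-T3")

b = total_resistance(human, 18)
print(f"breakdown at N = 18: R_conv = {b.R_conv_ox:.4g}, R_diff = {b.R_diff_ox:.4g}, "
      f"total = {b.R_total:.4g} (log10 = {b.log10_R_total:.3f})")

A, C = resistance_coefficients(human)
print(f"landscape coefficients: A = {A:.4g} per generation, C = {C:.4g}; C/A = {C / A:.4f}")

uncal = optimize_N(human)
print(f"uncalibrated optimum: N* = {uncal.N_star} (boundary = {uncal.at_boundary}), "
      f"continuous stationary point {uncal.N_continuous:.3f}")

cal = calibrate_kappa(human, N_target=18)
calibrated = optimize_N(human, options=TransportOptions(kappa=cal.kappa))
print(f"calibration factor kappa = {cal.kappa:.4g} places the optimum at "
      f"N* = {calibrated.N_star} (stationary point {calibrated.N_continuous:.3f})")

mouse = load_preset("mouse-E17.5")
cal_m = calibrate_kappa(mouse, N_target=22)
print(f"mouse E17.5: kappa = {cal_m.kappa:.4g} recovers N* = "
      f"{optimize_N(mouse, options=TransportOptions(kappa=cal_m.kappa)).N_star}")
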