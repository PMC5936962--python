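"""Oxygen content of fetal blood: Hill-bound plus dissolved.

Evaluates the Hill saturation curve at the umbilical-artery (15.7 mmHg) and
fetal-capillary (28.3 mmHg) partial pressures and contrasts the result with
the reported compartment concentrations the downstream resistance model uses.
The two disagree — that mismatch is one of the documented audit items.
"""

from placentox import (
    compartment_concentrations,
    dissolved_from_content,
    hill_saturation,
    load_preset,
    oxygen_state,
)

human = load_preset("human-T3")

print(f"half-saturation pressure 1/K = {1 / human.K_Hill:.0f} mmHg, "
      f"S there = {hill_saturation(25.0, human.K_Hill, human.n_Hill):.3f}")
print(f"dissolved O2 from 3 ml/l:      {dissolved_from_content(3.0):.3f} mol/m^3 (reported 0.13)")
print()
for name, P in [("umbilical artery", human.P_artery), ("fetal capillary", human.P_capillary)]:
    st = oxygen_state(P, human)
    print(f"{name} at {P} mmHg: S = {st.S:.4f}, Hill-bound = {st.C_bound:.3f}, "
          f"total = {st.C_total:.3f} mol/m^3")

printed = compartment_concentrations(human, source="printed")
computed = compartment_concentrations(human, source="computed")
print()
print(f"reported totals (used downstream): artery {printed[0]:.3f}, capillary {printed[1]:.3f}")
print(f"Hill-evaluated totals:             artery {computed[0]:.3f}, capillary {computed[1]:.3f}")
print("the driving content difference dC is "
      f"{abs(printed[0] - printed[1]):.3f} (reported) vs {abs(computed[0] - computed[1]):.3f} (Hill)")
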