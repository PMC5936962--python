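"""Build the human feto-placental Murray tree and print its morphometrics.

The tree starts at the umbilical artery (L0 = 0.5 m, d0 = 4 mm) and halves
its channel diameter and length by 2^(-1/3) at every symmetric bifurcation.
At the published optimal depth N = 18 we read off the total path length, the
terminal-capillary diameter (defined as the length deficit against the
infinite tree), the barrier thickness and the per-capillary exchange area.
"""

from placentox import build_tree, load_preset, tail_coefficient

human = load_preset("human-T3")
tree = build_tree(human, N=18)

print(f"tail coefficient 1/(1 - 2^(-1/3)) = {tail_coefficient('exact'):.6f} (rounds to 4.85)")
print(f"generations (incl. artery):  {tree.N + 1}")
print(f"terminal branches 2^N:       {tree.branch_counts[-1]:,}")
print(f"total path length L_tot:     {tree.L_total:.4f} m")
print(f"terminal capillary d_ft:     {tree.d_ft * 1e3:.3f} mm")
print(f"barrier thickness 0.2 d_ft:  {tree.delta * 1e3:.3f} mm")
print(f"exchange area (3pi/2) d_ft^2: {tree.area_exchange * 1e4:.3f} cm^2 per capillary")
print()
print("L_tot + d_ft equals the infinite-tree length L0/(1 - 2^(-1/3)):")
print(f"  {tree.L_total:.6f} + {tree.d_ft:.6f} = {tree.L_total + tree.d_ft:.6f} m "
      f"(limit {human.L0 / (1 - 2 ** (-1 / 3)):.6f} m)")
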