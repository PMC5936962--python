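"""Which published numbers do the closed forms reproduce, and which not?

Every comparison row pits a package-computed value against the printed
reference at the precision it was printed with.  Values the formulas
reproduce (tail coefficient, prefactors, oxygen totals, volume flow) come
out `reproduced`; the documented discrepancies (terminal-capillary diameter,
total lengths, Reynolds numbers, headline resistance totals and optima) are
flagged with a note on their origin.
"""

from placentox import build_comparisons, load_preset

for label in ("human-T3", "mouse-E17.5"):
    params = load_preset(label)
    print(f"=== {label} ===")
    for row in build_comparisons(params):
        if row["status"] == "reference_only":
            continue
        model, ref = row["model"], row["reference"]
        mark = "ok " if row["status"] == "reproduced" else "FLAG"
        print(f"  [{mark}] {row['quantity']:<22} model {model:.6g} vs printed {ref:.6g}")
    print()
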