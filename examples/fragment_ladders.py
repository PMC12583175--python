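"""Generate the diagnostic fragment ladders of two simple coumarins.

Scopoletin and isofraxidin fragment from [M+H]+ by sequential neutral
losses (CH3, CHO, CO, CO2, C2H2); the rungs printed here are the
characteristic ions a screening run looks for.
"""

from coumascreen import adduct_mz, display_round, generate_ladder, monoisotopic_mass, parse_formula

for name, formula, branches in [
    ("scopoletin", "C10H8O4", [["CH3", "CHO", "CO2"]]),
    ("isofraxidin", "C11H10O5", [["CH3", "CHO", "CO2", "CO"],
                                 ["CH3", "CO2", "CH3", "C2H2"]]),
]:
    mh = adduct_mz(monoisotopic_mass(parse_formula(formula)))
    print(f"{name} ({formula}): [M+H]+ = {display_round(mh)}")
    for steps in branches:
        ladder = generate_ladder(mh, steps)
        arrows = " -> ".join(
            f"{rung} (-{step})" for step, rung in zip(steps, ladder.display_rungs())
        )
        print(f"  {arrows}")

print()
print("Each arrow is one neutral loss; the m/z values are the fragment ions")
print("expected in the MS2 spectrum, at 2-decimal report precision.")
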