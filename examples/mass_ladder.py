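"""Build the molecular-mass class ladder for a 10-cellobiose chain.

Each class is a cellulose fragment one cellobiose unit (324 g/mol of
anhydro-mass) shorter than the previous one; the terminal class is
glucose.  A cleavage splits a parent into two descendants whose masses sum
to the parent mass plus one water (18 g/mol).
"""

from cellhydro import build_ladder, cleavage_masses

ladder = build_ladder(10)

print("class  molar mass (g/mol)  label")
for i, (mass, label) in enumerate(zip(ladder.masses, ladder.labels)):
    print(f"{i:>5}  {mass:>18}  {label}")

parent, child = 0, 5
m_child, m_comp = cleavage_masses(ladder, parent, child)
print(
    f"\ncleaving class {parent} ({ladder.masses[parent]} g/mol) into class {child}: "
    f"descendants {m_child} + {m_comp} = {m_child + m_comp} g/mol "
    f"(= parent + 18, the water taken up by the broken bond)"
)
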