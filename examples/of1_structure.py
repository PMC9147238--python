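"""The OF1 octasaccharide: parsing, counts, mass, charge, and NMR shifts.

OF1 is the purified low-molecular-weight digestion product from S. latissima
fucoidans: an alpha(1,3)-linked fucose backbone carrying two alpha(1,4)-linked
4-O-sulfated fucosyl branches, six sulfates over eight residues.
"""

from fucokit import glycan as g

of1 = g.parse_glycan(g.OF1_STRING)
print("notation:", g.OF1_STRING)
print("degree of polymerization:", g.degree_of_polymerization(of1))
print("sulfates:", g.sulfate_count(of1), " acetyls:", g.acetyl_count(of1))
print("linkage census:", g.linkage_census(of1))
print("validation violations:", g.validate(of1))
print(f"average mass (neutral): {g.molecular_mass(of1):.2f} Da")
print(f"monoisotopic mass: {g.molecular_mass(of1, 'monoisotopic'):.4f} Da")
print("net charge (fully deprotonated):", g.net_charge(of1))

# Spot-check the packaged chemical-shift table for the OF1 spin systems.
table = g.load_shift_table("of1")
h1, c1 = g.shift_lookup(table, "A", 1)
h4, c4 = g.shift_lookup(table, "G", 4)
print(f"residue A, position 1: dH = {h1} ppm, dC = {c1} ppm (anomeric CH)")
print(f"residue G, position 4: dH = {h4} ppm, dC = {c4} ppm "
      "(deshielded C4 marks the sulfate ester)")

# The ~1.7 kDa mass and -6 charge are consistent with the product running as
# a low-molecular-weight, strongly anionic band on carbohydrate PAGE.
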