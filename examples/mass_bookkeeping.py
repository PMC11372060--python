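"""Molar mass bookkeeping for native-gel band assignment.

Sums monomer masses to predict complex sizes (a KaiC3 hexamer; the full
clock complex of one hexamer, six KaiA3 dimers and six KaiB3 monomers) and
expresses a titration as a molar ratio.
"""

from cyanorhythm import DEFAULT_MASSES, complex_mass, molar_ratio

print("monomer masses (kDa):", DEFAULT_MASSES)
print(f"KaiC3 hexamer:        {complex_mass({'KaiC3': 6}):g} kDa")
full = {"KaiC3": 6, "KaiA3": 12, "KaiB3": 6}
print(f"full clock complex:   {complex_mass(full):g} kDa  ({full})")
ratio = molar_ratio(4.2, 3.4, 1)
print(f"4.2 uM KaiA3 vs 3.4 uM KaiC3 -> KaiA3:KaiC3 stoichiometry 1:{ratio}")
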