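"""Dead-end modification masses and accessibility classification.

A cross-linker with one hydrolyzed end leaves a fixed-mass modification on
the labeled residue; its light/heavy isotopolog pair is the basis of
quantitative footprinting.  This prints the monoisotopic masses of the two
BS2G dead-end isotopologs and classifies a few labeling yields.
"""

from xlrefine.datasets import (BS2G_DEADEND_D0_FORMULA,
                               BS2G_DEADEND_D4_FORMULA)
from xlrefine.quantxl import classify_accessibility, monoisotopic_mass

for name, formula in (("BS2G-D0 dead-end", BS2G_DEADEND_D0_FORMULA),
                      ("BS2G-D4 dead-end", BS2G_DEADEND_D4_FORMULA)):
    print(f"{name} ({formula}): {monoisotopic_mass(formula):.5f} Da")

print()
for y in (3.0, 7.0, 15.0):
    print(f"labeling yield {y:5.1f} % -> {classify_accessibility(y)}")

# The mass difference between the isotopologs (4 x D-for-H) is what makes
# the doublet recognizable in a spectrum:
delta = (monoisotopic_mass(BS2G_DEADEND_D4_FORMULA)
         - monoisotopic_mass(BS2G_DEADEND_D0_FORMULA))
print(f"\nisotopolog spacing: {delta:.5f} Da")
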