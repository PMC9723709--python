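"""How neighbours shift a species' IC90, and where the drug goes.

Computes the model IC90 of the focal species S1 alone, next to an
equally sensitive neighbour, and next to a drug-tolerant neighbour
(100-fold lower drug affinity), then compares the per-cell drug burden
at a common reference dose.
"""

from commpharm import (
    drug_content_per_cell,
    model_ic90,
    resistant_pair,
    table1,
)

pure = table1(1)
mixed = table1(2)
tolerant = resistant_pair()

icp = model_ic90(pure, "S1")
icm = model_ic90(mixed, "S1")
icr = model_ic90(tolerant, "S1")

print(f"IC90 of S1 alone:                  {icp:8.3f} ug/mL")
print(f"IC90 next to sensitive neighbour:  {icm:8.3f} ug/mL "
      f"({100 * (icm / icp - 1):+.1f}%)")
print(f"IC90 next to tolerant neighbour:   {icr:8.3f} ug/mL "
      f"({100 * (icr / icp - 1):+.1f}%)")

cs = drug_content_per_cell(mixed, "S1")
cr = drug_content_per_cell(tolerant, "S1")
print(f"\nper-cell drug at the reference dose ({cs.reference_dose:.1f} "
      "ug/mL):")
print(f"  pure culture:            {cs.content_pure:8.2f} ug/mL per OD")
print(f"  with sensitive neighbour:{cs.content_mixed:8.2f}  "
      f"(difference {cs.difference:+.1f})")
print(f"  with tolerant neighbour: {cr.content_mixed:8.2f}  "
      f"(difference {cr.difference:+.1f})")

# A sensitive neighbour soaks up its share of the drug, lowering the
# focal species' burden (positive difference) and raising its IC90.
# A tolerant neighbour keeps growing, returns drug to the environment
# and steals carbon, so the focal species carries more drug per cell
# (negative difference) and its IC90 drops below the pure-culture one.
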