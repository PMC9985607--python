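"""Derive cyclic products and their masses from autocyclase constructs.

Parses the bundled synthetic constructs for three disulfide-rich cyclic
peptides, derives the head-to-tail cyclic product (which retains the
LPGT scar) and prints masses and charge-state m/z values.
"""

from autocyclase import (SYNTHETIC_PEPTIDE_TARGETS, derive_products,
                         example_construct, mz_for_charge, parse_construct)

for name in SYNTHETIC_PEPTIDE_TARGETS:
    construct = parse_construct(example_construct(name))
    products = derive_products(construct, order=1)
    cyc = products.cyclic
    print(f"{name}: cyclo({cyc.sequence})  [{len(cyc.sequence)} aa, "
          f"{cyc.n_disulfides} disulfide(s)]")
    print(f"  monoisotopic {cyc.mass_mono:9.3f} Da   average {cyc.mass_avg:9.3f} Da")
    for z in (1, 2, 3):
        print(f"  [M+{z}H]{z}+  mono {mz_for_charge(cyc.mass_mono, z):8.2f}"
              f"   avg {mz_for_charge(cyc.mass_avg, z):8.2f}")

# The linear (hydrolysed) by-product of any construct weighs exactly one
# water more than the cyclic product -- a quick identity check on the mass
# bookkeeping.
p = derive_products(parse_construct(example_construct("cSFTI")))
print(f"\nwater-loss identity: linear - cyclic = "
      f"{p.linear_mass.mono - p.cyclic.mass_mono:.4f} Da (expect 18.0106)")
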