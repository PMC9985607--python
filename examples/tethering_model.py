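"""Linker span, effective molarity and the critical polymerisation concentration.

The linker must physically span ~35-45 A between the recognition site and
the sortase active site; a Gaussian-chain closure then gives the local
(effective) concentration of the tethered recognition site, and equating
intra- vs intermolecular fluxes through the shared saturable recognition
step gives the critical substrate concentration C* = Km*Ceff/(Km+Ceff)
above which tandem (oligomer-forming) reactions win.
"""

from autocyclase import (critical_concentration, effective_concentration,
                         required_linker_residues)

for span in (35.0, 45.0):
    n = required_linker_residues(span, per_residue_A=3.5)
    print(f"span {span:.0f} A at 3.5 A/residue -> {n} residues required")

n_flex = 12 + 5   # a 12-residue linker plus the disordered sortase N-terminus
ceff = effective_concentration(n_flex)
print(f"\ntether of {n_flex} flexible residues -> Ceff = {ceff * 1e3:.1f} mM")

km = 20e-6
for fold in (1.0, 5.3):
    c_star = critical_concentration(ceff, km * fold)
    print(f"Km = {km * fold * 1e6:5.0f} uM -> C* = {c_star * 1e6:6.1f} uM")
print("\nBecause Ceff >> Km, C* tracks Km almost proportionally: a 5.3-fold "
      "harder-binding\nenzyme raises the polymerisation onset ~5.3-fold while "
      "tethering keeps the\nintramolecular reaction feasible.")
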