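"""Cyclisation vs oligomerisation across starting concentrations.

Integrates the lumped competition network (unimolecular cyclisation at
0.01/h vs bimolecular tandem formation at 130/(M h)) to completion over
a concentration sweep and prints the product split.  Below the crossover
concentration k_uni/k_bi (~77 uM) the monomeric cyclic product
dominates; above it, cyclic oligomers take over.
"""

import numpy as np

from autocyclase import (RateParams, build_network, crossover_concentration,
                         product_fractions, run_to_completion)

params = RateParams(mode="lumped", k_uni=0.01, k_bi=130.0, k_hyd=0.0)
network = build_network(4, params, truncation_policy="drop")
print(f"crossover C* = k_uni/k_bi = {crossover_concentration(params) * 1e6:.0f} uM\n")
print(f"{'C0 (uM)':>8} {'monomer':>9} {'oligomer':>9} {'unreacted':>10}")
for c0_um in (2.5, 5, 10, 20, 50, 80, 200):
    tc = run_to_completion(network, params, c0_um * 1e-6)
    fr = product_fractions(tc)
    print(f"{c0_um:8.1f} {fr['monomer_cyclic']:9.3f} {fr['oligomer_cyclic']:9.3f} "
          f"{fr['unreacted']:10.5f}")
print("\nEach row is the fraction of starting target units ending up in each "
      "product class;\nmonomer yield stays >90% only in the dilute (first-order) "
      "regime.")
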