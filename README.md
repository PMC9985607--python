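# autocyclase

Kinetics, design and inference tools for **self-cyclising fusion proteins**
("autocyclases"): constructs that carry their own sortase A, so head-to-tail
macrocyclisation of the fused target proceeds *intramolecularly*.  The
package is for protein engineers and kineticists who want to understand and
tune the competition that governs such systems:

* **unimolecular cyclisation** (rate `k_uni·[A]`) → cyclic monomer,
* **bimolecular tandem formation** (rate `k_bi·[A]²`) → tandem autocyclases
  and, from them, cyclic oligomers,
* **hydrolysis** (rate `k_hyd·[A]`) → linear by-product.

It provides, as plain Python APIs:

* a mass-action ODE model of the full order-resolved network plus an exact
  Gillespie counterpart, with strict target-unit and enzyme-unit
  conservation accounting (`autocyclase.network`, `autocyclase.ssa`);
* the initial-velocity inference used to establish reaction order: OLS
  velocities in a ≤10%-conversion window, a non-negative least-squares fit
  of `v0 = k1·C0 + k2·C0²`, bootstrap intervals and regime labels from the
  linear fraction `k1/(k1 + k2·C0)` (`autocyclase.inference`);
* the tethering model: required linker length for a 35–45 Å span,
  Gaussian-chain effective molarity of the tethered recognition site, and
  the critical polymerisation concentration `C* = Km·Ceff/(Km + Ceff)`
  (`autocyclase.linker`);
* a construct parser that splits a fusion into
  cap | ENLYFQ/G | target | LPXTG | linker | (LVPR/S) | sortase | His-tag,
  derives the cyclic product (which retains the LPXT scar) and predicts
  monoisotopic/average masses and charge-state m/z (`autocyclase.construct`,
  `autocyclase.masses`);
* a synthetic-data generator for noisy LC/MS-style time courses and
  mass-weighted SDS-PAGE densitometry lanes (`autocyclase.synth`), and a
  seeded end-to-end workflow with a self-describing JSON report
  (`autocyclase.workflow`), also exposed as a thin `autocyc` CLI.

## Worked example

The dilute-regime claim in one screenful — integrate the lumped competition
(`k_uni = 0.01 /h`, `k_bi = 130 /(M h)`) to completion across a
concentration sweep:

```bash
$ python examples/simulate_competition.py
crossover C* = k_uni/k_bi = 77 uM

 C0 (uM)   monomer  oligomer  unreacted
     2.5     0.969     0.031    0.00005
     5.0     0.940     0.060    0.00005
    10.0     0.887     0.113    0.00005
    20.0     0.799     0.201    0.00005
    50.0     0.623     0.377    0.00005
    80.0     0.515     0.485    0.00005
   200.0     0.312     0.688    0.00005
```

At 5 µM, 94% of the material ends as the monomeric cyclic product — the
near-quantitative dilute-regime yield — while above the crossover
concentration `C* = k_uni/k_bi ≈ 77 µM` cyclic oligomers dominate.
Recovering the constants back from noisy synthetic triplicates:

```bash
$ python examples/infer_rate_constants.py
recovered k1 = 0.0096 /h   (generating value 0.0100)
recovered k2 = 123.9 /(M h)  (generating value 130.0)
95% CI k1: [0.0095, 0.0098]
95% CI k2: [103.6, 137.4]

regime per starting concentration:
   2.5uM: unimolecular  (linear fraction 0.969)
     5uM: unimolecular  (linear fraction 0.939)
    10uM: mixed         (linear fraction 0.886)
    20uM: mixed         (linear fraction 0.795)
```

Both constants come back within a few percent (the small shortfall is the
documented initial-window bias), and the regime labels reproduce the
first-order behaviour at 2.5–5 µM with bimolecular interference appearing
by 10 µM.  Other examples: `design_cyclic_peptides.py` (cyclic product
masses and m/z for disulfide-rich peptides), `tethering_model.py` (linker
span, effective molarity, Km-controlled critical concentration) and
`gel_densitometry.py` (densitometry ceiling of 0.5).

The same capabilities are scriptable from the shell, e.g.
`autocyc simulate --c0-um 5 --out tc.csv`, `autocyc design --fasta f.fa`,
`autocyc linker --span-a 35 --per-res-a 3.5`, `autocyc run --config run.yaml`.

See `docs/methods.md` for the model conventions (homodimer factor of two,
truncation policies, observable choice for the quadratic term) and known
limitations.

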