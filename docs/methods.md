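# Methods

## The system being modelled

An *autocyclase* is a fusion protein that carries its own ligase: a target
peptide or protein is fused, through a sortase A (SrtA) recognition site
(LPXTG, here LPGTG) and a flexible linker, to the SrtA enzyme itself, with a
TEV-cleavable cap in front and a His tag behind.  TEV cleavage (ENLYFQ↓G)
exposes an N-terminal glycine nucleophile; SrtA cleaves its recognition site
between T and G, forming a thioester (acyl-enzyme) intermediate, and the
tethered glycine attacks it head-to-tail.  Three fates compete:

1. **Unimolecular cyclisation** — intramolecular attack yields the cyclic
   monomer and releases SrtA; concentration-independent, first order.
2. **Bimolecular tandem formation** — the glycine of *another* autocyclase
   attacks, yielding a tandem autocyclase with several fused target units and
   one SrtA, the precursor of cyclic oligomers; second order.
3. **Hydrolysis** — the thioester is resolved by water, giving a linear
   product irreversibly.

## Reaction network (`network.py`, `ssa.py`)

Species are indexed by target-unit count n = 1..N: active autocyclases `An`,
thioester intermediates `Tn` (mechanistic mode only), cyclic products `Cn`,
linear products `Ln`, plus free enzyme `E` and an inert pool `Ainact`
(fraction `f_inactive` of starting material with misfolded enzyme, default 0).

The default **lumped** parameterisation collapses recognition, acylation and
attack into three channels with constants `k_uni` (1/h), `k_bi` (1/(M h)) and
`k_hyd` (1/h); defaults are the constants measured for the MSP11 system,
`k_uni = 0.01 /h`, `k_bi = 130 /(M h)`, `k_hyd = 0`.  The **mechanistic**
mode makes `Tn` explicit (`k_act`, `k_cyc`, `k_poly`, optional `k_rev`,
defaults user-supplied) for studying the intermediate; no sub-constants are
available from data, so the lumped mode is the calibration target.

Conventions that matter for the numbers:

* **Homodimerisation factor of two.** The `An + An` channel proceeds at rate
  `k_bi·[An]²` per unit volume, each event consuming two `An`, so
  `d[An]/dt` receives `−2·k_bi·[An]²`.  The matching SSA propensity is
  `(2·k_bi/(V·N_A)) · a(a−1)/2`.  With this convention the monomer yield of
  the pure competition obeys the branching quadrature
  `(1/C0)∫₀^C0 k_uni/(k_uni + 2 k_bi a) da` exactly when only cyclisation and
  homodimerisation drain the monomer, and the concentration at which the
  bimolecular *event rate* overtakes the unimolecular one is
  `C* = k_uni/k_bi ≈ 77 µM` — inside the 50–200 µM window where oligomers
  are observed to take over.  The alternative convention (channel rate
  `½k_bi[A]²`) would double the fitted `k_bi`; the choice is stated here so
  fitted constants are interpretable.
* **Truncation.** Default N = 4 (monomer/dimer species dominate
  observations; trimers appear at high C0).  `policy="drop"` removes any
  channel whose product would exceed N — both conservation ledgers then hold
  identically; `policy="absorb"` routes the product to the order-N species
  and books the surplus target units into an explicit `leakU` pool so the
  ledger still closes.  The reported `leak_fraction` is `leakU/C0`.
* **Conservation diagnostics.** Target units `Σ n([An]+[Tn]+[Cn]+[Ln])` and
  enzyme units `Σ([An]+[Tn]) + [E]` (plus inert and leak pools) must equal
  C0 at all times; the ODE path enforces ≤ 1e−6 relative drift (typically
  ~1e−15 at LSODA rtol 1e−8 / atol 1e−14 M) and the SSA is exact in copy
  numbers.
* **Oligomer ring closure** defaults to the same `k_uni` for every ring size
  (no data distinguishes them); `RateParams.ring_scale` is a per-order
  multiplier hook.

Units are molar and hours throughout the internals; the CLI accepts µM.

## Initial-velocity inference (`inference.py`)

`estimate_initial_velocity` takes the OLS slope over the initial window in
which the monitored product stays below 10% of C0 (configurable), requiring
at least four points; the window and residual-based SE are reported.  The
slope of a line fitted to a first-order rise truncated at conversion
fraction q underestimates `k·C0` by about `−ln(1−q)/2` (≈ 2.5% at q = 0.05)
— this window bias is inherent to the estimator and is why end-to-end
recovery is specified at 10%, not 1%.

The fitted law is `v0 = k1·C0 + k2·C0²` by **non-negative least squares**
(rate constants are physical).  The observable matters: the initial rate of
*free-enzyme release* is exactly `k_uni·C0 + k_bi·C0²` (one SrtA per
turnover, whichever channel fires), so fitting enzyme release recovers both
constants; the cyclic monomer alone forms at `k_uni·[A1]` and carries no
quadratic term.  The default product species is therefore `E`.

Regimes are labelled from the linear fraction `k1/(k1 + k2·C0)`:
unimolecular ≥ 0.90, bimolecular ≤ 0.10, mixed in between.  With the default
constants this reproduces first-order behaviour at 2.5–5 µM (linear fraction
0.97–0.94; exactly 0.9390 at 5 µM) and mixed behaviour at 10 µM (0.885).

Uncertainty is by case-resampling bootstrap of replicate velocities within
each concentration (percentile intervals, 1000 draws, seeded).  Known
limitation: with only three replicates per concentration the percentile
interval undercovers (≈ 78% against nominal 95% in our simulations);
coverage reaches ~92% at ten replicates.  Bias-corrected intervals would be
the next refinement.

## Tethering model (`linker.py`)

* `required_linker_residues` = ⌈span / contour-per-residue⌉ with 3.5 Å per
  extended residue, reproducing the 35 Å ↔ 10-residue correspondence (the
  35–45 Å / 3.5–4.5 Å window brackets 8–13 residues).
* `effective_concentration` uses the Gaussian-chain (Jacobson–Stockmayer
  type) end-closure `Ceff = (3/(2π⟨r²⟩))^{3/2}/N_A` with
  `⟨r²⟩ = contour·b` (Kuhn length b = 7.6 Å for GS-rich chains, contour
  3.8 Å/res); the flexible tether counts the linker plus, by default, 5
  disordered enzyme N-terminal residues.  Typical outputs are tens of mM
  for 10–20-residue tethers.  The model refuses chains shorter than one
  Kuhn segment, where the closure is meaningless; it ignores excluded
  volume and orientation factors, so Ceff is an order-of-magnitude scale,
  not a calibrated constant — which is all the competition argument needs.
* `critical_concentration` equates *initial fluxes* through the shared
  saturable recognition step: intramolecular ∝ Ceff/(Km+Ceff), saturable;
  intermolecular ∝ [A]/Km below saturation.  Hence
  `C* = Km·Ceff/(Km+Ceff)`, which tends to Km when Ceff ≫ Km: raising Km
  5.3-fold raises the polymerisation onset essentially 5.3-fold while the
  tethered intramolecular reaction stays feasible.  No measured Ceff or Km
  exists for these constructs, so C* is validated through limits and
  monotonicity, not a printed concentration.

## Construct parsing and product masses (`construct.py`, `masses.py`)

The parser anchors on the three unambiguous motifs (ENLYFQG, LP-X-TG,
terminal ≥6×H run), then identifies the linker after the recognition site
(named designs L7/L12/L7D/L14D/L19D, an explicit user linker, or a generic
span ending in the thrombin site LVPR↓S); everything between linker and His
tag is the enzyme body.  Extra LPXTG-like matches inside the target produce
warnings, and the match adjacent to the identified linker wins.  The TEV
motif is seven residues but the partition assigns its G to the target (the
nucleophile is shared), which is the one deliberate overlap in the segment
bookkeeping.

Products: the order-n cyclic product is the n-fold concatenation of
(target + LPXT) closed head-to-tail — the scar LPXT stays in the ring, the
recognition site's fifth residue (G) leaves with the linker–enzyme–tag
byproduct.  The linear hydrolysed counterpart is the same residues open
chain, exactly one water heavier.  Masses come from the standard residue
tables (monoisotopic and average always both computed, since published
"calculated" masses of intact peptides are often average-scale), with 2 H
subtracted per disulfide and m/z = (M + z·1.00728)/z.

The bundled example constructs (cSFTI, cKB1, cVc1.1) are **synthetic
reconstructions**: native peptide sequence + LPGTG recognition site with a
short placeholder enzyme body.  Their derived cyclic products reproduce the
published product ions where reconstruction is possible: cSFTI
(cyclo(GRCTKSIPPICFPDLPGT), 1 disulfide) gives [M+2H]²⁺ = 941.5
monoisotopic (the observed value) and 942.1 average (the calculated value);
cKB1 (cyclo(GVCGETCVGGTCNTPGCTCSWPVCTRNLPGT), scar overlapping the native
GLP, 3 disulfides) gives [M+3H]³⁺ = 1019.8 on the average scale *without*
the disulfide-hydrogen correction — with the correction every scale sits
2.0 lower, pinning the published calculation to the uncorrected convention.
The minimal cVc1.1 reconstruction does **not** reproduce its published ion
(1080.2 vs 1139.3), implying the original construct carried additional
residues that cannot be inferred from the native sequence; it is kept as a
worked example only.

## Synthetic data (`synth.py`)

Time courses emulate extracted-ion-chromatogram quantitation: the ODE truth
per C0 overlaid, per replicate, with multiplicative Gaussian noise
(relative SD 2%, reflecting that EIC areas scale with abundance) plus an
additive floor (1e−9 M); three replicates by default, all driven by one
seed with independent child streams per replicate, negative draws clipped
to zero and counted.  The true noise magnitude of the original
measurements is unreported; these defaults are declared assumptions sized
to make replicate error bars realistic, and are config-exposed.  Gel lanes
model Coomassie-type staining: band intensity ∝ mass × molar amount, with
either all-band normalisation (default; at complete conversion the
equimolar cyclic product and released enzyme with equal masses give the
cyclic band exactly 0.5 of the lane) or enzyme-excluded normalisation.
`apply_in_vivo_hydrolysis` books pre-reaction losses of dynamic-linker
constructs as a reduced effective C0 plus a pre-cleaved pool.

What passing tests on these synthetics do *not* show: real LC/MS noise is
heteroscedastic beyond the multiplicative model (ionisation suppression,
integration errors), gels saturate and smear, and per-construct rate
constants vary (a dynamic 14-residue linker completes cyclisation in ~1 h,
implying a much larger effective `k_uni` than the 0.01/h default).  The
pipeline validates the *method* — order discrimination, constant recovery,
regime labels — under stated conditions, not any particular construct.

## Problem sizes and determinism

Default study conditions: C0 grid {2.5, 5, 10, 20} µM, 13 time points over
6 h, triplicates; ODE runs use N = 4, drop policy; SSA checks use 10⁴
copies and 300–1000 trajectories; bootstrap 1000 draws (200–300 in tests).
Every stochastic stage derives its stream from a single seed (stage-name
hashed), so reports are byte-identical across reruns with the same seed.
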