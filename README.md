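# cagefield

Analysis toolkit for **designed local electric fields (LEFs) in caged
metal-oxo catalysts**. Supramolecular cages that trap an iron(IV)-oxo
porphyrin oxidant (a synthetic cytochrome-P450 analog) together with a
substrate can steer both reactivity and enantioselectivity through the
electric field that the cage, the oxidant's charged periphery and the
solvent exert at the Fe=O reaction center. `cagefield` provides the
quantitative machinery for that analysis:

- **Local electric fields** at probe points on the Fe=O axis from
  point-charge topologies, `F = k_C Σᵢ qᵢ (p − rᵢ)/|p − rᵢ|³`
  (k_C = 14.3996 V·Å·e⁻¹), projected per frame onto the reaction axis
  (**z**, Fe→O) and the lateral selectivity axis (**y**), decomposed by
  source group (periphery, cage, solvent, …).
- **Group dipole moments** from partial charges,
  `μ = k_D Σᵢ qᵢ (rᵢ − o)` (k_D = 4.80320 D/e·Å), and **field–dipole
  stabilization energies** `ΔE_a = k_E F_a μ_a`
  (k_E = 4.8009 kcal·mol⁻¹·D⁻¹·(V/Å)⁻¹; Gaussian sign convention,
  negative = stabilizing).
- **Selectivity analytics**: distance population histograms
  ("Boltzmann populations" under equilibrium sampling), representative
  most-populated snapshots, π-stacking contact occupancy, and
  two-state Boltzmann enantiomeric ratios
  `r = exp(ΔΔE‡ / RT)` and spin-state preferences from barrier
  differences.
- **Free-energy profiles** from staged nonequilibrium pulling via
  Jarzynski's equality `⟨exp(−βW)⟩ = exp(−βΔG)` with stagewise
  (adaptive-steering) stitching and percentile-bootstrap uncertainty.
- A **synthetic cage-system generator** (charged periphery ring, polar
  cage shell, solvent shell, two-population pro-R/pro-S distances,
  work traces with exact Jarzynski recovery targets) so every stage has
  an analytic or statistical oracle.

Intended users: computational chemists analysing MD trajectories of
host–guest catalyst models who need reproducible field/dipole/PMF
numbers, and method developers who want a fully oracled test bed.

## Worked example

Generate a synthetic study and analyse it end to end:

```sh
cagefield demo --seed 3 --outdir demo
cagefield run --config demo/config.yaml
```

which prints (abridged):

```
selectivity: {'ratio': 155.86, 'major': 'R', 'percent_major': 99.36, 'dd_barrier_kcal': 3.01}
pmf: {'total_dG_kcal': 20.10, 'stage_dG_kcal': [1.61, 2.38, ...], 'n_traj': 50}
distance_pairs: {'proR_O1': {'mode_A': 2.65, ...}, 'proS_O1': {'mode_A': 3.65, ...},
                 'stack1': {'occupancy': 0.95, ...}}
```

The ratio 155.9 : 1 is the two-state Boltzmann consequence of a
3.01 kcal/mol pro-R/pro-S barrier gap at 300 K; the PMF total of
20.10 kcal/mol recovers the linear 1 kcal/mol/Å profile built into the
demo's work traces (3→23 Å) within its bootstrap noise; the pro-R
distance mode sits ~1 Å closer to the oxo oxygen than pro-S, and the
scripted stacking contact is occupied 95% of the frames below 5 Å
(40-frame demo; the generator's asymptotic occupancy is 0.88).

Single quantities are available directly:

```sh
cagefield stabilize --fz -0.29 --muz 8.67 --fy 0.19 --muy 1.76
# dE_z = -12.07 kcal/mol
# dE_y = +1.61 kcal/mol
cagefield selectivity --barriers 4.8 7.81 --temp 298.15
# ratio 160.8 : 1 favoring R (99.38% major) at 298.15 K (ddE = 3.01 kcal/mol)
```

Library use mirrors the CLI: see `cagefield.lef.field_series`,
`cagefield.dipole.table1_report`, `cagefield.pmf.asmd_stitch`,
`cagefield.pipeline.run_full_analysis`.

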