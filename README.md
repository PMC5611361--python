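# twigscale

Leaf–stem allometry and stem hydraulics/mechanics analysis for twig-level
trait datasets, with a synthetic-data generator that emulates a nested
multi-species sampling design (species → individuals → twigs).

The package covers the full workflow of a comparative twig-trait study:

- **`synthetic_data`** — Yule phylogenies, species-level trait means evolved
  by multivariate Brownian motion on log10 scale with configurable SMA
  exponents and trade-off correlations, and raw measurement tables (twig
  architecture, vessel axes, gravimetrics, three-point bending) with
  individual- and twig-level multiplicative noise. Ground truth is retained
  so every downstream stage can be validated.
- **`xylem_mechanics`** — Poiseuille-equivalent vessel diameters from
  elliptical semi-axes, hydraulically weighted diameter, vessel
  density/fraction, Hagen–Poiseuille theoretical specific conductivity,
  wood density, saturated water content, and flexural stiffness / structural
  modulus of elasticity from load–deflection series.
- **`twig_architecture`** — per-twig derived traits (SLA, per-leaf lamina
  area/mass, petiole mass, leafing intensity) and two-stage species means
  (twigs → individual → species).
- **`allometry`** — standardized major axis (SMA) fits on log10 scale, 95%
  slope CIs, the residual-vs-fitted-axis slope test (isometry test against
  b0 = ±1), and a likelihood-ratio common-slope test across groups.
- **`phylo`** — newick parsing/validation (binary, rooted, positive branch
  lengths), phylogenetically independent contrasts, and through-origin
  contrast correlations.
- **`multivariate`** — pairwise-complete Pearson matrices (species level
  and contrast level), multiple factor analysis over stem/leaf variable
  groups, and nested species/individual/twig variance components.
- **`pipeline`** / **`cli`** — orchestration with CSV outputs, a JSON run
  manifest, and a markdown report.

## CLI

```sh
# synthetic dataset (tree + measurement CSVs + truth) into ./sim
twigscale simulate --seed 1 --outdir sim

# full analysis of a default synthetic scenario
twigscale all --seed 1 --outdir out

# derive species means from your own raw tables
twigscale derive --twig-csv twigs.csv --vessel-csv vessels.csv --out species.csv
```

`twigscale all` writes `species_means.csv`, `sma_table.csv` (Y, X, R2,
slope, CI, P), cross-species and PIC correlation matrices, MFA loadings /
scores / axis variances, per-trait variance components, `manifest.json`,
and `report.md`. A YAML/JSON config (`--config`) can replace the default
simulation with file inputs (`twig_csv`, `vessel_csv`, `gravimetric_csv`,
`bending_csv`, `tree_path`). Exit codes: 0 ok, 1 user error, 2 internal.

Expected input columns:

- twig table: `species,individual,twig,stem_area_mm2,stem_mass_g,leaf_count,
  total_lamina_area_cm2,total_lamina_mass_g,total_petiole_mass_g,
  petiole_area_mm2` (+ optional leaf-anatomy columns `lt_um,uet_um,pt_um,
  sp_um,let_um,ss_um,sd_per_mm2`)
- vessel table (long): `stem_id,species,individual,a_um,b_um,
  analyzed_area_mm2` — `a_um`/`b_um` are vessel SEMI-axes
- gravimetric table: `stem_id,species,individual,fw_g,sw_g,dw_g,volume_cm3`
- bending table (long, one row per load step): `stem_id,species,individual,
  span_mm,diameter_mm,load_n,deflection_mm`

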