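# junctension

Quantification toolkit for epithelial junction imaging and in-vitro
actin-binding biochemistry:

- **Block heat maps** — center-anchored block-averaged junctional
  intensity maps (default 3×3 µm² blocks) from multi-channel apical
  projections, normalized against a junctional reference channel
  (E-cadherin), averaged across discs under a minimum-count rule, and
  summarized by a posterior/anterior (P/A) intensity ratio per disc.
- **Junction masking** — Otsu / percentile / fixed thresholding of the
  reference channel restricts all quantification to junctional pixels.
- **Colocalization** — Pearson correlation between two channels over
  the junction mask.
- **Laser-ablation recoil** — initial recoil velocity from post-cut
  vertex-separation traces (displacement over the first second),
  with anterior-vs-posterior comparison.
- **Co-sedimentation binding** — supernatant/pellet lane densitometry,
  a single-site mass-action equilibrium model with ligand depletion, a
  two-ligand shared-site competition solver, binding-curve fitting and
  percent-displacement quantification.
- **Statistics** — group means ± 95% CI, Student's t-test, one-way
  ANOVA with Dunnett (vs control) or Tukey HSD (all pairs) adjustment.
- **Synthetic data** — seeded generators with known ground truth for
  all of the above: Voronoi-tessellated two-compartment disc images,
  saturating-exponential recoil traces, and equilibrium-model gel
  lanes. Every quantification stage is validated against this ground
  truth.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the end-to-end acceptance criteria
(oracle equivalence of the block quantifier, P/A ratio recovery on
seeded cohorts, the min-count averaging rule, normalization scale
invariance, colocalization limits, recoil closed forms, equilibrium
solver cross-checks, binding-fit recovery, gel round-trips, and
Dunnett vs a Monte-Carlo oracle).

## CLI

The umbrella command is `junctension`:

```sh
# synthetic inputs (TIFF + JSON truth sidecar / CSV)
junctension simulate disc   --config disc.json --out sim/ --seed 1 --n-discs 6
junctension simulate recoil --out rec/ --seed 1 --n-traces 20 --side anterior
junctension simulate gel    --config gel.json --out gel/ --seed 1

# per-disc heat maps, cohort average, render, per-disc P/A ratios
junctension heatmap --images sim/disc000.tif --images sim/disc001.tif \
    --out hm/ --block-um 3 --min-count 3 --mode ratio

# Pearson colocalization over the junction mask
junctension coloc --image sim/disc000.tif --channels signal,ecad --out coloc.csv

# recoil velocities (first-second endpoint by default)
junctension recoil --traces rec/traces.csv --window 1.0 --method endpoint --out v.csv

# co-sedimentation quantification / model fitting / competition sweep
junctension cosed quantify --in gel/lanes.csv --out frac.csv
junctension cosed fit --in gel/truth_series.csv --sites 2.0
junctension cosed compete --liga 12 --kda 5 --ligb-max 2.59 --kdb 0.5 --sites 2 \
    --out compete.csv

# group statistics from a CSV with columns group,value
junctension stats --in values.csv --design vs_control --control ctrl --out table.csv
```

Every CLI run writes a `run_manifest.json` (inputs, config, versions)
next to its outputs.

## Conventions

- Coordinates are 0-based (row, col), origin top-left; physical sizes
  in µm; µm→px conversion floors block-edge positions.
- The block grid is anchored so a block-lattice corner coincides with
  the annotated disc center; `center_index` is the block up-and-left of
  that corner. Partial edge blocks are dropped.
- Blocks with no masked pixels are NaN, never zero; cohort averaging
  pads smaller maps with NaN and requires `min_count` (default 3)
  contributing discs per block.
- P/A ratios are computed per disc and then summarized across discs;
  the averaged heat map is for display.
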