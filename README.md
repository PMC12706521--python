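# phylogrid

Spatial phylogenetics on gridded communities. `phylogrid` implements the
analysis pipeline used to map diversity and endemism of a regional species
assemblage — e.g. forest birds across a peninsula — from three ingredients:
a dated phylogeny, species distributions (range polygons or occurrence
points), and gridded climate/topography layers. Because the real inputs of
such studies (range maps, occurrence databases, paleoclimate rasters) are
rarely redistributable, the package ships a synthetic-data module that
generates all three with known ground truth, so every stage of the
pipeline is testable end to end.

## What it computes

For a binary cells × species matrix **A** on a regular grid and a rooted
phylogeny with branch lengths L_b:

* **SR** — species richness per cell; **WE** — weighted endemism,
  WE = Σ_i 1/r_i over resident species, where r_i is the number of cells
  species i occupies.
* **PD** (Faith) — total branch length of the rooted subtree spanning a
  cell's species; **PE** (Rosauer) — Σ_b L_b / R_b over those branches,
  where R_b counts the cells holding any descendant of branch b.
* **RPD / RPE** — PD and PE divided by the same metric on a *comparison
  tree* (same topology, all branches set to the mean length); values > 1
  flag concentrations of long, old branches.
* **TILD** — time-integrated lineage diversity, ∫ ln N(t) dt over the
  cell subtree's depth.
* **Null models & CANAPE** — fixed-fixed (`swap`, `curveball`) and
  fixed-equiprobable (`r0`) matrix randomizations, Monte-Carlo tail ranks
  for PD/RPD/PE/RPE, and the categorical analysis of neo- and
  paleo-endemism (neo / paleo / mixed / super).
* **Beta diversity** — PhyloSor similarity and the Baselga decomposition
  of phylogenetic dissimilarity into turnover and nestedness, with K-means
  regionalization and elbow selection of K.
* **Climate-change velocity** — per-cell |temporal trend| / spatial
  gradient (km/yr) from a gridded time series, min-max normalization and
  multi-variable combination.
* **Environmental correlates** — predictor screening at |r| < 0.5, OLS,
  Moran's I correlograms, distance-band spatial weights, and
  maximum-likelihood SAR error/lag models ranked by AIC.
* **NODF** nestedness of the community matrix (0–100).

## Worked example

```python
import numpy as np
import phylogrid as pg
from phylogrid.nullmodels import null_test, canape_classify

# a 12 x 12 grid of 25-km cells, 80 species, with a paleo-endemism hotspot
spec = pg.ScenarioSpec(hotspot="paleo", seed=0)
tree, cm = pg.simulate_scenario(spec)

table = pg.metric_table(cm, tree)
print(table.loc[[65, 0], ["SR", "WE", "PD", "PE", "RPE"]].round(3))

nr = null_test(cm, tree, "curveball", n_reps=499, n_itr=3000, seed=1)
res = canape_classify(nr)
hot = spec.hotspot_cells()
print(res.counts())
print("hotspot cells flagged:",
      np.isin(res.category[hot], ["paleo", "mixed", "super"]).sum(), "/", len(hot))
```

Output:

```
    SR     WE      PD     PE    RPE
65  20  2.367  39.385  2.947  1.323
0    6  0.358  19.227  0.416  1.012
```

Cell 65 sits in the middle of the simulated hotspot: its residents include
most of the 16 range-restricted long-branch endemics, so its weighted and
phylogenetic endemism (WE, PE) are roughly seven-fold the background cell
0, and its RPE ratio of 1.32 marks an excess of long rare branches. The
CANAPE step confirms this against 499 fixed-fixed randomizations:

```
{'not_significant': 131, 'neo': 2, 'paleo': 2, 'mixed': 8, 'super': 1}
hotspot cells flagged: 9 / 9
```

All nine hotspot cells are classified paleo/mixed/super, while only 4 of
the 135 occupied background cells (3%) reach any significant category —
consistent with the test's significance level.

A command-line interface mirrors the library:

```bash
phylogrid simulate --scenario scenario.yaml --out sim/
phylogrid diversity --matrix sim/community.csv --tree sim/tree.nwk --out metrics.csv
phylogrid canape    --matrix sim/community.csv --tree sim/tree.nwk --n-reps 999 --out canape.csv
phylogrid beta      --matrix sim/community.csv --tree sim/tree.nwk --k-max 10 --out clusters.csv
phylogrid velocity  --series climate/ --out vocc.asc
phylogrid correlates --metrics metrics.csv --predictors env.csv --out fits.json
```

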