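# junctiontrack

Single-molecule localization and tracking analysis of endoplasmic
reticulum–plasma membrane (ER-PM) junction organization.

ER-PM junctions are sub-200-nm sites where the ER calcium sensor STIM1 gates
the plasma-membrane channel ORAI1 to drive store-operated calcium entry.
Quantifying how ORAI1, STIM1 and cytoskeletal septin territories organize at
these sites requires photoactivated localization microscopy (PALM) and
single-particle tracking (sptPALM), and a matching analysis toolchain. This
package provides that toolchain for localization tables produced by standard
SMLM software:

* **Colocalization** — normalized colocalization in green,
  `NCG = (colocalized px / green px) / (red px / total px)`, on binary
  10-nm renderings (1 = random, >1 enrichment, <1 exclusion), and the
  stepwise-dilation **median distance** from a target channel to a reference
  territory (3-pixel/30-nm steps until 50% coverage).
* **Tracking** — frame-to-frame linking by optimal (Hungarian) assignment
  gated at 480 nm per 50-ms frame, no gap closing, minimum 3 localizations.
* **Diffusion** — ensemble MSD curves and two corrected estimators:
  `D₁ = 1.5·(MSD₁ − MSD₁,fixed)/(4·0.05 s)` (motion-blur factor 1.5 for
  continuous acquisition, localization error from fixed-cell calibration
  `MSD₁,fixed = 2σ² = 4σ²_axis`) and `D₂ = (MSD₂ − MSD₁)/(4·0.05 s)`
  (corrections cancel in the difference); confinement radius
  `r_c = √(plateau − MSD₁,fixed)`.
* **Junction-referenced trajectories** — STIM1-marked junction masks
  (density filter ≥5 neighbors in 100 nm → 10-nm raster → 50-nm dilation),
  on/off-junction track classification, maximum excursions d_max, and the
  two-state STIM-engagement fraction
  `f = (D_LSLD − D_WT)/(D_LSLD − D_STIM1)`,
  which reads the junctional wildtype-ORAI1 diffusion coefficient as a
  mixture of a free state (the STIM-blind LSLD mutant) and a bound state
  (STIM1 itself).
* **Cluster segmentation** — Voronoi tessellation clipped to the ROI, a
  Monte-Carlo complete-spatial-randomness threshold on polygon areas,
  watershed segmentation of the 10-nm first-rank density map with a
  10-pixel minimum, plus an independent connected-component particle
  analysis.
* **Synthetic data** — generators with ground truth for everything above:
  two-state free/bound Brownian trajectories with sub-frame motion blur and
  localization noise, stationary-emitter calibration fields, randomized
  disc-cluster fields, and dual-channel fields with a planted enrichment.

## Worked example

```python
from junctiontrack.diffusion import LocalizationCalibration, estimate_D1
from junctiontrack.junctions import engaged_fraction
from junctiontrack.simulate import ClusterSimConfig, simulate_cluster_field
from junctiontrack.clustering import (voronoi_field, mc_density_threshold,
                                      segment_clusters, cluster_summary)

# localization-error calibration from fixed-cell trajectories
cal = LocalizationCalibration(msd1_fixed=0.0085)   # μm²
print(f"sigma_2d = {cal.sigma_2d_nm:.1f} nm, sigma_axis = {cal.sigma_axis_nm:.1f} nm")

# corrected single-step D from on-junction mean first-step r², and the
# two-state engagement fraction
D_wt = estimate_D1(0.0147, cal.msd1_fixed).D
D_lsld = estimate_D1(0.0197, cal.msd1_fixed).D
print(f"D_wt = {D_wt:.4f} um^2/s, D_lsld = {D_lsld:.4f} um^2/s")
res = engaged_fraction(D_wt, D_lsld, D_stim1=0.0394)
print(f"fraction engaged = {res.fraction_engaged:.2f}")

# segment a simulated clustered field (17 discs of 200 nm in 4 × 4 μm)
table, truth = simulate_cluster_field(ClusterSimConfig(seed=1))
vf = voronoi_field(table)
thr = mc_density_threshold(vf, iterations=100, seed=2)
cs = segment_clusters(vf, thr.threshold)
s = cluster_summary(cs)
print(f"threshold = {thr.threshold:.0f} nm^2 ({thr.status})")
print(f"{s['n_clusters']} clusters, {s['clusters_per_um2']:.2f} /um^2, "
      f"fractional area {s['fractional_area']:.3f}, median diameter {s['median_diameter_nm']:.0f} nm")
```

prints

```
sigma_2d = 65.2 nm, sigma_axis = 46.1 nm
D_wt = 0.0465 um^2/s, D_lsld = 0.0840 um^2/s
fraction engaged = 0.84
threshold = 3641 nm^2 (ok)
21 clusters, 1.31 /um^2, fractional area 0.036, median diameter 192 nm
```

A 65-nm two-dimensional localization error (46 nm per axis) is subtracted
from every single-step estimate; after the blur and error corrections the
junctional wildtype channel diffuses at 0.0465 μm²/s against a free-state
reference of 0.0840 μm²/s, which the two-state mixture reads as 84% of
junctional channels engaged with STIM1. On the simulated field the
Monte-Carlo threshold accepts Voronoi cells below ≈3600 nm², and watershed
segmentation recovers close to the 17 planted 200-nm clusters (the count
fluctuates by a few across seeds; fractional area ≈ the planted 0.033).

## Command line

Every stage is also available as a config-driven subcommand producing
deterministic, manifest-hashed output tables:

```sh
junctiontrack simulate sim.yaml     # cluster_field | two_state | fixed_emitters
junctiontrack track cfg.yaml        # link localizations into trajectories
junctiontrack msd cfg.yaml          # MSD curve + D estimates
junctiontrack coloc cfg.yaml        # NCG + median distance per ROI
junctiontrack junctions cfg.yaml    # junction mask, on/off classes, excursions
junctiontrack clusters cfg.yaml     # Voronoi + particle-analysis segmentation
junctiontrack report cfg.yaml       # condition-level medians over ROIs
```

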