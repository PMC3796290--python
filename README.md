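# lcdmcensor

Censored analysis of labeled cortical distance maps (LCDMs) for cortical
morphometry.

An LCDM characterizes the laminar cortical mantle of a region of interest
as the multiset of signed distances from gray-matter (GM) voxel centroids
to the triangulated GM / white-matter (WM) boundary surface.  Pooling the
distances of all subjects within a diagnostic group gives a sensitive
overall comparison between groups, but says nothing about *where* (at
which depth in the cortical mantle) the differences occur.  Censoring
answers that question: sweep a threshold γ_k = k·δ across the mantle, keep
at each step only the distances d ≤ γ_k, run the group comparisons on the
censored sets, and read off the distance range over which significance
persists.

The package is aimed at neuroimaging researchers who have segmented label
volumes and GM/WM surface meshes (or precomputed distance tables) and want
depth-resolved group comparisons, and at methodologists who want to study
the statistical behavior of the censoring procedure itself.

## What it computes

- **Geometry** — signed distances `D_ijk = min_{s ∈ S(Δ)} ‖C_M(ν_k) − s‖₂`
  from each GM voxel centroid to the nearest vertex of the triangulated
  surface `S(Δ)`, negative on the WM side; retention filter
  [−0.5, 5.5] mm; slab and spherical-shell phantoms with analytically
  known distances.
- **Censoring** — per-group pooled multisets `D_i`; censored sets
  `C_{d,i}(k,δ) = {d ∈ D_i : d ≤ k·δ}` over the grid k = 0 … ⌊d_max/δ⌋
  (defaults δ = 0.01 mm, d_max = 5.5 mm).
- **Test battery per step** — Kruskal–Wallis and one-way ANOVA F (with
  homogeneity of variances, and Welch's heteroscedastic variant without
  it) for the multi-group hypothesis `H₀: F₁(k,δ) = F₂(k,δ) = F₃(k,δ)`;
  one-sided Wilcoxon rank sum and Welch's t for the group pairs, with
  optional Holm adjustment across the pairs within a step; maximal runs
  of consecutive significant steps `[d₁, d₂]`.
- **Simulator** — distances d = (J + U)/2 with stack index J drawn from a
  probability vector over half-millimeter stacks and U ~ Unif(0, r); the
  stack-shift parameter η and spread parameter r deform the reference
  distribution.
- **Monte Carlo harness** — empirical size and power curves with 95%
  confidence bands over replicated scenarios.

## Worked example

Generate one replication of the simulator's alternative scenario — sample
X from the reference stack distribution (r = 1), Y widened to r = 1.2, Z
from the tail-shifted stack vector — and sweep the censoring threshold:

```sh
lcdmcensor simulate --scenario alternative --n 10000 --seed 7 --out dist.csv
lcdmcensor censor-sweep --input dist.csv --delta 0.05 --min-run 5 \
    --out-sweep sweep.csv --out-runs runs.csv
```

`runs.csv` lists the persistent significance runs; the Wilcoxon rows are:

```text
hemisphere,test,pair,direction,d_start_mm,d_end_mm,steps,reliable
left,wilcoxon,X:Y,less,0.55,0.95,9,False
left,wilcoxon,X:Y,less,1.05,1.95,19,True
left,wilcoxon,X:Y,less,2.05,2.4,8,True
left,wilcoxon,X:Y,less,2.55,2.8,6,True
...
left,wilcoxon,X:Z,less,4.05,5.5,30,True
left,wilcoxon,Y:Z,less,4.4,5.5,23,True
left,wilcoxon,Y:Z,greater,0.55,1.4,18,False
left,wilcoxon,Y:Z,greater,1.55,1.9,8,True
```

Read: censored X distances are significantly smaller than Y's in bands
that start just past each half-millimeter stack boundary (0.55, 1.05,
1.55, … mm) — exactly where Y's widened stacks (r = 1.2) pile up extra
mass; X only becomes significantly smaller than Z beyond ~4 mm, where Z's
shifted stack vector places its extra tail mass; and Y exceeds Z at small
depths (`greater` direction read from the mirror 0.95 line of the
one-sided curve).  `reliable=False` flags steps below 1 mm, where
near-surface mislabeling makes results less trustworthy in real data.

The same pipeline runs on real geometry:

```sh
lcdmcensor make-phantom --kind shell --inner 2 --outer 4 --h 0.5 \
    --out-mesh shell.off --out-labels labels.json
lcdmcensor compute-distances --mesh shell.off --labels labels.json \
    --subject s1 --group Ctrl --out shell_dist.csv
```

NIfTI label volumes (`.nii`) and ASCII OFF/PLY meshes are accepted.

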