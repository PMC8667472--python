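# Methods

## Problem and model

Effective leaf area index is defined from the canopy gap fraction:
LAI_eff(θ) = Ω(θ) · LAI, with Ω the clumping index describing
non-random foliage placement. All analysis here is at nadir (θ = 0) and
Ω enters as a supplied scalar per plot — the identity is honored as the
*definition* of the ground truth, not re-derived from foliage geometry.
A nadir pulse survives to the ground with Beer–Lambert probability
T = exp(−G·Ω·LAI), where G is the extinction (leaf projection)
coefficient. The laser penetration index measured from classified
returns is the empirical estimate of T, which makes LAI_eff recoverable
from point clouds through a regression model.

## Terrain normalization

The DTM is gridded from a pre-planting bare-earth cloud and held fixed
for the season. Per-cell aggregator is the **minimum z** — robust to low
vegetation and debris; the default cell is **0.25 m**, fine enough to
resolve the 0.76 m row spacing. Empty cells are filled from the nearest
populated cell (grid distance transform), so the model has no no-data
holes. Points outside the grid clamp to the nearest cell rather than
erroring, since plot polygons may slightly exceed the flight footprint.
Heights are h = z − DTM(cell); **h < 0.10 m is ground**, h ≥ 0.10 m is
vegetation (the threshold itself counts as vegetation, consistent with a
strict "less than 10 cm" ground rule). Grid resolution and fill method
are deliberate engineering choices — field practice rarely reports them —
and both are config-exposed.

## Features

Eight model inputs per region: LPI; mean, sample SD (n−1), adjusted
Fisher–Pearson skewness and linear-interpolation (type-7) 75th
percentile of vegetation heights; VCI; 3D convex-hull volume of the
vegetation points; CAP. The coefficient of variation and maximum height
are computed and written to the feature table but are not model inputs.
VCI bins span [0.10 m, max height] at a **0.10 m** default bin width
(the bin size is a free parameter of the entropy index; 0.10 m matches
the ground-rule scale); 0·ln 0 := 0 and fewer than two bins is an error
("insufficient vertical extent"). A constant height sample has skewness
0 by convention. Degenerate hulls (coplanar/collinear) give volume 0
with a warning. Regions with fewer than 3 vegetation points are flagged
missing and excluded from model fitting, though their LPI and counts are
kept.

## CAP

The slab is cut at the **0.75 quantile of vegetation heights** (ground
points never enter the statistics) with **±4 cm** half-thickness. Points
are clustered by the symmetrized k-nearest-neighbor-within-radius
relation; iteratively joining clusters that share members converges to
exactly the connected components of that graph, so a single union-find
pass implements the region growing. Cluster area Aᵢ is the 2D
convex-hull area of the member points — deterministic and faithful to
planar cluster footprints; an alpha-shape would hug concave clusters
tighter and is a known alternative, not implemented. CAP sums Aᵢ over
clusters with Aᵢ strictly above the area threshold. Defaults: radius
0.10 m, k = 10, threshold 0.01 m² — all user-set knobs of the method
with no canonical field values; the defaults are sized to the ~0.1 m
lateral spread of a single plant at typical pulse densities. An empty
slab yields CAP = 0 (lower quantiles often lack points under poor
canopy penetration). Because cluster hulls may overlap, CAP is not
bounded by the whole-slab hull area; it is non-increasing in the
threshold.

## Regression protocol

Varieties — not records — are split 75/25 (round(0.75·V) to train), so
both replicates of a genotype always land on one side; the split is a
seeded permutation. SMLR is bidirectional stepwise OLS on the raw
feature scale: forward-add the candidate with the smallest partial-F
p-value below α = 0.05 (for one added coefficient the partial F equals
the squared t), backward-drop anything at or above α, iterate to a fixed
point; the search stops early if the current model reaches
float-precision residuals, where p-values are meaningless. PLSR and SVR
standardize inputs (z-score fitted on train). PLSR picks the component
count maximizing pooled 10-fold-CV R² on train; SVR grid-searches
C ∈ {0.1, 1, 10, 100}, γ ∈ {scale, 0.01, 0.1, 1}, ε ∈ {0.01, 0.1, 0.5},
degree ∈ {2, 3}, scored the same way, ties toward the earlier grid
entry. The headline metric is R² on the held-out 25 %; train and CV R²
are also recorded. A zero-variance evaluation target reports R² = 0
with a warning. The grid-search loop is hand-written over scikit-learn
SVR fits (fold-wise scaling included) because the leave-one-out weight
procedure repeats it nine times per run and meta-estimator overhead
dominates at these sample sizes.

## Feature weights

w = 1 − R²_new/R²_orig, with the split, folds and grids pinned to one
seed across the baseline and all eight reduced fits so weights reflect
feature removal only. A reduced model scoring below the test mean
(R²_new < 0) has no explanatory power left to lose; R²_new is floored at
0, bounding weights at 1. Negative weights (removal helps) are reported
as-is. A baseline with R² ≤ 0 raises rather than producing meaningless
ratios. Correlations are reported as |Pearson r| on a 0–1 scale.

## Synthetic scenes

The generator emulates the study design, not any particular field: plots
of 7.6 × 3.8 m with rows at 0.76 m; sorghum at 200,000 and maize at
75,000 plants/ha; pulse densities spanning 70 (high-altitude UAV), 500
(low-altitude UAV) and 1,400 (wheel-based) points/m², default 500;
sensor noise σ_z = 0.01 m (sensor range accuracy of ±3 cm taken as a
~1–1.5 cm 1σ). Each canopy pulse reaches the ground with probability
exp(−G·Ω·LAI) — G = 0.5 (spherical leaf-angle distribution at nadir),
Ω = 0.9 — else returns from a height drawn from a triangular profile
(mode at 60 % of the canopy span) laterally jittered (σ = 0.1 m) around
a random plant stem. Studies draw per-variety LAI_eff uniformly over
the observed field ranges (0.5–6 sorghum, 0.5–5 maize), give replicates
3 % multiplicative variation, and let canopy top height grow with LAI
(0.8 + 0.3·LAI, ±8 % variety jitter) so height features carry realistic
covariance with the target and with each other (|r| > 0.9 among height
features, as field data show). Features are extracted from the rows-2–3
two-row block of each plot.

What the generator does **not** emulate: multiple returns per pulse
(sensors in single-return mode), within-canopy multiple scattering,
wind/platform-induced plant movement, intensity/radiometry, tillering
geometry, and any terrain beyond a gentle analytic slope. Passing tests
therefore demonstrate the pipeline's correctness and its statistical
protocol on Beer–Lambert-consistent data — not field-level prediction
accuracy, which in real campaigns is bounded by reference-instrument
error and canopy complexity and sits well below the near-perfect R²
seen on synthetic panels. A feature-level generator (`feature_dataset`)
bypasses point clouds for protocol-only experiments; its `driver='lpi'`
mode makes the target depend on the gap fraction alone with the other
seven features uninformative, and `link='linear'` removes the
exponential curvature where a property (e.g., noise response of a
linear model) should not be confounded by it.

## Numerical choices and edge cases

LAS I/O is a minimal LAS 1.2 implementation (point formats 0–3,
uncompressed, 1 mm scale quantum) written against the format
specification; LAZ is not supported. PLY goes through trimesh (ASCII,
float32), CSV through a strict `x,y,z[,...]` dialect. Polygon clipping
is boundary-inclusive and idempotent, with a bounding-box prefilter for
large scenes. Clustering labels are renumbered by first appearance, so
they are independent of component discovery order. All stochastic code
takes explicit seeds; study generation is byte-reproducible.

Problem sizes in the test-suite and acceptance runs — 160-plot studies
at 500 points/m², 10⁵-pulse Beer–Lambert checks, 100-configuration
clustering oracles, 100-seed importance replicates at 20 varieties —
are the package's chosen desk-scale study conditions; they keep a full
run in minutes on one CPU while leaving every statistical check
adequately powered.

## Known limitations

Single-return physics only; no ground-filtering algorithms beyond the
min-grid DTM (no cloth simulation or progressive morphology); no CRS
handling (a single local projected frame is assumed); SMLR p-values are
nominal, not selection-adjusted; the CAP area threshold, radius and k
have no field-calibrated defaults and should be tuned per sensor and
crop.
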