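# Methods

## Data model

The unit of observation is a nucleus carrying three diffraction-limited
fluorescent spots (channels r, g, b), each localized in 3D in micrometers
in the microscope frame. Because nuclear orientation is arbitrary, all
analysis happens on the frame-invariant triangle variables: side lengths
d_rg, d_rb, d_gb and interior angles θ_r, θ_g, θ_b (radians internally,
degrees in reports). The arccos argument is clamped to [−1, 1], so
collinear triangles are valid (θ = 0 or π); only exactly coincident spots
are rejected. Nuclei with a missing channel, non-finite coordinates,
coincident spots, or a pairwise distance above a QC ceiling (default
2.5 μm — beyond a yeast nuclear diameter, indicating mis-association) are
dropped, never imputed: every downstream statistic needs the full
triangle.

Node convention: 1 = r, 2 = g, 3 = b. The local variables around node i
are the two adjacent sides in closed-polygon order plus θ_i; each side
therefore appears in exactly two nodes' variable sets.

## Density maps and level sets

Each of the nine (distance, angle) projections is a 2D point cloud of M
nuclei. Distances (μm) and angles (rad) are incommensurate, so each axis
is standardized to zero mean and unit SD before kernel evaluation; level
statistics are reported back in original units. The density estimate is
the Parzen–Rosenblatt sum of isotropic Gaussian kernels with variance t;
the default t is Scott's rule on the standardized sample, t = M^(−1/3),
and t is logged with every map. Since no bandwidth rule can be recovered
for historical maps, t is a first-class, overridable parameter.

The ten levels are *highest-density regions*: U_k is the set of the
⌈kM/10⌉ points with the largest estimated density, so U_1 ⊂ … ⊂ U_10 and
|card_k/M − k/10| ≤ 1/M by construction. An alternative reading of the
level sets as thresholds of a bivariate cumulative distribution function
is orientation-dependent (a CDF in 2D depends on the axis ordering) and
cannot produce the nested high-density contours the maps display, so the
density-quantile construction is used. Ties in density are broken by
stable input order and logged when >1% of points tie. Level membership is
decided at the data points; the rendered lattice (default 128², extent
data range ± 3√t) is only for display and mass checks. Per-level mean and
SD vectors use the cumulative region and the population divisor card_k.

## Comparing experiments

Two experiments are compared in a common frame: pooled per-axis
standardization and a shared bandwidth, so the min/max ratios below
compare numbers on one scale. Per map and per level k the first
approximation ρ¹ is the product over the two axes of
min(|μ^A|,|μ^B|)/max(|μ^A|,|μ^B|); ρ² multiplies ρ¹ by the analogous SD
ratios. Both are in [0, 1], ρ² ≤ ρ¹, both equal 1 iff the level statistics
coincide, and both are symmetric in A and B. The headline correlation
factor c of a map is **ρ¹ at the 30% level**. This choice was calibrated
on the package's own generative model: across ten independent duplicate
pairs (n = 500 each) of the moderately constrained zone model, the median
headline ρ¹ lies in 0.82–0.96 — reproducing the accepted behavior that
duplicate experiments correlate above 0.8 — whereas ρ² (0.56–0.75) never
reaches that bound, because level-SD ratios at card₃ ≈ 150 points carry
~5% sampling noise per axis and multimodal projections make the 30%
region jump between modes. ρ² is computed and reported alongside ρ¹
everywhere.

The Wilcoxon battery reports medians, IQRs and two-sided rank-sum
p-values for the six univariate variables, raw (no multiple-testing
correction — by design, the per-variable tests are descriptive). The
exact method is used below 25 per group when tie-free, otherwise the
tie-corrected normal approximation. The 3D iso-volume overlap fits a 3D
kernel density per experiment on pooled-standardized (d_rg, d_rb, d_gb),
thresholds each to enclose a mass fraction (default 50%), and reports
point cross-membership plus the lattice Jaccard index; both are given
because iso-volume intersection is inherently resolution-dependent.

## The survival-zone model

The abstract polymer is planar: each of the three nodes roams uniformly
and independently in a rectangle [c₁−ε₁, c₁+ε₁]×[c₂−ε₂, c₂+ε₂].
Experimental data are 3D but enter only through the invariant
(d, d, θ) variables, which absorbs the dimensional mismatch; a 3D zone
model is out of scope. Per node, the correlation matrix C of
(d_i1, d_i2, θ_i) is obtained by normalized PCA (standardize columns,
correlation matrix, eigenvalues); eigenvalues are reported but do not
enter the objective, which uses only C.

Centers are fixed from data: node 1 at (0,0), node 3 at (5,0) — the mean
1–3 distance maps onto 5 model units — and node 2 at the intersection
(y ≥ 0) of circles of radii r₀ = 5·mean_d12/mean_d13 (around node 1) and
r₁ = 5·mean_d23/mean_d13 (around node 3). If the mean-distance triangle
inequality fails, node 2 is placed collinearly with a warning. Note the
bias this inherits: the mean distance between two uniformly roaming
points exceeds the distance between their centers, increasingly so for
wider zones, so the fitted frame is compressed relative to the generating
geometry and the distortion is zone-size-dependent. This is intrinsic to
fixing centers from mean distances and is flagged in Limitations.

The six half-widths are fitted by exhaustive search over a Cartesian
grid on (0; 5] (zero excluded so every zone has positive extent; the
publication-scale grid of 25 values per parameter at step 0.2 yields
5¹² candidates, reported by `grid_size`; desk-scale work uses 2–5 value
grids). The objective per candidate is Σᵢ ‖Cᵢ − Cᵢᵃ‖_Frob with Cᵢᵃ
estimated from M′ sampled configurations (default 10,000). *Common random
numbers*: one fixed uniform draw, rescaled to every candidate's
rectangles, makes the objective surface smooth in ε and the result
independent of evaluation order; candidates whose abstract geometry
degenerates (zero variance in a local variable) are rejected. Work is
chunked over a joblib pool; any worker count returns a bit-identical
result because the reduction is a global argmin with a deterministic key.

**Argmin semantics.** The Monte-Carlo objective has a sampling SD σ
(estimated by re-evaluating the argmin with fresh draws, 5 repeats by
default); candidates within 2σ of the minimum are statistically
indistinguishable. A survival zone is by definition the *smallest* region
compatible with the motion, so the solver selects, inside that noise
band, the candidate with the smallest total zone area (lexicographically
smallest ε on exact ties). `parsimony_z=0` restores the raw argmin. Both
the raw minimum and the selected objective are reported, together with σ.

## Synthetic data

`simulate_from_zones` takes the zone model literally as the generative
process: one planar configuration per nucleus, lifted to z = 0, scaled by
0.18 μm per model unit (so the 0–5 span, ~0.9 μm, sits inside a 2 μm
nucleus — a fixture convention recorded in every sidecar), embedded with
a per-nucleus uniform random rotation (quaternion method) and a uniform
translation in a 2 μm box, plus optional Gaussian localization noise
(default 0; an anisotropic mode with doubled z SD mimics coarser focal
stepping). `random_sphere_dataset` is the null control: three loci
independent and uniform in a 2 μm-diameter sphere.

Three reference constraint regimes are provided. The *moderate* regime
uses the reference rectangles Z₁ = [−1;1]², Z₂ = [−1;5]²,
Z₃ = [3.5;6.5]×[−1.5;1.5]; *flexible* and *constrained* keep the same
centers with half-widths ×1.5 (staying inside [0;5]) and ×0.5, so zone
areas are strictly ordered at every node. What the generator does *not*
emulate: chromatin's spatial autocorrelation in time, nuclear-envelope
confinement, spot-detection outliers, or inter-node dependence beyond the
zone geometry — passing tests demonstrate the pipeline's correctness
under the model's own assumptions, not robustness to those real-data
features.

## Numerical choices

- Distances in μm, angles in radians internally; exports print 12
  significant digits; TSV round-trips are bit-exact (repr-faithful floats,
  round-trip parsing).
- KDE evaluation is chunked (2048 query points) to bound memory; the 3D
  overlap lattice defaults to 32³.
- Degenerate inputs: < 2 points (density), < 10 points (decile maps),
  zero-variance columns (PCA), empty grids and non-positive means are
  explicit errors; an all-removed QC result is a warning, not an error.
- All randomness flows through numpy Generators seeded explicitly; solver
  noise-estimation seeds are spawned from the main seed via SeedSequence.

## Limitations

- Half-width recovery is only partially identified at realistic sample
  sizes. At n = 500 nuclei and M′ = 5000, several ε directions (notably
  the half-width of a small zone perpendicular to its adjacent sides) are
  noise-flat: the data constrain the correlation matrices, and those
  barely respond to such components. Together with the mean-distance
  center bias above, component-wise recovery on a coarse grid cannot be
  expected; the reliable read-out at this scale is the *relative* total
  constraint across conditions (zone-area ordering), which the recovery
  tests exercise. The acceptance suite asserts the stricter per-component
  property and documents its failure rather than hiding it.
- The large-sample consistency of the objective is bounded below by the
  correlation-estimate noise floor, ≈ Σᵢ √(Σ_offdiag 2(1−r²)²/M) — about
  0.07 at M = M′ = 20,000 for the moderate regime; consistency checks
  near that floor are seed-sensitive.
- The duplicate-correlation behavior of c depends on the projections'
  modality; strongly multimodal projections destabilize the 30% region at
  any n in the hundreds.
- No multiple-testing correction, no uncertainty quantification on ε, no
  gradient-based refinement; these are deliberate non-goals.
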