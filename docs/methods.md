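# Methods

`glomquant` quantifies three attributes of olfactory-bulb glomeruli —
number, size, and shape — from manually segmented 3D label volumes, and
provides the statistical layer used to summarize and compare them
across age groups. Because the source image stacks of the study it
follows are not publicly deposited, the package validates every stage
on synthetic labeled bulbs with analytic ground truth, and ships the
study's printed per-dataset summary tables as fixture inputs for the
statistics layer.

## Label volumes and coordinates

A label volume is a 3D integer array indexed `(z, y, x)`: background 0,
one positive id per glomerulus. Ids need not be consecutive or form a
single connected component (`connected_component_count` is a QC report,
not a filter). Physical spacing is attached explicitly; the reference
grid is 1.76 × 1.76 µm in-plane with a 5 µm z-step. Physical
coordinates use the voxel-*center* convention, `(index + 0.5) ×
spacing` per axis, so the centroid of a symmetric digitized object
coincides with its continuous center. All physical points are reported
as `(x, y, z)` in µm.

Per-voxel volume defaults to `dx·dy·dz` (15.488 µm³ at the reference
spacing). The study reports a rounded per-voxel volume of 15.40 µm³ for
the same grid; a `voxel_volume_override` reproduces numbers computed
under that constant. The two figures are mutually inconsistent at the
fourth significant digit; the package does not decide which is the
typo, it supports both.

## Size: volume and effective diameter

Volume is the voxel count times the per-voxel volume — the natural
measure for a filled segmentation, with no shape assumption. The
*effective diameter* is the diameter of the sphere of equal volume,

    d_eff = (6V/π)^(1/3),

an objective scalar "diameter" for objects whose actual diameters vary
with direction. Because the map V → d_eff is strictly monotone, medians
commute with it for odd sample sizes (tested); for even sizes the
discrepancy is far below reporting precision.

## Shape: aspect-length ratios and sphericity

**ALR.** Each object's voxel-center coordinates are mean-centered,
their covariance matrix eigendecomposed, and the coordinates projected
onto the eigenvectors in descending-eigenvalue order. Extents are
max − min of the projections, sorted `lx ≥ ly ≥ lz`, and the
aspect-length ratios are `(lx/lz, ly/lz)`, each ≥ 1 with (1, 1) for a
perfect sphere. PCA runs on *physical* (µm) coordinates, not array
indices: with a 5/1.76 anisotropy, index-space PCA would report
orientation-dependent shape for identical objects. Extents use the
projected voxel centers with no added voxel width — the simplest
bounding-box convention — and any degenerate extent is floored at the
smallest spacing dimension so planar or linear objects keep a positive
`lz`. For perfect spheres the eigenbasis is arbitrary (tied
eigenvalues); extents are basis-invariant up to voxelization error, so
no tie-break is imposed.

**Sphericity.** `Ψ = π^(1/3) (6V)^(2/3) / A`: the surface area of the
equal-volume sphere divided by the object's surface area, 1.0 iff the
object is a sphere. `V` is the voxel-count volume (same figure as the
size analysis), not the mesh-enclosed volume. `A` comes from marching
cubes with spacing-aware vertices on a mask padded with background so
the isosurface closes.

A numerical choice that matters: meshing the raw 0/1 mask at level 0.5
places every vertex at an edge midpoint, and the staircase mesh
overestimates the area of digitized smooth objects by ~9% on an
isotropic grid and ~16% at the 1.76/5 µm reference spacing — enough to
cap the sphericity of a perfect digitized sphere at ~0.86. The default
therefore meshes a Gaussian-smoothed indicator (σ = 1 voxel), which
recovers analytic sphere and spheroid areas to within ~2% across the
tested size range. `smoothing_sigma=0` retains the raw-mask mesh; that
variant is the likely convention behind published whole-bulb sphericity
ranges topping out near 0.85, and users comparing against such values
should prefer it, while users wanting accurate areas should keep the
default. Digitized near-spheres can still exceed Ψ = 1 by a few
percent; values above 1 are logged and reported, never clamped.

Objects spanning fewer than ~10 z-slices (d_eff below ~50 µm at a 5 µm
z-step) carry visibly coarser shape metrics; the accuracy statements
below apply to the resolvable range.

## Statistics layer

* **Quantiles** interpolate linearly at position `p·(n−1)` in the
  sorted sample. This convention exactly reproduces the study's
  printed quartiles and IQRs, which is the decisive evidence that it
  is the one used there.
* **Group summaries** over the four bulbs of an age group are the
  median of the four per-dataset medians, with a percentile-bootstrap
  CI of the median (default 10,000 resamples, seeded). At n = 4 the
  percentile interval typically coincides with the sample min–max.
* **Mann–Whitney U**, reported for the first-named sample, counts
  pairs with a > b plus 0.5 per tie. The exact two-sided p doubles the
  smaller tail of the permutation null — enumerated over all
  `C(n1+n2, n1)` assignments of the pooled values (ties included) up
  to 200,000 splits, beyond which a tie-corrected normal approximation
  takes over. The reported `z_approx` is the plain deviate
  `(U − n1n2/2)/√(n1n2(n1+n2+1)/12)` and the effect size is the rank
  biserial `2U/(n1n2) − 1`. Published companion values `Z = 1.63`,
  `r = 0.82` alongside `U = 0` at 4-vs-4 are not reproducible from
  these standard formulas (which give |Z| = 2.31, |r| = 1.0); they are
  consistent with `Z = (U − 8)/√24` and `r = Z/2`. The package reports
  the standard formulas and flags the discrepancy rather than
  imitating an undocumented variant.
* **Moments.** Skewness `m3/m2^1.5` and excess kurtosis `m4/m2² − 3`
  use population (1/n) central moments; small-sample-adjusted
  estimators are available behind a flag.
* **Display rounding** is half-up (`round_half_up`): group medians of
  four values routinely land exactly on a half-cent (77.535 → 77.54),
  where banker's rounding would disagree with conventional reporting.

## Distribution fitting

Candidate families: Gaussian, gamma, generalized gamma (GG, Stacy
parameterization: scale a, shape v, power p), lognormal, Weibull —
every family the source analysis names plus two standard controls,
in place of a 50-family scan. Positive-support families pin the
location at zero. Fits are maximum likelihood; families are compared
with `AIC = 2k − 2logL` and `BIC = k ln n − 2logL` and selected by
minimal BIC, with the full per-family table retained.

The GG density is

    f(x) = p / (a^{pv} Γ(v)) · x^{pv−1} · exp(−(x/a)^p),

reducing to gamma at p = 1 and approximating a Gaussian on the positive
domain at p = 2 with large v. Its likelihood surface is ridge-prone
(a, v, p trade off along near-flat valleys), so the fit starts from the
gamma solution, profiles over p on a log grid from 0.2 to 5, and then
refines jointly (Nelder–Mead on log-parameters, function tolerance
1e-10). The density implementation is cross-checked pointwise against
an independent library parameterization in the tests.

KDE uses a Gaussian kernel. The published "bandwidth of 2" is ambiguous
— the same absolute value cannot be meant on µm and µm³ scales — so
both semantics are provided: `absolute` (kernel SD in data units, the
default, sensible for diameters) and `factor` (multiplier on Scott's
rule, used automatically for volume-scale data in the pipeline
report). Q-Q diagnostics pair order statistic i with the fitted
quantile at probability `(i − 0.5)/n`.

## Literature calculators

Three closed forms connect counts and volumes to the wider literature:
the Abercrombie profile-count correction `Nv = N·T/(T+d)` and its
inversion; glomeruli per intact odorant-receptor gene (default 1141
intact OR genes, taken as exact); and the linear OSN model
`y = 81.55x + 168,700` (µm³ total glomerular volume per OR gene as a
function of OSN count), whose slope and intercept are configuration
constants from an independent counting study, not refit here. Chained
computations keep full precision in intermediates and round only final
figures — printed reference values are internally consistent only
under that policy.

## Synthetic bulbs

`generate_bulb` fills a (z, y, x) grid with nonoverlapping
glomerulus-like objects and records analytic truth per object:

* **Diameter law**: truncated Gaussian, defaults µ = 78.12 µm,
  σ = 17.72 µm on [27.13, 158.28] µm — the adult (PD56) effective-
  diameter law and observed range of the study.
* **Aspect laws**: truncated Gaussians for the target a/c
  (µ 2.5, σ 0.7 on [1.11, 5.0]) and b/c (µ 1.3, σ 0.15 on [1.0, 2.0]),
  resampled to keep a/c ≥ b/c; chosen to span the observed adult ALR
  range with the observed medians. Size and shape are sampled
  independently — a generator convenience, not a biological claim.
* **Shape families**: spheres, triaxial ellipsoids, superellipsoids
  (`|u/a|^{2/ε} + |v/b|^{2/ε} + |w/c|^{2/ε} ≤ 1`, ε = 1 reducing
  exactly to the ellipsoid), and star-convex "tuberiform" blobs —
  spheres with a smooth low-order radial perturbation of bounded
  amplitude (≤ 25% of radius), whose volume is computed by spherical
  Gauss–Legendre quadrature of `r³/3`.
* **Voxelization** includes a voxel iff its center satisfies the
  implicit inequality in the rotated body frame; rotations are uniform
  random.
* **Placement** is rejection sampling with conservative
  bounding-sphere overlap tests (cap: 1,000 attempts per object),
  placing objects largest-first so elongated objects are not stranded;
  labels 1..n follow placement order. Deterministic given the seed
  (default 20250814).

The default 200-object bulb on a 180 × 800 × 800 grid (900 × 1408 ×
1408 µm) reproduces per-object analytic volumes within 0.7% and target
ALR within 0.12; these sizes keep a full generate–measure–fit–compare
cycle under ten seconds on one CPU. What the generator does *not*
emulate: the bulb's shell geometry and glomerular-layer packing,
imaging noise, staining heterogeneity, and the correlation structure
between size and shape of real glomeruli. Passing recovery tests
therefore demonstrates the correctness of the measurement chain on
known geometry, not segmentation accuracy on real stacks.

## Degenerate inputs and edge cases

Empty volumes yield an empty table with a warning; single-voxel objects
get floored extents `(floor, floor, floor)` and ALR (1, 1); objects too
small to carry a smoothed isosurface fall back to the raw-mask mesh;
zero-variance samples are rejected by the moment and fitting routines;
positive-support families refuse non-positive data and are dropped
(with reasons) from BIC selection rather than aborting it.

## Known limitations

* Shape metrics degrade below ~10 z-slices per object; at the
  reference spacing this affects glomeruli under ~50 µm.
* The exact Mann–Whitney null is enumerated, not computed by a
  ranksum-generating-function recursion; at the study's 4-vs-4 design
  this is instant, and the 200,000-split cap bounds the general cost.
* GG fitting optimizes a ridge-prone likelihood; different optimizers
  can land at parameter triples differing visibly while matching
  log-likelihood to high precision. Selection by BIC is insensitive to
  this.
* The bootstrap CI at n = 4 is a convention, not a calibrated
  interval; its coverage statement is only meaningful at larger n
  (tested at n = 50).
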