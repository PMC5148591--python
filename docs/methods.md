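# Methods

## The measurement problem

Cultured dorsal-root-ganglion (DRG) neurons are morphologically
heterogeneous: somas span roughly 20–200 µm in diameter, a fraction of
neurons carry no processes at all, and the remainder grow neurite
arbors whose extent and branching respond to growth-factor
supplementation. The package quantifies this with Sholl analysis on
8-bit grayscale images: concentric circles are centred on the soma,
starting at 50 µm with 10 µm radial steps, and the profile N(r_i) counts
neurite intersections with each circle. From the profile come three
scalar summaries — the enclosing radius (outermost circle still
crossed), the maximum number of intersections, and the radius at which
that maximum occurs — plus the branching-rate statistics described
below. Group differences are tested non-parametrically.

## Image chain

1. **Thresholding.** Foreground by Otsu's between-class-variance
   criterion (a fixed level is available). A constant image is an
   error, not an empty mask.
2. **Cleaning.** Components smaller than `min_component_px` (default
   20 px) are dropped as speckle; then only the 8-connected component
   containing the user-supplied soma seed is retained. This is the
   automated surrogate for the manual removal of debris, background
   staining and neurites of adjacent neurons: deterministic,
   idempotent, and conservative (anything not attached to the analysed
   neuron is discarded regardless of size).
3. **Soma segmentation.** Morphological opening with a disk of radius
   `ceil(1.5 × line_width)` pixels erases structures at neurite scale
   and keeps the soma; its maximum Feret diameter, corrected by one
   pixel (region extents span pixel boundaries while the physical rim
   runs through the outermost pixel centres), gives the soma diameter.
   Recovery is within 5% across the 20–200 µm range on synthetic
   ground truth.
4. **Profiling.** Soma pixels are removed before counting, so large
   somas (diameter > 100 µm, which swallow the 50 µm circle) cannot
   register a spurious full-circle intersection. Each circle is
   sampled at arc steps of 0.5 pixel; an intersection is one maximal
   foreground run along the circle with circular wrap-around.
   Background gaps narrower than `min_gap_px` (default 2 px) are closed
   and foreground runs narrower than `min_run_px` (default 1 px)
   dropped before counting: a circle grazing along the edge of a drawn
   line otherwise fragments into alternating samples. Counting runs
   rather than skeleton crossings makes the measure invariant to line
   width; skeletonization is deliberately not used.

Pixel conventions: 0-based indices, origin top-left, x rightward,
y downward; physical position = index × pixel size. All internal
mathematics is in µm; conversion happens only at module boundaries.

## Branching statistics

For a profile on radii r_0 < … < r_{n−1}:

- branching rate  b(r_i) = N(r_{i+1}) − N(r_i), the signed change in
  intersections per radial step. Positive entries are net branching in
  the annulus, negative entries net neurite termination. The signed
  difference is used deliberately: terminations then surface as
  negative entries, the minimum Bmin captures the zone of strongest
  pruning, and the observed strong negative correlation between Bmin
  and Bmax follows naturally. (An additive-termination variant
  b = ΔN + T cannot be distinguished from the signed difference by the
  available description; only the signed difference is implemented.)
- specific branching  bs(r_i) = b(r_i) / (π (r_{i+1}² − r_i²)), the
  rate normalised by the full annulus area (not the arc subtended by
  the arbor), in µm⁻².
- per neuron: Bmax/Bmin and Bsmax/Bsmin are plain extrema of these
  vectors; per treatment group they are averaged arithmetically.

Two identities hold exactly and are enforced by tests: the telescoping
sum Σ b = N(r_last) − N(r_first), and the round trip
bs(r_i)·π(r_{i+1}²−r_i²) = b(r_i).

Summary tie-break: if several radii share the maximum count, the
smallest radius is reported — stable under truncation of the outer
profile. A soma diameter of exactly 50 µm is classified "large"
(the >50/<50 split leaves the boundary undefined; a convention is
needed and documented). A neuron is "neurite-bearing" if foreground
extends ≥ 20 µm beyond the soma boundary — deliberately below the
50 µm grid start, so a neuron can bear short neurites yet have an
all-zero profile; the threshold is configurable because no operational
criterion for "presence of neurites" is standard.

## Statistical comparisons

Endpoint distributions are screened with three normality tests
(one-sample Kolmogorov–Smirnov against a normal with sample-estimated
moments — conservative without the Lilliefors correction, which is
accepted and noted — D'Agostino–Pearson omnibus, Shapiro–Wilk); any
p < 0.05 routes to the non-parametric branch. Groups are compared with
the tie-corrected Kruskal–Wallis test (χ² approximation, k−1 df),
followed by Dunn's multiple-comparison test on pooled ranks with tie
correction. The family-wise adjustment is Bonferroni by default, with
Holm and no-adjustment options. The package always takes the
non-parametric branch; repeated-measures ANOVA is out of scope.
Significance tiers: p < 0.001 '***', 0.001–0.01 '**', 0.01–0.05 '*',
otherwise 'ns'; α = 0.05 throughout. Association between soma-size
class and neurite presence uses the Pearson χ² test on the 2×2 table
without continuity correction. Viability is a pure count ratio
(100 × stained/total); calcein image analysis itself is not modelled.

Dunn's test is implemented in the package (z statistics on pooled mean
ranks with the Σ(t³−t)/(12(N−1)) tie term); Holm adjustment is
delegated to statsmodels. Degenerate all-tied input returns H = 0,
p = 1 rather than an error.

## Synthetic neurons

No reference images ship with the package, so every stage is validated
against synthetic neurons with exactly known geometry.

**Growth model.** A discrete-step branching random walk, chosen so that
ground-truth branching events map directly onto the quantities being
recovered. `n_primary` neurites leave the soma boundary at equally
spaced angles heading radially outward. Per step of length `step_len`
(default 10 µm) each active tip terminates with probability
`term_prob` (0.02), branches into two children deflected ±`branch_angle`
(0.5 rad) with probability `branch_prob` (0.04), else elongates with
Gaussian heading jitter `angle_sd` (0.15 rad per step — a directional
persistence length of ≈ 0.44 mm, in the range reported for neurites in
culture). Growth stops after `max_steps` (30) steps. Soma diameter
defaults to 60 µm and is constrained to [20, 200] µm unless explicitly
overridden. Defaults give arbors with enclosing radii around
250–330 µm and maximum intersection counts around 5–15, comparable to
well-arborised cultured DRG neurons.

**Rendering.** Soma disk and segments are drawn at `foreground_level`
with width `line_width` pixels and no anti-aliasing, so noiseless
images are exactly two-valued and mask-recovery tests can be exact.
Gaussian noise (sd 8 gray levels) is added and clipped; bright debris
blobs are scattered away from the arbor (they must be removed by the
cleaning stage, so they get the same intensity as the foreground — the
hard case). Default sampling is 0.5 µm/pixel with 3 px lines, i.e.
1.5 µm-wide neurites, typical of confocal imaging at the
magnifications used for whole-arbor fields. Ground truth is also
written as standard 7-column SWC (type 1 soma node, type 3 neurites,
radius = half the drawn line width in µm).

**Exact Sholl oracle.** Intersections of the segment union with each
circle are counted by segment–circle geometry: a segment whose
endpoint distances straddle the radius crosses once; a segment dipping
across the circle and back (perpendicular foot inside the segment,
closer than r, both endpoints outside) crosses twice; tangencies count
zero. An endpoint landing exactly on a circle is resolved by sign
inheritance along the parent chain, so a chain genuinely passing
through the circle at a segment junction counts once and a tip merely
ending on the circle counts zero. The oracle agrees exactly with a
dense-sampling sign-change count on random trees (property-tested over
50 seeds).

**What the generator does not emulate.** Single 2-D planes only (no
z-stacks or projection artifacts), no point-spread function, no
intensity gradients or uneven illumination, no satellite/Schwann-cell
rendering, no fasciculation or contact-mediated interactions between
neurites. Passing tests therefore demonstrate correctness of the
measurement chain on geometrically known input, not robustness to
every real staining artifact.

## Known limitation: sub-resolution crossing pairs

The image-based profile and the exact oracle disagree on about 15% of
(neuron, radius) pairs under the default growth and imaging conditions
(almost always by exactly one intersection). Instrumenting the
disagreements shows ~80% are tangential "dips": heading jitter makes a
neurite cross a circle twice within less than the drawn line width, so
the rendered image contains a single blob where the geometry has two
transversal crossings; the remainder are distinct neurites crossing a
circle closer together than the line width, plus occasional +1 cases
where a tip's rounded cap grazes the next circle. This is an
information limit of finite-resolution imaging, not an implementation
error — the profile cannot recover crossings the image does not
resolve. Consequences for real data: image-based Sholl counts are a
slightly smoothed lower envelope of the geometric truth wherever
neurites run tangentially or bundle tightly; group comparisons are
unaffected in practice because the smoothing applies to all groups
alike (the power and calibration experiments below run on exact oracle
profiles and the analysis drivers on image-based ones, with the same
conclusions).

## Simulation experiment sizes

Cohort-scale experiments run on oracle profiles (the generator→profile
→metrics chain without rendering), which makes replication cheap while
exercising the same downstream mathematics: power of Kruskal–Wallis on
Bmax for branching probability 0.02 vs 0.06 at 30 neurons/group, 50
replicates; type-I error with three groups of 30 resampled (with
replacement) from a single pool of 600 generator-derived Bmax values —
resampling one pool makes the groups identically distributed by
construction and keeps 2000 replicates fast; dose response of mean
Bmax over branching probabilities 0.00/0.03/0.08 at 30 neurons/level,
20 replicates; Bmin–Bmax correlation on an 80-neuron cohort with
branch and termination probabilities drawn uniformly from [0, 0.08]
and [0, 0.05]. The image-based validation cohort is 100 neurons.
Measured under these conditions: power 1.00, type-I rate ≈ 0.05,
mean Bmax strictly increasing in branching probability, r(Bmin, Bmax)
≈ −0.66 to −0.79.

## Numerical and degenerate-input choices

- Per-neuron seeds derive from the master seed via
  `numpy.random.SeedSequence([master, group_index, neuron_index])`;
  everything is bit-reproducible for a fixed configuration.
- Kruskal–Wallis on all-tied pooled data returns (0, 1); Dunn returns
  z = 0, p = 1 per pair in that case.
- An all-zero profile summarises to (enclosing = missing, max = 0,
  radius of max = missing).
- Per-neuron analysis failures (unreadable image, seed on background,
  soma not found, grid exceeding the frame) are logged and the neuron
  excluded; an empty analyzable cohort is fatal.
- The no-branching monotonicity property (profiles non-increasing when
  branch_prob = 0) is guaranteed only for jitter-free growth; heading
  jitter can transiently raise a count via a double crossing, which is
  why the test pins angle_sd = 0.
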