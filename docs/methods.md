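# Methods

## The processing model

A multi-view-stereo (MVS) reconstruction of a potted maize shoot is a
dense colored point cloud with three systematic defects this package
corrects before measuring anything: gray ghost points behind shaded leaf
backs, an arbitrary global scale, and (for plants taller than the imaging
rig) two separately reconstructed halves. The pipeline is strictly
feed-forward — denoise → calibrate → (register) → skeletonize → extract —
and every stage is a pure function of its inputs plus an explicit
configuration block, so a run is reproducible from its provenance log.

## Denoising

Noise points are identified by color, not geometry. Seeding uses an
a-priori list `C_L` of gray noise colors (12 triples with R ≈ G ≈ B in
[90, 170]); any point within ΔC ≤ 60 of a list entry (redmean metric)
seeds the region growth. Growth inspects each seed's k = 16 nearest
neighbors and classifies neighbor q as noise when

    δ_pq = η₁·ΔC_pq + η₂·θ_pq < δ*,    η₁ = −1/40, η₂ = 1/90,

with θ the angle between the PCA normals of p and q in degrees, folded to
[0°, 90°] so normal-sign ambiguity cannot flip a classification. Normals
come from k = 24 neighborhoods, oriented outward from the vertical axis.

The sign of η₁ deserves a note. With η₁ negative, a neighbor whose color
is *far* from a gray seed scores a more negative δ and is *more* readily
absorbed — the opposite of growth through a contiguous gray patch. Both
conventions are implemented (`invert_color_term`); grid calibration on
synthetic shoots (`calibrate_delta_threshold`) shows the negative-η₁ form
only behaves when δ* ≤ −8, where growth is inert and removal is carried
entirely by palette seeding (noise-recovery F1 = 1.0), while the inverted
form grows correctly with δ* ≈ 1.5 and collapses above ~2.5. The shipped
default is the negative-η₁ form with δ* = −8; flip `invert_color_term`
for a threshold near 1.5 if actual region growth is wanted (e.g., for
noise colors missing from the palette). Termination is guaranteed by a
visited set: every point is classified at most once, FIFO order.

## Scale calibration

The pot (default true radius 150 mm — a 30-cm pot) is segmented by color
(redmean distance ≤ 60 to the pot color) followed by
largest-connected-component selection at a neighbor radius of 3× the mean
point spacing. Circles are fitted at 15%, 50% and 85% of the segment's
z-extent (slab thickness 6% of pot height) with the algebraic Kåsa
least-squares fit — the linear system in (2a, 2b, r² − a² − b²) — and
τ = R_true / mean(radii), unweighted. The extreme slice positions avoid
rim flare and base contact; if the three radii disagree by more than 5%
(tapered pot) the middle slice alone is used, with a warning. Whether
"least squares" means algebraic or geometric fitting is ambiguous in
general; the algebraic fit was chosen for its closed form, and the test
suite holds it against a geometric Levenberg–Marquardt oracle (agreement
required within 0.1% whenever the RMS residual is below 2% of the
radius). At the shipped noise levels (1 mm jitter on a 150 mm radius with
thousands of slab points) the Kåsa small-radius bias is negligible.

## Registration

Trimmed iterative closest point, basal half `P` fixed and upper half `Q`
moving. Each iteration: nearest-neighbor correspondences from every p ∈ P
to the transformed Q, pairs beyond 3× the median distance dropped, then
the closed-form SVD (Kabsch) solve; the reported energy is the untrimmed
mean squared correspondence distance, and the energy trace is asserted
non-increasing in the loop (an increase raises an error rather than being
silently accepted). Initialization aligns centroid + principal axes of
user-supplied overlap crops (`principal_axis_init`), standing in for
interactive selection of the shared leaves; a manual 4×4 matrix is also
accepted. Defaults: relative-energy tolerance 1e-6, 100 iterations max,
merge deduplication radius 1.5× mean point spacing.

## Skeletonization

Contraction minimizes `‖W_L L X‖² + ‖W_H (X − X_prev)‖²` on a symmetrized
k-NN graph Laplacian (k = 12, uniform weights), with W_L doubling each
iteration from 1 and W_H = 1, until the k-neighborhood covariance is
quasi-1D (median (λ₁+λ₂)/λ₃ < 0.05) or 10 iterations. The cloud is
voxel-downsampled to 4 mm first; the sparse normal equations are solved
by LU factorization. Topology: farthest-point sampling at 10 mm
(internode scale), Euclidean minimum spanning tree, stem = tree path from
the lowest sample to the highest sample lying within a vertical gate
above the root (leaf arches are offset laterally; the gate prevents an
arched top leaf from capturing the stem), remaining branches = leaf
chains ordered junction → tip, branches shorter than 3 samples dropped as
contraction debris.

Refinement recenters every chain point to the centroid of cloud points in
a disk (radius 1.5× sample radius, slab half-thickness 0.5× sample
radius) in the plane normal to the local tangent, update capped at the
disk radius; leaf chains are refined against the cloud with points within
12 mm of the stem chain excluded, so the stem cylinder cannot drag blade
bases inward. Because contraction shrinks free chain ends substantially
(tens of mm at leaf tips and the stem apex), refinement includes a
guarded tip extension: the tip advances to the centroid of forward
support along a smoothed direction, stopping when support vanishes, the
direction breaks by more than 60°, or 35% of the chain length has been
added. Resampling fits a natural cubic spline through the chain
(chord-length parameterization) and emits points at uniform arc length,
endpoints preserved; chains with fewer than 4 points fall back to linear
interpolation.

## Trait extraction

All measurements happen in the stem-vertical frame (minimal rotation
carrying the stem chain's principal axis onto +z). Soil level is the pot
rim when the pipeline supplies it, else the stem-chain base.

* **Plant height** — maximum z over the stem chain and every leaf chain's
  arch, minus soil; a tip hanging below its arch never raises the value.
* **Leaf base angles** — the blade chain (leaf chain trimmed outside a
  12 mm stem clearance) provides tangent directions as chords over ±3
  resampled points; their angle-from-vertical is fitted linearly in arc
  length over the 15–55% window and evaluated at 5% of the blade arc
  measured from the stem surface. The collar offset uses the measured
  distance of the chain start from a smoothed (quadratic-in-z) stem axis
  minus the stem radius (median distance of near-stem cloud points),
  divided by sin of the base angle. A direct first-10%-chord estimate is
  biased by ~+10° here, because the topologized chain starts at the stem
  axis and junction placement quantizes at the sampling radius; the
  fitted-profile estimate is exact for a constant-curvature droop and
  degrades gracefully otherwise. Azimuth is the xy bearing of the window
  tangent sum (CCW from +x); growth height is the extrapolated collar z.
* **Leaf length** — blade-chain arc length plus the collar offset. Tip
  truncation that survives extension leaves a small negative bias
  (~2% mean at the shipped density).
* **Ring cuts** — nodes at 8 equal arc fractions of the trimmed
  (5%–95%) blade chain; ring radius r = 1.5× the width prior (config;
  refined once from the median measured width when `auto_width`), slab
  length l = 2× mean point spacing. Clustering is single linkage at 3×
  spacing, evaluated on a thicker support slab (|axial| ≤ 2l) so the thin
  measurement slab's sparse 1-D gap statistics cannot fragment the blade;
  only the most populous component is kept and the cut line is measured
  on its points within |axial| ≤ l. The line is constrained through the
  skeleton node (it lies on the midrib), residual-trimmed at 2× spacing,
  and the width is the projection extent with the order-statistics
  correction (n+1)/(n−1) for n ≥ 5, clipped at the ring diameter. Cuts
  whose segment midpoint is displaced from the node by more than 20% of
  their length are rejected as contamination from a touching organ, and
  an invalid cut retries once at ±2.5% arc shift.
* **Leaf width** — the longest valid cut line. In the pipeline an extra
  consistency cap (a ring may exceed its neighbors' maximum by at most
  2× spacing) protects the maximum from isolated missed contaminations;
  the bare `leaf_width` function implements the plain longest-cut rule.
* **Leaf area** — trapezoid sum of consecutive cut widths over their arc
  separations, plus a base cap tapering to zero at the collar and a tip
  cap tapering to the zero-width point extrapolated from the last two
  cuts (at most 20% of the chain beyond its end). With 8 perfect cuts on
  the generator's blade profile the trapezoid discretization alone is
  −2.1%; the caps recover most of the remainder.

## The synthetic generator

`synth.generate_shoot` builds, in millimetres: a pot wall (uniform
terracotta ±5 per channel), soil disk and ground annulus (dark soil
color), a stem cylinder to the plant top, and per-leaf blades. Each
midrib is an arc-length-parameterized circular arc in the vertical plane
of its azimuth: the tangent angle from vertical grows linearly from the
base inclination to inclination + droop at the tip. The blade is a flat
strip swept perpendicular to that plane with width profile
`w(u) = W·u^0.5 (1−u)^0.8 / norm` (maximum W near u = 0.38, ~0.2 W at
95% of length — a realistic acuminate maize tip that keeps sampled
support along the midrib almost to the end). Because the sweep direction
is orthogonal to the midrib plane, blade area is exactly `∫ w ds`
(closed form via the beta function), length is exactly the arc length,
and the arch height has a closed form — truth never touches the sampled
cloud. Gray noise echoes a fraction (default 10%) of leaf points 1–3 mm
behind the blade, recolored from the same gray palette the denoiser
ships; Gaussian jitter (default 0.5 mm) and a global scale factor follow.
Identical spec + seed gives bit-identical clouds, and scaling is exactly
equivariant.

Randomized study shoots (`random_spec`) model V5-stage plants: height
~400 mm, five leaves with alternating (distichous) azimuths ±20°,
inclinations 25–50°, droops 50–80°, lengths 180–320 mm, widths 35–55 mm,
attachments over the lower two thirds of the stem. V15/R1 presets scale
the same template to 1.8 m / 2 m plants with 12–13 leaves.

Default point density is 0.5 points/mm² (~200 k points for a V5 shoot
with pot). Real MVS clouds are denser still (millions of points); the
value keeps a 20-shoot recovery battery tractable on one CPU while
giving the thin-slab ring cuts sound sampling statistics. The generator
uses spatially uniform areal density and a single flat strip per blade —
it does not model the varying density, reconstruction holes, rolled leaf
margins or ghost geometry of real photogrammetry, so passing recovery
tests demonstrate correctness of the algorithms under the stated noise
model, not field-ready accuracy on arbitrary scans.

## Known limitations

* Leaves of the same phyllotactic rank parity can physically overlap near
  the stem; where blades actually touch, the ring-cut clustering cannot
  separate them and the affected cuts are rejected or capped. In rare
  configurations a leaf loses all its cuts and reports missing width and
  area (explicit NaN, never zero).
* The stem/leaf split assumes the stem (or tassel) reaches near the top
  of the plant inside a vertical column above the root; strongly leaning
  plants should be registered upright first.
* Tip truncation biases leaf length low by ~2% on average at the default
  density; plant height is unaffected (the stem apex is extended).
* Pot axis is assumed parallel to z and pots are modeled as right
  cylinders; tapered pots fall back to the middle slice.
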