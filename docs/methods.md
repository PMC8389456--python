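# Methods

This note documents the models, conventions, numerical choices and known
limitations behind `stakit`. It is written for users who need to know
exactly what the package computes, and for maintainers who need to know
why it computes it that way.

## Euler-angle engine (`stakit.rotations`)

A convention is the 4-tuple (axis string, intrinsic/extrinsic, angle
sense, reference/particle direction). Exactly 12 axis strings over
{x, y, z} avoid repeated neighbours; with the three binary choices this
gives 96 formulations, of which 48 are distinct as maps from triplets to
matrices (the two rotation-direction senses of the transpose pair
coincide for symmetric cases). Matrices are active, act on column
vectors, and the world frame is right-handed with z toward the viewer.
Angles are degrees at the API boundary, matching RELION and Dynamo
metadata; radians appear only internally.

Forward conversion composes elementary rotations: intrinsic =
`R(axis1) R(axis2) R(axis3)`, extrinsic reversed; particle-to-reference
conventions transpose the result. The inverse (matrix to Euler) reduces
every convention to the intrinsic/counter-clockwise/reference case and
solves it with closed-form element extraction whose sign factors are
computed at run time from cross products of basis vectors rather than
hard-coded per axis order — one code path covers all 12 orders. The
middle angle is returned in its canonical branch: [0°, 180°] for proper
Euler axes, [−90°, 90°] for Tait–Bryan axes; the dual solution
(a+180°, −b or 180°−b, c+180°) restores the branch when the reduction
lands outside it.

**Gimbal lock.** Within 10⁻⁶ degrees of a degenerate middle angle the
first and third rotations are coaxial and only their signed combination
is determined. Policy: the third angle is set to 0 and the first absorbs
the freedom. The absorbed sign depends on axis order and branch; rather
than tabulating it, both candidates are evaluated through the forward
conversion and the one that reproduces the input matrix is kept. Only
the matrix is contractually meaningful at lock.

Registry presets: `relion` = zyz, intrinsic, ccw, rotates reference onto
particle; `dynamo` = zxz, extrinsic, ccw, rotates particle onto
reference. These encode the documented conventions of the two packages
and are enforced by round-trip tests (dynamo→relion→dynamo preserves
matrices to < 10⁻¹⁰) rather than asserted axiomatically.

## Metadata formats (`stakit.io_formats`)

STAR values are kept as strings with typed access on demand; this is
what makes the value-level round trip exact across dialects, including
"nan" and oddly formatted numerics. Full-line `#` comments are dropped on
read; fields with internal whitespace are not quoted (RELION's writers
do not quote either) — this is the format's own limitation, documented
here. Dynamo tables are float matrices with 1-based column semantics
(tag 1; shifts 4–6; tdrot/tilt/narot 7–9; cc 10; tomogram 20; x,y,z
24–26); integers are serialized as integers and reals via `repr`, so
read∘write is value-exact. Mdoc files are written with CRLF endings
(SerialEM native) and sections renumbered 0..n−1.

## Geometrical picking (`stakit.picking`)

Orientations are rotation matrices throughout, in the "rotate reference
onto particle" sense; the particle z-axis is the third column. Euler
triplets exist only at the metadata boundary.

* **Sphere seeding** uses a Fibonacci (golden-angle) lattice with
  `N = round(4πr²/s²)` points for spacing `s` — deterministic positions,
  near-uniform area per point (median nearest-neighbour distance within
  ±25% of `s`); the in-plane angle is the only random element and is
  drawn from the caller's seed.
* **Surface meshing** is a 2.5D banded triangulation: each annotated
  slice's points are ordered by polar angle about the slice centroid and
  consecutive rings are zipped into triangle bands (equal-size rings of
  m points give 2m triangles per band). Annotated points become mesh
  vertices verbatim. Normals are oriented toward a user-declared outside
  point, defaulting to "away from the centroid" — appropriate for the
  convex-ish vesicle and membrane annotations this targets, wrong for
  strongly concave surfaces (documented limitation).
* **Surface seeding** allocates `round(area/s²)` particles to faces by
  largest remainder and samples barycentric coordinates from the seed;
  each particle's z-axis is its face normal.
* **Duplicate exclusion** is greedy by descending score with ties broken
  by lower tag; a particle is rejected only if a *kept* particle of the
  same tomogram lies strictly closer than the threshold. Dynamo's exact
  tie-breaking is undocumented; ours is stated and tested against a
  brute-force oracle.
* **Lattice-neighbour filtering** counts, in a single pass over the
  input set, neighbours at distance `expected·(1±tol)` (default
  tolerance 0.2) and keeps particles with at least the requested count.
  Being single-pass, removals never cascade.

## Tilt-series alignment (`stakit.tilt_alignment`)

### Projection model

One tilt-axis angle ψ for the whole series, per-image 2D shifts dᵢ, tilt
angles fixed at their nominal values (never refined, and bit-preserved in
every output):

    predicted(i, j) = Rot2(ψ) · Π · R_y(θᵢ) · r_j + dᵢ

with Π the orthographic projection onto (x, y) and r_j the 3D marker
position. Coordinates are pixels about the image center; ψ is measured
counter-clockwise from the image x-axis.

Two exact gauge freedoms exist and are fixed canonically: (ψ, r) ≡
(ψ+180°, −r) — ψ is reported in [0°, 180°) — and (r, d) ≡
(r + c, d − Rot2(ψ)ΠR_y(θ)c) — markers are centered at zero mean.
Because of the second freedom, *comparing shifts between two solutions is
only meaningful after removing the best-fit gauge vector c*;
`shift_gauge_residuals` does exactly that and is what the tests and the
acceptance script report. (A solution that found 14 of 15 beads is
displaced by bead/14 in its gauge while fitting the data equally well.)

### Pipeline stages and their parameters

All stage parameters derive from two physical inputs — fiducial diameter
(nm) and pixel size (Å/px) — giving the bead radius in pixels, unless
overridden:

| stage | parameter | default |
|---|---|---|
| synthetic template | side | 4·radius + 1, binary dark disc |
| detection | exclusion radius | one template width |
| detection | peaks per image | 50 |
| data template | subimages averaged | up to 300, best scoring |
| symmetry filter | threshold on mean 90°-rotation correlation | 0.4, after σ = radius/2 low-pass |
| trail linking | search radius | max(5·radius, 3.5% of image width) |
| reindexing | distance threshold | 5·radius |
| reintegration | search radius | 5·radius |
| marker merging | 3D radius | 3·radius |
| RMSD pruning | threshold | 1.5·radius |

Detection is two-pass normalized cross-correlation (`skimage`'s
`match_template`): a synthetic binary disc finds first candidates, the
average of up to 300 best subimages is the second-pass template. The
rotational-symmetry statistic (mean Pearson correlation of a subimage
with its own 90/180/270° rotations, after a mild low-pass) suppresses
straight-edge artifacts; the exact statistic Dynamo uses is unpublished,
so ours is a documented stand-in.

Trail linking pre-compensates consecutive-image motion with phase
correlation of low-passed images (without the low-pass the correlation
peak of a sparse bead constellation drowns in pixel noise), then links
mutual-best pairs scored by local-patch correlation minus a small
distance penalty. Trails that split one physical bead are healed later
by merging markers that triangulate within 3 bead radii of each other —
without the merge the duplicate markers bias the centroid gauge.

### Solving

The initial ψ comes from a 3°-step grid search over [0°, 180°), scoring
each candidate by the residual after a few linear marker/shift fits.
`solve_projection_model` then refines (ψ, d, r) jointly by damped
Gauss–Newton — the problem is linear in everything but ψ, so convergence
to machine precision takes a handful of steps. Robustness is IRLS with
Tukey bisquare weights (tuning constant 4.685 × normalized MAD of the
residual norms) on observation residuals; with 10% gross outliers the
robust solver recovers ψ to ~0.05° where plain least squares errs by
degrees (the ablation is part of the test suite). An earlier alternating
closed-form scheme (Procrustes ψ/shift step, re-triangulation step) was
abandoned: its linear convergence stalled around 0.5° even on noiseless
data.

### Center refinement and its noise floor

Each marker's observations are refined against a per-marker reference:
patches are subpixel-aligned (Fourier shift) on the current estimates,
averaged, and the reference is re-anchored on its center of mass (without
the anchor a common-mode position error feeds back into the reference
and oscillates instead of decaying). Each observation is then
re-localized by least-squares registration of its window against the
reference — Gauss–Newton on `window ≈ a·shift(ref, δ) + b` with spectral
derivatives. We use this rather than parabolic interpolation of the
correlation peak because the bead autocorrelation is wide and flat-topped:
parabolic interpolation shows ~0.3 px pixel-locking bias *on noiseless
data*, while the registration is exact there (median error 0.002 px) and
near the Cramér–Rao bound with noise.

That bound matters for interpreting residuals: for the simulator's bead
model (radius 4 px, σ = 1 px Gaussian blur, unit contrast) the
single-observation localization CRLB is 0.32 px per axis at SNR 2 —
about 0.45 px on the residual norm. Observed per-marker residual RMSDs
of ~0.5–0.6 px at SNR 2 are therefore at the information limit, not an
implementation deficit; ψ and shift estimates average over many
observations and come out one to two orders of magnitude tighter.

### Outputs

`.xf` holds one line of six floats per image encoding the *aligning*
transform: A = Rot2(−ψ), t = −A·d, applied to center-relative
coordinates. `.tlt` holds the nominal tilt angles at full precision, one
per line, bit-identical to the input. A plain-text residual report and a
JSON result accompany them.

On-the-fly batch mode is deliberately minimal: a directory poller that
aligns any stack + `.tlt` pair without an alignment JSON next to it
(`align_directory` / `watch_directory`, `stakit align-batch --watch`).
No daemon framework, no state beyond the output files themselves.

## Simulator (`stakit.fixtures`)

The simulator renders what the alignment pipeline assumes: gold beads as
dark Gaussian-blurred discs (unit contrast, 4× supersampled rasterization
so subpixel positions are honest), projected through the exact projection
model above, plus white Gaussian noise with σ = 1/SNR (SNR = peak bead
contrast over noise σ). Default study conditions: 41 tilts from −60° to
+60° in 3° steps, 15 beads of 4 px radius in a 512² field (a typical
8–10 Å/px preprocessing binning for 8–10 nm gold), tilt-axis angle 85.3°,
shifts uniform within ±20 px (±30 px in the randomized recovery study),
SNR 2 (SNR drawn from [1, 3] in the randomized study). Beads are placed
zero-mean so the gauge matches the solver's canonical form.

What the simulator deliberately omits — and hence what passing tests do
not demonstrate: CTF and defocus gradients, dose-dependent contrast
loss, sample drift within an exposure, ice-thickness background ramps,
bead size variation, and non-rigid sample motion. Real data adds all of
these; the pipeline's defaults (robust fitting, RMSD pruning) are the
mitigation, but accuracy numbers from the simulation should be read as
upper bounds.

All generators are pure functions of their seed/recipe; equal inputs
give bit-identical outputs.

## Interchange (`stakit.interop`)

dynamo→relion folds the Dynamo shift columns into the positions and
writes zero shifts on the way back, so a downstream refinement can never
double-count them. Orientation conversion is matrix-mediated; angles are
serialized with 8 decimals so a text round trip keeps matrices within
10⁻¹⁰. The coordinate scale between annotation tomograms and extraction
volumes is an explicit, mandatory-when-relevant parameter: silent
inference of binning factors is the main source of silent corruption in
this interchange, so there is none.

The 3.1→3.0 downgrade resolves each particle's optics group and copies
voltage, spherical aberration, amplitude contrast and image geometry into
the row; `_rlnImagePixelSize` becomes the `_rlnDetectorPixelSize` /
`_rlnMagnification`(=10000) pair, and Ångström origins are divided by
the group pixel size into pixel origins. The exact map the original
tooling used is not published; this one is validated by self-consistency
(idempotence, count and order preservation).

Tomography 5 filenames follow
`<basename>_<count>[<tilt_angle>]_fractions.<ext>`; both ASCII and
Unicode minus signs occur in the wild and both parse. Spoofed mdocs
order sections by the count field, carry the filename's tilt angle
verbatim, and re-read losslessly.

## Problem sizes

The test suite and the acceptance script regenerate everything they
measure. Chosen sizes: 1000 random documents per format for round trips;
1000 particles for interchange fidelity; 200 triplets × 48 convention
variants for the rotation oracle; 20 simulated series (test suite) and
12 (acceptance script) at 512² for parameter recovery, with the
robustness ablation run on exact-geometry trails at every series. These
sizes give stable medians while keeping a full run in minutes on one
CPU.
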