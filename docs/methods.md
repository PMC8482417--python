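# Methods

This note documents the models, parameters and numerical choices behind
`phytomer3d`, and what the synthetic pipeline does and does not establish
about real plants.

## The phytomer model

A maize shoot is represented as an ordered stack of phytomers. Each
phytomer couples three views of the same unit:

* **Mesh** `M` — an open triangle surface per component (leaf, sheath,
  internode, appendage) with per-vertex semantic labels (`vein`, `margin`,
  `interior`, `tip`, `collar_junction`, ...) and, for digitizer-derived
  meshes, the ordinal of the acquisition row each vertex came from.
* **Skeleton** `S` — an ordered base→tip polyline per component (leaf
  midrib, internode axis, sheath vein line, appendage axis). Skeleton
  points are constrained to be mesh vertices (within 1e-6 cm); closed
  components such as the internode therefore carry explicit axis cap-centre
  vertices so their skeleton stays on the mesh.
* **Parameters** `Q` — an extensible record per component: base height,
  length, inclination, azimuth (leaves only), max/min diameter, plus named
  extras (leaf width, tassel branch number, ear length/diameter, ...).

Conventions: right-handed frame, +Z up, azimuth counter-clockwise from +X
seen from above; lengths in centimetres; angles in degrees in data
structures and files, radians only inside trigonometry; phytomer indices
1-based in I/O, 0-based internally.

**Normalization** brings a phytomer to a canonical pose: internode base
(the node) at the origin, internode axis along +Z, and a final rotation
about Z putting the leaf midrib (or, lacking a leaf, the appendage axis)
in the +X half-plane, so the stored azimuth is 0. Because the reference
direction is computed equivariantly from the geometry, normalization is
idempotent and commutes with any prior rigid motion — both properties are
tested at 1e-6 cm.

**Type classification** is positional: phytomers 1..n_root are nodal-root
phytomers, the phytomer at the ear node is the ear phytomer, those below
and above it below-/above-ear, and the terminal phytomer is the tassel
when present (it carries no leaf or sheath).

## Synthetic digitizer and templates

The generator emulates a contact-digitizer acquisition campaign: points in
ordered rows from the sheath/node junction to the leaf tip, **five points
per row plus a single tip point**; rows 1–4 ring the sheath, row 5 is the
leaf/sheath collar junction, and the remaining rows cross the lamina.
Points 1 and 5 of each row are margin points and point 3 is the vein
point. On the collar row the two interior points carry the
`collar_junction` tag while the margin/vein tags are kept — the vein chain
must remain extractable through that row for closed-loop skeleton
recovery.

Parametric shapes (deliberately low-order; the acquisition standard, not
photorealism, is the point):

* **Midrib** — a planar curve leaving the collar at the inclination angle
  θ (from vertical), with tangent angle growing quadratically in arc
  length by a droop angle (default 50°) toward the tip. The curve is
  integrated on a 512-point grid and sampled at exact arc positions, so
  the requested leaf length is met to well under 1 % by the sampled
  polyline.
* **Lamina width** — `w(u) = W · u^a (1-u)^b / (p^a (1-p)^b)` with peak at
  `p = 0.35` of the midrib. The exponents (`a = 0.38736`,
  `b = a(1-p)/p`) are solved so the profile integrates to exactly
  `0.75 · L · W`: the mesh area of a generated leaf and the classical
  agronomic estimate 0.75 × length × width agree by construction, which
  makes closed-loop area checks meaningful. One lamina row is snapped onto
  the peak position (as a careful operator would digitize the widest
  cross-section), so the maximum row chord recovers the leaf width
  exactly. Rows run horizontally, perpendicular to the vertical midrib
  plane; an optional circular-arc fold (sagitta parameter) is off by
  default.
* **Sheath / internode** — linear frusta (`D_max → D_min`); sheath rows
  are half-rings of five points facing the leaf azimuth so the strip is
  C0-continuous into the lamina; the internode is a closed 5-ring frustum
  with axis cap centres.
* **Ear** — a capped spheroid of four 5-point rings on an axis tilted 25°
  toward the leaf; **tassel** — a central spike (slightly leaning, so the
  azimuth reference is defined) with curved branches digitized at
  bottom/middle/top points; **nodal roots** — three short downward spikes.

Default template resolution is 12 rows, giving 43–100 vertices per
phytomer — comfortably under the 200-vertex compactness budget that keeps
shoot assembly and canopy ray casting cheap.

**Cultivar profiles** hold per-parameter (mean, sd) pairs; draws are
Gaussian, clipped at ±3 sd and floored just above zero. The four built-in
ideotypes (`shortwide`, `longnarrow`, `tallmid`, `compact`) contrast leaf
length/width, internode length and leaf inclination the way commercial
hybrids do; they are synthetic stand-ins, not measurements. Every
stochastic operation takes an explicit seed and is bit-reproducible.

What the synthetic data does **not** contain: digitizer noise (off by
default, available via `noise_sd`), leaf twist and wrinkle microstructure,
organ collisions, senescent/withered lower leaves, and within-shoot
correlated parameter gradients. Tests passing on this generator therefore
establish the pipeline's internal consistency (geometry, conservation,
equivariance, retrieval, closed-loop recovery), not field accuracy.

## Template database

Each entry stores an OBJ + JSON-sidecar template plus four keyword groups
(agronomic; model info with storage path and vertex/face counts;
morphological parameters; free-form other). The index is one diff-able
JSON file. Similarity retrieval minimizes weighted Euclidean distance
over z-score-normalized shared numeric parameters, statistics computed
within the requested phytomer type's sub-database; missing parameters are
skipped with weight renormalization, ties break toward the smaller entry
id, and a brute-force scan is the test oracle. An empty query returns the
first entry by id (a deliberate convenience for geometric-only assembly);
a non-empty query sharing no parameter raises.

## Skeleton ↔ mesh conversion

**Mesh → skeleton.** Semantic meshes: vein-labelled vertices in
acquisition-row order, then the tip — exact by construction. Unordered
clouds: iterative Laplacian contraction over the symmetrized k-NN graph
(k = 8), solving per iteration the regularized least-squares system
`(W_L² LᵀL + W_H² I) P' = W_H² P` with `W_L` starting at 1.0 and doubling
each iteration (capped at 2048×), `W_H = 1`. Iteration count is an upper
bound (default 10): contraction **stops as soon as the cloud is locally
one-dimensional** — median fraction of neighbourhood PCA variance on the
first axis above 0.95. This convergence stop matters: once the cloud has
collapsed to a curve, further amplification no longer removes thickness
but starts smoothing away genuine skeleton curvature (a quarter-torus
test arc straightens by ~1 cm within two extra doublings; with the stop
it stays within 0.1 cm of the true centre arc, and a unit-radius cylinder
cloud contracts to within 0.1 cm of its axis). Contracted points are
ordered by projection on the chord between the two farthest points
(two farthest-point passes) and bin-averaged into a default 20-node
polyline.

**Skeleton → mesh.** (i) Retrieve the leaf template minimizing z-scored
distance on the descriptor vector (arc length, chord/arc ratio, base
inclination from vertical; weights 1/1/0.5). (ii) Uniform-scale by the
chord ratio and rigidly align the template vein endpoints to the target
endpoints (minimal rotation between chords; the residual spin about the
chord is left at the minimal-rotation solution). (iii) Resample the
target **at the template's vein arc-length fractions** — not uniformly —
so vein vertices correspond one-to-one; this choice makes self-conversion
exactly the identity. (iv) ARAP-deform with the vein vertices as hard
handles.

**ARAP.** Local/global alternation: per-vertex rotations from the SVD of
the weighted edge covariance (determinant-corrected), then a global
sparse solve of the cotangent Laplacian with handle rows eliminated and a
single factorization reused across iterations. Cotangent weights are
clamped at ≥ 0 (thin digitizer strips produce obtuse triangles whose
negative weights destabilize the solve); a vertex whose clamped one-ring
loses all weight falls back to uniform weights with a warning. The
iteration is initialized with the best-fit rigid motion of the handle set
(Kabsch), which makes rigid-target recovery exact in one iteration and
speeds up general convergence. Stopping: max vertex move below
1e-6 × bounding-box diagonal, or `max_iters` (default 50). The rigidity
energy is non-increasing by construction and asserted in tests.

## Assembly

Shoot assembly retrieves one template per slot, optionally rescales it
uniformly to the target leaf length (off by default — templates are used
verbatim after similarity selection), and applies rotation-about-Z then
translation. Heights are absolute node z by default; a cumulative mode
stacks per-slot increments. Non-monotone heights warn rather than fail
(real shoots lose lower leaves). Populations place shoots on a centred
grid — rows south→north along +Y, +X east, `row_distance` between rows,
`plant_spacing` within rows, `spacing = 1/(density × row_distance)` —
with per-shoot azimuths fixed, listed, or uniform-random under an
explicit seed. Placement is rigid, so within-phytomer geometry and total
vertex counts are conserved exactly; no collision resolution between
neighbouring leaves is attempted.

## Light interception

Direct beam only — no diffuse sky, no scattering; the interface leaves
room for a diffuse term later, and this is the main physical limitation
to keep in mind when reading absolute PAR numbers. Solar position uses
standard declination/hour-angle geometry on local solar time (the
longitude field is carried for interface completeness). Defaults emulate
a mid-summer day in the Beijing area: 39.93° N, 116.27° E, 30 June,
7 am–5 pm at a 30-minute step, incident PAR 1500 µmol m⁻² s⁻¹ at normal
incidence under a sine-of-elevation model (a `constant` model and a
`fixed_sun` override support controlled experiments and closed-form
checks).

Per time step with the sun up, every leaf triangle is sampled at 4
interior-biased random points (drawn once per simulation from the
explicit seed, so results are deterministic and adding geometry can only
reduce interception). Occlusion testing rotates the scene so the beam
runs along +Z, bins triangles into a uniform XY grid (≈ √T cells per
axis, capped at 192), and shadows a sample when any triangle in its cell
covers its XY position strictly above it along the beam (relative z
tolerance 1e-7 of the scene extent; samples are kept off triangle edges
so coplanar neighbours never self-shadow). Intercepted power per triangle
is `incident × area × |cos incidence| × unoccluded fraction` — both leaf
faces absorb; sheath, internode and appendages occlude but do not
accumulate. Accumulation is reported per (shoot, phytomer) as leaf area
(cm²), intercepted PAR (mol) and PAR per unit leaf area (mol m⁻²), with
per-step diagnostics; `summarize_central` averages the central block of
the grid (default 3×3) by phytomer index to avoid border effects.

Verified properties: closed-form flux on a horizontal unit leaf within
0.1 %; a fully shaded leaf intercepts exactly zero; total interception
never exceeds the incident flux through the canopy footprint; doubling
the sample count moves canopy totals by < 2 %; results are invariant
under rigid rotation of scene plus sun.

## Problem sizes

The test suite and acceptance script run at desk scale by choice: 2000
point clouds for skeletonization, 12–16-row leaves (41–61 vertices),
databases of 20–192 templates, canopies of 1–9 shoots for light physics
(with a 5-step day for occlusion properties and the full 21-step day for
the worked example) and a 200-shoot population for the assembly scale
check. The whole suite runs in well under a minute on one CPU.

## Known limitations

* Direct-beam light only; absolute interception values under real skies
  need a diffuse term.
* The Laplacian path assumes an unbranched, tube-like organ; branching
  skeletons (whole tassels) would need graph-aware ordering.
* Template retrieval uses skeleton-level descriptors for conversion and
  flat morphological distance for assembly; no learned similarity.
* Phytomers are static snapshots — no growth, wilting or diurnal leaf
  movement.
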