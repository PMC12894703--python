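# Methods

This note records the mathematical conventions, parameter choices and known
limitations behind the package; the README covers the user-facing surface.

## Rigid-motion model and conventions

A particle is an element (ω, **p**) of SE(3). The stored rotation ω maps
the canonical (reference) frame onto the particle; file readers convert
each dialect's Euler convention into this matrix convention at read time
(Relion ZYZ intrinsic angles are inverted on input, TOM/AV3 and Dynamo ZXZ
angles compose directly), and every reader/writer pair is round-trip
tested to 1e−6 in position and angular distance. Positions are continuous
0-based coordinates in the list's native unit (nm internally; voxel lists
carry an Å/voxel pixel size). Shift/offset columns (Relion origins, motl
shifts, Dynamo shifts) are folded into the position on input.

Angles are radians internally and degrees at every user-facing interface.
Axis–angle vectors use angle ∈ [0, π]; at π the axis sign is fixed by the
first nonzero component positive, making downstream axis binning
deterministic.

### Numerical choices in the SO(3) layer

`log_so3` derives the angle from atan2(‖antisymmetric part‖, (tr−1)/2),
which is stable over the whole group. The axis comes from the
antisymmetric part except within 1e−4 of π, where that part degenerates;
there the symmetric part is used: (R+Rᵀ)/2 = cosθ·I + (1−cosθ)·aaᵀ gives
aaᵀ with a well-conditioned denominator (1−cosθ ≈ 2), the best-conditioned
diagonal entry seeds the axis and off-diagonals supply the rest. Round
trips exp∘log stay below 1e−12 even for angles within 1e−12 of π. Near 0
the first-order skew extraction is exact to machine precision.

`swing_twist` decomposes r = cone · R(axis, α) via the quaternion
projection onto the axis; when r maps the axis to its negation the twist
is undefined and reported as 0 with cone = r (documented convention).
`project_to_so3` is the orthogonal-Procrustes projection UVᵀ with a
determinant sign fix on the last column of U.

## Twist descriptors

The descriptor stores one record per ordered (query, neighbor) pair with
0 < distance ≤ radius, restricted to equal tomogram ids (tomograms are
independent coordinate frames). The neighbor search is an exact
fixed-radius KD-tree query with closed-ball semantics (ties at exactly the
radius are included); the test suite checks equality with an O(n²)
brute-force scan. Records carry the twist vector, both distances, the unit
rotation axis (undefined below 1e−9 rad) and the two particles' in-plane
angles about their intrinsic z. The in-plane angles are frame metadata:
unlike every twist-derived field, they change under global rotations of
the scene (only their differences are invariant under in-plane rotations)
and they are excluded from the rotational-invariance contract, which is
enforced at 1e−8 for all pair-derived quantities.

Supports are defined purely in the query's canonical frame — never in
extrinsic coordinates — which is what preserves descriptor invariance
under reduction. Cylinders exist in a symmetric (height about the origin)
and a one-sided (axial range [0, h]) variant; cones optionally mirror
through the origin to form double cones; binary masks use nearest-voxel
lookup at threshold 0.5 with the center voxel at the origin (bit-exact
reproducibility over interpolation). A support must fit inside the
descriptor's initial radius, otherwise records it should contain were
never computed. Filter ranges are closed intervals, with angular fields
taken in degrees.

## Angular score

For a symmetry with geometric representative V (regular n-gon on S¹ for
Cn, platonic solid on S²), δ_V(ω₁, ω₂) is the symmetric spherical
Hausdorff distance between ω₁V and ω₂V, and σ_V = 1 − δ_V/m_V with m_V
the maximum of δ_V. The printed directed max–min form is not used: the
two directed distances genuinely differ for congruent rotated vertex
sets, so the symmetric Hausdorff (named by the defining equation) is
implemented and argument symmetry is asserted in tests.

For cyclic symmetry the inputs are first reduced to the plane (the
swing–twist in-plane portion about intrinsic z acts on the n-gon; the cone
portion is discarded). Consequences embraced here: δ_V collapses to the
circular fold of the in-plane difference into [0, π/n] (verified against
the explicit vertex-set computation), m_V = π/n exactly (36° for C5), and
left invariance holds over SO(2) — the group the projected score lives on
— rather than all of SO(3). Platonic m_V values are maximized numerically
(20 000 seeded sample rotations, Nelder–Mead refinement from the five best
starts) and cached per process; the tetrahedron value is cross-checked in
tests against an independent 10⁶-rotation sampling oracle at 0.1°.

The Cn symmetry scan scores every unordered record pair for each candidate
n, ranks candidates by median score (ties to the smallest n), and compares
the best candidate's score distribution against every other with a
two-sided Mann–Whitney U test (exact enumeration for tie-free samples of
at most 8, tie-corrected normal approximation otherwise). A scan where
every candidate reaches median 1 (e.g. all-identity orientations) is
flagged degenerate.

## Lattice features

Shells are greedy ascending groups of pair distances whose spread stays
below a tolerance fraction (default 0.1) of the group center; on an ideal
triangular lattice this yields shells at a, √3·a, 2a. The link of a query
is the graph on its first-shell neighbors with edges wherever two
neighbors are themselves a first-shell distance apart; reported features
are vertex/edge counts, Euler characteristic V−E, link type (closed cycle
/ open chain / fragments / empty) and the median and standard deviation of
the central angles (60° for regular flat hexagons, 72° at fivefold
vertices). This first-shell link construction is this package's
fully-specified stand-in for α-complex-based lattice topology features: it
exposes the same observable surface without an auxiliary complex.

Pentamer labeling standardizes (median θ, std θ, vertex count), keeps
principal components to 95% explained variance, splits by seeded 2-means
and names the cluster whose median central angle is nearer 72° the
pentamer class. On geodesic (icosphere) test lattices the edge lengths
spread ~16%, so those tests use shell tolerance 0.2; all 12 fivefold
vertices are recovered exactly.

## Dominant rotation axes

Record axes (sign-folded to the upper hemisphere: z > 0, then y > 0, then
x > 0) are histogrammed in an equal-area scheme of 8 polar rings × 16
azimuthal sectors. The dominant axis is found by cap voting rather than
the modal bin: each bin center plus the pole proposes a 15° spherical cap
(15° covers the hemisphere at this resolution), the fullest cap wins with
ties to the lowest candidate index, and the dominant axis is the
normalized mean of the axes in the winning cap. Cap voting avoids the
azimuthal fragmentation that would split a tight polar axis population
across all 16 sectors of the top ring and let a smaller off-pole
population win the modal bin.

## Synthetic study conditions

The chromatin generator defines the conditions all pattern-recognition
results refer to. Blocks are parametric (lengths nm, angles degrees):

- **Stacked pair**: neighbor at 6 nm along the query's intrinsic +y with a
  15° relative rotation about +y. 6 nm is the nucleosome stacking
  distance scale; 15° is the angular-distance peak stacked pairs produce.
- **Trinucleosome**: a stacked pair plus a linker-connected third particle:
  a screw-like step of 24.5 nm along +z with a 60° rotation about the
  linker axis (+z, the DNA entry/exit direction). The 24.5 nm linker
  distance is the observable the dinucleosome cluster centers on; the 60°
  linker twist and axis are this package's parametric choices.
- **Helix**: six stacked pairs chained by linker steps, with exactly one
  pair's twist inflated 3× (45°, outside the classifier window), so 10 of
  12 members belong to within-window stacked pairs by construction.

The reference composition is 6 helices, 350 stacked pairs, 340
trinucleosomes and 3200 mononucleosomes (4992 particles) in a
600×600×150 nm box. Blocks receive a Haar-random global rotation and a
uniform anchor, rejected until every member clears 10 nm from all placed
particles (uniform-grid hash, O(1) per check); mononucleosomes follow the
same rule. Block anchors are sampled inside the box but long blocks may
extend past its faces; nothing downstream assumes containment. All
generators are pure functions of (spec, seed).

The noise model adds an isotropic Gaussian to positions with per-component
σ = (0.8/3)·level nm — reading "deviations up to ~0.8 nm at level 1" as a
3σ bound — and perturbs rotations as r′ = project_to_so3(r + λN) with N
standard normal and λ the orientational level, whose level-1 deviations
reach the ~60° regime (Monte-Carlo calibrated in tests).

What the generator does **not** emulate: missing-wedge anisotropy,
picking-induced list incompleteness, density-map noise, or biologically
realistic chromatin fiber paths. Passing tests therefore demonstrate the
correctness and noise response of the geometric machinery on its stated
conditions, not classifier performance on experimental tomograms.

## Classification pipelines

**Stack classifier.** The descriptor (10 nm radius) is reduced by a
one-sided cylinder along intrinsic +y (radius 3 nm, axial range [0, 8] nm)
and an angular window of 15° ± 10°. Detection is at the pair level: a
surviving record pins down a stacked pair and *both* endpoints are labeled
stacked — the one-sided support sees a coin-stack pair only from its lower
member, but the partner is stacked all the same. This semantics is what
makes the three recovery fractions (100% stacks, 66.7% trinucleosomes,
83.3% helices) exact construction identities of the scene.

**Dinucleosome finder.** The descriptor (30 nm radius) is reduced by a
double cone along ±z (half-angle 30°, height 25 nm ≤ 30·cos 30°, so the
cone fits the spherical support). Each record contributes three features:
Euclidean distance, angular distance, and |cos| alignment of its rotation
axis with the dominant axis. The magnitude is used because a record and
its reverse carry opposite-sign axes for the same physical pair; keeping
the sign would split every dinucleosome population in two. Features are
z-scored and clustered by seeded k-means (k = 15, 10 restarts, clusters
relabeled by ascending center norm so partitions are reproducible and
row-order independent). Cluster composition counts a particle as
contained if any of its records is assigned to the cluster.

**Affiliation / cleaning.** Optional intrinsic-axis shift (e.g. by the
ring radius along −x, collapsing ring subunits toward their centers), then
descriptor → support → filters → connected components; components below
the minimum size (default 3) are dropped. Evaluation against a
ground-truth list uses greedy one-to-one positional matching within half
the truth's median first-NN distance, reporting global and per-tomogram
F1.

**Footprint mining.** Cross-list descriptors are summarized per query by
the occupancy of six 45° cones ordered (+y, −y, +x, −x, +z, −z); the
footprint id is the binary encoding of the occupancy vector. Per
frequency-ranked footprint, the dominant axis of the pooled records is
found as above, records within 30° of it are sub-binned into five
equal-width angular-distance ranges, and each range reports its medoid
pair as representative.

## Determinism and problem sizes

Every pipeline is a pure function of (inputs, config, seed); k-means seeds
and restart counts are fixed, cluster labels canonicalized, and record
order is sorted by (query_id, neighbor_id). The test suite runs the full
reference composition once for the acceptance checks and uses reduced
scenes (e.g. 2 helices / 40 stacks / 40 trinucleosomes / 300
mononucleosomes in a 250×250×120 nm box, and a 3×3 noise grid × 3 seeds at
similar scale) elsewhere; at these sizes the whole suite completes in
about a minute and the acceptance script in well under one.

## Known limitations

- Cyclic symmetry axes are fixed to intrinsic z; dihedral symmetries and
  continuous symmetry detection are out of scope.
- The angular score for platonic solids depends on the chosen
  representative orientation; a user-supplied reference orientation
  re-seats the vertex set, but no automatic registration is attempted.
- Proximity clustering is defined on undirected graphs and refuses
  cross-list (directed) descriptors.
- The mononucleosome background density is a box parameter; fractions
  reported for random classes (e.g. monos swept into the dinucleosome
  cluster) depend on it, unlike the structured-class identities.
- Supports compose by sequencing (intersection) only; there is no union
  or general boolean algebra beyond the mirrored cone.
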