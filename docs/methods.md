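# Methods

`capsidlattice` is a synthetic-data reimplementation of the cryo-electron
tomography (cryo-ET) lattice analysis used to characterize immature and
mature retroviral capsids: ground-truth lattice generation, tomogram
forward simulation, subtomogram alignment and averaging, and lattice
architecture analysis (spacing, pentamer detection and verification,
hexamer counting, recovery classification). This note records the models,
the parameters that matter, the numerical choices, and the limits of what
the synthetic experiments demonstrate.

## Ground-truth lattice models (`capsid_models`)

A capsid lattice is a set of sites (capsomer centres, nm) with orthonormal
local frames (z = outward lattice normal), a ring order (6 = hexamer,
5 = pentamer, a +π/3 disclination), a layer index, and bonds between
nearest neighbours. Invariants enforced across generators: bond lengths
within [0.8, 1.2] × the lattice constant; closed components carry exactly
12 pentamers and satisfy V − E + F = 2; heptamers are never generated.

**Immature shells** are hexamer-only quasi-hexagonal packings on a sphere:
Fibonacci-lattice seeding, a short in-surface repulsive relaxation, one
contiguous spherical-cap gap covering a configurable area fraction, and a
few small (1–3 site) defects. The site count follows the area argument
N = 4πr²/((√3/2)s²). The membrane (bilayer midplane convention) sits 6 nm
above the CA-layer radius. Defaults: spacing 8 nm, CA radius such that the
membrane diameter is in the 110–120 nm range at full scale; demo runs use
smaller radii (20–24 nm) so a full pipeline completes in minutes, which
changes counts but not spacings, noise levels, or geometry statistics.

**Closed polyhedral shells** are Caspar–Klug (h,k) triangulations of the
icosahedron: the 20 faces carry copies of the planar lattice triangle with
consistently right-handed winding (a mirrored face silently corrupts
chiral classes), points are projected to the sphere, duplicates on shared
edges merged, and bonds taken from the convex hull (which is the exact
Delaunay triangulation for points in convex position). A short tangential
spring relaxation evens out the flat-to-sphere projection distortion.
This yields exactly 12 pentamers (vertex degree 5) and 10(T−1) hexamers,
T = h² + hk + k².

**Fullerene cones** (the HIV-like 5/7 morphology) are built as exact
ring-stacked triangulations rather than from axially cut icosahedral caps:
an axial cut of a Goldberg shell can only produce 6/6-type pentamer
splits, never 5/7, because any vertex adjacent to a polar 5-ring is itself
at the pole. The construction: a tip apex pentamer; the remaining four
narrow-cap pentamers absorbed one or more at a time at "growth seams" of
the expanding ring stack (each absorption reduces the ring-growth rate by
one); a hexamer-only conical body at growth +1 site/ring; one wide
"shoulder" ring carrying 6 evenly spaced pentamers that flips the growth
rate to −5; a uniform five-seam descent; and a base apex pentamer closing
the final 5-ring. Ring sizes follow the discrete recurrence
r_next = 2r − r_prev − p (p = pentamers on the ring). A plan search over
narrow-cap pentamer distributions (with optional hexamer-only gap rings)
and shoulder positions (ring size ≡ 0 mod 5, ≥ 20 so the five descent
seams clear the body seam) hits any hexamer target ≥ 100 within 10%
(coverage gaps ≤ ~11% between achievable sizes). The embedding starts on
stacked circles and is spring-relaxed in 3D with a weak inflation
pressure; a final uniform rescale makes the mean bond length equal the
requested spacing exactly. All 12 pentamers are isolated (surrounded by
hexamers only), which the downstream detection requires. For the
paper-scale cone (~200 hexamers) the 5/7 split is clean under an axial
mid-plane count; for the smallest admissible cones the narrow-cap
pentamers necessarily spread down the body and a mid-plane count can read
6/6 even though the caps still carry 5 and 7.

**Spirals** wind a lattice sheet around the core axis with the radius
growing by `pitch` per turn (an Archimedean spiral in cross-section) and
poles truncated, so each full turn contributes ≈ 4π of integrated Gaussian
curvature; a straight swept sheet would be developable (zero curvature,
zero pentamers), contradicting the requirement that multi-turn spirals
carry more than 12 disclinations. Points are laid out row-wise at the
target spacing, triangulated by parameter-space merging, spring-relaxed,
and pentamers are assigned to the interior vertices where the discrete
angle deficit concentrates, with the count set by round(total deficit /
(π/3)) and non-adjacency enforced.

**Nested cores** are unions of independently generated layers (strictly
decreasing radii, clearance ≥ one spacing, no inter-layer bonds). Layer
lattice constants differ, so the bond-window invariant is checked per
layer.

## Tomogram simulation (`tomo_sim`)

The simulator renders final reconstructed volumes directly; tilt series,
motion, and exposure filtering are out of scope. Model space (nm) maps to
volume space at 10 Å/nm; the default voxel is 5.4 Å (four-fold binning of
a 1.35 Å pixel), boxes 24–48 voxels.

Templates are parametric Gaussian-blob units with exact Cn symmetry:
mature = a single ring of six protomer blobs (ring radius 0.32 × spacing);
immature = two stacked rings 40 Å apart with *different* radii (NTD wider
than CTD, matching their distinct per-layer lattice spacings) plus an
inner six-helix bundle of rods parallel to the symmetry axis with
adjacent rod axes 15 Å apart; pentamer = the five-fold analogue of the
mature unit. Rendering sums the oriented template over sites (optionally
re-using an external centring point so subsets share a frame), with an
optional membrane shell and RNP interior for immature particles.

The missing wedge is a hard Fourier mask: a coefficient is kept when its
angle in the plane normal to the tilt axis lies inside the tilt range
(Friedel-symmetrized); the operator is an idempotent projection. Noise is
white Gaussian added after the wedge, with variance set by the
signal-variance / noise-variance ratio (SNR) inside an explicit mask —
the definition must be fixed because the source material never defines
SNR. Default SNR 0.5, tilt ±60°.

Rotations about z used for symmetrization are implemented as exact
quarter-turns plus FFT shears; this is accurate to the shear-aliasing
floor (~1e−4 relative for band-unlimited content), noticeably better than
spline resampling, but not exactly idempotent — no Cartesian-grid method
is.

## Subtomogram alignment (`sta_core`)

Orientation convention: a particle's matrix R maps the reference frame to
the particle frame (the subtomogram models wedge(shift(rotate_R(ref)))).
Quaternion/matrix internally, ZYZ Euler degrees at I/O boundaries (STAR
tables with a documented TSV fallback).

Scoring: the soft mask (spherical, or cylindrical to isolate the lattice
layer from membrane and RNP) is applied to the reference *in the reference
frame* and travels with each trial rotation. The translation search is a
matched filter: the subtomogram is band-limited to the sampled Fourier
region (wedge ∩ low-pass, DC excluded), correlated with the rotated
zero-mean masked reference, and globally normalized. Two alternatives were
tried and rejected with synthetic probes: masking the subtomogram with a
centred mask biases the peak toward zero shift (the mask-overlap envelope
dominates); fully local normalization (FLCC) removes the lattice-energy
advantage that makes true sites outscore the three-fold "decoy" minima of
a honeycomb lattice. Sub-voxel shifts come from separable quadratic
interpolation of the correlation peak; angular search is a cone + in-plane
grid sorted by rotation magnitude, so correlation ties break toward the
smaller rotation. The first pass of a reference-free run searches the full
in-plane symmetry wedge (±180°/n).

Averaging is Fourier-space with per-voxel wedge-occupancy weighting (sum
of aligned coefficients / sum of rotated wedge masks, floored at 0.2),
zero-filling uncovered voxels and reporting the covered fraction, followed
by Cn symmetrization. Half sets split even/odd within each virus and never
share references. The adaptive low-pass filter follows the half-map FSC
0.5 crossing, floored at the previous filter and capped at 0.85 Nyquist
(small half-set averages overestimate their own resolution).

Gold-standard FSC: shell correlation of masked half maps; the correction
repeats the measurement with phases randomized beyond a frequency
(default: where the unmasked FSC first drops below 0.8) and applies
(FSC_t − FSC_n)/(1 − FSC_n) beyond it. Guinier sharpening fits
ln(spherical structure-factor average) against s²/4 over a configurable
band and applies exp(+B s²/4) with a soft low-pass at the FSC resolution.

### Scale and the reference-free bootstrap

The real analysis aligned tens of thousands of subtomograms; at that scale
a blind spherical seeding converges by progressive symmetry breaking. At
desk scale (~100–300 particles per virus, SNR 0.5) extensive experiments
(asymmetric-start iterations, stochastic subset references,
single-particle initial references, density-peak and analytic
matched-filter picking) show the translational register does not
bootstrap: the quasi-uniform honeycomb lattice offers three-fold decoy
minima, and the per-particle localization limit with even a perfect
reference is ≈ 1.5 nm median at these conditions. The demo pipeline
therefore mirrors the practice used for difficult real cases: simulated
manual picks. Picked positions are the hexamer sites jittered by
0.15 × spacing; orientations carry no ground-truth information (z along
the outward direction of a sphere fitted to the picks, random in-plane
angle). Refinement is pick-anchored — a translation-only pass against the
C6-averaged reference at pick poses, a reference rebuild, then one
orientation + translation pass — with a 0.25 × spacing trust region, and
it stops there because further self-consistent iteration only compounds
reference blur. Pentamer positions are never picked; they must be
recovered downstream from the hexamer arrangement, which is the point of
the analysis. Duplicate removal (greedy by descending CCC) and the
deterministic false-positive rules replace manual curation. The CCC
percentile cut (default keep 0.9) targets the junk population of
oversampled blind seeding; the pick-based demo keeps all particles
(keep fraction 1.0) since each seed corresponds to one annotated unit.

## Lattice analysis (`lattice_tools`)

Neighbour graphs connect positions within a distance window; brute-force
all-pairs and kd-tree construction are exact and identical (the brute
force is the oracle below 2,000 nodes). Spacing statistics are means/SDs
of edge lengths, pooled and per virus, measured with the [0.8, 1.2] ×
spacing window; graphs feeding pentamer detection use a slightly wider
window (0.75–1.30×, still far below the √3 second shell) so measurement
jitter cannot break five-rings.

Pentamer-coordinated positions are detected as chordless five-cycles whose
centroid is an empty disclination site — no node within 0.8 × the window
minimum (an occupied site would put a node within ~0.2 × spacing; the
puckered ring around a true disclination keeps its nodes at ≥ ~0.75 ×
spacing) — and whose ring is planar within 0.35 × d_min with a normal
aligned to the member normals. Candidates closer than d_min merge. On
noise-free generator geometry the census is exact for every morphology
(12 per closed component, 0 on flat sheets, robust to 0.05 × spacing
jitter over 10 seeds); at the demo's ~0.2 × spacing position noise only a
subset of rings survives, so the end-to-end check asserts the *verdicts*
of found candidates, not their count.

Verification extracts subtomograms at candidate positions, rotates the
candidate normal to +z, applies C5 symmetrization, and scores constrained
CCC against the pentamer template; the default threshold 0.25 sits midway
between the null (≈0) and a typical true correlation (>0.5). Occupied
pentamers (mature) verify true; empty pentameric holes (immature) verify
false.

Hexamer counting excludes flagged particles and summarizes per virus and
per group. Recovery classes use fixed thresholds (fully ≥ 0.95, nearly
≥ 0.80 of ground-truth sites matched within 0.5 × spacing) standing in
for the visual assessment used on real tomograms. Integrated discrete
curvature sums interior angle deficits (4π per closed component by
Gauss–Bonnet; π/3 per pentamer by convention). Lattice maps export as
Chimera CMM or TSV with per-virus CCC colour scales (min → red, max →
green; degenerate scales map to mid-scale).

## Rigid-body fitting (`map_fit`)

Coordinate models (PDB/mmCIF via gemmi; a generator builds ideal Cα
helix-bundle fixtures) fit into maps by local maximization of real-space
correlation between the map and a Gaussian-rendered model density (FWHM =
nominal resolution), six pose parameters, derivative-free simplex from the
given start — deterministic, mirroring an interactive fit. Helix
arithmetic uses the canonical α-helix rise of 1.5 Å/residue with inclusive
residue-span counting (so the 35-residue span 222–256 gives 52.5 Å, and a
50 Å rod holds 33 residues).

## What the synthetic experiments do and do not show

They exercise the full measurement chain — geometry generation, imaging
degradation, alignment, filtering, averaging, FSC/sharpening, and lattice
census — against known ground truth, and reproduce the qualitative
immature/mature contrast at pentamer-coordinated positions. They do not
emulate per-tilt CTF, dose damage, gold fiducials, crowding, membrane
deformation, or conformational heterogeneity, and the demo scale
(~60–150 sites per virus) is an order of magnitude below real virions, so
absolute resolutions and counts are not comparable to real-data values;
spacings, topological counts, and classification behaviour are.
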