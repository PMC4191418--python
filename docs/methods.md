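# Methods

This note documents the models, conventions, numerical choices and known
limitations behind `triplexkit`. Units throughout: distances in Å
(SASA in nm²), angles in degrees at API surfaces (radians internally),
energies in kcal/mol, k_B = 0.0019872041 kcal mol⁻¹ K⁻¹, default
temperature 300 K.

## Base frames and the standard reference geometry

Every nucleobase is assigned a right-handed orthonormal frame by
least-squares rigid superposition (SVD/Kabsch, proper-rotation branch
enforced) of an idealized planar base geometry onto the observed *ring*
atoms — exocyclic substituents are excluded from the fit so that pair
deformations do not tilt the frame. The idealized geometries are
expressed in the standard base reference frame of the field (origin in
the base plane, +x toward the major-groove edge, +z along the base
normal) and are embedded in `bases.py`.

Full-atom residue templates (sugar, phosphate, hydrogens) are assembled
at run time from the Chemical Component Dictionary ideal residues
shipped with biotite: the CCD residue is superposed into the standard
frame via its ring atoms, its base heavy atoms are snapped exactly onto
the embedded standard coordinates, and one shared sugar–phosphate
conformer (taken from the purine template) is grafted onto all four base
types. The shared backbone is a deliberate idealization: it makes every
residue's phosphate sit at the same position in its own base frame, so
fiber helices have perfectly regular backbones and the Zp metrics are
constant along a uniform helix. The resulting backbone geometry is
CCD-derived, not a fiber-diffraction model; absolute phosphate radii
(≈ 11 Å in a B fiber here) and hence absolute groove widths are offset
from crystallographic fibers, while all *relative* comparisons (B vs A,
bound vs free) are meaningful.

## Pair, step and helical parameters

The rotational decomposition is the symmetric mid-frame ("half-hinge")
construction. For two triads T₁, T₂: the hinge axis is z₁ × z₂ with
angle Γ; both triads are rotated by ±Γ/2 onto the common mid z-axis;
twist ω is the signed angle between the rotated x-axes about that axis;
the mid-frame x-axis bisects them; the phase φ of the hinge against the
mid y-axis splits Γ into roll = Γ cos φ and tilt = Γ sin φ; translations
are the origin difference expressed in mid-frame axes. The construction
is exactly invertible — `compose_step` is the closed-form inverse
(T₂ = T₁ Rz(ω/2 − φ) Ry(Γ) Rz(ω/2 + φ)) — and the round-trip is exact to
~1e-13, which the builder exploits and the tests quantify at 1e-6 over
1000 random parameter sets.

Intra-pair parameters use the same engine: the complementary base's
frame is flipped (y, z negated) and decomposed against the leading
base's frame, giving (shear, stretch, stagger, buckle, propeller,
opening); swapping the two bases negates exactly shear and buckle.
Reversing strand direction negates shift and tilt and preserves the
rest; both symmetries are property-tested.

Local helical parameters come from the screw decomposition of the step
rotation: the helical axis is its rotation axis (oriented along the
mid-frame z), helical twist its rotation angle, helical rise the origin
displacement along the axis; the axis point solves
(I − R)p = (o₂ − d·â) − R o₁ in the plane normal to the axis.
x/y-displacement are the mid-frame origin's offset from the axis in a
frame whose x is the mid-frame x projected perpendicular to the axis;
inclination and tip decompose the mid-frame z against that frame
(η = −arcsin(z_m·ŷ_h), so A-form steps have positive inclination).
Zero-rotation steps have no screw axis and are flagged degenerate, not
extrapolated; steps with twist within 5° of ±180° carry a quality flag
and are never unwrapped.

Zp is the z-component, in the mid-step frame, of the vector from the
complementary-strand phosphate of the step to the leading-strand
phosphate (P of residue i+1 and of residue 61−i in the 30-mer
numbering); Zp(h) is the same vector's component along the local helical
axis. On the fiber models built here, B-form Zp ≈ −0.06 Å and A-form
≈ +0.51 Å — the low/near-zero band versus a clearly raised value, the
discrimination the metric exists for, though the absolute A value is
backbone-model-dependent.

## Ensemble metrics

**Region statistics.** Two-stage averaging: each step's parameter is
time-averaged over frames, the region mean is the mean of those per-step
averages. The SEM block-averages the per-frame region-mean series by the
doubling scheme: the series is repeatedly halved by averaging adjacent
pairs, the naive SEM is computed at each level, and the estimate is
taken at the first level whose SEM changes by < 5% from the previous one
(plateau detection), falling back to the largest block. Validated
against the closed forms σ/√N (iid) and σ√((1+φ)/(1−φ)/N) (AR(1)).

**Groove widths** are raw inter-strand P–P distances (no phosphate-radius
subtraction): at base-pair i, minor = |P(i) − P̃(i−2)|,
major = |P(i) − P̃(i+2)| where P̃(j) is the phosphate of j's paired
residue; offsets are configurable. Terminal positions whose partner
phosphate does not exist are NaN, never extrapolated.

**Stacking overlaps** project each base-pair's polygon onto the step
mid-frame xy-plane and intersect them with shapely. The endocyclic
polygon of a pair is the union of its two base-ring polygons; the
exocyclic polygon extends each base's ring by the convex hull over its
exocyclic N/O/C substituents. Self-intersecting projections are repaired
by the even-odd rule (`buffer(0)`). Verified to 1% against a
Monte-Carlo ray-casting oracle at 10⁶ points.

**Bend angles** are measured at the central base pair (position 15 of
the 30-mer) between the COM vectors to the pairs ±d away; pair COM uses
the heavy base atoms only. 180° iff collinear; validated against the
inscribed-angle closed form on circular arcs.

**PCA** superposes every frame onto frame 0 by the atoms of the
mid-helix base pairs (11–20 by default, per the system's region map),
then diagonalizes the unweighted all-atom coordinate covariance. All
3N eigenvalues are retained so the mode count equals 3 × atom count;
variance fractions sum to 1. A `superpose=False` path exists for
ensembles that already share a frame of reference (and for exact
recovery tests, since superposition legitimately removes the rigid
component of any declared mode).

**Roll–Slide ellipses** are sample-covariance ellipses
{x : (x−μ)ᵀΣ⁻¹(x−μ) = s²} at score s = 3 by default; the 3σ contour
holds the χ²₂ mass P(χ²₂ ≤ 9) ≈ 98.9% of a Gaussian cloud, which the
tests verify. Per-step deformabilities are frame-SDs of roll and slide,
grouped into YR/RR/RY classes.

## Synthetic generators

**Fiber/ensemble builder.** Helices are rebuilt by composing step
transforms from a start frame, realizing pair parameters about each pair
frame (planar WC geometry by default) and placing the residue templates;
5′-terminal residues carry no phosphate. Canonical parameter sets:
B form (twist 36.0°, roll 0.6°, rise 3.32 Å, slide +0.37 Å) and A form
(31.1°, 8.0°, 3.31 Å, slide −1.53 Å) — twist/roll/rise are the standard
published reference values, slide the conventional B/A values.
Gaussian ensembles draw each step's six parameters from a declared
per-step mean/covariance (PSD-checked; eigendecomposition square root,
so singular covariances are allowed); draws with non-positive rise are
redrawn. The demo ensemble uses B-form means with spreads
(0.35, 0.35, 0.25 Å, 3.0°, 4.5°, 4.0°), a mild positive roll–slide
coupling (r = 0.4), and — for the bound state — an A-shifted homo-purine
tract (slide −1.2 Å, roll 5.6°, twist 33.1°, rise 3.30 Å), i.e. the
bound-state step-parameter means reported for this class of system are
used as the generator's declared truth. These choices emulate the
magnitudes of thermal step-parameter fluctuations; they do not emulate
sequence-specific force-field couplings, backbone/sugar degrees of
freedom, or solvent, so passing tests demonstrate correctness of the
analysis machinery on helices with known geometry, not fidelity to any
particular simulated trajectory.

**Reverse-Hoogsteen placement.** The third-strand base is placed by a
fixed rigid transform in the duplex purine's base frame: a 180° flip
about an in-plane axis (so the TFO base normal opposes the purine's,
matching the antiparallel strand sense) followed by an in-plane rotation
and translation frozen from a coplanar H-bond optimization —
A-A·T: N6(t)···N7(w) and N1(t)···N6(w); G-G·C: N1(t)···N7(w) and
N2(t)···O6(w), both donor–acceptor distances exactly 2.90 Å, steric
clearance > 3.5 Å between base heavy atoms, trans glycosidic
arrangement. This is an idealized synthetic construction (the transform
constants live in `builder.HOOGSTEEN_PLACEMENTS`), validated by H-bond
ranges (2.7–3.1 Å) and clash-freedom (≥ 2.0 Å), not by any force field;
TFO backbone conformation is whatever the rigid template implies.

**Umbrella sampler.** Windows are sampled by a vectorized
Metropolis–Hastings chain on the scalar periodic coordinate: burn-in
(1000 sweeps) is a plain random walk whose per-window step adapts toward
30–60% acceptance while estimating each window's location and spread;
production mixes the random walk with an independence proposal built
from those estimates (70% independence by default), with all proposal
densities evaluated as wrapped Gaussians (±2 periodic images) so the
Hastings ratio is exact on the circle. Samples are recorded every 4th
sweep. The chain targets exp(−(U(x) + k·Δ²/2)/kT) with Δ the
minimum-image angular difference in radians; seeded and bit-reproducible.

## WHAM and opening thermodynamics

The periodic WHAM estimates the window free-energy constants by direct
minimization of the convex WHAM likelihood
F(g) = −Σᵢ Nᵢ gᵢ + Σ_b M_b ln Σᵢ Nᵢ e^{gᵢ} c_{ib} (L-BFGS with analytic
gradient), then certifies the result with fixed-point sweeps of the
self-consistency equations until the largest constant changes by less
than the stated tolerance (10⁻⁶ kcal/mol default). Two numerical
choices matter at the production force constant k = 2000 kcal mol⁻¹ rad⁻²
(window σ ≈ 1°, bin width 0.5°):

* the bias Boltzmann factor c_{ib} is integrated analytically (erf) over
  each bin rather than evaluated at its centre — the bias changes by
  more than kT within a bin, and centre evaluation systematically
  distorts the unbiasing;
* the self-consistency is solved on an internally refined grid
  (8 sub-bins per reported bin) and the resulting bin masses aggregated
  onto the reported 720-bin grid, which removes the residual
  within-bin density-bias covariance.

Bins never visited by any window are masked (NaN) with a warning; the
profile is anchored at min W = 0. With a single unbiased window the
estimator reduces exactly to −kT ln(histogram) on the reported grid.
Remaining error at the production protocol is statistical: with 50 000
samples per window the recovered profile deviates from a declared
double-well truth by ≲ 0.2–0.3 kcal/mol pointwise (the window spacing of
5σ makes the inter-window constants the dominant noise term; this is a
property of the protocol, not of the estimator — per-seed fluctuation of
the maximum pointwise error straddles ~0.15–0.35 kcal/mol).

Per-bin errors split every window's series into 4 contiguous blocks, run
WHAM per block, anchor all block profiles at the bin where the mean
profile is lowest, and take the per-bin SD. ΔG of opening integrates
exp(−W/kT) over the closed and open bins (NaN bins carry zero weight)
and is invariant under profile offsets; the partition comes either from
an explicit per-bin mask or from per-window SASA majority labels with
nearest-window assignment, ties going to closed (conservative for
ΔG_open). The barrier is max W − min W, with optional per-direction
barriers about a stated split angle (positive rotation = major groove by
the default sign convention).

## SASA and the open/closed definition

SASA is a Shrake–Rupley-style numerical accessibility: a deterministic
golden-spiral point set (960 points/atom) on each atom's expanded sphere
(per-element radius + probe), a point being accessible iff outside every
neighbour's expanded sphere. Radii: C 0.14, O 0.13, P 0.13, H 0.10 nm,
and N 0.13 nm (nitrogen is not among the stated values; the oxygen value
is used). `sasa()` defaults to a zero probe and matches the isolated-
sphere and two-sphere closed forms to < 1%; identical inputs give
bit-identical areas.

Open/closed classification reports on H3 (pyrimidine) or N1 (purine)
with threshold 0.001 nm², but rolls a 0.14 nm water probe over the
atomic radii: with a bare zero-probe surface the reporter proton of even
a perfectly paired base keeps ~0.06 nm² of geometric accessibility
through inter-atomic gaps, and no intact pair would ever classify as
closed — the probe restores the intended semantics. Both the radii
table and probe are configurable on `OpenCloseDefinition`.

Synthetic flipped states for classification are produced by rigidly
rotating the flipping base about the axis through the two sugar COMs,
which changes the pseudo-dihedral by exactly the rotation angle.

## Pipeline determinism and problem sizes

All generators are seeded; `generate_demo` is byte-identical per seed,
and pipeline reruns with the same config reproduce identical output
hashes (recorded in `manifest.json`; timings go to `run.log` so the
manifest stays stable). The shipped problem sizes — 60-frame demo
ensembles, 2000-sample demo windows, 50 000-sample production windows,
400-frame deformability ensembles — were chosen so a complete validation
cycle runs in minutes on one CPU while leaving every statistical
assertion comfortably resolved; all are parameters, not constants.

## Known limitations

* Geometry is rigid-base: no backbone torsions, sugar pucker, or H-bond
  enumeration; the shared backbone conformer shifts absolute phosphate-
  derived quantities (groove widths, Zp magnitudes) relative to fiber-
  diffraction models.
* The reverse-Hoogsteen transform is an idealized coplanar construction;
  real triplets propeller and buckle.
* The Gaussian step ensembles have no inter-step or temporal
  correlations, so block-averaged SEMs on demo data behave like iid
  estimates (the AR(1) validation covers the correlated case
  synthetically).
* WHAM assumes the declared harmonic biases are exact; there is no MBAR
  generalization and no support for non-harmonic biases.
* PCA retains all 3N modes via a dense eigendecomposition, which is
  O((3N)³): fine for the 30-mer system (~5700 coordinates), slow beyond.
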