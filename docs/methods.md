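# Methods

This note documents the models and conventions behind `bilayerlab`: what each
observable means, how the synthetic generator plants it, which choices were
genuinely open and how they were made, and what the tests do and do not show
about real trajectories.

## Coordinate and data model

The bilayer normal is `z`.  Analyses that resolve position along the normal
(density profiles) recenter each frame so the mean `z` of all phosphate P
atoms is zero, i.e. the bilayer midplane is the origin; this mirrors the
convention of measuring everything relative to the phosphate plane.  Boxes
are orthorhombic only — CRYST1 records with angles other than 90° are
rejected rather than silently accepted, since none of the implemented
observables is defined here for sheared boxes.

Topologies come from multi-model PDB (one MODEL per frame, per-model CRYST1
with fallback to the first).  PDB carries neither masses nor charges:
masses come from a built-in standard atomic-mass table keyed on the element
symbol, and electron counts default to the neutral-atom atomic number.
Ignoring partial charges matches the behavior of the standard
electron-density commands in trajectory-analysis suites and keeps the
topology input minimal; for the group-resolved profiles computed here the
difference is well below the other approximations involved.

Molecules are delimited by TER records (fallback: one residue = one
molecule).  Before any center-of-mass computation, each molecule is made
whole across periodic boundaries by sequential unwrapping: every atom is
imaged to the periodic copy nearest the *preceding* atom of its molecule.
Imaging everything to the molecule's first atom would be simpler but wraps
the far end of any molecule whose extent exceeds half the box — a 22-residue
helix (~33 Å) in a ~52 Å box already triggers this — while successive atoms
are always close, so the sequential rule is safe for both.

## Bilayer observables

* `A_L = L_x L_y / m_lipid` per frame (`m_lipid` = lipids per leaflet).  No
  correction is made for the in-plane area occupied by an embedded peptide;
  the quantity is the literal box-area-per-lipid, so peptide-containing
  systems report slightly inflated `A_L`.  This caveat is deliberate: the
  definition stays model-free and directly comparable across systems.
* `V_L = (V_box − n_w V_w)/n_lipid`, `V_w = 30.53 Å³` (TIP3P).  A negative
  result (box smaller than its nominal water volume) is reported with a
  warning rather than an error, since it can only arise from inconsistent
  inputs the caller should see.
* `K_A = k_B T ⟨A⟩ / var(A)` with `A = L_x L_y`, reported in mN/m.  With
  areas in Å², `k_B T⟨A⟩/var(A)` in J/Å² equals `1.380649·T·⟨A⟩/var(A)` mN/m,
  so the constant `1.380649` is exact.  The per-lipid form
  `k_B T ⟨A_L⟩/(m_lipid σ²_{A_L})` is algebraically identical because
  `A_L = A/m_lipid`.  The variance is the unbiased (n−1) sample variance of
  the raw per-frame values — per-frame values are *not* block-averaged before
  the variance, which would suppress the fluctuations the estimator lives on.
  A fluid phosphatidylcholine bilayer at this temperature sits at roughly
  180–330 mN/m, which fixes the overall normalization unambiguously.
* Thicknesses `h(P–P)` and `h(C2–C2)` are per-frame distances between the
  mass-weighted centers of the selected atoms (P, or sn-2 C2) in the upper
  and lower leaflets.  Leaflets are assigned per lipid by whether its P atom
  lies above the mean P `z`; a flat (all-equal-`z`) phosphate set is rejected
  as a degenerate bilayer.
* `S_CD` per chain carbon is `⟨(3cos²θ−1)/2⟩` over both C–H bonds, all
  lipids and all frames, with θ against `z` and the C–H vector taken under
  the minimum-image convention.  The signed value is kept internally; plots
  and tables conventionally use `|S_CD|`.  Explicit hydrogens are required —
  there is no united-atom reconstruction.
* Electron density profiles histogram per-atom electron counts along
  recentred `z` (default bin 0.5 Å), frame-averaged and divided by the bin
  volume `⟨L_x L_y⟩·Δz`.  This makes the integral over a group's profile
  equal its total electron count — a conservation law the tests enforce.
  Optional leaflet symmetrization exists but is off by default, since real
  peptide-containing systems are genuinely asymmetric.

## Helix orientation

The reference structure is an ideal poly-alanine-like α-helix with
φ = −61°, ψ = −45°, ω = 180°, built from standard backbone internal
coordinates (N–Cα 1.458 Å, Cα–C 1.525 Å, C–N 1.329 Å; angles 121.7°,
111.2°, 116.2°) by natural-extension (NeRF) placement, then rigidly
re-oriented so that:

* the first principal axis of the Cα positions lies along **+x**, pointing
  N→C (a surface-bound helix lying in the membrane plane is then the
  zero-rotation baseline, τ = 90°);
* the radial offset of the central residue's Cα points along **+z**, which
  anchors ρ = 0.

For an observed backbone segment, the optimal proper rotation `R` from
reference to observation is found by Kabsch superposition (SVD with the
reflection branch rejected).  Then:

* helix axis `h = R·x̂`; tilt `τ = arccos(h·ẑ)` ∈ [0°, 180°];
* azimuthal rotation ρ is the signed angle, right-handed about `h`, from the
  normalized component of the lab `ẑ` perpendicular to `h` to the rotated
  reference radial vector `R·ẑ`, mapped to [0°, 360°).

The decomposition works on the fitted rotation matrix directly rather than
through a named Euler sequence; an equivalent z-y-z Euler report is available
for interoperability (`rotation_euler_zyz`).  Two consequences of the
conventions are worth stating: (i) ρ is invariant under rigid rotation of the
whole frame about `z`, because both the axis and the azimuth reference rotate
together — which is the physically desirable behavior for an angle meant to
describe which helical face points toward the headgroups; (ii) *absolute* ρ
values depend on the anchor residue choice, so only ρ differences (between
segments, or between systems analyzed with the same reference) are
convention-free.  When τ is within 1e-5° of 0° or 180° the azimuth reference
vanishes into numerical noise (the arccos noise floor near ±1) and ρ is
reported as NaN.

Insertion depth `z` is the mass-weighted backbone center of mass relative to
the mean `z` of the phosphate plane of the nearer leaflet, with the sign
chosen so positions toward the bilayer center are negative for either
leaflet.  Backbone RMSD removes rigid-body motion by Kabsch superposition
and measures against the iteratively refined mean structure by default
(`to_mean`; the reference-structure choice is genuinely open in the
flexibility-measure use case, so it is a documented option, with `to_first`
available).

Default segments for a 22-residue peptide: N-terminal = residues 5–10,
C-terminal = 14–20, full = 1–22; orientation is computed every frame by
default, with a stride option for sparser sampling.

## Contact analyses

* Hydrogen bonds: donor–acceptor heavy-atom distance ≤ 3.0 Å and D–H···A
  angle ≥ 135°, both configurable.  These are the common defaults of
  trajectory-analysis tooling; any geometric criterion is somewhat arbitrary,
  so the counts should be compared only across systems analyzed with the same
  criterion.
* Ring–metal distances use the unweighted centroid of the six ring carbons
  (equal masses make weighting moot).  Populations are reported as 0.1 Å
  histograms (fine enough to resolve ~0.2 Å features) plus cumulative
  fractions below configurable cutoffs; cation–π vs CH–π character is
  reported descriptively through distances, not classified energetically —
  that would require electronic-structure input outside this package's scope.
* Coordination-site occupancy: fraction of frames with min pairwise distance
  between two selections below a cutoff (default 2.8 Å, coordination-bond
  scale).
* Oxidized-chain reversal: a (frame, lipid) pair is flagged when the
  shortened chain's terminal carbon sits farther from the midplane than its
  leaflet's mean |z| of C2 atoms — the aldehyde tip has crossed from the
  hydrophobic core past the ester region toward the headgroups.
* Water-in-slab: water oxygens strictly between the two leaflet C2-plane
  means.  This is an operationalization: "water in the nonpolar domain" has
  no unique definition, and this one is the simplest that is exactly testable.

All distance computations use the minimum-image convention, so translating
any molecule by a full box vector changes nothing.

## Uncertainty machinery

Per-frame series discard an equilibration fraction (default 5%, mirroring a
proportional discard of a production run's initial segment) and report a
block-averaged standard error: the series is split into 5 contiguous equal
blocks (remainder dropped from the front) and the error is the sample standard
deviation of block means over √n_blocks.  Replicate simulations aggregate as:
single replicate → block SE; duplicates → half-range (the convention for
"averaged over duplicate runs"); three or more → standard error of replicate
means.  All defaults are echoed into every report so a summary is
self-describing, and JSON output uses sorted keys and fixed formatting so
identical inputs give byte-identical reports.

## The synthetic generator

The generator emulates exactly the statistical structure the analyses read —
nothing more.  Lipids are coarse toy molecules (one P, one C2, a short
explicit-H acyl chain) on a jittered grid; there are no forces, no
thermostats, no chemistry.  Defaults are the study-scale conditions: 40
lipids per leaflet (peptide-to-lipid ratio 1:40), T = 313 K, 56 waters per
lipid, free-bilayer `A_L = 67.1 Å²`, `V_L = 1206 Å³`, `h(P–P) = 37.5 Å`,
`h(C2–C2) = 27.4 Å`, an `|S_CD|` profile decaying ~0.21 → 0.10 along a
10-carbon toy chain, and a box-area variance chosen so the planted
`K_A = 254 mN/m`; the `oxpl` preset shifts to the oxidized-lipid mixture
scale (10% shortened chains, `h(P–P) = 36.4 Å`, `h(C2–C2) = 26.3 Å`,
`V_L = 1183 Å³`).  When the box area or water count is not given it scales
with the lipid count so small test systems stay geometrically sensible.

How each observable is planted:

* **Box areas** are i.i.d. normal per frame (mean/variance prescribed), or
  AR(1) with the same stationary variance when an autocorrelation is
  requested (for exercising block-averaged error estimation).  I.i.d. is the
  default because the fluctuation-formula recovery is cleanest without
  autocorrelation.  Lipid grid positions scale with √(area/area_mean), so
  topology is constant while the box fluctuates.
* **Box height** is set per frame so `(V_box − n_w V_w)/n_lipid` equals the
  planted `V_L` exactly on every frame.
* **P and C2 planes** sit exactly at ±h/2, so thicknesses are exact per
  frame.
* **`S_CD`**: each chain carbon's C–H bonds are placed at the fixed polar
  angle `θ_k = arccos(√((2S_k+1)/3))`, which makes the per-bond
  `(3cos²θ−1)/2` equal `S_k` identically — exact per frame, regardless of
  azimuth (azimuths follow a golden-angle schedule, no randomness needed).
  Because the per-sample value depends only on the polar angle, a separate
  *stochastic* mode exists for exercising statistical recovery: orientations
  are drawn from a two-component mixture (aligned-vs-isotropic for S ≥ 0,
  in-plane-vs-isotropic for S < 0) whose expectation is `S_k`; the planted
  value is then recovered only in the large-sample limit (±0.01 at ~2·10⁴
  draws per carbon).
* **Helix**: the reference helix is rotated by
  `R = Rot_y(τ−90°)·Rot_x(ρ)`, whose tilt/azimuth decomposition under the
  package's convention is exactly (τ, ρ), and translated so the full
  backbone's mass-weighted center of mass sits `z_true` below the upper P
  plane.  The ground truth records the *realized* per-segment depths
  (measured from the placed coordinates), so segment-level recovery is exact
  by construction.  An optional per-frame Gaussian jitter exercises the
  backbone-RMSD machinery.
* **Reversal events and contact occupancy** are scheduled by drawing, from
  the seeded generator, a permutation of the (frame, lipid) pairs or frames
  and flagging exactly `round(f·N)` of them, so the realized fraction is
  planted deterministically and recovered exactly.
* **Waters** fill the slabs outside the P planes and never enter the core
  (the water-in-slab count is zero unless a test plants one).

All randomness flows from a single `numpy` generator seeded by `seed`, with a
fixed consumption order, so identical parameters give bitwise-identical
trajectories.

What the generator does *not* emulate — and therefore what passing tests do
not show: realistic lipid conformations and their correlations, wrapped
coordinates, thermal roughness of the P/C2 planes, peptide flexibility,
solvent structure, or any coupling between observables (e.g. between area and
thickness).  Recovery on these fixtures demonstrates that the *estimators*
are correct, not that a real membrane would produce any particular values.

## Numerical choices and degenerate inputs

* Kabsch via SVD with `det > 0` enforced; fits are cross-checked in tests
  against an independent rotation-fitting implementation.
* Histogram bin edges are aligned to the bin-width grid with the outermost
  edges nudged outward, so floating-point drift can never exclude the extreme
  data values.
* `arccos` arguments are clipped to [−1, 1].
* Degenerate inputs are errors with specific messages: empty selections, flat
  phosphate planes, rigid boxes (`K_A` undefined), collinear/coincident
  backbone segments, missing hydrogens, wrong ring/metal selection sizes.

## Problem sizes used in the test and acceptance runs

The verification fixtures are deliberately small: tens of lipids, tens to a
few hundred frames for geometric recovery, 10⁴ frames (on a minimal 4-lipid
system) for the fluctuation-formula recovery, and 10⁵ orientation draws for
the isotropic order-parameter limit.  These sizes put sampling error well
inside the asserted tolerances while keeping the whole suite interactive;
they are choices of this package, and all scale linearly if larger fixtures
are wanted.

## Known limitations

* Orthorhombic boxes only; no binary trajectory formats (DCD/XTC/NetCDF) and
  no topology formats beyond PDB — convert externally if needed.
* `A_L` is box-based; no Voronoi per-leaflet decomposition.
* No secondary-structure assignment, kink-angle analysis, undulation spectra
  or lateral diffusion.
* Hydrogen-bond and coordination criteria are geometric conventions, not
  energetic classifications.
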