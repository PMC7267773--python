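# Methods

This note documents the models implemented in `protofil`, the conventions
and defaults that matter for interpreting its output, what the synthetic
fixtures do and do not emulate, and the design choices made where the
design was genuinely open.

## Rigid transforms and the screw decomposition

A transform is a proper rotation R plus translation t acting as
x ↦ Rx + t.  Superposition uses the Kabsch/SVD closed form with the
det = −1 branch corrected, so reflections are never produced (protein
chirality).  Inputs with fewer than three point pairs or collinear points
are rejected: the rotation would not be unique.

Every transform with a nonzero rotation angle has a unique Chasles form:
rotation by θ about an axis line plus a rise *d* along that axis.  The
implementation takes θ and the axis from the rotation matrix (via the
rotation vector), d as the axis component of t, and the axis point as the
minimum-norm solution of (I − R)p = t − d·u, i.e. the axis point closest
to the origin.  Conventions:

- canonical angle θ ∈ (0°, 180°];
- with θ positive about +u, d > 0 is a right-handed screw, d < 0
  left-handed; |d| below `rise_tolerance` (default 0.5 Å) reports
  handedness `none`;
- at θ = 180° exactly, the axis sign (hence the sign of d) is a pure
  convention; the rise is reported as a magnitude with
  `axis_sign_ambiguous` set;
- a numerically zero rotation is an error (`PureTranslationError`), not a
  screw with θ = 0: downstream classification needs a rotation order.

Screw parameters are conjugation-invariant (angle, |rise| and handedness
do not change under a change of frame); this is enforced by a property
test and is why the generator may be composed in either interface order.

## Interface transforms and C2 estimation

An interface transform is the superposition of the Cα trace of one
protomer selection onto its partner's, with correspondence by residue
offset within the (author-numbered) ranges — homodimer copies of the same
protein need no alignment.  Two estimates are kept:

- the **raw** one-way A→B superposition (reported, never modified), with
  its deviation from an exact two-fold (|180° − θ| and the axial rise);
- a **symmetrized exact C2**: the dimer is superposed onto its
  chain-swapped self ([A;B] → [B;A], 2N correspondences), which is
  automatically near-involutive and statistically tighter than the
  one-way estimate, then projected to exactly 180°/zero-rise.

The filament generator composes the symmetrized two-folds by default, so
coordinate noise does not leak into the composed twist and rise; passing
`symmetrize=False` composes the raw transforms.  Inputs more than 15°
from a two-fold are rejected rather than silently symmetrized.

When a multi-repeat assembly is available, `generator_from_assembly`
estimates the generator directly as the single transform superposing the
stacked coordinates of repeats 0..n−2 onto repeats 1..n−1; with n repeats
this averages n−1 observations and is the most precise route (used for
the ring noise-robustness property, where the 3-chain route's estimator
variance sits at the classification tolerance).

## Ring / spiral / helix classification

From the generator screw (θ, d), the nearest rotation order is
N = round(360/θ), and the closure residuals are |N·θ − 360| (degrees) and
|N·d| (Å).  Defaults: angle tolerance 2.0°, rise tolerance 1.0 Å per
ring closure — both configurable, and residuals are always reported so
callers can re-threshold.

- **closed ring**: both residuals within tolerance (the 9-fold geometry:
  θ = 40°, d ≈ 0);
- **spiral**: the angle closes but the rise does not, *and* the
  per-repeat |d| is small (≤ `spiral_rise_max`, default 5 Å) — the
  near-planar failed-ring geometry (θ = 40.2°, d = 3 Å);
- **open helix**: everything else, in particular any large per-repeat
  rise (θ = 120°, d = −80 Å).

The per-repeat rise ceiling separating spiral from helix is this
package's convention: a residual-only rule cannot distinguish a 3 Å
near-planar spiral from an 80 Å helical rise, since both leave a large
N·d.  Five ångströms — well above crystal-noise scale, well below any
genuine helical rise of an elongated protomer — is the package default.

The repeat unit is one coiled-coil dimer (two protomers), stepping via
the head interface.  "Order 3, 80 Å rise" is therefore per dimer repeat;
one full period (240 Å) contains six protomers, and a 9-ring contains
nine coiled-coil dimers.  The projection period m·|d| (m the rotation
order) is the axial distance between repeats with the same azimuthal
orientation — the spacing at which laterally projecting features (the
coiled-coil domains) recur on the same side of the filament.

## Bundle clash scoring

Steric compatibility of two filaments related by a pairing transform
(e.g. a secondary, non-generator crystal interface) is scored by counting
Cα–Cα pairs below a cutoff (default 4.0 Å, roughly the Cα packing
distance) between the filament and its transformed copy.  The verdict is
`compatible` iff the count is at most `allowed_pairs` (default 0).
Cα-only counting is a deliberately reproducible proxy for a qualitative
"do not clash strongly" statement; an all-atom variant can be had by
passing all-atom coordinates through the same counting.

## Domain-orientation comparisons

Given two structures and explicit residue correspondences (curated,
structure-guided alignments are *inputs*, not computed here), the first
domains are superposed and the residual rotation carrying the moved
second domain onto the reference's defines an axis in the reference
frame.  Axes from different structure pairs are compared as undirected
lines (angles folded to ≤ 90°).  Coiled-coil axes are directed N→C
principal components of the segment's Cα trace (requiring ≥ 8 residues
and an anisotropy ratio ≥ 2), and head-to-coiled-coil angle differences
are signed by the component of the cross product along a declared plane
normal, which is stored in the output — with no declared normal only the
magnitude is meaningful.

A practical conditioning note: rotation recovery through a *globular*
second domain is well-conditioned in every direction, while a single
helical segment is nearly collinear and its twist about its own axis is
poorly determined; comparisons should superpose head domains and measure
coiled-coil segments only through their direction vectors.

## Sedimentation-equilibrium model and K_D fit

Internally cgs (cm, g, erg; R = 8.3145×10⁷ erg mol⁻¹ K⁻¹).  The reduced
buoyant exponent is σ = M(1 − v̄ρ)ω²/(RT); the dimer exponent is exactly
2σ.  Concentrations are molar monomer-equivalents throughout (the dimer
contributes two monomer signals); mg/mL loadings convert by dividing by
the monomer molar mass.  Default fixture parameters: M = 16,500 g/mol,
v̄ = 0.73 mL/g, ρ = 1.005 g/mL, T = 277 K, ε = 1.

Each profile's reference (meniscus) monomer concentration is fixed by
conservation of mass with sector-shaped (∝ r) radial weighting, solved by
bracketing + Brent.  The default cell geometry is meniscus 6.0 cm, base
6.4 cm, 120 radial points — a typical 12-mm six-sector column; these are
explicit parameters, and the mass-conservation identity (sector-weighted
mean equals loading, to 1×10⁻⁸ relative, noiseless) is a tested invariant.

The global fit optimizes log K_D plus one log reference concentration per
profile by Levenberg–Marquardt least squares, with M, v̄, ρ, T held fixed.
The reported interval is the linearized (Jacobian) confidence range on
log K_D; non-convergence is reported explicitly, never as a silent
success.  "1% noise" in the recovery experiment means Gaussian noise with
standard deviation equal to 1% of each profile's mean signal.

The recovery experiment (the acceptance script) uses the three-speed
(11,600/19,700/34,000 rpm), three-loading (12/4/1.3 mg/mL) design with
truth K_D = 170 μM, 20 replicates; the median fitted K_D lands within a
few μM of the truth, comfortably inside the ±18 μM experimental
uncertainty band used as the pass criterion.

## Sequence charge and pI

Net charge is the Henderson–Hasselbalch sum: basic groups (N-terminus,
K, R, H) contribute +1/(1+10^(pH−pKa)), acidic groups (C-terminus, D, E,
C, Y) contribute −1/(1+10^(pKa−pH)).  Free termini are included by
default; X is ignored; no structure-based pKa shifts or modifications.
The sum is strictly decreasing in pH, so the pI is the unique zero,
found by bisection on [0, 14] (default tolerance 0.001 pH, verified
against a dense grid scan).

pI values are pKa-table-dependent, so the table is a named, swappable
object.  The default (`bjellqvist`) is the Bjellqvist-style set used by
common theoretical-pI calculators: N-term 7.5, C-term 3.55, D 4.05,
E 4.45, C 9.0, Y 10.0, H 5.98, K 10.0, R 12.0; Cys is treated as
ionizable.  Swapping the table shifts computed pIs by up to a few tenths
of a pH unit — any comparison against a published "theoretical pI" should
state the table.

## Synthetic fixtures: what they emulate, and what they do not

All fixtures are deterministic functions of (spec, seed), and their
expected outcomes are *analytic*, recorded alongside the coordinates:

- **toy protomer**: a packed pseudo-random Cα blob in a 12 Å sphere
  (minimum spacing 3.5 Å) plus an ideal α-helix trace (1.5 Å rise,
  2.3 Å radius, 100° twist per residue) — the head + coiled-coil
  architecture reduced to its geometry;
- **interface pair**: three chains A, B = C2_cc(A), C = C2_head(A) with
  the two axes at prescribed (α, h); the composed generator is exactly a
  screw (2α, 2h) about +z, and the construction places the arm at
  coiled-coil distance from axis 1 and the head ~8 Å off axis 2 so both
  interfaces show genuine packing contacts;
- **assembly**: the generator propagated over n repeats (ring for the
  closing geometry, helix otherwise), with optional coordinate noise;
- **bundle**: a filament plus a lateral pairing transform searched (along
  a slightly tilted direction, so contacts cross the cutoff one at a
  time) to realize an exact designed contact count;
- **AUC dataset**: the multi-speed multi-loading design above.

These fixtures validate the *geometry and inference machinery*, which is
the package's contribution.  They do not emulate real coordinate data:
no side chains, no missing loops unless introduced, no crystallographic
artifacts, and interface contacts that are generic packing rather than
evolved chemistry.  Passing tests therefore demonstrate that the pipeline
recovers prescribed geometry exactly and degrades gracefully under
isotropic coordinate noise (σ ≤ 0.3 Å: medians within 1° and 1 Å,
handedness never confused) — not that any particular deposited structure
has a particular screw, which requires running the same pipeline on
those coordinates.

## Numerical choices and degenerate inputs

- Orthonormality is enforced (and re-orthonormalized after long
  composition chains); every produced rotation satisfies det = +1 and
  RᵀR = I to 1×10⁻⁹.
- Altloc handling keeps the highest-occupancy conformer (first on ties);
  model 1 only; HETATM and waters excluded from interface detection.
- Contact definition: a residue pair counts once if *any* atom pair is
  below the cutoff (default 5.0 Å, ≥ 10 contacts to report an
  interface); ties in ranking break lexicographically by chain pair.
- Interface detection uses a k-d tree but is tested equal to the O(n²)
  all-pairs scan.
- PDB output is limited to 62 single-character chain labels; larger
  assemblies must be written as mmCIF (enforced with an explicit error).
- Degenerate inputs raise typed errors (pure translation, collinear
  points, isotropic cloud, empty selection, non-two-fold) rather than
  returning least-surprise values.

## Known limitations

- Residue correspondence across different proteins must be supplied;
  there is no automatic structural alignment of remote homologs.
- The spiral/helix boundary (`spiral_rise_max`) is a convention, not a
  physical constant; borderline generators should be judged from the
  reported residuals.
- The equilibrium model is ideal and two-state: no nonideality, no
  incompetent-fraction terms, no baseline drift (a per-profile baseline
  is off by default for synthetic data).
- The pI model ignores structural context; for folded coiled coils the
  effective pKas shift, so computed values characterize the sequence,
  not the folded protein.
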