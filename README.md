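# protofil

Screw-axis geometry of two-interface protein oligomers, and the
self-association analysis that goes with it.

Proteins of the XRCC4 superfamily (SAS6, CCDC61/VFL3, XRCC4, XLF)
oligomerize through two independent homodimerization interfaces — a
globular head-to-head dimer and a parallel coiled-coil dimer.  Each
interface is (approximately) a two-fold rotation, and the *composition*
of the two C2 rotations generates the higher-order assembly.  Whether the
result is the 9-fold SAS6 ring that templates centriole symmetry, a
near-planar spiral, or an open helical protofilament like the CCDC61
filament depends entirely on the relative geometry of the two axes.
`protofil` makes that argument computable: it extracts the interface
transforms from coordinates, composes and decomposes the generator, and
classifies the assembly, alongside the solution-biophysics side of the
same story (monomer–dimer K_D from sedimentation equilibrium, sequence
charge and isoelectric point).

The package is a library; the scripts in `examples/` are the guided tour.

## The geometry in two formulas

Any rigid motion with a nonzero rotation is a **screw** (Chasles): a
rotation by angle θ about an axis plus a translation *d* (the rise) along
it.  For two two-folds whose axes subtend an angle α and have a
common-perpendicular offset *h*:

    C2(head) ∘ C2(coiled-coil)  =  screw(θ = 2α, d = 2h)

about the common perpendicular.  Intersecting axes (*h* = 0) give a pure
rotation: if 2α divides 360° the assembly closes into an N-fold ring
(SAS6: α = 20°, N = 9).  A small residual rise gives a spiral that just
fails to close; a large one gives an open helix.  With the canonical
angle taken positive, the sign of *d* is the handedness — CCDC61's
α = 60°, h = −40 Å geometry yields the left-handed 3-fold screw with an
80 Å rise per coiled-coil-dimer repeat, and features pointing the same
direction recur every 3 × 80 Å = 24 nm along the filament.

For the solution side, sedimentation equilibrium of a monomer–dimer
system obeys

    signal(r) = ε·[ m₀ e^{σ(r²−r₀²)/2} + 2 (m₀²/K_D) e^{2σ(r²−r₀²)/2} ],
    σ = M(1 − v̄ρ)ω² / RT

and a global fit over speeds and loadings (one shared K_D, one reference
concentration per profile) recovers the dissociation constant
K_D = [M]²/[D].

## Worked example

`python examples/filament_screw.py` builds a three-chain fixture whose
two C2 axes subtend 60° with a −40 Å offset, extracts both interface
transforms and composes the filament generator:

```
coiled-coil interface: rmsd 5.01e-15 A, C2 deviation 0.000 deg
head interface:        rmsd 3.33e-14 A, C2 deviation 0.000 deg

assembly kind : open_helix
twist per repeat: 120.00 deg (rotation order 3)
rise per repeat : -80.00 A (left-handed)
projection period: 240.0 A = 24 nm
```

The twist/rise pair is read off the composed generator, not assumed: the
same pipeline run on a ring-geometry fixture (`examples/ring_spiral_helix.py`)
reports `closed_ring ... N=9`, and on a near-closing geometry reports a
spiral with its closure residuals.

`python examples/kd_from_sedimentation.py` simulates the three-speed,
three-loading equilibrium design for a 16.5 kDa monomer with
K_D = 170 μM and 1% noise, and fits it globally:

```
loadings: 727 uM, 242 uM, 79 uM
fitted K_D = 171.0 uM (1-sigma interval 169.8 - 172.3 uM, rms residual 4.33e-06, converged=True)
at a 480 uM loading: 34% monomer, 66% dimer-bound
```

The other examples cover domain-orientation comparisons
(`domain_orientation.py`), charge curves and pI (`isoelectric_point.py`),
and regeneration of the full fixture set with analytic expected values
(`generate_fixture_set.py`).

## Layout

- `src/protofil/structio.py` — PDB/mmCIF reading and writing (via gemmi),
  Cα/domain selection, packing-contact interface detection.
- `src/protofil/rigid.py` — rigid-transform algebra: Kabsch superposition,
  composition, screw (Chasles) decomposition/recomposition, C2 projection.
- `src/protofil/assembly.py` — interface transforms, filament generator,
  ring/spiral/helix classification, filament building, projection
  periodicity, bundle clash scoring.
- `src/protofil/orientation.py` — cross-structure domain-rotation axes,
  coiled-coil direction vectors, signed head-to-coiled-coil angles.
- `src/protofil/selfassoc.py` — sedimentation-equilibrium simulation and
  the global monomer–dimer K_D fit.
- `src/protofil/seqprop.py` — Henderson–Hasselbalch net charge and
  theoretical pI with a named, swappable pKa table.
- `src/protofil/synthetic.py` — deterministic fixture generators with
  analytically known expected outcomes.

See `docs/methods.md` for the models, conventions and their limitations.
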