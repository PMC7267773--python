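"""Synthetic fixtures with analytically known assembly geometry.

Everything the pipeline consumes can be generated here without any
deposited structure: two-domain toy protomers (compact head + straight
helical arm, mimicking the head/coiled-coil architecture of the XRCC4
superfamily), exact or noise-perturbed C2 dimers about prescribed axes,
three-chain interface pairs whose two C2 axes have a controlled
inter-axis angle and common-perpendicular offset, filament-bundle pairs
with a designed number of sub-cutoff contacts, and sedimentation-
equilibrium datasets.

The central analytic fact: composing 180° rotations about two axes that
subtend an angle α and have common-perpendicular offset h yields a screw
about the common perpendicular with rotation angle 2α and rise 2h
(a pure rotation when h = 0).  In the construction used here the two C2
axes lie in planes normal to z with the second axis displaced +h along z,
which makes the composed rise +2h about the +z screw axis — so the sign
of ``offset_h`` selects the handedness (positive = right-handed).
Fixtures therefore carry exact expected screw parameters alongside the
coordinates.
"""

from __future__ import annotations

import hashlib
import json
import string
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .rigid import RigidTransform
from .selfassoc import SelfAssocParams, mgml_to_molar, simulate_profiles, write_profiles_csv
from .structio import AtomRecord, Structure, write_structure

_CHAIN_LABELS = string.ascii_uppercase + string.ascii_lowercase + string.digits

__all__ = [
    "FixtureSpec",
    "FixtureManifest",
    "make_toy_protomer",
    "make_c2_dimer",
    "make_interface_pair",
    "make_assembly_fixture",
    "make_bundle_fixture",
    "generate_dataset",
    "AUC_SPEEDS_RPM",
    "AUC_LOADINGS_MGML",
    "DEFAULT_AUC_PARAMS",
    "CCDC61_LIKE",
    "SAS6_RING_LIKE",
    "CESAS6_SPIRAL_LIKE",
]

# The multi-speed, multi-loading equilibrium design used for the K_D fit:
# three rotor speeds, three loadings, 16.5 kDa monomer at 4 °C.
AUC_SPEEDS_RPM = (11_600.0, 19_700.0, 34_000.0)
AUC_LOADINGS_MGML = (12.0, 4.0, 1.3)
DEFAULT_AUC_PARAMS = SelfAssocParams(
    monomer_mass=16_500.0,
    vbar=0.73,
    solvent_density=1.005,
    temperature=277.0,
    kd=170e-6,
)

#: (alpha_deg, offset_h) presets: composed screw = (2*alpha, 2*h).
CCDC61_LIKE = {"alpha_deg": 60.0, "offset_h": -40.0}  # 120°, −80 Å, left-handed
SAS6_RING_LIKE = {"alpha_deg": 20.0, "offset_h": 0.0}  # 40°, 0 Å: 9-fold ring
CESAS6_SPIRAL_LIKE = {"alpha_deg": 20.1, "offset_h": 1.5}  # 40.2°, 3 Å: spiral


@dataclass(frozen=True)
class FixtureSpec:
    kind: str
    geometry: dict
    seed: int
    expected: dict = field(default_factory=dict)


@dataclass
class FixtureManifest:
    format_version: int
    seed: int
    entries: list[dict] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {"format_version": self.format_version, "seed": self.seed,
             "entries": self.entries},
            indent=1, sort_keys=True,
        )


def _ca_atom(chain: str, resnum: int, pos: np.ndarray) -> AtomRecord:
    return AtomRecord(
        chain_id=chain,
        residue_number=resnum,
        insertion_code=None,
        residue_name="ALA",
        atom_name="CA",
        element="C",
        position=pos,
        occupancy=1.0,
    )


def make_toy_protomer(
    n_head_residues: int = 60,
    n_arm_residues: int = 25,
    seed: int = 0,
    head_center: np.ndarray | None = None,
    arm_start: np.ndarray | None = None,
    arm_direction: np.ndarray | None = None,
    chain_id: str = "A",
) -> Structure:
    """Cα-only two-domain toy: packed pseudo-globular head + ideal-helix arm.

    The head is a seeded self-avoiding arrangement inside a 12 Å sphere
    (minimum Cα separation 3.5 Å); the arm is an ideal α-helix trace
    (1.5 Å rise per residue, 2.3 Å radius, 100° twist) along
    ``arm_direction``.  Deterministic per seed.
    """
    if n_head_residues < 8 or n_arm_residues < 8:
        raise ValueError("domain sizes must be >= 8 residues")
    rng = np.random.default_rng(seed)
    hc = np.zeros(3) if head_center is None else np.asarray(head_center, float)
    a0 = np.array([14.0, 2.0, 1.0]) if arm_start is None else np.asarray(arm_start, float)
    ad = np.array([1.0, 0.0, 0.0]) if arm_direction is None else np.asarray(arm_direction, float)
    ad = ad / np.linalg.norm(ad)

    head_pts: list[np.ndarray] = []
    attempts = 0
    while len(head_pts) < n_head_residues:
        p = rng.uniform(-12.0, 12.0, size=3)
        if np.linalg.norm(p) > 12.0:
            continue
        if head_pts and np.min(np.linalg.norm(np.array(head_pts) - p, axis=1)) < 3.5:
            attempts += 1
            if attempts > 200_000:
                raise RuntimeError("could not pack head sphere")
            continue
        head_pts.append(p)
    head = np.array(head_pts) + hc

    # ideal alpha-helix trace in a frame whose z is the arm direction
    t = np.arange(n_arm_residues)
    local = np.stack(
        [2.3 * np.cos(np.deg2rad(100.0) * t),
         2.3 * np.sin(np.deg2rad(100.0) * t),
         1.5 * t],
        axis=1,
    )
    # rotate local +z onto arm direction
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(z, ad)
    s = np.linalg.norm(v)
    if s < 1e-12:
        rot = np.eye(3) if ad @ z > 0 else np.diag([1.0, -1.0, -1.0])
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        rot = np.eye(3) + vx + vx @ vx * ((1 - ad @ z) / s**2)
    arm = local @ rot.T + a0

    atoms = [
        _ca_atom(chain_id, i + 1, head[i]) for i in range(n_head_residues)
    ] + [
        _ca_atom(chain_id, n_head_residues + 1 + j, arm[j]) for j in range(n_arm_residues)
    ]
    return Structure(identifier=f"toy_protomer_seed{seed}", atoms=atoms,
                     source_format="synthetic")


def make_c2_dimer(
    protomer: Structure,
    axis_point: np.ndarray,
    axis_direction: np.ndarray,
    noise_sd: float = 0.0,
    seed: int = 0,
    partner_chain: str = "B",
    min_clearance: float = 3.0,
) -> tuple[Structure, list[str]]:
    """Protomer plus its 180°-rotated partner about the given axis line.

    Optional isotropic Gaussian coordinate noise (per atom, both chains).
    Returns the two-chain structure and a list of warnings (a warning is
    emitted when the axis passes through the protomer so closely that the
    partner sits below ``min_clearance`` Å — under the ~3.8 Å Cα
    packing distance, i.e. a designed steric clash).
    """
    c2 = RigidTransform.from_rotvec_deg(axis_direction, 180.0, point=axis_point)
    rng = np.random.default_rng(seed)
    warnings: list[str] = []
    coords = protomer.coordinates()
    partner = c2.apply(coords)
    from scipy.spatial import cKDTree

    d, _ = cKDTree(partner).query(coords, k=1)
    if float(np.min(d)) < min_clearance:
        warnings.append(
            f"C2 axis passes through the protomer: partner clearance "
            f"{float(np.min(d)):.2f} A < {min_clearance} A"
        )
    atoms: list[AtomRecord] = []
    for a, p in zip(protomer.atoms, coords):
        q = p + rng.normal(0.0, noise_sd, 3) if noise_sd > 0 else p
        atoms.append(_ca_atom(a.chain_id, a.residue_number, q))
    for a, p in zip(protomer.atoms, partner):
        q = p + rng.normal(0.0, noise_sd, 3) if noise_sd > 0 else p
        atoms.append(_ca_atom(partner_chain, a.residue_number, q))
    return (
        Structure(f"{protomer.identifier}_c2dimer", atoms, "synthetic"),
        warnings,
    )


def interface_pair_axes(alpha_deg: float, offset_h: float) -> tuple[RigidTransform, RigidTransform]:
    """The two C2 transforms of the canonical interface-pair construction.

    Axis 1 (coiled-coil): along x through the origin.  Axis 2 (head):
    along (cos α, sin α, 0) through (0, 0, h).  Their common perpendicular
    is the z axis with signed offset h, so head∘cc is a screw about +z
    with angle 2α and rise 2h.
    """
    u1 = np.array([1.0, 0.0, 0.0])
    a = np.deg2rad(alpha_deg)
    u2 = np.array([np.cos(a), np.sin(a), 0.0])
    c2_cc = RigidTransform.from_rotvec_deg(u1, 180.0, point=(0.0, 0.0, 0.0))
    c2_head = RigidTransform.from_rotvec_deg(u2, 180.0, point=(0.0, 0.0, offset_h))
    return c2_head, c2_cc


def make_interface_pair(
    alpha_deg: float,
    offset_h: float,
    seed: int = 0,
    noise_sd: float = 0.0,
    n_head_residues: int = 60,
    n_arm_residues: int = 25,
) -> tuple[Structure, dict]:
    """Three-chain fixture: protomer A, coiled-coil partner B, head partner C.

    B = C2_cc(A) about axis 1; C = C2_head(A) about axis 2.  The composed
    generator C2_head ∘ C2_cc is analytically a screw with angle 2α and
    rise 2h about +z, which is returned in ``expected``.

    The protomer's arm runs parallel to axis 1 at coiled-coil distance
    (~2.2 Å off-axis, so the partner arm sits ~4.5 Å away) and its head is
    centred ~8 Å off axis 2, so both interfaces show genuine packing
    contacts for interface detection.
    """
    if not (0.0 < alpha_deg < 90.0):
        raise ValueError("alpha_deg must be in (0, 90)")
    c2_head, c2_cc = interface_pair_axes(alpha_deg, offset_h)
    a = np.deg2rad(alpha_deg)
    u2 = np.array([np.cos(a), np.sin(a), 0.0])
    # head centre: 8 A from axis 2 along +z
    head_center = np.array([0.0, 0.0, offset_h + 8.0])
    # arm: parallel to axis 1, off-axis by (y, z) = (1.6, 1.6)
    arm_start = np.array([16.0, 1.6, 1.6])
    protomer = make_toy_protomer(
        n_head_residues, n_arm_residues, seed=seed,
        head_center=head_center, arm_start=arm_start,
        arm_direction=np.array([1.0, 0.0, 0.0]), chain_id="A",
    )
    rng = np.random.default_rng(seed + 1)
    coords = protomer.coordinates()
    chain_b = c2_cc.apply(coords)
    chain_c = c2_head.apply(coords)
    atoms: list[AtomRecord] = []
    for label, pts in (("A", coords), ("B", chain_b), ("C", chain_c)):
        for a_rec, p in zip(protomer.atoms, pts):
            q = p + rng.normal(0.0, noise_sd, 3) if noise_sd > 0 else p
            atoms.append(_ca_atom(label, a_rec.residue_number, q))
    fixture = Structure(
        f"interface_pair_a{alpha_deg:g}_h{offset_h:g}_seed{seed}", atoms, "synthetic"
    )
    expected = {
        "angle_deg": 2.0 * alpha_deg,
        "rise": 2.0 * offset_h,
        "handedness": (
            "none" if abs(2.0 * offset_h) < 0.5 else ("right" if offset_h > 0 else "left")
        ),
        "screw_axis": [0.0, 0.0, 1.0],
        "n_residues": n_head_residues + n_arm_residues,
        "head_axis": u2.tolist(),
        "cc_axis": [1.0, 0.0, 0.0],
    }
    return fixture, expected


def make_assembly_fixture(
    alpha_deg: float,
    offset_h: float,
    n_repeats: int,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[Structure, dict]:
    """Multi-repeat ring or helix assembly with known generator geometry.

    Builds the interface-pair construction's protomer and its coiled-coil
    partner, then propagates the exact analytic generator (screw angle 2α,
    rise 2h about +z) over ``n_repeats`` repeats.  Chains are labelled in
    repeat order (two chains per repeat), and optional Gaussian noise is
    added to every atom.  For α = 20°, h = 0, n_repeats = 9 this is the
    9-fold closed-ring fixture.
    """
    from .rigid import compose as _compose
    from .rigid import transform_power

    c2_head, c2_cc = interface_pair_axes(alpha_deg, offset_h)
    g = _compose(c2_head, c2_cc)
    head_center = np.array([0.0, 0.0, offset_h + 8.0])
    arm_start = np.array([16.0, 1.6, 1.6])
    protomer = make_toy_protomer(
        seed=seed, head_center=head_center, arm_start=arm_start,
        arm_direction=np.array([1.0, 0.0, 0.0]), chain_id="A",
    )
    rng = np.random.default_rng(seed + 2)
    coords = protomer.coordinates()
    labels = list(_CHAIN_LABELS)
    atoms: list[AtomRecord] = []
    li = 0
    for k in range(n_repeats):
        gk = transform_power(g, k)
        for sub in (gk, _compose(gk, c2_cc)):
            pts = sub.apply(coords)
            label = labels[li]
            li += 1
            for a_rec, p in zip(protomer.atoms, pts):
                q = p + rng.normal(0.0, noise_sd, 3) if noise_sd > 0 else p
                atoms.append(_ca_atom(label, a_rec.residue_number, q))
    fixture = Structure(
        f"assembly_a{alpha_deg:g}_h{offset_h:g}_n{n_repeats}_seed{seed}",
        atoms, "synthetic",
    )
    expected = {
        "angle_deg": 2.0 * alpha_deg,
        "rise": 2.0 * offset_h,
        "handedness": (
            "none" if abs(2.0 * offset_h) < 0.5 else ("right" if offset_h > 0 else "left")
        ),
        "n_repeats": n_repeats,
        "chains_per_repeat": 2,
    }
    return fixture, expected


def make_bundle_fixture(
    generator_geometry: dict | None = None,
    n_repeats: int = 3,
    designed_contacts: int = 0,
    cutoff: float = 4.0,
    seed: int = 0,
):
    """Filament plus a lateral pairing transform with a designed clash count.

    Builds a filament from an interface-pair fixture, then searches lateral
    (x-direction) offsets of a translated copy until exactly
    ``designed_contacts`` Cα-Cα pairs fall below ``cutoff``.  Raises if no
    offset achieves the exact count (counts change by single pairs on a
    sufficiently fine grid, so this only fails for unreasonable designs).

    Returns ``(filament, pairing_transform, expected_count)``.
    """
    from .assembly import build_filament, filament_generator, interface_transform
    from .structio import DomainSelection

    geom = generator_geometry or CCDC61_LIKE
    fixture, expected = make_interface_pair(geom["alpha_deg"], geom["offset_h"], seed=seed)
    n_res = expected["n_residues"]
    sel = lambda ch: DomainSelection(ch, (1, n_res))
    cc = interface_transform(fixture, sel("A"), sel("B"), label="coiled_coil")
    head = interface_transform(fixture, sel("A"), sel("C"), label="head_to_head")
    g = filament_generator(head, cc)
    protomer = Structure(
        "bundle_protomer",
        [a for a in fixture.atoms if a.chain_id == "A"],
        "synthetic",
    )
    filament = build_filament(protomer, cc, g, n_repeats)

    from scipy.spatial import cKDTree

    ca = filament.calpha_coordinates()
    tree = cKDTree(ca)
    # slightly tilted search direction so contact pairs cross the cutoff
    # one at a time rather than in symmetric groups
    direction = np.array([1.0, 0.13, 0.041])
    direction /= np.linalg.norm(direction)

    def count_at(offset: float) -> int:
        shifted = ca + offset * direction
        return sum(len(h) for h in tree.query_ball_point(shifted, cutoff))

    if designed_contacts < 0:
        raise ValueError("designed_contacts must be >= 0")
    span = float(np.ptp(ca @ direction)) + 50.0  # guaranteed contact-free
    if designed_contacts == 0:
        offset = span
    else:
        offset = None
        # coarse inward scan to bracket, then fine scan for the exact count
        prev = span
        cand = None
        for cand in np.arange(span, 0.0, -0.25):
            if count_at(cand) >= designed_contacts:
                break
            prev = cand
        else:
            cand = None
        if cand is not None:
            for fine in np.arange(prev, max(cand - 0.25, 0.0), -0.002):
                c = count_at(fine)
                if c == designed_contacts:
                    offset = float(fine)
                    break
                if c > designed_contacts:
                    break
        if offset is None:
            raise RuntimeError(
                f"no lateral offset realizes exactly {designed_contacts} contacts"
            )
    pairing = RigidTransform(np.eye(3), offset * direction)
    return filament, pairing, designed_contacts


def generate_dataset(out_dir: str | Path, seed: int = 0, config: dict | None = None) -> FixtureManifest:
    """Write one fixture of every family plus a regeneration manifest.

    Families: toy protomer, noisy C2 dimer, ring-like / helix-like /
    spiral-like interface pairs, bundle pairing, and the multi-speed
    multi-loading equilibrium AUC dataset.  Regeneration with the same
    seed is bit-identical (the manifest records file SHA-256 digests).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = config or {}
    manifest = FixtureManifest(format_version=1, seed=seed)

    def add(path: Path, spec: FixtureSpec) -> None:
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        manifest.entries.append(
            {"path": path.name, "spec": asdict(spec), "sha256": digest}
        )

    protomer = make_toy_protomer(seed=seed)
    p = write_structure(protomer, out / "protomer.pdb", "pdb")
    add(p, FixtureSpec("protomer", {"n_head": 60, "n_arm": 25}, seed))

    dimer, _ = make_c2_dimer(
        protomer, axis_point=np.array([0.0, 0.0, 16.0]),
        axis_direction=np.array([1.0, 0.0, 0.0]),
        noise_sd=cfg.get("dimer_noise_sd", 0.2), seed=seed,
    )
    p = write_structure(dimer, out / "c2_dimer.pdb", "pdb")
    add(p, FixtureSpec("c2_dimer", {"noise_sd": cfg.get("dimer_noise_sd", 0.2)}, seed,
                       expected={"angle_deg": 180.0}))

    for name, geom in (
        ("ring", SAS6_RING_LIKE),
        ("helix", CCDC61_LIKE),
        ("spiral", CESAS6_SPIRAL_LIKE),
    ):
        fixture, expected = make_interface_pair(geom["alpha_deg"], geom["offset_h"], seed=seed)
        p = write_structure(fixture, out / f"interface_pair_{name}.pdb", "pdb")
        add(p, FixtureSpec("interface_pair", dict(geom), seed, expected=expected))

    filament, pairing, count = make_bundle_fixture(
        designed_contacts=cfg.get("designed_contacts", 7), seed=seed
    )
    bundle_path = out / "bundle_pairing.json"
    bundle_path.write_text(json.dumps(
        {"pairing": pairing.to_dict(), "expected_contacts": count,
         "n_repeats": filament.n_repeats}, indent=1, sort_keys=True))
    add(bundle_path, FixtureSpec("bundle", {"designed_contacts": count}, seed,
                                 expected={"contacts": count}))

    params = DEFAULT_AUC_PARAMS
    loadings = [mgml_to_molar(c, params.monomer_mass) for c in AUC_LOADINGS_MGML]
    profiles = simulate_profiles(
        params, list(AUC_SPEEDS_RPM), loadings,
        relative_noise=cfg.get("auc_relative_noise", 0.01), seed=seed,
    )
    p = write_profiles_csv(profiles, out / "aucdata.csv")
    add(p, FixtureSpec(
        "aucdata",
        {"speeds_rpm": list(AUC_SPEEDS_RPM), "loadings_mgml": list(AUC_LOADINGS_MGML),
         "relative_noise": cfg.get("auc_relative_noise", 0.01)},
        seed,
        expected={"kd_molar": params.kd},
    ))

    (out / "manifest.json").write_text(manifest.to_json())
    return manifest
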