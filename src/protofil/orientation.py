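"""Cross-family domain-orientation comparisons.

The higher-order assemblies of the XRCC4 superfamily differ because (1)
the relative orientation of the two head domains within the head-to-head
dimer and (2) the head-to-coiled-coil orientation differ between family
members.  This module quantifies both: after superposing the *first* head
domains of two structures, the residual rotation that carries one second
head domain onto the other defines an axis in the reference frame; axes
from different family pairs are compared as undirected lines (angles
folded to <= 90°).  Coiled-coil axes are directed N->C vectors from the
principal component of the segment's Cα trace, and head-to-coiled-coil
angle differences are signed relative to a declared plane normal (the
observable contrast is which side of the reference the coiled coil tilts
to).

Cross-protein residue correspondences are inputs (curated, structure-
guided alignments), supplied as explicit pair lists; no automatic
alignment is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .rigid import RigidTransform, compose, invert, superpose
from .structio import DomainSelection, Structure, select_calpha

__all__ = [
    "DomainMap",
    "RelativeRotation",
    "UnreliableAxisError",
    "relative_domain_rotation",
    "axis_angle_between",
    "coiledcoil_axis",
    "head_cc_angle",
    "correspondence_from_ranges",
]


class UnreliableAxisError(ValueError):
    """Point cloud too isotropic for a meaningful principal axis."""


@dataclass(frozen=True)
class DomainMap:
    """Two domains of one structure plus residue correspondences to a reference.

    ``correspondence1``/``correspondence2`` map this structure's author
    residue numbers to the reference's, one pair list per domain.  For a
    self-comparison the identity pairing of the selections is used.
    """

    structure_id: str
    domain1: DomainSelection
    domain2: DomainSelection
    correspondence1: tuple[tuple[int, int], ...]
    correspondence2: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        for name, corr in (("correspondence1", self.correspondence1),
                           ("correspondence2", self.correspondence2)):
            if len(corr) < 3:
                raise ValueError(f"{name} needs >= 3 pairs, got {len(corr)}")
            if len({p for p, _ in corr}) != len(corr) or len({q for _, q in corr}) != len(corr):
                raise ValueError(f"{name} has duplicate residues")


@dataclass(frozen=True)
class RelativeRotation:
    axis: np.ndarray | None  # unit vector in the reference frame; None at 0°
    angle_deg: float
    reference_axis_label: str
    domain1_rmsd: float
    domain2_rmsd: float
    warning: str | None = None


def correspondence_from_ranges(
    query_range: tuple[int, int], ref_range: tuple[int, int]
) -> tuple[tuple[int, int], ...]:
    """Positional pairing of two equal-length author-numbered ranges."""
    qlo, qhi = query_range
    rlo, rhi = ref_range
    if qhi - qlo != rhi - rlo:
        raise ValueError("ranges have different lengths")
    return tuple((qlo + k, rlo + k) for k in range(qhi - qlo + 1))


def _paired_coords(
    structure: Structure,
    selection: DomainSelection,
    correspondence: tuple[tuple[int, int], ...],
    side: int,
) -> tuple[np.ndarray, list[int]]:
    """Cα coordinates for the correspondence residues present in the structure."""
    coords, report = select_calpha(structure, selection)
    index = {n: k for k, n in enumerate(report["residues"])}
    rows, keys = [], []
    for pair in correspondence:
        n = pair[side]
        if n in index:
            rows.append(coords[index[n]])
            keys.append(pair[1 - side])
    return np.array(rows), keys


def _matched_pair(
    ref: Structure,
    query: Structure,
    sel_ref: DomainSelection,
    sel_query: DomainSelection,
    correspondence: tuple[tuple[int, int], ...],
) -> tuple[np.ndarray, np.ndarray]:
    """(query, ref) Cα arrays restricted to pairs present in both structures."""
    qc, qkeys = _paired_coords(query, sel_query, correspondence, side=0)
    rc, rkeys = _paired_coords(ref, sel_ref, [(q, r) for q, r in correspondence], side=1)
    rindex = {k: i for i, k in enumerate(rkeys)}
    # qkeys are reference residue numbers for each query row
    rows_q, rows_r = [], []
    qnum = {r: i for i, r in enumerate(qkeys)}
    for rnum, i in qnum.items():
        if rnum in rindex:
            rows_q.append(qc[i])
            rows_r.append(rc[rindex[rnum]])
    if len(rows_q) < 3:
        raise ValueError(f"only {len(rows_q)} correspondence residues present in both structures")
    return np.array(rows_q), np.array(rows_r)


def relative_domain_rotation(
    ref: Structure,
    query: Structure,
    map_ref: DomainMap,
    map_query: DomainMap,
    rmsd_ceiling: float = 3.0,
    label: str | None = None,
) -> RelativeRotation:
    """Residual second-domain rotation after first-domain superposition.

    Superposes the query's domain1 onto the reference's domain1, then
    finds the further rotation needed to carry the (already-moved) query
    domain2 onto the reference domain2.  The axis of that residual
    rotation, expressed in the reference frame, is the comparison axis —
    the construction that defines the z axis from the zCCDC61-vs-lmSAS6
    head pair and measures other family pairs against it.
    """
    q1, r1 = _matched_pair(ref, query, map_ref.domain1, map_query.domain1,
                           map_query.correspondence1)
    q2, r2 = _matched_pair(ref, query, map_ref.domain2, map_query.domain2,
                           map_query.correspondence2)
    t1, rmsd1 = superpose(q1, r1)
    warning = None
    if rmsd1 > rmsd_ceiling:
        warning = f"domain1 superposition rmsd {rmsd1:.2f} A exceeds {rmsd_ceiling} A"
    q2_in_ref = t1.apply(q2)
    t2, rmsd2 = superpose(q2_in_ref, r2)
    rotvec = Rotation.from_matrix(t2.rotation).as_rotvec()
    angle = float(np.linalg.norm(rotvec))
    angle_deg = float(np.rad2deg(angle))
    axis = None if angle < 1e-9 else rotvec / angle
    return RelativeRotation(
        axis=axis,
        angle_deg=angle_deg,
        reference_axis_label=label or f"{query.identifier} vs {ref.identifier}",
        domain1_rmsd=rmsd1,
        domain2_rmsd=rmsd2,
        warning=warning,
    )


def axis_angle_between(a: np.ndarray, b: np.ndarray) -> float:
    """Angle between two undirected axes, folded to [0, 90] degrees."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("zero vector has no direction")
    c = abs(float(a @ b) / (na * nb))
    return float(np.rad2deg(np.arccos(np.clip(c, -1.0, 1.0))))


def coiledcoil_axis(coords: np.ndarray, min_anisotropy: float = 2.0) -> np.ndarray:
    """Directed (N->C) principal axis of a coiled-coil segment's Cα trace.

    The axis is the leading principal component of the centred coordinates,
    with its sign fixed so it points from the first-residue end toward the
    last-residue end.  Requires >= 8 residues and an elongated cloud
    (leading-to-second singular-value ratio >= ``min_anisotropy``).
    """
    c = np.asarray(coords, dtype=float)
    if c.ndim != 2 or c.shape[1] != 3 or c.shape[0] < 8:
        raise ValueError("need an (N>=8, 3) Calpha array")
    centred = c - c.mean(axis=0)
    _, sv, vt = np.linalg.svd(centred, full_matrices=False)
    if sv[1] <= 0 or sv[0] / max(sv[1], 1e-300) < min_anisotropy:
        raise UnreliableAxisError(
            f"anisotropy ratio {sv[0] / max(sv[1], 1e-300):.2f} < {min_anisotropy}: "
            "no well-defined long axis"
        )
    axis = vt[0]
    if axis @ (c[-1] - c[0]) < 0:
        axis = -axis
    return axis / np.linalg.norm(axis)


def head_cc_angle(
    struct: Structure,
    head_sel: DomainSelection,
    cc_sel: DomainSelection,
    ref_struct: Structure,
    ref_head_sel: DomainSelection,
    ref_cc_sel: DomainSelection,
    correspondence: tuple[tuple[int, int], ...],
    plane_normal: np.ndarray | None = None,
) -> dict:
    """Signed head-to-coiled-coil orientation difference vs a reference.

    Superposes the query head onto the reference head, then measures the
    angle between the query's and the reference's coiled-coil N->C axes.
    The sign is the sign of the out-of-reference-plane component of the
    query axis along ``plane_normal`` (default: normal of the plane spanned
    by the reference coiled-coil axis and the rotation axis carrying it to
    the query axis is degenerate, so the default normal is the cross
    product of reference cc axis and query cc axis's projection — callers
    comparing several structures should pass one shared normal).
    """
    qh, rh = _matched_pair(ref_struct, struct, ref_head_sel, head_sel, correspondence)
    t, rmsd = superpose(qh, rh)
    q_cc, _ = select_calpha(struct, cc_sel)
    r_cc, _ = select_calpha(ref_struct, ref_cc_sel)
    q_axis = coiledcoil_axis(t.apply(q_cc))
    r_axis = coiledcoil_axis(r_cc)
    cosang = float(np.clip(q_axis @ r_axis, -1.0, 1.0))
    magnitude = float(np.rad2deg(np.arccos(cosang)))
    if plane_normal is None:
        n = np.cross(r_axis, q_axis)
        nn = np.linalg.norm(n)
        plane_normal = n / nn if nn > 1e-12 else np.array([0.0, 0.0, 1.0])
        sign = 1.0 if magnitude > 0 else 0.0
    else:
        plane_normal = np.asarray(plane_normal, dtype=float)
        plane_normal = plane_normal / np.linalg.norm(plane_normal)
        comp = float(np.cross(r_axis, q_axis) @ plane_normal)
        sign = float(np.sign(comp)) if abs(comp) > 1e-12 else 1.0
    return {
        "angle_deg": float(sign * magnitude),
        "magnitude_deg": magnitude,
        "head_rmsd": rmsd,
        "plane_normal": plane_normal.tolist(),
        "query_cc_axis": q_axis.tolist(),
        "reference_cc_axis": r_axis.tolist(),
    }
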