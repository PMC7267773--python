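"""Coordinate I/O, domain selection and interface detection.

PDB and mmCIF parsing/writing is delegated to gemmi; this module exposes a
flat, ordered atom-record view of model 1 that the geometry modules
consume, plus packing-contact detection used to find candidate
homodimerization interfaces between chains.

Author residue numbering is used throughout (the numbering printed in the
coordinate files), so residues can be cited the way the structural literature cites
them (e.g. F128, D129).  Altloc handling keeps the highest-occupancy
conformer (first encountered on ties).
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
from scipy.spatial import cKDTree

from .rigid import RigidTransform

__all__ = [
    "AtomRecord",
    "Structure",
    "DomainSelection",
    "InterfaceContact",
    "EmptySelectionError",
    "FormatError",
    "ChainLabelError",
    "read_structure",
    "write_structure",
    "select_calpha",
    "select_atoms",
    "detect_interfaces",
    "write_assembly",
]

_WATER_NAMES = {"HOH", "WAT", "DOD"}
_CHAIN_ALPHABET = string.ascii_uppercase + string.ascii_lowercase + string.digits


class EmptySelectionError(ValueError):
    """A domain selection matched no atoms."""


class FormatError(ValueError):
    """File could not be parsed into any atoms."""


class ChainLabelError(ValueError):
    """Ran out of single-character chain labels for PDB output."""


@dataclass(frozen=True)
class AtomRecord:
    chain_id: str
    residue_number: int
    insertion_code: str | None
    residue_name: str
    atom_name: str
    element: str
    position: np.ndarray  # (3,) Å
    occupancy: float = 1.0
    model_number: int = 1
    het: bool = False

    def __post_init__(self) -> None:
        p = np.asarray(self.position, dtype=float).reshape(3)
        if not np.all(np.isfinite(p)):
            raise ValueError("non-finite atom position")
        object.__setattr__(self, "position", p)


@dataclass
class Structure:
    """Ordered atom list of one model, with stable read/write ordering."""

    identifier: str
    atoms: list[AtomRecord] = field(default_factory=list)
    source_format: str = "synthetic"  # pdb | mmcif | synthetic

    @property
    def chain_ids(self) -> list[str]:
        seen: list[str] = []
        for a in self.atoms:
            if a.chain_id not in seen:
                seen.append(a.chain_id)
        return seen

    def chain_atoms(self, chain_id: str) -> list[AtomRecord]:
        return [a for a in self.atoms if a.chain_id == chain_id]

    def coordinates(self) -> np.ndarray:
        if not self.atoms:
            return np.zeros((0, 3))
        return np.array([a.position for a in self.atoms])

    def transformed(self, t: RigidTransform, chain_relabel: dict[str, str] | None = None) -> "Structure":
        """Copy with every position transformed and chains optionally relabelled."""
        relabel = chain_relabel or {}
        atoms = [
            AtomRecord(
                chain_id=relabel.get(a.chain_id, a.chain_id),
                residue_number=a.residue_number,
                insertion_code=a.insertion_code,
                residue_name=a.residue_name,
                atom_name=a.atom_name,
                element=a.element,
                position=t.apply(a.position),
                occupancy=a.occupancy,
                model_number=a.model_number,
                het=a.het,
            )
            for a in self.atoms
        ]
        return Structure(self.identifier, atoms, self.source_format)


@dataclass(frozen=True)
class DomainSelection:
    """Inclusive author-numbered residue range on one chain."""

    chain_id: str
    residue_range: tuple[int, int]
    atom_filter: str = "calpha_only"  # calpha_only | all

    def __post_init__(self) -> None:
        lo, hi = self.residue_range
        if lo > hi:
            raise ValueError(f"selection start {lo} > end {hi}")
        if self.atom_filter not in ("calpha_only", "all"):
            raise ValueError(f"bad atom_filter {self.atom_filter!r}")


@dataclass(frozen=True)
class InterfaceContact:
    chain_pair: tuple[str, str]  # sorted, unordered pair
    contact_count: int
    min_distance: float
    rank: int


def _detect_format(path: Path, format_hint: str | None) -> str:
    if format_hint in ("pdb", "mmcif"):
        return format_hint
    suffix = path.suffix.lower()
    if suffix in (".cif", ".mmcif"):
        return "mmcif"
    if suffix in (".pdb", ".ent"):
        return "pdb"
    raise FormatError(f"cannot infer format of {path}; pass format_hint")


def read_structure(path: str | Path, format_hint: str | None = None) -> Structure:
    """Parse model 1 of a PDB or mmCIF file into a flat atom list.

    Altlocs collapse to the highest-occupancy conformer (ties: first).
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such coordinate file: {path}")
    fmt = _detect_format(path, format_hint)
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Detect)
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"could not parse {path}: {exc}") from exc
    if len(st) == 0:
        raise FormatError(f"no models in {path}")
    st.setup_entities()
    model = st[0]
    atoms: list[AtomRecord] = []
    for chain in model:
        for res in chain:
            # altloc: keep the highest-occupancy copy of each atom name
            best: dict[str, gemmi.Atom] = {}
            for atom in res:
                prev = best.get(atom.name)
                if prev is None or atom.occ > prev.occ:
                    best[atom.name] = atom
            for atom in res:
                if best.get(atom.name) is not atom:
                    continue
                atoms.append(
                    AtomRecord(
                        chain_id=chain.name,
                        residue_number=res.seqid.num,
                        insertion_code=res.seqid.icode.strip() or None,
                        residue_name=res.name,
                        atom_name=atom.name,
                        element=atom.element.name,
                        position=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                        occupancy=float(atom.occ),
                        model_number=1,
                        het=res.het_flag == "H",
                    )
                )
    if not atoms:
        raise FormatError(f"no atoms parsed from {path}")
    return Structure(identifier=path.stem, atoms=atoms, source_format=fmt)


def _to_gemmi(structure: Structure) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = structure.identifier
    model = gemmi.Model("1")
    chain_map: dict[str, gemmi.Chain] = {}
    for a in structure.atoms:
        if a.chain_id not in chain_map:
            chain = gemmi.Chain(a.chain_id)
            model.add_chain(chain)
            chain_map[a.chain_id] = model[len(model) - 1]
        chain = chain_map[a.chain_id]
        last = chain[len(chain) - 1] if len(chain) else None
        if (
            last is None
            or last.seqid.num != a.residue_number
            or last.name != a.residue_name
        ):
            res = gemmi.Residue()
            res.name = a.residue_name
            res.seqid = gemmi.SeqId(a.residue_number, a.insertion_code or " ")
            res.het_flag = "H" if a.het else "A"
            chain.add_residue(res)
            last = chain[len(chain) - 1]
        atom = gemmi.Atom()
        atom.name = a.atom_name
        atom.element = gemmi.Element(a.element)
        atom.pos = gemmi.Position(*a.position)
        atom.occ = a.occupancy
        last.add_atom(atom)
    st.add_model(model)
    st.setup_entities()
    return st


def write_structure(structure: Structure, path: str | Path, fmt: str | None = None) -> Path:
    """Write to PDB or mmCIF (format from ``fmt`` or the file suffix)."""
    path = Path(path)
    fmt = _detect_format(path, fmt)
    st = _to_gemmi(structure)
    if fmt == "pdb":
        for cid in structure.chain_ids:
            if len(cid) > 1:
                raise ChainLabelError(
                    f"chain id {cid!r} does not fit PDB single-character field; use mmCIF"
                )
        st.write_pdb(str(path))
    else:
        st.make_mmcif_document().write_file(str(path))
    return path


def select_atoms(structure: Structure, selection: DomainSelection) -> list[AtomRecord]:
    """All atoms matching the selection, in file order."""
    lo, hi = selection.residue_range
    out = [
        a
        for a in structure.atoms
        if a.chain_id == selection.chain_id
        and lo <= a.residue_number <= hi
        and (selection.atom_filter == "all" or a.atom_name == "CA")
    ]
    if not out:
        raise EmptySelectionError(
            f"selection chain {selection.chain_id!r} residues {lo}-{hi} "
            f"({selection.atom_filter}) matched no atoms"
        )
    return out


def select_calpha(
    structure: Structure, selection: DomainSelection
) -> tuple[np.ndarray, dict]:
    """One Cα coordinate per residue in the range, ordered by residue number.

    Returns ``(coords, report)`` where ``report`` lists the residue numbers
    found and those missing from the range (chain gaps, e.g. disordered
    loops not built in a crystal structure).
    """
    sel = DomainSelection(selection.chain_id, selection.residue_range, "calpha_only")
    atoms = select_atoms(structure, sel)
    by_res: dict[int, AtomRecord] = {}
    for a in atoms:
        by_res.setdefault(a.residue_number, a)
    numbers = sorted(by_res)
    lo, hi = selection.residue_range
    missing = [n for n in range(lo, hi + 1) if n not in by_res]
    coords = np.array([by_res[n].position for n in numbers])
    report = {
        "chain_id": selection.chain_id,
        "residue_range": [lo, hi],
        "n_selected": len(numbers),
        "residues": numbers,
        "missing_residues": missing,
    }
    return coords, report


def detect_interfaces(
    structure: Structure,
    distance_cutoff: float = 5.0,
    min_contacts: int = 10,
) -> list[InterfaceContact]:
    """Chain pairs in packing contact, ranked by residue-pair contact count.

    A residue pair counts once if any atom of one residue lies within
    ``distance_cutoff`` Å of any atom of the other.  HETATM records and
    waters are excluded (protein-protein interfaces are the object of
    study).  Pairs with fewer than ``min_contacts`` contacts are dropped.
    Single-chain input yields an empty list.
    """
    chains = structure.chain_ids
    results: list[tuple[tuple[str, str], int, float]] = []
    per_chain: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for cid in chains:
        atoms = [
            a
            for a in structure.chain_atoms(cid)
            if not a.het and a.residue_name not in _WATER_NAMES
        ]
        if not atoms:
            continue
        coords = np.array([a.position for a in atoms])
        resids = np.array([a.residue_number for a in atoms])
        per_chain[cid] = (coords, resids)
    cids = list(per_chain)
    for i in range(len(cids)):
        for j in range(i + 1, len(cids)):
            ca, ra = per_chain[cids[i]]
            cb, rb = per_chain[cids[j]]
            tree = cKDTree(cb)
            pairs = tree.query_ball_point(ca, distance_cutoff)
            contact_res: set[tuple[int, int]] = set()
            min_d = np.inf
            for ai, hits in enumerate(pairs):
                if not hits:
                    continue
                d = np.linalg.norm(cb[hits] - ca[ai], axis=1)
                min_d = min(min_d, float(d.min()))
                for bi in hits:
                    contact_res.add((int(ra[ai]), int(rb[bi])))
            if len(contact_res) >= min_contacts:
                pair = tuple(sorted((cids[i], cids[j])))
                results.append((pair, len(contact_res), min_d))
    results.sort(key=lambda r: (-r[1], r[0]))
    return [
        InterfaceContact(chain_pair=pair, contact_count=count, min_distance=mind, rank=k + 1)
        for k, (pair, count, mind) in enumerate(results)
    ]


def write_assembly(
    structures: list[tuple[Structure, RigidTransform, str | None]],
    path: str | Path,
    fmt: str | None = None,
) -> Path:
    """Write transformed copies of structures as one multi-chain file.

    Each entry is ``(structure, transform, chain_prefix)``; chains are
    relabelled from a 62-character alphabet.  PDB output is limited to 62
    chains (single-character labels); request mmCIF beyond that.
    """
    path = Path(path)
    fmt = _detect_format(path, fmt)
    n_chains = sum(len(s.chain_ids) for s, _, _ in structures)
    if fmt == "pdb" and n_chains > len(_CHAIN_ALPHABET):
        raise ChainLabelError(
            f"{n_chains} chains exceed the {len(_CHAIN_ALPHABET)} single-character "
            "PDB labels; write mmCIF instead"
        )
    merged: list[AtomRecord] = []
    label_iter = iter(_CHAIN_ALPHABET) if fmt == "pdb" else None
    counter = 0
    for structure, transform, prefix in structures:
        relabel = {}
        for cid in structure.chain_ids:
            if fmt == "pdb":
                relabel[cid] = next(label_iter)
            else:
                relabel[cid] = f"{prefix or 'S'}{counter}{cid}"
            counter += 1
        merged.extend(structure.transformed(transform, relabel).atoms)
    out = Structure(identifier=Path(path).stem, atoms=merged, source_format=fmt)
    return write_structure(out, path, fmt)
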