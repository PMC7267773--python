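"""Sequence charge and theoretical isoelectric point.

Net charge at a given pH is the Henderson-Hasselbalch sum over ionizable
groups: each basic group (N-terminus, K, R, H) contributes
``+1 / (1 + 10^(pH - pKa))`` and each acidic group (C-terminus, D, E, C, Y)
contributes ``-1 / (1 + 10^(pKa - pH))``.  The theoretical pI is the pH at
which this sum vanishes; it is unique because the sum is strictly
decreasing in pH, so simple bisection on [0, 14] finds it.

pI values depend on the pKa table, so the table is a named, swappable
object rather than a hidden constant.  The default is the Bjellqvist-style
set used by the common "theoretical pI" web calculators.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

__all__ = [
    "IonizableModel",
    "SequenceRecord",
    "BJELLQVIST",
    "net_charge",
    "theoretical_pi",
    "read_fasta",
]

_STANDARD = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class IonizableModel:
    """Named pKa table: group -> (pKa, sign), sign +1 basic / -1 acidic.

    Groups are one-letter residue codes plus ``"Nterm"`` and ``"Cterm"``.
    """

    table_name: str
    pka: dict
    sign: dict

    def __post_init__(self) -> None:
        if set(self.pka) != set(self.sign):
            raise ValueError("pKa and sign tables must cover the same groups")
        for g, s in self.sign.items():
            if s not in (+1, -1):
                raise ValueError(f"sign for {g} must be +1 or -1")


#: Bjellqvist-style table (the set behind common theoretical-pI calculators).
BJELLQVIST = IonizableModel(
    table_name="bjellqvist",
    pka={
        "Nterm": 7.5, "Cterm": 3.55,
        "D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0,
        "H": 5.98, "K": 10.0, "R": 12.0,
    },
    sign={
        "Nterm": +1, "Cterm": -1,
        "D": -1, "E": -1, "C": -1, "Y": -1,
        "H": +1, "K": +1, "R": +1,
    },
)


@dataclass(frozen=True)
class SequenceRecord:
    identifier: str
    residues: str
    source: str = "literal"  # fasta | literal

    def __post_init__(self) -> None:
        seq = self.residues.upper()
        bad = set(seq) - _STANDARD - {"X"}
        if bad:
            raise ValueError(f"non-standard residues {sorted(bad)} in {self.identifier}")
        if not seq:
            raise ValueError("empty sequence")
        object.__setattr__(self, "residues", seq)

    def subrange(self, start: int, end: int) -> "SequenceRecord":
        """1-based inclusive subrange (e.g. the 144-287 coiled-coil region)."""
        if not (1 <= start <= end <= len(self.residues)):
            raise ValueError(f"range {start}-{end} outside 1-{len(self.residues)}")
        return SequenceRecord(
            f"{self.identifier}/{start}-{end}", self.residues[start - 1 : end], self.source
        )


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    records = [
        SequenceRecord(rec.id, str(rec.seq), source="fasta")
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def net_charge(
    seq: SequenceRecord,
    ph: float,
    model: IonizableModel = BJELLQVIST,
    include_termini: bool = True,
) -> float:
    """Henderson-Hasselbalch net charge in elementary charges (X ignored)."""
    groups: list[str] = [r for r in seq.residues if r in model.pka]
    if include_termini:
        groups += ["Nterm", "Cterm"]
    charge = 0.0
    for g in groups:
        pka, s = model.pka[g], model.sign[g]
        if s > 0:
            charge += 1.0 / (1.0 + 10.0 ** (ph - pka))
        else:
            charge -= 1.0 / (1.0 + 10.0 ** (pka - ph))
    return charge


def theoretical_pi(
    seq: SequenceRecord,
    model: IonizableModel = BJELLQVIST,
    tol: float = 0.001,
    include_termini: bool = True,
) -> float:
    """pH of zero net charge, by bisection on [0, 14] to ``tol`` pH units."""
    lo, hi = 0.0, 14.0
    f_lo = net_charge(seq, lo, model, include_termini)
    f_hi = net_charge(seq, hi, model, include_termini)
    if f_lo <= 0:
        return lo  # fully acidic composition even at pH 0 (degenerate)
    if f_hi >= 0:
        return hi
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if net_charge(seq, mid, model, include_termini) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
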