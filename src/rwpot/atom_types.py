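"""Residue-specific heavy-atom typing.

Each of the 167 heavy atoms of the 20 standard amino acids gets an integer
type id.  Chemically indistinguishable atoms related by a local symmetry
(e.g. the two carboxylate oxygens of ASP) share one id, which brings the
number of distinct types down to 158.  Hydrogens, terminal oxygens (OXT)
and non-standard residues are untyped and are skipped by every consumer.
"""

from __future__ import annotations

import hashlib
from functools import lru_cache

__all__ = [
    "RESIDUE_HEAVY_ATOMS",
    "STANDARD_RESIDUES",
    "N_ATOM_TYPES",
    "atom_type",
    "typing_table",
    "typing_hash",
    "write_typing_table",
]

# Heavy atoms per residue, PDB v3 names, backbone first.
RESIDUE_HEAVY_ATOMS: dict[str, tuple[str, ...]] = {
    "ALA": ("N", "CA", "C", "O", "CB"),
    "ARG": ("N", "CA", "C", "O", "CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"),
    "ASN": ("N", "CA", "C", "O", "CB", "CG", "OD1", "ND2"),
    "ASP": ("N", "CA", "C", "O", "CB", "CG", "OD1", "OD2"),
    "CYS": ("N", "CA", "C", "O", "CB", "SG"),
    "GLN": ("N", "CA", "C", "O", "CB", "CG", "CD", "OE1", "NE2"),
    "GLU": ("N", "CA", "C", "O", "CB", "CG", "CD", "OE1", "OE2"),
    "GLY": ("N", "CA", "C", "O"),
    "HIS": ("N", "CA", "C", "O", "CB", "CG", "ND1", "CD2", "CE1", "NE2"),
    "ILE": ("N", "CA", "C", "O", "CB", "CG1", "CG2", "CD1"),
    "LEU": ("N", "CA", "C", "O", "CB", "CG", "CD1", "CD2"),
    "LYS": ("N", "CA", "C", "O", "CB", "CG", "CD", "CE", "NZ"),
    "MET": ("N", "CA", "C", "O", "CB", "CG", "SD", "CE"),
    "PHE": ("N", "CA", "C", "O", "CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "PRO": ("N", "CA", "C", "O", "CB", "CG", "CD"),
    "SER": ("N", "CA", "C", "O", "CB", "OG"),
    "THR": ("N", "CA", "C", "O", "CB", "OG1", "CG2"),
    "TRP": ("N", "CA", "C", "O", "CB", "CG", "CD1", "CD2", "NE1", "CE2",
            "CE3", "CZ2", "CZ3", "CH2"),
    "TYR": ("N", "CA", "C", "O", "CB", "CG", "CD1", "CD2", "CE1", "CE2",
            "CZ", "OH"),
    "VAL": ("N", "CA", "C", "O", "CB", "CG1", "CG2"),
}

STANDARD_RESIDUES = frozenset(RESIDUE_HEAVY_ATOMS)

# Symmetry-equivalent atom pairs merged onto the first member's id.
_SYMMETRIC_MERGES: dict[tuple[str, str], str] = {
    ("PHE", "CD2"): "CD1",
    ("PHE", "CE2"): "CE1",
    ("TYR", "CD2"): "CD1",
    ("TYR", "CE2"): "CE1",
    ("ASP", "OD2"): "OD1",
    ("GLU", "OE2"): "OE1",
    ("ARG", "NH2"): "NH1",
    ("LEU", "CD2"): "CD1",
    ("VAL", "CG2"): "CG1",
}

# Legacy / variant atom names seen in decoy sets, mapped to PDB v3.
_NAME_ALIASES: dict[tuple[str, str], str] = {
    ("ILE", "CD"): "CD1",
}


def _build_map() -> dict[tuple[str, str], int]:
    mapping: dict[tuple[str, str], int] = {}
    next_id = 0
    for res in sorted(RESIDUE_HEAVY_ATOMS):
        for atom in RESIDUE_HEAVY_ATOMS[res]:
            canonical = _SYMMETRIC_MERGES.get((res, atom))
            if canonical is not None:
                mapping[(res, atom)] = mapping[(res, canonical)]
            else:
                mapping[(res, atom)] = next_id
                next_id += 1
    return mapping


_TYPE_MAP = _build_map()
N_ATOM_TYPES = len(set(_TYPE_MAP.values()))
assert N_ATOM_TYPES == 158


def atom_type(residue_name: str, atom_name: str) -> int | None:
    """Type id for a heavy atom, or ``None`` for anything untyped.

    Selenomethionine is accepted as MET (SE -> SD); ``OT1`` is read as the
    backbone carbonyl oxygen; hydrogens, OXT and unknown residues/atoms
    return ``None``.
    """
    res = residue_name.upper()
    name = atom_name.strip().upper()
    if res == "MSE":
        res = "MET"
        if name == "SE":
            name = "SD"
    if name == "OT1":
        name = "O"
    if name in ("OXT", "OT2"):
        return None
    # hydrogen / deuterium names may start with a digit (e.g. 1HB)
    stripped = name.lstrip("0123456789")
    if stripped.startswith(("H", "D")):
        return None
    name = _NAME_ALIASES.get((res, name), name)
    return _TYPE_MAP.get((res, name))


@lru_cache(maxsize=1)
def typing_table() -> tuple[tuple[str, str, int], ...]:
    """The full (residue, atom, type_id) table in deterministic order."""
    return tuple((res, atom, _TYPE_MAP[(res, atom)])
                 for res in sorted(RESIDUE_HEAVY_ATOMS)
                 for atom in RESIDUE_HEAVY_ATOMS[res])


@lru_cache(maxsize=1)
def typing_hash() -> str:
    """Stable hash of the typing scheme, stamped into every saved table."""
    text = "\n".join(f"{r}\t{a}\t{t}" for r, a, t in typing_table())
    return hashlib.md5(text.encode()).hexdigest()[:12]


def write_typing_table(path) -> None:
    with open(path, "w") as fh:
        fh.write("# residue\tatom\ttype_id\n")
        for res, atom, tid in typing_table():
            fh.write(f"{res}\t{atom}\t{tid}\n")
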