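"""Typed protein structures and PDB input/output.

Everything downstream (counting, training, scoring) consumes
:class:`TypedStructure`; no other module touches raw PDB text.  Parsing is
done with gemmi.  Hydrogens, waters, hetero compounds and alternate
conformations are stripped; selenomethionine is read as methionine;
residues missing any of N/CA/C are dropped with a warning.  Surviving
residues are re-indexed contiguously in file order, and sequence
separation is always computed on that index.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from .atom_types import RESIDUE_HEAVY_ATOMS, STANDARD_RESIDUES, atom_type

logger = logging.getLogger(__name__)

__all__ = [
    "TypedAtom",
    "Residue",
    "TypedStructure",
    "EmptyStructureError",
    "parse_pdb",
    "write_pdb",
    "generate_fixture",
    "perturb",
]


class EmptyStructureError(ValueError):
    """Raised when a file yields no usable standard amino-acid residues."""


@dataclass(frozen=True)
class TypedAtom:
    residue_index: int
    residue_name: str
    atom_name: str
    type_id: int
    position: np.ndarray  # (3,) float64, Angstrom

    def __eq__(self, other):
        if not isinstance(other, TypedAtom):
            return NotImplemented
        return (self.residue_index == other.residue_index
                and self.residue_name == other.residue_name
                and self.atom_name == other.atom_name
                and self.type_id == other.type_id
                and np.array_equal(self.position, other.position))


@dataclass
class Residue:
    index: int
    name: str
    atoms: list[TypedAtom] = field(default_factory=list)

    def atom(self, name: str) -> TypedAtom | None:
        for a in self.atoms:
            if a.atom_name == name:
                return a
        return None


@dataclass
class TypedStructure:
    chain_id: str
    residues: list[Residue]

    def __post_init__(self):
        self._arrays = None

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> list[str]:
        return [r.name for r in self.residues]

    def _flat(self):
        if self._arrays is None:
            coords, types, ridx = [], [], []
            for res in self.residues:
                for a in res.atoms:
                    coords.append(a.position)
                    types.append(a.type_id)
                    ridx.append(a.residue_index)
            self._arrays = (
                np.asarray(coords, dtype=float).reshape(-1, 3),
                np.asarray(types, dtype=np.intp),
                np.asarray(ridx, dtype=np.intp),
            )
        return self._arrays

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinates in file/atom order."""
        return self._flat()[0]

    @property
    def type_ids(self) -> np.ndarray:
        return self._flat()[1]

    @property
    def residue_indices(self) -> np.ndarray:
        return self._flat()[2]

    @property
    def n_atoms(self) -> int:
        return len(self._flat()[1])

    def ca_coords(self) -> np.ndarray:
        """(N, 3) C-alpha coordinates; raises if a residue lacks CA."""
        out = []
        for res in self.residues:
            ca = res.atom("CA")
            if ca is None:
                raise ValueError(f"residue {res.index} ({res.name}) has no CA")
            out.append(ca.position)
        return np.asarray(out)

    def with_coords(self, coords: np.ndarray) -> "TypedStructure":
        """Copy of the structure with every atom position replaced."""
        coords = np.asarray(coords, dtype=float).reshape(-1, 3)
        if coords.shape[0] != self.n_atoms:
            raise ValueError("coordinate count mismatch")
        residues, k = [], 0
        for res in self.residues:
            atoms = []
            for a in res.atoms:
                atoms.append(TypedAtom(a.residue_index, a.residue_name,
                                       a.atom_name, a.type_id,
                                       coords[k].copy()))
                k += 1
            residues.append(Residue(res.index, res.name, atoms))
        return TypedStructure(self.chain_id, residues)

    def __eq__(self, other):
        if not isinstance(other, TypedStructure):
            return NotImplemented
        if self.chain_id != other.chain_id or len(self) != len(other):
            return False
        for r1, r2 in zip(self.residues, other.residues):
            if (r1.index, r1.name) != (r2.index, r2.name):
                return False
            if r1.atoms != r2.atoms:
                return False
        return True


def _from_gemmi_chain(chain: gemmi.Chain, chain_id: str) -> TypedStructure:
    residues: list[Residue] = []
    for res in chain:
        name = res.name.upper()
        if name == "MSE":
            name = "MET"
        if name not in STANDARD_RESIDUES:
            continue
        atoms: list[tuple[str, np.ndarray]] = []
        seen: set[str] = set()
        for atom in res:
            aname = atom.name.strip().upper()
            if aname in seen:  # residual altloc duplicates
                continue
            tid = atom_type(name, atom.name)
            if tid is None:
                continue
            seen.add(aname)
            pos = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
            atoms.append((aname, pos))
        names = {a for a, _ in atoms}
        if not {"N", "CA", "C"} <= names:
            logger.warning("dropping residue %s %s: incomplete backbone",
                           name, res.seqid.num)
            continue
        idx = len(residues)
        residues.append(Residue(idx, name, [
            TypedAtom(idx, name, a, atom_type(name, a), p) for a, p in atoms
        ]))
    if not residues:
        raise EmptyStructureError(f"chain {chain_id!r}: no standard residues")
    return TypedStructure(chain_id, residues)


def parse_pdb(path, chain: str | None = None) -> TypedStructure:
    """Parse one protein chain of a PDB file into a :class:`TypedStructure`.

    Parameters
    ----------
    path
        PDB file with wwPDB v3 ATOM records (HETATM MSE is also accepted).
    chain
        Chain identifier; default is the first chain that yields at least
        one standard residue.  Only the first MODEL is read.
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError, OSError) as exc:
        raise IOError(f"cannot read PDB file {path}: {exc}") from exc
    st.remove_alternative_conformations()
    st.remove_hydrogens()
    st.remove_waters()
    if len(st) == 0:
        raise EmptyStructureError(f"{path}: no coordinates")
    model = st[0]
    last_error: Exception | None = None
    for ch in model:
        if chain is not None and ch.name != chain:
            continue
        try:
            return _from_gemmi_chain(ch, ch.name)
        except EmptyStructureError as exc:
            last_error = exc
    if chain is not None:
        raise EmptyStructureError(f"{path}: chain {chain!r} not usable")
    raise EmptyStructureError(
        f"{path}: no parseable protein chain ({last_error})")


_ELEMENTS = {"C": "C", "N": "N", "O": "O", "S": "S"}


def write_pdb(structure: TypedStructure, path) -> None:
    """Write a structure as a minimal single-chain PDB file."""
    st = gemmi.Structure()
    st.name = "rwpot"
    model = gemmi.Model("1")
    ch = gemmi.Chain(structure.chain_id or "A")
    for res in structure.residues:
        gres = gemmi.Residue()
        gres.name = res.name
        gres.seqid = gemmi.SeqId(res.index + 1, " ")
        for a in res.atoms:
            ga = gemmi.Atom()
            ga.name = a.atom_name
            ga.element = gemmi.Element(_ELEMENTS.get(a.atom_name[0], "C"))
            ga.pos = gemmi.Position(*a.position)
            ga.occ = 1.0
            ga.b_iso = 0.0
            gres.add_atom(ga)
        ch.add_residue(gres)
    model.add_chain(ch)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# Fixture generation: idealized backbone + deterministic side-chain stubs.
# ---------------------------------------------------------------------------

# Idealized backbone internal coordinates (Angstrom / degrees).
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O = 1.458, 1.525, 1.329, 1.231
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O = 111.0, 116.2, 121.7, 120.8
_OMEGA = 180.0

# (phi, psi) basins used for random torsion sampling.
_BASINS = ((-63.0, -43.0), (-120.0, 130.0))


def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
           bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """NeRF placement of atom d bonded to c, given chain a-b-c."""
    angle = math.radians(angle_deg)
    torsion = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * math.cos(angle),
        bond * math.sin(angle) * math.cos(torsion),
        bond * math.sin(angle) * math.sin(torsion),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _sidechain_torsion(k: int) -> float:
    return (60.0, 180.0, -60.0, 120.0, -120.0, 0.0)[k % 6]


def _build_residue_atoms(name: str, n: np.ndarray, ca: np.ndarray,
                         c: np.ndarray) -> dict[str, np.ndarray]:
    """Deterministic side-chain stub coordinates given the backbone."""
    pos = {"N": n, "CA": ca, "C": c}
    side = [a for a in RESIDUE_HEAVY_ATOMS[name] if a not in ("N", "CA", "C", "O")]
    if not side:
        return pos
    # CB from the backbone with the standard improper torsion
    cb = _place(c, n, ca, 1.530, 110.5, -122.5)
    pos[side[0]] = cb  # side[0] is always CB
    chain = [n, ca, cb]
    for k, aname in enumerate(side[1:]):
        nxt = _place(chain[-3], chain[-2], chain[-1], 1.50, 114.0,
                     _sidechain_torsion(k))
        pos[aname] = nxt
        chain.append(nxt)
    return pos


def generate_fixture(sequence: list[str] | str, seed: int = 0,
                     chain_id: str = "A",
                     max_retries: int = 40,
                     min_clearance: float = 2.5) -> TypedStructure:
    """Deterministic toy polypeptide with idealized geometry.

    The backbone is grown residue by residue with ideal bond lengths and
    angles and (phi, psi) torsions drawn from helix/strand basins plus
    Gaussian jitter; a residue placement is re-drawn (up to *max_retries*
    times) if any new backbone atom comes closer than *min_clearance* to
    the backbone of non-adjacent residues.  Side chains are deterministic
    geometric stubs, not rotamers.  Coordinates are quantized to 0.001 A so
    a written PDB re-parses to an identical structure.

    Parameters
    ----------
    sequence
        Residue names: a list of 3-letter codes or a 1-letter string.
    seed
        Seeds every random draw; identical inputs give identical output.
    """
    seq = _normalize_sequence(sequence)
    if len(seq) < 3:
        raise ValueError("sequence must have at least 3 residues")
    rng = np.random.default_rng(seed)

    backbone: list[dict[str, np.ndarray]] = []
    # first residue in a canonical pose
    n0 = np.zeros(3)
    ca0 = np.array([_B_N_CA, 0.0, 0.0])
    c0 = _place(np.array([-1.0, 1.0, 0.0]), n0, ca0, _B_CA_C, _A_N_CA_C, 120.0)
    backbone.append({"N": n0, "CA": ca0, "C": c0})

    guard: list[np.ndarray] = []  # backbone atoms of residues < i-1
    for i in range(1, len(seq)):
        prev = backbone[-1]
        placed = None
        for attempt in range(max_retries + 1):
            if attempt < max_retries:
                phi0, psi0 = _BASINS[rng.integers(len(_BASINS))]
                phi = phi0 + rng.normal(0.0, 12.0)
                psi = psi0 + rng.normal(0.0, 12.0)
            else:  # guaranteed-termination fallback: extended strand
                phi, psi = -120.0, 130.0
            # psi of residue i-1 positions N_i; phi of residue i positions C_i
            n_i = _place(prev["N"], prev["CA"], prev["C"], _B_C_N,
                         _A_CA_C_N, psi)
            ca_i = _place(prev["CA"], prev["C"], n_i, _B_N_CA,
                          _A_C_N_CA, _OMEGA)
            c_i = _place(prev["C"], n_i, ca_i, _B_CA_C, _A_N_CA_C, phi)
            cand = (n_i, ca_i, c_i)
            if not guard or attempt == max_retries:
                placed = cand
                break
            g = np.asarray(guard)
            dmin = min(np.linalg.norm(g - p, axis=1).min() for p in cand)
            if dmin >= min_clearance:
                placed = cand
                break
        n_i, ca_i, c_i = placed
        backbone.append({"N": n_i, "CA": ca_i, "C": c_i})
        guard.extend(backbone[-2].values())

    residues: list[Residue] = []
    for i, name in enumerate(seq):
        bb = backbone[i]
        pos = _build_residue_atoms(name, bb["N"], bb["CA"], bb["C"])
        # carbonyl O placed off the C, anti to the next N (or psi=0 pose)
        ref = backbone[i + 1]["N"] if i + 1 < len(seq) else bb["N"]
        o = _place(ref, bb["CA"], bb["C"], _B_C_O, _A_CA_C_O, 180.0) \
            if i + 1 < len(seq) else \
            _place(bb["N"], bb["CA"], bb["C"], _B_C_O, _A_CA_C_O, 0.0)
        pos["O"] = o
        atoms = [TypedAtom(i, name, a, atom_type(name, a),
                           np.round(pos[a], 3))
                 for a in RESIDUE_HEAVY_ATOMS[name]]
        residues.append(Residue(i, name, atoms))
    return TypedStructure(chain_id, residues)


_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}


def _normalize_sequence(sequence) -> list[str]:
    if isinstance(sequence, str):
        try:
            seq = [_ONE_TO_THREE[c.upper()] for c in sequence]
        except KeyError as exc:
            raise ValueError(f"unknown residue letter {exc}") from exc
    else:
        seq = [str(s).upper() for s in sequence]
    bad = [s for s in seq if s not in STANDARD_RESIDUES]
    if bad:
        raise ValueError(f"non-standard residues in sequence: {bad}")
    return seq


def perturb(structure: TypedStructure, sigma: float,
            seed: int | np.random.Generator = 0) -> TypedStructure:
    """Decoy by iid Gaussian displacement of every atom (sigma in A)."""
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    noise = rng.normal(0.0, sigma, size=(structure.n_atoms, 3)) \
        if sigma > 0 else np.zeros((structure.n_atoms, 3))
    return structure.with_coords(np.round(structure.coords + noise, 3))
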