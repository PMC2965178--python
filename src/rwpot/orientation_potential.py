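"""Side-chain orientation-dependent packing potential.

Each residue carries "vector pairs": ordered atom triples (X0, X1, X2)
defining two vectors X0->X1 and X0->X2 and hence a local right-handed
frame.  There are 20 vector-pair types: one side-chain triple for every
residue except GLY and ALA (18) plus two backbone triples defined for all
residues.  The relative orientation of two vector pairs A and B is coded
by three variables:

* the direction of B0 seen from A0, expressed in A's frame (26 bins:
  two polar caps plus three latitude bands x eight azimuth sectors),
* the direction of A0 seen from B0, expressed in B's frame (26 bins),
* the torsion angle of A1-A0-B0-B1 (4 bins of pi/2),

for 26 * 26 * 4 = 2704 orientation bins.  The reference distribution is
analytic: each direction bin's probability is its fraction of the sphere's
surface area, each torsion bin has probability 1/4, and the three factors
are independent.  Energies follow the same inverse-Boltzmann form as the
distance term, accumulated over contacting (any heavy-atom pair closer
than 10 A), non-consecutive residue pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .atom_types import typing_hash
from .structures_io import Residue, TypedStructure

logger = logging.getLogger(__name__)

__all__ = [
    "VectorPairDef",
    "OrientationBin",
    "OrientationPotential",
    "DegenerateGeometryError",
    "DEFAULT_VECTOR_PAIRS",
    "N_VECTOR_PAIR_TYPES",
    "N_DIRECTION_BINS",
    "N_TORSION_BINS",
    "N_ORIENTATION_BINS",
    "DIRECTION_REF_PROBS",
    "TORSION_REF_PROB",
    "build_frame",
    "direction_bin",
    "reference_probability",
    "orientation_reference_probs",
    "relative_orientation",
    "in_contact",
    "train_orientation",
    "score_orientation",
    "save_orientation_table",
    "load_orientation_table",
]

N_DIRECTION_BINS = 26
N_TORSION_BINS = 4
N_ORIENTATION_BINS = N_DIRECTION_BINS * N_DIRECTION_BINS * N_TORSION_BINS
DEFAULT_CONTACT_CUTOFF = 10.0  # A, strict upper bound
DEFAULT_W_ORIENT = 0.1
DEFAULT_CAP = 10.0
DEFAULT_MIN_SEPARATION = 2


class DegenerateGeometryError(ValueError):
    """Collinear triple or coincident origins: no frame can be built."""


@dataclass(frozen=True)
class VectorPairDef:
    """An atom triple defining a residue's orientation descriptor."""

    vp_type: int          # integer id in [0, 20)
    residue_scope: str    # residue name, or "backbone" (all residues)
    atoms: tuple[str, str, str]  # (X0, X1, X2)


def _default_defs() -> tuple[VectorPairDef, ...]:
    side = {
        "ARG": ("NE", "NH1", "NH2"),
        "ASN": ("CG", "OD1", "ND2"),
        "ASP": ("CG", "OD1", "OD2"),
        "CYS": ("CB", "SG", "CA"),
        "GLN": ("CD", "OE1", "NE2"),
        "GLU": ("CD", "OE1", "OE2"),
        "HIS": ("CG", "ND1", "CD2"),
        "ILE": ("CB", "CG1", "CG2"),
        "LEU": ("CB", "CD1", "CD2"),
        "LYS": ("CE", "NZ", "CD"),
        "MET": ("SD", "CE", "CG"),
        "PHE": ("CG", "CD1", "CD2"),
        "PRO": ("CG", "CB", "CD"),
        "SER": ("CB", "OG", "CA"),
        "THR": ("CB", "OG1", "CG2"),
        "TRP": ("CD2", "CZ2", "CE3"),
        "TYR": ("CZ", "OH", "CE1"),
        "VAL": ("CB", "CG1", "CG2"),
    }
    defs = [VectorPairDef(i, res, side[res])
            for i, res in enumerate(sorted(side))]
    defs.append(VectorPairDef(18, "backbone", ("N", "CA", "C")))
    defs.append(VectorPairDef(19, "backbone", ("CA", "C", "O")))
    return tuple(defs)


DEFAULT_VECTOR_PAIRS: tuple[VectorPairDef, ...] = _default_defs()
N_VECTOR_PAIR_TYPES = len(DEFAULT_VECTOR_PAIRS)
assert N_VECTOR_PAIR_TYPES == 20


def load_vector_pairs(path) -> tuple[VectorPairDef, ...]:
    """Read vector-pair definitions from TSV (residue, X0, X1, X2, vp_type)."""
    defs = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        res, x0, x1, x2, vp = line.split("\t")
        defs.append(VectorPairDef(int(vp), res, (x0, x1, x2)))
    if len({d.vp_type for d in defs}) != len(defs):
        raise ValueError("duplicate vp_type in vector-pair file")
    return tuple(defs)


def save_vector_pairs(defs, path) -> None:
    with open(path, "w") as fh:
        fh.write("# residue\tX0\tX1\tX2\tvp_type\n")
        for d in defs:
            fh.write(f"{d.residue_scope}\t{d.atoms[0]}\t{d.atoms[1]}"
                     f"\t{d.atoms[2]}\t{d.vp_type}\n")


# ---------------------------------------------------------------------------
# Geometry: frames, direction bins, torsions
# ---------------------------------------------------------------------------

_COLLINEAR_TOL = 1e-8


def build_frame(p0, p1, p2) -> np.ndarray:
    """Right-handed orthonormal frame of an atom triple.

    z along X0->X1; x is the component of X0->X2 orthogonal to z;
    y = z cross x.  Returns a 3x3 matrix whose ROWS are (x, y, z), so that
    ``frame @ v`` expresses a world vector v in the local frame.
    """
    p0, p1, p2 = (np.asarray(p, dtype=float) for p in (p0, p1, p2))
    z = p1 - p0
    nz = np.linalg.norm(z)
    if nz < _COLLINEAR_TOL:
        raise DegenerateGeometryError("X0 and X1 coincide")
    z = z / nz
    v = p2 - p0
    x = v - (v @ z) * z
    nx = np.linalg.norm(x)
    if nx < _COLLINEAR_TOL or np.linalg.norm(np.cross(p1 - p0, v)) < _COLLINEAR_TOL:
        raise DegenerateGeometryError("collinear atom triple")
    x = x / nx
    return np.stack([x, np.cross(z, x), z])


def _frames_batch(p0, p1, p2):
    """Vectorized build_frame; returns (frames (m,3,3), valid mask)."""
    z = p1 - p0
    nz = np.linalg.norm(z, axis=-1, keepdims=True)
    valid = nz[:, 0] > _COLLINEAR_TOL
    z = np.divide(z, np.where(nz > 0, nz, 1.0))
    v = p2 - p0
    x = v - np.sum(v * z, axis=-1, keepdims=True) * z
    nx = np.linalg.norm(x, axis=-1, keepdims=True)
    valid &= nx[:, 0] > _COLLINEAR_TOL
    x = np.divide(x, np.where(nx > 0, nx, 1.0))
    y = np.cross(z, x)
    return np.stack([x, y, z], axis=1), valid


# Latitude band edges (polar angle theta).
_THETA_EDGES = np.array([np.pi / 6, np.pi / 3, 2 * np.pi / 3, 5 * np.pi / 6])
_PHI_ORIGIN = np.pi / 8  # first azimuth sector opens at pi/8


def direction_bins(theta, phi) -> np.ndarray:
    """Vectorized 26-bin direction index for arrays of (theta, phi)."""
    theta = np.asarray(theta, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if np.any((theta < 0) | (theta > np.pi)):
        raise ValueError("theta out of [0, pi]")
    if np.any((phi < 0) | (phi >= 2 * np.pi)):
        raise ValueError("phi out of [0, 2 pi)")
    sector = (np.floor(((phi - _PHI_ORIGIN) % (2 * np.pi)) / (np.pi / 4))
              .astype(np.intp) % 8)
    band = np.searchsorted(_THETA_EDGES, theta, side="right")
    out = np.empty(theta.shape, dtype=np.intp)
    out[band == 0] = 0                       # north polar cap
    out[band == 4] = 1                       # south polar cap
    mid = (band >= 1) & (band <= 3)
    out[mid] = 2 + (band[mid] - 1) * 8 + sector[mid]
    return out


def direction_bin(theta: float, phi: float) -> int:
    """Direction bin of spherical angles: 2 polar caps (theta < pi/6 or
    theta > 5 pi/6) plus 3 latitude bands x 8 half-open azimuth sectors of
    width pi/4 starting at phi = pi/8 (the last sector wraps through 2 pi).
    """
    return int(direction_bins(np.atleast_1d(theta), np.atleast_1d(phi))[0])


def _direction_ref() -> np.ndarray:
    cap = (1.0 - np.cos(np.pi / 6)) / 2.0
    outer = (np.cos(np.pi / 6) - np.cos(np.pi / 3)) / 2.0 / 8.0
    equator = (np.cos(np.pi / 3) - np.cos(2 * np.pi / 3)) / 2.0 / 8.0
    p = np.empty(N_DIRECTION_BINS)
    p[0] = p[1] = cap
    p[2:10] = outer
    p[10:18] = equator
    p[18:26] = outer
    p.setflags(write=False)
    return p


#: Surface-area fraction of each of the 26 direction bins (sums to 1).
DIRECTION_REF_PROBS = _direction_ref()
TORSION_REF_PROB = 1.0 / N_TORSION_BINS


def reference_probability(bin: int) -> float:
    """Reference probability (sphere surface-area fraction) of one
    direction bin."""
    if not 0 <= bin < N_DIRECTION_BINS:
        raise ValueError(f"direction bin {bin} out of range")
    return float(DIRECTION_REF_PROBS[bin])


def orientation_reference_probs() -> np.ndarray:
    """(2704,) reference probability of every orientation bin: the product
    of the two direction-bin probabilities and 1/4 for the torsion."""
    p = (DIRECTION_REF_PROBS[:, None, None]
         * DIRECTION_REF_PROBS[None, :, None]
         * np.full(N_TORSION_BINS, TORSION_REF_PROB)[None, None, :])
    return p.reshape(-1)


@dataclass(frozen=True)
class OrientationBin:
    dir_ab: int
    dir_ba: int
    torsion: int

    @property
    def flat_index(self) -> int:
        return (self.dir_ab * N_DIRECTION_BINS + self.dir_ba) \
            * N_TORSION_BINS + self.torsion

    @classmethod
    def from_flat(cls, flat: int) -> "OrientationBin":
        d, t = divmod(flat, N_TORSION_BINS)
        a, b = divmod(d, N_DIRECTION_BINS)
        return cls(a, b, t)


def _dihedral_batch(p1, p2, p3, p4) -> np.ndarray:
    """IUPAC-signed dihedral p1-p2-p3-p4, mapped to [0, 2 pi)."""
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = b2 / np.linalg.norm(b2, axis=-1, keepdims=True)
    x = np.sum(n1 * n2, axis=-1)
    y = np.sum(np.cross(n1, n2) * b2n, axis=-1)
    return np.arctan2(y, x) % (2 * np.pi)


def _descriptor_batch(a_pos, b_pos):
    """Orientation descriptors for batches of triples.

    a_pos, b_pos: (m, 3, 3) arrays of (X0, X1, X2) positions.
    Returns (flat (m,), valid (m,)).
    """
    fa, va = _frames_batch(a_pos[:, 0], a_pos[:, 1], a_pos[:, 2])
    fb, vb = _frames_batch(b_pos[:, 0], b_pos[:, 1], b_pos[:, 2])
    v = b_pos[:, 0] - a_pos[:, 0]
    nv = np.linalg.norm(v, axis=-1, keepdims=True)
    valid = va & vb & (nv[:, 0] > 1e-6)
    u = np.divide(v, np.where(nv > 0, nv, 1.0))
    ua = np.einsum("mij,mj->mi", fa, u)
    ub = np.einsum("mij,mj->mi", fb, -u)

    def bins_of(w):
        theta = np.arccos(np.clip(w[:, 2], -1.0, 1.0))
        phi = np.arctan2(w[:, 1], w[:, 0]) % (2 * np.pi)
        phi[phi >= 2 * np.pi] = 0.0
        return direction_bins(theta, phi)

    da, db = bins_of(ua), bins_of(ub)
    omega = _dihedral_batch(a_pos[:, 1], a_pos[:, 0], b_pos[:, 0], b_pos[:, 1])
    t = np.minimum((omega // (np.pi / 2)).astype(np.intp), N_TORSION_BINS - 1)
    flat = (da * N_DIRECTION_BINS + db) * N_TORSION_BINS + t
    return flat, valid


def relative_orientation(a_triple, b_triple) -> OrientationBin:
    """Orientation bin of vector-pair instance A relative to B.

    a_triple/b_triple are (3, 3) arrays of (X0, X1, X2) positions.
    """
    a = np.asarray(a_triple, dtype=float)[None]
    b = np.asarray(b_triple, dtype=float)[None]
    # scalar path validates geometry loudly
    build_frame(*a[0])
    build_frame(*b[0])
    if np.linalg.norm(b[0, 0] - a[0, 0]) < 1e-6:
        raise DegenerateGeometryError("vector-pair origins coincide")
    flat, _ = _descriptor_batch(a, b)
    return OrientationBin.from_flat(int(flat[0]))


def in_contact(res_a: Residue, res_b: Residue,
               cutoff: float = DEFAULT_CONTACT_CUTOFF) -> bool:
    """True iff any heavy-atom pair across the residues is closer than
    *cutoff* (strict)."""
    pa = np.array([a.position for a in res_a.atoms])
    pb = np.array([a.position for a in res_b.atoms])
    return bool(cdist(pa, pb).min() < cutoff)


# ---------------------------------------------------------------------------
# Instance enumeration, training, scoring
# ---------------------------------------------------------------------------

@dataclass
class OrientationPotential:
    """Trained orientation energy table over (vp A, vp B, orientation bin)."""

    energy: np.ndarray                      # (20, 20, 2704), kT
    ref_prob: np.ndarray = field(
        default_factory=orientation_reference_probs)  # (2704,), sums to 1
    contact_cutoff: float = DEFAULT_CONTACT_CUTOFF
    w_orient: float = DEFAULT_W_ORIENT
    cap: float = DEFAULT_CAP
    min_separation: int = DEFAULT_MIN_SEPARATION
    n_structures: int = 0


def _instances(structure: TypedStructure, defs):
    """All vector-pair instances of a structure.

    Returns (res_idx (m,), vp_type (m,), triples (m, 3, 3)); residues
    lacking a required atom are skipped with a log entry.
    """
    res_idx, vp_type, triples = [], [], []
    for res in structure.residues:
        for d in defs:
            if d.residue_scope != "backbone" and d.residue_scope != res.name:
                continue
            atoms = [res.atom(name) for name in d.atoms]
            if any(a is None for a in atoms):
                logger.debug("residue %d %s lacks atoms for vp %d",
                             res.index, res.name, d.vp_type)
                continue
            res_idx.append(res.index)
            vp_type.append(d.vp_type)
            triples.append(np.stack([a.position for a in atoms]))
    if not res_idx:
        return (np.empty(0, np.intp), np.empty(0, np.intp),
                np.empty((0, 3, 3)))
    return (np.asarray(res_idx, np.intp), np.asarray(vp_type, np.intp),
            np.stack(triples))


def _contacting_residue_pairs(structure: TypedStructure, cutoff: float,
                              min_separation: int) -> np.ndarray:
    """(k, 2) residue-index pairs (i < j) in contact with |i-j| >= sep."""
    coords = structure.coords
    ridx = structure.residue_indices
    pairs = cKDTree(coords).query_pairs(cutoff, output_type="ndarray")
    if len(pairs) == 0:
        return np.empty((0, 2), np.intp)
    dist = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
    pairs = pairs[dist < cutoff]
    r = np.sort(ridx[pairs], axis=1)
    r = r[r[:, 1] - r[:, 0] >= min_separation]
    return np.unique(r, axis=0)


def _combo_arrays(structure, defs, cutoff, min_separation):
    """Instance-pair combinations over contacting residue pairs.

    Returns (typeA, typeB, a_pos, b_pos) with A on the lower residue index.
    """
    ridx, vtype, triples = _instances(structure, defs)
    pairs = _contacting_residue_pairs(structure, cutoff, min_separation)
    if len(pairs) == 0 or len(ridx) == 0:
        z = np.empty(0, np.intp)
        return z, z, np.empty((0, 3, 3)), np.empty((0, 3, 3))
    by_res: dict[int, np.ndarray] = {}
    for r in np.unique(ridx):
        by_res[int(r)] = np.flatnonzero(ridx == r)
    ia_all, ib_all = [], []
    for i, j in pairs:
        ia = by_res.get(int(i))
        ib = by_res.get(int(j))
        if ia is None or ib is None:
            continue
        g = np.meshgrid(ia, ib, indexing="ij")
        ia_all.append(g[0].ravel())
        ib_all.append(g[1].ravel())
    if not ia_all:
        z = np.empty(0, np.intp)
        return z, z, np.empty((0, 3, 3)), np.empty((0, 3, 3))
    ia = np.concatenate(ia_all)
    ib = np.concatenate(ib_all)
    return vtype[ia], vtype[ib], triples[ia], triples[ib]


def train_orientation(structures: list[TypedStructure],
                      defs=DEFAULT_VECTOR_PAIRS,
                      contact_cutoff: float = DEFAULT_CONTACT_CUTOFF,
                      cap: float = DEFAULT_CAP,
                      min_separation: int = DEFAULT_MIN_SEPARATION,
                      w_orient: float = DEFAULT_W_ORIENT,
                      return_counts: bool = False):
    """Train the orientation potential on a set of typed structures.

    Observed counts are accumulated in both orders (A, B, O_AB) and
    (B, A, O_BA) for every contacting non-consecutive residue pair, so the
    table is symmetric under the swap transformation.  Expected counts for
    a vector-pair type combination distribute its total observed count
    over the 2704 bins by the analytic reference probabilities.
    """
    if not structures:
        raise ValueError("empty training set")
    nvp = max(d.vp_type for d in defs) + 1
    counts = np.zeros((nvp, nvp, N_ORIENTATION_BINS))
    for s in structures:
        ta, tb, a_pos, b_pos = _combo_arrays(s, defs, contact_cutoff,
                                             min_separation)
        if len(ta) == 0:
            continue
        flat_ab, valid = _descriptor_batch(a_pos, b_pos)
        flat_ba, valid_ba = _descriptor_batch(b_pos, a_pos)
        keep = valid & valid_ba
        n_skip = int((~keep).sum())
        if n_skip:
            logger.info("skipped %d degenerate vector-pair combos", n_skip)
        np.add.at(counts, (ta[keep], tb[keep], flat_ab[keep]), 1.0)
        np.add.at(counts, (tb[keep], ta[keep], flat_ba[keep]), 1.0)

    ref = orientation_reference_probs()
    totals = counts.sum(axis=-1, keepdims=True)
    expected = totals * ref[None, None, :]
    energy = np.zeros_like(counts)
    seen = expected > 0
    both = seen & (counts > 0)
    energy[both] = -np.log(counts[both] / expected[both])
    energy[seen & (counts == 0)] = cap
    np.minimum(energy, cap, out=energy)
    pot = OrientationPotential(energy, ref, contact_cutoff, w_orient, cap,
                               min_separation, n_structures=len(structures))
    if return_counts:
        return pot, counts
    return pot


def score_orientation(structure: TypedStructure,
                      potential: OrientationPotential,
                      defs=DEFAULT_VECTOR_PAIRS) -> float:
    """Total orientation energy of a structure, kT (unweighted).

    Sums the table energy over every unordered vector-pair instance
    combination of contacting, non-consecutive residues (A taken on the
    lower residue index).
    """
    ta, tb, a_pos, b_pos = _combo_arrays(
        structure, defs, potential.contact_cutoff, potential.min_separation)
    if len(ta) == 0:
        return 0.0
    flat, valid = _descriptor_batch(a_pos, b_pos)
    return float(potential.energy[ta[valid], tb[valid], flat[valid]].sum())


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

def save_orientation_table(pot: OrientationPotential, path) -> None:
    path = Path(path)
    a, b, k = np.nonzero(pot.energy)
    with open(path, "w") as fh:
        fh.write("# kind=orientation\n")
        fh.write(f"# contact_cutoff={pot.contact_cutoff!r}\n")
        fh.write(f"# w_orient={pot.w_orient!r}\n")
        fh.write(f"# cap={pot.cap!r}\n")
        fh.write(f"# min_separation={pot.min_separation}\n")
        fh.write(f"# n_structures={pot.n_structures}\n")
        fh.write(f"# typing={typing_hash()}\n")
        fh.write("# columns=vp_a\tvp_b\tflat_bin\tenergy\n")
        for ia, ib, ik in zip(a, b, k):
            fh.write(f"{ia}\t{ib}\t{ik}\t{float(pot.energy[ia, ib, ik])!r}\n")
        fh.write("# end\n")


def load_orientation_table(path) -> OrientationPotential:
    from .distance_potential import TableCompatibilityError, _parse_header
    path = Path(path)
    lines = path.read_text().splitlines()
    meta = _parse_header(lines)
    if meta.get("kind") != "orientation":
        raise ValueError(f"{path}: not an orientation table")
    if meta.get("typing") != typing_hash():
        raise TableCompatibilityError(f"{path}: typing scheme mismatch")
    if lines[-1].strip() != "# end":
        raise ValueError(f"{path}: truncated table (missing end marker)")
    energy = np.zeros((N_VECTOR_PAIR_TYPES, N_VECTOR_PAIR_TYPES,
                       N_ORIENTATION_BINS))
    for line in lines:
        if line.startswith("#") or not line.strip():
            continue
        fa, fb, fk, fv = line.split("\t")
        energy[int(fa), int(fb), int(fk)] = float(fv)
    return OrientationPotential(
        energy,
        contact_cutoff=float(meta["contact_cutoff"]),
        w_orient=float(meta["w_orient"]),
        cap=float(meta["cap"]),
        min_separation=int(meta["min_separation"]),
        n_structures=int(meta.get("n_structures", 0)),
    )
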