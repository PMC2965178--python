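"""Distance-dependent atomic statistical potential with a random-walk
reference state.

Observed atom-pair counts are taken from a training set, binned by distance
(half-open 0.5 A shells up to the cutoff R0).  Expected counts for each
structure are the random-walk shell weights for that structure's own chain
length, scaled so that observed and expected agree at the cutoff: the
potential is defined only up to this anchoring, and anchoring at R0 makes
the energy of every pair type vanish in the shell containing R0.  The
energy, in kT units (kT = 1 here), is

    E(a, b, shell) = -ln( N_obs(a, b, shell) / N_exp(a, b, shell) ),

with unobserved shells of otherwise-observed pairs set to a finite cap and
pair types that never reach the anchoring region left flat at zero
(uninformative).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .atom_types import N_ATOM_TYPES, typing_hash
from .rw_reference import RWParams, shell_weights
from .structures_io import TypedStructure

__all__ = [
    "PairCountTable",
    "DistancePotential",
    "TableCompatibilityError",
    "count_pairs",
    "train",
    "score_rw",
    "save_table",
    "load_table",
]

DEFAULT_MIN_SEPARATION = 2  # exclude intra-residue and consecutive residues
DEFAULT_CAP = 10.0          # kT, assigned to unobserved shells
ANCHOR_FALLBACK_BINS = 4    # outer 2 A used when the top shell is empty


class TableCompatibilityError(ValueError):
    """A stored table does not match the current parameters or typing."""


@dataclass
class PairCountTable:
    """Symmetric observed pair counts over (type a, type b, shell).

    Stored symmetrically: every unordered pair increments both (a, b, k)
    and (b, a, k), so the array total is twice the number of pairs (a
    same-type pair adds 2 to its single cell).
    """

    counts: np.ndarray  # (158, 158, n_bins)
    n_structures: int
    params: RWParams

    def __post_init__(self):
        expected = (N_ATOM_TYPES, N_ATOM_TYPES, self.params.n_bins)
        if self.counts.shape != expected:
            raise ValueError(f"counts shape {self.counts.shape} != {expected}")

    @property
    def n_pairs(self) -> float:
        return float(self.counts.sum() / 2.0)

    def __iadd__(self, other: "PairCountTable"):
        if other.params != self.params:
            raise TableCompatibilityError("cannot merge: parameter mismatch")
        self.counts += other.counts
        self.n_structures += other.n_structures
        return self


@dataclass
class DistancePotential:
    """Trained energy table E(a, b, shell) in kT units."""

    energy: np.ndarray  # (158, 158, n_bins)
    params: RWParams
    cap: float = DEFAULT_CAP
    min_separation: int = DEFAULT_MIN_SEPARATION
    n_structures: int = 0


def _eligible_pairs(structure: TypedStructure, R0: float,
                    min_separation: int):
    """Unordered heavy-atom pairs with |i-j| >= min_separation, dist < R0.

    Returns (type_a, type_b, dist) arrays, one row per unordered pair.
    """
    coords = structure.coords
    if coords.shape[0] == 0:
        z = np.empty(0, dtype=np.intp)
        return z, z, np.empty(0)
    pairs = cKDTree(coords).query_pairs(R0, output_type="ndarray")
    if len(pairs) == 0:
        z = np.empty(0, dtype=np.intp)
        return z, z, np.empty(0)
    i, j = pairs[:, 0], pairs[:, 1]
    ridx = structure.residue_indices
    keep = np.abs(ridx[i] - ridx[j]) >= min_separation
    i, j = i[keep], j[keep]
    dist = np.linalg.norm(coords[i] - coords[j], axis=1)
    strict = dist < R0  # half-open upper bound
    i, j, dist = i[strict], j[strict], dist[strict]
    t = structure.type_ids
    return t[i], t[j], dist


def count_pairs(structure: TypedStructure, params: RWParams,
                min_separation: int = DEFAULT_MIN_SEPARATION) -> PairCountTable:
    """Observed pair counts of a single structure."""
    if structure.n_atoms == 0:
        raise ValueError("empty structure")
    ta, tb, dist = _eligible_pairs(structure, params.R0, min_separation)
    k = params.bin_of(dist)
    counts = np.zeros((N_ATOM_TYPES, N_ATOM_TYPES, params.n_bins))
    np.add.at(counts, (ta, tb, k), 1.0)
    np.add.at(counts, (tb, ta, k), 1.0)
    return PairCountTable(counts, 1, params)


def _expected_counts(obs: np.ndarray, N: int, params: RWParams,
                     min_separation: int = DEFAULT_MIN_SEPARATION) -> np.ndarray:
    """Per-structure expected counts, anchored to the observed cutoff shell.

    The random-walk shell weights for chain length N give the shape; the
    scale comes from the observed count in the top shell, falling back to
    the outer 2 A when that shell is empty for a pair type.  The
    reference sum starts at the same minimum sequence separation used for
    counting, so observed and expected describe the same pair population.
    """
    w = shell_weights(N, params, n_min=min(min_separation, N - 1) if N > 1 else 1)
    anchor = obs[:, :, -1]
    tail = obs[:, :, -ANCHOR_FALLBACK_BINS:].sum(axis=-1)
    w_tail = w[-ANCHOR_FALLBACK_BINS:].sum()
    scale = np.where(anchor > 0, anchor / w[-1],
                     np.where(tail > 0, tail / w_tail, 0.0))
    return scale[:, :, None] * w[None, None, :]


def train(structures: list[TypedStructure], params: RWParams,
          min_separation: int = DEFAULT_MIN_SEPARATION,
          cap: float = DEFAULT_CAP,
          return_counts: bool = False):
    """Train the distance potential on a set of typed structures.

    Expected counts are built structure by structure because the reference
    depends on each chain's own length N.
    """
    if not structures:
        raise ValueError("empty training set")
    shape = (N_ATOM_TYPES, N_ATOM_TYPES, params.n_bins)
    obs_tot = np.zeros(shape)
    exp_tot = np.zeros(shape)
    for s in structures:
        obs = count_pairs(s, params, min_separation).counts
        obs_tot += obs
        exp_tot += _expected_counts(obs, len(s), params, min_separation)

    energy = np.zeros(shape)
    seen = exp_tot > 0
    both = seen & (obs_tot > 0)
    with np.errstate(divide="ignore"):
        energy[both] = -np.log(obs_tot[both] / exp_tot[both])
    energy[seen & (obs_tot == 0)] = cap
    np.minimum(energy, cap, out=energy)
    pot = DistancePotential(energy, params, cap=cap,
                            min_separation=min_separation,
                            n_structures=len(structures))
    if return_counts:
        return pot, PairCountTable(obs_tot, len(structures), params)
    return pot


def score_rw(structure: TypedStructure, potential: DistancePotential,
             min_separation: int | None = None) -> float:
    """Total distance-potential energy of a structure, kT.

    Sums the table energy over every unordered heavy-atom pair with
    residue separation >= min_separation and distance < R0.  Depends on
    inter-atomic distances only, hence invariant to rigid motion.
    """
    if min_separation is None:
        min_separation = potential.min_separation
    ta, tb, dist = _eligible_pairs(structure, potential.params.R0,
                                   min_separation)
    if len(dist) == 0:
        return 0.0
    k = potential.params.bin_of(dist)
    return float(potential.energy[ta, tb, k].sum())


# ---------------------------------------------------------------------------
# Plain-text persistence
# ---------------------------------------------------------------------------

def _header(kind: str, params: RWParams, **extra) -> str:
    items = {
        "kind": kind,
        "lam": repr(params.lam),
        "R0": repr(params.R0),
        "dR": repr(params.dR),
        "aggregation": params.aggregation,
        "typing": typing_hash(),
        **{k: repr(v) if isinstance(v, float) else str(v)
           for k, v in extra.items()},
    }
    return "".join(f"# {k}={v}\n" for k, v in items.items())


def save_table(obj: PairCountTable | DistancePotential, path) -> None:
    """Write a count or potential table as sparse TSV with a header."""
    path = Path(path)
    if isinstance(obj, PairCountTable):
        head = _header("counts", obj.params, n_structures=obj.n_structures)
        arr = obj.counts
    elif isinstance(obj, DistancePotential):
        head = _header("potential", obj.params, cap=obj.cap,
                       min_separation=obj.min_separation,
                       n_structures=obj.n_structures)
        arr = obj.energy
    else:
        raise TypeError(type(obj))
    a, b, k = np.nonzero(arr)
    with open(path, "w") as fh:
        fh.write(head)
        fh.write("# columns=type_a\ttype_b\tbin\tvalue\n")
        for ia, ib, ik in zip(a, b, k):
            fh.write(f"{ia}\t{ib}\t{ik}\t{float(arr[ia, ib, ik])!r}\n")
        fh.write("# end\n")


def _parse_header(lines) -> dict[str, str]:
    meta = {}
    for line in lines:
        if not line.startswith("#"):
            break
        body = line[1:].strip()
        if "=" in body:
            key, val = body.split("=", 1)
            meta[key.strip()] = val.strip()
    return meta


def load_table(path, params: RWParams | None = None):
    """Load a table written by :func:`save_table`.

    Raises :class:`TableCompatibilityError` when the stored parameters or
    typing scheme do not match *params* / the current typing map.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    meta = _parse_header(lines)
    for key in ("kind", "lam", "R0", "dR", "aggregation", "typing"):
        if key not in meta:
            raise ValueError(f"{path}: missing header field {key!r}")
    stored = RWParams(lam=float(meta["lam"]), R0=float(meta["R0"]),
                      dR=float(meta["dR"]), aggregation=meta["aggregation"])
    if params is not None and stored != params:
        raise TableCompatibilityError(
            f"{path}: table parameters {stored} != session parameters {params}")
    if meta["typing"] != typing_hash():
        raise TableCompatibilityError(f"{path}: typing scheme mismatch")
    if lines[-1].strip() != "# end":
        raise ValueError(f"{path}: truncated table (missing end marker)")
    arr = np.zeros((N_ATOM_TYPES, N_ATOM_TYPES, stored.n_bins))
    for line in lines:
        if line.startswith("#") or not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 4:
            raise ValueError(f"{path}: malformed row {line!r}")
        a, b, k = int(fields[0]), int(fields[1]), int(fields[2])
        arr[a, b, k] = float(fields[3])
    if meta["kind"] == "counts":
        return PairCountTable(arr, int(meta["n_structures"]), stored)
    if meta["kind"] == "potential":
        return DistancePotential(arr, stored, cap=float(meta["cap"]),
                                 min_separation=int(meta["min_separation"]),
                                 n_structures=int(meta.get("n_structures", 0)))
    raise ValueError(f"{path}: unknown table kind {meta['kind']!r}")
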