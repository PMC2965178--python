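"""Synthetic training and decoy sets with known statistical structure.

Desk-scale stand-ins for a curated experimental structure library.  Three
kinds of object are generated, all bit-reproducible under a fixed seed:

* Gaussian-chain "structures": residue centers follow an ideal random
  walk whose step statistics match the reference state's Kuhn length, and
  each residue's atoms are a rigid template in an iid uniformly random
  orientation.  Atom pairs of residues i, j are then distributed (up to
  the small intra-residue offsets) exactly like the chain reference at
  separation n = |i - j| -- with the pair multiplicity N - n per
  separation, i.e. the "multiplicity" aggregation of the reference.
  Training on these chains should therefore recover a flat (zero)
  potential; an injected pair-distance bias should surface as an energy
  minimum in the biased shell.

* Contact-pair sets for the orientation term: isolated residue pairs in
  contact, either in iid uniformly random relative orientation (flat
  orientation energies expected) or pinned to one target orientation bin.

* Perturbation decoys: iid Gaussian coordinate noise of a given sigma
  applied to a native, with the true C-alpha RMSD ladder emitted
  alongside.

These generators emulate pair statistics, not protein chemistry: no
excluded volume between residues, no rotamers, no secondary structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .atom_types import RESIDUE_HEAVY_ATOMS, STANDARD_RESIDUES, atom_type
from .orientation_potential import (DEFAULT_VECTOR_PAIRS, OrientationBin,
                                    _THETA_EDGES, _PHI_ORIGIN, build_frame,
                                    relative_orientation)
from .rw_reference import RWParams
from .scoring_eval import kabsch_rmsd
from .structures_io import (Residue, TypedAtom, TypedStructure, _place,
                            _build_residue_atoms, perturb)

__all__ = [
    "PairBias",
    "OrientationBias",
    "SyntheticSpec",
    "make_training_set",
    "make_orientation_set",
    "make_decoy_set",
    "residue_template",
    "place_pair_in_bin",
    "direction_bin_center",
]


@dataclass(frozen=True)
class PairBias:
    """Pin some (atom_a, atom_b) distances to a preferred value."""

    residue_a: str
    atom_a: str
    residue_b: str
    atom_b: str
    distance: float       # A, must be < R0
    strength: float = 0.2  # fraction of residues recruited into pinned pairs
    jitter: float = 0.1   # A, Gaussian spread around the preferred distance


@dataclass(frozen=True)
class OrientationBias:
    """Pin contact-pair orientations to one target bin."""

    residue_a: str
    residue_b: str
    target: OrientationBin
    strength: float = 1.0  # fraction of pairs pinned (rest left random)


@dataclass(frozen=True)
class SyntheticSpec:
    n_structures: int = 20
    length: int = 50
    pair_bias: PairBias | None = None
    orientation_bias: OrientationBias | None = None
    noise_sigmas: tuple[float, ...] = (0.5, 1.0, 2.0, 4.0)
    seed: int = 0
    #: Uniform scale of the rigid residue templates.  1.0 keeps real
    #: covalent geometry; small values collapse each residue onto its
    #: chain node, making the atom-pair distance distribution equal the
    #: node (chain-reference) distribution exactly.  Directions are
    #: preserved, so orientation statistics are unaffected.
    template_scale: float = 1.0


# ---------------------------------------------------------------------------
# Rigid residue templates
# ---------------------------------------------------------------------------

def residue_template(name: str, scale: float = 1.0) -> tuple[list[str], np.ndarray]:
    """Canonical rigid template of a residue: (atom names, (m, 3) coords
    centered on CA), optionally scaled about CA."""
    if name not in STANDARD_RESIDUES:
        raise ValueError(f"non-standard residue {name!r}")
    n = np.array([1.458, 0.0, 0.0])
    ca = np.zeros(3)
    c = 1.525 * np.array([math.cos(math.radians(111.0)),
                          math.sin(math.radians(111.0)), 0.0])
    pos = _build_residue_atoms(name, n, ca, c)
    pos["O"] = _place(n, ca, c, 1.231, 120.8, 0.0)
    names = list(RESIDUE_HEAVY_ATOMS[name])
    return names, scale * np.stack([pos[a] for a in names])


def _make_residue(index: int, name: str, coords: np.ndarray,
                  names: list[str]) -> Residue:
    atoms = [TypedAtom(index, name, a, atom_type(name, a),
                       np.round(p, 3))
             for a, p in zip(names, coords)]
    return Residue(index, name, atoms)


def _placed_residue(index: int, name: str, center: np.ndarray,
                    rotation: np.ndarray, scale: float = 1.0,
                    anchor_atom: str = "CA") -> Residue:
    """Rigid template at *center*, rotated about *anchor_atom* (which is
    placed exactly at the center)."""
    names, tpl = residue_template(name, scale)
    tpl = tpl - tpl[names.index(anchor_atom)]
    return _make_residue(index, name, center + tpl @ rotation.T, names)


# ---------------------------------------------------------------------------
# Gaussian-chain training structures
# ---------------------------------------------------------------------------

def make_training_set(spec: SyntheticSpec,
                      params: RWParams | None = None) -> list[TypedStructure]:
    """Generate Gaussian-chain training structures per *spec*.

    Without biases, residue centers perform an ideal random walk with
    step variance lam per step (lam from *params*), so inter-residue
    distances follow the chain reference at every separation.  With a
    :class:`PairBias`, disjoint residue pairs are re-typed to the biased
    residues and translated so the biased atom-atom distance concentrates
    at the preferred value.
    """
    params = params or RWParams()
    bias = spec.pair_bias
    if bias is not None and bias.distance >= params.R0:
        raise ValueError(
            f"pair bias distance {bias.distance} A is outside the "
            f"interaction cutoff {params.R0} A")
    rng = np.random.default_rng(spec.seed)
    structures = []
    for _ in range(spec.n_structures):
        structures.append(_one_chain(spec, params, rng))
    return structures


def _one_chain(spec: SyntheticSpec, params: RWParams,
               rng: np.random.Generator) -> TypedStructure:
    N = spec.length
    steps = rng.normal(0.0, math.sqrt(params.lam / 3.0), size=(N - 1, 3))
    centers = np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])
    rotations = Rotation.random(N, rng=rng).as_matrix()
    names = ["GLY"] * N

    pinned: dict[int, np.ndarray] = {}
    bias = spec.pair_bias
    if bias is not None:
        n_pairs = max(1, int(round(bias.strength * N / 4.0)))
        chosen = rng.choice(N, size=2 * n_pairs, replace=False)
        for k in range(n_pairs):
            i, j = int(chosen[2 * k]), int(chosen[2 * k + 1])
            if abs(i - j) < 2:   # consecutive pairs are never counted
                continue
            names[i], names[j] = bias.residue_a, bias.residue_b
            d = bias.distance + rng.normal(0.0, bias.jitter)
            u = _random_unit(rng)
            # translate residue j so atom_b sits at distance d from atom_a
            na, ta = residue_template(bias.residue_a, spec.template_scale)
            nb, tb = residue_template(bias.residue_b, spec.template_scale)
            pa = centers[i] + ta[na.index(bias.atom_a)] @ rotations[i].T
            off_b = tb[nb.index(bias.atom_b)] @ rotations[j].T
            pinned[j] = pa + d * u - off_b

    residues = []
    for i in range(N):
        c = pinned.get(i, centers[i])
        residues.append(_placed_residue(i, names[i], c, rotations[i],
                                        spec.template_scale))
    return TypedStructure("A", residues)


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


# ---------------------------------------------------------------------------
# Orientation contact-pair sets
# ---------------------------------------------------------------------------

def direction_bin_center(bin: int) -> tuple[float, float]:
    """Representative (theta, phi) inside a direction bin."""
    if bin == 0:
        return np.pi / 12, 0.0
    if bin == 1:
        return np.pi - np.pi / 12, 0.0
    band, sector = divmod(bin - 2, 8)
    edges = np.concatenate([[0.0], _THETA_EDGES, [np.pi]])
    theta = 0.5 * (edges[band + 1] + edges[band + 2])
    phi = (_PHI_ORIGIN + (sector + 0.5) * np.pi / 4) % (2 * np.pi)
    return float(theta), float(phi)


def _sph(theta: float, phi: float) -> np.ndarray:
    return np.array([math.sin(theta) * math.cos(phi),
                     math.sin(theta) * math.sin(phi),
                     math.cos(theta)])


def _align(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation matrix sending unit vector a to unit vector b."""
    return Rotation.align_vectors(b[None], a[None])[0].as_matrix()


def _triple_of(res: Residue, defs) -> tuple[int, np.ndarray]:
    for d in defs:
        if d.residue_scope == res.name or \
                (d.residue_scope == "backbone" and d.vp_type == 18):
            if d.residue_scope == "backbone" and res.name not in ("GLY", "ALA"):
                continue
            atoms = [res.atom(nm) for nm in d.atoms]
            if all(a is not None for a in atoms):
                return d.vp_type, np.stack([a.position for a in atoms])
    raise ValueError(f"no vector pair for residue {res.name}")


def place_pair_in_bin(residue_a: str, residue_b: str,
                      target: OrientationBin,
                      rng: np.random.Generator,
                      separation: float = 6.0,
                      defs=DEFAULT_VECTOR_PAIRS) -> tuple[Residue, Residue]:
    """Construct two contacting residues whose primary vector-pair
    descriptor falls in *target* (built at the bin centers).

    Residue A gets a random orientation; B's position and orientation are
    then solved so that both direction bins and the torsion bin match.
    """
    ra = _placed_residue(0, residue_a,
                         np.zeros(3), Rotation.random(rng=rng).as_matrix())
    _, ta = _triple_of(ra, defs)
    frame_a = build_frame(*ta)
    th_a, ph_a = direction_bin_center(target.dir_ab)
    v = frame_a.T @ _sph(th_a, ph_a)          # world direction A0 -> B0
    b0 = ta[0] + separation * v

    # initial placement of B, then rotate so dir_ba matches
    rot_b = Rotation.random(rng=rng).as_matrix()
    names_b, tpl_b = residue_template(residue_b)
    rb = _make_residue(2, residue_b, b0 + tpl_b @ rot_b.T, names_b)
    # X0 of B's triple must be at b0: re-anchor the template on the triple
    for d in defs:
        if d.residue_scope == residue_b or \
                (d.residue_scope == "backbone" and residue_b in ("GLY", "ALA")
                 and d.vp_type == 18):
            x0_name = d.atoms[0]
            break
    x0_local = tpl_b[names_b.index(x0_name)]
    coords_b = b0 + (tpl_b - x0_local) @ rot_b.T
    rb = _make_residue(2, residue_b, coords_b, names_b)

    _, tb = _triple_of(rb, defs)
    frame_b = build_frame(*tb)
    th_b, ph_b = direction_bin_center(target.dir_ba)
    w_world = frame_b.T @ _sph(th_b, ph_b)    # direction currently mapping to target
    q = _align(w_world, -v)
    coords_b = b0 + (coords_b - b0) @ q.T
    rb = _make_residue(2, residue_b, coords_b, names_b)

    # fix the torsion by rotating B about the A0-B0 axis
    omega_t = (target.torsion + 0.5) * (np.pi / 2)
    for _ in range(2):
        _, tb = _triple_of(rb, defs)
        ob = relative_orientation(ta, tb)
        if ob == target:
            break
        omega_now = _torsion_angle(ta[1], ta[0], tb[0], tb[1])
        delta = omega_t - omega_now
        rot = Rotation.from_rotvec(delta * v).as_matrix()
        coords_b = b0 + (coords_b - b0) @ rot.T
        rb = _make_residue(2, residue_b, coords_b, names_b)
    _, tb = _triple_of(rb, defs)
    if relative_orientation(ta, tb) != target:
        # torsion sign convention flipped: rotate the other way
        omega_now = _torsion_angle(ta[1], ta[0], tb[0], tb[1])
        coords_b = b0 + (coords_b - b0) @ \
            Rotation.from_rotvec(-2 * (omega_t - omega_now) * v).as_matrix().T
        rb = _make_residue(2, residue_b, coords_b, names_b)
    return ra, rb


def _torsion_angle(p1, p2, p3, p4) -> float:
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    y = np.dot(np.cross(n1, n2), b2 / np.linalg.norm(b2))
    x = np.dot(n1, n2)
    return math.atan2(y, x) % (2 * np.pi)


def make_orientation_set(n_pairs: int,
                         residue_a: str = "GLY", residue_b: str = "GLY",
                         seed: int = 0,
                         bias: OrientationBias | None = None,
                         grid_spacing: float = 60.0,
                         anchor_atom: str = "CA") -> TypedStructure:
    """One structure of *n_pairs* isolated contacting residue pairs.

    Pair k occupies residue indices (k, k + n_pairs), so within-pair
    sequence separation is n_pairs (never consecutive), and pairs sit on
    a coarse 3-D grid so no cross-pair contacts arise.  Orientations are
    iid uniform unless *bias* pins a fraction of pairs to one bin.

    *anchor_atom* is the atom each random rotation pivots about.  The
    analytic product reference (area fractions x 1/4) is exact for a
    vector-pair type whose origin atom X0 is the anchor: then the
    inter-origin direction is independent of both residue orientations.
    For triples whose X0 is elsewhere the lever arm between anchor and X0
    correlates direction with orientation, as it does in real chains.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    rng = np.random.default_rng(seed)
    side = int(math.ceil(n_pairs ** (1.0 / 3.0)))
    first, second = [], []
    for k in range(n_pairs):
        base = grid_spacing * np.array([k % side, (k // side) % side,
                                        k // (side * side)], dtype=float)
        pin = bias is not None and rng.random() < bias.strength
        if pin:
            ra, rb = place_pair_in_bin(bias.residue_a, bias.residue_b,
                                       bias.target, rng)
        else:
            ra = _placed_residue(0, residue_a, np.zeros(3),
                                 Rotation.random(rng=rng).as_matrix(),
                                 anchor_atom=anchor_atom)
            rb = _placed_residue(0, residue_b,
                                 rng.uniform(4.0, 8.0) * _random_unit(rng),
                                 Rotation.random(rng=rng).as_matrix(),
                                 anchor_atom=anchor_atom)
        first.append(_shift(ra, base))
        second.append(_shift(rb, base))
    residues = []
    for k, r in enumerate(first + second):
        residues.append(Residue(k, r.name, [
            TypedAtom(k, a.residue_name, a.atom_name, a.type_id, a.position)
            for a in r.atoms]))
    return TypedStructure("A", residues)


def _shift(res: Residue, offset: np.ndarray) -> Residue:
    return Residue(res.index, res.name, [
        TypedAtom(res.index, a.residue_name, a.atom_name, a.type_id,
                  a.position + offset)
        for a in res.atoms])


# ---------------------------------------------------------------------------
# Perturbation decoys
# ---------------------------------------------------------------------------

def make_decoy_set(native: TypedStructure,
                   sigmas: tuple[float, ...] = (0.5, 1.0, 2.0, 4.0),
                   n_per_sigma: int = 50,
                   seed: int = 0):
    """Perturbation decoys spanning a controlled RMSD ladder.

    Returns (decoys, truth): a dict name -> structure and a DataFrame with
    columns (name, sigma, rmsd) holding the true C-alpha RMSD to native.
    """
    if native.n_atoms == 0:
        raise ValueError("empty native structure")
    rng = np.random.default_rng(seed)
    native_ca = native.ca_coords()
    decoys: dict[str, TypedStructure] = {}
    rows = []
    for sigma in sigmas:
        for i in range(n_per_sigma):
            name = f"decoy_s{sigma:g}_{i:03d}"
            d = perturb(native, sigma, rng)
            decoys[name] = d
            rows.append({"name": name, "sigma": sigma,
                         "rmsd": kabsch_rmsd(d.ca_coords(), native_ca)})
    truth = pd.DataFrame(rows, columns=["name", "sigma", "rmsd"])
    return decoys, truth
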