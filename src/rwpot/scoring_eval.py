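"""Hybrid scoring and decoy-set evaluation.

The hybrid score combines the distance term and the orientation term,

    E_total = E_dist + w_orient * E_orient,

with w_orient = 0.1 by default.  A decoy-set evaluation ranks the native
and decoys by energy and reports native recognition, the native Z-score
(E_native minus the mean energy, over the standard deviation, both taken
over the full set including the native), the best-quality model among the
top-1/5/10 lowest-energy decoys, and Pearson correlations between energy
and quality (C-alpha RMSD and TM-score), native excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .distance_potential import DistancePotential, score_rw
from .orientation_potential import (DEFAULT_VECTOR_PAIRS,
                                    OrientationPotential, score_orientation)
from .structures_io import TypedStructure

__all__ = [
    "DecoyReport",
    "score_rwplus",
    "kabsch_rotation",
    "kabsch_rmsd",
    "tm_score",
    "evaluate_decoy_set",
]


def score_rwplus(structure: TypedStructure,
                 dist_pot: DistancePotential,
                 orient_pot: OrientationPotential | None = None,
                 w_orient: float | None = None,
                 defs=DEFAULT_VECTOR_PAIRS) -> tuple[float, float, float]:
    """(E_dist, E_orient, E_total) of a structure, kT.

    With no orientation potential, E_orient = 0 and the hybrid score
    reduces to the distance term.
    """
    e_rw = score_rw(structure, dist_pot)
    if orient_pot is None:
        return e_rw, 0.0, e_rw
    if w_orient is None:
        w_orient = orient_pot.w_orient
    e_or = score_orientation(structure, orient_pot, defs)
    return e_rw, e_or, e_rw + w_orient * e_or


def kabsch_rotation(P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Optimal proper rotation matrix R minimizing |R P - Q| for centered
    coordinate sets (SVD with reflection correction)."""
    H = P.T @ Q
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    return Vt.T @ D @ U.T


def kabsch_rmsd(P, Q) -> float:
    """RMSD of two equal-length coordinate sets after optimal rigid
    superposition (rotation + translation, no reflection)."""
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("coordinate sets must both be (n, 3)")
    if P.shape[0] < 3:
        raise ValueError("need at least 3 points")
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    R = kabsch_rotation(Pc, Qc)
    diff = Pc @ R.T - Qc
    return float(np.sqrt((diff ** 2).sum() / P.shape[0]))


def tm_score(P, Q, d0: float | None = None, max_iter: int = 20) -> float:
    """Length-normalized structural similarity in (0, 1] for two already
    residue-matched C-alpha sets (P = model, Q = reference).

    TM = max over superpositions of (1/L) sum_i 1 / (1 + (d_i/d0)^2) with
    d0 = 1.24 (L - 15)^(1/3) - 1.8.  This is a fixed-correspondence,
    iterative-superposition approximation (seeded on the whole chain and
    on half-chain fragments), not the canonical dynamic-programming
    program; scores may differ slightly from it.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape:
        raise ValueError("length mismatch")
    L = P.shape[0]
    if d0 is None:
        d0 = 1.24 * (L - 15) ** (1.0 / 3.0) - 1.8 if L > 21 else 0.5
    d0 = max(d0, 0.5)

    def superpose_on(idx: np.ndarray) -> float:
        sel = idx
        best = 0.0
        for _ in range(max_iter):
            pm, qm = P[sel].mean(0), Q[sel].mean(0)
            R = kabsch_rotation(P[sel] - pm, Q[sel] - qm)
            d = np.linalg.norm((P - pm) @ R.T - (Q - qm), axis=1)
            score = float(np.sum(1.0 / (1.0 + (d / d0) ** 2)) / L)
            best = max(best, score)
            new_sel = np.flatnonzero(d < d0)
            if len(new_sel) < 3 or np.array_equal(new_sel, sel):
                break
            sel = new_sel
        return best

    seeds = [np.arange(L), np.arange(L // 2), np.arange(L // 2, L)]
    return max(superpose_on(s) for s in seeds if len(s) >= 3)


@dataclass
class DecoyReport:
    """Per-decoy energies plus ranking/correlation summary."""

    table: pd.DataFrame  # name, e_rw, e_orient, e_rwplus, rmsd, tm
    summary: dict = field(default_factory=dict)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6f")


def _pearson(x, y) -> float | None:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3 or np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
        return None
    return float(stats.pearsonr(x[ok], y[ok]).statistic)


def evaluate_decoy_set(native: TypedStructure | None,
                       decoys: dict[str, TypedStructure],
                       dist_pot: DistancePotential,
                       orient_pot: OrientationPotential | None = None,
                       quality: pd.DataFrame | None = None,
                       compute_rmsd: bool = True,
                       native_name: str = "native") -> DecoyReport:
    """Score a decoy set and compile the evaluation report.

    Parameters
    ----------
    native
        The reference structure; may be None (pure model ranking).
    decoys
        Mapping from decoy name to structure.
    quality
        Optional externally computed table with columns ``name`` and any
        of ``rmsd`` / ``tm``; overrides internal RMSD computation.
    compute_rmsd
        Compute C-alpha Kabsch RMSD against the native for decoys not
        covered by *quality* (requires equal residue counts).
    """
    if len(decoys) < 2:
        raise ValueError("need at least 2 decoys")
    qual = {}
    if quality is not None:
        for _, row in quality.iterrows():
            qual[str(row["name"])] = row

    entries = []
    native_ca = native.ca_coords() if native is not None else None
    items = ([(native_name, native)] if native is not None else []) \
        + sorted(decoys.items())
    for name, s in items:
        e_rw, e_or, e_tot = score_rwplus(s, dist_pot, orient_pot)
        rmsd = tm = None
        if name == native_name and native is not None:
            rmsd, tm = 0.0, 1.0
        if name in qual:
            row = qual[name]
            rmsd = float(row["rmsd"]) if "rmsd" in row and pd.notna(row["rmsd"]) else rmsd
            tm = float(row["tm"]) if "tm" in row and pd.notna(row["tm"]) else tm
        elif rmsd is None and compute_rmsd and native_ca is not None:
            try:
                rmsd = kabsch_rmsd(s.ca_coords(), native_ca)
            except ValueError:
                rmsd = None
        entries.append({"name": name, "e_rw": e_rw, "e_orient": e_or,
                        "e_rwplus": e_tot, "rmsd": rmsd, "tm": tm})

    df = pd.DataFrame(entries)
    # deterministic energy ranking; ties broken by name
    df = df.sort_values(["e_rwplus", "name"], kind="mergesort",
                        ignore_index=True)
    df["rank"] = np.arange(1, len(df) + 1)

    summary: dict = {"n_decoys": len(decoys)}
    energies = df["e_rwplus"].to_numpy()
    if native is not None:
        native_rank = int(df.loc[df["name"] == native_name, "rank"].iloc[0])
        summary["native_rank"] = native_rank
        summary["native_is_lowest"] = native_rank == 1
        sigma = float(np.std(energies))
        e_native = float(df.loc[df["name"] == native_name, "e_rwplus"].iloc[0])
        summary["z_native"] = \
            (e_native - float(np.mean(energies))) / sigma if sigma > 0 else None

    dec = df[df["name"] != native_name]
    for k in (1, 5, 10):
        top = dec.head(k)
        rms = top["rmsd"].dropna()
        tms = top["tm"].dropna()
        summary[f"top{k}_best_rmsd"] = float(rms.min()) if len(rms) else None
        summary[f"top{k}_best_tm"] = float(tms.max()) if len(tms) else None
    summary["corr_energy_rmsd"] = (
        _pearson(dec["e_rwplus"], dec["rmsd"])
        if dec["rmsd"].notna().any() else None)
    summary["corr_energy_tm"] = (
        _pearson(dec["e_rwplus"], dec["tm"])
        if dec["tm"].notna().any() else None)
    return DecoyReport(df, summary)
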