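"""Freely-jointed-chain (random-walk) reference state.

The reference state answers: how often would two atoms sit at distance R
if the only interaction were the entropic elasticity of a connected chain?
For an ideal chain of n Kuhn segments of length b (lam = b^2), the
end-to-end distance follows the Gaussian-chain radial density

    P(R | n) = 4 pi R^2 (3 / (2 pi n lam))^(3/2) exp(-3 R^2 / (2 n lam)).

Chain nodes are mapped to residues, so all atom pairs of residues i and j
carry separation n = |i - j|.  The aggregate reference over a protein of N
residues sums the per-separation densities for n = 1 .. N-1 (separations
beyond the chain length contribute nothing); only ratios of this aggregate
at two distances ever enter the potential, so its absolute normalization
is irrelevant.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

__all__ = [
    "RWParams",
    "fjc_density",
    "rw_probability",
    "expected_shell_weight",
    "shell_weights",
    "dfire_shell_ratio",
]

DFIRE_GAMMA = 1.61  # exponent of the ideal-gas finite-sphere baseline


@dataclass(frozen=True)
class RWParams:
    """Parameters of the random-walk reference and distance binning.

    Attributes
    ----------
    lam : float
        Squared Kuhn length, A^2.  The default 460 corresponds to a Kuhn
        length b = 21.4 A.
    R0 : float
        Interaction cutoff, A; the potential is anchored to zero there.
    dR : float
        Half-open distance bin width, A.
    aggregation : str
        How per-separation densities are combined into the aggregate
        reference: "uniform" sums them with equal weight, "multiplicity"
        weights separation n by its pair multiplicity N - n.
    """

    lam: float = 460.0
    R0: float = 15.5
    dR: float = 0.5
    aggregation: str = "uniform"

    def __post_init__(self):
        if self.lam <= 0 or self.R0 <= 0 or self.dR <= 0:
            raise ValueError("lam, R0 and dR must be positive")
        n = self.R0 / self.dR
        if abs(n - round(n)) > 1e-9:
            raise ValueError("R0 must be an integer multiple of dR")
        if self.aggregation not in ("uniform", "multiplicity"):
            raise ValueError(f"unknown aggregation {self.aggregation!r}")

    @property
    def b(self) -> float:
        """Kuhn length, A."""
        return float(np.sqrt(self.lam))

    @property
    def n_bins(self) -> int:
        return int(round(self.R0 / self.dR))

    def bin_of(self, r):
        """Half-open bin index floor(r / dR); valid for r < R0."""
        return np.floor(np.asarray(r) / self.dR).astype(np.intp)

    def bin_edges(self) -> np.ndarray:
        return np.arange(self.n_bins + 1) * self.dR


def fjc_density(R, n: int, params: RWParams) -> np.ndarray | float:
    """Radial end-to-end density P(R | n) of an ideal chain, 1/A.

    Proper probability density in R for every separation n >= 1, with
    second moment <R^2> = n * lam.
    """
    if n < 1:
        raise ValueError("separation n must be >= 1")
    R = np.asarray(R, dtype=float)
    if np.any(R < 0):
        raise ValueError("R must be nonnegative")
    a = 3.0 / (2.0 * n * params.lam)
    out = 4.0 * np.pi * R**2 * (a / np.pi) ** 1.5 * np.exp(-a * R**2)
    return out if out.ndim else float(out)


def rw_probability(R, N: int, params: RWParams, n_min: int = 1) -> np.ndarray | float:
    """Aggregate reference density over separations n = n_min .. N-1.

    Relative (unnormalized): only ratios at two distances are meaningful.
    Separations at or beyond the chain length contribute exactly zero.
    When pair counting excludes short sequence separations, pass the same
    minimum as *n_min* so the reference describes the same pair
    population as the counts.
    """
    if N < 2:
        raise ValueError("protein length N must be >= 2")
    if not 1 <= n_min < N:
        raise ValueError("need 1 <= n_min < N")
    R = np.asarray(R, dtype=float)
    if np.any(R < 0):
        raise ValueError("R must be nonnegative")
    n = np.arange(n_min, N)
    w = (N - n).astype(float) if params.aggregation == "multiplicity" \
        else np.ones(len(n))
    a = 3.0 / (2.0 * n * params.lam)  # (N-1,)
    dens = 4.0 * np.pi * R[..., None] ** 2 * (a / np.pi) ** 1.5 \
        * np.exp(-a * R[..., None] ** 2)
    out = dens @ w
    return out if out.ndim else float(out)


# 16-point Gauss-Legendre nodes/weights on [-1, 1]
_GL_X, _GL_W = np.polynomial.legendre.leggauss(16)


@lru_cache(maxsize=512)
def _shell_weights_cached(N: int, params: RWParams, n_min: int) -> np.ndarray:
    edges = params.bin_edges()
    lo, hi = edges[:-1], edges[1:]
    mid, half = (lo + hi) / 2.0, (hi - lo) / 2.0
    # (n_bins, 16) quadrature nodes
    r = mid[:, None] + half[:, None] * _GL_X[None, :]
    vals = rw_probability(r.ravel(), N, params, n_min).reshape(r.shape)
    w = (vals * _GL_W[None, :]).sum(axis=1) * half
    w.setflags(write=False)
    return w


def shell_weights(N: int, params: RWParams, n_min: int = 1) -> np.ndarray:
    """Integral of the aggregate reference over every distance shell.

    Returns an (n_bins,) array; element k is the reference weight of the
    half-open shell [k dR, (k+1) dR).  This is the per-structure shape of
    the expected pair counts for a protein of N residues.
    """
    return _shell_weights_cached(int(N), params, int(n_min))


def expected_shell_weight(bin: int, N: int, params: RWParams,
                          n_min: int = 1) -> float:
    """Reference weight of a single distance shell (see shell_weights)."""
    if not 0 <= bin < params.n_bins:
        raise ValueError(f"bin {bin} out of range [0, {params.n_bins})")
    return float(shell_weights(N, params, n_min)[bin])


def dfire_shell_ratio(R, R0: float) -> np.ndarray | float:
    """Ideal-gas finite-sphere reference ratio (R / R0)^1.61.

    The distance-power baseline the random-walk reference is compared
    against; at short range the random-walk ratio falls below this curve,
    which is what makes the resulting potential more repulsive there.
    """
    R = np.asarray(R, dtype=float)
    if np.any(R <= 0):
        raise ValueError("R must be positive")
    out = (R / R0) ** DFIRE_GAMMA
    return out if out.ndim else float(out)
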