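"""Constant-time lower bound on the RMSD via half-chain centroids.

For a chain U of length n let U_left be its first floor(n/2) residues and
U_right its last floor(n/2) residues (the middle residue of an odd-length
chain belongs to neither half, keeping the halves equal-sized).  The
half-split statistic is

    F(U) = |G(U_left) - G(U_right)| / 2,

with G the centroid.  F is invariant under rigid motions, so for two
equal-length chains D(S, T) = |F(S) - F(T)| can be evaluated without any
superposition, in O(1) once centroid prefix sums are available — and it
bounds the RMSD from below (exactly for even n; see ``lower_bound_D`` for
the odd-n slack).  Sliding-window tables of F over a long text chain are
the engine of the search filter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_geometry import Chain

__all__ = [
    "half_split_statistic",
    "lower_bound_D",
    "half_split_slack",
    "WindowFTable",
    "build_window_table",
]


def half_split_statistic(U: Chain) -> float:
    """F(U): half the distance between the two half-chain centroids.

    Requires ``len(U) >= 2``.  Rigid-motion invariant, since both centroids
    move with the chain.
    """
    n = len(U)
    if n < 2:
        raise ValueError("half-split statistic needs a chain of length >= 2")
    h = n // 2
    g_left = U.coords[:h].mean(axis=0)
    g_right = U.coords[-h:].mean(axis=0)
    return float(np.linalg.norm(g_left - g_right) / 2.0)


def half_split_slack(n: int) -> float:
    """Provable slack of the half-split bound at chain length n.

    D(S, T) <= half_split_slack(n) * RMSD(S, T) is guaranteed; the factor is
    sqrt(n / (2*floor(n/2))), i.e. exactly 1 for even n and sqrt(n/(n-1))
    for odd n.  See the proof in ``lower_bound_D``.
    """
    if n < 2:
        raise ValueError("slack undefined for chains shorter than 2")
    return float(np.sqrt(n / (2.0 * (n // 2))))


def lower_bound_D(S: Chain, T: Chain) -> float:
    """D(S, T) = |F(S) - F(T)|, a rigid-motion-free lower bound on RMSD.

    Proof of ``D <= half_split_slack(n) * RMSD``: superpose T optimally onto
    S and let delta_i = s_i - t_i be the residuals, so that
    sum_i |delta_i|^2 = n * RMSD^2.  With h = floor(n/2), the halves'
    centroid displacements a = |G(S_left) - G(T_left)| and
    b = |G(S_right) - G(T_right)| satisfy a^2 <= (1/h) * sum_left |delta|^2
    and likewise for b (Cauchy-Schwarz on the h residuals of each half).
    By the triangle inequality applied twice,

        D = | |G(S_l)-G(S_r)| - |G(T_l)-G(T_r)| | / 2 <= (a + b) / 2,

    and (a+b)/2 <= sqrt((a^2+b^2)/2) <= sqrt(sum|delta|^2 / (2h))
    = sqrt(n/(2h)) * RMSD.  For even n the factor is exactly 1, i.e.
    D <= RMSD; for odd n it is sqrt(n/(n-1)).  F being rigid-motion
    invariant, the choice of frame above is immaterial.
    """
    if len(S) != len(T):
        raise ValueError("lower bound needs two chains of equal length")
    return abs(half_split_statistic(S) - half_split_statistic(T))


@dataclass(frozen=True)
class WindowFTable:
    """F of every fixed-length window of a text chain.

    ``f_values[i]`` (0-based) is F of the window starting at 1-based
    position ``i + 1``; there are ``N - window_length + 1`` entries.
    """

    window_length: int
    f_values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.f_values, dtype=float)
        if self.window_length < 2:
            raise ValueError("window length must be >= 2")
        if vals.ndim != 1 or np.any(vals < 0) or not np.all(np.isfinite(vals)):
            raise ValueError("f_values must be a 1-D array of finite non-negative reals")
        object.__setattr__(self, "f_values", vals)

    def __len__(self) -> int:
        return len(self.f_values)

    def f_at(self, position: int) -> float:
        """F of the window starting at the given 1-based position."""
        return float(self.f_values[position - 1])


def build_window_table(P: Chain, m_prime: int) -> WindowFTable:
    """F of every length-``m_prime`` window of ``P`` in O(N) total time.

    Uses coordinate prefix sums: the centroid of any contiguous run is a
    difference of two prefix rows divided by the run length, so each
    window's two half-centroids cost O(1).
    """
    N = len(P)
    if not 2 <= m_prime <= N:
        raise ValueError(f"window length must satisfy 2 <= m' <= N, got {m_prime} (N={N})")
    h = m_prime // 2
    prefix = np.vstack([np.zeros((1, P.dim)), np.cumsum(P.coords, axis=0)])
    starts = np.arange(N - m_prime + 1)
    g_left = (prefix[starts + h] - prefix[starts]) / h
    g_right = (prefix[starts + m_prime] - prefix[starts + m_prime - h]) / h
    f = np.linalg.norm(g_left - g_right, axis=1) / 2.0
    return WindowFTable(window_length=m_prime, f_values=f)
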