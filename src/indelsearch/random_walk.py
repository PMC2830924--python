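"""Random-walk (freely-jointed chain) simulation and planted instances.

The freely-jointed chain is the standard idealization of a chain molecule
used for average-case analysis: successive bond vectors have fixed length
``r`` (3.8 Angstrom between adjacent C-alpha atoms in proteins) and
independent, uniformly random directions.  Excluded volume and backbone
dihedral preferences are deliberately ignored.  This module generates such
chains, splices noisy/indel-mutated copies of a query into a text chain
(with the exact ground-truth witness, for testing the search), and runs
the two Monte-Carlo experiments behind the average-case claims: the tail
probability of the half-split lower bound, Prob(D < c) = O(c/sqrt(n)), and
the scaling of the filter's candidate count, <N'> = O(N/m^(k+1)).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .core_geometry import Chain, _rmsd_arrays
from .indel_search import MatchReport, SearchParams, divide_query, enumerate_candidates
from .lower_bound import half_split_statistic

__all__ = [
    "RandomWalkParams",
    "PlantSpec",
    "generate_chain",
    "plant",
    "lower_bound_tail_experiment",
    "candidate_scaling_experiment",
]

CA_BOND_LENGTH = 3.8  # Angstrom between adjacent C-alpha atoms


@dataclass(frozen=True)
class RandomWalkParams:
    """Freely-jointed chain parameters: n residues, bond length r, RNG seed."""

    n: int
    r: float = CA_BOND_LENGTH
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("chain needs at least one residue")
        if not self.r > 0:
            raise ValueError("bond length must be positive")


def _walk_batch(rng: np.random.Generator, batch: int, n: int, r: float) -> np.ndarray:
    """``(batch, n, 3)`` stack of freely-jointed chains starting at the origin.

    Uniform bond directions come from normalized 3-D Gaussians, which is
    exact and branch-free.
    """
    steps = rng.normal(size=(batch, n - 1, 3)) if n > 1 else np.zeros((batch, 0, 3))
    if n > 1:
        steps *= r / np.linalg.norm(steps, axis=2, keepdims=True)
    coords = np.zeros((batch, n, 3))
    if n > 1:
        np.cumsum(steps, axis=1, out=coords[:, 1:, :])
    return coords


def generate_chain(params: RandomWalkParams, label: str = "walk") -> Chain:
    """One freely-jointed chain, deterministic given the seed.

    Every bond has length exactly ``r`` (to machine precision) and an
    independent, uniformly distributed direction.
    """
    rng = np.random.default_rng(params.seed)
    coords = _walk_batch(rng, 1, params.n, params.r)[0]
    return Chain(coords, label)


@dataclass(frozen=True)
class PlantSpec:
    """Recipe for splicing a mutated copy of a query into a text chain.

    The copy is built from ``query`` by deleting the 1-based residues in
    ``deletions`` (these become the witness's query-side deletions, k' of
    them) and inserting a spurious residue after each 1-based position in
    ``insertions`` (counted in the *reduced* copy; these become the
    text-side deletions, k'' of them).  The copy is then rigidly moved at
    random, perturbed by isotropic Gaussian noise of sd ``noise_sigma`` per
    coordinate, and written over the text window starting at 1-based
    ``position``.  The true witness RMSD is recomputed afterwards, not
    assumed.
    """

    query: Chain
    position: int
    noise_sigma: float = 0.0
    deletions: tuple[int, ...] = ()
    insertions: tuple[int, ...] = ()
    seed: int = 0
    bond_scale: float = CA_BOND_LENGTH


def plant(text: Chain, spec: PlantSpec) -> tuple[Chain, MatchReport]:
    """Splice the mutated query into the text; return (new text, ground truth).

    The returned report is the exact witness of the planted match: position,
    (k', k''), both deletion sets and the post-noise RMSD between the
    k'-reduced query and the k''-reduced planted window.
    """
    rng = np.random.default_rng(spec.seed)
    m = len(spec.query)
    dels0 = tuple(sorted(d - 1 for d in spec.deletions))
    if any(not 0 <= d < m for d in dels0) or len(set(dels0)) != len(dels0):
        raise ValueError("deletions must be distinct 1-based query residue indices")
    reduced = np.delete(spec.query.coords, dels0, axis=0)

    # insert spurious residues; remember where they land in the final window
    rows = [(row, False) for row in reduced]
    for pos in sorted(spec.insertions, reverse=True):
        if not 0 <= pos <= len(reduced):
            raise ValueError("insertion positions must lie within the reduced copy")
        left = rows[pos - 1][0] if pos >= 1 else rows[0][0]
        right = rows[pos][0] if pos < len(rows) else rows[-1][0]
        point = (left + right) / 2.0 + rng.normal(scale=spec.bond_scale / 2.0, size=3)
        rows.insert(pos, (point, True))
    window = np.array([row for row, _ in rows])
    inserted0 = tuple(idx for idx, (_, flag) in enumerate(rows) if flag)
    L = len(rows)

    i0 = spec.position - 1
    if not (0 <= i0 and i0 + L <= len(text)):
        raise ValueError(
            f"planted window of length {L} at position {spec.position} does not fit "
            f"in a text of length {len(text)}"
        )

    # random rigid motion: rotate about the copy centroid, land on the old window
    R = Rotation.random(rng=rng).as_matrix()
    g = window.mean(axis=0)
    target = text.coords[i0 : i0 + L].mean(axis=0)
    moved = (window - g) @ R.T + target
    if spec.noise_sigma > 0:
        moved = moved + rng.normal(scale=spec.noise_sigma, size=moved.shape)

    new_coords = text.coords.copy()
    new_coords[i0 : i0 + L] = moved
    new_text = Chain(new_coords, text.label)

    true_rmsd = _rmsd_arrays(reduced, np.delete(moved, inserted0, axis=0))
    report = MatchReport(
        structure_id=text.label,
        position=spec.position,
        k_prime=len(dels0),
        k_double_prime=len(inserted0),
        query_deletions=tuple(d + 1 for d in dels0),
        text_deletions=tuple(idx + 1 for idx in inserted0),
        rmsd=true_rmsd,
    )
    return new_text, report


def _half_split_batch(coords: np.ndarray) -> np.ndarray:
    """F for a ``(batch, n, 3)`` stack of chains."""
    n = coords.shape[1]
    h = n // 2
    g_left = coords[:, :h].mean(axis=1)
    g_right = coords[:, -h:].mean(axis=1)
    return np.linalg.norm(g_left - g_right, axis=1) / 2.0


def lower_bound_tail_experiment(
    n_values: Sequence[int],
    c_values: Sequence[float],
    trials: int = 10_000,
    r: float = 1.0,
    seed: int = 0,
    chunk: int = 2_000,
) -> pd.DataFrame:
    """Empirical Prob(D(S, T) < c) for independent random-walk pairs.

    One row per (n, c) cell with columns ``n``, ``c``, ``prob`` and the
    normalization ``prob * sqrt(n) / c`` whose flatness across cells is the
    testable form of the O(c/sqrt(n)) tail law.  Deterministic given the
    seed.
    """
    rng = np.random.default_rng(seed)
    records = []
    cs = np.asarray(list(c_values), dtype=float)
    for n in n_values:
        counts = np.zeros(len(cs))
        done = 0
        while done < trials:
            b = min(chunk, trials - done)
            f1 = _half_split_batch(_walk_batch(rng, b, n, r))
            f2 = _half_split_batch(_walk_batch(rng, b, n, r))
            d = np.abs(f1 - f2)
            counts += (d[None, :] < cs[:, None]).sum(axis=1)
            done += b
        for c, cnt in zip(cs, counts):
            prob = cnt / trials
            records.append(
                {"n": n, "c": c, "prob": prob, "normalized": prob * np.sqrt(n) / c}
            )
    return pd.DataFrame.from_records(records)


def candidate_scaling_experiment(
    N: int,
    m_values: Sequence[int],
    k: int,
    c: float,
    n_seeds: int = 30,
    r: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean filter candidate count N' on fresh random-walk texts and queries.

    One row per (m, replicate) with the candidate count and the counted
    filter cost; averaging over replicates and regressing log<N'> on log m
    exposes the O(N/m^(k+1)) decay, and ``filter_ops`` the O(k^2 N) cost.
    Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    params = SearchParams(c=c, k=k)
    records = []
    for m in m_values:
        for rep in range(n_seeds):
            text = Chain(_walk_batch(rng, 1, N, r)[0], "text")
            query = Chain(_walk_batch(rng, 1, m, r)[0], "query")
            qdiv = divide_query(query, k)
            profile = enumerate_candidates(text, qdiv, params)
            records.append(
                {
                    "N": N,
                    "m": m,
                    "k": k,
                    "c": c,
                    "replicate": rep,
                    "n_candidates": int(len(profile.candidates())),
                    "filter_ops": profile.filter_ops,
                }
            )
    return pd.DataFrame.from_records(records)
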