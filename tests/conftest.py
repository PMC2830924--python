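"""Shared fixtures and helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from indelsearch.core_geometry import Chain


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260918)


def random_chain(rng: np.random.Generator, n: int, dim: int = 3, scale: float = 1.0) -> Chain:
    """A chain of iid Gaussian points (no bond constraint)."""
    return Chain(rng.normal(scale=scale, size=(n, dim)))


def random_rotation(rng: np.random.Generator, dim: int = 3) -> np.ndarray:
    """A proper rotation, uniform for dim=3, Haar-ish via QR otherwise."""
    if dim == 3:
        return Rotation.random(rng=rng).as_matrix()
    q, r = np.linalg.qr(rng.normal(size=(dim, dim)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, -1] *= -1
    return q


def rigid_copy(rng: np.random.Generator, chain: Chain) -> Chain:
    """The chain under a random proper rotation and translation."""
    R = random_rotation(rng, chain.dim)
    v = rng.normal(scale=5.0, size=chain.dim)
    return chain.transform(R, v)


def plant_random(rng, text, query, k: int, noise_sigma: float, bond_scale: float = 1.0):
    """Splice a randomly indel-mutated, noised copy of the query into the text.

    Draws k' + k'' <= k deletion/insertion counts and positions at random and
    returns (new_text, ground_truth_report).
    """
    from indelsearch.random_walk import PlantSpec, plant

    m = len(query)
    ndel = int(rng.integers(0, k + 1))
    nins = int(rng.integers(0, k - ndel + 1))
    dels = tuple(sorted(rng.choice(np.arange(1, m + 1), size=ndel, replace=False).tolist()))
    ins = tuple(sorted(rng.choice(np.arange(0, m - ndel + 1), size=nins, replace=False).tolist()))
    length = m - ndel + nins
    position = int(rng.integers(1, len(text) - length + 2))
    spec = PlantSpec(
        query=query,
        position=position,
        noise_sigma=noise_sigma,
        deletions=dels,
        insertions=ins,
        seed=int(rng.integers(2**31)),
        bond_scale=bond_scale,
    )
    return plant(text, spec)


def report_key(report):
    """Comparable witness tuple of a MatchReport (exact floats included)."""
    return (
        report.structure_id,
        report.position,
        report.k_prime,
        report.k_double_prime,
        report.query_deletions,
        report.text_deletions,
        report.rmsd,
    )
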