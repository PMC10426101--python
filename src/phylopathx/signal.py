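"""Phylogenetic signal for binary traits (Fritz-Purvis D) and permutation
tests of association between distance matrices.

D scales the observed sum of sister-clade differences between two simulated
benchmarks: random tip shuffling (D = 1, no signal) and Brownian evolution
thresholded at the observed prevalence (D = 0, Brownian-level clumping).
Negative D means stronger-than-Brownian clumping.  The geographic test is a
Mantel permutation test reporting both the raw upper-triangle cross-product
z and the standardised correlation r.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .treeio import Phylogeny

__all__ = [
    "DResult",
    "MantelResult",
    "d_statistic",
    "mantel_test",
    "trait_distance",
    "geographic_distances",
]

EARTH_RADIUS_KM = 6371.0


@dataclass
class DResult:
    d_obs: float
    D: float
    p_random: float
    p_brownian: float
    mean_d_random: float
    mean_d_brownian: float
    n_permutations: int
    seed: int | None


@dataclass
class MantelResult:
    z: float  # raw upper-triangle cross-product
    r: float  # standardised (Pearson) statistic; nan if undefined
    p: float  # one-tailed permutation p for the declared tail
    tail: str
    n_permutations: int
    seed: int | None


def _align_binary(trait, tree: Phylogeny) -> np.ndarray:
    if isinstance(trait, pd.Series):
        missing = sorted(set(tree.tips) - set(trait.index))
        if missing:
            raise ValueError(f"trait missing for tips: {missing}")
        t = trait.loc[list(tree.tips)].to_numpy(dtype=float)
    else:
        t = np.asarray(trait, dtype=float)
        if t.shape != (len(tree.tips),):
            raise ValueError("trait vector length must match the number of tips")
    states = set(np.unique(t))
    if not states <= {0.0, 1.0}:
        raise ValueError("trait must be strictly 0/1")
    if len(states) < 2:
        raise ValueError("D undefined: trait has a single state")
    return t


def d_obs_value(trait, tree: Phylogeny) -> float:
    """Observed sum of sister-clade differences for one binary trait."""
    t = _align_binary(trait, tree)
    W = tree.contrast_weights()
    return float(np.abs(W @ t).sum())


def d_statistic(
    trait,
    tree: Phylogeny,
    n_permutations: int = 999,
    seed: int | None = None,
) -> DResult:
    """Fritz-Purvis D for a binary trait on a tree.

    ``p_random`` is the probability that clumping at least as strong as
    observed (d <= d_obs) arises under tip shuffling; ``p_brownian`` the
    analogous probability under Brownian-threshold simulation.  Permutation
    p-values are floored at 1/(B+1).  The same seed reproduces the result
    bit-for-bit.
    """
    t = _align_binary(trait, tree)
    n = len(t)
    k = int(t.sum())
    W = tree.contrast_weights()
    d_obs = float(np.abs(W @ t).sum())
    rng = np.random.default_rng(seed)
    B = int(n_permutations)
    if B < 1:
        raise ValueError("need at least one permutation")

    # tip shuffling: permute the observed states across tips
    shuf = np.tile(t[:, None], (1, B))
    shuf = rng.permuted(shuf, axis=0)
    d_rand = np.abs(W @ shuf).sum(axis=0)

    # Brownian threshold: latent MVN on the tree, cut at observed prevalence
    L = _safe_cholesky(tree.brownian_covariance())
    Z = L @ rng.standard_normal((n, B))
    ranks = np.argsort(np.argsort(Z, axis=0), axis=0)
    brow = (ranks >= n - k).astype(float)
    d_brow = np.abs(W @ brow).sum(axis=0)

    mean_r = float(d_rand.mean())
    mean_b = float(d_brow.mean())
    denom = mean_r - mean_b
    D = float((d_obs - mean_b) / denom) if denom != 0 else float("nan")
    eps = 1e-12
    p_random = (1 + int((d_rand <= d_obs + eps).sum())) / (B + 1)
    p_brownian = (1 + int((d_brow <= d_obs + eps).sum())) / (B + 1)
    return DResult(
        d_obs=d_obs, D=D, p_random=p_random, p_brownian=p_brownian,
        mean_d_random=mean_r, mean_d_brownian=mean_b,
        n_permutations=B, seed=seed,
    )


def _safe_cholesky(mat: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.cholesky(mat)
    except np.linalg.LinAlgError:
        return np.linalg.cholesky(mat + 1e-8 * np.mean(np.diag(mat)) * np.eye(len(mat)))


def _check_distance_matrix(m: np.ndarray, name: str) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"{name} must be square")
    if not np.allclose(m, m.T, atol=1e-8):
        raise ValueError(f"{name} must be symmetric")
    if not np.allclose(np.diag(m), 0.0, atol=1e-8):
        raise ValueError(f"{name} must have a zero diagonal")
    return m


def mantel_test(
    m1,
    m2,
    n_permutations: int = 9999,
    seed: int | None = None,
    tail: str = "greater",
) -> MantelResult:
    """Permutation test of association between two distance matrices.

    The statistic is computed on upper triangles; the permutation null
    jointly permutes the rows and columns of ``m2``.  The p-value is
    one-tailed, (1 + #{permuted >= observed}) / (B + 1) for ``tail='greater'``.
    If either matrix is constant off-diagonal the standardised r is undefined
    (returned as nan) while the raw z is still reported.
    """
    m1 = _check_distance_matrix(m1, "m1")
    m2 = _check_distance_matrix(m2, "m2")
    if m1.shape != m2.shape:
        raise ValueError(f"shape mismatch: {m1.shape} vs {m2.shape}")
    if tail not in ("greater", "less"):
        raise ValueError("tail must be 'greater' or 'less'")
    n = m1.shape[0]
    iu = np.triu_indices(n, k=1)
    a, b = m1[iu], m2[iu]
    z_obs = float(a @ b)
    if np.std(a) == 0 or np.std(b) == 0:
        r = float("nan")
    else:
        r = float(np.corrcoef(a, b)[0, 1])
    rng = np.random.default_rng(seed)
    B = int(n_permutations)
    count = 0
    for _ in range(B):
        perm = rng.permutation(n)
        zp = float(m1[iu] @ m2[np.ix_(perm, perm)][iu])
        if tail == "greater":
            count += zp >= z_obs - 1e-12
        else:
            count += zp <= z_obs + 1e-12
    p = (1 + count) / (B + 1)
    return MantelResult(z=z_obs, r=r, p=p, tail=tail, n_permutations=B, seed=seed)


def trait_distance(trait) -> np.ndarray:
    """0/1 mismatch matrix for a binary trait: d_ij = 0 if same state else 1."""
    t = np.asarray(trait, dtype=float)
    if not set(np.unique(t)) <= {0.0, 1.0}:
        raise ValueError("trait must be strictly 0/1")
    return (t[:, None] != t[None, :]).astype(float)


def geographic_distances(lat: Sequence[float], lon: Sequence[float]) -> np.ndarray:
    """Great-circle (haversine) distances in km, Earth radius 6371 km."""
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if lat.shape != lon.shape or lat.ndim != 1:
        raise ValueError("lat and lon must be 1-d and the same length")
    if np.any(np.abs(lat) > 90):
        raise ValueError("latitude out of [-90, 90]")
    if np.any(np.abs(lon) > 180):
        raise ValueError("longitude out of [-180, 180]")
    phi = np.radians(lat)
    lam = np.radians(lon)
    dphi = phi[:, None] - phi[None, :]
    dlam = lam[:, None] - lam[None, :]
    h = np.sin(dphi / 2) ** 2 + np.cos(phi)[:, None] * np.cos(phi)[None, :] * np.sin(dlam / 2) ** 2
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))
    np.fill_diagonal(d, 0.0)
    return d
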