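"""Commonality fusion completion and final cell clustering.

The high-order shared representation Z_s' completes each omic's specific
anchor graph by an elementwise (Hadamard) product, and the two completed
representations are blended by a convex combination with weight theta before
k-means clustering of the cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans


@dataclass
class FusionResult:
    """Completed, fused embeddings and the final cell partition."""

    Z_im1: np.ndarray
    Z_im2: np.ndarray
    theta: float
    Z_final: np.ndarray
    labels: np.ndarray
    n_clusters: int


def impute(Zs_prime: np.ndarray, Zspec: np.ndarray) -> np.ndarray:
    """Complete a specific representation with shared high-order information.

    Elementwise product Z_im = Z_s' ⊙ Z_spec; both factors must be m x n.
    """
    Zs_prime = np.asarray(Zs_prime, dtype=float)
    Zspec = np.asarray(Zspec, dtype=float)
    if Zs_prime.shape != Zspec.shape:
        raise ValueError(
            f"shape mismatch: {Zs_prime.shape} vs {Zspec.shape}"
        )
    return Zs_prime * Zspec


def fuse(Z_im1: np.ndarray, Z_im2: np.ndarray, theta: float) -> np.ndarray:
    """Convex blend theta * Z_im1 + (1 - theta) * Z_im2, 0 < theta < 1."""
    if not 0.0 < theta < 1.0:
        raise ValueError("theta must lie strictly in (0, 1)")
    Z_im1 = np.asarray(Z_im1, dtype=float)
    Z_im2 = np.asarray(Z_im2, dtype=float)
    if Z_im1.shape != Z_im2.shape:
        raise ValueError(f"shape mismatch: {Z_im1.shape} vs {Z_im2.shape}")
    return theta * Z_im1 + (1.0 - theta) * Z_im2


def cluster_cells(
    Z_final: np.ndarray,
    k: int,
    seed: int = 0,
    restarts: int = 10,
) -> np.ndarray:
    """k-means partition of the n cells (columns of Z_final), best of restarts."""
    Z_final = np.asarray(Z_final, dtype=float)
    n = Z_final.shape[1]
    if k > n:
        raise ValueError(f"cannot form k = {k} clusters from n = {n} cells")
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
    return km.fit_predict(Z_final.T)


def fuse_and_cluster(
    Zs_prime: np.ndarray,
    Z1: np.ndarray,
    Z2: np.ndarray,
    theta: float,
    k: int,
    seed: int = 0,
    restarts: int = 10,
) -> FusionResult:
    """Run completion, fusion and clustering in one step."""
    Z_im1 = impute(Zs_prime, Z1)
    Z_im2 = impute(Zs_prime, Z2)
    Z_final = fuse(Z_im1, Z_im2, theta)
    labels = cluster_cells(Z_final, k, seed=seed, restarts=restarts)
    return FusionResult(
        Z_im1=Z_im1,
        Z_im2=Z_im2,
        theta=theta,
        Z_final=Z_final,
        labels=labels,
        n_clusters=k,
    )
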