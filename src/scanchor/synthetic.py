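"""Paired two-view synthetic single-cell data with planted clusters.

The generator emulates the statistical regime of multiome experiments: a
common latent partition of cells; an RNA view of over-dispersed
negative-binomial counts with cluster-specific marker blocks and random
dropout; and an ATAC view of sparse near-binary peak openings where each
cluster has a designated block of preferentially open peaks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import OmicsView


@dataclass
class SyntheticSpec:
    """Parameters of the paired-view generator.

    ``rna_mean_separation`` is the log-scale shift applied to a cluster's
    marker-gene block, in units of the baseline log-mean spread (SD 1);
    ``rna_dispersion`` is the negative-binomial overdispersion (variance
    mu + dispersion * mu^2); the two ATAC probabilities are the Bernoulli
    open rates inside and outside a cluster's designated peak block.
    """

    n_cells: int = 300
    n_clusters: int = 3
    d_rna: int = 200
    d_atac: int = 500
    cluster_proportions: np.ndarray | None = None
    rna_mean_separation: float = 2.0
    rna_dispersion: float = 0.3
    atac_open_prob_in: float = 0.3
    atac_open_prob_out: float = 0.02
    dropout_rate: float = 0.3
    seed: int = 0
    deterministic_proportions: bool = False

    def __post_init__(self) -> None:
        if self.cluster_proportions is None:
            self.cluster_proportions = np.full(
                self.n_clusters, 1.0 / self.n_clusters
            )
        self.cluster_proportions = np.asarray(self.cluster_proportions, dtype=float)
        if self.cluster_proportions.size != self.n_clusters:
            raise ValueError("one proportion per cluster is required")
        if not np.isclose(self.cluster_proportions.sum(), 1.0):
            raise ValueError("cluster proportions must sum to 1")
        if np.any(self.cluster_proportions <= 0):
            raise ValueError("cluster proportions must be positive")
        if not self.atac_open_prob_in > self.atac_open_prob_out:
            raise ValueError("in-block open probability must exceed background")
        if min(self.d_rna, self.d_atac, self.n_cells) < self.n_clusters:
            raise ValueError("all dimensions must be at least n_clusters")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")


def moderate_overlap_spec(seed: int = 0) -> SyntheticSpec:
    """Conditions with partially overlapping clusters in both views.

    Weaker marker shifts, noisier counts and a smaller gap between in-block
    and background peak-open rates than the defaults, so that clustering is
    hard enough for the pipeline stages to differ measurably.
    """
    return SyntheticSpec(
        n_cells=300,
        n_clusters=3,
        d_rna=200,
        d_atac=500,
        rna_mean_separation=0.8,
        rna_dispersion=0.6,
        atac_open_prob_in=0.12,
        atac_open_prob_out=0.05,
        dropout_rate=0.4,
        seed=seed,
    )


def generate(spec: SyntheticSpec) -> tuple[OmicsView, OmicsView, np.ndarray]:
    """Draw one paired dataset; deterministic given ``spec.seed``.

    Returns the raw RNA view (genes x cells), the raw ATAC view
    (peaks x cells) sharing the same barcodes, and the planted cluster
    labels.
    """
    rng = np.random.default_rng(spec.seed)
    n, k = spec.n_cells, spec.n_clusters

    if spec.deterministic_proportions:
        counts = np.floor(spec.cluster_proportions * n).astype(int)
        counts[: n - counts.sum()] += 1
        labels = np.repeat(np.arange(k), counts)
    else:
        labels = rng.choice(k, size=n, p=spec.cluster_proportions)

    # RNA: baseline log-means with SD 1; each cluster's marker block shifted up
    base = rng.normal(0.5, 1.0, size=spec.d_rna)
    log_mu = np.tile(base[:, None], (1, k))
    blocks_rna = np.array_split(np.arange(spec.d_rna), k)
    for c in range(k):
        log_mu[blocks_rna[c], c] += spec.rna_mean_separation
    mu = np.exp(log_mu)[:, labels]  # d_rna x n
    if spec.rna_dispersion > 0:
        shape = 1.0 / spec.rna_dispersion
        lam = rng.gamma(shape, mu * spec.rna_dispersion)
    else:
        lam = mu
    rna = rng.poisson(lam).astype(float)
    if spec.dropout_rate > 0:
        rna *= rng.random(rna.shape) >= spec.dropout_rate

    # ATAC: Bernoulli block structure over peaks
    blocks_atac = np.array_split(np.arange(spec.d_atac), k)
    prob = np.full((spec.d_atac, n), spec.atac_open_prob_out)
    for c in range(k):
        cells_c = labels == c
        prob[np.ix_(blocks_atac[c], cells_c)] = spec.atac_open_prob_in
    atac = (rng.random((spec.d_atac, n)) < prob).astype(float)

    barcodes = [f"cell{i:05d}" for i in range(n)]
    rna_view = OmicsView(
        rna, "rna", [f"gene{g}" for g in range(spec.d_rna)], barcodes
    )
    atac_view = OmicsView(
        atac, "atac", [f"peak{p}" for p in range(spec.d_atac)], barcodes
    )
    return rna_view, atac_view, labels
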