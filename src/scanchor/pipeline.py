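"""End-to-end orchestration: views in, cluster labels and metrics out.

Stage order: normalize each view -> build the merged view -> initial anchors
by k-means on a cell subsample -> per-omic specific anchor graphs -> shared
anchor graph by cooperative optimization -> high-order propagation of the
shared graph -> completion of the specific graphs -> convex fusion ->
k-means over cells -> evaluation against ground truth when available.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import anchors as anc
from . import fusion as fus
from . import hgat
from .io import OmicsView, RunConfig, make_merged_view, normalize_view, write_labels
from .metrics import EvaluationReport, compute_report


def _energy_scaled(view: OmicsView) -> OmicsView:
    """Divide a view's matrix by the root mean squared cell (column) norm."""
    from dataclasses import replace

    scale = np.sqrt(np.mean(np.sum(view.matrix**2, axis=0)))
    if scale == 0:
        return view
    return replace(view, matrix=view.matrix / scale)


@dataclass
class PipelineResult:
    """All intermediates of one run, for inspection and testing."""

    config: RunConfig
    specific: list[anc.AnchorModel]
    shared: anc.SharedModel
    Zs_prime: np.ndarray | None
    fusion: fus.FusionResult | None
    labels: np.ndarray
    embedding: np.ndarray
    report: EvaluationReport | None
    barcodes: list[str]
    stage_seconds: dict[str, float] = field(default_factory=dict)


@dataclass
class RunManifest:
    """Everything needed to re-run a pipeline invocation identically."""

    config: dict
    input_digests: dict
    seed: int
    objective_traces: dict
    output_paths: dict
    stage_seconds: dict

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, default=str)


def run_views(
    rna: OmicsView,
    atac: OmicsView,
    config: RunConfig,
    truth: np.ndarray | None = None,
    no_hgat: bool = False,
    mac_only: bool = False,
) -> PipelineResult:
    """Run the full method on in-memory raw views.

    ``no_hgat`` replaces the high-order representation by all-ones, making
    the completion step the identity; ``mac_only`` clusters the shared anchor
    graph directly, skipping both attention and fusion.
    """
    config.validate_against(rna.n_cells)
    timer: dict[str, float] = {}

    t0 = time.perf_counter()
    rna_n = normalize_view(rna) if not rna.normalized else rna
    atac_n = normalize_view(atac) if not atac.normalized else atac
    if config.rescale_views:
        # Scale each view to unit mean per-cell energy so the unit-weight
        # graph regularizer is commensurate with the reconstruction term;
        # without this the anchor graphs collapse to one-hot assignments,
        # which carry no between-anchor geometry.
        rna_n = _energy_scaled(rna_n)
        atac_n = _energy_scaled(atac_n)
    merged = make_merged_view(rna_n, atac_n)
    timer["normalize"] = time.perf_counter() - t0

    m = config.n_anchors
    t0 = time.perf_counter()
    Y0 = anc.init_anchors(merged, m, config.seed)
    timer["init_anchors"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    d1 = rna_n.n_features
    specific = [
        anc.fit_specific_graph(
            rna_n,
            Y0[:d1],
            rho=config.rho,
            tol=config.tolerance,
            refit_anchors=config.refit_specific_anchors,
        ),
        anc.fit_specific_graph(
            atac_n,
            Y0[d1:],
            rho=config.rho,
            tol=config.tolerance,
            refit_anchors=config.refit_specific_anchors,
        ),
    ]
    timer["specific_graphs"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    views: list[OmicsView] = [rna_n, atac_n]
    if config.use_merged_view:
        views.append(merged)
    shared = anc.fit_shared(views, config, Y0)
    timer["shared_graph"] = time.perf_counter() - t0

    Z1, Z2 = specific[0].Z, specific[1].Z
    Zs_prime: np.ndarray | None = None
    fusion_result: fus.FusionResult | None = None
    if mac_only:
        t0 = time.perf_counter()
        labels = fus.cluster_cells(shared.Zs, config.n_clusters, seed=config.seed)
        embedding = shared.Zs
        timer["cluster"] = time.perf_counter() - t0
    else:
        t0 = time.perf_counter()
        if no_hgat:
            Zs_prime = np.ones_like(shared.Zs)
        else:
            Zs_prime = hgat.run_hgat(
                shared.Zs,
                layers=config.gat_layers,
                heads=config.gat_heads,
                knn_k=config.knn_k,
                seed=config.seed,
            )
        timer["hgat"] = time.perf_counter() - t0
        t0 = time.perf_counter()
        fusion_result = fus.fuse_and_cluster(
            Zs_prime, Z1, Z2, config.theta, config.n_clusters, seed=config.seed
        )
        labels = fusion_result.labels
        embedding = fusion_result.Z_final
        timer["fuse_cluster"] = time.perf_counter() - t0

    report = None
    if truth is not None:
        report = compute_report(labels, truth, embedding)

    return PipelineResult(
        config=config,
        specific=specific,
        shared=shared,
        Zs_prime=Zs_prime,
        fusion=fusion_result,
        labels=labels,
        embedding=embedding,
        report=report,
        barcodes=list(rna.barcodes),
        stage_seconds=timer,
    )


def _digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(
    config: RunConfig,
    rna: OmicsView,
    atac: OmicsView,
    out_dir: str | Path,
    truth: np.ndarray | None = None,
    input_paths: dict | None = None,
    no_hgat: bool = False,
    mac_only: bool = False,
    umap_export: bool = False,
) -> RunManifest:
    """Run the pipeline and persist labels, embedding, metrics and a manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    result = run_views(
        rna, atac, config, truth=truth, no_hgat=no_hgat, mac_only=mac_only
    )

    paths = {
        "labels": str(out_dir / "labels.tsv"),
        "embedding": str(out_dir / "embedding.csv"),
        "manifest": str(out_dir / "manifest.json"),
    }
    write_labels(paths["labels"], result.barcodes, result.labels)
    pd.DataFrame(result.embedding, columns=result.barcodes).to_csv(
        paths["embedding"], index=False
    )
    if result.report is not None:
        paths["metrics"] = str(out_dir / "metrics.json")
        with open(paths["metrics"], "w") as fh:
            json.dump(result.report.to_dict(), fh, indent=2)
    if umap_export:
        try:
            import umap

            coords = umap.UMAP(random_state=config.seed).fit_transform(
                result.embedding.T
            )
            paths["umap"] = str(out_dir / "umap.csv")
            pd.DataFrame(
                coords, index=result.barcodes, columns=["umap1", "umap2"]
            ).to_csv(paths["umap"])
        except ImportError:
            pass

    manifest = RunManifest(
        config={k: v for k, v in vars(config).items()},
        input_digests={
            k: _digest(p) for k, p in (input_paths or {}).items() if Path(p).exists()
        },
        seed=config.seed,
        objective_traces={
            "specific_rna": result.specific[0].objective_trace,
            "specific_atac": result.specific[1].objective_trace,
            "shared": result.shared.objective_trace,
        },
        output_paths=paths,
        stage_seconds=result.stage_seconds,
    )
    manifest.write(paths["manifest"])
    return manifest
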