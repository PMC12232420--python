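"""Typed containers and file I/O for paired single-cell matrices.

All matrices are kept feature x cell (columns are cells) regardless of the
on-disk orientation.  Supported formats are MatrixMarket triplets
(``matrix.mtx`` + ``features.tsv`` + ``barcodes.tsv``) and dense delimited
text with a barcode header row.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import io as spio
from scipy import sparse


class FormatError(ValueError):
    """Companion files or matrix dimensions are inconsistent."""


class AlignmentError(ValueError):
    """Views passed together do not share the same barcode order."""


class DegenerateInputError(ValueError):
    """Input matrix carries no usable signal (e.g. all zeros)."""


MODALITIES = ("rna", "atac", "merged")


@dataclass
class OmicsView:
    """One modality's feature x cell matrix with its annotations.

    Parameters
    ----------
    matrix
        Dense ``(d, n)`` array, features in rows, cells in columns.
    modality
        One of ``"rna"``, ``"atac"``, ``"merged"``.
    feature_names
        ``d`` unique feature identifiers.
    barcodes
        ``n`` unique cell barcodes; every view of one run must share the
        identical barcode order.
    normalized
        Set by :func:`normalize_view`; guards against double normalization.
    rna_rows
        For merged views, the number of leading rows that came from the RNA
        view (needed to normalize a raw merged matrix per-modality).
    """

    matrix: np.ndarray
    modality: str
    feature_names: list[str]
    barcodes: list[str]
    normalized: bool = False
    rna_rows: int | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise FormatError("matrix must be 2-D (features x cells)")
        d, n = self.matrix.shape
        if d < 1 or n < 2:
            raise FormatError(f"need d >= 1 features and n >= 2 cells, got {d} x {n}")
        if self.modality not in MODALITIES:
            raise FormatError(f"unknown modality {self.modality!r}")
        if len(self.feature_names) != d:
            raise FormatError(
                f"{len(self.feature_names)} feature names for {d} matrix rows"
            )
        if len(self.barcodes) != n:
            raise FormatError(f"{len(self.barcodes)} barcodes for {n} matrix columns")
        if len(set(self.barcodes)) != n:
            raise FormatError("barcodes are not unique")
        if not np.all(np.isfinite(self.matrix)):
            raise FormatError("matrix contains NaN or Inf")
        if not self.normalized and self.matrix.min() < 0:
            raise FormatError("raw count matrix has negative entries")

    @property
    def n_features(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[1]


@dataclass
class RunConfig:
    """Run parameters for the full anchor-graph clustering pipeline.

    ``anchor_multiplier`` times ``n_clusters`` gives the number of anchors m,
    following the convention that m is chosen from {10k, ..., 60k}.
    ``theta`` is the convex fusion weight between the two imputed specific
    representations and must lie strictly inside (0, 1).
    """

    n_clusters: int
    anchor_multiplier: int = 10
    theta: float = 0.5
    rho: float = 1.0
    gcn_layers: int = 2
    gcn_lr: float = 0.01
    gcn_weight_decay: float = 5e-3
    max_iterations: int = 1000
    validate_every: int = 30
    gat_layers: int = 2
    gat_heads: int = 3
    knn_k: int = 15
    seed: int = 0
    tolerance: float = 1e-6
    embed_dim: int | None = None  # shared dimension d; defaults to m
    use_merged_view: bool = True
    rescale_views: bool = True
    refit_specific_anchors: bool = True

    def __post_init__(self) -> None:
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be positive")
        if self.anchor_multiplier not in (10, 20, 30, 40, 50, 60):
            raise ValueError("anchor_multiplier must be one of 10..60 (step 10)")
        if not 0.0 < self.theta < 1.0:
            raise ValueError("theta must lie strictly in (0, 1)")
        if self.rho < 0:
            raise ValueError("rho must be nonnegative")
        if self.embed_dim is not None and self.embed_dim < self.n_anchors:
            raise ValueError("embed_dim must be >= number of anchors")

    @property
    def n_anchors(self) -> int:
        return self.anchor_multiplier * self.n_clusters

    def validate_against(self, n_cells: int) -> None:
        if self.n_anchors > n_cells:
            raise ValueError(
                f"m = {self.n_anchors} anchors exceed n = {n_cells} cells"
            )

    @classmethod
    def from_file(cls, path: str | os.PathLike) -> "RunConfig":
        """Read a flat key: value text file (YAML-compatible) into a config."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise FormatError("config file must contain flat key: value pairs")
        return cls(**raw)


def _read_lines(path: Path) -> list[str]:
    with open(path) as fh:
        return [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]


def read_view(
    path: str | os.PathLike,
    format: str,
    modality: str,
    *,
    features_path: str | os.PathLike | None = None,
    barcodes_path: str | os.PathLike | None = None,
    transpose: bool | None = None,
) -> OmicsView:
    """Read one modality's matrix from disk into an :class:`OmicsView`.

    For ``format="mtx"`` the matrix is accompanied by ``features.tsv`` and
    ``barcodes.tsv`` next to it (or at the explicit paths given).  The stored
    orientation is inferred by matching the axis lengths against the two
    companion files; ``transpose`` overrides the inference.

    For ``format="dense_delimited"`` the first row holds barcodes and the
    first column feature names (CSV or TSV, sniffed from the extension).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)

    if format == "mtx":
        features_path = Path(features_path or path.parent / "features.tsv")
        barcodes_path = Path(barcodes_path or path.parent / "barcodes.tsv")
        for companion in (features_path, barcodes_path):
            if not companion.exists():
                raise FileNotFoundError(companion)
        mat = spio.mmread(path)
        mat = mat.toarray() if sparse.issparse(mat) else np.asarray(mat)
        features = _read_lines(features_path)
        barcodes = _read_lines(barcodes_path)
        if transpose is None:
            if mat.shape == (len(features), len(barcodes)):
                transpose = False
            elif mat.shape == (len(barcodes), len(features)):
                transpose = True
            else:
                raise FormatError(
                    f"matrix is {mat.shape[0]} x {mat.shape[1]} but companions list "
                    f"{len(features)} features and {len(barcodes)} barcodes"
                )
        if transpose:
            mat = mat.T
        if mat.shape != (len(features), len(barcodes)):
            raise FormatError(
                f"matrix is {mat.shape[0]} x {mat.shape[1]} after orientation but "
                f"companions list {len(features)} features and {len(barcodes)} barcodes"
            )
        return OmicsView(mat, modality, features, barcodes)

    if format == "dense_delimited":
        sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
        frame = pd.read_csv(path, sep=sep, index_col=0)
        mat = frame.to_numpy(dtype=float)
        if transpose:
            mat = mat.T
            return OmicsView(mat, modality, list(frame.columns), list(frame.index))
        return OmicsView(mat, modality, list(frame.index), list(frame.columns))

    raise FormatError(f"unknown format {format!r}")


def write_view(view: OmicsView, path: str | os.PathLike, format: str) -> None:
    """Write a view in either supported format (round-trips with read_view)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "mtx":
        spio.mmwrite(path, sparse.coo_matrix(view.matrix))
        with open(path.parent / "features.tsv", "w") as fh:
            fh.write("\n".join(view.feature_names) + "\n")
        with open(path.parent / "barcodes.tsv", "w") as fh:
            fh.write("\n".join(view.barcodes) + "\n")
    elif format == "dense_delimited":
        sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
        pd.DataFrame(
            view.matrix, index=view.feature_names, columns=view.barcodes
        ).to_csv(path, sep=sep)
    else:
        raise FormatError(f"unknown format {format!r}")


def _normalize_rna(mat: np.ndarray, target_scale: float | None) -> np.ndarray:
    """Library-size scaling to a common depth, then log1p."""
    libsize = mat.sum(axis=0)
    nonzero = libsize > 0
    if target_scale is None:
        if not nonzero.any():
            raise DegenerateInputError("all cells have zero counts")
        target_scale = float(np.median(libsize[nonzero]))
    out = np.zeros_like(mat, dtype=float)
    out[:, nonzero] = mat[:, nonzero] / libsize[nonzero] * target_scale
    return np.log1p(out)


def _normalize_atac(mat: np.ndarray) -> np.ndarray:
    """TF-IDF weighting as used for chromatin-accessibility matrices.

    TF is the per-cell term frequency, IDF the inverse fraction of cells in
    which a peak is open; log1p of the 1e4-scaled product keeps the dynamic
    range comparable to log-normalized expression.
    """
    colsum = mat.sum(axis=0)
    nonzero = colsum > 0
    tf = np.zeros_like(mat, dtype=float)
    tf[:, nonzero] = mat[:, nonzero] / colsum[nonzero]
    n_cells = mat.shape[1]
    idf = n_cells / (1.0 + (mat > 0).sum(axis=1))
    return np.log1p(tf * idf[:, None] * 1e4)


def normalize_view(view: OmicsView, target_scale: float | None = None) -> OmicsView:
    """Return a normalized copy of a raw view.

    RNA views get per-cell library-size scaling followed by log1p; ATAC views
    get TF-IDF weighting; merged views are normalized per modality block
    (requires the view to carry ``rna_rows``).  Calling on an already
    normalized view raises rather than silently double-applying.
    """
    if view.normalized:
        raise ValueError("view is already normalized")
    if not np.any(view.matrix):
        raise DegenerateInputError("matrix is all zeros")
    if view.modality == "rna":
        mat = _normalize_rna(view.matrix, target_scale)
    elif view.modality == "atac":
        mat = _normalize_atac(view.matrix)
    else:
        if view.rna_rows is None:
            raise ValueError(
                "merged view lacks the RNA/ATAC row split; normalize the two "
                "modalities separately and use make_merged_view"
            )
        top = _normalize_rna(view.matrix[: view.rna_rows], target_scale)
        bottom = _normalize_atac(view.matrix[view.rna_rows :])
        mat = np.vstack([top, bottom])
    return replace(view, matrix=mat, normalized=True)


def make_merged_view(rna: OmicsView, atac: OmicsView) -> OmicsView:
    """Stack RNA features on top of ATAC features into one merged view."""
    if rna.barcodes != atac.barcodes:
        raise AlignmentError("RNA and ATAC views do not share barcode order")
    if rna.normalized != atac.normalized:
        raise AlignmentError("cannot merge a normalized with a raw view")
    return OmicsView(
        np.vstack([rna.matrix, atac.matrix]),
        "merged",
        list(rna.feature_names) + list(atac.feature_names),
        list(rna.barcodes),
        normalized=rna.normalized,
        rna_rows=rna.n_features,
    )


def read_labels(path: str | os.PathLike, barcodes: Sequence[str]) -> np.ndarray:
    """Read a two-column (barcode, label) TSV aligned to the given barcodes."""
    frame = pd.read_csv(path, sep="\t", header=None, names=["barcode", "label"])
    mapping = dict(zip(frame["barcode"].astype(str), frame["label"]))
    missing = [b for b in barcodes if b not in mapping]
    if missing:
        raise AlignmentError(f"{len(missing)} barcodes missing from label file")
    labels = [mapping[b] for b in barcodes]
    _, encoded = np.unique(labels, return_inverse=True)
    return encoded


def write_labels(
    path: str | os.PathLike, barcodes: Sequence[str], labels: Sequence[int]
) -> None:
    pd.DataFrame({"barcode": list(barcodes), "label": list(labels)}).to_csv(
        path, sep="\t", header=False, index=False
    )
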