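"""Multi-view anchor co-optimization.

Each omic view ``X_i`` (features x cells) is approximated through a small set
of m anchors: a specific anchor graph ``Z_i`` (m x n, nonnegative, column
sums 1) relates every cell to the view's own anchors ``Y_i``, while a shared
anchor graph ``Z_s`` relates cells to shared anchors ``Y_s`` that live in a
common d-dimensional space and are mapped into each view by an orthonormal
projection ``W_i``.  The shared objective

    sum_i alpha_i^2 ||X_i - W_i Y_s Z_s||_F^2 + ||Z_s||_F^2

is minimized by alternating exact block updates (orthogonal Procrustes for
``W_i`` and ``Y_s``, a simplex-projected ridge target for ``Z_s``, a
closed-form simplex solution for the view weights ``alpha``), interleaved
with gradient steps on a per-view graph convolutional network whose output
proposes ``Z_s`` through the weighted aggregation
``Z_s = sum_i alpha_i Y_s^T Z_GCN_i^T``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from sklearn.cluster import KMeans
from sklearn.preprocessing import normalize as _l2_normalize

from .io import OmicsView, RunConfig


class NumericalFailure(RuntimeError):
    """An optimization phase produced a non-finite objective."""


# ---------------------------------------------------------------------------
# simplex projection
# ---------------------------------------------------------------------------

def project_columns_to_simplex(M: np.ndarray) -> np.ndarray:
    """Euclidean projection of every column onto the probability simplex.

    Uses the sort-and-threshold algorithm: for a column v with sorted entries
    u_1 >= ... >= u_m, the projection is max(v - tau, 0) with
    tau = (sum of the largest j entries - 1) / j at the largest feasible j.
    """
    M = np.atleast_2d(np.asarray(M, dtype=float))
    if not np.all(np.isfinite(M)):
        raise ValueError("simplex projection requires finite entries")
    m, n = M.shape
    U = np.sort(M, axis=0)[::-1]
    css = np.cumsum(U, axis=0) - 1.0
    j = np.arange(1, m + 1)[:, None]
    cond = U - css / j > 0
    rho = m - 1 - np.argmax(cond[::-1], axis=0)  # last True index per column
    tau = css[rho, np.arange(n)] / (rho + 1.0)
    return np.maximum(M - tau, 0.0)


# ---------------------------------------------------------------------------
# anchors
# ---------------------------------------------------------------------------

def init_anchors(
    merged: OmicsView | np.ndarray,
    m: int,
    seed: int,
    subsample_frac: float = 0.5,
) -> np.ndarray:
    """Initial anchors: k-means centroids of a random cell subsample.

    A random subsample of cells (at least m of them) is clustered into m
    groups and the centroid columns form the d x m anchor matrix.  When the
    subsample size equals m every cell becomes its own centroid.
    """
    X = merged.matrix if isinstance(merged, OmicsView) else np.asarray(merged)
    n = X.shape[1]
    if m > n:
        raise ValueError(f"cannot place m = {m} anchors with only n = {n} cells")
    rng = np.random.default_rng(seed)
    size = max(m, min(n, int(round(subsample_frac * n))))
    idx = np.sort(rng.choice(n, size=size, replace=False))
    sub = X[:, idx].T  # cells as rows for clustering
    km = KMeans(n_clusters=m, n_init=10, random_state=seed).fit(sub)
    return km.cluster_centers_.T.copy()


@dataclass
class AnchorModel:
    """A fitted specific anchor graph: anchors Y (d x m) and graph Z (m x n)."""

    Y: np.ndarray
    Z: np.ndarray
    rho: float
    objective_trace: list[float] = field(default_factory=list)

    @property
    def n_anchors(self) -> int:
        return self.Y.shape[1]


def _specific_objective_cols(
    X: np.ndarray, Y: np.ndarray, Z: np.ndarray, rho: float
) -> np.ndarray:
    """Per-column value of ||x_j - Y z_j||^2 + rho ||z_j||^2."""
    R = X - Y @ Z
    return np.einsum("ij,ij->j", R, R) + rho * np.einsum("ij,ij->j", Z, Z)


def fit_specific_graph(
    view: OmicsView | np.ndarray,
    Y0: np.ndarray,
    rho: float = 1.0,
    max_iter: int = 50,
    tol: float = 1e-6,
    refit_anchors: bool = True,
) -> AnchorModel:
    """Fit one view's specific anchor graph by alternating minimization.

    The Z-step solves the ridge problem (Y^T Y + rho I) Z = Y^T X and projects
    each column onto the simplex; because the projection of the unconstrained
    minimizer is not itself the constrained minimizer, a candidate column is
    only accepted where it does not increase that column's objective, which
    keeps the recorded objective trace non-increasing.  The optional Y-step
    refits the anchors by regularized least squares under the same guard.
    """
    X = view.matrix if isinstance(view, OmicsView) else np.asarray(view, dtype=float)
    d, n = X.shape
    m = Y0.shape[1]
    if Y0.shape[0] != d:
        raise ValueError(f"anchor matrix has {Y0.shape[0]} rows, view has {d}")
    Y = Y0.copy()
    Z = np.full((m, n), 1.0 / m)
    eps = 1e-8
    obj_cols = _specific_objective_cols(X, Y, Z, rho)
    trace = [float(obj_cols.sum())]
    for _ in range(max_iter):
        # Z-step: ridge target, simplex projection, per-column descent guard
        G = Y.T @ Y + rho * np.eye(m)
        Z_cand = project_columns_to_simplex(np.linalg.solve(G, Y.T @ X))
        cand_cols = _specific_objective_cols(X, Y, Z_cand, rho)
        better = cand_cols < obj_cols
        Z[:, better] = Z_cand[:, better]
        obj_cols = np.where(better, cand_cols, obj_cols)
        # Y-step: regularized least-squares anchor refit, global guard
        if refit_anchors:
            ZZt = Z @ Z.T
            Y_cand = X @ Z.T @ np.linalg.inv(ZZt + eps * np.eye(m))
            cand_cols = _specific_objective_cols(X, Y_cand, Z, rho)
            if cand_cols.sum() < obj_cols.sum():
                Y = Y_cand
                obj_cols = cand_cols
        obj = float(obj_cols.sum())
        if not np.isfinite(obj):
            raise NumericalFailure("specific anchor-graph objective is not finite")
        prev = trace[-1]
        trace.append(obj)
        if abs(prev - obj) <= tol * max(1.0, abs(prev)):
            break
    return AnchorModel(Y=Y, Z=Z, rho=rho, objective_trace=trace)


# ---------------------------------------------------------------------------
# graphs and GCN
# ---------------------------------------------------------------------------

def build_knn_adjacency(features: np.ndarray, k: int) -> sparse.csr_matrix:
    """Symmetric 0/1 k-nearest-neighbour graph under cosine similarity.

    Each node is linked to its k most similar other nodes (ties broken by
    ascending node index) and the edge set is union-symmetrized; the diagonal
    is zero.
    """
    F = np.asarray(features, dtype=float)
    n = F.shape[0]
    if k >= n:
        raise ValueError(f"k = {k} must be smaller than the number of nodes {n}")
    Fn = _l2_normalize(F, norm="l2", axis=1)
    S = Fn @ Fn.T
    np.fill_diagonal(S, -np.inf)
    # stable top-k: order by similarity descending, then index ascending
    idx_grid = np.tile(np.arange(n), (n, 1))
    order = np.lexsort((idx_grid, -S), axis=1)[:, :k]
    rows = np.repeat(np.arange(n), k)
    A = sparse.csr_matrix(
        (np.ones(n * k), (rows, order.ravel())), shape=(n, n)
    )
    A = A.maximum(A.T)
    A.setdiag(0)
    A.eliminate_zeros()
    A.data[:] = 1.0
    return A


def normalized_adjacency(A: sparse.spmatrix) -> sparse.csr_matrix:
    """Self-loop augmented, symmetrically normalized adjacency D'^-1/2 A' D'^-1/2."""
    A = sparse.csr_matrix(A, dtype=float)
    Ahat = A + sparse.eye(A.shape[0], format="csr")
    deg = np.asarray(Ahat.sum(axis=1)).ravel()
    dinv = 1.0 / np.sqrt(deg)
    D = sparse.diags(dinv)
    return sparse.csr_matrix(D @ Ahat @ D)


def init_gcn_weights(
    rng: np.random.Generator, n_layers: int, dim_in: int, dim_out: int
) -> list[np.ndarray]:
    """Glorot-uniform weight matrices for a GCN mapping dim_in -> dim_out."""
    dims = [dim_in] + [dim_out] * n_layers
    weights = []
    for fan_in, fan_out in zip(dims[:-1], dims[1:]):
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        weights.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
    return weights


def gcn_forward(
    A: sparse.spmatrix | np.ndarray,
    H: np.ndarray,
    weights: list[np.ndarray],
) -> np.ndarray:
    """Graph convolution: repeated normalized propagation + linear map.

    Hidden layers use ReLU; the output layer is linear.  ``A`` is the raw
    adjacency (no self-loops); normalization with self-loops happens here.
    """
    Ahat = normalized_adjacency(sparse.csr_matrix(A))
    out = np.asarray(H, dtype=float)
    for li, W in enumerate(weights):
        out = Ahat @ out @ W
        if li < len(weights) - 1:
            out = np.maximum(out, 0.0)
    return out


def shared_Zs_from_gcn(
    Ys: np.ndarray, gcn_outputs: list[np.ndarray], alpha: np.ndarray
) -> np.ndarray:
    """Aggregate per-view GCN node representations into a shared graph.

    Z_s = sum_i alpha_i Y_s^T Z_GCN_i^T; no simplex projection is applied at
    this step.
    """
    return sum(a * (Ys.T @ Z.T) for a, Z in zip(alpha, gcn_outputs))


# ---------------------------------------------------------------------------
# closed-form block updates
# ---------------------------------------------------------------------------

def _procrustes(M: np.ndarray) -> np.ndarray:
    """argmax_{W^T W = I} Tr[W^T M] = U V^T from the thin SVD of M."""
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    if s.size and s.min() < 1e-12:
        warnings.warn(
            "Procrustes target is rank deficient; the maximizer is not unique",
            RuntimeWarning,
            stacklevel=3,
        )
    return U @ Vt


def update_W(Xi: np.ndarray, Ys: np.ndarray, Zs: np.ndarray) -> np.ndarray:
    """Orthonormal view projection maximizing Tr[W^T X_i Z_s^T Y_s^T]."""
    if Xi.shape[0] < Ys.shape[0]:
        raise ValueError("view dimension d_i must be at least the shared dimension d")
    return _procrustes(Xi @ Zs.T @ Ys.T)


def update_Ys(
    views: list[np.ndarray],
    W: list[np.ndarray],
    Zs: np.ndarray,
    alpha: np.ndarray,
) -> np.ndarray:
    """Orthonormal shared anchors maximizing Tr[Y_s^T sum alpha_i^2 W_i^T X_i Z_s^T]."""
    mats = [_as_matrix(v) for v in views]
    N = sum(a**2 * (Wi.T @ Xi @ Zs.T) for a, Wi, Xi in zip(alpha, W, mats))
    return _procrustes(N)


def update_Zs(
    views: list[np.ndarray],
    W: list[np.ndarray],
    Ys: np.ndarray,
    alpha: np.ndarray,
    include_regularizer: bool = True,
) -> np.ndarray:
    """Column-simplex shared graph minimizing the quadratic Z_s block.

    With the ||Z_s||^2 regularizer included (default) the exact minimizer of
    the shared objective is the simplex projection of
    sum_i alpha_i^2 Y_s^T W_i^T X_i / (sum_i alpha_i^2 + 1); dropping the
    regularizer from the denominator reproduces the plain quadratic-form
    block update.
    """
    mats = [_as_matrix(v) for v in views]
    alpha = np.asarray(alpha, dtype=float)
    sq = float((alpha**2).sum())
    if sq <= 0:
        raise ValueError("at least one view weight must be nonzero")
    num = sum(a**2 * (Ys.T @ Wi.T @ Xi) for a, Wi, Xi in zip(alpha, W, mats))
    denom = sq + (1.0 if include_regularizer else 0.0)
    return project_columns_to_simplex(num / denom)


def update_alpha(O: np.ndarray) -> np.ndarray:
    """Simplex view weights inversely proportional to reconstruction residuals.

    alpha_i = (1/O_i) / sum_j (1/O_j); views with exactly zero residual share
    all the weight uniformly (the limit of the formula as O_i -> 0).
    """
    O = np.asarray(O, dtype=float)
    if np.any(O < 0):
        raise ValueError("residuals must be nonnegative")
    zero = O == 0
    if zero.any():
        alpha = np.zeros_like(O)
        alpha[zero] = 1.0 / zero.sum()
        return alpha
    inv = 1.0 / O
    return inv / inv.sum()


def _as_matrix(view: OmicsView | np.ndarray) -> np.ndarray:
    return view.matrix if isinstance(view, OmicsView) else np.asarray(view, dtype=float)


def shared_objective(
    views: list[OmicsView | np.ndarray],
    W: list[np.ndarray],
    Ys: np.ndarray,
    Zs: np.ndarray,
    alpha: np.ndarray,
) -> tuple[float, np.ndarray]:
    """Evaluate the shared objective; returns (total, per-view residuals O_i)."""
    mats = [_as_matrix(v) for v in views]
    O = np.empty(len(mats))
    YsZs = Ys @ Zs
    for i, (Xi, Wi) in enumerate(zip(mats, W)):
        R = Xi - Wi @ YsZs
        O[i] = float(np.sum(R * R))
    total = float(np.sum(np.asarray(alpha) ** 2 * O) + np.sum(Zs * Zs))
    return total, O


# ---------------------------------------------------------------------------
# shared model and cooperative fit
# ---------------------------------------------------------------------------

@dataclass
class SharedModel:
    """State of the fitted shared anchor graph.

    ``Ys`` (d x m) has orthonormal columns; ``Zs`` (m x n) is nonnegative with
    unit column sums; each ``W[i]`` (d_i x d) has orthonormal columns; alpha
    lies on the probability simplex.  ``gcn_weights``/``adjacency``/``features``
    hold the per-view graph-convolution state used during cooperative fitting.
    """

    Ys: np.ndarray
    Zs: np.ndarray
    W: list[np.ndarray]
    alpha: np.ndarray
    embed_dim: int
    gcn_weights: list[list[np.ndarray]] = field(default_factory=list)
    adjacency: list[sparse.csr_matrix] = field(default_factory=list)
    features: list[np.ndarray] = field(default_factory=list)
    objective_trace: list[float] = field(default_factory=list)
    residuals: np.ndarray | None = None

    def save(self, path) -> None:
        """Dump the dense factors to a single .npz archive."""
        arrays = {"Ys": self.Ys, "Zs": self.Zs, "alpha": self.alpha}
        for i, Wi in enumerate(self.W):
            arrays[f"W{i}"] = Wi
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "SharedModel":
        with np.load(path) as data:
            W = [data[k] for k in sorted(data.files) if k.startswith("W")]
            return cls(
                Ys=data["Ys"],
                Zs=data["Zs"],
                W=W,
                alpha=data["alpha"],
                embed_dim=data["Ys"].shape[0],
            )


def _svd_reduce(X: np.ndarray, d: int, seed: int) -> np.ndarray:
    """Cells x d feature matrix via truncated SVD of X^T (zero-padded if rank-short)."""
    Xt = X.T
    r = min(d, min(Xt.shape) - 1) if min(Xt.shape) > 1 else 1
    r = max(r, 1)
    U, s, Vt = np.linalg.svd(Xt - Xt.mean(axis=0), full_matrices=False)
    H = U[:, :r] * s[:r]
    if r < d:
        H = np.hstack([H, np.zeros((H.shape[0], d - r))])
    return H


class _Adam:
    """Minimal Adam optimizer over a flat list of numpy arrays."""

    def __init__(self, params: list[np.ndarray], lr: float, weight_decay: float):
        self.lr = lr
        self.wd = weight_decay
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        for p, g, m, v in zip(params, grads, self.m, self.v):
            g = g + self.wd * p
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _gcn_forward_cached(
    Ahat: sparse.csr_matrix, H0: np.ndarray, weights: list[np.ndarray]
) -> tuple[np.ndarray, list]:
    """Forward pass keeping the per-layer caches needed for backprop."""
    cache = []
    out = H0
    for li, Wl in enumerate(weights):
        P = Ahat @ out  # propagate
        pre = P @ Wl
        cache.append((P, pre))
        out = np.maximum(pre, 0.0) if li < len(weights) - 1 else pre
    return out, cache


def _gcn_backward(
    Ahat: sparse.csr_matrix,
    weights: list[np.ndarray],
    cache: list,
    dZ: np.ndarray,
) -> list[np.ndarray]:
    grads: list[np.ndarray] = [np.empty(0)] * len(weights)
    grad_out = dZ
    for li in range(len(weights) - 1, -1, -1):
        P, pre = cache[li]
        if li < len(weights) - 1:
            grad_out = grad_out * (pre > 0)
        grads[li] = P.T @ grad_out
        if li > 0:
            grad_out = Ahat @ (grad_out @ weights[li].T)
    return grads


def fit_shared(
    views: list[OmicsView | np.ndarray],
    config: RunConfig,
    Y0: np.ndarray,
) -> SharedModel:
    """Cooperative optimization of the shared anchor graph across views.

    Alternates a gradient phase — Adam steps on per-view GCN weights, with
    Z_s tied to the GCN aggregation — with closed-form cycles
    (W -> Z_s -> Y_s -> alpha) every ``config.validate_every`` iterations.
    The GCN's Z_s proposal is adopted at a validation point only when it does
    not increase the objective, so the recorded per-cycle objective trace is
    non-increasing.  ``Y0`` is the merged-view initial anchor matrix; it is
    projected into the shared d-dimensional space and orthonormalized by QR
    to seed ``Ys``.
    """
    if len(views) < 2:
        raise ValueError("cooperative fitting requires at least two views")
    mats = [_as_matrix(v) for v in views]
    n = mats[0].shape[1]
    if any(X.shape[1] != n for X in mats):
        raise ValueError("all views must share the same number of cells")
    v = len(mats)
    m = Y0.shape[1]
    d = config.embed_dim or m
    if d < m:
        raise ValueError("shared dimension d must be at least the anchor count m")
    if any(X.shape[0] < d for X in mats):
        raise ValueError("every view must have at least d features")
    rng = np.random.default_rng(config.seed)

    # --- initialization -----------------------------------------------------
    # shared anchors: project merged Y0 to d dims by truncated SVD, then QR
    U, _, _ = np.linalg.svd(Y0, full_matrices=False)
    P = U[:, :d].T if U.shape[1] >= d else np.vstack(
        [U.T, np.zeros((d - U.shape[1], U.shape[0]))]
    )
    Q, _ = np.linalg.qr(P @ Y0)
    Ys = Q[:, :m]
    alpha = np.full(v, 1.0 / v)

    features = [_svd_reduce(X, d, config.seed) for X in mats]
    adjacency = [build_knn_adjacency(H, min(config.knn_k, n - 1)) for H in features]
    Ahats = [normalized_adjacency(A) for A in adjacency]
    gcn_weights = [
        init_gcn_weights(rng, config.gcn_layers, d, d) for _ in range(v)
    ]

    gcn_out = [
        _gcn_forward_cached(Ah, H, Wl)[0]
        for Ah, H, Wl in zip(Ahats, features, gcn_weights)
    ]
    Zs = project_columns_to_simplex(shared_Zs_from_gcn(Ys, gcn_out, alpha))
    W = [update_W(X, Ys, Zs) for X in mats]

    obj, O = shared_objective(mats, W, Ys, Zs, alpha)
    trace = [obj]

    flat_params = [Wl for per_view in gcn_weights for Wl in per_view]
    adam = _Adam(flat_params, lr=config.gcn_lr, weight_decay=config.gcn_weight_decay)
    sq1 = float((alpha**2).sum()) + 1.0
    # fixed per-phase pieces: C_i = Y_s^T W_i^T X_i, recomputed when W/Ys change
    C = [Ys.T @ Wi.T @ Xi for Wi, Xi in zip(W, mats)]

    for it in range(1, config.max_iterations + 1):
        # ---- GCN gradient step (closed-form blocks frozen) -----------------
        outs, caches = [], []
        for Ah, H, Wl in zip(Ahats, features, gcn_weights):
            out, cache = _gcn_forward_cached(Ah, H, Wl)
            outs.append(out)
            caches.append(cache)
        Zs_gcn = shared_Zs_from_gcn(Ys, outs, alpha)
        # dL/dZs for L = sum alpha^2 ||X - W Ys Zs||^2 + ||Zs||^2, using
        # (W Ys)^T W Ys = I:  G = 2[(sum alpha^2 + 1) Zs - sum alpha^2 C_i]
        G = 2.0 * (sq1 * Zs_gcn - sum(a**2 * Ci for a, Ci in zip(alpha, C)))
        grads: list[np.ndarray] = []
        for i in range(v):
            dZ = alpha[i] * (Ys @ G).T  # n x d
            grads.extend(_gcn_backward(Ahats[i], gcn_weights[i], caches[i], dZ))
        adam.step(flat_params, grads)

        # ---- closed-form validation cycle ----------------------------------
        if it % config.validate_every == 0 or it == config.max_iterations:
            outs = [
                _gcn_forward_cached(Ah, H, Wl)[0]
                for Ah, H, Wl in zip(Ahats, features, gcn_weights)
            ]
            Zs_prop = project_columns_to_simplex(
                shared_Zs_from_gcn(Ys, outs, alpha)
            )
            obj_prop, _ = shared_objective(mats, W, Ys, Zs_prop, alpha)
            if obj_prop <= trace[-1]:
                Zs = Zs_prop
            W = [update_W(X, Ys, Zs) for X in mats]
            Zs = update_Zs(mats, W, Ys, alpha)
            Ys = update_Ys(mats, W, Zs, alpha)
            _, O = shared_objective(mats, W, Ys, Zs, alpha)
            alpha = update_alpha(O)
            obj, O = shared_objective(mats, W, Ys, Zs, alpha)
            if not np.isfinite(obj):
                raise NumericalFailure(
                    "shared objective diverged during the closed-form phase"
                )
            prev = trace[-1]
            trace.append(obj)
            sq1 = float((alpha**2).sum()) + 1.0
            C = [Ys.T @ Wi.T @ Xi for Wi, Xi in zip(W, mats)]
            if abs(prev - obj) <= config.tolerance * max(1.0, abs(prev)):
                break

    return SharedModel(
        Ys=Ys,
        Zs=Zs,
        W=W,
        alpha=alpha,
        embed_dim=d,
        gcn_weights=gcn_weights,
        adjacency=adjacency,
        features=features,
        objective_trace=trace,
        residuals=O,
    )
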