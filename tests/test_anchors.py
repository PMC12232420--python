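import numpy as np
import pytest
from scipy.optimize import minimize

from scanchor import (
    OmicsView,
    RunConfig,
    build_knn_adjacency,
    fit_shared,
    fit_specific_graph,
    gcn_forward,
    init_anchors,
    project_columns_to_simplex,
    shared_Zs_from_gcn,
    shared_objective,
    update_W,
    update_Ys,
    update_Zs,
    update_alpha,
)
from scanchor.anchors import normalized_adjacency

from conftest import random_column_stochastic, random_orthonormal


# ---------------------------------------------------------------------------
# simplex projection
# ---------------------------------------------------------------------------

def qp_simplex_projection(v):
    """Independent oracle: solve min ||z - v||^2 on the simplex with SLSQP."""
    n = v.size
    res = minimize(
        lambda z: np.sum((z - v) ** 2),
        np.full(n, 1.0 / n),
        jac=lambda z: 2 * (z - v),
        bounds=[(0, None)] * n,
        constraints=[{"type": "eq", "fun": lambda z: z.sum() - 1.0}],
        method="SLSQP",
        options={"ftol": 1e-14, "maxiter": 500},
    )
    return res.x


def test_simplex_projection_examples():
    np.testing.assert_allclose(
        project_columns_to_simplex(np.array([[0.2], [0.3]])), [[0.45], [0.55]]
    )
    np.testing.assert_allclose(
        project_columns_to_simplex(np.array([[2.0], [0.0]])), [[1.0], [0.0]]
    )


@pytest.mark.parametrize("dim", [5, 50])
def test_simplex_projection_matches_qp_oracle(rng, dim):
    vs = rng.normal(scale=3.0, size=(50, dim))
    vs[0] = -np.abs(vs[0])  # all-negative column
    vs[1, :] = 0.7  # exact ties
    ours = project_columns_to_simplex(vs.T)
    for j in range(vs.shape[0]):
        np.testing.assert_allclose(ours[:, j], qp_simplex_projection(vs[j]), atol=1e-6)
    assert np.all(ours >= 0)
    np.testing.assert_allclose(ours.sum(axis=0), 1.0, atol=1e-8)


# ---------------------------------------------------------------------------
# anchors
# ---------------------------------------------------------------------------

def test_init_anchors_singleton_clusters_permute_cells(rng):
    X = rng.normal(size=(5, 8))
    Y = init_anchors(X, m=8, seed=0)
    # every centroid must be one of the cells, each used once
    used = set()
    for j in range(8):
        dists = np.linalg.norm(X - Y[:, [j]], axis=0)
        hit = int(np.argmin(dists))
        assert dists[hit] < 1e-10
        used.add(hit)
    assert used == set(range(8))


def test_init_anchors_recovers_point_masses(rng):
    c1, c2 = np.full(4, -5.0), np.full(4, 5.0)
    X = np.hstack(
        [c1[:, None] + rng.normal(scale=1e-9, size=(4, 30)),
         c2[:, None] + rng.normal(scale=1e-9, size=(4, 30))]
    )
    Y = init_anchors(X, m=2, seed=3, subsample_frac=1.0)
    got = sorted(Y[0])
    assert abs(got[0] - (-5.0)) < 1e-6 and abs(got[1] - 5.0) < 1e-6


def test_init_anchors_deterministic(rng):
    X = rng.normal(size=(6, 40))
    np.testing.assert_array_equal(
        init_anchors(X, 4, seed=9), init_anchors(X, 4, seed=9)
    )
    with pytest.raises(ValueError):
        init_anchors(X, 41, seed=0)


# ---------------------------------------------------------------------------
# specific anchor graph
# ---------------------------------------------------------------------------

def test_specific_graph_single_anchor_forces_ones(rng):
    X = rng.normal(size=(4, 10)) ** 2
    model = fit_specific_graph(X, X.mean(axis=1, keepdims=True), rho=0.5)
    np.testing.assert_allclose(model.Z, np.ones((1, 10)))


def test_specific_graph_orthogonal_identity_fit(rng):
    Q = random_orthonormal(rng, 8, 6)
    model = fit_specific_graph(Q, Q.copy(), rho=0.0, refit_anchors=False)
    # Z = I is feasible with objective 0, so the fit must do at least as well
    assert model.objective_trace[-1] <= np.sum((Q - Q @ np.eye(6)) ** 2) + 1e-8


def test_specific_graph_descends_and_satisfies_constraints(rng):
    X = rng.normal(size=(10, 50))
    Y0 = X[:, rng.choice(50, 5, replace=False)]
    model = fit_specific_graph(X, Y0, rho=1.0)
    Z0 = np.full((5, 50), 0.2)
    initial = np.sum((X - Y0 @ Z0) ** 2) + 1.0 * np.sum(Z0**2)
    assert model.objective_trace[-1] <= initial
    trace = model.objective_trace
    assert all(a >= b - 1e-8 for a, b in zip(trace, trace[1:]))
    assert np.all(model.Z >= 0)
    np.testing.assert_allclose(model.Z.sum(axis=0), 1.0, atol=1e-8)


# ---------------------------------------------------------------------------
# kNN graph and GCN
# ---------------------------------------------------------------------------

def test_knn_two_far_pairs():
    pts = np.array([[0.0, 1.0], [0.05, 1.0], [10.0, -9.0], [10.1, -9.0]])
    A = build_knn_adjacency(pts, k=1).toarray()
    expected = np.zeros((4, 4))
    expected[0, 1] = expected[1, 0] = 1
    expected[2, 3] = expected[3, 2] = 1
    np.testing.assert_array_equal(A, expected)


def test_knn_symmetric_and_zero_diagonal(rng):
    A = build_knn_adjacency(rng.normal(size=(20, 5)), k=3).toarray()
    np.testing.assert_array_equal(A, A.T)
    assert np.all(np.diag(A) == 0)
    assert set(np.unique(A)) <= {0.0, 1.0}


def test_knn_identical_points_ties_by_index():
    pts = np.ones((3, 2))
    A = build_knn_adjacency(pts, k=1).toarray()
    # each picks its lowest-index other node; symmetrization closes the set
    assert A[0, 1] == 1 and A[1, 0] == 1 and A[2, 0] == 1
    assert np.all(np.diag(A) == 0)


def test_knn_k_too_large():
    with pytest.raises(ValueError):
        build_knn_adjacency(np.ones((3, 2)), k=3)


def test_gcn_edgeless_graph_collapses_to_mlp(rng):
    H = rng.normal(size=(6, 4))
    W1, W2 = rng.normal(size=(4, 3)), rng.normal(size=(3, 3))
    A = np.zeros((6, 6))
    out = gcn_forward(A, H, [W1, W2])
    np.testing.assert_allclose(out, np.maximum(H @ W1, 0) @ W2, atol=1e-12)


def test_gcn_identical_rows_on_complete_graph(rng):
    n = 5
    A = np.ones((n, n)) - np.eye(n)
    H = np.tile(rng.normal(size=(1, 3)), (n, 1))
    out = gcn_forward(A, H, [rng.normal(size=(3, 2))])
    for i in range(1, n):
        np.testing.assert_allclose(out[i], out[0])


def test_gcn_path_graph_matches_hand_computation():
    """3-node path, one layer: out = D'^-1/2 A' D'^-1/2 H W computed by hand."""
    A = np.array([[0.0, 1, 0], [1, 0, 1], [0, 1, 0]])
    H = np.array([[1.0, 0], [0, 1], [1, 1]])
    W = np.array([[2.0], [1.0]])
    s6 = 1 / np.sqrt(6)
    Ahat = np.array([[0.5, s6, 0.0], [s6, 1 / 3, s6], [0.0, s6, 0.5]])
    np.testing.assert_allclose(gcn_forward(A, H, [W]), Ahat @ H @ W, atol=1e-12)
    np.testing.assert_allclose(normalized_adjacency(A).toarray(), Ahat, atol=1e-12)


def test_shared_zs_aggregation(rng):
    m = 4
    Ys = np.eye(m)
    out = rng.normal(size=(7, m))
    np.testing.assert_allclose(shared_Zs_from_gcn(Ys, [out], [1.0]), out.T)
    # two identical views at half weight each equal the single view
    np.testing.assert_allclose(
        shared_Zs_from_gcn(Ys, [out, out], [0.5, 0.5]),
        shared_Zs_from_gcn(Ys, [out], [1.0]),
    )
    # brute-force term-by-term sum on a random two-view instance
    Ys2 = random_orthonormal(rng, 5, 4)
    outs = [rng.normal(size=(7, 5)) for _ in range(2)]
    alpha = np.array([0.3, 0.7])
    expected = alpha[0] * Ys2.T @ outs[0].T + alpha[1] * Ys2.T @ outs[1].T
    np.testing.assert_allclose(shared_Zs_from_gcn(Ys2, outs, alpha), expected)


# ---------------------------------------------------------------------------
# closed-form block updates
# ---------------------------------------------------------------------------

def test_update_W_fixed_points(rng):
    Ys = np.eye(2)
    Zs = random_column_stochastic(rng, 2, 6)
    # engineer Xi so that M = Xi Zs^T Ys^T is the identity / an orthogonal Q
    M = np.eye(2)
    Xi = M @ np.linalg.pinv(Zs.T @ Ys.T)
    np.testing.assert_allclose(update_W(Xi, Ys, Zs), np.eye(2), atol=1e-8)
    th = 0.7
    Q = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    Xi = Q @ np.linalg.pinv(Zs.T @ Ys.T)
    np.testing.assert_allclose(update_W(Xi, Ys, Zs), Q, atol=1e-8)


def test_update_W_beats_rotation_grid(rng):
    Ys = random_orthonormal(rng, 2, 2)
    Zs = random_column_stochastic(rng, 2, 8)
    Xi = rng.normal(size=(2, 8))
    M = Xi @ Zs.T @ Ys.T
    W = update_W(Xi, Ys, Zs)
    ours = np.trace(W.T @ M)
    best = -np.inf
    for th in np.arange(0, 2 * np.pi, 0.001):
        c, s = np.cos(th), np.sin(th)
        for R in (np.array([[c, -s], [s, c]]), np.array([[c, s], [s, -c]])):
            best = max(best, np.trace(R.T @ M))
    assert ours >= best - 1e-3
    np.testing.assert_allclose(W.T @ W, np.eye(2), atol=1e-6)


def test_update_Ys_oracle(rng):
    d, m = 3, 2
    views = [rng.normal(size=(6, 10)), rng.normal(size=(9, 10))]
    W = [random_orthonormal(rng, 6, d), random_orthonormal(rng, 9, d)]
    Zs = random_column_stochastic(rng, m, 10)
    alpha = np.array([0.6, 0.4])
    Ys = update_Ys(views, W, Zs, alpha)
    N = sum(a**2 * Wi.T @ Xi @ Zs.T for a, Wi, Xi in zip(alpha, W, views))
    ours = np.trace(Ys.T @ N)
    samples = max(
        np.trace(random_orthonormal(rng, d, m).T @ N) for _ in range(10_000)
    )
    assert ours >= samples - 1e-3
    np.testing.assert_allclose(Ys.T @ Ys, np.eye(m), atol=1e-6)


def test_update_Zs_returns_feasible_target(rng):
    """When the quadratic target is already column-stochastic it is returned."""
    d = m = 3
    W = [random_orthonormal(rng, 7, d)]
    Ys = random_orthonormal(rng, d, m)
    Zstar = random_column_stochastic(rng, m, 9)
    X = W[0] @ Ys @ Zstar
    out = update_Zs([X], W, Ys, np.array([1.0]), include_regularizer=False)
    np.testing.assert_allclose(out, Zstar, atol=1e-8)


def test_update_Zs_uniform_for_constant_target(rng):
    d = m = 3
    W = [np.eye(4)[:, :3]]
    Ys = np.eye(3)
    X = np.ones((4, 5))
    out = update_Zs([X], W, Ys, np.array([1.0]))
    # Ys^T W^T X has equal entries per column -> projection is uniform
    np.testing.assert_allclose(out, np.full((3, 5), 1 / 3), atol=1e-10)


def test_update_Zs_beats_random_feasible_points(rng):
    d, m, n = 4, 3, 12
    views = [rng.normal(size=(8, n)), rng.normal(size=(10, n))]
    W = [random_orthonormal(rng, 8, d), random_orthonormal(rng, 10, d)]
    Ys = random_orthonormal(rng, d, m)
    alpha = np.array([0.5, 0.5])
    Zs = update_Zs(views, W, Ys, alpha)
    ours, _ = shared_objective(views, W, Ys, Zs, alpha)
    for _ in range(1000):
        cand = random_column_stochastic(rng, m, n)
        val, _ = shared_objective(views, W, Ys, cand, alpha)
        assert ours <= val + 1e-10


def test_update_alpha_examples_and_grid_oracle(rng):
    np.testing.assert_allclose(update_alpha(np.array([1.0, 1.0])), [0.5, 0.5])
    np.testing.assert_allclose(update_alpha(np.array([1.0, 3.0])), [0.75, 0.25])
    np.testing.assert_allclose(update_alpha(np.array([0.0, 2.0])), [1.0, 0.0])
    O = rng.uniform(0.5, 4.0, size=3)
    alpha = update_alpha(O)
    # 0.01-step simplex grid minimizer of sum alpha^2 O
    best, best_val = None, np.inf
    for a1 in np.arange(0, 1.0001, 0.01):
        for a2 in np.arange(0, 1.0001 - a1, 0.01):
            a = np.array([a1, a2, 1 - a1 - a2])
            val = float(np.sum(a**2 * O))
            if val < best_val:
                best, best_val = a, val
    assert np.max(np.abs(alpha - best)) <= 0.011
    assert float(np.sum(alpha**2 * O)) <= best_val + 1e-12


def test_shared_objective_perfect_reconstruction(rng):
    d, m, n = 3, 3, 8
    W = [random_orthonormal(rng, 6, d), random_orthonormal(rng, 7, d)]
    Ys = random_orthonormal(rng, d, m)
    Zs = random_column_stochastic(rng, m, n)
    views = [W[0] @ Ys @ Zs, W[1] @ Ys @ Zs]
    alpha = np.array([0.4, 0.6])
    total, O = shared_objective(views, W, Ys, Zs, alpha)
    np.testing.assert_allclose(O, 0.0, atol=1e-18)
    np.testing.assert_allclose(total, np.sum(Zs**2))
    # residuals are independent of alpha
    _, O2 = shared_objective(views, W, Ys, Zs, np.array([0.9, 0.1]))
    np.testing.assert_allclose(O, O2)


def test_shared_objective_brute_force(rng):
    views = [rng.normal(size=(5, 6)), rng.normal(size=(7, 6))]
    W = [random_orthonormal(rng, 5, 3), random_orthonormal(rng, 7, 3)]
    Ys = random_orthonormal(rng, 3, 2)
    Zs = random_column_stochastic(rng, 2, 6)
    alpha = np.array([0.3, 0.7])
    total, O = shared_objective(views, W, Ys, Zs, alpha)
    expected = sum(
        a**2 * np.sum((X - Wi @ Ys @ Zs) ** 2)
        for a, X, Wi in zip(alpha, views, W)
    ) + np.sum(Zs**2)
    np.testing.assert_allclose(total, expected)


def test_each_block_update_never_increases_objective(rng):
    """Every closed-form update applied alone is a descent step."""
    for _ in range(50):
        d, m, n = 4, 3, 15
        dims = [8, 12]
        views = [rng.normal(size=(di, n)) for di in dims]
        W = [random_orthonormal(rng, di, d) for di in dims]
        Ys = random_orthonormal(rng, d, m)
        Zs = random_column_stochastic(rng, m, n)
        alpha = rng.dirichlet(np.ones(2))
        base, O = shared_objective(views, W, Ys, Zs, alpha)

        W_new = [update_W(X, Ys, Zs) for X in views]
        assert shared_objective(views, W_new, Ys, Zs, alpha)[0] <= base + 1e-8

        Zs_new = update_Zs(views, W, Ys, alpha)
        assert shared_objective(views, W, Ys, Zs_new, alpha)[0] <= base + 1e-8

        Ys_new = update_Ys(views, W, Zs, alpha)
        assert shared_objective(views, W, Ys_new, Zs, alpha)[0] <= base + 1e-8

        alpha_new = update_alpha(O)
        assert shared_objective(views, W, Ys, Zs, alpha_new)[0] <= base + 1e-8


# ---------------------------------------------------------------------------
# cooperative fit
# ---------------------------------------------------------------------------

def _planted_instance(rng, dims=(20, 30), d=4, m=4, n=60):
    W_true = [random_orthonormal(rng, di, d) for di in dims]
    Ys_true = random_orthonormal(rng, d, m)
    Zs_true = random_column_stochastic(rng, m, n)
    views = [Wi @ Ys_true @ Zs_true for Wi in W_true]
    return views, W_true, Ys_true, Zs_true


def _config(**kw):
    defaults = dict(
        n_clusters=2,
        anchor_multiplier=10,
        max_iterations=120,
        validate_every=10,
        knn_k=5,
        seed=0,
    )
    defaults.update(kw)
    return RunConfig(**defaults)


def test_fit_shared_reaches_planted_objective(rng):
    views, W_true, Ys_true, Zs_true = _planted_instance(rng)
    cfg = _config(embed_dim=None, anchor_multiplier=10, n_clusters=2)
    # m = 20 anchors in d = 20 dims exceeds the planted rank; use Y0 from data
    Y0 = init_anchors(np.vstack(views), cfg.n_anchors, seed=0)
    model = fit_shared(views, cfg, Y0)
    planted = np.sum(Zs_true**2)  # residuals vanish at the planted truth
    assert model.objective_trace[-1] <= planted + np.sum(Zs_true**2)


def test_fit_shared_identical_views_balanced_alpha(rng):
    X = rng.normal(size=(25, 50))
    cfg = _config()
    Y0 = init_anchors(np.vstack([X, X]), cfg.n_anchors, seed=1)
    model = fit_shared([X, X.copy()], cfg, Y0)
    np.testing.assert_allclose(model.alpha, [0.5, 0.5], atol=1e-6)


def test_fit_shared_deterministic(rng):
    X1 = rng.normal(size=(22, 40))
    X2 = rng.normal(size=(28, 40))
    cfg = _config(max_iterations=40)
    Y0 = init_anchors(np.vstack([X1, X2]), cfg.n_anchors, seed=2)
    a = fit_shared([X1, X2], cfg, Y0)
    b = fit_shared([X1, X2], cfg, Y0)
    np.testing.assert_array_equal(a.Zs, b.Zs)
    np.testing.assert_array_equal(a.alpha, b.alpha)


def test_fit_shared_constraints_and_monotone_trace(rng):
    X1 = rng.normal(size=(22, 40))
    X2 = rng.normal(size=(30, 40))
    cfg = _config(max_iterations=60)
    Y0 = init_anchors(np.vstack([X1, X2]), cfg.n_anchors, seed=3)
    model = fit_shared([X1, X2], cfg, Y0)
    m, d = cfg.n_anchors, model.embed_dim
    np.testing.assert_allclose(model.Ys.T @ model.Ys, np.eye(m), atol=1e-6)
    for Wi in model.W:
        np.testing.assert_allclose(Wi.T @ Wi, np.eye(d), atol=1e-6)
    assert np.all(model.Zs >= 0)
    np.testing.assert_allclose(model.Zs.sum(axis=0), 1.0, atol=1e-8)
    assert np.all(model.alpha >= 0)
    assert abs(model.alpha.sum() - 1.0) < 1e-10
    trace = model.objective_trace
    assert all(a >= b - 1e-8 for a, b in zip(trace, trace[1:]))
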