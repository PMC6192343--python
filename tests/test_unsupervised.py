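"""PCA, sparse PCA and gene shaving: identities, planted recovery, null behavior."""

import numpy as np
import pytest

import thermosig as ts
from thermosig.unsupervised import _r2_curve, _shave_nest


def _matrix(vals, prefix="g"):
    p, n = vals.shape
    return ts.ExpressionMatrix(
        [f"{prefix}{i}" for i in range(p)], [f"s{j}" for j in range(n)], vals
    )


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


def test_pca_two_samples_symmetric_scores():
    m = _matrix(np.array([[1.0, 3.0], [2.0, 6.0], [0.0, 4.0]]))
    res = ts.pca_project(m)
    assert res.scores.shape[1] == 1
    np.testing.assert_allclose(res.scores.sum(axis=0), 0.0, atol=1e-12)


def test_pca_reconstruction_identity():
    rng = np.random.default_rng(0)
    vals = rng.standard_normal((30, 8))
    m = _matrix(vals)
    res = ts.pca_project(m)
    centered = vals - vals.mean(axis=1, keepdims=True)
    recon = res.loadings @ res.scores.T
    np.testing.assert_allclose(recon, centered, atol=1e-8)
    assert (np.diff(res.variance_explained) <= 1e-12).all()


def test_pca_constant_matrix_warns():
    m = _matrix(np.full((4, 5), 3.0))
    with pytest.warns(UserWarning, match="constant"):
        res = ts.pca_project(m)
    assert res.scores.shape[1] == 0


def test_pca_separates_planted_groups(small_study):
    """Temperature groups are separable along PC1 (positive silhouette)."""
    from sklearn.metrics import silhouette_score

    year = small_study.params.years[0]
    mat = small_study.matrices[year]
    sig = small_study.planted_signature()
    sub = mat.subset_probes(sorted(sig.probe_ids))
    res = ts.pca_project(sub)
    groups = small_study.metadata.for_samples(sub.sample_ids)["temperature_group"]
    assert silhouette_score(res.scores[:, :1], groups) > 0


# ---------------------------------------------------------------------------
# Sparse PCA
# ---------------------------------------------------------------------------


def test_sparse_pca_exact_cardinality_and_union():
    rng = np.random.default_rng(1)
    m = _matrix(rng.standard_normal((250, 12)))
    res = ts.sparse_pca(m, n_components=3, k=100)
    assert all(len(s) == 100 for s in res.supports)
    union = set().union(*map(set, res.supports))
    assert len(union) <= 300
    sig = ts.components_to_signature(res, [2, 3], name="sPC2+3")
    assert len(sig) <= 200


def test_sparse_pca_planted_support_recovery():
    rng = np.random.default_rng(2)
    n, p, k = 10, 60, 8
    base = rng.standard_normal(n) * 3
    vals = rng.standard_normal((p, n)) * 0.05
    vals[:k] += np.outer(rng.uniform(1, 2, k), base)
    res = ts.sparse_pca(_matrix(vals), n_components=1, k=k)
    assert set(res.supports[0]) == {f"g{i}" for i in range(k)}


def test_sparse_pca_unconstrained_limit_matches_pca():
    rng = np.random.default_rng(3)
    m = _matrix(rng.standard_normal((40, 10)))
    res = ts.sparse_pca(m, n_components=1, k=40)
    pca = ts.pca_project(m)
    u = np.zeros(40)
    idx = {p: i for i, p in enumerate(m.probe_ids)}
    for pid, val in zip(res.supports[0], res.loadings[0]):
        u[idx[pid]] = val
    cos = abs(u @ pca.loadings[:, 0]) / np.linalg.norm(u)
    assert cos >= 0.999


def test_sign_invariance_of_supports():
    """Flipping the data's sign flips components but not supports/signatures."""
    rng = np.random.default_rng(4)
    vals = rng.standard_normal((50, 9))
    r1 = ts.sparse_pca(_matrix(vals), n_components=2, k=10)
    r2 = ts.sparse_pca(_matrix(-vals), n_components=2, k=10)
    assert [set(s) for s in r1.supports] == [set(s) for s in r2.supports]


# ---------------------------------------------------------------------------
# Gene shaving
# ---------------------------------------------------------------------------


def test_shave_nest_sizes_alpha_half():
    rng = np.random.default_rng(5)
    m = _matrix(rng.standard_normal((8, 6)))
    res = ts.gene_shave(m, ts.ShavingParams(alpha=0.5, n_permutations=2, rng_seed=0))
    assert res.clusters[0].sizes == [8, 4, 2, 1]


def test_shave_nest_strictly_nested_and_top_gene_survives():
    rng = np.random.default_rng(6)
    X = rng.standard_normal((30, 10))
    X -= X.mean(axis=1, keepdims=True)
    nest, orientations = _shave_nest(X, 0.2)
    for a, b in zip(nest, nest[1:]):
        assert set(b) < set(a)
    # the top-scoring gene of each step survives to the next set
    from thermosig.unsupervised import _leading_component

    for a, b in zip(nest, nest[1:]):
        c = _leading_component(X[a])
        top = a[np.argmax(np.abs(X[a] @ c))]
        assert top in b


def test_shaving_planted_block_recovery():
    rng = np.random.default_rng(3)
    n, p = 20, 200
    vals = rng.standard_normal((p, n))
    base = rng.standard_normal(n) * 2
    vals[:10] = base[None, :] + rng.standard_normal((10, n)) * 0.4
    res = ts.gene_shave(_matrix(vals), ts.ShavingParams(rng_seed=0))
    sel = set(res.clusters[0].members)
    truth = {f"g{i}" for i in range(10)}
    assert len(sel & truth) / len(sel | truth) >= 0.8


def test_shaving_null_noise_gap_small():
    """Pure i.i.d. noise: the gap stays below 0.2 everywhere (20 seeds)."""
    for seed in range(20):
        rng = np.random.default_rng(seed)
        m = _matrix(rng.standard_normal((40, 15)))
        res = ts.gene_shave(m, ts.ShavingParams(n_permutations=10, rng_seed=seed))
        assert res.clusters[0].gap.max() < 0.2


def test_shaving_r2_matches_brute_force_small_instance():
    """For <=8 genes the selected R2 equals an independent recomputation."""
    rng = np.random.default_rng(8)
    vals = rng.standard_normal((8, 12))
    m = _matrix(vals)
    res = ts.gene_shave(m, ts.ShavingParams(alpha=0.3, n_permutations=3, rng_seed=1))
    cl = res.clusters[0]
    X = vals - vals.mean(axis=1, keepdims=True)
    idx = {p: i for i, p in enumerate(m.probe_ids)}
    # independent recomputation of the R2 curve over the recorded nest,
    # orienting members by their inner product with the nest level's own
    # leading direction (dense SVD, independent of the power iteration)
    for level, members in enumerate(cl.nest):
        rows = np.array([idx[g] for g in members])
        sub = X[rows]
        _, _, vt = np.linalg.svd(sub, full_matrices=False)
        sign = np.where(sub @ vt[0] >= 0, 1.0, -1.0)
        mean_profile = (sub * sign[:, None]).mean(axis=0)
        r2 = mean_profile.var(ddof=1) / sub.var(axis=1, ddof=1).mean()
        assert cl.r2[level] == pytest.approx(r2, abs=1e-9)
    assert cl.r2[np.argmax(cl.gap)] == pytest.approx(
        cl.r2[cl.sizes.index(cl.selected_size)]
    )


def test_shaving_deterministic_under_seed(small_study):
    year = small_study.params.years[0]
    sub = small_study.matrices[year].subset_probes(
        sorted(small_study.planted_signature().probe_ids)
    )
    p = ts.ShavingParams(n_permutations=5, rng_seed=9)
    r1 = ts.gene_shave(sub, p)
    r2 = ts.gene_shave(sub, p)
    assert r1.clusters[0].members == r2.clusters[0].members
    np.testing.assert_array_equal(r1.clusters[0].gap, r2.clusters[0].gap)


def test_components_to_signature_contracts():
    rng = np.random.default_rng(10)
    m = _matrix(rng.standard_normal((30, 8)))
    res = ts.sparse_pca(m, n_components=2, k=5)
    sig = ts.components_to_signature(res, [1, 2], name="u")
    assert len(sig) <= 10  # overlap allowed, no duplicates
    with pytest.raises(ts.ThermosigError):
        ts.components_to_signature(res, [5], name="oops")
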