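"""Feature-selecting unsupervised signature extraction.

Three routes from an expression matrix to a candidate probe set:

* plain PCA projection of the samples (for visual separation checks),
* cardinality-constrained sparse PCA by truncated power iteration with
  hard thresholding to the top-k absolute loadings and rank-1 deflation
  (each dimension selects exactly k probes), and
* gene shaving: repeatedly remove the fraction of genes least aligned
  with the leading principal component of the current gene set, score
  every nested cluster by the variance-explained ratio of its mean
  profile, and pick the cluster size maximising the gap over a
  within-row permutation null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import ExpressionMatrix, Signature, ThermosigError


@dataclass
class PCAResult:
    scores: np.ndarray  # samples x components
    loadings: np.ndarray  # probes x components
    variance_explained: np.ndarray  # per component
    sample_ids: list[str]
    probe_ids: list[str]


@dataclass
class SparsePCAResult:
    supports: list[list[str]]  # per component, probe IDs (size <= k)
    loadings: list[np.ndarray]  # per component, loadings on the support
    scores: np.ndarray  # samples x components
    k: int
    n_components: int
    sample_ids: list[str]
    converged: list[bool] = field(default_factory=list)


@dataclass
class ShavingParams:
    alpha: float = 0.10  # fraction shaved each step
    n_permutations: int = 20  # B, for the gap-statistic null
    max_clusters: int = 1
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ThermosigError(f"shave fraction must be in (0,1), got {self.alpha}")
        if self.n_permutations < 1:
            raise ThermosigError("need at least 1 permutation")


@dataclass
class ShavingCluster:
    sizes: list[int]  # strictly decreasing nest sizes
    nest: list[list[str]]  # member probe IDs at each size
    r2: np.ndarray  # observed variance-explained ratio per size
    r2_null: np.ndarray  # mean permutation-null R2 per size
    gap: np.ndarray  # r2 - r2_null
    selected_size: int
    members: list[str]  # members at the selected size
    mean_profile: np.ndarray  # cluster-mean expression across samples


@dataclass
class ShavingResult:
    clusters: list[ShavingCluster]
    params: ShavingParams
    sample_ids: list[str]


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


def pca_project(matrix: ExpressionMatrix, center: bool = True) -> PCAResult:
    """SVD-based PCA of samples on probe features (probe-wise centering)."""
    if matrix.shape[1] < 2:
        raise ThermosigError("PCA needs at least 2 samples")
    if matrix.has_missing():
        raise ThermosigError("PCA cannot handle missing values; impute or filter first")
    X = matrix.values
    Xc = X - X.mean(axis=1, keepdims=True) if center else X.copy()
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    n = matrix.shape[1]
    var = S**2 / max(n - 1, 1)
    nonzero = S > S.max() * 1e-12 if S.size and S.max() > 0 else np.zeros(S.size, bool)
    if not nonzero.any():
        warnings.warn("constant matrix: zero principal components", stacklevel=2)
    r = int(nonzero.sum())
    return PCAResult(
        scores=(Vt[:r].T * S[:r]),
        loadings=U[:, :r],
        variance_explained=var[:r],
        sample_ids=list(matrix.sample_ids),
        probe_ids=list(matrix.probe_ids),
    )


# ---------------------------------------------------------------------------
# Sparse PCA: truncated power iteration + deflation
# ---------------------------------------------------------------------------


def _hard_threshold(u: np.ndarray, k: int) -> np.ndarray:
    if k >= u.size:
        return u
    keep = np.argpartition(np.abs(u), -k)[-k:]
    out = np.zeros_like(u)
    out[keep] = u[keep]
    return out


def sparse_pca(
    matrix: ExpressionMatrix,
    n_components: int = 3,
    k: int = 100,
    max_iter: int = 500,
    tol: float = 1e-9,
) -> SparsePCAResult:
    """Sparse components with exact per-dimension cardinality min(k, n_probes).

    Each component is found by power iteration on the (deflated) data with
    hard thresholding to the top-k absolute loadings after every step;
    initialisation is the leading left singular vector of the current
    residual, making the procedure deterministic.
    """
    if k < 1:
        raise ThermosigError("k must be >= 1")
    if matrix.has_missing():
        raise ThermosigError("sparse PCA cannot handle missing values")
    X = matrix.values
    R = X - X.mean(axis=1, keepdims=True)
    p = R.shape[0]
    k_eff = min(k, p)
    supports: list[list[str]] = []
    loadings: list[np.ndarray] = []
    scores_cols: list[np.ndarray] = []
    converged: list[bool] = []
    probe_arr = np.asarray(matrix.probe_ids)
    for _ in range(n_components):
        U, S, Vt = np.linalg.svd(R, full_matrices=False)
        u = _hard_threshold(U[:, 0], k_eff)
        nrm = np.linalg.norm(u)
        u = u / nrm if nrm > 0 else U[:, 0]
        ok = False
        for _ in range(max_iter):
            w = R @ (R.T @ u)
            w = _hard_threshold(w, k_eff)
            nrm = np.linalg.norm(w)
            if nrm == 0:
                break
            w /= nrm
            if np.linalg.norm(w - u) < tol or np.linalg.norm(w + u) < tol:
                u = w
                ok = True
                break
            u = w
        if not ok:
            warnings.warn("sparse PCA did not converge; returning best iterate", stacklevel=2)
        # pad support to exactly k_eff probes (next-largest loadings) when
        # thresholding left zeros among the top-k slots
        supp_idx = np.flatnonzero(u)
        if supp_idx.size < k_eff:
            dense = np.abs(U[:, 0])
            dense[supp_idx] = np.inf
            extra = np.argsort(-dense)[: k_eff]
            supp_idx = np.unique(np.concatenate([supp_idx, extra]))[:k_eff]
        supp_idx = np.sort(supp_idx[:k_eff])
        supports.append(list(probe_arr[supp_idx]))
        loadings.append(u[supp_idx])
        sc = R.T @ u
        scores_cols.append(sc)
        converged.append(ok)
        R = R - np.outer(u, u @ R)
    return SparsePCAResult(
        supports=supports,
        loadings=loadings,
        scores=np.column_stack(scores_cols),
        k=k_eff,
        n_components=n_components,
        sample_ids=list(matrix.sample_ids),
        converged=converged,
    )


# ---------------------------------------------------------------------------
# Gene shaving
# ---------------------------------------------------------------------------


def _leading_component(X: np.ndarray) -> np.ndarray:
    """Leading right singular vector (sample-space direction) of X."""
    # power iteration on the small n x n Gram matrix
    G = X.T @ X
    n = G.shape[0]
    v = np.ones(n) / np.sqrt(n)
    for _ in range(1000):
        w = G @ v
        nrm = np.linalg.norm(w)
        if nrm == 0:
            return v
        w /= nrm
        if np.linalg.norm(w - v) < 1e-12 or np.linalg.norm(w + v) < 1e-12:
            return w
        v = w
    return v


def _shave_nest(X: np.ndarray, alpha: float):
    """Nested index sets from all genes down to a single gene.

    Also returns, per nest level, the member orientations (sign of the
    inner product with that level's leading component): anti-correlated
    genes belong to the same cluster but must be sign-flipped before the
    cluster mean is formed, or up- and down-regulated members cancel.
    """
    idx = np.arange(X.shape[0])
    nest = [idx.copy()]
    orientations = []
    while idx.size > 1:
        sub = X[idx]
        c = _leading_component(sub)
        proj = sub @ c
        sign = np.where(proj >= 0, 1.0, -1.0)
        orientations.append(sign.copy())
        score = np.abs(proj)
        n_drop = max(int(np.floor(alpha * idx.size)), 1)
        n_drop = min(n_drop, idx.size - 1)
        order = np.argsort(score, kind="stable")
        keep = np.sort(order[n_drop:])
        idx = idx[keep]
        nest.append(idx.copy())
    orientations.append(np.ones(1))
    return nest, orientations


def _cluster_mean(X: np.ndarray, idx: np.ndarray, sign: np.ndarray) -> np.ndarray:
    return (X[idx] * sign[:, None]).mean(axis=0)


def _r2_curve(X: np.ndarray, nest, orientations) -> np.ndarray:
    """Variance of the oriented cluster mean over the average member variance."""
    out = np.empty(len(nest))
    for i, (idx, sign) in enumerate(zip(nest, orientations)):
        mean_profile = _cluster_mean(X, idx, sign)
        v_between = mean_profile.var(ddof=1)
        v_members = X[idx].var(axis=1, ddof=1).mean()
        out[i] = v_between / v_members if v_members > 0 else 0.0
    return out


def gene_shave(matrix: ExpressionMatrix, params: ShavingParams) -> ShavingResult:
    """Gene shaving with a within-row permutation gap statistic.

    Rows are centered; each shaving step removes the floor(alpha*|S|)
    genes (at least one) with the smallest |inner product| with the
    leading principal component of the current set. The observed R2 curve
    is compared against B full shaving runs on row-permuted data; the
    selected size maximises the gap. Further clusters are extracted after
    regressing every gene on the selected cluster mean.
    """
    if matrix.shape[0] < 3:
        raise ThermosigError("gene shaving needs at least 3 genes")
    if matrix.has_missing():
        raise ThermosigError("gene shaving cannot handle missing values")
    rng = np.random.default_rng(params.rng_seed)
    X = matrix.values - matrix.values.mean(axis=1, keepdims=True)
    probe_arr = np.asarray(matrix.probe_ids)
    clusters: list[ShavingCluster] = []
    for _ in range(params.max_clusters):
        if not np.any(X.var(axis=1) > 0):
            warnings.warn("degenerate zero-variance gene set; stopping", stacklevel=2)
            break
        nest, orientations = _shave_nest(X, params.alpha)
        sizes = [int(ix.size) for ix in nest]
        r2 = _r2_curve(X, nest, orientations)
        null = np.zeros(len(nest))
        for _ in range(params.n_permutations):
            Xp = np.array([rng.permutation(row) for row in X])
            Xp -= Xp.mean(axis=1, keepdims=True)
            nest_p, orient_p = _shave_nest(Xp, params.alpha)
            null += _r2_curve(Xp, nest_p, orient_p)
        null /= params.n_permutations
        gap = r2 - null
        best = int(np.argmax(gap))
        members_idx = nest[best]
        members = list(probe_arr[members_idx])
        mean_profile = _cluster_mean(X, members_idx, orientations[best])
        clusters.append(
            ShavingCluster(
                sizes=sizes,
                nest=[list(probe_arr[ix]) for ix in nest],
                r2=r2,
                r2_null=null,
                gap=gap,
                selected_size=sizes[best],
                members=members,
                mean_profile=mean_profile,
            )
        )
        # orthogonalise: residuals of each gene regressed on the cluster mean
        mp = mean_profile
        denom = float(mp @ mp)
        if denom <= 0:
            break
        beta = (X @ mp) / denom
        X = X - np.outer(beta, mp)
        X -= X.mean(axis=1, keepdims=True)
    return ShavingResult(clusters=clusters, params=params, sample_ids=list(matrix.sample_ids))


# ---------------------------------------------------------------------------
# Signatures from components
# ---------------------------------------------------------------------------


def select_separating_components(
    result: SparsePCAResult, group_labels, min_t: float = 2.0
) -> list[int]:
    """1-based indices of components whose scores separate two groups.

    Separation is measured by the two-sample Welch t statistic of the
    component scores; components with |t| >= ``min_t`` are kept (the best
    single component when none reach it). Automates the study-style manual
    choice of "the dimensions showing the strongest separation".
    """
    labels = np.asarray([str(g) for g in group_labels])
    levels = list(dict.fromkeys(labels))
    if len(levels) != 2:
        raise ThermosigError("component selection needs exactly 2 groups")
    a, b = (labels == levels[0]), (labels == levels[1])
    tvals = []
    for j in range(result.scores.shape[1]):
        x, y = result.scores[a, j], result.scores[b, j]
        vx, vy = x.var(ddof=1) / x.size, y.var(ddof=1) / y.size
        denom = np.sqrt(vx + vy)
        tvals.append(abs(x.mean() - y.mean()) / denom if denom > 0 else 0.0)
    chosen = [j + 1 for j, t in enumerate(tvals) if t >= min_t]
    return chosen or [int(np.argmax(tvals)) + 1]


def components_to_signature(result, which, name: str) -> Signature:
    """Union of the selected components' supports / cluster members.

    ``which`` holds 1-based component indices for sparse PCA, or 1-based
    cluster indices for shaving results.
    """
    probes: set[str] = set()
    if isinstance(result, SparsePCAResult):
        for c in which:
            if not (1 <= c <= len(result.supports)):
                raise ThermosigError(f"component {c} out of range")
            probes |= set(result.supports[c - 1])
        prov = f"method=sparse_pca; components={list(which)}; k={result.k}"
    elif isinstance(result, ShavingResult):
        for c in which:
            if not (1 <= c <= len(result.clusters)):
                raise ThermosigError(f"cluster {c} out of range")
            probes |= set(result.clusters[c - 1].members)
        prov = (
            f"method=gene_shaving; clusters={list(which)}; "
            f"alpha={result.params.alpha}; B={result.params.n_permutations}"
        )
    else:
        raise ThermosigError(f"unsupported result type {type(result).__name__}")
    if not probes:
        raise ThermosigError("empty component selection")
    return Signature(name, frozenset(probes), None, prov)
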