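"""Temporal-concatenation group ICA (GICA).

Pipeline: per-subject temporal PCA -> concatenation -> group PCA -> extended
Infomax spatial ICA, optionally stabilized by ICASSO (many restarts, cluster
the estimates, keep centrotypes with a quality index), then dual-regression
back-reconstruction of subject-specific time courses and maps, and
template-based labeling with an artifact screen (|r| < 0.2 against every
template => artifact).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import skew

__all__ = [
    "ComponentSet",
    "ReductionOperators",
    "reduce_and_concat",
    "infomax_ica",
    "icasso_select",
    "back_reconstruct",
    "label_components",
    "amari_index",
]


@dataclass
class ComponentSet:
    """Spatial maps and (optionally) time courses from a decomposition.

    spatial_maps are z-scaled over the mask (mean 0, SD 1 per map).
    stability_iq is present only when ICASSO produced the set.
    """

    spatial_maps: np.ndarray  # (N, V)
    time_courses: np.ndarray | None = None  # (T, N) for a single subject
    stability_iq: np.ndarray | None = None  # (N,) in [0, 1]
    labels: list | None = None  # per component: network name or "artifact"
    template_correlations: list | None = None  # per component: (best |r|, template id)
    unstable: np.ndarray | None = None  # bool flags from ICASSO cluster-size rule
    converged: bool = True

    @property
    def n_components(self) -> int:
        return self.spatial_maps.shape[0]


@dataclass
class ReductionOperators:
    """Projections retained by reduce_and_concat for back-reconstruction."""

    subject_bases: list  # per subject, (T, n_subject_pcs) orthonormal
    group_basis: np.ndarray  # (M * n_subject_pcs, n_group_pcs) orthonormal
    subject_ids: list


def _zscale_maps(maps: np.ndarray) -> np.ndarray:
    maps = maps - maps.mean(axis=1, keepdims=True)
    sd = maps.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return maps / sd


def _fix_sign(maps: np.ndarray, time_courses: np.ndarray | None = None):
    """Flip each map (and its time course) so spatial skewness >= 0."""
    signs = np.where(skew(maps, axis=1) < 0, -1.0, 1.0)
    maps = maps * signs[:, None]
    if time_courses is not None:
        time_courses = time_courses * signs[None, :]
    return maps, time_courses


# ---------------------------------------------------------------------------
# dimension reduction
# ---------------------------------------------------------------------------

def reduce_and_concat(series, n_subject_pcs: int, n_group_pcs: int):
    """Temporal PCA per subject, concatenation, then group PCA.

    Subject data X_m is (T, V); its top ``n_subject_pcs`` temporal
    eigenvectors U_m give the reduced block U_m^T X_m (rows = reduced time
    dimension).  Blocks are stacked across subjects and reduced again to
    ``n_group_pcs`` rows.  Returns (Y, ops): Y is (n_group_pcs, V).
    """
    M = len(series)
    T = series[0].n_timepoints
    V = series[0].n_voxels
    if n_subject_pcs > min(T, V):
        raise ValueError(f"n_subject_pcs={n_subject_pcs} exceeds min(T,V)={min(T, V)}")
    if n_group_pcs > n_subject_pcs * M:
        raise ValueError(
            f"n_group_pcs={n_group_pcs} exceeds concatenated rows {n_subject_pcs * M}"
        )
    blocks = []
    bases = []
    for s in series:
        X = s.data - s.data.mean(axis=0)
        # eigenvectors of X X^T (T x T) = left singular vectors of X
        C = X @ X.T
        w, U = np.linalg.eigh(C)
        order = np.argsort(w)[::-1][:n_subject_pcs]
        U = U[:, order]
        bases.append(U)
        blocks.append(U.T @ X)
    concat = np.vstack(blocks)  # (M * p, V)
    rank = np.linalg.matrix_rank(concat)
    if n_group_pcs > rank:
        raise ValueError(f"n_group_pcs={n_group_pcs} exceeds concatenated rank {rank}")
    G = concat @ concat.T
    w, Q = np.linalg.eigh(G)
    order = np.argsort(w)[::-1][:n_group_pcs]
    Q = Q[:, order]
    Y = Q.T @ concat
    ops = ReductionOperators(
        subject_bases=bases, group_basis=Q, subject_ids=[s.subject_id for s in series]
    )
    return Y, ops


# ---------------------------------------------------------------------------
# extended Infomax ICA
# ---------------------------------------------------------------------------

def _whiten_rows(X: np.ndarray, n_components: int):
    """Whiten rows-as-variables; returns (Z, sphering) with Z Z^T / n = I."""
    X = X - X.mean(axis=1, keepdims=True)
    C = X @ X.T / X.shape[1]
    w, Q = np.linalg.eigh(C)
    order = np.argsort(w)[::-1][:n_components]
    w, Q = w[order], Q[:, order]
    if w[-1] <= 0:
        raise ValueError("data rank below requested number of components")
    sph = (Q / np.sqrt(w)).T  # (n, R)
    return sph @ X, sph


def infomax_ica(
    X: np.ndarray,
    n_components: int | None = None,
    seed: int = 0,
    max_iter: int = 512,
    tol: float = 1e-6,
    lr: float = 0.05,
    anneal: float = 0.9,
):
    """Extended Infomax ICA with block-wise natural-gradient updates.

    Rows of X are mixed signals, columns samples.  Data are whitened
    internally.  Each pass re-estimates which components are sub- vs
    super-Gaussian from the sign of their kurtosis and switches the
    nonlinearity accordingly, then sweeps the (seeded-permuted) samples in
    blocks of ~sqrt(V).  The learning rate decays by ``anneal`` whenever the
    per-pass weight change grows (oscillation near a fixed point) and halves
    when an update blows up, so the weight change contracts to the ``tol``
    stopping threshold.

    Returns
    -------
    dict with keys:
      sources : (n, V) independent component estimates (z-scaled rows)
      unmixing : (n, R) total unmixing (applies to the raw input rows)
      W : (n, n) rotation applied to whitened data
      converged : bool
    """
    X = np.asarray(X, dtype=np.float64)
    R, V = X.shape
    n = n_components or R
    if n > R:
        raise ValueError(f"n_components={n} exceeds {R} input rows")
    Z, sph = _whiten_rows(X, n)
    rng = np.random.default_rng(seed)
    W = np.linalg.qr(rng.standard_normal((n, n)))[0]
    I = np.eye(n)
    block = max(64, int(math.sqrt(V)))
    converged = False
    prev_change = np.inf
    for _ in range(max_iter):
        U = W @ Z
        m2 = np.mean(U**2, axis=1)
        m4 = np.mean(U**4, axis=1)
        signs = np.where(m4 / np.maximum(m2, 1e-12) ** 2 - 3.0 >= 0, 1.0, -1.0)
        perm = rng.permutation(V)
        W_old = W.copy()
        blew_up = False
        for b0 in range(0, V, block):
            Zb = Z[:, perm[b0 : b0 + block]]
            nb = Zb.shape[1]
            U = W @ Zb
            Y = np.tanh(U)
            dW = lr * (I - (signs[:, None] * Y) @ U.T / nb - U @ U.T / nb) @ W
            if not np.all(np.isfinite(dW)) or np.max(np.abs(dW)) > 1.0:
                blew_up = True
                break
            W = W + dW
        if blew_up:
            lr *= 0.5
            W = W_old
            continue
        change = np.max(np.abs(W - W_old))
        if change > prev_change:
            lr *= anneal
        prev_change = change
        if change < tol:
            converged = True
            break
    if not converged:
        warnings.warn("Infomax did not converge within max_iter", RuntimeWarning)
    S = W @ Z
    return {
        "sources": _zscale_maps(S),
        "unmixing": W @ sph,
        "W": W,
        "sphering": sph,
        "converged": converged,
    }


def amari_index(P: np.ndarray) -> float:
    """Permutation-invariant separation error of a gain matrix P = W A.

    0 means P is a scaled permutation (perfect separation); normalized to
    [0, 1].
    """
    P = np.abs(np.asarray(P, dtype=np.float64))
    n = P.shape[0]
    rows = (P / P.max(axis=1, keepdims=True)).sum(axis=1) - 1
    cols = (P / P.max(axis=0, keepdims=True)).sum(axis=0) - 1
    return float((rows.sum() + cols.sum()) / (2 * n * (n - 1)))


# ---------------------------------------------------------------------------
# ICASSO stability selection
# ---------------------------------------------------------------------------

def icasso_select(
    X: np.ndarray,
    n_components: int,
    n_runs: int = 100,
    min_cluster_size: int = 80,
    seed: int = 0,
    max_iter: int = 512,
) -> ComponentSet:
    """Stability-selected group components from repeated Infomax runs.

    Runs Infomax ``n_runs`` times from distinct seeds, pools all component
    maps, clusters them by absolute-correlation similarity (average-linkage
    agglomerative, cut at ``n_components`` clusters), and keeps each
    cluster's centrotype (the member with maximal within-cluster similarity
    sum).  Quality index iq = mean intra-cluster similarity minus mean
    similarity to everything outside the cluster.  Clusters smaller than
    ``min_cluster_size`` are kept but flagged unstable.
    """
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    if min_cluster_size > n_runs:
        raise ValueError("min_cluster_size cannot exceed n_runs")
    runs = []
    all_converged = True
    for r in range(n_runs):
        res = infomax_ica(X, n_components, seed=seed + r, max_iter=max_iter)
        runs.append(res["sources"])
        all_converged &= res["converged"]
    pool = np.vstack(runs)  # (n_runs * n, V)
    sim = np.abs(np.corrcoef(pool))
    np.clip(sim, 0.0, 1.0, out=sim)
    dist = 1.0 - sim
    # condensed distance for average-linkage clustering
    iu = np.triu_indices(pool.shape[0], 1)
    Zl = linkage(dist[iu], method="average")
    labels = fcluster(Zl, t=n_components, criterion="maxclust")

    maps = np.empty((n_components, pool.shape[1]))
    iq = np.empty(n_components)
    unstable = np.zeros(n_components, dtype=bool)
    for k in range(1, n_components + 1):
        members = np.flatnonzero(labels == k)
        out = np.flatnonzero(labels != k)
        intra = sim[np.ix_(members, members)]
        within = (intra.sum(axis=1) - 1.0) / max(len(members) - 1, 1)
        centro = members[np.argmax(within)]
        maps[k - 1] = pool[centro]
        mean_intra = within.mean() if len(members) > 1 else 1.0
        mean_extra = sim[np.ix_(members, out)].mean() if out.size else 0.0
        iq[k - 1] = mean_intra - mean_extra
        if len(members) < min_cluster_size:
            unstable[k - 1] = True
    maps, _ = _fix_sign(_zscale_maps(maps))
    return ComponentSet(
        spatial_maps=maps, stability_iq=iq, unstable=unstable, converged=all_converged
    )


# ---------------------------------------------------------------------------
# back-reconstruction and labeling
# ---------------------------------------------------------------------------

def back_reconstruct(group_components: ComponentSet, ops: ReductionOperators, series):
    """Subject-specific maps/time courses by spatial-temporal dual regression.

    Stage 1 regresses the group spatial maps onto each subject's data to get
    time courses; stage 2 regresses those time courses back onto the data to
    get subject maps.  Exact when the data are a noiseless product of the
    group maps with any time courses.
    """
    if ops is not None and [s.subject_id for s in series] != ops.subject_ids:
        raise ValueError("subject list does not match the reduction operators")
    S = group_components.spatial_maps  # (N, V)
    out = []
    for s in series:
        X = s.data - s.data.mean(axis=0)
        TC, *_ = np.linalg.lstsq(S.T, X.T, rcond=None)
        TC = TC.T  # (T, N)
        maps, *_ = np.linalg.lstsq(TC, X, rcond=None)  # (N, V)
        maps, TC = _fix_sign(_zscale_maps(maps), TC)
        out.append(ComponentSet(spatial_maps=maps, time_courses=TC))
    return out


def label_components(
    components: ComponentSet,
    templates: dict,
    artifact_r_threshold: float = 0.2,
    gray_matter_mask: np.ndarray | None = None,
) -> ComponentSet:
    """Label each component by its best-matching template.

    Best match = highest spatial |Pearson r| across templates (ties broken by
    template order); label is the template name when the best |r| reaches
    ``artifact_r_threshold``, else "artifact".  With a gray-matter mask,
    components whose squared-map energy fraction inside gray matter is below
    0.5 are also flagged artifact.
    """
    if not templates:
        raise ValueError("empty template set")
    names = list(templates.keys())
    tmat = np.vstack([np.asarray(templates[n], dtype=np.float64) for n in names])
    if tmat.shape[1] != components.spatial_maps.shape[1]:
        raise ValueError("templates and components are on different masks")
    tz = _zscale_maps(tmat)
    cz = _zscale_maps(components.spatial_maps)
    r = np.abs(cz @ tz.T) / cz.shape[1]  # (N, n_templates) |Pearson r|
    best = np.argmax(r, axis=1)  # argmax keeps first index on exact ties
    labels = []
    template_corrs = []
    gm = None
    if gray_matter_mask is not None:
        gm = np.asarray(gray_matter_mask, dtype=bool).ravel()
    for i in range(components.n_components):
        br = float(r[i, best[i]])
        lab = names[best[i]] if br >= artifact_r_threshold else "artifact"
        if gm is not None and lab != "artifact":
            e = components.spatial_maps[i] ** 2
            if e[gm].sum() / e.sum() < 0.5:
                lab = "artifact"
        labels.append(lab)
        template_corrs.append((br, names[best[i]]))
    components.labels = labels
    components.template_correlations = template_corrs
    return components
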