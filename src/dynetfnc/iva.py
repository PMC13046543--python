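"""Spatial dynamics via independent vector analysis (IVA).

Each subject's series is cut into L half-overlapping windows (default 48 TRs,
50% overlap, so a 192-TR series gives L = 7).  The M x L window datasets,
each modeled as x = A s with a window-specific T_w x N mixing matrix, are
jointly unmixed by IVA: the n-th rows of all demixing outputs form one
source component vector (SCV), and the IVA cost rewards dependence *within*
an SCV (the same network seen in every subject/window) while enforcing
independence *between* SCVs.  IVA-G uses a multivariate-Gaussian SCV prior
(second-order statistics), IVA-L a multivariate-Laplacian prior (higher
order); IVA-GL runs IVA-G and refines from its solution with IVA-L, which is
more robust than either alone.  Both use relative (natural) gradient updates
with backtracking so the cost never increases on an accepted step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .gica import amari_index

__all__ = [
    "WindowSegmentation",
    "SCVSet",
    "segment_windows",
    "iva_g",
    "iva_l",
    "iva_gl",
    "screen_sdcs",
    "joint_isi",
]

EPS = 1e-12


@dataclass
class WindowSegmentation:
    """One subject's series cut into L overlapping windows.

    windows[l] is (T_w, V), demeaned and variance-normalized per voxel within
    the window.  Window l covers TRs [l*step, l*step + T_w).
    """

    windows: np.ndarray  # (L, T_w, V)
    window_length_trs: int
    n_windows: int
    overlap_fraction: float
    subject_id: str = ""

    @property
    def step_trs(self) -> int:
        return int(round(self.window_length_trs * (1 - self.overlap_fraction)))


def segment_windows(series, window_trs: int = 48, overlap_fraction: float = 0.5) -> WindowSegmentation:
    """Segment a BoldSeries into half-open windows covering [0, T) exactly.

    Requires (1-overlap)*window_trs to be a positive integer step and
    (T - window_trs) divisible by it, so the last window ends at T.
    """
    if not (0 <= overlap_fraction < 1):
        raise ValueError("overlap_fraction must be in [0, 1)")
    step_f = (1 - overlap_fraction) * window_trs
    step = int(round(step_f))
    if step < 1 or abs(step_f - step) > 1e-9:
        raise ValueError(
            f"(1-overlap)*window={step_f} is not a positive integer step"
        )
    T = series.n_timepoints
    if window_trs > T:
        raise ValueError(f"window {window_trs} exceeds series length {T}")
    if (T - window_trs) % step:
        valid = [w for w in range(2, T + 1) if (T - w) % max(int(round((1 - overlap_fraction) * w)), 1) == 0]
        raise ValueError(
            f"T={T} not segmentable by window={window_trs}, overlap={overlap_fraction}; "
            f"valid window lengths at this overlap include {valid[:8]}..."
        )
    L = (T - window_trs) // step + 1
    V = series.n_voxels
    win = np.empty((L, window_trs, V))
    for l in range(L):
        X = series.data[l * step : l * step + window_trs].copy()
        X -= X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        win[l] = X / sd
    return WindowSegmentation(
        windows=win,
        window_length_trs=window_trs,
        n_windows=L,
        overlap_fraction=overlap_fraction,
        subject_id=series.subject_id,
    )


# ---------------------------------------------------------------------------
# IVA core
# ---------------------------------------------------------------------------

def _whiten_dataset(X: np.ndarray, n_components: int):
    """PCA-whiten a (T_w, V) dataset to (N, V); returns (Z, P) with Z = P X.

    Strictly linear (no mean removal), so the source estimates satisfy
    y = (W P) x exactly; window data are already demeaned per voxel.
    """
    C = X @ X.T / X.shape[1]
    w, Q = np.linalg.eigh(C)
    order = np.argsort(w)[::-1][:n_components]
    w, Q = w[order], Q[:, order]
    if w[-1] <= 0:
        raise ValueError("dataset rank below requested number of components")
    P = (Q / np.sqrt(w)).T
    return P @ X, P


def _iva_cost(Y: np.ndarray, Ws: np.ndarray, prior: str) -> float:
    """Y is (D, N, V); Ws is (D, N, N).  Constant terms dropped."""
    D, N, V = Y.shape
    cost = 0.0
    for n in range(N):
        yn = Y[:, n, :]  # (D, V)
        if prior == "gauss":
            sigma = yn @ yn.T / V
            sign, logdet = np.linalg.slogdet(sigma)
            if sign <= 0:
                return np.inf
            cost += 0.5 * logdet
        else:
            cost += np.mean(np.sqrt(np.sum(yn**2, axis=0) + EPS))
    for d in range(D):
        sign, logdet = np.linalg.slogdet(Ws[d])
        if sign == 0:
            return np.inf
        cost -= logdet
    return float(cost)


def _iva_scores(Y: np.ndarray, prior: str) -> np.ndarray:
    """Multivariate score phi with same shape as Y."""
    D, N, V = Y.shape
    phi = np.empty_like(Y)
    for n in range(N):
        yn = Y[:, n, :]
        if prior == "gauss":
            sigma = yn @ yn.T / V
            phi[:, n, :] = np.linalg.solve(sigma, yn)
        else:
            norm = np.sqrt(np.sum(yn**2, axis=0) + EPS)
            phi[:, n, :] = yn / norm
    return phi


def _iva_core(
    Z: np.ndarray,
    prior: str,
    W0: np.ndarray,
    max_iter: int = 1024,
    tol: float = 1e-6,
    lr: float = 0.5,
):
    """Relative-gradient IVA on pre-whitened datasets Z (D, N, V).

    Accepts a step only if the cost does not increase (backtracking halves
    the learning rate otherwise).  Converged when the maximum entry of the
    relative gradient I - E[phi y^T] falls below tol.
    """
    D, N, V = Z.shape
    W = W0.copy()
    I = np.eye(N)
    Y = np.einsum("dij,djv->div", W, Z)
    cost = _iva_cost(Y, W, prior)
    converged = False
    for _ in range(max_iter):
        phi = _iva_scores(Y, prior)
        G = I[None] - np.einsum("dnv,dmv->dnm", phi, Y) / V  # (D, N, N)
        gnorm = np.max(np.abs(G))
        if gnorm < tol:
            converged = True
            break
        accepted = False
        while lr > 1e-8:
            W_new = W + lr * np.einsum("dnm,dmk->dnk", G, W)
            Y_new = np.einsum("dij,djv->div", W_new, Z)
            cost_new = _iva_cost(Y_new, W_new, prior)
            if cost_new <= cost + 1e-12:
                W, Y, cost = W_new, Y_new, cost_new
                accepted = True
                lr = min(lr * 1.2, 1.0)
                break
            lr *= 0.5
        if not accepted:
            break
    if not converged:
        warnings.warn(f"IVA-{prior[0].upper()} stopped before gradient tolerance", RuntimeWarning)
    return W, Y, converged


def _prep_datasets(datasets, n_components: int):
    V = datasets[0].shape[1]
    if any(X.shape[1] != V for X in datasets):
        raise ValueError("all datasets must share the voxel dimension V")
    if n_components > min(X.shape[0] for X in datasets):
        raise ValueError("n_components exceeds the smallest dataset row count")
    Z = np.empty((len(datasets), n_components, V))
    P = []
    for d, X in enumerate(datasets):
        Z[d], Pd = _whiten_dataset(np.asarray(X, dtype=np.float64), n_components)
        P.append(Pd)
    return Z, P


def _random_orthonormal(n: int, rng) -> np.ndarray:
    return np.linalg.qr(rng.standard_normal((n, n)))[0]


def iva_g(datasets, n_components: int, seed: int = 0, max_iter: int = 1024, tol: float = 1e-6):
    """IVA with a multivariate-Gaussian SCV prior (second-order statistics).

    Returns dict with ``demixing`` (list of N x T_w total demixing matrices),
    ``rotations`` (square W per dataset, applies to whitened data),
    ``whitening``, ``sources`` (list of N x V), ``converged``.
    """
    Z, P = _prep_datasets(datasets, n_components)
    rng = np.random.default_rng(seed)
    W0 = np.stack([_random_orthonormal(n_components, rng) for _ in range(Z.shape[0])])
    W, Y, conv = _iva_core(Z, "gauss", W0, max_iter=max_iter, tol=tol)
    return _package(W, Y, P, conv)


def iva_l(
    datasets,
    n_components: int,
    init_demixing: np.ndarray | None = None,
    seed: int = 0,
    max_iter: int = 1024,
    tol: float = 1e-6,
):
    """IVA with a multivariate-Laplacian SCV prior (higher-order statistics).

    ``init_demixing`` (D, N, N) warm-starts the rotations (e.g. from IVA-G);
    otherwise a seeded random orthonormal start is used.
    """
    Z, P = _prep_datasets(datasets, n_components)
    D = Z.shape[0]
    if init_demixing is not None:
        W0 = np.asarray(init_demixing, dtype=np.float64).copy()
        if W0.shape != (D, n_components, n_components):
            raise ValueError(f"init_demixing shape {W0.shape} != {(D, n_components, n_components)}")
    else:
        rng = np.random.default_rng(seed)
        W0 = np.stack([_random_orthonormal(n_components, rng) for _ in range(D)])
    W, Y, conv = _iva_core(Z, "laplace", W0, max_iter=max_iter, tol=tol)
    return _package(W, Y, P, conv)


def _package(W: np.ndarray, Y: np.ndarray, P: list, converged: bool) -> dict:
    # sign-align each SCV to its first dataset
    D, N, V = Y.shape
    for n in range(N):
        ref = Y[0, n]
        for d in range(1, D):
            if ref @ Y[d, n] < 0:
                Y[d, n] *= -1
                W[d, n] *= -1
    demix = [W[d] @ P[d] for d in range(D)]
    return {
        "demixing": demix,
        "rotations": W,
        "whitening": P,
        "sources": [Y[d] for d in range(D)],
        "converged": converged,
    }


@dataclass
class SCVSet:
    """IVA output over M subjects x L windows, organized by SCV.

    ``demixing[(m, l)]`` is the N x T_w total demixing W applied to the
    window's (normalized) data; ``sources[(m, l)]`` the resulting N x V
    source maps (row n across every (m, l) is SCV n).
    """

    demixing: dict  # (m, l) -> (N, T_w)
    sources: dict  # (m, l) -> (N, V)
    n_components: int
    n_subjects: int
    n_windows: int
    converged: bool = True

    def scv(self, n: int) -> np.ndarray:
        """All source maps of SCV n, stacked (M*L, V) in (m, l) order."""
        return np.vstack(
            [self.sources[(m, l)][n]
             for m in range(self.n_subjects) for l in range(self.n_windows)]
        )

    def scv_mean_map(self, n: int) -> np.ndarray:
        return self.scv(n).mean(axis=0)

    @property
    def dataset_keys(self):
        return [(m, l) for m in range(self.n_subjects) for l in range(self.n_windows)]


def iva_gl(segmentations, n_components: int = 20, seed: int = 0, max_iter: int = 1024, tol: float = 1e-6) -> SCVSet:
    """IVA-GL over all subjects' window segmentations.

    Flattens the M x L window datasets, runs IVA-G from a seeded random
    start, refines with IVA-L initialized at the IVA-G solution, and
    assembles the SCV-organized result.
    """
    segs = list(segmentations)
    M = len(segs)
    L = segs[0].n_windows
    V = segs[0].windows.shape[2]
    if any(s.n_windows != L or s.windows.shape[2] != V for s in segs):
        raise ValueError("all subjects must share L windows and V voxels")
    datasets = [segs[m].windows[l] for m in range(M) for l in range(L)]
    res_g = iva_g(datasets, n_components, seed=seed, max_iter=max_iter, tol=tol)
    res_l = iva_l(datasets, n_components, init_demixing=res_g["rotations"],
                  max_iter=max_iter, tol=tol)
    demix = {}
    sources = {}
    idx = 0
    for m in range(M):
        for l in range(L):
            demix[(m, l)] = res_l["demixing"][idx]
            sources[(m, l)] = res_l["sources"][idx]
            idx += 1
    return SCVSet(
        demixing=demix, sources=sources, n_components=n_components,
        n_subjects=M, n_windows=L,
        converged=res_g["converged"] and res_l["converged"],
    )


def screen_sdcs(scvset: SCVSet, templates: dict, keep: int = 9) -> SCVSet:
    """Keep the ``keep`` components whose SCV-mean maps best match templates.

    Automated stand-in for visual artifact screening: components are ranked
    by their best |Pearson r| against the template set and the top ``keep``
    retained, preserving rank order.
    """
    if keep > scvset.n_components:
        raise ValueError("keep exceeds the number of components")
    names = list(templates.keys())
    tmat = np.vstack([templates[n] for n in names]).astype(np.float64)
    tz = (tmat - tmat.mean(axis=1, keepdims=True)) / tmat.std(axis=1, keepdims=True)
    best = np.empty(scvset.n_components)
    for n in range(scvset.n_components):
        mp = scvset.scv_mean_map(n)
        mz = (mp - mp.mean()) / (mp.std() or 1.0)
        best[n] = np.max(np.abs(mz @ tz.T)) / mp.size
    order = np.argsort(-best)[:keep]
    demix = {k: v[order] for k, v in scvset.demixing.items()}
    sources = {k: v[order] for k, v in scvset.sources.items()}
    return SCVSet(
        demixing=demix, sources=sources, n_components=keep,
        n_subjects=scvset.n_subjects, n_windows=scvset.n_windows,
        converged=scvset.converged,
    )


def joint_isi(gains) -> float:
    """Joint inter-symbol interference of per-dataset gain matrices W_d A_d.

    Sums |G_d| over datasets and applies the permutation-invariant Amari
    error; 0 means every dataset is unmixed by one shared permutation.
    """
    G = np.sum([np.abs(np.asarray(g, dtype=np.float64)) for g in gains], axis=0)
    return amari_index(G)
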