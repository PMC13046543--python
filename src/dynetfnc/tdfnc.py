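"""Temporal dynamic functional network connectivity (FNC).

Static FNC is the Pearson correlation of component time courses over the
full series.  Dynamic FNC slides a rectangular window (default 18 TRs, step
1 TR) along the time courses, correlates within each window, Fisher
z-transforms the upper triangle, down-samples to high-variance exemplar
windows, and clusters windows across subjects with two-stage k-means into
recurring connectivity states.  State occupancy metrics (window counts,
membership at a minimum-window rule, mean dwell time) summarize the result
per subject.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

__all__ = [
    "WindowedFNC",
    "StateModel",
    "static_fnc",
    "sliding_window_fnc",
    "select_exemplars",
    "cluster_states",
    "state_metrics",
    "fisher_z",
    "inverse_fisher_z",
    "vectorize_fnc",
]


def fisher_z(r: np.ndarray) -> np.ndarray:
    return np.arctanh(np.clip(r, -0.999999, 0.999999))


def inverse_fisher_z(z: np.ndarray) -> np.ndarray:
    return np.tanh(z)


@dataclass
class WindowedFNC:
    """Stack of symmetric per-window correlation matrices for one subject."""

    matrices: np.ndarray  # (W, N, N)
    window_width_trs: int
    step_trs: int
    window_start_indices: np.ndarray  # (W,), 0-based

    @property
    def n_windows(self) -> int:
        return self.matrices.shape[0]

    @property
    def n_components(self) -> int:
        return self.matrices.shape[1]


@dataclass
class StateModel:
    """k-means solution over all subjects' windowed FNC vectors.

    Centroids live in Fisher-z space of the vectorized upper triangle
    (E = N(N-1)/2 entries).  ``assignments`` maps subject id to a length-W
    label array (labels 0..k-1).
    """

    k: int
    centroids: np.ndarray  # (k, E), Fisher-z scale
    assignments: dict  # subject_id -> (W,) int labels
    validity_curve: dict | None = None  # candidate k -> within/between ratio


def static_fnc(time_courses: np.ndarray) -> np.ndarray:
    """Pearson correlation of the full time courses; (N, N) symmetric, unit diag."""
    tc = np.asarray(time_courses, dtype=np.float64)
    if tc.shape[0] < 3:
        raise ValueError("need at least 3 time points")
    sd = tc.std(axis=0)
    if np.any(sd == 0):
        bad = np.flatnonzero(sd == 0)
        raise ValueError(f"constant time course for component(s) {bad.tolist()}")
    C = np.corrcoef(tc.T)
    np.fill_diagonal(C, 1.0)
    return np.clip((C + C.T) / 2, -1.0, 1.0)


def sliding_window_fnc(
    time_courses: np.ndarray, width_trs: int = 18, step_trs: int = 1
) -> WindowedFNC:
    """Per-window Pearson FNC.  Window w covers rows [w*step, w*step + width)."""
    tc = np.asarray(time_courses, dtype=np.float64)
    T = tc.shape[0]
    if width_trs > T:
        raise ValueError(f"window width {width_trs} exceeds series length {T}")
    if step_trs < 1:
        raise ValueError("step must be >= 1")
    W = (T - width_trs) // step_trs + 1
    starts = np.arange(W) * step_trs
    mats = np.empty((W, tc.shape[1], tc.shape[1]))
    for w, s in enumerate(starts):
        mats[w] = static_fnc(tc[s : s + width_trs])
    return WindowedFNC(
        matrices=mats,
        window_width_trs=width_trs,
        step_trs=step_trs,
        window_start_indices=starts,
    )


def vectorize_fnc(matrices: np.ndarray) -> np.ndarray:
    """Upper triangle (k=1) of each matrix in the stack -> (W, E)."""
    matrices = np.asarray(matrices)
    N = matrices.shape[-1]
    iu = np.triu_indices(N, 1)
    return matrices[..., iu[0], iu[1]]


def select_exemplars(wfnc: WindowedFNC) -> np.ndarray:
    """Indices of windows at strict local maxima of FNC variance.

    The per-window variance is taken across the E upper-triangle values.
    Endpoints qualify when greater than their single neighbor.  If no strict
    local maximum exists (e.g. constant variance), the first global maximum
    is returned, so at least one exemplar always comes back.
    """
    if wfnc.n_windows < 3:
        raise ValueError("need at least 3 windows to pick exemplars")
    v = vectorize_fnc(wfnc.matrices).var(axis=1)
    W = v.size
    is_max = np.zeros(W, dtype=bool)
    is_max[0] = v[0] > v[1]
    is_max[-1] = v[-1] > v[-2]
    interior = (v[1:-1] > v[:-2]) & (v[1:-1] > v[2:])
    is_max[1:-1] = interior
    idx = np.flatnonzero(is_max)
    if idx.size == 0:
        idx = np.array([int(np.argmax(v))])
    return idx


def _within_between_ratio(X: np.ndarray, labels: np.ndarray, centroids: np.ndarray) -> float:
    within = np.linalg.norm(X - centroids[labels], axis=1).mean()
    k = centroids.shape[0]
    if k < 2:
        return np.inf
    iu = np.triu_indices(k, 1)
    between = np.linalg.norm(centroids[iu[0]] - centroids[iu[1]], axis=1).mean()
    return float(within / between)


def _elbow(ks: np.ndarray, vals: np.ndarray) -> int:
    """k at the maximum curvature (discrete second difference) of the curve."""
    if len(ks) < 3:
        return int(ks[np.argmin(vals)])
    curv = vals[:-2] - 2 * vals[1:-1] + vals[2:]
    return int(ks[1 + int(np.argmax(curv))])


def cluster_states(
    all_wfnc: dict,
    k: int | str = "auto",
    seed: int = 0,
    k_range=range(2, 11),
) -> StateModel:
    """Two-stage k-means over all subjects' windows.

    Stage 1 clusters the pooled exemplar vectors (k-means++, n_init=10); the
    resulting centroids initialize a second k-means over every window of
    every subject, run to convergence.  Vectors are Fisher z-transformed
    before clustering.  With ``k="auto"`` the within/between cluster-distance
    ratio is evaluated on the exemplars for each candidate k and the elbow
    (max curvature) is chosen.
    """
    subject_ids = list(all_wfnc.keys())
    ex_vecs = []
    all_vecs = []
    counts = []
    for sid in subject_ids:
        wf = all_wfnc[sid]
        vecs = fisher_z(vectorize_fnc(wf.matrices))
        all_vecs.append(vecs)
        ex_vecs.append(vecs[select_exemplars(wf)])
        counts.append(vecs.shape[0])
    E = np.vstack(ex_vecs)
    X = np.vstack(all_vecs)

    validity = None
    if k == "auto":
        validity = {}
        for kk in k_range:
            if kk > np.unique(E, axis=0).shape[0]:
                break
            km = KMeans(n_clusters=kk, n_init=10, random_state=seed).fit(E)
            validity[kk] = _within_between_ratio(E, km.labels_, km.cluster_centers_)
        ks = np.array(sorted(validity))
        k = _elbow(ks, np.array([validity[kk] for kk in ks]))
    k = int(k)
    if np.unique(E, axis=0).shape[0] < k:
        raise ValueError(f"only {np.unique(E, axis=0).shape[0]} distinct exemplars for k={k}")

    km1 = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(E)
    km2 = KMeans(n_clusters=k, init=km1.cluster_centers_, n_init=1, random_state=seed)
    labels = km2.fit_predict(X)

    assignments = {}
    pos = 0
    for sid, c in zip(subject_ids, counts):
        assignments[sid] = labels[pos : pos + c].copy()
        pos += c
    return StateModel(
        k=k, centroids=km2.cluster_centers_, assignments=assignments,
        validity_curve=validity,
    )


def state_metrics(assignments: np.ndarray, min_windows: int = 10, states=None):
    """Per-state occupancy for one subject's window labels.

    Returns a dict state -> (n_windows, member_flag, mean_dwell) where
    member_flag marks subjects with at least ``min_windows`` windows in the
    state and mean_dwell is the average consecutive-run length (in windows);
    0 windows gives dwell 0.
    """
    a = np.asarray(assignments)
    if a.size == 0:
        raise ValueError("empty assignment sequence")
    if states is None:
        states = np.unique(a)
    out = {}
    # run-length encode once
    change = np.flatnonzero(np.diff(a)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [a.size]])
    run_states = a[starts]
    run_lens = ends - starts
    for s in states:
        n = int(np.sum(a == s))
        runs = run_lens[run_states == s]
        dwell = float(runs.mean()) if runs.size else 0.0
        out[int(s)] = (n, n >= min_windows, dwell)
    return out
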