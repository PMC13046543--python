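"""Synthetic multi-subject fMRI-like data with known ground truth.

Emulates a resting-state study of M subjects scanned for T TRs: a set of
shared spatial sources (compact center-surround blobs on a 3-D grid), per
subject a Markov state-switching process that changes the inter-source
covariance between K connectivity states, optional per-window multiplicative
jitter of the source maps (the spatial dynamics IVA is designed to recover),
i.i.d. Gaussian sensor noise at a requested SNR, and a clinical table whose
symptom score can be planted to correlate with a chosen connectivity edge.

Every stochastic choice derives from one integer seed, so identical calls
produce bit-identical datasets.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .imageio import BoldSeries, mask_to_indices

__all__ = [
    "PlacementError",
    "PlantedEffects",
    "GroundTruth",
    "generate_spatial_sources",
    "generate_state_covariances",
    "generate_state_timecourses",
    "generate_dataset",
    "write_dataset",
]

#: typical symptom-score scale: range 10-79, mean 44.66, SD 17.96
SCORE_MEAN = 44.66
SCORE_SD = 17.96
#: disease duration range in months (1 month to 1 year)
DURATION_RANGE = (1.0, 12.0)


class PlacementError(ValueError):
    """Grid too small to place the requested number of source blobs."""


# ---------------------------------------------------------------------------
# spatial sources
# ---------------------------------------------------------------------------

def generate_spatial_sources(
    grid_shape,
    n_sources: int,
    blob_radius_vox: float = 2.0,
    seed: int = 0,
):
    """Place ``n_sources`` smooth center-surround blobs on a 3-D grid.

    Each source is a difference-of-Gaussians bump (center width
    ``blob_radius_vox``, surround width 1.6x, zero integral), z-scaled over
    the mask.  The zero-mean profile keeps pairwise correlations between
    sources far below the 0.2 artifact-screening threshold even on small
    grids.

    Returns
    -------
    sources : (N, V) float64 array
    mask : 3-D uint8 array (all-ones grid mask)

    Raises
    ------
    PlacementError
        If the grid cannot hold ``n_sources`` centers at the minimum
        separation (3.5 blob radii).
    """
    grid_shape = tuple(int(g) for g in grid_shape)
    if n_sources < 2:
        raise ValueError("need at least 2 sources")
    rng = np.random.default_rng(seed)
    r = float(blob_radius_vox)
    margin = max(1, int(math.ceil(r)))
    sep = max(3, int(math.ceil(3.5 * r)))
    axes = []
    for dim in grid_shape:
        hi = dim - 1 - margin
        if hi < margin:
            axes.append([])
        else:
            axes.append(list(range(margin, hi + 1, sep)))
    candidates = list(itertools.product(*axes))
    if len(candidates) < n_sources:
        raise PlacementError(
            f"grid {grid_shape} holds only {len(candidates)} blob centers at "
            f"separation {sep} (radius {r}); {n_sources} requested"
        )
    chosen = rng.choice(len(candidates), size=n_sources, replace=False)
    centers = np.array([candidates[i] for i in chosen], dtype=float)

    coords = np.stack(
        np.meshgrid(*[np.arange(d, dtype=float) for d in grid_shape], indexing="ij"),
        axis=-1,
    ).reshape(-1, 3)
    V = coords.shape[0]
    sources = np.empty((n_sources, V))
    surround = 1.6
    beta = surround ** -3  # zero total integral for the DoG profile
    for i, c in enumerate(centers):
        d2 = np.sum((coords - c) ** 2, axis=1)
        bump = np.exp(-d2 / (2 * r**2)) - beta * np.exp(-d2 / (2 * (surround * r) ** 2))
        sources[i] = bump
    sources -= sources.mean(axis=1, keepdims=True)
    sources /= sources.std(axis=1, keepdims=True)

    cc = np.corrcoef(sources)
    off = np.abs(cc[np.triu_indices(n_sources, 1)])
    if off.size and off.max() >= 0.2:
        raise PlacementError(
            f"source maps too correlated (max |r|={off.max():.3f}); "
            "enlarge the grid or shrink the blob radius"
        )
    mask = np.ones(grid_shape, dtype=np.uint8)
    return sources, mask


# ---------------------------------------------------------------------------
# state covariances and time courses
# ---------------------------------------------------------------------------

def _check_spd(C: np.ndarray, name: str = "covariance") -> np.ndarray:
    C = np.asarray(C, dtype=np.float64)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError(f"{name} must be square, got {C.shape}")
    if not np.allclose(C, C.T, atol=1e-10):
        raise ValueError(f"{name} is not symmetric")
    try:
        np.linalg.cholesky(C)
    except np.linalg.LinAlgError:
        raise ValueError(f"{name} is not positive definite") from None
    return C


def _nearest_unit_spd(C: np.ndarray, eig_floor: float = 0.05) -> np.ndarray:
    """Project a symmetric matrix to SPD with unit diagonal."""
    C = (C + C.T) / 2
    w, Q = np.linalg.eigh(C)
    C = (Q * np.maximum(w, eig_floor)) @ Q.T
    d = np.sqrt(np.diag(C))
    C = C / np.outer(d, d)
    np.fill_diagonal(C, 1.0)
    return C


def generate_state_covariances(
    n_sources: int, k_states: int, rho: float = 0.45, seed: int = 0
):
    """K distinct unit-diagonal SPD correlation matrices.

    State k uses a rank-one +/- sign pattern: C = (1-rho) I + rho u u^T with
    u in {-1,+1}^N, giving off-diagonal entries of +/- rho and eigenvalues
    {1-rho, 1-rho+rho N} — well separated states for clustering tests.
    """
    rng = np.random.default_rng(seed)
    seen = set()
    covs = []
    while len(covs) < k_states:
        u = rng.choice([-1.0, 1.0], size=n_sources)
        u *= u[0]  # canonical global sign
        key = tuple(u)
        if key in seen:
            continue
        seen.add(key)
        C = (1 - rho) * np.eye(n_sources) + rho * np.outer(u, u)
        np.fill_diagonal(C, 1.0)
        covs.append(C)
        if len(seen) >= 2 ** (n_sources - 1) and len(covs) < k_states:
            raise ValueError(f"cannot build {k_states} distinct states for N={n_sources}")
    return covs


def generate_state_timecourses(
    T: int,
    state_covariances,
    dwell_mean_trs: float = 40.0,
    seed: int = 0,
):
    """Markov dwell process over K covariance states.

    Segment lengths are geometric with mean ``dwell_mean_trs``; segment states
    cycle through shuffled permutations of 1..K (no immediate repeats), so all
    states occur whenever the series holds at least K segments.  Within a
    segment, rows are zero-mean Gaussian with the segment's covariance.

    Returns
    -------
    tc : (T, N) array
    state_sequence : (T,) int array with labels in 1..K
    """
    covs = [_check_spd(C) for C in state_covariances]
    K = len(covs)
    N = covs[0].shape[0]
    if any(C.shape[0] != N for C in covs):
        raise ValueError("all state covariances must share one size")
    if T < 2 * dwell_mean_trs and dwell_mean_trs < T:
        raise ValueError(f"T={T} too short for mean dwell {dwell_mean_trs}")
    rng = np.random.default_rng(seed)

    # segment boundaries
    if dwell_mean_trs >= T:
        lengths = [T]
    else:
        lengths = []
        total = 0
        p = 1.0 / float(dwell_mean_trs)
        while total < T:
            seg = int(rng.geometric(p))
            seg = min(seg, T - total)
            lengths.append(seg)
            total += seg

    # segment states: repeated shuffled 1..K, avoiding immediate repeats
    states = []
    while len(states) < len(lengths):
        perm = list(rng.permutation(K) + 1)
        if states and perm[0] == states[-1]:
            perm[0], perm[-1] = perm[-1], perm[0]
        states.extend(perm)
    states = states[: len(lengths)]

    chols = [np.linalg.cholesky(C) for C in covs]
    tc = np.empty((T, N))
    seq = np.empty(T, dtype=np.int64)
    pos = 0
    for seg_len, s in zip(lengths, states):
        z = rng.standard_normal((seg_len, N))
        tc[pos : pos + seg_len] = z @ chols[s - 1].T
        seq[pos : pos + seg_len] = s
        pos += seg_len
    return tc, seq


# ---------------------------------------------------------------------------
# full dataset
# ---------------------------------------------------------------------------

@dataclass
class PlantedEffects:
    """Ground-truth effects to plant in a dataset.

    group_*: make edge ``group_edge`` of state ``group_state`` differ between
    the patient (TS) and control (N) groups by ``group_delta_r``.
    clinical_*: make the clinical score (or duration) correlate with the
    subject-level strength of edge ``clinical_edge`` in state
    ``clinical_state`` at exactly ``clinical_r`` (per-subject edge strengths
    are jittered with SD ``edge_subject_sd`` to create the spread).
    """

    group_state: int | None = None
    group_edge: tuple | None = None
    group_delta_r: float = 0.0
    clinical_state: int | None = None
    clinical_edge: tuple | None = None
    clinical_r: float = 0.0
    clinical_target: str = "score"
    edge_subject_sd: float = 0.12

    def validate(self, n_sources: int, k_states: int) -> None:
        for name, edge in (("group_edge", self.group_edge), ("clinical_edge", self.clinical_edge)):
            if edge is not None:
                i, j = edge
                if not (0 <= i < n_sources and 0 <= j < n_sources and i != j):
                    raise ValueError(f"{name}={edge} invalid for n_sources={n_sources}")
        for name, st in (("group_state", self.group_state), ("clinical_state", self.clinical_state)):
            if st is not None and not (1 <= st <= k_states):
                raise ValueError(f"{name}={st} outside 1..{k_states}")
        if self.clinical_target not in ("score", "duration"):
            raise ValueError("clinical_target must be 'score' or 'duration'")


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    spatial_sources: np.ndarray  # (N, V), z-scaled
    state_sequences: np.ndarray  # (M, T) labels in 1..K, one row per subject
    state_covariances: list  # K base (N, N) correlation matrices (control group)
    subject_state_covariances: list  # per subject, list of K matrices actually used
    mixing_per_window: np.ndarray  # (M, L, T_w, N) time courses per IVA window
    timecourses: np.ndarray  # (M, T, N)
    clinical_table: pd.DataFrame  # subject_id, group, score, duration_months
    mask: np.ndarray
    seed: int
    true_edge_strengths: np.ndarray | None = None  # per subject, planted clinical edge


def _exact_corr_partner(x: np.ndarray, r: float, rng) -> np.ndarray:
    """Standardized vector whose sample correlation with x is exactly r."""
    zx = (x - x.mean()) / x.std()
    g = rng.standard_normal(x.size)
    g = g - g.mean()
    g -= zx * (g @ zx) / (zx @ zx)  # orthogonalize
    zg = g / g.std()
    y = r * zx + math.sqrt(max(0.0, 1 - r**2)) * zg
    return y / y.std()


def generate_dataset(
    n_subjects: int = 24,
    T: int = 192,
    grid_shape=(12, 12, 12),
    n_sources: int = 4,
    k_states: int = 3,
    snr: float = 5.0,
    spatial_jitter: float = 0.0,
    planted_effects: PlantedEffects | None = None,
    seed: int = 0,
    tr_seconds: float = 2.0,
    blob_radius_vox: float = 2.0,
    dwell_mean_trs: float = 40.0,
    state_rho: float = 0.45,
    jitter_block_trs: int = 24,
    iva_window_trs: int = 48,
):
    """Generate ``n_subjects`` BOLD series plus the generating ground truth.

    data_m = timecourses_m @ (sources modulated per jitter block)
             + Gaussian noise scaled so var(signal)/var(noise) = snr.

    The first half of subjects is the patient (TS) group, the second half
    controls (N).  ``snr=np.inf`` disables noise.
    """
    if n_subjects % 2:
        raise ValueError("n_subjects must be even (half per group)")
    if not (snr > 0):
        raise ValueError("snr must be positive")
    effects = planted_effects or PlantedEffects()
    effects.validate(n_sources, k_states)
    rng = np.random.default_rng(seed)

    sources, mask = generate_spatial_sources(
        grid_shape, n_sources, blob_radius_vox, seed=int(rng.integers(2**31))
    )
    mask_idx = mask_to_indices(mask)
    V = sources.shape[1]
    base_covs = generate_state_covariances(
        n_sources, k_states, rho=state_rho, seed=int(rng.integers(2**31))
    )

    M = n_subjects
    groups = ["TS"] * (M // 2) + ["N"] * (M // 2)

    # per-subject covariances: group effect + clinical per-subject spread
    subject_covs = []
    true_edges = np.full(M, np.nan)
    for m in range(M):
        covs_m = [C.copy() for C in base_covs]
        if effects.group_edge is not None and groups[m] == "TS":
            i, j = effects.group_edge
            C = covs_m[effects.group_state - 1]
            v = np.clip(C[i, j] + effects.group_delta_r, -0.9, 0.9)
            C[i, j] = C[j, i] = v
            covs_m[effects.group_state - 1] = _nearest_unit_spd(C)
        if effects.clinical_edge is not None:
            i, j = effects.clinical_edge
            C = covs_m[effects.clinical_state - 1]
            v = np.clip(C[i, j] + rng.normal(0, effects.edge_subject_sd), -0.9, 0.9)
            C[i, j] = C[j, i] = v
            covs_m[effects.clinical_state - 1] = _nearest_unit_spd(C)
            true_edges[m] = covs_m[effects.clinical_state - 1][i, j]
        subject_covs.append(covs_m)

    # clinical table
    score = SCORE_MEAN + SCORE_SD * rng.standard_normal(M)
    duration = rng.uniform(*DURATION_RANGE, size=M)
    if effects.clinical_edge is not None:
        partner = _exact_corr_partner(true_edges, effects.clinical_r, rng)
        if effects.clinical_target == "score":
            score = SCORE_MEAN + SCORE_SD * partner
        else:
            mid = np.mean(DURATION_RANGE)
            duration = mid + (DURATION_RANGE[1] - mid) / 2.5 * partner
    clinical = pd.DataFrame(
        {
            "subject_id": [f"sub-{m:02d}" for m in range(M)],
            "group": groups,
            "score": np.round(score, 4),
            "duration_months": np.round(duration, 4),
        }
    )

    # IVA-window bookkeeping for the ground-truth mixing matrices
    step = iva_window_trs // 2
    L = (T - iva_window_trs) // step + 1 if T >= iva_window_trs else 0

    series = []
    all_tc = np.empty((M, T, n_sources))
    all_seq = np.empty((M, T), dtype=np.int64)
    mixing = np.empty((M, max(L, 1), iva_window_trs, n_sources)) if L else None
    n_blocks = int(math.ceil(T / jitter_block_trs))
    for m in range(M):
        sub_seed = int(rng.integers(2**31))
        tc, seq = generate_state_timecourses(
            T, subject_covs[m], dwell_mean_trs=dwell_mean_trs, seed=sub_seed
        )
        all_tc[m], all_seq[m] = tc, seq
        sub_rng = np.random.default_rng(sub_seed + 1)
        signal = np.empty((T, V))
        for b in range(n_blocks):
            rows = slice(b * jitter_block_trs, min((b + 1) * jitter_block_trs, T))
            S = sources
            if spatial_jitter > 0:
                g = _smooth_field(grid_shape, sub_rng)
                S = sources * (1.0 + spatial_jitter * g)
            signal[rows] = tc[rows] @ S
        if np.isinf(snr):
            data = signal
        else:
            noise_sd = math.sqrt(signal.var() / snr)
            data = signal + sub_rng.normal(0.0, noise_sd, size=signal.shape)
        series.append(
            BoldSeries(
                data=data,
                tr_seconds=tr_seconds,
                mask_voxel_indices=mask_idx,
                grid_shape=grid_shape,
                subject_id=f"sub-{m:02d}",
            )
        )
        for l in range(L):
            mixing[m, l] = tc[l * step : l * step + iva_window_trs]

    truth = GroundTruth(
        spatial_sources=sources,
        state_sequences=all_seq,
        state_covariances=base_covs,
        subject_state_covariances=subject_covs,
        mixing_per_window=mixing if L else np.empty((M, 0, 0, n_sources)),
        timecourses=all_tc,
        clinical_table=clinical,
        mask=mask,
        seed=seed,
        true_edge_strengths=true_edges if effects.clinical_edge is not None else None,
    )
    return series, truth


def _smooth_field(grid_shape, rng) -> np.ndarray:
    """Unit-SD smooth random field over the flattened grid (few broad bumps)."""
    coords = np.stack(
        np.meshgrid(*[np.arange(d, dtype=float) for d in grid_shape], indexing="ij"),
        axis=-1,
    ).reshape(-1, 3)
    field = np.zeros(coords.shape[0])
    width = max(grid_shape) / 3.0
    for _ in range(4):
        c = rng.uniform(0, np.array(grid_shape, dtype=float))
        amp = rng.standard_normal()
        field += amp * np.exp(-np.sum((coords - c) ** 2, axis=1) / (2 * width**2))
    field -= field.mean()
    sd = field.std()
    return field / sd if sd > 0 else field


def write_dataset(series, truth: GroundTruth, out_dir) -> None:
    """Persist a dataset: per-subject 4-D NIfTI, mask, ground truth, clinical CSV."""
    from pathlib import Path

    from .imageio import save_bold_series, save_mask

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for s in series:
        save_bold_series(
            s.data, s.mask_voxel_indices, s.grid_shape,
            out / f"{s.subject_id}_bold.nii.gz", tr_seconds=s.tr_seconds,
        )
    save_mask(truth.mask, out / "mask.nii.gz")
    truth.clinical_table.to_csv(out / "clinical.csv", index=False)
    np.savez_compressed(
        out / "ground_truth.npz",
        spatial_sources=truth.spatial_sources,
        state_sequences=truth.state_sequences,
        state_covariances=np.array(truth.state_covariances),
        timecourses=truth.timecourses,
        mixing_per_window=truth.mixing_per_window,
        seed=truth.seed,
    )
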