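"""Spatial dynamic FNC: normalized mutual information between SDC maps.

Connectivity between two spatial components in one subject-window is the
mutual information of their voxel value distributions, estimated from a
joint histogram with equal-frequency (rank) bins and Miller-Madow bias
correction, then mapped to the information coefficient of correlation

    r* = sqrt(1 - exp(-2 I))  in [0, 1),

which is exactly |rho| when the pair is bivariate Gaussian and exactly 0
under independence.  The standard deviation of r* across a subject's L
windows quantifies how much each connection fluctuates over time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MIMatrixStack",
    "EdgeVariability",
    "normalized_mi",
    "mi_connectivity",
    "edge_variability",
    "default_n_bins",
]


def default_n_bins(V: int) -> int:
    """Histogram bin count: max(8, floor(V^(1/3)))."""
    return max(8, int(np.floor(V ** (1.0 / 3.0))))


def _equal_frequency_bins(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Rank-based bin labels in 0..n_bins-1 (ties broken by position)."""
    order = np.argsort(x, kind="stable")
    labels = np.empty(x.size, dtype=np.intp)
    labels[order] = np.minimum((np.arange(x.size) * n_bins) // x.size, n_bins - 1)
    return labels


def normalized_mi(map_a: np.ndarray, map_b: np.ndarray, n_bins: int | None = None) -> float:
    """Normalized MI between two maps, in [0, 1); symmetric in its arguments.

    Equal-frequency binning makes the estimate invariant to strictly
    monotone transforms of either map.  The Miller-Madow correction removes
    the leading histogram bias; the corrected I is floored at 0, so exactly
    independent inputs (factorizing joint histogram) map to exactly 0.
    """
    a = np.asarray(map_a, dtype=np.float64).ravel()
    b = np.asarray(map_b, dtype=np.float64).ravel()
    if a.size != b.size:
        raise ValueError("maps must have equal length")
    V = a.size
    if n_bins is None:
        n_bins = default_n_bins(V)
    if V < 10 * n_bins**2:
        raise ValueError(f"V={V} too small for n_bins={n_bins} (need >= 10*n_bins^2)")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("constant map has no information content")
    la = _equal_frequency_bins(a, n_bins)
    lb = _equal_frequency_bins(b, n_bins)
    joint = np.zeros((n_bins, n_bins))
    np.add.at(joint, (la, lb), 1.0)
    joint /= V
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    nz = joint > 0
    I = float(np.sum(joint[nz] * np.log(joint[nz] / np.outer(px, py)[nz])))
    # Miller-Madow: H_mm = H + (occupied-1)/(2V); I = Hx + Hy - Hxy
    mx = int(np.sum(px > 0))
    my = int(np.sum(py > 0))
    mxy = int(np.sum(nz))
    I += (mx + my - mxy - 1) / (2.0 * V)
    I = max(I, 0.0)
    return float(np.sqrt(1.0 - np.exp(-2.0 * I)))


@dataclass
class MIMatrixStack:
    """Per (subject, window) symmetric P x P normalized-MI matrices.

    Diagonal is 0 by convention (self-MI is uninformative here).
    """

    values: np.ndarray  # (M, L, P, P)
    n_bins: int

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_windows(self) -> int:
        return self.values.shape[1]

    def to_frame(self, subject_ids=None) -> pd.DataFrame:
        M, L, P, _ = self.values.shape
        sids = subject_ids or [f"sub-{m:02d}" for m in range(M)]
        rows = []
        for m in range(M):
            for l in range(L):
                for i in range(P):
                    for j in range(i + 1, P):
                        rows.append((sids[m], l, i, j, self.values[m, l, i, j]))
        return pd.DataFrame(
            rows, columns=["subject_id", "window", "component_i", "component_j", "value"]
        )


@dataclass
class EdgeVariability:
    """STD of normalized MI across windows, per subject and per group."""

    std_per_edge: np.ndarray  # (M, P, P)
    group_mean_std: dict  # group label -> (P, P)


def mi_connectivity(scvset, n_bins: int | None = None) -> MIMatrixStack:
    """Normalized-MI connectivity for every subject, window, and SDC pair."""
    M, L, P = scvset.n_subjects, scvset.n_windows, scvset.n_components
    V = next(iter(scvset.sources.values())).shape[1]
    if n_bins is None:
        n_bins = default_n_bins(V)
    vals = np.zeros((M, L, P, P))
    for m in range(M):
        for l in range(L):
            maps = scvset.sources[(m, l)]
            for i in range(P):
                for j in range(i + 1, P):
                    v = normalized_mi(maps[i], maps[j], n_bins)
                    vals[m, l, i, j] = vals[m, l, j, i] = v
    return MIMatrixStack(values=vals, n_bins=n_bins)


def plot_group_std_heatmaps(variability: EdgeVariability, path, component_names=None):
    """Render per-group mean-STD matrices as heatmaps (one panel per group)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    groups = list(variability.group_mean_std)
    fig, axes = plt.subplots(1, max(len(groups), 1), figsize=(4.2 * max(len(groups), 1), 4))
    axes = np.atleast_1d(axes)
    vmax = max(v.max() for v in variability.group_mean_std.values()) if groups else 1.0
    for ax, g in zip(axes, groups):
        im = ax.imshow(variability.group_mean_std[g], vmin=0, vmax=vmax, cmap="viridis")
        ax.set_title(f"{g}: mean STD of normalized MI")
        if component_names:
            ax.set_xticks(range(len(component_names)), component_names, rotation=90)
            ax.set_yticks(range(len(component_names)), component_names)
        fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def edge_variability(mi_stack: MIMatrixStack, groups=None) -> EdgeVariability:
    """Sample STD (n-1 denominator) of each edge's MI across the L windows.

    ``groups`` maps subject index -> group label; group matrices are the
    means of member subjects' STD matrices.
    """
    vals = mi_stack.values
    M, L = vals.shape[:2]
    if L < 2:
        raise ValueError("need at least 2 windows for an STD")
    std = vals.std(axis=1, ddof=1)  # (M, P, P)
    group_mean = {}
    if groups is not None:
        labels = [groups[m] for m in range(M)]
        for g in dict.fromkeys(labels):
            members = [m for m, gl in enumerate(labels) if gl == g]
            group_mean[g] = std[members].mean(axis=0)
    return EdgeVariability(std_per_edge=std, group_mean_std=group_mean)
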