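"""Group comparison and clinical correlation.

Edge-wise two-sample t-tests on static and per-state dynamic FNC, a
Mann-Whitney U test for the STD of spatial (MI) connectivity, Benjamini-
Hochberg FDR control at alpha = 0.05, and Pearson correlation of significant
connectivity features with clinical scores.  Subjects contribute to a state
comparison only when they spend at least ``min_windows`` (default 10)
windows in that state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .tdfnc import StateModel, fisher_z, vectorize_fnc

__all__ = [
    "GroupStatsResult",
    "ClinicalCorrelation",
    "two_sample_t",
    "mann_whitney_u",
    "fdr_bh",
    "compare_state_fnc",
    "compare_edge_matrix",
    "correlate_clinical",
]


@dataclass
class GroupStatsResult:
    """Edge-wise test results for one family (one state, or the static FNC)."""

    statistic: np.ndarray  # (E,)
    p_raw: np.ndarray
    q_fdr: np.ndarray
    significant: np.ndarray  # bool, q < alpha
    test_name: str
    alpha: float
    n_per_group: tuple
    edges: list | None = None  # optional (i, j) labels per entry

    def to_frame(self, state=None) -> pd.DataFrame:
        E = len(self.p_raw)
        edges = self.edges or [(np.nan, np.nan)] * E
        return pd.DataFrame(
            {
                "state": [state] * E,
                "component_i": [e[0] for e in edges],
                "component_j": [e[1] for e in edges],
                "statistic": self.statistic,
                "p": self.p_raw,
                "q": self.q_fdr,
                "significant": self.significant,
            }
        )


@dataclass
class ClinicalCorrelation:
    feature: str
    score: str
    r: float
    p: float
    n: int


def two_sample_t(values_a, values_b, equal_var: bool = True):
    """Two-sided two-sample t-test (pooled variance by default)."""
    a = np.asarray(values_a, dtype=np.float64)
    b = np.asarray(values_b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("non-finite values in input")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0 and a.mean() == b.mean():
        return 0.0, 1.0
    t, p = sps.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


def _exact_u_pmf(n1: int, n2: int) -> np.ndarray:
    """Exact null PMF of the Mann-Whitney U statistic.

    Counts N(u; m, n) satisfy N(u; m, n) = N(u-n; m-1, n) + N(u; m, n-1)
    with N(u; m, 0) = N(u; 0, n) = [u == 0].
    """
    max_u = n1 * n2
    # counts[m, u] for the current n; start at n = 0
    counts = np.zeros((n1 + 1, max_u + 1))
    counts[:, 0] = 1.0
    for n in range(1, n2 + 1):
        new = np.zeros_like(counts)
        new[0, 0] = 1.0
        for m in range(1, n1 + 1):
            new[m] = counts[m]  # N(u; m, n-1)
            new[m, n:] += new[m - 1, :-n]  # N(u-n; m-1, n)
        counts = new
    pmf = counts[n1]
    return pmf / pmf.sum()


def mann_whitney_u(values_a, values_b, exact_max_n: int = 20):
    """Two-sided Mann-Whitney U test; returns (U of group a, p).

    Uses the exact null distribution (rank-count recurrence) when the
    combined sample size is at most ``exact_max_n`` and the data are free of
    ties; otherwise the normal approximation with tie correction.  All-tied
    input returns p = 1.
    """
    a = np.asarray(values_a, dtype=np.float64)
    b = np.asarray(values_b, dtype=np.float64)
    if a.size < 1 or b.size < 1:
        raise ValueError("each group needs at least 1 observation")
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    r1 = ranks[:n1].sum()
    U = r1 - n1 * (n1 + 1) / 2.0
    has_ties = np.unique(pooled).size < pooled.size
    if not has_ties and (n1 + n2) <= exact_max_n:
        pmf = _exact_u_pmf(n1, n2)
        u_lo = int(round(min(U, n1 * n2 - U)))
        p = float(min(1.0, pmf[: u_lo + 1].sum() + pmf[n1 * n2 - u_lo :].sum()))
    else:
        mu = n1 * n2 / 2.0
        tie_counts = np.array([np.sum(pooled == v) for v in np.unique(pooled)])
        n = n1 + n2
        tie_term = np.sum(tie_counts**3 - tie_counts) / (n * (n - 1))
        var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
        if var <= 0:
            return float(U), 1.0
        z = (U - mu - np.sign(U - mu) * 0.5) / math.sqrt(var)
        p = float(2 * sps.norm.sf(abs(z)))
    return float(U), min(p, 1.0)


def fdr_bh(p_values, alpha: float = 0.05):
    """Benjamini-Hochberg step-up; returns (q_values, reject flags).

    q values are monotone (cumulative minimum from the largest p); an edge is
    rejected iff q < alpha.
    """
    p = np.asarray(p_values, dtype=np.float64)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q, q < alpha


def subject_state_fnc(wfnc, assignments, min_windows: int = 10):
    """Per-state Fisher-z mean FNC vector for one subject.

    Returns dict state -> (E,) vector, only for states meeting the
    membership rule (at least ``min_windows`` windows).
    """
    vecs = fisher_z(vectorize_fnc(wfnc.matrices))  # (W, E)
    a = np.asarray(assignments)
    out = {}
    for s in np.unique(a):
        idx = np.flatnonzero(a == s)
        if idx.size >= min_windows:
            out[int(s)] = vecs[idx].mean(axis=0)
    return out


def compare_state_fnc(
    state_model: StateModel,
    wfnc_per_subject: dict,
    groups: dict,
    min_windows: int = 10,
    alpha: float = 0.05,
    fdr_family: str = "state",
):
    """Edge-wise group comparison of dynamic FNC within each state.

    Subject-level values are Fisher-z means of in-state window correlations;
    subjects failing the membership rule are excluded; a state is skipped
    (with a logged reason) when either group keeps fewer than 2 members.
    ``fdr_family`` controls whether BH runs within each state (default,
    matching per-state reporting) or globally over all tested edges.

    Returns (results: state -> GroupStatsResult, skipped: state -> reason).
    """
    subject_ids = list(wfnc_per_subject.keys())
    states = sorted({int(s) for a in state_model.assignments.values() for s in np.unique(a)})
    skipped = {}
    uniq = list(dict.fromkeys(groups[sid] for sid in subject_ids))
    if len(uniq) != 2:
        raise ValueError(f"need exactly 2 groups, got {uniq}")
    ga, gb = uniq

    subject_values = {
        sid: subject_state_fnc(
            wfnc_per_subject[sid], state_model.assignments[sid], min_windows
        )
        for sid in subject_ids
    }
    collected = {}
    for s in states:
        va, vb = [], []
        for sid in subject_ids:
            sv = subject_values[sid]
            if s in sv:
                (va if groups[sid] == ga else vb).append(sv[s])
        if len(va) < 2 or len(vb) < 2:
            skipped[s] = (
                f"state {s}: {len(va)} {ga} / {len(vb)} {gb} members after the "
                f"{min_windows}-window rule; need 2 per group"
            )
            continue
        collected[s] = (np.array(va), np.array(vb))

    any_wf = next(iter(wfnc_per_subject.values()))
    N = any_wf.n_components
    iu = np.triu_indices(N, 1)
    edges = list(zip(iu[0].tolist(), iu[1].tolist()))

    raw = {}
    for s, (va, vb) in collected.items():
        E = va.shape[1]
        tvals = np.empty(E)
        pvals = np.empty(E)
        for e in range(E):
            tvals[e], pvals[e] = two_sample_t(va[:, e], vb[:, e])
        raw[s] = (tvals, pvals, (va.shape[0], vb.shape[0]))

    results = {}
    if fdr_family == "global" and raw:
        allp = np.concatenate([raw[s][1] for s in raw])
        q_all, rej_all = fdr_bh(allp, alpha)
        pos = 0
        for s in raw:
            tvals, pvals, nn = raw[s]
            E = pvals.size
            results[s] = GroupStatsResult(
                statistic=tvals, p_raw=pvals, q_fdr=q_all[pos : pos + E],
                significant=rej_all[pos : pos + E], test_name="two_sample_t",
                alpha=alpha, n_per_group=nn, edges=edges,
            )
            pos += E
    else:
        for s, (tvals, pvals, nn) in raw.items():
            q, rej = fdr_bh(pvals, alpha)
            results[s] = GroupStatsResult(
                statistic=tvals, p_raw=pvals, q_fdr=q, significant=rej,
                test_name="two_sample_t", alpha=alpha, n_per_group=nn, edges=edges,
            )
    return results, skipped


def compare_edge_matrix(values_a: np.ndarray, values_b: np.ndarray, alpha: float = 0.05,
                        test: str = "t", edges=None) -> GroupStatsResult:
    """Edge-wise comparison of two groups' (n, E) feature matrices.

    ``test`` is "t" (pooled two-sample t) or "mannwhitney" (used for the STD
    of spatial MI connectivity).
    """
    A = np.atleast_2d(np.asarray(values_a, dtype=np.float64))
    B = np.atleast_2d(np.asarray(values_b, dtype=np.float64))
    E = A.shape[1]
    stat = np.empty(E)
    p = np.empty(E)
    for e in range(E):
        if test == "t":
            stat[e], p[e] = two_sample_t(A[:, e], B[:, e])
        else:
            stat[e], p[e] = mann_whitney_u(A[:, e], B[:, e])
    q, rej = fdr_bh(p, alpha)
    return GroupStatsResult(
        statistic=stat, p_raw=p, q_fdr=q, significant=rej,
        test_name="two_sample_t" if test == "t" else "mann_whitney_u",
        alpha=alpha, n_per_group=(A.shape[0], B.shape[0]), edges=edges,
    )


def correlate_clinical(features, scores, feature_name: str = "feature",
                       score_name: str = "score") -> ClinicalCorrelation:
    """Pearson correlation between one connectivity feature and one score.

    Intended for features already flagged significant by the group
    comparison.  Two-sided p; inputs must be paired, finite, non-constant,
    with n >= 3.
    """
    x = np.asarray(features, dtype=np.float64)
    y = np.asarray(scores, dtype=np.float64)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired inputs with n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in input")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance input")
    r, p = sps.pearsonr(x, y)
    return ClinicalCorrelation(feature=feature_name, score=score_name,
                               r=float(r), p=float(p), n=int(x.size))
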