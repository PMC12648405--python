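"""Nonparametric statistics: cluster-based permutation tests, paired
Wilcoxon signed-rank comparisons, and Benjamini–Hochberg FDR control.

The cluster permutation engine operates on two groups of observations
over an arbitrary 1D or 2D feature field (timepoints, or a
frequency × distance-bin grid).  Cells exceeding a two-sided t threshold
are grouped into contiguous clusters (4-connected in 2D), each cluster's
mass is the sum of its t values, and significance is assessed against
the permutation distribution of the maximum absolute cluster mass under
shuffled group labels.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = ["ClusterResult", "cluster_permutation_test", "paired_wilcoxon", "bh_fdr"]


@dataclass
class ClusterResult:
    """Outcome of a two-group cluster permutation test on one field."""

    t_obs: np.ndarray            # observed t field
    clusters: list[np.ndarray]   # boolean masks, one per observed cluster
    cluster_masses: np.ndarray
    cluster_pvalues: np.ndarray
    null_max_mass: np.ndarray    # permutation distribution of max |mass|
    alpha: float

    @property
    def sig_mask(self) -> np.ndarray:
        """Cells belonging to any cluster with p <= alpha."""
        mask = np.zeros_like(self.t_obs, dtype=bool)
        for cl, p in zip(self.clusters, self.cluster_pvalues):
            if p <= self.alpha:
                mask |= cl
        return mask

    @property
    def min_pvalue(self) -> float:
        """Permutation p of the largest-mass cluster (1.0 if no cluster)."""
        if len(self.cluster_pvalues) == 0:
            return 1.0
        return float(self.cluster_pvalues.min())


def _t_field(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pooled-variance two-sample t per cell; x, y are (n_obs, *shape)."""
    n1, n2 = x.shape[0], y.shape[0]
    m1, m2 = x.mean(axis=0), y.mean(axis=0)
    v1 = x.var(axis=0, ddof=1)
    v2 = y.var(axis=0, ddof=1)
    sp = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    denom = np.sqrt(sp * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, (m1 - m2) / denom, 0.0)
    return t


def _clusters_and_masses(t: np.ndarray, thresh: float) -> tuple[list[np.ndarray], np.ndarray]:
    """Contiguous supra-threshold clusters, positive and negative separately."""
    clusters: list[np.ndarray] = []
    masses: list[float] = []
    for sign in (1.0, -1.0):
        supra = (sign * t) > thresh
        if not supra.any():
            continue
        labeled, n = ndimage.label(supra)  # 1D runs / 2D 4-connectivity
        for lab in range(1, n + 1):
            mask = labeled == lab
            clusters.append(mask)
            masses.append(float(t[mask].sum()))
    return clusters, np.asarray(masses, float)


def cluster_permutation_test(
    x: np.ndarray,
    y: np.ndarray,
    n_perm: int = 1000,
    alpha: float = 0.05,
    cluster_alpha: float = 0.05,
    seed: int | np.random.Generator | None = None,
) -> ClusterResult:
    """Two-sided cluster-based permutation test of group means.

    ``x`` and ``y`` are (n_obs, *field_shape) stacks of observations
    (windows).  The cluster-forming threshold is the two-sided t critical
    value at ``cluster_alpha``; the null is the permutation distribution
    of the maximum absolute cluster mass under full label exchange.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n1 = x.shape[0]
    pooled = np.concatenate([x, y], axis=0)
    df = pooled.shape[0] - 2
    thresh = float(sps.t.ppf(1 - cluster_alpha / 2, df))

    t_obs = _t_field(x, y)
    clusters, masses = _clusters_and_masses(t_obs, thresh)

    null = np.zeros(n_perm)
    n_tot = pooled.shape[0]
    for p in range(n_perm):
        idx = rng.permutation(n_tot)
        t_p = _t_field(pooled[idx[:n1]], pooled[idx[n1:]])
        _, m = _clusters_and_masses(t_p, thresh)
        null[p] = np.abs(m).max() if len(m) else 0.0

    if len(masses):
        # p = (1 + #{null >= |mass|}) / (1 + n_perm)
        pvals = (1.0 + (null[None, :] >= np.abs(masses)[:, None]).sum(axis=1)) / (1.0 + n_perm)
    else:
        pvals = np.array([])
    return ClusterResult(t_obs, clusters, masses, pvals, null, alpha)


def paired_wilcoxon(a: np.ndarray, b: np.ndarray) -> dict:
    """Paired two-sided Wilcoxon signed-rank test with rank-biserial effect size.

    Ties (zero differences) are dropped (the classic Wilcoxon procedure);
    all-tied input returns p = 1 and effect size 0.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    d = a - b
    nz = d[d != 0]
    if len(nz) == 0:
        return {"statistic": 0.0, "p": 1.0, "effect_size": 0.0, "n": 0}
    res = sps.wilcoxon(nz, alternative="two-sided", method="auto")
    ranks = sps.rankdata(np.abs(nz))
    w_pos = ranks[nz > 0].sum()
    w_neg = ranks[nz < 0].sum()
    rb = (w_pos - w_neg) / (w_pos + w_neg)  # matched-pairs rank-biserial r
    return {"statistic": float(res.statistic), "p": float(res.pvalue),
            "effect_size": float(rb), "n": int(len(nz))}


def bh_fdr(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up FDR control.

    Returns (reject flags, adjusted p-values); adjusted p-values are
    monotone non-decreasing in raw-p rank.
    """
    p = np.asarray(p_values, float)
    if p.size == 0:
        return np.array([], bool), np.array([])
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj
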