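"""Nonparametric statistical primitives shared by the analysis stages.

Voxelwise group comparisons use Mann-Whitney U tests; voxelwise associations
with continuous decline measures use Spearman rank correlations converted to
t statistics.  Multiple comparisons across in-mask voxels are controlled by
the Benjamini-Hochberg false-discovery-rate step-up procedure.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "mann_whitney_u",
    "bh_fdr",
    "spearman",
    "voxelwise_map",
    "VoxelStatMap",
]

# Total-sample-size cutoff below which the exact permutation distribution of
# the rank sum is enumerated instead of using the normal approximation.
_EXACT_N_MAX = 20


def _rank_with_ties(values: np.ndarray) -> np.ndarray:
    return sps.rankdata(values, method="average")


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Returns ``(U, p)`` where ``U = min(U_x, U_y)``.  For combined sample
    sizes up to 20 the p-value is computed by exact enumeration of all
    ``C(n_x + n_y, n_x)`` group assignments of the pooled ranks (valid with
    ties); larger samples use the tie-corrected, continuity-corrected normal
    approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    nx, ny = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = _rank_with_ties(pooled)
    u_x = float(ranks[:nx].sum() - nx * (nx + 1) / 2.0)
    u_y = float(nx * ny - u_x)
    u_min = min(u_x, u_y)

    if nx + ny <= _EXACT_N_MAX:
        # Enumerate every assignment of nx pooled observations to group x and
        # double the lower tail P(U_x <= min(U_x, U_y)); under H0 the U_x
        # distribution is symmetric about nx*ny/2, so this is the usual
        # two-sided exact p.
        count_le = 0
        total = 0
        for combo in itertools.combinations(range(nx + ny), nx):
            rs = ranks[list(combo)].sum()
            ux = rs - nx * (nx + 1) / 2.0
            if ux <= u_min + 1e-12:
                count_le += 1
            total += 1
        p = min(1.0, 2.0 * count_le / total)
    else:
        mean = nx * ny / 2.0
        tie_counts = np.unique(pooled, return_counts=True)[1]
        n = nx + ny
        tie_term = (tie_counts**3 - tie_counts).sum() / (n * (n - 1))
        sd = math.sqrt(nx * ny / 12.0 * ((n + 1) - tie_term))
        if sd == 0:
            return u_min, 1.0
        z = (u_min - mean + 0.5) / sd  # continuity correction toward the mean
        p = min(1.0, 2.0 * sps.norm.cdf(z))
    return u_min, float(p)


def bh_fdr(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR control.

    Returns ``(q_values, reject_mask)`` where q-values are the
    monotone-enforced adjusted p-values and the mask flags ``q_value <= q``.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy(), np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, q_values, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return q_values, reject


def spearman(x, y) -> tuple[float, float, float]:
    """Spearman rank correlation with its t conversion.

    Returns ``(rho, t, p)`` with ``t = rho * sqrt((n - 2) / (1 - rho**2))``
    and a two-sided p-value from the t distribution with ``n - 2`` degrees
    of freedom.  Constant input yields ``(nan, nan, nan)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan"), float("nan")
    rho = float(np.corrcoef(_rank_with_ties(x), _rank_with_ties(y))[0, 1])
    if abs(rho) >= 1.0:
        rho = math.copysign(1.0, rho)
        return rho, math.copysign(math.inf, rho), 0.0
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    p = 2.0 * sps.t.sf(abs(t), df=n - 2)
    return rho, float(t), float(p)


@dataclass
class VoxelStatMap:
    """Per-voxel statistics with FDR correction over in-mask voxels."""

    stat: np.ndarray          # U statistic or Spearman rho per voxel
    t: np.ndarray             # t statistic (nan for the U branch)
    p: np.ndarray             # raw two-sided p per voxel
    q: np.ndarray             # BH-adjusted q per voxel
    mask: np.ndarray          # boolean, q <= q_threshold
    signed_logq: np.ndarray = field(default=None)  # sign(effect) * -log10(q)
    kind: str = "group_diff"
    q_threshold: float = 0.05


def voxelwise_map(maps, target, kind: str = "group_diff", q: float = 0.05) -> VoxelStatMap:
    """Per-voxel univariate statistics against a target, BH-corrected.

    ``maps`` is subjects x voxels.  For ``kind='group_diff'`` the target is a
    binary group indicator and each voxel gets a two-sided Mann-Whitney U
    test (effect sign from the difference of group means of ranks).  For
    ``kind='spearman'`` the target is continuous and each voxel gets a
    Spearman correlation with its t-based p-value.
    """
    X = np.asarray(maps, dtype=float)
    target = np.asarray(target)
    if X.ndim != 2:
        raise ValueError("maps must be 2-D (subjects x voxels)")
    if X.shape[1] == 0:
        raise ValueError("empty voxel mask")
    n_vox = X.shape[1]
    stat = np.full(n_vox, np.nan)
    tstat = np.full(n_vox, np.nan)
    pvals = np.ones(n_vox)
    sign = np.zeros(n_vox)

    if kind == "group_diff":
        g = target.astype(bool)
        if g.sum() == 0 or (~g).sum() == 0:
            raise ValueError("both groups must be non-empty")
        for v in range(n_vox):
            u, p = mann_whitney_u(X[g, v], X[~g, v])
            stat[v] = u
            pvals[v] = p
            sign[v] = np.sign(np.median(X[g, v]) - np.median(X[~g, v]))
    elif kind == "spearman":
        for v in range(n_vox):
            rho, t, p = spearman(X[:, v], target)
            if math.isnan(rho):
                stat[v], pvals[v] = np.nan, 1.0
                continue
            stat[v], tstat[v], pvals[v] = rho, t, p
            sign[v] = np.sign(rho)
    else:
        raise ValueError(f"unknown kind {kind!r}")

    qvals, reject = bh_fdr(pvals, q=q)
    with np.errstate(divide="ignore"):
        logq = -np.log10(np.maximum(qvals, np.finfo(float).tiny))
    return VoxelStatMap(
        stat=stat, t=tstat, p=pvals, q=qvals, mask=reject,
        signed_logq=sign * logq, kind=kind, q_threshold=q,
    )
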