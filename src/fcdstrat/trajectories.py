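"""Longitudinal cognitive/motor decline quantification.

Per-subject per-task decline is summarized by the ordinary-least-squares
slope over all available visits — the simplest measure given few, noisy
time points.  Slopes are oriented so negative means decline, corrected for
healthy aging and sex using coefficients estimated on controls only,
normalized per task by the interquartile range to a dimensionless scale,
and combined into decorrelated components by PCA on a Minimum Covariance
Determinant (MCD) robust covariance estimate.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "fit_slope",
    "slopes_from_panel",
    "residualize_on_controls",
    "iqr_normalize",
    "mcd_covariance",
    "robust_pca",
    "PcModel",
]

# Support-subset count above which exhaustive MCD search gives way to
# FAST-MCD C-step iteration.
_EXHAUSTIVE_MAX_SUBSETS = 100_000


def fit_slope(times, scores) -> float:
    """OLS slope of score against time (years); nan when undefined."""
    t = np.asarray(times, dtype=float)
    s = np.asarray(scores, dtype=float)
    keep = np.isfinite(t) & np.isfinite(s)
    t, s = t[keep], s[keep]
    if t.size < 2 or np.ptp(t) == 0:
        return float("nan")
    tc = t - t.mean()
    return float((tc @ (s - s.mean())) / (tc @ tc))


def slopes_from_panel(panel: pd.DataFrame, tasks: list | None = None,
                      orient: dict[str, int] | None = None) -> pd.DataFrame:
    """Subject x task slope matrix from a long-format score panel.

    ``panel`` needs columns subject_id, task, time_years, score.  ``orient``
    maps task name to its decline sign; oriented slopes satisfy
    "negative slope indicates decline".  Subjects with fewer than two
    distinct time points for a task get NaN there.
    """
    required = {"subject_id", "task", "time_years", "score"}
    missing = required - set(panel.columns)
    if missing:
        raise ValueError(f"panel is missing columns {sorted(missing)}")
    wide = {}
    for (sid, task), grp in panel.groupby(["subject_id", "task"], sort=True):
        slope = fit_slope(grp["time_years"].values, grp["score"].values)
        if orient is not None:
            slope *= orient.get(task, 1)
        wide.setdefault(sid, {})[task] = slope
    out = pd.DataFrame.from_dict(wide, orient="index").sort_index()
    if tasks is not None:
        out = out.reindex(columns=tasks)
    out.index.name = "subject_id"
    return out


def residualize_on_controls(slopes: pd.DataFrame, age: pd.Series,
                            sex: pd.Series, control_ids) -> pd.DataFrame:
    """Remove healthy age/sex expectations estimated from controls.

    Per task, ``slope ~ 1 + age + male`` is fitted on control rows only and
    the fitted prediction (including the intercept) is subtracted from every
    subject, so corrected control slopes are centred near zero.
    """
    control_ids = [c for c in control_ids if c in slopes.index]
    if len(control_ids) < 3:
        raise ValueError("need at least 3 controls with slope data")
    age = age.reindex(slopes.index).astype(float)
    sex_num = sex.reindex(slopes.index).map(
        lambda s: 1.0 if s in (1, "M", "male", "m") else 0.0)
    design = np.column_stack([np.ones(len(slopes)), age.values, sex_num.values])
    ctrl_mask = slopes.index.isin(control_ids)
    Dc = design[ctrl_mask]
    if np.ptp(Dc[:, 1]) == 0:
        raise ValueError("singular design: control ages are constant")
    rank = np.linalg.matrix_rank(Dc)
    if rank < Dc.shape[1]:
        # A constant-sex control group still allows an age fit.
        if np.ptp(Dc[:, 2]) == 0:
            Dc = Dc[:, :2]
            design_all = design[:, :2]
        else:
            raise ValueError("singular design: age/sex covariates are collinear")
    else:
        design_all = design
    corrected = slopes.copy()
    for task in slopes.columns:
        y = slopes[task].values.astype(float)
        ok = ctrl_mask & np.isfinite(y)
        if ok.sum() < Dc.shape[1] + 1:
            raise ValueError(f"too few controls with data for task {task!r}")
        beta, *_ = np.linalg.lstsq(design[ok][:, :design_all.shape[1]],
                                   y[ok], rcond=None)
        corrected[task] = y - design_all @ beta
    return corrected


def iqr_normalize(slopes: pd.DataFrame) -> pd.DataFrame:
    """Divide each task's slopes by its interquartile range.

    Quartiles use linear interpolation (the numpy default).
    """
    out = slopes.copy()
    for task in slopes.columns:
        vals = slopes[task].dropna().values
        if vals.size == 0:
            raise ValueError(f"task {task!r} has no slope data")
        q1, q3 = np.percentile(vals, [25, 75])
        iqr = q3 - q1
        if iqr <= 0:
            raise ValueError(f"task {task!r} has zero interquartile range")
        out[task] = slopes[task] / iqr
    return out


def _consistency_factor(n: int, h: int, p: int) -> float:
    """Large-sample consistency correction for the MCD scatter estimate."""
    if h >= n:
        return 1.0
    alpha = h / n
    q = sps.chi2.ppf(alpha, df=p)
    return alpha / sps.chi2.cdf(q, df=p + 2)


def _subset_cov(X: np.ndarray, idx) -> tuple[np.ndarray, np.ndarray]:
    sub = X[list(idx)]
    loc = sub.mean(axis=0)
    cov = np.cov(sub, rowvar=False, ddof=1)
    return loc, np.atleast_2d(cov)


def _logdet(cov: np.ndarray) -> float:
    sign, ld = np.linalg.slogdet(cov)
    return ld if sign > 0 else math.inf


def mcd_covariance(X, support_fraction: float | None = None, seed: int = 0,
                   n_restarts: int = 500, reweight: bool = True
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Minimum Covariance Determinant location/scatter.

    Finds the size-``h`` subset whose sample covariance has minimal
    determinant; ``h = ceil((n + p + 1) / 2)`` by default.  When the number
    of subsets ``C(n, h)`` is small the search is exhaustive, otherwise
    FAST-MCD C-steps from random seeds are used.  The scatter matrix
    carries the standard chi-square consistency correction (equal to 1 when
    ``h = n``, where the estimate reduces to the classical covariance).
    With ``reweight=True`` (the usual finite-sample refinement) the raw
    estimate is followed by one reweighting step that keeps observations
    within the 97.5% chi-square Mahalanobis radius, restoring efficiency on
    clean data while preserving robustness.

    Returns ``(covariance, location, support_index_array)``.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (observations x variables)")
    n, p = X.shape
    if n <= p:
        raise ValueError(
            f"need more observations than variables (n={n}, p={p}); "
            "use fewer tasks or more subjects")
    h_min = int(math.ceil((n + p + 1) / 2))
    if support_fraction is None:
        h = h_min
    else:
        h = int(math.ceil(support_fraction * n))
        if not h_min <= h <= n:
            raise ValueError(f"support size h={h} outside [{h_min}, {n}]")

    if h == n:
        loc, cov = _subset_cov(X, range(n))
        return cov, loc, np.arange(n)

    rng = np.random.default_rng(seed)

    def c_steps(idx: np.ndarray) -> tuple[float, np.ndarray]:
        idx = np.asarray(idx)
        prev = None
        for _ in range(100):
            loc, cov = _subset_cov(X, idx)
            if _logdet(cov) == math.inf:
                cov = cov + 1e-10 * np.eye(p)
            d = _mahalanobis_sq(X, loc, cov)
            new_idx = np.sort(np.argsort(d, kind="stable")[:h])
            if prev is not None and np.array_equal(new_idx, prev):
                break
            prev = idx = new_idx
        loc, cov = _subset_cov(X, idx)
        return _logdet(cov), idx

    if math.comb(n, h) <= _EXHAUSTIVE_MAX_SUBSETS:
        best_ld, best_idx = math.inf, None
        for combo in itertools.combinations(range(n), h):
            _, cov = _subset_cov(X, combo)
            ld = _logdet(cov)
            if ld < best_ld:
                best_ld, best_idx = ld, np.array(combo)
        support = best_idx
    else:
        best_ld, support = math.inf, None
        for _ in range(n_restarts):
            start = rng.choice(n, size=p + 1, replace=False)
            # Grow a full-rank starting subset if needed.
            tries = 0
            while _logdet(_subset_cov(X, start)[1]) == math.inf and tries < 20:
                start = rng.choice(n, size=min(n, len(start) + 1), replace=False)
                tries += 1
            loc, cov = _subset_cov(X, start)
            d = _mahalanobis_sq(X, loc, cov + 1e-10 * np.eye(p))
            idx0 = np.sort(np.argsort(d, kind="stable")[:h])
            ld, idx = c_steps(idx0)
            if ld < best_ld:
                best_ld, support = ld, idx

    loc, cov = _subset_cov(X, support)
    cov = cov * _consistency_factor(n, h, p)
    if reweight and h < n:
        d = _mahalanobis_sq(X, loc, cov)
        keep = d <= sps.chi2.ppf(0.975, df=p)
        if keep.sum() > p:
            loc = X[keep].mean(axis=0)
            cov = np.atleast_2d(np.cov(X[keep], rowvar=False, ddof=1))
            # consistency for the 97.5% trimming radius
            cov = cov * (0.975 / sps.chi2.cdf(sps.chi2.ppf(0.975, df=p),
                                              df=p + 2))
            support = np.where(keep)[0]
    return cov, loc, support


def _mahalanobis_sq(X: np.ndarray, loc: np.ndarray, cov: np.ndarray) -> np.ndarray:
    diff = X - loc
    sol = np.linalg.solve(cov, diff.T)
    return np.einsum("ij,ji->i", diff, sol)


@dataclass
class PcModel:
    """Eigendecomposition of a robust task-slope covariance."""

    covariance: np.ndarray
    location: np.ndarray
    loadings: np.ndarray        # columns are eigenvectors, sorted by eigenvalue
    eigenvalues: np.ndarray
    variance_fractions: np.ndarray
    tasks: list
    fit_population: str         # "all" | "preHD_only"
    n_components: int

    def project(self, slopes: pd.DataFrame) -> pd.DataFrame:
        """PC scores of (corrected, IQR-normalized) slopes."""
        X = slopes[self.tasks].values.astype(float) - self.location
        scores = X @ self.loadings[:, :self.n_components]
        cols = [f"PC{i + 1}" for i in range(self.n_components)]
        return pd.DataFrame(scores, index=slopes.index, columns=cols)


def robust_pca(slope_panel: pd.DataFrame, population: str = "preHD_only",
               fit_ids=None, n_components: int = 5, support_fraction=None,
               seed: int = 0) -> PcModel:
    """PCA of the MCD covariance of the slope panel.

    ``population`` names the fit variant: "all" (controls + pre-HD,
    age/sex-corrected slopes) or "preHD_only" (the stratification variant);
    ``fit_ids`` selects the rows accordingly.  Eigenvector signs are fixed
    so each component's largest-magnitude loading is positive.
    """
    data = slope_panel if fit_ids is None else slope_panel.loc[
        [i for i in fit_ids if i in slope_panel.index]]
    X = data.dropna(axis=0).values.astype(float)
    if not np.isfinite(X).all():
        raise ValueError("non-finite values in slope panel")
    cov, loc, _ = mcd_covariance(X, support_fraction=support_fraction, seed=seed)
    if not np.isfinite(cov).all():
        raise ValueError("non-finite robust covariance")
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    for j in range(evecs.shape[1]):
        k = np.argmax(np.abs(evecs[:, j]))
        if evecs[k, j] < 0:
            evecs[:, j] *= -1
    total = evals.sum()
    if total <= 0:
        warnings.warn("non-positive total variance in robust covariance",
                      RuntimeWarning, stacklevel=2)
    n_components = min(n_components, evecs.shape[1])
    return PcModel(
        covariance=cov, location=loc, loadings=evecs, eigenvalues=evals,
        variance_fractions=evals / total if total > 0 else evals,
        tasks=list(slope_panel.columns), fit_population=population,
        n_components=n_components,
    )
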