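"""Removal of non-functional variance from FCD feature matrices.

Three corrections, none of which ever sees group or subgroup labels:

* ComBat site harmonization — per-voxel site location/scale adjustment,
  optionally with parametric empirical-Bayes shrinkage of the site
  parameters; biological covariates are deliberately excluded so class
  information cannot leak into the harmonized features.
* Grey-matter-concentration (GMC) residualization — the linear effect of
  local GMC on FCD is estimated per voxel across subjects and subtracted,
  yielding local-atrophy-controlled maps.
* Motion detrending — the linear weight of mean framewise displacement on
  each feature is learned from healthy controls and its slope contribution
  removed from everyone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "HarmonizationModel",
    "combat_fit",
    "combat_apply",
    "ComBatHarmonizer",
    "gmc_residualize",
    "GmcResidualizer",
    "motion_detrend",
    "MotionDetrender",
    "gmc_only_classifier",
]


@dataclass
class HarmonizationModel:
    """Fitted ComBat parameters (no biological covariates)."""

    grand_mean: np.ndarray          # per voxel
    pooled_scale: np.ndarray        # per voxel
    site_gamma: dict                # site -> per-voxel location (gamma*)
    site_delta: dict                # site -> per-voxel scale (delta*)
    sites: tuple
    method: str                     # "eb" | "exact"


def _site_params(Z: np.ndarray, site_rows: dict, method: str,
                 eb_iter: int = 100, eb_tol: float = 1e-8
                 ) -> tuple[dict, dict]:
    gamma_star, delta_star = {}, {}
    for s, rows in site_rows.items():
        Zs = Z[rows]
        n_i = len(rows)
        g_hat = Zs.mean(axis=0)
        ssq = ((Zs - g_hat) ** 2).sum(axis=0)
        if method == "exact":
            # ddof-0 scale makes fit-and-apply exactly idempotent
            gamma_star[s] = g_hat
            delta_star[s] = np.sqrt(np.maximum(ssq / n_i, 1e-12))
            continue
        d2_hat = ssq / (n_i - 1)
        # Parametric empirical Bayes: normal prior on gamma, inverse-gamma
        # on delta^2, hyperparameters by the method of moments across voxels.
        g_bar = g_hat.mean()
        tau2 = g_hat.var()
        m = d2_hat.mean()
        s2 = d2_hat.var()
        if s2 <= 0 or tau2 <= 0:
            gamma_star[s] = g_hat
            delta_star[s] = np.sqrt(np.maximum(d2_hat, 1e-12))
            continue
        lam = (2 * s2 + m**2) / s2           # inverse-gamma shape
        theta = (m * s2 + m**3) / s2         # inverse-gamma scale
        g_star = g_hat.copy()
        d2_star = d2_hat.copy()
        for _ in range(eb_iter):
            g_new = (n_i * tau2 * g_hat + d2_star * g_bar) / (n_i * tau2 + d2_star)
            resid_sq = ssq + n_i * (g_hat - g_new) ** 2
            d2_new = (theta + 0.5 * resid_sq) / (n_i / 2.0 + lam - 1.0)
            if (np.max(np.abs(g_new - g_star)) < eb_tol
                    and np.max(np.abs(d2_new - d2_star)) < eb_tol):
                g_star, d2_star = g_new, d2_new
                break
            g_star, d2_star = g_new, d2_new
        gamma_star[s] = g_star
        delta_star[s] = np.sqrt(np.maximum(d2_star, 1e-12))
    return gamma_star, delta_star


def combat_fit(features, sites, method: str = "eb") -> HarmonizationModel:
    """Estimate per-site location/scale adjustments for every voxel.

    ``method='eb'`` shrinks the per-site per-voxel estimates via parametric
    empirical Bayes (the classic batch-adjustment recipe); ``method='exact'``
    uses the raw estimates, which removes site means and variances exactly
    and makes fit-and-apply idempotent.
    """
    X = np.asarray(features, dtype=float)
    sites = np.asarray(sites)
    site_list = tuple(pd.unique(sites).tolist())
    site_rows = {s: np.where(sites == s)[0] for s in site_list}
    for s, rows in site_rows.items():
        if len(rows) < 2:
            raise ValueError(f"site {s!r} has a single subject; "
                             "site scale is undefined")
    n = len(X)
    site_means = {s: X[r].mean(axis=0) for s, r in site_rows.items()}
    alpha = sum(len(r) / n * site_means[s] for s, r in site_rows.items())
    resid2 = np.zeros(X.shape[1])
    for s, r in site_rows.items():
        resid2 += ((X[r] - site_means[s]) ** 2).sum(axis=0)
    sigma = np.sqrt(np.maximum(resid2 / n, 1e-12))
    Z = (X - alpha) / sigma
    if len(site_list) == 1:
        # nothing to harmonize: a single site is its own reference
        v = X.shape[1]
        gamma_star = {site_list[0]: np.zeros(v)}
        delta_star = {site_list[0]: np.ones(v)}
    else:
        gamma_star, delta_star = _site_params(Z, site_rows, method)
    return HarmonizationModel(grand_mean=alpha, pooled_scale=sigma,
                              site_gamma=gamma_star, site_delta=delta_star,
                              sites=site_list, method=method)


def combat_apply(model: HarmonizationModel, features, sites) -> np.ndarray:
    """Harmonize features using fitted site parameters.

    Sites unseen at fit time (e.g. a held-out imaging site inside
    cross-validation) get plain location/scale estimates from their own
    rows, standardized against the fitted grand mean and pooled scale; no
    label information is involved either way.
    """
    X = np.asarray(features, dtype=float)
    sites = np.asarray(sites)
    Z = (X - model.grand_mean) / model.pooled_scale
    out = np.empty_like(Z)
    for s in pd.unique(sites):
        rows = np.where(sites == s)[0]
        if s in model.site_gamma:
            g, d = model.site_gamma[s], model.site_delta[s]
        else:
            if len(rows) < 2:
                raise ValueError(f"unseen site {s!r} needs >= 2 rows to "
                                 "estimate its adjustment")
            g = Z[rows].mean(axis=0)
            d = np.sqrt(np.maximum(((Z[rows] - g) ** 2).mean(axis=0), 1e-12))
        out[rows] = (Z[rows] - g) / d
    return out * model.pooled_scale + model.grand_mean


class ComBatHarmonizer:
    """Preprocessor adapter: fit on training rows, apply anywhere."""

    def __init__(self, method: str = "eb"):
        self.method = method
        self.model_: HarmonizationModel | None = None

    def fit(self, X: np.ndarray, meta: pd.DataFrame) -> "ComBatHarmonizer":
        self.model_ = combat_fit(X, meta["site"].values, method=self.method)
        return self

    def transform(self, X: np.ndarray, meta: pd.DataFrame) -> np.ndarray:
        return combat_apply(self.model_, X, meta["site"].values)


def gmc_residualize(fcd_maps, gmc_maps, fit_mask=None
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-voxel linear removal of grey-matter concentration from FCD.

    For each voxel, ``FCD ~ intercept + GMC`` is fitted across the fit rows
    (all rows by default; training rows inside cross-validation) and the
    prediction is subtracted from every subject.  Voxels with constant GMC
    fall back to intercept-only fits (mean-centering) with a warning.

    Returns ``(residual_maps, slopes, intercepts)``.
    """
    F = np.asarray(fcd_maps, dtype=float)
    G = np.asarray(gmc_maps, dtype=float)
    if F.shape != G.shape:
        raise ValueError("FCD and GMC matrices must have equal shape")
    fit = np.ones(len(F), dtype=bool) if fit_mask is None else np.asarray(fit_mask)
    Gf, Ff = G[fit], F[fit]
    g_mean = Gf.mean(axis=0)
    f_mean = Ff.mean(axis=0)
    g_var = ((Gf - g_mean) ** 2).mean(axis=0)
    constant = g_var == 0
    if constant.any():
        warnings.warn(f"{int(constant.sum())} voxel(s) with constant GMC: "
                      "intercept-only fit", RuntimeWarning, stacklevel=2)
    slope = np.zeros_like(g_mean)
    ok = ~constant
    slope[ok] = (((Gf - g_mean) * (Ff - f_mean)).mean(axis=0)[ok] / g_var[ok])
    intercept = f_mean - slope * g_mean
    residual = F - (intercept + slope * G)
    return residual, slope, intercept


class GmcResidualizer:
    """Preprocessor adapter for LOSO pipelines.

    Holds the full-cohort GMC matrix; ``meta`` must carry a ``row`` column
    with each subject's index into it, so the fit sees training-row GMC only.
    """

    def __init__(self, gmc_all: np.ndarray):
        self.gmc_all = np.asarray(gmc_all, dtype=float)
        self.slope_ = None
        self.intercept_ = None

    def fit(self, X: np.ndarray, meta: pd.DataFrame) -> "GmcResidualizer":
        G = self.gmc_all[meta["row"].values]
        _, self.slope_, self.intercept_ = gmc_residualize(X, G)
        return self

    def transform(self, X: np.ndarray, meta: pd.DataFrame) -> np.ndarray:
        G = self.gmc_all[meta["row"].values]
        return X - (self.intercept_ + self.slope_ * G)


def motion_detrend(features, fd_mean, control_mask
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Remove the control-learned linear motion trend from each feature.

    Per feature, ``feature ~ intercept + fd_mean`` is fitted on controls;
    only the slope term ``weight * (fd - mean control fd)`` is subtracted
    from every subject, so control feature means are preserved.

    Returns ``(corrected_features, weights)``.
    """
    X = np.asarray(features, dtype=float)
    fd = np.asarray(fd_mean, dtype=float)
    ctrl = np.asarray(control_mask, dtype=bool)
    if ctrl.sum() < 3:
        raise ValueError("need at least 3 controls")
    fd_c = fd[ctrl]
    if np.ptp(fd_c) == 0:
        raise ValueError("zero motion variance in controls")
    fd0 = fd_c.mean()
    w = ((fd_c - fd0) @ (X[ctrl] - X[ctrl].mean(axis=0))) / ((fd_c - fd0) ** 2).sum()
    corrected = X - np.outer(fd - fd0, w)
    return corrected, w


class MotionDetrender:
    """Preprocessor adapter; ``meta`` needs ``fd_mean`` and ``group``."""

    def __init__(self):
        self.weights_ = None
        self.fd0_ = None

    def fit(self, X: np.ndarray, meta: pd.DataFrame) -> "MotionDetrender":
        ctrl = meta["group"].values == "control"
        fd = meta["fd_mean"].values.astype(float)
        _, self.weights_ = motion_detrend(X, fd, ctrl)
        self.fd0_ = float(fd[ctrl].mean())
        return self

    def transform(self, X: np.ndarray, meta: pd.DataFrame) -> np.ndarray:
        fd = meta["fd_mean"].values.astype(float)
        return X - np.outer(fd - self.fd0_, self.weights_)


def gmc_only_classifier(gmc_maps, train_labels, sites, model_spec=None,
                        meta: pd.DataFrame | None = None, n_perm: int = 1000,
                        n_boot: int = 1000, seed: int = 0):
    """Negative control: the LOSO machinery applied to GMC features.

    Returns ``(LosoResult, report_dict)`` with the same schema as the FCD
    reports, so the two are machine-comparable.
    """
    from .stratify import loso_cv, permutation_pvalue, site_avg_auc

    result = loso_cv(gmc_maps, train_labels, sites, model_spec=model_spec,
                     meta=meta, seed=seed)
    y = np.asarray(train_labels, dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_auc, boot_auc, per_site = site_avg_auc(
            result.decisions, y, sites, n_boot=n_boot, seed=seed)

        def stat(perm_y):
            try:
                m, _, _ = site_avg_auc(result.decisions, perm_y, sites,
                                       n_boot=0, seed=0)
            except ValueError:
                return -np.inf
            return m

        p = permutation_pvalue(mean_auc, stat, y, sites, n_perm=n_perm,
                               seed=seed)
    report = {
        "measure": "gmc_only",
        "per_site_auc": {str(k): v for k, v in per_site.items()},
        "site_avg_auc": mean_auc,
        "bootstrap_median_auc": boot_auc,
        "auc_permutation_p": p,
    }
    return result, report
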