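"""Site-robust stratification of pre-HD subjects from single-visit FCD maps.

Decline measures (task slopes or PC projections) are discretized into
fast / intermediate / slow subgroups around the median, at half a robust,
IQR-based standard deviation.  Elastic-net-penalized logistic regression is
trained on the extreme subgroups under leave-one-site-out cross-validation
(LOSO-CV) with nested 5-fold hyperparameter selection; binary separation is
scored by the site-averaged AUC (with a bootstrap-median variant) and the
continuous decision value is validated against decline rates by
Fisher-z-pooled within-site Spearman correlations.  Significance comes from
within-site label permutations.

Every preprocessing step (feature standardization, age/sex correction,
harmonization, CAG augmentation) is fitted on training-site rows only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "robust_sd",
    "discretize",
    "DeclineLabels",
    "ModelSpec",
    "StratifierModel",
    "fit_elasticnet_logistic",
    "AgeSexCorrector",
    "CagAugmenter",
    "loso_cv",
    "LosoResult",
    "auc_score",
    "site_avg_auc",
    "pooled_spearman",
    "permutation_pvalue",
    "add_genetic_feature",
    "EvaluationReport",
    "evaluate_stratification",
]

# sigma of a normal with unit IQR: 2 * Phi^{-1}(0.75)
_IQR_TO_SD = 2.0 * sps.norm.ppf(0.75)


def robust_sd(values) -> float:
    """SD of the normal distribution matching the sample IQR: IQR / 1.349."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 4:
        raise ValueError("need at least 4 values")
    q1, q3 = np.percentile(v, [25, 75])
    iqr = q3 - q1
    if iqr <= 0:
        warnings.warn("zero IQR; robust SD is 0 (all labels intermediate)",
                      RuntimeWarning, stacklevel=2)
        return 0.0
    return float(iqr / _IQR_TO_SD)


@dataclass
class DeclineLabels:
    """Fast / intermediate / slow subgroup assignment for one measure."""

    measure: str
    values: pd.Series
    labels: pd.Series           # "fast" | "intermediate" | "slow"
    median: float
    robust_sd: float

    @property
    def is_extreme(self) -> pd.Series:
        return self.labels.isin(["fast", "slow"])

    def binary(self) -> pd.Series:
        """1 = fast decliner, 0 = slow/stable; NaN for intermediate."""
        out = pd.Series(np.nan, index=self.labels.index)
        out[self.labels == "fast"] = 1.0
        out[self.labels == "slow"] = 0.0
        return out


def discretize(values: pd.Series, measure: str = "") -> DeclineLabels:
    """Tercile-like subgroups: fast below, slow above median -+ rsd/2.

    Decline measures are oriented so lower values mean faster decline.
    Values exactly at a boundary are labelled intermediate.
    """
    values = pd.Series(values).astype(float)
    med = float(np.median(values.dropna()))
    rsd = robust_sd(values.dropna())
    labels = pd.Series("intermediate", index=values.index, dtype=object)
    if rsd > 0:  # zero robust SD: no resolvable extremes, all intermediate
        lo, hi = med - rsd / 2.0, med + rsd / 2.0
        labels[values < lo] = "fast"
        labels[values > hi] = "slow"
        labels[values.isna()] = "intermediate"
    return DeclineLabels(measure=measure, values=values, labels=labels,
                         median=med, robust_sd=rsd)


@dataclass
class ModelSpec:
    """Elastic-net logistic hyper-grid and fitting controls."""

    lambdas: tuple = tuple(np.logspace(-3, 2, 8))
    alphas: tuple = (0.1, 0.5, 0.9)
    inner_folds: int = 5
    max_iter: int = 2000
    tol: float = 1e-4
    standardize: bool = True

    @classmethod
    def fast(cls) -> "ModelSpec":
        """Reduced grid for desk-scale runs."""
        return cls(lambdas=(0.01, 0.1, 1.0, 10.0), alphas=(0.5,),
                   max_iter=1000, tol=1e-3)


@dataclass
class StratifierModel:
    """Linear decision rule with its training-time preprocessing recipe."""

    coef: np.ndarray
    intercept: float
    l1_ratio: float
    lam: float
    training_sites: tuple
    feature_mean: np.ndarray
    feature_scale: np.ndarray
    preprocessors: tuple = ()

    def decision_values(self, X: np.ndarray, meta: pd.DataFrame | None = None
                        ) -> np.ndarray:
        """Affine score w.x + b (rank-equivalent to the signed distance to
        the decision hyperplane)."""
        for prep in self.preprocessors:
            X = prep.transform(X, meta)
        Xs = (X - self.feature_mean) / self.feature_scale
        return Xs @ self.coef + self.intercept

    def predict(self, X: np.ndarray, meta: pd.DataFrame | None = None
                ) -> np.ndarray:
        return (self.decision_values(X, meta) > 0).astype(int)


def auc_score(y_true, scores) -> float:
    """AUC via the rank (Mann-Whitney) statistic, tie-aware."""
    y = np.asarray(y_true).astype(int)
    s = np.asarray(scores, dtype=float)
    n1 = int(y.sum())
    n0 = y.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC needs both classes")
    ranks = sps.rankdata(s)
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def _fit_single(X, y, lam, alpha, spec: ModelSpec, seed: int) -> LogisticRegression:
    clf = LogisticRegression(
        penalty="elasticnet", solver="saga", l1_ratio=alpha, C=1.0 / lam,
        max_iter=spec.max_iter, tol=spec.tol, random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # saga convergence at strong penalty
        clf.fit(X, y)
    return clf


def fit_elasticnet_logistic(X, y, model_spec: ModelSpec | None = None,
                            seed: int = 0, training_sites=()) -> StratifierModel:
    """Nested-CV elastic-net logistic regression.

    The (lambda, l1_ratio) pair is chosen by mean AUC over stratified
    ``inner_folds``-fold cross-validation inside the training set, then the
    model is refitted on the full training set with the winners.
    """
    spec = model_spec or ModelSpec()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training labels contain a single class")

    if spec.standardize:
        mean = X.mean(axis=0)
        scale = X.std(axis=0)
        scale[scale == 0] = 1.0
    else:
        mean = np.zeros(X.shape[1])
        scale = np.ones(X.shape[1])
    Xs = (X - mean) / scale

    n_splits = min(spec.inner_folds, int(np.bincount(y).min()))
    best = None
    if n_splits >= 2 and (len(spec.lambdas) > 1 or len(spec.alphas) > 1):
        skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
        folds = list(skf.split(Xs, y))
        for lam in spec.lambdas:
            for alpha in spec.alphas:
                scores = []
                for tr, va in folds:
                    if np.unique(y[tr]).size < 2 or np.unique(y[va]).size < 2:
                        continue
                    clf = _fit_single(Xs[tr], y[tr], lam, alpha, spec, seed)
                    scores.append(auc_score(y[va], Xs[va] @ clf.coef_.ravel()))
                mean_auc = np.mean(scores) if scores else 0.5
                if best is None or mean_auc > best[0] + 1e-12:
                    best = (mean_auc, lam, alpha)
        _, lam, alpha = best
    else:
        lam, alpha = spec.lambdas[0], spec.alphas[0]

    clf = _fit_single(Xs, y, lam, alpha, spec, seed)
    return StratifierModel(
        coef=clf.coef_.ravel().copy(), intercept=float(clf.intercept_[0]),
        l1_ratio=float(alpha), lam=float(lam),
        training_sites=tuple(training_sites),
        feature_mean=mean, feature_scale=scale,
    )


class AgeSexCorrector:
    """Per-feature linear healthy-aging/sex correction learned on controls.

    Fit uses training-set control rows only; the fitted prediction,
    intercept included, is subtracted from every row it is applied to, so
    features become deviations from the healthy expectation.
    """

    def __init__(self):
        self.beta_ = None

    def fit(self, X: np.ndarray, meta: pd.DataFrame) -> "AgeSexCorrector":
        ctrl = (meta["group"].values == "control")
        if ctrl.sum() < 3:
            raise ValueError("no (or too few) controls in the training set")
        D = self._design(meta)[ctrl]
        self.beta_, *_ = np.linalg.lstsq(D, X[ctrl], rcond=None)
        return self

    @staticmethod
    def _design(meta: pd.DataFrame) -> np.ndarray:
        male = (meta["sex"].values == "M").astype(float)
        return np.column_stack([np.ones(len(meta)), meta["age"].values, male])

    def transform(self, X: np.ndarray, meta: pd.DataFrame) -> np.ndarray:
        if self.beta_ is None:
            raise RuntimeError("corrector not fitted")
        return X - self._design(meta) @ self.beta_


class CagAugmenter:
    """Append a CAG-repeat column standardized with training-row moments."""

    def __init__(self):
        self.mean_ = None
        self.sd_ = None

    def fit(self, X: np.ndarray, meta: pd.DataFrame) -> "CagAugmenter":
        cag = meta["cag"].values.astype(float)
        if np.isnan(cag).any():
            raise ValueError("CAG missing for some training rows")
        self.mean_ = float(cag.mean())
        self.sd_ = float(cag.std())
        return self

    def transform(self, X: np.ndarray, meta: pd.DataFrame) -> np.ndarray:
        cag = meta["cag"].values.astype(float)
        if np.isnan(cag).any():
            raise ValueError("CAG missing for some rows")
        sd = self.sd_ if self.sd_ > 0 else 1.0
        return np.column_stack([X, (cag - self.mean_) / sd])


def add_genetic_feature(X, cag, train_mask=None) -> np.ndarray:
    """Convenience wrapper around :class:`CagAugmenter` on plain arrays."""
    X = np.asarray(X, dtype=float)
    meta = pd.DataFrame({"cag": np.asarray(cag, dtype=float)})
    aug = CagAugmenter()
    fit_meta = meta if train_mask is None else meta[np.asarray(train_mask)]
    fit_X = X if train_mask is None else X[np.asarray(train_mask)]
    aug.fit(fit_X, fit_meta)
    return aug.transform(X, meta)


@dataclass
class LosoResult:
    """Per-subject decision values and per-site fitted models."""

    decisions: np.ndarray          # one score per subject (from the fold
                                   # where their site was held out)
    predictions: np.ndarray        # decision > 0
    sites: np.ndarray
    models: dict = field(default_factory=dict)   # site -> StratifierModel


def loso_cv(features, train_labels, sites, model_spec: ModelSpec | None = None,
            meta: pd.DataFrame | None = None, preprocessor_factories=(),
            seed: int = 0) -> LosoResult:
    """Leave-one-site-out cross-validation.

    ``train_labels`` is a float array with 1 (fast / positive), 0 (slow /
    negative) or NaN (intermediate: scored but excluded from training).
    For each site, preprocessors and the classifier are fitted on the
    labelled rows of all *other* sites, then every held-out-site subject —
    including intermediates — receives a decision value.
    """
    X = np.asarray(features, dtype=float)
    yt = np.asarray(train_labels, dtype=float)
    sites = np.asarray(sites)
    site_list = sorted(pd.unique(sites).tolist())
    if len(site_list) < 2:
        raise ValueError("LOSO-CV needs at least 2 sites")
    if meta is None:
        meta = pd.DataFrame(index=np.arange(len(X)))
    meta = meta.reset_index(drop=True)

    decisions = np.full(len(X), np.nan)
    models: dict = {}
    for s in site_list:
        test_mask = sites == s
        train_mask = (~test_mask) & np.isfinite(yt)
        if np.unique(yt[train_mask]).size < 2:
            warnings.warn(f"training set for held-out site {s} lacks both "
                          "classes; site skipped", RuntimeWarning, stacklevel=2)
            continue
        # Preprocessors see every training-site row (controls and
        # intermediates included); they never receive labels, so this
        # widens the fit population without leaking class information.
        prep_rows = ~test_mask
        Xp = X[prep_rows]
        meta_p = meta[prep_rows].reset_index(drop=True)
        preps = []
        for factory in preprocessor_factories:
            prep = factory().fit(Xp, meta_p)
            Xp = prep.transform(Xp, meta_p)
            preps.append(prep)
        labelled = np.isfinite(yt[prep_rows])
        model = fit_elasticnet_logistic(
            Xp[labelled], yt[prep_rows][labelled].astype(int), model_spec,
            seed=seed, training_sites=tuple(t for t in site_list if t != s))
        model.preprocessors = tuple(preps)
        models[s] = model
        decisions[test_mask] = model.decision_values(
            X[test_mask], meta[test_mask].reset_index(drop=True))
    return LosoResult(decisions=decisions, predictions=(decisions > 0).astype(int),
                      sites=sites, models=models)


def site_avg_auc(decision_values, labels, sites, n_boot: int = 1000,
                 seed: int = 0) -> tuple[float, float, dict]:
    """Site-wise AUCs averaged across sites, with a bootstrap-median variant.

    Only rows with binary (non-NaN) labels enter; sites lacking both
    classes are excluded with a warning.  The bootstrap resamples subjects
    with replacement within each site and reports the median of the
    resampled site-averaged AUCs.
    """
    d = np.asarray(decision_values, dtype=float)
    y = np.asarray(labels, dtype=float)
    sites = np.asarray(sites)
    keep = np.isfinite(y) & np.isfinite(d)
    per_site: dict = {}
    site_data = {}
    for s in pd.unique(sites[keep]):
        m = keep & (sites == s)
        ys, ds = y[m].astype(int), d[m]
        if np.unique(ys).size < 2:
            warnings.warn(f"site {s} lacks both classes; excluded from AUC",
                          RuntimeWarning, stacklevel=2)
            continue
        per_site[s] = auc_score(ys, ds)
        site_data[s] = (ys, ds)
    if not per_site:
        raise ValueError("no site with both classes")
    mean_auc = float(np.mean(list(per_site.values())))

    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    for b in range(n_boot):
        vals = []
        for ys, ds in site_data.values():
            idx = rng.integers(0, len(ys), size=len(ys))
            yb, db = ys[idx], ds[idx]
            if yb.min() == yb.max():
                continue
            vals.append(auc_score(yb, db))
        boot[b] = np.mean(vals) if vals else np.nan
    boot_median = float(np.nanmedian(boot)) if n_boot > 0 else float("nan")
    return mean_auc, boot_median, per_site


def pooled_spearman(decision_values, decline_values, sites,
                    min_site_n: int = 3) -> tuple[float, dict]:
    """Within-site Spearman correlations pooled through Fisher's z.

    Note the *positive* convention: decision values are oriented so larger
    means faster decline while decline measures are oriented so lower means
    faster decline, so callers pass ``-decline`` (or flip the sign) as
    appropriate; this function correlates its two arguments as given.
    """
    d = np.asarray(decision_values, dtype=float)
    v = np.asarray(decline_values, dtype=float)
    sites = np.asarray(sites)
    keep = np.isfinite(d) & np.isfinite(v)
    per_site = {}
    for s in pd.unique(sites[keep]):
        m = keep & (sites == s)
        if m.sum() < min_site_n:
            warnings.warn(f"site {s} has < {min_site_n} subjects; excluded "
                          "from pooled Spearman", RuntimeWarning, stacklevel=2)
            continue
        rho = sps.spearmanr(d[m], v[m]).statistic
        per_site[s] = float(rho)
    if not per_site:
        raise ValueError("no site with enough subjects")
    z = np.arctanh(np.clip(list(per_site.values()), -1 + 1e-15, 1 - 1e-15))
    return float(np.tanh(z.mean())), per_site


def permutation_pvalue(observed_stat: float, stat_fn, labels, sites,
                       n_perm: int = 1000, seed: int = 0,
                       alternative: str = "greater") -> float:
    """Within-site label-permutation p-value with the add-one rule.

    ``stat_fn(permuted_labels)`` recomputes the statistic; labels are
    permuted independently within each site.  ``p = (1 + #{null >=
    observed}) / (1 + n_perm)``, so p-values are never zero.
    """
    y = np.asarray(labels)
    sites = np.asarray(sites)
    if pd.unique(y[~pd.isna(y)]).size < 2:
        warnings.warn("degenerate labels; permutation p = 1",
                      RuntimeWarning, stacklevel=2)
        return 1.0
    rng = np.random.default_rng(seed)
    site_idx = {s: np.where(sites == s)[0] for s in pd.unique(sites)}
    count = 0
    for _ in range(n_perm):
        perm = y.copy()
        for idx in site_idx.values():
            perm[idx] = perm[rng.permutation(idx)]
        null = stat_fn(perm)
        if alternative == "greater":
            extreme = null >= observed_stat - 1e-12
        elif alternative == "less":
            extreme = null <= observed_stat + 1e-12
        else:
            raise ValueError(f"unknown alternative {alternative!r}")
        count += bool(extreme)
    return (1.0 + count) / (1.0 + n_perm)


@dataclass
class EvaluationReport:
    """Classifier validation metrics for one decline measure."""

    measure: str
    per_site_auc: dict
    site_avg_auc: float
    bootstrap_median_auc: float
    auc_permutation_p: float
    per_site_spearman: dict
    pooled_spearman: float
    spearman_permutation_p: float
    n_per_site: dict
    n_fast: int
    n_slow: int
    n_intermediate: int

    def to_dict(self) -> dict:
        return {
            "measure": self.measure,
            "per_site_auc": {str(k): v for k, v in self.per_site_auc.items()},
            "site_avg_auc": self.site_avg_auc,
            "bootstrap_median_auc": self.bootstrap_median_auc,
            "auc_permutation_p": self.auc_permutation_p,
            "per_site_spearman": {str(k): v
                                  for k, v in self.per_site_spearman.items()},
            "pooled_spearman": self.pooled_spearman,
            "spearman_permutation_p": self.spearman_permutation_p,
            "n_per_site": {str(k): int(v) for k, v in self.n_per_site.items()},
            "n_fast": self.n_fast, "n_slow": self.n_slow,
            "n_intermediate": self.n_intermediate,
        }


def evaluate_stratification(result: LosoResult, decline_labels: DeclineLabels,
                            eval_mask=None, n_perm: int = 1000,
                            n_boot: int = 1000, seed: int = 0) -> EvaluationReport:
    """Full evaluation of a LOSO stratification run.

    Binary separation uses fast-vs-slow subjects only; the continuous
    validation correlates decision values with the (sign-flipped) decline
    measure over all evaluated subjects.  ``eval_mask`` restricts evaluation
    (e.g. to pre-HD subjects).
    """
    d = result.decisions
    sites = result.sites
    mask = np.ones(len(d), dtype=bool) if eval_mask is None else np.asarray(eval_mask)
    y = decline_labels.binary().values.copy()
    y[~mask] = np.nan
    values = decline_labels.values.values.copy().astype(float)
    values[~mask] = np.nan

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        try:
            mean_auc, boot_auc, per_site_auc = site_avg_auc(
                d, y, sites, n_boot=n_boot, seed=seed)
        except ValueError:
            warnings.warn("no site with both classes; AUC undefined for "
                          f"measure {decline_labels.measure!r}",
                          RuntimeWarning, stacklevel=2)
            mean_auc, boot_auc, per_site_auc = float("nan"), float("nan"), {}
        # Larger decision value should mean faster decline = lower measure.
        rho, per_site_rho = pooled_spearman(d, -values, sites)

        def auc_stat(perm_y):
            try:
                m, _, _ = site_avg_auc(d, perm_y, sites, n_boot=0, seed=0)
            except ValueError:
                return -np.inf
            return m

        def rho_stat(perm_v):
            try:
                r, _ = pooled_spearman(d, -perm_v, sites)
            except ValueError:
                return -np.inf
            return r

        p_auc = (permutation_pvalue(mean_auc, auc_stat, y, sites,
                                    n_perm=n_perm, seed=seed)
                 if np.isfinite(mean_auc) else float("nan"))
        p_rho = permutation_pvalue(rho, rho_stat, values, sites,
                                   n_perm=n_perm, seed=seed + 1)

    labels = decline_labels.labels.values[mask]
    n_site = pd.Series(sites[mask]).value_counts().to_dict()
    return EvaluationReport(
        measure=decline_labels.measure,
        per_site_auc=per_site_auc, site_avg_auc=mean_auc,
        bootstrap_median_auc=boot_auc, auc_permutation_p=p_auc,
        per_site_spearman=per_site_rho, pooled_spearman=rho,
        spearman_permutation_p=p_rho, n_per_site=n_site,
        n_fast=int((labels == "fast").sum()),
        n_slow=int((labels == "slow").sum()),
        n_intermediate=int((labels == "intermediate").sum()),
    )
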