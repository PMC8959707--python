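"""Per-region linear models of covariate-adjusted volume on activity features.

For each of the 116 atlas regions, the residualized volume is regressed on the
candidate activity features (60 autoencoder + 64 time-frequency columns, or
the 64 time-frequency columns alone).  Backward elimination repeatedly refits
OLS and removes the least significant feature until every retained coefficient
has p < alpha.  The in-sample Pearson correlation r between fitted and actual
volumes and the model R^2 are recorded; the 116 overall F-test p-values are
passed through the Benjamini-Hochberg step-up procedure at q = 0.05, and
non-significant regions are flagged excluded.  Lobe-level summaries and a
paired comparison between the two candidate feature sets mirror the tabulated
outputs of the analysis.

OLS is solved by QR; the fit object carries the usual t and F inference.  At
the saturated corner (n close to K) in-sample r is driven upward by selection
over many candidates — a property of the procedure, reported as such.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.linalg import solve_triangular

from .atlas import SUMMARY_LOBES

__all__ = [
    "OLSFit",
    "RegionModelResult",
    "fit_ols",
    "backward_eliminate",
    "bh_fdr",
    "fit_all_regions",
    "lobe_summary",
    "compare_feature_sets",
    "export_violin_data",
]


@dataclass
class OLSFit:
    """Ordinary-least-squares fit with intercept and standard inference."""

    names: list[str]  # coefficient names, intercept first
    params: np.ndarray
    bse: np.ndarray
    tvalues: np.ndarray
    pvalues: np.ndarray
    fitted: np.ndarray
    r_squared: float
    f_pvalue: float
    df_resid: int

    def feature_pvalues(self) -> dict[str, float]:
        return dict(zip(self.names[1:], self.pvalues[1:]))


def fit_ols(y: np.ndarray, X: np.ndarray | pd.DataFrame, names: list[str] | None = None) -> OLSFit:
    """OLS of y on [1, X] with t tests per coefficient and the overall F test.

    Raises on rank deficiency (naming the dependent columns) and when there
    are not more observations than parameters.
    """
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        X = X.to_numpy(dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1 and X.shape[1] == len(y) and len(y) != 1:
        X = X.T
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    if names is None:
        names = [f"x{i + 1}" for i in range(k)]
    if n <= k + 1:
        raise ValueError(f"need n > k + 1 observations (n={n}, k={k})")
    design = np.column_stack([np.ones(n), X])
    q, r = np.linalg.qr(design)
    diag = np.abs(np.diag(r))
    bad = diag < 1e-10 * max(diag.max(), 1.0)
    if bad.any():
        cols = [(["intercept", *names])[i] for i in np.flatnonzero(bad)]
        raise ValueError(f"rank-deficient design; dependent columns: {cols}")
    params = solve_triangular(r, q.T @ y)
    fitted = design @ params
    resid = y - fitted
    df_resid = n - (k + 1)
    rss = float(resid @ resid)
    sigma2 = rss / df_resid
    r_inv = solve_triangular(r, np.eye(k + 1))
    bse = np.sqrt(sigma2 * (r_inv**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvalues = params / bse
    pvalues = 2.0 * sps.t.sf(np.abs(tvalues), df_resid)
    tss = float(((y - y.mean()) ** 2).sum())
    r_squared = 1.0 - rss / tss if tss > 0 else 0.0
    if k > 0 and tss > 0 and r_squared < 1.0:
        f_stat = (r_squared / k) / ((1.0 - r_squared) / df_resid)
        f_pvalue = float(sps.f.sf(f_stat, k, df_resid))
    elif r_squared >= 1.0:
        f_pvalue = 0.0
    else:
        f_pvalue = 1.0
    return OLSFit(
        names=["intercept", *names],
        params=params,
        bse=bse,
        tvalues=tvalues,
        pvalues=pvalues,
        fitted=fitted,
        r_squared=float(r_squared),
        f_pvalue=f_pvalue,
        df_resid=df_resid,
    )


@dataclass
class RegionModelResult:
    """Final per-region model after backward elimination."""

    region_id: int
    region_name: str
    lobe: str
    retained_features: list[str]
    coefficients: dict[str, float]  # includes "intercept"
    pvalues: dict[str, float]
    r: float
    r_squared: float
    model_p: float
    fdr_adjusted_p: float = np.nan
    fdr_significant: bool = False
    excluded: bool = False
    exclusion_reason: str = ""


def _prescreen(y: np.ndarray, X: pd.DataFrame, keep: int) -> pd.DataFrame:
    """Keep the ``keep`` columns with largest |marginal correlation| to y."""
    xc = X.to_numpy(dtype=float)
    xc = xc - xc.mean(axis=0)
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum(axis=0) * (yc @ yc))
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = np.abs(xc.T @ yc) / denom
    corr = np.nan_to_num(corr)
    order = np.argsort(-corr, kind="stable")[:keep]
    cols = [X.columns[i] for i in sorted(order)]
    return X[cols]


def backward_eliminate(
    y: np.ndarray, X: pd.DataFrame, alpha: float = 0.05
) -> tuple[OLSFit | None, list[str]]:
    """Iteratively drop the least significant feature until all p < alpha.

    Each round refits OLS and removes the single feature with the largest
    p-value if that p >= alpha (ties broken toward the feature latest in
    column order).  If the starting set is too large for the sample
    (n <= K + 1), it is pre-screened to the n - 10 features with the largest
    marginal correlations, with a warning.  Returns (final fit, retained
    feature names); the fit is None when nothing survives.
    """
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    if X.shape[1] >= n - 1:
        keep = max(n - 10, 1)
        warnings.warn(
            f"saturated start (n={n}, K={X.shape[1]}); pre-screening to {keep} features",
            stacklevel=2,
        )
        X = _prescreen(y, X, keep)
    current = X.copy()
    while current.shape[1] > 0:
        try:
            fit = fit_ols(y, current)
        except ValueError as err:
            if "dependent columns" not in str(err):
                raise
            # drop the last-listed collinear feature and retry
            msg = str(err)
            bad = [c for c in current.columns if f"'{c}'" in msg]
            drop = bad[-1] if bad else current.columns[-1]
            current = current.drop(columns=[drop])
            continue
        feature_p = np.nan_to_num(fit.pvalues[1:], nan=1.0)
        worst = float(feature_p.max())
        if worst < alpha:
            return fit, list(current.columns)
        # tie-break: among equal largest p-values, drop the latest column
        ties = np.flatnonzero(feature_p == worst)
        current = current.drop(columns=[current.columns[ties[-1]]])
    return None, []


def bh_fdr(p_values: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: rejection flags and adjusted p-values.

    Rejects all hypotheses with rank <= k* where k* is the largest k with
    p_(k) <= k q / m; adjusted p-values are the monotone step-up values
    min_{j>=k} (m p_(j) / j) clipped to 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-D array")
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    thresholds = q * np.arange(1, m + 1) / m
    passing = np.flatnonzero(ranked <= thresholds)
    reject = np.zeros(m, dtype=bool)
    if passing.size:
        reject[order[: passing[-1] + 1]] = True
    adj_sorted = np.minimum.accumulate((ranked * m / np.arange(1, m + 1))[::-1])[::-1]
    adjusted = np.empty(m)
    adjusted[order] = np.clip(adj_sorted, 0.0, 1.0)
    return reject, adjusted


def fit_all_regions(
    features: pd.DataFrame,
    residuals: pd.DataFrame,
    atlas: pd.DataFrame,
    alpha: float = 0.05,
    q: float = 0.05,
) -> list[RegionModelResult]:
    """One backward-eliminated model per atlas region, FDR-controlled jointly.

    ``features`` and ``residuals`` are subject-indexed frames; subjects must
    match.  The overall F-test p of each final model enters the BH procedure;
    regions that fail FDR or retain no features are flagged excluded.
    """
    if set(features.index) != set(residuals.index):
        raise ValueError("subject mismatch between feature and volume tables")
    features = features.sort_index()
    residuals = residuals.loc[features.index]
    results: list[RegionModelResult] = []
    for _, row in atlas.iterrows():
        region = row["region_name"]
        y = residuals[region].to_numpy(dtype=float)
        fit, retained = backward_eliminate(y, features, alpha=alpha)
        if fit is None:
            results.append(
                RegionModelResult(
                    region_id=int(row["region_id"]),
                    region_name=region,
                    lobe=row["lobe"],
                    retained_features=[],
                    coefficients={},
                    pvalues={},
                    r=np.nan,
                    r_squared=np.nan,
                    model_p=1.0,
                    excluded=True,
                    exclusion_reason="no_features_retained",
                )
            )
            continue
        r = float(np.corrcoef(fit.fitted, y)[0, 1]) if np.std(fit.fitted) > 0 else np.nan
        results.append(
            RegionModelResult(
                region_id=int(row["region_id"]),
                region_name=region,
                lobe=row["lobe"],
                retained_features=retained,
                coefficients=dict(zip(fit.names, fit.params)),
                pvalues=dict(zip(fit.names, fit.pvalues)),
                r=r,
                r_squared=fit.r_squared,
                model_p=fit.f_pvalue,
            )
        )
    reject, adjusted = bh_fdr(np.array([res.model_p for res in results]), q=q)
    for res, rej, adj in zip(results, reject, adjusted):
        res.fdr_adjusted_p = float(adj)
        res.fdr_significant = bool(rej)
        if not rej and not res.excluded:
            res.excluded = True
            res.exclusion_reason = "fdr_not_significant"
    return results


def results_frame(results: list[RegionModelResult]) -> pd.DataFrame:
    """Flat per-region table (one row per region) for export."""
    return pd.DataFrame(
        {
            "region_id": [r.region_id for r in results],
            "region_name": [r.region_name for r in results],
            "lobe": [r.lobe for r in results],
            "n_retained": [len(r.retained_features) for r in results],
            "r": [r.r for r in results],
            "r2": [r.r_squared for r in results],
            "model_p": [r.model_p for r in results],
            "fdr_adjusted_p": [r.fdr_adjusted_p for r in results],
            "excluded": [r.excluded for r in results],
            "exclusion_reason": [r.exclusion_reason for r in results],
        }
    )


def lobe_summary(results: list[RegionModelResult], atlas: pd.DataFrame) -> pd.DataFrame:
    """Per-lobe mean (SD) of r and R^2 over non-excluded regions.

    Vermis regions are modelled but omitted here, so the 116 regions reduce to
    108 tabulated ones across 9 lobes.
    """
    lobe_counts = atlas["lobe"].value_counts()
    rows = []
    for lobe in SUMMARY_LOBES:
        members = [r for r in results if r.lobe == lobe]
        ok = [r for r in members if not r.excluded]
        rs = np.array([r.r for r in ok])
        r2s = np.array([r.r_squared for r in ok])
        rows.append(
            {
                "lobe": lobe,
                "n_regions": int(lobe_counts.get(lobe, 0)),
                "n_excluded": len(members) - len(ok),
                "mean_r": rs.mean() if rs.size else np.nan,
                "sd_r": rs.std(ddof=1) if rs.size > 1 else (0.0 if rs.size else np.nan),
                "mean_r2": r2s.mean() if r2s.size else np.nan,
                "sd_r2": r2s.std(ddof=1) if r2s.size > 1 else (0.0 if r2s.size else np.nan),
            }
        )
    return pd.DataFrame(rows)


def _paired_t(diff: np.ndarray) -> float:
    diff = diff[np.isfinite(diff)]
    if diff.size < 2 or np.std(diff, ddof=1) == 0.0:
        if diff.size and np.std(diff, ddof=1) == 0.0 and diff.mean() != 0.0:
            warnings.warn("zero-variance nonzero paired differences", stacklevel=3)
        if np.allclose(diff, 0.0):
            warnings.warn("degenerate paired test (zero differences); p = 1", stacklevel=3)
        return 1.0
    t = sps.ttest_rel(diff, np.zeros_like(diff))
    return float(t.pvalue)


def compare_feature_sets(
    results_a: list[RegionModelResult],
    results_b: list[RegionModelResult],
    atlas: pd.DataFrame,
) -> pd.DataFrame:
    """Per-lobe paired t-tests on r and R^2 between two feature sets.

    Regions are paired by identity; Bonferroni adjustment multiplies by the
    number of summary lobes (9), separately for each metric, capped at 1.
    """
    by_region_b = {r.region_name: r for r in results_b}
    if set(by_region_b) != {r.region_name for r in results_a}:
        raise ValueError("region mismatch between result lists")
    rows = []
    n_lobes = len(SUMMARY_LOBES)
    for lobe in SUMMARY_LOBES:
        members = [r for r in results_a if r.lobe == lobe]
        diff_r = np.array([r.r - by_region_b[r.region_name].r for r in members])
        diff_r2 = np.array(
            [r.r_squared - by_region_b[r.region_name].r_squared for r in members]
        )
        p_r = _paired_t(diff_r)
        p_r2 = _paired_t(diff_r2)
        rows.append(
            {
                "lobe": lobe,
                "mean_diff_r": np.nanmean(diff_r) if diff_r.size else np.nan,
                "p_correlation": p_r,
                "p_correlation_bonferroni": min(1.0, p_r * n_lobes),
                "mean_diff_r2": np.nanmean(diff_r2) if diff_r2.size else np.nan,
                "p_r2": p_r2,
                "p_r2_bonferroni": min(1.0, p_r2 * n_lobes),
            }
        )
    return pd.DataFrame(rows)


def export_violin_data(
    results_a: list[RegionModelResult],
    results_b: list[RegionModelResult],
    atlas: pd.DataFrame,
    labels: tuple[str, str] = ("dl_tf", "tf_only"),
) -> pd.DataFrame:
    """Long-format (lobe, region, feature_set, r) table for distribution plots.

    Vermis regions are omitted, so two complete result lists give 108 x 2 rows.
    """
    rows = []
    for label, results in zip(labels, (results_a, results_b)):
        for r in results:
            if r.lobe == "vermis":
                continue
            rows.append(
                {"lobe": r.lobe, "region": r.region_name, "feature_set": label, "r": r.r}
            )
    return pd.DataFrame(rows)
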