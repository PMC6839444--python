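"""Differential-abundance and association statistics for qPCR cohorts.

Per-assay group tests (Student's t / one-way ANOVA with Tukey),
covariate-adjusted logistic odds ratios, volcano tables, Fisher's exact
2x2, partial Pearson correlations, correlation clustering and two-sample
t-test design power.

No multiple-testing adjustment is applied by default; a Benjamini-Hochberg
column can be requested explicitly (``fdr=True`` on the differential
operations) but is off otherwise.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .qpcr import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "DifferentialResult",
    "CorrelationResult",
    "ks_normality",
    "log2_transform",
    "two_group_differential",
    "three_group_differential",
    "volcano_table",
    "fisher_exact_2x2",
    "partial_correlation",
    "correlation_cluster",
    "cohens_d_from_fold",
    "power_two_sample_t",
]


@dataclass
class DifferentialResult:
    """Per-assay differential statistics.

    ``fold_change`` is linear-scale case vs control (2**mean log2
    difference); ``adjusted_or`` is the covariate-adjusted logistic odds
    ratio per log2 unit of the marker, with a Wald 95% CI.  For the
    three-group design the logistic fields hold per-category dicts keyed
    by group name and ``tukey_p`` holds the pairwise contrasts.
    """

    assay_id: str
    test: str
    group_means: dict
    fold_change: float
    p_value: float
    adjusted_or: float | dict | None = None
    or_ci: tuple | dict | None = None
    or_p: float | dict | None = None
    tukey_p: dict | None = None
    separation: bool = False
    notes: list = field(default_factory=list)


@dataclass
class CorrelationResult:
    x: str
    y: str
    n: int
    r: float
    p: float
    r_adjusted: float | None = None
    p_adjusted: float | None = None
    covariates: tuple = ()


# --------------------------------------------------------------------------
# Normality / transforms
# --------------------------------------------------------------------------


def ks_normality(values, lilliefors: bool = False) -> tuple[float, float]:
    """One-sample KS test against a normal with estimated mean/SD.

    Returns ``(statistic, p)``; the statistic is the sup-difference between
    the empirical CDF and the fitted normal CDF.  With estimated parameters
    the classic KS p-value is conservative (inflated); pass
    ``lilliefors=True`` for the corrected variant.

    Raises on < 5 observations or a constant sample (SD = 0).
    """
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if x.size < 5:
        raise ValueError("need >= 5 observations")
    mu, sd = x.mean(), x.std(ddof=1)
    if sd == 0:
        raise ValueError("constant sample: normality test degenerate")
    if lilliefors:
        from statsmodels.stats.diagnostic import lilliefors as _lf

        stat, p = _lf(x, dist="norm")
        return float(stat), float(p)
    stat, p = sps.kstest(x, "norm", args=(mu, sd))
    return float(stat), float(p)


def log2_transform(
    em: ExpressionMatrix, policy: str = "always", alpha: float = 0.05
) -> pd.DataFrame:
    """log2 of the rq matrix, per policy.

    ``policy="always"`` transforms every assay; ``"if_nonnormal"`` keeps an
    assay on the linear scale when the KS normality test does not reject at
    ``alpha`` (decision logged per assay).
    """
    rq = em.rq
    vals = rq.to_numpy()
    if np.any(vals[~np.isnan(vals)] <= 0):
        raise ValueError("rq values must be positive")
    if policy == "always":
        return np.log2(rq)
    if policy != "if_nonnormal":
        raise ValueError(f"unknown policy {policy!r}")
    out = rq.copy()
    for aid in rq.index:
        row = rq.loc[aid].dropna()
        transform = True
        if len(row) >= 5 and row.std(ddof=1) > 0:
            _, p = ks_normality(row)
            transform = p < alpha
        if transform:
            out.loc[aid] = np.log2(rq.loc[aid])
            logger.debug("log2_transform: %s transformed", aid)
        else:
            logger.debug("log2_transform: %s left linear (normal at alpha=%g)", aid, alpha)
    return out


# --------------------------------------------------------------------------
# Logistic helpers
# --------------------------------------------------------------------------

_SEPARATION_COEF = 15.0  # |log-OR| beyond this on standardized-ish data => separation


def _fit_logit(y: np.ndarray, X: np.ndarray):
    """Logit ML fit; returns (params, cov, converged, separation)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = sm.Logit(y, X)
            res = model.fit(disp=0, maxiter=200)
            params = np.asarray(res.params)
            cov = np.asarray(res.cov_params())
            converged = bool(res.mle_retvals.get("converged", True))
        except Exception:
            return None, None, False, True
    separation = (not converged) or bool(np.any(np.abs(params[1:]) > _SEPARATION_COEF))
    return params, cov, converged, separation


def _wald_or(params, cov, idx: int) -> tuple[float, tuple, float]:
    beta = params[idx]
    se = np.sqrt(cov[idx, idx])
    z = beta / se if se > 0 else np.inf
    p = 2 * sps.norm.sf(abs(z))
    lo, hi = beta - 1.959963984540054 * se, beta + 1.959963984540054 * se
    return float(np.exp(beta)), (float(np.exp(lo)), float(np.exp(hi))), float(p)


# --------------------------------------------------------------------------
# Differential tests
# --------------------------------------------------------------------------


def _prep_covariates(covariates, samples) -> np.ndarray | None:
    if covariates is None:
        return None
    cov = pd.DataFrame(covariates)
    cov = cov.loc[samples]
    return cov.to_numpy(dtype=float)


def two_group_differential(
    em: ExpressionMatrix,
    labels,
    covariates=None,
    equal_var: bool = True,
    fdr: bool = False,
) -> list[DifferentialResult]:
    """Per-assay case-vs-control t-test plus covariate-adjusted logistic OR.

    ``labels`` maps sample id -> {"case", "control"} (dict or Series).
    For each assay: two-sided Student's t on log2 rq (Welch with
    ``equal_var=False``); fold change = 2**(mean case - mean control);
    and a logistic model outcome ~ log2(rq) + covariates, reported as the
    Wald OR/CI/p per log2 unit.  Complete-case rows are used for the
    regression; t-test uses all per-group observations.

    Zero-variance assays get p = 1 (warning noted on the result); complete
    separation flags the result and leaves the OR non-estimable.
    """
    labels = pd.Series(labels)
    samples = [s for s in em.sample_ids if s in labels.index]
    lab = labels[samples]
    case_ids = [s for s in samples if lab[s] == "case"]
    ctrl_ids = [s for s in samples if lab[s] == "control"]
    if len(case_ids) < 2 or len(ctrl_ids) < 2:
        raise ValueError("both groups need >= 2 samples")

    log2rq = np.log2(em.rq[samples])
    cov_mat = _prep_covariates(covariates, samples)
    y_all = np.array([1.0 if lab[s] == "case" else 0.0 for s in samples])

    results: list[DifferentialResult] = []
    for aid in em.assay_ids:
        row = log2rq.loc[aid]
        a = row[case_ids].dropna().to_numpy()
        b = row[ctrl_ids].dropna().to_numpy()
        notes: list[str] = []
        if len(a) < 2 or len(b) < 2:
            results.append(
                DifferentialResult(
                    assay_id=aid, test="t", group_means={},
                    fold_change=np.nan, p_value=np.nan,
                    notes=["insufficient data"],
                )
            )
            continue
        mean_case, mean_ctrl = a.mean(), b.mean()
        if a.std() == 0 and b.std() == 0 and mean_case == mean_ctrl:
            t_p, t_stat = 1.0, 0.0
            notes.append("zero variance")
        else:
            t_stat, t_p = sps.ttest_ind(a, b, equal_var=equal_var)
            if np.isnan(t_p):
                t_p = 1.0
                notes.append("zero variance")
        fold = float(2.0 ** (mean_case - mean_ctrl))

        # adjusted logistic OR on complete cases
        x = row.to_numpy(dtype=float)
        keep = ~np.isnan(x)
        X_cols = [x[keep]]
        if cov_mat is not None:
            keep_cov = ~np.isnan(cov_mat).any(axis=1)
            keep = keep & keep_cov
            X_cols = [x[keep], cov_mat[keep]]
        X = np.column_stack([np.ones(keep.sum())] + [np.atleast_2d(c.T).T if c.ndim > 1 else c for c in X_cols])
        y = y_all[keep]
        adj_or = or_ci = or_p = None
        separation = False
        if np.unique(y).size == 2 and np.std(X[:, 1]) > 0:
            params, covp, converged, separation = _fit_logit(y, X)
            if params is not None and not separation:
                adj_or, or_ci, or_p = _wald_or(params, covp, 1)
            elif separation:
                notes.append("separation: OR non-estimable")
        else:
            notes.append("logistic model skipped (degenerate design)")

        results.append(
            DifferentialResult(
                assay_id=aid,
                test="welch_t" if not equal_var else "student_t",
                group_means={"case": float(mean_case), "control": float(mean_ctrl)},
                fold_change=fold,
                p_value=float(t_p),
                adjusted_or=adj_or,
                or_ci=or_ci,
                or_p=or_p,
                separation=separation,
                notes=notes,
            )
        )
    if fdr:
        _attach_fdr(results)
    return results


def three_group_differential(
    em: ExpressionMatrix,
    labels,
    covariates=None,
    baseline: str = "control",
    fdr: bool = False,
) -> list[DifferentialResult]:
    """One-way ANOVA + Tukey HSD per assay, with multinomial logistic ORs.

    ``labels`` maps sample id -> group name; ``baseline`` names the
    reference category (default "control").  Fold changes are reported per
    non-baseline group vs baseline in ``group_means`` / ``fold_change``
    (fold_change holds the max-|log2| contrast for volcano use; per-group
    folds are in ``group_means``).  Multinomial ORs (per log2 unit,
    adjusted for covariates) are dicts keyed by non-baseline group.
    """
    labels = pd.Series(labels)
    samples = [s for s in em.sample_ids if s in labels.index]
    lab = labels[samples]
    groups = list(pd.unique(lab))
    if baseline not in groups:
        raise ValueError(f"baseline group {baseline!r} absent")
    for g in groups:
        if (lab == g).sum() < 2:
            raise ValueError(f"group {g!r} has < 2 samples")
    others = [g for g in groups if g != baseline]

    log2rq = np.log2(em.rq[samples])
    cov_mat = _prep_covariates(covariates, samples)
    group_codes = {g: i for i, g in enumerate([baseline] + others)}
    y_all = np.array([group_codes[lab[s]] for s in samples], dtype=float)

    results: list[DifferentialResult] = []
    for aid in em.assay_ids:
        row = log2rq.loc[aid]
        by_group = {g: row[lab.index[lab == g]].dropna().to_numpy() for g in groups}
        notes: list[str] = []
        if any(len(v) < 2 for v in by_group.values()):
            results.append(
                DifferentialResult(
                    assay_id=aid, test="anova", group_means={},
                    fold_change=np.nan, p_value=np.nan, notes=["insufficient data"],
                )
            )
            continue

        arrays = [by_group[g] for g in groups]
        if all(v.std() == 0 for v in arrays) and len({v.mean() for v in arrays}) == 1:
            f_p = 1.0
            tukey = {(g1, g2): 1.0 for i, g1 in enumerate(groups) for g2 in groups[i + 1:]}
            notes.append("zero variance")
        else:
            _, f_p = sps.f_oneway(*arrays)
            if np.isnan(f_p):
                f_p = 1.0
                notes.append("zero variance")
                tukey = {(g1, g2): 1.0 for i, g1 in enumerate(groups) for g2 in groups[i + 1:]}
            else:
                hsd = sps.tukey_hsd(*arrays)
                tukey = {
                    (groups[i], groups[j]): float(hsd.pvalue[i, j])
                    for i in range(len(groups))
                    for j in range(i + 1, len(groups))
                }

        means = {g: float(by_group[g].mean()) for g in groups}
        folds = {g: float(2.0 ** (means[g] - means[baseline])) for g in others}
        lead = max(others, key=lambda g: abs(np.log2(folds[g])))

        # multinomial logistic, baseline category = `baseline`
        x = row.to_numpy(dtype=float)
        keep = ~np.isnan(x)
        parts = [x]
        if cov_mat is not None:
            keep = keep & ~np.isnan(cov_mat).any(axis=1)
            parts.append(cov_mat)
        X = np.column_stack([np.ones(len(x))] + [p if p.ndim > 1 else p[:, None] for p in parts])[keep]
        y = y_all[keep]
        or_d: dict = {}
        ci_d: dict = {}
        p_d: dict = {}
        separation = False
        if len(np.unique(y)) == len(groups) and np.std(X[:, 1]) > 0:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    res = sm.MNLogit(y, X).fit(disp=0, maxiter=200)
                    params = np.asarray(res.params)  # (k_exog, k_cat-1)
                    bse = np.asarray(res.bse)
                    converged = bool(res.mle_retvals.get("converged", True))
                    for j, g in enumerate(others):
                        beta, se = params[1, j], bse[1, j]
                        if (not converged) or abs(beta) > _SEPARATION_COEF:
                            separation = True
                            continue
                        z = beta / se if se > 0 else np.inf
                        or_d[g] = float(np.exp(beta))
                        ci_d[g] = (
                            float(np.exp(beta - 1.959963984540054 * se)),
                            float(np.exp(beta + 1.959963984540054 * se)),
                        )
                        p_d[g] = float(2 * sps.norm.sf(abs(z)))
                except Exception:
                    separation = True
            if separation:
                notes.append("separation: some ORs non-estimable")
        else:
            notes.append("multinomial model skipped (degenerate design)")

        results.append(
            DifferentialResult(
                assay_id=aid,
                test="anova",
                group_means={**means, "fold_vs_baseline": folds},
                fold_change=folds[lead],
                p_value=float(f_p),
                adjusted_or=or_d or None,
                or_ci=ci_d or None,
                or_p=p_d or None,
                tukey_p=tukey,
                separation=separation,
                notes=notes,
            )
        )
    if fdr:
        _attach_fdr(results)
    return results


def _attach_fdr(results: list[DifferentialResult]) -> None:
    ps = np.array([r.p_value for r in results])
    ok = ~np.isnan(ps)
    q = np.full_like(ps, np.nan)
    if ok.sum():
        q[ok] = multipletests(ps[ok], method="fdr_bh")[1]
    for r, qi in zip(results, q):
        r.notes.append(f"fdr_bh_q={qi:.4g}")


def volcano_table(results: list[DifferentialResult], alpha: float = 0.05) -> pd.DataFrame:
    """Volcano coordinates: log2 fold change, -log10 p, significance flag."""
    if not results:
        raise ValueError("results must be non-empty")
    rows = []
    for r in results:
        rows.append(
            {
                "assay_id": r.assay_id,
                "log2_fold_change": np.log2(r.fold_change) if r.fold_change > 0 else np.nan,
                "neg_log10_p": -np.log10(r.p_value) if r.p_value > 0 else np.inf,
                "p_value": r.p_value,
                "significant": bool(r.p_value < alpha),
            }
        )
    return pd.DataFrame(rows).set_index("assay_id")


# --------------------------------------------------------------------------
# Fisher / correlation
# --------------------------------------------------------------------------


def fisher_exact_2x2(table) -> tuple[float, float]:
    """Two-sided Fisher exact p and conditional-MLE odds ratio for a 2x2.

    p sums hypergeometric probabilities of all tables (with the observed
    margins) no more probable than the observed one.  A zero margin makes
    the table degenerate: p = 1 by convention (warning).
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0) or np.any(t != np.round(t)):
        raise ValueError("table must be 2x2 non-negative integers")
    t = t.astype(int)
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        warnings.warn("zero margin: Fisher p = 1 by convention", stacklevel=2)
        return 1.0, np.nan
    res = sps.fisher_exact(t, alternative="two-sided")
    odds = sps.contingency.odds_ratio(t, kind="conditional")
    return float(res.pvalue), float(odds.statistic)


def partial_correlation(x, y, covariates=None) -> CorrelationResult:
    """Pearson correlation, optionally partialled on covariates.

    Simple r/p always computed.  With covariates, ``r_adjusted`` is the
    Pearson correlation of the least-squares residuals of x and y on
    [1, covariates]; its p comes from the t distribution with n - k - 2
    degrees of freedom.  Rows with any missing value are dropped
    (pairwise-complete including covariates; n reported on the result).

    A zero-variance residual (e.g. x identical to a covariate) raises.
    """
    xs = pd.Series(np.asarray(x, dtype=float))
    ys = pd.Series(np.asarray(y, dtype=float))
    name_x = getattr(x, "name", "x") or "x"
    name_y = getattr(y, "name", "y") or "y"
    frames = [xs.rename("_x"), ys.rename("_y")]
    cov_names: tuple = ()
    if covariates is not None:
        cov_df = pd.DataFrame(covariates).reset_index(drop=True)
        cov_names = tuple(map(str, cov_df.columns))
        frames.append(cov_df)
    df = pd.concat([f.reset_index(drop=True) for f in frames], axis=1).dropna()
    k = len(cov_names)
    n = len(df)
    if n <= k + 2:
        raise ValueError(f"need n > k + 2 (n={n}, k={k})")

    xv, yv = df["_x"].to_numpy(), df["_y"].to_numpy()
    if xv.std() == 0 or yv.std() == 0:
        raise ValueError("zero-variance input")
    r, p = sps.pearsonr(xv, yv)

    r_adj = p_adj = None
    if k:
        Z = np.column_stack([np.ones(n), df.iloc[:, 2:].to_numpy(dtype=float)])
        rx = xv - Z @ np.linalg.lstsq(Z, xv, rcond=None)[0]
        ry = yv - Z @ np.linalg.lstsq(Z, yv, rcond=None)[0]
        tol_x = 1e-10 * max(1.0, float(xv.std()))
        tol_y = 1e-10 * max(1.0, float(yv.std()))
        if rx.std() <= tol_x or ry.std() <= tol_y:
            raise ValueError("residual variance is zero: partial correlation undefined")
        r_adj = float(np.corrcoef(rx, ry)[0, 1])
        df_t = n - k - 2
        denom = 1.0 - r_adj**2
        if denom <= 0:
            p_adj = 0.0
        else:
            t_stat = r_adj * np.sqrt(df_t / denom)
            p_adj = float(2 * sps.t.sf(abs(t_stat), df_t))

    return CorrelationResult(
        x=str(name_x), y=str(name_y), n=n,
        r=float(r), p=float(p),
        r_adjusted=r_adj, p_adjusted=p_adj, covariates=cov_names,
    )


def correlation_cluster(
    em: ExpressionMatrix,
    top_k: int = 50,
    method: str = "average",
    cut_height: float = 0.5,
) -> tuple[pd.DataFrame, pd.Series]:
    """Cluster the top-k most abundant assays by expression correlation.

    Pairwise Pearson matrix on log2 rq (pairwise-complete), hierarchical
    clustering with the given linkage on distance 1 - r, cut at
    ``cut_height``.  Constant assays are excluded with a warning.
    Returns (correlation matrix, cluster assignment Series).
    """
    if top_k < 2:
        raise ValueError("top_k must be >= 2")
    log2rq = np.log2(em.rq)
    abundance = log2rq.mean(axis=1)
    top = abundance.sort_values(ascending=False).index[:top_k]
    sub = log2rq.loc[top]

    sds = sub.std(axis=1, ddof=1)
    constant = sds[(sds == 0) | sds.isna()].index
    if len(constant):
        warnings.warn(
            f"{len(constant)} constant assay(s) excluded from clustering", stacklevel=2
        )
        sub = sub.drop(index=constant)
    if sub.shape[0] < 2:
        raise ValueError("fewer than 2 non-constant assays to cluster")

    corr = sub.T.corr(method="pearson")
    dist = 1.0 - corr.to_numpy()
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    linkage = hierarchy.linkage(squareform(dist, checks=False), method=method)
    assignment = hierarchy.fcluster(linkage, t=cut_height, criterion="distance")
    return corr, pd.Series(assignment, index=corr.index, name="cluster")


# --------------------------------------------------------------------------
# Design power
# --------------------------------------------------------------------------


def cohens_d_from_fold(fold_change: float, relative_sd: float) -> float:
    """Standardized effect size (fold_change - 1) / relative SD."""
    if relative_sd <= 0:
        raise ValueError("relative_sd must be positive")
    return (fold_change - 1.0) / relative_sd


def power_two_sample_t(
    d: float,
    n1: int,
    n2: int,
    alpha: float = 0.05,
    sidedness: str = "two-sided",
) -> float:
    """Power of a two-sample Student's t-test from the noncentral t.

    Noncentrality d*sqrt(n1*n2/(n1+n2)), df = n1+n2-2.  At d = 0 the
    two-sided power equals alpha exactly.
    """
    if d < 0:
        raise ValueError("d must be >= 0")
    if n1 < 2 or n2 < 2:
        raise ValueError("group sizes must be >= 2")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if sidedness not in ("two-sided", "one-sided"):
        raise ValueError(f"unknown sidedness {sidedness!r}")

    df = n1 + n2 - 2
    nc = d * np.sqrt(n1 * n2 / (n1 + n2))
    if sidedness == "one-sided":
        tcrit = sps.t.ppf(1 - alpha, df)
        return float(sps.nct.sf(tcrit, df, nc))
    tcrit = sps.t.ppf(1 - alpha / 2, df)
    return float(sps.nct.sf(tcrit, df, nc) + sps.nct.cdf(-tcrit, df, nc))
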