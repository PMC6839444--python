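"""ROC analysis and logistic-combination biomarker panels.

Empirical ROC curves with explicit tie handling (a positive/negative tie
contributes 1/2 to the AUC, so AUC equals the Mann-Whitney statistic
U / (n_pos * n_neg)), DeLong covariance machinery for AUC confidence
intervals and paired AUC comparisons, logistic panel fitting, and
operating-point selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

from .qpcr import ExpressionMatrix

__all__ = [
    "RocResult",
    "PanelModel",
    "OperatingPoint",
    "roc_curve",
    "delong_variance",
    "delong_test",
    "fit_panel",
    "operating_point",
    "compare_marker_vs_panel",
    "loo_scores",
]

_Z95 = 1.959963984540054


@dataclass
class RocResult:
    thresholds: np.ndarray  # ascending; prediction rule: score >= threshold -> positive
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    auc_ci: tuple
    ci_method: str
    n_pos: int
    n_neg: int
    scores: np.ndarray = field(repr=False, default=None)
    labels: np.ndarray = field(repr=False, default=None)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
            }
        )


@dataclass
class PanelModel:
    marker_ids: list
    coefficients: np.ndarray  # aligned with marker_ids
    intercept: float
    scores: pd.Series  # linear predictor per subject (complete cases)
    converged: bool
    separation: bool
    dropped_collinear: list = field(default_factory=list)
    seed: int | None = None


@dataclass
class OperatingPoint:
    threshold: float
    sensitivity: float
    specificity: float
    tp: int
    fp: int
    tn: int
    fn: int
    rule: str


def _clean_scores_labels(scores, labels):
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if y.dtype == bool:
        y = y.astype(int)
    y = y.astype(float).astype(int)
    ok = ~np.isnan(s)
    s, y = s[ok], y[ok]
    if not set(np.unique(y)) <= {0, 1}:
        raise ValueError("labels must be binary 0/1")
    if (y == 1).sum() == 0 or (y == 0).sum() == 0:
        raise ValueError("both classes must be present")
    return s, y


def _auc_mann_whitney(s: np.ndarray, y: np.ndarray) -> float:
    """AUC as concordance probability with 1/2 credit for ties."""
    ranks = sps.rankdata(s)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def _delong_structural_components(s: np.ndarray, y: np.ndarray):
    """Per-subject placement values V10 (positives) and V01 (negatives)."""
    pos, neg = s[y == 1], s[y == 0]
    m, n = len(pos), len(neg)
    # midrank-based placements
    v10 = np.empty(m)
    v01 = np.empty(n)
    for i, p in enumerate(pos):
        v10[i] = (np.sum(p > neg) + 0.5 * np.sum(p == neg)) / n
    for j, q in enumerate(neg):
        v01[j] = (np.sum(pos > q) + 0.5 * np.sum(pos == q)) / m
    return v10, v01


def delong_variance(scores, labels) -> float:
    """DeLong sampling variance of the empirical AUC."""
    s, y = _clean_scores_labels(scores, labels)
    v10, v01 = _delong_structural_components(s, y)
    m, n = len(v10), len(v01)
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return float(s10 / m + s01 / n)


def roc_curve(scores, labels, ci: str = "delong", n_boot: int = 2000, seed: int = 0) -> RocResult:
    """Empirical ROC over all distinct score thresholds.

    Predicted positive when score >= threshold.  AUC is the Mann-Whitney
    concordance (ties count 1/2); the 95% CI uses the DeLong variance by
    default (truncated to [0, 1]) or a stratified bootstrap
    (``ci="bootstrap"``).
    """
    s, y = _clean_scores_labels(scores, labels)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())

    thresholds = np.unique(s)
    # sens/spec for rule score >= t, plus the all-negative endpoint
    sens = np.array([(s[y == 1] >= t).mean() for t in thresholds])
    spec = np.array([(s[y == 0] < t).mean() for t in thresholds])
    auc = _auc_mann_whitney(s, y)

    if ci == "delong":
        var = delong_variance(s, y)
        half = _Z95 * np.sqrt(var)
        lo, hi = max(0.0, auc - half), min(1.0, auc + half)
    elif ci == "bootstrap":
        rng = np.random.default_rng(seed)
        pos_idx = np.flatnonzero(y == 1)
        neg_idx = np.flatnonzero(y == 0)
        aucs = np.empty(n_boot)
        for b in range(n_boot):
            bi = np.concatenate(
                [rng.choice(pos_idx, n_pos), rng.choice(neg_idx, n_neg)]
            )
            aucs[b] = _auc_mann_whitney(s[bi], y[bi])
        lo, hi = np.percentile(aucs, [2.5, 97.5])
    else:
        raise ValueError(f"unknown ci method {ci!r}")

    return RocResult(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        auc_ci=(float(lo), float(hi)),
        ci_method=ci,
        n_pos=n_pos,
        n_neg=n_neg,
        scores=s,
        labels=y,
    )


def delong_test(scores_a, scores_b, labels) -> tuple[float, float]:
    """Paired DeLong test for equality of two correlated AUCs.

    Returns (AUC_a - AUC_b, two-sided p).  Scores must be on the same
    subjects in the same order.
    """
    sa = np.asarray(scores_a, dtype=float)
    sb = np.asarray(scores_b, dtype=float)
    y = np.asarray(labels).astype(float).astype(int)
    ok = ~(np.isnan(sa) | np.isnan(sb))
    sa, sb, y = sa[ok], sb[ok], y[ok]
    if (y == 1).sum() == 0 or (y == 0).sum() == 0:
        raise ValueError("both classes must be present")

    va10, va01 = _delong_structural_components(sa, y)
    vb10, vb01 = _delong_structural_components(sb, y)
    auc_a = va10.mean()
    auc_b = vb10.mean()
    m, n = len(va10), len(va01)
    s10 = np.cov(np.vstack([va10, vb10]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([va01, vb01]), ddof=1) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    diff = float(auc_a - auc_b)
    if var_diff <= 0:
        # identical placements: AUCs are equal with certainty
        return diff, 1.0 if diff == 0 else 0.0
    z = diff / np.sqrt(var_diff)
    return diff, float(2 * sps.norm.sf(abs(z)))


def fit_panel(em: ExpressionMatrix, marker_ids, outcome, seed: int | None = None) -> PanelModel:
    """Maximum-likelihood logistic combination of markers.

    Fits outcome ~ log2(rq) of the given markers on complete-case
    subjects.  Exactly collinear (duplicated) markers are dropped with a
    warning before fitting; the score is unchanged by the drop.  On
    separation the model is flagged but the linear-predictor score is
    still returned (its ranking remains usable).
    """
    marker_ids = list(marker_ids)
    missing = [m for m in marker_ids if m not in em.rq.index]
    if missing:
        raise ValueError(f"markers absent from matrix: {missing}")
    outcome = pd.Series(outcome)
    samples = [s for s in em.sample_ids if s in outcome.index]

    X_df = np.log2(em.rq.loc[marker_ids, samples]).T
    y_s = outcome[samples].astype(float)
    keep = X_df.notna().all(axis=1) & y_s.notna()
    X_df, y_s = X_df[keep.to_numpy()], y_s[keep.to_numpy()]
    if set(y_s.unique()) != {0.0, 1.0}:
        raise ValueError("outcome must be binary with both classes present")

    # drop exactly collinear columns (keeps the first of each duplicate set)
    kept, dropped = [], []
    M = X_df.to_numpy(dtype=float)
    cols = np.ones((len(X_df), 1))
    for j, mid in enumerate(marker_ids):
        trial = np.column_stack([cols, M[:, j]])
        if np.linalg.matrix_rank(trial) > cols.shape[1]:
            cols = trial
            kept.append(mid)
        else:
            dropped.append(mid)
    if dropped:
        warnings.warn(f"collinear marker(s) dropped: {dropped}", stacklevel=2)

    X = cols
    y = y_s.to_numpy()
    separation = False
    converged = False
    params = np.zeros(X.shape[1])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=500)
            params = np.asarray(res.params)
            converged = bool(res.mle_retvals.get("converged", True))
        except Exception:
            converged = False
    if (not converged) or np.any(np.abs(params[1:]) > 25):
        separation = True
    if separation:
        # ridge fallback: coefficients shrink but the score direction (and
        # therefore the ROC ranking) stays usable under perfect separation
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = sm.Logit(y, X).fit_regularized(
                    alpha=1e-3 * len(y), L1_wt=0.0, disp=0, maxiter=500
                )
                params = np.asarray(res.params)
                converged = False
            except Exception:
                pass

    scores = pd.Series(X @ params, index=X_df.index, name="panel_score")
    coef = pd.Series(params[1:], index=kept).reindex(marker_ids).fillna(0.0)
    return PanelModel(
        marker_ids=marker_ids,
        coefficients=coef.to_numpy(),
        intercept=float(params[0]),
        scores=scores,
        converged=converged,
        separation=separation,
        dropped_collinear=dropped,
        seed=seed,
    )


def loo_scores(em: ExpressionMatrix, marker_ids, outcome) -> pd.Series:
    """Leave-one-out cross-validated panel scores (held-out linear predictor)."""
    outcome = pd.Series(outcome)
    samples = [s for s in em.sample_ids if s in outcome.index]
    X_df = np.log2(em.rq.loc[list(marker_ids), samples]).T
    y_s = outcome[samples].astype(float)
    keep = X_df.notna().all(axis=1) & y_s.notna()
    X_df, y_s = X_df[keep.to_numpy()], y_s[keep.to_numpy()]
    out = {}
    for sid in X_df.index:
        tr = X_df.index != sid
        ytr = y_s[tr].to_numpy()
        if len(np.unique(ytr)) < 2:
            out[sid] = np.nan
            continue
        Xtr = np.column_stack([np.ones(tr.sum()), X_df[tr].to_numpy()])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = sm.Logit(ytr, Xtr).fit(disp=0, maxiter=500)
                params = np.asarray(res.params)
            except Exception:
                out[sid] = np.nan
                continue
        xrow = np.concatenate([[1.0], X_df.loc[sid].to_numpy(dtype=float)])
        out[sid] = float(xrow @ params)
    return pd.Series(out, name="panel_score_loo")


def operating_point(roc: RocResult, rule: str = "youden", value: float | None = None) -> OperatingPoint:
    """Select an ROC operating point.

    Rules: ``youden`` (max sensitivity + specificity - 1),
    ``fixed_specificity`` (max sensitivity with specificity >= value),
    ``fixed_sensitivity`` (max specificity with sensitivity >= value).
    Ties break toward higher specificity.  An unattainable constraint
    raises, naming the best achievable value.
    """
    sens, spec, thr = roc.sensitivity, roc.specificity, roc.thresholds
    if rule == "youden":
        j = sens + spec - 1.0
        order = np.lexsort((spec, j))  # last index: max J, then max specificity
        idx = order[-1]
    elif rule == "fixed_specificity":
        if value is None:
            raise ValueError("fixed_specificity needs a target value")
        ok = spec >= value
        if not ok.any():
            raise ValueError(
                f"specificity {value} unattainable; best achievable {spec.max():.4f}"
            )
        cand = np.flatnonzero(ok)
        idx = cand[np.lexsort((spec[cand], sens[cand]))[-1]]
    elif rule == "fixed_sensitivity":
        if value is None:
            raise ValueError("fixed_sensitivity needs a target value")
        ok = sens >= value
        if not ok.any():
            raise ValueError(
                f"sensitivity {value} unattainable; best achievable {sens.max():.4f}"
            )
        cand = np.flatnonzero(ok)
        idx = cand[np.argmax(spec[cand])]
    else:
        raise ValueError(f"unknown rule {rule!r}")

    t = float(thr[idx])
    s, y = roc.scores, roc.labels
    pred = s >= t
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    tn = int(np.sum(~pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    return OperatingPoint(
        threshold=t,
        sensitivity=float(sens[idx]),
        specificity=float(spec[idx]),
        tp=tp, fp=fp, tn=tn, fn=fn,
        rule=rule if value is None else f"{rule}({value})",
    )


def compare_marker_vs_panel(
    em: ExpressionMatrix, marker: str, panel: PanelModel, outcome, alpha: float = 0.05
) -> dict:
    """Does adding `marker` to the panel improve its AUC?

    Fits an augmented panel (panel markers + marker), computes ROC/AUC for
    the lone marker, the panel, and the augmented panel on the shared
    complete-case subjects, and runs a paired DeLong test on
    (augmented - panel).  Returns a dict report; ``improves`` is the
    significance call at ``alpha``.
    """
    outcome = pd.Series(outcome)
    aug = fit_panel(em, list(panel.marker_ids) + [marker], outcome)
    subjects = [s for s in panel.scores.index if s in aug.scores.index]

    y = outcome[subjects]
    marker_scores = np.log2(em.rq.loc[marker, subjects]).astype(float)
    panel_scores = panel.scores[subjects]
    aug_scores = aug.scores[subjects]

    roc_marker = roc_curve(marker_scores, y)
    roc_panel = roc_curve(panel_scores, y)
    roc_aug = roc_curve(aug_scores, y)
    diff, p = delong_test(aug_scores, panel_scores, y)

    return {
        "marker": marker,
        "auc_marker": roc_marker.auc,
        "auc_marker_ci": roc_marker.auc_ci,
        "auc_panel": roc_panel.auc,
        "auc_panel_ci": roc_panel.auc_ci,
        "auc_augmented": roc_aug.auc,
        "auc_augmented_ci": roc_aug.auc_ci,
        "auc_difference": diff,
        "delong_p": p,
        "improves": bool(p < alpha and diff > 0),
        "n_subjects": len(subjects),
    }
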