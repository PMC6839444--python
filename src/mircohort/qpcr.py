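"""Ct-table parsing, detection filtering, normalization and quantification.

The central object is a :class:`CtMatrix` (assays x samples of raw qPCR
cycle-threshold values, NaN = undetermined).  The processing chain is

    parse_ct_table -> detection_filter -> global_mean_normalize
        -> relative_quantity -> downstream statistics

plus two side operations: reference-gene stability scoring
(:func:`normfinder_stability`) and absolute quantification through a
dilution series (:func:`standard_curve_quantify`).

Conventions
-----------
* A cell counts as *detected* when a Ct value is present and does not
  exceed ``detection_limit`` (default 35 cycles); values above the limit
  are treated as non-amplification.
* ``dct`` is Ct minus the per-sample global mean, so *lower* dct means
  *higher* abundance; ``rq = 2**-ddct`` is on the linear scale with the
  reference group's geometric mean pinned to 1.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_DETECTION_LIMIT = 35.0

__all__ = [
    "CtMatrix",
    "NormalizedMatrix",
    "ExpressionMatrix",
    "StabilityResult",
    "StandardCurve",
    "DetectionReport",
    "ParseError",
    "DataError",
    "CalibrationError",
    "parse_ct_table",
    "write_ct_table",
    "detection_filter",
    "global_mean_normalize",
    "relative_quantity",
    "assay_cv",
    "normfinder_stability",
    "standard_curve_quantify",
]


class ParseError(ValueError):
    """Malformed input table (message carries the offending line)."""


class DataError(ValueError):
    """Structurally valid input that violates a data contract."""


class CalibrationError(ValueError):
    """Standard curve cannot be fit or is physically invalid."""


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------


@dataclass
class CtMatrix:
    """Raw Ct values, one row per assay, one column per sample.

    Parameters
    ----------
    ct
        DataFrame indexed by assay id with sample-id columns; missing /
        undetermined wells are NaN.
    detection_limit
        Ct above this value counts as undetected (but is retained in the
        matrix; filtering happens in :func:`detection_filter`).
    """

    ct: pd.DataFrame
    detection_limit: float = DEFAULT_DETECTION_LIMIT

    def __post_init__(self) -> None:
        if not isinstance(self.ct, pd.DataFrame):
            raise TypeError("ct must be a pandas DataFrame")
        if self.ct.index.has_duplicates:
            raise DataError("duplicate assay ids")
        if self.ct.columns.has_duplicates:
            raise DataError("duplicate sample ids")
        vals = self.ct.to_numpy(dtype=float)
        present = vals[~np.isnan(vals)]
        if present.size and (np.any(present <= 0) or np.any(present > 50)):
            raise DataError("Ct values must lie in (0, 50]")
        self.ct = self.ct.astype(float)

    @property
    def assay_ids(self) -> list:
        return list(self.ct.index)

    @property
    def sample_ids(self) -> list:
        return list(self.ct.columns)

    @property
    def n_assays(self) -> int:
        return self.ct.shape[0]

    @property
    def n_samples(self) -> int:
        return self.ct.shape[1]

    def detected(self) -> pd.DataFrame:
        """Boolean mask of detected wells (present and <= detection_limit)."""
        return self.ct.notna() & (self.ct <= self.detection_limit)


@dataclass
class NormalizedMatrix:
    """Per-sample global-mean-centered dCt values plus the subtracted offsets."""

    dct: pd.DataFrame
    sample_offsets: pd.Series
    mean_basis: str = "per_sample_detected"

    @property
    def assay_ids(self) -> list:
        return list(self.dct.index)

    @property
    def sample_ids(self) -> list:
        return list(self.dct.columns)


@dataclass
class ExpressionMatrix:
    """Linear-scale relative quantities (2^-ddCt), reference geomean = 1."""

    rq: pd.DataFrame
    reference_samples: list = field(default_factory=list)

    @property
    def assay_ids(self) -> list:
        return list(self.rq.index)

    @property
    def sample_ids(self) -> list:
        return list(self.rq.columns)

    def log2(self) -> pd.DataFrame:
        return np.log2(self.rq)


@dataclass
class StabilityResult:
    """Reference-gene stability scores; lower value = more stable."""

    table: pd.DataFrame  # columns: stability, intra_var, inter_var; sorted
    excluded: list = field(default_factory=list)

    @property
    def ranking(self) -> list:
        return list(self.table.index)

    def best(self) -> str:
        return self.table.index[0]


@dataclass
class StandardCurve:
    slope: float  # cycles per log10 quantity; < 0 for a valid curve
    intercept: float  # cycles at log10(q) = 0
    r_squared: float

    @property
    def efficiency(self) -> float:
        """Amplification efficiency, 1.0 == perfect doubling per cycle."""
        return 10.0 ** (-1.0 / self.slope) - 1.0

    def quantify(self, ct) -> np.ndarray:
        """Invert Ct values through the fitted line to linear quantities."""
        ct = np.asarray(ct, dtype=float)
        return 10.0 ** ((ct - self.intercept) / self.slope)


@dataclass
class DetectionReport:
    threshold: int
    n_input: int
    retained: list
    removed: list
    detected_counts: pd.Series

    @property
    def n_retained(self) -> int:
        return len(self.retained)

    @property
    def n_removed(self) -> int:
        return len(self.removed)

    @property
    def pct_retained(self) -> float:
        """Percentage of input assays retained, rounded to one decimal."""
        return round(100.0 * self.n_retained / self.n_input, 1)


# --------------------------------------------------------------------------
# Parsing / writing
# --------------------------------------------------------------------------

_MISSING_TOKENS = {"", "undetermined", "na", "nan", "n/a", "null", "undet"}


def _parse_ct_cell(token: str, lineno: int) -> float:
    token = token.strip()
    if token.lower() in _MISSING_TOKENS:
        return math.nan
    try:
        return float(token)
    except ValueError:
        raise ParseError(f"line {lineno}: cannot parse Ct value {token!r}") from None


def parse_ct_table(
    path,
    dialect: str = "long",
    sep: str = "\t",
    detection_limit: float = DEFAULT_DETECTION_LIMIT,
) -> CtMatrix:
    """Read a delimited Ct table into a :class:`CtMatrix`.

    Parameters
    ----------
    path
        Text file.  ``long`` dialect: header ``sample_id, assay_id, ct``;
        ``wide`` dialect: first column assay ids, remaining columns one per
        sample.  "Undetermined"/"NA"/empty cells become missing.
    dialect
        ``"long"`` or ``"wide"``.

    Raises
    ------
    ParseError
        Malformed row (message names the line number).
    DataError
        Duplicated (sample, assay) pair.
    """
    if dialect not in ("long", "wide"):
        raise ValueError(f"unknown dialect {dialect!r}")

    with open(path, "rt", encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    lines = [ln for ln in lines if ln.strip() != ""]
    if not lines:
        raise ParseError("empty file")

    if dialect == "long":
        header = [h.strip().lower() for h in lines[0].split(sep)]
        if len(header) < 3:
            raise ParseError("line 1: long dialect needs sample_id, assay_id, ct columns")
        try:
            i_s = header.index("sample_id")
            i_a = header.index("assay_id")
            i_c = header.index("ct")
        except ValueError:
            raise ParseError(
                "line 1: header must contain sample_id, assay_id and ct"
            ) from None
        records: dict[tuple, float] = {}
        samples: list = []
        assays: list = []
        for lineno, ln in enumerate(lines[1:], start=2):
            parts = ln.split(sep)
            if len(parts) < 3:
                raise ParseError(f"line {lineno}: expected >= 3 fields, got {len(parts)}")
            sid, aid = parts[i_s].strip(), parts[i_a].strip()
            key = (aid, sid)
            if key in records:
                raise DataError(f"duplicate (sample={sid}, assay={aid}) pair")
            records[key] = _parse_ct_cell(parts[i_c], lineno)
            if sid not in samples:
                samples.append(sid)
            if aid not in assays:
                assays.append(aid)
        mat = pd.DataFrame(np.nan, index=assays, columns=samples, dtype=float)
        for (aid, sid), v in records.items():
            mat.loc[aid, sid] = v
    else:  # wide
        header = [h.strip() for h in lines[0].split(sep)]
        samples = header[1:]
        if len(samples) != len(set(samples)):
            raise DataError("duplicate sample ids in wide header")
        rows, assays = [], []
        for lineno, ln in enumerate(lines[1:], start=2):
            parts = ln.split(sep)
            if len(parts) != len(header):
                raise ParseError(
                    f"line {lineno}: expected {len(header)} fields, got {len(parts)}"
                )
            aid = parts[0].strip()
            if aid in assays:
                raise DataError(f"duplicate assay id {aid!r}")
            assays.append(aid)
            rows.append([_parse_ct_cell(tok, lineno) for tok in parts[1:]])
        mat = pd.DataFrame(rows, index=assays, columns=samples, dtype=float)

    return CtMatrix(ct=mat, detection_limit=detection_limit)


def write_ct_table(m: CtMatrix, path, dialect: str = "wide", sep: str = "\t") -> None:
    """Write a CtMatrix as delimited text; missing cells emitted as NA."""
    if dialect == "wide":
        out = m.ct.copy()
        out.index.name = "assay_id"
        out.to_csv(path, sep=sep, na_rep="NA")
    elif dialect == "long":
        long = (
            m.ct.rename_axis("assay_id")
            .reset_index()
            .melt(id_vars="assay_id", var_name="sample_id", value_name="ct")
        )
        long = long[["sample_id", "assay_id", "ct"]]
        long.to_csv(path, sep=sep, na_rep="NA", index=False)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


# --------------------------------------------------------------------------
# Detection filter
# --------------------------------------------------------------------------


def detection_filter(
    m: CtMatrix,
    min_samples: int = 10,
    min_fraction: float = 0.15,
) -> tuple[CtMatrix, DetectionReport]:
    """Drop assays detected in too few samples.

    The retention threshold is the stricter of the two criteria,
    ``max(min_samples, ceil(min_fraction * n_samples))``.  A well counts as
    detected only if its Ct is present and <= the matrix's detection limit.

    Returns the filtered matrix and a :class:`DetectionReport` accounting
    for every input assay (retained + removed == input).
    """
    if m.n_assays == 0 or m.n_samples == 0:
        raise DataError("empty Ct matrix")
    if min_samples < 1 and not (0 < min_fraction <= 1):
        raise ValueError("need min_samples >= 1 or min_fraction in (0, 1]")

    threshold = int(min_samples)
    if min_fraction is not None and min_fraction > 0:
        threshold = max(threshold, math.ceil(min_fraction * m.n_samples))
    threshold = max(threshold, 1)

    counts = m.detected().sum(axis=1)
    keep = counts >= threshold
    retained = list(m.ct.index[keep])
    removed = list(m.ct.index[~keep])
    logger.info(
        "detection filter: %d/%d assays retained (threshold %d of %d samples)",
        len(retained), m.n_assays, threshold, m.n_samples,
    )
    filtered = CtMatrix(ct=m.ct.loc[keep].copy(), detection_limit=m.detection_limit)
    report = DetectionReport(
        threshold=threshold,
        n_input=m.n_assays,
        retained=retained,
        removed=removed,
        detected_counts=counts,
    )
    return filtered, report


# --------------------------------------------------------------------------
# Normalization and quantification
# --------------------------------------------------------------------------


def global_mean_normalize(
    m: CtMatrix, mean_basis: str = "per_sample_detected"
) -> NormalizedMatrix:
    """Center each sample on its global mean Ct.

    ``mean_basis``:

    * ``per_sample_detected`` (default) — each sample's offset is the mean
      Ct over *that sample's* detected assays.
    * ``common_detected`` — offset is the mean over the set of assays
      detected in every sample, the same set for all samples.

    Missing cells stay missing; undetected-but-present Ct values (above the
    detection limit) are excluded from the mean but still centered.
    """
    if mean_basis not in ("per_sample_detected", "common_detected"):
        raise ValueError(f"unknown mean_basis {mean_basis!r}")

    det = m.detected()
    if mean_basis == "common_detected":
        common = det.all(axis=1)
        if not common.any():
            raise DataError("no assay is detected in every sample")
        basis = m.ct.where(pd.DataFrame(
            np.tile(common.to_numpy()[:, None], (1, m.n_samples)),
            index=m.ct.index, columns=m.ct.columns,
        ))
    else:
        basis = m.ct.where(det)

    n_basis = basis.notna().sum(axis=0)
    empty = n_basis[n_basis == 0]
    if len(empty):
        raise DataError(f"sample(s) with zero detected assays: {list(empty.index)}")

    offsets = basis.mean(axis=0)
    dct = m.ct.sub(offsets, axis=1)
    return NormalizedMatrix(dct=dct, sample_offsets=offsets, mean_basis=mean_basis)


def relative_quantity(
    nm: NormalizedMatrix, reference_samples
) -> ExpressionMatrix:
    """2^-ddCt relative quantities against a reference sample group.

    Per assay, ddCt = dct - mean(dct over reference samples with data);
    rq = 2**-ddCt, so the geometric mean of rq over the reference samples
    equals 1 for every assay with reference data.  Assays with no reference
    data get all-missing rq (warning logged).
    """
    ref = [s for s in reference_samples]
    if not ref:
        raise ValueError("reference_samples must be non-empty")
    missing = [s for s in ref if s not in nm.dct.columns]
    if missing:
        raise DataError(f"reference samples absent from matrix: {missing}")

    ref_mean = nm.dct[ref].mean(axis=1)  # skips NaN per assay
    no_ref = ref_mean.isna()
    if no_ref.any():
        warnings.warn(
            f"{int(no_ref.sum())} assay(s) have no reference-group data; rq set missing",
            stacklevel=2,
        )
    ddct = nm.dct.sub(ref_mean, axis=0)
    rq = np.power(2.0, -ddct)
    return ExpressionMatrix(rq=rq, reference_samples=ref)


def assay_cv(em: ExpressionMatrix, sample_subset=None, scale: str = "rq") -> pd.Series:
    """Per-assay coefficient of variation (SD/mean) over a sample subset.

    Computed on linear-scale rq by default (``scale="ct"`` uses -log2(rq),
    i.e. the ddCt scale).  Assays with fewer than 2 observations get NaN.
    """
    if sample_subset is None:
        sample_subset = em.sample_ids
    subset = list(sample_subset)
    if not subset:
        raise ValueError("sample_subset must be non-empty")
    data = em.rq[subset]
    if scale == "ct":
        data = -np.log2(data)
    elif scale != "rq":
        raise ValueError(f"unknown scale {scale!r}")
    n = data.notna().sum(axis=1)
    mean = data.mean(axis=1)
    sd = data.std(axis=1, ddof=1)
    cv = sd / mean
    cv[n < 2] = np.nan
    return cv


# --------------------------------------------------------------------------
# NormFinder-style stability
# --------------------------------------------------------------------------


def normfinder_stability(data, group_labels) -> StabilityResult:
    """Rank assays by combined intra-/inter-group variability (lower = stabler).

    Implements a grouped variance-decomposition stability model.  With
    ``l`` assays, ``G`` groups and ``n_g`` samples per group, on values
    ``y`` (Ct or dCt; the score is invariant to per-sample shifts):

    1. center by sample: ``x = y - (per-sample mean over assays)``;
    2. per assay/group mean ``x_ig`` and residual variance ``v_ig``;
    3. bias-corrected intra-group variance
       ``s2_ig = max(0, (v_ig - sum_i v_ig / (l (l-1))) * l / (l-2))``
       (the correction removes the covariance injected by step 1);
    4. inter-group deviations ``d_ig = x_ig - mean_g(x_ig)``, shrunk toward 0
       by ``g2 / (g2 + s2_ig / n_g)`` where ``g2`` is a method-of-moments
       estimate of the variance of true group differences across assays;
    5. stability_i = mean over groups of ``|d_shrunk_ig| + sqrt(s2_ig/n_g)``.

    Accepts a :class:`CtMatrix`, :class:`NormalizedMatrix` or plain
    DataFrame (assays x samples).  Assays with any missing value among the
    grouped samples are excluded from scoring (listed in ``excluded``).

    Raises
    ------
    DataError
        Fewer than 2 groups, a group with < 2 samples, or < 3 scoreable
        assays.
    """
    if isinstance(data, CtMatrix):
        mat = data.ct
    elif isinstance(data, NormalizedMatrix):
        mat = data.dct
    else:
        mat = pd.DataFrame(data)

    labels = pd.Series(group_labels)
    if len(labels) != mat.shape[1]:
        if set(getattr(group_labels, "keys", lambda: [])()) >= set(mat.columns):
            labels = pd.Series({c: group_labels[c] for c in mat.columns})
            labels = labels[mat.columns]
        else:
            raise ValueError("group_labels length must match sample count")
    labels.index = mat.columns

    groups = list(pd.unique(labels))
    if len(groups) < 2:
        raise DataError("need >= 2 groups")
    for g in groups:
        if (labels == g).sum() < 2:
            raise DataError(f"group {g!r} has < 2 samples")

    complete = mat.notna().all(axis=1)
    excluded = list(mat.index[~complete])
    if excluded:
        warnings.warn(
            f"{len(excluded)} assay(s) with missing values excluded from stability scoring",
            stacklevel=2,
        )
    y = mat.loc[complete].to_numpy(dtype=float)
    assay_ids = list(mat.index[complete])
    l = y.shape[0]
    if l < 3:
        raise DataError("need >= 3 assays with complete data")

    x = y - y.mean(axis=0, keepdims=True)  # per-sample centering

    G = len(groups)
    xbar = np.empty((l, G))
    v = np.empty((l, G))
    n_g = np.empty(G)
    for k, g in enumerate(groups):
        cols = (labels == g).to_numpy()
        xg = x[:, cols]
        n_g[k] = xg.shape[1]
        xbar[:, k] = xg.mean(axis=1)
        v[:, k] = xg.var(axis=1, ddof=1)

    # intra-group variances, corrected for the per-sample centering
    corr = v.sum(axis=0, keepdims=True) / (l * (l - 1))
    s2 = np.clip((v - corr) * l / (l - 2), 0.0, None)
    z = s2 / n_g[None, :]  # sampling variance of the group means

    d = xbar - xbar.mean(axis=1, keepdims=True)
    # method-of-moments estimate of true group-difference variance
    g2 = max(0.0, (d**2 - (1 - 1 / G) * z).sum() / (l * (G - 1)))
    with np.errstate(invalid="ignore", divide="ignore"):
        shrink = np.where(g2 + z > 0, g2 / (g2 + z), 0.0)
    d_shrunk = d * shrink

    stability = (np.abs(d_shrunk) + np.sqrt(z)).mean(axis=1)
    intra = s2.mean(axis=1)
    inter = (d**2).mean(axis=1)

    table = pd.DataFrame(
        {"stability": stability, "intra_var": intra, "inter_var": inter},
        index=pd.Index(assay_ids, name="assay_id"),
    ).sort_values("stability", kind="stable")
    table["rank"] = np.arange(1, len(table) + 1)
    return StabilityResult(table=table, excluded=excluded)


# --------------------------------------------------------------------------
# Standard curve
# --------------------------------------------------------------------------


def standard_curve_quantify(standards, unknowns=()) -> tuple[StandardCurve, np.ndarray]:
    """Fit Ct = slope * log10(q) + intercept and invert unknown Cts.

    Parameters
    ----------
    standards
        Sequence of ``(log10_quantity, ct)`` pairs; >= 3 points spanning
        >= 2 log10 units.
    unknowns
        Ct values to convert to linear quantities through the fitted line.

    Raises
    ------
    CalibrationError
        Too few / too narrow standards, or a non-negative fitted slope
        (no dilution response).
    """
    pts = np.asarray(list(standards), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise CalibrationError("need >= 3 (log10 quantity, Ct) standards")
    logq, ct = pts[:, 0], pts[:, 1]
    if logq.max() - logq.min() < 2.0:
        raise CalibrationError("standards must span >= 2 log10 units")

    slope, intercept = np.polyfit(logq, ct, 1)
    if slope >= 0:
        raise CalibrationError(f"non-negative slope {slope:.4g}: no dilution response")
    fitted = slope * logq + intercept
    ss_res = float(np.sum((ct - fitted) ** 2))
    ss_tot = float(np.sum((ct - ct.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0

    curve = StandardCurve(slope=float(slope), intercept=float(intercept), r_squared=r2)
    quantities = curve.quantify(np.asarray(list(unknowns), dtype=float))
    return curve, quantities
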