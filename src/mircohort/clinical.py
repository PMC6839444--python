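"""Derived clinical variables: free testosterone, HOMA-IR, MetS, strata.

Operates on scalars (vectorized over numpy arrays where noted) and on a
per-subject clinical table (pandas DataFrame) through
:func:`derive_clinical_table`.

Column dictionary for clinical tables
-------------------------------------
``subject_id, group`` ("control" | "pcos"), ``age`` (years), ``bmi``
(kg/m2), ``waist`` (cm), ``sbp, dbp`` (mmHg), ``total_t, shbg, dheas,
androstenedione`` (nmol/L), ``fasting_glucose`` (mmol/L),
``fasting_insulin`` (mU/L), ``hdl, triglycerides`` (mmol/L), optional
``albumin`` (g/L, default 43).  Derived columns appended (never
overwritten): ``free_t`` (nmol/L), ``homa_ir``, ``mets`` (boolean),
``mets_n_flags``, per-criterion ``mets_flag_*``, ``androgen_stratum``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "KA_ALBUMIN",
    "KS_SHBG",
    "ALBUMIN_MW",
    "DEFAULT_ALBUMIN_G_L",
    "FREE_T_THRESHOLD",
    "MetSResult",
    "free_testosterone",
    "homa_ir",
    "classify_mets",
    "stratify_androgen",
    "derive_clinical_table",
]

# Mass-action association constants (L/mol) for the two testosterone carriers
KA_ALBUMIN = 3.6e4
KS_SHBG = 1.0e9
ALBUMIN_MW = 69_000.0  # g/mol
DEFAULT_ALBUMIN_G_L = 43.0
FREE_T_THRESHOLD = 0.034  # nmol/L, biochemical hyperandrogenism cutoff

MET_S_CRITERIA = ("waist", "bp", "glucose", "hdl", "triglycerides")


def free_testosterone(total_t, shbg, albumin: float = DEFAULT_ALBUMIN_G_L):
    """Free testosterone (nmol/L) from the two-ligand binding equilibrium.

    Solves the mass-action system for testosterone partitioned between
    albumin (association constant 3.6e4 L/mol, linear binding) and SHBG
    (1e9 L/mol, saturable).  With N = 1 + Ka*[albumin] the free fraction
    FT satisfies the quadratic

        Ks*N*FT**2 + (N + Ks*(SHBG - T))*FT - T = 0     (mol/L units)

    whose positive root is returned.  The result satisfies the mass
    balance FT*N + Ks*FT*SHBG/(1 + Ks*FT) = T to 1e-9 relative.

    Parameters are in assay units: ``total_t`` and ``shbg`` in nmol/L,
    ``albumin`` in g/L.  Accepts scalars or numpy arrays.
    """
    t = np.asarray(total_t, dtype=float)
    s = np.asarray(shbg, dtype=float)
    alb = np.asarray(albumin, dtype=float)
    if np.any(t < 0) or np.any(s < 0) or np.any(alb < 0):
        raise ValueError("concentrations must be non-negative")

    t_mol = t * 1e-9
    s_mol = s * 1e-9
    alb_mol = alb / ALBUMIN_MW
    n = 1.0 + KA_ALBUMIN * alb_mol
    if np.any(n <= 0) or np.any((s_mol <= 0) & (n <= 0)):
        raise ValueError("no binding capacity")

    a = KS_SHBG * n
    b = n + KS_SHBG * (s_mol - t_mol)
    c = -t_mol
    disc = b * b - 4.0 * a * c
    if np.any(disc < 0):
        raise ArithmeticError("no positive root for the binding quadratic")
    # numerically stable positive root (b may be large and positive)
    ft_mol = (2.0 * -c) / (b + np.sqrt(disc))
    ft = ft_mol * 1e9
    return float(ft) if np.isscalar(total_t) or np.ndim(total_t) == 0 else ft


def homa_ir(fasting_insulin, fasting_glucose):
    """HOMA-IR = fasting insulin (mU/L) x fasting glucose (mmol/L) / 22.5."""
    ins = np.asarray(fasting_insulin, dtype=float)
    glc = np.asarray(fasting_glucose, dtype=float)
    if np.any(ins < 0) or np.any(glc < 0):
        raise ValueError("inputs must be non-negative")
    out = ins * glc / 22.5
    return float(out) if np.ndim(fasting_insulin) == 0 and np.ndim(fasting_glucose) == 0 else out


@dataclass
class MetSResult:
    mets: bool | None  # None when indeterminate
    flags: dict
    n_flags: int | None
    missing: list

    @property
    def indeterminate(self) -> bool:
        return self.mets is None


def classify_mets(
    waist=None,
    sbp=None,
    dbp=None,
    glucose=None,
    hdl=None,
    triglycerides=None,
    record: pd.Series | dict | None = None,
) -> MetSResult:
    """Metabolic-syndrome call: positive when >= 3 of 5 criteria hold.

    Criteria: waist >= 80 cm; BP >= 130 systolic or >= 85 diastolic;
    fasting glucose >= 5.6 mmol/L; HDL < 1.3 mmol/L (strict);
    triglycerides >= 1.7 mmol/L.

    Missing inputs make the classification indeterminate: ``mets`` is None
    and ``missing`` names the absent fields.
    """
    if record is not None:
        rec = dict(record)
        waist = rec.get("waist", waist)
        sbp = rec.get("sbp", sbp)
        dbp = rec.get("dbp", dbp)
        glucose = rec.get("fasting_glucose", rec.get("glucose", glucose))
        hdl = rec.get("hdl", hdl)
        triglycerides = rec.get("triglycerides", triglycerides)

    def _missing(x):
        return x is None or (isinstance(x, float) and np.isnan(x))

    missing = []
    for name, value in (
        ("waist", waist), ("sbp", sbp), ("dbp", dbp),
        ("fasting_glucose", glucose), ("hdl", hdl), ("triglycerides", triglycerides),
    ):
        if _missing(value):
            missing.append(name)
    if missing:
        return MetSResult(mets=None, flags={}, n_flags=None, missing=missing)

    flags = {
        "waist": waist >= 80.0,
        "bp": sbp >= 130.0 or dbp >= 85.0,
        "glucose": glucose >= 5.6,
        "hdl": hdl < 1.3,
        "triglycerides": triglycerides >= 1.7,
    }
    n = sum(flags.values())
    return MetSResult(mets=n >= 3, flags=flags, n_flags=n, missing=[])


def stratify_androgen(group: str, free_t: float, threshold: float = FREE_T_THRESHOLD) -> str:
    """Androgen stratum: pcos with free T strictly above threshold -> hyper.

    Controls are returned unchanged.  The boundary is exclusive: free T
    exactly at the threshold is normoandrogenic.
    """
    if group == "control":
        return "control"
    if group != "pcos":
        raise ValueError(f"unknown group {group!r}")
    if free_t is None or (isinstance(free_t, float) and np.isnan(free_t)):
        raise ValueError("free_t missing; derive it before stratifying")
    return "hyper_pcos" if free_t > threshold else "normo_pcos"


def derive_clinical_table(
    table: pd.DataFrame,
    albumin_default: float = DEFAULT_ALBUMIN_G_L,
    free_t_threshold: float = FREE_T_THRESHOLD,
) -> pd.DataFrame:
    """Append derived columns to a raw clinical table (copy returned).

    Adds ``free_t``, ``homa_ir``, MetS flags/counts/call and
    ``androgen_stratum``.  Existing input columns are never overwritten;
    an ``albumin`` column is used when present, else the default.
    """
    out = table.copy()
    alb = out["albumin"] if "albumin" in out.columns else albumin_default
    out["free_t"] = free_testosterone(
        out["total_t"].to_numpy(), out["shbg"].to_numpy(), np.asarray(alb, dtype=float)
    )
    out["homa_ir"] = homa_ir(
        out["fasting_insulin"].to_numpy(), out["fasting_glucose"].to_numpy()
    )

    mets_calls = [classify_mets(record=row) for _, row in out.iterrows()]
    out["mets"] = [r.mets for r in mets_calls]
    out["mets_n_flags"] = [r.n_flags for r in mets_calls]
    for crit in MET_S_CRITERIA:
        out[f"mets_flag_{crit}"] = [r.flags.get(crit) for r in mets_calls]

    out["androgen_stratum"] = [
        stratify_androgen(g, ft, threshold=free_t_threshold)
        for g, ft in zip(out["group"], out["free_t"])
    ]
    return out
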