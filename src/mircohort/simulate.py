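"""Seeded synthetic cohorts: Ct matrices, clinical tables and ground truth.

The generative model works on the Ct (log2) scale: each assay has a base
Ct, group effects are additive Ct shifts of -log2(fold change), every
sample carries an additive offset (removed later by global-mean
normalization), and noise is Gaussian with optional shared latent factors
producing correlated assay clusters.  Assays designated non-detectable are
emitted as missing in most samples so they fail the downstream detection
filter.

Clinical variables are drawn per group from configurable location/scale
families (log-normal for skewed variables, normal otherwise).  A
per-subject latent "metabolic severity" factor correlates the
MetS-determining variables so that the rule classifier sees realistic
joint exceedances; MetS status is therefore a *consequence* of the drawn
values, never assigned directly.  Marker-MetS signals are planted as Ct
shifts applied to the subjects whose drawn values satisfy the rule.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import clinical as clin
from .qpcr import CtMatrix, DEFAULT_DETECTION_LIMIT

__all__ = [
    "ConfigError",
    "EffectSpec",
    "ClusterSpec",
    "ClinicalVarSpec",
    "CohortConfig",
    "GroundTruth",
    "default_clinical_params",
    "generate_ct_matrix",
    "generate_clinical_table",
    "generate_cohort",
    "make_detection_fixture",
]

GROUPS = ("control", "normo_pcos", "hyper_pcos")


class ConfigError(ValueError):
    """Invalid cohort configuration; the message names the offending field."""


@dataclass
class EffectSpec:
    """Planted fold change (linear scale, vs control) for one assay.

    The control group fold is fixed at 1; ``fold_normo`` / ``fold_hyper``
    are >0 linear fold changes realised as -log2(fold) Ct shifts.
    """

    assay: int
    fold_normo: float = 1.0
    fold_hyper: float = 1.0

    def validate(self, n_assays: int) -> None:
        if not 0 <= self.assay < n_assays:
            raise ConfigError(f"effect_specs: assay index {self.assay} >= n_assays")
        if self.fold_normo <= 0 or self.fold_hyper <= 0:
            raise ConfigError("effect_specs: fold_change must be > 0")


@dataclass
class ClusterSpec:
    """Assay indices sharing a latent noise factor with correlation rho."""

    assays: tuple
    rho: float

    def validate(self, n_assays: int) -> None:
        if not 0 <= self.rho < 1:
            raise ConfigError("cluster_specs: rho must be in [0, 1)")
        for a in self.assays:
            if not 0 <= a < n_assays:
                raise ConfigError(f"cluster_specs: assay index {a} >= n_assays")


@dataclass
class ClinicalVarSpec:
    """Per-group marginal distribution of one clinical variable.

    ``family`` is "lognormal" (loc = median, scale = IQR) or "normal"
    (loc = mean, scale = SD).  ``mets_loading`` in (-1, 1) couples the
    variable to the subject's latent metabolic-severity factor without
    changing its marginal distribution.
    """

    family: str
    loc: dict  # group -> location
    scale: dict  # group -> scale
    mets_loading: float = 0.0

    def validate(self, name: str) -> None:
        if self.family not in ("lognormal", "normal"):
            raise ConfigError(f"clinical_params[{name}]: unknown family {self.family!r}")
        for g in GROUPS:
            if g not in self.loc or g not in self.scale:
                raise ConfigError(f"clinical_params[{name}]: missing group {g!r}")
            if self.scale[g] < 0:
                raise ConfigError(f"clinical_params[{name}]: negative scale for {g!r}")
            if self.family == "lognormal" and self.loc[g] <= 0:
                raise ConfigError(f"clinical_params[{name}]: lognormal needs loc > 0")
        if not -1 < self.mets_loading < 1:
            raise ConfigError(f"clinical_params[{name}]: mets_loading must be in (-1, 1)")


def default_clinical_params() -> dict:
    """Location/scale structure patterned on a PCOS case-control cohort.

    Hormone and metabolic variables are given per androgen stratum
    (control / normoandrogenic / hyperandrogenic), medians+IQR for skewed
    variables, mean+SD otherwise.  Waist and blood pressure carry positive
    severity loadings (HDL negative) so metabolic-syndrome flags co-occur.
    """

    def spec(family, c, n, h, loading=0.0):
        return ClinicalVarSpec(
            family=family,
            loc={"control": c[0], "normo_pcos": n[0], "hyper_pcos": h[0]},
            scale={"control": c[1], "normo_pcos": n[1], "hyper_pcos": h[1]},
            mets_loading=loading,
        )

    return {
        "age": spec("normal", (27, 5), (29, 5), (27, 4.5)),
        "bmi": spec("lognormal", (25.0, 6.9), (23.8, 4.7), (28.4, 6.2), 0.3),
        "waist": spec("normal", (79, 10), (78, 10), (88, 11), 0.6),
        "sbp": spec("normal", (118, 10), (118, 10), (123, 12), 0.5),
        "dbp": spec("normal", (75, 8), (75, 8), (79, 9), 0.5),
        "total_t": spec("lognormal", (1.1, 0.5), (1.9, 1.1), (3.7, 2.3)),
        "shbg": spec("lognormal", (71.0, 36.3), (88.0, 53.0), (46.0, 36.0), -0.3),
        "dheas": spec("normal", (5291, 1949), (4642, 1644), (7554, 2393)),
        "androstenedione": spec("lognormal", (4.4, 2.5), (5.4, 2.5), (10.1, 4.3)),
        "fasting_glucose": spec("lognormal", (5.0, 0.5), (5.1, 0.4), (5.2, 0.6), 0.5),
        "fasting_insulin": spec("lognormal", (7.7, 5.5), (6.2, 5.6), (8.8, 8.8), 0.5),
        "hdl": spec("lognormal", (1.6, 0.4), (1.6, 0.5), (1.4, 0.5), -0.5),
        "triglycerides": spec("lognormal", (0.6, 0.2), (0.6, 0.3), (1.0, 0.8), 0.6),
    }


@dataclass
class CohortConfig:
    n_per_group: tuple = (20, 23, 19)  # (control, normo_pcos, hyper_pcos)
    n_assays: int = 750
    frac_detectable: float = 0.4
    effect_specs: list = field(default_factory=list)
    cluster_specs: list = field(default_factory=list)
    mets_effects: list = field(default_factory=list)  # (assay index, ct shift for MetS subjects)
    ct_noise_sd: float = 0.5
    base_ct_range: tuple = (18.0, 32.0)
    sample_offset_sd: float = 0.5
    detection_limit: float = DEFAULT_DETECTION_LIMIT
    detect_prob_undetectable: float = 0.06  # upper bound of per-assay detection prob
    clinical_params: dict | None = None
    seed: int = 0

    def validate(self) -> None:
        if len(self.n_per_group) != 3 or any(int(n) < 2 for n in self.n_per_group):
            raise ConfigError("n_per_group: need three group counts, each >= 2")
        if self.n_assays < 1:
            raise ConfigError("n_assays: must be >= 1")
        if not 0 < self.frac_detectable <= 1:
            raise ConfigError("frac_detectable: must be in (0, 1]")
        if self.ct_noise_sd < 0:
            raise ConfigError("ct_noise_sd: must be >= 0")
        if self.sample_offset_sd < 0:
            raise ConfigError("sample_offset_sd: must be >= 0")
        lo, hi = self.base_ct_range
        if not (0 < lo < hi <= 50):
            raise ConfigError("base_ct_range: need 0 < min < max <= 50")
        for e in self.effect_specs:
            e.validate(self.n_assays)
        for c in self.cluster_specs:
            c.validate(self.n_assays)
        for a, _shift in self.mets_effects:
            if not 0 <= a < self.n_assays:
                raise ConfigError(f"mets_effects: assay index {a} >= n_assays")
        for name, spec in (self.clinical_params or {}).items():
            spec.validate(name)

    @property
    def n_samples(self) -> int:
        return int(sum(self.n_per_group))

    def assay_ids(self) -> list:
        width = max(4, len(str(self.n_assays)))
        return [f"miR-{i:0{width}d}" for i in range(self.n_assays)]

    def sample_ids(self) -> list:
        return [f"S{i:03d}" for i in range(self.n_samples)]

    def strata(self) -> list:
        out = []
        for g, n in zip(GROUPS, self.n_per_group):
            out.extend([g] * int(n))
        return out


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must rediscover."""

    seed: int
    detectable: list
    base_ct: pd.Series
    effects: pd.DataFrame  # index assay_id; fold_normo, fold_hyper
    group_mean_ct: pd.DataFrame  # planted per-group mean Ct (noise-free)
    subjects: pd.DataFrame | None = None  # planted_stratum, mets per subject
    mets_effects: list = field(default_factory=list)

    def to_json(self, path) -> None:
        payload = {
            "seed": self.seed,
            "detectable": list(self.detectable),
            "base_ct": self.base_ct.to_dict(),
            "effects": self.effects.reset_index().to_dict(orient="records"),
            "group_mean_ct": self.group_mean_ct.reset_index().to_dict(orient="records"),
            "mets_effects": [[a, s] for a, s in self.mets_effects],
        }
        if self.subjects is not None:
            payload["subjects"] = self.subjects.reset_index().to_dict(orient="records")
        with open(path, "wt", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1, default=lambda o: bool(o) if isinstance(o, np.bool_) else o)


# --------------------------------------------------------------------------
# Generators
# --------------------------------------------------------------------------


def _lognormal_sigma(median: float, iqr: float) -> float:
    # IQR of a lognormal = median * 2*sinh(0.6745*sigma)
    if iqr == 0:
        return 0.0
    return math.asinh(iqr / (2.0 * median)) / 0.67448975


def generate_clinical_table(config: CohortConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw a per-subject raw clinical table from the configured per-group
    distributions.

    Returns columns ``subject_id`` (index), ``group`` (control/pcos) plus
    one column per configured variable.  Derived variables (free T,
    HOMA-IR, MetS, stratum) are intentionally absent — they are computed
    downstream by the clinical-derivation stage.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    params = config.clinical_params or default_clinical_params()

    strata = config.strata()
    n = config.n_samples
    severity = rng.standard_normal(n)  # shared latent metabolic factor

    data: dict[str, np.ndarray] = {}
    for name in sorted(params):
        spec = params[name]
        lam = spec.mets_loading
        eps = rng.standard_normal(n)
        z = lam * severity + math.sqrt(1.0 - lam * lam) * eps
        values = np.empty(n)
        for i, stratum in enumerate(strata):
            loc, scale = spec.loc[stratum], spec.scale[stratum]
            if spec.family == "lognormal":
                sigma = _lognormal_sigma(loc, scale)
                values[i] = loc * math.exp(sigma * z[i])
            else:
                values[i] = loc + scale * z[i]
        data[name] = values

    table = pd.DataFrame(data, index=pd.Index(config.sample_ids(), name="subject_id"))
    table.insert(0, "group", ["control" if s == "control" else "pcos" for s in strata])
    return table


def _planted_group_shifts(config: CohortConfig) -> np.ndarray:
    """Per-assay x per-group additive Ct shifts (-log2 of planted folds)."""
    shifts = np.zeros((config.n_assays, 3))
    for e in config.effect_specs:
        shifts[e.assay, 1] = -math.log2(e.fold_normo)
        shifts[e.assay, 2] = -math.log2(e.fold_hyper)
    return shifts


def generate_ct_matrix(
    config: CohortConfig,
    rng: np.random.Generator | None = None,
    mets_status: pd.Series | None = None,
) -> tuple[CtMatrix, GroundTruth]:
    """Simulate the raw Ct matrix and its ground truth.

    Ct = base + group shift + per-sample offset + (cluster-correlated)
    noise [+ MetS marker shift when ``mets_status`` is supplied].  Exactly
    ``round(frac_detectable * n_assays)`` assays are detectable; the rest
    receive a small per-assay detection probability so they are missing in
    well over the filter threshold of samples.  Deterministic given
    (config, seed).
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)

    n_a, n_s = config.n_assays, config.n_samples
    assay_ids = config.assay_ids()
    sample_ids = config.sample_ids()
    strata = np.array(config.strata())
    group_idx = np.array([GROUPS.index(s) for s in strata])

    n_det = int(round(config.frac_detectable * n_a))
    det_idx = np.sort(rng.choice(n_a, size=n_det, replace=False))
    detectable_mask = np.zeros(n_a, dtype=bool)
    detectable_mask[det_idx] = True

    lo, hi = config.base_ct_range
    base = rng.uniform(lo, hi, size=n_a)
    shifts = _planted_group_shifts(config)
    offsets = rng.normal(0.0, config.sample_offset_sd, size=n_s)

    noise = rng.standard_normal((n_a, n_s))
    for c in config.cluster_specs:
        factor = rng.standard_normal(n_s)
        idx = np.asarray(list(c.assays), dtype=int)
        noise[idx] = math.sqrt(c.rho) * factor[None, :] + math.sqrt(1 - c.rho) * noise[idx]
    noise *= config.ct_noise_sd

    ct = base[:, None] + shifts[:, group_idx] + offsets[None, :] + noise

    if mets_status is not None and config.mets_effects:
        mets_vec = mets_status.reindex(sample_ids).fillna(False).to_numpy(dtype=bool)
        for a, shift in config.mets_effects:
            ct[a, mets_vec] += shift

    # detection / dropout
    p_det = np.ones(n_a)
    p_det[~detectable_mask] = rng.uniform(
        0.0, config.detect_prob_undetectable, size=(~detectable_mask).sum()
    )
    present = rng.random((n_a, n_s)) < p_det[:, None]
    ct = np.where(present, ct, np.nan)
    ct = np.where(ct > config.detection_limit, np.nan, ct)  # poor amplification
    ct = np.clip(ct, 0.5, 50.0)

    mat = pd.DataFrame(ct, index=assay_ids, columns=sample_ids)

    effects = pd.DataFrame(
        {
            "assay_id": [assay_ids[e.assay] for e in config.effect_specs],
            "fold_normo": [e.fold_normo for e in config.effect_specs],
            "fold_hyper": [e.fold_hyper for e in config.effect_specs],
        }
    ).set_index("assay_id")
    group_mean = pd.DataFrame(
        base[:, None] + shifts, index=pd.Index(assay_ids, name="assay_id"), columns=list(GROUPS)
    )
    truth = GroundTruth(
        seed=config.seed,
        detectable=[assay_ids[i] for i in det_idx],
        base_ct=pd.Series(base, index=assay_ids, name="base_ct"),
        effects=effects,
        group_mean_ct=group_mean,
        mets_effects=[(assay_ids[a], s) for a, s in config.mets_effects],
    )
    return CtMatrix(ct=mat, detection_limit=config.detection_limit), truth


def generate_cohort(config: CohortConfig) -> tuple[CtMatrix, pd.DataFrame, GroundTruth]:
    """Full synthetic cohort: clinical table first, then the Ct matrix.

    MetS status is derived from the drawn clinical values through the rule
    classifier and fed back into the Ct generator so configured
    ``mets_effects`` shift the marker assays of affected subjects.  One
    seed drives everything.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    clinical_table = generate_clinical_table(config, rng=rng)
    derived = clin.derive_clinical_table(clinical_table)
    mets = derived["mets"].astype(bool)

    matrix, truth = generate_ct_matrix(config, rng=rng, mets_status=mets)
    truth.subjects = pd.DataFrame(
        {
            "planted_stratum": config.strata(),
            "mets": mets.to_numpy(),
        },
        index=clinical_table.index,
    )
    return matrix, clinical_table, truth


def make_detection_fixture(
    n_assays: int = 750,
    n_samples: int = 62,
    n_pass: int = 303,
    min_samples: int = 10,
    min_fraction: float = 0.15,
    seed: int = 0,
) -> CtMatrix:
    """Ct matrix in which exactly ``n_pass`` assays pass the detection rule.

    Threshold = max(min_samples, ceil(min_fraction * n_samples)); passing
    assays are detected in every sample, failing assays in threshold - 1
    samples.  Values are mildly randomized (seeded) but detection counts
    are exact by construction.
    """
    if not 0 <= n_pass <= n_assays:
        raise ValueError("n_pass must be within [0, n_assays]")
    threshold = max(int(min_samples), math.ceil(min_fraction * n_samples))
    rng = np.random.default_rng(seed)
    ct = rng.uniform(20.0, 30.0, size=(n_assays, n_samples))
    for i in range(n_pass, n_assays):
        absent = rng.choice(n_samples, size=n_samples - (threshold - 1), replace=False)
        ct[i, absent] = np.nan
    ids = [f"miR-{i:04d}" for i in range(n_assays)]
    cols = [f"S{j:03d}" for j in range(n_samples)]
    return CtMatrix(ct=pd.DataFrame(ct, index=ids, columns=cols))
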