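"""Pipeline configuration: YAML schema, validation, defaults.

The config file has one top-level mapping; exactly one of ``input`` (paths
to Ct + clinical tables) or ``synthetic`` (cohort generator parameters)
must be present.  Unknown keys are rejected.  ``validate_config`` returns
*all* violations, not just the first.
"""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import dataclass, field

import yaml

from .simulate import ClusterSpec, CohortConfig, EffectSpec

__all__ = ["PipelineConfig", "load_config", "validate_config", "config_hash"]

_DEFAULTS: dict = {
    "seed": 0,
    "output_dir": "mircohort_out",
    "log_level": "INFO",
    "input": None,
    "synthetic": None,
    "preprocess": {
        "min_samples": 10,
        "min_fraction": 0.15,
        "detection_limit": 35.0,
        "mean_basis": "per_sample_detected",
    },
    "stats": {
        "alpha": 0.05,
        "adjust_covariates": ["age", "bmi"],
        "equal_var": True,
        "fdr": False,
    },
    "panel": {
        "markers": None,  # None -> top 3 single-marker AUCs among candidates
        "outcome": "mets",
        "within_group": "pcos",
        "ci": "delong",
        "cv": "none",
    },
}

_INPUT_KEYS = {"ct_table", "dialect", "clinical_table"}
_SYNTH_KEYS = {
    "n_per_group", "n_assays", "frac_detectable", "ct_noise_sd",
    "sample_offset_sd", "base_ct_range", "detection_limit",
    "effects", "clusters", "mets_effects",
}


@dataclass
class PipelineConfig:
    seed: int
    output_dir: str
    log_level: str
    input: dict | None
    synthetic: dict | None
    preprocess: dict = field(default_factory=dict)
    stats: dict = field(default_factory=dict)
    panel: dict = field(default_factory=dict)

    def cohort_config(self) -> CohortConfig:
        """Build the synthetic-cohort config from the ``synthetic`` block."""
        if self.synthetic is None:
            raise ValueError("config has no synthetic block")
        s = self.synthetic
        effects = [
            EffectSpec(
                assay=int(e["assay"]),
                fold_normo=float(e.get("fold_normo", 1.0)),
                fold_hyper=float(e.get("fold_hyper", 1.0)),
            )
            for e in s.get("effects", [])
        ]
        clusters = [
            ClusterSpec(assays=tuple(int(a) for a in c["assays"]), rho=float(c["rho"]))
            for c in s.get("clusters", [])
        ]
        kwargs = dict(
            n_per_group=tuple(s.get("n_per_group", (20, 23, 19))),
            n_assays=int(s.get("n_assays", 750)),
            frac_detectable=float(s.get("frac_detectable", 0.4)),
            effect_specs=effects,
            cluster_specs=clusters,
            mets_effects=[(int(a), float(d)) for a, d in s.get("mets_effects", [])],
            ct_noise_sd=float(s.get("ct_noise_sd", 0.5)),
            seed=int(self.seed),
        )
        if "sample_offset_sd" in s:
            kwargs["sample_offset_sd"] = float(s["sample_offset_sd"])
        if "base_ct_range" in s:
            kwargs["base_ct_range"] = tuple(float(v) for v in s["base_ct_range"])
        if "detection_limit" in s:
            kwargs["detection_limit"] = float(s["detection_limit"])
        return CohortConfig(**kwargs)

    def echo(self) -> dict:
        return {
            "seed": self.seed,
            "output_dir": self.output_dir,
            "log_level": self.log_level,
            "input": self.input,
            "synthetic": self.synthetic,
            "preprocess": self.preprocess,
            "stats": self.stats,
            "panel": self.panel,
        }


def validate_config(raw: dict) -> list[str]:
    """Schema check; returns a list of human-readable violations (all of them)."""
    problems: list[str] = []
    if not isinstance(raw, dict):
        return ["config root must be a mapping"]

    known = set(_DEFAULTS)
    for key in raw:
        if key not in known:
            problems.append(f"unknown key {key!r}")

    has_input = raw.get("input") is not None
    has_synth = raw.get("synthetic") is not None
    if has_input == has_synth:
        problems.append("exactly one of 'input' and 'synthetic' must be supplied")

    if has_input:
        inp = raw["input"]
        if not isinstance(inp, dict):
            problems.append("'input' must be a mapping")
        else:
            for key in inp:
                if key not in _INPUT_KEYS:
                    problems.append(f"input: unknown key {key!r}")
            if "ct_table" not in inp:
                problems.append("input: 'ct_table' is required")
            if inp.get("dialect", "long") not in ("long", "wide"):
                problems.append("input: dialect must be 'long' or 'wide'")

    if has_synth:
        syn = raw["synthetic"]
        if not isinstance(syn, dict):
            problems.append("'synthetic' must be a mapping")
        else:
            for key in syn:
                if key not in _SYNTH_KEYS:
                    problems.append(f"synthetic: unknown key {key!r}")
            frac = syn.get("frac_detectable", 0.4)
            if not 0 < float(frac) <= 1:
                problems.append("synthetic: frac_detectable must be in (0, 1]")

    pre = raw.get("preprocess", {})
    if isinstance(pre, dict):
        for key in pre:
            if key not in _DEFAULTS["preprocess"]:
                problems.append(f"preprocess: unknown key {key!r}")
        mf = pre.get("min_fraction", 0.15)
        if not 0 < float(mf) <= 1:
            problems.append("preprocess: min_fraction must be in (0, 1]")
        if pre.get("mean_basis", "per_sample_detected") not in (
            "per_sample_detected", "common_detected",
        ):
            problems.append("preprocess: unknown mean_basis")
    else:
        problems.append("'preprocess' must be a mapping")

    st = raw.get("stats", {})
    if isinstance(st, dict):
        for key in st:
            if key not in _DEFAULTS["stats"]:
                problems.append(f"stats: unknown key {key!r}")
        alpha = st.get("alpha", 0.05)
        try:
            if not 0 < float(alpha) < 1:
                problems.append("stats: alpha must be in (0, 1)")
        except (TypeError, ValueError):
            problems.append("stats: alpha must be a number")
    else:
        problems.append("'stats' must be a mapping")

    pn = raw.get("panel", {})
    if isinstance(pn, dict):
        for key in pn:
            if key not in _DEFAULTS["panel"]:
                problems.append(f"panel: unknown key {key!r}")
        if pn.get("ci", "delong") not in ("delong", "bootstrap"):
            problems.append("panel: ci must be 'delong' or 'bootstrap'")
        if pn.get("cv", "none") not in ("none", "loo"):
            problems.append("panel: cv must be 'none' or 'loo'")
    else:
        problems.append("'panel' must be a mapping")

    return problems


def load_config(path, overrides: dict | None = None) -> PipelineConfig:
    """Load, validate and default-expand a YAML config file."""
    with open(path, "rt", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if overrides:
        raw = _deep_merge(raw, overrides)
    problems = validate_config(raw)
    if problems:
        raise ValueError("invalid config:\n  - " + "\n  - ".join(problems))

    merged = _deep_merge(copy.deepcopy(_DEFAULTS), raw)
    return PipelineConfig(
        seed=int(merged["seed"]),
        output_dir=str(merged["output_dir"]),
        log_level=str(merged["log_level"]),
        input=merged["input"],
        synthetic=merged["synthetic"],
        preprocess=merged["preprocess"],
        stats=merged["stats"],
        panel=merged["panel"],
    )


def config_hash(cfg: PipelineConfig) -> str:
    """Hash of the result-determining settings (output_dir/log_level excluded)."""
    echo = {k: v for k, v in cfg.echo().items() if k not in ("output_dir", "log_level")}
    blob = json.dumps(echo, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _deep_merge(base: dict, extra: dict) -> dict:
    out = dict(base)
    for k, v in extra.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = v
    return out
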