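"""Study orchestration: configs, end-to-end analyses, and reports.

Three entry points wire the library modules together:

* :func:`run_risk_scan` — per-design bistability classification grids and
  at-risk fractions over the (α, γ) plane,
* :func:`run_coexpression_study` — analytic and sampled allele-coupling
  statistics (covariance, correlation, shrinkage MI) across regulator
  settings,
* :func:`run_timecourse_study` / :func:`run_flow_analysis` — the
  flow-cytometry chain (optional MESF calibration → percentile alignment →
  GMM/BIC/bimodality per condition and day → MI per day).

Configuration is a YAML mapping validated against a per-study schema
(unknown keys are rejected before any computation); every report carries a
provenance block (config hash, seed, package version) and identical configs
produce identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._errors import ConfigError
from .allele_coupling import (
    AlleleKinetics,
    JointCountModel,
    RegulatorDistribution,
    allelic_correlation,
    joint_covariance,
    sample_joint_counts,
)
from .expression_stats import (
    ExpressionSample,
    align_first_percentile,
    bimodality_filter,
    fit_gmm,
    mesf_calibrate,
    mi_shrinkage,
    select_model_bic,
)
from .feedback_model import ReporterDesign, gamma_factor, risk_map
from .io import read_beads_csv, read_events_csv, write_events_csv
from .synthetic_data import PopulationSpec, TimecourseSpec, generate_timecourse

__all__ = [
    "StudyConfig",
    "SCHEMAS",
    "run_risk_scan",
    "run_coexpression_study",
    "run_timecourse_study",
    "run_flow_analysis",
    "analyze_events",
]

# Published schemas: per study kind, the full set of accepted keys with
# (type, required) contracts.  Unknown keys are rejected.
SCHEMAS: dict[str, dict[str, tuple[type, bool]]] = {
    "risk_scan": {
        "study": (str, True),
        "seed": (int, False),
        "designs": (list, True),
        "grid": (dict, True),
        "hill": ((int, float), False),
    },
    "coexpression": {
        "study": (str, True),
        "seed": (int, True),
        "n_draws": (int, True),
        "lam": ((int, float), True),
        "regulators": (list, True),
    },
    "timecourse": {
        "study": (str, True),
        "seed": (int, True),
        "n_cells": (int, True),
        "days": (list, False),
        "high_weight_start": ((int, float), False),
        "weight_decay_rate": ((int, float), False),
        "mean_drift": ((int, float), False),
        "correlation": ((int, float), False),
    },
    "flow_analysis": {
        "study": (str, True),
        "seed": (int, False),
        "reference_day": (int, False),
        "align": (bool, False),
        "p0": ((int, float), False),
    },
}

_GRID_KEYS = {"alpha_min", "alpha_max", "n_alpha", "gamma_min", "gamma_max", "n_gamma"}


@dataclass(frozen=True)
class StudyConfig:
    """A validated study configuration."""

    kind: str
    params: dict

    @classmethod
    def from_dict(cls, raw: dict) -> "StudyConfig":
        if not isinstance(raw, dict) or "study" not in raw:
            raise ConfigError("config must be a mapping with a 'study' key")
        kind = raw["study"]
        if kind not in SCHEMAS:
            raise ConfigError(f"unknown study kind {kind!r}; expected one of {sorted(SCHEMAS)}")
        schema = SCHEMAS[kind]
        unknown = set(raw) - set(schema)
        if unknown:
            raise ConfigError(f"unknown key(s) for study {kind!r}: {sorted(unknown)}")
        for key, (typ, required) in schema.items():
            if required and key not in raw:
                raise ConfigError(f"study {kind!r} requires key {key!r}")
            if key in raw and not isinstance(raw[key], typ):
                raise ConfigError(f"key {key!r} must be of type {typ}")
        if kind == "risk_scan":
            grid = raw["grid"]
            if set(grid) != _GRID_KEYS:
                raise ConfigError(f"grid must define exactly {sorted(_GRID_KEYS)}")
        return cls(kind=kind, params=dict(raw))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    def hash(self) -> str:
        blob = json.dumps(self.params, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def provenance(self) -> dict:
        return {
            "config_hash": self.hash(),
            "seed": self.params.get("seed"),
            "package_version": __version__,
        }


def _write_json(obj: dict, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=float) + "\n")


def _parse_design(entry) -> ReporterDesign:
    if isinstance(entry, str):
        if entry in ("wildtype", "knock_in", "bac"):
            return ReporterDesign(kind=entry)
        raise ConfigError(f"design {entry!r} requires parameters; use a mapping")
    if isinstance(entry, dict):
        return ReporterDesign(
            kind=entry.get("kind"),
            epsilon=entry.get("epsilon"),
            delta=entry.get("delta"),
            insert_count=entry.get("insert_count", 1),
        )
    raise ConfigError(f"cannot interpret design entry {entry!r}")


def run_risk_scan(config: StudyConfig, outdir: str | Path) -> dict:
    """Classification grids and at-risk fractions for each reporter design."""
    if config.kind != "risk_scan":
        raise ConfigError("run_risk_scan requires a risk_scan config")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    g = config.params["grid"]
    alphas = np.linspace(g["alpha_min"], g["alpha_max"], int(g["n_alpha"]))
    gammas = np.linspace(g["gamma_min"], g["gamma_max"], int(g["n_gamma"]))
    hill = float(config.params.get("hill", 2.0))

    summary: dict = {"provenance": config.provenance(), "designs": {}}
    for entry in config.params["designs"]:
        design = _parse_design(entry)
        table = risk_map(design, alphas, gammas, hill_coeff=hill)
        name = design.kind
        table.to_csv(outdir / f"riskmap_{name}.csv", index=False, float_format="%.10g")
        summary["designs"][name] = {
            "gamma_factor": gamma_factor(design),
            "at_risk_fraction": float(table["at_risk"].mean()),
            "n_cells_at_risk": int(table["at_risk"].sum()),
            "grid_size": int(len(table)),
        }
    _write_json(summary, outdir / "risk_scan_summary.json")
    return summary


def run_coexpression_study(config: StudyConfig, outdir: str | Path) -> dict:
    """Allele-coupling statistics across regulator settings.

    For each regulator setting, samples ``n_draws`` paired counts at the
    configured per-allele mean, and tabulates the analytic covariance and
    correlation beside their sample estimates and the estimated MI between
    allele outputs.
    """
    if config.kind != "coexpression":
        raise ConfigError("run_coexpression_study requires a coexpression config")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    lam = float(config.params["lam"])
    n = int(config.params["n_draws"])
    seed = int(config.params["seed"])
    kin = AlleleKinetics.from_means(lam, lam)

    rows = []
    for i, reg_cfg in enumerate(config.params["regulators"]):
        reg_cfg = dict(reg_cfg)
        family = reg_cfg.pop("family", None)
        if family == "constant":
            reg = RegulatorDistribution.constant(reg_cfg.get("value", 1.0))
        elif family == "gamma":
            reg = RegulatorDistribution.gamma(reg_cfg["shape"], reg_cfg["scale"])
        elif family == "gumbel":
            reg = RegulatorDistribution.gumbel(reg_cfg["loc"], reg_cfg["scale"])
        else:
            raise ConfigError(f"unsupported regulator family {family!r} in config")
        model = JointCountModel(kinetics=kin, regulator=reg)
        draws = sample_joint_counts(model, n=n, seed=seed + i)
        m1 = draws["m1"].to_numpy(dtype=float)
        m2 = draws["m2"].to_numpy(dtype=float)
        mi = mi_shrinkage(m1, m2)
        rows.append(
            {
                "setting": f"{family}" + (f"_theta={reg.scale:g}" if family == "gamma" else ""),
                "family": family,
                "analytic_cov": joint_covariance(model),
                "sample_cov": float(np.cov(m1, m2)[0, 1]),
                "analytic_corr": allelic_correlation(model),
                "sample_corr": float(np.corrcoef(m1, m2)[0, 1]),
                "mi_nats": mi.value,
                "n_draws": n,
            }
        )
    table = pd.DataFrame(rows)
    table.to_csv(outdir / "coexpression.csv", index=False, float_format="%.10g")
    report = {"provenance": config.provenance(), "settings": rows}
    _write_json(report, outdir / "coexpression_report.json")
    return report


def _analyze_channel(values: np.ndarray, seed: int) -> dict:
    fit1 = fit_gmm(values, k=1, seed=seed)
    fit2 = fit_gmm(values, k=2, seed=seed)
    chosen = select_model_bic(fit1, fit2)
    accepted, reasons = bimodality_filter(fit2)
    bimodal = chosen.n_components == 2 and accepted
    return {
        "bic_k1": fit1.bic,
        "bic_k2": fit2.bic,
        "selected_components": chosen.n_components,
        "weights": list(chosen.weights),
        "means": list(chosen.means),
        "sds": list(chosen.sds),
        "bimodality_criteria_pass": bool(accepted),
        "bimodality_reasons": reasons,
        "bimodal": bool(bimodal),
    }


def analyze_events(
    sample: ExpressionSample,
    reference_day: Optional[int] = None,
    align: bool = True,
    seed: int = 0,
    p0: float = 0.05,
) -> dict:
    """Run alignment → GMM/BIC/bimodality → per-day MI on an event table.

    Returns a nested report keyed by condition and day with per-channel
    mixture verdicts and the shrinkage MI between the log-transformed
    channels.  Bimodality of a channel requires both BIC selection of the
    two-component model and the weight/peak-dominance criteria.
    """
    shifts: dict = {}
    if align and sample.data["day"].nunique() > 1:
        sample, shifts = align_first_percentile(sample, reference_day=reference_day)
    report: dict = {"shifts": {f"{ch}/day{day}": s for (ch, day), s in shifts.items()}, "groups": {}}
    for (condition, day), sub in sample.data.groupby(["condition", "day"], sort=True):
        entry: dict = {}
        logvals = {}
        for ch in ("nanog", "reporter"):
            v = sub[ch].to_numpy(dtype=float)
            lv = np.log(v[v > 0])
            logvals[ch] = (sub[ch].to_numpy(dtype=float), v > 0)
            entry[ch] = _analyze_channel(lv, seed=seed)
        both = logvals["nanog"][1] & logvals["reporter"][1]
        mi = mi_shrinkage(
            np.log(logvals["nanog"][0][both]), np.log(logvals["reporter"][0][both]), p0=p0
        )
        entry["mi_nats"] = mi.value
        entry["mi_shrinkage_intensity"] = mi.shrinkage
        entry["n_cells"] = int(len(sub))
        report["groups"][f"{condition}/day{int(day)}"] = entry
    return report


def run_timecourse_study(config: StudyConfig, outdir: str | Path) -> dict:
    """Generate a synthetic differentiation time course and analyze it."""
    if config.kind != "timecourse":
        raise ConfigError("run_timecourse_study requires a timecourse config")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    p = config.params
    spec = TimecourseSpec(
        days=tuple(p.get("days", (0, 1, 2, 3, 5, 7))),
        n_cells=int(p["n_cells"]),
        seed=int(p["seed"]),
        high_weight_start=float(p.get("high_weight_start", 0.7)),
        weight_decay_rate=float(p.get("weight_decay_rate", 0.4)),
        mean_drift=float(p.get("mean_drift", 0.08)),
        correlation=float(p.get("correlation", 0.6)),
    )
    sample = generate_timecourse(spec)
    write_events_csv(sample, outdir / "timecourse_events.csv")
    analysis = analyze_events(sample, seed=int(p["seed"]))
    report = {"provenance": config.provenance(), "analysis": analysis}
    _write_json(report, outdir / "timecourse_report.json")
    return report


def run_flow_analysis(
    events_csv: str | Path,
    config: StudyConfig,
    beads_csv: Optional[str | Path] = None,
    outdir: str | Path = ".",
) -> dict:
    """Full flow-cytometry analysis of an event CSV (optionally calibrated)."""
    if config.kind != "flow_analysis":
        raise ConfigError("run_flow_analysis requires a flow_analysis config")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sample = read_events_csv(events_csv)
    calibration = None
    if beads_csv is not None:
        beads = read_beads_csv(beads_csv)
        cal_info = {}
        for ch in ("nanog", "reporter"):
            sample, cal = mesf_calibrate(beads, sample, ch)
            cal_info[ch] = {"slope": cal.slope, "intercept": cal.intercept}
        calibration = cal_info
    analysis = analyze_events(
        sample,
        reference_day=config.params.get("reference_day"),
        align=config.params.get("align", True),
        seed=int(config.params.get("seed", 0)),
        p0=float(config.params.get("p0", 0.05)),
    )
    report = {
        "provenance": config.provenance(),
        "calibration": calibration,
        "analysis": analysis,
    }
    _write_json(report, outdir / "flow_analysis_report.json")
    return report
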