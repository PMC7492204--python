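"""End-to-end analysis pipeline and input validation.

Stages mirror the study's workflow: cohort (simulated or ingested), endpoint
derivation, baseline group comparison, univariate survival analyses, and the
dual-gated CART in both model variants.  Every run writes a manifest with the
seed, a hash of the effective configuration, per-stage row/event counts and a
SHA-256 digest of each output file.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .baseline import table1_report
from .cart import CartConfig, build_tree, render_tree
from .cohort import CohortConfig, default_config, generate_cohort
from .coxph import cox_fit
from .cutpoints import best_binary_split
from .endpoints import ENDPOINT_KINDS, endpoint_table
from .io import (
    ENDPOINTS_FILE,
    PATIENTS_FILE,
    RELAPSES_FILE,
    VISITS_FILE,
    read_cohort,
    write_cohort,
    write_endpoints,
)
from .records import KFS_SYSTEMS
from .survival import SurvivalDataset, km_estimate, km_table, logrank_test

_FLOAT_FMT = "%.6g"


# ---------------------------------------------------------------------------
# Configuration file (flat key = value text)

_CONFIG_KEYS = {
    "n_subjects": int,
    "seed": int,
    "prop_female": float,
    "prop_polysymptomatic": float,
    "dropout_rate_target": float,
    "horizon": float,
    "visit_window_weeks": float,
    "alpha": float,
    "min_node_size": int,
    "variant": str,
}


def parse_config_file(path: str | Path) -> dict:
    """Parse a flat ``key = value`` configuration file."""
    overrides: dict = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        if key not in _CONFIG_KEYS:
            raise ValueError(f"{path}:{lineno}: unknown configuration key {key!r}")
        overrides[key] = _CONFIG_KEYS[key](value)
    return overrides


def make_cohort_config(overrides: dict) -> CohortConfig:
    cfg = default_config(
        seed=overrides.get("seed", 0), n_subjects=overrides.get("n_subjects", 300)
    )
    fields = {
        k: v
        for k, v in overrides.items()
        if k in {f.name for f in dataclasses.fields(CohortConfig)}
    }
    return dataclasses.replace(cfg, **fields)


# ---------------------------------------------------------------------------
# Validation

@dataclass
class ValidationReport:
    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def add(self, message: str) -> None:
        self.violations.append(message)


def validate_tables(input_dir: str | Path) -> ValidationReport:
    """Schema and eligibility checks on the three cohort tables.

    Violations are reported, not raised: EDSS on the half-point grid and
    <= 6.5 at baseline, KFS grades in 0..6 or 9, strictly increasing visit
    months with a month-0 baseline, >= 1 pre-baseline relapse, and
    non-negative relapse grade increases.
    """
    input_dir = Path(input_dir)
    report = ValidationReport()
    try:
        patients = pd.read_csv(input_dir / PATIENTS_FILE)
        visits = pd.read_csv(input_dir / VISITS_FILE)
        relapses = pd.read_csv(input_dir / RELAPSES_FILE)
    except FileNotFoundError as exc:
        report.add(f"missing input table: {exc.filename}")
        return report

    for col in ("subject_id", "sex", "baseline_edss", "relapse_count_2y"):
        if col not in patients.columns:
            report.add(f"patients.csv: missing column {col!r}")
            return report

    for row_no, p in patients.iterrows():
        sid = p["subject_id"]
        edss = float(p["baseline_edss"])
        if edss > 6.5:
            report.add(
                f"patients.csv row {row_no} ({sid}): baseline EDSS {edss} exceeds "
                "the 6.5 eligibility maximum"
            )
        if round(edss * 2) != edss * 2 or edss < 0:
            report.add(f"patients.csv row {row_no} ({sid}): EDSS {edss} off the half-point grid")
        if int(p["relapse_count_2y"]) < 1:
            report.add(
                f"patients.csv row {row_no} ({sid}): eligibility requires at least one "
                "pre-baseline relapse on platform therapy"
            )

    for sid, group in visits.groupby("subject_id"):
        months = group["month"].to_numpy()
        if not np.all(np.diff(np.sort(months)) > 0):
            report.add(f"visits.csv ({sid}): visit months not strictly increasing")
        if 0.0 not in months:
            report.add(f"visits.csv ({sid}): no baseline (month 0) visit")
        for s in KFS_SYSTEMS:
            col = f"kfs_{s}"
            bad = group[~(group[col].isin(range(7)) | (group[col] == 9))]
            for row_no in bad.index:
                report.add(f"visits.csv row {row_no} ({sid}): {col} outside 0..6/9")

    for row_no, r in relapses.iterrows():
        for s in KFS_SYSTEMS:
            if int(r[f"delta_{s}"]) < 0:
                report.add(f"relapses.csv row {row_no}: negative delta_{s}")
    pre_counts = (relapses["onset_month"] < 0).groupby(relapses["subject_id"]).sum()
    for sid in patients["subject_id"]:
        if pre_counts.get(sid, 0) < 1:
            report.add(f"relapses.csv ({sid}): no pre-baseline index relapse")
    return report


# ---------------------------------------------------------------------------
# Pipeline

@dataclass
class RunManifest:
    seed: int
    config_hash: str
    tool_version: str
    stage_counts: dict[str, dict] = field(default_factory=dict)
    output_digests: dict[str, str] = field(default_factory=dict)
    input_digests: dict[str, str] = field(default_factory=dict)
    started_at: str = ""
    finished_at: str = ""
    failed_stage: Optional[str] = None

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


_UNIVARIATE_PREDICTORS = [
    ("poly_index", "binary"),
    ("female", "binary"),
    ("relapse_count_2y", "ordinal"),
    ("baseline_edss", "ordinal"),
    ("age_at_baseline", "continuous"),
    ("age_at_first_symptom", "continuous"),
    ("disease_duration", "continuous"),
    ("dominant_symptom", "categorical"),
    ("most_affected_kfs", "categorical"),
    ("prior_dmt", "categorical"),
]


def _univariate_fits(table: pd.DataFrame, kind: str) -> dict:
    """Per-endpoint univariate analyses: group KM landmarks, the phenotype
    Cox fit, and the strongest cut-point per predictor."""
    d = SurvivalDataset(
        table["time"].to_numpy(),
        table["event"].to_numpy(),
        table.drop(columns=["time", "event"]).reset_index(drop=True),
    )
    out: dict = {"endpoint": kind, "n": len(d), "n_events": d.n_events}
    if d.n_events == 0:
        out["skipped"] = "no events; Cox and log-rank stages not applicable"
        return out

    fit = cox_fit(d, ["poly_index"])
    groups = [d.subset(d.covariates["poly_index"].to_numpy() == v) for v in (0, 1)]
    lr = logrank_test(groups) if all(len(g) for g in groups) else None
    out["poly_index"] = {
        "hr": float(fit.hr.iloc[0]),
        "ci95": [float(fit.ci95_low.iloc[0]), float(fit.ci95_high.iloc[0])],
        "wald_p": float(fit.wald_p.iloc[0]),
        "score_p": fit.score_p,
        "logrank_p": lr.p_value if lr else None,
        "converged": fit.converged,
    }
    cutoffs = {}
    for variable, vkind in _UNIVARIATE_PREDICTORS:
        split = best_binary_split(d, variable, vkind)
        if split is not None:
            cutoffs[variable] = split.to_dict()
    out["strongest_cutoffs"] = cutoffs
    return out


def run_pipeline(
    output_dir: str | Path,
    input_dir: Optional[str | Path] = None,
    config_path: Optional[str | Path] = None,
    seed: Optional[int] = None,
    variant: str = "both",
    horizon: float = 24.0,
    alpha: float = 0.05,
    min_node_size: int = 5,
) -> RunManifest:
    """Run the full analysis; simulate a cohort when ``input_dir`` is None.

    Writes patients/visits/relapses (when simulating), endpoints.csv,
    table1.csv, km_curves.csv, fits.json, tree_A.json/tree_B.json and
    manifest.json into ``output_dir``.
    """
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    overrides = parse_config_file(config_path) if config_path else {}
    if seed is not None:
        overrides["seed"] = seed
    alpha = overrides.get("alpha", alpha)
    min_node_size = overrides.get("min_node_size", min_node_size)
    horizon = overrides.get("horizon", horizon)
    if variant == "both":
        variant = overrides.get("variant", "both")

    cohort_cfg = make_cohort_config(overrides)
    config_blob = json.dumps(
        {
            "cohort": repr(cohort_cfg),
            "alpha": alpha,
            "min_node_size": min_node_size,
            "horizon": horizon,
            "variant": variant,
            "input_dir": str(input_dir) if input_dir else "simulate",
        },
        sort_keys=True,
    )
    manifest = RunManifest(
        seed=cohort_cfg.seed,
        config_hash=hashlib.sha256(config_blob.encode()).hexdigest(),
        tool_version=__version__,
        started_at=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    outputs: list[Path] = []
    try:
        # --- stage: cohort
        if input_dir is None:
            cohort = generate_cohort(cohort_cfg)
            outputs += write_cohort(cohort, output_dir)
        else:
            for name in (PATIENTS_FILE, VISITS_FILE, RELAPSES_FILE):
                manifest.input_digests[name] = _sha256(Path(input_dir) / name)
            cohort = read_cohort(input_dir)
        manifest.stage_counts["cohort"] = {"n_subjects": len(cohort)}

        # --- stage: endpoints
        tables = {kind: endpoint_table(cohort, kind, horizon) for kind in ENDPOINT_KINDS}
        endpoints_long = pd.concat(tables.values(), ignore_index=True)
        outputs.append(write_endpoints(endpoints_long, output_dir))
        manifest.stage_counts["endpoints"] = {
            kind: {"rows": len(t), "events": int(t["event"].sum())}
            for kind, t in tables.items()
        }

        # --- stage: baseline table
        patients_df = tables["cDAF"].drop(columns=["time", "event", "censoring_reason"])
        table1 = table1_report(patients_df)
        table1_path = output_dir / "table1.csv"
        table1.to_csv(table1_path, index=False, float_format=_FLOAT_FMT)
        outputs.append(table1_path)
        manifest.stage_counts["table1"] = {"rows": len(table1)}

        # --- stage: survival analyses
        curves = {}
        fits = {}
        for kind, t in tables.items():
            d_all = SurvivalDataset(
                t["time"].to_numpy(), t["event"].to_numpy(),
                t.drop(columns=["time", "event"]).reset_index(drop=True),
            )
            curves[f"{kind}|all"] = km_estimate(d_all)
            for label, value in (("mono", 0), ("poly", 1)):
                sub = d_all.subset(d_all.covariates["poly_index"].to_numpy() == value)
                if len(sub):
                    curves[f"{kind}|{label}"] = km_estimate(sub)
            fits[kind] = _univariate_fits(t, kind)
        km_frame = km_table(curves)
        km_frame.insert(0, "endpoint", km_frame["group"].str.split("|").str[0])
        km_frame["group"] = km_frame["group"].str.split("|").str[1]
        km_path = output_dir / "km_curves.csv"
        km_frame.to_csv(km_path, index=False, float_format=_FLOAT_FMT)
        outputs.append(km_path)
        fits_path = output_dir / "fits.json"
        fits_path.write_text(json.dumps(fits, indent=2, sort_keys=True))
        outputs.append(fits_path)
        manifest.stage_counts["survival"] = {"curves": len(curves)}

        # --- stage: CART
        cdaf = tables["cDAF"]
        d_cdaf = SurvivalDataset(
            cdaf["time"].to_numpy(), cdaf["event"].to_numpy(),
            cdaf.drop(columns=["time", "event"]).reset_index(drop=True),
        )
        variants = ("A", "B") if variant == "both" else (variant,)
        for var in variants:
            cfg = CartConfig(
                alpha=alpha, min_node_size=min_node_size, model_variant=var, horizon=horizon
            )
            tree = build_tree(d_cdaf, cfg)
            tree_path = output_dir / f"tree_{var}.json"
            tree_path.write_text(render_tree(tree))
            outputs.append(tree_path)
            manifest.stage_counts[f"cart_{var}"] = {
                "leaves": tree.n_leaves, "depth": tree.depth
            }
    except Exception as exc:
        manifest.failed_stage = f"{type(exc).__name__}: {exc}"
        raise
    finally:
        for path in outputs:
            manifest.output_digests[path.name] = _sha256(path)
        manifest.finished_at = time.strftime("%Y-%m-%dT%H:%M:%S")
        (output_dir / "manifest.json").write_text(manifest.to_json())
    return manifest
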