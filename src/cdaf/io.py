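"""Delimited-text persistence for cohorts and derived endpoints.

Three comma-separated UTF-8 tables with header rows describe a cohort:

* ``patients.csv`` — one row per subject: baseline covariates and the
  termination month (empty when the subject completed follow-up);
* ``visits.csv`` — subject id, visit month, EDSS, and the eight KFS grades;
* ``relapses.csv`` — subject id, onset month relative to baseline (negative
  for the pre-baseline index relapse), per-system grade increases, and the
  three qualifying-context flags.

Endpoints are written to ``endpoints.csv`` (subject id, endpoint kind, time,
event, censoring reason).
"""

from __future__ import annotations

import math
from pathlib import Path

import pandas as pd

from .records import KFS_SYSTEMS, KFSProfile, PatientRecord, RelapseEvent, Visit

PATIENTS_FILE = "patients.csv"
VISITS_FILE = "visits.csv"
RELAPSES_FILE = "relapses.csv"
ENDPOINTS_FILE = "endpoints.csv"

_FLOAT_FMT = "%.6g"


def cohort_frames(cohort: list[PatientRecord]) -> dict[str, pd.DataFrame]:
    """The three-table relational form of a cohort."""
    patients, visits, relapses = [], [], []
    for rec in cohort:
        patients.append(
            {
                "subject_id": rec.subject_id,
                "sex": rec.sex,
                "age_at_baseline": rec.age_at_baseline,
                "age_at_first_symptom": rec.age_at_first_symptom,
                "baseline_edss": rec.baseline_edss,
                "prior_dmt": rec.prior_dmt,
                "dmt_duration": rec.dmt_duration,
                "relapse_count_2y": rec.prebaseline_relapse_count_2y,
                "termination_month": rec.termination_month,
            }
        )
        for v in rec.visits:
            row = {"subject_id": rec.subject_id, "month": v.month, "edss": v.edss}
            row.update({f"kfs_{s}": v.kfs.score(s) for s in KFS_SYSTEMS})
            visits.append(row)
        for r in [rec.index_relapse, *rec.postbaseline_relapses]:
            row = {"subject_id": rec.subject_id, "onset_month": r.onset_month}
            row.update({f"delta_{s}": r.delta(s) for s in KFS_SYSTEMS})
            row.update(
                duration_gt_24h=int(r.duration_gt_24h),
                fever_or_infection=int(r.fever_or_infection),
                preceded_by_30d_stability=int(r.preceded_by_30d_stability),
            )
            relapses.append(row)
    return {
        PATIENTS_FILE: pd.DataFrame(patients),
        VISITS_FILE: pd.DataFrame(visits),
        RELAPSES_FILE: pd.DataFrame(relapses),
    }


def write_cohort(cohort: list[PatientRecord], directory: str | Path) -> list[Path]:
    """Write patients/visits/relapses CSVs; returns the paths written."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, frame in cohort_frames(cohort).items():
        path = directory / name
        frame.to_csv(path, index=False, float_format=_FLOAT_FMT)
        paths.append(path)
    return paths


def _relapse_from_row(row: pd.Series) -> RelapseEvent:
    deltas = {
        s: int(row[f"delta_{s}"]) for s in KFS_SYSTEMS if int(row[f"delta_{s}"]) > 0
    }
    return RelapseEvent(
        onset_month=float(row["onset_month"]),
        system_deltas=deltas,
        duration_gt_24h=bool(int(row["duration_gt_24h"])),
        fever_or_infection=bool(int(row["fever_or_infection"])),
        preceded_by_30d_stability=bool(int(row["preceded_by_30d_stability"])),
    )


def read_cohort(directory: str | Path) -> list[PatientRecord]:
    """Reconstruct a cohort from the three CSV tables.

    The index relapse is the latest pre-baseline relapse (negative onset).
    """
    directory = Path(directory)
    patients = pd.read_csv(directory / PATIENTS_FILE)
    visits = pd.read_csv(directory / VISITS_FILE)
    relapses = pd.read_csv(directory / RELAPSES_FILE)

    visits_by_subject = dict(tuple(visits.groupby("subject_id", sort=False)))
    relapses_by_subject = dict(tuple(relapses.groupby("subject_id", sort=False)))

    cohort = []
    for _, p in patients.iterrows():
        sid = p["subject_id"]
        vrows = visits_by_subject.get(sid)
        if vrows is None:
            raise ValueError(f"subject {sid} has no visits")
        vrows = vrows.sort_values("month")
        visit_list = [
            Visit(
                month=float(v["month"]),
                edss=float(v["edss"]),
                kfs=KFSProfile(**{s: int(v[f"kfs_{s}"]) for s in KFS_SYSTEMS}),
            )
            for _, v in vrows.iterrows()
        ]
        rrows = relapses_by_subject.get(sid)
        pre, post = [], []
        if rrows is not None:
            for _, r in rrows.sort_values("onset_month").iterrows():
                ev = _relapse_from_row(r)
                (pre if ev.onset_month < 0 else post).append(ev)
        if not pre:
            raise ValueError(f"subject {sid} has no pre-baseline index relapse")
        term = p["termination_month"]
        cohort.append(
            PatientRecord(
                subject_id=str(sid),
                sex=str(p["sex"]),
                age_at_baseline=float(p["age_at_baseline"]),
                age_at_first_symptom=float(p["age_at_first_symptom"]),
                baseline_edss=float(p["baseline_edss"]),
                baseline_kfs=visit_list[0].kfs,
                prior_dmt=str(p["prior_dmt"]),
                dmt_duration=float(p["dmt_duration"]),
                prebaseline_relapse_count_2y=int(p["relapse_count_2y"]),
                index_relapse=pre[-1],
                visits=visit_list,
                postbaseline_relapses=post,
                termination_month=None if (term is None or (isinstance(term, float) and math.isnan(term))) else float(term),
            )
        )
    return cohort


def write_endpoints(frame: pd.DataFrame, directory: str | Path) -> Path:
    path = Path(directory) / ENDPOINTS_FILE
    cols = ["subject_id", "endpoint_kind", "time", "event", "censoring_reason"]
    frame[cols].to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path
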