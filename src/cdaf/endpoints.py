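"""Clinical endpoint rules for the cDAF analysis.

Encodes the study rules for a qualifying relapse, the mono- vs polysymptomatic
index-relapse phenotype, the dominant symptom and most-affected KFS categories,
sustained (3-month confirmed) disability progression, and the construction of
the three time-to-event endpoints:

* ``relapse_free`` — time to first post-baseline qualifying relapse,
* ``progression_free`` — time to confirmed >= 1.0-point EDSS increase,
* ``cDAF`` (clinical disease activity-free) — time to whichever comes first.

Subjects without an event are censored at the earlier of early termination,
their last assessment and the analysis horizon.
"""

from __future__ import annotations

from typing import TYPE_CHECKING, Optional

import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .survival import SurvivalDataset

from .records import (
    INDEX_SYSTEMS,
    KFS_SYSTEMS,
    QUALIFYING_SYSTEMS,
    TIE_PRIORITY,
    UNKNOWN_SCORE,
    EndpointOutcome,
    KFSProfile,
    PatientRecord,
    RelapseEvent,
)

ENDPOINT_KINDS = ("cDAF", "relapse_free", "progression_free")

#: Nominal scheduled visit months after baseline.
VISIT_SCHEDULE = (6.0, 12.0, 18.0, 24.0)

#: The protocol's visit time window: four weeks, in months.
VISIT_WINDOW_MONTHS = 28.0 / 30.4375

#: EDSS increase from baseline that defines disability progression.
PROGRESSION_EDSS_DELTA = 1.0

#: Months between a progression visit and its confirmation visit.
CONFIRMATION_LAG_MONTHS = 3.0

#: Categories reported for the most-affected baseline KFS; low-frequency
#: systems (brainstem, bowel/bladder, cerebral/mental, other) are pooled.
MOST_AFFECTED_CATEGORIES = ("pyramidal", "sensory", "cerebellar", "visual", "others")
_POOLED_AS_OTHERS = frozenset({"brainstem", "bowel_bladder", "cerebral_mental", "other"})


class ClassificationError(ValueError):
    """A relapse or KFS profile does not admit the requested classification."""


class MalformedRecordError(ValueError):
    """A patient record violates an assumption of endpoint derivation."""


def is_qualifying_relapse(r: RelapseEvent) -> bool:
    """Apply the study's qualifying-relapse rule.

    A relapse qualifies when symptoms last > 24 h, are preceded by >= 30 days
    of clinical stability, occur without concurrent fever/infection, and
    produce either a 2-grade increase in at least one functional system or a
    1-grade increase in at least two — excluding bowel/bladder and
    cerebral/mental changes from both counts.
    """
    if not (r.duration_gt_24h and r.preceded_by_30d_stability and not r.fever_or_infection):
        return False
    deltas = [r.delta(s) for s in QUALIFYING_SYSTEMS]
    return max(deltas) >= 2 or sum(d >= 1 for d in deltas) >= 2


def classify_index_relapse(r: RelapseEvent) -> str:
    """Phenotype the index relapse as ``"mono"`` or ``"poly"``.

    Counts the core systems (pyramidal, cerebellar, brainstem, sensory/pain,
    visual/optic) with any grade increase; bowel/bladder or cerebral/mental
    accompaniment never changes the phenotype.
    """
    n_affected = sum(r.delta(s) >= 1 for s in INDEX_SYSTEMS)
    if n_affected == 0:
        raise ClassificationError(
            "index relapse affects no core functional system "
            "(only bowel/bladder, cerebral/mental or 'other' changes)"
        )
    return "mono" if n_affected == 1 else "poly"


def _priority_argmax(scores: dict[str, int]) -> str:
    """Argmax over a system->score map with the fixed tie-break priority."""
    best = max(scores.values())
    for system in TIE_PRIORITY:
        if scores.get(system) == best:
            return system
    raise AssertionError("unreachable: empty score map")


def most_affected_kfs(p: KFSProfile) -> str:
    """Most-affected baseline KFS category.

    The system with the highest grade wins (grade 9 = unknown is ignored);
    ties are broken by a fixed priority order standing in for the study's
    investigator arbitration.  Brainstem, bowel/bladder, cerebral/mental and
    "other" are pooled into ``"others"``.
    """
    scores = {s: p.score(s) for s in KFS_SYSTEMS if p.score(s) != UNKNOWN_SCORE}
    if not scores:
        raise ClassificationError("all KFS scores unknown (9); most-affected KFS undefined")
    system = _priority_argmax(scores)
    return "others" if system in _POOLED_AS_OTHERS else system


def dominant_symptom(r: RelapseEvent) -> str:
    """Dominant symptom of the index relapse: the core system with the
    largest grade increase, ties broken by the fixed priority order."""
    deltas = {s: r.delta(s) for s in INDEX_SYSTEMS}
    if max(deltas.values()) < 1:
        raise ClassificationError("relapse affects no core functional system")
    return _priority_argmax(deltas)


def _is_scheduled(month: float) -> bool:
    return any(abs(month - m) <= VISIT_WINDOW_MONTHS for m in VISIT_SCHEDULE)


def derive_progression_time(rec: PatientRecord) -> Optional[float]:
    """Month of the earliest confirmed disability progression, if any.

    Progression is an EDSS increase of >= 1.0 point over baseline observed at
    a scheduled visit and sustained at a confirmation assessment three months
    later (within the protocol's four-week window).  An unconfirmed increase
    — confirmation visit missing, or back below the threshold — is not an
    event.
    """
    baseline = rec.visit_at(0.0)
    if baseline is None:
        raise MalformedRecordError(f"{rec.subject_id}: no baseline visit")
    for visit in rec.visits:
        if visit.month <= 0 or not _is_scheduled(visit.month):
            continue
        if visit.edss - baseline.edss < PROGRESSION_EDSS_DELTA:
            continue
        target = visit.month + CONFIRMATION_LAG_MONTHS
        for conf in rec.visits:
            if conf.month <= visit.month:
                continue
            if abs(conf.month - target) <= VISIT_WINDOW_MONTHS:
                if conf.edss - baseline.edss >= PROGRESSION_EDSS_DELTA:
                    return visit.month
                break  # confirmation assessed but below threshold
    return None


def first_relapse_time(rec: PatientRecord) -> Optional[float]:
    """Onset month of the first post-baseline qualifying relapse, if any."""
    times = [
        r.onset_month
        for r in rec.postbaseline_relapses
        if r.onset_month > 0 and is_qualifying_relapse(r)
    ]
    return min(times) if times else None


def derive_endpoint(rec: PatientRecord, kind: str, horizon: float = 24.0) -> EndpointOutcome:
    """Derive one time-to-event outcome for one subject.

    ``cDAF`` is the composite: the earlier of the first qualifying relapse
    and confirmed progression.  With no event by the horizon the subject is
    censored at min(termination month, last visit month, horizon).
    """
    if kind not in ENDPOINT_KINDS:
        raise ValueError(f"unknown endpoint kind {kind!r}; expected one of {ENDPOINT_KINDS}")
    if horizon <= 0:
        raise ValueError("horizon must be > 0")
    post_visits = [v for v in rec.visits if v.month > 0]
    if not post_visits:
        raise MalformedRecordError(f"{rec.subject_id}: no post-baseline visits")

    candidates: list[float] = []
    if kind in ("cDAF", "relapse_free"):
        t = first_relapse_time(rec)
        if t is not None:
            candidates.append(t)
    if kind in ("cDAF", "progression_free"):
        t = derive_progression_time(rec)
        if t is not None:
            candidates.append(t)
    event_time = min(candidates) if candidates else None

    if event_time is not None and event_time <= horizon:
        return EndpointOutcome(endpoint_kind=kind, time=event_time, event=True)

    last_visit = max(v.month for v in post_visits)
    censor_time = min(
        horizon,
        last_visit,
        rec.termination_month if rec.termination_month is not None else float("inf"),
    )
    reason = (
        "early_termination"
        if rec.termination_month is not None and rec.termination_month <= censor_time < horizon
        else "end_of_observation"
    )
    return EndpointOutcome(endpoint_kind=kind, time=censor_time, event=False, censoring_reason=reason)


def covariate_row(rec: PatientRecord) -> dict:
    """Baseline covariates for one subject, as used by the survival stages."""
    return {
        "subject_id": rec.subject_id,
        "sex": rec.sex,
        "female": 1 if rec.sex == "F" else 0,
        "age_at_baseline": rec.age_at_baseline,
        "age_at_first_symptom": rec.age_at_first_symptom,
        "disease_duration": rec.disease_duration,
        "baseline_edss": rec.baseline_edss,
        "prior_dmt": rec.prior_dmt,
        "dmt_duration": rec.dmt_duration,
        "relapse_count_2y": rec.prebaseline_relapse_count_2y,
        "index_phenotype": classify_index_relapse(rec.index_relapse),
        "poly_index": 1 if classify_index_relapse(rec.index_relapse) == "poly" else 0,
        "dominant_symptom": dominant_symptom(rec.index_relapse),
        "most_affected_kfs": most_affected_kfs(rec.baseline_kfs),
    }


def endpoint_table(
    cohort: list[PatientRecord], kind: str, horizon: float = 24.0
) -> pd.DataFrame:
    """Per-subject (time, event, covariates) table for one endpoint.

    This is the join of the derived outcomes with the baseline covariates
    that the Kaplan-Meier, Cox and CART stages operate on.
    """
    rows = []
    for rec in cohort:
        out = derive_endpoint(rec, kind, horizon)
        row = covariate_row(rec)
        row.update(
            endpoint_kind=kind,
            time=out.time,
            event=int(out.event),
            censoring_reason=out.censoring_reason or "",
        )
        rows.append(row)
    return pd.DataFrame(rows)


def endpoint_dataset(
    cohort: list[PatientRecord], kind: str, horizon: float = 24.0
) -> "SurvivalDataset":
    """Endpoint table packaged as a :class:`~cdaf.survival.SurvivalDataset`."""
    from .survival import SurvivalDataset

    table = endpoint_table(cohort, kind, horizon)
    return SurvivalDataset(
        table["time"].to_numpy(),
        table["event"].to_numpy(),
        table.drop(columns=["time", "event"]).reset_index(drop=True),
    )
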