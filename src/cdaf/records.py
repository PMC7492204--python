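"""Domain records for an RRMS treatment-switch cohort.

The unit of analysis is one subject followed for up to 24 months after a
change to high-dose subcutaneous interferon beta-1a: baseline covariates, the
pre-baseline ("index") relapse, scheduled visits with EDSS and the eight
Kurtzke functional-system (KFS) grades, and post-baseline relapse events.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

#: The eight Kurtzke functional systems, in the fixed order used throughout.
KFS_SYSTEMS = (
    "pyramidal",
    "cerebellar",
    "brainstem",
    "sensory",
    "bowel_bladder",
    "visual",
    "cerebral_mental",
    "other",
)

#: Systems whose worsening can qualify a relapse (bowel/bladder and
#: cerebral/mental changes never qualify on their own).
QUALIFYING_SYSTEMS = (
    "pyramidal",
    "cerebellar",
    "brainstem",
    "sensory",
    "visual",
    "other",
)

#: Systems counted when phenotyping the index relapse as mono- vs
#: polysymptomatic (the five "core" neurological domains).
INDEX_SYSTEMS = ("pyramidal", "cerebellar", "brainstem", "sensory", "visual")

#: Deterministic tie-break priority for argmax rules (highest priority first).
#: Stands in for the study's investigator arbitration of ties.
TIE_PRIORITY = (
    "pyramidal",
    "cerebellar",
    "brainstem",
    "sensory",
    "visual",
    "bowel_bladder",
    "cerebral_mental",
    "other",
)

#: Prior disease-modifying therapies (the four platform injectables).
DMT_CATEGORIES = ("sc-IFNb-1a-22", "im-IFNb-1a", "glatiramer", "sc-IFNb-1b")

UNKNOWN_SCORE = 9


@dataclass(frozen=True)
class KFSProfile:
    """Grades for the eight Kurtzke functional systems at one assessment.

    Each grade is an integer in 0..6; 9 encodes "unknown".
    """

    pyramidal: int = 0
    cerebellar: int = 0
    brainstem: int = 0
    sensory: int = 0
    bowel_bladder: int = 0
    visual: int = 0
    cerebral_mental: int = 0
    other: int = 0

    def __post_init__(self) -> None:
        for name in KFS_SYSTEMS:
            score = getattr(self, name)
            if not (0 <= score <= 6 or score == UNKNOWN_SCORE):
                raise ValueError(
                    f"KFS score for {name!r} must be in 0..6 or 9 (unknown), got {score}"
                )

    def score(self, system: str) -> int:
        return getattr(self, system)

    def as_dict(self) -> dict[str, int]:
        return {name: getattr(self, name) for name in KFS_SYSTEMS}


@dataclass(frozen=True)
class RelapseEvent:
    """One relapse: onset time and the per-system grade increases.

    ``onset_month`` is months from baseline; negative for pre-baseline
    relapses (the index relapse).  The three flags capture the qualifying
    rule's clinical context: symptom duration beyond 24 h, absence of
    concurrent fever/infection, and at least 30 days of preceding stability.
    """

    onset_month: float
    system_deltas: dict[str, int] = field(default_factory=dict)
    duration_gt_24h: bool = True
    fever_or_infection: bool = False
    preceded_by_30d_stability: bool = True

    def __post_init__(self) -> None:
        for name, delta in self.system_deltas.items():
            if name not in KFS_SYSTEMS:
                raise ValueError(f"unknown functional system {name!r}")
            if delta < 0:
                raise ValueError(f"system delta for {name!r} must be >= 0, got {delta}")

    def delta(self, system: str) -> int:
        return self.system_deltas.get(system, 0)


@dataclass(frozen=True)
class Visit:
    """A scheduled (or confirmation) assessment: month, EDSS, KFS grades."""

    month: float
    edss: float
    kfs: KFSProfile

    def __post_init__(self) -> None:
        if self.edss < 0 or self.edss > 10 or round(self.edss * 2) != self.edss * 2:
            raise ValueError(f"EDSS must be on the 0-10 half-point grid, got {self.edss}")


@dataclass
class PatientRecord:
    """One subject's baseline covariates and longitudinal event stream."""

    subject_id: str
    sex: str  # "F" / "M"
    age_at_baseline: float
    age_at_first_symptom: float
    baseline_edss: float
    baseline_kfs: KFSProfile
    prior_dmt: str
    dmt_duration: float
    prebaseline_relapse_count_2y: int
    index_relapse: RelapseEvent
    visits: list[Visit] = field(default_factory=list)
    postbaseline_relapses: list[RelapseEvent] = field(default_factory=list)
    termination_month: Optional[float] = None

    def __post_init__(self) -> None:
        if self.prior_dmt not in DMT_CATEGORIES:
            raise ValueError(f"prior_dmt must be one of {DMT_CATEGORIES}, got {self.prior_dmt!r}")
        if self.prebaseline_relapse_count_2y < 1:
            raise ValueError("eligibility requires >= 1 pre-baseline relapse")
        if self.baseline_edss > 6.5:
            raise ValueError("eligibility requires baseline EDSS <= 6.5")
        months = [v.month for v in self.visits]
        if months:
            if months[0] != 0:
                raise ValueError("baseline visit at month 0 must be first")
            if any(b <= a for a, b in zip(months, months[1:])):
                raise ValueError("visit months must be strictly increasing")

    @property
    def disease_duration(self) -> float:
        """Years from first MS symptom to baseline."""
        return self.age_at_baseline - self.age_at_first_symptom

    def visit_at(self, month: float) -> Optional[Visit]:
        for v in self.visits:
            if v.month == month:
                return v
        return None

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class EndpointOutcome:
    """A derived time-to-event outcome for one subject and one endpoint."""

    endpoint_kind: str  # "cDAF" | "relapse_free" | "progression_free"
    time: float
    event: bool
    censoring_reason: Optional[str] = None  # "end_of_observation" | "early_termination"

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise ValueError(f"endpoint time must be > 0, got {self.time}")
        if self.event and self.censoring_reason is not None:
            raise ValueError("event and censoring_reason are mutually exclusive")
        if not self.event and self.censoring_reason is None:
            raise ValueError("censored outcomes must carry a censoring_reason")
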