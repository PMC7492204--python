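import pytest

from cdaf.records import KFSProfile, PatientRecord, RelapseEvent, Visit


def make_patient(
    subject_id="S0001",
    visits=None,
    postbaseline_relapses=None,
    termination_month=None,
    baseline_edss=2.0,
    index_deltas=None,
    relapse_count=1,
):
    """A minimal internally-consistent patient record for rule tests."""
    kfs = KFSProfile(pyramidal=2, sensory=1)
    if visits is None:
        visits = [Visit(m, baseline_edss, kfs) for m in (0.0, 6.0, 12.0, 18.0, 24.0)]
    return PatientRecord(
        subject_id=subject_id,
        sex="F",
        age_at_baseline=38.0,
        age_at_first_symptom=30.0,
        baseline_edss=baseline_edss,
        baseline_kfs=kfs,
        prior_dmt="glatiramer",
        dmt_duration=2.4,
        prebaseline_relapse_count_2y=relapse_count,
        index_relapse=RelapseEvent(-3.0, index_deltas or {"pyramidal": 2}),
        visits=visits,
        postbaseline_relapses=postbaseline_relapses or [],
        termination_month=termination_month,
    )


@pytest.fixture
def patient_factory():
    return make_patient
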