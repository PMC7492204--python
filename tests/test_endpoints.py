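"""Clinical endpoint rules: qualifying relapse, phenotype, progression, cDAF."""

import itertools

import pytest

from cdaf.endpoints import (
    ClassificationError,
    MalformedRecordError,
    classify_index_relapse,
    derive_endpoint,
    derive_progression_time,
    dominant_symptom,
    is_qualifying_relapse,
    most_affected_kfs,
)
from cdaf.records import (
    INDEX_SYSTEMS,
    KFS_SYSTEMS,
    TIE_PRIORITY,
    KFSProfile,
    RelapseEvent,
    Visit,
)
from tests.conftest import make_patient


def relapse(deltas, **flags):
    return RelapseEvent(onset_month=1.0, system_deltas=deltas, **flags)


class TestQualifyingRelapse:
    @pytest.mark.parametrize(
        "deltas,flags,expected",
        [
            ({"pyramidal": 2}, {}, True),  # 2-grade increase in one system
            ({"sensory": 1, "visual": 1}, {}, True),  # 1-grade in two systems
            ({"sensory": 1}, {}, False),  # 1-grade in only one system
            ({"bowel_bladder": 2, "cerebral_mental": 1}, {}, False),  # excluded systems only
            ({"pyramidal": 2}, {"fever_or_infection": True}, False),
            ({"pyramidal": 2}, {"duration_gt_24h": False}, False),
            ({"pyramidal": 2}, {"preceded_by_30d_stability": False}, False),
            ({"other": 2}, {}, True),  # "other" counts; only bowel/cerebral excluded
            ({"bowel_bladder": 2, "sensory": 1, "visual": 1}, {}, True),
        ],
    )
    def test_rule(self, deltas, flags, expected):
        assert is_qualifying_relapse(relapse(deltas, **flags)) is expected


class TestIndexPhenotype:
    @pytest.mark.parametrize(
        "deltas,expected",
        [
            ({"pyramidal": 2}, "mono"),
            ({"pyramidal": 1, "cerebellar": 1}, "poly"),
            # bowel/bladder and cerebral/mental accompaniment never flips mono
            ({"visual": 2, "bowel_bladder": 1, "cerebral_mental": 1}, "mono"),
            ({"sensory": 2, "brainstem": 1, "visual": 1}, "poly"),
        ],
    )
    def test_classification(self, deltas, expected):
        assert classify_index_relapse(relapse(deltas)) == expected

    def test_excluded_systems_only_is_an_error(self):
        with pytest.raises(ClassificationError):
            classify_index_relapse(relapse({"bowel_bladder": 2}))


class TestMostAffectedKFS:
    def test_unique_argmax(self):
        assert most_affected_kfs(KFSProfile(pyramidal=3, sensory=2, visual=1)) == "pyramidal"

    def test_low_frequency_systems_pool_to_others(self):
        assert most_affected_kfs(KFSProfile(brainstem=4, pyramidal=2)) == "others"
        assert most_affected_kfs(KFSProfile(bowel_bladder=3)) == "others"

    def test_unknown_scores_ignored(self):
        assert most_affected_kfs(KFSProfile(pyramidal=9, sensory=2)) == "sensory"

    def test_all_unknown_is_error(self):
        with pytest.raises(ClassificationError):
            most_affected_kfs(KFSProfile(**{s: 9 for s in KFS_SYSTEMS}))

    def test_two_way_ties_follow_fixed_priority(self):
        # exhaustive two-way tie enumeration: the higher-priority system wins
        for a, b in itertools.combinations(KFS_SYSTEMS, 2):
            profile = KFSProfile(**{a: 2, b: 2})
            winner = a if TIE_PRIORITY.index(a) < TIE_PRIORITY.index(b) else b
            expected = (
                "others"
                if winner in ("brainstem", "bowel_bladder", "cerebral_mental", "other")
                else winner
            )
            assert most_affected_kfs(profile) == expected, (a, b)


class TestDominantSymptom:
    def test_unique_argmax(self):
        assert dominant_symptom(relapse({"sensory": 2, "pyramidal": 1})) == "sensory"
        assert dominant_symptom(relapse({"visual": 2})) == "visual"

    def test_ties_follow_fixed_priority(self):
        for a, b in itertools.combinations(INDEX_SYSTEMS, 2):
            winner = a if TIE_PRIORITY.index(a) < TIE_PRIORITY.index(b) else b
            assert dominant_symptom(relapse({a: 1, b: 1})) == winner, (a, b)

    def test_excluded_systems_do_not_dominate(self):
        assert dominant_symptom(relapse({"bowel_bladder": 3, "sensory": 1, "visual": 1})) == "sensory"


def visits_with_edss(pairs, kfs=KFSProfile(pyramidal=2)):
    return [Visit(m, e, kfs) for m, e in pairs]


class TestProgression:
    def test_confirmed_increase(self):
        rec = make_patient(
            visits=visits_with_edss([(0, 2.0), (6, 2.0), (12, 3.0), (15, 3.0), (18, 3.0), (24, 3.0)])
        )
        assert derive_progression_time(rec) == 12

    def test_unconfirmed_increase_is_not_progression(self):
        rec = make_patient(
            visits=visits_with_edss([(0, 2.0), (6, 2.0), (12, 3.0), (15, 2.0), (18, 2.0), (24, 2.0)])
        )
        assert derive_progression_time(rec) is None

    def test_missing_confirmation_visit_is_not_progression(self):
        rec = make_patient(visits=visits_with_edss([(0, 2.0), (6, 2.0), (12, 3.0)]))
        assert derive_progression_time(rec) is None

    def test_below_threshold_increase(self):
        rec = make_patient(
            visits=visits_with_edss([(0, 2.0), (6, 2.5), (12, 2.5), (18, 2.5), (24, 2.5)])
        )
        assert derive_progression_time(rec) is None

    def test_deleting_confirmation_always_removes_progression(self):
        rec = make_patient(
            visits=visits_with_edss([(0, 2.0), (6, 2.0), (12, 3.0), (15, 3.0), (18, 3.0), (24, 3.0)])
        )
        m = derive_progression_time(rec)
        assert m == 12
        # drop the confirmation assessment at m+3
        pruned = make_patient(visits=[v for v in rec.visits if v.month != 15.0])
        # the later scheduled visit at 18 is outside the 4-week confirmation
        # window of month 15, so progression at 12 is no longer confirmed;
        # 18 itself then confirms at no later visit within window
        assert derive_progression_time(pruned) is None


def qualifying_at(month):
    return RelapseEvent(onset_month=month, system_deltas={"pyramidal": 2})


class TestDeriveEndpoint:
    def test_relapse_only_cdaf(self):
        rec = make_patient(postbaseline_relapses=[qualifying_at(8.0)])
        out = derive_endpoint(rec, "cDAF")
        assert (out.time, out.event) == (8.0, True)

    def test_cdaf_is_min_of_components(self):
        rec = make_patient(
            visits=visits_with_edss([(0, 2.0), (6, 3.0), (9, 3.0), (12, 3.0), (18, 3.0), (24, 3.0)]),
            postbaseline_relapses=[qualifying_at(10.0)],
        )
        assert derive_endpoint(rec, "progression_free").time == 6.0
        assert derive_endpoint(rec, "relapse_free").time == 10.0
        out = derive_endpoint(rec, "cDAF")
        assert (out.time, out.event) == (6.0, True)

    def test_censoring_at_early_termination(self):
        rec = make_patient(
            visits=visits_with_edss([(0, 2.0), (6, 2.0), (12, 2.0), (16, 2.0)]),
            termination_month=16.0,
        )
        out = derive_endpoint(rec, "cDAF")
        assert (out.time, out.event, out.censoring_reason) == (16.0, False, "early_termination")

    def test_censoring_at_end_of_observation(self):
        out = derive_endpoint(make_patient(), "cDAF")
        assert (out.time, out.event, out.censoring_reason) == (24.0, False, "end_of_observation")

    def test_nonqualifying_relapse_does_not_count(self):
        rec = make_patient(
            postbaseline_relapses=[
                RelapseEvent(5.0, {"pyramidal": 2}, fever_or_infection=True)
            ]
        )
        assert derive_endpoint(rec, "relapse_free").event is False

    def test_event_after_horizon_censors_at_horizon(self):
        rec = make_patient(postbaseline_relapses=[qualifying_at(30.0)])
        out = derive_endpoint(rec, "cDAF", horizon=24.0)
        assert (out.time, out.event) == (24.0, False)

    def test_adding_relapse_never_increases_cdaf_time(self):
        base = make_patient(postbaseline_relapses=[qualifying_at(14.0)])
        t0 = derive_endpoint(base, "cDAF").time
        for extra in (2.0, 10.0, 20.0):
            rec = make_patient(postbaseline_relapses=[qualifying_at(14.0), qualifying_at(extra)])
            assert derive_endpoint(rec, "cDAF").time <= t0

    def test_no_postbaseline_visits_is_malformed(self):
        rec = make_patient(visits=visits_with_edss([(0, 2.0)]))
        with pytest.raises(MalformedRecordError):
            derive_endpoint(rec, "cDAF")
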