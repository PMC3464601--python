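"""Episode extraction and the six incident-case selection algorithms."""

from __future__ import annotations

import pandas as pd
import pytest

from hddlink.selection import (
    extract_fall_injury_episodes,
    hip_fracture_filter,
    scenario_spec,
    select_reference_standard,
    select_unlinked_scenario,
)
from hddlink.synthetic import simulate_cohort

from conftest import degenerate_config


def ep(i, **kw):
    row = dict(
        episode_id=i, hospital_id="H001", hospital_sector="public",
        hospital_patient_id="H001-000001", admission_date="2006-01-10",
        discharge_date="2006-01-20", age_at_admission=80, sex="F",
        admission_source="private_residence", care_type="acute",
        admission_category="emergency", discharge_status="home",
        principal_diagnosis="S72.0", additional_diagnoses="",
        ext_mechanism="W01", ext_place="Y92.0", ext_activity="U73.1",
        procedure_codes="47519-00",
    )
    row.update(kw)
    return row


class TestExtraction:
    def test_extraction_criteria(self, tiny_episode_frame):
        kept = extract_fall_injury_episodes(tiny_episode_frame)
        assert kept["episode_id"].tolist() == [1, 4]

    def test_malformed_codes_excluded_not_fatal(self):
        df = pd.DataFrame(
            [dict(episode_id=1, ext_mechanism="??", principal_diagnosis="S72.0",
                  age_at_admission=70),
             dict(episode_id=2, ext_mechanism="W01", principal_diagnosis=None,
                  age_at_admission=70)]
        )
        assert len(extract_fall_injury_episodes(df)) == 0

    @pytest.mark.parametrize(
        "dx,kept",
        [("S72.1", True), ("S72.04", True), ("S72.3", False), ("S71.9", False),
         ("S72.9", False)],
    )
    def test_hip_fracture_boundary(self, dx, kept):
        df = pd.DataFrame([ep(1, principal_diagnosis=dx)])
        assert (len(hip_fracture_filter(df)) == 1) is kept


class TestScenarioSpecs:
    def test_shipped_flag_bundles(self):
        base = scenario_spec("base")
        assert base.exclude_inhospital_death and base.exclude_readmit_30d
        assert not (base.exclude_readmit_120d or base.exclude_revision_only
                    or base.exclude_nonacute or base.exclude_nonemergency)
        s1 = scenario_spec("S1")
        assert s1.exclude_readmit_30d and not s1.exclude_inhospital_death
        s2 = scenario_spec("S2")
        assert (s2.exclude_inhospital_death and s2.exclude_readmit_30d
                and s2.exclude_readmit_120d and not s2.exclude_revision_only)
        s3, s4 = scenario_spec("S3"), scenario_spec("S4")
        for s in (s3, s4):
            assert (s.exclude_readmit_120d and s.exclude_revision_only
                    and s.exclude_nonacute and s.exclude_nonemergency)
        assert s3.exclude_inhospital_death and not s4.exclude_inhospital_death
        ref = scenario_spec("reference")
        assert ref.use_person_linkage and ref.use_external_cause_rule
        assert not ref.exclude_inhospital_death

    def test_unknown_scenario_lists_shipped_names(self):
        with pytest.raises(KeyError, match="S1"):
            scenario_spec("S9")


class TestUnlinkedSelection:
    def test_inhospital_death_base_vs_s1(self):
        df = pd.DataFrame([ep(1, discharge_status="died_in_hospital")])
        _, base = select_unlinked_scenario(df, "base")
        _, s1 = select_unlinked_scenario(df, "S1")
        assert not base[1] and s1[1]

    def test_readmission_same_public_hospital_excluded(self):
        df = pd.DataFrame(
            [ep(1), ep(2, admission_date="2006-02-09", discharge_date="2006-02-15")]
        )  # readmitted 20 days after discharge, same hospital+patient id
        _, labels = select_unlinked_scenario(df, "base")
        assert labels[1] and not labels[2]

    def test_readmission_different_hospital_undetectable(self):
        df = pd.DataFrame(
            [ep(1), ep(2, admission_date="2006-02-09", discharge_date="2006-02-15",
                       hospital_id="H002", hospital_patient_id="H002-000009")]
        )
        _, labels = select_unlinked_scenario(df, "base")
        assert labels[1] and labels[2]

    def test_readmission_private_hospital_undetectable(self):
        df = pd.DataFrame(
            [ep(1, hospital_sector="private"),
             ep(2, admission_date="2006-02-09", discharge_date="2006-02-15",
                hospital_sector="private")]
        )
        _, labels = select_unlinked_scenario(df, "base")
        assert labels[1] and labels[2]

    def test_120d_window_only_under_s2(self):
        df = pd.DataFrame(
            [ep(1), ep(2, admission_date="2006-03-21", discharge_date="2006-03-25")]
        )  # 60-day gap: inside 120d window, outside 30d window
        _, base = select_unlinked_scenario(df, "base")
        _, s2 = select_unlinked_scenario(df, "S2")
        assert base[2] and not s2[2]

    def test_revision_only_excluded_under_s3_retained_under_base(self):
        df = pd.DataFrame([ep(1, procedure_codes="49324-00")])
        _, base = select_unlinked_scenario(df, "base")
        _, s3 = select_unlinked_scenario(df, "S3")
        assert base[1] and not s3[1]
        # revision plus fixation code is not "revision only"
        df2 = pd.DataFrame([ep(1, procedure_codes="49324-00;47519-00")])
        _, s3b = select_unlinked_scenario(df2, "S3")
        assert s3b[1]

    def test_transfer_in_episodes_fail_admission_source_inclusion(self):
        df = pd.DataFrame([ep(1, admission_source="transfer")])
        _, labels = select_unlinked_scenario(df, "S1")
        assert not labels[1]

    def test_label_completeness_and_idempotence(self):
        df = pd.DataFrame(
            [ep(1), ep(2, admission_date="2006-02-09", discharge_date="2006-02-15"),
             ep(3, hospital_patient_id="H001-000002", admission_date="2007-05-01",
                discharge_date="2007-05-10")]
        )
        inc, labels = select_unlinked_scenario(df, "base")
        assert set(labels.index) == {1, 2, 3}
        inc2, labels2 = select_unlinked_scenario(
            df[df["episode_id"].isin(inc["index_episode_id"])], "base"
        )
        assert sorted(inc2["index_episode_id"]) == sorted(inc["index_episode_id"])


class TestReferenceStandard:
    def assignment(self, df):
        return pd.Series(0, index=pd.Index(df["episode_id"], name="episode_id"))

    def test_admissions_90_days_apart_are_one_incident(self):
        df = pd.DataFrame(
            [ep(1), ep(2, admission_date="2006-04-20", discharge_date="2006-04-30",
                       ext_mechanism="W05", ext_place="Y92.2", ext_activity="U73.3")]
        )
        inc, labels = select_reference_standard(df, self.assignment(df))
        assert len(inc) == 1 and labels[1] and not labels[2]

    def test_clearance_met_and_triple_differs_two_incidents(self):
        df = pd.DataFrame(
            [ep(1), ep(2, admission_date="2006-12-21", discharge_date="2006-12-31",
                       ext_mechanism="W05", ext_place="Y92.2", ext_activity="U73.3")]
        )  # 335 days later, all three external-cause codes differ
        inc, labels = select_reference_standard(df, self.assignment(df))
        assert len(inc) == 2 and labels[2]

    def test_identical_triple_keeps_one_incident_despite_clearance(self):
        df = pd.DataFrame(
            [ep(1), ep(2, admission_date="2006-08-08", discharge_date="2006-08-18")]
        )  # 200 days later but identical mechanism/place/activity
        inc, _ = select_reference_standard(df, self.assignment(df))
        assert len(inc) == 1

    def test_partial_triple_difference_is_not_enough(self):
        df = pd.DataFrame(
            [ep(1), ep(2, admission_date="2006-12-21", discharge_date="2006-12-31",
                       ext_mechanism="W05")]  # place and activity unchanged
        )
        inc, _ = select_reference_standard(df, self.assignment(df))
        assert len(inc) == 1

    def test_external_cause_rule_switch(self):
        df = pd.DataFrame(
            [ep(1), ep(2, admission_date="2006-08-08", discharge_date="2006-08-18")]
        )
        inc, _ = select_reference_standard(
            df, self.assignment(df), use_external_cause_rule=False
        )
        assert len(inc) == 2

    def test_death_and_nonqualifying_episodes(self):
        df = pd.DataFrame(
            [ep(1, discharge_status="died_in_hospital"),
             ep(2, admission_date="2006-02-01", care_type="non_acute")]
        )
        inc, labels = select_reference_standard(df, self.assignment(df))
        assert labels[1] and not labels[2]  # death disregarded; non-acute not qualifying

    def test_unassigned_episode_raises(self):
        df = pd.DataFrame([ep(1)])
        with pytest.raises(ValueError, match="not assigned"):
            select_reference_standard(df, pd.Series(dtype=float))


class TestOracleAndMonotonicity:
    def test_degenerate_config_every_scenario_recovers_truth(self):
        cfg = degenerate_config(400)
        episodes, truth = simulate_cohort(cfg, 21)
        extracted = extract_fall_injury_episodes(episodes)
        assignment = truth.episodes.set_index("episode_id")["true_person_id"]
        true_index = set(
            truth.episodes.loc[
                truth.episodes["true_incident_event_id"].notna(), "episode_id"
            ]
        )
        inc_ref, _ = select_reference_standard(extracted, assignment)
        assert set(inc_ref["index_episode_id"]) == true_index
        for name in ("base", "S1", "S2", "S3", "S4"):
            inc, _ = select_unlinked_scenario(extracted, name)
            assert set(inc["index_episode_id"]) == true_index, name

    def test_reference_standard_recovers_true_community_events(self, big_sim):
        """On the true person partition with generator defaults honouring
        the clearance/external-cause assumptions, the reference selector
        identifies exactly the generator's community incident events."""
        _, episodes, truth = big_sim
        extracted = extract_fall_injury_episodes(episodes)
        assignment = truth.episodes.set_index("episode_id")["true_person_id"]
        inc, _ = select_reference_standard(extracted, assignment)
        community_events = truth.events[truth.events["community"]]
        index_eps = truth.episodes[
            truth.episodes["true_incident_event_id"].isin(community_events["event_id"])
        ]["episode_id"]
        assert set(inc["index_episode_id"]) == set(index_eps)

    def test_scenario_count_ordering(self, big_sim):
        _, episodes, _ = big_sim
        extracted = extract_fall_injury_episodes(episodes)
        counts = {
            name: len(select_unlinked_scenario(extracted, name)[0])
            for name in ("base", "S1", "S2", "S3", "S4")
        }
        assert counts["S1"] >= counts["base"] >= counts["S2"] >= counts["S3"]
        assert counts["S4"] >= counts["S3"]
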