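"""Comorbidity ascertainment, Charlson index and prevalence tables."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hddlink.comorbidity import (
    ComorbidityRecord,
    ascertain_comorbidities,
    charlson_index,
    load_code_map,
    parse_additional_diagnoses,
    prevalence_table,
    resolve_hierarchy,
    top_k_share,
)
from hddlink.config import CorruptionSpec, SimulationConfig
from hddlink.selection import extract_fall_injury_episodes, select_reference_standard
from hddlink.synthetic import simulate_cohort


@pytest.fixture(scope="module")
def code_map():
    return load_code_map()


def person_eps(rows):
    base = dict(
        episode_id=1, admission_date="2006-06-01", discharge_date="2006-06-10",
        additional_diagnoses="",
    )
    return pd.DataFrame([{**base, **r} for r in rows])


def incident(episode_id=1, admission="2006-06-01", person=0):
    return pd.Series(
        dict(index_episode_id=episode_id, person_id=person, admission_date=admission)
    )


class TestCharlsonIndex:
    def test_empty_set_scores_zero(self, code_map):
        assert charlson_index([], code_map) == 0

    def test_hand_summed_weights(self, code_map):
        # dementia (1) + congestive heart failure (1) = 2
        assert charlson_index(["dementia", "congestive_heart_failure"], code_map) == 2
        # renal (2) + metastatic cancer (6) = 8
        assert charlson_index(["renal_disease", "metastatic_cancer"], code_map) == 8

    def test_hierarchy_severer_form_wins(self, code_map):
        assert (
            charlson_index(["diabetes", "diabetes_with_complications"], code_map) == 2
        )
        assert (
            charlson_index(["cancer", "metastatic_cancer"], code_map) == 6
        )
        assert resolve_hierarchy({"mild_liver_disease", "moderate_severe_liver_disease"}) == {
            "moderate_severe_liver_disease"
        }

    def test_non_charlson_conditions_carry_no_weight(self, code_map):
        assert charlson_index(["osteoporosis", "delirium"], code_map) == 0

    def test_unknown_condition_rejected(self, code_map):
        with pytest.raises(KeyError):
            charlson_index(["gout"], code_map)


class TestAscertainment:
    def test_lookback_finds_condition_on_prior_episode(self, code_map):
        eps = person_eps(
            [
                dict(episode_id=9, admission_date="2005-09-01",
                     discharge_date="2005-09-05", additional_diagnoses="F00:P"),
                dict(episode_id=1),
            ]
        )
        with_lb = ascertain_comorbidities(incident(), eps, code_map, True)
        without = ascertain_comorbidities(incident(), eps, code_map, False)
        assert "dementia" in with_lb.present
        assert "dementia" not in without.present

    def test_hospital_acquired_codes_never_count(self, code_map):
        eps = person_eps([dict(additional_diagnoses="F05:A")])
        rec = ascertain_comorbidities(incident(), eps, code_map, True)
        assert "delirium" not in rec.present
        rec2 = ascertain_comorbidities(
            incident(), person_eps([dict(additional_diagnoses="F05:P")]), code_map, True
        )
        assert "delirium" in rec2.present

    def test_no_codes_anywhere_gives_empty_record(self, code_map):
        rec = ascertain_comorbidities(incident(), person_eps([{}]), code_map, True)
        assert rec.present == frozenset() and rec.charlson_index == 0

    def test_index_hospitalisation_is_first_multiday_record(self, code_map):
        # same-day index episode; the multiday transfer record carries codes
        eps = person_eps(
            [
                dict(episode_id=1, discharge_date="2006-06-01"),
                dict(episode_id=2, admission_date="2006-06-01",
                     discharge_date="2006-06-12", additional_diagnoses="I50:P"),
            ]
        )
        rec = ascertain_comorbidities(incident(), eps, code_map, False)
        assert "congestive_heart_failure" in rec.present

    def test_records_after_next_incident_not_searched(self, code_map):
        eps = person_eps(
            [
                dict(episode_id=1),
                dict(episode_id=2, admission_date="2007-06-01",
                     discharge_date="2007-06-10", additional_diagnoses="N18:P"),
            ]
        )
        rec = ascertain_comorbidities(
            incident(), eps, code_map, True,
            next_incident_admission=pd.Timestamp("2007-05-01"),
        )
        assert "renal_disease" not in rec.present

    def test_empty_code_map_rejected(self):
        from hddlink.comorbidity import CodeMap

        with pytest.raises(ValueError):
            ascertain_comorbidities(
                incident(), person_eps([{}]),
                CodeMap(prefixes={}, charlson={}, weight={}), True,
            )

    def test_onset_flag_parsing(self):
        assert parse_additional_diagnoses("E11.2:P;F05:A") == [
            ("E11.2", "P"), ("F05", "A")
        ]
        assert parse_additional_diagnoses(np.nan) == []


class TestPrevalenceTable:
    def rec(self, i, conds):
        return ComorbidityRecord(i, i, frozenset(conds), 0, 0)

    def test_universal_condition_scores_100(self, code_map):
        recs = [self.rec(i, ["dementia"]) for i in range(5)]
        tbl = prevalence_table(recs, code_map).set_index("condition")
        assert tbl.loc["dementia", "prevalence_pct"] == 100.0
        assert tbl.loc["any_charlson", "prevalence_pct"] == 100.0

    def test_wilson_interval_hand_computed(self, code_map):
        recs = [self.rec(i, ["renal_disease"] if i < 3 else []) for i in range(10)]
        tbl = prevalence_table(recs, code_map).set_index("condition")
        row = tbl.loc["renal_disease"]
        assert row["prevalence_pct"] == 30.0
        # independent Wilson computation
        z = stats.norm.ppf(0.975)
        p, n = 0.3, 10
        centre = (p + z * z / (2 * n)) / (1 + z * z / n)
        half = (z / (1 + z * z / n)) * np.sqrt(p * (1 - p) / n + z * z / (4 * n * n))
        assert row["ci_low_pct"] == pytest.approx(100 * (centre - half), abs=1e-9)
        assert row["ci_high_pct"] == pytest.approx(100 * (centre + half), abs=1e-9)

    def test_rank_ties_broken_by_name(self, code_map):
        recs = [self.rec(0, ["dementia", "cancer"])]
        tbl = prevalence_table(recs, code_map)
        body = tbl[tbl["rank"].notna() & (tbl["numerator"] > 0)]
        assert body["condition"].tolist() == ["cancer", "dementia"]

    def test_any_comorbidity_bounds_single_conditions(self, code_map):
        recs = [self.rec(i, ["dementia"] if i % 2 else ["cancer"]) for i in range(10)]
        tbl = prevalence_table(recs, code_map).set_index("condition")
        singles = tbl.drop(["any_charlson", "any_comorbidity"])["prevalence_pct"]
        assert tbl.loc["any_comorbidity", "prevalence_pct"] >= singles.max()

    def test_empty_input_rejected(self, code_map):
        with pytest.raises(ValueError):
            prevalence_table([], code_map)

    def test_top_k_share(self, code_map):
        recs = [self.rec(0, ["dementia", "cancer"]), self.rec(1, ["dementia"]),
                self.rec(2, ["renal_disease", "delirium"])]
        tbl = prevalence_table(recs, code_map)
        # top 3 by count: dementia(2), cancer(1), delirium(1) -> 4/5
        assert top_k_share(tbl, 3) == pytest.approx(80.0)


class TestGeneratedDataProperties:
    def test_configured_prevalences_recovered_with_full_coding(
        self, perfect_coding_run, code_map
    ):
        cfg, truth, extracted, incidents = perfect_coding_run
        persons = truth.persons.set_index("person_id")
        n = len(incidents)
        # with full coding and present-on-admission flags, ascertainment on
        # the index record recovers the person's true condition set, so the
        # estimated prevalence is binomial around the configured one
        conds = persons["conditions"].fillna("").str.split(";")
        tested = {c: p for c, p in cfg.comorbidity_prevalences.items() if p >= 0.01}
        a = 0.01 / len(tested)  # family-wise 99% across all conditions
        for cond, p in tested.items():
            hits = int(conds.loc[incidents["person_id"]].map(lambda cs: cond in cs).sum())
            lo = stats.binom.ppf(a / 2, n, p)
            hi = stats.binom.ppf(1 - a / 2, n, p)
            assert lo <= hits <= hi, cond

    def test_lookback_monotonicity_and_undercoding_direction(self, code_map):
        """No-lookback prevalence <= lookback prevalence <= true prevalence
        (in expectation) when episodes under-code conditions."""
        cfg = SimulationConfig(
            n_persons=6000, per_episode_coding_prob=0.6,
            hospital_acquired_prob=0.0, key_corruption=CorruptionSpec.none(),
            seed=31,
        )
        episodes, truth = simulate_cohort(cfg, 31)
        extracted = extract_fall_injury_episodes(episodes)
        assignment = truth.episodes.set_index("episode_id")["true_person_id"]
        incidents, _ = select_reference_standard(extracted, assignment)
        ext = extracted.assign(
            _person=assignment.reindex(extracted["episode_id"]).to_numpy()
        )
        by_person = {p: g for p, g in ext.groupby("_person")}
        recs = {}
        for lb in (True, False):
            recs[lb] = [
                ascertain_comorbidities(row, by_person[row["person_id"]],
                                        code_map, lookback_enabled=lb)
                for _, row in incidents.iterrows()
            ]
        t_with = prevalence_table(recs[True], code_map).set_index("condition")
        t_without = prevalence_table(recs[False], code_map).set_index("condition")
        persons = truth.persons.set_index("person_id")
        conds = persons["conditions"].fillna("").loc[incidents["person_id"]]
        for cond, p_true in cfg.comorbidity_prevalences.items():
            if p_true < 0.02:
                continue
            with_lb = t_with.loc[cond, "prevalence_pct"]
            without_lb = t_without.loc[cond, "prevalence_pct"]
            true_prev = 100 * conds.str.split(";").map(lambda cs: cond in cs).mean()
            assert without_lb <= with_lb + 1e-9, cond
            assert with_lb <= true_prev + 1.5, cond  # sampling slack
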