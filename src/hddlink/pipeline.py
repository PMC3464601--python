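"""End-to-end experiment: simulate -> corrupt -> link -> select -> profile.

One :class:`~hddlink.config.ExperimentConfig` (one seed) drives every
stage.  Two reference standards are evaluated: one built on the generator's
true person partition (isolating case-selection algorithm bias) and one
built on the linkage output (adding linkage error, as in a real linked
dataset where the linkage is taken at face value).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .comorbidity import (
    CodeMap,
    ComorbidityRecord,
    ascertain_comorbidities,
    load_code_map,
    prevalence_table,
)
from .config import ExperimentConfig
from .evaluation import (
    accuracy_measures,
    age_specific_rates,
    compare_proportions,
    confusion,
    direct_standardise,
    standard_population,
)
from .linkage import LinkagePass, link_records, linkage_quality, standardise_keys
from .selection import (
    extract_fall_injury_episodes,
    scenario_spec,
    select_reference_standard,
    select_unlinked_scenario,
)
from .synthetic import CohortTruth, corrupt_linkage_keys, population_table, simulate_cohort


@dataclass
class ExperimentResult:
    """Everything one experiment run produced."""

    config: ExperimentConfig
    episodes: pd.DataFrame
    truth: CohortTruth
    linkage: pd.DataFrame
    linkage_quality: dict
    extracted: pd.DataFrame
    labels: pd.DataFrame                  # episode_id x scenario booleans
    incidents: dict[str, pd.DataFrame]
    accuracy: pd.DataFrame
    prevalence: dict[str, pd.DataFrame]
    prevalence_compare: pd.DataFrame
    rates: pd.DataFrame
    standardised_rates: pd.DataFrame
    log_lines: list[str] = field(default_factory=list)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.episodes.to_csv(out / "episodes.csv", index=False)
        self.truth.write(out)
        self.linkage.to_csv(out / "linkage.csv", index=False)
        self.labels.to_csv(out / "labels.csv")
        for name, inc in self.incidents.items():
            inc.to_csv(out / f"incidents_{name}.csv", index=False)
        self.accuracy.to_csv(out / "accuracy.csv", index=False)
        for name, tbl in self.prevalence.items():
            tbl.to_csv(out / f"prevalence_{name}.csv", index=False)
        self.prevalence_compare.to_csv(out / "prevalence_compare.csv", index=False)
        self.rates.to_csv(out / "rates.csv", index=False)
        self.standardised_rates.to_csv(out / "standardised_rates.csv", index=False)
        meta = {
            "package_version": __version__,
            "seed": self.config.seed,
            "config": self.config.model_dump(mode="json"),
            "linkage_quality": self.linkage_quality,
        }
        (out / "metadata.json").write_text(json.dumps(meta, indent=2))
        (out / "run.log").write_text("\n".join(self.log_lines) + "\n")


def _prepare_episode_frame(extracted: pd.DataFrame) -> pd.DataFrame:
    df = extracted.copy()
    df["admission_date"] = pd.to_datetime(df["admission_date"])
    df["discharge_date"] = pd.to_datetime(df["discharge_date"])
    return df


def _records_for(
    incidents: pd.DataFrame,
    episodes_by_person: dict,
    code_map: CodeMap,
    lookback: bool,
) -> list[ComorbidityRecord]:
    inc = incidents.sort_values(["person_id", "admission_date"])
    next_adm = inc.groupby("person_id")["admission_date"].shift(-1)
    records = []
    for (_, row), nxt in zip(inc.iterrows(), next_adm):
        person_eps = episodes_by_person.get(row["person_id"])
        records.append(
            ascertain_comorbidities(
                row, person_eps, code_map, lookback_enabled=lookback,
                next_incident_admission=None if pd.isna(nxt) else nxt,
            )
        )
    return records


def _unlinked_pseudo_person(df: pd.DataFrame) -> pd.Series:
    public = df["hospital_sector"] == "public"
    return pd.Series(
        np.where(
            public,
            df["hospital_id"].astype(str) + ":" + df["hospital_patient_id"].astype(str),
            "ep:" + df["episode_id"].astype(str),
        ),
        index=df.index,
    )


def run_experiment(config: ExperimentConfig) -> ExperimentResult:
    """Run the full pipeline and return the result bundle.

    Identical (config, seed) produces an identical bundle; if
    ``config.out_dir`` is set the bundle is also written there.
    """
    cfg = config
    bands = tuple(cfg.age_bands)
    seeds = np.random.SeedSequence(cfg.seed).generate_state(2) % (2**31)
    log: list[str] = []

    episodes, truth = simulate_cohort(cfg.simulation, int(seeds[0]))
    log.append(f"simulate: {len(episodes)} episodes, "
               f"{len(truth.persons)} persons, {len(truth.events)} true events")

    episodes = corrupt_linkage_keys(
        episodes, truth, cfg.simulation.key_corruption, int(seeds[1])
    )
    episodes = standardise_keys(episodes)
    result_link = link_records(episodes, [LinkagePass(tuple(p)) for p in cfg.linkage_passes])
    quality = linkage_quality(result_link, truth)
    log.append(f"link: {result_link.assignments['person_id'].nunique()} clusters, "
               f"quality={quality}")

    extracted = _prepare_episode_frame(extract_fall_injury_episodes(episodes))
    log.append(f"extract: {len(extracted)} fall-injury episodes retained")

    truth_assignment = truth.episodes.set_index("episode_id")["true_person_id"]
    link_assignment = result_link.person_of()

    incidents: dict[str, pd.DataFrame] = {}
    labels = {}
    for basis, assignment in (("truth", truth_assignment), ("linked", link_assignment)):
        inc, lab = select_reference_standard(
            extracted, assignment, clearance_days=cfg.clearance_days,
            age_bands=bands,
        )
        incidents[f"reference_{basis}"] = inc
        labels[f"reference_{basis}"] = lab
        log.append(f"select reference ({basis} partition): {len(inc)} incidents")

    for name in cfg.scenarios:
        spec = scenario_spec(name)
        inc, lab = select_unlinked_scenario(
            extracted, spec,
            readmission_window_30=cfg.readmission_window_days,
            age_bands=bands,
        )
        incidents[name] = inc
        labels[name] = lab
        log.append(f"select {name}: {len(inc)} incidents")

    label_frame = pd.DataFrame(labels)
    label_frame.index.name = "episode_id"

    acc_rows = []
    for basis in ("truth", "linked"):
        ref_lab = label_frame[f"reference_{basis}"]
        for name in cfg.scenarios:
            cm = confusion(ref_lab, label_frame[name])
            rep = accuracy_measures(cm, scenario=name, ci_method=cfg.ci_method)
            acc_rows.append(
                dict(
                    reference_basis=basis, scenario=name,
                    n_reference=rep.n_reference, n_scenario=rep.n_scenario,
                    overestimation_pct=rep.overestimation_pct,
                    sensitivity=rep.sensitivity,
                    sensitivity_lo=rep.sensitivity_ci[0] if rep.sensitivity_ci else None,
                    sensitivity_hi=rep.sensitivity_ci[1] if rep.sensitivity_ci else None,
                    specificity=rep.specificity,
                    specificity_lo=rep.specificity_ci[0] if rep.specificity_ci else None,
                    specificity_hi=rep.specificity_ci[1] if rep.specificity_ci else None,
                    ppv=rep.ppv,
                    ppv_lo=rep.ppv_ci[0] if rep.ppv_ci else None,
                    ppv_hi=rep.ppv_ci[1] if rep.ppv_ci else None,
                    npv=rep.npv,
                    npv_lo=rep.npv_ci[0] if rep.npv_ci else None,
                    npv_hi=rep.npv_ci[1] if rep.npv_ci else None,
                )
            )
    accuracy = pd.DataFrame(acc_rows)

    # comorbidity profiles: linked reference vs each unlinked scenario
    code_map = load_code_map()
    ext_linked = extracted.assign(
        _person=link_assignment.reindex(extracted["episode_id"]).to_numpy()
    )
    by_person_linked = {p: g for p, g in ext_linked.groupby("_person")}
    ext_unlinked = extracted.assign(_person=_unlinked_pseudo_person(extracted))
    by_person_unlinked = {p: g for p, g in ext_unlinked.groupby("_person")}

    prevalence: dict[str, pd.DataFrame] = {}
    recs_linked = _records_for(
        incidents["reference_linked"], by_person_linked, code_map, cfg.lookback
    )
    prevalence["reference_linked"] = prevalence_table(
        recs_linked, code_map, ci_method=cfg.ci_method
    )
    for name in cfg.scenarios:
        recs = _records_for(incidents[name], by_person_unlinked, code_map, cfg.lookback)
        prevalence[name] = prevalence_table(recs, code_map, ci_method=cfg.ci_method)
    log.append("comorbidity: prevalence tables built for "
               f"{1 + len(cfg.scenarios)} sources")

    ref_tbl = prevalence["reference_linked"].set_index("condition")
    cmp_rows = []
    for name in cfg.scenarios:
        tbl = prevalence[name].set_index("condition")
        for cond in ref_tbl.index:
            a, b = ref_tbl.loc[cond], tbl.loc[cond]
            test = compare_proportions(
                int(a["numerator"]), int(a["denominator"]),
                int(b["numerator"]), int(b["denominator"]),
            )
            cmp_rows.append(
                dict(
                    scenario=name, condition=cond,
                    linked_pct=a["prevalence_pct"], unlinked_pct=b["prevalence_pct"],
                    difference_pct=b["prevalence_pct"] - a["prevalence_pct"],
                    p_value=test["p_value"], method=test["method"],
                )
            )
    prevalence_compare = pd.DataFrame(cmp_rows)

    pop = population_table(cfg.simulation, bands)
    rates = age_specific_rates(incidents["reference_linked"], pop)
    standardised = direct_standardise(rates, standard_population(pop, bands))
    log.append("rates: age-specific and directly standardised rates computed")

    result = ExperimentResult(
        config=cfg,
        episodes=episodes,
        truth=truth,
        linkage=result_link.assignments,
        linkage_quality=quality,
        extracted=extracted,
        labels=label_frame,
        incidents=incidents,
        accuracy=accuracy,
        prevalence=prevalence,
        prevalence_compare=prevalence_compare,
        rates=rates,
        standardised_rates=standardised,
        log_lines=log,
    )
    if cfg.out_dir:
        result.write(cfg.out_dir)
    return result
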