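"""Incident fall-related hip fracture case selection.

Implements the episode extraction step and six case-identification
algorithms: a reference standard that operates on person-linked data with a
120-day clearance period and an external-cause disagreement rule, and five
unlinked-data algorithms (base case and scenarios S1-S4) that operate on
episode-level data where readmissions are detectable only within the same
public hospital.

Inclusion criteria shared by all six: principal diagnosis hip fracture
(S72.0-S72.2) and admission source "private residence/accommodation"
(community-dwelling).  The scenarios differ in which exclusion criteria
they add:

============================  ===== ==== == == == ==
criterion                     ref   base S1 S2 S3 S4
============================  ===== ==== == == == ==
readmission within 30 days     x     x   x  x  x  x
readmission within 120 days    x             x  x  x
in-hospital death                    x      x  x
hip revision procedures only   x                x  x
non-acute care type            x                x  x
non-emergency admission        x                x  x
============================  ===== ==== == == == ==

(the reference standard realises both readmission rows through its
clearance period on linked persons rather than as same-hospital window
checks).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from ._util import DEFAULT_AGE_BANDS, age_band, fiscal_year
from .codes import (
    REVISION_PROCEDURES,
    is_fall_mechanism,
    is_hip_fracture,
    is_injury_principal,
    series_predicate,
)

log = logging.getLogger(__name__)

INCIDENT_COLUMNS = [
    "index_episode_id", "person_id", "admission_date", "fiscal_year",
    "age_band", "sex",
]


@dataclass(frozen=True)
class ScenarioSpec:
    """A named bundle of inclusion/exclusion flags for case selection."""

    name: str
    require_hip_fracture_dx: bool = True
    require_private_residence: bool = True
    exclude_inhospital_death: bool = False
    exclude_readmit_30d: bool = False
    exclude_readmit_120d: bool = False
    exclude_revision_only: bool = False
    exclude_nonacute: bool = False
    exclude_nonemergency: bool = False
    use_person_linkage: bool = False
    use_external_cause_rule: bool = False


_SHIPPED: dict[str, ScenarioSpec] = {
    "reference": ScenarioSpec(
        name="reference",
        exclude_readmit_30d=True,
        exclude_readmit_120d=True,
        exclude_revision_only=True,
        exclude_nonacute=True,
        exclude_nonemergency=True,
        use_person_linkage=True,
        use_external_cause_rule=True,
    ),
    "base": ScenarioSpec(
        name="base", exclude_inhospital_death=True, exclude_readmit_30d=True
    ),
    "S1": ScenarioSpec(name="S1", exclude_readmit_30d=True),
    "S2": ScenarioSpec(
        name="S2",
        exclude_inhospital_death=True,
        exclude_readmit_30d=True,
        exclude_readmit_120d=True,
    ),
    "S3": ScenarioSpec(
        name="S3",
        exclude_inhospital_death=True,
        exclude_readmit_30d=True,
        exclude_readmit_120d=True,
        exclude_revision_only=True,
        exclude_nonacute=True,
        exclude_nonemergency=True,
    ),
}
_SHIPPED["S4"] = replace(_SHIPPED["S3"], name="S4", exclude_inhospital_death=False)


def scenario_spec(name: str) -> ScenarioSpec:
    """Return a shipped scenario spec by name."""
    if name not in _SHIPPED:
        raise KeyError(
            f"unknown scenario {name!r}; shipped scenarios: {sorted(_SHIPPED)}"
        )
    return _SHIPPED[name]


def extract_fall_injury_episodes(episodes: pd.DataFrame) -> pd.DataFrame:
    """Extract fall-related injury episodes in people aged 65+.

    Keeps episodes whose external-cause mechanism is a fall (W00-W19),
    whose principal diagnosis is an injury (S00-T75 or T79; the cut at
    T75/T79 excludes complications of medical care), and whose age at
    admission is 65+.  Malformed codes simply fail the code predicates and
    are excluded (logged, not fatal).
    """
    mech = series_predicate(episodes["ext_mechanism"], is_fall_mechanism)
    dx = series_predicate(episodes["principal_diagnosis"], is_injury_principal)
    age = pd.to_numeric(episodes["age_at_admission"], errors="coerce") >= 65
    keep = mech & dx & age.fillna(False)
    dropped = len(episodes) - int(keep.sum())
    if dropped:
        log.debug("extract_fall_injury_episodes dropped %d episodes", dropped)
    return episodes[keep].copy()


def hip_fracture_filter(episodes: pd.DataFrame) -> pd.DataFrame:
    """Keep episodes whose principal diagnosis is hip fracture S72.0-S72.2."""
    keep = series_predicate(episodes["principal_diagnosis"], is_hip_fracture)
    return episodes[keep].copy()


def _revision_only(episodes: pd.DataFrame) -> pd.Series:
    """True where the procedure list is non-empty and every code is a hip
    revision procedure."""

    def check(cell) -> bool:
        if not isinstance(cell, str) or not cell.strip():
            return False
        codes = [c for c in cell.split(";") if c]
        return bool(codes) and all(c in REVISION_PROCEDURES for c in codes)

    return episodes["procedure_codes"].map(check)


def _incident_frame(selected: pd.DataFrame, person_ids: pd.Series,
                    bands: tuple[str, ...]) -> pd.DataFrame:
    adm = pd.to_datetime(selected["admission_date"])
    return pd.DataFrame(
        {
            "index_episode_id": selected["episode_id"].to_numpy(),
            "person_id": person_ids.to_numpy(),
            "admission_date": adm.to_numpy(),
            "fiscal_year": fiscal_year(adm).to_numpy(),
            "age_band": age_band(selected["age_at_admission"], bands).to_numpy(),
            "sex": selected["sex"].to_numpy(),
        }
    ).sort_values("index_episode_id").reset_index(drop=True)


def select_unlinked_scenario(
    episodes: pd.DataFrame,
    spec: ScenarioSpec | str,
    readmission_window_30: int = 30,
    readmission_window_120: int = 120,
    age_bands: tuple[str, ...] = DEFAULT_AGE_BANDS,
) -> tuple[pd.DataFrame, pd.Series]:
    """Identify incident cases on unlinked (episode-level) data.

    Readmission exclusions use the only identification available without a
    system-wide patient identifier: the hospital-generated patient id,
    which exists per hospital — so a readmission is detectable only when
    both episodes occurred at the same *public* hospital.  The gap is
    admission date minus the latest prior discharge date at that hospital,
    in whole days; a gap in [0, window] excludes the episode.

    Returns the incident-case table and a boolean label per input episode.
    """
    if isinstance(spec, str):
        spec = scenario_spec(spec)
    if spec.use_person_linkage:
        raise ValueError("use select_reference_standard for linked scenarios")

    df = episodes.copy()
    df["admission_date"] = pd.to_datetime(df["admission_date"])
    df["discharge_date"] = pd.to_datetime(df["discharge_date"])

    ok = pd.Series(True, index=df.index)
    if spec.require_hip_fracture_dx:
        ok &= series_predicate(df["principal_diagnosis"], is_hip_fracture)
    if spec.require_private_residence:
        ok &= df["admission_source"] == "private_residence"
    if spec.exclude_inhospital_death:
        ok &= df["discharge_status"] != "died_in_hospital"
    if spec.exclude_nonacute:
        ok &= df["care_type"] == "acute"
    if spec.exclude_nonemergency:
        ok &= df["admission_category"] == "emergency"
    if spec.exclude_revision_only:
        ok &= ~_revision_only(df)

    window = None
    if spec.exclude_readmit_120d:
        window = readmission_window_120
    elif spec.exclude_readmit_30d:
        window = readmission_window_30
    if window is not None:
        # latest prior discharge of the same pseudo-person (same public
        # hospital patient id); private-hospital episodes are undetectable
        srt = df.sort_values(
            ["hospital_id", "hospital_patient_id", "admission_date",
             "discharge_date", "episode_id"]
        )
        grp = srt.groupby(["hospital_id", "hospital_patient_id"], sort=False)
        prev_max = (
            grp["discharge_date"]
            .cummax()
            .groupby([srt["hospital_id"], srt["hospital_patient_id"]], sort=False)
            .shift()
        )
        gap = (srt["admission_date"] - prev_max).dt.days
        readmit = (
            (gap >= 0) & (gap <= window) & (srt["hospital_sector"] == "public")
        ).reindex(df.index).fillna(False)
        ok &= ~readmit

    labels = ok.copy()
    labels.index = df["episode_id"].to_numpy()
    labels.name = spec.name

    selected = df[ok]
    public = selected["hospital_sector"] == "public"
    pseudo = np.where(
        public,
        selected["hospital_id"].astype(str) + ":" + selected["hospital_patient_id"].astype(str),
        "ep:" + selected["episode_id"].astype(str),
    )
    incidents = _incident_frame(selected, pd.Series(pseudo, index=selected.index),
                                age_bands)
    return incidents, labels.sort_index()


def select_reference_standard(
    episodes: pd.DataFrame,
    person_assignment: pd.Series,
    clearance_days: int = 120,
    use_external_cause_rule: bool = True,
    age_bands: tuple[str, ...] = DEFAULT_AGE_BANDS,
) -> tuple[pd.DataFrame, pd.Series]:
    """Identify incident cases on person-linked data (the reference
    standard).

    Qualifying episodes are hip-fracture admissions from private residence
    with emergency admission for acute care and no revision-only procedure
    list; discharge status is disregarded.  Within each person the first
    qualifying episode founds an incident; each later qualifying episode
    founds a new incident iff at least ``clearance_days`` have elapsed
    since the previous incident chain's last discharge AND (when the
    external-cause rule is on) its mechanism/place/activity triple differs
    from the previous incident's in all three components.  Other qualifying
    episodes extend the current incident's chain.

    ``person_assignment`` maps episode_id -> person id (from linkage or
    from ground truth).
    """
    df = episodes.copy()
    df["admission_date"] = pd.to_datetime(df["admission_date"])
    df["discharge_date"] = pd.to_datetime(df["discharge_date"])

    assigned = person_assignment.reindex(df["episode_id"])
    if assigned.isna().any():
        missing = assigned[assigned.isna()].index.tolist()[:5]
        raise ValueError(f"episodes not assigned to any person, e.g. {missing}")
    df["_person"] = assigned.to_numpy()

    qualifying = (
        series_predicate(df["principal_diagnosis"], is_hip_fracture)
        & (df["admission_source"] == "private_residence")
        & (df["admission_category"] == "emergency")
        & (df["care_type"] == "acute")
        & ~_revision_only(df)
    )

    labels = pd.Series(False, index=df["episode_id"].to_numpy(), name="reference")
    incident_rows = []
    q = df[qualifying].sort_values(
        ["_person", "admission_date", "discharge_date", "episode_id"]
    )
    for person, grp in q.groupby("_person", sort=False):
        anchor_discharge = None
        triple = None
        for row in grp.itertuples():
            t = (row.ext_mechanism, row.ext_place, row.ext_activity)
            if anchor_discharge is None:
                new_incident = True
            else:
                gap = (row.admission_date - anchor_discharge).days
                differs = (
                    not use_external_cause_rule
                    or all(a != b for a, b in zip(t, triple))
                )
                new_incident = gap >= clearance_days and differs
            if new_incident:
                labels.loc[row.episode_id] = True
                incident_rows.append(row.Index)
                triple = t
                anchor_discharge = row.discharge_date
            else:
                anchor_discharge = max(anchor_discharge, row.discharge_date)

    selected = df.loc[incident_rows]
    incidents = _incident_frame(selected, selected["_person"], age_bands)
    return incidents, labels.sort_index()
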