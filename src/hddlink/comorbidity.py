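"""Charlson (Deyo adaptation) and fall-risk comorbidity ascertainment.

Conditions are detected from additional-diagnosis ICD-10 codes on hospital
episodes.  Three rules matter clinically:

* only diagnoses flagged *present on admission* count — codes flagged as
  having arisen during the episode are adverse events, not comorbidities;
* ascertainment searches the index hospitalisation record (the first
  multiday record of the incident's episode chain) and, when lookback is
  enabled, the person's earlier records in the dataset;
* the Charlson index applies severity hierarchies (uncomplicated diabetes
  is subsumed by diabetes with complications, mild by moderate/severe liver
  disease, solid tumour by metastatic cancer) before summing weights.

The ICD-10 prefix lists ship as an editable CSV asset
(``data/comorbidity_codes.csv``); the engine is code-list-agnostic.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from .evaluation import proportion_ci

#: milder condition -> severer condition that subsumes it in the index
HIERARCHIES: dict[str, str] = {
    "diabetes": "diabetes_with_complications",
    "mild_liver_disease": "moderate_severe_liver_disease",
    "cancer": "metastatic_cancer",
}


@dataclass(frozen=True)
class CodeMap:
    """Condition -> ICD-10 code prefixes, with Charlson flags and weights."""

    prefixes: dict[str, tuple[str, ...]]
    charlson: dict[str, bool]
    weight: dict[str, int]
    _normalised: dict[str, tuple[str, ...]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "_normalised",
            {c: tuple(_norm(p) for p in ps) for c, ps in self.prefixes.items()},
        )

    @property
    def conditions(self) -> tuple[str, ...]:
        return tuple(self.prefixes)

    def match(self, code: str) -> list[str]:
        """Conditions whose prefix list matches this diagnosis code."""
        n = _norm(code)
        return [c for c, ps in self._normalised.items() if any(n.startswith(p) for p in ps)]


def _norm(code: str) -> str:
    return code.strip().upper().replace(".", "")


def load_code_map(path: str | Path | None = None) -> CodeMap:
    """Load the shipped (or a user-supplied) comorbidity code map CSV."""
    if path is None:
        src = resources.files("hddlink.data").joinpath("comorbidity_codes.csv")
        text = src.read_text()
    else:
        text = Path(path).read_text()
    prefixes: dict[str, tuple[str, ...]] = {}
    charlson: dict[str, bool] = {}
    weight: dict[str, int] = {}
    for row in csv.DictReader(text.splitlines()):
        cond = row["condition"]
        prefixes[cond] = tuple(p for p in row["prefixes"].split(";") if p)
        charlson[cond] = bool(int(row["charlson"]))
        weight[cond] = int(row["weight"])
    if not prefixes:
        raise ValueError("code map is empty")
    return CodeMap(prefixes=prefixes, charlson=charlson, weight=weight)


def parse_additional_diagnoses(cell) -> list[tuple[str, str]]:
    """Parse the serialised additional-diagnosis cell "CODE:P;CODE:A".

    Onset flags: "P" = present on admission, "A" = arose during episode.
    """
    if not isinstance(cell, str) or not cell:
        return []
    out = []
    for item in cell.split(";"):
        code, _, onset = item.partition(":")
        if code:
            out.append((code, onset or "P"))
    return out


def resolve_hierarchy(present: set[str]) -> set[str]:
    """Drop milder conditions subsumed by a severer coded form."""
    return {c for c in present if HIERARCHIES.get(c) not in present}


def charlson_index(present_conditions, code_map: CodeMap) -> int:
    """Deyo-weighted Charlson comorbidity index of a resolved condition set."""
    total = 0
    for c in resolve_hierarchy(set(present_conditions)):
        if c not in code_map.weight:
            raise KeyError(f"unknown condition: {c!r}")
        if code_map.charlson[c]:
            total += code_map.weight[c]
    return total


@dataclass(frozen=True)
class ComorbidityRecord:
    """Per-incident ascertained comorbidities."""

    incident_id: int
    person_id: object
    present: frozenset[str]
    charlson_index: int
    lookback_days_available: int


def ascertain_comorbidities(
    incident: pd.Series,
    person_episodes: pd.DataFrame,
    code_map: CodeMap,
    lookback_enabled: bool = True,
    next_incident_admission: pd.Timestamp | None = None,
) -> ComorbidityRecord:
    """Ascertain one incident case's comorbidities.

    ``incident`` must carry ``index_episode_id``, ``person_id`` and
    ``admission_date``; ``person_episodes`` are the person's episodes
    available in the dataset (any order).  The index hospitalisation is the
    first multiday record of the incident's chain (episodes admitted at or
    after the incident admission and, if known, before the next incident);
    if no chain record is multiday, the index episode itself is used.  A
    condition is present iff a matching code flagged present-on-admission
    appears on the index hospitalisation record or, with lookback, on any
    record admitted earlier.
    """
    if not code_map.conditions:
        raise ValueError("empty code map")
    eps = person_episodes.copy()
    eps["admission_date"] = pd.to_datetime(eps["admission_date"])
    eps["discharge_date"] = pd.to_datetime(eps["discharge_date"])
    adm0 = pd.Timestamp(incident["admission_date"])

    chain = eps[eps["admission_date"] >= adm0]
    if next_incident_admission is not None:
        chain = chain[chain["admission_date"] < pd.Timestamp(next_incident_admission)]
    chain = chain.sort_values(["admission_date", "discharge_date", "episode_id"])
    multiday = chain[chain["discharge_date"] > chain["admission_date"]]
    if len(multiday):
        index_record = multiday.iloc[0]
    elif len(chain):
        index_record = chain.iloc[0]
    else:
        index_record = eps.loc[eps["episode_id"] == incident["index_episode_id"]].iloc[0]

    searched = [index_record]
    if lookback_enabled:
        earlier = eps[eps["admission_date"] < index_record["admission_date"]]
        searched.extend(row for _, row in earlier.iterrows())

    present: set[str] = set()
    for rec in searched:
        for code, onset in parse_additional_diagnoses(rec["additional_diagnoses"]):
            if onset != "P":
                continue
            present.update(code_map.match(code))

    lookback_days = int((adm0 - eps["admission_date"].min()).days) if len(eps) else 0
    return ComorbidityRecord(
        incident_id=int(incident["index_episode_id"]),
        person_id=incident["person_id"],
        present=frozenset(present),
        charlson_index=charlson_index(present, code_map),
        lookback_days_available=max(lookback_days, 0),
    )


def prevalence_table(
    records: list[ComorbidityRecord],
    code_map: CodeMap,
    ci_method: str = "wilson",
) -> pd.DataFrame:
    """Prevalence (%) of each condition among incident cases, with CIs.

    Adds summary rows ``any_charlson`` and ``any_comorbidity``; conditions
    are rank-ordered by descending count with alphabetical tie-break.
    """
    if not records:
        raise ValueError("no comorbidity records supplied")
    n = len(records)
    rows = []
    for cond in code_map.conditions:
        x = sum(1 for r in records if cond in r.present)
        rows.append((cond, x))
    rows.sort(key=lambda t: (-t[1], t[0]))
    any_ch = sum(
        1 for r in records if any(code_map.charlson.get(c) for c in r.present)
    )
    any_co = sum(1 for r in records if r.present)
    out = []
    for rank, (cond, x) in enumerate(rows, start=1):
        lo, hi = proportion_ci(x, n, method=ci_method)
        out.append(
            dict(
                condition=cond, numerator=x, denominator=n,
                prevalence_pct=100 * x / n,
                ci_low_pct=100 * lo, ci_high_pct=100 * hi, rank=rank,
            )
        )
    for label, x in (("any_charlson", any_ch), ("any_comorbidity", any_co)):
        lo, hi = proportion_ci(x, n, method=ci_method)
        out.append(
            dict(
                condition=label, numerator=x, denominator=n,
                prevalence_pct=100 * x / n,
                ci_low_pct=100 * lo, ci_high_pct=100 * hi, rank=pd.NA,
            )
        )
    return pd.DataFrame(out).astype({"rank": "Int64"})


def top_k_share(table: pd.DataFrame, k: int = 3) -> float:
    """Share (%) of all coded comorbidity instances accounted for by the
    ``k`` most common conditions."""
    body = table[~table["condition"].isin(["any_charlson", "any_comorbidity"])]
    total = body["numerator"].sum()
    if total == 0:
        return 0.0
    top = body.nsmallest(k, "rank")["numerator"].sum()
    return float(100 * top / total)
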