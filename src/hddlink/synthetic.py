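"""Synthetic episode-level hospital discharge data with ground truth.

Real admitted-episodes collections of this kind are restricted government
datasets; this module generates data with the same schema and the same
statistical nuisance structure (inter-hospital transfers, 30- and 120-day
readmissions, revision-procedure admissions, non-acute care episodes,
in-hospital deaths, second hip-fracture events, linkage-key corruption),
together with the ground truth the real data lack: the true person behind
every episode and the true incident fall-related hip-fracture events.

The simulated cohort is the set of people aged 65+ with at least one
fall-related hospital admission during the study window.  Every incident
hip-fracture event produces one acute emergency index episode (principal
diagnosis S72.0-S72.2, fall mechanism W00-W19) and, with configured
probabilities, follow-on episodes that a naive episode count would mistake
for new cases.  Non-hip-fracture fall injuries (wrist, humerus, vertebral
fractures, head injuries, femoral shaft fractures ...) are also emitted so
that specificity has a denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.stats import norm

from ._util import DEFAULT_AGE_BANDS, _band_edges, fiscal_year
from .codes import PRIMARY_HIP_PROCEDURES, REVISION_PROCEDURES
from .comorbidity import load_code_map
from .config import CorruptionSpec, SimulationConfig

#: Principal diagnoses for non-hip-fracture fall injuries (all within the
#: injury range S00-T75/T79; S72.3 is a femoral *shaft* fracture and must be
#: rejected by the hip-fracture filter).
NONFRACTURE_DX = (
    "S52.5", "S42.2", "S32.0", "S06.0", "S72.3", "S70.0", "S82.6", "T14.0",
)

COUNTRIES = ("australia", "italy", "greece", "united kingdom", "vietnam", "other")

EPISODE_COLUMNS = [
    "episode_id", "hospital_id", "hospital_sector", "hospital_patient_id",
    "admission_date", "discharge_date", "age_at_admission", "sex",
    "admission_source", "care_type", "admission_category", "discharge_status",
    "principal_diagnosis", "additional_diagnoses",
    "ext_mechanism", "ext_place", "ext_activity", "procedure_codes",
    "key_sex", "key_dob", "key_postcode", "key_medicare", "key_country",
]


@dataclass
class CohortTruth:
    """Generator-side ground truth enabling oracle evaluation.

    episodes: one row per episode — true_person_id, true_incident_event_id
        (set on index episodes only), chain_event_id (set on every episode
        belonging to an event, including transfers and readmissions), role,
        transfer_partner (sender episode_id, on transfer-receiver rows).
    persons: one row per person — demographics, residence, master linkage
        keys, semicolon-joined true comorbidity set.
    events: one row per true incident event — person, index admission date,
        is_second flag, community flag (False for nursing-home residents).
    """

    episodes: pd.DataFrame
    persons: pd.DataFrame
    events: pd.DataFrame

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.episodes.to_csv(out / "truth_episodes.csv", index=False)
        self.persons.to_csv(out / "truth_persons.csv", index=False)
        self.events.to_csv(out / "truth_events.csv", index=False)

    @classmethod
    def read(cls, out_dir: str | Path) -> "CohortTruth":
        out = Path(out_dir)
        return cls(
            episodes=pd.read_csv(out / "truth_episodes.csv"),
            persons=pd.read_csv(out / "truth_persons.csv"),
            events=pd.read_csv(
                out / "truth_events.csv", parse_dates=["admission_date"]
            ),
        )


def age_quantile_function(anchors: dict[float, float]):
    """Monotone quantile function through (probability, age) anchor points.

    A PCHIP interpolant through the anchors reproduces the anchored median
    and quartiles exactly while staying monotone, which two-parameter
    families cannot do for a left-skewed age profile.
    """
    items = sorted(anchors.items())
    p = np.array([q for q, _ in items])
    a = np.array([x for _, x in items])
    return PchipInterpolator(p, a)


def age_band_shares(
    anchors: dict[float, float], bands: tuple[str, ...] = DEFAULT_AGE_BANDS
) -> dict[str, float]:
    """P(floor(age) falls in band) under the anchored age distribution."""
    qf = age_quantile_function(anchors)
    grid_p = np.linspace(0.0, 1.0, 200_001)
    grid_a = qf(grid_p)

    def cdf(x: float) -> float:
        return float(np.interp(x, grid_a, grid_p))

    shares = {}
    for lo, hi, label in _band_edges(tuple(bands)):
        upper = 1.0 if np.isinf(hi) else cdf(hi + 1)
        shares[label] = upper - cdf(lo)
    return shares


def _truncated_lognormal_gap(rng, cfg: SimulationConfig, hi: float) -> float:
    """Days between first and second fracture admissions, truncated to
    [gap_min, hi] (the window imposes the upper truncation, as it does on
    the real data's observed gaps)."""
    mu = np.log(cfg.second_fracture_gap_log_median)
    sig = cfg.second_fracture_gap_log_sigma
    plo = norm.cdf((np.log(max(cfg.second_fracture_gap_min, 1)) - mu) / sig)
    phi = norm.cdf((np.log(hi) - mu) / sig)
    u = rng.uniform(plo, phi)
    return float(np.exp(mu + sig * norm.ppf(u)))


class _Builder:
    """Accumulates episode rows with stable per-hospital patient ids."""

    def __init__(self) -> None:
        self.rows: list[dict] = []
        self._pat_ids: dict[tuple[int, str], str] = {}
        self._next_ep = 1

    def patient_id(self, person: int, hospital: str) -> str:
        key = (person, hospital)
        if key not in self._pat_ids:
            self._pat_ids[key] = f"{hospital}-{len(self._pat_ids) + 1:06d}"
        return self._pat_ids[key]

    def add(self, **row) -> int:
        row["episode_id"] = self._next_ep
        self._next_ep += 1
        self.rows.append(row)
        return row["episode_id"]


def _los(rng, median: float, cap: int) -> int:
    return int(min(cap, 1 + round(rng.lognormal(np.log(median), 0.6))))


def simulate_cohort(
    config: SimulationConfig, seed: int | None = None
) -> tuple[pd.DataFrame, CohortTruth]:
    """Generate the episode table and its ground truth.

    Episodes carry uncorrupted master linkage keys; apply
    :func:`corrupt_linkage_keys` afterwards to induce linkage error.
    Identical (config, seed) always produces identical tables.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    start = pd.Timestamp(cfg.study_start)
    window = (pd.Timestamp(cfg.study_end) - start).days

    code_map = load_code_map()
    cond_names = [c for c in cfg.comorbidity_prevalences if c in code_map.conditions]
    unknown = set(cfg.comorbidity_prevalences) - set(code_map.conditions)
    if unknown:
        raise ValueError(
            f"comorbidity_prevalences names unknown conditions: {sorted(unknown)}"
        )

    hospitals = [f"H{i:03d}" for i in range(cfg.n_hospitals)]
    n_public = int(round(cfg.public_hospital_fraction * cfg.n_hospitals))
    sector = {h: ("public" if i < n_public else "private") for i, h in enumerate(hospitals)}

    def draw_hospital() -> str:
        if rng.random() < cfg.public_hospital_fraction and n_public:
            return hospitals[rng.integers(0, n_public)]
        if n_public < cfg.n_hospitals:
            return hospitals[n_public + rng.integers(0, cfg.n_hospitals - n_public)]
        return hospitals[rng.integers(0, cfg.n_hospitals)]

    qf = age_quantile_function(cfg.age_quantile_anchors)
    n = cfg.n_persons
    ages = np.floor(qf(rng.uniform(size=n))).astype(int)
    sexes = np.where(rng.random(n) < cfg.female_fraction, "F", "M")
    nursing = rng.random(n) < cfg.nursing_home_fraction
    has_fracture = rng.random(n) < cfg.fracture_hazard
    has_second = has_fracture & (rng.random(n) < cfg.second_fracture_prob)
    n_nonfrac = rng.poisson(cfg.nonfracture_fall_rate, size=n)
    # a person must have at least one admission to be in the cohort
    n_nonfrac[(~has_fracture) & (n_nonfrac == 0)] = 1

    cond_flags = {
        c: rng.random(n) < cfg.comorbidity_prevalences[c] for c in cond_names
    }

    # Medicare surrogates: most persons unique; a configurable fraction share
    # a family card number with another person (pairs in draw order).
    medicare = np.array(
        [f"{rng.integers(10**9, 10**10 - 1)}" for _ in range(n)], dtype=object
    )
    shared = np.flatnonzero(rng.random(n) < cfg.shared_medicare_prob)
    for i in range(0, len(shared) - 1, 2):
        medicare[shared[i + 1]] = medicare[shared[i]]
    postcodes = np.array(
        [f"{3000 + rng.integers(0, 1000)}" for _ in range(n)], dtype=object
    )
    countries = rng.choice(
        COUNTRIES, size=n, p=[0.62, 0.08, 0.07, 0.11, 0.05, 0.07]
    )

    builder = _Builder()
    truth_ep_rows: list[dict] = []
    event_rows: list[dict] = []
    person_rows: list[dict] = []
    next_event = 1

    def coded_diagnoses(person: int) -> str:
        items = []
        for c in cond_names:
            if cond_flags[c][person] and rng.random() < cfg.per_episode_coding_prob:
                onset = "A" if rng.random() < cfg.hospital_acquired_prob else "P"
                prefixes = code_map.prefixes[c]
                items.append(f"{prefixes[rng.integers(0, len(prefixes))]}:{onset}")
        return ";".join(items)

    def fresh_triple(avoid: tuple[str, str, str] | None = None) -> tuple[str, str, str]:
        while True:
            t = (
                f"W{rng.integers(0, 20):02d}",
                f"Y92.{rng.integers(0, 10)}",
                f"U73.{rng.integers(0, 10)}",
            )
            if avoid is None or not cfg.ext_cause_triple_always_differs:
                return t
            if t[0] != avoid[0] and t[1] != avoid[1] and t[2] != avoid[2]:
                return t

    for i in range(n):
        source_home = "nursing_home" if nursing[i] else "private_residence"
        person_day_offsets: list[int] = []
        person_episode_plan: list[dict] = []  # realised after dob is known

        def emit(day: int, **kw) -> dict:
            plan = dict(day=day, **kw)
            person_episode_plan.append(plan)
            person_day_offsets.append(day)
            return plan

        first_triples: tuple[str, str, str] | None = None
        event_ids_of_person: list[int] = []

        def build_event_chain(t_index: int, is_second: bool, avoid_triple):
            """Plan one incident event's episode chain; returns
            (event_id, chain_end_day, triple)."""
            nonlocal next_event
            event_id = next_event
            next_event += 1
            triple = fresh_triple(avoid_triple)
            dx = f"S72.{rng.integers(0, 3)}"
            death = rng.random() < cfg.inhospital_death_prob
            transfer = rng.random() < cfg.transfer_prob
            h0 = draw_hospital()
            los0 = _los(rng, 7, 40)
            index_status = "home"
            if transfer:
                index_status = "transfer"
            elif death:
                index_status = "died_in_hospital"
            emit(
                t_index, event_id=event_id, role="index", hospital=h0,
                los=los0, source=source_home, care="acute", cat="emergency",
                status=index_status, dx=dx, triple=triple,
                procs=PRIMARY_HIP_PROCEDURES[rng.integers(0, len(PRIMARY_HIP_PROCEDURES))],
            )
            last_end = t_index + los0
            last_hosp = h0
            if transfer:
                h1 = h0
                while h1 == h0:
                    h1 = draw_hospital()
                los1 = _los(rng, 10, 60)
                emit(
                    last_end, event_id=event_id, role="transfer", hospital=h1,
                    los=los1, source="transfer",
                    care="non_acute" if rng.random() < cfg.nonacute_episode_prob else "acute",
                    cat="non_emergency",
                    status="died_in_hospital" if death else "home",
                    dx=dx, triple=triple, procs="", partner_prev=True,
                )
                last_end = last_end + los1
                last_hosp = h1
            if not death:
                for window_lo, window_hi, prob in (
                    (1, 30, cfg.readmission_30d_prob),
                    (31, 120, cfg.readmission_120d_prob),
                ):
                    if rng.random() < prob:
                        gap = int(rng.integers(window_lo, window_hi + 1))
                        adm = last_end + gap
                        if adm > window:
                            continue
                        if rng.random() < cfg.same_hospital_readmission_prob:
                            h = last_hosp
                            same = True
                        else:
                            h = draw_hospital()
                            same = h == last_hosp
                        revision = rng.random() < cfg.revision_readmission_prob
                        los = _los(rng, 4, 14)
                        emit(
                            adm, event_id=event_id,
                            role=f"readmit_{window_hi}d", hospital=h, los=los,
                            source=source_home,
                            care="non_acute" if rng.random() < cfg.nonacute_episode_prob else "acute",
                            cat="non_emergency" if rng.random() < cfg.nonemergency_readmission_prob else "emergency",
                            status="home", dx=dx, triple=triple,
                            procs=sorted(REVISION_PROCEDURES)[rng.integers(0, len(REVISION_PROCEDURES))] if revision else "",
                            same_hospital=same,
                        )
                        last_end = adm + los
            return event_id, last_end, triple

        if has_fracture[i]:
            if has_second[i]:
                gap_hi = max(window - 340, cfg.second_fracture_gap_min + 30)
                gap = _truncated_lognormal_gap(rng, cfg, gap_hi)
                t1 = int(rng.integers(0, max(1, window - int(gap) - 340)))
            else:
                gap = None
                t1 = int(rng.integers(0, window + 1))
            ev1, chain1_end, triple1 = build_event_chain(t1, False, None)
            event_ids_of_person.append(ev1)
            first_triples = triple1
            event_rows.append(
                dict(event_id=ev1, person_id=i, day=t1, is_second=False,
                     community=not nursing[i])
            )
            if has_second[i]:
                t2 = max(t1 + int(round(gap)), chain1_end + cfg.second_fracture_gap_min + 1)
                ev2, _, _ = build_event_chain(t2, True, first_triples)
                event_ids_of_person.append(ev2)
                event_rows.append(
                    dict(event_id=ev2, person_id=i, day=t2, is_second=True,
                         community=not nursing[i])
                )

        for _ in range(n_nonfrac[i]):
            day = int(rng.integers(0, window + 1))
            mech_is_fall = rng.random() >= 0.1
            triple = fresh_triple(None)
            emit(
                day, event_id=None, role="nonfracture", hospital=draw_hospital(),
                los=int(rng.integers(0, 11)), source=source_home, care="acute",
                cat="emergency", status="home",
                dx=NONFRACTURE_DX[rng.integers(0, len(NONFRACTURE_DX))],
                triple=triple if mech_is_fall else ("X59", triple[1], triple[2]),
                procs="",
            )

        # anchor date of birth so age at first admission equals the drawn age
        first_day = min(person_day_offsets)
        dob = start + pd.Timedelta(days=first_day) - pd.Timedelta(
            days=int((ages[i] + rng.uniform(0.02, 0.98)) * 365.25)
        )
        person_rows.append(
            dict(
                person_id=i, sex=sexes[i], age_at_entry=int(ages[i]),
                residence="nursing_home" if nursing[i] else "community",
                dob=dob.date().isoformat(), postcode=postcodes[i],
                medicare=medicare[i], country=countries[i],
                conditions=";".join(c for c in cond_names if cond_flags[c][i]),
            )
        )

        prev_eid_by_event: dict[int, int] = {}
        for plan in sorted(person_episode_plan, key=lambda p: (p["day"], p.get("role", ""))):
            adm = start + pd.Timedelta(days=plan["day"])
            if adm > pd.Timestamp(cfg.study_end):
                continue
            age_adm = int((adm - pd.Timestamp(dob)).days // 365.25)
            eid = builder.add(
                hospital_id=plan["hospital"],
                hospital_sector=sector[plan["hospital"]],
                hospital_patient_id=builder.patient_id(i, plan["hospital"]),
                admission_date=adm.date().isoformat(),
                discharge_date=(adm + pd.Timedelta(days=plan["los"])).date().isoformat(),
                age_at_admission=age_adm,
                sex=sexes[i],
                admission_source=plan["source"],
                care_type=plan["care"],
                admission_category=plan["cat"],
                discharge_status=plan["status"],
                principal_diagnosis=plan["dx"],
                additional_diagnoses=coded_diagnoses(i),
                ext_mechanism=plan["triple"][0],
                ext_place=plan["triple"][1],
                ext_activity=plan["triple"][2],
                procedure_codes=plan["procs"],
                key_sex=sexes[i],
                key_dob=dob.date().isoformat(),
                key_postcode=postcodes[i],
                key_medicare=medicare[i],
                key_country=countries[i],
            )
            partner = None
            if plan.get("partner_prev") and plan["event_id"] in prev_eid_by_event:
                partner = prev_eid_by_event[plan["event_id"]]
            if plan["event_id"] is not None:
                prev_eid_by_event[plan["event_id"]] = eid
            truth_ep_rows.append(
                dict(
                    episode_id=eid, true_person_id=i,
                    true_incident_event_id=(
                        plan["event_id"] if plan["role"] == "index" else None
                    ),
                    chain_event_id=plan["event_id"], role=plan["role"],
                    transfer_partner=partner,
                )
            )

    episodes = pd.DataFrame(builder.rows, columns=EPISODE_COLUMNS)
    truth = CohortTruth(
        episodes=pd.DataFrame(truth_ep_rows).astype(
            {"true_incident_event_id": "Int64", "transfer_partner": "Int64"}
        ),
        persons=pd.DataFrame(person_rows),
        events=(
            pd.DataFrame(event_rows)
            .assign(
                admission_date=lambda d: start + pd.to_timedelta(d["day"], unit="D")
            )
            .drop(columns=["day"])
            if event_rows
            else pd.DataFrame(
                columns=["event_id", "person_id", "is_second", "community", "admission_date"]
            )
        ),
    )
    return episodes, truth


def corrupt_linkage_keys(
    episodes: pd.DataFrame,
    truth: CohortTruth,
    spec: CorruptionSpec,
    seed: int = 0,
) -> pd.DataFrame:
    """Independently perturb each episode's recorded linkage keys.

    Models transcription error in recorded identifiers: date-of-birth
    errors, postcode changes (house moves or typos), and Medicare numbers
    missing or mistyped.  Truth is untouched; only the key_* columns change.
    """
    rng = np.random.default_rng(seed)
    out = episodes.copy()
    m = len(out)

    hit = rng.random(m) < spec.dob_error_prob
    if hit.any():
        offsets = rng.choice([-3650, -365, -30, -10, -1, 1, 10, 30, 365, 3650], size=m)
        dob = pd.to_datetime(out["key_dob"], errors="coerce")
        new = (dob + pd.to_timedelta(offsets, unit="D")).dt.date.astype(str)
        out.loc[hit, "key_dob"] = new[hit]

    hit = rng.random(m) < spec.postcode_change_prob
    if hit.any():
        out.loc[hit, "key_postcode"] = [
            f"{3000 + rng.integers(0, 1000)}" for _ in range(int(hit.sum()))
        ]

    hit = rng.random(m) < spec.medicare_missing_prob
    out.loc[hit, "key_medicare"] = ""

    hit = (rng.random(m) < spec.medicare_error_prob) & (out["key_medicare"] != "")
    if hit.any():
        def mangle(s: str) -> str:
            pos = rng.integers(0, len(s))
            digit = str((int(s[pos]) + 1 + rng.integers(0, 9)) % 10)
            return s[:pos] + digit + s[pos + 1:]

        out.loc[hit, "key_medicare"] = out.loc[hit, "key_medicare"].map(mangle)
    return out


def population_table(
    config: SimulationConfig,
    bands: tuple[str, ...] = DEFAULT_AGE_BANDS,
) -> pd.DataFrame:
    """Synthetic age-sex population denominators per fiscal year.

    The source population has its own (younger) age-sex structure,
    configured separately from the case mix; hip-fracture cases are much
    older than the population they arise from, which is what drives the
    age gradient in admission rates.  The community denominator subtracts
    nursing-home residents, because the incidence analysis targets
    community-dwelling people only.
    """
    shares = config.population_age_band_shares
    missing = [b for b in bands if b not in shares]
    if missing:
        raise ValueError(f"population_age_band_shares lacks bands {missing}")
    total_share = sum(shares[b] for b in bands)
    shares = {b: shares[b] / total_share for b in bands}
    years = sorted(
        {
            fiscal_year(pd.Timestamp(config.study_start)),
            fiscal_year(pd.Timestamp(config.study_end)),
        }
        | {
            fiscal_year(pd.Timestamp(config.study_start) + pd.Timedelta(days=d))
            for d in range(0, (pd.Timestamp(config.study_end) - pd.Timestamp(config.study_start)).days, 300)
        }
    )
    rows = []
    ff = config.population_female_fraction
    for year in years:
        for sex, frac in (("F", ff), ("M", 1 - ff)):
            for band in bands:
                pop = int(round(config.resolved_total_population * frac * shares[band]))
                nh = int(round(pop * config.nursing_home_fraction))
                rows.append(
                    dict(
                        fiscal_year=year, sex=sex, age_band=band,
                        population_estimate=pop, nursing_home_residents=nh,
                        community_denominator=pop - nh,
                    )
                )
    return pd.DataFrame(rows)
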