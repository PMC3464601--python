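"""Configuration models for the simulator, linkage and pipeline.

All stochastic behaviour of an experiment is governed by a single
:class:`ExperimentConfig` (one seed, one simulation spec, one linkage spec),
so a run is fully reproducible from the config file alone.
"""

from __future__ import annotations

from datetime import date
from pathlib import Path

import yaml
from pydantic import BaseModel, Field, model_validator

#: Person-level comorbidity prevalences used as generator defaults.  These
#: emulate the comorbidity mix of community-dwelling older hip-fracture
#: patients ascertained from linked discharge data (fractions, not %).
DEFAULT_COMORBIDITY_PREVALENCES: dict[str, float] = {
    "renal_disease": 0.076,
    "dementia": 0.071,
    "congestive_heart_failure": 0.057,
    "diabetes": 0.054,
    "diabetes_with_complications": 0.053,
    "chronic_pulmonary_disease": 0.043,
    "osteoporosis": 0.039,
    "parkinsons_disease": 0.030,
    "delirium": 0.026,
    "cerebrovascular_disease": 0.022,
    "myocardial_infarction": 0.020,
    "cancer": 0.018,
    "vision_impairment": 0.017,
    "deafness": 0.014,
    "hemiplegia_paraplegia": 0.013,
    "peptic_ulcer_disease": 0.002,
    "mild_liver_disease": 0.002,
    "rheumatologic_disease": 0.001,
}

#: Default stepwise deterministic matching passes (a configurable emulation
#: of a multi-pass production linkage system, not a claim about any real one).
DEFAULT_LINKAGE_PASSES: list[list[str]] = [
    ["key_sex", "key_dob", "key_medicare"],
    ["key_sex", "key_dob", "key_postcode", "key_country"],
    ["key_medicare"],
]


class _Prob(float):
    pass


class CorruptionSpec(BaseModel):
    """Per-episode, independent corruption probabilities for linkage keys.

    Defaults are calibrated so that the shipped three-pass matcher run on
    default synthetic data misses about 15% of same-person inter-hospital
    transfer pairs (false negatives) while keeping the rate of incorrectly
    merged pairs in the 1-2% range (false positives).
    """

    dob_error_prob: float = Field(0.082, ge=0, le=1)
    postcode_change_prob: float = Field(0.205, ge=0, le=1)
    medicare_missing_prob: float = Field(0.16, ge=0, le=1)
    medicare_error_prob: float = Field(0.065, ge=0, le=1)

    @classmethod
    def none(cls) -> "CorruptionSpec":
        """A spec that leaves every key untouched."""
        return cls(
            dob_error_prob=0.0,
            postcode_change_prob=0.0,
            medicare_missing_prob=0.0,
            medicare_error_prob=0.0,
        )


class SimulationConfig(BaseModel):
    """Parameters of the synthetic episode-level discharge data generator.

    The simulated cohort is the set of community- and nursing-home-dwelling
    people aged 65+ who have at least one fall-related hospital admission in
    the study window; ``fracture_hazard`` is the probability such a person's
    fall injury is (or includes) a hip fracture event.
    """

    n_persons: int = Field(5000, gt=0)
    study_start: date = date(2005, 7, 1)
    study_end: date = date(2008, 6, 30)

    # demographics
    female_fraction: float = Field(0.72, ge=0, le=1)
    nursing_home_fraction: float = Field(0.25, ge=0, le=1)
    #: age quantile anchors (probability -> age) of the cohort age
    #: distribution; interpolated monotonically. Defaults give median 81,
    #: IQR 72-86 on support [65, 105].
    age_quantile_anchors: dict[float, float] = Field(
        default_factory=lambda: {0.0: 65.0, 0.25: 72.0, 0.5: 81.0, 0.75: 86.0, 1.0: 105.0}
    )

    # event process
    fracture_hazard: float = Field(0.5, ge=0, le=1)
    second_fracture_prob: float = Field(0.023, ge=0, le=1)
    second_fracture_gap_log_median: float = Field(335.0, gt=0)
    second_fracture_gap_log_sigma: float = Field(0.694, gt=0)
    second_fracture_gap_min: int = Field(120, ge=0)
    ext_cause_triple_always_differs: bool = True

    # nuisance (multiple-counting) processes
    transfer_prob: float = Field(0.25, ge=0, le=1)
    readmission_30d_prob: float = Field(0.12, ge=0, le=1)
    readmission_120d_prob: float = Field(0.10, ge=0, le=1)
    revision_readmission_prob: float = Field(0.30, ge=0, le=1)
    nonacute_episode_prob: float = Field(0.20, ge=0, le=1)
    nonemergency_readmission_prob: float = Field(0.50, ge=0, le=1)
    inhospital_death_prob: float = Field(0.05, ge=0, le=1)
    nonfracture_fall_rate: float = Field(0.8, ge=0)

    # hospitals
    public_hospital_fraction: float = Field(0.8, ge=0, le=1)
    same_hospital_readmission_prob: float = Field(0.81, ge=0, le=1)
    n_hospitals: int = Field(60, gt=1)

    # comorbidity coding
    comorbidity_prevalences: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_COMORBIDITY_PREVALENCES)
    )
    per_episode_coding_prob: float = Field(0.75, ge=0, le=1)
    hospital_acquired_prob: float = Field(0.05, ge=0, le=1)

    # linkage keys
    key_corruption: CorruptionSpec = Field(default_factory=CorruptionSpec)
    shared_medicare_prob: float = Field(0.012, ge=0, le=1)

    # population denominators; None -> scaled to the cohort (44 persons of
    # source population per cohort member, giving realistic per-100k rates)
    total_population_per_year: int | None = Field(None, gt=0)
    #: age structure of the source population (declining with age, unlike
    #: the older case mix — this is what produces the age gradient in rates)
    population_age_band_shares: dict[str, float] = Field(
        default_factory=lambda: {
            "65-69": 0.32, "70-74": 0.26, "75-79": 0.19, "80-84": 0.13, "85+": 0.10,
        }
    )
    population_female_fraction: float = Field(0.54, ge=0, le=1)

    seed: int = 0

    @property
    def resolved_total_population(self) -> int:
        if self.total_population_per_year is not None:
            return self.total_population_per_year
        return 44 * self.n_persons

    @model_validator(mode="after")
    def _check(self) -> "SimulationConfig":
        if self.study_start >= self.study_end:
            raise ValueError("study_start must precede study_end")
        for p, a in self.age_quantile_anchors.items():
            if not 0 <= p <= 1:
                raise ValueError("age_quantile_anchors: probabilities must be in [0,1]")
        anchors = sorted(self.age_quantile_anchors.items())
        ages = [a for _, a in anchors]
        if ages != sorted(ages) or anchors[0][0] != 0 or anchors[-1][0] != 1:
            raise ValueError(
                "age_quantile_anchors must span p=0..1 with non-decreasing ages"
            )
        for cond, p in self.comorbidity_prevalences.items():
            if not 0 <= p <= 1:
                raise ValueError(f"comorbidity_prevalences[{cond}] must be in [0,1]")
        if self.second_fracture_gap_min < 0:
            raise ValueError("second_fracture_gap_min must be >= 0")
        return self


class ExperimentConfig(BaseModel):
    """End-to-end experiment: simulate, corrupt, link, select, evaluate."""

    simulation: SimulationConfig = Field(default_factory=SimulationConfig)
    linkage_passes: list[list[str]] = Field(
        default_factory=lambda: [list(p) for p in DEFAULT_LINKAGE_PASSES]
    )
    scenarios: list[str] = Field(
        default_factory=lambda: ["base", "S1", "S2", "S3", "S4"]
    )
    ci_method: str = "wilson"
    age_bands: list[str] = Field(
        default_factory=lambda: ["65-69", "70-74", "75-79", "80-84", "85+"]
    )
    readmission_window_days: int = Field(30, ge=0)
    clearance_days: int = Field(120, ge=0)
    lookback: bool = True
    out_dir: str | None = None
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "ExperimentConfig":
        if not self.linkage_passes or any(len(p) == 0 for p in self.linkage_passes):
            raise ValueError("linkage_passes must be a non-empty list of non-empty key lists")
        if self.ci_method not in {"wilson", "exact", "wald"}:
            raise ValueError("ci_method must be one of wilson|exact|wald")
        return self


def load_config(path: str | Path) -> ExperimentConfig:
    """Read an :class:`ExperimentConfig` from a YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return ExperimentConfig.model_validate(raw)


def save_config(cfg: ExperimentConfig, path: str | Path) -> None:
    """Write a config to YAML; ``load_config`` round-trips it losslessly."""
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.model_dump(mode="json"), fh, sort_keys=False)
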