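"""Generator and pipeline configuration.

A :class:`GeneratorConfig` fully determines a synthetic cohort: reference-panel
structure (Balding-Nichols differentiation), admixture distributions per ethnic
group, the ancestry -> self-identification model, covariate marginals per group,
effect sizes on the log-CRP scale, and disease (phecode) prevalence models.
Configurations serialize to YAML and round-trip exactly.

The packaged presets transcribe the marginals and fitted coefficients of a large
two-ethnicity biobank cohort (Black / White, n = 433,298) as generative ground
truth; see :func:`load_preset`.
"""

from __future__ import annotations

import dataclasses
import hashlib
import math
from dataclasses import dataclass, field

import numpy as np
import yaml

from .exceptions import ConfigurationError

SMOKING_LEVELS = ("never", "previous", "current", "prefer_not_to_answer")
INSOMNIA_LEVELS = ("never_rarely", "sometimes", "usually", "prefer_not_to_answer")

#: Recognised keys of ``crp_effects`` and the covariate each applies to.
CRP_EFFECT_KEYS = (
    "intercept",
    "ethnicity",            # indicator of Black ethnicity
    "age",                  # per year, applied to mean-centered age
    "sex_male",             # indicator of male sex
    "bmi",                  # per kg/m^2
    "townsend",             # per Townsend unit
    "smoking_previous",
    "smoking_current",
    "smoking_prefer_not_to_answer",
    "insomnia_sometimes",
    "insomnia_usually",
    "insomnia_prefer_not_to_answer",
    "mdd",
    "recruitment_year",     # per year, applied to (year - mid-span year)
    "pc1",
    "pc2",
    "ethnicity_sex",        # Black x male interaction
)

# Stage names for the documented seed-splitting rule (see child_rng).
STAGES = (
    "reference_panel",
    "admixed_cohort",
    "ethnic_identity",
    "covariates",
    "crp",
    "disease_codes",
)


def child_rng(seed: int, stage: str) -> np.random.Generator:
    """Deterministic per-stage RNG.

    A single global ``seed`` is fanned out to independent per-stage streams via
    ``np.random.SeedSequence(seed).spawn``-style keys, so any stage can be
    rerun in isolation and reproduce the exact draws of a full run.
    """
    if stage not in STAGES:
        raise ConfigurationError(f"unknown generator stage {stage!r}")
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(STAGES.index(stage),))
    return np.random.default_rng(ss)


@dataclass
class ThetaParams:
    """Mean and SD of a group's African admixture fraction (clipped normal)."""

    mean: float
    sd: float


@dataclass
class GroupCovariates:
    """Per-ethnic-group covariate marginals (independent within group)."""

    age_mean: float
    age_sd: float
    female_p: float
    bmi_mean: float
    bmi_sd: float
    townsend_mean: float
    townsend_sd: float
    pc1_mean: float
    pc1_sd: float
    pc2_mean: float
    pc2_sd: float
    smoking: dict = field(default_factory=dict)   # level -> probability
    insomnia: dict = field(default_factory=dict)  # level -> probability
    mdd_p: float = 0.0


@dataclass
class DiseaseParams:
    """Logistic prevalence model for one phecode.

    P(case) = logistic(baseline + beta_crp * log CRP + beta_eth * [Black]
                       + beta_age * age_centered + beta_sex * [male])
    """

    baseline: float
    beta_crp: float = 0.0
    beta_eth: float = 0.0
    beta_age: float = 0.0
    beta_sex: float = 0.0


@dataclass
class GeneratorConfig:
    n_participants: int = 10_000
    n_variants: int = 10_000
    n_reference_per_pop: int = 200
    fst: float = 0.15
    ancestral_maf_range: tuple = (0.05, 0.5)
    group_proportions: dict = field(default_factory=dict)  # ethnicity -> probability
    group_theta: dict = field(default_factory=dict)        # ethnicity -> ThetaParams
    identity_crossover: float = 0.29
    identity_slope: float = 50.0
    identity_mode: str = "logistic"  # or "threshold" (slope -> infinity limit)
    covariate_params: dict = field(default_factory=dict)   # ethnicity -> GroupCovariates
    recruitment_years: tuple = (2006, 2010)
    crp_effects: dict = field(default_factory=dict)
    crp_sigma: float = 1.0
    disease_params: dict = field(default_factory=dict)     # phecode (str) -> DiseaseParams
    seed: int = 0

    # -- validation ---------------------------------------------------------

    def validate(self) -> "GeneratorConfig":
        def _finite(name, x):
            if not (isinstance(x, (int, float)) and math.isfinite(float(x))):
                raise ConfigurationError(f"{name} must be finite, got {x!r}")
            return float(x)

        if self.n_participants < 1 or self.n_variants < 1:
            raise ConfigurationError("n_participants and n_variants must be >= 1")
        if not (0.0 < _finite("fst", self.fst) < 1.0):
            raise ConfigurationError(f"fst must be in (0, 1), got {self.fst}")
        lo, hi = self.ancestral_maf_range
        if not (0.0 < lo <= hi < 1.0):
            raise ConfigurationError(
                f"ancestral_maf_range must satisfy 0 < lo <= hi < 1, got {self.ancestral_maf_range}"
            )
        if self.group_proportions:
            tot = sum(self.group_proportions.values())
            if abs(tot - 1.0) > 1e-8:
                raise ConfigurationError(f"group_proportions sum to {tot}, expected 1")
        for group, tp in self.group_theta.items():
            if not (0.0 <= tp.mean <= 1.0):
                raise ConfigurationError(f"group_theta[{group}].mean outside [0, 1]")
            if tp.sd < 0:
                raise ConfigurationError(f"group_theta[{group}].sd negative")
        if not (0.0 <= _finite("identity_crossover", self.identity_crossover) <= 1.0):
            raise ConfigurationError("identity_crossover must lie in [0, 1]")
        if self.identity_mode not in ("logistic", "threshold"):
            raise ConfigurationError(f"unknown identity_mode {self.identity_mode!r}")
        if self.identity_mode == "logistic" and not self.identity_slope > 0:
            raise ConfigurationError("identity_slope must be positive")
        for group, cp in self.covariate_params.items():
            for nm in ("age_sd", "bmi_sd", "townsend_sd", "pc1_sd", "pc2_sd"):
                if getattr(cp, nm) <= 0:
                    raise ConfigurationError(f"covariate_params[{group}].{nm} must be > 0")
            for nm in ("female_p", "mdd_p"):
                if not (0.0 <= getattr(cp, nm) <= 1.0):
                    raise ConfigurationError(f"covariate_params[{group}].{nm} outside [0, 1]")
            for cat, levels in (("smoking", SMOKING_LEVELS), ("insomnia", INSOMNIA_LEVELS)):
                probs = getattr(cp, cat)
                if set(probs) - set(levels):
                    raise ConfigurationError(
                        f"covariate_params[{group}].{cat} has unknown levels "
                        f"{sorted(set(probs) - set(levels))}"
                    )
                if abs(sum(probs.values()) - 1.0) > 1e-8:
                    raise ConfigurationError(
                        f"covariate_params[{group}].{cat} probabilities sum to "
                        f"{sum(probs.values())}, expected 1"
                    )
        unknown = set(self.crp_effects) - set(CRP_EFFECT_KEYS)
        if unknown:
            raise ConfigurationError(
                f"crp_effects names effects for absent covariates: {sorted(unknown)}"
            )
        for k, v in self.crp_effects.items():
            _finite(f"crp_effects[{k}]", v)
        if not self.crp_sigma > 0:
            raise ConfigurationError(f"crp_sigma must be > 0, got {self.crp_sigma}")
        y0, y1 = self.recruitment_years
        if y1 < y0:
            raise ConfigurationError("recruitment_years must be (first, last) with first <= last")
        return self

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        def _plain(x):
            if isinstance(x, dict):
                return {k: _plain(v) for k, v in x.items()}
            if isinstance(x, (list, tuple)):
                return [_plain(v) for v in x]
            if isinstance(x, np.generic):
                return x.item()
            return x

        d = _plain(dataclasses.asdict(self))
        d["ancestral_maf_range"] = list(d["ancestral_maf_range"])
        d["recruitment_years"] = list(d["recruitment_years"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown configuration fields: {sorted(unknown)}")
        if "ancestral_maf_range" in d:
            d["ancestral_maf_range"] = tuple(d["ancestral_maf_range"])
        if "recruitment_years" in d:
            d["recruitment_years"] = tuple(d["recruitment_years"])
        if "group_theta" in d:
            d["group_theta"] = {
                g: tp if isinstance(tp, ThetaParams) else ThetaParams(**tp)
                for g, tp in d["group_theta"].items()
            }
        if "covariate_params" in d:
            d["covariate_params"] = {
                g: cp if isinstance(cp, GroupCovariates) else GroupCovariates(**cp)
                for g, cp in d["covariate_params"].items()
            }
        if "disease_params" in d:
            d["disease_params"] = {
                str(p): dp if isinstance(dp, DiseaseParams) else DiseaseParams(**dp)
                for p, dp in d["disease_params"].items()
            }
        return cls(**d).validate()

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "GeneratorConfig":
        if hasattr(source, "read"):
            text = source.read()
        else:
            try:
                with open(source) as fh:
                    text = fh.read()
            except (OSError, ValueError):
                text = str(source)
        return cls.from_dict(yaml.safe_load(text))

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()

    def replace(self, **kw) -> "GeneratorConfig":
        return dataclasses.replace(self, **kw).validate()


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

#: Observed White-group CRP marginal used to calibrate the generator:
#: mean 2.59 mg/L with 22.58% of values above the clinical 3 mg/L threshold.
WHITE_CRP_SPEC = {"target_mean": 2.59, "target_exceedance": 0.2258, "threshold": 3.0}

_BASE_EFFECTS = {"intercept": 0.0, "ethnicity": 0.08, "age": 0.02, "sex_male": -0.06}

_FULL_EFFECTS = {
    "intercept": 0.0,
    "ethnicity": 0.43,
    "age": 0.03,
    "sex_male": -0.46,
    "bmi": 0.22,
    "insomnia_prefer_not_to_answer": 0.1,
    "insomnia_sometimes": 0.05,
    "insomnia_usually": 0.16,
    "mdd": 0.68,
    "recruitment_year": -0.07,
    "smoking_current": 0.84,
    "smoking_prefer_not_to_answer": 0.24,
    "smoking_previous": 0.05,
    "pc1": 0.0,
    "pc2": 0.01,
    "townsend": 0.04,
}

_INTERACTION_EFFECTS = dict(_BASE_EFFECTS, ethnicity_sex=-0.9)


def _ukbb_covariates() -> dict:
    """Covariate marginals per ethnic group.

    Age, sex, and Townsend transcribe the cohort's per-group marginals; BMI,
    smoking, insomnia and MDD are not reported per group in the source table
    and use realistic biobank-scale values (documented in the methods note).
    The pc1/pc2 columns are synthetic proxies of the top genotype PCs (ancestry
    separated), used only when the genotype stage is skipped.
    """
    white = GroupCovariates(
        age_mean=56.78, age_sd=8.02, female_p=0.5426,
        bmi_mean=27.4, bmi_sd=4.7,
        townsend_mean=-1.48, townsend_sd=2.98,
        pc1_mean=0.0, pc1_sd=0.8, pc2_mean=0.0, pc2_sd=0.7,
        smoking={"never": 0.55, "previous": 0.345, "current": 0.10,
                 "prefer_not_to_answer": 0.005},
        insomnia={"never_rarely": 0.25, "sometimes": 0.47, "usually": 0.278,
                  "prefer_not_to_answer": 0.002},
        mdd_p=0.006,
    )
    black = GroupCovariates(
        age_mean=52.08, age_sd=8.08, female_p=0.5764,
        bmi_mean=29.6, bmi_sd=5.2,
        townsend_mean=2.63, townsend_sd=3.42,
        pc1_mean=8.0, pc1_sd=3.0, pc2_mean=2.0, pc2_sd=1.5,
        smoking={"never": 0.62, "previous": 0.23, "current": 0.14,
                 "prefer_not_to_answer": 0.01},
        insomnia={"never_rarely": 0.30, "sometimes": 0.45, "usually": 0.24,
                  "prefer_not_to_answer": 0.01},
        mdd_p=0.008,
    )
    return {"White": white, "Black": black}


def _toy_disease_params() -> dict:
    """Disease models loosely following the top disparity-table effect sizes."""
    return {
        "10.0":   DiseaseParams(baseline=-6.4, beta_crp=0.5553, beta_eth=2.4005),
        "71.0":   DiseaseParams(baseline=-6.8, beta_crp=0.4330, beta_eth=2.1890),
        "250.2":  DiseaseParams(baseline=-3.6, beta_crp=0.4181, beta_eth=1.2079,
                                beta_age=0.03, beta_sex=0.3),
        "250.1":  DiseaseParams(baseline=-5.5, beta_crp=0.05, beta_eth=0.4),
        "251.1":  DiseaseParams(baseline=-5.8, beta_crp=0.4070, beta_eth=1.1555),
        "401.1":  DiseaseParams(baseline=-2.8, beta_crp=0.25, beta_eth=0.7,
                                beta_age=0.05, beta_sex=0.2),
        "401.21": DiseaseParams(baseline=-6.5, beta_crp=0.4050, beta_eth=2.3777),
        "295.1":  DiseaseParams(baseline=-6.0, beta_crp=0.4371, beta_eth=1.5061),
        "585.3":  DiseaseParams(baseline=-5.2, beta_crp=0.4880, beta_eth=1.0582,
                                beta_age=0.06),
        "580.2":  DiseaseParams(baseline=-6.6, beta_crp=0.4383, beta_eth=1.4397),
        "697.0":  DiseaseParams(baseline=-6.5, beta_crp=0.4169, beta_eth=1.6291),
        "695.42": DiseaseParams(baseline=-6.7, beta_crp=0.3087, beta_eth=1.7328,
                                beta_sex=-0.8),
        "282.5":  DiseaseParams(baseline=-8.0, beta_crp=0.2726, beta_eth=6.7412),
    }


def white_group_moments(config: GeneratorConfig) -> tuple:
    """(mean, variance) of the linear predictor within the White group.

    Used to calibrate the preset intercept and residual SD so that the White
    marginal of CRP matches the observed lognormal (mean, exceedance) spec.
    Age is centered at the configured cohort-wide mean age; recruitment year
    at the middle of the span.
    """
    eff = dict(config.crp_effects)
    cp = config.covariate_params["White"]
    props = config.group_proportions
    cohort_age = sum(props[g] * config.covariate_params[g].age_mean for g in props)
    y0, y1 = config.recruitment_years
    years = np.arange(y0, y1 + 1) - (y0 + y1) / 2.0
    e = eff.get

    def cat_moments(probs, prefix):
        vals = {lvl: e(f"{prefix}_{lvl}", 0.0) for lvl in probs}
        m = sum(probs[lvl] * vals[lvl] for lvl in probs)
        v = sum(probs[lvl] * vals[lvl] ** 2 for lvl in probs) - m**2
        return m, v

    sm_m, sm_v = cat_moments(cp.smoking, "smoking")
    in_m, in_v = cat_moments(cp.insomnia, "insomnia")
    male_p = 1.0 - cp.female_p
    mean = (
        e("intercept", 0.0)
        + e("age", 0.0) * (cp.age_mean - cohort_age)
        + e("sex_male", 0.0) * male_p
        + e("bmi", 0.0) * cp.bmi_mean
        + e("townsend", 0.0) * cp.townsend_mean
        + e("pc1", 0.0) * cp.pc1_mean
        + e("pc2", 0.0) * cp.pc2_mean
        + e("mdd", 0.0) * cp.mdd_p
        + e("recruitment_year", 0.0) * years.mean()
        + sm_m + in_m
    )
    var = (
        (e("age", 0.0) * cp.age_sd) ** 2
        + e("sex_male", 0.0) ** 2 * male_p * (1 - male_p)
        + (e("bmi", 0.0) * cp.bmi_sd) ** 2
        + (e("townsend", 0.0) * cp.townsend_sd) ** 2
        + (e("pc1", 0.0) * cp.pc1_sd) ** 2
        + (e("pc2", 0.0) * cp.pc2_sd) ** 2
        + e("mdd", 0.0) ** 2 * cp.mdd_p * (1 - cp.mdd_p)
        + e("recruitment_year", 0.0) ** 2 * years.var()
        + sm_v + in_v
    )
    return mean, var


def _calibrate_preset(config: GeneratorConfig) -> GeneratorConfig:
    """Solve the preset intercept and residual SD from the White CRP marginal."""
    from .synthgen import calibrate_lognormal  # late import to avoid a cycle

    mu_w, sigma_w = calibrate_lognormal(**WHITE_CRP_SPEC)
    mean_lp, var_lp = white_group_moments(config)
    resid_var = sigma_w**2 - var_lp
    if resid_var <= 0:
        raise ConfigurationError(
            "configured covariate effects already exceed the target log-CRP variance"
        )
    eff = dict(config.crp_effects)
    eff["intercept"] = eff.get("intercept", 0.0) + (mu_w - mean_lp)
    return config.replace(crp_effects=eff, crp_sigma=float(np.sqrt(resid_var)))


PRESET_NAMES = ("ukbb2021", "ukbb2021-base", "ukbb2021-interaction", "ukbb2021-small")


def load_preset(name: str, n_participants: int | None = None,
                seed: int | None = None) -> GeneratorConfig:
    """Return a packaged preset configuration.

    ``ukbb2021``             Table-style fully adjusted coefficients as truth.
    ``ukbb2021-base``        base-model coefficients (ethnicity 0.08, age 0.02,
                             male -0.06) as truth; all other effects zero.
    ``ukbb2021-interaction`` base effects plus an ethnicity x sex interaction.
    ``ukbb2021-small``       small fully adjusted smoke preset (n = 2,000,
                             2,000 variants) for end-to-end runs.

    The intercept and residual SD of every preset are calibrated so the White
    group's marginal CRP distribution has mean 2.59 mg/L and 22.58% exceedance
    of the 3 mg/L clinical threshold.
    """
    if name not in PRESET_NAMES:
        raise ConfigurationError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    effects = {
        "ukbb2021": _FULL_EFFECTS,
        "ukbb2021-base": _BASE_EFFECTS,
        "ukbb2021-interaction": _INTERACTION_EFFECTS,
        "ukbb2021-small": _FULL_EFFECTS,
    }[name]
    small = name == "ukbb2021-small"
    config = GeneratorConfig(
        n_participants=2_000 if small else 50_000,
        n_variants=2_000 if small else 10_000,
        n_reference_per_pop=50 if small else 200,
        fst=0.15,
        ancestral_maf_range=(0.05, 0.5),
        group_proportions={"Black": 6_456 / 433_298, "White": 426_842 / 433_298},
        group_theta={"Black": ThetaParams(0.8781, 0.1050),
                     "White": ThetaParams(0.0003, 0.0046)},
        identity_crossover=0.29,
        identity_slope=50.0,
        identity_mode="logistic",
        covariate_params=_ukbb_covariates(),
        recruitment_years=(2006, 2010),
        crp_effects=dict(effects),
        crp_sigma=1.0,  # replaced by calibration below
        disease_params=_toy_disease_params(),
        seed=0,
    )
    config = _calibrate_preset(config)
    if n_participants is not None:
        config = config.replace(n_participants=int(n_participants))
    if seed is not None:
        config = config.replace(seed=int(seed))
    return config.validate()
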