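"""Synthetic cohort generator.

Emulates the data structure of a two-ethnicity biobank cohort: Balding-Nichols
reference panels for two continental ancestries, an admixed study cohort with
per-group admixture distributions, an ancestry-driven ethnic self-identification
model, group-specific covariate marginals, a log-normal CRP model driven by
configurable effect sizes, and phecode-linked ICD-10 disease codes generated
from per-disease logistic prevalence models.

Every operation is deterministic given the configuration seed; stages use
independent sub-streams (see :func:`crpdecomp.config.child_rng`) so any stage
can be rerun in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import (
    GeneratorConfig,
    INSOMNIA_LEVELS,
    SMOKING_LEVELS,
    child_rng,
)
from .exceptions import CalibrationError, ConfigurationError
from .genotypes import GenotypeMatrix, VARIANT_COLUMNS

#: Reference population label per ancestry group (one panel population each).
PANEL_POPULATIONS = {"AFR_ref": "African", "EUR_ref": "European"}

# Non strand-ambiguous ref/alt pairs used for simulated variants, so that
# harmonization never discards simulated data as A/T or C/G ambiguous.
_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "C"), ("T", "G"),
                 ("G", "A"), ("C", "A"), ("C", "T"), ("G", "T")]


@dataclass
class ReferencePanel:
    """Labeled reference genotypes plus the generative truth behind them."""

    genotypes: GenotypeMatrix
    population_labels: np.ndarray          # per reference sample
    ancestry_groups: dict                  # population -> regional group
    population_freqs: pd.DataFrame         # per-variant true allele frequency per population
    ancestral_freqs: np.ndarray            # per-variant ancestral frequency

    def __post_init__(self):
        pops = set(self.population_labels)
        if pops - set(self.ancestry_groups):
            raise ConfigurationError("every population must map to exactly one group")
        counts = pd.Series(self.population_labels).map(self.ancestry_groups).value_counts()
        if len(counts) < 2 or (counts < 2).any():
            raise ConfigurationError("need >= 2 ancestry groups with >= 2 samples each")

    def group_of(self, sample_index: int) -> str:
        return self.ancestry_groups[self.population_labels[sample_index]]

    def group_freqs(self, group: str) -> np.ndarray:
        pops = [p for p, g in self.ancestry_groups.items() if g == group]
        if not pops:
            raise ConfigurationError(f"panel has no population in group {group!r}")
        return self.population_freqs[pops].mean(axis=1).to_numpy()


@dataclass
class TrueAncestry:
    """Generative admixture truth (unobservable in real data)."""

    theta_afr: np.ndarray   # per-participant African admixture fraction in [0, 1]
    group: np.ndarray       # per-participant ethnic group used to draw theta


def _variant_frame(n_variants: int, rng: np.random.Generator) -> pd.DataFrame:
    pairs = [_ALLELE_PAIRS[i] for i in rng.integers(0, len(_ALLELE_PAIRS), n_variants)]
    pos = np.arange(1, n_variants + 1) * 1_000
    return pd.DataFrame(
        {
            "chrom": "1",
            "pos": pos,
            "ref": [p[0] for p in pairs],
            "alt": [p[1] for p in pairs],
            "id": [f"1:{p}" for p in pos],
        }
    )[VARIANT_COLUMNS]


def simulate_reference_panel(config: GeneratorConfig) -> ReferencePanel:
    """Simulate two-population reference panels under the Balding-Nichols model.

    Ancestral frequencies are uniform on ``ancestral_maf_range``; each
    population's frequency is Beta(p(1-F)/F, (1-p)(1-F)/F) around the
    ancestral p with differentiation F = ``fst``; reference genotypes are
    Binomial(2, population frequency).
    """
    config.validate()
    rng = child_rng(config.seed, "reference_panel")
    lo, hi = config.ancestral_maf_range
    p_anc = rng.uniform(lo, hi, config.n_variants)
    F = config.fst
    scale = (1.0 - F) / F
    freqs = {}
    for pop in PANEL_POPULATIONS:
        freqs[pop] = rng.beta(p_anc * scale, (1.0 - p_anc) * scale)
    variants = _variant_frame(config.n_variants, rng)
    n = config.n_reference_per_pop
    blocks, labels, ids = [], [], []
    for pop in PANEL_POPULATIONS:
        blocks.append(rng.binomial(2, freqs[pop][None, :], (n, config.n_variants)))
        labels += [pop] * n
        ids += [f"{pop}_{i}" for i in range(n)]
    genotypes = GenotypeMatrix(np.array(ids, dtype=object), variants,
                               np.vstack(blocks).astype(float))
    return ReferencePanel(
        genotypes=genotypes,
        population_labels=np.array(labels, dtype=object),
        ancestry_groups=dict(PANEL_POPULATIONS),
        population_freqs=pd.DataFrame(freqs),
        ancestral_freqs=p_anc,
    )


def draw_admixture(config: GeneratorConfig, rng=None) -> TrueAncestry:
    """Draw each participant's ethnic group and African admixture fraction.

    Groups follow ``group_proportions``; theta is Normal(group mean, group SD)
    clipped to [0, 1] — the clipping reproduces the point masses of fully
    African- or European-ancestry participants seen in real cohorts.
    """
    if rng is None:
        rng = child_rng(config.seed, "admixed_cohort")
    groups = sorted(config.group_proportions)
    if not groups:
        raise ConfigurationError("group_proportions is empty")
    probs = [config.group_proportions[g] for g in groups]
    group = rng.choice(groups, size=config.n_participants, p=probs)
    theta = np.empty(config.n_participants)
    for g in groups:
        if g not in config.group_theta:
            raise ConfigurationError(f"group_theta missing for configured group {g!r}")
        tp = config.group_theta[g]
        mask = group == g
        theta[mask] = rng.normal(tp.mean, tp.sd, mask.sum())
    return TrueAncestry(theta_afr=np.clip(theta, 0.0, 1.0), group=group.astype(object))


def simulate_admixed_cohort(config: GeneratorConfig, panel: ReferencePanel):
    """Simulate study genotypes for an admixed cohort.

    Returns ``(GenotypeMatrix, TrueAncestry)``. Genotypes are
    Binomial(2, theta * f_AFR + (1 - theta) * f_EUR) per variant, using the
    panel's true population frequencies.
    """
    config.validate()
    for g in ("African", "European"):
        if g not in set(panel.ancestry_groups.values()):
            raise ConfigurationError(f"panel lacks required ancestry group {g!r}")
    rng = child_rng(config.seed, "admixed_cohort")
    truth = draw_admixture(config, rng)
    f_afr = panel.group_freqs("African")
    f_eur = panel.group_freqs("European")
    p = truth.theta_afr[:, None] * f_afr[None, :] + (1.0 - truth.theta_afr[:, None]) * f_eur[None, :]
    dosages = rng.binomial(2, p).astype(float)
    ids = np.array([f"S{i:06d}" for i in range(config.n_participants)], dtype=object)
    return GenotypeMatrix(ids, panel.genotypes.variants.copy(), dosages), truth


def assign_ethnic_identity(theta, config: GeneratorConfig, rng=None) -> np.ndarray:
    """Draw Black/White self-identification labels from admixture.

    P(identify Black | theta) = logistic(slope * (theta - crossover)); in
    ``threshold`` mode (the slope -> infinity limit) the label is Black iff
    theta >= crossover.
    """
    config.validate()
    theta = np.asarray(getattr(theta, "theta_afr", theta), dtype=float)
    if config.identity_mode == "threshold":
        black = theta >= config.identity_crossover
    else:
        if rng is None:
            rng = child_rng(config.seed, "ethnic_identity")
        p_black = 1.0 / (1.0 + np.exp(-config.identity_slope * (theta - config.identity_crossover)))
        black = rng.uniform(size=theta.shape) < p_black
    return np.where(black, "Black", "White").astype(object)


def simulate_covariates(config: GeneratorConfig, ethnicity, rng=None) -> pd.DataFrame:
    """Simulate the participant covariate table given ethnic identities.

    Continuous covariates are Normal per group; smoking, insomnia and sex are
    categorical per group; MDD is Bernoulli; recruitment year is uniform over
    the configured span. Covariates are independent within group.
    """
    config.validate()
    if rng is None:
        rng = child_rng(config.seed, "covariates")
    ethnicity = np.asarray(ethnicity, dtype=object)
    n = len(ethnicity)
    for g in np.unique(ethnicity):
        if g not in config.covariate_params:
            raise ConfigurationError(f"covariate_params missing for group {g!r}")
    df = pd.DataFrame({
        "participant_id": [f"S{i:06d}" for i in range(n)],
        "ethnicity": ethnicity,
        "age": np.nan, "sex": "", "bmi": np.nan, "townsend": np.nan,
        "pc1": np.nan, "pc2": np.nan, "smoking": "", "insomnia": "",
        "mdd": 0,
        "recruitment_year": rng.integers(config.recruitment_years[0],
                                         config.recruitment_years[1] + 1, n),
    })
    for g in np.unique(ethnicity):
        cp = config.covariate_params[g]
        m = ethnicity == g
        k = int(m.sum())
        df.loc[m, "age"] = rng.normal(cp.age_mean, cp.age_sd, k)
        df.loc[m, "sex"] = np.where(rng.uniform(size=k) < cp.female_p, "female", "male")
        df.loc[m, "bmi"] = rng.normal(cp.bmi_mean, cp.bmi_sd, k)
        df.loc[m, "townsend"] = rng.normal(cp.townsend_mean, cp.townsend_sd, k)
        df.loc[m, "pc1"] = rng.normal(cp.pc1_mean, cp.pc1_sd, k)
        df.loc[m, "pc2"] = rng.normal(cp.pc2_mean, cp.pc2_sd, k)
        for col, levels, probs in (("smoking", SMOKING_LEVELS, cp.smoking),
                                   ("insomnia", INSOMNIA_LEVELS, cp.insomnia)):
            lv = [l for l in levels if l in probs]
            df.loc[m, col] = rng.choice(lv, size=k, p=[probs[l] for l in lv])
        df.loc[m, "mdd"] = (rng.uniform(size=k) < cp.mdd_p).astype(int)
    df["mdd"] = df["mdd"].astype(int)
    df["recruitment_year"] = df["recruitment_year"].astype(int)
    return df


def crp_linear_predictor(table: pd.DataFrame, config: GeneratorConfig) -> np.ndarray:
    """Evaluate the configured log-CRP linear predictor on a covariate table.

    Age enters mean-centered at the realized cohort mean; recruitment year
    enters centered at the middle of the configured span (a pure intercept
    shift relative to raw-year coding).
    """
    eff = config.crp_effects
    e = eff.get
    y_mid = sum(config.recruitment_years) / 2.0
    black = (table["ethnicity"] == "Black").to_numpy(float)
    male = (table["sex"] == "male").to_numpy(float)
    lp = np.full(len(table), e("intercept", 0.0))
    lp += e("ethnicity", 0.0) * black
    lp += e("age", 0.0) * (table["age"].to_numpy() - table["age"].mean())
    lp += e("sex_male", 0.0) * male
    lp += e("bmi", 0.0) * table["bmi"].to_numpy()
    lp += e("townsend", 0.0) * table["townsend"].to_numpy()
    lp += e("pc1", 0.0) * table["pc1"].to_numpy()
    lp += e("pc2", 0.0) * table["pc2"].to_numpy()
    lp += e("mdd", 0.0) * table["mdd"].to_numpy(float)
    lp += e("recruitment_year", 0.0) * (table["recruitment_year"].to_numpy(float) - y_mid)
    for lvl in ("previous", "current", "prefer_not_to_answer"):
        lp += e(f"smoking_{lvl}", 0.0) * (table["smoking"] == lvl).to_numpy(float)
    for lvl in ("sometimes", "usually", "prefer_not_to_answer"):
        lp += e(f"insomnia_{lvl}", 0.0) * (table["insomnia"] == lvl).to_numpy(float)
    lp += e("ethnicity_sex", 0.0) * black * male
    return lp


def simulate_crp(table: pd.DataFrame, config: GeneratorConfig, rng=None) -> pd.DataFrame:
    """Add a ``crp`` column (mg/L): CRP = exp(linear predictor + N(0, sigma))."""
    config.validate()
    if rng is None:
        rng = child_rng(config.seed, "crp")
    out = table.copy()
    lp = crp_linear_predictor(table, config)
    out["crp"] = np.exp(lp + rng.normal(0.0, config.crp_sigma, len(table)))
    return out


def calibrate_lognormal(target_mean: float, target_exceedance: float,
                        threshold: float, tail: str = "heavy") -> tuple:
    """Solve (mu, sigma) of a lognormal with a given mean and tail exceedance.

    Finds mu, sigma such that E[X] = ``target_mean`` and
    P(X > ``threshold``) = ``target_exceedance`` for X ~ lognormal(mu, sigma).
    Substituting mu = ln(threshold) - c * sigma with c = Phi^{-1}(1 - q) into
    the mean identity exp(mu + sigma^2/2) = m gives the quadratic
    sigma^2/2 - c*sigma + ln(threshold/m) = 0. Both positive roots can be
    valid; ``tail='heavy'`` (default) picks the larger sigma, ``'light'`` the
    smaller.
    """
    if not target_mean > 0:
        raise CalibrationError(f"target_mean must be > 0, got {target_mean}")
    if not 0.0 < target_exceedance < 1.0:
        raise CalibrationError("target_exceedance must lie strictly in (0, 1)")
    if not threshold > 0:
        raise CalibrationError(f"threshold must be > 0, got {threshold}")
    if tail not in ("heavy", "light"):
        raise CalibrationError(f"tail must be 'heavy' or 'light', got {tail!r}")
    c = stats.norm.ppf(1.0 - target_exceedance)
    logratio = np.log(threshold / target_mean)
    disc = c * c - 2.0 * logratio
    if disc < 0:
        raise CalibrationError(
            "infeasible (mean, exceedance) pair: the exceedance constraint "
            "cannot be met by any positive-sigma lognormal with this mean"
        )
    roots = [c - np.sqrt(disc), c + np.sqrt(disc)]
    roots = [s for s in roots if s > 0]
    if not roots:
        raise CalibrationError(
            "infeasible (mean, exceedance) pair: no positive-sigma solution "
            "(the mean constraint forces a non-positive sigma)"
        )
    sigma = max(roots) if tail == "heavy" else min(roots)
    mu = np.log(threshold) - c * sigma
    return float(mu), float(sigma)


def simulate_disease_codes(table: pd.DataFrame, config: GeneratorConfig,
                           phemap, rng=None) -> pd.DataFrame:
    """Add an ``icd10_codes`` column of semicolon-joined diagnosis codes.

    For each configured phecode, case status is Bernoulli with
    logit P(case) = baseline + beta_crp*log(CRP) + beta_eth*[Black]
    + beta_age*age_centered + beta_sex*[male]; each case receives the first
    inclusion ICD-10 code of the phecode's map entry.
    """
    config.validate()
    if rng is None:
        rng = child_rng(config.seed, "disease_codes")
    if "crp" not in table:
        raise ConfigurationError("simulate_disease_codes requires a crp column")
    log_crp = np.log(table["crp"].to_numpy())
    black = (table["ethnicity"] == "Black").to_numpy(float)
    male = (table["sex"] == "male").to_numpy(float)
    age_c = table["age"].to_numpy() - table["age"].mean()
    from .phewas import _normalize_phecode

    codes = [[] for _ in range(len(table))]
    for phecode in sorted(config.disease_params, key=float):
        dp = config.disease_params[phecode]
        entry = phemap.entries.get(_normalize_phecode(phecode))
        if entry is None or not entry.inclusion_codes:
            raise ConfigurationError(
                f"phecode {phecode} absent from map or has no inclusion codes"
            )
        eta = (dp.baseline + dp.beta_crp * log_crp + dp.beta_eth * black
               + dp.beta_age * age_c + dp.beta_sex * male)
        case = rng.uniform(size=len(table)) < 1.0 / (1.0 + np.exp(-eta))
        icd = sorted(entry.inclusion_codes)[0]
        for i in np.nonzero(case)[0]:
            codes[i].append(icd)
    out = table.copy()
    out["icd10_codes"] = [";".join(c) for c in codes]
    return out


def simulate_cohort_table(config: GeneratorConfig, phemap=None) -> pd.DataFrame:
    """Generate a full participant table without the genotype stage.

    Draws admixture truth, self-identified ethnicity, covariates and CRP (and
    disease codes when ``phemap`` is given). The returned table carries the
    true admixture fraction in ``african_fraction``; when genotypes are
    simulated the ancestry stage replaces it with its own estimate.
    """
    truth = draw_admixture(config)
    ethnicity = assign_ethnic_identity(truth.theta_afr, config)
    table = simulate_covariates(config, ethnicity)
    table["african_fraction"] = truth.theta_afr
    table["ancestry_group"] = truth.group
    table = simulate_crp(table, config)
    if phemap is not None and config.disease_params:
        table = simulate_disease_codes(table, config, phemap)
    return table


def write_truth_files(config: GeneratorConfig, truth: TrueAncestry, out_dir) -> None:
    """Write TSV ground-truth files (theta per participant, effect sizes)."""
    import os

    theta = pd.DataFrame({
        "participant_id": [f"S{i:06d}" for i in range(len(truth.theta_afr))],
        "group": truth.group,
        "theta_afr": truth.theta_afr,
    })
    theta.to_csv(os.path.join(out_dir, "truth_theta.tsv"), sep="\t", index=False)
    eff = pd.DataFrame(sorted(config.crp_effects.items()), columns=["effect", "value"])
    eff.to_csv(os.path.join(out_dir, "truth_effects.tsv"), sep="\t", index=False)
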