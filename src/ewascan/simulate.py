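"""Synthetic multi-cohort survey studies with the structure the scan assumes.

The generator emulates the statistical features the pipeline must cope with
in national-health-survey data -- stratified clustered sampling with
lognormal design weights, right-skewed (lognormal) exposure concentrations
censored at an assay detection limit, correlated exposure blocks within an
environmental class, a handful of truly associated factors among many
nulls, and a dichotomous phenotype driven by a logistic model on
standardized log exposures plus demographic covariates. Structure, not
marginal realism per analyte, is the contract: every study carries its own
generated codebook and a truth table of planted per-SD log odds ratios
(zero for null factors), so estimator output can be scored against truth.

The fasting-glucose phenotype is written as a deterministic transform of
the latent case status (cases >= 130 mg/dL, controls < 120 mg/dL, noise
bounded away from the 126 mg/dL threshold), so case classification exactly
inverts the generative label and upstream tests stay sharp.
"""

from __future__ import annotations

import dataclasses
import os
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq
from scipy.special import expit, logit

from .codebook import Codebook, CohortTable, FactorDescriptor

#: environmental class labels used to bin generated factors (survey-style)
CLASS_NAMES = (
    "nutrients", "heavy metals", "organochlorine pesticides",
    "polychlorinated biphenyls", "dioxins", "furans", "phenols",
    "phthalates", "polyaromatic hydrocarbons", "volatile organic compounds",
    "bacteria", "viruses", "allergens", "cotinine", "dialkyl phosphates",
    "perchlorate", "phytoestrogens", "carbamate pesticides",
    "organophosphate pesticides", "pyrethroids", "herbicides",
)

ETHNICITY_LEVELS = ("white", "black", "mexican", "other")
ETHNICITY_PROBS = (0.45, 0.20, 0.20, 0.15)


@dataclasses.dataclass
class SimulationConfig:
    """Full generative specification of a synthetic multi-cohort study.

    Planted effects are per-SD log odds ratios on the standardized
    (population-standardized) log10 exposure; covariate effects act on
    age - 42 (per year), BMI - 27 (per unit), a female indicator, and SES
    tertile indicators (3rd tertile referent), matching the adjustment set
    the scan fits. The linear predictor is centered per cohort so the
    realized prevalence tracks ``baseline_prevalence``.
    """

    n_cohorts: int = 4
    n_per_cohort: int = 2500
    cohort_ids: tuple[str, ...] | None = None
    n_factors: int = 200
    block_size: int = 4
    rho: float = 0.3
    n_strata: int = 15
    psus_per_stratum: int = 3
    weight_mean: float = 10000.0
    weight_sigma: float = 0.5
    informative_weights: bool = False
    baseline_prevalence: float = 0.065
    log_mu: float = 1.0
    log_sigma: float = 0.5
    lod_quantile: float = 0.15
    planted_effects: dict[str, float] = dataclasses.field(default_factory=dict)
    covariate_effects: dict[str, float] = dataclasses.field(
        default_factory=lambda: {"age": 0.03, "bmi": 0.07,
                                 "sex_female": -0.3, "ses_t1": 0.3,
                                 "ses_t2": 0.1})
    missing_rate: float = 0.0
    frac_shared: float = 1.0
    n_subset_targeted: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if not -1.0 < self.rho < 1.0:
            raise ValueError("|rho| must be < 1")
        if not 0.0 <= self.lod_quantile < 1.0:
            raise ValueError("lod_quantile must be in [0, 1)")
        if not 0.0 < self.baseline_prevalence < 1.0:
            raise ValueError("baseline_prevalence must be in (0, 1)")
        if self.n_factors < 1 or self.n_per_cohort < 10:
            raise ValueError("degenerate study size")
        bad = [s for s in self.planted_effects
               if s not in set(factor_symbols(self.n_factors))]
        if bad:
            raise ValueError(f"planted symbols not in factor registry: {bad}")

    @property
    def resolved_cohort_ids(self) -> tuple[str, ...]:
        if self.cohort_ids is not None:
            return tuple(self.cohort_ids)
        return tuple(f"cohort-{i + 1}" for i in range(self.n_cohorts))


def factor_symbols(n_factors: int) -> list[str]:
    return [f"EXP{i:04d}" for i in range(n_factors)]


@dataclasses.dataclass
class SimulatedStudy:
    cohorts: list[CohortTable]
    codebook: Codebook
    truth: pd.DataFrame  # symbol, env_class, log_or, odds_ratio
    config: SimulationConfig


def _block_assignment(cfg: SimulationConfig) -> list[list[int]]:
    """Partition factor indices into correlation blocks.

    Factors carrying a planted effect get singleton blocks: a null factor
    correlated with a causal one has a nonzero *marginal* association, which
    would make the truth table's zero entries ambiguous. Null factors fill
    blocks of ``block_size`` in index order.
    """
    syms = factor_symbols(cfg.n_factors)
    planted = [i for i, s in enumerate(syms) if s in cfg.planted_effects]
    nulls = [i for i in range(cfg.n_factors) if i not in set(planted)]
    blocks = [[i] for i in planted]
    for b0 in range(0, len(nulls), cfg.block_size):
        blocks.append(nulls[b0:b0 + cfg.block_size])
    return blocks


def _make_codebook(cfg: SimulationConfig, lod: float,
                   subset_targeted: set[str],
                   blocks: list[list[int]]) -> Codebook:
    syms = factor_symbols(cfg.n_factors)
    env_class = {}
    for b, idx in enumerate(blocks):
        for i in idx:
            env_class[i] = CLASS_NAMES[b % len(CLASS_NAMES)]
    factors = []
    for i, sym in enumerate(syms):
        factors.append(FactorDescriptor(
            symbol=sym, display_name=f"factor {i}", env_class=env_class[i],
            scale="continuous", units="ng/mL",
            lod=lod if cfg.lod_quantile > 0 else None,
            subset_targeted=sym in subset_targeted))
    return Codebook(factors)


def _measured_pattern(cfg: SimulationConfig,
                      rng: np.random.Generator) -> dict[str, tuple[str, ...]]:
    """Symbol -> cohorts measuring it. Shared factors appear everywhere;
    the rest are single-cohort. Planted factors are always shared."""
    ids = cfg.resolved_cohort_ids
    out: dict[str, tuple[str, ...]] = {}
    for sym in factor_symbols(cfg.n_factors):
        if sym in cfg.planted_effects or rng.random() < cfg.frac_shared:
            out[sym] = ids
        else:
            out[sym] = (ids[rng.integers(len(ids))],)
    return out


def simulate_study(cfg: SimulationConfig,
                   seed: int | None = None) -> SimulatedStudy:
    """Draw a full multi-cohort study; byte-identical given the same seed."""
    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    ids = cfg.resolved_cohort_ids
    syms = factor_symbols(cfg.n_factors)
    lod = float(10.0 ** (cfg.log_mu
                         + stats.norm.ppf(cfg.lod_quantile) * cfg.log_sigma)) \
        if cfg.lod_quantile > 0 else 0.0

    subset_targeted = set(syms[-cfg.n_subset_targeted:]) \
        if cfg.n_subset_targeted else set()
    blocks = _block_assignment(cfg)
    codebook = _make_codebook(cfg, lod, subset_targeted, blocks)
    measured = _measured_pattern(cfg, rng)

    beta = np.array([cfg.planted_effects.get(s, 0.0) for s in syms])
    ce = cfg.covariate_effects

    cohorts = []
    for cid in ids:
        n = cfg.n_per_cohort
        age = np.clip(rng.normal(42.0, 15.0, n), 18.0, 85.0)
        female = rng.random(n) < 0.5
        bmi = np.clip(rng.normal(27.0, 5.0, n), 15.0, 60.0)
        ethnicity = rng.choice(ETHNICITY_LEVELS, size=n, p=ETHNICITY_PROBS)
        poverty = rng.uniform(0.0, 5.0, n)
        cuts = np.quantile(poverty, [1 / 3, 2 / 3])
        tert = np.searchsorted(cuts, poverty, side="right") + 1

        # correlated blocks of standard-normal log-exposure scores
        z = np.empty((n, cfg.n_factors))
        r = cfg.rho
        for idx in blocks:
            common = rng.normal(size=(n, 1))
            indep = rng.normal(size=(n, len(idx)))
            z[:, idx] = (np.sqrt(r) * common + np.sqrt(1.0 - r) * indep
                         if r > 0 else indep)

        eta_cov = (ce.get("age", 0.0) * (age - 42.0)
                   + ce.get("bmi", 0.0) * (bmi - 27.0)
                   + ce.get("sex_female", 0.0) * female
                   + ce.get("ses_t1", 0.0) * (tert == 1)
                   + ce.get("ses_t2", 0.0) * (tert == 2))
        # calibrate the intercept so the realized mean risk equals the
        # target prevalence (a fixed logit(p0) would overshoot by Jensen's
        # inequality over the covariate/exposure effect variance)
        eta_rest = (eta_cov - eta_cov.mean()) + z @ beta
        intercept = brentq(
            lambda c: expit(c + eta_rest).mean() - cfg.baseline_prevalence,
            -30.0, 30.0)
        eta = intercept + eta_rest
        case = rng.random(n) < 1.0 / (1.0 + np.exp(-eta))

        # FBG deterministic in latent status, noise bounded away from 126
        fbg = np.where(case,
                       130.0 + rng.uniform(0.0, 60.0, n),
                       95.0 + rng.uniform(-14.0, 24.0, n))

        stratum = rng.integers(cfg.n_strata, size=n)
        psu = rng.integers(cfg.psus_per_stratum, size=n)
        weight = rng.lognormal(np.log(cfg.weight_mean)
                               - cfg.weight_sigma ** 2 / 2.0,
                               cfg.weight_sigma, n)
        if cfg.informative_weights:
            weight = weight * np.where(case, 0.6, 1.1)

        df = pd.DataFrame({
            "fbg": fbg, "age": age,
            "sex": np.where(female, "female", "male"),
            "bmi": bmi, "ethnicity": ethnicity, "poverty_index": poverty,
            "stratum": stratum, "psu": psu, "weight": weight,
            "diagnosed": np.where(case, rng.random(n) < 0.5,
                                  rng.random(n) < 0.02).astype(int),
            "triglycerides": rng.lognormal(np.log(120.0), 0.4, n),
            "cholesterol": rng.lognormal(np.log(190.0), 0.2, n),
            "supplement_count": rng.poisson(1.0, n),
        })
        for comp in ("diet_vitamin_a", "diet_vitamin_c", "diet_vitamin_e",
                     "diet_beta_carotene", "diet_carbohydrate",
                     "diet_protein", "diet_fat", "diet_fiber"):
            df[comp] = rng.lognormal(np.log(50.0), 0.5, n)

        x = 10.0 ** (cfg.log_mu + cfg.log_sigma * z)
        present = []
        exp_cols = {}
        for j, sym in enumerate(syms):
            if cid not in measured[sym]:
                continue
            col = x[:, j].copy()
            if cfg.missing_rate > 0:
                col[rng.random(n) < cfg.missing_rate] = np.nan
            if sym in subset_targeted:
                col[~female] = np.nan  # assay run only in females
            exp_cols[sym] = col
            present.append(sym)
        df = pd.concat([df, pd.DataFrame(exp_cols, index=df.index)], axis=1)
        cohorts.append(CohortTable(cohort_id=cid, data=df,
                                   exposure_columns=tuple(present)))

    truth = pd.DataFrame({
        "symbol": syms,
        "env_class": [codebook[s].env_class for s in syms],
        "log_or": beta,
        "odds_ratio": np.exp(beta),
    })
    return SimulatedStudy(cohorts=cohorts, codebook=codebook, truth=truth,
                          config=cfg)


def make_null_study(cfg: SimulationConfig,
                    seed: int | None = None) -> SimulatedStudy:
    """Same generative process with every planted effect forced to zero."""
    null_cfg = dataclasses.replace(cfg, planted_effects={})
    return simulate_study(null_cfg, seed=seed)


def canonical_study_config(seed: int = 0,
                       planted_effects: Mapping[str, float] | None = None,
                       ) -> SimulationConfig:
    """Canonical demo preset: 4 cohorts of ~2500 participants, 200 factors
    in 21 classes with partial cross-cohort overlap, ~6.5% prevalence, five
    planted factors spanning risk (OR 1.5-2.2) and protection (OR 0.6)."""
    if planted_effects is None:
        planted_effects = {
            "EXP0000": float(np.log(1.7)),
            "EXP0010": float(np.log(1.5)),
            "EXP0020": float(np.log(2.2)),
            "EXP0030": float(np.log(0.6)),
            "EXP0040": float(np.log(0.6)),
        }
    return SimulationConfig(
        n_cohorts=4, n_per_cohort=2500,
        cohort_ids=("1999-2000", "2001-2002", "2003-2004", "2005-2006"),
        n_factors=200, block_size=4, rho=0.3,
        planted_effects=dict(planted_effects),
        frac_shared=0.75, missing_rate=0.05, lod_quantile=0.15, seed=seed)


def recovery_config(log_or: float, seed: int = 0,
                    n: int = 2500) -> SimulationConfig:
    """Single-cohort, single-planted-factor preset for estimator checks.

    No LOD censoring and no missingness, and the generating covariate terms
    coincide exactly with the fitted adjustment set, so the planted per-SD
    log odds ratio is the true coefficient of the fitted model.
    """
    return SimulationConfig(
        n_cohorts=1, n_per_cohort=n, n_factors=1, block_size=1, rho=0.0,
        n_strata=15, psus_per_stratum=3, lod_quantile=0.0, missing_rate=0.0,
        planted_effects={"EXP0000": log_or}, seed=seed)


def write_study(study: SimulatedStudy, outdir: str | os.PathLike) -> None:
    """Emit the same CSV + codebook YAML the ingestion layer reads, plus the
    truth table."""
    outdir = os.fspath(outdir)
    os.makedirs(outdir, exist_ok=True)
    for t in study.cohorts:
        t.data.to_csv(os.path.join(outdir, f"cohort_{t.cohort_id}.csv"),
                      index=False)
    study.codebook.to_yaml(os.path.join(outdir, "codebook.yaml"))
    study.truth.to_csv(os.path.join(outdir, "truth.csv"), index=False)
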