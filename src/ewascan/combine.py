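"""Combined-cohort estimation, prototype risk prediction, sensitivity analyses.

Pooling k cohorts divides each participant's original sampling weight by k
(the "average weight" rule of the source survey's analytic guidelines) and
adds a cohort indicator to the adjustment set; stratum and PSU labels are
namespaced by cohort so identical labels in different cohorts never collide.

Predicted absolute risks translate a per-SD odds ratio into probabilities
for a fixed *prototype participant* (by default a 45-year-old white male,
BMI 27 kg/m^2, middle SES tertile, most recent cohort) at exposure one SD
below and one SD above the mean log exposure. The exact logistic identity
logit(p_high) - logit(p_low) = 2 * beta holds by construction.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .codebook import Codebook, CohortTable, STATUS_COLUMN
from .screen import (DEFAULT_COVARIATES, AssociationResult, ExposureSpec,
                     ModelFrame, association_from_fit, build_model_frame)
from .survey import FitResult, fit_weighted_logistic


@dataclasses.dataclass(frozen=True)
class CombinedDesign:
    member_cohorts: tuple[str, ...]

    @property
    def k(self) -> int:
        return len(self.member_cohorts)


def combine_cohorts(tables: Sequence[CohortTable],
                    ) -> tuple[CohortTable, CombinedDesign]:
    """Pool cohorts: weight/k, cohort column, namespaced strata and PSUs.

    With k = 1 the weights are returned unchanged and no cohort adjustment
    is implied (a single-level cohort column would be dropped as constant).
    """
    if not tables:
        raise ValueError("no cohorts to combine")
    ids = tuple(t.cohort_id for t in tables)
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate cohort ids in pool: {ids}")
    k = len(tables)
    parts = []
    for t in tables:
        df = t.data.copy()
        df["cohort"] = t.cohort_id
        df["weight"] = df["weight"] / k
        df["stratum"] = t.cohort_id + "|" + df["stratum"].astype(str)
        df["psu"] = t.cohort_id + "|" + df["psu"].astype(str)
        parts.append(df)
    pooled = pd.concat(parts, ignore_index=True, sort=False)
    exposure_columns = tuple(dict.fromkeys(
        s for t in tables for s in t.exposure_columns))
    return (CohortTable(cohort_id="+".join(ids), data=pooled,
                        exposure_columns=exposure_columns),
            CombinedDesign(member_cohorts=ids))


def _member_tables_for(tables: Sequence[CohortTable],
                       symbol: str) -> list[CohortTable]:
    members = []
    for t in tables:
        if symbol in t.exposure_columns and t.data[symbol].notna().any():
            members.append(t)
    return members


def fit_combined(tables: Sequence[CohortTable], codebook: Codebook,
                 symbol: str,
                 covariates: Sequence[str] = DEFAULT_COVARIATES,
                 lonely_psu: str = "error", reference: str = "t",
                 extra_log10_terms: Mapping[str, str] | None = None,
                 extra_linear_terms: Sequence[str] = (),
                 exclude_mask_column: str | None = None,
                 ) -> tuple[AssociationResult, FitResult, ModelFrame]:
    """Pooled fit of one factor over the cohorts that measured it.

    Cohorts where the factor is absent are dropped from that factor's pool
    (weights divided by the number of *member* cohorts). The cohort-dummy
    referent is the most recent member cohort, which is also the reference
    cohort for prototype predictions. z-scoring is recomputed on the pooled
    complete-case analysis set.
    """
    members = _member_tables_for(tables, symbol)
    if not members:
        raise ValueError(f"factor {symbol!r} measured in no cohort")
    pooled, cdesign = combine_cohorts(members)
    if exclude_mask_column is not None:
        keep = ~pooled.data[exclude_mask_column].fillna(0).astype(bool)
        pooled = CohortTable(cohort_id=pooled.cohort_id,
                             data=pooled.data.loc[keep].reset_index(drop=True),
                             exposure_columns=pooled.exposure_columns)
        n_case = int((pooled.data[STATUS_COLUMN] == 1).sum())
        if n_case == 0 or n_case == len(pooled.data):
            raise ValueError(
                f"{symbol}: exclusion leaves {n_case} cases of "
                f"{len(pooled.data)} rows; no estimable model")
    fd = codebook[symbol]
    spec = ExposureSpec(symbol=symbol,
                        transform=("categorical" if fd.scale == "categorical"
                                   else "log10_z"),
                        referent_level=fd.referent_level)
    referent = max(cdesign.member_cohorts) if cdesign.k > 1 else None
    frame = build_model_frame(pooled, spec, covariates,
                              cohort_referent=referent,
                              extra_log10_terms=extra_log10_terms,
                              extra_linear_terms=extra_linear_terms)
    fit = fit_weighted_logistic(frame.y, frame.X, frame.design,
                                term_names=frame.term_names,
                                lonely_psu=lonely_psu)
    res = association_from_fit(fit, frame, frame.exposure_terms[0], symbol,
                               fd.env_class, reference=reference)
    return res, fit, frame


@dataclasses.dataclass(frozen=True)
class PrototypeProfile:
    """Fixed covariate profile used to express effects as absolute risks."""

    age: float = 45.0
    sex: str = "male"
    ethnicity: str = "white"
    bmi: float = 27.0
    ses: str = "t2"  # middle tertile
    cohort: str | None = None  # None -> the fit's referent (most recent)


@dataclasses.dataclass(frozen=True)
class PrototypePrediction:
    p_low: float
    p_high: float
    z_low: float
    z_high: float
    exposure_low: float | None
    exposure_high: float | None


def _profile_vector(fit: FitResult, frame: ModelFrame,
                    profile: PrototypeProfile, z: float) -> np.ndarray:
    x = np.zeros(len(fit.term_names))
    exposure = frame.exposure_terms
    if len(exposure) != 1 or frame.stats is None:
        raise ValueError("prototype prediction is defined for continuous "
                         "(log10-z) single-term exposures")
    for j, name in enumerate(fit.term_names):
        if name == "intercept":
            x[j] = 1.0
        elif name == exposure[0]:
            x[j] = z
        elif name == "age":
            x[j] = profile.age
        elif name == "bmi":
            x[j] = profile.bmi
        elif name == "sex:female":
            x[j] = 1.0 if profile.sex == "female" else 0.0
        elif name.startswith("ethnicity:"):
            x[j] = 1.0 if name.split(":", 1)[1] == profile.ethnicity else 0.0
        elif name.startswith("ses:"):
            x[j] = 1.0 if name.split(":", 1)[1] == profile.ses else 0.0
        elif name.startswith("cohort:"):
            x[j] = (1.0 if profile.cohort is not None
                    and name.split(":", 1)[1] == profile.cohort else 0.0)
        else:
            raise ValueError(
                f"model term {name!r} has no prototype value; prediction is "
                "defined for the baseline adjustment set only")
    # profile levels must exist in the model (referents are implicit zeros)
    for field, prefix in (("ethnicity", "ethnicity:"), ("ses", "ses:")):
        level = getattr(profile, field)
        referent = frame.referents.get(field)
        if referent is not None and level != referent and \
                f"{prefix}{level}" not in fit.term_names:
            raise ValueError(f"profile {field} level {level!r} absent from "
                             "the model and not the referent")
    if profile.cohort is not None and \
            frame.referents.get("cohort") != profile.cohort and \
            f"cohort:{profile.cohort}" not in fit.term_names:
        raise ValueError(f"profile cohort {profile.cohort!r} absent from the "
                         "model and not the referent")
    return x


def predict_prototype(fit: FitResult, frame: ModelFrame,
                      profile: PrototypeProfile = PrototypeProfile(),
                      z_levels: tuple[float, float] = (-1.0, 1.0),
                      ) -> PrototypePrediction:
    """Predicted case probability for the prototype at low/high exposure.

    Low/high are log-exposure levels ``z_levels`` SDs from the mean (default
    -1 and +1); the corresponding raw exposure levels 10**(mean + z*sd) are
    reported alongside.
    """
    z_low, z_high = z_levels
    x_low = _profile_vector(fit, frame, profile, z_low)
    x_high = _profile_vector(fit, frame, profile, z_high)
    p_low = float(expit(x_low @ fit.coefficients))
    p_high = float(expit(x_high @ fit.coefficients))
    st = frame.stats
    return PrototypePrediction(
        p_low=p_low, p_high=p_high, z_low=z_low, z_high=z_high,
        exposure_low=st.raw_level(z_low) if st else None,
        exposure_high=st.raw_level(z_high) if st else None)


def risk_shift(p_low: float, odds_ratio: float, n_sd: float = 2.0) -> float:
    """Predicted probability after an ``n_sd``-SD exposure shift, from a
    baseline probability and a per-SD odds ratio.

    Implements the logistic odds identity
    p_high = expit(logit(p_low) + n_sd * ln(odds_ratio)), the arithmetic by
    which a per-SD OR and a low-exposure risk determine the high-exposure
    risk.
    """
    if not 0.0 < p_low < 1.0:
        raise ValueError("p_low must be in (0, 1)")
    if not odds_ratio > 0:
        raise ValueError("odds_ratio must be > 0")
    return float(expit(logit(p_low) + n_sd * np.log(odds_ratio)))


# ---------------------------------------------------------------------------
# sensitivity analyses

SENSITIVITY_MODES = ("exclude_diagnosed", "lipid_adjust", "diet_adjust",
                     "combined_adjust")

DEFAULT_FOOD_COMPONENTS = ("diet_vitamin_a", "diet_vitamin_c",
                           "diet_vitamin_e", "diet_beta_carotene",
                           "diet_carbohydrate", "diet_protein", "diet_fat",
                           "diet_fiber")


@dataclasses.dataclass(frozen=True)
class SensitivitySpec:
    """One of the secondary validity analyses.

    - ``exclude_diagnosed``: drop participants self-reporting a physician
      diagnosis (reverse-causality probe) and refit.
    - ``lipid_adjust``: additionally adjust for log10 total triglycerides
      and log10 total cholesterol (lipophilicity confounding probe).
    - ``diet_adjust``: additionally adjust for log10 dietary-recall amounts
      of the named food components plus an integer supplement-use count.
    - ``combined_adjust``: lipid and diet adjustments simultaneously.
    """

    mode: str
    food_components: tuple[str, ...] = DEFAULT_FOOD_COMPONENTS
    diagnosed_column: str = "diagnosed"
    triglycerides_column: str = "triglycerides"
    cholesterol_column: str = "cholesterol"
    supplement_column: str = "supplement_count"

    def __post_init__(self) -> None:
        if self.mode not in SENSITIVITY_MODES:
            raise ValueError(f"mode must be one of {SENSITIVITY_MODES}")


@dataclasses.dataclass
class SensitivityResult:
    symbol: str
    mode: str
    baseline: AssociationResult
    adjusted: AssociationResult

    @property
    def or_pct_change(self) -> float:
        """Relative OR change vs baseline, 100*(OR_adj/OR_base - 1)."""
        return 100.0 * (self.adjusted.or_point / self.baseline.or_point - 1.0)


def run_sensitivity(tables: Sequence[CohortTable], codebook: Codebook,
                    symbol: str, spec: SensitivitySpec,
                    covariates: Sequence[str] = DEFAULT_COVARIATES,
                    baseline: AssociationResult | None = None,
                    lonely_psu: str = "error",
                    reference: str = "t") -> SensitivityResult:
    """Refit one validated factor's combined-cohort model under a
    sensitivity mode and report the adjusted effect next to baseline."""
    if baseline is None:
        baseline, _, _ = fit_combined(tables, codebook, symbol, covariates,
                                      lonely_psu=lonely_psu,
                                      reference=reference)
    log_terms: dict[str, str] = {}
    lin_terms: list[str] = []
    exclude_col = None
    if spec.mode == "exclude_diagnosed":
        exclude_col = spec.diagnosed_column
    if spec.mode in ("lipid_adjust", "combined_adjust"):
        log_terms["log10_triglycerides"] = spec.triglycerides_column
        log_terms["log10_cholesterol"] = spec.cholesterol_column
    if spec.mode in ("diet_adjust", "combined_adjust"):
        for comp in spec.food_components:
            log_terms[f"log10_{comp}"] = comp
        lin_terms.append(spec.supplement_column)
    adjusted, _, _ = fit_combined(tables, codebook, symbol, covariates,
                                  lonely_psu=lonely_psu, reference=reference,
                                  extra_log10_terms=log_terms or None,
                                  extra_linear_terms=lin_terms,
                                  exclude_mask_column=exclude_col)
    return SensitivityResult(symbol=symbol, mode=spec.mode,
                             baseline=baseline, adjusted=adjusted)


def sensitivity_to_frame(results: Sequence[SensitivityResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append({
            "symbol": r.symbol, "mode": r.mode,
            "or_baseline": r.baseline.or_point,
            "ci_low_baseline": r.baseline.ci_low,
            "ci_high_baseline": r.baseline.ci_high,
            "p_baseline": r.baseline.p_value,
            "or_adjusted": r.adjusted.or_point,
            "ci_low_adjusted": r.adjusted.ci_low,
            "ci_high_adjusted": r.adjusted.ci_high,
            "p_adjusted": r.adjusted.p_value,
            "or_pct_change": r.or_pct_change,
            "n_obs_adjusted": r.adjusted.n_obs})
    return pd.DataFrame(rows)
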