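"""Per-factor adjusted models and the environment-wide scan within a cohort.

Each retained factor is tested one at a time in a survey-weighted logistic
regression of case status on the standardized (log10, then z-scored)
exposure, adjusted for age, sex, BMI, ethnicity, and socioeconomic status
(tertile of the poverty index, 3rd tertile referent). Reported odds ratios
are per one standard deviation of the log exposure, which puts factors with
very different units and ranges on a common effect scale.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .codebook import Codebook, CohortTable, STATUS_COLUMN
from .survey import (FitResult, SurveyDesign, SurveyError,
                     fit_weighted_logistic, wald_test)

logger = logging.getLogger(__name__)

DEFAULT_COVARIATES = ("age", "sex", "bmi", "ethnicity", "ses")
ETHNICITY_REFERENT = "white"
SEX_REFERENT = "male"
SES_REFERENT_TERTILE = 3


class ZeroVarianceError(ValueError):
    """Exposure (after transformation) has zero sample variance."""


@dataclasses.dataclass(frozen=True)
class TransformStats:
    """Mean and sample SD (denominator n-1) of log10 exposure on the
    complete-case analysis set; recorded for audit and for mapping z-scores
    back to raw exposure levels (10**(mean +/- z*sd))."""

    mean: float
    sd: float

    def raw_level(self, z: float) -> float:
        return float(10.0 ** (self.mean + z * self.sd))


def standardize_exposure(values) -> tuple[np.ndarray, TransformStats]:
    """log10-then-z transform of a positive exposure vector.

    Raises on nonpositive values (these should have been handled by the
    below-LOD substitution) and on zero sample variance.
    """
    x = np.asarray(values, dtype=float)
    if np.any(~np.isfinite(x)):
        raise ValueError("standardize_exposure requires finite values; "
                         "apply complete-case filtering first")
    bad = np.flatnonzero(x <= 0)
    if bad.size:
        raise ValueError(
            f"nonpositive exposure values at rows {bad[:10].tolist()}"
            f"{'...' if bad.size > 10 else ''}; cannot log-transform")
    lx = np.log10(x)
    mean = float(lx.mean())
    sd = float(lx.std(ddof=1)) if lx.size > 1 else 0.0
    if sd == 0.0:
        raise ZeroVarianceError("zero variance after log transform")
    return (lx - mean) / sd, TransformStats(mean=mean, sd=sd)


@dataclasses.dataclass
class ExposureSpec:
    symbol: str
    transform: str = "log10_z"  # or "categorical"
    referent_level: str | None = None
    transform_stats: TransformStats | None = None


@dataclasses.dataclass
class ModelFrame:
    """Response, model matrix, design, and term metadata for one factor model."""

    y: np.ndarray
    X: np.ndarray
    term_names: list[str]
    design: SurveyDesign
    exposure_terms: list[str]
    rows: np.ndarray  # positions within the classified cohort table
    stats: TransformStats | None
    referents: dict[str, str]
    cohort_id: str


def _dummies(series: pd.Series, referent, prefix: str,
             ) -> tuple[list[str], list[np.ndarray]]:
    levels = [lv for lv in pd.unique(series.dropna()) if lv != referent]
    try:
        levels = sorted(levels)
    except TypeError:
        pass
    names = [f"{prefix}:{lv}" for lv in levels]
    cols = [(series == lv).to_numpy(dtype=float) for lv in levels]
    return names, cols


def ses_tertiles(poverty_index: pd.Series) -> pd.Series:
    """Unweighted within-cohort tertiles of the poverty index (1 = lowest)."""
    x = pd.to_numeric(poverty_index, errors="coerce")
    cuts = x.quantile([1 / 3, 2 / 3]).to_numpy()
    t = np.searchsorted(cuts, x.to_numpy(), side="right") + 1
    return pd.Series(np.where(x.notna(), t, np.nan), index=x.index)


def build_model_frame(table: CohortTable, spec: ExposureSpec | str,
                      covariates: Sequence[str] = DEFAULT_COVARIATES,
                      *,
                      extra_log10_terms: Mapping[str, str] | None = None,
                      extra_linear_terms: Sequence[str] = (),
                      cohort_referent: str | None = None,
                      ) -> ModelFrame:
    """Assemble response, model matrix, and survey design for one factor.

    Complete-case: a row enters iff status, the exposure, every covariate,
    and every extra adjustment column are non-missing. The z-score statistics
    of the exposure are computed on exactly this analysis set. SES tertiles
    are computed within cohort on all classified rows with a poverty index.

    ``extra_log10_terms`` maps term name -> column to enter as log10(column)
    (used by the lipid/diet sensitivity adjustments); ``extra_linear_terms``
    lists columns entering untransformed (e.g., a supplement-use count).
    ``cohort_referent`` activates cohort dummies (for pooled fits) with the
    given referent cohort.
    """
    if isinstance(spec, str):
        spec = ExposureSpec(symbol=spec)
    df = table.data
    if STATUS_COLUMN not in df:
        raise ValueError("table must be classified first (no status column)")

    covariates = list(covariates)
    extra_log10_terms = dict(extra_log10_terms or {})
    extra_linear_terms = list(extra_linear_terms)

    needed = [spec.symbol]
    for c in covariates:
        needed.append("poverty_index" if c == "ses" else c)
    needed += list(extra_log10_terms.values()) + extra_linear_terms
    if cohort_referent is not None:
        needed.append("cohort")
    missing_cols = [c for c in needed if c not in df.columns]
    if missing_cols:
        raise KeyError(f"cohort {table.cohort_id!r} lacks columns "
                       f"{missing_cols}")

    ses = ses_tertiles(df["poverty_index"]) if "ses" in covariates else None

    mask = df[STATUS_COLUMN].notna()
    for col in needed:
        mask &= pd.to_numeric(df[col], errors="coerce").notna() \
            if df[col].dtype.kind in "ifub" else df[col].notna()
    if ses is not None:
        mask &= ses.notna()
    rows = np.flatnonzero(mask.to_numpy())
    sub = df.iloc[rows]
    n = len(sub)
    if n == 0:
        raise SurveyError(f"{spec.symbol}: empty complete-case analysis set")

    names: list[str] = ["intercept"]
    cols: list[np.ndarray] = [np.ones(n)]
    referents: dict[str, str] = {}
    tstats: TransformStats | None = None

    # exposure term(s)
    exposure_terms: list[str] = []
    if spec.transform == "log10_z":
        z, tstats = standardize_exposure(sub[spec.symbol].to_numpy())
        spec.transform_stats = tstats
        names.append(spec.symbol)
        cols.append(z)
        exposure_terms.append(spec.symbol)
    elif spec.transform == "categorical":
        if spec.referent_level is None:
            raise ValueError(f"{spec.symbol}: categorical factor needs a "
                             "referent level from the codebook")
        dn, dc = _dummies(sub[spec.symbol], spec.referent_level, spec.symbol)
        if not dn:
            raise ZeroVarianceError(f"{spec.symbol}: only the referent level "
                                    "present")
        referents[spec.symbol] = spec.referent_level
        names += dn
        cols += dc
        exposure_terms += dn
    else:
        raise ValueError(f"unknown transform {spec.transform!r}")

    for c in covariates:
        if c == "sex":
            ind = (sub["sex"] != SEX_REFERENT).to_numpy(dtype=float) \
                if sub["sex"].dtype == object \
                else np.asarray(sub["sex"], dtype=float)
            names.append("sex:female")
            referents["sex"] = SEX_REFERENT
            cols.append(ind)
        elif c == "ethnicity":
            dn, dc = _dummies(sub["ethnicity"], ETHNICITY_REFERENT,
                              "ethnicity")
            referents["ethnicity"] = ETHNICITY_REFERENT
            names += dn
            cols += dc
        elif c == "ses":
            s = ses.iloc[rows]
            for t in (1, 2, 3):
                if t == SES_REFERENT_TERTILE:
                    continue
                names.append(f"ses:t{t}")
                cols.append((s == t).to_numpy(dtype=float))
            referents["ses"] = f"t{SES_REFERENT_TERTILE}"
        else:
            names.append(c)
            cols.append(pd.to_numeric(sub[c]).to_numpy(dtype=float))

    for name, col in extra_log10_terms.items():
        v = pd.to_numeric(sub[col]).to_numpy(dtype=float)
        bad = np.flatnonzero(v <= 0)
        if bad.size:
            raise ValueError(
                f"{name}: nonpositive values at rows {bad[:10].tolist()} "
                "cannot enter as log10; clean or offset them explicitly")
        names.append(name)
        cols.append(np.log10(v))
    for col in extra_linear_terms:
        names.append(col)
        cols.append(pd.to_numeric(sub[col]).to_numpy(dtype=float))

    if cohort_referent is not None:
        dn, dc = _dummies(sub["cohort"], cohort_referent, "cohort")
        referents["cohort"] = cohort_referent
        names += dn
        cols += dc

    # drop covariate columns constant on the analysis set (never the exposure)
    keep = []
    for j, (nm, col) in enumerate(zip(names, cols)):
        if nm != "intercept" and nm not in exposure_terms \
                and np.ptp(col) == 0.0:
            warnings.warn(f"{spec.symbol}: covariate {nm!r} constant on the "
                          "analysis set; dropped", UserWarning, stacklevel=2)
            continue
        keep.append(j)
    names = [names[j] for j in keep]
    X = np.column_stack([cols[j] for j in keep])

    design = SurveyDesign(sub["stratum"].to_numpy(), sub["psu"].to_numpy(),
                          sub["weight"].to_numpy(dtype=float))
    y = sub[STATUS_COLUMN].to_numpy(dtype=float)
    return ModelFrame(y=y, X=X, term_names=names, design=design,
                      exposure_terms=exposure_terms, rows=rows, stats=tstats,
                      referents=referents, cohort_id=table.cohort_id)


@dataclasses.dataclass
class AssociationResult:
    """Effect of one factor (or one non-referent level) in one cohort."""

    symbol: str
    env_class: str
    cohort_id: str
    term: str
    beta: float
    se: float
    or_point: float
    ci_low: float
    ci_high: float
    p_value: float
    n_obs: int
    n_case: int
    n_control: int
    transform_stats: TransformStats | None = None
    error: str | None = None

    @property
    def failed(self) -> bool:
        return self.error is not None


def _failed_result(symbol: str, env_class: str, cohort_id: str,
                   message: str) -> AssociationResult:
    nan = float("nan")
    return AssociationResult(symbol=symbol, env_class=env_class,
                             cohort_id=cohort_id, term=symbol, beta=nan,
                             se=nan, or_point=nan, ci_low=nan, ci_high=nan,
                             p_value=nan, n_obs=0, n_case=0, n_control=0,
                             error=message)


def association_from_fit(fit: FitResult, frame: ModelFrame, term: str,
                         symbol: str, env_class: str,
                         ci_level: float = 0.95,
                         reference: str = "t") -> AssociationResult:
    j = fit.term_index(term)
    beta = float(fit.coefficients[j])
    se = float(fit.se[j])
    if reference == "t" and fit.df_design >= 1:
        crit = float(stats.t.ppf(0.5 + ci_level / 2, df=fit.df_design))
    else:
        crit = float(stats.norm.ppf(0.5 + ci_level / 2))
    _, p = wald_test(fit, term, reference=reference)
    return AssociationResult(
        symbol=symbol, env_class=env_class, cohort_id=frame.cohort_id,
        term=term, beta=beta, se=se, or_point=float(np.exp(beta)),
        ci_low=float(np.exp(beta - crit * se)),
        ci_high=float(np.exp(beta + crit * se)), p_value=p,
        n_obs=fit.n_obs, n_case=fit.n_case, n_control=fit.n_control,
        transform_stats=frame.stats)


def screen_factor(table: CohortTable, codebook: Codebook, symbol: str,
                  covariates: Sequence[str] = DEFAULT_COVARIATES,
                  lonely_psu: str = "error",
                  reference: str = "t",
                  ) -> tuple[list[AssociationResult], FitResult | None,
                             ModelFrame | None]:
    """Fit one factor's adjusted model; never raises on per-factor failure."""
    fd = codebook[symbol]
    spec = ExposureSpec(symbol=symbol,
                        transform=("categorical" if fd.scale == "categorical"
                                   else "log10_z"),
                        referent_level=fd.referent_level)
    try:
        frame = build_model_frame(table, spec, covariates)
        fit = fit_weighted_logistic(frame.y, frame.X, frame.design,
                                    term_names=frame.term_names,
                                    lonely_psu=lonely_psu)
    except (SurveyError, ZeroVarianceError, ValueError, KeyError) as exc:
        logger.info("factor %s failed in cohort %s: %s", symbol,
                    table.cohort_id, exc)
        return [_failed_result(symbol, fd.env_class, table.cohort_id,
                               str(exc))], None, None
    results = [association_from_fit(fit, frame, term, symbol, fd.env_class,
                                    reference=reference)
               for term in frame.exposure_terms]
    return results, fit, frame


def screen_cohort(table: CohortTable, codebook: Codebook,
                  symbols: Sequence[str] | None = None,
                  covariates: Sequence[str] = DEFAULT_COVARIATES,
                  lonely_psu: str = "error",
                  reference: str = "t") -> list[AssociationResult]:
    """Run the environment-wide scan: one adjusted model per retained factor.

    Exactly one result per continuous factor (or per non-referent level of a
    categorical factor); failures are recorded as flagged results with a
    missing p-value, never silently skipped, and never abort the scan.
    """
    if symbols is None:
        symbols = table.exposure_columns
    out: list[AssociationResult] = []
    for sym in symbols:
        res, _, _ = screen_factor(table, codebook, sym, covariates,
                                  lonely_psu=lonely_psu, reference=reference)
        out.extend(res)
    return out


def results_to_frame(results: Sequence[AssociationResult]) -> pd.DataFrame:
    """Tidy factor x cohort table of scan results (stable column names)."""
    rows = []
    for r in results:
        d = dataclasses.asdict(r)
        ts = d.pop("transform_stats")
        d["log10_mean"] = ts["mean"] if ts else float("nan")
        d["log10_sd"] = ts["sd"] if ts else float("nan")
        rows.append(d)
    return pd.DataFrame(rows, columns=[
        "symbol", "env_class", "cohort_id", "term", "beta", "se", "or_point",
        "ci_low", "ci_high", "p_value", "n_obs", "n_case", "n_control",
        "log10_mean", "log10_sd", "error"])
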