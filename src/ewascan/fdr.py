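"""Permutation-null false discovery rate and multi-cohort validation.

The multiplicity control is empirical: case/control labels are shuffled B
times within each cohort (default B = 1000) and the whole scan recomputed on
each shuffle, giving a null distribution of per-factor p-values. The FDR at
a working level alpha is the ratio of the proportion of null tests called
significant to the proportion of observed tests called significant.

Validation then requires a factor to be significant at alpha in at least two
cohorts; its own FDR is estimated by counting, replicate by replicate (the
same shuffle index is paired across cohorts), how many factors reach
significance in two or more permuted cohorts.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .codebook import Codebook, CohortTable, STATUS_COLUMN
from .screen import (DEFAULT_COVARIATES, AssociationResult, build_model_frame,
                     ExposureSpec, ModelFrame, ZeroVarianceError)
from .survey import SurveyError, fit_weighted_logistic, wald_test


@dataclasses.dataclass
class NullDistribution:
    """Per-replicate, per-factor null p-values for one cohort."""

    cohort_id: str
    p_values: pd.DataFrame  # B rows x factor columns
    B: int
    seed: int
    n_failed: int = 0

    def pooled(self) -> np.ndarray:
        """All finite null p-values pooled across factors and replicates."""
        v = self.p_values.to_numpy().ravel()
        return v[np.isfinite(v)]


def permute_labels(status: np.ndarray, B: int, seed: int) -> np.ndarray:
    """B independent uniform permutations of the status vector (B x n).

    Each replicate preserves the cohort's case/control counts exactly and is
    shared by every factor tested in that replicate.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    status = np.asarray(status)
    rng = np.random.default_rng(seed)
    out = np.empty((B, status.size), dtype=status.dtype)
    for b in range(B):
        out[b] = status[rng.permutation(status.size)]
    return out


def permutation_null(table: CohortTable, codebook: Codebook,
                     symbols: Sequence[str], B: int, seed: int,
                     covariates: Sequence[str] = DEFAULT_COVARIATES,
                     lonely_psu: str = "error",
                     reference: str = "t",
                     failure_warn_fraction: float = 0.01,
                     ) -> NullDistribution:
    """Recompute the scan on B label shuffles of one classified cohort.

    One label permutation per replicate is shared across all factors
    (exposures and covariates stay attached to their rows), preserving the
    cross-factor correlation of null statistics that the validation-stage
    FDR counting relies on. Failed permutation fits are recorded as missing
    and counted; a failure fraction above ``failure_warn_fraction`` warns.
    """
    frames: dict[str, ModelFrame] = {}
    for sym in symbols:
        fd = codebook[sym]
        spec = ExposureSpec(symbol=sym,
                            transform=("categorical"
                                       if fd.scale == "categorical"
                                       else "log10_z"),
                            referent_level=fd.referent_level)
        try:
            frames[sym] = build_model_frame(table, spec, covariates)
        except (SurveyError, ZeroVarianceError, ValueError, KeyError):
            continue  # factor already fails on the observed data

    status = table.data[STATUS_COLUMN].to_numpy()
    perms = permute_labels(status, B, seed)
    syms = list(frames)
    P = np.full((B, len(syms)), np.nan)
    n_failed = 0
    for b in range(B):
        y_full = perms[b]
        for j, sym in enumerate(syms):
            fr = frames[sym]
            y = y_full[fr.rows].astype(float)
            try:
                fit = fit_weighted_logistic(
                    y, fr.X, fr.design, term_names=fr.term_names,
                    lonely_psu=lonely_psu, check_rank=False)
                _, p = wald_test(fit, fr.exposure_terms[0],
                                 reference=reference)
                P[b, j] = p
            except SurveyError:
                n_failed += 1
    total = B * max(len(syms), 1)
    if n_failed > failure_warn_fraction * total:
        warnings.warn(
            f"cohort {table.cohort_id!r}: {n_failed}/{total} permutation "
            "fits failed and were dropped from the null pool",
            UserWarning, stacklevel=2)
    return NullDistribution(cohort_id=table.cohort_id,
                            p_values=pd.DataFrame(P, columns=syms),
                            B=B, seed=seed, n_failed=n_failed)


@dataclasses.dataclass(frozen=True)
class FDREstimate:
    """Ratio-of-proportions FDR at a working significance level."""

    alpha: float
    prop_null_significant: float
    prop_observed_significant: float
    fdr: float  # NaN when there are no observed discoveries

    @property
    def defined(self) -> bool:
        return np.isfinite(self.fdr)


def estimate_fdr(observed_p, null_p, alpha: float) -> FDREstimate:
    """FDR = P(null p <= alpha) / P(observed p <= alpha).

    Missing p-values (failed fits) are excluded from both pools. The ratio
    is missing (NaN) when no observed test is significant at alpha.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    obs = np.asarray(observed_p, dtype=float)
    nul = np.asarray(null_p, dtype=float)
    obs = obs[np.isfinite(obs)]
    nul = nul[np.isfinite(nul)]
    if obs.size == 0 or nul.size == 0:
        raise ValueError("empty observed or null p-value pool")
    prop_null = float((nul <= alpha).mean())
    prop_obs = float((obs <= alpha).mean())
    fdr = prop_null / prop_obs if prop_obs > 0 else float("nan")
    return FDREstimate(alpha=alpha, prop_null_significant=prop_null,
                       prop_observed_significant=prop_obs, fdr=fdr)


def select_significant(results: Sequence[AssociationResult],
                       alpha: float = 0.02) -> set[str]:
    """Cohort-level discoveries: p <= alpha (inclusive); missing p never
    qualifies."""
    return {r.symbol for r in results
            if np.isfinite(r.p_value) and r.p_value <= alpha}


@dataclasses.dataclass
class ValidationReport:
    """Multi-cohort validation outcome at a working alpha."""

    alpha: float
    table: pd.DataFrame  # symbol, n_measured, n_significant, eligible, validated
    validation_fdr: float = float("nan")
    expected_false_validations: float = float("nan")

    @property
    def validated(self) -> list[str]:
        return self.table.loc[self.table["validated"], "symbol"].tolist()

    @property
    def n_validated(self) -> int:
        return int(self.table["validated"].sum())

    def to_json_dict(self) -> dict:
        return {"alpha": self.alpha, "n_validated": self.n_validated,
                "validated": self.validated,
                "validation_fdr": (None if not np.isfinite(self.validation_fdr)
                                   else self.validation_fdr),
                "expected_false_validations": (
                    None if not np.isfinite(self.expected_false_validations)
                    else self.expected_false_validations)}


def _pvalue_matrix(results_by_cohort: Mapping[str, Sequence[AssociationResult]],
                   ) -> pd.DataFrame:
    """Factor x cohort matrix of p-values; NaN where not measured/failed."""
    records: dict[str, dict[str, float]] = {}
    for cid, results in results_by_cohort.items():
        for r in results:
            records.setdefault(r.symbol, {})[cid] = r.p_value
    return pd.DataFrame.from_dict(records, orient="index",
                                  columns=list(results_by_cohort))


def validate_multicohort(
        results_by_cohort: Mapping[str, Sequence[AssociationResult]],
        alpha: float = 0.02,
        registry: Mapping[str, Sequence[str]] | None = None,
        ) -> ValidationReport:
    """Validated = significant at alpha in >= 2 cohorts.

    A factor measured in fewer than two cohorts is *ineligible* (it cannot
    be validated or refuted), which is distinct from failing validation.
    ``registry`` (symbol -> cohorts measured in) overrides measurement
    counts when a factor's model failed in a cohort where it was measured.
    """
    pm = _pvalue_matrix(results_by_cohort)
    rows = []
    for sym, pvals in pm.iterrows():
        if registry is not None and sym in registry:
            n_measured = len(registry[sym])
        else:
            n_measured = int(pvals.notna().sum())
        n_sig = int((pvals <= alpha).sum())
        eligible = n_measured >= 2
        rows.append({"symbol": sym, "n_measured": n_measured,
                     "n_significant": n_sig, "eligible": eligible,
                     "validated": bool(eligible and n_sig >= 2)})
    table = pd.DataFrame(rows, columns=["symbol", "n_measured",
                                        "n_significant", "eligible",
                                        "validated"])
    return ValidationReport(alpha=alpha, table=table)


def count_validations(p_by_cohort: np.ndarray, alpha: float) -> int:
    """Count factors significant at alpha in >= 2 cohorts (rows = factors)."""
    sig = (p_by_cohort <= alpha) & np.isfinite(p_by_cohort)
    return int((sig.sum(axis=1) >= 2).sum())


def estimate_validation_fdr(nulls: Mapping[str, NullDistribution],
                            report: ValidationReport,
                            alpha: float | None = None,
                            ) -> ValidationReport:
    """Validation-stage FDR from paired permutation replicates.

    Replicate b of cohort 1 pairs with replicate b of every other cohort;
    for each replicate the number of factors significant in >= 2 permuted
    cohorts is counted. The expected false-validation count is the mean over
    replicates, and the validation FDR divides it by the observed number of
    validated factors (missing when nothing validated).
    """
    if alpha is None:
        alpha = report.alpha
    Bs = {nd.B for nd in nulls.values()}
    if len(Bs) != 1:
        raise ValueError(f"mismatched replicate counts across cohorts: {Bs}")
    B = Bs.pop()
    symbols = sorted({s for nd in nulls.values() for s in nd.p_values.columns})
    counts = np.zeros(B)
    # stack into B x factor x cohort
    mats = []
    for cid, nd in nulls.items():
        m = np.full((B, len(symbols)), np.nan)
        idx = [symbols.index(s) for s in nd.p_values.columns]
        m[:, idx] = nd.p_values.to_numpy()
        mats.append(m)
    cube = np.stack(mats, axis=2)
    for b in range(B):
        counts[b] = count_validations(cube[b], alpha)
    expected_false = float(counts.mean())
    n_val = report.n_validated
    vfdr = expected_false / n_val if n_val > 0 else float("nan")
    return dataclasses.replace(report, validation_fdr=vfdr,
                               expected_false_validations=expected_false)
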