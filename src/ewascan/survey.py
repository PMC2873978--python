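"""Design-based (survey-weighted) logistic regression.

Point estimates maximize the weighted Bernoulli pseudo-likelihood

    l(beta) = sum_i w_i [ y_i log mu_i + (1 - y_i) log(1 - mu_i) ],
    mu_i = expit(x_i' beta),

by Newton/IRLS with step-halving. Variances honor a stratified, clustered,
weighted design via Taylor linearization: the sandwich A^{-1} B A^{-1} where
A is the weighted Fisher information and B is the stratified between-PSU
covariance of summed weighted score contributions, with PSU totals centered
at their stratum mean and the usual n_h/(n_h - 1) stratum factor. The
with-replacement approximation is used throughout (no finite-population
correction), matching the convention of large national health surveys.

Inference references beta_j / SE_j against a t distribution with
df = (#PSUs) - (#strata), the standard design-based degrees of freedom.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.special import expit


class SurveyError(ValueError):
    """Base class for estimation failures on a survey design."""


class RankDeficiencyError(SurveyError):
    """Model matrix is not full column rank on the analysis set."""


class SeparationError(SurveyError):
    """Complete/quasi-complete separation: |beta| diverges, mu pinned at 0/1."""


class LonelyPsuError(SurveyError):
    """A stratum contains a single PSU, so its variance contribution is undefined."""


class ConvergenceWarning(UserWarning):
    pass


class _DesignPrep:
    """Sort order and PSU/stratum segment boundaries, cached on the design."""

    __slots__ = ("order", "psu_starts", "psu_stratum", "n_psu", "n_strata",
                 "stratum_sizes", "psu_per_stratum_starts")

    def __init__(self, stratum: np.ndarray, psu: np.ndarray) -> None:
        s_uniq, s_codes = np.unique(stratum, return_inverse=True)
        p_codes = np.unique(psu, return_inverse=True)[1]
        # PSU labels are nested in stratum; a reused label in another stratum
        # is a different PSU, so key on the (stratum, psu) pair.
        key = s_codes.astype(np.int64) * (p_codes.max() + 1) + p_codes
        self.order = np.argsort(key, kind="stable")
        sorted_key = key[self.order]
        first = np.empty(sorted_key.size, dtype=bool)
        first[0] = True
        np.not_equal(sorted_key[1:], sorted_key[:-1], out=first[1:])
        self.psu_starts = np.flatnonzero(first)
        self.psu_stratum = s_codes[self.order][self.psu_starts]
        self.n_psu = self.psu_starts.size
        self.n_strata = len(s_uniq)
        self.stratum_sizes = np.bincount(self.psu_stratum,
                                         minlength=self.n_strata)
        ps_first = np.empty(self.n_psu, dtype=bool)
        ps_first[0] = True
        np.not_equal(self.psu_stratum[1:], self.psu_stratum[:-1],
                     out=ps_first[1:])
        self.psu_per_stratum_starts = np.flatnonzero(ps_first)


class SurveyDesign:
    """Stratified, clustered, weighted sampling design for one analysis set.

    Parameters
    ----------
    stratum, psu : array-like
        Per-row stratum and primary-sampling-unit labels. PSUs are nested in
        strata; PSU labels may repeat across strata without collision.
    weight : array-like
        Positive, finite sampling weights.
    """

    def __init__(self, stratum, psu, weight) -> None:
        self.stratum = np.asarray(stratum)
        self.psu = np.asarray(psu)
        self.weight = np.asarray(weight, dtype=float)
        n = self.weight.size
        if self.stratum.size != n or self.psu.size != n:
            raise ValueError("stratum, psu and weight must have equal length")
        if n == 0:
            raise ValueError("empty design")
        if not np.all(np.isfinite(self.weight)) or np.any(self.weight <= 0):
            raise ValueError("weights must be finite and > 0")
        self._prep: _DesignPrep | None = None

    def __len__(self) -> int:
        return self.weight.size

    @property
    def prep(self) -> _DesignPrep:
        if self._prep is None:
            self._prep = _DesignPrep(self.stratum, self.psu)
        return self._prep

    @property
    def n_psu(self) -> int:
        return self.prep.n_psu

    @property
    def n_strata(self) -> int:
        return self.prep.n_strata

    @property
    def df_design(self) -> int:
        return self.prep.n_psu - self.prep.n_strata

    def subset(self, index) -> "SurveyDesign":
        return SurveyDesign(self.stratum[index], self.psu[index],
                            self.weight[index])


@dataclasses.dataclass
class FitResult:
    """Survey-weighted logistic fit: coefficients plus design-based covariance."""

    coefficients: np.ndarray
    covariance: np.ndarray
    term_names: list[str]
    n_obs: int
    n_case: int
    n_control: int
    df_design: int
    converged: bool
    iterations: int

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.covariance), 0.0, None))

    def term_index(self, term: str) -> int:
        try:
            return self.term_names.index(term)
        except ValueError:
            raise KeyError(f"term {term!r} not in model "
                           f"(terms: {self.term_names})") from None


def _rank_check(X: np.ndarray, term_names: Sequence[str]) -> None:
    r = np.linalg.qr(X, mode="r")
    d = np.abs(np.diag(r))
    tol = max(X.shape) * np.finfo(float).eps * (d.max() if d.size else 0.0)
    bad = np.flatnonzero(d <= tol)
    if bad.size:
        names = [term_names[j] for j in bad]
        raise RankDeficiencyError(
            f"model matrix rank-deficient; collinear terms: {names}")


def _weighted_loglik(w, y, mu) -> float:
    mu = np.clip(mu, 1e-12, 1.0 - 1e-12)
    return float(np.sum(w * (y * np.log(mu) + (1.0 - y) * np.log1p(-mu))))


def taylor_covariance(X: np.ndarray, resid_w: np.ndarray, info: np.ndarray,
                      design: SurveyDesign,
                      lonely_psu: str = "error") -> np.ndarray:
    """Taylor-linearization sandwich A^{-1} B A^{-1}.

    ``resid_w`` are the weighted raw residuals w_i (y_i - mu_i); ``info`` is
    the weighted information X' diag(w mu (1-mu)) X evaluated at the estimate.
    B sums, per stratum h with n_h PSUs, n_h/(n_h-1) times the outer products
    of PSU score totals centered at the stratum mean.

    ``lonely_psu``: "error" raises on a single-PSU stratum; "certainty"
    treats such a stratum as sampled with certainty (zero variance
    contribution).
    """
    prep = design.prep
    if lonely_psu not in ("error", "certainty"):
        raise ValueError("lonely_psu must be 'error' or 'certainty'")
    if lonely_psu == "error" and np.any(prep.stratum_sizes == 1):
        lonely = int(np.sum(prep.stratum_sizes == 1))
        raise LonelyPsuError(
            f"{lonely} stratum/strata contain a single PSU; design variance "
            "is undefined (pass lonely_psu='certainty' to treat them as "
            "certainty strata with zero variance contribution)")
    U = X * resid_w[:, None]
    Z = np.add.reduceat(U[prep.order], prep.psu_starts, axis=0)
    # stratum means of PSU totals, broadcast back to PSUs (stratum codes are
    # dense and psu_stratum is sorted, so reduceat rows line up with codes)
    means = (np.add.reduceat(Z, prep.psu_per_stratum_starts, axis=0)
             / prep.stratum_sizes[:, None])
    dev = Z - means[prep.psu_stratum]
    n_h = prep.stratum_sizes[prep.psu_stratum].astype(float)
    factor = np.where(n_h > 1, n_h / np.maximum(n_h - 1.0, 1.0), 0.0)
    devs = dev * np.sqrt(factor)[:, None]
    B = devs.T @ devs
    a_inv = np.linalg.inv(info)
    cov = a_inv @ B @ a_inv
    return (cov + cov.T) / 2.0


def fit_weighted_logistic(y, X, design: SurveyDesign, *,
                          term_names: Sequence[str] | None = None,
                          max_iter: int = 100, tol: float = 1e-8,
                          lonely_psu: str = "error",
                          check_rank: bool = True) -> FitResult:
    """Fit a survey-weighted logistic regression.

    Convergence is declared when max|delta beta| < ``tol`` (default 1e-8)
    within ``max_iter`` Newton steps; a step that decreases the
    pseudo-likelihood is halved. A non-converged fit without evidence of
    separation is returned flagged (``converged=False``); downstream tests
    treat its p-values as missing.
    """
    y = np.asarray(y, dtype=float)
    X = np.ascontiguousarray(X, dtype=float)
    if X.ndim != 2 or y.shape[0] != X.shape[0] or len(design) != X.shape[0]:
        raise ValueError("incompatible shapes for y, X, design")
    uy = np.unique(y)
    if not np.all(np.isin(uy, (0.0, 1.0))):
        raise ValueError("response must be binary 0/1")
    if uy.size < 2:
        raise SurveyError("response has no variation (all cases or all controls)")
    n, p = X.shape
    names = list(term_names) if term_names is not None else [
        f"x{j}" for j in range(p)]
    if check_rank:
        _rank_check(X, names)
    w = design.weight

    beta = np.zeros(p)
    eta = np.zeros(n)
    mu = np.full(n, 0.5)
    ll = _weighted_loglik(w, y, mu)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        grad = X.T @ (w * (y - mu))
        wmu = w * mu * (1.0 - mu)
        info = (X * wmu[:, None]).T @ X
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            raise SeparationError(
                "information matrix singular during iteration (fitted "
                "probabilities pinned at 0/1: separation or degenerate fit)")
        # step-halving on pseudo-likelihood decrease
        for _ in range(40):
            cand = beta + step
            eta_c = X @ cand
            mu_c = expit(eta_c)
            ll_c = _weighted_loglik(w, y, mu_c)
            if ll_c >= ll - 1e-10:
                break
            step = step / 2.0
        delta = np.max(np.abs(cand - beta))
        beta, eta, mu, ll = cand, eta_c, mu_c, ll_c
        if np.max(np.abs(beta)) > 1e3:
            raise SeparationError(
                "diverging coefficients (|beta| > 1e3): complete or "
                "quasi-complete separation")
        if delta < tol:
            converged = True
            break
    if not converged:
        if np.max(np.abs(eta)) > 30.0:
            raise SeparationError(
                "fitted probabilities numerically pinned at 0/1 without "
                "convergence: separation")
        warnings.warn("IRLS did not converge in "
                      f"{max_iter} iterations (max|delta|={delta:.2e})",
                      ConvergenceWarning, stacklevel=2)

    wmu = w * mu * (1.0 - mu)
    info = (X * wmu[:, None]).T @ X
    cov = taylor_covariance(X, w * (y - mu), info, design,
                            lonely_psu=lonely_psu)
    return FitResult(
        coefficients=beta, covariance=cov, term_names=names,
        n_obs=n, n_case=int(y.sum()), n_control=int(n - y.sum()),
        df_design=design.df_design, converged=converged, iterations=it)


def wald_test(fit: FitResult, term: str, *,
              reference: str = "t") -> tuple[float, float]:
    """Two-sided Wald test of a single coefficient.

    Default reference is t with df = #PSUs - #strata; ``reference="normal"``
    uses the standard normal instead (both conventions are common; the t is
    the conservative design-based default).
    """
    j = fit.term_index(term)
    beta = fit.coefficients[j]
    se = fit.se[j]
    if not fit.converged or not np.isfinite(se):
        return float("nan"), float("nan")
    if se == 0.0:
        warnings.warn(f"zero standard error for term {term!r}; p set to "
                      "missing", UserWarning, stacklevel=2)
        return float("nan"), float("nan")
    t = beta / se
    if reference == "normal":
        p = 2.0 * stats.norm.sf(abs(t))
    elif reference == "t":
        if fit.df_design < 1:
            return float(t), float("nan")
        p = 2.0 * stats.t.sf(abs(t), df=fit.df_design)
    else:
        raise ValueError("reference must be 't' or 'normal'")
    return float(t), float(p)
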