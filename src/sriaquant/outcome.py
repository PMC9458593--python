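"""Delayed-graft-function outcome modelling.

Logistic regression of the DGF indicator (dialysis within the first
post-transplant week) on donor, recipient and histology covariates, in the
two-step form used for transplant risk-factor analyses: a univariate screen
retaining candidates at Wald p < 0.1, then a multivariate fit of the
retained set with Wald odds-ratio confidence intervals and a variance
inflation factor (VIF) collinearity check.

The model surface follows the statsmodels convention: a
:class:`DgfLogisticModel` built from data whose :meth:`fit` returns a
:class:`LogisticResults` carrying estimates, uncertainties, diagnostics and
a ``summary()`` table.  The maximum-likelihood fit is iteratively
reweighted least squares (IRLS) written here so the iteration trace (and
hence the likelihood-monotonicity diagnostic) is available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TermEstimate",
    "LogisticFit",
    "LogisticResults",
    "DgfLogisticModel",
    "fit_logistic",
    "univariate_screen",
    "ScreenResult",
    "vif",
    "dgf_analysis",
    "DEFAULT_CANDIDATES",
]

_Z_95 = 1.96

# Candidate risk factors screened for DGF by default.  Categorical donor
# type is coded as an NHBD indicator (BDD reference).
DEFAULT_CANDIDATES = [
    "sria_paraffin_pct",
    "sria_frozen_pct",
    "if_grade_original",
    "remuzzi_final_grade",
    "cit_hours",
    "donor_age",
    "donor_male",
    "recipient_age",
    "recipient_male",
    "dsa_present",
]


@dataclass(frozen=True)
class TermEstimate:
    name: str
    coefficient: float
    se: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    p: float
    vif: Optional[float] = None


@dataclass
class LogisticFit:
    """Raw fit payload: per-term estimates plus convergence diagnostics."""

    terms: list[TermEstimate]
    intercept: float
    intercept_se: float
    n: int
    converged: bool
    loglik: float
    n_iter: int
    loglik_trace: list[float]
    diagnostic: Optional[str] = None


def _sigmoid(eta: np.ndarray) -> np.ndarray:
    out = np.empty_like(eta)
    pos = eta >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-eta[pos]))
    e = np.exp(eta[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def _log_likelihood(y: np.ndarray, eta: np.ndarray) -> float:
    # numerically stable: sum y*eta - log(1 + exp(eta))
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def _irls(
    X: np.ndarray,
    y: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> tuple[np.ndarray, np.ndarray, bool, list[float], Optional[str]]:
    """IRLS for the binomial GLM with logit link.

    Returns (beta, covariance, converged, loglik_trace, diagnostic).  Each
    iteration solves the weighted least-squares normal equations with
    weights mu(1-mu); a step that would decrease the log-likelihood is
    halved (step-halving keeps the trace non-decreasing).
    """
    n, p = X.shape
    beta = np.zeros(p)
    eta = X @ beta
    ll = _log_likelihood(y, eta)
    trace = [ll]
    converged = False
    diagnostic = None
    for _ in range(max_iter):
        mu = _sigmoid(eta)
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        z = eta + (y - mu) / w
        sw = np.sqrt(w)
        beta_new, *_ = np.linalg.lstsq(X * sw[:, None], z * sw, rcond=None)
        step = beta_new - beta
        # step-halving: guarantee the likelihood never decreases
        factor = 1.0
        for _half in range(30):
            cand = beta + factor * step
            ll_new = _log_likelihood(y, X @ cand)
            if ll_new >= ll - 1e-12:
                break
            factor *= 0.5
        beta = beta + factor * step
        eta = X @ beta
        ll_new = _log_likelihood(y, eta)
        trace.append(ll_new)
        rel = abs(ll_new - ll) / (abs(ll) + 1e-12)
        ll = ll_new
        if rel < tol:
            converged = True
            break
    if np.max(np.abs(beta)) > 30.0:
        converged = False
        diagnostic = (
            "possible complete separation: a coefficient diverged "
            "(|beta| > 30); Wald inference is unreliable"
        )
    mu = _sigmoid(eta)
    w = np.clip(mu * (1.0 - mu), 1e-10, None)
    info = (X * w[:, None]).T @ X
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.full((p, p), np.nan)
        if diagnostic is None:
            diagnostic = "singular information matrix"
        converged = False
    if not converged and diagnostic is None:
        diagnostic = f"no convergence within {max_iter} IRLS iterations"
    return beta, cov, converged, trace, diagnostic


def fit_logistic(
    outcome: Iterable,
    covariates: Optional[pd.DataFrame] = None,
    tol: float = 1e-8,
    max_iter: int = 100,
    compute_vif: bool = True,
) -> LogisticFit:
    """Maximum-likelihood logistic fit of a boolean outcome on named columns.

    An intercept is always included; ``covariates=None`` (or an empty frame)
    fits the intercept-only model.  Wald z-tests give per-term p-values and
    95% CIs on the odds-ratio scale (exp(beta +/- 1.96 se)).
    """
    y = np.asarray(outcome).astype(float)
    if y.ndim != 1:
        raise ValueError("outcome must be one-dimensional")
    if not np.all(np.isin(y, (0.0, 1.0))):
        raise ValueError("outcome must be boolean (0/1)")
    if covariates is None:
        covariates = pd.DataFrame(index=range(y.size))
    X_cov = covariates.astype(float)
    names = list(X_cov.columns)
    n = y.size
    if len(X_cov) != n:
        raise ValueError("outcome and covariates must have equal length")
    if y.min() == y.max():
        raise ValueError("outcome has a single class; the model is not identified")
    if n <= len(names) + 1:
        raise ValueError("need n > number of terms + 1")
    for name in names:
        if np.ptp(X_cov[name].to_numpy()) == 0.0:
            raise ValueError(f"covariate {name!r} is constant")
    X = np.column_stack([np.ones(n), X_cov.to_numpy()])
    beta, cov, converged, trace, diagnostic = _irls(X, y, tol=tol, max_iter=max_iter)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    from scipy import stats as _st

    vifs: dict[str, float] = {}
    if compute_vif and len(names) >= 2:
        try:
            vifs = vif(X_cov)
        except ValueError:
            vifs = {}
    terms = []
    def _exp(v: float) -> float:
        return math.exp(v) if v < 700.0 else float("inf")

    for j, name in enumerate(names, start=1):
        b, s = float(beta[j]), float(se[j])
        z = b / s if s > 0 else np.nan
        terms.append(
            TermEstimate(
                name=name,
                coefficient=b,
                se=s,
                odds_ratio=_exp(b),
                ci_low=_exp(b - _Z_95 * s),
                ci_high=_exp(b + _Z_95 * s),
                p=float(2.0 * _st.norm.sf(abs(z))) if np.isfinite(z) else float("nan"),
                vif=vifs.get(name),
            )
        )
    return LogisticFit(
        terms=terms,
        intercept=float(beta[0]),
        intercept_se=float(se[0]),
        n=n,
        converged=converged,
        loglik=trace[-1],
        n_iter=len(trace) - 1,
        loglik_trace=trace,
        diagnostic=diagnostic,
    )


def vif(covariates: pd.DataFrame) -> dict[str, float]:
    """Variance inflation factors, VIF_j = 1 / (1 - R^2_j).

    R^2_j comes from the OLS regression (with intercept) of covariate j on
    the remaining covariates.  Exact collinearity is reported as ``inf``.
    """
    X = covariates.astype(float)
    names = list(X.columns)
    if len(names) < 2:
        raise ValueError("VIF needs at least 2 covariates")
    arr = X.to_numpy()
    for j, name in enumerate(names):
        if np.ptp(arr[:, j]) == 0.0:
            raise ValueError(f"covariate {name!r} is constant")
    out: dict[str, float] = {}
    n = arr.shape[0]
    for j, name in enumerate(names):
        yj = arr[:, j]
        others = np.column_stack(
            [np.ones(n)] + [arr[:, k] for k in range(len(names)) if k != j]
        )
        coef, *_ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ coef
        ss_res = float(resid @ resid)
        ss_tot = float(np.sum((yj - yj.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot
        if r2 >= 1.0 - 1e-12:
            out[name] = float("inf")
        else:
            out[name] = 1.0 / (1.0 - r2)
    return out


@dataclass
class ScreenResult:
    """Per-candidate univariate fits and the retained set."""

    fits: dict[str, LogisticFit]
    errors: dict[str, str]
    retained: list[str]
    alpha_in: float

    def p_values(self) -> dict[str, float]:
        return {name: f.terms[0].p for name, f in self.fits.items()}


def univariate_screen(
    data: pd.DataFrame,
    outcome: str,
    candidates: Sequence[str],
    alpha_in: float = 0.1,
) -> ScreenResult:
    """Single-covariate logistic fits; retain candidates with Wald p < alpha_in.

    Per-candidate errors (constant column, failed fit, ...) are recorded and
    do not abort the screen.
    """
    if len(candidates) == 0:
        raise ValueError("at least one candidate covariate is required")
    y = _coerce_outcome(data[outcome])
    fits: dict[str, LogisticFit] = {}
    errors: dict[str, str] = {}
    retained: list[str] = []
    for name in candidates:
        try:
            X = _coerce_design(data[[name]])
            f = fit_logistic(y, X, compute_vif=False)
            fits[name] = f
            p = f.terms[0].p
            if np.isfinite(p) and p < alpha_in:
                retained.append(name)
        except Exception as exc:  # propagate per-covariate, keep screening
            errors[name] = str(exc)
    return ScreenResult(fits=fits, errors=errors, retained=retained, alpha_in=alpha_in)


def _coerce_outcome(col: pd.Series) -> np.ndarray:
    return col.astype(bool).to_numpy().astype(float)


def _coerce_design(df: pd.DataFrame) -> pd.DataFrame:
    """Code booleans as 0/1 and the donor_type category as an NHBD indicator."""
    out = {}
    for name in df.columns:
        col = df[name]
        if col.dtype == object or str(col.dtype) == "category":
            levels = sorted(col.astype(str).unique())
            if set(levels) <= {"BDD", "NHBD"}:
                out["nhbd"] = (col.astype(str) == "NHBD").astype(float)
            elif len(levels) == 2:
                out[f"{name}_{levels[1]}"] = (col.astype(str) == levels[1]).astype(float)
            else:
                raise ValueError(
                    f"cannot code categorical covariate {name!r} with levels {levels}"
                )
        else:
            out[name] = col.astype(float)
    return pd.DataFrame(out, index=df.index)


class LogisticResults:
    """Results wrapper with statsmodels-style accessors and summary()."""

    def __init__(self, model: "DgfLogisticModel", fit: LogisticFit):
        self.model = model
        self._fit = fit

    # -- convenience accessors ------------------------------------------
    @property
    def params(self) -> pd.Series:
        vals = {"intercept": self._fit.intercept}
        vals.update({t.name: t.coefficient for t in self._fit.terms})
        return pd.Series(vals)

    @property
    def bse(self) -> pd.Series:
        vals = {"intercept": self._fit.intercept_se}
        vals.update({t.name: t.se for t in self._fit.terms})
        return pd.Series(vals)

    @property
    def odds_ratios(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "odds_ratio": [t.odds_ratio for t in self._fit.terms],
                "ci_low": [t.ci_low for t in self._fit.terms],
                "ci_high": [t.ci_high for t in self._fit.terms],
                "p": [t.p for t in self._fit.terms],
                "vif": [t.vif for t in self._fit.terms],
            },
            index=[t.name for t in self._fit.terms],
        )

    @property
    def converged(self) -> bool:
        return self._fit.converged

    @property
    def diagnostic(self) -> Optional[str]:
        return self._fit.diagnostic

    @property
    def llf(self) -> float:
        return self._fit.loglik

    @property
    def nobs(self) -> int:
        return self._fit.n

    @property
    def intercept(self) -> float:
        return self._fit.intercept

    @property
    def terms(self) -> list[TermEstimate]:
        return self._fit.terms

    @property
    def loglik_trace(self) -> list[float]:
        return self._fit.loglik_trace

    def predict(self, X: Optional[pd.DataFrame] = None) -> np.ndarray:
        if X is None:
            X = self.model.exog
        Xc = _coerce_design(X)[[t.name for t in self._fit.terms]] \
            if len(self._fit.terms) else pd.DataFrame(index=X.index)
        eta = self._fit.intercept + (
            Xc.to_numpy() @ np.array([t.coefficient for t in self._fit.terms])
            if len(self._fit.terms) else 0.0
        )
        return _sigmoid(np.atleast_1d(np.asarray(eta, dtype=float)))

    def to_dict(self) -> dict:
        return {
            "intercept": self._fit.intercept,
            "n": self._fit.n,
            "converged": self._fit.converged,
            "loglik": self._fit.loglik,
            "diagnostic": self._fit.diagnostic,
            "terms": [
                {
                    "name": t.name,
                    "coefficient": t.coefficient,
                    "se": t.se,
                    "odds_ratio": t.odds_ratio,
                    "ci_low": t.ci_low,
                    "ci_high": t.ci_high,
                    "p": t.p,
                    "vif": t.vif,
                }
                for t in self._fit.terms
            ],
        }

    def summary(self) -> str:
        lines = [
            "Logistic regression for delayed graft function",
            "=" * 62,
            f"n = {self.nobs}   log-likelihood = {self.llf:.3f}   "
            f"converged = {self.converged}",
            f"intercept = {self.intercept:.3f} (SE {self._fit.intercept_se:.3f})",
            "-" * 62,
            f"{'term':<22}{'OR':>8}{'95% CI':>18}{'p':>8}{'VIF':>6}",
        ]
        for t in self._fit.terms:
            ci = f"{t.ci_low:.3f}-{t.ci_high:.3f}"
            vif_s = f"{t.vif:.3f}" if t.vif is not None else "-"
            lines.append(
                f"{t.name:<22}{t.odds_ratio:>8.3f}{ci:>18}{t.p:>8.3f}{vif_s:>6}"
            )
        if self.diagnostic:
            lines.append(f"note: {self.diagnostic}")
        return "\n".join(lines)


class DgfLogisticModel:
    """Logistic model of a binary outcome on named covariates.

    Parameters
    ----------
    endog : boolean outcome vector.
    exog : DataFrame of covariates (may be empty for intercept-only);
        booleans are coded 0/1, donor type as an NHBD indicator.
    """

    def __init__(self, endog: Iterable, exog: Optional[pd.DataFrame] = None):
        self.endog = np.asarray(list(endog) if not isinstance(endog, np.ndarray) else endog)
        self.exog = exog if exog is not None else pd.DataFrame(
            index=range(len(self.endog))
        )

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        outcome: str = "dgf",
        covariates: Optional[Sequence[str]] = None,
    ) -> "DgfLogisticModel":
        if covariates is None:
            covariates = [c for c in DEFAULT_CANDIDATES if c in data.columns]
        return cls(_coerce_outcome(data[outcome]), data[list(covariates)])

    def fit(self, tol: float = 1e-8, max_iter: int = 100) -> LogisticResults:
        X = _coerce_design(self.exog) if len(self.exog.columns) else self.exog
        raw = fit_logistic(self.endog, X, tol=tol, max_iter=max_iter)
        return LogisticResults(self, raw)


def dgf_analysis(
    data: pd.DataFrame,
    outcome: str = "dgf",
    candidates: Optional[Sequence[str]] = None,
    alpha_in: float = 0.1,
) -> tuple[ScreenResult, LogisticResults]:
    """Screen-then-fit: univariate screen at alpha_in, then multivariate fit.

    With ``alpha_in = 1.0`` every candidate is retained, so the second step
    is the direct all-candidate fit.  An empty retained set degenerates to
    the intercept-only model.
    """
    if candidates is None:
        candidates = [c for c in DEFAULT_CANDIDATES if c in data.columns]
    screen = univariate_screen(data, outcome, candidates, alpha_in=alpha_in)
    model = DgfLogisticModel.from_dataframe(data, outcome, screen.retained)
    return screen, model.fit()
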