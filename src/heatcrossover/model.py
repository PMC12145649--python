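"""Conditional quasi-Poisson regression for the case-crossover design.

Conditioning Poisson counts on each stratum's total eliminates the stratum
intercepts and leaves a multinomial likelihood: within stratum s with days
j = 1..J_s, counts y_sj and linear predictors eta_sj = x_sj' beta,

    l(beta) = sum_s [ sum_j y_sj * eta_sj  -  n_s * log sum_k exp(eta_sk) ],

with n_s = sum_j y_sj.  The score and Hessian are analytic (multinomial
moments), the objective is concave, and Newton-Raphson with step-halving
from beta = 0 converges globally.  Overdispersion is handled quasi-style:
the variance is assumed proportional to the mean, phi is estimated from the
Pearson statistic on the fitted within-stratum means mu_sj = n_s * p_sj
with residual degrees of freedom N - p - S (N analysed days, p free
coefficients, S informative strata — the eliminated stratum parameters
count), and the covariance is scaled by phi.  Rate ratios are exp(beta)
with Wald 95% intervals on the log scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ModelFit",
    "RRReport",
    "conditional_loglik",
    "fit",
    "report_rr",
    "stratified_analysis",
    "SUPPRESSION_THRESHOLD",
    "Z_95",
]

# reporting rule: outcomes with fewer exposed-day events than this are
# flagged suppressed (fitted anyway; the flag governs presentation)
SUPPRESSION_THRESHOLD = 20

Z_95 = 1.959964  # normal 97.5% quantile for Wald intervals

_MAX_ITER = 100
_SCORE_TOL = 1e-8
_REL_LL_TOL = 1e-10


class ConvergenceError(RuntimeError):
    def __init__(self, trace):
        self.trace = trace
        super().__init__(
            f"Newton-Raphson did not converge in {len(trace)} iterations; "
            f"final max|score| = {trace[-1][1]:.3g}"
        )


@dataclass
class _Strata:
    """Sorted-by-stratum arrays with reduceat boundaries."""

    y: np.ndarray  # counts, length N
    X: np.ndarray  # design matrix, N x p
    starts: np.ndarray  # first row of each stratum
    n_s: np.ndarray  # stratum totals sum_j y_sj
    sizes: np.ndarray

    @classmethod
    def from_table(cls, table: pd.DataFrame, covariates=()) -> "_Strata":
        cols = ["x", *covariates]
        t = table.sort_values("stratum_id", kind="stable")
        y = t["y"].to_numpy(dtype=float)
        X = t[cols].to_numpy(dtype=float)
        codes = pd.factorize(t["stratum_id"], sort=False)[0]
        starts = np.flatnonzero(np.r_[True, np.diff(codes) != 0])
        n_s = np.add.reduceat(y, starts)
        sizes = np.diff(np.r_[starts, len(y)])
        return cls(y=y, X=X, starts=starts, n_s=n_s, sizes=sizes)

    def expand(self, per_stratum: np.ndarray) -> np.ndarray:
        return np.repeat(per_stratum, self.sizes)


def _loglik_parts(beta: np.ndarray, s: _Strata):
    """Log-likelihood, score, Hessian and fitted means at beta."""
    eta = s.X @ beta
    if not np.isfinite(eta).all():
        bad = int(np.flatnonzero(~np.isfinite(eta))[0])
        stratum = int(np.searchsorted(s.starts, bad, side="right") - 1)
        raise FloatingPointError(f"non-finite linear predictor in stratum #{stratum}")
    m = s.expand(np.maximum.reduceat(eta, s.starts))
    w = np.exp(eta - m)
    denom = np.add.reduceat(w, s.starts)
    lse = np.maximum.reduceat(eta, s.starts) + np.log(denom)
    p = w / s.expand(denom)
    mu = s.expand(s.n_s) * p
    ll = float(s.y @ eta - s.n_s @ lse)
    score = s.X.T @ (s.y - mu)
    # Hessian = -(X' diag(mu) X - sum_s n_s g_s g_s'),  g_s = X_s' p_s
    G = np.add.reduceat(s.X * p[:, None], s.starts, axis=0)
    H = -(s.X.T @ (s.X * mu[:, None]) - (G * s.n_s[:, None]).T @ G)
    return ll, score, H, mu


def conditional_loglik(beta, table: pd.DataFrame, covariates=()):
    """Stratum-conditional log-likelihood with analytic score and Hessian.

    Returns (loglik, score, hessian) at ``beta`` for the stratified table
    (columns stratum_id, y, x and any covariate columns).
    """
    s = _Strata.from_table(table, covariates)
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    ll, score, H, _ = _loglik_parts(beta, s)
    return ll, score, H


@dataclass
class ModelFit:
    """Conditional quasi-Poisson fit summary."""

    beta: np.ndarray
    cov: np.ndarray  # phi-scaled covariance
    cov_unscaled: np.ndarray
    dispersion: float
    loglik: float
    n_strata_used: int
    n_days: int
    n_exposed_events: int
    converged: bool
    iterations: int
    term_names: tuple[str, ...] = field(default_factory=tuple)

    @property
    def se(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.sqrt(np.diag(self.cov))

    @property
    def rr(self) -> float:
        return float(np.exp(self.beta[0]))


def _check_rank(s: _Strata, names) -> None:
    """Full-rank check after within-stratum centering (strata absorb means)."""
    means = np.add.reduceat(s.X, s.starts, axis=0) / s.sizes[:, None]
    centered = s.X - np.repeat(means, s.sizes, axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    tol = max(centered.shape) * np.finfo(float).eps * (sv[0] if sv.size else 0.0)
    rank = int(np.sum(sv > tol)) if sv.size else 0
    if rank < centered.shape[1]:
        # name columns whose centered variant is (nearly) in the span of others
        aliased = []
        for j, name in enumerate(names):
            others = np.delete(centered, j, axis=1)
            resid = centered[:, j]
            if others.shape[1]:
                coef, *_ = np.linalg.lstsq(others, resid, rcond=None)
                resid = resid - others @ coef
            if np.linalg.norm(resid) <= tol * 10:
                aliased.append(name)
        raise np.linalg.LinAlgError(
            f"design matrix rank deficient after within-stratum centering; "
            f"aliased columns: {aliased or list(names)}"
        )


def fit(table: pd.DataFrame, covariates=()) -> ModelFit:
    """Maximise the conditional likelihood by Newton-Raphson with step-halving.

    ``table`` must already be informative (see design.filter_informative).
    Convergence requires max|score| < 1e-8 and relative log-likelihood change
    < 1e-10.  The exposure coefficient is the first term; ``covariates``
    names additional linear-predictor columns (e.g. ``rh_pct``).
    """
    s = _Strata.from_table(table, covariates)
    names = ("x", *covariates)
    _check_rank(s, names)
    p = s.X.shape[1]
    beta = np.zeros(p)
    ll, score, H, _ = _loglik_parts(beta, s)
    trace = []
    converged = False
    it = 0
    for it in range(1, _MAX_ITER + 1):
        step = np.linalg.solve(-H, score)
        new_beta, new = beta + step, None
        slack = 1e-10 * (abs(ll) + 1.0)  # rounding-aware monotone-ascent check
        for _ in range(30):  # step-halving keeps the ascent monotone
            new = _loglik_parts(new_beta, s)
            if new[0] >= ll - slack:
                break
            new_beta = beta + (new_beta - beta) / 2.0
        rel_change = abs(new[0] - ll) / (abs(ll) + 1e-12)
        beta, (ll, score, H, mu) = new_beta, new
        trace.append((ll, float(np.max(np.abs(score)))))
        if np.max(np.abs(score)) < _SCORE_TOL and rel_change < _REL_LL_TOL:
            converged = True
            break
    if not converged:
        raise ConvergenceError(trace)
    cov_unscaled = np.linalg.inv(-H)
    n_days = len(s.y)
    n_strata = len(s.starts)
    pearson = float(np.sum((s.y - mu) ** 2 / mu))
    df = n_days - p - n_strata
    dispersion = pearson / df if df > 0 else np.nan
    exposed_events = int(s.y[s.X[:, 0] > 0].sum())
    return ModelFit(
        beta=beta,
        cov=dispersion * cov_unscaled if np.isfinite(dispersion) else cov_unscaled,
        cov_unscaled=cov_unscaled,
        dispersion=dispersion,
        loglik=ll,
        n_strata_used=n_strata,
        n_days=n_days,
        n_exposed_events=exposed_events,
        converged=converged,
        iterations=it,
        term_names=names,
    )


@dataclass
class RRReport:
    """Rate ratio with 95% CI in the field's percent-change idiom."""

    outcome: str
    exposure_def: str
    slice: str
    rr: float
    ci_low: float
    ci_high: float
    n_exposed_events: int
    suppressed: bool
    phi: float
    n_strata: int
    converged: bool
    error: str | None = None

    @property
    def pct_change(self) -> float:
        return 100.0 * (self.rr - 1.0)

    def format_abstract(self) -> str:
        """'29% (16-44%)' — integer percent change with its CI."""
        lo = 100.0 * (self.ci_low - 1.0)
        hi = 100.0 * (self.ci_high - 1.0)
        if not all(np.isfinite(v) for v in (self.pct_change, lo, hi)):
            return "not estimable"
        return f"{round(self.pct_change):d}% ({round(lo):d}-{round(hi):d}%)"

    def to_row(self) -> dict:
        return {
            "outcome": self.outcome,
            "exposure_def": self.exposure_def,
            "slice": self.slice,
            "rr": self.rr,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "pct_change": self.pct_change,
            "n_exposed_events": self.n_exposed_events,
            "suppressed": self.suppressed,
            "phi": self.phi,
            "n_strata": self.n_strata,
            "converged": self.converged,
            "error": self.error or "",
        }


def report_rr(
    fit_result: ModelFit,
    exposed_event_count: int,
    outcome: str = "",
    exposure_def: str = "",
    slice_name: str = "all",
) -> RRReport:
    """Rate ratio, Wald 95% CI and the suppression flag for one fit.

    ``exposed_event_count`` is the total event count on exposed days in the
    full (pre-filtering) analysis table; fewer than 20 exposed events flags
    the estimate as suppressed for presentation while keeping diagnostics.
    """
    b = float(fit_result.beta[0])
    se = float(fit_result.se[0])
    with np.errstate(over="ignore"):
        ci_low, ci_high = np.exp(b - Z_95 * se), np.exp(b + Z_95 * se)
    return RRReport(
        outcome=outcome,
        exposure_def=exposure_def,
        slice=slice_name,
        rr=float(np.exp(b)),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        n_exposed_events=int(exposed_event_count),
        suppressed=bool(exposed_event_count < SUPPRESSION_THRESHOLD),
        phi=float(fit_result.dispersion),
        n_strata=fit_result.n_strata_used,
        converged=fit_result.converged,
    )


def _not_estimable(outcome, exposure_def, slice_name, exposed, message) -> RRReport:
    return RRReport(
        outcome=outcome,
        exposure_def=exposure_def,
        slice=slice_name,
        rr=float("nan"),
        ci_low=float("nan"),
        ci_high=float("nan"),
        n_exposed_events=int(exposed),
        suppressed=bool(exposed < SUPPRESSION_THRESHOLD),
        phi=float("nan"),
        n_strata=0,
        converged=False,
        error=message,
    )


def stratified_analysis(
    tables: dict[str, pd.DataFrame],
    outcome: str = "",
    exposure_def: str = "",
    covariates=(),
) -> list[RRReport]:
    """Independent fits over demographic slices of one outcome/exposure.

    ``tables`` maps slice name (``all``, ``M``, ``F``, ``age_0_4``, ...) to
    its assembled stratified table.  Sex-missing records enter only the
    unstratified slice upstream.  A slice that fails (no informative strata,
    no convergence) is reported as not-estimable without aborting others.
    """
    from .design import filter_informative

    reports = []
    for slice_name, table in tables.items():
        exposed = int(table.loc[table["x"] > 0, "y"].sum())
        try:
            informative, _ = filter_informative(table)
            result = fit(informative, covariates=covariates)
        except (ValueError, ConvergenceError, np.linalg.LinAlgError, FloatingPointError) as exc:
            reports.append(
                _not_estimable(outcome, exposure_def, slice_name, exposed, str(exc))
            )
            continue
        reports.append(
            report_rr(result, exposed, outcome, exposure_def, slice_name)
        )
    return reports
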