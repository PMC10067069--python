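"""Contingency and survival statistics, implemented from first principles.

Everything a two-group prognostic evaluation needs:

* odds ratio with the Woolf (log-normal) confidence interval and the
  Haldane–Anscombe +0.5 correction for zero cells;
* two-sided Fisher exact test by full hypergeometric enumeration, with the
  point-probability criterion for "as or more extreme";
* Kaplan–Meier product-limit estimation with Greenwood variance and
  log-transformed confidence intervals;
* the two-group log-rank test;
* Cox proportional-hazards fitting by Newton–Raphson with step-halving and
  the Efron (default) or Breslow correction for tied event times.

scipy supplies only distribution functions (normal/chi-square CDFs); the
estimators and tests themselves are authored here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm


# --------------------------------------------------------------------------
# 2x2 contingency
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ContingencyTable2x2:
    """Progression x risk-group counts.

    ``a``/``b``: exposed (e.g. high-risk) with/without the outcome;
    ``c``/``d``: unexposed with/without the outcome.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(int(v) != v or v < 0 for v in cells):
            raise ValueError("cells must be non-negative integers")
        if sum(cells) < 1:
            raise ValueError("table must contain at least one observation")

    @classmethod
    def from_groups(
        cls, exposed_events: int, exposed_total: int,
        unexposed_events: int, unexposed_total: int,
    ) -> "ContingencyTable2x2":
        return cls(
            exposed_events, exposed_total - exposed_events,
            unexposed_events, unexposed_total - unexposed_events,
        )


@dataclass(frozen=True)
class OddsRatioResult:
    or_estimate: float
    ci_low: float
    ci_high: float
    alpha: float
    corrected: bool  # Haldane–Anscombe +0.5 applied (a zero cell was present)


def odds_ratio(table: ContingencyTable2x2, alpha: float = 0.05) -> OddsRatioResult:
    """Odds ratio with the Woolf log-normal confidence interval.

    CI: exp(ln OR ± z_{1-alpha/2} * sqrt(1/a + 1/b + 1/c + 1/d)).  Any zero
    cell triggers the Haldane–Anscombe correction (+0.5 to every cell) and
    the result is flagged ``corrected``.
    """
    a, b, c, d = float(table.a), float(table.b), float(table.c), float(table.d)
    corrected = min(a, b, c, d) == 0
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_est = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = norm.ppf(1 - alpha / 2)
    return OddsRatioResult(
        or_estimate=or_est,
        ci_low=math.exp(math.log(or_est) - z * se),
        ci_high=math.exp(math.log(or_est) + z * se),
        alpha=alpha,
        corrected=corrected,
    )


def _log_comb(n: int, k: int) -> float:
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


def fisher_table_probabilities(table: ContingencyTable2x2) -> tuple[np.ndarray, np.ndarray]:
    """Hypergeometric point probability of every table with the same margins.

    Returns (values of cell ``a``, probabilities), enumerated over the full
    feasible range.  Probabilities sum to 1 up to floating error.
    """
    r1, r2 = table.a + table.b, table.c + table.d
    c1 = table.a + table.c
    n = r1 + r2
    lo, hi = max(0, c1 - r2), min(r1, c1)
    xs = np.arange(lo, hi + 1)
    log_denom = _log_comb(n, c1)
    log_p = np.array(
        [_log_comb(r1, x) + _log_comb(r2, c1 - x) - log_denom for x in xs]
    )
    return xs, np.exp(log_p)


def fisher_exact(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p by full enumeration.

    The p-value sums the hypergeometric probabilities of every table with
    the observed margins whose point probability does not exceed that of
    the observed table (point-probability two-sided criterion, with 1e-12
    relative slack against floating ties).
    """
    xs, probs = fisher_table_probabilities(table)
    p_obs = probs[xs == table.a][0]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


# --------------------------------------------------------------------------
# Kaplan–Meier
# --------------------------------------------------------------------------

@dataclass
class KMCurve:
    """Product-limit estimate after each distinct event time."""

    event_times: np.ndarray  # ascending, each with >= 1 event
    survival: np.ndarray  # S(t) just after each event time
    greenwood_var: np.ndarray
    cum_hazard_var: np.ndarray  # Var of log S(t): sum d/(n(n-d))
    n_risk: np.ndarray
    n_event: np.ndarray
    n_total: int
    last_observed: float  # latest follow-up time (event or censoring)
    degenerate: bool = False  # no events: S identically 1


@dataclass(frozen=True)
class SurvivalEstimate:
    survival: float
    ci_low: float
    ci_high: float
    extrapolated: bool


def km_fit(times: Sequence[float], events: Sequence[int]) -> KMCurve:
    """Kaplan–Meier product-limit estimator with Greenwood variance.

    S(t) = prod_{t_i <= t} (1 - d_i / n_i) over distinct event times t_i
    with d_i events and n_i at risk.  Subjects censored at an event time
    remain at risk for the event at that time.  A sample with no events
    yields a degenerate constant-1 curve (flagged).
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.shape != e.shape or t.ndim != 1 or len(t) == 0:
        raise ValueError("times and events must be equal-length 1-d sequences")
    if (t <= 0).any():
        raise ValueError("all times must be > 0")
    if not np.isin(e, (0, 1)).all():
        raise ValueError("events must be 0/1 indicators")
    n_total = len(t)
    last = float(t.max())
    if e.sum() == 0:
        z = np.array([])
        return KMCurve(z, z, z, z, z, z, n_total, last, degenerate=True)
    event_times = np.unique(t[e == 1])
    n_risk = np.array([(t >= tau).sum() for tau in event_times])
    n_event = np.array([((t == tau) & (e == 1)).sum() for tau in event_times])
    frac = 1.0 - n_event / n_risk
    survival = np.cumprod(frac)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = n_event / (n_risk * (n_risk - n_event))
        cumsum = np.cumsum(terms)
        greenwood = survival**2 * cumsum
    return KMCurve(
        event_times, survival, greenwood, cumsum,
        n_risk, n_event, n_total, last,
    )


def survival_at(
    curve: KMCurve, t: float, alpha: float = 0.05, transform: str = "log"
) -> SurvivalEstimate:
    """Step-function evaluation of S(t) with a Greenwood confidence interval.

    Right-continuous: at an event time the post-jump value is returned.
    ``transform="log"`` (default) builds the CI as S * exp(±z * se(log S));
    ``"plain"`` uses S ± z * sqrt(greenwood).  Evaluation beyond the last
    observed follow-up returns the final value flagged ``extrapolated``.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    extrapolated = t > curve.last_observed
    if curve.degenerate:
        return SurvivalEstimate(1.0, 1.0, 1.0, extrapolated)
    k = int(np.searchsorted(curve.event_times, t, side="right")) - 1
    if k < 0:
        return SurvivalEstimate(1.0, 1.0, 1.0, extrapolated)
    s = float(curve.survival[k])
    z = norm.ppf(1 - alpha / 2)
    if transform == "log":
        if s <= 0:
            lo = hi = 0.0
        else:
            se_log = math.sqrt(curve.cum_hazard_var[k])
            lo, hi = s * math.exp(-z * se_log), min(1.0, s * math.exp(z * se_log))
    elif transform == "plain":
        se = math.sqrt(curve.greenwood_var[k]) if np.isfinite(curve.greenwood_var[k]) else 0.0
        lo, hi = max(0.0, s - z * se), min(1.0, s + z * se)
    else:
        raise ValueError(f"unknown CI transform {transform!r}")
    return SurvivalEstimate(s, lo, hi, extrapolated)


def log_rank(
    group_a: tuple[Sequence[float], Sequence[int]],
    group_b: tuple[Sequence[float], Sequence[int]],
) -> tuple[float, float]:
    """Two-group log-rank test: (chi-square statistic, p-value, 1 df).

    At each pooled distinct event time, the observed events in group A are
    compared with the expectation under the hypergeometric null given the
    groups' risk-set sizes; the variance-weighted squared excess is
    chi-square with 1 degree of freedom.
    """
    ta, ea = np.asarray(group_a[0], float), np.asarray(group_a[1], int)
    tb, eb = np.asarray(group_b[0], float), np.asarray(group_b[1], int)
    if len(ta) == 0 or len(tb) == 0:
        raise ValueError("both groups must be non-empty")
    if ea.sum() + eb.sum() == 0:
        raise ValueError("log-rank requires at least one event")
    event_times = np.unique(np.concatenate([ta[ea == 1], tb[eb == 1]]))
    excess = 0.0
    var = 0.0
    for tau in event_times:
        n1 = (ta >= tau).sum()
        n2 = (tb >= tau).sum()
        d1 = ((ta == tau) & (ea == 1)).sum()
        d2 = ((tb == tau) & (eb == 1)).sum()
        n, d = n1 + n2, d1 + d2
        if n < 2:
            continue
        e1 = d * n1 / n
        excess += d1 - e1
        var += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0, 1.0
    chi = excess**2 / var
    return float(chi), float(chi2.sf(chi, df=1))


# --------------------------------------------------------------------------
# Cox proportional hazards
# --------------------------------------------------------------------------

@dataclass
class CoxFit:
    covariates: list[str]
    coefficients: np.ndarray
    hazard_ratios: np.ndarray
    se: np.ndarray
    ci_low: np.ndarray  # hazard-ratio scale
    ci_high: np.ndarray
    wald_z: np.ndarray
    wald_p: np.ndarray
    log_partial_likelihood: float
    n_iterations: int
    converged: bool
    monotone_likelihood: bool  # perfect separation: coefficients diverged
    alpha: float = 0.05

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.coefficients,
                "HR": self.hazard_ratios,
                "se": self.se,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "z": self.wald_z,
                "p": self.wald_p,
            },
            index=self.covariates,
        )


def _cox_loglik(
    beta: np.ndarray,
    X: np.ndarray,
    groups: list[tuple[slice, np.ndarray]],
    ties: str,
    want_derivs: bool,
) -> tuple[float, np.ndarray | None, np.ndarray | None]:
    """Efron/Breslow partial log-likelihood (and derivatives) on pre-sorted data.

    ``groups``: per distinct time (descending), the slice of sorted rows at
    that time and the boolean event flags within the slice.  Risk sets are
    cumulative prefixes of the descending-time sort.
    """
    n, p = X.shape
    xb = X @ beta
    xb = np.clip(xb, -500, 500)
    r = np.exp(xb)
    rx = r[:, None] * X
    rxx = rx[:, :, None] * X[:, None, :]
    cr = np.cumsum(r)
    crx = np.cumsum(rx, axis=0)
    crxx = np.cumsum(rxx, axis=0)
    ll = 0.0
    g = np.zeros(p) if want_derivs else None
    H = np.zeros((p, p)) if want_derivs else None
    for sl, ev in groups:
        d = int(ev.sum())
        if d == 0:
            continue
        end = sl.stop - 1
        S_R, U_R, M_R = cr[end], crx[end], crxx[end]
        rows = np.arange(sl.start, sl.stop)[ev]
        S_D = r[rows].sum()
        U_D = rx[rows].sum(axis=0)
        M_D = rxx[rows].sum(axis=0)
        ll += xb[rows].sum()
        for j in range(d):
            w = (j / d) if ties == "efron" else 0.0
            phi = S_R - w * S_D
            ll -= math.log(phi)
            if want_derivs:
                u = U_R - w * U_D
                m = M_R - w * M_D
                g -= u / phi
                H -= m / phi - np.outer(u, u) / phi**2
        if want_derivs:
            g += X[rows].sum(axis=0)
    return ll, g, H


def cox_fit(
    records: pd.DataFrame,
    covariates: Sequence[str],
    duration_col: str = "ttp_years",
    event_col: str = "event",
    ties: str = "efron",
    alpha: float = 0.05,
    tol: float = 1e-9,
    max_iter: int = 100,
) -> CoxFit:
    """Fit a Cox proportional-hazards model by Newton–Raphson.

    Maximizes the partial likelihood with the Efron (default) or Breslow
    correction for tied event times; Newton steps use step-halving when a
    full step would decrease the likelihood.  Convergence: change in log
    partial likelihood below ``tol`` (or a vanishing score).  Wald CIs and
    p-values per covariate; non-convergence and monotone-likelihood
    (perfect separation, detected by a diverging coefficient norm) are
    flagged rather than raised.
    """
    if ties not in ("efron", "breslow"):
        raise ValueError(f"unknown ties method {ties!r}")
    covariates = list(covariates)
    t = records[duration_col].to_numpy(dtype=float)
    e = records[event_col].to_numpy(dtype=int)
    X = records[list(covariates)].to_numpy(dtype=float)
    if e.sum() < 2:
        raise ValueError("Cox fitting requires at least 2 events")
    order = np.argsort(-t, kind="stable")
    ts, es, Xs = t[order], e[order], X[order]
    # group rows by distinct time (descending)
    groups: list[tuple[slice, np.ndarray]] = []
    i = 0
    n = len(ts)
    while i < n:
        j = i
        while j < n and ts[j] == ts[i]:
            j += 1
        groups.append((slice(i, j), es[i:j].astype(bool)))
        i = j

    p = X.shape[1]
    beta = np.zeros(p)
    ll, g, H = _cox_loglik(beta, Xs, groups, ties, True)
    converged = False
    monotone = False
    it = 0
    for it in range(1, max_iter + 1):
        if np.abs(g).max() < 1e-12:
            converged = True
            break
        try:
            delta = np.linalg.solve(-H, g)
        except np.linalg.LinAlgError:
            delta = np.linalg.pinv(-H) @ g
        step = 1.0
        for _ in range(30):
            ll_new, g_new, H_new = _cox_loglik(beta + step * delta, Xs, groups, ties, True)
            if ll_new >= ll - 1e-14:
                break
            step /= 2
        change = abs(ll_new - ll)
        beta = beta + step * delta
        ll, g, H = ll_new, g_new, H_new
        if np.abs(beta).max() > 20:  # HR beyond e^20: perfect separation
            monotone = True
            break
        if change < tol and np.abs(g).max() < 1e-6:
            converged = True
            break
    info_diag = np.diag(-H)
    cov = np.linalg.pinv(-H)
    with np.errstate(invalid="ignore"):
        se = np.where(info_diag < 1e-12, np.inf, np.sqrt(np.abs(np.diag(cov))))
    z_crit = norm.ppf(1 - alpha / 2)
    with np.errstate(invalid="ignore", over="ignore"):
        wald_z = np.where(np.isinf(se), 0.0, beta / se)
        ci_low = np.exp(beta - z_crit * se)
        ci_high = np.exp(beta + z_crit * se)
    wald_p = 2 * norm.sf(np.abs(wald_z))
    return CoxFit(
        covariates=covariates,
        coefficients=beta,
        hazard_ratios=np.exp(beta),
        se=se,
        ci_low=ci_low,
        ci_high=ci_high,
        wald_z=wald_z,
        wald_p=wald_p,
        log_partial_likelihood=float(ll),
        n_iterations=it,
        converged=converged and not monotone,
        monotone_likelihood=monotone,
        alpha=alpha,
    )


# --------------------------------------------------------------------------
# cohort encoding
# --------------------------------------------------------------------------

#: Default multivariate model: risk group adjusted for age, lesion site and
#: binary dysplasia grade.
DEFAULT_MULTIVARIATE = ["risk_high", "age", "site_tongue", "dysplasia_high"]

UNIVARIATE_CANDIDATES = [
    "risk_high", "age", "gender_male", "prior_oscc_yes", "aveh_present",
    "site_tongue", "dysplasia_high",
]


def encode_covariates(records: pd.DataFrame) -> pd.DataFrame:
    """Numeric design columns from a cohort table.

    Adds 0/1 indicators (``risk_high`` from a ``group`` column if present,
    ``site_tongue``, ``dysplasia_high`` = moderate/severe, ``gender_male``,
    ``prior_oscc_yes``, ``aveh_present``) alongside the numeric ``age``.
    """
    out = records.copy()
    if "group" in out.columns:
        out["risk_high"] = (out["group"] == "high").astype(int)
    if "site" in out.columns:
        out["site_tongue"] = (out["site"] == "tongue").astype(int)
    if "dysplasia" in out.columns:
        out["dysplasia_high"] = (out["dysplasia"] == "moderate/severe").astype(int)
    if "gender" in out.columns:
        out["gender_male"] = (out["gender"] == "M").astype(int)
    if "prior_oscc" in out.columns:
        out["prior_oscc_yes"] = (out["prior_oscc"] == "yes").astype(int)
    if "aveh" in out.columns:
        out["aveh_present"] = (out["aveh"] == "present").astype(int)
    return out


def progression_table(records: pd.DataFrame) -> ContingencyTable2x2:
    """2x2 progression-by-risk-group table from a stratified cohort."""
    if "group" not in records.columns:
        raise ValueError("records must carry a 'group' column (run stratify first)")
    high = records[records["group"] == "high"]
    low = records[records["group"] == "low"]
    return ContingencyTable2x2.from_groups(
        int(high["event"].sum()), len(high), int(low["event"].sum()), len(low)
    )
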