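"""Survival and group-comparison statistics.

The battery used for carrier/non-carrier outcome analysis:

* Kaplan-Meier product-limit estimator with Greenwood variance;
* k-sample log-rank test (observed minus expected over hypergeometric
  variance at each distinct event time);
* Cox proportional-hazards regression by Newton-Raphson maximisation of
  the partial likelihood, with Efron's tie correction by default and
  Breslow's behind a flag; Wald 95% confidence intervals;
* forward-stepwise Cox selection (entry at Wald p < 0.05, no removal)
  for auxiliary prognostic covariates such as NT-proBNP in 1000 pg/mL
  steps and Seattle Heart Failure Model score tertiles;
* ANOVA / chi-square / Fisher exact group comparisons and Pearson
  correlation (delegated to scipy).

Ties between events and censorings at the same time follow the standard
convention: events precede censorings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


# ----------------------------------------------------------- Kaplan-Meier

@dataclass
class KMCurve:
    """Product-limit survival estimate evaluated at the distinct event
    times, with Greenwood variance."""

    times: np.ndarray          # distinct event times, ascending
    n_at_risk: np.ndarray
    n_events: np.ndarray
    survival: np.ndarray
    greenwood_var: np.ndarray
    n: int

    def survival_at(self, t: float) -> float:
        """S(t): right-continuous step function, S=1 before the first event."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "n_at_risk": self.n_at_risk,
                "n_events": self.n_events,
                "survival": self.survival,
                "greenwood_var": self.greenwood_var,
            }
        )


def km_estimate(times, events) -> KMCurve:
    """Kaplan-Meier estimate from follow-up times and event flags."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.size == 0:
        raise ValueError("empty input")
    if times.shape != events.shape:
        raise ValueError("times and event flags differ in length")
    if (times < 0).any():
        raise ValueError("negative follow-up time")

    event_times = np.unique(times[events])
    n_at_risk = np.empty(event_times.size, dtype=np.int64)
    n_events = np.empty(event_times.size, dtype=np.int64)
    surv = np.empty(event_times.size, dtype=float)
    gvar = np.empty(event_times.size, dtype=float)
    s = 1.0
    gw = 0.0  # running sum d / (n (n - d))
    for i, t in enumerate(event_times):
        n = int((times >= t).sum())  # events precede censorings at ties
        d = int((events & (times == t)).sum())
        n_at_risk[i] = n
        n_events[i] = d
        s *= 1.0 - d / n
        if n > d:
            gw += d / (n * (n - d))
            gvar[i] = s * s * gw
        else:
            gvar[i] = 0.0  # S hits 0; Greenwood undefined, variance 0
        surv[i] = s
    return KMCurve(event_times, n_at_risk, n_events, surv, gvar, n=times.size)


# --------------------------------------------------------------- log-rank

@dataclass
class LogrankResult:
    statistic: float
    df: int
    p_value: float
    observed: np.ndarray
    expected: np.ndarray


def logrank_test(groups, times, events) -> LogrankResult:
    """k-sample log-rank test.

    At each distinct event time the per-group observed event counts are
    compared with their hypergeometric expectation given the group sizes at
    risk; the quadratic form over the first k-1 groups gives a chi-square
    statistic on k-1 degrees of freedom.
    """
    groups = np.asarray(groups)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    labels = np.unique(groups)
    k = labels.size
    if k < 2:
        raise ValueError("log-rank test requires at least 2 groups")
    if not events.any():
        raise ValueError("log-rank test requires at least 1 event")

    gidx = np.searchsorted(labels, groups)
    event_times = np.unique(times[events])
    observed = np.zeros(k)
    expected = np.zeros(k)
    V = np.zeros((k - 1, k - 1))
    for t in event_times:
        at_risk = times >= t
        n = at_risk.sum()
        d = (events & (times == t)).sum()
        n_g = np.bincount(gidx[at_risk], minlength=k).astype(float)
        d_g = np.bincount(gidx[events & (times == t)], minlength=k).astype(float)
        observed += d_g
        expected += d * n_g / n
        if n > 1:
            p = n_g[: k - 1] / n
            cov = (np.diag(p) - np.outer(p, p)) * d * (n - d) / (n - 1)
            V += cov
    z = (observed - expected)[: k - 1]
    try:
        stat = float(z @ np.linalg.solve(V, z))
    except np.linalg.LinAlgError:
        stat = float(z @ np.linalg.pinv(V) @ z)
    df = k - 1
    return LogrankResult(stat, df, float(stats.chi2.sf(stat, df)), observed, expected)


# ------------------------------------------------------------------- Cox

@dataclass
class CoxResult:
    """Fitted proportional-hazards model."""

    names: list[str]
    coef: np.ndarray
    se: np.ndarray
    hr: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    p: np.ndarray
    loglik: float
    ties: str
    n: int
    n_events: int
    iterations: int

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.coef,
                "hr": self.hr,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "p": self.p,
            },
            index=self.names,
        )


class SeparationError(RuntimeError):
    """Monotone partial likelihood (complete separation)."""


def _cox_loglik_grad_info(beta, X, times, events, ties):
    """Partial log-likelihood, gradient and observed information."""
    n, p = X.shape
    order = np.argsort(-times, kind="stable")  # decreasing time
    Xs = X[order]
    ts = times[order]
    es = events[order]
    eta = Xs @ beta
    w = np.exp(eta)

    ll = 0.0
    grad = np.zeros(p)
    info = np.zeros((p, p))
    S0 = 0.0
    S1 = np.zeros(p)
    S2 = np.zeros((p, p))
    i = 0
    while i < n:
        t = ts[i]
        j = i
        while j < n and ts[j] == t:
            j += 1
        block = slice(i, j)
        wX = w[block, None] * Xs[block]
        S0 += w[block].sum()
        S1 += wX.sum(axis=0)
        S2 += Xs[block].T @ wX
        dmask = es[block]
        d = int(dmask.sum())
        if d > 0:
            Xd = Xs[block][dmask]
            wd = w[block][dmask]
            ll += eta[block][dmask].sum()
            grad += Xd.sum(axis=0)
            s0d = wd.sum()
            s1d = (wd[:, None] * Xd).sum(axis=0)
            s2d = Xd.T @ (wd[:, None] * Xd)
            for l in range(d):
                frac = l / d if ties == "efron" else 0.0
                phi0 = S0 - frac * s0d
                phi1 = S1 - frac * s1d
                phi2 = S2 - frac * s2d
                ll -= np.log(phi0)
                u = phi1 / phi0
                grad -= u
                info += phi2 / phi0 - np.outer(u, u)
        i = j
    return ll, grad, info


def cox_ph(
    X,
    times,
    events,
    names: list[str] | None = None,
    ties: str = "efron",
    max_iter: int = 100,
    tol: float = 1e-9,
) -> CoxResult:
    """Fit a Cox proportional-hazards model.

    Parameters
    ----------
    X : (n, p) covariate matrix (no intercept).
    ties : "efron" (default) or "breslow".
    tol : convergence on the gradient max-norm.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    n, p = X.shape
    if names is None:
        names = [f"x{i}" for i in range(p)]
    if ties not in ("efron", "breslow"):
        raise ValueError("ties must be 'efron' or 'breslow'")
    n_events = int(events.sum())
    if n_events < p:
        raise ValueError(f"{n_events} events for {p} covariates")
    sds = X.std(axis=0)
    for j, sd in enumerate(sds):
        if sd == 0:
            raise ValueError(f"covariate {names[j]!r} is constant")

    beta = np.zeros(p)
    ll, grad, info = _cox_loglik_grad_info(beta, X, times, events, ties)
    # the gradient is a sum over events, so its attainable precision scales
    # with |loglik|; a vanishing Newton step is the secondary stop rule
    converged = np.max(np.abs(grad)) < tol
    it = 0
    while not converged and it < max_iter:
        it += 1
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as exc:
            raise SeparationError(
                f"singular information matrix (covariate {names[int(np.argmax(np.abs(beta)))]!r})"
            ) from exc
        # step-halving keeps the likelihood non-decreasing up to round-off
        alpha = 1.0
        for _ in range(30):
            cand = beta + alpha * step
            ll_new, grad_new, info_new = _cox_loglik_grad_info(cand, X, times, events, ties)
            if ll_new >= ll - 1e-12 * max(1.0, abs(ll)):
                break
            alpha /= 2
        delta = np.max(np.abs(cand - beta))
        beta, ll, grad, info = cand, ll_new, grad_new, info_new
        # |beta| = 20 is HR ~ 5e8: only a monotone likelihood gets there
        if np.max(np.abs(beta)) > 20:
            worst = names[int(np.argmax(np.abs(beta)))]
            raise SeparationError(
                f"monotone likelihood: coefficient for {worst!r} diverges "
                "(complete separation)"
            )
        converged = (
            np.max(np.abs(grad)) < tol
            or delta < 1e-12 * (1.0 + np.max(np.abs(beta)))
        )
    if not converged:
        raise SeparationError("Newton-Raphson failed to converge")

    cov = np.linalg.inv(info)
    se = np.sqrt(np.diag(cov))
    zcrit = stats.norm.ppf(0.975)
    z = beta / se
    return CoxResult(
        names=list(names),
        coef=beta,
        se=se,
        hr=np.exp(beta),
        ci_low=np.exp(beta - zcrit * se),
        ci_high=np.exp(beta + zcrit * se),
        p=2 * stats.norm.sf(np.abs(z)),
        loglik=ll,
        ties=ties,
        n=n,
        n_events=n_events,
        iterations=it,
    )


# --------------------------------------------------------------- stepwise

def nt_probnp_per_1000(values) -> np.ndarray:
    """Rescale NT-proBNP (pg/mL) to 1000 pg/mL steps for Cox entry."""
    return np.asarray(values, dtype=float) / 1000.0


def tertile_indicators(values, prefix: str = "tertile") -> pd.DataFrame:
    """Encode a continuous score as tertile membership indicators with the
    lowest tertile as reference."""
    values = np.asarray(values, dtype=float)
    tert = pd.qcut(pd.Series(values).rank(method="first"), 3, labels=False)
    return pd.DataFrame(
        {
            f"{prefix}_2": (tert == 1).astype(float),
            f"{prefix}_3": (tert == 2).astype(float),
        }
    )


@dataclass
class StepwiseResult:
    model: CoxResult
    entered: list[str]
    log: list[dict] = field(default_factory=list)


def stepwise_cox(
    base: pd.DataFrame,
    candidates: pd.DataFrame,
    times,
    events,
    alpha_enter: float = 0.05,
    ties: str = "efron",
) -> StepwiseResult:
    """Forward-stepwise Cox selection.

    Base covariates are always retained.  Candidate groups are columns of
    ``candidates``; at each step the candidate with the smallest Wald p in
    the augmented model enters if p < ``alpha_enter``.  Entered covariates
    are never removed; the entry log records the likelihood-ratio against
    the previous step's model.
    """
    base = pd.DataFrame(base)
    candidates = pd.DataFrame(candidates)
    entered: list[str] = []
    log: list[dict] = []
    remaining = list(candidates.columns)

    def fit(cols: list[str]) -> CoxResult:
        Xdf = pd.concat([base, candidates[cols]], axis=1)
        return cox_ph(Xdf.to_numpy(), times, events, names=list(Xdf.columns), ties=ties)

    current = fit(entered) if (len(base.columns) or entered) else None
    while remaining:
        best_name, best_p, best_fit = None, np.inf, None
        for name in remaining:
            try:
                trial = fit(entered + [name])
            except (ValueError, SeparationError):
                continue
            p_val = trial.p[trial.names.index(name)]
            if p_val < best_p:
                best_name, best_p, best_fit = name, p_val, trial
        if best_name is None or best_p >= alpha_enter:
            break
        lr = (
            2 * (best_fit.loglik - current.loglik)
            if current is not None
            else np.nan
        )
        log.append(
            {"step": len(entered) + 1, "entered": best_name, "wald_p": float(best_p),
             "lr_statistic": float(lr)}
        )
        entered.append(best_name)
        remaining.remove(best_name)
        current = best_fit
    if current is None:
        raise ValueError("no covariates entered and no base covariates supplied")
    return StepwiseResult(model=current, entered=entered, log=log)


# ---------------------------------------------------- group comparisons

@dataclass
class GroupCompareResult:
    test: str  # "anova" | "chi2" | "fisher"
    statistic: float
    p_value: float


def group_compare(values, groups, kind: str) -> GroupCompareResult:
    """Compare a variable between groups.

    Continuous variables use one-way ANOVA.  Categorical variables use the
    Pearson chi-square test (no continuity correction); 2x2 tables fall
    back to Fisher's exact test under Cochran's conditions (any expected
    cell count below 5, or total n below 40).
    """
    values = np.asarray(values)
    groups = np.asarray(groups)
    if kind == "continuous":
        samples = [values[groups == g].astype(float) for g in np.unique(groups)]
        stat, p = stats.f_oneway(*samples)
        return GroupCompareResult("anova", float(stat), float(p))
    if kind != "categorical":
        raise ValueError("kind must be 'continuous' or 'categorical'")
    table = pd.crosstab(values, groups).to_numpy()
    stat, p, _, expected = stats.chi2_contingency(table, correction=False)
    if table.shape == (2, 2) and ((expected < 5).any() or table.sum() < 40):
        odds, p = stats.fisher_exact(table)
        return GroupCompareResult("fisher", float(odds), float(p))
    return GroupCompareResult("chi2", float(stat), float(p))


def pearson_r(x, y) -> tuple[float, float]:
    """Product-moment correlation and its two-sided p (t transform)."""
    r, p = stats.pearsonr(np.asarray(x, dtype=float), np.asarray(y, dtype=float))
    return float(r), float(p)
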