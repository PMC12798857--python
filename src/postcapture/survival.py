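"""Post-capture survival: Kaplan-Meier and Cox proportional hazards.

Time-to-event records cover the 31-day window (capture day 0 through day
30); animals alive at the horizon are administratively censored at day 31,
and direct capture mortalities enter with time 0. The Cox model uses the
Efron approximation for tied event times, block Wald chi-square tests under
sum-to-zero factor coding (type III), Harrell's concordance index, and a
scaled-Schoenfeld-residual score test of proportional hazards on the
Kaplan-Meier-transformed time axis.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .lmm import _encode_factor
from .telemetry import Deployment, SURVIVAL_WINDOW_DAYS

log = logging.getLogger(__name__)

HORIZON = 31.0          # administrative censoring time, days
DAY0_EVENT_TIME = 0.5   # Cox risk-set shift for day-0 deaths


def build_survival_records(deployments: list[Deployment]) -> pd.DataFrame:
    """Time-to-event rows from cleaned deployments.

    A detected end-of-data inside days 0-30 counts as a mortality (death
    and collar drop are indistinguishable to the detector); all other
    deployments are censored at the 31-day horizon.
    """
    rows = []
    for dep in deployments:
        if not dep.eligible_survival:
            continue
        if dep.fixes.empty:
            log.info("%s: no collar data, skipped from detected records",
                     dep.deployment_id)
            continue
        tcol = ("timestamp_local" if "timestamp_local" in dep.fixes.columns
                else "timestamp_utc")
        last_day = dep.day_of(dep.fixes[tcol].iloc[-1])
        event = 0
        # collars that stop early without a stationary cluster censor at
        # their last data day; complete collars censor at the horizon
        time = HORIZON if last_day >= SURVIVAL_WINDOW_DAYS - 1 else float(max(last_day, 0))
        if dep.end_date is not None:
            day = dep.day_of(dep.end_date)
            if 0 <= day <= SURVIVAL_WINDOW_DAYS - 1:
                event, time = 1, float(day)
        rows.append({"deployment_id": dep.deployment_id, "time": time,
                     "event": event, "method": dep.method, "sex": dep.sex,
                     "season": dep.thermal_season})
    return pd.DataFrame(rows)


@dataclass
class KMFit:
    """Product-limit estimate with Greenwood SE and log-scale 95% CI."""

    table: pd.DataFrame    # time, n_risk, n_events, survival, se, lo, hi
    group: object = None

    def survival_at(self, t: float) -> float:
        tab = self.table[self.table["time"] <= t]
        return float(tab["survival"].iloc[-1]) if len(tab) else 1.0

    def se_at(self, t: float) -> float:
        tab = self.table[self.table["time"] <= t]
        return float(tab["se"].iloc[-1]) if len(tab) else 0.0


def km_fit(records: pd.DataFrame, group: str | None = None
           ) -> KMFit | dict[object, KMFit]:
    """Kaplan-Meier estimator (deaths precede censorings at tied times)."""
    if records.empty:
        raise ValueError("km_fit: no records")
    if group is not None:
        return {lv: km_fit(sub) for lv, sub in records.groupby(group)}
    t = records["time"].to_numpy(dtype=float)
    d = records["event"].to_numpy(dtype=int)
    order = np.lexsort((1 - d, t))  # events first within a tied time
    t, d = t[order], d[order]
    rows = []
    surv = 1.0
    gw = 0.0  # Greenwood sum d/(n(n-d))
    n = len(t)
    i = 0
    while i < n:
        ti = t[i]
        at_risk = n - i
        deaths = int(d[(t == ti)].sum())
        i += int((t == ti).sum())
        if deaths == 0:
            continue
        surv *= 1.0 - deaths / at_risk
        if at_risk > deaths:
            gw += deaths / (at_risk * (at_risk - deaths))
        se = surv * np.sqrt(gw)
        z = stats.norm.ppf(0.975)
        lo = surv * np.exp(-z * np.sqrt(gw)) if surv > 0 else 0.0
        hi = min(surv * np.exp(z * np.sqrt(gw)), 1.0) if surv > 0 else 0.0
        rows.append({"time": ti, "n_risk": at_risk, "n_events": deaths,
                     "survival": surv, "se": se, "ci_lo": lo, "ci_hi": hi})
    return KMFit(table=pd.DataFrame(
        rows, columns=["time", "n_risk", "n_events", "survival", "se",
                       "ci_lo", "ci_hi"]))


def _cox_design(records: pd.DataFrame, covariates: list[str]
                ) -> tuple[np.ndarray, list[str], dict[str, np.ndarray]]:
    """Sum-to-zero coded covariate matrix; constant columns dropped."""
    blocks, names, term_cols = [], [], {}
    col = 0
    for cov in covariates:
        levels = sorted(records[cov].unique())
        if len(levels) < 2:
            warnings.warn(f"covariate {cov!r} is constant; dropped")
            continue
        X = _encode_factor(records[cov].to_numpy(), levels)
        blocks.append(X)
        names.extend(f"{cov}[{lv}]" for lv in levels[:-1])
        term_cols[cov] = np.arange(col, col + X.shape[1])
        col += X.shape[1]
    if not blocks:
        raise ValueError("no usable covariates")
    return np.hstack(blocks), names, term_cols


@dataclass
class CoxFit:
    beta: np.ndarray
    cov: np.ndarray
    names: list[str]
    term_cols: dict[str, np.ndarray]
    loglik: float
    times: np.ndarray = field(repr=False)
    events: np.ndarray = field(repr=False)
    X: np.ndarray = field(repr=False)
    monotone_warning: bool = False

    @property
    def hazard_ratios(self) -> np.ndarray:
        return np.exp(self.beta)

    def risk_score(self, X: np.ndarray | None = None) -> np.ndarray:
        return (self.X if X is None else X) @ self.beta


def _efron_ll_grad_hess(beta, t, d, X):
    """Efron partial log-likelihood with gradient and Hessian."""
    p = X.shape[1]
    eta = X @ beta
    w = np.exp(eta)
    ll, grad = 0.0, np.zeros(p)
    hess = np.zeros((p, p))
    order = np.argsort(-t, kind="mergesort")  # decreasing time
    ts, ds, Xs, ws = t[order], d[order], X[order], w[order]
    S0 = 0.0
    S1 = np.zeros(p)
    S2 = np.zeros((p, p))
    i = 0
    n = len(ts)
    while i < n:
        ti = ts[i]
        j = i
        while j < n and ts[j] == ti:
            S0 += ws[j]
            S1 += ws[j] * Xs[j]
            S2 += ws[j] * np.outer(Xs[j], Xs[j])
            j += 1
        dead = np.arange(i, j)[ds[i:j] == 1]
        D = len(dead)
        if D:
            T0 = ws[dead].sum()
            T1 = (ws[dead, None] * Xs[dead]).sum(axis=0)
            T2 = np.einsum("k,ki,kj->ij", ws[dead], Xs[dead], Xs[dead])
            ll += eta[order][dead].sum()
            grad += Xs[dead].sum(axis=0)
            for l in range(D):
                f = l / D
                Z0 = S0 - f * T0
                Z1 = S1 - f * T1
                Z2 = S2 - f * T2
                ll -= np.log(Z0)
                grad -= Z1 / Z0
                hess -= Z2 / Z0 - np.outer(Z1, Z1) / Z0 ** 2
        i = j
    return ll, grad, hess


def cox_fit(records: pd.DataFrame, covariates: list[str],
            max_iter: int = 50, tol: float = 1e-9) -> CoxFit:
    """Cox model by Newton-Raphson on the Efron partial likelihood.

    Day-0 deaths are shifted to time 0.5 so they contribute risk sets.
    Flags (without penalizing) a monotone-likelihood pattern where a
    coefficient diverges.
    """
    rec = records.copy()
    rec.loc[(rec["time"] <= 0) & (rec["event"] == 1), "time"] = DAY0_EVENT_TIME
    X, names, term_cols = _cox_design(rec, covariates)
    t = rec["time"].to_numpy(dtype=float)
    d = rec["event"].to_numpy(dtype=int)
    beta = np.zeros(X.shape[1])
    ll_old = -np.inf
    monotone = False
    for it in range(max_iter):
        ll, grad, hess = _efron_ll_grad_hess(beta, t, d, X)
        info = -hess
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            raise np.linalg.LinAlgError("singular information matrix in cox_fit")
        # step halving keeps the likelihood non-decreasing
        factor = 1.0
        while factor > 1e-4:
            cand = beta + factor * step
            ll_new, _, _ = _efron_ll_grad_hess(cand, t, d, X)
            if ll_new >= ll - 1e-12:
                break
            factor /= 2.0
        beta = beta + factor * step
        if np.max(np.abs(beta)) > 15.0:
            monotone = True
            warnings.warn("possible monotone likelihood (separation) in cox_fit")
            break
        if ll_old > -np.inf and abs(ll_new - ll_old) <= tol * (abs(ll_old) + 1e-12):
            ll_old = ll_new
            break
        ll_old = ll_new
    else:
        raise RuntimeError(f"cox_fit did not converge in {max_iter} iterations")
    ll, grad, hess = _efron_ll_grad_hess(beta, t, d, X)
    cov = np.linalg.inv(-hess)
    return CoxFit(beta=beta, cov=cov, names=names, term_cols=term_cols,
                  loglik=ll, times=t, events=d, X=X,
                  monotone_warning=monotone)


def wald_type3_cox(fit: CoxFit, term: str) -> tuple[float, int, float]:
    """Block Wald chi-square on one factor's coefficient rows."""
    if term not in fit.term_cols:
        raise KeyError(f"term {term!r} not in model")
    idx = fit.term_cols[term]
    b = fit.beta[idx]
    V = fit.cov[np.ix_(idx, idx)]
    chi2 = float(b @ np.linalg.solve(V, b))
    return chi2, len(idx), float(stats.chi2.sf(chi2, len(idx)))


def concordance(fit: CoxFit | None, records: pd.DataFrame,
                risk: np.ndarray | None = None) -> tuple[float, float]:
    """Harrell's C over usable pairs, with a jackknife (U-statistic) SE.

    A pair is usable when one subject's event time precedes the other's
    follow-up; ties in risk score count one half.
    """
    t = records["time"].to_numpy(dtype=float)
    d = records["event"].to_numpy(dtype=int)
    if risk is None:
        rec = records.copy()
        rec.loc[(rec["time"] <= 0) & (rec["event"] == 1), "time"] = DAY0_EVENT_TIME
        X, _, _ = _cox_design(rec, list(fit.term_cols))
        risk = X @ fit.beta
    n = len(t)
    pair_w = np.zeros(n)   # score sum of pairs touching each subject
    pair_n = np.zeros(n)   # usable-pair count per subject
    total_w = 0.0
    total_n = 0.0
    for i in range(n):
        if d[i] != 1:
            continue
        comparable = (t > t[i]) | ((t == t[i]) & (d == 0))
        for j in np.nonzero(comparable)[0]:
            s = 1.0 if risk[i] > risk[j] else (0.5 if risk[i] == risk[j] else 0.0)
            total_w += s
            total_n += 1
            pair_w[i] += s
            pair_w[j] += s
            pair_n[i] += 1
            pair_n[j] += 1
    if total_n == 0:
        raise ValueError("concordance: no usable pairs")
    c = total_w / total_n
    loo = np.array([(total_w - pair_w[k]) / (total_n - pair_n[k])
                    for k in range(n) if pair_n[k] < total_n])
    se = float(np.sqrt((len(loo) - 1) / len(loo) * np.sum((loo - loo.mean()) ** 2)))
    return float(c), se


def _schoenfeld_residuals(fit: CoxFit) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Schoenfeld residuals x_i - xbar(t_i) at each event (Efron ties).

    For a set of D tied deaths the risk-set mean is averaged over the D
    Efron denominators, matching the residuals of the fitting routine.
    With no ties this reduces to the plain risk-set weighted mean.
    """
    t, d, X = fit.times, fit.events, fit.X
    w = np.exp(X @ fit.beta)
    ev = np.nonzero(d == 1)[0]
    ev = ev[np.argsort(t[ev], kind="mergesort")]
    resid = np.empty((len(ev), X.shape[1]))
    times = np.empty(len(ev))
    k = 0
    while k < len(ev):
        ti = t[ev[k]]
        tied = [i for i in ev if t[i] == ti]
        D = len(tied)
        at_risk = t >= ti
        S0 = w[at_risk].sum()
        S1 = (w[at_risk, None] * X[at_risk]).sum(axis=0)
        T0 = w[tied].sum()
        T1 = (w[tied, None] * X[tied]).sum(axis=0)
        xbar = np.mean([(S1 - (l / D) * T1) / (S0 - (l / D) * T0)
                        for l in range(D)], axis=0)
        for i in tied:
            resid[k] = X[i] - xbar
            times[k] = ti
            k += 1
    return resid, times, ev


def schoenfeld_test(fit: CoxFit, km_times: pd.DataFrame | None = None
                    ) -> pd.DataFrame:
    """Score test for proportional hazards on scaled Schoenfeld residuals.

    The time axis is transformed by the Kaplan-Meier survival estimate
    (left-continuous at event times). Returns per-covariate chi-square
    (df 1) rows plus a GLOBAL row (df = number of coefficients).
    """
    resid, ev_times, _ = _schoenfeld_residuals(fit)
    dcount = len(resid)
    if dcount < 3:
        raise ValueError("schoenfeld_test: fewer than 3 events")
    km = km_fit(pd.DataFrame({"time": fit.times, "event": fit.events}))
    # KM estimate at each event time (right-continuous, the survival
    # toolchain convention for the km time transform)
    g = np.array([km.survival_at(ti) for ti in ev_times])
    gt = g - g.mean()
    ssg = float(gt @ gt)
    u = resid.T @ gt                        # p-vector score
    V = fit.cov                             # = I(beta)^-1
    chi2_global = float(dcount * u @ V @ u / ssg)
    p = resid.shape[1]
    rows = []
    cu = V @ u
    for term, idx in fit.term_cols.items():
        for j in idx:
            chi2_j = float(dcount * cu[j] ** 2 / (V[j, j] * ssg))
            rows.append({"covariate": fit.names[j], "chi2": chi2_j,
                         "df": 1, "p": float(stats.chi2.sf(chi2_j, 1))})
    rows.append({"covariate": "GLOBAL", "chi2": chi2_global, "df": p,
                 "p": float(stats.chi2.sf(chi2_global, p))})
    return pd.DataFrame(rows)


@dataclass
class SurvivalFit:
    """Bundle of the survival stage's outputs."""

    km_overall: KMFit
    km_by: dict[str, dict[object, KMFit]]
    cox: CoxFit | None
    wald: pd.DataFrame | None
    c_index: float | None
    c_index_se: float | None
    schoenfeld: pd.DataFrame | None


def analyze_survival(records: pd.DataFrame,
                     covariates: tuple[str, ...] = ("method", "sex", "season"),
                     fit_cox: bool = True) -> SurvivalFit:
    """KM models (overall and per grouping factor) and the Cox model."""
    km_overall = km_fit(records)
    km_by = {cov: km_fit(records, group=cov) for cov in covariates}
    cox = wald = None
    c = c_se = None
    sch = None
    if fit_cox and records["event"].sum() >= 3:
        cox = cox_fit(records, list(covariates))
        wald = pd.DataFrame([
            {"term": cov, **dict(zip(("chi2", "df", "p"),
                                     wald_type3_cox(cox, cov)))}
            for cov in cox.term_cols])
        c, c_se = concordance(cox, records)
        try:
            sch = schoenfeld_test(cox)
        except ValueError:
            log.info("schoenfeld test unavailable (too few events)")
    return SurvivalFit(km_overall=km_overall, km_by=km_by, cox=cox,
                       wald=wald, c_index=c, c_index_se=c_se,
                       schoenfeld=sch)
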