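"""Survival machinery implemented from first principles: Kaplan-Meier
product-limit curves, the k-group log-rank test, Cox proportional hazards
by Newton-Raphson on the partial likelihood (Breslow or Efron ties), and
the maximally selected log-rank cutpoint used to dichotomize a continuous
score.

The maximal-statistic p-value is deliberately NOT corrected for the
cutpoint search; the cutpoint only dichotomizes, and the reported
group-difference p comes from the ordinary log-rank on the chosen split,
which is optimistic (documented caveat).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

_Z975 = stats.norm.ppf(0.975)


@dataclass
class KMCurve:
    times: np.ndarray  # increasing distinct event times
    survival: np.ndarray  # S(t) just after each event time
    at_risk: np.ndarray
    n_events: np.ndarray


@dataclass
class CoxTerm:
    name: str
    beta: float
    se: float
    hr: float
    ci_low: float
    ci_high: float
    p: float


@dataclass
class CoxFit:
    terms: list[CoxTerm]
    loglik: float
    converged: bool
    n: int
    n_events: int
    separation: bool = False

    def __getitem__(self, name: str) -> CoxTerm:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)


@dataclass
class CutpointResult:
    cutpoint: float
    statistic: float  # standardized log-rank at the chosen cutpoint
    group_sizes: tuple[int, int]  # (n_low, n_high)
    scanned: list[tuple[float, float]]


def _check_surv(times, events) -> tuple[np.ndarray, np.ndarray]:
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=float)
    if times.size == 0:
        raise ValueError("empty survival input")
    if times.shape != events.shape:
        raise ValueError("times and events must have equal length")
    if (times < 0).any():
        raise ValueError("negative survival times")
    if not np.isin(events, (0.0, 1.0)).all():
        raise ValueError("events must be 0 or 1")
    return times, events.astype(int)


def km_estimate(times: Sequence[float], events: Sequence[int]) -> KMCurve:
    """Product-limit estimator; simultaneous events at identical times are
    handled as ties."""
    times, events = _check_surv(times, events)
    order = np.argsort(times, kind="stable")
    t_sorted, e_sorted = times[order], events[order]
    event_times = np.unique(t_sorted[e_sorted == 1])
    surv, at_risk, n_ev = [], [], []
    s = 1.0
    for t in event_times:
        n_t = int((t_sorted >= t).sum())
        d_t = int(((t_sorted == t) & (e_sorted == 1)).sum())
        s *= 1.0 - d_t / n_t
        surv.append(s)
        at_risk.append(n_t)
        n_ev.append(d_t)
    return KMCurve(
        times=event_times,
        survival=np.asarray(surv),
        at_risk=np.asarray(at_risk, dtype=int),
        n_events=np.asarray(n_ev, dtype=int),
    )


def median_survival(curve: KMCurve) -> float:
    """First time at which survival drops to <= 0.5; nan if never reached."""
    below = np.flatnonzero(curve.survival <= 0.5)
    return float(curve.times[below[0]]) if below.size else float("nan")


def logrank_test(
    times: Sequence[float], events: Sequence[int], groups: Sequence
) -> tuple[float, int, float]:
    """k-group log-rank test: observed-vs-expected chi-square on k-1 df with
    hypergeometric variance (tie-correct)."""
    times, events = _check_surv(times, events)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    k = labels.size
    if k < 2:
        raise ValueError("log-rank test needs at least 2 groups")
    gi = np.searchsorted(labels, groups)
    event_times = np.unique(times[events == 1])
    O = np.zeros(k)
    E = np.zeros(k)
    V = np.zeros((k, k))
    for t in event_times:
        at_risk = times >= t
        n_t = int(at_risk.sum())
        d_t = int(((times == t) & (events == 1)).sum())
        n_gt = np.bincount(gi[at_risk], minlength=k).astype(float)
        d_gt = np.bincount(gi[(times == t) & (events == 1)], minlength=k).astype(float)
        O += d_gt
        E += d_t * n_gt / n_t
        if n_t > 1:
            frac = n_gt / n_t
            vc = d_t * (n_t - d_t) / (n_t - 1.0)
            V += vc * (np.diag(frac) - np.outer(frac, frac))
    diff = (O - E)[: k - 1]
    Vsub = V[: k - 1, : k - 1]
    chi2 = float(diff @ np.linalg.pinv(Vsub) @ diff)
    df = k - 1
    return chi2, df, float(stats.chi2.sf(chi2, df))


def _two_group_logrank_z(
    times: np.ndarray, events: np.ndarray, high: np.ndarray
) -> float:
    """Standardized log-rank statistic (O - E)/sqrt(V) for the high group."""
    order = np.argsort(times, kind="stable")
    t_s, e_s = times[order], events[order]
    h_s = np.asarray(high, dtype=float)[order]
    event_times = np.unique(t_s[e_s == 1])
    starts = np.searchsorted(t_s, event_times, side="left")
    n_t = (t_s.size - starts).astype(float)
    suffix_h = np.concatenate([np.cumsum(h_s[::-1])[::-1], [0.0]])
    n1 = suffix_h[starts]
    ev = e_s == 1
    grp = np.searchsorted(event_times, t_s[ev])
    d_t = np.bincount(grp, minlength=event_times.size).astype(float)
    d1 = np.bincount(grp, weights=h_s[ev], minlength=event_times.size)
    frac = n1 / n_t
    o, e = d1.sum(), (d_t * frac).sum()
    ok = n_t > 1
    v = float(
        (d_t[ok] * (n_t[ok] - d_t[ok]) / (n_t[ok] - 1.0) * frac[ok] * (1.0 - frac[ok])).sum()
    )
    return float((o - e) / np.sqrt(v)) if v > 0 else 0.0


def cox_fit(
    times: Sequence[float],
    events: Sequence[int],
    covariates: np.ndarray,
    names: Sequence[str] | None = None,
    ties: str = "breslow",
    max_iter: int = 50,
    tol: float = 1e-8,
) -> CoxFit:
    """Cox proportional-hazards fit by Newton-Raphson on the partial
    likelihood with Breslow (default) or Efron tie handling.

    Wald confidence intervals and p-values; convergence and monotone-
    likelihood (|beta| > 20) states are reported honestly rather than
    silently clipped."""
    times, events = _check_surv(times, events)
    X = np.atleast_2d(np.asarray(covariates, dtype=float))
    if X.shape[0] != times.size:
        X = X.T
    if X.shape[0] != times.size:
        raise ValueError("covariate rows must match number of subjects")
    n, p = X.shape
    if names is None:
        names = [f"x{j}" for j in range(p)]
    if not np.isfinite(X).all():
        raise ValueError("covariates must be finite")
    if events.sum() == 0:
        raise ValueError("no events in survival data")
    sds = X.std(axis=0)
    if (sds == 0).any():
        raise ValueError(f"constant covariate column: {names[int(np.argmax(sds == 0))]!r}")
    if np.linalg.matrix_rank(X - X.mean(axis=0)) < p:
        raise ValueError("rank-deficient covariate matrix (collinear columns)")
    if ties not in ("breslow", "efron"):
        raise ValueError("ties must be 'breslow' or 'efron'")

    order = np.argsort(times, kind="stable")
    t_s, e_s, X_s = times[order], events[order], X[order]
    event_times = np.unique(t_s[e_s == 1])
    # risk-set start index for each event time in the ascending sort
    starts = np.searchsorted(t_s, event_times, side="left")
    event_rows = np.flatnonzero(e_s == 1)
    grp = np.searchsorted(event_times, t_s[event_rows])
    d_counts = np.bincount(grp, minlength=event_times.size).astype(float)
    x_event_sum = X_s[event_rows].sum(axis=0)
    tie_rows = [event_rows[grp == i] for i in range(event_times.size)]

    def loglik_grad_hess(beta: np.ndarray):
        eta = X_s @ beta
        eta = eta - eta.max()  # overflow guard; cancels in the ratios
        w = np.exp(eta)
        wX = w[:, None] * X_s
        wXX = np.einsum("i,ij,ik->ijk", w, X_s, X_s)
        S0 = np.cumsum(w[::-1])[::-1]
        S1 = np.cumsum(wX[::-1], axis=0)[::-1]
        S2 = np.cumsum(wXX[::-1], axis=0)[::-1]
        if ties == "breslow":
            s0, s1, s2 = S0[starts], S1[starts], S2[starts]
            mean1 = s1 / s0[:, None]
            ll = float(eta[event_rows].sum() - (d_counts * np.log(s0)).sum())
            grad = x_event_sum - (d_counts[:, None] * mean1).sum(axis=0)
            hess = -(
                np.einsum("t,tjk->jk", d_counts / s0, s2)
                - np.einsum("t,tj,tk->jk", d_counts, mean1, mean1)
            )
            return ll, grad, hess
        # efron
        ll = float(eta[event_rows].sum())
        grad = x_event_sum.astype(float).copy()
        hess = np.zeros((p, p))
        for t_idx, start in enumerate(starts):
            rows = tie_rows[t_idx]
            d = len(rows)
            s0, s1, s2 = S0[start], S1[start], S2[start]
            wd = w[rows].sum()
            wd1 = wX[rows].sum(axis=0)
            wd2 = wXX[rows].sum(axis=0)
            for l in range(d):
                f = l / d
                s0l = s0 - f * wd
                s1l = s1 - f * wd1
                s2l = s2 - f * wd2
                ll -= np.log(s0l)
                mean1 = s1l / s0l
                grad -= mean1
                hess -= s2l / s0l - np.outer(mean1, mean1)
        return ll, grad, hess

    beta = np.zeros(p)
    ll, grad, hess = loglik_grad_hess(beta)
    converged = False
    for _ in range(max_iter):
        if np.linalg.norm(grad) < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(-hess, grad, rcond=None)[0]
        # step-halving to guarantee ascent
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            ll_new, grad_new, hess_new = loglik_grad_hess(cand)
            if ll_new >= ll - 1e-12:
                break
            scale /= 2.0
        beta, ll, grad, hess = cand, ll_new, grad_new, hess_new
    else:
        if np.linalg.norm(grad) < tol:
            converged = True
    if not converged:
        warnings.warn("Cox fit did not converge; returning last iterate", stacklevel=2)

    separation = bool((np.abs(beta) > 20).any())
    if separation:
        warnings.warn(
            "monotone partial likelihood suspected (|beta| > 20)", stacklevel=2
        )
    cov = np.linalg.pinv(-hess)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    terms = []
    for j, name in enumerate(names):
        b, s = float(beta[j]), float(se[j])
        z = b / s if s > 0 else np.inf * np.sign(b)
        terms.append(
            CoxTerm(
                name=name,
                beta=b,
                se=s,
                hr=float(np.exp(b)),
                ci_low=float(np.exp(b - _Z975 * s)),
                ci_high=float(np.exp(b + _Z975 * s)),
                p=float(2.0 * stats.norm.sf(abs(z))),
            )
        )
    return CoxFit(
        terms=terms,
        loglik=float(ll),
        converged=converged,
        n=n,
        n_events=int(events.sum()),
        separation=separation,
    )


def surv_cutpoint(
    score: Sequence[float],
    times: Sequence[float],
    events: Sequence[int],
    minprop: float = 0.1,
) -> CutpointResult:
    """Maximally selected log-rank cutpoint.

    Candidates are midpoints between consecutive distinct sorted scores
    whose split keeps both groups at >= minprop of the cohort; the chosen
    cutpoint maximizes the absolute standardized two-group log-rank
    statistic (ties broken toward the smallest cutpoint)."""
    score = np.asarray(score, dtype=float)
    times, events = _check_surv(times, events)
    if score.size != times.size:
        raise ValueError("score length must match survival data")
    if not (0.0 < minprop < 0.5):
        raise ValueError("minprop must lie in (0, 0.5)")
    n = score.size
    distinct = np.unique(score)
    if distinct.size < 2:
        raise ValueError("no feasible cutpoint candidates (constant score)")
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    scanned: list[tuple[float, float]] = []
    best_cut, best_z = None, 0.0
    min_n = minprop * n
    for cut in mids:
        high = score > cut
        n_high = int(high.sum())
        n_low = n - n_high
        if min(n_low, n_high) < min_n:
            continue
        z = _two_group_logrank_z(times, events, high)
        scanned.append((float(cut), z))
        if best_cut is None or abs(z) > abs(best_z) + 1e-12:
            best_cut, best_z = float(cut), z
    if best_cut is None:
        raise ValueError("no feasible cutpoint candidates under minprop")
    high = score > best_cut
    return CutpointResult(
        cutpoint=best_cut,
        statistic=best_z,
        group_sizes=(int((~high).sum()), int(high.sum())),
        scanned=scanned,
    )
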