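"""Survival estimators and cohort stratification schemes.

Kaplan-Meier product-limit estimation, the multi-group log-rank test,
and a single-binary-covariate Cox proportional-hazards fit (Breslow or
Efron ties, Newton-Raphson) are implemented directly so they can be
validated against independent oracles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "KMCurve",
    "LogRankResult",
    "CoxResult",
    "km_estimate",
    "logrank_test",
    "cox_hr",
    "stratify_samples",
]


@dataclass
class KMCurve:
    """Product-limit curve: S(t) evaluated at the distinct event times."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray

    def survival_at(self, t: float) -> float:
        """Right-continuous step-function evaluation; S = 1 before the first event."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass(frozen=True)
class LogRankResult:
    chi2: float
    df: int
    p_value: float


@dataclass(frozen=True)
class CoxResult:
    log_hr: float
    hr: float
    se: float
    ci95: tuple[float, float]
    p_value: float
    converged: bool
    n_iter: int


def _check_times(times: np.ndarray, events: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.shape != e.shape or t.ndim != 1:
        raise ValueError("times and events must be paired 1-D vectors")
    if t.size == 0:
        raise ValueError("need at least one subject")
    if (t < 0).any():
        raise ValueError("negative follow-up time")
    if not np.isin(e, (0, 1)).all():
        raise ValueError("events must be 0/1")
    return t, e


def km_estimate(times, events) -> KMCurve:
    """Kaplan-Meier product-limit estimator.

    Censored observations reduce the risk set without introducing steps.
    """
    t, e = _check_times(times, events)
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    event_times = np.unique(t[e == 1])
    surv = np.empty(event_times.size)
    at_risk = np.empty(event_times.size, dtype=int)
    s = 1.0
    for i, et in enumerate(event_times):
        n_risk = int((t >= et).sum())
        d = int(((t == et) & (e == 1)).sum())
        s *= 1.0 - d / n_risk
        surv[i] = s
        at_risk[i] = n_risk
    return KMCurve(event_times, surv, at_risk)


def logrank_test(groups, times, events) -> LogRankResult:
    """Multi-group log-rank test; ties pooled at identical event times.

    Two groups use the scalar (O-E)^2 / V statistic; g > 2 uses the
    quadratic form over the first g-1 groups with the hypergeometric
    covariance matrix. df = g - 1.
    """
    t, e = _check_times(times, events)
    g = np.asarray(groups)
    if g.shape != t.shape:
        raise ValueError("groups must align with times/events")
    labels = np.unique(g)
    k = labels.size
    if k < 2:
        raise ValueError("log-rank test requires >= 2 groups")
    event_times = np.unique(t[e == 1])
    obs = np.zeros(k)
    exp = np.zeros(k)
    cov = np.zeros((k, k))
    for et in event_times:
        at_risk = t >= et
        n = at_risk.sum()
        d = int(((t == et) & (e == 1)).sum())
        n_j = np.array([(at_risk & (g == lab)).sum() for lab in labels], dtype=float)
        d_j = np.array(
            [((t == et) & (e == 1) & (g == lab)).sum() for lab in labels],
            dtype=float,
        )
        obs += d_j
        exp += d * n_j / n
        if n > 1:
            frac = n_j / n
            scale = d * (n - d) / (n - 1)
            cov += scale * (np.diag(frac) - np.outer(frac, frac))
    diff = (obs - exp)[: k - 1]
    v = cov[: k - 1, : k - 1]
    if k == 2:
        chi2 = float(diff[0] ** 2 / v[0, 0]) if v[0, 0] > 0 else 0.0
    else:
        chi2 = float(diff @ np.linalg.pinv(v) @ diff)
    chi2 = max(chi2, 0.0)
    p = float(stats.chi2.sf(chi2, k - 1))
    return LogRankResult(chi2, k - 1, max(min(p, 1.0), np.nextafter(0, 1)))


def _cox_loglik_breslow(beta: float, x, t, e) -> tuple[float, float, float]:
    """(loglik, gradient, hessian) of the Breslow partial likelihood,
    single binary covariate."""
    event_times = np.unique(t[e == 1])
    ll = grad = hess = 0.0
    for et in event_times:
        at_risk = t >= et
        dead = (t == et) & (e == 1)
        d = int(dead.sum())
        s_dead = float(x[dead].sum())
        w = np.exp(beta * x[at_risk])
        s0 = float(w.sum())
        s1 = float((w * x[at_risk]).sum())
        s2 = float((w * x[at_risk] ** 2).sum())
        ll += beta * s_dead - d * math.log(s0)
        grad += s_dead - d * s1 / s0
        hess -= d * (s2 / s0 - (s1 / s0) ** 2)
    return ll, grad, hess


def _cox_loglik_efron(beta: float, x, t, e) -> tuple[float, float, float]:
    event_times = np.unique(t[e == 1])
    ll = grad = hess = 0.0
    for et in event_times:
        at_risk = t >= et
        dead = (t == et) & (e == 1)
        d = int(dead.sum())
        s_dead = float(x[dead].sum())
        w = np.exp(beta * x[at_risk])
        s0 = float(w.sum())
        s1 = float((w * x[at_risk]).sum())
        s2 = float((w * x[at_risk] ** 2).sum())
        wd = np.exp(beta * x[dead])
        d0 = float(wd.sum())
        d1 = float((wd * x[dead]).sum())
        d2 = float((wd * x[dead] ** 2).sum())
        ll += beta * s_dead
        for j in range(d):
            f = j / d
            z0 = s0 - f * d0
            z1 = s1 - f * d1
            z2 = s2 - f * d2
            ll -= math.log(z0)
            grad += -z1 / z0
            hess -= z2 / z0 - (z1 / z0) ** 2
        grad += s_dead
    return ll, grad, hess


def cox_hr(
    group,
    times,
    events,
    ties: str = "breslow",
    tol: float = 1e-8,
    max_iter: int = 50,
) -> CoxResult:
    """Cox proportional-hazards fit for a single binary covariate.

    Newton-Raphson on the partial likelihood until the log-likelihood
    change is below ``tol`` or ``max_iter`` iterations. Complete
    separation of events (monotone likelihood) is reported via
    ``converged=False`` with the last iterate.
    """
    t, e = _check_times(times, events)
    x = np.asarray(group, dtype=float)
    if x.shape != t.shape:
        raise ValueError("group must align with times/events")
    if not np.isin(x, (0, 1)).all():
        raise ValueError("group must be a binary 0/1 vector")
    for lvl in (0, 1):
        if e[x == lvl].sum() == 0:
            raise ValueError(f"group {lvl} has no events")
    loglik_fn = {"breslow": _cox_loglik_breslow, "efron": _cox_loglik_efron}.get(ties)
    if loglik_fn is None:
        raise ValueError(f"unknown tie method {ties!r}")

    beta = 0.0
    ll_old, grad, hess = loglik_fn(beta, x, t, e)
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        if hess >= 0:
            break
        step = -grad / hess
        # dampen huge steps toward separation
        step = max(min(step, 5.0), -5.0)
        beta_new = beta + step
        ll_new, grad, hess = loglik_fn(beta_new, x, t, e)
        beta = beta_new
        if abs(ll_new - ll_old) < tol:
            converged = True
            ll_old = ll_new
            break
        ll_old = ll_new
    if abs(beta) > 15:
        converged = False
    se = math.sqrt(-1.0 / hess) if hess < 0 else math.inf
    z = beta / se if se > 0 and math.isfinite(se) else 0.0
    p = float(2 * stats.norm.sf(abs(z)))
    ci = (beta - 1.959963984540054 * se, beta + 1.959963984540054 * se)

    def _safe_exp(v: float) -> float:
        return math.inf if v > 700 else math.exp(v)

    return CoxResult(
        log_hr=float(beta),
        hr=float(_safe_exp(beta)),
        se=float(se),
        ci95=(float(_safe_exp(ci[0])), float(_safe_exp(ci[1]))),
        p_value=p,
        converged=converged,
        n_iter=n_iter,
    )


def _median_split(values: pd.Series) -> pd.Series:
    """'high' iff strictly greater than the median; ties go to 'low'."""
    med = values.median()
    return pd.Series(
        np.where(values > med, "high", "low"), index=values.index, name="group"
    )


def stratify_samples(
    data: pd.DataFrame,
    scheme: str,
    gene: str | None = None,
    gene_b: str | None = None,
    snp: str | None = None,
    exclude_deep_loss_gene: str | None = None,
    genotype_stratum: str = "high",
    genotype_mode: str = "tt_vs_rest",
) -> pd.Series:
    """Assign group labels per sample under the named stratification scheme.

    Schemes (columns expected on ``data``):

    - ``median_split``: 'high' iff ``expr_<gene>`` > median (ties low).
    - ``cn_split``: 'gain_amp' (code >= 1) vs 'diploid' on ``cn_<gene>``.
    - ``joint_high``: four groups 'A_high/B_high' etc. from the two genes'
      median splits; both-high is the exposure group.
    - ``genotype_within_stratum``: median-split ``expr_<gene>``, keep the
      requested stratum, then 'TT' vs 'TC/CC' (or TT vs CC) on
      ``genotype_<snp>``.
    - ``gleason_subgroup``: '<=6', '7', '>=8' from ``gleason``.

    When ``exclude_deep_loss_gene`` is set, samples with CN code -2 for
    that gene are dropped before anything else (including the median).
    Samples outside the scheme's domain get label NA and should be
    dropped by the caller.
    """
    df = data.copy()
    if exclude_deep_loss_gene is not None:
        col = f"cn_{exclude_deep_loss_gene}"
        if col not in df.columns:
            raise ValueError(f"missing column {col!r} for deep-loss exclusion")
        df = df.loc[df[col] != -2]

    def need(col: str) -> pd.Series:
        if col not in df.columns:
            raise ValueError(f"scheme {scheme!r} requires column {col!r}")
        return df[col]

    if scheme == "median_split":
        return _median_split(need(f"expr_{gene}"))
    if scheme == "cn_split":
        cn = need(f"cn_{gene}")
        return pd.Series(
            np.where(cn >= 1, "gain_amp", "diploid"), index=df.index, name="group"
        )
    if scheme == "joint_high":
        a = _median_split(need(f"expr_{gene}"))
        b = _median_split(need(f"expr_{gene_b}"))
        lab = a.str.cat(b, sep="/")
        return lab.rename("group")
    if scheme == "genotype_within_stratum":
        stratum = _median_split(need(f"expr_{gene}"))
        geno = need(f"genotype_{snp}")
        keep = stratum == genotype_stratum
        geno = geno[keep]
        if keep.sum() == 0:
            raise ValueError("empty expression stratum")
        if genotype_mode == "tt_vs_rest":
            lab = np.where(geno == "TT", "TT", "TC/CC")
            return pd.Series(lab, index=geno.index, name="group")
        if genotype_mode == "tt_vs_cc":
            sub = geno[geno.isin(["TT", "CC"])]
            return pd.Series(sub.to_numpy(), index=sub.index, name="group")
        raise ValueError(f"unknown genotype_mode {genotype_mode!r}")
    if scheme == "gleason_subgroup":
        gl = need("gleason").astype(int)
        lab = np.where(gl <= 6, "<=6", np.where(gl == 7, "7", ">=8"))
        return pd.Series(lab, index=df.index, name="group")
    raise ValueError(f"unknown stratification scheme {scheme!r}")
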