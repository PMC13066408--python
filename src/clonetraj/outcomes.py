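"""Relapse-outcome models on clone composition.

The covariate of interest is the NOTCH1-wild-type tumor fraction at
diagnosis: the difference, in percentage points, between the CCF of the
largest clone and the CCF of the largest clone carrying a NOTCH1 event
(a clone carries the marker if it or any ancestor acquired it, so under
the subtree-inclusive CCF convention the largest carrier already counts
all mutant descendants). The covariate is related to time to relapse by
a Cox proportional-hazards model whose partial likelihood (Efron tie
handling) is maximized by Newton iterations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import CloneTreeDocument, NORMAL_NODE_ID


class SeparationError(RuntimeError):
    """Monotone partial likelihood (perfect separation): no finite MLE."""


def notch_wt_fraction(tree: CloneTreeDocument, timepoint: int,
                      marker_gene: str = "NOTCH1",
                      mode: str = "max_clone") -> float:
    """Percentage of tumor cells not carrying the marker mutation.

    ``mode='max_clone'`` (default) subtracts the CCF of the single
    largest marker-carrying clone; ``mode='sum_branches'`` subtracts the
    summed CCF of the maximal disjoint marker-carrying branches.
    """
    if timepoint not in tree.timepoints:
        raise ValueError(f"tree has no timepoint {timepoint}")
    nodes = tree.malignant_nodes()
    if not nodes:
        raise ValueError("tree has no malignant clones")
    parents = tree.parent_map()

    def carries(nid: str) -> bool:
        cur: str | None = nid
        while cur is not None and cur != NORMAL_NODE_ID:
            if marker_gene in tree.node(cur).events:
                return True
            cur = parents[cur]
        return False

    ccf = {n.node_id: n.ccf_by_timepoint.get(timepoint, 0.0) for n in nodes}
    largest = max(ccf.values())
    carriers = [n.node_id for n in nodes if carries(n.node_id)]
    if not carriers:
        value = 100.0 * largest
    elif mode == "max_clone":
        value = 100.0 * (largest - max(ccf[c] for c in carriers))
    elif mode == "sum_branches":
        maximal = [c for c in carriers
                   if not any(tree.is_strict_ancestor(o, c) for o in carriers)]
        value = 100.0 * (largest - sum(ccf[c] for c in maximal))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return float(min(100.0, max(0.0, value)))


@dataclass
class SurvivalRecord:
    patient_id: str
    covariate: float  # NOTCH1-wild-type tumor fraction, percentage points
    time: float       # days
    event: bool
    strata: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.covariate <= 100.0:
            raise ValueError(f"covariate outside [0,100]: {self.covariate}")
        if self.time <= 0:
            raise ValueError("time must be positive")


# ---------------------------------------------------------------------------
# Cox proportional hazards, Efron ties

def _efron_ll_grad_hess(beta: np.ndarray, X: np.ndarray, time: np.ndarray,
                        event: np.ndarray):
    """Log partial likelihood, gradient and Hessian under Efron ties."""
    n, p = X.shape
    order = np.argsort(-time, kind="stable")  # descending: grow the risk set
    Xs, ts, es = X[order], time[order], event[order]
    eta = Xs @ beta
    eta = np.clip(eta, -500, 500)
    w = np.exp(eta)

    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    s0 = 0.0
    s1 = np.zeros(p)
    s2 = np.zeros((p, p))
    i = 0
    while i < n:
        j = i
        while j < n and ts[j] == ts[i]:
            j += 1
        for idx in range(i, j):  # everyone at this time enters the risk set
            s0 += w[idx]
            s1 += w[idx] * Xs[idx]
            s2 += w[idx] * np.outer(Xs[idx], Xs[idx])
        deaths = [idx for idx in range(i, j) if es[idx]]
        d = len(deaths)
        if d:
            d0 = sum(w[idx] for idx in deaths)
            d1 = np.sum([w[idx] * Xs[idx] for idx in deaths], axis=0)
            d2 = np.sum([w[idx] * np.outer(Xs[idx], Xs[idx]) for idx in deaths],
                        axis=0)
            for idx in deaths:
                ll += eta[idx]
            for l in range(d):
                frac = l / d
                a0 = s0 - frac * d0
                a1 = s1 - frac * d1
                a2 = s2 - frac * d2
                ll -= np.log(a0)
                grad_term = a1 / a0
                grad -= grad_term
                hess -= a2 / a0 - np.outer(grad_term, grad_term)
            for idx in deaths:
                grad += Xs[idx]
        i = j
    return ll, grad, hess


@dataclass
class CoxPHResults:
    """Fitted Cox model: per-unit log-hazard, Wald inference, summary()."""

    params: np.ndarray
    bse: np.ndarray
    n: int
    n_events: int
    loglik: float
    names: list[str]
    alpha: float = 0.05

    @property
    def beta(self) -> float:
        return float(self.params[0])

    @property
    def hr(self) -> float:
        return float(np.exp(self.params[0]))

    def conf_int(self) -> np.ndarray:
        z = stats.norm.ppf(1.0 - self.alpha / 2.0)
        return np.column_stack([self.params - z * self.bse,
                                self.params + z * self.bse])

    @property
    def ci_low(self) -> float:
        return float(np.exp(self.conf_int()[0, 0]))

    @property
    def ci_high(self) -> float:
        return float(np.exp(self.conf_int()[0, 1]))

    @property
    def pvalues(self) -> np.ndarray:
        z = self.params / self.bse
        return 2.0 * stats.norm.sf(np.abs(z))

    @property
    def p_value(self) -> float:
        return float(self.pvalues[0])

    def hazard_increase_percent(self, per_units: float = 1.0) -> float:
        """(HR - 1) x 100 for a covariate increase of ``per_units``."""
        return float((np.exp(self.params[0] * per_units) - 1.0) * 100.0)

    def summary(self) -> pd.DataFrame:
        ci = self.conf_int()
        return pd.DataFrame({
            "coef": self.params,
            "exp(coef)": np.exp(self.params),
            "se(coef)": self.bse,
            "exp(coef) lower 95%": np.exp(ci[:, 0]),
            "exp(coef) upper 95%": np.exp(ci[:, 1]),
            "z": self.params / self.bse,
            "p": self.pvalues,
        }, index=self.names)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"<CoxPHResults n={self.n} events={self.n_events} "
                f"HR={self.hr:.4f} [{self.ci_low:.4f}, {self.ci_high:.4f}] "
                f"p={self.p_value:.3g}>")


class CoxPH:
    """Cox proportional-hazards model (Efron tie handling).

    Parameters
    ----------
    time, event
        Follow-up time and event indicator per subject.
    X
        Covariate vector (n,) or matrix (n, p).
    strata
        Optional stratum labels; the partial likelihood is summed over
        strata (separate baseline hazards, shared coefficients).
    """

    def __init__(self, time, event, X, strata=None,
                 names: list[str] | None = None):
        self.time = np.asarray(time, dtype=float)
        self.event = np.asarray(event, dtype=bool)
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        self.X = X
        self.strata = None if strata is None else np.asarray(strata)
        self.names = names or [f"x{i}" for i in range(X.shape[1])]
        if self.event.sum() < 2:
            raise ValueError("need at least 2 observed events")
        if np.allclose(self.X.std(axis=0), 0):
            raise ValueError("covariate is constant: no information")

    def _ll_grad_hess(self, beta):
        if self.strata is None:
            return _efron_ll_grad_hess(beta, self.X, self.time, self.event)
        ll, grad = 0.0, np.zeros_like(beta)
        hess = np.zeros((len(beta), len(beta)))
        for s in np.unique(self.strata):
            m = self.strata == s
            l, g, h = _efron_ll_grad_hess(beta, self.X[m], self.time[m],
                                          self.event[m])
            ll += l
            grad += g
            hess += h
        return ll, grad, hess

    def fit(self, tol: float = 1e-8, max_iter: int = 100) -> CoxPHResults:
        # Center the covariates for numerical stability; beta is unchanged.
        mu = self.X.mean(axis=0)
        Xc = self.X - mu
        model = CoxPH.__new__(CoxPH)
        model.time, model.event, model.X = self.time, self.event, Xc
        model.strata, model.names = self.strata, self.names

        beta = np.zeros(Xc.shape[1])
        ll, grad, hess = model._ll_grad_hess(beta)
        for _ in range(max_iter):
            if np.max(np.abs(grad)) < tol:
                break
            try:
                step = np.linalg.solve(hess, -grad)
            except np.linalg.LinAlgError:
                raise SeparationError(
                    "singular information matrix (monotone likelihood?)") from None
            # damped Newton with step halving; the acceptance slack covers
            # floating-point noise in the summed log-likelihood
            t = 1.0
            slack = 1e-9 * (1.0 + abs(ll))
            for _ in range(40):
                cand = beta + t * step
                ll_new, grad_new, hess_new = model._ll_grad_hess(cand)
                if ll_new >= ll - slack:
                    beta, ll, grad, hess = cand, ll_new, grad_new, hess_new
                    break
                t /= 2.0
            else:  # pragma: no cover - pathological
                break
            if np.max(np.abs(beta)) > 80:
                raise SeparationError(
                    "divergent coefficient: perfect separation, no estimate")
        else:
            if np.max(np.abs(grad)) > 1e-4:
                raise SeparationError(
                    "Newton iterations did not converge (monotone likelihood?)")
        cov = np.linalg.inv(-hess)
        bse = np.sqrt(np.diag(cov))
        # a monotone partial likelihood flattens out at huge |beta| with an
        # exploding standard error instead of failing to converge
        scale = np.maximum(self.X.std(axis=0), 1e-12)
        if np.any(np.abs(beta) * scale > 15) or np.any(bse * scale > 50):
            raise SeparationError(
                "monotone likelihood (perfect separation): no finite estimate")
        return CoxPHResults(params=beta, bse=bse, n=len(self.time),
                            n_events=int(self.event.sum()), loglik=float(ll),
                            names=self.names)


def fit_cox_ph(records: list[SurvivalRecord], stratify: bool = False) -> CoxPHResults:
    """Fit the relapse-hazard model on NOTCH1-wild-type fractions.

    The reported HR is per percentage point of wild-type tumor fraction.
    """
    time = [r.time for r in records]
    event = [r.event for r in records]
    x = [r.covariate for r in records]
    strata = [r.strata for r in records] if stratify else None
    model = CoxPH(time, event, x, strata=strata, names=["notch1_wt_fraction_pct"])
    return model.fit()


# ---------------------------------------------------------------------------
# relapse-time comparison by mutation status

def time_to_relapse_by_status(times_mutated, times_wildtype,
                              method: str = "ranksum") -> float:
    """Compare time to relapse between marker-mutated and wild-type
    relapsed patients. Default: two-sided Wilcoxon rank-sum (exact when
    sample sizes allow); ``method='logrank'`` treats all times as events
    in a standard log-rank test."""
    a = np.asarray(times_mutated, dtype=float)
    b = np.asarray(times_wildtype, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 relapsed patients per status group")
    if method == "ranksum":
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
        return float(res.pvalue)
    if method == "logrank":
        return _logrank_p(a, b)
    raise ValueError(f"unknown method {method!r}")


def _logrank_p(a: np.ndarray, b: np.ndarray) -> float:
    times = np.concatenate([a, b])
    group = np.concatenate([np.zeros(len(a)), np.ones(len(b))])
    obs = 0.0
    exp = 0.0
    var = 0.0
    for t in np.unique(times):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & (group == 0)).sum()
        d = (times == t).sum()
        d1 = ((times == t) & (group == 0)).sum()
        obs += d1
        exp += d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var <= 0:
        return 1.0
    z = (obs - exp) / np.sqrt(var)
    return float(2.0 * stats.norm.sf(abs(z)))
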