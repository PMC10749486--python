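"""Diagnostic accuracy of a binary positivity call against disease labels.

From a 2x2 table (positivity call vs cancer/HD label) this module
computes sensitivity, specificity, predictive values, the positive
likelihood ratio and the diagnostic odds ratio (DOR), with Wilson score
confidence intervals for the proportions and a Baptista-Pike mid-p
exact conditional interval for the DOR.

The Baptista-Pike interval inverts the probability-ordering (Sterne
type) exact test of the odds ratio under Fisher's noncentral
hypergeometric distribution: for a given odds ratio psi the p-value is
the total probability of all tables (with the observed margins) no more
probable than the observed one, and the confidence set is the psi
region where that p-value exceeds alpha.  The mid-p variant counts the
boundary outcomes with weight one half, which shortens the interval and
brings its coverage close to (rather than above) the nominal level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, minimize_scalar
from scipy.stats import chi2, nchypergeom_fisher
from statsmodels.stats.proportion import proportion_confint


@dataclass(frozen=True)
class Table2x2:
    """Counts of positivity calls vs disease labels.

    tp: positive call in cancer; fp: positive call in HD;
    fn: negative call in cancer; tn: negative call in HD.
    """

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        for name in ("tp", "fp", "fn", "tn"):
            val = getattr(self, name)
            if val < 0 or int(val) != val:
                raise ValueError(f"{name} must be a non-negative integer, got {val!r}")

    @property
    def n_cancer(self) -> int:
        return self.tp + self.fn

    @property
    def n_hd(self) -> int:
        return self.fp + self.tn

    @classmethod
    def from_calls(cls, calls, is_cancer) -> "Table2x2":
        """Tabulate boolean calls against boolean cancer labels.

        Pairs with a missing call are excluded.
        """
        import pandas as pd

        c = np.asarray(calls, dtype=object)
        y = np.asarray(is_cancer, dtype=bool)
        keep = np.array([not pd.isna(x) for x in c], dtype=bool)
        c = np.array([bool(x) for x in c[keep]])
        y = y[keep]
        return cls(
            tp=int((c & y).sum()),
            fp=int((c & ~y).sum()),
            fn=int((~c & y).sum()),
            tn=int((~c & ~y).sum()),
        )


@dataclass(frozen=True)
class AccuracyReport:
    """Point estimates and 95% CIs for the Table2x2 accuracy battery.

    Proportions are on the [0, 1] scale; rendering to percent happens
    in the report layer.  ``dor`` is ``inf`` when fp*fn = 0 (flagged via
    ``dor_infinite``); ``ppv``/``npv`` are ``nan`` when their column
    margin is empty.
    """

    table: Table2x2
    sn: float
    sn_ci: tuple[float, float]
    sp: float
    sp_ci: tuple[float, float]
    ppv: float
    ppv_ci: tuple[float, float]
    npv: float
    npv_ci: tuple[float, float]
    lr_plus: float
    dor: float
    dor_ci: tuple[float, float]
    level: float = 0.95
    ci_method: str = "wilson"
    dor_ci_method: str = "baptista-pike-midp"

    @property
    def dor_infinite(self) -> bool:
        return math.isinf(self.dor)


def wilson_ci(successes: int, n: int, level: float = 0.95,
              brown: bool = False) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion.

    The plain Wilson interval is the default and the validated surface.
    ``brown=True`` applies a boundary modification in the spirit of the
    modified (Brown-style) hybrid used by some commercial software:
    for 1 or 2 successes (or failures) the affected limit is replaced by
    the one-sided Poisson chi-square bound.  That variant is provided
    for comparison only.
    """
    if n < 1:
        raise ValueError("wilson_ci: n must be >= 1")
    if not 0 <= successes <= n:
        raise ValueError("wilson_ci: successes must be in [0, n]")
    alpha = 1.0 - level
    lo, hi = proportion_confint(successes, n, alpha=alpha, method="wilson")
    lo, hi = float(lo), float(hi)
    if successes == 0:
        lo = 0.0
    if successes == n:
        hi = 1.0
    if brown:
        if successes in (1, 2):
            lo = 0.5 * chi2.ppf(alpha, 2 * successes) / n
        if n - successes in (1, 2):
            hi = 1.0 - 0.5 * chi2.ppf(alpha, 2 * (n - successes)) / n
    return max(lo, 0.0), min(hi, 1.0)


# ---------------------------------------------------------------------------
# Baptista-Pike exact conditional interval for the odds ratio


def _support(t: Table2x2) -> np.ndarray:
    lo = max(0, (t.tp + t.fp) - t.n_hd)
    hi = min(t.n_cancer, t.tp + t.fp)
    return np.arange(lo, hi + 1)


def _ordering_pvalue(psi: float, t: Table2x2, midp: bool) -> float:
    """Probability-ordering p-value at odds ratio psi.

    Sums P(X = y | psi) over outcomes y no more probable than the
    observed cell; mid-p counts equally-probable outcomes (including
    the observed one) with weight one half.
    """
    N = t.tp + t.fp + t.fn + t.tn
    K = t.n_cancer
    n = t.tp + t.fp
    xs = _support(t)
    dist = nchypergeom_fisher(N, K, n, psi)
    pm = dist.pmf(xs)
    px = dist.pmf(t.tp)
    rel = 1e-9 * max(px, 1e-300)
    less = pm < px - rel
    eq = np.abs(pm - px) <= rel
    if midp:
        return float(pm[less].sum() + 0.5 * pm[eq].sum())
    return float(pm[less].sum() + pm[eq].sum())


def _conditional_mle_log_or(t: Table2x2) -> float:
    N = t.tp + t.fp + t.fn + t.tn
    K = t.n_cancer
    n = t.tp + t.fp
    res = minimize_scalar(
        lambda lp: -nchypergeom_fisher(N, K, n, math.exp(lp)).logpmf(t.tp),
        bounds=(-30.0, 30.0),
        method="bounded",
        options={"xatol": 1e-10},
    )
    return float(res.x)


def baptista_pike_ci(t: Table2x2, level: float = 0.95,
                     midp: bool = True) -> tuple[float, float]:
    """Baptista-Pike exact conditional CI for the (diagnostic) odds ratio.

    Inverts the probability-ordering test of the noncentral
    hypergeometric model by bisection on the log-odds scale (tolerance
    1e-8).  When the observed cell sits at the boundary of its
    conditional support the corresponding limit is 0 or ``inf``.  The
    interval is invariant to simultaneously swapping both rows and both
    columns of the table (which maps the odds ratio to itself).
    """
    if t.n_cancer == 0 or t.n_hd == 0 or (t.tp + t.fp) == 0 or (t.fn + t.tn) == 0:
        raise ValueError("baptista_pike_ci: a table margin is zero")
    alpha = 1.0 - level
    xs = _support(t)
    at_min = t.tp == xs[0]
    at_max = t.tp == xs[-1]
    center = _conditional_mle_log_or(t)
    span = 60.0

    def pv(logpsi):
        return _ordering_pvalue(math.exp(logpsi), t, midp) - alpha

    if at_min:
        lo = 0.0
    else:
        a = center - span
        lo = math.exp(brentq(pv, a, center, xtol=1e-8)) if pv(a) < 0 else 0.0
    if at_max:
        hi = math.inf
    else:
        b = center + span
        hi = math.exp(brentq(pv, center, b, xtol=1e-8)) if pv(b) < 0 else math.inf
    return lo, hi


def accuracy_report(t: Table2x2, level: float = 0.95) -> AccuracyReport:
    """Full accuracy battery for one marker or panel.

    sn = tp/(tp+fn), sp = tn/(fp+tn), ppv = tp/(tp+fp),
    npv = tn/(tn+fn), LR+ = sn/(1-sp), DOR = (tp*tn)/(fp*fn).
    Operates on counts only, so it is invariant to sample order.
    """
    if t.n_cancer == 0 or t.n_hd == 0:
        raise ValueError("accuracy_report: need at least one cancer and one HD sample")
    sn = t.tp / t.n_cancer
    sp = t.tn / t.n_hd
    ppv = t.tp / (t.tp + t.fp) if (t.tp + t.fp) > 0 else math.nan
    npv = t.tn / (t.tn + t.fn) if (t.tn + t.fn) > 0 else math.nan
    lr_plus = sn / (1.0 - sp) if sp < 1.0 else math.inf
    dor = (t.tp * t.tn) / (t.fp * t.fn) if t.fp * t.fn > 0 else math.inf
    nan_ci = (math.nan, math.nan)
    try:
        dor_ci = baptista_pike_ci(t, level)
    except ValueError:
        dor_ci = nan_ci
    return AccuracyReport(
        table=t,
        sn=sn,
        sn_ci=wilson_ci(t.tp, t.n_cancer, level),
        sp=sp,
        sp_ci=wilson_ci(t.tn, t.n_hd, level),
        ppv=ppv,
        ppv_ci=wilson_ci(t.tp, t.tp + t.fp, level) if (t.tp + t.fp) > 0 else nan_ci,
        npv=npv,
        npv_ci=wilson_ci(t.tn, t.tn + t.fn, level) if (t.tn + t.fn) > 0 else nan_ci,
        lr_plus=lr_plus,
        dor=dor,
        dor_ci=dor_ci,
        level=level,
    )
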