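"""Net antibody signal, healthy-donor cutoffs, and positivity calls.

A sample is seropositive for a marker when its net Alpha count exceeds
the healthy-donor (HD) reference cutoff, defined as the HD mean plus two
HD standard deviations (sample SD, n-1 denominator).  The strict
inequality (value > cutoff) is deliberate: a value sitting exactly on
the cutoff is called negative.  Cutoffs are always fitted on the HD
samples of the analyzed dataset, never on cancer sera.

Group-level comparisons use the Mann-Whitney U test on net counts and
Pearson's chi-square (no continuity correction) on positivity strata.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Cohort
from .errors import ConfigError, FitError

TERNARY_LEVELS = ("pos", "neg")


@dataclass(frozen=True)
class CutoffModel:
    """HD reference distribution and the derived seropositivity cutoff."""

    marker_id: str
    hd_mean: float
    hd_sd: float
    cutoff: float
    n_hd: int
    zero_sd: bool = False  # all-constant HD reference; cutoff degenerates to the mean

    def __post_init__(self):
        if self.n_hd < 2:
            raise FitError(f"{self.marker_id}: need >= 2 HD values, got {self.n_hd}")


def net_alpha(fusion, gst):
    """Net Alpha counts: fusion-antigen signal minus GST-control background.

    Vectorized; missing inputs propagate to missing outputs, and
    negative results are preserved (a serum can react more with the GST
    control than with the fusion antigen).
    """
    f = np.asarray(fusion, dtype=float)
    g = np.asarray(gst, dtype=float)
    return f - g


def fit_cutoff(hd_values, marker_id: str = "") -> CutoffModel:
    """Fit the HD mean + 2 SD cutoff from healthy-donor net counts.

    Non-finite values are dropped; at least two finite values are
    required.  A zero-SD (all-constant) reference yields a cutoff equal
    to the mean and sets the ``zero_sd`` warning flag.
    """
    x = np.asarray(hd_values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 2:
        raise FitError(f"{marker_id or 'marker'}: need >= 2 finite HD values, got {x.size}")
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    zero = sd == 0.0
    if zero:
        warnings.warn(
            f"{marker_id or 'marker'}: constant HD reference, cutoff equals the mean",
            stacklevel=2,
        )
    return CutoffModel(marker_id, mean, sd, mean + 2.0 * sd, int(x.size), zero)


def fit_cutoffs(cohort: Cohort) -> dict[str, CutoffModel]:
    """Fit one cutoff model per marker on the cohort's HD samples."""
    hd = cohort.net.loc[cohort.hd_ids()]
    return {m: fit_cutoff(hd[m], m) for m in cohort.markers}


def call_positive(values, model: CutoffModel) -> pd.Series:
    """Seropositivity calls: True iff value strictly exceeds the cutoff.

    Returns a nullable-boolean Series; missing values yield missing
    calls.
    """
    idx = values.index if isinstance(values, pd.Series) else None
    v = pd.Series(np.asarray(values, dtype=float), index=idx)
    calls = pd.Series(v > model.cutoff, index=v.index, dtype="boolean")
    calls[v.isna()] = pd.NA
    return calls


def call_matrix(cohort: Cohort, models: dict[str, CutoffModel]) -> pd.DataFrame:
    """Per-sample, per-marker positivity calls (nullable boolean frame)."""
    missing = [m for m in cohort.markers if m not in models]
    if missing:
        raise ConfigError(f"no cutoff model for marker(s): {missing}")
    return pd.DataFrame(
        {m: call_positive(cohort.net[m], models[m]) for m in cohort.markers},
        index=cohort.net.index,
    )


def mann_whitney_u(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test with midrank tie handling.

    Returns ``(U, p)`` where U counts wins of ``a`` over ``b`` (ties
    half).  Exact enumeration is used when both groups have at most
    eight observations and no ties cross the groups; otherwise the
    normal approximation with tie and continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if a.size == 0 or b.size == 0:
        raise ValueError("mann_whitney_u: both samples must be non-empty")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (a.size <= 8 and b.size <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def pearson_chisq(table) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 (or r x c) table, no continuity correction.

    Raises ``ValueError`` on a zero marginal (statistic undefined).
    """
    t = np.asarray(table, dtype=float)
    if (t < 0).any() or t.sum() <= 0:
        raise ValueError("pearson_chisq: cells must be >= 0 with a positive total")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("pearson_chisq: zero marginal, statistic undefined")
    stat, p, _, _ = stats.chi2_contingency(t, correction=False)
    return float(stat), float(p)


def positivity_table(cohort: Cohort, models: dict[str, CutoffModel]) -> pd.DataFrame:
    """Per-marker positivity counts and rates per group, with Mann-Whitney p.

    One row per marker: counts and percentage of positive calls among
    cancer patients and HDs, plus the two-sided Mann-Whitney p-value
    comparing net counts between the groups.  Percentages are exact
    (100 * k / n); rounding happens only at rendering.
    """
    calls = call_matrix(cohort, models)
    is_cancer = cohort.samples["group"] == "CANCER"
    rows = []
    for m in cohort.markers:
        c = calls[m]
        valid = c.notna()
        cc = c[valid & is_cancer]
        ch = c[valid & ~is_cancer]
        n_cancer, n_hd = int(cc.size), int(ch.size)
        k_cancer, k_hd = int(cc.sum()), int(ch.sum())
        _, p = mann_whitney_u(
            cohort.net.loc[is_cancer, m], cohort.net.loc[~is_cancer, m]
        )
        rows.append(
            {
                "marker": m,
                "n_cancer": n_cancer,
                "n_positive_cancer": k_cancer,
                "pct_cancer": 100.0 * k_cancer / n_cancer if n_cancer else np.nan,
                "n_hd": n_hd,
                "n_positive_hd": k_hd,
                "pct_hd": 100.0 * k_hd / n_hd if n_hd else np.nan,
                "mannwhitney_p": p,
            }
        )
    return pd.DataFrame(rows).set_index("marker")


def clinical_association_table(
    cohort: Cohort, calls: pd.DataFrame, markers: list[str] | None = None
) -> pd.DataFrame:
    """Chi-square association of marker positivity with clinical strata.

    For each marker and each clinical factor (sex, age above/below the
    cancer-cohort median, early vs advanced Dukes stage, CEA / CA19-9 /
    anti-p53 status) cross-tabulates positivity among cancer patients
    and reports the Pearson chi-square p-value.  Samples with a missing
    stratum value (e.g. ND stage) are excluded pairwise from that row
    only.
    """
    markers = markers or list(calls.columns)
    cancer = cohort.samples[cohort.samples["group"] == "CANCER"]
    strata: dict[str, pd.Series] = {}
    sex = cancer["sex"].where(cancer["sex"].isin(["M", "F"]))
    strata["sex"] = sex
    if cancer["age"].notna().any():
        med = float(cancer["age"].dropna().median())
        age = pd.Series(pd.NA, index=cancer.index, dtype="object")
        age[cancer["age"].notna() & (cancer["age"] <= med)] = f"<= {med:g}"
        age[cancer["age"].notna() & (cancer["age"] > med)] = f"> {med:g}"
        strata["age"] = age
    stage = pd.Series(pd.NA, index=cancer.index, dtype="object")
    stage[cancer["dukes_stage"].isin(["A", "B"])] = "early"
    stage[cancer["dukes_stage"].isin(["C", "D"])] = "advanced"
    strata["dukes"] = stage
    for col, name in (("cea_positive", "cea"), ("ca199_positive", "ca199"),
                      ("p53ab_positive", "p53ab")):
        strata[name] = cancer[col].where(cancer[col].isin(TERNARY_LEVELS))
    rows = []
    for m in markers:
        call = calls.loc[cancer.index, m]
        for name, stratum in strata.items():
            ok = stratum.notna() & call.notna()
            if ok.sum() == 0:
                continue
            tab = pd.crosstab(stratum[ok], call[ok].astype(bool))
            try:
                stat, p = pearson_chisq(tab.to_numpy())
            except ValueError:
                stat, p = np.nan, np.nan
            rows.append({"marker": m, "factor": name, "n": int(ok.sum()),
                         "chisq": stat, "p": p})
    return pd.DataFrame(rows)
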