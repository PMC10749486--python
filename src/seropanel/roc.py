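"""Z-score standardization, composite panels, ROC/AUC, and paired AUC tests.

Composite marker panels are scored by summing per-marker Z scores,
where each marker (autoantibody or clinical) is standardized against
the healthy-donor reference: z = (value - HD mean) / HD SD.  Elevated
antibody levels in cancer therefore map to higher composite scores, so
an informative panel has AUC > 0.5.  The sign can be flipped per marker
for analytes where disease lowers the value.

AUC uses the midrank/trapezoid convention throughout, which makes the
empirical AUC identical to the Mann-Whitney win probability
U / (n_pos * n_neg), ties counting one half.

Paired comparison of two correlated AUCs measured on the same samples
uses the DeLong placement-value (structural component) estimator of
var(auc_a - auc_b), or a stratified paired bootstrap.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve

from .cohort import Cohort
from .errors import ConfigError, StandardizationError
from .positivity import CutoffModel

#: clinical analytes that can join composite panels, mapped to the cohort
#: metadata columns providing their per-sample values (anti-p53 status is
#: a 0/1 indicator, standardized like any other value).
CLINICAL_SOURCES = {
    "CEA": "cea_value",
    "CA19-9": "ca199_value",
    "p53Ab": "p53ab_positive",
}


def zscore(values, model: CutoffModel, flip: bool = False):
    """Standardize values against the HD reference of ``model``.

    z = (value - hd_mean) / hd_sd; with ``flip`` the sign is reversed
    for markers where disease lowers the analyte.  A value equal to the
    positivity cutoff (mean + 2 SD) maps to z = 2 exactly.
    """
    if model.hd_sd <= 0:
        raise StandardizationError(
            f"{model.marker_id}: zero HD standard deviation, cannot standardize"
        )
    idx = values.index if isinstance(values, pd.Series) else None
    z = (np.asarray(values, dtype=float) - model.hd_mean) / model.hd_sd
    if flip:
        z = -z
    return pd.Series(z, index=idx) if idx is not None else z


def zscore_table(
    cohort: Cohort,
    models: dict[str, CutoffModel],
    include_clinical: bool = True,
) -> pd.DataFrame:
    """Per-sample Z scores for every antibody marker and clinical analyte.

    Antibody markers are standardized with their fitted HD cutoff
    models; clinical analytes (CEA, CA19-9 values; anti-p53 status as a
    0/1 indicator) are standardized against the HD mean and SD of the
    same column, exactly like the antibody markers.
    """
    cols = {}
    for m in cohort.markers:
        if m not in models:
            raise ConfigError(f"no cutoff model for marker {m!r}")
        cols[m] = zscore(cohort.net[m], models[m])
    if include_clinical:
        hd_mask = (cohort.samples["group"] == "HD").to_numpy()
        for name, source in CLINICAL_SOURCES.items():
            raw = cohort.samples[source]
            if source.endswith("_positive"):
                vals = raw.map({"pos": 1.0, "neg": 0.0}).astype(float)
            else:
                vals = pd.to_numeric(raw, errors="coerce").astype(float)
            hd_vals = vals.to_numpy()[hd_mask]
            hd_vals = hd_vals[np.isfinite(hd_vals)]
            if hd_vals.size < 2 or np.std(hd_vals, ddof=1) == 0:
                continue  # analyte absent or constant in HDs: not standardizable
            mean = float(np.mean(hd_vals))
            sd = float(np.std(hd_vals, ddof=1))
            cols[name] = (vals - mean) / sd
    return pd.DataFrame(cols, index=cohort.samples.index)


def composite_score(ztable: pd.DataFrame, markers) -> pd.Series:
    """Panel score: per-sample sum of the selected markers' Z scores.

    A sample missing any component gets a missing composite (excluded
    pairwise by downstream ROC, which logs the count).  Order of
    ``markers`` is irrelevant.
    """
    markers = list(markers)
    if not markers:
        raise ConfigError("composite_score: empty marker subset")
    unknown = [m for m in markers if m not in ztable.columns]
    if unknown:
        raise ConfigError(f"composite_score: unknown marker(s) {unknown}")
    sub = ztable[markers]
    out = sub.sum(axis=1)
    out[sub.isna().any(axis=1)] = np.nan
    return out


@dataclass(frozen=True)
class ROCResult:
    """Empirical ROC curve and its trapezoidal AUC."""

    thresholds: np.ndarray  # descending
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    n_pos: int
    n_neg: int
    n_excluded: int = 0  # samples dropped for missing scores


def _clean_scores(scores, labels):
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if y.dtype.kind in "OUS":
        y = np.array([str(v).upper() == "CANCER" for v in y])
    y = y.astype(bool)
    keep = np.isfinite(s)
    return s[keep], y[keep], int((~keep).sum())


def roc_curve(scores, labels) -> ROCResult:
    """Empirical ROC over unique score thresholds, AUC by trapezoid.

    ``labels`` may be booleans (True = cancer) or 'HD'/'CANCER'
    strings.  Ties in the scores produce diagonal segments; the curve
    runs from (0,0) to (1,1).  Samples with missing scores are excluded
    pairwise and counted in ``n_excluded``.
    """
    s, y, dropped = _clean_scores(scores, labels)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_curve: both classes must be present")
    fpr, tpr, thr = _sk_roc_curve(y, s, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(thr, fpr, tpr, auc, n_pos, n_neg, dropped)


def auc_mann_whitney(scores, labels) -> float:
    """AUC via the midrank Mann-Whitney identity: U / (n_pos * n_neg).

    Independent of the threshold-sweep route in :func:`roc_curve`;
    the two agree exactly under the tie conventions used here.
    """
    s, y, _ = _clean_scores(scores, labels)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("auc_mann_whitney: both classes must be present")
    ranks = stats.rankdata(s)
    u = ranks[y].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


# ---------------------------------------------------------------------------
# DeLong paired AUC comparison


def _placements(scores: np.ndarray, y: np.ndarray):
    """AUC plus per-case and per-control placement values.

    The placement of a case is the fraction of controls scoring below
    it (ties one half); symmetrically for controls.  Their means both
    equal the AUC; their empirical variances are the structural
    components of the DeLong variance estimator.
    """
    pos = scores[y]
    neg = scores[~y]
    m, n = pos.size, neg.size
    ranks_all = stats.rankdata(np.concatenate([pos, neg]))
    v10 = (ranks_all[:m] - stats.rankdata(pos)) / n
    v01 = 1.0 - (ranks_all[m:] - stats.rankdata(neg)) / m
    return float(v10.mean()), v10, v01


@dataclass(frozen=True)
class DeLongResult:
    """Paired DeLong comparison of two AUCs on the same samples."""

    auc_a: float
    auc_b: float
    var_diff: float
    z_statistic: float
    p: float
    n_pos: int
    n_neg: int


def delong_auc_variance(scores, labels) -> tuple[float, float]:
    """(AUC, DeLong variance) of a single score vector."""
    s, y, _ = _clean_scores(scores, labels)
    auc, v10, v01 = _placements(s, y)
    m, n = v10.size, v01.size
    var = v10.var(ddof=1) / m + v01.var(ddof=1) / n
    return auc, float(var)


def delong_test(scores_a, scores_b, labels) -> DeLongResult:
    """Two-sided DeLong test of auc_a - auc_b for paired scores.

    Both score vectors must be measured on the same samples with the
    same labels.  The variance of the difference includes the
    covariance between the two placement-value vectors.  Identical
    score vectors give z = 0, p = 1 by convention; zero estimated
    variance with unequal AUCs is an error.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    y = np.asarray(labels)
    if a.shape != b.shape or a.shape[0] != y.shape[0]:
        raise ValueError("delong_test: scores and labels must be aligned")
    keep = np.isfinite(a) & np.isfinite(b)
    a, b = a[keep], b[keep]
    if y.dtype.kind in "OUS":
        y = np.array([str(v).upper() == "CANCER" for v in y])
    y = y.astype(bool)[keep]
    m, n = int(y.sum()), int((~y).sum())
    if m == 0 or n == 0:
        raise ValueError("delong_test: both classes must be present")
    auc_a, v10a, v01a = _placements(a, y)
    auc_b, v10b, v01b = _placements(b, y)
    if np.array_equal(a, b):
        return DeLongResult(auc_a, auc_b, 0.0, 0.0, 1.0, m, n)
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n
    var = float(max(var, 0.0))
    diff = auc_a - auc_b
    if var == 0.0:
        if abs(diff) < 1e-14:
            return DeLongResult(auc_a, auc_b, 0.0, 0.0, 1.0, m, n)
        raise ValueError("delong_test: zero variance estimate with unequal AUCs")
    z = diff / np.sqrt(var)
    p = float(2.0 * stats.norm.sf(abs(z)))
    return DeLongResult(auc_a, auc_b, var, float(z), min(p, 1.0), m, n)


def bootstrap_auc_test(
    scores_a,
    scores_b,
    labels,
    reps: int = 2000,
    seed: int | None = None,
    method: str = "normal",
) -> float:
    """Stratified paired bootstrap test of auc_a - auc_b.

    Cases and controls are resampled separately (so no resample is
    degenerate), with the same indices applied to both score vectors to
    preserve pairing.  ``method='normal'`` converts the observed
    difference to a z statistic using the bootstrap SE;
    ``method='signflip'`` uses twice the smaller tail proportion of the
    bootstrap distribution around zero.  Deterministic given ``seed``.
    """
    if reps < 100:
        raise ValueError("bootstrap_auc_test: reps must be >= 100")
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    y = np.asarray(labels)
    if y.dtype.kind in "OUS":
        y = np.array([str(v).upper() == "CANCER" for v in y])
    y = y.astype(bool)
    keep = np.isfinite(a) & np.isfinite(b)
    a, b, y = a[keep], b[keep], y[keep]
    if np.array_equal(a, b):
        return 1.0
    pos_idx = np.flatnonzero(y)
    neg_idx = np.flatnonzero(~y)
    if pos_idx.size == 0 or neg_idx.size == 0:
        raise ValueError("bootstrap_auc_test: both classes must be present")
    rng = np.random.default_rng(seed)
    obs = auc_mann_whitney(a, y) - auc_mann_whitney(b, y)
    diffs = np.empty(reps)
    for r in range(reps):
        pi = rng.choice(pos_idx, pos_idx.size, replace=True)
        ni = rng.choice(neg_idx, neg_idx.size, replace=True)
        idx = np.concatenate([pi, ni])
        yy = np.concatenate([np.ones(pi.size, bool), np.zeros(ni.size, bool)])
        diffs[r] = auc_mann_whitney(a[idx], yy) - auc_mann_whitney(b[idx], yy)
    if method == "normal":
        se = diffs.std(ddof=1)
        if se == 0.0:
            return 1.0 if obs == 0.0 else 0.0
        z = obs / se
        return float(min(2.0 * stats.norm.sf(abs(z)), 1.0))
    if method == "signflip":
        lo = (np.sum(diffs < 0) + 0.5 * np.sum(diffs == 0)) / reps
        hi = (np.sum(diffs > 0) + 0.5 * np.sum(diffs == 0)) / reps
        return float(min(2.0 * min(lo, hi), 1.0))
    raise ConfigError(f"unknown bootstrap method {method!r}")


# ---------------------------------------------------------------------------
# panel enumeration


def panel_sweep(
    ztable: pd.DataFrame,
    labels,
    candidate: str,
    clinical: list[str],
) -> pd.DataFrame:
    """AUC ranking of a candidate marker alone and with clinical partners.

    Evaluates the candidate alone, each clinical marker alone, and the
    candidate combined with every non-empty subset of the clinical
    markers, returning one row per panel sorted by descending AUC.
    """
    names = [candidate] + list(clinical)
    unknown = [m for m in names if m not in ztable.columns]
    if unknown:
        raise ConfigError(f"panel_sweep: unknown marker(s) {unknown}")
    panels: list[tuple[str, ...]] = [(candidate,)] + [(c,) for c in clinical]
    for k in range(1, len(clinical) + 1):
        for combo in itertools.combinations(clinical, k):
            panels.append((candidate, *combo))
    rows = []
    for panel in panels:
        score = composite_score(ztable, list(panel))
        res = roc_curve(score, labels)
        rows.append(
            {
                "panel": " + ".join(panel),
                "size": len(panel),
                "auc": res.auc,
                "n_pos": res.n_pos,
                "n_neg": res.n_neg,
                "n_excluded": res.n_excluded,
            }
        )
    return (
        pd.DataFrame(rows)
        .sort_values(["auc", "panel"], ascending=[False, True], kind="mergesort")
        .reset_index(drop=True)
    )


def delong_comparison_matrix(ztable: pd.DataFrame, labels,
                             panels: dict[str, list[str]]) -> pd.DataFrame:
    """Pairwise DeLong comparison of named panels.

    Returns a long-format frame with one row per ordered pair
    (delta_auc = auc_a - auc_b, z, p); the test is antisymmetric so
    only unordered pairs are listed once, in the given panel order.
    """
    scores = {name: composite_score(ztable, mk) for name, mk in panels.items()}
    names = list(panels)
    rows = []
    for i, na in enumerate(names):
        for nb in names[i + 1:]:
            res = delong_test(scores[na], scores[nb], labels)
            rows.append(
                {
                    "panel_a": na,
                    "panel_b": nb,
                    "auc_a": res.auc_a,
                    "auc_b": res.auc_b,
                    "delta_auc": res.auc_a - res.auc_b,
                    "z": res.z_statistic,
                    "p": res.p,
                }
            )
    return pd.DataFrame(rows)
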