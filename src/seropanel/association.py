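"""Inter-marker correlation, positivity overlap, and stage stratification.

Spearman rank correlation across antibody markers and clinical analyte
values characterizes whether a candidate marker carries independent
information; the positivity-overlap (Venn region) report shows how many
cancer patients each marker catches that the others miss; Dukes-stage
stratification splits the cancer cohort into early (A, B) and advanced
(C, D) disease for re-analysis against the common HD control group.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

from .cohort import Cohort
from .errors import ConfigError

#: clinical analyte columns entering the correlation matrix as continuous
#: values (Spearman needs paired measurements, not binary status)
CLINICAL_VALUE_COLUMNS = {"CEA": "cea_value", "CA19-9": "ca199_value"}


@dataclass(frozen=True)
class CorrelationMatrix:
    """Pairwise-complete Spearman correlations with per-cell n."""

    rho: pd.DataFrame
    n: pd.DataFrame

    @property
    def markers(self) -> list[str]:
        return list(self.rho.columns)


def spearman_matrix(
    cohort: Cohort,
    markers: list[str] | None = None,
    include_clinical: bool = True,
    min_pairs: int = 3,
) -> CorrelationMatrix:
    """Midrank Spearman correlation across markers, pairwise complete.

    Cells backed by fewer than ``min_pairs`` complete pairs are set to
    NaN (flagged missing).  Clinical analytes enter as continuous
    values when present; analytes with no values are skipped.
    """
    cols = {m: cohort.net[m] for m in (markers or cohort.markers)}
    if include_clinical:
        for name, src in CLINICAL_VALUE_COLUMNS.items():
            vals = pd.to_numeric(cohort.samples[src], errors="coerce")
            if vals.notna().sum() >= min_pairs:
                cols[name] = vals
    data = pd.DataFrame(cols, index=cohort.samples.index)
    rho = data.corr(method="spearman", min_periods=min_pairs)
    notna = data.notna().astype(int)
    n = notna.T @ notna
    np.fill_diagonal(rho.to_numpy(), 1.0)
    return CorrelationMatrix(rho=rho, n=n)


def overlap_report(calls: pd.DataFrame) -> pd.DataFrame:
    """Exact Venn region counts over the power set of selected markers.

    ``calls`` is a boolean frame (samples x markers, at most 6 markers;
    missing calls count as negative).  Returns one row per region of
    the Venn diagram -- the set of samples positive for exactly that
    marker combination -- including the all-negative region.  Region
    counts over the positive regions sum to the number of samples
    positive for at least one marker, and per-marker totals equal the
    column sums of ``calls``.
    """
    markers = list(calls.columns)
    if len(markers) > 6:
        raise ConfigError(f"overlap_report: at most 6 markers (got {len(markers)})")
    if not markers:
        raise ConfigError("overlap_report: no markers given")
    c = calls.fillna(False).astype(bool)
    rows = []
    for pattern in product([True, False], repeat=len(markers)):
        mask = np.ones(len(c), dtype=bool)
        for m, want in zip(markers, pattern):
            mask &= c[m].to_numpy() == want
        members = [m for m, want in zip(markers, pattern) if want]
        rows.append(
            {
                "region": " & ".join(members) if members else "(none)",
                "n_markers": len(members),
                "count": int(mask.sum()),
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["marker_totals"] = {m: int(c[m].sum()) for m in markers}
    return out


@dataclass(frozen=True)
class StageSplit:
    """Early/advanced partition of the cancer cohort by Dukes stage."""

    early_ids: list[str]  # Dukes A, B
    advanced_ids: list[str]  # Dukes C, D
    excluded_ids: list[str]  # stage ND or missing

    @property
    def n_excluded(self) -> int:
        return len(self.excluded_ids)


def stratify_by_stage(cohort: Cohort) -> StageSplit:
    """Partition cancer samples into early (A, B) and advanced (C, D).

    Samples with ND or missing stage are excluded from stratified
    analyses (but remain in whole-cohort analyses).  Raises if no
    cancer sample carries a usable stage.
    """
    cancer = cohort.samples[cohort.samples["group"] == "CANCER"]
    stage = cancer["dukes_stage"]
    early = list(cancer.index[stage.isin(["A", "B"])])
    advanced = list(cancer.index[stage.isin(["C", "D"])])
    excluded = [i for i in cancer.index if i not in set(early) | set(advanced)]
    if not early and not advanced:
        raise ValueError("stratify_by_stage: no cancer sample has a usable Dukes stage")
    return StageSplit(early, advanced, excluded)


def stage_subcohort(cohort: Cohort, cancer_ids) -> Cohort:
    """Sub-cohort with the full HD set plus the given cancer samples.

    Cutoff models and Z references must still be fitted once on the
    full HD set so that positivity calls never change across strata.
    """
    ids = cohort.hd_ids() + list(cancer_ids)
    return cohort.subset(ids)
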