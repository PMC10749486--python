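"""End-to-end analysis pipeline and report rendering.

``run_pipeline`` ties the modules together: load or simulate a cohort,
fit HD cutoffs, call positivity, and write the full report bundle --
positivity table, accuracy table, correlation matrix, overlap report,
AUC ranking, pairwise DeLong comparisons, and stage-stratified
variants -- plus a JSON manifest with the seed, package version and
SHA-256 digest of every artifact.  The bundle is a pure function of the
run configuration: identical config (seed included) gives byte-identical
files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .accuracy import AccuracyReport, Table2x2, accuracy_report
from .association import (
    overlap_report,
    spearman_matrix,
    stage_subcohort,
    stratify_by_stage,
)
from .cohort import Cohort, read_cohort, write_cohort
from .errors import ConfigError
from .positivity import (
    call_matrix,
    clinical_association_table,
    fit_cutoffs,
    positivity_table,
)
from .roc import delong_comparison_matrix, panel_sweep, zscore_table
from .simulate import SyntheticConfig, crc_like_config, generate

log = logging.getLogger("seropanel")

#: default clinical partners for panel sweeps
DEFAULT_CLINICAL = ("CEA", "CA19-9", "p53Ab")


@dataclass
class RunConfig:
    """Everything a pipeline run depends on.

    Exactly one of ``input_path`` / ``synthetic`` must be set.  ``seed``
    drives every stochastic step (simulation, bootstrap); sub-seeds are
    split from it so partial reruns stay reproducible.
    """

    out_dir: Path
    input_path: Path | None = None
    synthetic: SyntheticConfig | None = None
    candidate: str | None = None  # lead marker for panel sweeps; default: first
    clinical: tuple[str, ...] = DEFAULT_CLINICAL
    bootstrap_reps: int = 2000
    seed: int = 0

    def __post_init__(self):
        if (self.input_path is None) == (self.synthetic is None):
            raise ConfigError("exactly one of input_path or synthetic must be given")
        self.out_dir = Path(self.out_dir)


# ---------------------------------------------------------------------------
# rendering helpers


def format_estimate_ci(est: float, lo: float, hi: float, percent: bool = True) -> str:
    """Render "est (lo-hi)" the way clinical accuracy tables print it.

    Percentages to one decimal place with an en dash between the
    bounds, e.g. ``12.2 (7.0–20.6)``.
    """
    scale = 100.0 if percent else 1.0
    return f"{est * scale:.1f} ({lo * scale:.1f}–{hi * scale:.1f})"


def _fmt_or(x: float) -> str:
    return "inf" if x != x or x == float("inf") else f"{x:.1f}"


def render_accuracy_row(marker: str, rep: AccuracyReport) -> dict[str, str]:
    return {
        "marker": marker,
        "sn": format_estimate_ci(rep.sn, *rep.sn_ci),
        "sp": format_estimate_ci(rep.sp, *rep.sp_ci),
        "ppv": format_estimate_ci(rep.ppv, *rep.ppv_ci),
        "npv": format_estimate_ci(rep.npv, *rep.npv_ci),
        "lr_plus": _fmt_or(rep.lr_plus),
        "dor": f"{_fmt_or(rep.dor)} ({_fmt_or(rep.dor_ci[0])}–{_fmt_or(rep.dor_ci[1])})",
    }


def _accuracy_machine_row(marker: str, rep: AccuracyReport) -> dict:
    return {
        "marker": marker,
        "tp": rep.table.tp, "fp": rep.table.fp,
        "fn": rep.table.fn, "tn": rep.table.tn,
        "sn": rep.sn, "sn_lo": rep.sn_ci[0], "sn_hi": rep.sn_ci[1],
        "sp": rep.sp, "sp_lo": rep.sp_ci[0], "sp_hi": rep.sp_ci[1],
        "ppv": rep.ppv, "ppv_lo": rep.ppv_ci[0], "ppv_hi": rep.ppv_ci[1],
        "npv": rep.npv, "npv_lo": rep.npv_ci[0], "npv_hi": rep.npv_ci[1],
        "lr_plus": rep.lr_plus,
        "dor": rep.dor, "dor_lo": rep.dor_ci[0], "dor_hi": rep.dor_ci[1],
    }


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    path.write_text(df.to_csv(sep="\t", index=index), encoding="utf-8")


# ---------------------------------------------------------------------------
# the pipeline


def analyze_cohort(cohort: Cohort, candidate: str | None = None,
                   clinical: tuple[str, ...] = DEFAULT_CLINICAL) -> dict:
    """Run the full analysis in memory; returns a dict of result frames."""
    models = fit_cutoffs(cohort)
    calls = call_matrix(cohort, models)
    pos_table = positivity_table(cohort, models)
    labels = cohort.samples["group"]

    reports = {
        m: accuracy_report(
            Table2x2.from_calls(calls[m], labels == "CANCER")
        )
        for m in cohort.markers
    }
    acc_machine = pd.DataFrame([_accuracy_machine_row(m, r) for m, r in reports.items()])
    acc_rendered = pd.DataFrame([render_accuracy_row(m, r) for m, r in reports.items()])

    corr = spearman_matrix(cohort)
    cancer_calls = calls.loc[cohort.cancer_ids(), cohort.markers[:6]]
    overlap = overlap_report(cancer_calls)
    assoc = clinical_association_table(cohort, calls)

    ztable = zscore_table(cohort, models)
    cand = candidate or cohort.markers[0]
    clin = tuple(c for c in clinical if c in ztable.columns)
    sweep = panel_sweep(ztable, labels, cand, list(clin))
    panels = {cand: [cand]}
    panels.update({c: [c] for c in clin})
    panels[f"{cand} + " + " + ".join(clin)] = [cand, *clin] if clin else [cand]
    delong = delong_comparison_matrix(ztable, labels, panels)

    # stage-stratified sweeps against the common HD control group,
    # reusing the whole-cohort cutoff models and Z references
    strata = {}
    try:
        split = stratify_by_stage(cohort)
        for name, ids in (("early", split.early_ids), ("advanced", split.advanced_ids)):
            if not ids:
                continue
            sub = stage_subcohort(cohort, ids)
            sub_z = ztable.loc[sub.sample_ids]
            sub_labels = sub.samples["group"]
            strata[name] = panel_sweep(sub_z, sub_labels, cand, list(clin))
        if split.n_excluded:
            log.info("stage stratification: %d cancer sample(s) excluded (ND stage)",
                     split.n_excluded)
    except ValueError:
        log.info("stage stratification skipped: no staged cancer samples")

    return {
        "models": models,
        "calls": calls,
        "positivity": pos_table,
        "accuracy_reports": reports,
        "accuracy": acc_machine,
        "accuracy_rendered": acc_rendered,
        "correlation": corr,
        "overlap": overlap,
        "clinical_association": assoc,
        "ztable": ztable,
        "auc_ranking": sweep,
        "delong": delong,
        "stage_ranking": strata,
    }


def run_pipeline(run: RunConfig) -> dict[str, Path]:
    """Execute a run and write the report bundle; returns artifact paths."""
    out = run.out_dir
    out.mkdir(parents=True, exist_ok=True)
    if run.synthetic is not None:
        cohort = generate(run.synthetic)
        input_digest = hashlib.sha256(
            json.dumps(run.synthetic.to_dict(), sort_keys=True).encode()
        ).hexdigest()
        write_cohort(cohort, out / "cohort.tsv")
    else:
        cohort = read_cohort(run.input_path)
        input_digest = hashlib.sha256(Path(run.input_path).read_bytes()).hexdigest()

    res = analyze_cohort(cohort, run.candidate, run.clinical)

    paths: dict[str, Path] = {}

    def emit(name: str, df: pd.DataFrame, index: bool = False):
        p = out / name
        _write_tsv(df, p, index=index)
        paths[name] = p

    emit("positivity.tsv", res["positivity"], index=True)
    emit("accuracy.tsv", res["accuracy"])
    emit("accuracy_rendered.tsv", res["accuracy_rendered"])
    emit("correlation.tsv", res["correlation"].rho, index=True)
    emit("overlap.tsv", res["overlap"])
    emit("auc_ranking.tsv", res["auc_ranking"])
    emit("delong.tsv", res["delong"])
    for name, frame in res["stage_ranking"].items():
        emit(f"auc_ranking_{name}.tsv", frame)

    manifest = {
        "seropanel_version": __version__,
        "seed": run.seed,
        "input_digest": input_digest,
        "artifacts": {
            name: hashlib.sha256(p.read_bytes()).hexdigest()
            for name, p in sorted(paths.items())
        },
    }
    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    paths["manifest.json"] = mpath
    return paths


def default_run(out_dir, seed: int = 0) -> RunConfig:
    """Convenience: a run over the bundled CRC-like synthetic cohort."""
    return RunConfig(
        out_dir=Path(out_dir),
        synthetic=crc_like_config(seed=seed),
        candidate="FIRdexon2",
        seed=seed,
    )
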