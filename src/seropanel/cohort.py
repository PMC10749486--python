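"""Cohort I/O and validation.

A cohort is a case-control immunoassay study: one row per serum sample
(healthy donor or cancer patient) with clinical metadata, plus a
sample x marker matrix of AlphaLISA counts.  Net antibody signal for a
marker is the count measured against the GST-fusion antigen minus the
count against the GST-only control; files may carry either the raw pair
(``<marker>_fusion`` / ``<marker>_gst``) or a precomputed
``<marker>_net`` column.

Tables are plain UTF-8 CSV/TSV, one row per sample, wide marker columns
-- the natural shape of a 384-well panel export.  Missing values are
empty cells; ``N.D.`` (not determined) stage strings map to the ``ND``
category.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import CohortValidationError, ConfigError, InputError, SchemaError

GROUPS = ("HD", "CANCER")
SEXES = ("M", "F", "unknown")
STAGES = ("A", "B", "C", "D", "ND")
TERNARY = ("pos", "neg")

#: metadata columns in canonical write order (after sample_id)
META_COLUMNS = (
    "group",
    "sex",
    "age",
    "dukes_stage",
    "cea_positive",
    "ca199_positive",
    "p53ab_positive",
    "cea_value",
    "ca199_value",
)

_ND_STRINGS = {"nd", "n.d.", "n.d", "not determined"}


@dataclass
class Cohort:
    """Samples x markers measurement table plus per-sample metadata.

    Attributes
    ----------
    samples : pandas.DataFrame
        Indexed by ``sample_id``; columns are :data:`META_COLUMNS`.
    net : pandas.DataFrame
        Net Alpha counts (fusion minus GST control), indexed like
        ``samples``, one column per marker.  May be negative.
    fusion, gst : pandas.DataFrame or None
        Raw counts when the source carried them; ``None`` when only net
        counts were available.
    provenance : dict
        Free-text metadata (source file, generator seed, ...).
    """

    samples: pd.DataFrame
    net: pd.DataFrame
    fusion: pd.DataFrame | None = None
    gst: pd.DataFrame | None = None
    provenance: dict = field(default_factory=dict)

    @property
    def markers(self) -> list[str]:
        return list(self.net.columns)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.samples.index)

    def group_mask(self, group: str) -> pd.Series:
        if group not in GROUPS:
            raise ConfigError(f"unknown group {group!r}; expected one of {GROUPS}")
        return self.samples["group"] == group

    def hd_ids(self) -> list[str]:
        return list(self.samples.index[self.samples["group"] == "HD"])

    def cancer_ids(self) -> list[str]:
        return list(self.samples.index[self.samples["group"] == "CANCER"])

    def subset(self, sample_ids) -> "Cohort":
        """Row-subset preserving column structure and provenance."""
        ids = list(sample_ids)
        return Cohort(
            samples=self.samples.loc[ids].copy(),
            net=self.net.loc[ids].copy(),
            fusion=None if self.fusion is None else self.fusion.loc[ids].copy(),
            gst=None if self.gst is None else self.gst.loc[ids].copy(),
            provenance=dict(self.provenance),
        )

    def equals(self, other: "Cohort") -> bool:
        """Field-by-field equality of samples and measurements."""
        if self.markers != other.markers or self.sample_ids != other.sample_ids:
            return False
        if not self.samples.equals(other.samples):
            return False
        if not _frame_close(self.net, other.net):
            return False
        for a, b in ((self.fusion, other.fusion), (self.gst, other.gst)):
            if (a is None) != (b is None):
                return False
            if a is not None and not _frame_close(a, b):
                return False
        return True


def _frame_close(a: pd.DataFrame, b: pd.DataFrame) -> bool:
    if list(a.columns) != list(b.columns) or len(a) != len(b):
        return False
    av, bv = a.to_numpy(float), b.to_numpy(float)
    both_nan = np.isnan(av) & np.isnan(bv)
    return bool(np.all(both_nan | (av == bv)))


# ---------------------------------------------------------------------------
# parsing helpers


def _norm_stage(x):
    if pd.isna(x) or str(x).strip() == "":
        return pd.NA
    s = str(x).strip()
    if s.lower() in _ND_STRINGS:
        return "ND"
    return s.upper() if s.upper() in STAGES else s


def _norm_ternary(x):
    if pd.isna(x) or str(x).strip() == "":
        return pd.NA
    s = str(x).strip().lower()
    if s in ("pos", "positive", "1", "true", "+"):
        return "pos"
    if s in ("neg", "negative", "0", "false", "-"):
        return "neg"
    return pd.NA  # unparseable optional field -> missing, never zero


def _norm_sex(x):
    if pd.isna(x) or str(x).strip() == "":
        return "unknown"
    s = str(x).strip().upper()
    if s in ("M", "MALE"):
        return "M"
    if s in ("F", "FEMALE"):
        return "F"
    return "unknown"


def _float_series(raw: pd.Series) -> pd.Series:
    """Exact (round-trip) string-to-float parsing; unparseable -> NaN.

    ``pd.to_numeric`` is not guaranteed to round-trip the shortest repr
    of a float64, which would break read(write(c)) == c.
    """

    def conv(s):
        try:
            return float(s)
        except (TypeError, ValueError):
            return np.nan

    return pd.Series([conv(x) for x in raw], index=raw.index, dtype=float)


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","


def read_cohort(path, schema: dict[str, str] | None = None) -> Cohort:
    """Read and validate a cohort table.

    Parameters
    ----------
    path : str or Path
        CSV or TSV file (delimiter chosen from the extension).
    schema : dict, optional
        Maps canonical column names (``sample_id``, ``group``, metadata
        names, ``<marker>_net`` ...) to the column names actually used
        in the file.

    Raises
    ------
    SchemaError
        If a mandatory column (sample_id, group, at least one marker)
        cannot be resolved.
    InputError
        If the file is empty.
    CohortValidationError
        If the parsed cohort violates a structural invariant.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    try:
        df = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise InputError(f"empty cohort file: {path}") from None
    if df.empty:
        raise InputError(f"cohort file has no data rows: {path}")
    if schema:
        rename = {v: k for k, v in schema.items()}
        df = df.rename(columns=rename)
    for col in ("sample_id", "group"):
        if col not in df.columns:
            raise SchemaError(f"mandatory column {col!r} missing from {path.name}")

    # discover markers from wide column names, preserving file order
    fusion_m = [c[: -len("_fusion")] for c in df.columns if c.endswith("_fusion")]
    gst_m = [c[: -len("_gst")] for c in df.columns if c.endswith("_gst")]
    net_m = [c[: -len("_net")] for c in df.columns if c.endswith("_net")]
    paired = [m for m in fusion_m if m in gst_m]
    markers = list(dict.fromkeys(paired + net_m))
    if not markers:
        raise SchemaError(
            "no marker columns found: need '<marker>_fusion'+'<marker>_gst' "
            "pairs or '<marker>_net' columns"
        )
    for m in fusion_m:
        if m not in gst_m:
            raise SchemaError(f"marker {m!r} has a _fusion column but no _gst column")

    ids = df["sample_id"].astype(str).str.strip()
    samples = pd.DataFrame(index=pd.Index(ids, name="sample_id"))
    raw = df.set_index(samples.index)
    samples["group"] = raw["group"].str.strip().str.upper()
    samples["sex"] = [_norm_sex(x) for x in raw.get("sex", pd.Series("", index=raw.index))]
    samples["age"] = pd.to_numeric(
        raw.get("age", pd.Series("", index=raw.index)).replace("", pd.NA), errors="coerce"
    ).astype("Int64")
    samples["dukes_stage"] = [
        _norm_stage(x) for x in raw.get("dukes_stage", pd.Series("", index=raw.index))
    ]
    for col in ("cea_positive", "ca199_positive", "p53ab_positive"):
        samples[col] = [_norm_ternary(x) for x in raw.get(col, pd.Series("", index=raw.index))]
    for col in ("cea_value", "ca199_value"):
        samples[col] = _float_series(raw.get(col, pd.Series("", index=raw.index)))
    samples["dukes_stage"] = samples["dukes_stage"].astype("object")

    def numeric(col):
        return _float_series(raw[col])

    have_raw = bool(paired) and all(m in paired for m in markers)
    fusion = gst = None
    if have_raw:
        fusion = pd.DataFrame({m: numeric(f"{m}_fusion") for m in markers})
        gst = pd.DataFrame({m: numeric(f"{m}_gst") for m in markers})
        net = fusion - gst
        # a _net column, if also present, must agree; prefer the raw pair
    else:
        cols = {}
        for m in markers:
            if f"{m}_net" in df.columns:
                cols[m] = numeric(f"{m}_net")
            else:
                cols[m] = numeric(f"{m}_fusion") - numeric(f"{m}_gst")
        net = pd.DataFrame(cols)

    cohort = Cohort(
        samples=samples,
        net=net,
        fusion=fusion,
        gst=gst,
        provenance={"source": str(path)},
    )
    violations = validate_cohort(cohort)
    fatal = [v for v in violations if v.fatal]
    if fatal:
        raise CohortValidationError("; ".join(v.message for v in fatal))
    return cohort


def write_cohort(cohort: Cohort, path) -> Path:
    """Write a cohort as a normalized CSV/TSV table.

    Deterministic column order, empty string for missing values, floats
    at full (repr) precision so that read(write(c)) == c.
    """
    path = Path(path)
    out = pd.DataFrame(index=cohort.samples.index)
    for col in META_COLUMNS:
        out[col] = cohort.samples[col]
    if cohort.fusion is not None and cohort.gst is not None:
        for m in cohort.markers:
            out[f"{m}_fusion"] = cohort.fusion[m]
            out[f"{m}_gst"] = cohort.gst[m]
    else:
        for m in cohort.markers:
            out[f"{m}_net"] = cohort.net[m]
    buf = io.StringIO()
    out.to_csv(buf, sep=_sep_for(path), na_rep="")
    path.write_text(buf.getvalue(), encoding="utf-8")
    return path


# ---------------------------------------------------------------------------
# validation


@dataclass(frozen=True)
class Violation:
    """One invariant violation found by :func:`validate_cohort`."""

    field: str
    subject: str  # sample id / marker id / "" for cohort-level
    message: str
    fatal: bool = False


def validate_cohort(cohort: Cohort) -> list[Violation]:
    """Check every structural invariant; empty list iff the cohort is valid.

    Reports rather than raises, so callers can surface all problems at
    once.  Violations that make downstream analysis meaningless
    (duplicate ids, dimension mismatch) are marked ``fatal``.
    """
    v: list[Violation] = []
    s = cohort.samples
    ids = s.index.astype(str)

    dup = ids[ids.duplicated()].unique()
    for d in dup:
        v.append(Violation("sample_id", d, f"duplicated sample_id {d!r}", fatal=True))
    for i, sid in enumerate(ids):
        if sid == "" or sid.lower() == "nan":
            v.append(Violation("sample_id", sid, f"empty sample_id at row {i}", fatal=True))

    bad_group = s.index[~s["group"].isin(GROUPS)]
    for sid in bad_group:
        v.append(
            Violation("group", sid, f"sample {sid!r}: group must be one of {GROUPS}", fatal=True)
        )
    for grp in GROUPS:
        if not (s["group"] == grp).any():
            v.append(Violation("group", "", f"cohort has no {grp} samples"))

    hd = s[s["group"] == "HD"]
    staged_hd = hd.index[hd["dukes_stage"].notna() & (hd["dukes_stage"] != "ND")]
    for sid in staged_hd:
        v.append(
            Violation(
                "dukes_stage", sid, f"HD sample {sid!r} carries Dukes stage "
                f"{hd.loc[sid, 'dukes_stage']!r} (must be ND or missing)"
            )
        )
    bad_stage = s.index[s["dukes_stage"].notna() & ~s["dukes_stage"].isin(STAGES)]
    for sid in bad_stage:
        v.append(Violation("dukes_stage", sid, f"sample {sid!r}: unknown stage"))

    neg_age = s.index[s["age"].notna() & (s["age"] < 0)]
    for sid in neg_age:
        v.append(Violation("age", sid, f"sample {sid!r}: negative age"))

    if list(cohort.net.index) != list(s.index):
        v.append(Violation("measurements", "", "measurement rows do not match sample list",
                           fatal=True))
    for frame, name in ((cohort.fusion, "fusion"), (cohort.gst, "gst")):
        if frame is not None and list(frame.columns) != cohort.markers:
            v.append(Violation("measurements", name,
                               f"{name} markers differ from net markers", fatal=True))
    if cohort.fusion is not None and cohort.gst is not None:
        recomputed = cohort.fusion.to_numpy(float) - cohort.gst.to_numpy(float)
        netv = cohort.net.to_numpy(float)
        ok = np.isclose(recomputed, netv, rtol=1e-9, atol=1e-9) | (
            np.isnan(recomputed) & np.isnan(netv)
        )
        if not ok.all():
            bad = np.argwhere(~ok)
            sid = str(s.index[bad[0][0]])
            mk = cohort.markers[bad[0][1]]
            v.append(Violation("net", sid,
                               f"net != fusion - gst for sample {sid!r}, marker {mk!r}"))
    return v


def cohort_from_frames(
    samples: pd.DataFrame,
    net: pd.DataFrame,
    fusion: pd.DataFrame | None = None,
    gst: pd.DataFrame | None = None,
    provenance: dict | None = None,
) -> Cohort:
    """Assemble a cohort from in-memory frames, raising on fatal problems."""
    cohort = Cohort(samples, net, fusion, gst, provenance or {})
    fatal = [x for x in validate_cohort(cohort) if x.fatal]
    if fatal:
        raise CohortValidationError("; ".join(x.message for x in fatal))
    return cohort
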