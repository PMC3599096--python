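"""Longitudinal data model and CSV readers/writers.

Two tabular interfaces carry a glaucoma-style study:

* risk CSV — ``subject_id,group,eye,day,iop_mmHg``: irregular intraocular
  pressure measurements per subject and eye, days counted from the first
  laser induction (day 0).
* degeneration CSV — ``subject_id,eye,region,day,value,n_replicates``: FA
  (or FA-ratio) time series per subject, eye and region.  The value kind
  (quantitative in (0, 1] vs relative affected/fellow ratio) is declared by
  a ``# kind: ...`` comment line at the top of the file or by the caller.

Dialect is fixed: UTF-8, comma separator, ``.`` decimal, mandatory header.
Replicate averaging happens upstream (scans are averaged before tabulation);
``n_replicates`` is carried as metadata only.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RiskSeries",
    "DegenerationSeries",
    "StudyDataset",
    "ParseError",
    "read_risk_csv",
    "write_risk_csv",
    "read_degeneration_csv",
    "write_degeneration_csv",
    "derive_relative_series",
    "write_fit_report",
    "read_fit_report",
]

GROUPS = ("glaucoma", "control")
EYES = ("affected", "fellow")
REGIONS = ("optic_nerve", "optic_radiation", "other")
KINDS = ("quantitative", "relative")


class ParseError(ValueError):
    """Raised for malformed input tables; carries the offending row."""


def _validate_days(days: np.ndarray, context: str) -> None:
    if days.ndim != 1:
        raise ValueError(f"{context}: days must be one-dimensional")
    if days.size and days[0] < 0:
        raise ValueError(f"{context}: days must be >= 0")
    if np.any(np.diff(days) <= 0):
        raise ValueError(f"{context}: days must be strictly increasing")


@dataclass
class RiskSeries:
    """One subject-eye's irregular IOP time series (mmHg vs day)."""

    subject_id: str
    group: str
    eye: str
    days: np.ndarray
    iop: np.ndarray

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.eye not in EYES:
            raise ValueError(f"eye must be one of {EYES}, got {self.eye!r}")
        self.days = np.asarray(self.days, dtype=float)
        self.iop = np.asarray(self.iop, dtype=float)
        if self.days.shape != self.iop.shape:
            raise ValueError("days and iop must have equal length")
        _validate_days(self.days, f"risk series {self.subject_id}/{self.eye}")
        if not np.all(np.isfinite(self.iop)) or np.any(self.iop <= 0):
            raise ValueError(
                f"risk series {self.subject_id}/{self.eye}: IOP must be finite and positive"
            )

    def __len__(self) -> int:
        return self.days.size

    def spans(self, days: np.ndarray) -> bool:
        days = np.asarray(days, dtype=float)
        return bool(days.size == 0 or (days.min() >= self.days[0] and days.max() <= self.days[-1]))


@dataclass
class DegenerationSeries:
    """One subject-eye-region integrity-biomarker (FA) time series."""

    subject_id: str
    eye: str
    region: str
    days: np.ndarray
    values: np.ndarray
    kind: str = "quantitative"
    n_replicates: int = 3

    def __post_init__(self) -> None:
        if self.eye not in EYES:
            raise ValueError(f"eye must be one of {EYES}, got {self.eye!r}")
        if self.region not in REGIONS:
            raise ValueError(f"region must be one of {REGIONS}, got {self.region!r}")
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}, got {self.kind!r}")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        self.days = np.asarray(self.days, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.days.shape != self.values.shape:
            raise ValueError("days and values must have equal length")
        ctx = f"degeneration series {self.subject_id}/{self.eye}/{self.region}"
        _validate_days(self.days, ctx)
        if not np.all(np.isfinite(self.values)) or np.any(self.values <= 0):
            raise ValueError(f"{ctx}: values must be finite and positive")
        if self.kind == "quantitative" and np.any(self.values > 1):
            raise ValueError(f"{ctx}: quantitative values must lie in (0, 1]")

    def __len__(self) -> int:
        return self.days.size


@dataclass
class StudyDataset:
    """A full study: risk series, degeneration series, optional histology.

    Every glaucoma-subject degeneration series must be covered by a matching
    affected-eye risk series spanning its measurement days (the cumulative
    risk cannot be evaluated outside the measured IOP span).
    """

    risk_series: list[RiskSeries] = field(default_factory=list)
    degen_series: list[DegenerationSeries] = field(default_factory=list)
    histology: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        glaucoma_ids = {s.subject_id for s in self.risk_series if s.group == "glaucoma"}
        for d in self.degen_series:
            if d.subject_id not in glaucoma_ids:
                continue
            risk = self.risk_for(d.subject_id, "affected")
            if risk is None or not risk.spans(d.days):
                raise ValueError(
                    f"degeneration series {d.subject_id}/{d.eye}/{d.region} lacks a "
                    "spanning affected-eye risk series"
                )

    def risk_for(self, subject_id: str, eye: str) -> RiskSeries | None:
        for s in self.risk_series:
            if s.subject_id == subject_id and s.eye == eye:
                return s
        return None

    def degen(
        self,
        region: str | None = None,
        kind: str | None = None,
        eye: str | None = None,
        glaucoma_only: bool = False,
    ) -> list[DegenerationSeries]:
        glaucoma_ids = {s.subject_id for s in self.risk_series if s.group == "glaucoma"}
        out = []
        for d in self.degen_series:
            if region is not None and d.region != region:
                continue
            if kind is not None and d.kind != kind:
                continue
            if eye is not None and d.eye != eye:
                continue
            if glaucoma_only and d.subject_id not in glaucoma_ids:
                continue
            out.append(d)
        return out


# ---------------------------------------------------------------------------
# CSV interfaces

_RISK_COLUMNS = ["subject_id", "group", "eye", "day", "iop_mmHg"]
_DEGEN_COLUMNS = ["subject_id", "eye", "region", "day", "value", "n_replicates"]


def _read_table(path: str | Path, columns: list[str], skiprows: int = 0) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep=",", encoding="utf-8", skiprows=skiprows)
    except Exception as exc:  # noqa: BLE001 - rewrap with file context
        raise ParseError(f"{path}: cannot parse CSV ({exc})") from exc
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")
    return df


def _numeric(df: pd.DataFrame, col: str, path: str | Path) -> pd.Series:
    converted = pd.to_numeric(df[col], errors="coerce")
    bad = converted.isna() & df[col].notna() | df[col].isna()
    if bad.any():
        row = int(bad.idxmax()) + 2  # 1-based, plus header line
        raise ParseError(f"{path}: non-numeric {col!r} at line {row}: {df[col][bad.idxmax()]!r}")
    return converted


def read_risk_csv(path: str | Path) -> list[RiskSeries]:
    """Read all per-(subject, eye) IOP series from a risk CSV."""
    df = _read_table(path, _RISK_COLUMNS)
    df = df.copy()
    df["day"] = _numeric(df, "day", path)
    df["iop_mmHg"] = _numeric(df, "iop_mmHg", path)
    dup = df.duplicated(subset=["subject_id", "eye", "day"])
    if dup.any():
        row = int(dup.idxmax()) + 2
        raise ParseError(f"{path}: duplicate (subject, eye, day) at line {row}")
    series = []
    for (sid, eye), grp in df.groupby(["subject_id", "eye"], sort=True):
        grp = grp.sort_values("day")
        groups = grp["group"].unique()
        if len(groups) != 1:
            raise ParseError(f"{path}: inconsistent group labels for subject {sid}")
        series.append(
            RiskSeries(
                subject_id=str(sid),
                group=str(groups[0]),
                eye=str(eye),
                days=grp["day"].to_numpy(),
                iop=grp["iop_mmHg"].to_numpy(),
            )
        )
    return series


def write_risk_csv(series: Iterable[RiskSeries], path: str | Path) -> None:
    rows = [
        (s.subject_id, s.group, s.eye, d, v)
        for s in series
        for d, v in zip(s.days, s.iop)
    ]
    pd.DataFrame(rows, columns=_RISK_COLUMNS).to_csv(path, index=False)


def read_degeneration_csv(path: str | Path, kind: str | None = None) -> list[DegenerationSeries]:
    """Read per-(subject, eye, region) FA series.

    ``kind`` overrides the in-file ``# kind:`` metadata comment; files with
    neither default to quantitative.
    """
    path = Path(path)
    skip = 0
    with open(path, encoding="utf-8") as fh:
        first = fh.readline().strip()
    file_kind = None
    if first.startswith("#"):
        skip = 1
        tag = first.lstrip("#").strip()
        if tag.lower().startswith("kind:"):
            file_kind = tag.split(":", 1)[1].strip()
    resolved = kind or file_kind or "quantitative"
    if resolved not in KINDS:
        raise ParseError(f"{path}: unknown kind {resolved!r}")
    df = _read_table(path, _DEGEN_COLUMNS, skiprows=skip)
    df = df.copy()
    df["day"] = _numeric(df, "day", path)
    df["value"] = _numeric(df, "value", path)
    df["n_replicates"] = _numeric(df, "n_replicates", path)
    dup = df.duplicated(subset=["subject_id", "eye", "region", "day"])
    if dup.any():
        raise ParseError(f"{path}: duplicate (subject, eye, region, day) at line {int(dup.idxmax()) + 2 + skip}")
    series = []
    for (sid, eye, region), grp in df.groupby(["subject_id", "eye", "region"], sort=True):
        grp = grp.sort_values("day")
        try:
            series.append(
                DegenerationSeries(
                    subject_id=str(sid),
                    eye=str(eye),
                    region=str(region),
                    days=grp["day"].to_numpy(),
                    values=grp["value"].to_numpy(),
                    kind=resolved,
                    n_replicates=int(grp["n_replicates"].iloc[0]),
                )
            )
        except ValueError as exc:
            raise ParseError(f"{path}: {exc}") from exc
    return series


def write_degeneration_csv(series: Iterable[DegenerationSeries], path: str | Path) -> None:
    series = list(series)
    kinds = {s.kind for s in series}
    if len(kinds) > 1:
        raise ValueError("cannot mix quantitative and relative series in one file")
    rows = [
        (s.subject_id, s.eye, s.region, d, v, s.n_replicates)
        for s in series
        for d, v in zip(s.days, s.values)
    ]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# kind: {series[0].kind if series else 'quantitative'}\n")
        pd.DataFrame(rows, columns=_DEGEN_COLUMNS).to_csv(fh, index=False)


def derive_relative_series(
    affected: DegenerationSeries, fellow: DegenerationSeries
) -> DegenerationSeries:
    """Affected/fellow ratio series (rFA), the paper-standard normalisation."""
    if affected.subject_id != fellow.subject_id or affected.region != fellow.region:
        raise ValueError("affected and fellow series must share subject and region")
    if not np.array_equal(affected.days, fellow.days):
        raise ValueError("affected and fellow series must share measurement days")
    if np.any(fellow.values <= 0):
        raise ValueError("fellow values must be positive to form a ratio")
    return DegenerationSeries(
        subject_id=affected.subject_id,
        eye="affected",
        region=affected.region,
        days=affected.days.copy(),
        values=affected.values / fellow.values,
        kind="relative",
        n_replicates=affected.n_replicates,
    )


# ---------------------------------------------------------------------------
# Fit report (Table-1-shaped CSV + full-precision JSON sidecar)

_REPORT_COLUMNS = ["model", "N0", "r0", "beta", "gamma", "R2", "P", "F", "df1", "df2", "F_P"]


def _report_rows(results: Sequence, comparisons: Sequence) -> list[dict]:
    comparison_by_full = {id(c.full): c for c in comparisons}
    rows = []
    for res in results:
        row = {c: "" for c in _REPORT_COLUMNS}
        row["model"] = res.spec.name
        p = res.params
        if "n0" in res.spec.free_parameters():
            row["N0"] = p.n0
        row["r0"] = p.r0
        if "beta" in res.spec.free_parameters():
            row["beta"] = p.beta
        if "gamma" in res.spec.free_parameters():
            row["gamma"] = p.gamma
        row["R2"] = res.r2
        row["P"] = res.p_value
        comp = comparison_by_full.get(id(res))
        if comp is not None:
            row["F"] = comp.F
            row["df1"] = comp.df1
            row["df2"] = comp.df2
            row["F_P"] = comp.p_value
        rows.append(row)
    return rows


def write_fit_report(results: Sequence, path: str | Path, comparisons: Sequence = ()) -> None:
    """Write fit results as a Table-1-shaped CSV plus a JSON sidecar.

    The CSV mirrors the conventional parameter-table layout (blank cells for
    fixed/absent parameters); the ``.json`` sidecar keeps full precision and
    round-trips bit-exactly via :func:`read_fit_report`.
    """
    path = Path(path)
    pd.DataFrame(_report_rows(results, comparisons), columns=_REPORT_COLUMNS).to_csv(
        path, index=False
    )
    payload = {
        "results": [_result_to_json(r) for r in results],
        "comparisons": [
            {
                "reduced": c.reduced.spec.name,
                "full": c.full.spec.name,
                "F": c.F,
                "df1": c.df1,
                "df2": c.df2,
                "p_value": c.p_value,
            }
            for c in comparisons
        ],
    }
    path.with_suffix(".json").write_text(json.dumps(payload, indent=2))


def _result_to_json(res) -> dict:
    return {
        "model": res.spec.name,
        "params": dataclasses.asdict(res.params),
        "coupling": dataclasses.asdict(res.coupling) if res.coupling is not None else None,
        "rss": res.rss,
        "tss": res.tss,
        "n": res.n,
        "p_free": res.p_free,
        "r2": res.r2,
        "p_value": res.p_value,
        "flags": list(res.flags),
    }


def read_fit_report(path: str | Path) -> dict:
    """Load the JSON sidecar of a fit report (full precision)."""
    path = Path(path)
    if path.suffix != ".json":
        path = path.with_suffix(".json")
    return json.loads(path.read_text())
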