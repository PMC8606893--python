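"""Longitudinal PK dataset model and I/O in a NONMEM-like tabular dialect.

The in-memory model mirrors therapeutic-drug-monitoring (TDM) practice:
each subject carries a dosing history, a set of measured sirolimus
concentrations, a body weight and any number of extra covariates (age,
albumin, ...).  On disk the dataset is a UTF-8 CSV with the familiar
NONMEM column conventions (ID, TIME, AMT, DV, EVID, MDV, WT) and ``.`` as
the missing-value token; the column names are remappable via a dialect.

Times are hours since each subject's first dose; amounts are mg;
concentrations are ng/ml.  Observations below the assay's lower limit of
quantitation (3.5 ng/ml for the Emit sirolimus immunoassay) are carried
with a BQL flag holding the limit itself, never a measured value.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ASSAY_LOWER_LIMIT",
    "ASSAY_UPPER_LIMIT",
    "DEFAULT_DIALECT",
    "DoseRecord",
    "ObservationRecord",
    "SubjectData",
    "PKDataset",
    "Finding",
    "DatasetError",
    "DialectError",
    "DatasetParseError",
    "DatasetValidationError",
    "read_dataset",
    "write_dataset",
    "validate_dataset",
]

#: Linear range of the Emit 2000 sirolimus assay (ng/ml).
ASSAY_LOWER_LIMIT = 3.5
ASSAY_UPPER_LIMIT = 30.0

#: Logical field -> column name, NONMEM conventions.
DEFAULT_DIALECT: dict[str, str] = {
    "id": "ID",
    "time": "TIME",
    "amt": "AMT",
    "dv": "DV",
    "evid": "EVID",
    "mdv": "MDV",
    "wt": "WT",
    "bql": "BQL",
    "ii": "II",
    "ss": "SS",
}

_REQUIRED_FIELDS = ("id", "time", "amt", "dv", "evid", "wt")
_OPTIONAL_FIELDS = ("mdv", "bql", "ii", "ss")


class DatasetError(Exception):
    """Base class for dataset I/O and validation failures."""


class DialectError(DatasetError):
    """A required column is absent after dialect mapping."""


class DatasetParseError(DatasetError):
    """A cell could not be parsed; carries the offending row index."""


class DatasetValidationError(DatasetError):
    """Structurally invalid dataset (e.g. duplicate observation rows)."""


@dataclass(frozen=True)
class DoseRecord:
    """A single oral dosing event.

    ``interval`` > 0 with ``steady_state`` marks an implied history of
    doses every ``interval`` hours up to and including ``time``.
    """

    time: float
    amount: float
    interval: float = 0.0
    steady_state: bool = False

    def __post_init__(self) -> None:
        if self.amount <= 0:
            raise ValueError(f"dose amount must be positive, got {self.amount}")
        if self.time < 0:
            raise ValueError(f"dose time must be nonnegative, got {self.time}")
        if self.interval < 0:
            raise ValueError(f"dose interval must be nonnegative, got {self.interval}")
        if self.steady_state and self.interval <= 0:
            raise ValueError("steady-state dose record requires a positive interval")


@dataclass(frozen=True)
class ObservationRecord:
    """A measured concentration; BQL records carry the quantitation limit."""

    time: float
    concentration: float
    bql: bool = False

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError(f"observation time must be nonnegative, got {self.time}")
        if not self.bql and self.concentration < 0:
            raise ValueError(
                f"concentration must be nonnegative, got {self.concentration}"
            )


@dataclass
class SubjectData:
    """One subject's dosing history, observations and covariates."""

    subject_id: str
    weight: float
    doses: list[DoseRecord] = field(default_factory=list)
    observations: list[ObservationRecord] = field(default_factory=list)
    covariates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.observations and not self.doses:
            raise ValueError(
                f"subject {self.subject_id!r} has observations but no doses"
            )
        self.doses = sorted(self.doses, key=lambda d: d.time)
        self.observations = sorted(self.observations, key=lambda o: o.time)


@dataclass
class PKDataset:
    """An ordered cohort of subjects."""

    subjects: list[SubjectData] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise DatasetValidationError(f"duplicate subject ids: {dupes}")

    @property
    def subject_ids(self) -> list[str]:
        return [s.subject_id for s in self.subjects]

    @property
    def n_observations(self) -> int:
        return sum(len(s.observations) for s in self.subjects)

    def __len__(self) -> int:
        return len(self.subjects)

    def __iter__(self):
        return iter(self.subjects)


@dataclass(frozen=True)
class Finding:
    """One validation finding: machine-readable, never raised."""

    severity: str  # "error" | "warning"
    subject_id: str | None
    code: str
    message: str


def _resolve_dialect(dialect: Mapping[str, str] | None) -> dict[str, str]:
    d = dict(DEFAULT_DIALECT)
    if dialect:
        d.update(dialect)
    return d


def _numeric(df: pd.DataFrame, col: str) -> pd.Series:
    raw = df[col]
    out = np.empty(len(raw))
    # builtin float() parses exactly (correctly rounded), unlike the fast
    # csv float path, so written repr values round-trip bit-identically
    for i, v in enumerate(raw.to_numpy()):
        if v is None or (isinstance(v, float) and np.isnan(v)):
            out[i] = np.nan
            continue
        try:
            out[i] = float(v)
        except (TypeError, ValueError):
            raise DatasetParseError(
                f"non-numeric value {v!r} in column {col!r} at data row {i}"
            ) from None
    return pd.Series(out, index=raw.index)


def read_dataset(path, dialect: Mapping[str, str] | None = None) -> PKDataset:
    """Read a NONMEM-convention CSV into a :class:`PKDataset`.

    Dose rows are EVID=1; observation rows are EVID=0 with MDV=0.  Any
    column that is neither a dialect column nor ID is treated as a
    subject-constant extra covariate.
    """
    d = _resolve_dialect(dialect)
    df = pd.read_csv(path, na_values=["."], dtype=object, skipinitialspace=True)
    for f in _REQUIRED_FIELDS:
        if d[f] not in df.columns:
            raise DialectError(f"required column {d[f]!r} (field {f!r}) is missing")

    time = _numeric(df, d["time"])
    amt = _numeric(df, d["amt"])
    dv = _numeric(df, d["dv"])
    evid = _numeric(df, d["evid"]).fillna(0).astype(int)
    wt = _numeric(df, d["wt"])
    mdv = (
        _numeric(df, d["mdv"]).fillna(0).astype(int)
        if d["mdv"] in df.columns
        else pd.Series(0, index=df.index)
    )
    bql = (
        _numeric(df, d["bql"]).fillna(0).astype(int)
        if d["bql"] in df.columns
        else pd.Series(0, index=df.index)
    )
    ii = _numeric(df, d["ii"]) if d["ii"] in df.columns else pd.Series(np.nan, index=df.index)
    ss = (
        _numeric(df, d["ss"]).fillna(0).astype(int)
        if d["ss"] in df.columns
        else pd.Series(0, index=df.index)
    )

    known = {d[f] for f in _REQUIRED_FIELDS + _OPTIONAL_FIELDS if d[f] in df.columns}
    extra_cols = [c for c in df.columns if c not in known and c != d["id"]]
    extras = {c: _numeric(df, c) for c in extra_cols}

    ids = df[d["id"]].astype(str)
    seen_obs: set[tuple[str, float]] = set()
    subjects: list[SubjectData] = []
    order: dict[str, int] = {}
    doses_by: dict[str, list[DoseRecord]] = {}
    obs_by: dict[str, list[ObservationRecord]] = {}
    wt_by: dict[str, float] = {}
    cov_by: dict[str, dict[str, float]] = {}

    for i in df.index:
        sid = ids.iloc[i]
        if sid not in order:
            order[sid] = len(order)
            doses_by[sid] = []
            obs_by[sid] = []
            wt_by[sid] = float(wt.iloc[i])
            cov_by[sid] = {
                c: float(extras[c].iloc[i])
                for c in extra_cols
                if not pd.isna(extras[c].iloc[i])
            }
        ev = int(evid.iloc[i])
        t = float(time.iloc[i])
        if ev == 1:
            doses_by[sid].append(
                DoseRecord(
                    time=t,
                    amount=float(amt.iloc[i]),
                    interval=0.0 if pd.isna(ii.iloc[i]) else float(ii.iloc[i]),
                    steady_state=bool(ss.iloc[i]),
                )
            )
        elif ev == 0 and int(mdv.iloc[i]) == 0:
            key = (sid, t)
            if key in seen_obs:
                raise DatasetValidationError(
                    f"duplicate observation row for subject {sid!r} at TIME={t}"
                )
            seen_obs.add(key)
            obs_by[sid].append(
                ObservationRecord(
                    time=t,
                    concentration=float(dv.iloc[i]),
                    bql=bool(bql.iloc[i]),
                )
            )

    for sid in sorted(order, key=order.get):
        subjects.append(
            SubjectData(
                subject_id=sid,
                weight=wt_by[sid],
                doses=doses_by[sid],
                observations=obs_by[sid],
                covariates=cov_by[sid],
            )
        )
    return PKDataset(subjects=subjects)


def write_dataset(ds: PKDataset, path, dialect: Mapping[str, str] | None = None) -> None:
    """Write a dataset in the same dialect :func:`read_dataset` accepts.

    Numeric fields are written at full precision (Python repr), so a
    read/write round trip is bit-exact.
    """
    d = _resolve_dialect(dialect)
    cov_names: list[str] = []
    for s in ds.subjects:
        for c in s.covariates:
            if c not in cov_names:
                cov_names.append(c)
    cols = [d[f] for f in ("id", "time", "amt", "dv", "evid", "mdv", "wt", "bql", "ii", "ss")]
    cols += cov_names
    rows: list[dict] = []
    for s in ds.subjects:
        events: list[tuple[float, int, dict]] = []
        for rec in s.doses:
            events.append(
                (
                    rec.time,
                    1,
                    {
                        d["amt"]: rec.amount,
                        d["dv"]: ".",
                        d["evid"]: 1,
                        d["mdv"]: 1,
                        d["bql"]: 0,
                        d["ii"]: rec.interval if rec.interval > 0 else ".",
                        d["ss"]: int(rec.steady_state),
                    },
                )
            )
        for rec in s.observations:
            events.append(
                (
                    rec.time,
                    0,
                    {
                        d["amt"]: ".",
                        d["dv"]: rec.concentration,
                        d["evid"]: 0,
                        d["mdv"]: 0,
                        d["bql"]: int(rec.bql),
                        d["ii"]: ".",
                        d["ss"]: 0,
                    },
                )
            )
        # doses first at equal times so a trough at a dose instant reads back
        # in a stable order
        events.sort(key=lambda e: (e[0], -e[1]))
        for t, _, payload in events:
            row = {d["id"]: s.subject_id, d["time"]: t, d["wt"]: s.weight}
            row.update(payload)
            for c in cov_names:
                row[c] = s.covariates.get(c, ".")
            rows.append(row)

    def fmt(v) -> str:
        # repr of builtin float is the shortest exactly round-tripping digits
        if isinstance(v, (float, np.floating)):
            return repr(float(v))
        if isinstance(v, (int, np.integer)):
            return str(int(v))
        return str(v)

    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(cols)
        for row in rows:
            writer.writerow([fmt(row[c]) for c in cols])


def validate_dataset(ds: PKDataset) -> list[Finding]:
    """Check a dataset and return findings; never raises, never mutates."""
    findings: list[Finding] = []
    if ds.n_observations == 0:
        findings.append(
            Finding("warning", None, "no-observations", "dataset has no observations")
        )
    for s in ds.subjects:
        if s.weight <= 0:
            findings.append(
                Finding(
                    "error",
                    s.subject_id,
                    "nonpositive-weight",
                    f"weight must be positive, got {s.weight}",
                )
            )
        for seq, label in ((s.doses, "dose"), (s.observations, "observation")):
            times = [r.time for r in seq]
            if any(b < a for a, b in zip(times, times[1:])):
                findings.append(
                    Finding(
                        "error",
                        s.subject_id,
                        "unsorted-times",
                        f"{label} times are not sorted",
                    )
                )
        if s.doses and s.observations:
            first_dose = s.doses[0].time
            for o in s.observations:
                if o.time < first_dose:
                    findings.append(
                        Finding(
                            "error",
                            s.subject_id,
                            "observation-before-dose",
                            f"observation at t={o.time} h precedes first dose "
                            f"at t={first_dose} h",
                        )
                    )
        for o in s.observations:
            if o.bql:
                continue
            if o.concentration < ASSAY_LOWER_LIMIT:
                findings.append(
                    Finding(
                        "warning",
                        s.subject_id,
                        "below-assay-range",
                        f"concentration {o.concentration} ng/ml is below the "
                        f"assay lower limit of linearity {ASSAY_LOWER_LIMIT} ng/ml",
                    )
                )
            elif o.concentration > ASSAY_UPPER_LIMIT:
                findings.append(
                    Finding(
                        "warning",
                        s.subject_id,
                        "above-assay-range",
                        f"concentration {o.concentration} ng/ml is above the "
                        f"assay upper limit of linearity {ASSAY_UPPER_LIMIT} ng/ml",
                    )
                )
    return findings
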