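"""Reading, writing and assembling FAERS-style quarterly ASCII extracts.

A quarter is six ``$``-delimited files with one header line and no quoting
(the FAERS ASCII convention): DEMO (report-level demographics and
administrative fields), DRUG (one row per reported drug, with a role code),
REAC (MedDRA preferred terms), OUTC (outcome codes), THER (therapy start /
end dates per drug) and INDI (indications per drug).

``read_quarter`` keeps every field as its raw string token and adds parsed
date columns; ``assemble_reports`` joins the child files onto DEMO and
yields one :class:`SafetyReport` per DEMO row, degrading unparseable fields
to missing rather than aborting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, Iterator, List, Mapping, Optional, Sequence, Set, Union

import pandas as pd

from .dates import FuzzyDate, parse_faers_date

logger = logging.getLogger(__name__)

__all__ = [
    "FILE_NAMES",
    "ROLE_CODES",
    "OUTCOME_CODES",
    "RawQuarter",
    "DrugUse",
    "SafetyReport",
    "ReportSet",
    "read_quarter",
    "write_quarter",
    "assemble_reports",
    "region_of_country",
    "age_to_years",
]

FILE_NAMES = ("demo", "drug", "reac", "outc", "ther", "indi")

ROLE_CODES = {"PS", "SS", "C", "I"}
OUTCOME_CODES = {"DE", "LT", "HO", "DS", "CA", "RI", "OT"}

#: expected columns per file; the first in each list is the join key
_COLUMNS: Dict[str, List[str]] = {
    "demo": [
        "primaryid", "caseid", "caseversion", "fda_dt", "event_dt",
        "age", "age_cod", "sex", "occp_cod", "occr_country",
    ],
    "drug": ["primaryid", "drug_seq", "role_cod", "drugname", "prod_ai"],
    "reac": ["primaryid", "pt", "pt_cod"],
    "outc": ["primaryid", "outc_cod"],
    "ther": ["primaryid", "dsg_drug_seq", "start_dt", "end_dt"],
    "indi": ["primaryid", "indi_drug_seq", "indi_pt"],
}

_DATE_COLUMNS = {
    "demo": ["fda_dt", "event_dt"],
    "ther": ["start_dt", "end_dt"],
}


def _load_region_map() -> Dict[str, str]:
    text = resources.files("faerspv.data").joinpath("country_continent.tsv").read_text()
    mapping: Dict[str, str] = {}
    for line in text.splitlines()[1:]:
        if line.strip():
            code, region = line.split("\t")
            mapping[code] = region
    return mapping


_REGION_MAP = _load_region_map()


def region_of_country(code: str) -> Optional[str]:
    """Five-region scheme (Europe/America/Asia/Oceania/Africa) from an
    ISO-3166 alpha-2 occurrence-country code; unmapped codes are missing."""
    if not code:
        return None
    return _REGION_MAP.get(str(code).strip().upper())


# age units: conversion factor to years (day-based units use a 365-day year
# so whole multiples of a year convert exactly)
_AGE_FACTORS = {
    "YR": 1.0,
    "DEC": 10.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.0,
    "DY": 1.0 / 365.0,
    "HR": 1.0 / 8760.0,
}

MAX_PLAUSIBLE_AGE = 120.0


def age_to_years(value: str, unit: str) -> Optional[float]:
    """Convert a raw FAERS age value + unit code to years.

    Empty unit is taken as years (the dominant FAERS convention); unknown
    units, negative values and implausible ages (> 120 y) become missing.
    """
    s = str(value).strip()
    if not s:
        return None
    try:
        v = float(s)
    except ValueError:
        return None
    u = str(unit).strip().upper() or "YR"
    factor = _AGE_FACTORS.get(u)
    if factor is None:
        return None
    years = v * factor
    if years < 0 or years > MAX_PLAUSIBLE_AGE:
        logger.warning("implausible age %r %s dropped", value, unit)
        return None
    return years


@dataclass
class RawQuarter:
    """One quarter's six files as raw string DataFrames.

    Columns listed in ``_COLUMNS`` are guaranteed present; date fields keep
    their raw tokens and gain a ``*_parsed`` companion column of
    :class:`~faerspv.dates.FuzzyDate` (or ``None``).
    """

    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    outc: pd.DataFrame
    ther: pd.DataFrame
    indi: pd.DataFrame
    orphan_counts: Dict[str, int] = field(default_factory=dict)

    def frames(self) -> Dict[str, pd.DataFrame]:
        return {name: getattr(self, name) for name in FILE_NAMES}

    def raw_frames(self) -> Dict[str, pd.DataFrame]:
        """Frames restricted to the raw (writable) columns."""
        out = {}
        for name, df in self.frames().items():
            out[name] = df[_COLUMNS[name]].reset_index(drop=True)
        return out

    @property
    def n_reports(self) -> int:
        return len(self.demo)

    def equals(self, other: "RawQuarter") -> bool:
        mine, theirs = self.raw_frames(), other.raw_frames()
        return all(mine[name].equals(theirs[name]) for name in FILE_NAMES)


def _add_parsed_dates(name: str, df: pd.DataFrame) -> int:
    """Attach ``*_parsed`` columns; returns the count of unparseable tokens."""
    bad = 0
    for col in _DATE_COLUMNS.get(name, []):
        parsed = []
        for tok in df[col].tolist():
            p = parse_faers_date(tok)
            if p is None and str(tok).strip():
                bad += 1
            parsed.append(p)
        df[col + "_parsed"] = pd.Series(parsed, dtype=object, index=df.index)
    return bad


def _read_file(name: str, path: Union[str, Path]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="$", dtype=str, keep_default_na=False)
    df.columns = [c.strip().lower() for c in df.columns]
    expected = _COLUMNS[name]
    unknown = [c for c in df.columns if c not in expected]
    if unknown:
        logger.warning("%s: ignoring unknown column(s) %s", path, unknown)
        df = df.drop(columns=unknown)
    for col in expected:
        if col not in df.columns:
            df[col] = ""
    df = df[expected]
    bad = _add_parsed_dates(name, df)
    if bad:
        logger.warning("%s: %d unparseable date token(s) set to missing", path, bad)
    return df


def _locate_files(path: Union[str, Path]) -> Dict[str, Path]:
    path = Path(path)
    found: Dict[str, Path] = {}
    if not path.is_dir():
        raise FileNotFoundError(f"quarter directory not found: {path}")
    for entry in sorted(path.iterdir()):
        stem = entry.name.lower()
        for name in FILE_NAMES:
            if stem.startswith(name) and name not in found:
                found[name] = entry
    missing = [n for n in FILE_NAMES if n not in found]
    if missing:
        raise FileNotFoundError(
            f"missing mandatory quarter file(s) {missing} in {path}"
        )
    return found


def read_quarter(path: Union[str, Path, Mapping[str, Union[str, Path]]]) -> RawQuarter:
    """Read one quarter from a directory (files named DEMO*/DRUG*/...,
    case-insensitive) or an explicit ``{name: path}`` mapping.

    Child rows whose primary id does not appear in DEMO are dropped and
    counted in ``orphan_counts`` (referential integrity is enforced, never
    silently assumed).
    """
    if isinstance(path, Mapping):
        files = {n: Path(p) for n, p in path.items()}
        missing = [n for n in FILE_NAMES if n not in files]
        if missing:
            raise FileNotFoundError(f"missing mandatory quarter file(s) {missing}")
    else:
        files = _locate_files(path)
    frames = {name: _read_file(name, files[name]) for name in FILE_NAMES}
    known = set(frames["demo"]["primaryid"])
    orphans: Dict[str, int] = {}
    for name in FILE_NAMES[1:]:
        df = frames[name]
        keep = df["primaryid"].isin(known)
        dropped = int((~keep).sum())
        if dropped:
            logger.warning("%s: dropped %d orphan row(s)", name, dropped)
            frames[name] = df[keep].reset_index(drop=True)
        orphans[name] = dropped
    for name in ("drug",):
        bad_roles = ~frames[name]["role_cod"].isin(ROLE_CODES | {""})
        if bad_roles.any():
            logger.warning("drug: %d row(s) with unknown role code", int(bad_roles.sum()))
    return RawQuarter(orphan_counts=orphans, **frames)


def write_quarter(quarter: RawQuarter, path: Union[str, Path]) -> Dict[str, Path]:
    """Write the six ``$``-delimited files under ``path``.

    Only raw columns are written, so ``read_quarter(write_quarter(q))``
    reproduces ``q`` field for field, and identical quarters produce
    byte-identical files.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    written: Dict[str, Path] = {}
    for name, df in quarter.raw_frames().items():
        target = path / f"{name.upper()}.txt"
        df.to_csv(target, sep="$", index=False, lineterminator="\n")
        written[name] = target
    return written


@dataclass
class DrugUse:
    """One drug row of a report, with its earliest therapy start."""

    raw_name: str
    active_ingredient: str
    role: str
    seq: str
    start: Optional[FuzzyDate] = None       # earliest start, any precision
    start_day: Optional[FuzzyDate] = None   # earliest day-precision start
    name: Optional[str] = None              # canonical generic, filled later

    @property
    def is_suspect(self) -> bool:
        return self.role in ("PS", "SS")


@dataclass
class SafetyReport:
    """One spontaneous report after joining the six files."""

    case_id: str
    primary_id: str
    case_version: int
    receipt_date: Optional[FuzzyDate]
    event_date: Optional[FuzzyDate]
    age_years: Optional[float]
    sex: Optional[str]                # 'female' | 'male' | None
    region: Optional[str]             # Europe/America/Asia/Oceania/Africa
    reporter: Optional[str]           # 'health-professional' | 'non-health-professional'
    drugs: List[DrugUse] = field(default_factory=list)
    reactions: Set[str] = field(default_factory=set)
    outcomes: Set[str] = field(default_factory=set)
    indications: Set[str] = field(default_factory=set)

    @property
    def report_year(self) -> Optional[int]:
        return self.receipt_date.year if self.receipt_date else None

    def suspect_names(self) -> Set[str]:
        """Canonical names of suspect-role drugs (after normalization)."""
        return {d.name for d in self.drugs if d.is_suspect and d.name}


@dataclass
class ReportSet(Sequence):
    """Assembled reports plus the bookkeeping needed to account for every
    input row (reports-in = reports-out + dropped)."""

    reports: List[SafetyReport]
    n_input: int
    n_dropped_no_reaction: int

    def __len__(self) -> int:
        return len(self.reports)

    def __getitem__(self, i):
        return self.reports[i]

    def __iter__(self) -> Iterator[SafetyReport]:
        return iter(self.reports)


_REPORTER_MAP = {
    "MD": "health-professional",
    "PH": "health-professional",
    "OT": "health-professional",
    "HP": "health-professional",
    "CN": "non-health-professional",
    "LW": "non-health-professional",
}

_SEX_MAP = {"F": "female", "M": "male"}


def assemble_reports(quarter: RawQuarter) -> ReportSet:
    """Join child rows onto DEMO rows and build one report per DEMO row.

    Degraded fields become missing; reports with no usable reaction term
    are dropped and counted (a report must describe at least one event).
    """
    ther_starts: Dict[tuple, List[FuzzyDate]] = {}
    for pid, seq, start in zip(
        quarter.ther["primaryid"], quarter.ther["dsg_drug_seq"],
        quarter.ther["start_dt_parsed"],
    ):
        if start is not None:
            ther_starts.setdefault((pid, seq), []).append(start)

    drugs_by_pid: Dict[str, List[DrugUse]] = {}
    for pid, seq, role, name, ai in zip(
        quarter.drug["primaryid"], quarter.drug["drug_seq"],
        quarter.drug["role_cod"], quarter.drug["drugname"],
        quarter.drug["prod_ai"],
    ):
        starts = ther_starts.get((pid, seq), [])
        start = min(starts, key=lambda d: d.sort_key) if starts else None
        day_starts = [d for d in starts if d.precision == "day"]
        start_day = min(day_starts, key=lambda d: d.sort_key) if day_starts else None
        drugs_by_pid.setdefault(pid, []).append(
            DrugUse(raw_name=name, active_ingredient=ai, role=role.strip().upper(),
                    seq=seq, start=start, start_day=start_day)
        )

    reac_by_pid: Dict[str, Set[str]] = {}
    for pid, pt in zip(quarter.reac["primaryid"], quarter.reac["pt"]):
        term = " ".join(str(pt).lower().split())
        if term:
            reac_by_pid.setdefault(pid, set()).add(term)

    outc_by_pid: Dict[str, Set[str]] = {}
    for pid, code in zip(quarter.outc["primaryid"], quarter.outc["outc_cod"]):
        c = str(code).strip().upper()
        if c in OUTCOME_CODES:
            outc_by_pid.setdefault(pid, set()).add(c)

    indi_by_pid: Dict[str, Set[str]] = {}
    for pid, term in zip(quarter.indi["primaryid"], quarter.indi["indi_pt"]):
        t = " ".join(str(term).lower().split())
        if t:
            indi_by_pid.setdefault(pid, set()).add(t)

    reports: List[SafetyReport] = []
    dropped = 0
    demo = quarter.demo
    for pid, caseid, version, fda, event, age, age_cod, sex, occp, country in zip(
        demo["primaryid"], demo["caseid"], demo["caseversion"],
        demo["fda_dt_parsed"], demo["event_dt_parsed"],
        demo["age"], demo["age_cod"], demo["sex"], demo["occp_cod"],
        demo["occr_country"],
    ):
        reactions = reac_by_pid.get(pid, set())
        if not reactions:
            dropped += 1
            continue
        try:
            ver = int(str(version).strip() or "1")
        except ValueError:
            ver = 1
        reports.append(SafetyReport(
            case_id=str(caseid).strip() or str(pid),
            primary_id=str(pid),
            case_version=ver,
            receipt_date=fda,
            event_date=event,
            age_years=age_to_years(age, age_cod),
            sex=_SEX_MAP.get(str(sex).strip().upper()),
            region=region_of_country(country),
            reporter=_REPORTER_MAP.get(str(occp).strip().upper()),
            drugs=drugs_by_pid.get(pid, []),
            reactions=reactions,
            outcomes=outc_by_pid.get(pid, set()),
            indications=indi_by_pid.get(pid, set()),
        ))
    if dropped:
        logger.warning("assemble_reports: dropped %d report(s) with no reactions", dropped)
    return ReportSet(reports=reports, n_input=len(demo), n_dropped_no_reaction=dropped)
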