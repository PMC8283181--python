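"""Case-cohort construction for ICI-associated pericardial toxicity.

The case definition has two legs: the report lists at least one of the 15
MedDRA preferred terms for pericardial disorders among its reactions, and
at least one immune checkpoint inhibitor as a *suspect* drug (role code PS
or SS — concomitant or interacting ICIs never qualify a report).

Reports are first deduplicated to one per case id (FAERS revises cases
over time; only the latest version is analyzable), then classified by
regimen: a single suspect ICI gives that monotherapy, one of the three
marketed pairs gives that combination, and any other multi-ICI suspect set
falls into an "other" bucket.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, FrozenSet, Iterable, List, Optional, Set, Tuple, Union

import pandas as pd

from .io import ReportSet, SafetyReport

logger = logging.getLogger(__name__)

__all__ = [
    "PERICARDIAL_PTS",
    "ICI_DRUGS",
    "ICI_CLASS",
    "Regimen",
    "CaseRecord",
    "CaseCohort",
    "is_pericardial_pt",
    "normalize_drug_name",
    "deduplicate",
    "classify_regimen",
    "label_from_suspects",
    "compute_tto",
    "tto_bin",
    "indication_group",
    "build_cohort",
    "TTO_BINS",
]


def _load_pts() -> Dict[str, str]:
    text = resources.files("faerspv.data").joinpath("pericardial_pts.tsv").read_text()
    entries: Dict[str, str] = {}
    for line in text.splitlines()[1:]:
        if line.strip():
            name, code = line.split("\t")
            entries[name.strip().lower()] = code.strip()
    return entries


def _load_drugs() -> Tuple[Dict[str, str], Dict[str, str]]:
    """Returns (alias -> generic, generic -> target class)."""
    text = resources.files("faerspv.data").joinpath("ici_drugs.tsv").read_text()
    aliases: Dict[str, str] = {}
    classes: Dict[str, str] = {}
    for line in text.splitlines()[1:]:
        if not line.strip():
            continue
        generic, brands, target = line.split("\t")
        generic = generic.strip().lower()
        classes[generic] = target.strip()
        aliases[generic] = generic
        for brand in brands.split(";"):
            brand = brand.strip().lower()
            if brand:
                aliases[brand] = generic
    return aliases, classes


#: pericardial-disorder preferred terms: name -> 8-digit MedDRA code
PERICARDIAL_PTS: Dict[str, str] = _load_pts()
_PT_CODES: Set[str] = set(PERICARDIAL_PTS.values())

_ALIASES, ICI_CLASS = _load_drugs()
ICI_DRUGS: Tuple[str, ...] = tuple(ICI_CLASS)

#: the three marketed ICI pairs reported as combination regimens
_COMBINATIONS: Dict[FrozenSet[str], str] = {
    frozenset({"ipilimumab", "nivolumab"}): "ipilimumab+nivolumab",
    frozenset({"ipilimumab", "pembrolizumab"}): "ipilimumab+pembrolizumab",
    frozenset({"tremelimumab", "durvalumab"}): "tremelimumab+durvalumab",
}

_CLASS_STRATEGY = {
    "PD-1": "anti-PD-1 mono",
    "PD-L1": "anti-PD-L1 mono",
    "CTLA-4": "anti-CTLA-4 mono",
}

#: closed-on-the-left onset bins (days), as rendered in the clinical table
TTO_BINS: Tuple[Tuple[str, int, float], ...] = (
    ("0-30", 0, 30),
    ("31-60", 31, 60),
    ("61-90", 61, 90),
    ("91-180", 91, 180),
    (">180", 181, float("inf")),
)


def is_pericardial_pt(pt: Union[str, int]) -> bool:
    """True iff the preferred-term name (case/whitespace-insensitive) or its
    8-digit MedDRA code belongs to the pericardial-disorder term set."""
    s = " ".join(str(pt).strip().lower().split())
    return s in PERICARDIAL_PTS or s in _PT_CODES


_PAREN_RE = re.compile(r"\([^)]*\)")
_NON_ALPHA_RE = re.compile(r"[^a-z]+")


def normalize_drug_name(raw: str) -> Optional[str]:
    """Map a verbatim drug string to its canonical ICI generic name.

    Parenthetical suffixes, dose text and punctuation are stripped before a
    word-level match against generic and brand names.  Strings that match
    no ICI — or ambiguously match more than one — give ``None``.
    """
    if not raw:
        return None
    s = _PAREN_RE.sub(" ", str(raw).lower())
    words = set(_NON_ALPHA_RE.sub(" ", s).split())
    hits = {_ALIASES[w] for w in words if w in _ALIASES}
    if len(hits) == 1:
        return hits.pop()
    return None


def canonicalize_drugs(report: SafetyReport) -> None:
    """Fill each drug row's canonical name in place (verbatim name first,
    active-ingredient field as fallback)."""
    for d in report.drugs:
        if d.name is None:
            d.name = normalize_drug_name(d.raw_name) or normalize_drug_name(
                d.active_ingredient
            )


def deduplicate(reports: Iterable[SafetyReport]) -> List[SafetyReport]:
    """One report per case id: highest case version wins, ties broken by
    latest receipt date, then highest primary id."""
    best: Dict[str, SafetyReport] = {}

    def rank(r: SafetyReport) -> tuple:
        receipt = r.receipt_date.sort_key if r.receipt_date else (0, 0, 0)
        try:
            pid = int(r.primary_id)
        except ValueError:
            pid = 0
        return (r.case_version, receipt, pid)

    n_in = 0
    for r in reports:
        n_in += 1
        cur = best.get(r.case_id)
        if cur is None or rank(r) > rank(cur):
            best[r.case_id] = r
    kept = list(best.values())
    if n_in != len(kept):
        logger.info("deduplicate: %d report(s) in, %d kept", n_in, len(kept))
    return kept


@dataclass(frozen=True)
class Regimen:
    """An ICI regimen label and the therapeutic strategy it implies."""

    label: str
    strategy: str


def label_from_suspects(suspects: FrozenSet[str]) -> Optional[Regimen]:
    """Regimen from the set of suspect ICI generics; ``None`` if empty."""
    suspects = frozenset(suspects)
    if not suspects:
        return None
    if len(suspects) == 1:
        drug = next(iter(suspects))
        return Regimen(drug, _CLASS_STRATEGY[ICI_CLASS[drug]])
    combo = _COMBINATIONS.get(suspects)
    if combo is not None:
        return Regimen(combo, "combination")
    return Regimen("other-multi-ICI", "other")


def classify_regimen(report: SafetyReport) -> Regimen:
    """Regimen of a report that has at least one suspect ICI."""
    canonicalize_drugs(report)
    regimen = label_from_suspects(frozenset(report.suspect_names()) & set(ICI_DRUGS))
    if regimen is None:
        raise ValueError(
            f"report {report.primary_id} has no suspect ICI; regimen undefined"
        )
    return regimen


def _tto_with_status(report: SafetyReport) -> Tuple[Optional[int], str]:
    event = report.event_date
    if event is None or event.precision != "day":
        return None, "missing"
    starts = [
        d.start_day for d in report.drugs
        if d.is_suspect and d.name in ICI_CLASS and d.start_day is not None
    ]
    if not starts:
        return None, "missing"
    start = min(starts, key=lambda d: d.sort_key)
    days = event - start
    if days < 0:
        return None, "negative"   # incorrect record: onset before therapy start
    return days, "ok"


def compute_tto(report: SafetyReport) -> Optional[int]:
    """Days from the earliest day-precision suspect-ICI therapy start to
    the event date; missing when either operand is absent or coarser than
    day precision, or when the interval is negative (incorrect record)."""
    canonicalize_drugs(report)
    return _tto_with_status(report)[0]


def tto_bin(days: Optional[int]) -> Optional[str]:
    if days is None:
        return None
    for label, lo, hi in TTO_BINS:
        if lo <= days <= hi:
            return label
    return None


def _load_indication_map() -> List[Tuple[str, str]]:
    text = resources.files("faerspv.data").joinpath("indication_groups.tsv").read_text()
    pairs = []
    for line in text.splitlines()[1:]:
        if line.strip():
            keyword, group = line.split("\t")
            pairs.append((keyword.strip().lower(), group.strip()))
    return pairs


_INDICATION_MAP = _load_indication_map()

#: priority when a report maps to several groups (specific before generic)
_GROUP_PRIORITY = [
    "Melanoma", "Lung cancer", "Hematological cancer and lymphoma",
    "Gastrointestinal cancer", "Head and neck cancer", "Breast cancer",
    "Tumors of female reproductive organs", "Mesothelioma",
    "Tumors of urinary system", "Other indications",
    "Non-specified malignant neoplasm",
]
_GROUP_RANK = {g: i for i, g in enumerate(_GROUP_PRIORITY)}


def indication_group(indications: Iterable[str]) -> str:
    """Map a report's indication terms to one clinical-table row label."""
    groups = set()
    for term in indications:
        t = " ".join(str(term).lower().split())
        for keyword, group in _INDICATION_MAP:
            if keyword in t:
                groups.add(group)
                break
    if not groups:
        return "Unknown or missing"
    return min(groups, key=lambda g: _GROUP_RANK.get(g, len(_GROUP_RANK)))


@dataclass
class CaseRecord:
    """One cohort case: the underlying report plus derived analysis fields."""

    report: SafetyReport
    regimen: Regimen
    fatal: bool
    tto_days: Optional[int]
    tto_bin: Optional[str]
    indication_group: str

    # convenience passthroughs used by the clinical-features module
    @property
    def sex(self) -> Optional[str]:
        return self.report.sex

    @property
    def age_years(self) -> Optional[float]:
        return self.report.age_years

    @property
    def region(self) -> Optional[str]:
        return self.report.region

    @property
    def reporter(self) -> Optional[str]:
        return self.report.reporter

    @property
    def report_year(self) -> Optional[int]:
        return self.report.report_year

    @property
    def outcomes(self) -> Set[str]:
        return self.report.outcomes

    @property
    def outcome_known(self) -> bool:
        return bool(self.report.outcomes)


@dataclass
class CaseCohort:
    """The pericardial case set with step-by-step filter provenance."""

    records: List[CaseRecord]
    provenance: Dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rec in self.records:
            rows.append({
                "case_id": rec.report.case_id,
                "primary_id": rec.report.primary_id,
                "regimen": rec.regimen.label,
                "strategy": rec.regimen.strategy,
                "fatal": rec.fatal,
                "outcome_known": rec.outcome_known,
                "tto_days": rec.tto_days,
                "tto_bin": rec.tto_bin,
                "sex": rec.sex,
                "age_years": rec.age_years,
                "region": rec.region,
                "reporter": rec.reporter,
                "report_year": rec.report_year,
                "indication_group": rec.indication_group,
                "reactions": ";".join(sorted(rec.report.reactions)),
                "outcomes": ";".join(sorted(rec.report.outcomes)),
            })
        return pd.DataFrame(rows)


def build_cohort(reports: Union[Iterable[SafetyReport], ReportSet]) -> CaseCohort:
    """Apply the case definition to deduplicated reports.

    Keeps reports with >= 1 pericardial preferred term and >= 1 suspect
    ICI; a report with several pericardial terms still counts once.  Every
    filter step's in/out counts land in the cohort provenance, as does the
    number of negative (incorrect) onset intervals set to missing.
    """
    reports = list(reports)
    n_input = len(reports)
    n_pericardial = 0
    n_negative_tto = 0
    records: List[CaseRecord] = []
    for r in reports:
        if not any(is_pericardial_pt(pt) for pt in r.reactions):
            continue
        n_pericardial += 1
        canonicalize_drugs(r)
        suspects = frozenset(r.suspect_names()) & set(ICI_DRUGS)
        regimen = label_from_suspects(suspects)
        if regimen is None:
            continue
        days, status = _tto_with_status(r)
        if status == "negative":
            n_negative_tto += 1
        records.append(CaseRecord(
            report=r,
            regimen=regimen,
            fatal="DE" in r.outcomes,
            tto_days=days,
            tto_bin=tto_bin(days),
            indication_group=indication_group(r.indications),
        ))
    provenance = {
        "reports_in": n_input,
        "with_pericardial_pt": n_pericardial,
        "with_suspect_ici": len(records),
        "cases": len(records),
        "negative_tto_set_missing": n_negative_tto,
    }
    return CaseCohort(records=records, provenance=provenance)
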