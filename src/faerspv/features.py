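"""Descriptive and comparative clinical analyses of the case cohort.

Reproduces the clinical surface of a pharmacovigilance case series: the
characteristics table (counts and percentages for the total, fatal and
non-fatal columns of nine characteristic blocks), stratified fatality
rates, time-to-onset summaries per regimen, and fatal-vs-non-fatal
hypothesis tests (chi-square for categories, Mann-Whitney for two-group
onset times, Kruskal-Wallis across regimens, t test for normal continuous
variables).

Two denominators coexist by design and are both exposed: table-style
percentages divide by the column total (unknown rows included), while
shares of documented onset times divide by the documented-TTO count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import CaseCohort, CaseRecord, TTO_BINS

__all__ = [
    "pct_half_up",
    "GroupTestResult",
    "TtoSummary",
    "CharacteristicsTable",
    "fatality_rate",
    "summarize_tto",
    "compare_fatal_nonfatal",
    "kruskal_tto",
    "build_characteristics_table",
]

UNKNOWN = "Unknown or missing"


def pct_half_up(n: int, d: int) -> Optional[float]:
    """Exact percentage n/d*100 rounded half-up to 2 decimals (integer
    arithmetic, so 36.585 prints as 36.59 regardless of float binning)."""
    if d == 0:
        return None
    return ((2 * n * 10000 + d) // (2 * d)) / 100


# ---------------------------------------------------------------------------
# row predicates for the characteristic blocks

def _age_group(rec: CaseRecord) -> str:
    a = rec.age_years
    if a is None:
        return UNKNOWN
    if a < 18:
        return "<18"
    if a < 65:
        return "18-64"
    if a < 85:
        return "65-84"
    return ">=85"


def _gender(rec: CaseRecord) -> str:
    return {"female": "Female", "male": "Male"}.get(rec.sex, UNKNOWN)


def _region(rec: CaseRecord) -> str:
    return rec.region or UNKNOWN


def _reporter(rec: CaseRecord) -> str:
    return {
        "health-professional": "Health-care professional",
        "non-health-professional": "Non-health-care professional",
    }.get(rec.reporter, UNKNOWN)


def _year(rec: CaseRecord) -> str:
    y = rec.report_year
    if y is None:
        return UNKNOWN
    return "2020 (Q1)" if y == 2020 else str(y)


def _tto_bin(rec: CaseRecord) -> str:
    return rec.tto_bin or UNKNOWN


#: display precedence for mutually exclusive outcome rows
_OUTCOME_ORDER = (
    ("DE", "Death"),
    ("LT", "Life-threatening"),
    ("DS", "Disability"),
    ("HO", "Hospitalization"),
)


def _outcome(rec: CaseRecord) -> str:
    if not rec.outcomes:
        return UNKNOWN
    for code, label in _OUTCOME_ORDER:
        if code in rec.outcomes:
            return label
    return "Other serious"   # OT, CA, RI


_INDICATION_ROWS = [
    "Melanoma", "Lung cancer", "Hematological cancer and lymphoma",
    "Gastrointestinal cancer", "Head and neck cancer", "Breast cancer",
    "Tumors of female reproductive organs", "Mesothelioma",
    "Non-specified malignant neoplasm", "Tumors of urinary system",
    "Other indications", UNKNOWN,
]

#: regimen block rows: (display label, aggregate?, matcher)
_REGIMEN_ROWS: List[Tuple[str, bool, Callable[[CaseRecord], bool]]] = [
    ("Monotherapy", True,
     lambda r: r.regimen.strategy in ("anti-PD-1 mono", "anti-PD-L1 mono",
                                      "anti-CTLA-4 mono")),
    ("Anti-CTLA-4 monotherapy", True,
     lambda r: r.regimen.strategy == "anti-CTLA-4 mono"),
    ("Ipilimumab", False, lambda r: r.regimen.label == "ipilimumab"),
    ("Tremelimumab", False, lambda r: r.regimen.label == "tremelimumab"),
    ("Anti-PD-1 monotherapy", True,
     lambda r: r.regimen.strategy == "anti-PD-1 mono"),
    ("Pembrolizumab", False, lambda r: r.regimen.label == "pembrolizumab"),
    ("Nivolumab", False, lambda r: r.regimen.label == "nivolumab"),
    ("Cemiplimab", False, lambda r: r.regimen.label == "cemiplimab"),
    ("Anti-PD-L1 monotherapy", True,
     lambda r: r.regimen.strategy == "anti-PD-L1 mono"),
    ("Atezolizumab", False, lambda r: r.regimen.label == "atezolizumab"),
    ("Avelumab", False, lambda r: r.regimen.label == "avelumab"),
    ("Durvalumab", False, lambda r: r.regimen.label == "durvalumab"),
    ("Combination therapy", True,
     lambda r: r.regimen.strategy == "combination"),
    ("Ipilimumab + nivolumab", False,
     lambda r: r.regimen.label == "ipilimumab+nivolumab"),
    ("Ipilimumab + pembrolizumab", False,
     lambda r: r.regimen.label == "ipilimumab+pembrolizumab"),
    ("Tremelimumab + durvalumab", False,
     lambda r: r.regimen.label == "tremelimumab+durvalumab"),
    ("Other multi-ICI", False, lambda r: r.regimen.label == "other-multi-ICI"),
]


@dataclass
class GroupTestResult:
    """Outcome of one between-group comparison."""

    test: str                       # chi-square | t | Mann-Whitney | Kruskal-Wallis
    statistic: Optional[float]
    pvalue: Optional[float]
    groups: Tuple[str, ...]
    n_excluded: int = 0             # records dropped as unknown/missing
    untestable: bool = False
    note: str = ""


@dataclass
class TtoSummary:
    """Onset-time summary for one group of cases."""

    group: str
    n: int
    median: float
    q1: float
    q3: float
    bin_counts: Dict[str, int] = field(default_factory=dict)


def _status(rec: CaseRecord) -> str:
    if rec.fatal:
        return "fatal"
    return "nonfatal" if rec.outcome_known else "unknown"


def fatality_rate(
    cohort: CaseCohort, stratifier: Union[str, Callable[[CaseRecord], Optional[str]]]
) -> pd.DataFrame:
    """Fatal count, total count and percentage per stratum.

    The denominator is every cohort report in the stratum, including those
    with unknown outcome.  ``stratifier`` is a CaseRecord attribute name or
    a callable; empty strata are simply absent.
    """
    if isinstance(stratifier, str):
        attr = stratifier
        stratifier = lambda rec: getattr(rec, attr)  # noqa: E731
    counts: Dict[str, List[int]] = {}
    for rec in cohort:
        label = stratifier(rec)
        label = UNKNOWN if label is None else str(label)
        entry = counts.setdefault(label, [0, 0])
        entry[1] += 1
        if rec.fatal:
            entry[0] += 1
    rows = [
        {"stratum": label, "fatal": fatal, "total": total,
         "pct": pct_half_up(fatal, total)}
        for label, (fatal, total) in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["stratum", "fatal", "total", "pct"])


def _quartiles(values: Sequence[float]) -> Tuple[float, float, float]:
    q1, med, q3 = np.percentile(np.asarray(values, dtype=float), [25, 50, 75])
    return float(q1), float(med), float(q3)


def summarize_tto(
    cohort: CaseCohort,
    grouping: Union[str, Callable[[CaseRecord], Optional[str]]] = "regimen_label",
) -> List[TtoSummary]:
    """Median / quartiles (linear-interpolation convention) and bin counts
    of documented onset times per group; all-missing groups are omitted."""
    if grouping == "regimen_label":
        getter = lambda rec: rec.regimen.label  # noqa: E731
    elif grouping == "strategy":
        getter = lambda rec: rec.regimen.strategy  # noqa: E731
    elif grouping == "fatal":
        getter = _status  # fatal / nonfatal / unknown
    elif isinstance(grouping, str):
        attr = grouping
        getter = lambda rec: getattr(rec, attr)  # noqa: E731
    else:
        getter = grouping
    values: Dict[str, List[int]] = {}
    bins: Dict[str, Dict[str, int]] = {}
    for rec in cohort:
        if rec.tto_days is None:
            continue
        label = str(getter(rec))
        values.setdefault(label, []).append(rec.tto_days)
        b = bins.setdefault(label, {name: 0 for name, _, _ in TTO_BINS})
        b[rec.tto_bin] += 1
    out = []
    for label in sorted(values):
        q1, med, q3 = _quartiles(values[label])
        out.append(TtoSummary(group=label, n=len(values[label]), median=med,
                              q1=q1, q3=q3, bin_counts=bins[label]))
    return out


_CATEGORICAL_GETTERS: Dict[str, Callable[[CaseRecord], str]] = {
    "sex": _gender,
    "age_group": _age_group,
    "report_year": _year,
    "region": _region,
    "indication_group": lambda r: r.indication_group,
    "reporter": _reporter,
    "tto_bin": _tto_bin,
    "strategy": lambda r: (r.regimen.strategy
                           if r.regimen.strategy != "other" else UNKNOWN),
}


def _chi2_fatal(
    cohort: CaseCohort, getter: Callable[[CaseRecord], str]
) -> GroupTestResult:
    rows: Dict[str, List[int]] = {}
    excluded = 0
    for rec in cohort:
        status = _status(rec)
        label = getter(rec)
        if status == "unknown" or label == UNKNOWN:
            excluded += 1
            continue
        entry = rows.setdefault(label, [0, 0])
        entry[0 if status == "fatal" else 1] += 1
    obs = pd.DataFrame(rows, index=["fatal", "nonfatal"]).T
    obs = obs.loc[(obs.sum(axis=1) > 0), obs.sum(axis=0) > 0]
    if obs.shape[0] < 2 or obs.shape[1] < 2:
        return GroupTestResult("chi-square", None, None, ("fatal", "nonfatal"),
                               excluded, untestable=True,
                               note="degenerate table after exclusions")
    chi2, p, dof, expected = sps.chi2_contingency(obs.to_numpy(), correction=False)
    note = ""
    n_small = int((expected < 5).sum())
    if n_small:
        note = f"{n_small} expected cell(s) < 5"
    return GroupTestResult("chi-square", float(chi2), float(p),
                           ("fatal", "nonfatal"), excluded, note=note)


def _fatal_nonfatal_values(
    cohort: CaseCohort, value: Callable[[CaseRecord], Optional[float]]
) -> Tuple[List[float], List[float], int]:
    fatal, nonfatal, excluded = [], [], 0
    for rec in cohort:
        status = _status(rec)
        v = value(rec)
        if status == "unknown" or v is None:
            excluded += 1
            continue
        (fatal if status == "fatal" else nonfatal).append(float(v))
    return fatal, nonfatal, excluded


def compare_fatal_nonfatal(cohort: CaseCohort, characteristic: str) -> GroupTestResult:
    """Hypothesis test between fatal and non-fatal cases.

    Categorical characteristics use the chi-square test on the fatal-by-
    category table (no continuity correction; unknown/missing rows
    excluded).  'tto' uses the Mann-Whitney test on documented onset days.
    'age' applies a Shapiro normality pre-check per group: both normal at
    the 5% level -> Welch t test, otherwise Mann-Whitney.
    """
    if characteristic in _CATEGORICAL_GETTERS:
        return _chi2_fatal(cohort, _CATEGORICAL_GETTERS[characteristic])
    if characteristic == "tto":
        fatal, nonfatal, excl = _fatal_nonfatal_values(
            cohort, lambda r: r.tto_days)
        if not fatal or not nonfatal:
            return GroupTestResult("Mann-Whitney", None, None,
                                   ("fatal", "nonfatal"), excl, untestable=True)
        stat, p = sps.mannwhitneyu(fatal, nonfatal, alternative="two-sided")
        return GroupTestResult("Mann-Whitney", float(stat), float(p),
                               ("fatal", "nonfatal"), excl)
    if characteristic == "age":
        fatal, nonfatal, excl = _fatal_nonfatal_values(
            cohort, lambda r: r.age_years)
        if len(fatal) < 3 or len(nonfatal) < 3:
            return GroupTestResult("t", None, None, ("fatal", "nonfatal"),
                                   excl, untestable=True, note="too few values")
        normal = all(
            sps.shapiro(np.asarray(g)[:5000]).pvalue > 0.05
            for g in (fatal, nonfatal)
            if len(set(g)) > 1
        ) and len(set(fatal)) > 1 and len(set(nonfatal)) > 1
        if normal:
            stat, p = sps.ttest_ind(fatal, nonfatal, equal_var=False)
            return GroupTestResult("t", float(stat), float(p),
                                   ("fatal", "nonfatal"), excl)
        stat, p = sps.mannwhitneyu(fatal, nonfatal, alternative="two-sided")
        return GroupTestResult("Mann-Whitney", float(stat), float(p),
                               ("fatal", "nonfatal"), excl,
                               note="non-normal by Shapiro pre-check")
    raise ValueError(f"unknown characteristic {characteristic!r}")


def kruskal_tto(
    cohort: CaseCohort,
    grouping: str = "regimen_label",
    groups: Optional[Sequence[str]] = None,
) -> GroupTestResult:
    """Kruskal-Wallis comparison of documented onset times across regimens
    (or any grouping); groups with no documented TTO are dropped."""
    summaries = {s.group: s for s in summarize_tto(cohort, grouping)}
    samples: Dict[str, List[int]] = {}
    if grouping == "regimen_label":
        getter = lambda rec: rec.regimen.label  # noqa: E731
    elif grouping == "strategy":
        getter = lambda rec: rec.regimen.strategy  # noqa: E731
    else:
        getter = lambda rec: getattr(rec, grouping)  # noqa: E731
    for rec in cohort:
        if rec.tto_days is None:
            continue
        label = str(getter(rec))
        if groups is not None and label not in groups:
            continue
        samples.setdefault(label, []).append(rec.tto_days)
    samples = {k: v for k, v in samples.items() if v}
    if len(samples) < 2:
        return GroupTestResult("Kruskal-Wallis", None, None,
                               tuple(samples), untestable=True)
    stat, p = sps.kruskal(*samples.values())
    return GroupTestResult("Kruskal-Wallis", float(stat), float(p),
                           tuple(samples))


# ---------------------------------------------------------------------------
# the characteristics table

@dataclass
class CharacteristicsTable:
    """Counts/percentages for every characteristic block, the per-block
    tests, and the continuous summaries that accompany the table."""

    frame: pd.DataFrame
    tests: Dict[str, Optional[GroupTestResult]]
    totals: Dict[str, int]               # total / fatal / nonfatal sizes
    medians: Dict[str, Dict[str, Tuple[float, float, float]]]

    def pvalue(self, block: str) -> Optional[float]:
        t = self.tests.get(block)
        return t.pvalue if t is not None and not t.untestable else None

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    def render(self) -> str:
        """Plain-text rendering in the layout of the published table."""
        lines = [
            f"{'Characteristic':42s} {'Total n (%)':>16s} "
            f"{'Fatal n (%)':>16s} {'Non-fatal n (%)':>16s}",
            f"{'Total':42s} {self.totals['total']:>16d} "
            f"{self.totals['fatal']:>16d} {self.totals['nonfatal']:>16d}",
        ]

        def cell(n, p):
            return f"{n} ({p:.2f})" if p is not None else str(n)

        for block, sub in self.frame.groupby("block", sort=False):
            p = self.pvalue(block)
            lines.append(f"-- {block}" + (f"  p = {p:.3f}" if p is not None else ""))
            for row in sub.itertuples():
                lines.append(
                    f"  {row.label:40s} {cell(row.total_n, row.total_pct):>16s} "
                    f"{cell(row.fatal_n, row.fatal_pct):>16s} "
                    f"{cell(row.nonfatal_n, row.nonfatal_pct):>16s}"
                )
        return "\n".join(lines)

    summary = render


def _block_rows(
    block: str,
    labels: Sequence[str],
    getter: Callable[[CaseRecord], str],
    groups: Dict[str, List[CaseRecord]],
    totals: Dict[str, int],
) -> List[dict]:
    rows = []
    seen = {g: [getter(rec) for rec in recs] for g, recs in groups.items()}
    extra = sorted({lbl for lst in seen.values() for lbl in lst} - set(labels))
    for label in list(labels) + extra:
        counts = {g: seen[g].count(label) for g in groups}
        rows.append({
            "block": block, "label": label,
            "total_n": counts["total"], "total_pct":
                pct_half_up(counts["total"], totals["total"]) if counts["total"] else None,
            "fatal_n": counts["fatal"], "fatal_pct":
                pct_half_up(counts["fatal"], totals["fatal"]) if counts["fatal"] else None,
            "nonfatal_n": counts["nonfatal"], "nonfatal_pct":
                pct_half_up(counts["nonfatal"], totals["nonfatal"]) if counts["nonfatal"] else None,
        })
    return rows


def build_characteristics_table(cohort: CaseCohort) -> CharacteristicsTable:
    """All nine characteristic blocks with counts, percentages and tests.

    Percentages divide by the column size (unknown rows included); the
    fatal/non-fatal split excludes the unknown-outcome reports from both
    columns, so block totals satisfy fatal + nonfatal + unknown = total.
    """
    records = list(cohort)
    groups = {
        "total": records,
        "fatal": [r for r in records if _status(r) == "fatal"],
        "nonfatal": [r for r in records if _status(r) == "nonfatal"],
    }
    totals = {g: len(v) for g, v in groups.items()}

    year_labels = [str(y) for y in range(2011, 2020)] + ["2020 (Q1)"]
    blocks: List[Tuple[str, Sequence[str], Callable[[CaseRecord], str]]] = [
        ("gender", ["Female", "Male", UNKNOWN], _gender),
        ("age_group", ["<18", "18-64", "65-84", ">=85", UNKNOWN], _age_group),
        ("reporting_year", year_labels, _year),
        ("region", ["Europe", "America", "Asia", "Oceania", "Africa", UNKNOWN],
         _region),
        ("indication", _INDICATION_ROWS, lambda r: r.indication_group),
        ("outcome", ["Death", "Life-threatening", "Disability", "Hospitalization",
                     "Other serious", UNKNOWN], _outcome),
        ("reporter", ["Non-health-care professional", "Health-care professional",
                      UNKNOWN], _reporter),
        ("tto_bin", [name for name, _, _ in TTO_BINS] + [UNKNOWN], _tto_bin),
    ]
    rows: List[dict] = []
    for name, labels, getter in blocks:
        rows += _block_rows(name, labels, getter, groups, totals)

    for label, _aggregate, matcher in _REGIMEN_ROWS:
        counts = {g: sum(1 for rec in groups[g] if matcher(rec)) for g in groups}
        if label == "Other multi-ICI" and counts["total"] == 0:
            continue
        rows.append({
            "block": "regimen", "label": label,
            "total_n": counts["total"], "total_pct":
                pct_half_up(counts["total"], totals["total"]) if counts["total"] else None,
            "fatal_n": counts["fatal"], "fatal_pct":
                pct_half_up(counts["fatal"], totals["fatal"]) if counts["fatal"] else None,
            "nonfatal_n": counts["nonfatal"], "nonfatal_pct":
                pct_half_up(counts["nonfatal"], totals["nonfatal"]) if counts["nonfatal"] else None,
        })

    tests: Dict[str, Optional[GroupTestResult]] = {}
    if totals["fatal"] and totals["nonfatal"]:
        tests = {
            "gender": compare_fatal_nonfatal(cohort, "sex"),
            "age_group": compare_fatal_nonfatal(cohort, "age_group"),
            "reporting_year": compare_fatal_nonfatal(cohort, "report_year"),
            "region": compare_fatal_nonfatal(cohort, "region"),
            "indication": compare_fatal_nonfatal(cohort, "indication_group"),
            "outcome": None,   # degenerate by construction
            "reporter": compare_fatal_nonfatal(cohort, "reporter"),
            "tto_bin": compare_fatal_nonfatal(cohort, "tto"),
            "regimen": compare_fatal_nonfatal(cohort, "strategy"),
        }

    medians: Dict[str, Dict[str, Tuple[float, float, float]]] = {}
    for kind, value in (("age", lambda r: r.age_years),
                        ("tto", lambda r: r.tto_days)):
        per_group = {}
        for g, recs in groups.items():
            vals = [value(r) for r in recs if value(r) is not None]
            if vals:
                q1, med, q3 = _quartiles(vals)
                per_group[g] = (med, q1, q3)
        medians[kind] = per_group

    frame = pd.DataFrame(rows, columns=[
        "block", "label", "total_n", "total_pct",
        "fatal_n", "fatal_pct", "nonfatal_n", "nonfatal_pct",
    ])
    return CharacteristicsTable(frame=frame, tests=tests, totals=totals,
                                medians=medians)
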