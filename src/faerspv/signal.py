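"""Disproportionality statistics and signal criteria.

Spontaneous-report signal detection compares how often a drug-event pair is
reported against how often it would be reported under independence.  Two
statistics are computed from the 2x2 report-count table

    a = drug & event    b = drug, no event
    c = event, no drug  d = neither

* the reporting odds ratio ROR = (a*d)/(b*c), with a Woolf (log-normal)
  95% confidence interval, exp(ln ROR +/- z*sqrt(1/a+1/b+1/c+1/d)); when
  any cell is zero the Haldane-Anscombe +0.5 correction is applied to all
  four cells and flagged;

* the Bayesian information component IC = log2((N_obs+0.5)/(N_exp+0.5)),
  with N_exp = N_drug*N_event/N_total, whose lower 95% credibility bound is
  the analytic approximation IC025 = IC - 3.3*(N_obs+0.5)^-1/2
  - 2*(N_obs+0.5)^-3/2 (isolated in :func:`ic_credibility_lower` so a
  posterior-simulation alternative can be swapped in).

A signal is declared when IC025 > 0, or when ROR025 > 1 with at least
``n_min`` (default 3) co-reported cases.  Against the full database both
statistics apply; between two regimen subgroups only the ROR is meaningful
(the IC's expected count presumes a whole-database frame) so IC fields are
left empty there.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, List, Optional, Sequence, Set, Tuple, Union

import pandas as pd

from .cohort import ICI_DRUGS, is_pericardial_pt, canonicalize_drugs, label_from_suspects
from .io import SafetyReport

__all__ = [
    "Z_95",
    "ContingencyTable",
    "SignalStats",
    "Selector",
    "ComparisonDesign",
    "build_contingency",
    "compute_ror",
    "expected_count",
    "compute_ic",
    "ic_credibility_lower",
    "classify_signal",
    "run_signal_table",
    "default_designs",
    "DisproportionalityModel",
    "DisproportionalityResults",
]

#: two-sided 95% normal quantile
Z_95 = 1.959964


@dataclass(frozen=True)
class ContingencyTable:
    """Report counts underlying one drug-event comparison."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        for name in "abcd":
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"cell {name} must be a non-negative integer, got {v}")

    @property
    def n_total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def n_drug(self) -> int:
        return self.a + self.b

    @property
    def n_event(self) -> int:
        return self.a + self.c


@dataclass
class SignalStats:
    """Point estimates, interval bounds and the signal verdict for one row."""

    n_observed: int
    n_expected: Optional[float] = None
    ror: Optional[float] = None
    ror025: Optional[float] = None
    ror975: Optional[float] = None
    ic: Optional[float] = None
    ic025: Optional[float] = None
    signal_ror: Optional[bool] = None
    signal_ic: Optional[bool] = None
    zero_cell_corrected: bool = False


def compute_ror(
    table: ContingencyTable, z: float = Z_95
) -> Tuple[Optional[float], Optional[float], Optional[float], bool]:
    """ROR point estimate and Woolf 95% CI; returns (ror, lo, hi, corrected).

    Zero cells trigger the Haldane-Anscombe +0.5 correction on all four
    cells rather than dropping the comparison; ``corrected`` records that.
    An empty margin (a+b or a+c zero even after correction makes no sense
    to report) still yields the corrected estimate, never an exception.
    """
    a, b, c, d = float(table.a), float(table.b), float(table.c), float(table.d)
    corrected = min(a, b, c, d) == 0
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    ror = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo = math.exp(math.log(ror) - z * se)
    hi = math.exp(math.log(ror) + z * se)
    return ror, lo, hi, corrected


def expected_count(n_drug: float, n_event: float, n_total: float) -> float:
    """Independence expectation N_drug * N_event / N_total."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if n_drug > n_total or n_event > n_total:
        raise ValueError("margins cannot exceed n_total")
    return (n_drug * n_event) / n_total


def ic_credibility_lower(ic: float, n_observed: float) -> float:
    """Analytic lower 95% credibility bound for the information component."""
    shrunk = n_observed + 0.5
    return ic - 3.3 * shrunk ** -0.5 - 2.0 * shrunk ** -1.5


def compute_ic(n_observed: float, n_expected: float) -> Tuple[float, float]:
    """Shrunken observed/expected log2 ratio and its lower 95% bound."""
    if n_observed < 0 or n_expected < 0:
        raise ValueError("counts must be non-negative")
    ic = math.log2((n_observed + 0.5) / (n_expected + 0.5))
    return ic, ic_credibility_lower(ic, n_observed)


def classify_signal(stats: SignalStats, n_min: int = 3) -> SignalStats:
    """Set the signal flags: IC025 > 0; ROR025 > 1 with >= ``n_min`` cases."""
    if stats.ror025 is not None:
        stats.signal_ror = stats.ror025 > 1.0 and stats.n_observed >= n_min
    if stats.ic025 is not None:
        stats.signal_ic = stats.ic025 > 0.0
    return stats


# ---------------------------------------------------------------------------
# comparison designs

@dataclass(frozen=True)
class Selector:
    """Predicate over a report's regimen, expressed on its label/strategy.

    kind: 'any' (any suspect ICI), 'label', 'strategy', or 'strategy_in'.
    """

    kind: str
    value: Union[str, Tuple[str, ...], None] = None

    def matches(self, label: Optional[str], strategy: Optional[str]) -> bool:
        if label is None:
            return False
        if self.kind == "any":
            return True
        if self.kind == "label":
            return label == self.value
        if self.kind == "strategy":
            return strategy == self.value
        if self.kind == "strategy_in":
            return strategy in self.value
        raise ValueError(f"unknown selector kind {self.kind!r}")


@dataclass(frozen=True)
class ComparisonDesign:
    """One row of the signal table: target vs comparator for an event set.

    ``comparator=None`` means the full-database remainder (both ROR and IC
    computed); a named comparator restricts the frame to the two groups and
    yields ROR only.  ``row_kind`` drives table layout (total / class /
    drug / combination / comparison).
    """

    name: str
    target: Selector
    comparator: Optional[Selector] = None
    row_kind: str = "drug"
    n_min: int = 3

    @property
    def full_database(self) -> bool:
        return self.comparator is None


EventPredicate = Callable[[Set[str]], bool]


def pericardial_event(reactions: Set[str]) -> bool:
    return any(is_pericardial_pt(pt) for pt in reactions)


def annotate_reports(
    reports: Iterable[SafetyReport], event: EventPredicate = pericardial_event
) -> List[Tuple[Optional[str], Optional[str], bool]]:
    """Per report: (regimen label, strategy, has event) — computed once and
    shared across all designs."""
    out = []
    ici = set(ICI_DRUGS)
    for r in reports:
        canonicalize_drugs(r)
        regimen = label_from_suspects(frozenset(r.suspect_names()) & ici)
        if regimen is None:
            out.append((None, None, event(r.reactions)))
        else:
            out.append((regimen.label, regimen.strategy, event(r.reactions)))
    return out


def _cells(
    annotated: Sequence[Tuple[Optional[str], Optional[str], bool]],
    design: ComparisonDesign,
) -> ContingencyTable:
    a = b = c = d = 0
    for label, strategy, has_event in annotated:
        in_target = design.target.matches(label, strategy)
        if design.full_database:
            in_frame, in_comp = True, not in_target
        else:
            in_comp = (not in_target) and design.comparator.matches(label, strategy)
            in_frame = in_target or in_comp
        if not in_frame:
            continue
        if in_target:
            if has_event:
                a += 1
            else:
                b += 1
        else:
            if has_event:
                c += 1
            else:
                d += 1
    return ContingencyTable(a, b, c, d)


def build_contingency(
    reports: Iterable[SafetyReport],
    design: ComparisonDesign,
    event: EventPredicate = pericardial_event,
) -> ContingencyTable:
    """Classify each report into exactly one cell of the design's table."""
    return _cells(annotate_reports(reports, event), design)


def stats_for_table(table: ContingencyTable, design: ComparisonDesign) -> SignalStats:
    """Full statistics row for one design; a = 0 yields empty statistics."""
    stats = SignalStats(n_observed=table.a)
    if table.a == 0:
        return stats
    stats.ror, stats.ror025, stats.ror975, stats.zero_cell_corrected = compute_ror(table)
    if design.full_database:
        stats.n_expected = expected_count(table.n_drug, table.n_event, table.n_total)
        stats.ic, stats.ic025 = compute_ic(table.a, stats.n_expected)
    return classify_signal(stats, design.n_min)


def default_designs() -> List[ComparisonDesign]:
    """The standard signal-table layout: one total row, three class rows and
    eight monotherapy rows against the full database (ROR + IC), three
    combination rows (ROR + IC), and four subgroup comparisons (ROR only)."""
    designs: List[ComparisonDesign] = [
        ComparisonDesign("Total ICIs", Selector("any"), row_kind="total"),
    ]
    for strategy, label in (
        ("anti-PD-1 mono", "Anti-PD-1"),
        ("anti-PD-L1 mono", "Anti-PD-L1"),
        ("anti-CTLA-4 mono", "Anti-CTLA-4"),
    ):
        designs.append(
            ComparisonDesign(label, Selector("strategy", strategy), row_kind="class")
        )
    for drug in ICI_DRUGS:
        designs.append(
            ComparisonDesign(drug.capitalize(), Selector("label", drug), row_kind="drug")
        )
    for combo in ("ipilimumab+nivolumab", "ipilimumab+pembrolizumab",
                  "tremelimumab+durvalumab"):
        designs.append(
            ComparisonDesign(
                combo.replace("+", " + ").capitalize(),
                Selector("label", combo), row_kind="combination",
            )
        )
    mono_pd = Selector("strategy_in", ("anti-PD-1 mono", "anti-PD-L1 mono"))
    designs += [
        ComparisonDesign(
            "Anti-PD-1 vs anti-CTLA-4",
            Selector("strategy", "anti-PD-1 mono"),
            Selector("strategy", "anti-CTLA-4 mono"), row_kind="comparison",
        ),
        ComparisonDesign(
            "Anti-PD-L1 vs anti-CTLA-4",
            Selector("strategy", "anti-PD-L1 mono"),
            Selector("strategy", "anti-CTLA-4 mono"), row_kind="comparison",
        ),
        ComparisonDesign(
            "Anti-PD-1 vs anti-PD-L1",
            Selector("strategy", "anti-PD-1 mono"),
            Selector("strategy", "anti-PD-L1 mono"), row_kind="comparison",
        ),
        ComparisonDesign(
            "Combination vs monotherapy",
            Selector("strategy", "combination"), mono_pd, row_kind="comparison",
        ),
    ]
    return designs


def run_signal_table(
    reports: Iterable[SafetyReport],
    designs: Optional[Sequence[ComparisonDesign]] = None,
    event: EventPredicate = pericardial_event,
) -> pd.DataFrame:
    """One statistics row per design.

    Rows with no co-reported case carry empty statistics (not zeros), and
    subgroup-comparison rows carry no IC columns.
    """
    if designs is None:
        designs = default_designs()
    annotated = annotate_reports(reports, event)
    rows = []
    for design in designs:
        table = _cells(annotated, design)
        stats = stats_for_table(table, design)
        rows.append({
            "row_kind": design.row_kind,
            "label": design.name,
            "comparator": "full database" if design.full_database else design.comparator.value,
            "n": stats.n_observed,
            "n_expected": stats.n_expected,
            "ror": stats.ror,
            "ror025": stats.ror025,
            "ror975": stats.ror975,
            "ic": stats.ic,
            "ic025": stats.ic025,
            "signal_ror": stats.signal_ror,
            "signal_ic": stats.signal_ic,
            "zero_cell_corrected": stats.zero_cell_corrected,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# model / results surface

class DisproportionalityModel:
    """Disproportionality analysis of a report collection.

    Parameters
    ----------
    reports
        Deduplicated spontaneous reports (the comparator frame).
    designs
        Comparison designs; defaults to the standard regimen layout.
    event
        Predicate deciding whether a report's reaction set contains the
        event of interest; defaults to the pericardial-disorder term set.
    """

    def __init__(
        self,
        reports: Iterable[SafetyReport],
        designs: Optional[Sequence[ComparisonDesign]] = None,
        event: EventPredicate = pericardial_event,
    ):
        self.reports = list(reports)
        self.designs = list(designs) if designs is not None else default_designs()
        self.event = event

    def fit(self) -> "DisproportionalityResults":
        table = run_signal_table(self.reports, self.designs, self.event)
        return DisproportionalityResults(self, table)


class DisproportionalityResults:
    """Fitted signal table with export and display helpers."""

    def __init__(self, model: DisproportionalityModel, table: pd.DataFrame):
        self.model = model
        self.table = table

    @property
    def signals(self) -> pd.DataFrame:
        """Rows meeting either signal criterion."""
        t = self.table
        return t[(t["signal_ror"] == True) | (t["signal_ic"] == True)]  # noqa: E712

    def summary(self) -> str:
        cols = ["row_kind", "label", "n", "ror", "ror025", "ror975",
                "ic", "ic025", "signal_ror", "signal_ic"]
        t = self.table[cols].copy()
        for c in ("ror", "ror025", "ror975", "ic", "ic025"):
            t[c] = t[c].map(lambda v: "" if pd.isna(v) else f"{v:.2f}")
        for c in ("signal_ror", "signal_ic"):
            t[c] = t[c].map(lambda v: "" if pd.isna(v) else ("yes" if v else "no"))
        header = "Disproportionality signal table (events vs comparator frame)"
        return header + "\n" + t.to_string(index=False)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def to_json(self, path) -> None:
        self.table.to_json(path, orient="records", indent=2)
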