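"""Synthetic FAERS-like databases with controlled drug-event association.

Two generators live here:

* :func:`generate_database` emits a full six-file quarter (plus a ground-
  truth ledger) whose drug-event association structure is controlled by an
  odds-multiplier map: for each report the pericardial-event odds are the
  baseline odds times the product of the multipliers of its suspect-role
  study drugs, so the *true reporting odds ratio* of a drug-event pair is
  exactly the configured multiplier.  Demographics, missingness, date
  precision, duplicate case versions and free-text drug-name noise emulate
  the quirks the pipeline must survive.

* :func:`build_table2_fixture` deterministically reconstructs the 705-case
  published characteristics table: each characteristic is assigned
  independently within outcome status by sequential fill, which is exact on
  every characteristic-by-fatality margin (the published table constrains
  nothing beyond those two-way margins).  A self-audit re-derives all nine
  blocks against the shipped machine-readable copy on every construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from importlib import resources
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .cohort import (
    CaseCohort,
    CaseRecord,
    ICI_CLASS,
    PERICARDIAL_PTS,
    label_from_suspects,
    tto_bin,
)
from .dates import FuzzyDate
from .io import RawQuarter, SafetyReport, DrugUse, _add_parsed_dates
from .signal import ComparisonDesign, ContingencyTable, _cells

__all__ = [
    "SynthConfigError",
    "DrugSpec",
    "SynthConfig",
    "default_config",
    "GeneratorLedger",
    "sample_ledger",
    "generate_database",
    "TtoStudyConfig",
    "generate_tto_cohort",
    "build_table2_fixture",
    "FixtureAuditError",
]


class SynthConfigError(ValueError):
    """Invalid generator configuration; the message names the field."""


@dataclass
class DrugSpec:
    """One catalogue drug: how often it appears and in which role."""

    name: str
    exposure_prob: float
    suspect_prob: float = 1.0   # P(role PS/SS | exposed); else concomitant
    brand_prob: float = 0.3     # P(verbatim name uses the brand name)


@dataclass
class SynthConfig:
    """Full parameterization of the synthetic-database generator.

    Probabilities are per report; the association map gives the
    reporting-odds multiplier a suspect-role exposure applies to the
    pericardial event family (1.0 = no association).
    """

    n_reports: int = 50_000
    seed: Optional[int] = None
    drugs: List[DrugSpec] = field(default_factory=list)
    pericardial_prob: float = 0.01
    background_pts: Dict[str, float] = field(default_factory=dict)
    association: Dict[str, float] = field(default_factory=dict)
    duplicate_rate: float = 0.10
    # demographics (defaults shaped like the published case series)
    sex_weights: Dict[str, float] = field(
        default_factory=lambda: {"F": 0.36, "M": 0.54, "": 0.10})
    age_mean: float = 63.0
    age_sd: float = 10.0
    age_missing_rate: float = 0.197
    country_weights: Dict[str, float] = field(
        default_factory=lambda: {"FR": 0.12, "DE": 0.13, "GB": 0.12, "US": 0.28,
                                 "CA": 0.04, "JP": 0.20, "CN": 0.06, "AU": 0.02,
                                 "ZA": 0.005, "": 0.025})
    reporter_weights: Dict[str, float] = field(
        default_factory=lambda: {"MD": 0.55, "PH": 0.13, "OT": 0.10,
                                 "CN": 0.18, "LW": 0.03, "": 0.01})
    year_weights: Dict[int, float] = field(
        default_factory=lambda: {2011: 0.001, 2012: 0.004, 2013: 0.01,
                                 2014: 0.015, 2015: 0.04, 2016: 0.11,
                                 2017: 0.16, 2018: 0.28, 2019: 0.31,
                                 2020: 0.08})
    indication_weights: Dict[str, float] = field(
        default_factory=lambda: {"non-small cell lung cancer": 0.35,
                                 "malignant melanoma": 0.12,
                                 "renal cell carcinoma": 0.07,
                                 "hodgkin's disease": 0.03,
                                 "gastric cancer": 0.04,
                                 "breast cancer": 0.04,
                                 "hypertension": 0.10,
                                 "": 0.25})
    # onset and outcome
    tto_mu: float = 3.6          # log-days; exp(3.6) ~ 37 d median onset
    tto_sigma: float = 1.0
    start_missing_rate: float = 0.25
    start_month_precision_rate: float = 0.10
    event_missing_rate: float = 0.10
    negative_tto_rate: float = 0.02
    fatality_case_prob: float = 0.1745
    fatality_background_prob: float = 0.05
    nonfatal_outcome_weights: Dict[str, float] = field(
        default_factory=lambda: {"HO": 0.45, "LT": 0.12, "OT": 0.24,
                                 "DS": 0.01, "": 0.18})

    def validate(self) -> None:
        if self.n_reports < 1:
            raise SynthConfigError("n_reports must be >= 1")
        if not self.drugs:
            raise SynthConfigError("drugs catalogue must not be empty")
        for spec in self.drugs:
            for fname in ("exposure_prob", "suspect_prob", "brand_prob"):
                v = getattr(spec, fname)
                if not 0.0 <= v <= 1.0:
                    raise SynthConfigError(
                        f"drugs[{spec.name}].{fname} must be in [0, 1]")
        for fname in ("pericardial_prob", "duplicate_rate", "age_missing_rate",
                      "start_missing_rate", "start_month_precision_rate",
                      "event_missing_rate", "negative_tto_rate",
                      "fatality_case_prob", "fatality_background_prob"):
            v = getattr(self, fname)
            if not 0.0 <= v <= 1.0:
                raise SynthConfigError(f"{fname} must be in [0, 1]")
        for name, mult in self.association.items():
            if mult <= 0:
                raise SynthConfigError(f"association[{name}] must be > 0")
        for fname in ("sex_weights", "country_weights", "reporter_weights",
                      "year_weights", "indication_weights",
                      "nonfatal_outcome_weights", "background_pts"):
            weights = getattr(self, fname)
            if any(w < 0 for w in weights.values()):
                raise SynthConfigError(f"{fname} must be non-negative")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "SynthConfig":
        data = dict(data)
        if "drugs" in data:
            data["drugs"] = [d if isinstance(d, DrugSpec) else DrugSpec(**d)
                             for d in data["drugs"]]
        if "year_weights" in data:
            data["year_weights"] = {int(k): v for k, v in data["year_weights"].items()}
        known = cls.__dataclass_fields__  # type: ignore[attr-defined]
        unknown = set(data) - set(known)
        if unknown:
            raise SynthConfigError(f"unknown config field(s): {sorted(unknown)}")
        return cls(**data)


def default_config(n_reports: int = 50_000, seed: Optional[int] = None,
                   association: Optional[Dict[str, float]] = None) -> SynthConfig:
    """A database shaped like the study setting: eight checkpoint
    inhibitors with exposure shares echoing the case series, two common
    co-medications, and a small catalogue of frequent background events."""
    drugs = [
        DrugSpec("nivolumab", 0.020),
        DrugSpec("pembrolizumab", 0.012),
        DrugSpec("atezolizumab", 0.005),
        DrugSpec("durvalumab", 0.002),
        DrugSpec("ipilimumab", 0.004),
        DrugSpec("avelumab", 0.0006),
        DrugSpec("cemiplimab", 0.0006),
        DrugSpec("tremelimumab", 0.0002),
        DrugSpec("aspirin", 0.08, suspect_prob=0.2),
        DrugSpec("metformin", 0.06, suspect_prob=0.1),
    ]
    background = {
        "nausea": 0.06, "diarrhoea": 0.05, "fatigue": 0.05, "pyrexia": 0.04,
        "dyspnoea": 0.04, "rash": 0.03, "headache": 0.03, "myocarditis": 0.002,
    }
    return SynthConfig(n_reports=n_reports, seed=seed, drugs=drugs,
                       background_pts=background,
                       association=dict(association or {}))


_BRANDS = {
    "nivolumab": "OPDIVO", "pembrolizumab": "KEYTRUDA", "cemiplimab": "LIBTAYO",
    "atezolizumab": "TECENTRIQ", "avelumab": "BAVENCIO", "durvalumab": "IMFINZI",
    "ipilimumab": "YERVOY",
}

_PT_NAMES = [name.title() for name in PERICARDIAL_PTS]


class GeneratorLedger:
    """Per-report ground truth of one generation run.

    One row per emitted report (injected duplicates included and flagged);
    the contingency cells of any comparison design can be recomputed from
    the ledger alone, which is what the generator-vs-pipeline identity
    checks compare against.
    """

    def __init__(self, frame: pd.DataFrame):
        self.frame = frame

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def unique_cases(self) -> pd.DataFrame:
        return self.frame[~self.frame["is_duplicate"]]

    def cells(self, design: ComparisonDesign) -> ContingencyTable:
        """Contingency cells over unique cases (what the pipeline sees
        after deduplication)."""
        df = self.unique_cases
        annotated = list(zip(
            df["regimen_label"].where(df["regimen_label"].notna(), None),
            df["strategy"].where(df["strategy"].notna(), None),
            df["pericardial"].astype(bool),
        ))
        return _cells(annotated, design)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def _truth_arrays(config: SynthConfig, rng: np.random.Generator) -> dict:
    """Vectorized core draws: exposures, roles, events, fatality, onset."""
    n = config.n_reports
    exposed: Dict[str, np.ndarray] = {}
    suspect: Dict[str, np.ndarray] = {}
    for spec in config.drugs:
        e = rng.random(n) < spec.exposure_prob
        s = e & (rng.random(n) < spec.suspect_prob)
        exposed[spec.name], suspect[spec.name] = e, s

    p0 = config.pericardial_prob
    if p0 <= 0.0:   # zero baseline odds stay zero under any multiplier
        event = np.zeros(n, dtype=bool)
    else:
        log_odds = np.full(n, np.log(p0 / (1.0 - p0)))
        for name, mult in config.association.items():
            if name in suspect and mult != 1.0:
                log_odds = log_odds + suspect[name] * np.log(mult)
        p_event = 1.0 / (1.0 + np.exp(-log_odds))
        event = rng.random(n) < p_event

    fatal = np.where(event,
                     rng.random(n) < config.fatality_case_prob,
                     rng.random(n) < config.fatality_background_prob)

    ici_names = [s.name for s in config.drugs if s.name in ICI_CLASS]
    any_ici_suspect = np.zeros(n, dtype=bool)
    for name in ici_names:
        any_ici_suspect |= suspect[name]
    tto = np.round(rng.lognormal(config.tto_mu, config.tto_sigma, n)).astype(int)

    labels = np.full(n, None, dtype=object)
    strategies = np.full(n, None, dtype=object)
    suspect_sets = np.full(n, "", dtype=object)
    stack = np.column_stack([suspect[name] for name in ici_names]) if ici_names \
        else np.zeros((n, 0), dtype=bool)
    for i in np.nonzero(any_ici_suspect)[0]:
        names = frozenset(name for j, name in enumerate(ici_names) if stack[i, j])
        regimen = label_from_suspects(names)
        labels[i], strategies[i] = regimen.label, regimen.strategy
        suspect_sets[i] = ";".join(sorted(names))

    return {
        "exposed": exposed, "suspect": suspect, "event": event, "fatal": fatal,
        "tto": tto, "any_ici_suspect": any_ici_suspect,
        "regimen_label": labels, "strategy": strategies,
        "suspect_set": suspect_sets, "ici_names": ici_names,
    }


def _ledger_frame(config: SynthConfig, truth: dict) -> pd.DataFrame:
    n = config.n_reports
    caseid = np.arange(1, n + 1)
    frame = pd.DataFrame({
        "caseid": caseid,
        "primaryid": caseid * 10 + 1,
        "is_duplicate": False,
        "pericardial": truth["event"],
        "fatal": truth["fatal"],
        "true_tto": np.where(truth["any_ici_suspect"], truth["tto"], -1),
        "regimen_label": truth["regimen_label"],
        "strategy": truth["strategy"],
        "suspects": truth["suspect_set"],
    })
    for name in truth["exposed"]:
        frame[f"exposed_{name}"] = truth["exposed"][name]
        frame[f"suspect_{name}"] = truth["suspect"][name]
    return frame


def sample_ledger(config: SynthConfig, seed: Optional[int] = None) -> GeneratorLedger:
    """Ground-truth draw without file materialization.

    Samples the same association structure as :func:`generate_database`
    (exposures, roles, events, fatality, onset) and returns only the
    ledger — the cheap path for calibration studies that need thousands of
    replicate databases.
    """
    config.validate()
    rng = np.random.default_rng(seed if seed is not None else config.seed)
    return GeneratorLedger(_ledger_frame(config, _truth_arrays(config, rng)))


def _date_tokens(dates: pd.Series) -> np.ndarray:
    return dates.dt.strftime("%Y%m%d").to_numpy(dtype=object)


def generate_database(
    config: SynthConfig,
    seed: Optional[int] = None,
    out_dir=None,
) -> Tuple[RawQuarter, GeneratorLedger]:
    """Generate one FAERS-like quarter plus its ground-truth ledger.

    Fully reproducible from the seed: the same (config, seed) pair yields
    byte-identical files.  Duplicate case versions mutate only the receipt
    date, case version and primary id, so correct deduplication leaves the
    analyzable content unchanged.
    """
    config.validate()
    rng = np.random.default_rng(seed if seed is not None else config.seed)
    truth = _truth_arrays(config, rng)
    n = config.n_reports
    caseid = np.arange(1, n + 1)
    primaryid = caseid * 10 + 1

    def _choice(weights: Dict, size: int) -> np.ndarray:
        keys = list(weights)
        p = np.asarray([weights[k] for k in keys], dtype=float)
        return rng.choice(np.asarray(keys, dtype=object), size=size, p=p / p.sum())

    sex = _choice(config.sex_weights, n)
    occp = _choice(config.reporter_weights, n)
    country = _choice(config.country_weights, n)
    years = _choice(config.year_weights, n).astype(int)

    age = rng.normal(config.age_mean, config.age_sd, n)
    for _ in range(16):  # truncated normal on [0, 120] by resampling
        bad = (age < 0) | (age > 120)
        if not bad.any():
            break
        age[bad] = rng.normal(config.age_mean, config.age_sd, int(bad.sum()))
    age = np.clip(age, 0, 120)
    age_tok = np.round(age).astype(int).astype(str).astype(object)
    age_missing = rng.random(n) < config.age_missing_rate
    age_tok[age_missing] = ""
    age_cod = np.where(age_missing, "", "YR").astype(object)

    # receipt within the sampled year (first quarter only for the last year)
    max_year = max(config.year_weights)
    span = np.where(years == max_year, 90, 365)
    receipt = (pd.to_datetime(years.astype(str) + "-01-01")
               + pd.to_timedelta(rng.integers(0, span), unit="D"))
    event_dates = receipt - pd.to_timedelta(rng.integers(0, 60, n), unit="D")

    # therapy start: event minus onset; a small fraction is deliberately
    # inverted (start after event) to exercise the incorrect-record rule
    tto = truth["tto"]
    start = event_dates - pd.to_timedelta(tto, unit="D")
    negative = rng.random(n) < config.negative_tto_rate
    start = start.where(~negative,
                        event_dates + pd.to_timedelta(rng.integers(1, 100, n), unit="D"))
    start_tok = _date_tokens(pd.Series(start)).copy()
    month_prec = rng.random(n) < config.start_month_precision_rate
    start_tok[month_prec] = pd.Series(start[month_prec]).dt.strftime("%Y%m").to_numpy(dtype=object)
    start_missing = rng.random(n) < config.start_missing_rate
    start_tok[start_missing] = ""
    event_tok = _date_tokens(pd.Series(event_dates)).copy()
    event_missing = rng.random(n) < config.event_missing_rate
    event_tok[event_missing] = ""

    demo = pd.DataFrame({
        "primaryid": primaryid.astype(str),
        "caseid": caseid.astype(str),
        "caseversion": "1",
        "fda_dt": _date_tokens(pd.Series(receipt)),
        "event_dt": event_tok,
        "age": age_tok,
        "age_cod": age_cod,
        "sex": sex,
        "occp_cod": occp,
        "occr_country": country,
    })

    # drug / therapy rows, one block per catalogue drug
    drug_blocks, ther_blocks = [], []
    has_primary = np.zeros(n, dtype=bool)
    for spec in config.drugs:
        mask = truth["exposed"][spec.name]
        idx = np.nonzero(mask)[0]
        if idx.size == 0:
            continue
        is_suspect = truth["suspect"][spec.name][idx]
        role = np.where(is_suspect & ~has_primary[idx], "PS",
                        np.where(is_suspect, "SS", "C")).astype(object)
        has_primary[idx] |= is_suspect
        brand = _BRANDS.get(spec.name)
        use_brand = (rng.random(idx.size) < spec.brand_prob) if brand else \
            np.zeros(idx.size, dtype=bool)
        names = np.where(use_brand, brand, spec.name.upper()).astype(object)
        dose_suffix = rng.random(idx.size) < 0.2
        names[dose_suffix] = names[dose_suffix] + " (10 MG/ML)"
        drug_blocks.append(pd.DataFrame({
            "report": idx, "role_cod": role, "drugname": names,
            "prod_ai": spec.name.upper(),
        }))
        if spec.name in ICI_CLASS:
            tok = start_tok[idx]
            ther_blocks.append(pd.DataFrame({
                "report": idx, "start_dt": tok, "end_dt": "",
            }).assign(_block=len(drug_blocks) - 1))

    drug = pd.concat(drug_blocks).reset_index(drop=True) if drug_blocks else \
        pd.DataFrame(columns=["report", "role_cod", "drugname", "prod_ai"])
    drug["_order"] = drug.index
    drug = drug.sort_values(["report", "_order"], kind="stable").reset_index(drop=True)
    drug["drug_seq"] = drug.groupby("report").cumcount() + 1

    seq_lookup = {}  # (report, block) -> seq, for THER/INDI joins
    block_of_row = np.concatenate([
        np.full(len(b), i) for i, b in enumerate(drug_blocks)
    ]) if drug_blocks else np.array([], dtype=int)
    drug["_block"] = block_of_row[drug["_order"].to_numpy()] if len(drug) else []
    for rep, blk, seq in zip(drug["report"], drug["_block"], drug["drug_seq"]):
        seq_lookup[(rep, blk)] = seq

    ther_rows = []
    for tb in ther_blocks:
        blk = tb["_block"].iloc[0]
        for rep, s in zip(tb["report"], tb["start_dt"]):
            if s:
                ther_rows.append((rep, seq_lookup[(rep, blk)], s))
    ther = pd.DataFrame(ther_rows, columns=["report", "dsg_drug_seq", "start_dt"])
    ther["end_dt"] = ""

    # reactions: one pericardial PT for event reports, Bernoulli background
    reac_blocks = []
    ev_idx = np.nonzero(truth["event"])[0]
    if ev_idx.size:
        pts = rng.choice(np.asarray(_PT_NAMES, dtype=object), size=ev_idx.size)
        reac_blocks.append(pd.DataFrame({"report": ev_idx, "pt": pts}))
    for pt, prob in config.background_pts.items():
        mask = rng.random(n) < prob
        idx = np.nonzero(mask)[0]
        if idx.size:
            reac_blocks.append(pd.DataFrame({"report": idx, "pt": pt.title()}))
    reac = pd.concat(reac_blocks).reset_index(drop=True) if reac_blocks else \
        pd.DataFrame(columns=["report", "pt"])
    covered = np.zeros(n, dtype=bool)
    covered[reac["report"].to_numpy(dtype=int)] = True
    filler = np.nonzero(~covered)[0]
    if filler.size:  # every report describes at least one event
        reac = pd.concat([reac, pd.DataFrame({"report": filler, "pt": "Drug ineffective"})])
    reac = reac.sort_values(["report", "pt"], kind="stable").reset_index(drop=True)
    reac["pt_cod"] = ""

    # outcomes
    outc_rows = []
    fatal_idx = np.nonzero(truth["fatal"])[0]
    outc_rows.append(pd.DataFrame({"report": fatal_idx, "outc_cod": "DE"}))
    nonfatal_idx = np.nonzero(~truth["fatal"])[0]
    codes = _choice(config.nonfatal_outcome_weights, nonfatal_idx.size)
    keep = codes != ""
    outc_rows.append(pd.DataFrame({"report": nonfatal_idx[keep],
                                   "outc_cod": codes[keep]}))
    outc = pd.concat(outc_rows).sort_values("report", kind="stable").reset_index(drop=True)

    # indications, attached to the report's first drug row
    indi_terms = _choice(config.indication_weights, n)
    first_seq = drug.groupby("report")["drug_seq"].min() if len(drug) else pd.Series(dtype=int)
    indi_rows = []
    for rep, term in enumerate(indi_terms):
        if term and rep in first_seq.index:
            indi_rows.append((rep, first_seq[rep], term))
    indi = pd.DataFrame(indi_rows, columns=["report", "indi_drug_seq", "indi_pt"])

    def _finalize(df: pd.DataFrame, seq_col: Optional[str] = None) -> pd.DataFrame:
        out = df.copy()
        out.insert(0, "primaryid", primaryid[out.pop("report").to_numpy(dtype=int)].astype(str))
        if seq_col is not None:
            out[seq_col] = out[seq_col].astype(int).astype(str)
        return out

    drug_final = _finalize(
        drug[["report", "drug_seq", "role_cod", "drugname", "prod_ai"]], "drug_seq")
    drug_final = drug_final[["primaryid", "drug_seq", "role_cod", "drugname", "prod_ai"]]
    reac_final = _finalize(reac[["report", "pt", "pt_cod"]])
    outc_final = _finalize(outc[["report", "outc_cod"]])
    ther_final = _finalize(ther[["report", "dsg_drug_seq", "start_dt", "end_dt"]],
                           "dsg_drug_seq")
    indi_final = _finalize(indi[["report", "indi_drug_seq", "indi_pt"]],
                           "indi_drug_seq")

    ledger = _ledger_frame(config, truth)

    # duplicate injection: a later case version with a shifted receipt date
    n_dup = int(round(config.duplicate_rate * n))
    if n_dup:
        dup_cases = np.sort(rng.choice(caseid, size=n_dup, replace=False))
        dup_pos = dup_cases - 1
        dup_pid = (dup_cases * 10 + 2).astype(str)
        dup_demo = demo.iloc[dup_pos].copy()
        dup_demo["primaryid"] = dup_pid
        dup_demo["caseversion"] = "2"
        dup_receipt = receipt[dup_pos] + pd.to_timedelta(30, unit="D")
        dup_demo["fda_dt"] = _date_tokens(pd.Series(dup_receipt))
        demo = pd.concat([demo, dup_demo], ignore_index=True)

        old_pid = (dup_cases * 10 + 1).astype(str)
        pid_map = dict(zip(old_pid, dup_pid))

        def _dup_children(df: pd.DataFrame) -> pd.DataFrame:
            sel = df[df["primaryid"].isin(pid_map)].copy()
            sel["primaryid"] = sel["primaryid"].map(pid_map)
            return pd.concat([df, sel], ignore_index=True)

        drug_final = _dup_children(drug_final)
        reac_final = _dup_children(reac_final)
        outc_final = _dup_children(outc_final)
        ther_final = _dup_children(ther_final)
        indi_final = _dup_children(indi_final)

        dup_ledger = ledger.iloc[dup_pos].copy()
        dup_ledger["primaryid"] = dup_cases * 10 + 2
        dup_ledger["is_duplicate"] = True
        ledger = pd.concat([ledger, dup_ledger], ignore_index=True)

    frames = {"demo": demo, "drug": drug_final, "reac": reac_final,
              "outc": outc_final, "ther": ther_final, "indi": indi_final}
    for name, df in frames.items():
        for col in df.columns:
            df[col] = df[col].astype(str)
        _add_parsed_dates(name, df)
    quarter = RawQuarter(**frames)

    if out_dir is not None:
        from .io import write_quarter

        write_quarter(quarter, out_dir)
        GeneratorLedger(ledger).to_csv(str(out_dir) + "/LEDGER.csv")
    return quarter, GeneratorLedger(ledger)


# ---------------------------------------------------------------------------
# onset-time study cohorts

@dataclass
class TtoStudyConfig:
    """Design of a simulated onset-time study: group-specific log-normal
    onset days with Bernoulli fatality.  Defaults encode the shifted
    design (fatal onset scale exp(3.2) vs non-fatal exp(3.7) days at
    n = 400); set the two location parameters equal for null studies."""

    n: int = 400
    fatal_prob: float = 0.3
    mu_fatal: float = 3.2
    sigma_fatal: float = 1.0
    mu_nonfatal: float = 3.7
    sigma_nonfatal: float = 1.0
    regimen_weights: Dict[str, float] = field(
        default_factory=lambda: {"nivolumab": 0.5, "pembrolizumab": 0.3,
                                 "ipilimumab": 0.2})
    tto_missing_rate: float = 0.0


def _minimal_case(i: int, regimen_label: str, fatal: bool,
                  tto: Optional[int]) -> CaseRecord:
    suspects = frozenset(regimen_label.split("+"))
    drugs = [DrugUse(raw_name=name, active_ingredient=name,
                     role="PS" if j == 0 else "SS", seq=str(j + 1), name=name)
             for j, name in enumerate(sorted(suspects))]
    report = SafetyReport(
        case_id=f"SIM-{i:06d}", primary_id=f"{i + 1}", case_version=1,
        receipt_date=FuzzyDate(2019, 6, 15), event_date=None, age_years=None,
        sex=None, region=None, reporter=None, drugs=drugs,
        reactions={"pericardial effusion"},
        outcomes={"DE"} if fatal else {"HO"}, indications=set(),
    )
    return CaseRecord(report=report, regimen=label_from_suspects(suspects),
                      fatal=fatal, tto_days=tto, tto_bin=tto_bin(tto),
                      indication_group="Unknown or missing")


def generate_tto_cohort(config: TtoStudyConfig, seed: Optional[int] = None) -> CaseCohort:
    """Simulated pericardial cohort for onset-time power / size studies."""
    rng = np.random.default_rng(seed)
    n = config.n
    if n == 0:
        return CaseCohort(records=[], provenance={"source": "tto-study", "n": 0})
    fatal = rng.random(n) < config.fatal_prob
    mu = np.where(fatal, config.mu_fatal, config.mu_nonfatal)
    sigma = np.where(fatal, config.sigma_fatal, config.sigma_nonfatal)
    tto = np.round(rng.lognormal(mu, sigma)).astype(int)
    missing = rng.random(n) < config.tto_missing_rate
    keys = list(config.regimen_weights)
    p = np.asarray([config.regimen_weights[k] for k in keys], dtype=float)
    labels = rng.choice(np.asarray(keys, dtype=object), size=n, p=p / p.sum())
    records = [
        _minimal_case(i, labels[i], bool(fatal[i]),
                      None if missing[i] else int(tto[i]))
        for i in range(n)
    ]
    return CaseCohort(records=records,
                      provenance={"source": "tto-study", "n": n})


# ---------------------------------------------------------------------------
# the deterministic characteristics-table fixture

_REGION_TO_COUNTRY = {"Europe": "FR", "America": "US", "Asia": "JP",
                      "Oceania": "AU", "Africa": "ZA", None: ""}
_GROUP_TO_TERM = {
    "Melanoma": "malignant melanoma",
    "Lung cancer": "non-small cell lung cancer",
    "Hematological cancer and lymphoma": "lymphoma",
    "Gastrointestinal cancer": "gastric cancer",
    "Head and neck cancer": "head and neck cancer",
    "Breast cancer": "breast cancer",
    "Tumors of female reproductive organs": "ovarian cancer",
    "Mesothelioma": "mesothelioma",
    "Non-specified malignant neoplasm": "malignant neoplasm",
    "Tumors of urinary system": "bladder cancer",
    "Other indications": "sarcoma",
    "Unknown or missing": "",
}
_SEX_TO_TOKEN = {"female": "F", "male": "M", None: ""}
_REPORTER_TO_TOKEN = {"health-professional": "MD",
                      "non-health-professional": "CN", None: ""}


def cohort_to_quarter(cohort: CaseCohort) -> RawQuarter:
    """Materialize a cohort as FAERS-style quarter files.

    Each record becomes one report whose derived fields survive the full
    read -> assemble -> build_cohort round trip: the event date is set to
    the receipt date and the therapy start is backdated by the onset days,
    so onset, year, region, reporter and regimen are all recoverable.
    """
    import datetime as _dt

    demo_rows, drug_rows, reac_rows, outc_rows, ther_rows, indi_rows = \
        [], [], [], [], [], []
    for i, rec in enumerate(cohort):
        r = rec.report
        pid = str(i + 1)
        receipt = r.receipt_date or FuzzyDate(2019, 6, 15)
        if rec.tto_days is not None:
            event = receipt.to_date()
            start = event - _dt.timedelta(days=int(rec.tto_days))
            event_tok = event.strftime("%Y%m%d")
            start_tok = start.strftime("%Y%m%d")
        else:
            event_tok, start_tok = "", ""
        age = "" if r.age_years is None else str(int(round(r.age_years)))
        demo_rows.append((pid, r.case_id, "1", receipt.token(), event_tok,
                          age, "YR" if age else "", _SEX_TO_TOKEN[r.sex],
                          _REPORTER_TO_TOKEN[r.reporter],
                          _REGION_TO_COUNTRY.get(r.region, "")))
        for d in r.drugs:
            name = (d.name or d.raw_name).upper()
            drug_rows.append((pid, d.seq, d.role, name, name))
            if start_tok and d.name in ICI_CLASS:
                ther_rows.append((pid, d.seq, start_tok, ""))
        for pt in sorted(r.reactions):
            reac_rows.append((pid, pt.title(), ""))
        for code in sorted(r.outcomes):
            outc_rows.append((pid, code))
        term = _GROUP_TO_TERM.get(rec.indication_group, rec.indication_group)
        if term and r.drugs:
            indi_rows.append((pid, r.drugs[0].seq, term))

    frames = {
        "demo": pd.DataFrame(demo_rows, columns=[
            "primaryid", "caseid", "caseversion", "fda_dt", "event_dt",
            "age", "age_cod", "sex", "occp_cod", "occr_country"]),
        "drug": pd.DataFrame(drug_rows, columns=[
            "primaryid", "drug_seq", "role_cod", "drugname", "prod_ai"]),
        "reac": pd.DataFrame(reac_rows, columns=["primaryid", "pt", "pt_cod"]),
        "outc": pd.DataFrame(outc_rows, columns=["primaryid", "outc_cod"]),
        "ther": pd.DataFrame(ther_rows, columns=[
            "primaryid", "dsg_drug_seq", "start_dt", "end_dt"]),
        "indi": pd.DataFrame(indi_rows, columns=[
            "primaryid", "indi_drug_seq", "indi_pt"]),
    }
    for name, df in frames.items():
        _add_parsed_dates(name, df)
    return RawQuarter(**frames)


class FixtureAuditError(AssertionError):
    """The reconstructed fixture failed its margin self-audit."""


def _table2() -> dict:
    return json.loads(
        resources.files("faerspv.data").joinpath("table2.json").read_text())


_SEX_FROM_LABEL = {"Female": "female", "Male": "male", "Unknown or missing": None}
_AGE_FROM_LABEL = {"<18": 10.0, "18-64": 40.0, "65-84": 70.0, ">=85": 90.0,
                   "Unknown or missing": None}
_REGION_FROM_LABEL = {"Europe": "Europe", "America": "America", "Asia": "Asia",
                      "Oceania": "Oceania", "Africa": "Africa",
                      "Unknown or missing": None}
_REPORTER_FROM_LABEL = {"Health-care professional": "health-professional",
                        "Non-health-care professional": "non-health-professional",
                        "Unknown or missing": None}
_OUTCOME_FROM_LABEL = {"Death": {"DE"}, "Life-threatening": {"LT"},
                       "Disability": {"DS"}, "Hospitalization": {"HO"},
                       "Other serious": {"OT"}, "Unknown or missing": set()}
#: bin-representative onset days (bin membership is the reproducible
#: surface; the published medians are not recoverable from binned counts)
_TTO_FROM_LABEL = {"0-30": 15, "31-60": 45, "61-90": 75, "91-180": 135,
                   ">180": 270, "Unknown or missing": None}


def _spread(block_rows: List[dict], column: str, size: int) -> List[str]:
    """Sequential fill of one status column: repeat each row label by its
    count, in table order.  For the unknown-outcome column the per-row
    count is the margin gap total - fatal - nonfatal."""
    labels: List[str] = []
    for row in block_rows:
        if row.get("aggregate"):
            continue
        if column == "unknown":
            k = row["total"] - row["fatal"] - row["nonfatal"]
        else:
            k = row[column]
        labels.extend([row["label"]] * k)
    if len(labels) != size:
        raise FixtureAuditError(
            f"column {column!r} fills {len(labels)} of {size} records")
    return labels


def build_table2_fixture() -> CaseCohort:
    """Deterministic 705-record cohort matching every published
    characteristic-by-fatality margin exactly.

    Characteristics are assigned independently within outcome status by
    sequential fill; the joint distribution across characteristics is
    therefore one margin-exact choice among many, which is all the
    published two-way margins constrain.  A self-audit re-derives all nine
    blocks against the shipped machine-readable table and raises
    :class:`FixtureAuditError` naming the first mismatching block.
    """
    spec = _table2()
    sizes = spec["total"]
    n_fatal, n_nonfatal = sizes["fatal"], sizes["nonfatal"]
    n_unknown = sizes["total"] - n_fatal - n_nonfatal

    assignments: Dict[str, Dict[str, List[str]]] = {}
    for block, rows in spec["blocks"].items():
        assignments[block] = {
            "fatal": _spread(rows, "fatal", n_fatal),
            "nonfatal": _spread(rows, "nonfatal", n_nonfatal),
            "unknown": _spread(rows, "unknown", n_unknown),
        }

    regimen_rows = {r["label"]: r for r in spec["blocks"]["regimen"]}
    regimen_of_label = {r["label"]: r["regimen"]
                        for r in spec["blocks"]["regimen"] if "regimen" in r}

    records: List[CaseRecord] = []
    i = 0
    for status, size in (("fatal", n_fatal), ("nonfatal", n_nonfatal),
                         ("unknown", n_unknown)):
        for k in range(size):
            get = lambda block: assignments[block][status][k]  # noqa: E731
            regimen_label = regimen_of_label[get("regimen")]
            suspects = frozenset(regimen_label.split("+"))
            drugs = [DrugUse(raw_name=name, active_ingredient=name,
                             role="PS" if j == 0 else "SS", seq=str(j + 1),
                             name=name)
                     for j, name in enumerate(sorted(suspects))]
            year_label = get("reporting_year")
            year = 2020 if year_label == "2020 (Q1)" else int(year_label)
            tto = _TTO_FROM_LABEL[get("tto_bin")]
            if status == "fatal":
                outcomes = {"DE"}
            elif status == "nonfatal":
                outcomes = set(_OUTCOME_FROM_LABEL[get("outcome")])
            else:
                outcomes = set()
            report = SafetyReport(
                case_id=f"T2-{i:04d}", primary_id=str(i + 1), case_version=1,
                receipt_date=FuzzyDate(year, 6, 15),
                event_date=None,
                age_years=_AGE_FROM_LABEL[get("age_group")],
                sex=_SEX_FROM_LABEL[get("gender")],
                region=_REGION_FROM_LABEL[get("region")],
                reporter=_REPORTER_FROM_LABEL[get("reporter")],
                drugs=drugs,
                reactions={"pericardial effusion"},
                outcomes=outcomes,
                indications=set(),
            )
            indication = get("indication")
            records.append(CaseRecord(
                report=report,
                regimen=label_from_suspects(suspects),
                fatal=status == "fatal",
                tto_days=tto, tto_bin=tto_bin(tto),
                indication_group=indication,
            ))
            i += 1

    cohort = CaseCohort(
        records=records,
        provenance={"source": "characteristics-table fixture",
                    "cases": len(records)},
    )
    _audit_fixture(cohort, spec)
    return cohort


def _audit_fixture(cohort: CaseCohort, spec: dict) -> None:
    """Re-derive all nine blocks and compare to the shipped table."""
    from .features import build_characteristics_table

    table = build_characteristics_table(cohort)
    frame = table.frame.set_index(["block", "label"])
    for block, rows in spec["blocks"].items():
        for row in rows:
            try:
                got = frame.loc[(block, row["label"])]
            except KeyError:
                raise FixtureAuditError(
                    f"block {block!r}: row {row['label']!r} missing") from None
            for col, key in (("total_n", "total"), ("fatal_n", "fatal"),
                             ("nonfatal_n", "nonfatal")):
                if int(got[col]) != row[key]:
                    raise FixtureAuditError(
                        f"block {block!r} row {row['label']!r}: "
                        f"{key} = {int(got[col])}, expected {row[key]}")
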