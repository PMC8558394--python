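"""Phecode-based disease scans and the rank-sum disparity score.

ICD-10 diagnosis codes map to curated phenotype codes (phecodes); each phecode
entry carries inclusion ICD-10 codes and exclusion phecode ranges that remove
related conditions from the control group (e.g. type 1 diabetics are neither
cases nor controls for type 2 diabetes). Per disease, a single multivariable
logistic model of case status on ethnicity, mean-centered age, sex and log CRP
yields the CRP and ethnicity effects; Bonferroni filtering and a rank-sum of
the two effect sizes order diseases by joint association strength.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .crpmodels import CRPLogisticModel, build_design
from .exceptions import InputError, PhecodeParseError, SeparationError
from .exceptions import RankDeficiencyError

logger = logging.getLogger(__name__)

SCAN_TERMS = ["ethnicity", "age_centered", "sex", "log_crp"]


@dataclass
class PhecodeEntry:
    phecode: str
    inclusion_codes: set
    exclusion_ranges: list      # [(low, high) floats, low <= high]
    category: str
    description: str


@dataclass
class PhecodeMap:
    entries: dict = field(default_factory=dict)   # phecode (str) -> PhecodeEntry

    def __len__(self):
        return len(self.entries)

    def icd_to_phecodes(self) -> dict:
        """ICD-10 code -> set of phecodes that include it."""
        out: dict = {}
        for e in self.entries.values():
            for icd in e.inclusion_codes:
                out.setdefault(icd, set()).add(e.phecode)
        return out

    def participant_phecodes(self, icd_codes) -> set:
        lookup = self.icd_to_phecodes()
        out: set = set()
        for icd in icd_codes:
            out |= lookup.get(icd, set())
        return out


def _normalize_phecode(value) -> str:
    f = float(value)
    if f <= 0:
        raise ValueError(f"phecode must be positive, got {value}")
    if round(f, 2) != f:
        raise ValueError(f"phecode has more than 2 fractional digits: {value}")
    return f"{f:g}"


def load_phecode_map(source) -> PhecodeMap:
    """Load and validate a phecode map CSV.

    Expected columns: phecode, icd10, exclude_low, exclude_high, category,
    description. Multiple rows per phecode add inclusion ICD-10 codes;
    duplicate (phecode, icd10) rows and malformed ranges raise
    :class:`PhecodeParseError` with the offending line numbers.
    """
    df = pd.read_csv(source, dtype={"icd10": str})
    required = ["phecode", "icd10", "exclude_low", "exclude_high",
                "category", "description"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise PhecodeParseError(f"phecode map missing columns {missing}")
    lines = df.index.to_numpy() + 2  # header is line 1
    bad = []
    entries: dict = {}
    seen_pairs = set()
    for i, row in df.iterrows():
        line = int(lines[i])
        try:
            code = _normalize_phecode(row["phecode"])
        except ValueError:
            bad.append((line, "bad phecode"))
            continue
        lo, hi = float(row["exclude_low"]), float(row["exclude_high"])
        if not lo <= hi:
            bad.append((line, "exclusion range low > high"))
            continue
        pair = (code, row["icd10"])
        if pair in seen_pairs:
            bad.append((line, "duplicate (phecode, icd10) row"))
            continue
        seen_pairs.add(pair)
        entry = entries.setdefault(
            code, PhecodeEntry(code, set(), [], str(row["category"]),
                               str(row["description"])))
        entry.inclusion_codes.add(str(row["icd10"]))
        if (lo, hi) not in entry.exclusion_ranges:
            entry.exclusion_ranges.append((lo, hi))
    if bad:
        raise PhecodeParseError(
            "malformed phecode map rows: "
            + "; ".join(f"line {l}: {m}" for l, m in bad),
            lines=[l for l, _ in bad],
        )
    return PhecodeMap(entries=entries)


def load_toy_map() -> PhecodeMap:
    """The small phecode map bundled for tests and smoke runs."""
    with resources.files("crpdecomp.data").joinpath("toy_phecodes.csv").open() as fh:
        return load_phecode_map(fh)


@dataclass
class CaseControlCohort:
    phecode: str
    case_ids: np.ndarray
    control_ids: np.ndarray


def _split_codes(value) -> list:
    if isinstance(value, (list, set, tuple)):
        return list(value)
    if pd.isna(value) or value == "":
        return []
    return str(value).split(";")


def build_case_control(phecode, pmap: PhecodeMap,
                       table: pd.DataFrame) -> CaseControlCohort:
    """Case/control split for one phecode with exclusion-range control removal.

    Cases carry at least one inclusion ICD-10 code. Controls carry no
    inclusion code and no phecode (from any of their diagnoses) inside any of
    the entry's exclusion ranges; everyone else is excluded from the cohort.
    """
    code = _normalize_phecode(phecode)
    if code not in pmap.entries:
        raise InputError(f"phecode {phecode} not in map")
    entry = pmap.entries[code]
    lookup = pmap.icd_to_phecodes()
    case, control = [], []
    for pid, codes in zip(table["participant_id"], table["icd10_codes"]):
        icds = _split_codes(codes)
        if any(icd in entry.inclusion_codes for icd in icds):
            case.append(pid)
            continue
        phecodes = set()
        for icd in icds:
            phecodes |= lookup.get(icd, set())
        excluded = any(
            lo <= float(p) <= hi for p in phecodes
            for lo, hi in entry.exclusion_ranges
        )
        if not excluded:
            control.append(pid)
    return CaseControlCohort(code, np.array(case, dtype=object),
                             np.array(control, dtype=object))


def phecode_incidence(table, pmap: PhecodeMap):
    """Participant x phecode membership matrix (via inclusion ICD-10 codes).

    Returns ``(phecodes, M)`` where ``M[i, j]`` is True when participant i
    carries an inclusion code of phecode j. Parsed once per scan so the
    per-disease case/control split reduces to boolean column operations.
    """
    phecodes = sorted(pmap.entries, key=float)
    idx = {p: j for j, p in enumerate(phecodes)}
    lookup = pmap.icd_to_phecodes()
    M = np.zeros((len(table), len(phecodes)), dtype=bool)
    for i, val in enumerate(table["icd10_codes"].to_numpy()):
        for icd in _split_codes(val):
            for p in lookup.get(icd, ()):
                M[i, idx[p]] = True
    return phecodes, M


def _case_control_masks(code: str, pmap: PhecodeMap, phecodes, M):
    """Boolean (case, control) masks; equivalent to :func:`build_case_control`."""
    j = phecodes.index(code)
    entry = pmap.entries[code]
    case = M[:, j]
    excl_cols = [
        k for k, p in enumerate(phecodes)
        if any(lo <= float(p) <= hi for lo, hi in entry.exclusion_ranges)
    ]
    in_excluded_range = M[:, excl_cols].any(axis=1) if excl_cols \
        else np.zeros(len(M), dtype=bool)
    control = ~case & ~in_excluded_range
    return case, control


def disease_scan(table, pmap: PhecodeMap, min_cases: int = 20,
                 phecodes=None, mode: str = "joint") -> pd.DataFrame:
    """Per-phecode logistic scan of case status.

    ``mode='joint'`` (default) fits one model per disease with ethnicity,
    mean-centered age, sex and log CRP together and reads both effects from
    it; ``mode='separate'`` fits two models, each with age and sex plus one of
    the two exposures. Diseases with fewer than ``min_cases`` cases, or whose
    fit fails to converge or separates, are flagged ``skipped``.
    """
    if min_cases < 1:
        raise InputError("min_cases must be >= 1")
    if mode not in ("joint", "separate"):
        raise InputError(f"unknown scan mode {mode!r}")
    all_codes, M = phecode_incidence(table, pmap)
    if phecodes is None:
        phecodes = all_codes
    else:
        phecodes = [_normalize_phecode(p) for p in phecodes]
    designs = {"joint": (build_design(table, SCAN_TERMS), SCAN_TERMS)}
    if mode == "separate":
        designs["crp"] = (build_design(table, ["age_centered", "sex", "log_crp"]),
                          ["age_centered", "sex", "log_crp"])
        designs["eth"] = (build_design(table, ["age_centered", "sex", "ethnicity"]),
                          ["age_centered", "sex", "ethnicity"])
    rows = []
    for code in phecodes:
        entry = pmap.entries[code]
        case, control = _case_control_masks(code, pmap, all_codes, M)
        row = {
            "phecode": code,
            "category": entry.category,
            "description": entry.description,
            "n_cases": int(case.sum()),
            "n_controls": int(control.sum()),
            "beta_crp": np.nan, "p_crp": np.nan,
            "beta_eth": np.nan, "p_eth": np.nan,
            "skipped": False,
        }
        if row["n_cases"] < min_cases:
            row["skipped"] = True
            rows.append(row)
            continue
        mask = case | control
        y = case[mask].astype(float)
        try:
            if mode == "joint":
                X, terms = designs["joint"]
                res = CRPLogisticModel(y, X[mask], terms, outcome_name="case").fit()
                row["beta_crp"] = res.params["log_crp"]
                row["p_crp"] = res.pvalues["log_crp"]
                row["beta_eth"] = res.params["ethnicity[Black]"]
                row["p_eth"] = res.pvalues["ethnicity[Black]"]
            else:
                for key, bkey, pkey, col in (
                    ("crp", "beta_crp", "p_crp", "log_crp"),
                    ("eth", "beta_eth", "p_eth", "ethnicity[Black]"),
                ):
                    X, terms = designs[key]
                    res = CRPLogisticModel(y, X[mask], terms,
                                           outcome_name="case").fit()
                    row[bkey] = res.params[col]
                    row[pkey] = res.pvalues[col]
        except (SeparationError, RankDeficiencyError) as err:
            logger.warning("phecode %s flagged: %s", code, err)
            row["skipped"] = True
        rows.append(row)
    return pd.DataFrame(rows)


def bonferroni_flags(tbl: pd.DataFrame, alpha: float = 0.05,
                     m: int | None = None) -> pd.DataFrame:
    """Add ``sig_crp`` / ``sig_eth`` flags at the Bonferroni threshold alpha/m.

    ``m`` defaults to the number of diseases actually scanned (not skipped);
    significance is strict (p exactly at the threshold is not significant).
    """
    out = tbl.copy()
    if m is None:
        m = int((~out["skipped"]).sum())
    if m < 1:
        raise InputError("m must be >= 1")
    thr = alpha / m
    out["sig_crp"] = (out["p_crp"] < thr) & ~out["skipped"]
    out["sig_eth"] = (out["p_eth"] < thr) & ~out["skipped"]
    out.attrs["bonferroni_threshold"] = thr
    return out


def rank_sum_disparity(tbl: pd.DataFrame, top_k: int = 20) -> pd.DataFrame:
    """Rank-sum disparity score over diseases significant in both scans.

    Effect sizes are ranked ascending (largest effect = largest rank, average
    ranks on ties) separately for the CRP and ethnicity scans;
    ``rank_sum = rank_crp + rank_eth`` and the table is sorted by descending
    rank sum (phecode as a deterministic tiebreak), truncated to ``top_k``.
    """
    need = {"sig_crp", "sig_eth"}
    if need - set(tbl.columns):
        raise InputError("run bonferroni_flags before rank_sum_disparity")
    eligible = tbl[tbl["sig_crp"] & tbl["sig_eth"]].copy()
    if len(eligible) == 0:
        logger.info("rank_sum_disparity: no disease significant in both scans")
        return eligible.assign(rank_crp=pd.Series(dtype=float),
                               rank_eth=pd.Series(dtype=float),
                               rank_sum=pd.Series(dtype=float))
    eligible["rank_crp"] = rankdata(eligible["beta_crp"], method="average")
    eligible["rank_eth"] = rankdata(eligible["beta_eth"], method="average")
    eligible["rank_sum"] = eligible["rank_crp"] + eligible["rank_eth"]
    eligible = eligible.sort_values(
        ["rank_sum", "phecode"], ascending=[False, True]
    ).reset_index(drop=True)
    return eligible.head(top_k)


def manhattan_frame(tbl: pd.DataFrame, which: str = "crp") -> pd.DataFrame:
    """Plot-data table (category, phecode, -log10 p) for one scan."""
    pcol = {"crp": "p_crp", "eth": "p_eth"}.get(which)
    if pcol is None:
        raise InputError("which must be 'crp' or 'eth'")
    sub = tbl[~tbl["skipped"]]
    with np.errstate(divide="ignore"):
        neglog = -np.log10(sub[pcol].to_numpy(float))
    return pd.DataFrame({
        "category": sub["category"], "phecode": sub["phecode"],
        "neg_log10_p": neglog,
    })
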