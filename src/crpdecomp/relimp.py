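"""LMG relative-importance decomposition of R-squared.

The LMG metric attributes the full model's R-squared to regressor groups by
averaging each group's sequential R-squared increase over all orderings in
which the groups can enter the model. It is computed here by the equivalent
subset-weighted sum

    share(g) = (1/G) * sum_{k=0}^{G-1} C(G-1, k)^{-1}
               * sum_{|S|=k, g not in S} [R2(S + g) - R2(S)]

with exact enumeration of all 2^G subsets (G <= 20). Categorical covariates
enter as indivisible groups (e.g. the three non-reference smoking indicators
form one group), so each covariate receives one share and one rank. Shares
sum exactly to the full-model R-squared.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .exceptions import InputError, RankDeficiencyError

MAX_GROUPS = 20


@dataclass
class RegressorGrouping:
    """Ordered (group name, design-column list) pairs plus the outcome column."""

    groups: list          # [(name, [columns...]), ...]
    outcome: str

    def __post_init__(self):
        if len(self.groups) < 1:
            raise InputError("need at least one regressor group")
        seen = set()
        for _, cols in self.groups:
            for c in cols:
                if c in seen:
                    raise InputError(f"design column {c!r} appears in two groups")
                seen.add(c)

    @property
    def names(self) -> list:
        return [n for n, _ in self.groups]


def _gram(data: pd.DataFrame, grouping: RegressorGrouping):
    """Centered cross-product matrices for fast subset R-squared."""
    all_cols = [c for _, cols in grouping.groups for c in cols]
    missing = [c for c in all_cols + [grouping.outcome] if c not in data.columns]
    if missing:
        raise InputError(f"columns missing from data: {missing}")
    X = data[all_cols].to_numpy(dtype=float)
    y = data[grouping.outcome].to_numpy(dtype=float)
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    return Xc.T @ Xc, Xc.T @ yc, float(yc @ yc), all_cols


def _subset_r2(XtX, Xty, Syy, col_idx, group_names=None) -> float:
    if len(col_idx) == 0:
        return 0.0
    idx = np.asarray(col_idx)
    A = XtX[np.ix_(idx, idx)]
    b = Xty[idx]
    try:
        L = np.linalg.cholesky(A)
    except np.linalg.LinAlgError:
        raise RankDeficiencyError(
            f"rank-deficient regressor subset {group_names}", terms=group_names
        )
    # exactly collinear columns can survive the factorization with a tiny
    # pivot from rounding; treat those as rank deficient too
    if (np.diag(L) ** 2 <= 1e-10 * np.max(np.diag(A))).any():
        raise RankDeficiencyError(
            f"rank-deficient regressor subset {group_names}", terms=group_names
        )
    z = np.linalg.solve(L, b)
    return float(z @ z / Syy)


def r2_of_subset(data: pd.DataFrame, grouping: RegressorGrouping, subset) -> float:
    """OLS R-squared (with intercept) using the groups named in ``subset``."""
    XtX, Xty, Syy, all_cols = _gram(data, grouping)
    names = set(subset)
    unknown = names - set(grouping.names)
    if unknown:
        raise InputError(f"unknown groups in subset: {sorted(unknown)}")
    col_idx = [all_cols.index(c) for n, cols in grouping.groups if n in names
               for c in cols]
    return _subset_r2(XtX, Xty, Syy, col_idx, group_names=sorted(names))


@dataclass
class ImportanceResult:
    shares: pd.Series        # per-group contribution to R2 (sums to total_r2)
    ranks: pd.Series         # 1 = largest share; ties share the smaller rank
    total_r2: float

    @property
    def normalized_shares(self) -> pd.Series:
        """Shares rescaled to sum to 1 (fraction of explained variance)."""
        return self.shares / self.total_r2

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "group": self.shares.index,
            "share": self.shares.to_numpy(),
            "share_of_r2_pct": 100.0 * self.normalized_shares.to_numpy(),
            "rank": self.ranks.to_numpy(),
        })


def lmg_shares(data: pd.DataFrame, grouping: RegressorGrouping) -> ImportanceResult:
    """Exact LMG decomposition over regressor groups.

    Enumerates all 2^G subsets once, caching each subset's R-squared, then
    combines sequential increments with the order-averaging weights.
    """
    G = len(grouping.groups)
    if G > MAX_GROUPS:
        raise InputError(
            f"{G} groups exceeds the exact-enumeration limit of {MAX_GROUPS}; "
            "a sampling approximation over orderings would be required"
        )
    XtX, Xty, Syy, all_cols = _gram(data, grouping)
    group_cols = [
        [all_cols.index(c) for c in cols] for _, cols in grouping.groups
    ]

    r2_cache = {}

    def r2_of_mask(mask: int) -> float:
        if mask not in r2_cache:
            idx = [c for g in range(G) if mask >> g & 1 for c in group_cols[g]]
            names = [grouping.names[g] for g in range(G) if mask >> g & 1]
            r2_cache[mask] = _subset_r2(XtX, Xty, Syy, idx, group_names=names)
        return r2_cache[mask]

    shares = np.zeros(G)
    others = [[h for h in range(G) if h != g] for g in range(G)]
    for g in range(G):
        bit = 1 << g
        total = 0.0
        for k in range(G):
            w = 1.0 / comb(G - 1, k)
            inc = 0.0
            for S in combinations(others[g], k):
                mask = sum(1 << h for h in S)
                inc += r2_of_mask(mask | bit) - r2_of_mask(mask)
            total += w * inc
        shares[g] = total / G
    full_r2 = r2_of_mask((1 << G) - 1)
    shares_s = pd.Series(shares, index=grouping.names)
    return ImportanceResult(shares=shares_s, ranks=ranks_from_shares(shares_s),
                            total_r2=full_r2)


def ranks_from_shares(shares: pd.Series) -> pd.Series:
    """Rank 1 = largest share; exact ties share the smaller rank, next skipped."""
    return pd.Series(rankdata(-np.asarray(shares), method="min").astype(int),
                     index=shares.index)


def importance_ranks(result: ImportanceResult) -> pd.DataFrame:
    """Ranked table, largest share first (ties share the smaller rank)."""
    return result.frame().sort_values(["rank", "group"]).reset_index(drop=True)


def table2_grouping(design: pd.DataFrame, outcome: str = "log_crp") -> RegressorGrouping:
    """The 11-covariate grouping of the fully adjusted CRP model.

    Each categorical covariate's indicator columns form one group; continuous
    covariates are singleton groups.
    """
    spec = [
        ("Ethnicity", ["ethnicity[Black]"]),
        ("Age", ["age_centered"]),
        ("Sex", ["sex[male]"]),
        ("BMI", ["bmi"]),
        ("Insomnia", ["insomnia[sometimes]", "insomnia[usually]",
                      "insomnia[prefer_not_to_answer]"]),
        ("MDD", ["mdd"]),
        ("Recruitment year", ["recruitment_year"]),
        ("Smoking", ["smoking[previous]", "smoking[current]",
                     "smoking[prefer_not_to_answer]"]),
        ("PC1", ["pc1"]),
        ("PC2", ["pc2"]),
        ("Townsend index", ["townsend"]),
    ]
    groups = [(n, [c for c in cols if c in design.columns]) for n, cols in spec]
    groups = [(n, cols) for n, cols in groups if cols]
    return RegressorGrouping(groups=groups, outcome=outcome)
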