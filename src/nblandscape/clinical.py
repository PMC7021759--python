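"""Cohort contingency tables and mutual-exclusivity statistics.

Implements the association battery used on the neuroblastoma cohort:
per-stratum mutation frequencies with exact Clopper-Pearson intervals,
two-tailed Fisher / Pearson chi-square association tests (with the
expected-count rule for choosing between them), and the stratified
Cochran-Mantel-Haenszel test used for ATRX-mutation x MYCN-amplification
mutual exclusivity across cohorts of origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.contingency_tables import StratifiedTable

__all__ = [
    "ContingencyTable",
    "build_contingency",
    "fisher_two_tailed",
    "chi_square_test",
    "select_test",
    "cmh_test",
    "clopper_pearson",
    "TABLE1_STRATA",
    "ALT_BY_ATRX",
]


@dataclass
class ContingencyTable:
    """A 2x2 table (optionally stratified) of mutation x clinical grouping."""

    counts: np.ndarray
    row_labels: tuple[str, str] = ("group1", "group2")
    col_labels: tuple[str, str] = ("mutant", "wildtype")
    strata: list[np.ndarray] = field(default_factory=list)
    n_missing: int = 0

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (2, 2):
            raise ValueError("counts must be 2x2")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def expected(self) -> np.ndarray:
        return np.outer(self.row_totals, self.col_totals) / max(self.total, 1)

    def row_percent(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return self.counts / self.row_totals[:, None]


def build_contingency(
    cohort: pd.DataFrame,
    variable: str = "stratum",
    status: str = "mutant",
    grouping: tuple[str, str] | None = None,
) -> ContingencyTable:
    """Tally a patient-level cohort table into a 2x2 contingency table.

    ``cohort`` has one row per patient; ``variable`` names the clinical
    column and ``status`` the boolean mutation column. ``grouping`` fixes
    the row order (first level = first row); by default levels are taken in
    order of first appearance. Rows with missing values in either column are
    excluded and counted in ``n_missing``.
    """
    import warnings
    sub = cohort[[variable, status]]
    missing = sub.isna().any(axis=1)
    n_missing = int(missing.sum())
    sub = sub[~missing]
    if grouping is None:
        levels = tuple(pd.unique(sub[variable]))
    else:
        levels = grouping
    if len(levels) != 2:
        raise ValueError(
            f"grouping must yield exactly 2 levels, got {list(levels)}"
        )
    counts = np.zeros((2, 2), dtype=np.int64)
    for i, level in enumerate(levels):
        mask = sub[variable] == level
        k = int(sub.loc[mask, status].astype(bool).sum())
        counts[i] = [k, int(mask.sum()) - k]
    if counts.sum() == 0:
        warnings.warn("empty cohort: all-zero contingency table")
    return ContingencyTable(
        counts,
        row_labels=(str(levels[0]), str(levels[1])),
        n_missing=n_missing,
    )


def fisher_two_tailed(table: ContingencyTable | np.ndarray) -> float:
    """Two-sided Fisher exact p by point-probability summation.

    Sums hypergeometric point probabilities of all tables (with the observed
    margins) no more probable than the observed one — the standard two-sided
    definition. A zero margin makes every table equally (un)informative and
    returns p = 1.
    """
    counts = table.counts if isinstance(table, ContingencyTable) else np.asarray(table)
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        return 1.0
    return float(stats.fisher_exact(counts, alternative="two-sided")[1])


def chi_square_test(table: ContingencyTable | np.ndarray) -> dict:
    """Pearson chi-square (1 df, no continuity correction)."""
    counts = table.counts if isinstance(table, ContingencyTable) else np.asarray(table)
    t = ContingencyTable(counts)
    if (t.expected() == 0).any():
        raise ValueError(
            "zero expected count: the chi-square approximation is invalid, "
            "use fisher_two_tailed"
        )
    statistic, p, _, _ = stats.chi2_contingency(counts, correction=False)
    return {"statistic": float(statistic), "p": float(p)}


def select_test(table: ContingencyTable | np.ndarray,
                min_expected: float = 5.0) -> str:
    """Choose the exact test when the asymptotic one is unsafe.

    Fisher when any expected count is below ``min_expected`` or any observed
    cell is zero; Pearson chi-square otherwise.
    """
    counts = table.counts if isinstance(table, ContingencyTable) else np.asarray(table)
    t = ContingencyTable(counts)
    if (t.counts == 0).any() or (t.expected() < min_expected).any():
        return "fisher"
    return "chi_square"


def cmh_test(strata: list[np.ndarray]) -> dict:
    """Cochran-Mantel-Haenszel test across 2x2 strata.

    Returns the MH chi-square statistic (1 df, no continuity correction),
    its p-value and the MH common odds ratio. All-zero strata are dropped
    with a warning; with a single stratum the statistic is the unstratified
    MH statistic (the Pearson chi-square scaled by (N-1)/N).
    """
    import warnings
    kept = []
    for i, s in enumerate(strata):
        s = np.asarray(s, dtype=float)
        if s.shape != (2, 2):
            raise ValueError(f"stratum {i} is not 2x2")
        if s.sum() == 0:
            warnings.warn(f"dropping all-zero stratum {i}")
            continue
        kept.append(s)
    if not kept:
        raise ValueError("no usable strata")
    st = StratifiedTable(kept)
    res = st.test_null_odds(correction=False)
    return {
        "statistic": float(res.statistic),
        "p": float(res.pvalue),
        "common_odds_ratio": float(st.oddsratio_pooled),
    }


def clopper_pearson(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact (Clopper-Pearson) binomial confidence interval via beta quantiles."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not (0 <= k <= n):
        raise ValueError("require 0 <= k <= n")
    alpha = 1.0 - level
    lower = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    upper = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lower, upper


# -- published cohort margins ----------------------------------------------------------
#
# Per-classification strata of the ANBL12B8 neuroblastoma cohort:
# (level, n patients, n ATRX-mutant). Denominators differ between
# classifications because not every assay/classifier was applied to every
# tumor.

TABLE1_STRATA: dict[str, list[tuple[str, int, int]]] = {
    "inss_stage": [("non-stage 4", 312, 5), ("stage 4", 162, 14)],
    "risk_group": [("low/intermediate", 375, 5), ("high", 96, 14)],
    "sex": [("female", 253, 12), ("male", 221, 7)],
    "mycn_fish": [("not amplified", 431, 18), ("amplified", 39, 1)],
    "mycn_ngs": [("not amplified", 447, 19), ("amplified", 28, 0)],
    "alk": [("no mutation", 454, 17), ("mutation", 21, 2)],
    "ploidy": [("hyperdiploid", 277, 10), ("diploid", 179, 8)],
    "loh_11q": [("no", 301, 5), ("yes", 27, 5)],
    "loh_1p": [("no", 290, 9), ("yes", 38, 1)],
    "histology": [("favorable", 314, 1), ("unfavorable", 136, 17)],
    "age_18mo": [("<18 months", 213, 0), (">=18 months", 261, 19)],
    "grade": [("differentiating", 43, 3), ("poorly/undifferentiated", 283, 15)],
    "mki": [("low/intermediate", 298, 18), ("high", 32, 0)],
    "race": [("black", 55, 5), ("other", 378, 12)],
}

#: ALT positivity by ATRX status: 17/19 ALT+ among mutants, 4/18 among wild type
ALT_BY_ATRX = np.array([[17, 2], [4, 14]])
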