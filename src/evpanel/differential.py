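"""Per-protein case-vs-control differential expression.

The test is a one-sided Wilcoxon rank-sum test with the alternative that
case abundances are stochastically greater than control abundances.  With
zero-inflated spectral counts at cohort sizes around a dozen samples per
arm, ties (blocks of exact zeros) are the norm, so the null distribution is
computed exactly whenever feasible: mid-ranks are assigned to the pooled
values and the permutation distribution of the case rank-sum over all
C(n, n_case) group relabelings is obtained by a subset-sum shift algorithm
(Streitberg–Röhmel) on doubled mid-ranks.  For larger cohorts the normal
approximation with tie-corrected variance and continuity correction is used
and the method is recorded in the result.

Fold changes are ratios of linear-scale group means; a protein detected in
cases but in no control (control mean exactly 0) is flagged CASE_EXCLUSIVE
instead of receiving an infinite ratio.  The filter cascade reproduces the
tiered selection used in discovery: significance at raw p < alpha combined
with fold-change thresholds (defaults 1.2, 2.0, 3.0), case-exclusive
proteins passing every tier.
"""

from __future__ import annotations

import dataclasses
import enum
import math
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, rankdata

from .matrix import AbundanceMatrix
from .panel import auc_mann_whitney

__all__ = [
    "FoldChangeFlag",
    "RankSumResult",
    "wilcoxon_one_sided",
    "fold_change",
    "DifferentialRecord",
    "differential_table",
    "records_to_frame",
    "write_differential_table",
    "FilterConfig",
    "FilterCascadeResult",
    "apply_filter_cascade",
    "benjamini_hochberg",
]

# Exact permutation null is used up to this pooled sample size (the study
# cohort is 13 + 15 = 28).
EXACT_LIMIT = 30


class FoldChangeFlag(enum.Enum):
    CASE_EXCLUSIVE = "***"  # ctrl mean 0, case mean > 0
    UNDEFINED = "NA"        # both means 0


@dataclasses.dataclass(frozen=True)
class RankSumResult:
    p_value: float
    rank_sum: float  # case-group mid-rank sum
    method: str      # "exact" | "normal"

    def __float__(self) -> float:
        return self.p_value


@lru_cache(maxsize=4096)
def _upper_tail(ranks2: tuple[int, ...], n_case: int) -> np.ndarray:
    """P(case rank-sum*2 >= s) for s = 0..total, over all C(n, n_case) subsets.

    ``ranks2`` are the doubled mid-ranks of the pooled sample (integers).
    Counts stay below C(30, 15) < 2**53, so float64 arithmetic is exact.
    """
    total = int(sum(ranks2))
    dp = np.zeros((n_case + 1, total + 1))
    dp[0, 0] = 1.0
    for r in ranks2:
        for k in range(n_case, 0, -1):
            dp[k, r:] += dp[k - 1, : total + 1 - r]
    counts = dp[n_case]
    tail = counts[::-1].cumsum()[::-1] / math.comb(len(ranks2), n_case)
    tail.setflags(write=False)
    return tail


def wilcoxon_one_sided(case_values, ctrl_values) -> RankSumResult:
    """One-sided Wilcoxon rank-sum p-value (alternative: case > ctrl).

    Exact permutation null (tie-aware, via mid-ranks) when the pooled size
    is <= 30; otherwise the tie-corrected normal approximation with
    continuity correction.
    """
    case = np.asarray(case_values, dtype=float)
    ctrl = np.asarray(ctrl_values, dtype=float)
    if case.size == 0 or ctrl.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([case, ctrl])
    ranks = rankdata(pooled)
    rank_sum = float(ranks[: case.size].sum())
    n = pooled.size
    if n <= EXACT_LIMIT:
        ranks2 = tuple(int(round(2 * r)) for r in sorted(ranks))
        tail = _upper_tail(ranks2, case.size)
        observed2 = int(round(2 * rank_sum))
        p = float(tail[observed2])
        return RankSumResult(p_value=p, rank_sum=rank_sum, method="exact")
    res = mannwhitneyu(case, ctrl, alternative="greater", method="asymptotic")
    return RankSumResult(p_value=float(res.pvalue), rank_sum=rank_sum, method="normal")


def fold_change(avg_case: float, avg_ctrl: float) -> float | FoldChangeFlag:
    """case:ctrl ratio of linear-scale means, or a flag when undefined.

    ``CASE_EXCLUSIVE`` when the control mean is exactly 0 and the case mean
    positive (the protein was never detected in controls); ``UNDEFINED``
    when both means are 0.
    """
    if avg_case < 0 or avg_ctrl < 0:
        raise ValueError("group means must be nonnegative")
    if avg_ctrl > 0:
        return avg_case / avg_ctrl
    if avg_case > 0:
        return FoldChangeFlag.CASE_EXCLUSIVE
    return FoldChangeFlag.UNDEFINED


@dataclasses.dataclass
class DifferentialRecord:
    """One row of the differential table (gene-level summary)."""

    gene: str
    avg_ctrl: float
    avg_case: float
    fold_change: float | FoldChangeFlag
    p_value: float
    auc: float
    test_method: str = "exact"

    @property
    def case_exclusive(self) -> bool:
        return self.fold_change is FoldChangeFlag.CASE_EXCLUSIVE

    def _fold_sort_key(self) -> float:
        if self.case_exclusive:
            return math.inf
        if self.fold_change is FoldChangeFlag.UNDEFINED:
            return -math.inf
        return float(self.fold_change)


def differential_table(matrix: AbundanceMatrix) -> list[DifferentialRecord]:
    """Per-gene means, fold change / exclusivity, one-sided p, and AUC.

    Requires a linear-scale matrix with both groups present.  Records are
    ordered by ascending p, then descending fold change (case-exclusive
    first among equals), then gene symbol, so the output is deterministic
    and invariant to sample order.
    """
    if matrix.scale != "linear":
        raise ValueError("differential_table requires linear-scale abundances")
    case_cols = matrix.case_samples
    ctrl_cols = matrix.ctrl_samples
    if not case_cols or not ctrl_cols:
        raise ValueError("both case and ctrl samples are required")
    records = []
    case_data = matrix.data[case_cols].to_numpy(dtype=float)
    ctrl_data = matrix.data[ctrl_cols].to_numpy(dtype=float)
    for i, gene in enumerate(matrix.data.index):
        cvals, gvals = case_data[i], ctrl_data[i]
        test = wilcoxon_one_sided(cvals, gvals)
        records.append(
            DifferentialRecord(
                gene=str(gene),
                avg_ctrl=float(gvals.mean()),
                avg_case=float(cvals.mean()),
                fold_change=fold_change(float(cvals.mean()), float(gvals.mean())),
                p_value=test.p_value,
                auc=auc_mann_whitney(cvals, gvals),
                test_method=test.method,
            )
        )
    records.sort(key=lambda r: (r.p_value, -r._fold_sort_key(), r.gene))
    return records


def records_to_frame(records: Iterable[DifferentialRecord]) -> pd.DataFrame:
    """Tabular view with the published column order; case-exclusive rows get
    the literal ``***`` in the fold-change column."""
    rows = []
    for r in records:
        fc = r.fold_change.value if isinstance(r.fold_change, FoldChangeFlag) else r.fold_change
        rows.append(
            {
                "gene": r.gene,
                "avg_ctrl": r.avg_ctrl,
                "avg_case": r.avg_case,
                "fold_change": fc,
                "auc": r.auc,
                "p_value": r.p_value,
            }
        )
    return pd.DataFrame(rows, columns=["gene", "avg_ctrl", "avg_case", "fold_change", "auc", "p_value"])


def write_differential_table(records: Iterable[DifferentialRecord], path) -> None:
    records_to_frame(records).to_csv(path, sep="\t", index=False, float_format="%.6g")


@dataclasses.dataclass
class FilterConfig:
    """Tiered filter: raw p < alpha plus fold-change thresholds.

    ``inclusive_tiers`` lists thresholds compared with >= instead of >
    (the highest discovery tier is "3-fold or higher" while the lower tiers
    are strict ">1.2-fold"/">2-fold").  Case-exclusive proteins pass every
    tier unless ``exclusive_counts_as_pass`` is disabled.
    """

    alpha: float = 0.05
    fold_tiers: tuple[float, ...] = (1.2, 2.0, 3.0)
    inclusive_tiers: tuple[float, ...] = (3.0,)
    exclusive_counts_as_pass: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        tiers = tuple(self.fold_tiers)
        if any(t <= 1 for t in tiers) or list(tiers) != sorted(tiers) or len(set(tiers)) != len(tiers):
            raise ValueError("fold_tiers must be > 1 and strictly increasing")
        self.fold_tiers = tiers


@dataclasses.dataclass
class FilterCascadeResult:
    tiers: dict[float, set[str]]            # fold threshold -> passing genes
    exclusive_counts: dict[float, int]      # fold threshold -> case-exclusive tally
    alpha: float


def apply_filter_cascade(
    records: Sequence[DifferentialRecord],
    config: FilterConfig | None = None,
) -> FilterCascadeResult:
    """Select, per fold tier f, genes with p < alpha and fold change beyond f
    (or case-exclusive).  Higher tiers are nested within lower ones."""
    config = config or FilterConfig()
    tiers: dict[float, set[str]] = {}
    exclusive: dict[float, int] = {}
    for tier in config.fold_tiers:
        inclusive = tier in config.inclusive_tiers
        selected: set[str] = set()
        n_excl = 0
        for r in records:
            if not r.p_value < config.alpha:
                continue
            if r.case_exclusive:
                if config.exclusive_counts_as_pass:
                    selected.add(r.gene)
                    n_excl += 1
                continue
            if isinstance(r.fold_change, FoldChangeFlag):
                continue
            fc = float(r.fold_change)
            if (fc >= tier) if inclusive else (fc > tier):
                selected.add(r.gene)
        tiers[tier] = selected
        exclusive[tier] = n_excl
    return FilterCascadeResult(tiers=tiers, exclusive_counts=exclusive, alpha=config.alpha)


def benjamini_hochberg(records: Sequence[DifferentialRecord]) -> Mapping[str, float]:
    """Optional BH-adjusted q-values (off by default in the cascade, which
    filters on raw p as in the discovery procedure)."""
    from statsmodels.stats.multitest import multipletests

    pvals = [r.p_value for r in records]
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    return {r.gene: float(q) for r, q in zip(records, qvals)}
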