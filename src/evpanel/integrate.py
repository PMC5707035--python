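"""Set-level integration of EV proteomes with reference datasets.

Gene symbols are matched exactly after upper-casing both sides.  Reported
percentages are rounded half away from zero to integers (full precision is
kept in the returned records).  The operations cover:

* two-set Venn partitioning (case-identified vs control-identified EV
  proteins);
* intersection and complement counts against reference proteomes (cell-line
  EV proteins; historical unfractionated-plasma identifications);
* per-protein NSAF enrichment of case EVs over unfractionated plasma, with
  proteins absent from plasma flagged EV_ONLY (infinite enrichment) and
  counted as exceeding any finite threshold.
"""

from __future__ import annotations

import dataclasses
import enum
import math
from typing import Iterable, Mapping

__all__ = [
    "VennPartition",
    "venn_partition",
    "intersect_with_reference",
    "novel_vs_reference",
    "EnrichmentFlag",
    "EnrichmentRatioRecord",
    "nsaf_enrichment",
    "round_percent",
]


def _norm(genes: Iterable[str]) -> set[str]:
    return {str(g).upper() for g in genes}


def round_percent(count: int, total: int) -> int:
    """Integer percent, rounding half away from zero (the reporting style
    used for discovery counts such as "238 (42%)")."""
    if total <= 0:
        raise ValueError("total must be positive")
    return int(math.floor(100.0 * count / total + 0.5))


@dataclasses.dataclass
class VennPartition:
    only_a: set[str]
    shared: set[str]
    only_b: set[str]

    @property
    def counts(self) -> tuple[int, int, int]:
        return len(self.only_a), len(self.shared), len(self.only_b)

    @property
    def total(self) -> int:
        return len(self.only_a) + len(self.shared) + len(self.only_b)

    @property
    def size_a(self) -> int:
        return len(self.only_a) + len(self.shared)

    @property
    def size_b(self) -> int:
        return len(self.only_b) + len(self.shared)


def venn_partition(set_a: Iterable[str], set_b: Iterable[str]) -> VennPartition:
    """Exact two-set algebra: unique-to-A, shared, unique-to-B."""
    a, b = _norm(set_a), _norm(set_b)
    return VennPartition(only_a=a - b, shared=a & b, only_b=b - a)


def intersect_with_reference(query: Iterable[str], reference: Iterable[str]) -> tuple[int, int]:
    """(count, rounded percent) of query genes also present in the reference."""
    q, r = _norm(query), _norm(reference)
    if not q:
        raise ValueError("query set is empty")
    count = len(q & r)
    return count, round_percent(count, len(q))


def novel_vs_reference(query: Iterable[str], reference: Iterable[str]) -> tuple[int, int]:
    """(count, rounded percent) of query genes absent from the reference."""
    q, r = _norm(query), _norm(reference)
    if not q:
        raise ValueError("query set is empty")
    count = len(q - r)
    return count, round_percent(count, len(q))


class EnrichmentFlag(enum.Enum):
    EV_ONLY = "EV_ONLY"  # plasma mean 0, EV mean > 0: infinite enrichment


@dataclasses.dataclass
class EnrichmentRatioRecord:
    gene: str
    mean_nsaf_ev_case: float
    mean_nsaf_plasma: float
    ratio: float | EnrichmentFlag

    @property
    def ev_only(self) -> bool:
        return self.ratio is EnrichmentFlag.EV_ONLY


def nsaf_enrichment(
    ev_nsaf: Mapping[str, float],
    plasma_nsaf: Mapping[str, float],
    threshold: float = 10.0,
) -> tuple[list[EnrichmentRatioRecord], int]:
    """Per-gene EV:plasma mean-NSAF ratios and the count above ``threshold``.

    Genes absent from the plasma reference are treated as plasma mean 0 and
    flagged EV_ONLY; they count toward ``n_above_threshold``.  Returns
    records sorted by descending enrichment (EV_ONLY first) then gene.
    """
    plasma = {str(g).upper(): float(v) for g, v in plasma_nsaf.items()}
    records: list[EnrichmentRatioRecord] = []
    n_above = 0
    for gene, ev_val in ev_nsaf.items():
        gene_u = str(gene).upper()
        ev_val = float(ev_val)
        if ev_val < 0:
            raise ValueError(f"negative NSAF for {gene_u}")
        pl_val = plasma.get(gene_u, 0.0)
        if pl_val > 0:
            ratio: float | EnrichmentFlag = ev_val / pl_val
            if ratio > threshold:
                n_above += 1
        elif ev_val > 0:
            ratio = EnrichmentFlag.EV_ONLY
            n_above += 1
        else:
            ratio = 0.0
        records.append(
            EnrichmentRatioRecord(
                gene=gene_u,
                mean_nsaf_ev_case=ev_val,
                mean_nsaf_plasma=pl_val,
                ratio=ratio,
            )
        )
    records.sort(
        key=lambda r: (-math.inf if r.ev_only else -float(r.ratio), r.gene)
    )
    return records, n_above
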