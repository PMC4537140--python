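"""Exact-test overlap between the palmitoylome and an external gene list.

Builds the 2x2 contingency table over the background universe (in list x
in compendium), runs the two-sided Fisher exact test (point-probability
rule), and reports sample and conditional-MLE odds ratios with the exact
conditional confidence interval, plus both directional overlap percentages
(e.g. the share of synaptic genes that are palmitoylated, and conversely).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
from scipy import stats
from scipy.stats.contingency import odds_ratio as _odds_ratio

from .enrich import Background
from .errors import ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContingencyTable:
    """Counts over the background universe; rows = in list, cols = in compendium."""

    a: int  # in list and in compendium
    b: int  # in list, not in compendium
    c: int  # not in list, in compendium
    d: int  # neither
    row_label: str = "in_list"
    col_label: str = "in_compendium"

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValidationError("contingency cells must be non-negative")

    @property
    def N(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


@dataclass
class OverlapResult:
    table: ContingencyTable
    p_two_sided: float
    odds_ratio_sample: float
    odds_ratio_cmle: Optional[float]
    ci_95: tuple[Optional[float], Optional[float]]
    fold: float
    percent_overlap: float  # a / (a + b)
    converse_percent: float  # a / (a + c)
    converse_fold: float

    def to_dict(self) -> dict:
        return {
            "cells": {"a": self.table.a, "b": self.table.b, "c": self.table.c, "d": self.table.d},
            "N": self.table.N,
            "p_two_sided": self.p_two_sided,
            "odds_ratio_sample": self.odds_ratio_sample,
            "odds_ratio_cmle": self.odds_ratio_cmle,
            "ci_95": list(self.ci_95),
            "fold": self.fold,
            "percent_overlap": self.percent_overlap,
            "converse_percent": self.converse_percent,
            "converse_fold": self.converse_fold,
        }


def build_contingency(
    compendium: Iterable[str], gene_list: Iterable[str], background: Background
) -> ContingencyTable:
    """2x2 membership table evaluated over the background universe only.

    List or compendium genes outside the background are dropped (logged).
    """
    universe = background.genes
    comp = {str(g).strip().upper() for g in compendium if str(g).strip()} & universe
    lst = {str(g).strip().upper() for g in gene_list if str(g).strip()}
    dropped = len(lst - universe)
    if dropped:
        logger.info("dropped %d list genes outside the background", dropped)
    lst &= universe
    if not lst:
        raise ValidationError("gene list has no members inside the background")
    a = len(lst & comp)
    b = len(lst - comp)
    c = len(comp - lst)
    d = len(universe) - a - b - c
    return ContingencyTable(a=a, b=b, c=c, d=d)


def fisher_exact_two_sided(table: ContingencyTable) -> float:
    """Two-sided Fisher exact p by the point-probability rule.

    Sums, over all tables with the observed margins, the probabilities of
    tables no more likely than the observed one.
    """
    p = stats.fisher_exact(table.as_array(), alternative="two-sided")[1]
    return float(min(1.0, p))


def fisher_exact_one_sided(table: ContingencyTable) -> float:
    """Upper-tail Fisher p (over-representation direction on cell a)."""
    return float(stats.fisher_exact(table.as_array(), alternative="greater")[1])


def odds_ratio_ci(
    table: ContingencyTable, level: float = 0.95
) -> tuple[float, Optional[float], tuple[Optional[float], Optional[float]]]:
    """Sample OR, conditional-MLE OR, and the exact conditional interval.

    The sample OR uses the Haldane 0.5 continuity correction only when a
    cell is zero. Degenerate margins give an undefined (None) cMLE/CI.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if min(a + b, c + d, a + c, b + d) == 0:
        logger.warning("degenerate margins; odds ratio undefined")
        return float("nan"), None, (None, None)
    if min(a, b, c, d) == 0:
        or_sample = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        or_sample = (a * d) / (b * c)
    res = _odds_ratio(table.as_array(), kind="conditional")
    ci = res.confidence_interval(confidence_level=level)
    return float(or_sample), float(res.statistic), (float(ci.low), float(ci.high))


def overlap_summary(
    compendium: Iterable[str], gene_list: Iterable[str], background: Background
) -> OverlapResult:
    """Full two-direction overlap report for one gene list."""
    table = build_contingency(compendium, gene_list, background)
    p = fisher_exact_two_sided(table)
    or_sample, or_cmle, ci = odds_ratio_ci(table)
    N = table.N
    list_size = table.a + table.b
    comp_size = table.a + table.c
    percent = table.a / list_size if list_size else 0.0
    converse = table.a / comp_size if comp_size else 0.0
    # fold: palmitoylated fraction inside the list over that in the universe
    fold = percent / (comp_size / N) if comp_size else float("nan")
    converse_fold = converse / (list_size / N) if list_size else float("nan")
    return OverlapResult(
        table=table,
        p_two_sided=p,
        odds_ratio_sample=or_sample,
        odds_ratio_cmle=or_cmle,
        ci_95=ci,
        fold=fold,
        percent_overlap=percent,
        converse_percent=converse,
        converse_fold=converse_fold,
    )
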