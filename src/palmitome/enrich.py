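"""Over-representation analysis of annotation terms in the palmitoylome.

Terms (disease associations, pathway maps, process networks, GO biological
processes, metabolic networks) are tested with the one-sided hypergeometric
tail against a custom MS-detectable proteome background; p-values are
Benjamini-Hochberg adjusted within each annotation category; a term is
significant when FDR < 0.001 and fold enrichment FE >= 2, where
FE = (k/n) / (K/N) for k query hits among n query genes and K term genes
among the N background genes. Significant disease terms roll up into broad
disease classes by keyword matching.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError, FormatError, ValidationError

logger = logging.getLogger(__name__)

CATEGORIES = ("disease", "pathway_map", "process_network", "go_bp", "metabolic_network")

DISEASE_CLASSES = ("cancer", "nervous_system", "infection", "anemia", "gastrointestinal", "other")

#: first-match keyword rules; cancer precedes nervous_system so that e.g.
#: neuroblastoma lands with the cancers
DEFAULT_KEYWORD_MAP: list[tuple[str, str]] = [
    ("cancer", r"carcinoma|cancer|leukem|lymphoma|melanoma|glioma|blastoma|sarcoma|tumou?r|neoplas|myeloma|adenoma"),
    ("nervous_system", r"schizophren|huntington|sclerosis|epilep|neuro|parkinson|alzheim|dementia|ataxia|dystonia|palsy|seizure|mental|psychi|bipolar|autism|myasthen|nervous|brain|cognit"),
    ("infection", r"infect|viral|virus|bacteri|hepatitis|sepsis|tubercul|pneumonia|influenza|hiv|malaria|parasit"),
    ("anemia", r"ana?emia"),
    ("gastrointestinal", r"gastr|bowel|colitis|crohn|intestin|ulcer|esophag|digest"),
]


@dataclass
class Background:
    """Gene universe conditioning enrichment on MS detectability."""

    genes: frozenset[str]
    provenance: list[str] = field(default_factory=list)
    appended: int = 0

    @property
    def size(self) -> int:
        return len(self.genes)


@dataclass
class AnnotationTerm:
    term_id: str
    name: str
    category: str
    genes: frozenset[str]

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ConfigurationError(f"unknown category {self.category!r}")
        self.genes = frozenset(self.genes)


def build_background(
    proteome_lists: Mapping[str, Iterable[str]], compendium: Iterable[str]
) -> Background:
    """Union of proteome gene lists, with missing compendium genes appended.

    Palmitoylome genes absent from the MS proteome union are added so the
    query is always a subset of the universe; the appended count is logged.
    """
    union: set[str] = set()
    provenance = []
    for name, genes in proteome_lists.items():
        genes = {str(g).strip().upper() for g in genes if str(g).strip()}
        union |= genes
        provenance.append(name)
    if not union:
        raise ConfigurationError("background union is empty")
    compendium = {str(g).strip().upper() for g in compendium if str(g).strip()}
    appended = len(compendium - union)
    if appended:
        logger.info("appended %d compendium genes absent from the background union", appended)
    return Background(genes=frozenset(union | compendium), provenance=provenance, appended=appended)


def hypergeometric_p(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeom(N, K, n), stable in log space."""
    if not (0 <= k <= min(K, n)) or K > N or n > N or min(k, K, n, N) < 0:
        raise ValidationError(f"invalid hypergeometric arguments k={k} K={K} n={n} N={N}")
    if k == 0:
        return 1.0
    logp = hypergeom.logsf(k - 1, N, K, n)
    return float(min(1.0, np.exp(logp)))


def fold_enrichment(k: int, K: int, n: int, N: int) -> float:
    """FE = (k/n) / (K/N): query frequency over background frequency."""
    if K <= 0 or n <= 0:
        raise ValidationError("fold enrichment undefined for K=0 or n=0")
    return (k / n) / (K / N)


def bh_fdr(p_values: Sequence[float], grouping: Optional[Sequence] = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, optionally within groups."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p <= 0) | (p > 1) | ~np.isfinite(p)).any():
        raise ValidationError("p-values must lie in (0, 1]")
    out = np.empty_like(p)
    if grouping is None:
        out[:] = multipletests(p, method="fdr_bh")[1]
        return out
    grouping = np.asarray(grouping)
    for g in pd.unique(grouping):
        mask = grouping == g
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def read_gmt(path: str | Path, category: str) -> list[AnnotationTerm]:
    """Read a GMT gene-set file (term id, description, genes per line)."""
    terms = []
    path = Path(path)
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise FormatError(f"{path}:{lineno}: GMT line needs id, description and >=1 gene")
        terms.append(
            AnnotationTerm(
                term_id=parts[0],
                name=parts[1] or parts[0],
                category=category,
                genes=frozenset(g.strip().upper() for g in parts[2:] if g.strip()),
            )
        )
    return terms


def write_gmt(terms: Iterable[AnnotationTerm], path: str | Path) -> None:
    lines = [
        "\t".join([t.term_id, t.name] + sorted(t.genes)) for t in terms
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def run_enrichment(
    compendium: Iterable[str],
    terms: Iterable[AnnotationTerm],
    background: Background,
    fdr_threshold: float = 0.001,
    fe_threshold: float = 2.0,
    min_term_size: int = 3,
) -> pd.DataFrame:
    """Term-level over-representation results, one row per surviving term.

    Terms and the query are intersected with the background first; terms
    with fewer than ``min_term_size`` background genes are dropped. The
    result is sorted by FDR within category and carries the significance
    flag (FDR < threshold and FE >= threshold).
    """
    universe = background.genes
    query = {str(g).strip().upper() for g in compendium if str(g).strip()}
    dropped = len(query - universe)
    if dropped:
        logger.info("dropped %d query genes outside the background", dropped)
    query &= universe
    if not query:
        raise ValidationError("no compendium genes inside the background")
    n, N = len(query), len(universe)
    rows = []
    for term in terms:
        term_genes = term.genes & universe
        K = len(term_genes)
        if K < min_term_size:
            continue
        k = len(term_genes & query)
        p = hypergeometric_p(k, K, n, N)
        rows.append(
            {
                "term_id": term.term_id,
                "name": term.name,
                "category": term.category,
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "p": p,
                "FE": fold_enrichment(k, K, n, N),
            }
        )
    result = pd.DataFrame(
        rows, columns=["term_id", "name", "category", "k", "K", "n", "N", "p", "FE"]
    )
    if result.empty:
        result["FDR"] = result["significant"] = []
        return result
    result["FDR"] = bh_fdr(result["p"].to_numpy(), grouping=result["category"].to_numpy())
    result["significant"] = (result["FDR"] < fdr_threshold) & (result["FE"] >= fe_threshold)
    result = result.sort_values(["category", "FDR", "term_id"], kind="mergesort").reset_index(drop=True)
    return result


def top_terms(results: pd.DataFrame, category: str, top: int = 15) -> pd.DataFrame:
    """Figure-style report: top significant terms with -log10 FDR and FE."""
    sig = results[(results["category"] == category) & results["significant"]].copy()
    sig = sig.nsmallest(top, "FDR")
    sig["neg_log10_fdr"] = -np.log10(np.clip(sig["FDR"], 1e-300, None))
    return sig[["term_id", "name", "neg_log10_fdr", "FE"]].reset_index(drop=True)


def classify_disease_terms(
    names: Iterable[str],
    keyword_map: Optional[Sequence[tuple[str, str]]] = None,
) -> pd.DataFrame:
    """Assign each significant disease term to one broad class.

    First matching keyword rule wins; unmatched terms go to ``other`` with
    a log line. Returns per-class counts and fractions.
    """
    rules = [(cls, re.compile(pat, re.I)) for cls, pat in (keyword_map or DEFAULT_KEYWORD_MAP)]
    assignments = []
    for name in names:
        for cls, pattern in rules:
            if pattern.search(str(name)):
                assignments.append((name, cls))
                break
        else:
            logger.info("disease term %r unmatched by keyword map; classed as other", name)
            assignments.append((name, "other"))
    frame = pd.DataFrame(assignments, columns=["name", "disease_class"])
    counts = frame["disease_class"].value_counts()
    total = len(frame)
    summary = pd.DataFrame(
        {
            "disease_class": list(DISEASE_CLASSES),
            "count": [int(counts.get(c, 0)) for c in DISEASE_CLASSES],
        }
    )
    summary["fraction"] = summary["count"] / total if total else 0.0
    summary.attrs["assignments"] = frame
    return summary
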