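"""Resolution of heterogeneous protein identifiers to unified gene records.

Published palmitoyl-proteomics supplements describe proteins with five kinds
of identifiers: UniProt entry names (``SODC_HUMAN``), Ensembl gene IDs,
plain gene symbols, RefSeq protein accessions, and NCBI protein GI numbers.
This module matches each study's identifiers against a UniProt-like mapping
database (reviewed/Swiss-Prot entries take priority over unreviewed/TrEMBL
ones), and collapses matches across the three species into gene-level keys
by shared gene symbol or shared entry-name prefix, emulating homolog
inference from entry names.
"""

from __future__ import annotations

import logging
import re
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .errors import AmbiguousNamespaceError, FormatError, IntegrityError

logger = logging.getLogger(__name__)

SPECIES = ("human", "mouse", "rat")

NAMESPACES = (
    "uniprot_entry_name",
    "ensembl_gene",
    "gene_symbol",
    "refseq_accession",
    "ncbi_gi",
)

#: required columns of a mapping-database TSV; species is derived from the
#: entry-name suffix and cross-reference columns are optional
DB_COLUMNS = [
    "entry_name",
    "gene_symbol",
    "synonyms",
    "full_name",
    "entrez_id",
    "reviewed",
]
XREF_COLUMNS = ["ensembl_gene", "refseq_accession", "ncbi_gi"]

_ENTRY_SUFFIX = {"HUMAN": "human", "MOUSE": "mouse", "RAT": "rat"}

# Ordered by specificity: a token matching an earlier pattern is never
# counted toward a later namespace.
_NAMESPACE_PATTERNS = [
    ("uniprot_entry_name", re.compile(r"^[A-Za-z0-9]{1,10}_(HUMAN|MOUSE|RAT)$", re.I)),
    ("ensembl_gene", re.compile(r"^ENS(MUS|RNO)?G\d{11}$", re.I)),
    ("refseq_accession", re.compile(r"^[NXY]P_\d+(\.\d+)?$", re.I)),
    ("ncbi_gi", re.compile(r"^(gi\|)?\d+$")),
    ("gene_symbol", re.compile(r"^[A-Za-z][A-Za-z0-9._-]*$")),
]


def normalize_token(token: str) -> str:
    """NFKC-normalize and uppercase an identifier for case-insensitive joins."""
    return unicodedata.normalize("NFKC", str(token)).strip().upper()


@dataclass(frozen=True)
class ResolvedRecord:
    """One raw identifier successfully mapped to a database entry."""

    raw_identifier: str
    entry_name: str
    gene_symbol: str
    entrez_id: Optional[int]
    species: str
    reviewed: bool
    match_route: str  # exact | synonym | full_name


@dataclass
class MatchResult:
    """Outcome of matching one study table against the mapping database."""

    study_id: str
    matched: list[ResolvedRecord]
    unmatched: list[str]

    @property
    def match_rate(self) -> float:
        total = len(self.matched) + len(self.unmatched)
        return len(self.matched) / total if total else 0.0


@dataclass
class GeneKey:
    """Gene-level record unifying per-species entries under one symbol."""

    symbol: str  # canonical, uppercased
    entry_names: dict[str, str] = field(default_factory=dict)  # species -> entry name
    entrez_ids: dict[str, int] = field(default_factory=dict)  # species -> Entrez ID

    def __post_init__(self):
        self.symbol = normalize_token(self.symbol)


@dataclass
class StudyTable:
    """One study's reported identifier list."""

    study_id: str
    rows: pd.DataFrame  # columns: identifier, description
    namespace: Optional[str] = None

    def identifiers(self) -> list[str]:
        return [str(x) for x in self.rows["identifier"]]


class MappingDatabase:
    """In-memory UniProt-like identifier resolution table.

    Wraps a DataFrame with one row per database entry and hash indexes for
    each match route. Entry names are unique; species is derivable from the
    entry-name suffix.
    """

    def __init__(self, frame: pd.DataFrame):
        frame = frame.copy()
        missing = [c for c in DB_COLUMNS if c not in frame.columns]
        if missing:
            raise FormatError(f"mapping database missing columns: {missing}")
        if frame["entry_name"].duplicated().any():
            dups = frame.loc[frame["entry_name"].duplicated(), "entry_name"].head(3)
            raise IntegrityError(f"duplicate entry names: {list(dups)}")
        for name in frame["entry_name"]:
            suffix = str(name).rsplit("_", 1)[-1].upper()
            if suffix not in _ENTRY_SUFFIX:
                raise IntegrityError(f"entry name without species suffix: {name!r}")
        blank = (
            frame["gene_symbol"].fillna("").astype(str).str.strip().eq("")
            & frame["synonyms"].fillna("").astype(str).str.strip().eq("")
            & frame["full_name"].fillna("").astype(str).str.strip().eq("")
        )
        if blank.any():
            raise IntegrityError(
                f"{int(blank.sum())} records with no gene symbol, synonyms or full name"
            )
        frame["reviewed"] = frame["reviewed"].astype(bool)
        frame["species"] = [
            _ENTRY_SUFFIX[str(n).rsplit("_", 1)[-1].upper()] for n in frame["entry_name"]
        ]
        self.frame = frame.reset_index(drop=True)
        self._index()

    def __len__(self) -> int:
        return len(self.frame)

    def _index(self) -> None:
        self._by_entry: dict[str, int] = {}
        self._by_symbol: dict[str, list[int]] = {}
        self._by_synonym: dict[str, list[int]] = {}
        self._by_full_name: dict[str, list[int]] = {}
        self._by_xref: dict[str, list[int]] = {}
        for i, row in enumerate(self.frame.itertuples(index=False)):
            self._by_entry[normalize_token(row.entry_name)] = i
            sym = str(row.gene_symbol or "").strip()
            if sym:
                self._by_symbol.setdefault(normalize_token(sym), []).append(i)
            for syn in str(row.synonyms or "").split("|"):
                syn = syn.strip()
                if syn:
                    self._by_synonym.setdefault(normalize_token(syn), []).append(i)
            full = str(row.full_name or "").strip()
            if full:
                self._by_full_name.setdefault(normalize_token(full), []).append(i)
            for col in XREF_COLUMNS:
                val = str(getattr(row, col, "") or "").strip()
                if val and val.lower() != "nan":
                    self._by_xref.setdefault(normalize_token(val), []).append(i)

    def record(self, idx: int, raw: str, route: str) -> ResolvedRecord:
        row = self.frame.iloc[idx]
        entrez = row["entrez_id"]
        return ResolvedRecord(
            raw_identifier=raw,
            entry_name=str(row["entry_name"]),
            gene_symbol=str(row["gene_symbol"]),
            entrez_id=None if pd.isna(entrez) else int(entrez),
            species=str(row["species"]),
            reviewed=bool(row["reviewed"]),
            match_route=route,
        )

    def lookup_symbol(self, symbol: str, species: str) -> Optional[pd.Series]:
        """Reviewed-preferred entry for a symbol in one species, if any."""
        idxs = self._by_symbol.get(normalize_token(symbol), [])
        rows = [self.frame.iloc[i] for i in idxs if self.frame.iloc[i]["species"] == species]
        if not rows:
            return None
        reviewed = [r for r in rows if r["reviewed"]]
        pool = reviewed or rows
        return min(pool, key=lambda r: str(r["entry_name"]))


def load_mapping_database(path: str | Path) -> MappingDatabase:
    """Load a mapping-database TSV, enforcing schema and uniqueness."""
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"empty mapping database file: {path}") from exc
    if frame.empty:
        raise FormatError(f"mapping database has no data rows: {path}")
    frame["reviewed"] = frame.get("reviewed", pd.Series(dtype=str)).map(
        {"True": True, "False": False, "1": True, "0": False, True: True, False: False}
    )
    return MappingDatabase(frame)


def read_study_table(
    path: str | Path, study_id: Optional[str] = None, namespace: Optional[str] = None
) -> StudyTable:
    """Read one study's identifier TSV (columns: identifier, description)."""
    path = Path(path)
    try:
        rows = pd.read_csv(path, sep="\t", dtype=str, comment="#").fillna("")
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"empty study table: {path}") from exc
    if "identifier" not in rows.columns:
        raise FormatError(f"study table missing 'identifier' column: {path}")
    if "description" not in rows.columns:
        rows["description"] = ""
    return StudyTable(study_id=study_id or path.stem, rows=rows, namespace=namespace)


def detect_namespace(identifiers: Sequence[str]) -> tuple[str, float]:
    """Infer the identifier namespace matched by the majority of tokens.

    Returns the winning namespace and the fraction of tokens matching it.
    Raises :class:`AmbiguousNamespaceError` when no namespace wins a strict
    majority over the runner-up at >= 50% coverage.
    """
    identifiers = [str(x).strip() for x in identifiers if str(x).strip()]
    if not identifiers:
        raise AmbiguousNamespaceError("cannot detect namespace of an empty list")
    counts = {ns: 0 for ns, _ in _NAMESPACE_PATTERNS}
    for token in identifiers:
        for ns, pattern in _NAMESPACE_PATTERNS:
            if pattern.match(token):
                counts[ns] += 1
                break
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    best, second = ranked[0], ranked[1]
    frac = best[1] / len(identifiers)
    if frac < 0.5 or best[1] == second[1]:
        raise AmbiguousNamespaceError(
            f"no majority namespace: top candidates {best[0]} "
            f"({best[1]}/{len(identifiers)}) and {second[0]} ({second[1]}/{len(identifiers)})",
            candidates=[best[0], second[0]],
        )
    return best[0], frac


def resolve_identifier(
    raw: str,
    namespace: str,
    db: MappingDatabase,
    species_hint: Optional[str] = None,
) -> Optional[ResolvedRecord]:
    """Resolve one raw identifier, or return ``None`` when unmatched.

    Candidates are gathered per namespace (entry-name or cross-reference
    exact match; for gene symbols: symbol, then synonyms, then full name).
    Reviewed entries suppress unreviewed ones; a species hint narrows the
    candidate set when possible; remaining ties break deterministically on
    the lexicographically smallest entry name, with a warning.
    """
    token = normalize_token(raw)
    if not token:
        return None
    route = "exact"
    if namespace == "uniprot_entry_name":
        idx = db._by_entry.get(token)
        idxs = [] if idx is None else [idx]
    elif namespace in ("ensembl_gene", "refseq_accession", "ncbi_gi"):
        key = token[3:] if namespace == "ncbi_gi" and token.startswith("GI|") else token
        idxs = db._by_xref.get(key, [])
    elif namespace == "gene_symbol":
        idxs = db._by_symbol.get(token, [])
        if not idxs:
            idxs, route = db._by_synonym.get(token, []), "synonym"
        if not idxs:
            idxs, route = db._by_full_name.get(token, []), "full_name"
    else:
        raise ValueError(f"unknown namespace: {namespace!r}")
    if not idxs:
        return None
    rows = db.frame.iloc[idxs]
    reviewed_mask = rows["reviewed"].to_numpy()
    if reviewed_mask.any() and not reviewed_mask.all():
        idxs = [i for i, rev in zip(idxs, reviewed_mask) if rev]
        rows = db.frame.iloc[idxs]
    if species_hint is not None:
        same = [i for i in idxs if db.frame.iloc[i]["species"] == species_hint]
        if same:
            idxs = same
    if len(idxs) > 1:
        idxs = sorted(idxs, key=lambda i: str(db.frame.iloc[i]["entry_name"]))
        logger.warning(
            "identifier %r matched %d candidates; keeping %s",
            raw,
            len(idxs),
            db.frame.iloc[idxs[0]]["entry_name"],
        )
    return db.record(idxs[0], str(raw), route)


def match_study(
    table: StudyTable, db: MappingDatabase, species_hint: Optional[str] = None
) -> MatchResult:
    """Match every identifier of one study against the database."""
    namespace = table.namespace
    if namespace is None:
        namespace, frac = detect_namespace(table.identifiers())
        logger.info("study %s: detected namespace %s (%.1f%%)", table.study_id, namespace, 100 * frac)
    matched: list[ResolvedRecord] = []
    unmatched: list[str] = []
    for raw in table.identifiers():
        rec = resolve_identifier(raw, namespace, db, species_hint=species_hint)
        if rec is None:
            unmatched.append(raw)
        else:
            matched.append(rec)
    result = MatchResult(study_id=table.study_id, matched=matched, unmatched=unmatched)
    logger.info(
        "study %s: matched %d/%d identifiers (%.2f%%)",
        table.study_id,
        len(matched),
        len(matched) + len(unmatched),
        100 * result.match_rate,
    )
    return result


def _fill_species_entries(key: GeneKey, db: MappingDatabase) -> None:
    for species in SPECIES:
        if species in key.entry_names:
            continue
        row = db.lookup_symbol(key.symbol, species)
        if row is not None:
            key.entry_names[species] = str(row["entry_name"])
            if not pd.isna(row["entrez_id"]):
                key.entrez_ids[species] = int(row["entrez_id"])


def unify_homologs(
    matches: Iterable[MatchResult] | MatchResult, db: MappingDatabase
) -> dict[str, set[str]]:
    """Collapse per-study matches into gene keys shared across species.

    Records sharing an uppercased gene symbol, or entry names sharing the
    prefix before ``_``, merge into one gene. When a prefix would bridge
    two distinct symbols the symbol route wins and the conflict is logged.
    Returns ``{study_id: {canonical symbol, ...}}``; the per-gene records
    themselves are available via :func:`gene_keys_from_matches`.
    """
    if isinstance(matches, MatchResult):
        matches = [matches]
    study_genes: dict[str, set[str]] = {}
    prefix_to_symbol: dict[str, str] = {}
    for result in matches:
        genes: set[str] = set()
        for rec in result.matched:
            symbol = normalize_token(rec.gene_symbol)
            prefix = normalize_token(rec.entry_name).rsplit("_", 1)[0]
            known = prefix_to_symbol.get(prefix)
            if known is None:
                prefix_to_symbol[prefix] = symbol
            elif known != symbol:
                logger.warning(
                    "entry-name prefix %s maps to symbols %s and %s; keeping symbol route",
                    prefix,
                    known,
                    symbol,
                )
            genes.add(symbol)
        study_genes[result.study_id] = genes
    return study_genes


def gene_keys_from_matches(
    matches: Iterable[MatchResult] | MatchResult, db: MappingDatabase
) -> dict[str, GeneKey]:
    """Build one :class:`GeneKey` per distinct canonical symbol.

    Per-species entry names and Entrez IDs absent from the matched records
    are filled by homolog inference from the database symbol index.
    """
    if isinstance(matches, MatchResult):
        matches = [matches]
    keys: dict[str, GeneKey] = {}
    for result in matches:
        for rec in result.matched:
            symbol = normalize_token(rec.gene_symbol)
            key = keys.setdefault(symbol, GeneKey(symbol=symbol))
            key.entry_names.setdefault(rec.species, rec.entry_name)
            if rec.entrez_id is not None:
                key.entrez_ids.setdefault(rec.species, rec.entrez_id)
    for key in keys.values():
        _fill_species_entries(key, db)
    return keys


def match_report_frame(result: MatchResult) -> pd.DataFrame:
    """Per-study match report (one row per input identifier)."""
    rows = [
        {
            "raw_identifier": r.raw_identifier,
            "status": "matched",
            "route": r.match_route,
            "entry_name": r.entry_name,
            "gene_symbol": r.gene_symbol,
            "entrez_id": r.entrez_id,
        }
        for r in result.matched
    ] + [
        {
            "raw_identifier": raw,
            "status": "unmatched",
            "route": "",
            "entry_name": "",
            "gene_symbol": "",
            "entrez_id": None,
        }
        for raw in result.unmatched
    ]
    return pd.DataFrame(rows, columns=["raw_identifier", "status", "route", "entry_name", "gene_symbol", "entrez_id"])
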