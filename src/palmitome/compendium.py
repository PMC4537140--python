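"""Merging per-study gene sets into the annotated palmitoylome compendium.

Each gene gets one row carrying 0/1 evidence flags per study and per
detection method, the number of supporting studies, a neuronal/non-neuronal
source class, and a confidence tier. Genes seen several times within one
study are flagged once: annotation is per study, not per peptide or
replicate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd

from .errors import ConfigurationError, FormatError
from .identifiers import SPECIES, GeneKey, StudyTable, normalize_token

logger = logging.getLogger(__name__)

METHODS = ("ABE", "acyl_RAC", "bioorthogonal", "bioorthogonal_HAM")
TIERS = ("single_study", "multi_study", "multi_method", "multi_method_with_HAM")
SOURCE_CLASSES = ("neuronal_only", "non_neuronal_only", "both")

MANIFEST_COLUMNS = ["study_id", "species", "tissue_source", "fraction", "methods", "neuronal"]


@dataclass
class StudyMeta:
    """One row of the study manifest (organism, source, detection method)."""

    study_id: str
    species: str
    tissue_source: str = ""
    fraction: str = ""
    methods: frozenset[str] = frozenset()
    neuronal: bool = False

    def __post_init__(self):
        self.methods = frozenset(self.methods)
        if not self.methods:
            raise ConfigurationError(f"study {self.study_id}: empty method set")
        unknown = self.methods - set(METHODS)
        if unknown:
            raise ConfigurationError(f"study {self.study_id}: unknown methods {sorted(unknown)}")


@dataclass
class ExclusionRule:
    """Manual removal of specific rows from one study's table."""

    study_id: str
    raw_identifier: str
    reason: str

    def __post_init__(self):
        if not self.reason.strip():
            raise ConfigurationError("exclusion rule without a reason")


@dataclass
class CompendiumEntry:
    gene_key: GeneKey
    study_flags: dict[str, int] = field(default_factory=dict)
    method_flags: dict[str, int] = field(default_factory=dict)
    source_class: str = "both"
    confidence_tier: str = "single_study"

    @property
    def n_studies(self) -> int:
        return sum(self.study_flags.values())

    @property
    def n_methods(self) -> int:
        return sum(self.method_flags.values())


def read_manifest(path: str | Path) -> list[StudyMeta]:
    """Read the study manifest TSV (methods pipe-delimited, neuronal 0/1)."""
    frame = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = [c for c in MANIFEST_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"manifest missing columns: {missing}")
    metas = []
    for row in frame.itertuples(index=False):
        metas.append(
            StudyMeta(
                study_id=str(row.study_id),
                species=str(row.species),
                tissue_source=str(row.tissue_source),
                fraction=str(row.fraction),
                methods=frozenset(m for m in str(row.methods).split("|") if m),
                neuronal=str(row.neuronal).strip() in ("1", "True", "true"),
            )
        )
    return metas


def apply_exclusions(table: StudyTable, rules: Iterable[ExclusionRule]) -> StudyTable:
    """Drop manually excluded rows (e.g. identifications later disproved)."""
    rows = table.rows
    for rule in rules:
        if rule.study_id != table.study_id:
            continue
        mask = rows["identifier"].map(normalize_token) == normalize_token(rule.raw_identifier)
        n = int(mask.sum())
        if n == 0:
            logger.warning(
                "exclusion rule for %s matched no rows in study %s (%s)",
                rule.raw_identifier,
                table.study_id,
                rule.reason,
            )
        else:
            logger.info(
                "study %s: removed %d row(s) for %s (%s)",
                table.study_id,
                n,
                rule.raw_identifier,
                rule.reason,
            )
        rows = rows[~mask]
    return StudyTable(study_id=table.study_id, rows=rows.reset_index(drop=True), namespace=table.namespace)


def assign_confidence(n_studies: int, methods: Iterable[str]) -> str:
    """Confidence tier from study and method multiplicity.

    Hydroxylamine-controlled bioorthogonal labeling plus an orthogonal
    method ranks highest; then any two methods; then any two studies.
    """
    methods = set(methods)
    if len(methods) >= 2 and "bioorthogonal_HAM" in methods:
        return "multi_method_with_HAM"
    if len(methods) >= 2:
        return "multi_method"
    if n_studies >= 2:
        return "multi_study"
    return "single_study"


def _source_class(study_flags: Mapping[str, int], meta_by_id: Mapping[str, StudyMeta]) -> str:
    neuronal = any(v and meta_by_id[s].neuronal for s, v in study_flags.items())
    non_neuronal = any(v and not meta_by_id[s].neuronal for s, v in study_flags.items())
    if neuronal and non_neuronal:
        return "both"
    return "neuronal_only" if neuronal else "non_neuronal_only"


def build_compendium(
    gene_keys_per_study: Mapping[str, Iterable[GeneKey | str]],
    manifest: Iterable[StudyMeta],
    gene_keys: Optional[Mapping[str, GeneKey]] = None,
) -> list[CompendiumEntry]:
    """Merge per-study gene sets into one entry per distinct gene.

    ``gene_keys_per_study`` maps study id to the study's consolidated gene
    set (GeneKeys or canonical symbols); ``gene_keys`` optionally supplies
    the full per-gene records when symbols are passed. Output is sorted by
    gene symbol for reproducible files.
    """
    manifest = list(manifest)
    meta_by_id = {m.study_id: m for m in manifest}
    missing = [s for s in gene_keys_per_study if s not in meta_by_id]
    if missing:
        raise ConfigurationError(f"studies without manifest metadata: {missing}")
    study_ids = [m.study_id for m in manifest if m.study_id in gene_keys_per_study]

    entries: dict[str, CompendiumEntry] = {}
    for study_id in sorted(gene_keys_per_study):
        for item in gene_keys_per_study[study_id]:
            key = item if isinstance(item, GeneKey) else None
            symbol = normalize_token(item.symbol if key else item)
            if key is None and gene_keys is not None:
                key = gene_keys.get(symbol)
            entry = entries.get(symbol)
            if entry is None:
                entry = CompendiumEntry(
                    gene_key=key or GeneKey(symbol=symbol),
                    study_flags={s: 0 for s in study_ids},
                    method_flags={m: 0 for m in METHODS},
                )
                entries[symbol] = entry
            elif key is not None:
                # merge species evidence accumulated across studies
                for sp, en in key.entry_names.items():
                    entry.gene_key.entry_names.setdefault(sp, en)
                for sp, ez in key.entrez_ids.items():
                    entry.gene_key.entrez_ids.setdefault(sp, ez)
            entry.study_flags[study_id] = 1  # per-study flag: repeated hits stay 1

    for entry in entries.values():
        for study_id, flag in entry.study_flags.items():
            if flag:
                for method in meta_by_id[study_id].methods:
                    entry.method_flags[method] = 1
        entry.source_class = _source_class(entry.study_flags, meta_by_id)
        entry.confidence_tier = assign_confidence(
            entry.n_studies, [m for m, v in entry.method_flags.items() if v]
        )
    return [entries[s] for s in sorted(entries)]


def partition_by_source(entries: Iterable[CompendiumEntry]) -> dict:
    """Counts and fractions of genes by neuronal/non-neuronal provenance."""
    entries = list(entries)
    counts = {c: 0 for c in SOURCE_CLASSES}
    for e in entries:
        counts[e.source_class] += 1
    total = len(entries)
    fractions = {c: (counts[c] / total if total else 0.0) for c in SOURCE_CLASSES}
    return {"counts": counts, "fractions": fractions, "total": total}


def compendium_frame(entries: Iterable[CompendiumEntry], manifest: Iterable[StudyMeta]) -> pd.DataFrame:
    """Tabular form of the compendium (fixed column order, sorted by symbol)."""
    manifest = list(manifest)
    study_ids = [m.study_id for m in manifest]
    rows = []
    for e in sorted(entries, key=lambda e: e.gene_key.symbol):
        row = {"gene_symbol": e.gene_key.symbol}
        for sp in SPECIES:
            row[f"entry_name_{sp}"] = e.gene_key.entry_names.get(sp, "")
            row[f"entrez_{sp}"] = e.gene_key.entrez_ids.get(sp, "")
        for s in study_ids:
            row[s] = e.study_flags.get(s, 0)
        for m in METHODS:
            row[m] = e.method_flags.get(m, 0)
        row["n_studies"] = e.n_studies
        row["confidence_tier"] = e.confidence_tier
        row["source_class"] = e.source_class
        rows.append(row)
    cols = (
        ["gene_symbol"]
        + [f"entry_name_{sp}" for sp in SPECIES]
        + [f"entrez_{sp}" for sp in SPECIES]
        + study_ids
        + list(METHODS)
        + ["n_studies", "confidence_tier", "source_class"]
    )
    return pd.DataFrame(rows, columns=cols)


def write_compendium(entries: Iterable[CompendiumEntry], manifest: Iterable[StudyMeta], path: str | Path) -> None:
    compendium_frame(entries, manifest).to_csv(path, sep="\t", index=False)


def read_compendium(path: str | Path, manifest: Iterable[StudyMeta]) -> list[CompendiumEntry]:
    """Read a compendium TSV back into entries (inverse of write_compendium)."""
    manifest = list(manifest)
    meta_by_id = {m.study_id: m for m in manifest}
    try:
        frame = pd.read_csv(path, sep="\t", dtype=str, comment="#").fillna("")
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"empty compendium file: {path}") from exc
    required = ["gene_symbol", "n_studies"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise FormatError(f"compendium missing columns: {missing}")
    study_ids = [s for s in meta_by_id if s in frame.columns]
    if not study_ids:
        raise FormatError("compendium has no per-study flag columns matching the manifest")
    entries = []
    for lineno, row in enumerate(frame.to_dict("records"), start=2):
        key = GeneKey(symbol=row["gene_symbol"])
        for sp in SPECIES:
            en = str(row.get(f"entry_name_{sp}", "")).strip()
            if en:
                key.entry_names[sp] = en
            ez = str(row.get(f"entrez_{sp}", "")).strip()
            if ez:
                try:
                    key.entrez_ids[sp] = int(float(ez))
                except ValueError as exc:
                    raise FormatError(f"line {lineno}: bad entrez id {ez!r}") from exc
        try:
            study_flags = {s: int(float(row[s])) for s in study_ids}
        except ValueError as exc:
            raise FormatError(f"line {lineno}: non-numeric study flag") from exc
        entry = CompendiumEntry(gene_key=key, study_flags=study_flags,
                                method_flags={m: 0 for m in METHODS})
        for study_id, flag in study_flags.items():
            if flag:
                for method in meta_by_id[study_id].methods:
                    entry.method_flags[method] = 1
        entry.source_class = _source_class(study_flags, meta_by_id)
        entry.confidence_tier = assign_confidence(
            entry.n_studies, [m for m, v in entry.method_flags.items() if v]
        )
        entries.append(entry)
    return entries


def compendium_gene_sets(entries: Iterable[CompendiumEntry]) -> dict[str, set[str]]:
    """Per-study gene sets implied by the flags (column-sum view)."""
    sets: dict[str, set[str]] = {}
    for e in entries:
        for s, v in e.study_flags.items():
            if v:
                sets.setdefault(s, set()).add(e.gene_key.symbol)
    return sets
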