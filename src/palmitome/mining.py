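"""Mining disease mutations at known or putatively palmitoylated cysteines.

Substitution tokens (``C6F``) are parsed and checked against the protein
sequence; cysteine mutations are classified against site evidence with the
precedence known > predicted > di-Cys adjacent > Cys-rich region >
no evidence. Di-Cys means an immediately adjacent second cysteine; a
Cys-rich region is any 10-residue window containing the site with at least
three cysteines. Coordinates are 1-based protein positions.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

from .errors import FormatError, ParseError

logger = logging.getLogger(__name__)

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

CLASSIFICATIONS = (
    "known_palmitoylated",
    "predicted",
    "di_cys_adjacent",
    "cys_rich_region",
    "no_evidence",
    "not_cysteine",
    "ref_mismatch",
)

_SUBSTITUTION = re.compile(r"^([A-Za-z])(\d+)([A-Za-z])$")


@dataclass(frozen=True)
class MutationRecord:
    gene: str
    ref_aa: str
    position: int  # 1-based
    alt_aa: str
    disease: str = ""

    @property
    def substitution(self) -> str:
        return f"{self.ref_aa}{self.position}{self.alt_aa}"


@dataclass
class SiteEvidence:
    """Palmitoylation-site evidence for one gene (1-based positions)."""

    known_sites: frozenset[int] = frozenset()
    predicted_sites: frozenset[int] = frozenset()


@dataclass
class MiningResult:
    mutation: MutationRecord
    classification: str
    context: str  # 21-residue window centered on the site


def parse_substitution(token: str) -> tuple[str, int, str]:
    """Parse ``C6F`` -> ('C', 6, 'F'); malformed tokens raise ParseError."""
    m = _SUBSTITUTION.match(str(token).strip())
    if not m:
        raise ParseError(f"malformed substitution token: {token!r}")
    ref, pos, alt = m.group(1).upper(), int(m.group(2)), m.group(3).upper()
    if ref not in AMINO_ACIDS or alt not in AMINO_ACIDS:
        raise ParseError(f"non-standard amino acid in {token!r}")
    if pos < 1:
        raise ParseError(f"position must be >= 1 in {token!r}")
    if ref == alt:
        raise ParseError(f"reference and alternate residues identical in {token!r}")
    return ref, pos, alt


def detect_di_cys(sequence: str, position: int) -> bool:
    """True when the cysteine at ``position`` has an adjacent cysteine."""
    i = position - 1
    seq = sequence.upper()
    left = i > 0 and seq[i - 1] == "C"
    right = i + 1 < len(seq) and seq[i + 1] == "C"
    return left or right


def detect_cys_rich(sequence: str, position: int, window: int = 10, min_cys: int = 3) -> bool:
    """True when some length-``window`` substring covering ``position`` has
    at least ``min_cys`` cysteines (window clamped to the sequence)."""
    seq = sequence.upper()
    L = len(seq)
    w = min(window, L)
    i = position - 1
    lo = max(0, i - w + 1)
    hi = min(i, L - w)
    for start in range(lo, hi + 1):
        if seq[start : start + w].count("C") >= min_cys:
            return True
    return False


def _context(sequence: str, position: int, flank: int = 10) -> str:
    i = position - 1
    return sequence[max(0, i - flank) : i + flank + 1]


def classify_mutation(
    record: MutationRecord,
    evidence: SiteEvidence,
    sequence: str,
    window: int = 10,
    min_cys: int = 3,
) -> MiningResult:
    """Classify one mutation against site evidence and sequence context.

    Non-cysteine records and reference mismatches are flagged as such;
    cysteine records receive the highest-precedence tier they satisfy.
    """
    seq = sequence.upper()
    pos = record.position
    if pos > len(seq) or seq[pos - 1] != record.ref_aa:
        cls = "not_cysteine" if record.ref_aa != "C" else "ref_mismatch"
        if record.ref_aa == "C":
            logger.warning(
                "%s %s: sequence has %r at position %d",
                record.gene,
                record.substitution,
                seq[pos - 1] if pos <= len(seq) else None,
                pos,
            )
        return MiningResult(record, cls, _context(seq, min(pos, len(seq))))
    if record.ref_aa != "C":
        return MiningResult(record, "not_cysteine", _context(seq, pos))
    if pos in evidence.known_sites:
        cls = "known_palmitoylated"
    elif pos in evidence.predicted_sites:
        cls = "predicted"
    elif detect_di_cys(seq, pos):
        cls = "di_cys_adjacent"
    elif detect_cys_rich(seq, pos, window=window, min_cys=min_cys):
        cls = "cys_rich_region"
    else:
        cls = "no_evidence"
    return MiningResult(record, cls, _context(seq, pos))


def filter_cysteine_mutations(
    records: Iterable[MutationRecord], sequences: Mapping[str, str]
) -> dict[str, list[MutationRecord]]:
    """Partition records into cysteine / not_cysteine / ref_mismatch / no_sequence."""
    parts: dict[str, list[MutationRecord]] = {
        "cysteine": [],
        "not_cysteine": [],
        "ref_mismatch": [],
        "no_sequence": [],
    }
    for rec in records:
        seq = sequences.get(rec.gene)
        if seq is None:
            logger.warning("no sequence for gene %s; record %s flagged", rec.gene, rec.substitution)
            parts["no_sequence"].append(rec)
            continue
        seq = seq.upper()
        if rec.ref_aa != "C":
            parts["not_cysteine"].append(rec)
        elif rec.position > len(seq) or seq[rec.position - 1] != "C":
            parts["ref_mismatch"].append(rec)
        else:
            parts["cysteine"].append(rec)
    return parts


def read_sequences(path: str | Path) -> dict[str, str]:
    """Gene -> protein sequence from a FASTA file (record id = gene)."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def read_mutations(path: str | Path) -> list[MutationRecord]:
    """Mutation TSV (gene, substitution, disease) -> parsed records."""
    frame = pd.read_csv(path, sep="\t", dtype=str, comment="#").fillna("")
    for col in ("gene", "substitution"):
        if col not in frame.columns:
            raise FormatError(f"mutation table missing column {col!r}: {path}")
    records = []
    for row in frame.itertuples(index=False):
        ref, pos, alt = parse_substitution(row.substitution)
        records.append(
            MutationRecord(
                gene=str(row.gene),
                ref_aa=ref,
                position=pos,
                alt_aa=alt,
                disease=str(getattr(row, "disease", "")),
            )
        )
    return records


def read_site_evidence(path: str | Path) -> dict[str, SiteEvidence]:
    """Evidence TSV (gene, position, tier in {known, predicted})."""
    frame = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    for col in ("gene", "position", "tier"):
        if col not in frame.columns:
            raise FormatError(f"evidence table missing column {col!r}: {path}")
    known: dict[str, set[int]] = {}
    predicted: dict[str, set[int]] = {}
    for row in frame.itertuples(index=False):
        tier = str(row.tier).strip().lower()
        if tier not in ("known", "predicted"):
            raise FormatError(f"unknown evidence tier {row.tier!r}")
        target = known if tier == "known" else predicted
        target.setdefault(str(row.gene), set()).add(int(row.position))
    genes = set(known) | set(predicted)
    return {
        g: SiteEvidence(
            known_sites=frozenset(known.get(g, ())),
            predicted_sites=frozenset(predicted.get(g, ())),
        )
        for g in genes
    }


def mine_mutations(
    records: Iterable[MutationRecord],
    sequences: Mapping[str, str],
    evidence: Mapping[str, SiteEvidence],
    window: int = 10,
    min_cys: int = 3,
) -> pd.DataFrame:
    """Full mining report: one row per mutation with its classification."""
    rows = []
    for rec in records:
        seq = sequences.get(rec.gene)
        if seq is None:
            rows.append(
                {
                    "gene": rec.gene,
                    "substitution": rec.substitution,
                    "disease": rec.disease,
                    "classification": "no_sequence",
                    "context": "",
                }
            )
            continue
        result = classify_mutation(
            rec, evidence.get(rec.gene, SiteEvidence()), seq, window=window, min_cys=min_cys
        )
        rows.append(
            {
                "gene": rec.gene,
                "substitution": rec.substitution,
                "disease": rec.disease,
                "classification": result.classification,
                "context": result.context,
            }
        )
    return pd.DataFrame(rows, columns=["gene", "substitution", "disease", "classification", "context"])
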