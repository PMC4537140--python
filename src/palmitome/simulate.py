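"""Synthetic emulation of the fifteen palmitoyl-proteomics supplements.

Generates every input the pipeline consumes with known ground truth: a
UniProt-like mapping database over a background universe of genes in three
species; fifteen study tables in five identifier namespaces with controlled
noise; a study manifest; GMT annotation collections with planted fold
enrichments; a synaptic gene list with a planted compendium-membership odds
ratio; and protein sequences with planted cysteine motifs plus a matching
mutation table.

The latent-palmitoylome model: a fixed subset of the universe is the true
palmitoylome; each study detects each true gene independently with its
detection probability. Studies inside a planted cluster share a common
per-gene uniform draw (common random numbers), so their detected sets are
strongly nested while each study keeps its marginal detection rate -
reproducing the single significant study pair seen in real data.

Default parameters are calibrated to the published study design: 9 human /
5 mouse / 1 rat studies, three neuronal sources, detection probabilities
solving the printed neuronal/non-neuronal source partition, and a noise
rate whose unmappable share reproduces the reported mean unmatched rate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import nchypergeom_fisher

from .compendium import StudyMeta, MANIFEST_COLUMNS
from .enrich import AnnotationTerm, write_gmt
from .errors import ConfigurationError
from .identifiers import MappingDatabase, StudyTable

# internal rng stream indices (one independent stream per artifact kind)
_STREAM_MAPPING, _STREAM_LATENT, _STREAM_STUDIES = 0, 1, 2
_STREAM_TERMS, _STREAM_SYNAPTIC, _STREAM_SEQS, _STREAM_BACKGROUND = 3, 4, 5, 6

_AA_NO_CYS = "ADEFGHIKLMNPQRSTVWY"

# study roster emulating the published table: id, species, namespace,
# tissue, fraction, methods, neuronal flag, detection-probability class
_ROSTER = [
    ("wei_2014", "human", "uniprot_entry_name", "HUVEC endothelial cells", "total cell lysate", ("ABE",), False),
    ("ivaldi_2012", "human", "gene_symbol", "B lymphocytes", "membrane lysate", ("ABE",), False),
    ("marin_2012", "human", "gene_symbol", "endothelial EA.hy926", "total cell lysate", ("ABE",), False),
    ("dowal_2011", "human", "uniprot_entry_name", "resting platelets", "membrane lysate", ("ABE",), False),
    ("forrester_2011", "human", "uniprot_entry_name", "HEK293 cells", "membrane lysate", ("acyl_RAC",), False),
    ("wilson_2011", "human", "gene_symbol", "Jurkat T cells", "total cell lysate", ("bioorthogonal",), False),
    ("yang_2010", "human", "gene_symbol", "prostate DU145", "membrane fractions", ("ABE",), False),
    ("martin_2009", "human", "ensembl_gene", "Jurkat T cells", "membrane lysate", ("bioorthogonal_HAM",), False),
    ("zhang_2008", "human", "refseq_accession", "HeLa cells", "membrane lysate", ("acyl_RAC",), False),
    ("wan_2013", "mouse", "gene_symbol", "brain", "total cell lysate", ("ABE",), True),
    ("martin_2012", "mouse", "gene_symbol", "T-cell hybridoma", "membrane lysate", ("bioorthogonal_HAM",), False),
    ("li_2012", "mouse", "gene_symbol", "neuronal stem cells", "membrane lysate", ("bioorthogonal_HAM",), True),
    ("merrick_2011", "mouse", "ncbi_gi", "RAW 264.7 macrophages", "membrane lysate", ("ABE",), False),
    ("yount_2010", "mouse", "gene_symbol", "DC2.4 dendritic cells", "total cell lysate", ("bioorthogonal",), False),
    ("kang_2008", "rat", "gene_symbol", "embryonic neurons and brain", "synaptosomal fraction", ("ABE",), True),
]

# detection probabilities solving the printed neuronal/non-neuronal
# source-partition marginals; the planted duplicate pair leaves 11
# effectively independent non-neuronal studies
DETECTION_NEURONAL = 0.113
DETECTION_NON_NEURONAL = 0.058

_SPECIES_ENSEMBL = {"human": "ENSG", "mouse": "ENSMUSG", "rat": "ENSRNOG"}
_SPECIES_SUFFIX = {"human": "HUMAN", "mouse": "MOUSE", "rat": "RAT"}
_SPECIES_OFFSET = {"human": 0, "mouse": 1, "rat": 2}

DISEASE_CLASS_NAMES = {
    "nervous_system": [
        "Schizophrenia", "Huntington disease", "Amyotrophic lateral sclerosis",
        "Temporal lobe epilepsy", "Parkinson disease", "Alzheimer disease",
        "Spinocerebellar ataxia", "Primary dystonia", "Cerebral palsy",
        "Generalized seizure disorder", "X-linked mental retardation",
        "Bipolar disorder", "Autism spectrum disorder", "Myasthenia gravis",
    ],
    "cancer": [
        "Pancreatic ductal carcinoma", "Neuroblastoma", "Chronic myeloid leukemia",
        "B-cell lymphoma", "Cutaneous melanoma", "Malignant glioma",
        "Osteosarcoma", "Breast cancer", "Colorectal cancer",
        "Hepatocellular carcinoma", "Multiple myeloma", "Renal cell carcinoma",
        "Small cell lung cancer", "Endometrial adenoma",
    ],
    "infection": ["Hepatitis C infection", "Pulmonary tuberculosis", "Influenza infection"],
    "anemia": ["Hemolytic anemia", "Aplastic anaemia"],
    "gastrointestinal": ["Ulcerative colitis", "Inflammatory bowel disease", "Chronic gastritis"],
    "other": ["Rheumatoid arthritis", "Osteoporosis", "Dilated cardiomyopathy", "Type 2 diabetes mellitus"],
}

DEFAULT_DISEASE_CLASS_COUNTS = {
    "nervous_system": 14, "cancer": 14, "infection": 3,
    "anemia": 2, "gastrointestinal": 3, "other": 4,
}


@dataclass
class MotifSpec:
    """How many genes to plant per palmitoylation-evidence tier."""

    known: int = 1
    predicted: int = 1
    di_cys: int = 1
    cys_rich: int = 1
    no_evidence: int = 1
    non_cys_decoys: int = 1
    mismatch_decoys: int = 1
    seq_length: int = 240


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study; defaults emulate the source design."""

    seed: int = 0
    n_genes: int = 2880  # latent true palmitoylome size
    n_background: int = 17858  # background universe size
    n_studies: int = 15
    detection_prob: Optional[Sequence[float] | float] = None  # per study; None = roster defaults
    noise_rate: float = 0.1165  # corrupted identifier fraction
    planted_clusters: Sequence[Sequence[int]] = ((7, 10),)  # the two same-lab HAM studies
    planted_terms: Sequence[tuple[int, float]] = ((50, 6.0),)
    n_decoy_terms: int = 40
    decoy_term_size: int = 50
    disease_class_counts: dict = field(default_factory=lambda: dict(DEFAULT_DISEASE_CLASS_COUNTS))
    disease_term_size: int = 120
    disease_fe: float = 3.0
    n_decoy_disease_terms: int = 20
    synaptic_list_size: int = 1028
    synaptic_overlap_odds: float = 7.0
    background_holdout: int = 50  # latent genes withheld from the proteome union
    motif_spec: MotifSpec = field(default_factory=MotifSpec)

    def __post_init__(self):
        if isinstance(self.motif_spec, dict):
            self.motif_spec = MotifSpec(**self.motif_spec)
        self.validate()

    def validate(self) -> None:
        if self.n_genes <= 0 or self.n_background <= 0 or self.n_studies <= 0:
            raise ConfigurationError("sizes must be positive")
        if self.n_genes > self.n_background:
            raise ConfigurationError("latent palmitoylome larger than background universe")
        if not 0.0 <= self.noise_rate <= 1.0:
            raise ConfigurationError("noise_rate must lie in [0, 1]")
        for p in self.detection_probs():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError("detection probabilities must lie in [0, 1]")
        for cluster in self.planted_clusters:
            if len(cluster) < 2:
                raise ConfigurationError("planted clusters need >= 2 studies")
            for idx in cluster:
                if not 0 <= idx < self.n_studies:
                    raise ConfigurationError(f"planted cluster index {idx} out of range")
        seen: set[int] = set()
        for cluster in self.planted_clusters:
            if seen & set(cluster):
                raise ConfigurationError("planted clusters must be disjoint")
            seen |= set(cluster)
        for size, fe in self.planted_terms:
            if size < 1:
                raise ConfigurationError("planted term size must be >= 1")
            if fe <= 0:
                raise ConfigurationError("target fold enrichment must be positive")
            if fe * self.n_genes / self.n_background > 1.0:
                raise ConfigurationError(
                    f"target FE {fe} unattainable at n={self.n_genes}, N={self.n_background}"
                )
        if self.disease_fe * self.n_genes / self.n_background > 1.0:
            raise ConfigurationError("disease_fe unattainable for this universe")
        if not 0 < self.synaptic_list_size <= self.n_background:
            raise ConfigurationError("synaptic list size out of range")
        if self.synaptic_overlap_odds <= 0:
            raise ConfigurationError("synaptic overlap odds must be positive")
        if not 0 <= self.background_holdout <= self.n_genes:
            raise ConfigurationError("background_holdout out of range")

    def detection_probs(self) -> list[float]:
        if self.detection_prob is None:
            return [
                DETECTION_NEURONAL if self.roster()[s][6] else DETECTION_NON_NEURONAL
                for s in range(self.n_studies)
            ]
        if np.isscalar(self.detection_prob):
            return [float(self.detection_prob)] * self.n_studies
        probs = [float(p) for p in self.detection_prob]
        if len(probs) != self.n_studies:
            raise ConfigurationError("detection_prob length must equal n_studies")
        return probs

    def roster(self) -> list[tuple]:
        """Study roster, cycling the built-in 15-study design if needed."""
        roster = []
        for s in range(self.n_studies):
            base = _ROSTER[s % len(_ROSTER)]
            study_id = base[0] if s < len(_ROSTER) else f"{base[0]}_rep{s // len(_ROSTER)}"
            roster.append((study_id,) + base[1:])
        return roster

    def _rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), stream])


def _symbol(i: int) -> str:
    return f"GS{i + 1:05d}"


def _species_symbol(symbol: str, species: str) -> str:
    return symbol if species == "human" else symbol.capitalize()


def _xrefs(i: int, species: str) -> dict[str, str]:
    off = _SPECIES_OFFSET[species]
    return {
        "ensembl_gene": f"{_SPECIES_ENSEMBL[species]}{i + 1:011d}",
        "refseq_accession": f"NP_{100000 + 3 * i + off:06d}",
        "ncbi_gi": str(5_000_000 + 3 * i + off),
    }


def _entrez(i: int, species: str) -> int:
    return {"human": 10_000, "mouse": 200_000, "rat": 400_000}[species] + i


def generate_mapping_db(config: SimulationConfig) -> tuple[MappingDatabase, pd.DataFrame]:
    """UniProt-like database plus the identifier -> gene ground-truth map.

    Every universe gene gets one reviewed entry per species (with species
    cross-references), 0-2 unreviewed duplicates sharing its symbol, and
    0-3 synonyms.
    """
    rng = config._rng(_STREAM_MAPPING)
    n = config.n_background
    n_synonyms = rng.integers(0, 4, size=n)
    n_unreviewed = rng.choice([0, 1, 2], size=n, p=[0.7, 0.2, 0.1])
    unrev_species = rng.integers(0, 3, size=n)
    rows = []
    truth = []
    species_list = ("human", "mouse", "rat")
    for i in range(n):
        sym = _symbol(i)
        synonyms = [f"SY{i + 1:05d}X{j}" for j in range(int(n_synonyms[i]))]
        full_name = f"Palmitoyl substrate protein {sym}"
        for species in species_list:
            entry = f"{sym}_{_SPECIES_SUFFIX[species]}"
            xrefs = _xrefs(i, species)
            rows.append(
                {
                    "entry_name": entry,
                    "gene_symbol": _species_symbol(sym, species),
                    "synonyms": "|".join(synonyms),
                    "full_name": full_name,
                    "entrez_id": _entrez(i, species),
                    "species": species,
                    "reviewed": True,
                    **xrefs,
                }
            )
            truth.append((entry, sym, "uniprot_entry_name"))
            for kind, value in xrefs.items():
                truth.append((value, sym, kind))
        truth.append((sym, sym, "gene_symbol"))
        for syn in synonyms:
            truth.append((syn, sym, "synonym"))
        truth.append((full_name, sym, "full_name"))
        for k in range(int(n_unreviewed[i])):
            species = species_list[unrev_species[i]]
            entry = f"Q{i + 1:05d}{k}_{_SPECIES_SUFFIX[species]}"
            rows.append(
                {
                    "entry_name": entry,
                    "gene_symbol": _species_symbol(sym, species),
                    "synonyms": "",
                    "full_name": full_name,
                    "entrez_id": _entrez(i, species),
                    "species": species,
                    "reviewed": False,
                    "ensembl_gene": "",
                    "refseq_accession": "",
                    "ncbi_gi": "",
                }
            )
            truth.append((entry, sym, "uniprot_entry_name"))
    frame = pd.DataFrame(rows)
    truth_frame = pd.DataFrame(truth, columns=["identifier", "gene_symbol", "kind"])
    return MappingDatabase(frame), truth_frame


def latent_palmitoylome(config: SimulationConfig) -> np.ndarray:
    """Universe indices of the latent (true) palmitoylome, sorted."""
    rng = config._rng(_STREAM_LATENT)
    return np.sort(rng.choice(config.n_background, size=config.n_genes, replace=False))


def manifest_from_config(config: SimulationConfig) -> list[StudyMeta]:
    return [
        StudyMeta(
            study_id=r[0], species=r[1], tissue_source=r[3],
            fraction=r[4], methods=frozenset(r[5]), neuronal=r[6],
        )
        for r in config.roster()
    ]


def generate_study_tables(
    config: SimulationConfig, db: MappingDatabase
) -> tuple[list[StudyTable], pd.DataFrame, dict[str, set[str]]]:
    """Per-study identifier tables, row-level truth, and true gene sets.

    Returns (tables, row_truth, study_gene_sets); row_truth has one row per
    emitted identifier with its source gene and corruption kind.
    """
    rng = config._rng(_STREAM_STUDIES)
    roster = config.roster()
    probs = config.detection_probs()
    latent = latent_palmitoylome(config)
    cluster_of = {}
    for c, cluster in enumerate(config.planted_clusters):
        for idx in cluster:
            cluster_of[idx] = c
    cluster_draws = {
        c: rng.random(config.n_genes) for c in range(len(config.planted_clusters))
    }
    tables = []
    truth_rows = []
    study_sets: dict[str, set[str]] = {}
    unmappable_counter = 0
    for s, (study_id, species, namespace, *_rest) in enumerate(roster):
        if s in cluster_of:
            detected = cluster_draws[cluster_of[s]] < probs[s]
        else:
            detected = rng.random(config.n_genes) < probs[s]
        gene_idx = latent[detected]
        study_sets[study_id] = {_symbol(int(i)) for i in gene_idx}
        rows = []
        for i in gene_idx:
            i = int(i)
            sym = _symbol(i)
            if namespace == "uniprot_entry_name":
                ident = f"{sym}_{_SPECIES_SUFFIX[species]}"
            elif namespace == "ensembl_gene":
                ident = _xrefs(i, species)["ensembl_gene"]
            elif namespace == "refseq_accession":
                ident = _xrefs(i, species)["refseq_accession"]
            elif namespace == "ncbi_gi":
                ident = _xrefs(i, species)["ncbi_gi"]
            else:
                ident = _species_symbol(sym, species)
            corruption = "none"
            if config.noise_rate > 0 and rng.random() < config.noise_rate:
                kind = rng.choice(["case", "synonym", "unmappable"], p=[0.5, 0.3, 0.2])
                if kind == "synonym" and namespace == "gene_symbol":
                    idxs = db._by_synonym  # synonyms indexed by normalized token
                    synonyms = [
                        t for t in (f"SY{i + 1:05d}X{j}" for j in range(4)) if t.upper() in idxs
                    ]
                    if synonyms:
                        ident = synonyms[int(rng.integers(len(synonyms)))]
                        corruption = "synonym"
                    else:
                        ident = ident.lower()
                        corruption = "case"
                elif kind == "unmappable":
                    ident = f"UNMAPPED{unmappable_counter:05d}"
                    unmappable_counter += 1
                    corruption = "unmappable"
                else:
                    ident = ident.lower()
                    corruption = "case"
            rows.append((ident, f"Palmitoyl substrate protein {sym}"))
            truth_rows.append((study_id, ident, sym, corruption))
        frame = pd.DataFrame(rows, columns=["identifier", "description"])
        tables.append(StudyTable(study_id=study_id, rows=frame, namespace=namespace))
    row_truth = pd.DataFrame(truth_rows, columns=["study_id", "identifier", "gene_symbol", "corruption"])
    return tables, row_truth, study_sets


def generate_annotation_sets(
    config: SimulationConfig,
    background: Sequence[str],
    compendium: Optional[Iterable[str]] = None,
) -> tuple[list[AnnotationTerm], pd.DataFrame]:
    """GMT-style term collections with planted fold enrichments.

    Planted terms draw each member from the compendium with probability
    FE * n / N (so the expected fold enrichment equals the target); decoys
    sample the universe uniformly (expected FE = 1). A disease category is
    generated with class-named significant terms mirroring the published
    rollup, plus uniform decoy disease terms.
    """
    rng = config._rng(_STREAM_TERMS)
    background = [str(g).upper() for g in background]
    if compendium is None:
        comp = {_symbol(int(i)) for i in latent_palmitoylome(config)}
    else:
        comp = {str(g).upper() for g in compendium}
    comp_list = sorted(comp & set(background))
    other_list = sorted(set(background) - comp)
    if not comp_list:
        raise ConfigurationError("compendium does not intersect the background")
    n, N = len(comp_list), len(background)

    def planted_term(term_id: str, name: str, category: str, size: int, fe: float) -> AnnotationTerm:
        if size < 1:
            raise ConfigurationError(f"term {term_id}: size must be >= 1")
        q = fe * n / N
        if q > 1.0:
            raise ConfigurationError(f"term {term_id}: target FE {fe} unattainable")
        k = int(rng.binomial(size, q))
        k = min(k, len(comp_list), size)
        members = list(rng.choice(comp_list, size=k, replace=False)) + list(
            rng.choice(other_list, size=size - k, replace=False)
        )
        return AnnotationTerm(term_id=term_id, name=name, category=category, genes=frozenset(members))

    terms: list[AnnotationTerm] = []
    truth = []
    for t, (size, fe) in enumerate(config.planted_terms):
        term = planted_term(f"GO_PLANTED_{t:03d}", f"planted process {t}", "go_bp", size, fe)
        terms.append(term)
        truth.append((term.term_id, "go_bp", "", size, fe))
    for t in range(config.n_decoy_terms):
        members = rng.choice(background, size=config.decoy_term_size, replace=False)
        term = AnnotationTerm(
            term_id=f"GO_DECOY_{t:03d}", name=f"decoy process {t}",
            category="go_bp", genes=frozenset(members),
        )
        terms.append(term)
        truth.append((term.term_id, "go_bp", "", config.decoy_term_size, 1.0))
    d = 0
    for cls, count in config.disease_class_counts.items():
        names = DISEASE_CLASS_NAMES[cls]
        for j in range(count):
            name = names[j % len(names)] + ("" if j < len(names) else f" type {j}")
            term = planted_term(
                f"DIS_PLANTED_{d:03d}", name, "disease",
                config.disease_term_size, config.disease_fe,
            )
            terms.append(term)
            truth.append((term.term_id, "disease", cls, config.disease_term_size, config.disease_fe))
            d += 1
    for t in range(config.n_decoy_disease_terms):
        members = rng.choice(background, size=config.disease_term_size, replace=False)
        term = AnnotationTerm(
            term_id=f"DIS_DECOY_{t:03d}", name=f"Unspecified syndrome {t}",
            category="disease", genes=frozenset(members),
        )
        terms.append(term)
        truth.append((term.term_id, "disease", "", config.disease_term_size, 1.0))
    truth_frame = pd.DataFrame(truth, columns=["term_id", "category", "disease_class", "size", "target_fe"])
    return terms, truth_frame


def generate_synaptic_list(
    config: SimulationConfig,
    background: Sequence[str],
    compendium: Optional[Iterable[str]] = None,
) -> tuple[list[str], dict]:
    """Synaptic gene list with planted compendium-membership odds.

    The overlap count is drawn from Fisher's noncentral hypergeometric
    distribution with the configured odds, then members are sampled
    uniformly inside/outside the compendium.
    """
    rng = config._rng(_STREAM_SYNAPTIC)
    background = [str(g).upper() for g in background]
    if compendium is None:
        comp = {_symbol(int(i)) for i in latent_palmitoylome(config)}
    else:
        comp = {str(g).upper() for g in compendium}
    comp_list = sorted(comp & set(background))
    other_list = sorted(set(background) - comp)
    if not comp_list:
        raise ConfigurationError("compendium does not intersect the background")
    L = config.synaptic_list_size
    N = len(background)
    a = int(
        nchypergeom_fisher.rvs(N, len(comp_list), L, config.synaptic_overlap_odds, random_state=rng)
    )
    a = min(a, len(comp_list), L)
    members = list(rng.choice(comp_list, size=a, replace=False)) + list(
        rng.choice(other_list, size=L - a, replace=False)
    )
    truth = {"odds": config.synaptic_overlap_odds, "overlap": a, "list_size": L, "N": N}
    return sorted(members), truth


def generate_background_lists(
    config: SimulationConfig, background: Sequence[str]
) -> dict[str, list[str]]:
    """Two overlapping MS-proteome gene lists whose union misses a few
    latent palmitoylome genes, exercising the append-to-background path."""
    rng = config._rng(_STREAM_BACKGROUND)
    background = [str(g).upper() for g in background]
    latent = [_symbol(int(i)) for i in latent_palmitoylome(config)]
    holdout = set(rng.choice(latent, size=config.background_holdout, replace=False))
    union = [g for g in background if g not in holdout]
    perm = rng.permutation(len(union))
    third = len(union) // 3
    list_a = [union[i] for i in sorted(perm[: 2 * third])]
    list_b = [union[i] for i in sorted(perm[third:])]
    return {"proteome_ms_1": list_a, "proteome_ms_2": list_b}


def generate_sequences_and_mutations(
    config: SimulationConfig,
) -> tuple[dict[str, str], pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Protein sequences with planted Cys motifs plus mutation/evidence tables.

    Returns (sequences, mutations, site_evidence, truth): truth lists the
    expected classification of every planted mutation.
    """
    rng = config._rng(_STREAM_SEQS)
    spec = config.motif_spec
    latent = latent_palmitoylome(config)
    symbols = iter(_symbol(int(i)) for i in latent)

    sequences: dict[str, str] = {}
    mutations = []
    evidence = []
    truth = []

    def new_seq() -> list[str]:
        return list(rng.choice(list(_AA_NO_CYS), size=spec.seq_length))

    def add(gene, seq, sub, disease, expected):
        sequences[gene] = "".join(seq)
        mutations.append((gene, sub, disease))
        truth.append((gene, sub, expected))

    for _ in range(spec.known):
        gene, seq = next(symbols), new_seq()
        seq[5] = "C"
        add(gene, seq, "C6F", "ALS-like neurodegeneration", "known_palmitoylated")
        evidence.append((gene, 6, "known"))
    for _ in range(spec.predicted):
        gene, seq = next(symbols), new_seq()
        seq[73] = "C"
        add(gene, seq, "C74Y", "Lysosomal storage disorder", "predicted")
        evidence.append((gene, 74, "predicted"))
    for _ in range(spec.di_cys):
        gene, seq = next(symbols), new_seq()
        seq[111] = seq[112] = "C"
        add(gene, seq, "C113R", "Lysosomal storage disorder", "di_cys_adjacent")
    for _ in range(spec.cys_rich):
        gene, seq = next(symbols), new_seq()
        for pos in (40, 42, 45):  # three Cys in a 10-residue window, none adjacent
            seq[pos - 1] = "C"
        add(gene, seq, "C42G", "Temporal lobe epilepsy", "cys_rich_region")
    for _ in range(spec.no_evidence):
        gene, seq = next(symbols), new_seq()
        seq[149] = "C"
        add(gene, seq, "C150S", "Idiopathic neuropathy", "no_evidence")
    for _ in range(spec.non_cys_decoys):
        gene, seq = next(symbols), new_seq()
        seq[3] = "A"
        add(gene, seq, "A4V", "ALS-like neurodegeneration", "not_cysteine")
    for _ in range(spec.mismatch_decoys):
        gene, seq = next(symbols), new_seq()  # position 10 is deliberately not Cys
        add(gene, seq, "C10R", "Unassigned disorder", "ref_mismatch")

    mut_frame = pd.DataFrame(mutations, columns=["gene", "substitution", "disease"])
    ev_frame = pd.DataFrame(evidence, columns=["gene", "position", "tier"])
    truth_frame = pd.DataFrame(truth, columns=["gene", "substitution", "expected_classification"])
    return sequences, mut_frame, ev_frame, truth_frame


@dataclass
class SimulationResult:
    """Everything the generator produced, with ground truth attached."""

    config: SimulationConfig
    db: MappingDatabase
    identifier_truth: pd.DataFrame
    manifest: list[StudyMeta]
    studies: list[StudyTable]
    row_truth: pd.DataFrame
    study_gene_sets: dict[str, set[str]]
    latent_genes: set[str]
    background_genes: list[str]
    background_lists: dict[str, list[str]]
    terms: list[AnnotationTerm]
    term_truth: pd.DataFrame
    synaptic_list: list[str]
    synaptic_truth: dict
    sequences: dict[str, str]
    mutations: pd.DataFrame
    site_evidence: pd.DataFrame
    mutation_truth: pd.DataFrame


def simulate(config: Optional[SimulationConfig] = None) -> SimulationResult:
    """Generate the full synthetic input suite for one configuration."""
    config = config or SimulationConfig()
    db, id_truth = generate_mapping_db(config)
    tables, row_truth, study_sets = generate_study_tables(config, db)
    background = [_symbol(i) for i in range(config.n_background)]
    latent = {_symbol(int(i)) for i in latent_palmitoylome(config)}
    terms, term_truth = generate_annotation_sets(config, background)
    synaptic, syn_truth = generate_synaptic_list(config, background)
    bg_lists = generate_background_lists(config, background)
    sequences, mutations, evidence, mut_truth = generate_sequences_and_mutations(config)
    return SimulationResult(
        config=config,
        db=db,
        identifier_truth=id_truth,
        manifest=manifest_from_config(config),
        studies=tables,
        row_truth=row_truth,
        study_gene_sets=study_sets,
        latent_genes=latent,
        background_genes=background,
        background_lists=bg_lists,
        terms=terms,
        term_truth=term_truth,
        synaptic_list=synaptic,
        synaptic_truth=syn_truth,
        sequences=sequences,
        mutations=mutations,
        site_evidence=evidence,
        mutation_truth=mut_truth,
    )


def write_simulation(result: SimulationResult, outdir: str | Path) -> dict[str, Path]:
    """Write every artifact as plain text; byte-identical under a fixed seed."""
    outdir = Path(outdir)
    (outdir / "studies").mkdir(parents=True, exist_ok=True)
    (outdir / "gene_sets").mkdir(exist_ok=True)
    (outdir / "truth").mkdir(exist_ok=True)
    paths: dict[str, Path] = {}

    def tsv(frame: pd.DataFrame, rel: str) -> Path:
        p = outdir / rel
        frame.to_csv(p, sep="\t", index=False)
        return p

    paths["mapping_db"] = tsv(result.db.frame, "mapping_db.tsv")
    paths["identifier_truth"] = tsv(result.identifier_truth, "truth/identifier_truth.tsv")
    manifest_frame = pd.DataFrame(
        [
            {
                "study_id": m.study_id, "species": m.species, "tissue_source": m.tissue_source,
                "fraction": m.fraction, "methods": "|".join(sorted(m.methods)),
                "neuronal": int(m.neuronal),
            }
            for m in result.manifest
        ],
        columns=MANIFEST_COLUMNS,
    )
    paths["manifest"] = tsv(manifest_frame, "manifest.tsv")
    for table in result.studies:
        paths[f"study:{table.study_id}"] = tsv(table.rows, f"studies/{table.study_id}.tsv")
    paths["row_truth"] = tsv(result.row_truth, "truth/study_row_truth.tsv")
    sets_frame = pd.DataFrame(
        [(s, "|".join(sorted(genes))) for s, genes in sorted(result.study_gene_sets.items())],
        columns=["study_id", "genes"],
    )
    paths["study_gene_sets"] = tsv(sets_frame, "truth/study_gene_sets.tsv")
    p = outdir / "truth/latent_genes.txt"
    p.write_text("\n".join(sorted(result.latent_genes)) + "\n")
    paths["latent_genes"] = p
    p = outdir / "background_universe.txt"
    p.write_text("\n".join(result.background_genes) + "\n")
    paths["background_universe"] = p
    for name, genes in result.background_lists.items():
        p = outdir / f"{name}.txt"
        p.write_text("\n".join(genes) + "\n")
        paths[name] = p
    for category in ("go_bp", "disease"):
        subset = [t for t in result.terms if t.category == category]
        p = outdir / f"gene_sets/{category}.gmt"
        write_gmt(subset, p)
        paths[f"gmt:{category}"] = p
    paths["term_truth"] = tsv(result.term_truth, "truth/term_truth.tsv")
    p = outdir / "synaptic_genes.txt"
    p.write_text("\n".join(result.synaptic_list) + "\n")
    paths["synaptic"] = p
    p = outdir / "truth/synaptic_truth.json"
    p.write_text(json.dumps(result.synaptic_truth, indent=2, sort_keys=True) + "\n")
    paths["synaptic_truth"] = p
    fasta = outdir / "sequences.fasta"
    with fasta.open("w") as fh:
        for gene in sorted(result.sequences):
            fh.write(f">{gene}\n{result.sequences[gene]}\n")
    paths["sequences"] = fasta
    paths["mutations"] = tsv(result.mutations, "mutations.tsv")
    paths["site_evidence"] = tsv(result.site_evidence, "site_evidence.tsv")
    paths["mutation_truth"] = tsv(result.mutation_truth, "truth/mutation_truth.tsv")
    return paths
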