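"""End-to-end orchestration: curate -> compendium -> cluster -> enrich ->
overlap -> mine, with reproducible seeds and a machine-readable summary."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from . import __version__
from .errors import ConfigurationError, PalmitomeError
from . import cluster as _cluster
from . import compendium as _compendium
from . import enrich as _enrich
from . import identifiers as _identifiers
from . import mining as _mining
from . import overlap as _overlap

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    mapping_db: str
    manifest: str
    studies_dir: str
    background_lists: Sequence[str]
    gene_sets_dir: Optional[str] = None
    synaptic_list: Optional[str] = None
    sequences: Optional[str] = None
    mutations: Optional[str] = None
    site_evidence: Optional[str] = None
    exclusions: Optional[str] = None
    fdr: float = 0.001
    fe: float = 2.0
    boot: int = 5000
    scales: Sequence[float] = _cluster.DEFAULT_SCALES
    min_term_size: int = 3
    seed: int = 0
    outdir: str = "palmitome_out"

    def __post_init__(self):
        if not (0 < self.fdr < 1):
            raise ConfigurationError("fdr threshold must lie in (0, 1)")
        if self.fe <= 0 or self.boot <= 0:
            raise ConfigurationError("fe and boot thresholds must be positive")
        for path in self.input_paths():
            if not Path(path).exists():
                raise ConfigurationError(f"input path does not exist: {path}")

    def input_paths(self) -> list[str]:
        paths = [self.mapping_db, self.manifest, self.studies_dir, *self.background_lists]
        for p in (self.gene_sets_dir, self.synaptic_list, self.sequences,
                  self.mutations, self.site_evidence, self.exclusions):
            if p is not None:
                paths.append(p)
        return paths

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]


def _read_gene_list(path: str | Path) -> list[str]:
    return [
        line.strip().upper()
        for line in Path(path).read_text().splitlines()
        if line.strip() and not line.startswith("#")
    ]


def _read_exclusions(path: str | Path) -> list[_compendium.ExclusionRule]:
    frame = pd.read_csv(path, sep="\t", dtype=str, comment="#").fillna("")
    return [
        _compendium.ExclusionRule(
            study_id=str(r.study_id), raw_identifier=str(r.raw_identifier), reason=str(r.reason)
        )
        for r in frame.itertuples(index=False)
    ]


def run_all(config: PipelineConfig) -> dict:
    """Run every stage in order; any failure aborts naming the stage.

    Partial outputs written before the failing stage are preserved.
    Returns the JSON-serializable run summary.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = f"# palmitome {__version__} seed={config.seed} config={config.digest()}\n"

    def write_tsv(frame: pd.DataFrame, name: str) -> None:
        path = outdir / name
        with path.open("w") as fh:
            fh.write(header)
            frame.to_csv(fh, sep="\t", index=False)

    summary: dict = {"version": __version__, "seed": config.seed, "config": config.digest()}
    stage = "curate"
    try:
        db = _identifiers.load_mapping_database(config.mapping_db)
        manifest = _compendium.read_manifest(config.manifest)
        meta_by_id = {m.study_id: m for m in manifest}
        rules = _read_exclusions(config.exclusions) if config.exclusions else []
        study_files = sorted(Path(config.studies_dir).glob("*.tsv"))
        if not study_files:
            raise ConfigurationError(f"no study tables in {config.studies_dir}")
        matches = []
        for path in study_files:
            table = _identifiers.read_study_table(path)
            table = _compendium.apply_exclusions(table, rules)
            meta = meta_by_id.get(table.study_id)
            hint = meta.species if meta else None
            result = _identifiers.match_study(table, db, species_hint=hint)
            matches.append(result)
            write_tsv(_identifiers.match_report_frame(result), f"match_{table.study_id}.tsv")
        study_genes = _identifiers.unify_homologs(matches, db)
        gene_keys = _identifiers.gene_keys_from_matches(matches, db)
        summary["curate"] = {
            "studies": len(matches),
            "mean_match_rate": float(pd.Series([m.match_rate for m in matches]).mean()),
            "min_match_rate": float(min(m.match_rate for m in matches)),
        }

        stage = "compendium"
        entries = _compendium.build_compendium(study_genes, manifest, gene_keys=gene_keys)
        frame = _compendium.compendium_frame(entries, manifest)
        write_tsv(frame, "compendium.tsv")
        partition = _compendium.partition_by_source(entries)
        summary["compendium"] = {"n_genes": len(entries), "source_partition": partition}

        stage = "cluster"
        matrix = _cluster.to_binary_matrix(entries, [m.study_id for m in manifest if m.study_id in study_genes])
        dist = _cluster.binary_distance(matrix)
        write_tsv(dist.reset_index().rename(columns={"index": "study"}), "binary_distance.tsv")
        tree = _cluster.average_linkage(dist)
        support = _cluster.bootstrap_support(
            matrix, tree, n_samplings=config.boot, scales=config.scales, seed=config.seed
        )
        labels = {
            ms: f"AU={support.au[ms]:.2f}/BP={support.bp[ms]:.2f}" if support.au[ms] is not None
            else f"BP={support.bp[ms]:.2f}"
            for ms in support.node_members
        }
        (outdir / "dendrogram.nwk").write_text(tree.to_newick(labels) + "\n")
        write_tsv(support.table(), "bootstrap_support.tsv")
        summary["cluster"] = {
            "nodes": [
                {"members": sorted(ms), "bp": support.bp[ms], "au": support.au[ms]}
                for ms in support.node_members
            ],
            "n_samplings": config.boot,
        }

        compendium_genes = sorted(e.gene_key.symbol for e in entries)
        stage = "enrich"
        background = _enrich.build_background(
            {Path(p).stem: _read_gene_list(p) for p in config.background_lists},
            compendium_genes,
        )
        summary["background"] = {"N": background.size, "appended": background.appended}
        if config.gene_sets_dir:
            terms = []
            for path in sorted(Path(config.gene_sets_dir).glob("*.gmt")):
                category = path.stem
                terms.extend(_enrich.read_gmt(path, category))
            results = _enrich.run_enrichment(
                compendium_genes, terms, background,
                fdr_threshold=config.fdr, fe_threshold=config.fe,
                min_term_size=config.min_term_size,
            )
            write_tsv(results, "enrichment.tsv")
            sig = results[results["significant"]]
            summary["enrich"] = {
                "n_terms": int(len(results)),
                "significant_per_category": {
                    str(c): int(n) for c, n in sig.groupby("category").size().items()
                },
            }
            disease_sig = sig[sig["category"] == "disease"]
            if len(disease_sig):
                rollup = _enrich.classify_disease_terms(disease_sig["name"])
                write_tsv(rollup, "disease_classes.tsv")
                summary["enrich"]["disease_classes"] = dict(
                    zip(rollup["disease_class"], (int(c) for c in rollup["count"]))
                )

        stage = "overlap"
        if config.synaptic_list:
            synaptic = _read_gene_list(config.synaptic_list)
            overlap = _overlap.overlap_summary(compendium_genes, synaptic, background)
            (outdir / "overlap.json").write_text(json.dumps(overlap.to_dict(), indent=2) + "\n")
            summary["overlap"] = overlap.to_dict()

        stage = "mine"
        if config.mutations and config.sequences:
            records = _mining.read_mutations(config.mutations)
            sequences = _mining.read_sequences(config.sequences)
            evidence = (
                _mining.read_site_evidence(config.site_evidence) if config.site_evidence else {}
            )
            report = _mining.mine_mutations(records, sequences, evidence)
            write_tsv(report, "mutation_mining.tsv")
            summary["mine"] = report["classification"].value_counts().to_dict()
    except PalmitomeError:
        logger.error("pipeline failed during stage %r", stage)
        raise
    except Exception as exc:  # annotate foreign errors with the stage name
        raise PalmitomeError(f"stage {stage!r} failed: {exc}") from exc

    (outdir / "run_summary.json").write_text(json.dumps(summary, indent=2, default=str) + "\n")
    return summary
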