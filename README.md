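# palmitome

Curation and meta-analysis of mammalian palmitoylation proteomics studies.

S-acylation (palmitoylation) is the reversible thioester attachment of
long-chain fatty acids — typically palmitate — to protein cysteines.
Over a dozen proteomics studies (ABE, Acyl-RAC, and bioorthogonal-labeling
assays across human, mouse, and rat) each report a few hundred candidate
palmitoyl-proteins, but in heterogeneous supplemental tables with five
different identifier conventions. `palmitome` is a pipeline for researchers
who want one consolidated, gene-level palmitoylome and the downstream
statistics that such a compendium supports:

1. **Identifier consolidation** — resolve UniProt entry names, Ensembl gene
   IDs, gene symbols, RefSeq accessions, and NCBI GI numbers against a
   UniProt-like mapping database, with Swiss-Prot (reviewed) priority and
   cross-species homolog unification by shared gene symbol / entry-name
   prefix.
2. **Compendium assembly** — one row per gene with per-study and per-method
   0/1 evidence flags, study counts, a neuronal / non-neuronal source
   class, and a confidence tier (multi-method evidence with a
   hydroxylamine-controlled bioorthogonal assay ranks highest).
3. **Study clustering** — studies as binary presence/absence vectors over
   genes, asymmetric binary (Jaccard) distance
   `d(i,j) = |S_i △ S_j| / |S_i ∪ S_j|`, average linkage (UPGMA), and
   multiscale bootstrap support: BP (bootstrap probability at scale 1) and
   the approximately-unbiased AU p-value from the signed-distance /
   curvature fit `z(r) = v√r + c/√r`, `AU = 1 − Φ(v − c)`.
4. **Enrichment** — one-sided hypergeometric over-representation of GMT
   annotation terms against a custom MS-detectable proteome background,
   Benjamini–Hochberg FDR within each annotation category, fold enrichment
   `FE = (k/n)/(K/N)`, significance rule `FDR < 0.001 ∧ FE ≥ 2`, and a
   keyword rollup of significant disease terms into broad classes
   (nervous system, cancer, infection, anemia, gastrointestinal, other).
5. **Overlap analysis** — 2×2 membership tables over the background
   universe, two-sided Fisher exact test, sample and conditional-MLE odds
   ratios with exact conditional confidence intervals, and directional
   overlap percentages (e.g. the share of synaptic genes that are
   palmitoylated).
6. **Mutation mining** — disease substitutions (`C6F`) at cysteines
   classified against palmitoylation-site evidence with precedence
   known > predicted > di-Cys adjacent > Cys-rich region > no evidence.

A first-class synthetic-data generator (`palmitome.simulate`) emulates all
fifteen study supplements, the mapping database, annotation collections,
the synaptic list, and mutation fixtures with known ground truth, so every
stage is testable without downloads. Its defaults are calibrated to the
published study design (9 human / 5 mouse / 1 rat studies, three neuronal
sources, a compendium of ~1,838 genes in a 17,858-gene background).

## Worked example

```bash
palmitome simulate --seed 1 --outdir sim
palmitome run-all --inputs sim --outdir out --seed 1 --boot 500
```

The run summary (also written to `out/run_summary.json`) includes:

```json
"curate":     {"studies": 15, "mean_match_rate": 0.9809, "min_match_rate": 0.9560},
"compendium": {"n_genes": 1768,
               "source_partition": {"counts": {"neuronal_only": 442,
                                               "non_neuronal_only": 918,
                                               "both": 408}}},
"overlap":    {"p_two_sided": 7.05e-109, "odds_ratio_sample": 5.68, ...}
```

Reading: 98.1% of reported identifiers were resolved to the mapping
database on average; the consolidated compendium contains 1,768 genes, of
which 442 were seen only in the three neuronal studies and 918 only in
non-neuronal ones; and compendium membership is overwhelmingly enriched
inside the synaptic gene list (Fisher p ≪ 1e-100 at the planted odds).
`out/dendrogram.nwk` carries AU/BP node labels — the planted same-lab study
pair is recovered with BP = 1.0 — and `out/enrichment.tsv` lists per-term
k/K/n/N, p, FDR, FE and the significance flag.

Every stage is also a library call (`palmitome.match_study`,
`build_compendium`, `average_linkage`, `bootstrap_support`,
`run_enrichment`, `overlap_summary`, `mine_mutations`) operating on
pandas DataFrames and plain dataclasses.

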