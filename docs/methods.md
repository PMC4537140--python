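# Methods

## The curation model

The pipeline treats a "palmitoylome" as a set of genes, not proteoforms:
the detection assays (ABE, Acyl-RAC, bioorthogonal labeling) rarely
distinguish protein isoforms but always map to a single gene, so every
stage operates on gene-level keys. A gene's evidence is the set of studies
that reported it, flagged per study — a study that reported the same
protein in several fractions or replicates still contributes a single 1.
Method flags are derived from the study flags through the manifest: a
method column is 1 iff some flagging study used that method.

Identifier resolution proceeds per namespace. Entry names and the three
cross-reference kinds (Ensembl gene, RefSeq protein, NCBI GI) resolve by
exact lookup after NFKC normalization and uppercasing; gene symbols
resolve by symbol, then synonym, then full name — primary names are more
reliable than synonyms, so the first non-empty candidate set wins. When
both reviewed (Swiss-Prot-like) and unreviewed (TrEMBL-like) entries match,
only reviewed entries survive; a species hint (the study's organism)
narrows ties; any remaining tie breaks deterministically on the
lexicographically smallest entry name, with a logged warning, so permuting
input rows can never change the resolved gene set. Unmatched identifiers
are reported and excluded — the compendium contains matched entries only.

Homolog unification collapses records sharing an uppercased symbol or an
entry-name prefix (the part before `_`); when a prefix would bridge two
distinct symbols the symbol route wins and the conflict is logged.
Per-species entry names and Entrez IDs missing from the evidence are
filled from the mapping database by symbol lookup (reviewed preferred).

Confidence tiers order the evidence the way practitioners weigh it:
`multi_method_with_HAM` (≥2 methods including hydroxylamine-controlled
bioorthogonal labeling) > `multi_method` > `multi_study` > `single_study`.

## Clustering and bootstrap support

Studies are columns of a genes × studies 0/1 matrix. The distance is the
asymmetric binary (Jaccard) distance — discordant genes over genes present
in at least one of the two studies — because joint absence carries no
information in presence/absence proteomics. Trees are built by UPGMA;
merge heights are the raw average inter-cluster distances (not halved),
and ties break on the lexicographically smallest label pair so trees are
reproducible.

Support values come from multiscale bootstrap of genes (rows): at each
scale r ∈ {0.5, …, 1.4}, `n_samplings` resamples of round(r·n_genes) genes
are drawn with replacement, the studies are re-clustered, and a clade
counts as recovered when its exact member set reappears. BP is the
recovery fraction at r = 1. AU is estimated by weighted least squares of
z(r) = Φ⁻¹(1 − BP_r) against v√r + c/√r (binomial information weights),
with AU = 1 − Φ(v − c); v is the signed distance and c the curvature of
the boundary. Nodes whose BP is 0 or 1 at all but one scale leave the
regression unidentifiable; their AU is reported as undefined rather than
silently clamped — a clade recovered in every replicate at every scale
(e.g. a duplicated study pair) therefore shows BP = 1.0 and no AU.

The default sampling count follows the source design (5000); tests and
the acceptance script use 120–500 samplings, which bounds the Monte-Carlo
standard error of BP at ≈ 0.025 — ample for the ≥ 0.95 recovery checks.

## Enrichment and overlap statistics

Over-representation is the one-sided hypergeometric upper tail
P(X ≥ k) for X ~ Hypergeom(N, K, n), computed via the log survival
function; fold enrichment is FE = (k/n)/(K/N). The background universe is
the union of MS-proteome gene lists with any missing compendium genes
appended, so the query is always nested in the universe and enrichment is
conditioned on MS detectability. FDR is Benjamini–Hochberg within each
annotation category, mirroring per-category reporting; the significance
rule is FDR < 0.001 and FE ≥ 2 (both required). Terms with fewer than
`min_term_size = 3` background genes are dropped as uninformative
(configurable). Significant disease terms roll up to broad classes by
ordered first-match keyword rules; cancer precedes nervous-system so that
terms like neuroblastoma land with the cancers; unmatched names fall to
`other` with a log line.

Overlap analysis builds the 2×2 membership table over the background
universe only — the single construction under which an exact test is
valid — and uses the two-sided Fisher exact test with the conventional
point-probability rule. Both the sample odds ratio (Haldane 0.5 correction
only when a cell is zero) and the conditional-MLE odds ratio with its
exact conditional confidence interval are reported, because published
interval conventions vary and no single variant can be assumed.

## Mutation mining

Substitutions are 1-based protein coordinates (`C6F`). Records are checked
against the sequence: non-cysteine references and reference mismatches are
flagged, not dropped silently. Cysteine records receive the highest
evidence tier they satisfy: annotated/known site > externally predicted
site > di-Cys (an immediately adjacent cysteine, ±1) > Cys-rich region
(≥ 3 cysteines within some 10-residue window containing the site) > no
evidence. "Cys-rich" has no canonical definition in the literature; the
window and count are explicit, configurable parameters rather than hidden
constants. Predicted sites are always an input file — the package never
runs a site predictor. Each report row carries a 21-residue context window.

## The synthetic-data generator

The generator emulates the fifteen-study design: 9 human, 5 mouse, 1 rat
study; five identifier namespaces; three neuronal sources (the brain,
neuronal-stem-cell, and embryonic-neuron/brain studies); four detection
methods. A latent palmitoylome (a fixed subset of the background universe)
is sampled by each study independently with its detection probability;
studies inside a planted cluster share a common per-gene uniform draw, so
with equal probabilities they detect identical sets — the planted pair is
the same-laboratory pair of hydroxylamine-controlled studies, emulating
the one significant cluster seen in real data.

Calibrated defaults (chosen from the published design, then left alone):

| parameter | default | rationale |
|---|---|---|
| `n_background` | 17,858 | size of the MS-detectable background universe |
| `n_genes` (latent) | 2,880 | solves the source-partition equations below |
| detection prob., neuronal | 0.113 | 1 − (1−p)³ = 0.302 ⇒ 452 neuronal-only genes |
| detection prob., other | 0.058 | 1 − (1−p)¹¹ = 0.482 ⇒ 966 non-neuronal-only genes |
| `noise_rate` | 0.1165 | 20% of corruptions are unmappable ⇒ 2.33% mean unmatched |
| `synaptic_overlap_odds` | 7.0 | sample odds ratio implied by the published 2×2 ≈ 7.5 |
| planted term | K=50, FE=6 | a strongly enriched process-sized term |
| disease terms | 40 × (K=120, FE=3) | decisively significant terms, FE near the reported 2.0–2.6 |

With these values the expected consolidated compendium is ≈ 1,838 genes
with ≈ 452 detected only in neuronal and ≈ 966 only in non-neuronal
studies (per-replicate Monte-Carlo spread ≈ 4%). Identifier noise splits
50% case perturbation / 30% synonym substitution / 20% unmappable token;
only unmappable tokens fail resolution, the others exercise the
case-insensitive and synonym routes. Planted annotation terms draw each
member from the latent palmitoylome with probability FE·n/N (so expected
fold enrichment equals the target and infeasible targets are rejected);
decoy terms sample the universe uniformly. The synaptic list draws its
overlap count from Fisher's noncentral hypergeometric distribution at the
configured odds, which at odds = 1 reduces to the central null — the basis
of the calibration tests. Sequence fixtures plant one gene per evidence
tier with motifs spaced so no site accidentally satisfies a
higher-precedence tier.

What the generator does **not** emulate: peptide- or spectrum-level
evidence, abundance, method-specific false-positive profiles (the assays'
failure modes are only known qualitatively), real gene nomenclature
irregularities, or correlated annotation structure (terms are sampled
independently). Passing tests therefore demonstrate correctness of the
statistical machinery and curation logic under the stated generative
model, not robustness to every pathology of real supplementary tables.

## Numerical and design choices

- All randomness flows through `numpy` Generators seeded from
  (seed, stream-index) pairs, one independent stream per artifact kind;
  identical seed + configuration reproduces every output byte for byte.
- Hypergeometric tails are evaluated in log space; p-values are clipped
  into (0, 1].
- Degenerate cases are explicit: all-zero column pairs get distance 0 with
  a warning; degenerate 2×2 margins yield undefined odds ratios, reported
  as such; empty candidate sets are an unmatched state, not an error.
- Output files are sorted (genes by symbol, results by FDR within
  category) with fixed column order, so runs are diff-able.
- Problem sizes in tests and the acceptance script (300-gene fixtures for
  unit tests; the full 17,858-gene universe with 400–500 bootstrap
  samplings for end-to-end checks) were chosen so the Monte-Carlo error of
  every checked quantity is small against its tolerance.

## Known limitations

- The homolog-unification rule (shared symbol or entry-name prefix) can
  over-merge paralogs whose symbols collide across species and cannot
  recover homologs with discordant nomenclature; real curation would add
  orthology tables.
- AU p-values are undefined for clades at the BP extremes; consumers must
  handle the reported `None`.
- The disease keyword map is a heuristic classifier; novel term phrasings
  fall to `other` (logged) rather than being guessed.
- The published confidence interval convention for the overlap odds ratio
  is not identifiable from printed values alone; this package reports the
  documented variants side by side instead of matching any single one.
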