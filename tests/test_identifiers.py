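"""Identifier resolution: loaders, namespace detection, reviewed priority,
match rates, and homolog unification."""

import pandas as pd
import pytest

import palmitome as pt
from palmitome.errors import AmbiguousNamespaceError, FormatError, IntegrityError
from palmitome.identifiers import (
    StudyTable,
    gene_keys_from_matches,
    match_report_frame,
)

from conftest import small_config


class TestLoader:
    def test_well_formed_file_round_trips_row_count(self, tiny_db, tmp_path):
        path = tmp_path / "db.tsv"
        tiny_db.frame.to_csv(path, sep="\t", index=False)
        assert len(pt.load_mapping_database(path)) == len(tiny_db)

    def test_duplicate_entry_name_rejected(self, tiny_db, tmp_path):
        frame = pd.concat([tiny_db.frame, tiny_db.frame.iloc[[0]]])
        path = tmp_path / "dup.tsv"
        frame.to_csv(path, sep="\t", index=False)
        with pytest.raises(IntegrityError):
            pt.load_mapping_database(path)

    def test_empty_file_is_a_format_error(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("")
        with pytest.raises(FormatError):
            pt.load_mapping_database(path)

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "short.tsv"
        path.write_text("entry_name\tgene_symbol\nSODC_HUMAN\tSOD1\n")
        with pytest.raises(FormatError):
            pt.load_mapping_database(path)


class TestNamespaceDetection:
    @pytest.mark.parametrize(
        "tokens, expected",
        [
            (["SODC_HUMAN", "NPC1_HUMAN"], "uniprot_entry_name"),
            (["ENSG00000000003"], "ensembl_gene"),
            (["ENSMUSG00000022982", "ENSG00000141458"], "ensembl_gene"),
            (["NP_000445", "NP_035564.1"], "refseq_accession"),
            (["4507149", "255652944"], "ncbi_gi"),
            (["SOD1", "Npc1", "LGI1"], "gene_symbol"),
        ],
    )
    def test_pattern_majorities(self, tokens, expected):
        namespace, fraction = pt.detect_namespace(tokens)
        assert namespace == expected
        assert fraction == 1.0

    def test_fifty_fifty_mixture_is_ambiguous(self):
        with pytest.raises(AmbiguousNamespaceError) as err:
            pt.detect_namespace(["12345", "SOD1_X"])  # gi vs symbol, one each
        assert len(err.value.candidates) == 2


class TestResolve:
    def test_case_insensitive_symbol_with_reviewed_priority(self, tiny_db):
        rec = pt.resolve_identifier("sod1", "gene_symbol", tiny_db, species_hint="human")
        assert rec.entry_name == "SODC_HUMAN"
        assert rec.reviewed

    def test_unreviewed_entry_used_when_no_reviewed_candidate(self, tiny_db):
        rec = pt.resolve_identifier("ORPHAN1", "gene_symbol", tiny_db)
        assert rec.entry_name == "X11111_HUMAN"
        assert not rec.reviewed

    def test_synonym_and_full_name_routes(self, tiny_db):
        assert pt.resolve_identifier("ALS1", "gene_symbol", tiny_db,
                                     species_hint="human").match_route == "synonym"
        rec = pt.resolve_identifier(
            "NPC intracellular cholesterol transporter 1", "gene_symbol", tiny_db
        )
        assert rec.match_route == "full_name" and rec.gene_symbol == "NPC1"

    def test_species_hint_prefers_same_species(self, tiny_db):
        rec = pt.resolve_identifier("SOD1", "gene_symbol", tiny_db, species_hint="mouse")
        assert rec.entry_name == "SODC_MOUSE"

    def test_cross_reference_namespaces(self, tiny_db):
        assert pt.resolve_identifier("ENSG00000141458", "ensembl_gene", tiny_db).gene_symbol == "NPC1"
        assert pt.resolve_identifier("NP_000445", "refseq_accession", tiny_db).gene_symbol == "SOD1"
        assert pt.resolve_identifier("157821697", "ncbi_gi", tiny_db).gene_symbol == "Lgi1"

    def test_absent_token_is_unmatched_not_error(self, tiny_db):
        assert pt.resolve_identifier("NOSUCHGENE", "gene_symbol", tiny_db) is None


def _table(idents, study_id="s1", namespace="gene_symbol"):
    return StudyTable(
        study_id=study_id,
        rows=pd.DataFrame({"identifier": idents, "description": ""}),
        namespace=namespace,
    )


class TestMatchStudy:
    def test_match_rate_counts_unmatched(self, tiny_db):
        idents = ["SOD1"] * 9 + ["ZZZ_NOT_A_GENE"]
        result = pt.match_study(_table(idents), tiny_db)
        assert result.match_rate == pytest.approx(0.9)
        assert result.unmatched == ["ZZZ_NOT_A_GENE"]

    def test_row_order_never_changes_resolved_gene_set(self, tiny_db):
        idents = ["SOD1", "NPC1", "Lgi1", "ALS1", "nosuch"]
        forward = pt.match_study(_table(idents), tiny_db)
        backward = pt.match_study(_table(idents[::-1]), tiny_db)
        as_set = lambda r: {m.gene_symbol.upper() for m in r.matched}
        assert as_set(forward) == as_set(backward)

    def test_report_frame_has_one_row_per_identifier(self, tiny_db):
        result = pt.match_study(_table(["SOD1", "nosuch"]), tiny_db)
        report = match_report_frame(result)
        assert len(report) == 2
        assert set(report["status"]) == {"matched", "unmatched"}


def test_reviewed_priority_holds_across_synthetic_database(sim):
    """Wherever reviewed and unreviewed entries share a symbol, resolution
    returns the reviewed one."""
    db = sim.db
    dup_symbols = (
        db.frame.assign(sym=db.frame["gene_symbol"].str.upper())
        .groupby("sym")["reviewed"]
        .agg(["any", "all"])
    )
    mixed = dup_symbols[dup_symbols["any"] & ~dup_symbols["all"]].index[:50]
    assert len(mixed) > 0
    for symbol in mixed:
        rec = pt.resolve_identifier(symbol, "gene_symbol", db)
        assert rec.reviewed


def test_match_rate_stays_above_published_floor_at_5pct_noise():
    cfg = small_config(seed=5, noise_rate=0.05, n_background=2000, n_genes=600,
                       planted_terms=((30, 2.0),))
    res = pt.simulate(cfg)
    rates = [
        pt.match_study(t, res.db, species_hint=m.species).match_rate
        for t, m in zip(res.studies, res.manifest)
    ]
    assert sum(rates) / len(rates) >= 0.90


class TestUnifyHomologs:
    def test_shared_prefix_and_symbol_collapse_across_species(self, tiny_db):
        table_h = _table(["SODC_HUMAN"], "h", "uniprot_entry_name")
        table_m = _table(["SODC_MOUSE"], "m", "uniprot_entry_name")
        matches = [pt.match_study(table_h, tiny_db), pt.match_study(table_m, tiny_db)]
        keys = gene_keys_from_matches(matches, tiny_db)
        assert set(keys) == {"SOD1"}
        assert set(keys["SOD1"].entry_names) == {"human", "mouse"}

    def test_single_species_gene_filled_from_database(self, tiny_db):
        matches = pt.match_study(_table(["SOD1"], namespace="gene_symbol"), tiny_db)
        keys = gene_keys_from_matches(matches, tiny_db)
        # mouse homolog inferred from the shared symbol
        assert keys["SOD1"].entry_names["mouse"] == "SODC_MOUSE"
        assert keys["SOD1"].entrez_ids["human"] == 6647

    def test_case_differences_produce_single_key(self, tiny_db):
        m1 = pt.match_study(_table(["SOD1"], "a"), tiny_db)
        m2 = pt.match_study(_table(["Sod1"], "b"), tiny_db)
        genes = pt.unify_homologs([m1, m2], tiny_db)
        assert genes["a"] == genes["b"] == {"SOD1"}
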