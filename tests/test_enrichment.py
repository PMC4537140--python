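"""Enrichment statistics: hypergeometric tail, BH FDR, fold enrichment,
significance rule, disease-class rollup."""

import itertools
import math

import numpy as np
import pytest

import palmitome as pt
from palmitome.enrich import AnnotationTerm, top_terms
from palmitome.errors import ConfigurationError, ValidationError
from palmitome.simulate import generate_annotation_sets, latent_palmitoylome, _symbol

from conftest import small_config


def enumeration_tail(k, K, n, N):
    """P(|draw ∩ marked| >= k) by exhaustive enumeration of all C(N, n) draws."""
    marked = set(range(K))
    hits = total = 0
    for draw in itertools.combinations(range(N), n):
        total += 1
        if len(marked & set(draw)) >= k:
            hits += 1
    return hits / total


class TestHypergeometric:
    def test_textbook_example_against_enumeration(self):
        assert pt.hypergeometric_p(4, 4, 5, 10) == pytest.approx(6 / 252)
        assert pt.hypergeometric_p(4, 4, 5, 10) == pytest.approx(enumeration_tail(4, 4, 5, 10))

    def test_zero_hits_certain(self):
        assert pt.hypergeometric_p(0, 4, 5, 10) == 1.0

    def test_degenerate_universe(self):
        assert pt.hypergeometric_p(3, 3, 3, 3) == 1.0

    def test_bound_violations_rejected(self):
        for args in [(5, 4, 5, 10), (1, 11, 5, 10), (-1, 4, 5, 10)]:
            with pytest.raises(ValidationError):
                pt.hypergeometric_p(*args)

    def test_matches_enumeration_for_small_universes(self):
        """Full sweep over N <= 9 (enumeration over all C(N, n) draws)."""
        for N in range(1, 10):
            for K in range(N + 1):
                for n in range(N + 1):
                    for k in range(min(K, n) + 1):
                        assert pt.hypergeometric_p(k, K, n, N) == pytest.approx(
                            enumeration_tail(k, K, n, N), rel=1e-12
                        ), (k, K, n, N)

    def test_equals_one_sided_fisher_on_matched_table(self):
        # cross-module consistency: hypergeometric tail == Fisher upper tail
        for a, b, c, d in [(4, 6, 2, 8), (10, 5, 3, 12), (0, 4, 4, 4)]:
            table = pt.ContingencyTable(a=a, b=b, c=c, d=d)
            from palmitome.overlap import fisher_exact_one_sided

            k, K, n, N = a, a + c, a + b, a + b + c + d
            assert pt.hypergeometric_p(k, K, n, N) == pytest.approx(
                fisher_exact_one_sided(table), rel=1e-9
            )


class TestBH:
    def test_step_up_example(self):
        out = pt.bh_fdr([0.005, 0.01, 0.03, 0.04])
        assert np.allclose(out, [0.02, 0.02, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert pt.bh_fdr([0.123]) == pytest.approx([0.123])

    def test_equal_ps_unchanged(self):
        assert np.allclose(pt.bh_fdr([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    def test_grouping_adjusts_within_category_only(self):
        p = [0.03, 0.5, 0.01, 0.02]
        grouped = pt.bh_fdr(p, grouping=["x", "x", "y", "y"])
        ungrouped = pt.bh_fdr(p)
        assert np.allclose(grouped, [0.06, 0.5, 0.02, 0.02])
        assert not np.allclose(grouped, ungrouped)

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValidationError):
            pt.bh_fdr([0.0, 0.5])


class TestFoldEnrichment:
    @pytest.mark.parametrize(
        "k, K, n, N, fe",
        [(4, 4, 5, 10, 2.0), (2, 4, 5, 10, 1.0), (0, 4, 5, 10, 0.0)],
    )
    def test_arithmetic(self, k, K, n, N, fe):
        assert pt.fold_enrichment(k, K, n, N) == pytest.approx(fe)

    def test_empty_term_rejected(self):
        with pytest.raises(ValidationError):
            pt.fold_enrichment(0, 0, 5, 10)


class TestBackground:
    def test_missing_compendium_genes_appended(self):
        bg = pt.build_background({"ms": [f"G{i}" for i in range(100)]},
                                 ["G1", "G2", "X1", "X2", "X3", "X4", "X5"])
        assert bg.size == 105
        assert bg.appended == 5

    def test_subset_compendium_appends_nothing(self):
        bg = pt.build_background({"ms": ["A", "B", "C"]}, ["A"])
        assert bg.appended == 0 and bg.size == 3

    def test_duplicates_across_lists_counted_once(self):
        bg = pt.build_background({"l1": ["A", "B"], "l2": ["B", "C"]}, [])
        assert bg.size == 3

    def test_empty_union_rejected(self):
        with pytest.raises(ConfigurationError):
            pt.build_background({"l1": []}, ["A"])


class TestRunEnrichment:
    def _setup(self):
        universe = [f"G{i:03d}" for i in range(100)]
        bg = pt.Background(genes=frozenset(universe))
        query = universe[:20]
        return universe, bg, query

    def test_both_conditions_required_for_significance(self):
        universe, bg, query = self._setup()
        # k=8 of K=30 vs n=20/N=100: FE = (8/20)/(30/100) = 1.33 -> never significant
        weak = AnnotationTerm("t1", "weak", "go_bp", frozenset(query[:8] + universe[50:72]))
        # k=10 of K=12: FE = (10/20)/(12/100) ~ 4.2 and tiny p -> significant
        strong = AnnotationTerm("t2", "strong", "go_bp", frozenset(query[:10] + universe[90:92]))
        res = pt.run_enrichment(query, [weak, strong], bg).set_index("term_id")
        assert not res.loc["t1", "significant"]
        assert bool(res.loc["t2", "significant"])
        assert res.loc["t2", "FE"] >= 2 and res.loc["t2", "FDR"] < 0.001

    def test_small_terms_dropped(self):
        universe, bg, query = self._setup()
        tiny = AnnotationTerm("t", "tiny", "go_bp", frozenset(universe[:2]))
        res = pt.run_enrichment(query, [tiny], bg, min_term_size=3)
        assert res.empty

    def test_top_terms_report_shape(self):
        universe, bg, query = self._setup()
        strong = AnnotationTerm("t2", "strong", "go_bp", frozenset(query[:10] + universe[90:92]))
        res = pt.run_enrichment(query, [strong], bg)
        report = top_terms(res, "go_bp", top=5)
        assert list(report.columns) == ["term_id", "name", "neg_log10_fdr", "FE"]
        assert len(report) == 1


def test_planted_fold_enrichment_recovered_in_expectation():
    """Mean empirical FE of a planted term over 200 replicates is within
    3 Monte-Carlo standard errors of the target."""
    target = 3.0
    fes = []
    for seed in range(200):
        cfg = small_config(
            seed=seed, planted_terms=((40, target),), n_decoy_terms=0,
            disease_class_counts={}, n_decoy_disease_terms=0,
        )
        background = [_symbol(i) for i in range(cfg.n_background)]
        terms, _ = generate_annotation_sets(cfg, background)
        latent = {_symbol(int(i)) for i in latent_palmitoylome(cfg)}
        term = next(t for t in terms if t.term_id.startswith("GO_PLANTED"))
        k = len(term.genes & latent)
        fes.append((k / len(latent)) / (len(term.genes) / cfg.n_background))
    fes = np.asarray(fes)
    se = fes.std(ddof=1) / np.sqrt(len(fes))
    assert abs(fes.mean() - target) < 3 * se


class TestDiseaseClassification:
    @pytest.mark.parametrize(
        "name, cls",
        [
            ("Schizophrenia", "nervous_system"),
            ("Huntington disease", "nervous_system"),
            ("Pancreatic ductal carcinoma", "cancer"),
            ("Neuroblastoma", "cancer"),
            ("Hemolytic anemia", "anemia"),
            ("Aplastic anaemia", "anemia"),
            ("Ulcerative colitis", "gastrointestinal"),
            ("Chronic gastritis", "gastrointestinal"),
            ("Hepatitis C infection", "infection"),
            ("Completely novel syndrome", "other"),
        ],
    )
    def test_keyword_assignments(self, name, cls):
        summary = pt.classify_disease_terms([name])
        assignments = summary.attrs["assignments"]
        assert assignments.iloc[0]["disease_class"] == cls

    def test_generator_name_pool_classifies_to_its_planted_class(self):
        from palmitome.simulate import DISEASE_CLASS_NAMES

        for cls, names in DISEASE_CLASS_NAMES.items():
            assigned = pt.classify_disease_terms(names).attrs["assignments"]["disease_class"]
            assert (assigned == cls).all(), cls

    def test_fourteen_of_forty_rolls_up_to_35_percent(self):
        names = (
            [f"Spinocerebellar ataxia type {i}" for i in range(14)]
            + [f"Colorectal cancer stage {i}" for i in range(14)]
            + [f"Hepatitis C infection {i}" for i in range(3)]
            + [f"Aplastic anaemia {i}" for i in range(2)]
            + [f"Ulcerative colitis {i}" for i in range(3)]
            + [f"Unclassified syndrome {i}" for i in range(4)]
        )
        summary = pt.classify_disease_terms(names).set_index("disease_class")
        assert summary.loc["nervous_system", "count"] == 14
        assert summary.loc["cancer", "count"] == 14
        assert summary.loc["nervous_system", "fraction"] == pytest.approx(0.35)
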