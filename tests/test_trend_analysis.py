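import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import littrend as lt
from littrend.fusion_embedding import DocumentVector


def _dv(doc_id, vec):
    return DocumentVector(doc_id, np.asarray(vec, dtype=float), 1.0)


def _corpus(entries):
    return lt.Corpus([lt.Document(i, t, y, g) for i, t, y, g in entries])


class TestYearlyProfiles:
    def test_single_document_profile_is_its_vector(self):
        corpus = _corpus([("a", "x", 2014, "lung")])
        profiles, skipped = lt.yearly_profiles([_dv("a", [1.0, 2.0])], corpus)
        assert skipped == 0
        assert len(profiles) == 1
        assert np.allclose(profiles[0].vector, [1.0, 2.0])
        assert profiles[0].n_docs == 1

    def test_opposite_vectors_cancel(self):
        corpus = _corpus([("a", "x", 2015, "g"), ("b", "y", 2015, "g")])
        profiles, _ = lt.yearly_profiles(
            [_dv("a", [1.0, -2.0]), _dv("b", [-1.0, 2.0])], corpus
        )
        assert np.allclose(profiles[0].vector, 0.0)

    def test_three_document_mean(self):
        corpus = _corpus([(i, "x", 2016, "g") for i in "abc"])
        vecs = [[1.0, 0.0], [0.0, 3.0], [2.0, 3.0]]
        profiles, _ = lt.yearly_profiles(
            [_dv(i, v) for i, v in zip("abc", vecs)], corpus
        )
        assert np.allclose(profiles[0].vector, [1.0, 2.0])

    def test_yearless_documents_skipped_and_counted(self):
        corpus = _corpus([("a", "x", 2016, "g"), ("b", "y", None, "g")])
        profiles, skipped = lt.yearly_profiles(
            [_dv("a", [1.0]), _dv("b", [5.0])], corpus
        )
        assert skipped == 1 and len(profiles) == 1

    def test_all_yearless_rejected(self):
        corpus = _corpus([("a", "x", None, "g")])
        with pytest.raises(ValueError):
            lt.yearly_profiles([_dv("a", [1.0])], corpus)


class TestPairwiseGroupSimilarity:
    def _profiles(self, entries):
        return [lt.YearlyProfile(g, y, np.asarray(v, float), 1) for g, y, v in entries]

    def test_identical_profiles_similarity_one(self):
        sims = lt.pairwise_group_similarity(
            self._profiles([("a", 2014, [1, 2]), ("b", 2014, [2, 4])])
        )
        assert sims[2014].lookup("a", "b") == pytest.approx(1.0)

    def test_orthogonal_profiles_zero(self):
        sims = lt.pairwise_group_similarity(
            self._profiles([("a", 2014, [1, 0]), ("b", 2014, [0, 1])])
        )
        assert sims[2014].lookup("a", "b") == pytest.approx(0.0)

    def test_known_value(self):
        sims = lt.pairwise_group_similarity(
            self._profiles([("a", 2014, [1, 2, 0]), ("b", 2014, [2, 1, 0])])
        )
        assert sims[2014].lookup("a", "b") == pytest.approx(0.8)

    def test_symmetry_and_unit_diagonal(self):
        rng = np.random.default_rng(0)
        profiles = self._profiles(
            [(f"g{i}", 2015, rng.normal(size=4)) for i in range(4)]
        )
        sm = lt.pairwise_group_similarity(profiles)[2015]
        assert np.allclose(sm.matrix, sm.matrix.T)
        assert np.allclose(np.diag(sm.matrix), 1.0)
        assert np.all(sm.matrix <= 1 + 1e-12) and np.all(sm.matrix >= -1 - 1e-12)

    def test_zero_profile_gets_zero_similarity(self):
        sims = lt.pairwise_group_similarity(
            self._profiles([("a", 2014, [0, 0]), ("b", 2014, [1, 1])])
        )
        assert sims[2014].lookup("a", "b") == 0.0

    def test_group_scale_invariance(self):
        base = self._profiles([("a", 2014, [1, 2, 3]), ("b", 2014, [3, 1, 0])])
        scaled = self._profiles([("a", 2014, [4, 8, 12]), ("b", 2014, [3, 1, 0])])
        s1 = lt.pairwise_group_similarity(base)[2014].lookup("a", "b")
        s2 = lt.pairwise_group_similarity(scaled)[2014].lookup("a", "b")
        assert s1 == pytest.approx(s2)

    def test_no_shared_year_rejected(self):
        with pytest.raises(ValueError):
            lt.pairwise_group_similarity(
                self._profiles([("a", 2014, [1]), ("b", 2015, [1])])
            )


class TestMergeKeywordWeights:
    def test_stated_merge_rule(self):
        merged = lt.merge_keyword_weights(
            [[("egfr", 0.5), ("tumor", 0.3)], [("egfr", 0.2), ("crispr", 0.4)]]
        )
        assert merged == pytest.approx(
            {"egfr": 0.7, "tumor": 0.3, "crispr": 0.4}
        )

    def test_single_list_identity(self):
        merged = lt.merge_keyword_weights([[("aa", 1.5), ("bb", 0.5)]])
        assert merged == {"aa": 1.5, "bb": 0.5}

    @settings(derandomize=True, max_examples=200)
    @given(
        st.lists(
            st.lists(
                st.tuples(st.text("abcd", min_size=1, max_size=3),
                          st.floats(0, 10, allow_nan=False)),
                max_size=8,
            ),
            max_size=6,
        )
    )
    def test_weight_conservation(self, lists):
        merged = lt.merge_keyword_weights(lists)
        total_in = sum(w for kws in lists for _, w in kws)
        assert sum(merged.values()) == pytest.approx(total_in, abs=1e-9)


class TestYearlyHotspots:
    def test_single_doc_ten_terms_yields_one(self):
        text = " ".join(f"term{i:02d}" for i in range(10))
        corpus = _corpus([("a", text, 2014, None)])
        tables = lt.yearly_hotspots(corpus, fraction=0.1, top_n=50)
        assert len(tables[2014].hotspots) == 1

    def test_planted_term_in_correct_year_only(self):
        spec = lt.GeneratorSpec(
            n_topics=2, docs_per_topic=30, background_vocab_size=80,
            topic_vocab_size=15, doc_length_mean=40.0,
            years=(2014, 2015), planted_year_terms={2014: ("oncotermx",)},
            injection_rate=0.08, seed=3,
        )
        corpus, _ = lt.generate_trend_corpus(spec)
        tables = lt.yearly_hotspots(corpus, fraction=0.1, top_n=50)
        assert "oncotermx" in tables[2014].terms()
        assert "oncotermx" not in tables[2015].terms()

    def test_tables_ranked_descending(self):
        corpus = _corpus(
            [(f"d{i}", " ".join(f"w{j}" for j in range(i + 3)), 2014, None)
             for i in range(4)]
        )
        tables = lt.yearly_hotspots(corpus, fraction=0.5, top_n=10)
        weights = [w for _, w in tables[2014].hotspots]
        assert weights == sorted(weights, reverse=True)

    def test_monotone_planted_signal(self):
        # More occurrences of the planted term never lowers its yearly rank.
        base = ["alpha beta gamma delta epsilon zeta eta theta"] * 3
        ranks = []
        for count in (2, 5, 9):
            texts = [t + " planted" * count for t in base]
            corpus = _corpus(
                [(f"d{i}", t, 2014, None) for i, t in enumerate(texts)]
            )
            tables = lt.yearly_hotspots(corpus, fraction=0.5, top_n=20)
            terms = tables[2014].terms()
            ranks.append(terms.index("planted") if "planted" in terms else len(terms))
        assert ranks[0] >= ranks[1] >= ranks[2]


@pytest.fixture(scope="module")
def trend_setup():
    spec = lt.GeneratorSpec(
            n_topics=3, docs_per_topic=30, background_vocab_size=100,
            topic_vocab_size=20, doc_length_mean=40.0,
            years=(2014, 2015, 2016),
            planted_year_terms={y: (f"hot{y}a", f"hot{y}b") for y in (2014, 2015, 2016)},
        seed=5,
    )
    corpus, truth = lt.generate_trend_corpus(spec)
    table = lt.train_word_vectors(
        corpus, lt.Word2VecConfig(dimension=30, epochs=3, seed=0)
    )
    dvs = lt.corpus_document_vectors(corpus, table, "tr-w2v")
    return corpus, dvs, truth


class TestImprovedYearlyHotspots:
    def test_identical_years_have_empty_differential(self):
        docs = []
        for y in (2014, 2015):
            for i in range(4):
                docs.append((f"d{y}{i}", "alpha beta gamma delta epsilon", y, None))
        corpus = _corpus(docs)
        dvs = [_dv(d.doc_id, [1.0, 0.0]) for d in corpus]
        res = lt.improved_yearly_hotspots(
            corpus, dvs, k=1, per_cluster_top=5, fraction=1.0
        )
        assert all(len(t.hotspots) == 0 for t in res.differential.values())
        assert set(res.common_core) == set(res.tables[2014].terms())

    def test_degenerate_k_reduces_to_basic(self, trend_setup):
        corpus, dvs, _ = trend_setup
        basic = lt.yearly_hotspots(corpus, fraction=0.1, top_n=50)
        res = lt.improved_yearly_hotspots(
            corpus, dvs, k=1, per_cluster_top=50, fraction=0.1,
            differential_filter=False,
        )
        for year in basic:
            assert res.differential[year].hotspots == basic[year].hotspots

    def test_planted_terms_recovered_in_differential(self, trend_setup):
        corpus, dvs, truth = trend_setup
        res = lt.improved_yearly_hotspots(
            corpus, dvs, k=3, per_cluster_top=10, fraction=0.1
        )
        hits = 0
        for term, year, _ in truth.planted:
            if term in set(res.differential[year].terms()):
                hits += 1
            for other in res.differential:
                if other != year:
                    assert term not in set(res.differential[other].terms())
        assert hits >= 0.9 * len(truth.planted)

    def test_k_exceeding_year_size_names_year(self, trend_setup):
        corpus, dvs, _ = trend_setup
        with pytest.raises(ValueError, match="2014"):
            lt.improved_yearly_hotspots(corpus, dvs, k=10_000)
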