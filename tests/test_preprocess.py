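"""Token cleaning, MWE merging, lemmatization and vectorization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nephrotext.preprocess import (DocTermMatrix, PreprocessConfig, TokenDoc,
                                   load_dtm, merge_mwe, lemmatize,
                                   preprocess_text, save_dtm, tokenize_clean,
                                   vectorize)


class TestTokenizeClean:
    def test_empty_text(self, plain_config):
        assert tokenize_clean("", plain_config) == []

    def test_negations_survive_stopword_filtering(self, plain_config):
        toks = tokenize_clean("Es ist keine Nekrose und kein Anhalt", plain_config)
        assert "keine" in toks and "kein" in toks
        assert "ist" not in toks and "und" not in toks

    def test_numbers_removed_alphanumerics_kept(self, plain_config):
        text = "am 12.03.2021 ca 5% der Glomeruli, Oxford m1 e0 s1"
        toks = tokenize_clean(text, plain_config)
        # independent oracle: no token may consist solely of digits/punct
        assert all(any(ch.isalpha() for ch in t) for t in toks)
        assert {"m1", "e0", "s1"} <= set(toks)
        assert "ca" not in toks  # configured stop-word addition

    def test_rerunning_pipeline_is_noop(self, plain_config):
        cfg = PreprocessConfig(mwe_list=(("lupus", "nephritis"),))
        doc = preprocess_text("d", "Lupus Nephritis ohne 5% Befund, keine Nekrose", cfg)
        again = preprocess_text("d", " ".join(doc.tokens), cfg)
        assert again.tokens == doc.tokens


class TestMergeMwe:
    def test_named_expression_merged(self):
        assert merge_mwe(["lupus", "nephritis"], [("lupus", "nephritis")]) == [
            "lupus_nephritis"
        ]

    def test_empty_mwe_list_identity(self):
        assert merge_mwe(["a", "b"], []) == ["a", "b"]

    def test_overlapping_patterns_leftmost_longest(self):
        out = merge_mwe(["a", "b", "c"], [("a", "b"), ("b", "c")])
        assert out == ["a_b", "c"]

    @given(st.lists(st.sampled_from("abcd"), min_size=0, max_size=8))
    @settings(deadline=None, max_examples=60)
    def test_matches_exhaustive_leftmost_longest_oracle(self, tokens):
        mwes = [("a", "b"), ("a", "b", "c"), ("c", "d")]

        def oracle(toks):
            # brute force: at each position try all patterns, longest first
            if not toks:
                return []
            for pat in sorted(mwes, key=len, reverse=True):
                if tuple(toks[: len(pat)]) == pat:
                    return ["_".join(pat)] + oracle(toks[len(pat):])
            return [toks[0]] + oracle(toks[1:])

        assert merge_mwe(tokens, mwes) == oracle(tokens)


class TestLemmatize:
    def test_identity_default(self):
        assert lemmatize(["a", "b"]) == ["a", "b"]

    def test_replacement_table_applied_after_lemmatizer(self):
        out = lemmatize(["glomerulis"], lemmatizer=str.lower,
                        replacements={"glomerulis": "glomerulus"})
        assert out == ["glomerulus"]

    @given(st.lists(st.text(alphabet="xyz", min_size=1, max_size=5), max_size=20))
    @settings(deadline=None, max_examples=50)
    def test_length_preserved(self, tokens):
        assert len(lemmatize(tokens, lemmatizer=lambda t: t + "!")) == len(tokens)


class TestVectorize:
    def test_count_mode_single_doc(self):
        dtm = vectorize([TokenDoc("d", ("a", "a", "b"))], mode="count")
        row = dict(zip(dtm.vocabulary, np.asarray(dtm.matrix.todense()).ravel()))
        assert row == {"a": 2, "b": 1}

    def test_idf_matches_hand_computation(self):
        """Smoothed idf on a 3-doc toy: idf = ln((1+n)/(1+df)) + 1."""
        docs = [TokenDoc("1", ("x", "y")), TokenDoc("2", ("x",)), TokenDoc("3", ("x", "z"))]
        dtm = vectorize(docs, mode="tfidf")
        j_x = dtm.vocabulary.index("x")
        j_y = dtm.vocabulary.index("y")
        idf_x = np.log(4 / 4) + 1
        idf_y = np.log(4 / 2) + 1
        # doc 1 row before L2 norm is (1*idf_x, 1*idf_y)
        expected = np.array([idf_x, idf_y]) / np.hypot(idf_x, idf_y)
        row = np.asarray(dtm.matrix[0].todense()).ravel()
        assert row[j_x] == pytest.approx(expected[0], abs=1e-12)
        assert row[j_y] == pytest.approx(expected[1], abs=1e-12)

    def test_tfidf_rows_unit_l2(self):
        docs = [TokenDoc(str(i), tuple("abcab"[: i + 2])) for i in range(3)]
        dtm = vectorize(docs, mode="tfidf")
        norms = np.sqrt(np.asarray(dtm.matrix.multiply(dtm.matrix).sum(axis=1))).ravel()
        assert np.allclose(norms, 1.0)

    def test_count_columns_conserve_corpus_frequencies(self):
        docs = [TokenDoc("1", ("a", "b", "a")), TokenDoc("2", ("b", "c"))]
        dtm = vectorize(docs, mode="count")
        sums = dict(zip(dtm.vocabulary,
                        np.asarray(dtm.matrix.sum(axis=0)).ravel()))
        assert sums == {"a": 2, "b": 2, "c": 1}

    def test_vocabulary_shrinks_as_stopwords_grow(self):
        text = "alpha beta gamma delta"
        cfg0 = PreprocessConfig(stopwords=frozenset(), stopword_additions=())
        cfg1 = PreprocessConfig(stopwords=frozenset({"alpha", "beta"}),
                                stopword_additions=())
        d0 = preprocess_text("d", text, cfg0)
        d1 = preprocess_text("d", text, cfg1)
        assert set(d1.tokens) < set(d0.tokens)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            vectorize([], mode="count")
        with pytest.raises(ValueError):
            vectorize([TokenDoc("d", ())], mode="tfidf")

    def test_mtx_roundtrip(self, tmp_path):
        docs = [TokenDoc("1", ("a", "b")), TokenDoc("2", ("b", "c"))]
        dtm = vectorize(docs, mode="count")
        save_dtm(dtm, tmp_path / "m")
        back = load_dtm(tmp_path / "m")
        assert back.vocabulary == dtm.vocabulary
        assert back.doc_ids == dtm.doc_ids
        assert back.mode == "count"
        assert (back.matrix != dtm.matrix).nnz == 0

    def test_mwe_config_validated(self):
        with pytest.raises(ValueError):
            PreprocessConfig(mwe_list=(("solo",),))
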