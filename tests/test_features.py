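"""Tokenization, n-gram vocabulary construction, and binary transform.

The fit/transform path (which delegates to scikit-learn's vectorizer) is
checked against an independent brute-force oracle that enumerates every
token window in every document by hand.
"""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from odcert import VectorizerConfig, Vocabulary, fit_vocabulary, tokenize, transform
from odcert.errors import ValidationError
from odcert.features import default_stop_words, extract_ngrams, remove_stop_words

CFG12 = VectorizerConfig(ngram_min=1, ngram_max=2, min_count=1)


# ---------------------------------------------------------------- oracle
def oracle_ngrams(text, cfg):
    """Brute-force n-gram enumeration, independent of the vectorizer."""
    tokens = []
    run = []
    for ch in text + " ":
        if ch.isalnum():
            run.append(ch)
        else:
            if len(run) >= 2:
                tokens.append("".join(run))
            run = []
    tokens = [t for t in tokens if t.lower() not in cfg.stop_words]
    grams = []
    for width in range(cfg.ngram_min, cfg.ngram_max + 1):
        for i in range(len(tokens) - width + 1):
            grams.append(" ".join(tokens[i : i + width]))
    return grams


def oracle_vocabulary(corpus, cfg):
    counts = {}
    for doc in corpus:
        grams = set(oracle_ngrams(doc, cfg)) if cfg.count_mode == "document" else oracle_ngrams(doc, cfg)
        for g in grams:
            counts[g] = counts.get(g, 0) + 1
    return sorted(g for g, c in counts.items() if c >= cfg.min_count)


WORDS = st.sampled_from(
    ["ACUTE", "COCAINE", "TOXICITY", "OVERDOSE", "THE", "OF", "HEROIN", "X42", "MI", "FAILURE"]
)
DOCS = st.lists(WORDS, max_size=8).map(" ".join)


# ----------------------------------------------------------- tokenization
@pytest.mark.parametrize(
    "text,expected",
    [
        ("ACUTE COCAINE TOXICITY", ["ACUTE", "COCAINE", "TOXICITY"]),
        ("", []),
        ("A OD X42", ["OD", "X42"]),  # single characters dropped
    ],
)
def test_tokenize(text, expected):
    assert tokenize(text) == expected


def test_remove_stop_words_closes_ranks():
    cfg = VectorizerConfig(stop_words=frozenset({"due", "to"}))
    assert remove_stop_words(["DUE", "TO", "COCAINE"], cfg) == ["COCAINE"]
    assert remove_stop_words(["ACUTE", "COCAINE", "TOXICITY"], cfg) == [
        "ACUTE",
        "COCAINE",
        "TOXICITY",
    ]
    assert remove_stop_words(["DUE", "TO"], cfg) == []


@pytest.mark.parametrize(
    "tokens,lo,hi,expected",
    [
        (
            ["ACUTE", "COCAINE", "TOXICITY"],
            1,
            2,
            ["ACUTE", "COCAINE", "TOXICITY", "ACUTE COCAINE", "COCAINE TOXICITY"],
        ),
        (["ONLY"], 2, 3, []),
        (["A1", "A2", "A3", "A4"], 3, 3, ["A1 A2 A3", "A2 A3 A4"]),
    ],
)
def test_extract_ngrams_windows(tokens, lo, hi, expected):
    got = extract_ngrams(tokens, lo, hi)
    # order within each width is positional; compare as multisets per width
    assert sorted(got) == sorted(expected)


# ------------------------------------------------------------ vocabulary
def test_min_count_threshold_boundary():
    cfg = VectorizerConfig(ngram_max=2, min_count=5)
    vocab = fit_vocabulary(["COCAINE OVERDOSE"] * 5, cfg)
    assert set(vocab.entries) == {"COCAINE", "OVERDOSE", "COCAINE OVERDOSE"}
    assert all(c == 5 for c in vocab.doc_counts.values())
    assert fit_vocabulary(["COCAINE OVERDOSE"] * 4, cfg).size == 0


def test_empty_corpus_rejected():
    with pytest.raises(ValidationError):
        fit_vocabulary([], CFG12)


def test_vocabulary_indices_are_dense_and_lexicographic():
    vocab = fit_vocabulary(["HEROIN OVERDOSE DEATH", "COCAINE OVERDOSE"], CFG12)
    names = list(vocab.entries)
    assert names == sorted(names)
    assert sorted(vocab.entries.values()) == list(range(vocab.size))


def test_document_vs_total_counting_modes():
    # one document repeats the token: total occurrences 3, doc frequency 1
    corpus = ["HEROIN HEROIN HEROIN", "SEPSIS"]
    doc_cfg = VectorizerConfig(ngram_max=1, min_count=2, count_mode="document")
    tot_cfg = VectorizerConfig(ngram_max=1, min_count=2, count_mode="total")
    assert "HEROIN" not in fit_vocabulary(corpus, doc_cfg).entries
    assert "HEROIN" in fit_vocabulary(corpus, tot_cfg).entries


@given(st.lists(DOCS, min_size=1, max_size=50), st.integers(1, 3))
def test_fit_transform_matches_brute_force_oracle(corpus, min_count):
    cfg = VectorizerConfig(ngram_min=1, ngram_max=3, min_count=min_count)
    vocab = fit_vocabulary(corpus, cfg)
    assert list(vocab.entries) == oracle_vocabulary(corpus, cfg)
    X = transform(corpus, vocab).toarray()
    for i, doc in enumerate(corpus):
        present = set(oracle_ngrams(doc, cfg))
        for gram, j in vocab.entries.items():
            assert X[i, j] == (1 if gram in present else 0)


def test_transform_is_binary_under_repetition(table1_certificate):
    vocab = fit_vocabulary(
        ["OVERDOSE OVERDOSE OVERDOSE"], VectorizerConfig(min_count=1, ngram_max=1)
    )
    X = transform(["OVERDOSE OVERDOSE", "OVERDOSE"], vocab).toarray()
    assert set(X.ravel()) <= {0, 1}
    assert (X[0] == X[1]).all()


def test_worked_example_features(table1_certificate):
    from odcert import FieldSet, combine_fields

    text = combine_fields(table1_certificate, FieldSet.ALL_SECTIONS)
    vocab = fit_vocabulary([text], VectorizerConfig(min_count=1))
    X = transform([text], vocab).toarray()[0]
    assert X[vocab.entries["ACUTE COCAINE"]] == 1
    assert "POISONING" not in vocab.entries  # would be 0: never seen
    # a text sharing no n-grams with the vocabulary gives an all-zero row
    assert transform(["PULMONARY EMBOLISM"], vocab).toarray().sum() == 0


def test_unseen_test_time_ngrams_are_ignored():
    vocab = fit_vocabulary(["HEROIN OVERDOSE"], VectorizerConfig(min_count=1))
    X = transform(["FENTANYL OVERDOSE NOVELDRUG"], vocab).toarray()[0]
    assert X[vocab.entries["OVERDOSE"]] == 1
    assert X.sum() == 1


def test_vocabulary_json_round_trip(tmp_path):
    corpus = ["HEROIN OVERDOSE", "COCAINE TOXICITY", "HEROIN TOXICITY"]
    vocab = fit_vocabulary(corpus, CFG12)
    path = tmp_path / "vocab.json"
    vocab.save(path)
    loaded = Vocabulary.load(path)
    assert loaded == vocab
    assert (transform(corpus, loaded) != transform(corpus, vocab)).nnz == 0


def test_all_sections_vocabulary_dominates_no_scc():
    """Dropping the SCC section can only shrink the feature space: every
    unigram kept under NO_SCC is kept under ALL_SECTIONS (document
    frequencies can only rise when a section is added), and the total
    vocabulary is no smaller."""
    from odcert import FieldSet, GeneratorConfig, combine_fields, generate

    certs = generate(GeneratorConfig(n=1200, od_prevalence=0.05, seed=17))
    cfg = VectorizerConfig()
    vocab_all = fit_vocabulary([combine_fields(c, FieldSet.ALL_SECTIONS) for c in certs], cfg)
    vocab_noscc = fit_vocabulary([combine_fields(c, FieldSet.NO_SCC) for c in certs], cfg)
    unigrams_all = {g for g in vocab_all.entries if " " not in g}
    unigrams_noscc = {g for g in vocab_noscc.entries if " " not in g}
    assert unigrams_noscc <= unigrams_all
    assert vocab_noscc.size <= vocab_all.size


def test_default_stop_words_contains_cited_examples():
    sw = default_stop_words()
    assert {"the", "an", "and"} <= sw
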