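"""Bag-of-n-grams featureization of certificate text.

Certifier language on death certificates is terse, fully capitalized, and
rarely grammatical, so features are simple presence indicators: the
combined free-text field is tokenized into words, stop words are removed,
and all unigrams, bigrams, and trigrams over the remaining (now adjacent)
tokens become candidate features.  N-grams seen in fewer documents than a
frequency floor are discarded; surviving n-grams index the columns of a
sparse binary document-by-feature matrix (1 = the n-gram occurs anywhere
in the record's combined text).

The heavy lifting is delegated to scikit-learn's ``CountVectorizer``
(binary mode), whose analyzer has exactly these semantics; this module
pins the configuration, keeps per-feature document counts, and gives the
vocabulary a deterministic (lexicographic) order and a plain-JSON
persistence format so a trained model's feature space can be re-created
bit-for-bit.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp
from sklearn.feature_extraction.text import CountVectorizer

from .errors import ValidationError

__all__ = [
    "VectorizerConfig",
    "Vocabulary",
    "default_stop_words",
    "extract_ngrams",
    "fit_vocabulary",
    "remove_stop_words",
    "tokenize",
    "transform",
]

# Same default as the scikit-learn analyzer: maximal alphanumeric runs of
# length >= 2; single characters carry no signal on certificates.
_TOKEN_RE = re.compile(r"(?u)\b\w\w+\b")


@lru_cache(maxsize=None)
def default_stop_words() -> frozenset[str]:
    """The stop-word list shipped with the package, lowercase-normalized."""
    text = resources.files("odcert.data").joinpath("stopwords_en.txt").read_text()
    return frozenset(
        line.strip().lower()
        for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    )


@dataclass(frozen=True)
class VectorizerConfig:
    """Settings for vocabulary construction.

    ``min_count`` is by default a DOCUMENT-frequency floor (an n-gram must
    occur in at least that many records); set ``count_mode="total"`` to
    count every occurrence instead.  Features are always binary presence
    indicators regardless of counting mode.
    """

    ngram_min: int = 1
    ngram_max: int = 3
    min_count: int = 5
    stop_words: frozenset[str] = field(default_factory=default_stop_words)
    count_mode: str = "document"  # or "total"

    def __post_init__(self) -> None:
        if not (1 <= self.ngram_min <= self.ngram_max):
            raise ValidationError(
                f"need 1 <= ngram_min <= ngram_max, got {self.ngram_min}..{self.ngram_max}"
            )
        if self.min_count < 1:
            raise ValidationError(f"min_count must be >= 1, got {self.min_count}")
        if self.count_mode not in ("document", "total"):
            raise ValidationError(f"unknown count_mode {self.count_mode!r}")
        object.__setattr__(self, "stop_words", frozenset(w.lower() for w in self.stop_words))

    def to_dict(self) -> dict:
        return {
            "ngram_min": self.ngram_min,
            "ngram_max": self.ngram_max,
            "min_count": self.min_count,
            "stop_words": sorted(self.stop_words),
            "count_mode": self.count_mode,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "VectorizerConfig":
        d = dict(d)
        if "stop_words" in d:
            d["stop_words"] = frozenset(d["stop_words"])
        return cls(**d)


def tokenize(text: str) -> list[str]:
    """Split normalized text into tokens, preserving capitalization."""
    return _TOKEN_RE.findall(text)


def remove_stop_words(tokens: Sequence[str], cfg: VectorizerConfig) -> list[str]:
    """Drop stop words; survivors close ranks and become adjacent."""
    return [t for t in tokens if t.lower() not in cfg.stop_words]


def extract_ngrams(tokens: Sequence[str], ngram_min: int, ngram_max: int) -> list[str]:
    """All contiguous runs of ``ngram_min``..``ngram_max`` tokens, in order."""
    grams = []
    n = len(tokens)
    for width in range(ngram_min, ngram_max + 1):
        for i in range(n - width + 1):
            grams.append(" ".join(tokens[i : i + width]))
    return grams


@dataclass
class Vocabulary:
    """Retained n-grams with their column indices and document counts.

    ``entries`` maps n-gram -> column index with indices 0..size-1 in
    lexicographic n-gram order; ``doc_counts`` records in how many fitting
    documents each n-gram occurred.
    """

    entries: dict[str, int]
    doc_counts: dict[str, int]
    config: VectorizerConfig

    @property
    def size(self) -> int:
        return len(self.entries)

    def save(self, path: str | Path) -> None:
        payload = {
            "config": self.config.to_dict(),
            "entries": [
                [gram, idx, self.doc_counts[gram]]
                for gram, idx in sorted(self.entries.items(), key=lambda kv: kv[1])
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "Vocabulary":
        payload = json.loads(Path(path).read_text())
        entries = {gram: idx for gram, idx, _ in payload["entries"]}
        doc_counts = {gram: cnt for gram, _, cnt in payload["entries"]}
        return cls(entries, doc_counts, VectorizerConfig.from_dict(payload["config"]))


def _vectorizer(cfg: VectorizerConfig, vocabulary=None, binary: bool = True) -> CountVectorizer:
    return CountVectorizer(
        lowercase=False,
        token_pattern=_TOKEN_RE.pattern,
        ngram_range=(cfg.ngram_min, cfg.ngram_max),
        stop_words=[w.upper() for w in sorted(cfg.stop_words)],
        binary=binary,
        vocabulary=vocabulary,
    )


def fit_vocabulary(corpus: Sequence[str], cfg: VectorizerConfig | None = None) -> Vocabulary:
    """Build the vocabulary of n-grams meeting the frequency floor.

    Raises :class:`ValidationError` on an empty corpus.  A corpus in which
    nothing survives the floor yields an empty vocabulary (a legal but
    degenerate feature space).
    """
    cfg = cfg or VectorizerConfig()
    if len(corpus) == 0:
        raise ValidationError("cannot fit a vocabulary on an empty corpus")
    vec = _vectorizer(cfg, binary=(cfg.count_mode == "document"))
    try:
        counts = vec.fit_transform(corpus)
    except ValueError:
        # analyzer produced no terms at all (e.g. every document empty)
        return Vocabulary({}, {}, cfg)
    totals = np.asarray(counts.sum(axis=0)).ravel()
    names = vec.get_feature_names_out()
    keep = totals >= cfg.min_count
    kept = sorted(names[keep])
    entries = {gram: i for i, gram in enumerate(kept)}
    if cfg.count_mode == "document":
        doc_totals = totals
    else:
        doc_totals = np.asarray((counts > 0).sum(axis=0)).ravel()
    by_name = dict(zip(names, doc_totals))
    doc_counts = {gram: int(by_name[gram]) for gram in kept}
    return Vocabulary(entries, doc_counts, cfg)


def transform(texts: Sequence[str], vocab: Vocabulary) -> sp.csr_matrix:
    """Binary document-by-feature matrix for ``texts`` under ``vocab``.

    N-grams absent from the vocabulary are ignored, so unseen test-time
    tokens contribute nothing.
    """
    if vocab.size == 0:
        return sp.csr_matrix((len(texts), 0), dtype=np.int64)
    vec = _vectorizer(vocab.config, vocabulary=vocab.entries)
    return vec.transform(texts)
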