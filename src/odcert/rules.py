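"""Rule-based keyword baseline.

The traditional surveillance shortcut: scan each certificate's combined
free text for any phrase from a curated list of overdose-indicative words
and bigrams, and classify the death as an overdose iff at least one phrase
occurs.  Matching is on token boundaries — a phrase must appear as a
contiguous token subsequence of the text — so a two-letter phrase never
fires on a fragment embedded in a longer word.

The package ships a default list as a clearly-marked synthetic stand-in;
operational lists are jurisdiction-specific and should be supplied by the
user (one phrase per line, ``#`` comments).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from .certificates import normalize_text
from .errors import InputError, ValidationError
from .features import tokenize

__all__ = ["PhraseList", "default_phrases", "load_phrases", "rule_classify", "rule_predict"]


@dataclass
class PhraseList:
    """Ordered, de-duplicated list of normalized phrases plus provenance."""

    phrases: list[str]
    source: str = ""

    def __len__(self) -> int:
        return len(self.phrases)

    def __iter__(self):
        return iter(self.phrases)

    def token_tuples(self) -> list[tuple[str, ...]]:
        return [tuple(p.split(" ")) for p in self.phrases]


def _normalize_lines(lines: Iterable[str], source: str, max_tokens: int | None) -> PhraseList:
    phrases: list[str] = []
    seen = set()
    for raw in lines:
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        phrase = " ".join(tokenize(normalize_text(line)))
        if not phrase:
            continue
        n_tokens = phrase.count(" ") + 1
        if max_tokens is not None and n_tokens > max_tokens:
            raise ValidationError(
                f"phrase {line!r} has {n_tokens} tokens (limit {max_tokens}); "
                "pass allow_long=True to accept it"
            )
        if phrase not in seen:
            seen.add(phrase)
            phrases.append(phrase)
    return PhraseList(phrases, source)


def load_phrases(path: str | Path, allow_long: bool = False) -> PhraseList:
    """Read a phrase file: one word/bigram per line, ``#`` comments.

    Phrases are normalized with the same pipeline as certificate text.
    Phrases longer than two tokens are rejected unless ``allow_long``.
    """
    try:
        lines = Path(path).read_text().splitlines()
    except OSError as exc:
        raise InputError(f"cannot read phrase list {path}: {exc}") from exc
    return _normalize_lines(lines, str(path), None if allow_long else 2)


def default_phrases() -> PhraseList:
    """The packaged stand-in list of overdose-indicative words/bigrams."""
    text = resources.files("odcert.data").joinpath("overdose_phrases_synthetic.txt").read_text()
    return _normalize_lines(text.splitlines(), "odcert builtin (synthetic stand-in)", 2)


def rule_classify(text: str, phrase_list: PhraseList) -> bool:
    """True iff any phrase occurs as a contiguous token run of ``text``.

    ``text`` must already be normalized (see
    :func:`odcert.certificates.combine_fields`).
    """
    tokens = tokenize(text)
    if not tokens:
        return False
    ngrams_present: set[tuple[str, ...]] = set()
    widths = {len(p) for p in phrase_list.token_tuples()}
    for width in widths:
        for i in range(len(tokens) - width + 1):
            ngrams_present.add(tuple(tokens[i : i + width]))
    return any(p in ngrams_present for p in phrase_list.token_tuples())


def rule_predict(texts: Sequence[str], phrase_list: PhraseList) -> list[bool]:
    """Vectorized convenience wrapper over :func:`rule_classify`."""
    return [rule_classify(t, phrase_list) for t in texts]
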