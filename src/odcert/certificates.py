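"""Death-certificate records, gold labels, and text assembly.

A US standard death certificate carries a cause-of-death section with an
immediate cause ("line a") followed by up to three "due to (or as a
consequence of)" lines, a "significant conditions contributing" (SCC)
section, and a free-text description of injury that is completed only for
injury deaths.  After registration, NCHS assigns each record a single
ICD-10 underlying cause of death (UCOD); the surveillance definition of a
drug-overdose death is a UCOD in X40-X44 (unintentional poisoning),
X60-X64 (intentional self-poisoning), X85 (assault by poisoning), or
Y10-Y14 (poisoning of undetermined intent).

This module provides the record type, tabular I/O with a configurable
column mapping, UCOD-based gold labeling, and the normalization that turns
a certificate's free-text fields into the single uppercase string every
downstream component (vectorizer and rule matcher alike) consumes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from .errors import ConfigurationError, InputError, ValidationError

__all__ = [
    "DeathCertificate",
    "FieldSet",
    "OVERDOSE_UCOD_PREFIXES",
    "TEXT_FIELDS",
    "combine_fields",
    "label_from_ucod",
    "normalize_text",
    "read_certificates",
    "write_predictions",
]

#: Text fields in the order they appear on the certificate.
TEXT_FIELDS = ("cause_a", "cause_b", "cause_c", "cause_d", "scc", "injury_desc")

#: 3-character ICD-10 UCOD prefixes defining a drug-overdose death.
OVERDOSE_UCOD_PREFIXES = frozenset(
    {f"X{i}" for i in range(40, 45)}
    | {f"X{i}" for i in range(60, 65)}
    | {"X85"}
    | {f"Y{i}" for i in range(10, 15)}
)

_CODE_SHAPE = re.compile(r"^[A-Z][0-9]{2}")
_NON_ALNUM = re.compile(r"[^A-Z0-9]+")


class FieldSet(Enum):
    """Which free-text sections feed the combined classification text.

    ALL_SECTIONS uses every section; NO_SCC drops the "significant
    conditions contributing" section, which records conditions (including
    prior, non-fatal overdoses) that did not initiate the causal chain.
    """

    ALL_SECTIONS = "all_sections"
    NO_SCC = "no_scc"

    @property
    def fields(self) -> tuple[str, ...]:
        if self is FieldSet.NO_SCC:
            return tuple(f for f in TEXT_FIELDS if f != "scc")
        return TEXT_FIELDS


@dataclass
class DeathCertificate:
    """One death-certificate record.

    Missing text is represented as the empty string, never ``None``;
    blank "due to" lines are the norm on real certificates.
    """

    id: str = ""
    cause_a: str = ""
    cause_b: str = ""
    cause_c: str = ""
    cause_d: str = ""
    scc: str = ""
    injury_desc: str = ""
    ucod: str = ""
    label: Optional[bool] = None

    def text(self, field_set: FieldSet = FieldSet.ALL_SECTIONS) -> str:
        return combine_fields(self, field_set)


def label_from_ucod(code: str) -> bool:
    """True iff ``code`` denotes a drug-overdose underlying cause of death.

    Matching is on the uppercased 3-character prefix; any fourth digit or
    dot suffix is ignored (NCHS UCOD codes are 3-4 characters).

    Raises
    ------
    ValidationError
        If ``code`` does not start with a letter followed by two digits.
    """
    c = code.strip().upper()
    if not _CODE_SHAPE.match(c):
        raise ValidationError(f"not an ICD-10 code: {code!r}")
    return c[:3] in OVERDOSE_UCOD_PREFIXES


def normalize_text(text: str) -> str:
    """Uppercase, replace punctuation runs with single spaces, and trim.

    Every character outside [A-Z0-9] becomes a space, so "FENTANYL/HEROIN"
    yields two words rather than one merged token.
    """
    return _NON_ALNUM.sub(" ", text.upper()).strip()


def combine_fields(dc: DeathCertificate, field_set: FieldSet) -> str:
    """Concatenate the selected sections, in certificate order, normalized."""
    raw = " ".join(getattr(dc, f) for f in field_set.fields)
    return normalize_text(raw)


def _resolve_sep(source: str | Path, sep: Optional[str]) -> str:
    if sep is not None:
        return sep
    suffix = Path(source).suffix.lower()
    return "\t" if suffix in (".tsv", ".tab") else ","


def read_certificates(
    source: str | Path,
    column_map: Optional[Mapping[str, str]] = None,
    sep: Optional[str] = None,
) -> list[DeathCertificate]:
    """Read certificates from a delimited file with a header row.

    Parameters
    ----------
    source:
        CSV path (or TSV, inferred from the extension unless ``sep`` is
        given).
    column_map:
        Maps record field names (``id``, ``cause_a`` .. ``cause_d``,
        ``scc``, ``injury_desc``, ``ucod``) to column names in the file.
        Fields left unmapped default to a column of the same name when one
        exists, otherwise to empty text.  Mapping a field to a column the
        file does not contain is a configuration error.

    When a non-empty UCOD is present the gold label is derived from it, so
    ``label`` always agrees with :func:`label_from_ucod`.
    """
    try:
        df = pd.read_csv(
            source, sep=_resolve_sep(source, sep), dtype=str, keep_default_na=False
        )
    except OSError as exc:
        raise InputError(f"cannot read {source}: {exc}") from exc
    except pd.errors.ParserError as exc:
        raise InputError(f"cannot parse {source}: {exc}") from exc

    column_map = dict(column_map or {})
    fields = ("id",) + TEXT_FIELDS + ("ucod",)
    for fld, col in column_map.items():
        if fld not in fields:
            raise ConfigurationError(f"unknown certificate field {fld!r} in column map")
        if col not in df.columns:
            raise ConfigurationError(
                f"column {col!r} (mapped to field {fld!r}) not present in {source}"
            )
    resolved = {
        fld: column_map.get(fld, fld if fld in df.columns else None) for fld in fields
    }

    records = []
    for _, row in df.iterrows():
        values = {
            fld: (str(row[col]).strip() if col is not None else "")
            for fld, col in resolved.items()
        }
        label = label_from_ucod(values["ucod"]) if values["ucod"] else None
        records.append(DeathCertificate(label=label, **values))
    return records


def write_predictions(
    source: str | Path,
    predictions: Sequence[bool],
    out: str | Path,
    scores: Optional[Sequence[float]] = None,
    flags: Optional[Sequence[str]] = None,
    sep: Optional[str] = None,
) -> None:
    """Copy the input table to ``out`` with appended prediction columns.

    Adds ``predicted_overdose`` (0/1), optionally ``decision_score`` and a
    free-text ``flag`` column (e.g. a no-features warning).
    """
    resolved_sep = _resolve_sep(source, sep)
    df = pd.read_csv(source, sep=resolved_sep, dtype=str, keep_default_na=False)
    if len(predictions) != len(df):
        raise ValidationError(
            f"{len(predictions)} predictions for {len(df)} input rows"
        )
    df["predicted_overdose"] = [int(bool(p)) for p in predictions]
    if scores is not None:
        df["decision_score"] = list(scores)
    if flags is not None:
        df["flag"] = list(flags)
    df.to_csv(out, sep=_resolve_sep(out, sep), index=False)
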