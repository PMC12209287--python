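"""Keyword-lexicon extraction of the binary semantic flags.

Two flags anchor the fuzzy rule base: ``severity_flag`` (a severe
psychotic-spectrum diagnosis is documented) and ``compliance_flag``
(1 means non-compliance indicators are present in the behavioural
description).  Both are derived by case- and accent-insensitive
substring matching against a small editable lexicon.
"""

from __future__ import annotations

import json
import re
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .exceptions import OrdercastError

DEFAULT_SEVERITY_TERMS = ("schizophrenia", "psychosis", "bipolar disorder")
DEFAULT_NONCOMPLIANCE_TERMS = ("non-compliance", "refused", "discontinued")


def normalize_text(text: str) -> str:
    """Lowercase, strip accents (NFKD), collapse whitespace."""
    text = unicodedata.normalize("NFKD", text)
    text = "".join(ch for ch in text if not unicodedata.combining(ch))
    return re.sub(r"\s+", " ", text.lower()).strip()


def _clean_terms(terms: Iterable[str], what: str) -> tuple[str, ...]:
    seen: dict[str, None] = {}
    for t in terms:
        n = normalize_text(t)
        if not n:
            raise OrdercastError(f"empty {what} term after normalization: {t!r}")
        seen.setdefault(n, None)
    return tuple(seen)


@dataclass(frozen=True)
class Lexicon:
    """Term lists used for flag extraction, stored normalized and
    de-duplicated."""

    severity_terms: tuple[str, ...] = DEFAULT_SEVERITY_TERMS
    noncompliance_terms: tuple[str, ...] = DEFAULT_NONCOMPLIANCE_TERMS

    def __post_init__(self):
        object.__setattr__(self, "severity_terms",
                           _clean_terms(self.severity_terms, "severity"))
        object.__setattr__(self, "noncompliance_terms",
                           _clean_terms(self.noncompliance_terms, "non-compliance"))

    @classmethod
    def from_json(cls, path: str | Path) -> "Lexicon":
        """Load from a JSON file with keys ``severity_terms`` and
        ``noncompliance_terms``."""
        data = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(severity_terms=tuple(data["severity_terms"]),
                   noncompliance_terms=tuple(data["noncompliance_terms"]))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"severity_terms": list(self.severity_terms),
             "noncompliance_terms": list(self.noncompliance_terms)},
            indent=2), encoding="utf-8")


@dataclass(frozen=True)
class SemanticFlags:
    severity_flag: int
    compliance_flag: int  # 1 = non-compliance indicators present

    def __post_init__(self):
        for name in ("severity_flag", "compliance_flag"):
            if getattr(self, name) not in (0, 1):
                raise OrdercastError(f"{name} must be 0 or 1")


def _any_term(text: str, terms: tuple[str, ...]) -> int:
    norm = normalize_text(text)
    return int(any(t in norm for t in terms))


def severity_flag(main_diagnosis: str, other_diagnoses: Iterable[str] = (),
                  lexicon: Lexicon | None = None) -> int:
    """1 iff any severity term occurs in the concatenated diagnosis text."""
    lexicon = lexicon or Lexicon()
    joined = " ".join([main_diagnosis, *other_diagnoses])
    return _any_term(joined, lexicon.severity_terms)


def compliance_flag(symptoms_text: str, lexicon: Lexicon | None = None) -> int:
    """1 iff any non-compliance term occurs in the behavioural text."""
    lexicon = lexicon or Lexicon()
    return _any_term(symptoms_text, lexicon.noncompliance_terms)


def extract_flags(main_diagnosis: str, other_diagnoses: Iterable[str],
                  symptoms_text: str,
                  lexicon: Lexicon | None = None) -> SemanticFlags:
    """Both flags for one record."""
    lexicon = lexicon or Lexicon()
    return SemanticFlags(
        severity_flag=severity_flag(main_diagnosis, other_diagnoses, lexicon),
        compliance_flag=compliance_flag(symptoms_text, lexicon),
    )
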