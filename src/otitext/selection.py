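"""Search-string selection of otitis-relevant records.

Mirrors the first stage of free-text surveillance pipelines: a battery of
literal substrings and regular expressions, built to catch typographical
errors and abbreviations, is scanned over every free-text field of every
visit.  A record is retained when any term matches any field.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import yaml

from .classes import VisitRecord

#: Default otitis search terms: stems, the "oma" abbreviation and one-edit
#: misspellings of "otite".  Fully overridable via a YAML pattern file.
DEFAULT_SEARCH_TERMS: tuple[str, ...] = (
    "otit",        # otite, otitis, otitica ...
    r"\boma\b",    # abbreviation for otite media acuta
    "otorrea",
    "timpan",      # timpano, timpanica
    "otoscop",     # otoscopia, otoscopico
    "orecchi",     # orecchio, orecchie
    "oite",        # deletion typo of otite
    "otie",
    "ottite",      # doubling typo
    r"ot[i1l]te",  # substitution typos
)


@dataclass(frozen=True)
class SearchPattern:
    """Compiled disjunction of search terms."""

    terms: tuple[str, ...]
    case_insensitive: bool
    _regexes: tuple[re.Pattern, ...]

    def matches(self, text: str) -> bool:
        return any(rx.search(text) for rx in self._regexes)


def compile_search_pattern(
    terms: list[str] | tuple[str, ...],
    case_insensitive: bool = True,
) -> SearchPattern:
    """Compile terms into a pattern; literal substrings and regexes both work.

    Terms are compiled individually so an invalid regex error can name the
    offending term.
    """
    if not terms:
        raise ValueError("search pattern needs at least one term")
    flags = re.IGNORECASE if case_insensitive else 0
    regexes = []
    for term in terms:
        try:
            regexes.append(re.compile(term, flags))
        except re.error as exc:
            raise ValueError(f"invalid search term {term!r}: {exc}") from exc
    return SearchPattern(tuple(terms), case_insensitive, tuple(regexes))


def default_search_pattern() -> SearchPattern:
    return compile_search_pattern(list(DEFAULT_SEARCH_TERMS))


def select_records(corpus: list[VisitRecord], pattern: SearchPattern) -> list[VisitRecord]:
    """Retain records where any field matches the pattern, preserving order.

    Matching is per-field: fields are never concatenated, so a term cannot
    match across a field boundary.
    """
    return [rec for rec in corpus if any(pattern.matches(t) for t in rec.fields.values())]


def load_pattern_yaml(path) -> SearchPattern:
    """Read a pattern file: list of {term, regex: bool} entries (or bare strings).

    Literal (non-regex) entries are escaped before compilation.
    """
    with open(path, encoding="utf-8") as fh:
        obj = yaml.safe_load(fh)
    entries = obj["terms"] if isinstance(obj, dict) else obj
    case_insensitive = obj.get("case_insensitive", True) if isinstance(obj, dict) else True
    terms = []
    for e in entries:
        if isinstance(e, str):
            terms.append(e)
        elif e.get("regex", False):
            terms.append(e["term"])
        else:
            terms.append(re.escape(e["term"]))
    return compile_search_pattern(terms, case_insensitive)
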