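"""Packaged lexicons: COVID keywords, stop words, script markers, aliases.

All lexicons ship as editable UTF-8 plain-text files under
``rumorgroups/data``; every loader also accepts a user-supplied path so the
defaults are a starting point, not a commitment.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

__all__ = [
    "KeywordLexicon",
    "ScriptLexicon",
    "load_keywords",
    "load_stopwords",
    "load_script_lexicon",
    "load_attribution_aliases",
]


def _read_lines(source) -> list[str]:
    text = Path(source).read_text(encoding="utf-8") if not hasattr(source, "read") else source.read()
    out = []
    for line in text.splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def _packaged(name: str) -> Path:
    return resources.files("rumorgroups.data").joinpath(name)  # type: ignore[return-value]


@dataclass(frozen=True)
class KeywordLexicon:
    """A flat list of keywords, matched case-insensitively as substrings."""

    terms: tuple[str, ...]

    def __post_init__(self):
        if not self.terms:
            raise ValueError("keyword lexicon must be non-empty")
        object.__setattr__(self, "terms", tuple(t.lower() for t in self.terms))

    def __contains__(self, term: str) -> bool:
        return term.lower() in self.terms

    def __len__(self) -> int:
        return len(self.terms)


@dataclass(frozen=True)
class ScriptLexicon:
    """Markers of probable mainland-China origin in a traditional-script corpus.

    ``simplified_only_chars`` holds codepoints whose simplified form differs
    from the traditional one (so their presence in a Taiwanese message is a
    script signal); ``phrases`` holds mainland-usage vocabulary that flags a
    message even when written in traditional characters.
    """

    simplified_only_chars: frozenset[str]
    phrases: tuple[str, ...] = ()
    traditional_chars: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        if not self.simplified_only_chars:
            raise ValueError("simplified character set must be non-empty")
        if self.simplified_only_chars & self.traditional_chars:
            raise ValueError("simplified-only and traditional-only sets overlap")


def load_keywords(path=None) -> KeywordLexicon:
    """Load the COVID keyword list (default: the packaged 33-term list)."""
    with resources.as_file(_packaged("covid_keywords.txt")) as default:
        return KeywordLexicon(tuple(_read_lines(path or default)))


def load_stopwords(path=None) -> frozenset[str]:
    with resources.as_file(_packaged("stopwords_zh.txt")) as default:
        return frozenset(_read_lines(path or default))


def load_script_lexicon(mapping_path=None, phrases_path=None) -> ScriptLexicon:
    """Build the script lexicon from the simplified↔traditional table.

    The table is tab-separated ``simplified<TAB>traditional``; the traditional
    column doubles as the disjointness check required by the invariant.
    """
    with resources.as_file(_packaged("simplified_traditional.tsv")) as default:
        rows = _read_lines(mapping_path or default)
    simp, trad = set(), set()
    for row in rows:
        parts = row.split("\t")
        if len(parts) != 2:
            raise ValueError(f"malformed mapping row: {row!r}")
        s, t = parts[0].strip(), parts[1].strip()
        simp.add(s)
        trad.add(t)
    with resources.as_file(_packaged("china_phrases.txt")) as default:
        phrases = tuple(_read_lines(phrases_path or default))
    return ScriptLexicon(
        simplified_only_chars=frozenset(simp),
        phrases=phrases,
        traditional_chars=frozenset(trad - simp),
    )


def load_attribution_aliases(path=None) -> dict[str, list[str]]:
    """Party → aliases mapping for misquote attribution counts."""
    if path is not None:
        data = json.loads(Path(path).read_text(encoding="utf-8"))
    else:
        data = json.loads(_packaged("attribution_aliases.json").read_text(encoding="utf-8"))
    for party, aliases in data.items():
        if not aliases:
            raise ValueError(f"party {party!r} has no aliases")
    return {p: list(a) for p, a in data.items()}
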