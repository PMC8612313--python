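"""Pluggable tokenizers.

A tokenizer is any callable ``text -> list[str]``. The clustering pipeline
never depends on a particular segmenter: synthetic and latin corpora use
whitespace splitting, Chinese corpora default to per-character tokens, and a
dictionary-based segmenter (jieba) is picked up automatically when installed.
"""
from __future__ import annotations

from typing import Callable, List

Tokenizer = Callable[[str], List[str]]

__all__ = ["Tokenizer", "whitespace_tokenizer", "character_tokenizer", "get_tokenizer"]


def whitespace_tokenizer(text: str) -> list[str]:
    return text.split()


def character_tokenizer(text: str) -> list[str]:
    """One token per non-space character.

    Dictionary-free fallback for Chinese: near-duplicate detection with set
    distances degrades gracefully to character unigrams, since near-identical
    messages share near-identical character sets.
    """
    return [ch for ch in text if not ch.isspace()]


def _jieba_tokenizer(text: str) -> list[str]:
    import jieba  # pragma: no cover - optional dependency

    return [t for t in jieba.lcut(text) if t.strip()]


_REGISTRY: dict[str, Tokenizer] = {
    "whitespace": whitespace_tokenizer,
    "character": character_tokenizer,
    "jieba": _jieba_tokenizer,
}


def get_tokenizer(name_or_callable) -> Tokenizer:
    """Resolve a tokenizer by registry name, or pass a callable through."""
    if callable(name_or_callable):
        return name_or_callable
    try:
        return _REGISTRY[name_or_callable]
    except KeyError:
        raise ValueError(
            f"unknown tokenizer {name_or_callable!r}; choose from {sorted(_REGISTRY)}"
        ) from None
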