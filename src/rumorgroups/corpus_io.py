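"""Message tables, character filtering and the tokenization pipeline.

The ingest schema is one record per reported message: an opaque id, an
ISO-8601 report timestamp, a scrambled user hash and the raw text. The
preprocessing pipeline (character filter → tokenize → stop-word removal →
minimum-length filter) turns each surviving message into a ``TokenizedDoc``
whose distinct-token set is the binary word vector every later stage works on.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Optional, Sequence

import pandas as pd

from .lexicons import load_stopwords
from .tokenizers import Tokenizer, get_tokenizer

__all__ = [
    "Message",
    "TokenizedDoc",
    "SchemaError",
    "RecordError",
    "read_messages",
    "messages_from_frame",
    "write_tokenized",
    "filter_characters",
    "preprocess",
]

REQUIRED_COLUMNS = ("message_id", "report_timestamp", "user_hash", "text")

#: Codepoint ranges kept by the default character filter: CJK Unified
#: Ideographs, extensions A–H and the compatibility block. Simplified and
#: traditional characters both live in these ranges, so the filter keeps both.
CJK_RANGES = (
    (0x3400, 0x4DBF),
    (0x4E00, 0x9FFF),
    (0xF900, 0xFAFF),
    (0x20000, 0x2EE5F),
)


class SchemaError(ValueError):
    """The input table is missing a required column."""


class RecordError(ValueError):
    """A single record is malformed; carries the offending 1-based data row."""

    def __init__(self, row: int, message: str):
        super().__init__(f"row {row}: {message}")
        self.row = row


@dataclass(frozen=True)
class Message:
    message_id: str
    report_timestamp: pd.Timestamp
    user_hash: str
    text: str


@dataclass(frozen=True)
class TokenizedDoc:
    """An ordered token list plus the derived distinct-token set."""

    message_id: str
    tokens: tuple[str, ...]
    token_set: frozenset[str] = field(init=False)

    def __post_init__(self):
        object.__setattr__(self, "token_set", frozenset(self.tokens))

    @property
    def n_tokens(self) -> int:
        return len(self.tokens)


def _parse_timestamps(frame: pd.DataFrame) -> list[pd.Timestamp]:
    parsed = pd.to_datetime(frame["report_timestamp"], errors="coerce", utc=True, format="ISO8601")
    bad = parsed.isna() & frame["report_timestamp"].notna()
    if bad.any():
        row = int(bad.to_numpy().nonzero()[0][0])
        raise RecordError(row + 1, f"unparseable timestamp {frame['report_timestamp'].iloc[row]!r}")
    if parsed.isna().any():
        row = int(parsed.isna().to_numpy().nonzero()[0][0])
        raise RecordError(row + 1, "missing timestamp")
    return list(parsed)


def messages_from_frame(frame: pd.DataFrame) -> list[Message]:
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    stamps = _parse_timestamps(frame)
    return [
        Message(
            message_id=str(frame["message_id"].iloc[i]),
            report_timestamp=stamps[i],
            user_hash=str(frame["user_hash"].iloc[i]),
            text="" if pd.isna(frame["text"].iloc[i]) else str(frame["text"].iloc[i]),
        )
        for i in range(len(frame))
    ]


def read_messages(path, format: Optional[str] = None) -> list[Message]:
    """Read a message table from CSV (RFC-4180, UTF-8) or JSON Lines.

    ``format`` is inferred from the file suffix when omitted. Input order is
    preserved; timestamps must parse as ISO-8601 (an aware or naive stamp;
    naive stamps are taken as UTC).
    """
    path = Path(path)
    if format is None:
        format = "jsonl" if path.suffix.lower() in {".jsonl", ".ndjson", ".json"} else "csv"
    if format == "csv":
        frame = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[])
    elif format == "jsonl":
        frame = pd.read_json(path, lines=True, dtype=str, convert_dates=False)
        if frame.empty:
            frame = pd.DataFrame(columns=REQUIRED_COLUMNS)
    else:
        raise ValueError(f"unknown format {format!r}")
    return messages_from_frame(frame)


def write_tokenized(docs: Iterable[TokenizedDoc], path) -> None:
    """Dump tokenized documents as JSON Lines (id + ordered token list)."""
    with open(path, "w", encoding="utf-8") as fh:
        for doc in docs:
            fh.write(json.dumps({"message_id": doc.message_id, "tokens": list(doc.tokens)},
                                ensure_ascii=False) + "\n")


def filter_characters(text: str, keep: Optional[str] = "cjk") -> str:
    """Remove characters outside the configured script ranges.

    ``keep="cjk"`` (default) retains CJK ideographs only — both simplified and
    traditional codepoints, which share the same Unicode blocks. ``keep=None``
    disables filtering (synthetic/latin corpora).
    """
    if keep is None or keep == "all":
        return text
    if keep != "cjk":
        raise ValueError(f"unknown script spec {keep!r}")
    return "".join(
        ch for ch in text
        if any(lo <= ord(ch) <= hi for lo, hi in CJK_RANGES)
    )


def preprocess(
    messages: Sequence[Message],
    tokenizer: Tokenizer | str = "character",
    stopwords: Optional[Iterable[str]] = None,
    min_tokens: int = 20,
    char_filter: Optional[str] = "cjk",
) -> list[TokenizedDoc]:
    """Run the full preprocessing pipeline.

    Order matters and is fixed: character filter → tokenize → drop stop-word
    tokens → drop documents with fewer than ``min_tokens`` remaining tokens
    (the length filter counts post-stop-word tokens). Surviving documents keep
    corpus order. ``stopwords=None`` loads the packaged Chinese list; pass an
    empty collection to disable stop-word removal.
    """
    tok = get_tokenizer(tokenizer)
    stop = frozenset(load_stopwords() if stopwords is None else stopwords)
    out: list[TokenizedDoc] = []
    for msg in messages:
        tokens = [t for t in tok(filter_characters(msg.text, keep=char_filter)) if t not in stop]
        if len(tokens) >= min_tokens:
            out.append(TokenizedDoc(message_id=msg.message_id, tokens=tuple(tokens)))
    return out
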