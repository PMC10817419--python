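"""Text normalization, vocabulary building and fixed-length encoding.

All free-text fields of a visit are merged into one token stream with a
reserved ``SEP`` token between consecutive non-empty fields; numeric tokens
are collapsed to ``NUM``; unknown words map to ``OOV``; the stream is
padded/truncated to a fixed length L with the ``PAD`` token (index 0).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .classes import OtitisClass, VisitRecord

PAD = "PAD"
OOV = "OOV"
SEP = "SEP"
NUM = "NUM"
RESERVED_TOKENS: tuple[str, ...] = (PAD, OOV, SEP, NUM)

#: Tokens wholly composed of digits with an optional decimal comma/point.
#: Mixed alphanumerics ("b12") are left untouched.
DEFAULT_NUMBER_PATTERN = r"^\d+(?:[.,]\d+)?$"

_TOKEN_SPLIT = re.compile(r"[^\w]+", re.UNICODE)


@dataclass
class PreprocessConfig:
    max_length: int = 1000
    lowercase: bool = True
    number_pattern: str = DEFAULT_NUMBER_PATTERN
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_length < 1:
            raise ValueError("max_length must be >= 1")
        self._number_re = re.compile(self.number_pattern)


def tokenize(text: str, lowercase: bool = True) -> list[str]:
    """Split on whitespace and punctuation; punctuation is dropped."""
    if lowercase:
        text = text.lower()
    return [t for t in _TOKEN_SPLIT.split(text) if t]


def merge_fields(record: VisitRecord, config: PreprocessConfig | None = None) -> list[str]:
    """Tokenize and join all fields in stored order, SEP between non-empty ones.

    Empty fields contribute no tokens and no extra separator; a record whose
    fields are all empty yields an empty sequence.
    """
    cfg = config or PreprocessConfig()
    out: list[str] = []
    for text in record.fields.values():
        toks = tokenize(text, cfg.lowercase)
        if not toks:
            continue
        if out:
            out.append(SEP)
        out.extend(toks)
    return normalize_numbers(out, cfg)


def normalize_numbers(tokens: Sequence[str], config: PreprocessConfig | None = None) -> list[str]:
    cfg = config or PreprocessConfig()
    return [NUM if cfg._number_re.match(t) else t for t in tokens]


@dataclass
class Vocabulary:
    """Token-to-index bijection with reserved PAD/OOV/SEP/NUM entries.

    Indices run 0..size-1 with no gaps; PAD is always index 0, then the
    other reserved tokens, then corpus tokens by descending frequency with
    lexicographic tie-break.
    """

    index: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.index:
            self.index = {t: i for i, t in enumerate(RESERVED_TOKENS)}
        self._validate()

    def _validate(self) -> None:
        for i, t in enumerate(RESERVED_TOKENS):
            if self.index.get(t) != i:
                raise ValueError(f"reserved token {t} must have index {i}")
        indices = sorted(self.index.values())
        if indices != list(range(len(self.index))):
            raise ValueError("vocabulary indices must be 0..size-1 without gaps")

    @property
    def size(self) -> int:
        return len(self.index)

    def __contains__(self, token: str) -> bool:
        return token in self.index

    def lookup(self, token: str) -> int:
        return self.index.get(token, self.index[OOV])

    def tokens(self) -> list[str]:
        """Tokens in index order."""
        inv = sorted(self.index.items(), key=lambda kv: kv[1])
        return [t for t, _ in inv]


def build_vocabulary(token_streams: Iterable[Sequence[str]], min_count: int = 1) -> Vocabulary:
    """Count tokens over all streams and keep those with frequency >= min_count.

    Reserved tokens get the first indices regardless of their appearance in
    the streams.
    """
    freq: dict[str, int] = {}
    for stream in token_streams:
        for tok in stream:
            if tok in RESERVED_TOKENS:
                continue
            freq[tok] = freq.get(tok, 0) + 1
    kept = [t for t, c in freq.items() if c >= min_count]
    kept.sort(key=lambda t: (-freq[t], t))
    index = {t: i for i, t in enumerate(RESERVED_TOKENS)}
    for t in kept:
        index[t] = len(index)
    return Vocabulary(index)


@dataclass
class EncodedRecord:
    """Fixed-length integer index sequence plus optional label."""

    indices: np.ndarray  # shape (L,), dtype int64
    label: Optional[OtitisClass] = None
    record_id: Optional[str] = None


def encode_record(
    record: VisitRecord,
    vocab: Vocabulary,
    config: PreprocessConfig | None = None,
) -> EncodedRecord:
    """merge -> normalize -> index (unknown -> OOV) -> pad/truncate to L.

    Head truncation keeps the first L tokens (the diagnosis field comes
    first in merged order, so the head carries the diagnostic signal);
    shorter sequences are post-padded with PAD.
    """
    cfg = config or PreprocessConfig()
    tokens = merge_fields(record, cfg)
    L = cfg.max_length
    idx = np.zeros(L, dtype=np.int64)  # PAD == 0
    for i, tok in enumerate(tokens[:L]):
        idx[i] = vocab.lookup(tok)
    return EncodedRecord(indices=idx, label=record.gold_label, record_id=record.visit_id)


def decode_indices(indices: Sequence[int], vocab: Vocabulary, strip_pad: bool = True) -> list[str]:
    """Inverse mapping, used for round-trip checks and error inspection."""
    inv = {i: t for t, i in vocab.index.items()}
    toks = [inv[int(i)] for i in indices]
    if strip_pad:
        while toks and toks[-1] == PAD:
            toks.pop()
    return toks


def encode_corpus(
    corpus: Sequence[VisitRecord],
    vocab: Vocabulary,
    config: PreprocessConfig | None = None,
) -> list[EncodedRecord]:
    cfg = config or PreprocessConfig()
    return [encode_record(rec, vocab, cfg) for rec in corpus]
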