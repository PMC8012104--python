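"""Hierarchical text representation.

A document is an ordered list of tokens (words) with 0-based half-open
character spans, each token nested in exactly one sentence, one paragraph and
one display line. Sentence and paragraph indices partition the token and
sentence sequences respectively, mirroring the word < sentence < paragraph
hierarchy that the multi-scale similarity measures are defined over.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

TEXT_COLUMNS = ["surface", "char_start", "char_end", "sentence_id", "paragraph_id", "line_id"]


class StructuralError(ValueError):
    """A text table violates the token/sentence/paragraph nesting invariants."""


@dataclass(frozen=True)
class Token:
    token_id: int
    surface: str
    char_start: int
    char_end: int
    sentence_id: int
    paragraph_id: int
    line_id: int

    @property
    def char_span(self) -> tuple[int, int]:
        return (self.char_start, self.char_end)

    def __len__(self) -> int:
        return self.char_end - self.char_start


class TextStructure:
    """Validated token sequence with sentence/paragraph/line indices.

    Parameters
    ----------
    tokens
        Tokens in document order. ``token_id`` is assigned positionally and
        must equal each token's index in the list.
    """

    def __init__(self, tokens: list[Token]):
        if not tokens:
            raise StructuralError("no tokens")
        self.tokens = list(tokens)
        self._validate()
        self.sentence_index = self._build_sentence_index()
        self.paragraph_index = self._build_paragraph_index()
        self.line_tokens = self._build_line_tokens()
        # leftmost character of each display line; fixation positions are
        # expressed in line-local character units
        self.line_origin = {
            line: min(self.tokens[t].char_start for t in toks)
            for line, toks in self.line_tokens.items()
        }

    # -- validation ---------------------------------------------------------
    def _validate(self) -> None:
        prev_end = None
        prev_sent = None
        prev_para = None
        for i, tok in enumerate(self.tokens):
            if tok.token_id != i:
                raise StructuralError(f"token_id {tok.token_id} at position {i} is not positional")
            if tok.char_end <= tok.char_start:
                raise StructuralError(f"empty span for token {i} ({tok.surface!r})")
            if prev_end is not None and tok.char_start < prev_end:
                raise StructuralError(f"overlapping spans at tokens {i - 1} and {i}")
            if prev_sent is not None:
                if tok.sentence_id < prev_sent:
                    raise StructuralError(f"sentence_id decreases at token {i}")
                if tok.sentence_id > prev_sent + 1:
                    raise StructuralError(f"non-contiguous sentence ids at token {i}")
                if tok.sentence_id == prev_sent and tok.paragraph_id != prev_para:
                    raise StructuralError(f"sentence {tok.sentence_id} spans two paragraphs")
                if tok.paragraph_id < prev_para or tok.paragraph_id > prev_para + 1:
                    raise StructuralError(f"paragraph ids not contiguous at token {i}")
            prev_end = tok.char_end
            prev_sent = tok.sentence_id
            prev_para = tok.paragraph_id
        if self.tokens[0].sentence_id != 0 or self.tokens[0].paragraph_id != 0:
            raise StructuralError("sentence and paragraph ids must start at 0")

    def _build_sentence_index(self) -> dict[int, tuple[int, int]]:
        index: dict[int, tuple[int, int]] = {}
        for i, tok in enumerate(self.tokens):
            lo, _ = index.get(tok.sentence_id, (i, i))
            index[tok.sentence_id] = (lo, i + 1)
        return index

    def _build_paragraph_index(self) -> dict[int, tuple[int, int]]:
        index: dict[int, tuple[int, int]] = {}
        for tok in self.tokens:
            lo, hi = index.get(tok.paragraph_id, (tok.sentence_id, tok.sentence_id))
            index[tok.paragraph_id] = (min(lo, tok.sentence_id), max(hi, tok.sentence_id + 1))
        return index

    def _build_line_tokens(self) -> dict[int, list[int]]:
        lines: dict[int, list[int]] = {}
        for i, tok in enumerate(self.tokens):
            lines.setdefault(tok.line_id, []).append(i)
        return lines

    # -- accessors ----------------------------------------------------------
    @property
    def n_tokens(self) -> int:
        return len(self.tokens)

    @property
    def n_sentences(self) -> int:
        return len(self.sentence_index)

    @property
    def n_paragraphs(self) -> int:
        return len(self.paragraph_index)

    def sentence_tokens(self, sentence_id: int) -> list[Token]:
        lo, hi = self.sentence_index[sentence_id]
        return self.tokens[lo:hi]

    def paragraph_sentences(self, paragraph_id: int) -> range:
        lo, hi = self.paragraph_index[paragraph_id]
        return range(lo, hi)

    def paragraph_of_sentence(self, sentence_id: int) -> int:
        return self.tokens[self.sentence_index[sentence_id][0]].paragraph_id

    def is_line_edge(self, token_id: int) -> bool:
        """True when the token is the first or last word of its display line."""
        toks = self.line_tokens[self.tokens[token_id].line_id]
        return token_id == toks[0] or token_id == toks[-1]

    # -- IO -----------------------------------------------------------------
    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "TextStructure":
        missing = [c for c in TEXT_COLUMNS if c not in df.columns]
        if missing:
            raise StructuralError(f"text table missing columns: {missing}")
        tokens = [
            Token(
                token_id=i,
                surface=str(row.surface),
                char_start=int(row.char_start),
                char_end=int(row.char_end),
                sentence_id=int(row.sentence_id),
                paragraph_id=int(row.paragraph_id),
                line_id=int(row.line_id),
            )
            for i, row in enumerate(df.itertuples(index=False))
        ]
        return cls(tokens)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (t.surface, t.char_start, t.char_end, t.sentence_id, t.paragraph_id, t.line_id)
                for t in self.tokens
            ],
            columns=TEXT_COLUMNS,
        )

    def write(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


def load_text_table(path) -> TextStructure:
    """Read a UTF-8 TSV token table (surface, char_start, char_end, sentence_id,
    paragraph_id, line_id) into a validated :class:`TextStructure`."""
    df = pd.read_csv(path, sep="\t", dtype={"surface": str})
    if df.empty:
        raise StructuralError("no tokens")
    return TextStructure.from_dataframe(df)
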