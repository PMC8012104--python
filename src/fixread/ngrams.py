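"""N-gram count tables, log word frequency, and surprisal.

Surprisal of a word is the negative natural log of its conditional probability
given up to two preceding words in the same sentence (trigram model with
order backoff), estimated from a Google-n-gram-style count table:

    surprisal(w_i) = -ln P(w_i | w_{i-2} w_{i-1})
    P(w_i | context) = count(context + w_i) / count(context)

All log quantities are in nats. Sparsity is handled by stupid-backoff-style
order reduction: the estimate comes from the highest order at which both the
context and the full n-gram have positive counts, falling back to the relative
unigram frequency and finally to an add-one floor for unseen words, so every
query yields a finite, non-negative value.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .text import TextStructure

logger = logging.getLogger(__name__)


class NGramParseError(ValueError):
    pass


@dataclass(frozen=True)
class SurprisalValue:
    """Surprisal in nats plus the n-gram order that produced it (after backoff)."""

    value: float
    order_used: int

    def __post_init__(self):
        if self.value < 0:
            raise ValueError("surprisal must be non-negative")


class NGramTable:
    """Counts for n-grams of order 1..max_order keyed by tuples of surfaces."""

    def __init__(self, counts: Mapping[tuple[str, ...], int], max_order: int = 3):
        self.max_order = int(max_order)
        self.counts: dict[tuple[str, ...], int] = {}
        for gram, c in counts.items():
            gram = tuple(gram)
            if c < 0:
                raise NGramParseError(f"negative count for {gram}")
            if 1 <= len(gram) <= self.max_order:
                self.counts[gram] = self.counts.get(gram, 0) + int(c)
        self.total_unigrams = sum(c for g, c in self.counts.items() if len(g) == 1)
        self.vocabulary_size = sum(1 for g in self.counts if len(g) == 1)

    def count(self, gram: Sequence[str]) -> int:
        return self.counts.get(tuple(gram), 0)

    @classmethod
    def from_tokens(cls, stream: Iterable[str], max_order: int = 3) -> "NGramTable":
        """Exact n-gram counts (orders 1..max_order) of a raw token stream."""
        toks = list(stream)
        if not toks:
            raise ValueError("empty token stream")
        counts: dict[tuple[str, ...], int] = {}
        for n in range(1, max_order + 1):
            for i in range(len(toks) - n + 1):
                g = tuple(toks[i : i + n])
                counts[g] = counts.get(g, 0) + 1
        return cls(counts, max_order=max_order)

    def write(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for gram in sorted(self.counts):
                fh.write(" ".join(gram) + "\t" + str(self.counts[gram]) + "\n")


def load_ngram_table(path, max_order: int = 3) -> NGramTable:
    """Read a UTF-8 n-gram file: space-separated tokens, TAB, integer count.

    Records of order above ``max_order`` are skipped (and logged), matching the
    Google n-gram dialect where files may mix orders.
    """
    counts: dict[tuple[str, ...], int] = {}
    n_skipped = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise NGramParseError(f"line {lineno}: expected 'tokens<TAB>count'")
            gram = tuple(parts[0].split())
            if not gram:
                raise NGramParseError(f"line {lineno}: empty n-gram")
            try:
                c = int(parts[1])
            except ValueError as exc:
                raise NGramParseError(f"line {lineno}: count {parts[1]!r} not an integer") from exc
            if c < 0:
                raise NGramParseError(f"line {lineno}: negative count {c}")
            if len(gram) > max_order:
                n_skipped += 1
                continue
            counts[gram] = counts.get(gram, 0) + c
    if n_skipped:
        logger.info("skipped %d n-grams above order %d", n_skipped, max_order)
    table = NGramTable(counts, max_order=max_order)
    if table.total_unigrams <= 0:
        raise NGramParseError("table has no unigram mass")
    return table


def _unseen_probability(table: NGramTable) -> float:
    # add-one floor over (total + vocabulary + 1): strictly below any seen
    # word's relative frequency, so frequency stays increasing in count
    return 1.0 / (table.total_unigrams + table.vocabulary_size + 1)


def word_frequency(table: NGramTable, surface: str) -> float:
    """Log relative unigram frequency ln(count(w)/total), in nats.

    Unseen words get the smoothed floor ln(1/(total + V + 1)).
    """
    if not surface:
        raise ValueError("empty surface")
    if table.total_unigrams <= 0:
        raise ValueError("table has no unigram mass")
    c = table.count((surface,))
    if c > 0:
        return math.log(c / table.total_unigrams)
    return math.log(_unseen_probability(table))


def surprisal(table: NGramTable, context: Sequence[str], target: str) -> SurprisalValue:
    """-ln P(target | context) with trigram -> bigram -> unigram backoff.

    The estimate uses the highest order at which both the conditioning context
    and the full n-gram have positive counts; otherwise it falls back to the
    (smoothed) unigram, which guarantees a finite non-negative value.
    """
    if not target:
        raise ValueError("empty target")
    if table.total_unigrams <= 0:
        raise ValueError("table has no unigram mass")
    context = tuple(context)
    if len(context) > 2:
        raise ValueError("context limited to the previous two words")
    for ctx in (context[-2:], context[-1:]) if context else ():
        if not ctx:
            continue
        c_ctx = table.count(ctx)
        c_full = table.count(ctx + (target,))
        if c_ctx > 0 and c_full > 0:
            return SurprisalValue(max(0.0, -math.log(c_full / c_ctx)), len(ctx) + 1)
    c = table.count((target,))
    if c > 0:
        return SurprisalValue(max(0.0, -math.log(c / table.total_unigrams)), 1)
    return SurprisalValue(-math.log(_unseen_probability(table)), 1)


def annotate_surprisal(text: TextStructure, table: NGramTable) -> list[SurprisalValue]:
    """Per-token surprisal; the conditioning context never crosses a sentence
    boundary, so sentence-initial words are scored with an empty context."""
    out: list[SurprisalValue] = []
    for tok in text.tokens:
        lo, _ = text.sentence_index[tok.sentence_id]
        ctx_lo = max(lo, tok.token_id - 2)
        context = tuple(t.surface for t in text.tokens[ctx_lo : tok.token_id])
        out.append(surprisal(table, context, tok.surface))
    return out
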