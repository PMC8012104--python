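"""Shared fixtures and independent oracle implementations.

The oracles deliberately re-derive quantities from raw inputs (token streams,
fixation event replay) without using the package's own data structures, so
they stay independent of the code paths they check.
"""

import math

import numpy as np
import pandas as pd
import pytest

from fixread.text import TextStructure, Token


# ---------------------------------------------------------------------------
# oracle: surprisal by brute-force recount of the raw token stream
# ---------------------------------------------------------------------------

def brute_force_surprisal(stream, sentence_ids, max_order=3):
    """Per-token surprisal recomputed from scratch.

    Counts every n-gram of the raw stream by direct scanning, then applies
    -ln(count(context+w)/count(context)) at the highest order where both
    counts are positive, with context truncated at sentence boundaries,
    falling back to count(w)/total and finally 1/(total + V + 1).
    """
    def count(gram):
        n = len(gram)
        return sum(
            1 for i in range(len(stream) - n + 1) if tuple(stream[i : i + n]) == tuple(gram)
        )

    total = len(stream)
    vocab = len(set(stream))
    out = []
    for i, w in enumerate(stream):
        ctx = []
        for j in (i - 1, i - 2):
            if j >= 0 and sentence_ids[j] == sentence_ids[i]:
                ctx.insert(0, stream[j])
            else:
                break
        value = None
        for k in (2, 1):
            if len(ctx) >= k:
                c_ctx = count(ctx[-k:])
                c_full = count(ctx[-k:] + [w])
                if c_ctx > 0 and c_full > 0:
                    value = -math.log(c_full / c_ctx)
                    break
        if value is None:
            c = count([w])
            value = -math.log(c / total) if c > 0 else -math.log(1.0 / (total + vocab + 1))
        out.append(max(0.0, value))
    return out


# ---------------------------------------------------------------------------
# oracle: viewing-time decomposition by explicit event replay
# ---------------------------------------------------------------------------

def replay_decomposition(fixations):
    """Tag each (token, duration) fixation FFD/RFD/RRD by replaying the
    scanpath with explicit eyes-have-left bookkeeping; returns per-token dict
    {token: [ffd, rfd, rrd]}."""
    comp = {}
    left = set()
    visited = set()
    in_first_pass = {}
    prev = None
    for token, duration in fixations:
        if prev is not None and prev != token:
            left.add(prev)
        comp.setdefault(token, [0, 0, 0])
        if token not in visited:
            visited.add(token)
            forward = prev is None or prev < token
            in_first_pass[token] = forward
            comp[token][0 if forward else 2] += duration
        elif token in left and prev != token:
            in_first_pass[token] = False
            comp[token][2] += duration
        elif token in left and prev == token and not in_first_pass[token]:
            comp[token][2] += duration
        else:
            comp[token][1 if in_first_pass[token] else 2] += duration
        prev = token
    return comp


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture
def tiny_text():
    """Two display lines of four words each, one sentence per line."""
    spans = [(0, 2), (2, 4), (4, 6), (6, 8), (8, 10), (10, 12), (12, 14), (14, 16)]
    tokens = [
        Token(
            token_id=i,
            surface=f"w{i}",
            char_start=a,
            char_end=b,
            sentence_id=0 if i < 4 else 1,
            paragraph_id=0,
            line_id=0 if i < 4 else 1,
        )
        for i, (a, b) in enumerate(spans)
    ]
    return TextStructure(tokens)


@pytest.fixture
def toy_document():
    """Three sentences over two paragraphs with hand-made 2-D embeddings."""
    words = [
        # sentence 0, paragraph 0
        ("aa", 0, 0), ("b", 0, 0), ("cc", 0, 0),
        # sentence 1, paragraph 0
        ("aa", 1, 0), ("dd", 1, 0),
        # sentence 2, paragraph 1
        ("e", 2, 1), ("b", 2, 1),
    ]
    tokens = []
    pos = 0
    for i, (s, sid, pid) in enumerate(words):
        tokens.append(
            Token(i, s, pos, pos + len(s), sid, pid, line_id=sid)
        )
        pos += len(s)
    return TextStructure(tokens)
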