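"""Fixation filtering and viewing-time decomposition.

A word's total viewing time is split additively into three components:

* **FFD** — first fixation duration: the first fixation of the word's first
  pass, where a first pass is the maximal run of consecutive fixations on the
  word beginning with its first arrival from an earlier token (a forward
  saccade).
* **RFD** — refixation duration: the remaining fixations of that first-pass
  run, before the eyes leave the word.
* **RRD** — re-reading duration: all other fixations on the word (regressions
  in and later re-visits). A word first entered by a regressive saccade has
  FFD = RFD = 0 and all of its time in RRD.

Gaze duration GD = FFD + RFD; total = FFD + RFD + RRD, so the components
conserve the summed duration of the retained fixations exactly.

Filtering applies, per fixation and in a fixed precedence: blink, trial
first/last fixation, line-switch fixation (line differs from the previous
fixation's), duration bounds (< min_dur or > max_dur; endpoints retained),
first/last word of the display line, and unmappable positions (exact word
boundaries, off-text). The stream-structure facts the neighbour-relative rules
need (trial edge flags, previous fixation's line) are annotated once on first
contact with a raw stream, which makes the filter idempotent on its output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .text import TextStructure

FIXATION_COLUMNS = [
    "participant_id",
    "trial_id",
    "seq_index",
    "line_id",
    "char_pos",
    "duration",
    "blink",
]

EXCLUSION_REASONS = [
    "blink",
    "trial_first_last",
    "line_switch",
    "duration_low",
    "duration_high",
    "line_first_last_word",
    "boundary_saccade",
    "unmapped",
]

MEASURE_COLUMNS = ["participant_id", "trial_id", "token_id", "FFD", "RFD", "RRD", "GD", "total", "skipped"]


class FixationParseError(ValueError):
    pass


class FixationStructureError(ValueError):
    pass


@dataclass
class FixationRecord:
    participant_id: str
    trial_id: int
    seq_index: int
    line_id: int
    char_pos: float
    duration: float
    blink: bool = False
    # stream-structure annotations, set once per raw stream
    is_trial_first: bool = False
    is_trial_last: bool = False
    prev_line_id: Optional[int] = None
    _annotated: bool = field(default=False, repr=False)
    # assigned during filtering
    token_id: Optional[int] = None


@dataclass
class FilterReport:
    """Partition of the input fixations: every fixation is either retained or
    counted under exactly one (first-matching) exclusion reason."""

    n_input: int
    n_retained: int
    excluded: dict[str, int]

    def __post_init__(self):
        if self.n_input != self.n_retained + sum(self.excluded.values()):
            raise ValueError("filter report does not partition the input")

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {"n_input": self.n_input, "n_retained": self.n_retained, "excluded": self.excluded},
            indent=2,
            sort_keys=True,
        )
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(payload + "\n")
        return payload


TrialKey = tuple[str, int]
FixationGroups = dict[TrialKey, list[FixationRecord]]


def annotate_stream(groups: FixationGroups) -> FixationGroups:
    """Freeze stream-structure facts onto each record (trial edges, previous
    fixation's line). Already-annotated records are left untouched."""
    for recs in groups.values():
        if not recs or recs[0]._annotated:
            continue
        prev_line = None
        for i, rec in enumerate(recs):
            rec.is_trial_first = i == 0
            rec.is_trial_last = i == len(recs) - 1
            rec.prev_line_id = prev_line
            rec._annotated = True
            prev_line = rec.line_id
    return groups


def group_fixations(records: list[FixationRecord]) -> FixationGroups:
    groups: FixationGroups = {}
    for rec in records:
        groups.setdefault((rec.participant_id, rec.trial_id), []).append(rec)
    for key, recs in groups.items():
        recs.sort(key=lambda r: r.seq_index)
        seqs = [r.seq_index for r in recs]
        if any(b <= a for a, b in zip(seqs, seqs[1:])):
            raise FixationStructureError(f"seq_index not strictly increasing in trial {key}")
    return annotate_stream(groups)


def load_fixations(path) -> FixationGroups:
    """Read a fixation-log TSV, group by (participant, trial), order by
    seq_index, and annotate stream structure."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in FIXATION_COLUMNS if c not in df.columns]
    if missing:
        raise FixationParseError(f"fixation log missing columns: {missing}")
    records = []
    for row in df.itertuples(index=False):
        if row.duration <= 0:
            raise FixationParseError(
                f"non-positive duration {row.duration} at seq {row.seq_index}"
            )
        records.append(
            FixationRecord(
                participant_id=str(row.participant_id),
                trial_id=int(row.trial_id),
                seq_index=int(row.seq_index),
                line_id=int(row.line_id),
                char_pos=float(row.char_pos),
                duration=float(row.duration),
                blink=bool(row.blink),
            )
        )
    return group_fixations(records)


def write_fixations(groups: FixationGroups, path) -> None:
    rows = [
        (r.participant_id, r.trial_id, r.seq_index, r.line_id, r.char_pos, r.duration, int(r.blink))
        for key in sorted(groups)
        for r in groups[key]
    ]
    pd.DataFrame(rows, columns=FIXATION_COLUMNS).to_csv(path, sep="\t", index=False)


def map_fixation_to_token(fix: FixationRecord, text: TextStructure) -> Optional[int]:
    """Token on the fixation's line whose span strictly contains the position.

    Positions exactly on a span edge (word boundaries included) and off-text
    positions map to None.
    """
    token_id, _ = _map_with_reason(fix, text)
    return token_id


def _map_with_reason(fix: FixationRecord, text: TextStructure) -> tuple[Optional[int], str]:
    line_toks = text.line_tokens.get(fix.line_id)
    if not line_toks:
        return None, "unmapped"
    pos = text.line_origin[fix.line_id] + fix.char_pos
    prev_end = None
    for tid in line_toks:
        tok = text.tokens[tid]
        if tok.char_start < pos < tok.char_end:
            return tid, "ok"
        if prev_end is not None and pos == prev_end == tok.char_start:
            return None, "boundary_saccade"  # landed exactly between two words
        prev_end = tok.char_end
    return None, "unmapped"


def filter_fixations(
    groups: FixationGroups,
    text: TextStructure,
    min_dur: float = 80.0,
    max_dur: float = 800.0,
) -> tuple[FixationGroups, FilterReport]:
    """Apply the exclusion rules and assign each retained fixation a token.

    Rules are evaluated per fixation in a fixed precedence so the report is
    deterministic; duration bounds are strict (exactly ``min_dur`` or
    ``max_dur`` is retained).
    """
    annotate_stream(groups)
    excluded = {reason: 0 for reason in EXCLUSION_REASONS}
    retained: FixationGroups = {}
    n_input = 0
    for key, recs in groups.items():
        kept = []
        for rec in recs:
            n_input += 1
            reason = _exclusion_reason(rec, text, min_dur, max_dur)
            if reason is None:
                kept.append(rec)
            else:
                excluded[reason] += 1
        retained[key] = kept
    report = FilterReport(
        n_input=n_input,
        n_retained=sum(len(v) for v in retained.values()),
        excluded=excluded,
    )
    return retained, report


def _exclusion_reason(
    rec: FixationRecord, text: TextStructure, min_dur: float, max_dur: float
) -> Optional[str]:
    if rec.blink:
        return "blink"
    if rec.is_trial_first or rec.is_trial_last:
        return "trial_first_last"
    if rec.prev_line_id is not None and rec.line_id != rec.prev_line_id:
        return "line_switch"
    if rec.duration < min_dur:
        return "duration_low"
    if rec.duration > max_dur:
        return "duration_high"
    token_id, map_reason = _map_with_reason(rec, text)
    if token_id is not None:
        if text.is_line_edge(token_id):
            return "line_first_last_word"
        rec.token_id = token_id
        return None
    return map_reason


def decompose_viewing_times(retained: FixationGroups, text: TextStructure) -> pd.DataFrame:
    """Per (participant, trial, token) FFD/RFD/RRD/GD/total decomposition.

    Every token of the text appears in each trial's output; tokens that
    received no retained fixation are emitted with zero components and
    ``skipped`` set.
    """
    rows = []
    for (pid, trial), recs in sorted(retained.items()):
        ffd = {}
        rfd = {}
        rrd = {}
        seen: set[int] = set()  # tokens whose first arrival already happened
        first_pass_open: Optional[int] = None  # token whose first pass is the current run
        prev_token: Optional[int] = None
        for rec in recs:
            if rec.token_id is None:
                raise FixationStructureError(
                    "unmapped fixation reached decomposition; run filter_fixations first"
                )
            t = rec.token_id
            if t != prev_token:
                # a new run starts; any open first pass is now closed
                if t not in seen:
                    # first arrival: forward entry iff no predecessor or the
                    # previous fixation was on an earlier token
                    forward = prev_token is None or prev_token < t
                    first_pass_open = t if forward else None
                    seen.add(t)
                    if forward:
                        ffd[t] = rec.duration
                    else:
                        rrd[t] = rrd.get(t, 0) + rec.duration
                else:
                    first_pass_open = None
                    rrd[t] = rrd.get(t, 0) + rec.duration
            else:
                if first_pass_open == t:
                    rfd[t] = rfd.get(t, 0) + rec.duration
                else:
                    rrd[t] = rrd.get(t, 0) + rec.duration
            prev_token = t
        for tok in text.tokens:
            t = tok.token_id
            f, r, rr = ffd.get(t, 0), rfd.get(t, 0), rrd.get(t, 0)
            total = f + r + rr
            rows.append((pid, trial, t, f, r, rr, f + r, total, total == 0))
    return pd.DataFrame(rows, columns=MEASURE_COLUMNS)
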