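"""Fixation mapping, filtering and viewing-time decomposition, checked
against hand-derived partitions and an event-replay oracle."""

import numpy as np
import pandas as pd
import pytest

from conftest import replay_decomposition
from fixread.gaze import (
    FixationParseError,
    FixationRecord,
    FixationStructureError,
    decompose_viewing_times,
    filter_fixations,
    group_fixations,
    load_fixations,
    map_fixation_to_token,
    write_fixations,
)
from fixread.simulate import (
    GeneratorConfig,
    generate_embeddings,
    generate_ngram_counts,
    generate_participants,
    generate_scanpaths,
    generate_text,
    token_covariates,
)


def _fix(seq, line, pos, dur=200, blink=False, pid="p", trial=0):
    return FixationRecord(
        participant_id=pid, trial_id=trial, seq_index=seq, line_id=line,
        char_pos=pos, duration=dur, blink=blink,
    )


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------

def test_load_fixations_round_trip(tmp_path):
    groups = group_fixations([_fix(i, 0, 3.0) for i in range(5)])
    p = tmp_path / "fix.tsv"
    write_fixations(groups, p)
    again = load_fixations(p)
    assert list(again) == [("p", 0)]
    assert len(again[("p", 0)]) == 5
    assert again[("p", 0)][0].is_trial_first
    assert again[("p", 0)][-1].is_trial_last


def test_duplicate_seq_index_rejected():
    with pytest.raises(FixationStructureError, match="seq_index"):
        group_fixations([_fix(1, 0, 3.0), _fix(1, 0, 4.0)])


def test_missing_column_rejected(tmp_path):
    p = tmp_path / "fix.tsv"
    p.write_text("participant_id\ttrial_id\tseq_index\n")
    with pytest.raises(FixationParseError, match="line_id"):
        load_fixations(p)


def test_nonpositive_duration_rejected(tmp_path):
    p = tmp_path / "fix.tsv"
    pd.DataFrame(
        [("p", 0, 0, 0, 3.0, 0.0, 0)],
        columns=["participant_id", "trial_id", "seq_index", "line_id", "char_pos",
                 "duration", "blink"],
    ).to_csv(p, sep="\t", index=False)
    with pytest.raises(FixationParseError, match="duration"):
        load_fixations(p)


# ---------------------------------------------------------------------------
# mapping
# ---------------------------------------------------------------------------

def test_map_inside_word(tiny_text):
    assert map_fixation_to_token(_fix(0, 0, 1.5), tiny_text) == 0
    assert map_fixation_to_token(_fix(0, 1, 3.0), tiny_text) == 5  # line-local units


def test_map_boundary_is_unmapped(tiny_text):
    # exactly between tokens 0 [0,2) and 1 [2,4)
    assert map_fixation_to_token(_fix(0, 0, 2.0), tiny_text) is None


def test_map_off_text_is_unmapped(tiny_text):
    assert map_fixation_to_token(_fix(0, 0, 99.0), tiny_text) is None
    assert map_fixation_to_token(_fix(0, 7, 1.0), tiny_text) is None


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def _constructed_log():
    """Ten fixations violating one rule each plus two clean ones.

    tiny_text: line 0 tokens 0-3 (spans 0-8), line 1 tokens 4-7 (local 0-8).
    """
    return group_fixations([
        _fix(0, 0, 3.0),              # trial-first
        _fix(1, 0, 3.0, blink=True),  # blink
        _fix(2, 0, 3.0),              # clean, token 1
        _fix(3, 0, 5.0, dur=70),      # too short
        _fix(4, 0, 5.0, dur=900),     # too long
        _fix(5, 0, 5.0),              # clean, token 2
        _fix(6, 0, 4.0),              # boundary between tokens 1 and 2
        _fix(7, 0, 7.0),              # line-final word (token 3)
        _fix(8, 1, 3.0),              # line switch
        _fix(9, 1, 5.0),              # trial-last
    ])


def test_filter_reproduces_hand_partition(tiny_text):
    retained, report = filter_fixations(_constructed_log(), tiny_text)
    assert report.n_input == 10
    assert report.n_retained == 2
    assert report.excluded == {
        "blink": 1,
        "trial_first_last": 2,
        "line_switch": 1,
        "duration_low": 1,
        "duration_high": 1,
        "line_first_last_word": 1,
        "boundary_saccade": 1,
        "unmapped": 0,
    }
    kept = retained[("p", 0)]
    assert [r.token_id for r in kept] == [1, 2]


def test_duration_endpoints_retained(tiny_text):
    groups = group_fixations([
        _fix(0, 0, 3.0),
        _fix(1, 0, 3.0, dur=80),
        _fix(2, 0, 5.0, dur=800),
        _fix(3, 0, 3.0),
    ])
    retained, report = filter_fixations(groups, tiny_text)
    assert report.excluded["duration_low"] == 0
    assert report.excluded["duration_high"] == 0
    # only the trial-edge fixations go; the 80/800 ms ones stay
    assert report.n_retained == 2
    assert sorted(r.duration for r in retained[("p", 0)]) == [80, 800]


def test_filter_is_idempotent(tiny_text):
    retained, report = filter_fixations(_constructed_log(), tiny_text)
    again, report2 = filter_fixations(retained, tiny_text)
    assert report2.n_input == report.n_retained
    assert report2.n_retained == report.n_retained
    assert sum(report2.excluded.values()) == 0


def test_filter_accounting_partitions_input(tiny_text):
    _, report = filter_fixations(_constructed_log(), tiny_text)
    assert report.n_input == report.n_retained + sum(report.excluded.values())


def test_empty_trial_gives_empty_output(tiny_text):
    retained, report = filter_fixations({("p", 0): []}, tiny_text)
    assert retained[("p", 0)] == []
    assert report.n_input == 0


# ---------------------------------------------------------------------------
# decomposition
# ---------------------------------------------------------------------------

def _measures_for(scanpath, text):
    """scanpath: list of (token_id, duration); builds retained records."""
    recs = []
    for i, (tid, dur) in enumerate(scanpath):
        r = _fix(i, text.tokens[tid].line_id,
                 text.tokens[tid].char_start - text.line_origin[text.tokens[tid].line_id]
                 + len(text.tokens[tid]) / 2, dur=dur)
        r.token_id = tid
        recs.append(r)
    df = decompose_viewing_times({("p", 0): recs}, text)
    return df.set_index("token_id")


def test_first_pass_refixation_and_revisit(tiny_text):
    m = _measures_for([(1, 200), (1, 150), (2, 300), (1, 100)], tiny_text)
    assert m.loc[1, ["FFD", "RFD", "RRD", "GD", "total"]].tolist() == [200, 150, 100, 350, 450]


def test_single_fixation_word(tiny_text):
    m = _measures_for([(1, 240), (2, 100)], tiny_text)
    assert m.loc[1, ["FFD", "RFD", "RRD"]].tolist() == [240, 0, 0]


def test_regressive_first_entry_goes_to_rrd(tiny_text):
    # token 1 is skipped in first pass, then entered from the right
    m = _measures_for([(2, 200), (1, 180)], tiny_text)
    assert m.loc[1, ["FFD", "RFD", "RRD"]].tolist() == [0, 0, 180]
    # and a later refixation during that regressive visit stays RRD
    m2 = _measures_for([(2, 200), (1, 180), (1, 90)], tiny_text)
    assert m2.loc[1, ["FFD", "RFD", "RRD"]].tolist() == [0, 0, 270]


def test_skipped_words_flagged(tiny_text):
    m = _measures_for([(1, 200)], tiny_text)
    assert bool(m.loc[2, "skipped"])
    assert m.loc[2, "total"] == 0
    assert not bool(m.loc[1, "skipped"])


def test_unmapped_fixation_raises(tiny_text):
    r = _fix(0, 0, 3.0)
    with pytest.raises(FixationStructureError, match="filter"):
        decompose_viewing_times({("p", 0): [r]}, tiny_text)


@pytest.mark.parametrize("seed", range(3))
def test_decomposition_matches_event_replay_oracle(tiny_text, seed):
    """Random scanpaths over interior tokens: component assignment matches an
    independent event-replay oracle, and components conserve total duration."""
    rng = np.random.default_rng(seed)
    interior = [1, 2, 5, 6]
    for _ in range(200):
        n = int(rng.integers(1, 12))
        path = [(int(rng.choice(interior)), int(rng.integers(81, 799))) for _ in range(n)]
        m = _measures_for(path, tiny_text)
        oracle = replay_decomposition(path)
        for tid, (f, r, rr) in oracle.items():
            assert m.loc[tid, ["FFD", "RFD", "RRD"]].tolist() == [f, r, rr], path
        assert m["total"].sum() == sum(d for _, d in path)
        assert (m["GD"] == m["FFD"] + m["RFD"]).all()


def test_conservation_on_generated_scanpaths():
    cfg = GeneratorConfig(seed=11, n_per_group=1, n_paragraphs=4)
    rng = np.random.default_rng(cfg.seed)
    text = generate_text(cfg, rng)
    table = generate_ngram_counts([t.surface for t in text.tokens])
    emb = generate_embeddings(text, cfg, np.random.default_rng(cfg.seed + 1))
    parts = generate_participants(cfg)
    covs = token_covariates(text, table, emb)
    groups, _ = generate_scanpaths(text, covs, parts, cfg, np.random.default_rng(cfg.seed + 2))
    retained, _ = filter_fixations(groups, text)
    measures = decompose_viewing_times(retained, text)
    by_trial = measures.groupby(["participant_id", "trial_id"])["total"].sum()
    for key, recs in retained.items():
        assert by_trial.get(key, 0) == sum(r.duration for r in recs)
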