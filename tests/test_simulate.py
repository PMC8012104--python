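"""Synthetic-data generator: determinism, distributional targets, the
embedding concentration hierarchy, and scanpath round-trip fidelity."""

import math

import numpy as np
import pytest
from scipy import stats

from fixread.gaze import decompose_viewing_times, filter_fixations
from fixread.ngrams import NGramTable, surprisal
from fixread.similarity import similarity_features
from fixread.simulate import (
    ConfigError,
    GeneratorConfig,
    generate_dataset,
    generate_embeddings,
    generate_ngram_counts,
    generate_participants,
    generate_scanpaths,
    generate_text,
    simulate_lmm_dataset,
    token_covariates,
)


def _small_cfg(**kw):
    base = dict(seed=5, n_per_group=1, n_paragraphs=3, sentences_per_paragraph=4,
                words_per_sentence=5, vocab_size=60)
    base.update(kw)
    return GeneratorConfig(**base)


# ---------------------------------------------------------------------------
# text
# ---------------------------------------------------------------------------

def test_text_token_count_and_determinism():
    cfg = GeneratorConfig(seed=1, n_paragraphs=2, sentences_per_paragraph=2,
                          words_per_sentence=5)
    t1 = generate_text(cfg)
    t2 = generate_text(cfg)
    assert t1.n_tokens == 20
    assert t1.to_dataframe().equals(t2.to_dataframe())


def test_word_lengths_bounded():
    text = generate_text(_small_cfg())
    assert all(1 <= len(t) <= 5 for t in text.tokens)


def test_zipf_exponent_zero_is_uniform():
    cfg = GeneratorConfig(seed=2, zipf_exponent=0.0, vocab_size=20, n_paragraphs=50,
                          sentences_per_paragraph=10, words_per_sentence=20)
    text = generate_text(cfg)
    counts = {}
    for t in text.tokens:
        counts[t.surface] = counts.get(t.surface, 0) + 1
    n = text.n_tokens
    observed = np.array(list(counts.values()))
    # words never drawn count as zero cells
    observed = np.concatenate([observed, np.zeros(cfg.vocab_size - len(observed))])
    _, p = stats.chisquare(observed, f_exp=np.full(cfg.vocab_size, n / cfg.vocab_size))
    assert p > 0.01


def test_one_word_sentences_all_sentence_initial():
    cfg = _small_cfg(words_per_sentence=1)
    text = generate_text(cfg)
    table = generate_ngram_counts([t.surface for t in text.tokens])
    from fixread.ngrams import annotate_surprisal

    assert all(s.order_used == 1 for s in annotate_surprisal(text, table))


def test_invalid_config_rejected():
    with pytest.raises(ConfigError):
        GeneratorConfig(p_refix=1.5).validate()
    with pytest.raises(ConfigError):
        GeneratorConfig(embedding_dim=1).validate()
    with pytest.raises(ConfigError):
        GeneratorConfig(sd_resid=-1.0).validate()


# ---------------------------------------------------------------------------
# n-gram counts
# ---------------------------------------------------------------------------

def test_ngram_counts_hand_checked():
    table = generate_ngram_counts(["a", "b", "a", "b"])
    assert table.count(("a",)) == 2
    assert table.count(("a", "b")) == 2
    assert table.count(("b", "a")) == 1
    assert surprisal(table, ("a",), "b").value == pytest.approx(0.0, abs=1e-12)


def test_unigram_mass_equals_stream_length():
    stream = list("abracadabra")
    assert generate_ngram_counts(stream).total_unigrams == len(stream)


# ---------------------------------------------------------------------------
# embeddings
# ---------------------------------------------------------------------------

def test_infinite_concentration_gives_exact_parent():
    cfg = _small_cfg(concentration_sentence=math.inf)
    text = generate_text(cfg)
    emb = generate_embeddings(text, cfg)
    feats = similarity_features(text, emb)
    assert np.allclose(feats["sent_para"], 1.0, atol=1e-12)


def test_zero_concentration_gives_near_orthogonal():
    # many independent random unit directions at dim 128: mean cosine near 0
    cfg = GeneratorConfig(seed=3, concentration_sentence=0.0, n_paragraphs=40,
                          sentences_per_paragraph=6, words_per_sentence=2,
                          vocab_size=100)
    text = generate_text(cfg)
    emb = generate_embeddings(text, cfg)
    feats = similarity_features(text, emb)
    assert abs(feats.groupby(text.to_dataframe()["sentence_id"].values)["sent_para"]
               .first().mean()) < 0.05


def test_concentration_monotone_in_sent_para():
    lo_cfg = _small_cfg(concentration_sentence=0.5, n_paragraphs=10)
    hi_cfg = _small_cfg(concentration_sentence=8.0, n_paragraphs=10)
    lo = similarity_features(generate_text(lo_cfg),
                             generate_embeddings(generate_text(lo_cfg), lo_cfg))
    hi = similarity_features(generate_text(hi_cfg),
                             generate_embeddings(generate_text(hi_cfg), hi_cfg))
    assert hi["sent_para"].mean() > lo["sent_para"].mean()


def test_topic_shifts_lower_cross_topic_para_similarity():
    # concentration must dominate sqrt(dim) for near-parent cosines
    cfg = GeneratorConfig(seed=4, n_paragraphs=60, sentences_per_paragraph=2,
                          words_per_sentence=2, n_topics=2, topic_shift_rate=0.5,
                          concentration_paragraph=60.0, vocab_size=100)
    text = generate_text(cfg)
    emb = generate_embeddings(text, cfg)
    feats = similarity_features(text, emb)
    pp = feats.join(text.to_dataframe()[["paragraph_id"]]).groupby("paragraph_id")[
        "para_para"].first().dropna()
    # bimodal: within-topic pairs near 1, cross-topic pairs lower
    assert pp.max() > 0.8
    assert pp.min() < pp.max() - 0.2


# ---------------------------------------------------------------------------
# scanpaths
# ---------------------------------------------------------------------------

def _full_world(cfg):
    rng = np.random.default_rng(cfg.seed)
    text = generate_text(cfg, rng)
    table = generate_ngram_counts([t.surface for t in text.tokens])
    emb = generate_embeddings(text, cfg, np.random.default_rng(cfg.seed + 1))
    parts = generate_participants(cfg)
    covs = token_covariates(text, table, emb)
    groups, truth = generate_scanpaths(text, covs, parts, cfg,
                                       np.random.default_rng(cfg.seed + 2))
    return text, groups, truth


def test_degenerate_no_refix_no_regress():
    cfg = _small_cfg(p_refix=0.0, p_regress=0.0, p_skip=0.0)
    _, _, truth = _full_world(cfg)
    assert (truth.components[["RFD", "RRD"]].to_numpy() == 0).all()


def test_deterministic_limit_all_ffd_equal():
    beta = {"intercept": math.log(220.0), "freq": 0.0, "surprisal": 0.0,
            "word_sent": 0.0, "sent_sent": 0.0, "sent_para": 0.0,
            "para_para": 0.0, "ability": 0.0}
    cfg = _small_cfg(beta=beta, sd_participant=0.0, sd_word=0.0, sd_resid=0.0,
                     grade5_shift=0.0, p_refix=0.0, p_regress=0.0, p_skip=0.0)
    _, _, truth = _full_world(cfg)
    ffd = truth.components["FFD"]
    assert (ffd == round(math.exp(math.log(220.0)))).all()


def test_round_trip_exact_recovery():
    cfg = _small_cfg(n_per_group=2, n_paragraphs=5)
    text, groups, truth = _full_world(cfg)
    retained, _ = filter_fixations(groups, text)
    measures = decompose_viewing_times(retained, text).set_index(
        ["participant_id", "trial_id", "token_id"]
    )
    gt = truth.components.set_index(["participant_id", "trial_id", "token_id"])
    got = measures.loc[gt.index, ["FFD", "RFD", "RRD"]].to_numpy()
    assert (got == gt[["FFD", "RFD", "RRD"]].to_numpy()).all()


def test_contaminant_counts_match_report():
    cfg = _small_cfg(rate_blink=0.2, rate_short=0.1, rate_long=0.1, rate_boundary=0.1)
    text, groups, truth = _full_world(cfg)
    retained, report = filter_fixations(groups, text)
    assert report.excluded["blink"] > 0
    assert report.excluded["duration_low"] > 0
    assert report.excluded["duration_high"] > 0
    assert report.excluded["boundary_saccade"] > 0
    # contaminants never disturb the informative fixations
    measures = decompose_viewing_times(retained, text).set_index(
        ["participant_id", "trial_id", "token_id"]
    )
    gt = truth.components.set_index(["participant_id", "trial_id", "token_id"])
    got = measures.loc[gt.index, ["FFD", "RFD", "RRD"]].to_numpy()
    assert (got == gt[["FFD", "RFD", "RRD"]].to_numpy()).all()


def test_raising_surprisal_effect_raises_ffd():
    base = dict(n_per_group=2, n_paragraphs=8, p_skip=0.0, p_refix=0.0, p_regress=0.0)
    lo_cfg = _small_cfg(**base)
    hi_cfg = _small_cfg(**base)
    hi_cfg.beta = dict(hi_cfg.beta, surprisal=0.4)
    lo_cfg.beta = dict(lo_cfg.beta, surprisal=0.0)
    _, _, lo_truth = _full_world(lo_cfg)
    _, _, hi_truth = _full_world(hi_cfg)
    z = lo_truth.covariates["surprisal"]
    high_tokens = z[z > z.quantile(0.8)].index
    lo_mean = lo_truth.components.set_index("token_id").loc[
        lambda d: d.index.isin(high_tokens), "FFD"].replace(0, np.nan).mean()
    hi_mean = hi_truth.components.set_index("token_id").loc[
        lambda d: d.index.isin(high_tokens), "FFD"].replace(0, np.nan).mean()
    assert hi_mean > lo_mean


# ---------------------------------------------------------------------------
# dataset emission
# ---------------------------------------------------------------------------

def test_generate_dataset_files_and_determinism(tmp_path):
    cfg = _small_cfg()
    p1 = generate_dataset(cfg, tmp_path / "a")
    p2 = generate_dataset(cfg, tmp_path / "b")
    for name in p1:
        assert p1[name].exists()
        assert p1[name].read_bytes() == p2[name].read_bytes(), name


def test_simulate_lmm_dataset_shape_and_truth():
    df, truth = simulate_lmm_dataset(n_participants=6, n_words=10, rng=0)
    assert len(df) == 60
    assert df["participant_id"].nunique() == 6
    assert set(truth["beta"]) >= {"intercept", "freq", "ability"}
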