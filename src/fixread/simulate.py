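"""Synthetic reading-study generator with known injected effect structure.

Emulates the five inputs of a developmental eye-tracking reading study —
tokenized text, n-gram counts, unit embeddings, a participant table, and
fixation scanpaths — so that every downstream stage (feature computation,
gaze decomposition, mixed-model and path inference) can be tested against a
recorded ground truth.

Design of the generated world
-----------------------------
* **Text**: a Zipf-distributed vocabulary of 1-5 character words, sampled
  into sentences, grouped into paragraphs, and wrapped onto fixed-width
  display lines (no inter-word spaces, as in Chinese text).
* **N-gram counts**: exact counts of the generated token stream, so surprisal
  computed from the table equals the stream's empirical conditional
  probabilities.
* **Embeddings**: a topic hierarchy on the unit sphere. Each paragraph draws
  a vector near its topic; sentence vectors are concentration-weighted
  perturbations of their paragraph vector; word vectors of their sentence
  vector. Higher concentration means higher expected cosine to the parent
  (``concentration = inf`` gives exact equality; ``0`` gives independent
  random directions).
* **Scanpaths**: per participant x token, a latent log-duration linear
  predictor eta = x'beta + u_participant + u_word drives a lognormal first
  fixation; refixations and within-line regressions occur with configurable
  probabilities; contaminants (blinks, out-of-range durations, boundary
  landings) are opt-in extra fixations, so with their rates at zero the gaze
  pipeline recovers the generated components exactly for all line-interior
  tokens.

Everything is deterministic under (seed, config).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .gaze import FixationRecord, FixationGroups, annotate_stream, write_fixations
from .ngrams import NGramTable, annotate_surprisal, word_frequency
from .similarity import EmbeddingSet, similarity_features
from .text import TextStructure, Token

ABILITY_LEVELS = ("poor", "average", "good")
ABILITY_CODE = {"poor": -1.0, "average": 0.0, "good": 1.0}
GRADES = (4, 5)

FIXED_EFFECTS = ("freq", "surprisal", "word_sent", "sent_sent", "sent_para", "para_para", "ability")


class ConfigError(ValueError):
    pass


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic study, with defaults at the study scale.

    ``beta`` is on the latent log-duration (log-ms) scale used by the
    scanpath generator; covariates are standardized internally before the
    linear predictor is formed, so each entry is the log-duration shift per
    SD of the covariate.
    """

    seed: int = 0
    # participants: n per ability group x grade (3 x 2 cells)
    n_per_group: int = 10
    # text layout: paragraphs of 5-7 display lines come out of
    # sentences_per_paragraph x words_per_sentence under line_width_chars
    n_paragraphs: int = 12
    sentences_per_paragraph: int = 6
    words_per_sentence: int = 6
    vocab_size: int = 500
    zipf_exponent: float = 1.1
    min_word_len: int = 1
    max_word_len: int = 5
    line_width_chars: int = 20
    # embeddings
    embedding_dim: int = 128
    n_topics: int = 3
    topic_shift_rate: float = 0.3
    concentration_paragraph: float = 4.0
    concentration_sentence: float = 4.0
    concentration_word: float = 2.0
    # true fixed effects on log-duration (per SD of each covariate)
    beta: dict = field(
        default_factory=lambda: {
            "intercept": math.log(220.0),
            "freq": -0.04,
            "surprisal": 0.04,
            "word_sent": -0.01,
            "sent_sent": -0.03,
            "sent_para": -0.02,
            "para_para": -0.02,
            "ability": -0.04,
        }
    )
    # optional ability x similarity interaction slopes (log scale, per SD)
    ability_interactions: dict = field(default_factory=dict)
    grade5_shift: float = -0.05
    # random-effect and residual SDs on the log scale
    sd_participant: float = 0.08
    sd_word: float = 0.05
    sd_resid: float = 0.15
    # scanpath behaviour
    p_skip: float = 0.10
    p_refix: float = 0.25
    p_regress: float = 0.15
    refix_scale: float = 0.7
    regress_scale: float = 0.8
    # contaminant rates (per generated fixation, opt-in)
    rate_blink: float = 0.0
    rate_short: float = 0.0
    rate_long: float = 0.0
    rate_boundary: float = 0.0

    def validate(self) -> None:
        for name in ("p_skip", "p_refix", "p_regress", "topic_shift_rate",
                     "rate_blink", "rate_short", "rate_long", "rate_boundary"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [0, 1]")
        for name in ("sd_participant", "sd_word", "sd_resid"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.embedding_dim < 2:
            raise ConfigError("embedding_dim must be >= 2")
        if self.vocab_size < 1:
            raise ConfigError("vocab_size must be positive")
        if not 1 <= self.min_word_len <= self.max_word_len <= 5:
            raise ConfigError("word lengths must satisfy 1 <= min <= max <= 5")

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True, indent=2)


@dataclass
class GroundTruth:
    """Everything needed to score recovery against the generator."""

    beta: dict
    sd_participant: float
    sd_word: float
    sd_resid: float
    u_participant: dict
    u_word: dict
    covariates: pd.DataFrame          # per-token standardized covariates used in eta
    eta: pd.DataFrame                 # per (participant, token) linear predictor
    components: pd.DataFrame          # generated FFD/RFD/RRD per (participant, token)
    measurable_tokens: list           # line-interior tokens (survive structural filters)

    def write(self, path) -> None:
        payload = {
            "beta": self.beta,
            "sd_participant": self.sd_participant,
            "sd_word": self.sd_word,
            "sd_resid": self.sd_resid,
            "u_participant": {str(k): v for k, v in self.u_participant.items()},
            "u_word": {str(k): v for k, v in self.u_word.items()},
            "measurable_tokens": list(map(int, self.measurable_tokens)),
            "covariates": self.covariates.reset_index().to_dict(orient="list"),
            "components": self.components.to_dict(orient="list"),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# text
# ---------------------------------------------------------------------------

_ALPHABET = "abcdefghijklmnopqrstuvwxyz"


def _make_vocabulary(cfg: GeneratorConfig, rng: np.random.Generator) -> list[str]:
    """Distinct surfaces of 1-5 characters; deterministic under the rng."""
    vocab: list[str] = []
    seen = set()
    lengths = rng.integers(cfg.min_word_len, cfg.max_word_len + 1, size=cfg.vocab_size * 4)
    i = 0
    while len(vocab) < cfg.vocab_size:
        if i >= lengths.size:
            lengths = rng.integers(cfg.min_word_len, cfg.max_word_len + 1, size=cfg.vocab_size * 4)
            i = 0
        ln = int(lengths[i])
        i += 1
        w = "".join(_ALPHABET[j] for j in rng.integers(0, len(_ALPHABET), size=ln))
        if w not in seen:
            seen.add(w)
            vocab.append(w)
    return vocab


def generate_text(cfg: GeneratorConfig, rng: np.random.Generator | None = None) -> TextStructure:
    """Zipf-sampled document wrapped onto fixed-width display lines."""
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    vocab = _make_vocabulary(cfg, rng)
    ranks = np.arange(1, cfg.vocab_size + 1, dtype=float)
    probs = ranks ** (-cfg.zipf_exponent)
    probs /= probs.sum()

    tokens: list[Token] = []
    char = 0
    line_id = 0
    line_used = 0
    sid = 0
    for pid in range(cfg.n_paragraphs):
        for _ in range(cfg.sentences_per_paragraph):
            draws = rng.choice(cfg.vocab_size, size=cfg.words_per_sentence, p=probs)
            for v in draws:
                surface = vocab[int(v)]
                if line_used + len(surface) > cfg.line_width_chars and line_used > 0:
                    line_id += 1
                    line_used = 0
                tokens.append(
                    Token(
                        token_id=len(tokens),
                        surface=surface,
                        char_start=char,
                        char_end=char + len(surface),
                        sentence_id=sid,
                        paragraph_id=pid,
                        line_id=line_id,
                    )
                )
                char += len(surface)
                line_used += len(surface)
            sid += 1
        # paragraphs start on a fresh display line
        if line_used > 0:
            line_id += 1
            line_used = 0
    return TextStructure(tokens)


def generate_ngram_counts(stream, max_order: int = 3) -> NGramTable:
    """Exact n-gram counts of the raw token stream (orders 1..max_order)."""
    return NGramTable.from_tokens(stream, max_order=max_order)


# ---------------------------------------------------------------------------
# embeddings
# ---------------------------------------------------------------------------

def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _perturb(parent: np.ndarray, concentration: float, rng: np.random.Generator) -> np.ndarray:
    """Unit vector at concentration-controlled angular distance from parent.

    concentration -> inf returns the parent exactly; 0 gives an independent
    uniform direction.
    """
    z = rng.standard_normal(parent.size)
    if math.isinf(concentration):
        return parent.copy()
    if concentration == 0.0:
        return _unit(z)
    return _unit(concentration * parent + z)


def generate_embeddings(
    text: TextStructure, cfg: GeneratorConfig, rng: np.random.Generator | None = None
) -> EmbeddingSet:
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    d = cfg.embedding_dim
    topics = [_unit(rng.standard_normal(d)) for _ in range(max(1, cfg.n_topics))]
    vectors: dict[tuple[str, int], np.ndarray] = {}
    topic_idx = 0
    for pid in sorted(text.paragraph_index):
        if pid > 0 and rng.random() < cfg.topic_shift_rate:
            topic_idx = (topic_idx + 1 + int(rng.integers(0, len(topics) - 1))) % len(topics) \
                if len(topics) > 1 else 0
        vectors[("para", pid)] = _perturb(topics[topic_idx], cfg.concentration_paragraph, rng)
    for sid in sorted(text.sentence_index):
        pvec = vectors[("para", text.paragraph_of_sentence(sid))]
        vectors[("sent", sid)] = _perturb(pvec, cfg.concentration_sentence, rng)
    for tok in text.tokens:
        svec = vectors[("sent", tok.sentence_id)]
        vectors[("word", tok.token_id)] = _perturb(svec, cfg.concentration_word, rng)
    return EmbeddingSet(vectors, dimension=d)


# ---------------------------------------------------------------------------
# participants
# ---------------------------------------------------------------------------

def generate_participants(cfg: GeneratorConfig) -> pd.DataFrame:
    """Balanced participant table: n_per_group per ability x grade cell."""
    rows = []
    i = 0
    for grade in GRADES:
        for ability in ABILITY_LEVELS:
            for _ in range(cfg.n_per_group):
                rows.append((f"p{i:03d}", grade, ability))
                i += 1
    return pd.DataFrame(rows, columns=["participant_id", "grade", "ability"])


# ---------------------------------------------------------------------------
# token-level covariates
# ---------------------------------------------------------------------------

def token_covariates(text: TextStructure, table: NGramTable, emb: EmbeddingSet) -> pd.DataFrame:
    """Per-token modelling covariates: freq, surprisal and the four
    similarity measures (NaN where undefined)."""
    feats = similarity_features(text, emb)
    feats.insert(0, "surprisal", [s.value for s in annotate_surprisal(text, table)])
    feats.insert(0, "freq", [word_frequency(table, t.surface) for t in text.tokens])
    return feats


def _zscore(col: pd.Series) -> pd.Series:
    sd = col.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        return col * 0.0
    return (col - col.mean()) / sd


# ---------------------------------------------------------------------------
# scanpaths
# ---------------------------------------------------------------------------

def generate_scanpaths(
    text: TextStructure,
    covariates: pd.DataFrame,
    participants: pd.DataFrame,
    cfg: GeneratorConfig,
    rng: np.random.Generator | None = None,
) -> tuple[FixationGroups, GroundTruth]:
    """Fixation logs for every participant with recorded ground truth.

    Each paragraph is one trial. Tokens are read in order; line-edge tokens
    are always fixated (their fixations are structurally excluded downstream),
    interior tokens are skipped with probability ``p_skip``. Refixations stay
    within the first-pass run; regressions re-visit an earlier interior token
    of the same display line. Contaminants are extra fixations that the filter
    removes without touching the informative ones.
    """
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 2)

    # standardized covariates for eta (NaN similarities -> 0 after z-scoring:
    # document-initial units simply sit at the covariate mean in generation)
    Z = covariates.copy()
    for c in Z.columns:
        Z[c] = _zscore(Z[c].fillna(Z[c].mean()))
    Z = Z.fillna(0.0)

    u_part = {
        row.participant_id: float(rng.normal(0.0, cfg.sd_participant))
        for row in participants.itertuples(index=False)
    }
    u_word = {t.token_id: float(rng.normal(0.0, cfg.sd_word)) for t in text.tokens}

    beta = cfg.beta
    eta_rows = []
    comp_rows = []
    groups: FixationGroups = {}

    measurable = [
        t.token_id for t in text.tokens if not text.is_line_edge(t.token_id)
    ]

    for prow in participants.itertuples(index=False):
        pid = prow.participant_id
        ability = ABILITY_CODE[prow.ability]
        grade_shift = cfg.grade5_shift if prow.grade == 5 else 0.0
        # per-token eta for this participant
        eta_tok = {}
        for t in text.tokens:
            x = Z.loc[t.token_id]
            eta = beta["intercept"] + grade_shift + beta["ability"] * ability
            for name in FIXED_EFFECTS:
                if name == "ability":
                    continue
                eta += beta.get(name, 0.0) * float(x[name])
            for name, slope in cfg.ability_interactions.items():
                eta += slope * ability * float(x[name])
            eta += u_part[pid] + u_word[t.token_id]
            eta_tok[t.token_id] = eta
            eta_rows.append((pid, t.token_id, eta))

        for trial, paragraph in enumerate(sorted(text.paragraph_index)):
            recs: list[FixationRecord] = []
            seq = [0]

            def _dur(token_id: int, scale: float = 1.0) -> int:
                e = eta_tok[token_id] + math.log(scale) if scale != 1.0 else eta_tok[token_id]
                d = int(round(math.exp(e + rng.normal(0.0, cfg.sd_resid))))
                return min(max(d, 81), 799)

            def _emit(token_id: int, duration: int, blink=False, char_pos=None) -> None:
                tok = text.tokens[token_id]
                if char_pos is None:
                    char_pos = (
                        tok.char_start - text.line_origin[tok.line_id] + len(tok) / 2.0
                    )
                recs.append(
                    FixationRecord(
                        participant_id=pid,
                        trial_id=trial,
                        seq_index=seq[0],
                        line_id=tok.line_id,
                        char_pos=float(char_pos),
                        duration=float(duration),
                        blink=blink,
                    )
                )
                seq[0] += 1

            def _contaminate(token_id: int) -> None:
                tok = text.tokens[token_id]
                if rng.random() < cfg.rate_blink:
                    _emit(token_id, _dur(token_id), blink=True)
                if rng.random() < cfg.rate_short:
                    _emit(token_id, int(rng.integers(1, 80)))
                if rng.random() < cfg.rate_long:
                    _emit(token_id, int(rng.integers(801, 1200)))
                line_toks = text.line_tokens[tok.line_id]
                if token_id != line_toks[-1] and rng.random() < cfg.rate_boundary:
                    # land exactly on the boundary with the next word
                    _emit(token_id, _dur(token_id),
                          char_pos=tok.char_end - text.line_origin[tok.line_id])

            sent_lo, sent_hi = text.paragraph_index[paragraph]
            tok_lo = text.sentence_index[sent_lo][0]
            tok_hi = text.sentence_index[sent_hi - 1][1]
            ffd = {}
            rfd = {}
            rrd = {}
            fixated_interior: list[int] = []
            prev_line = None
            for tid in range(tok_lo, tok_hi):
                tok = text.tokens[tid]
                edge = text.is_line_edge(tid)
                if tok.line_id != prev_line:
                    fixated_interior = []  # regressions stay within the line
                    prev_line = tok.line_id
                if not edge and rng.random() < cfg.p_skip:
                    continue
                trial_last = tid == tok_hi - 1
                d1 = _dur(tid)
                _emit(tid, d1)
                if not trial_last:
                    # nothing may follow the final token's fixation, so the
                    # trial-last exclusion always lands on a line-edge token
                    _contaminate(tid)
                if not edge:
                    ffd[tid] = d1
                if not trial_last and rng.random() < cfg.p_refix:
                    d2 = _dur(tid, cfg.refix_scale)
                    _emit(tid, d2)
                    if not edge:
                        rfd[tid] = rfd.get(tid, 0) + d2
                # regressions launch only from fixated interior tokens, so a
                # retained fixation always separates the target's first pass
                # from the re-visit
                if (not trial_last and not edge and fixated_interior
                        and rng.random() < cfg.p_regress):
                    back = int(rng.choice(fixated_interior))
                    d3 = _dur(back, cfg.regress_scale)
                    _emit(back, d3)
                    rrd[back] = rrd.get(back, 0) + d3
                if not edge:
                    fixated_interior.append(tid)
            groups[(pid, trial)] = recs
            for tid in range(tok_lo, tok_hi):
                if text.is_line_edge(tid):
                    continue
                comp_rows.append(
                    (pid, trial, tid, ffd.get(tid, 0), rfd.get(tid, 0), rrd.get(tid, 0))
                )

    annotate_stream(groups)
    truth = GroundTruth(
        beta=dict(beta),
        sd_participant=cfg.sd_participant,
        sd_word=cfg.sd_word,
        sd_resid=cfg.sd_resid,
        u_participant=u_part,
        u_word=u_word,
        covariates=Z,
        eta=pd.DataFrame(eta_rows, columns=["participant_id", "token_id", "eta"]),
        components=pd.DataFrame(
            comp_rows, columns=["participant_id", "trial_id", "token_id", "FFD", "RFD", "RRD"]
        ),
        measurable_tokens=measurable,
    )
    return groups, truth


# ---------------------------------------------------------------------------
# direct feature-level simulation (for estimator calibration studies)
# ---------------------------------------------------------------------------

def simulate_lmm_dataset(
    n_participants: int = 60,
    n_words: int = 400,
    beta: dict | None = None,
    sd_participant: float = 50.0,
    sd_word: float = 30.0,
    sd_resid: float = 80.0,
    rng: np.random.Generator | int | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Fully crossed participants x words dataset on the ms scale.

    DV = intercept + X beta + u_participant + u_word + e with standardized
    covariates mimicking the modelling dataset's columns (freq, surprisal,
    the four similarities, ability). Used for parameter-recovery and type-I
    calibration of the mixed model, where the generative model is exactly the
    fitted one.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if beta is None:
        beta = {name: 0.0 for name in FIXED_EFFECTS}
    full = {"intercept": 250.0, **{name: 0.0 for name in FIXED_EFFECTS}}
    full.update(beta)

    # word-level covariates (standardized); the four similarities correlate
    # through a shared sentence-level component, as in real text
    base = rng.standard_normal(n_words)
    cov = {
        "freq": rng.standard_normal(n_words),
        "surprisal": rng.standard_normal(n_words),
        "word_sent": 0.6 * base + 0.8 * rng.standard_normal(n_words),
        "sent_sent": 0.6 * base + 0.8 * rng.standard_normal(n_words),
        "sent_para": 0.6 * base + 0.8 * rng.standard_normal(n_words),
        "para_para": 0.6 * base + 0.8 * rng.standard_normal(n_words),
    }
    cov = {k: (v - v.mean()) / v.std(ddof=1) for k, v in cov.items()}
    ability_lvls = np.array([-1.0, 0.0, 1.0])[
        rng.integers(0, 3, size=n_participants)
    ]
    ability = (ability_lvls - ability_lvls.mean())
    sd_a = ability.std(ddof=1)
    ability = ability / sd_a if sd_a > 0 else ability

    p_idx = np.repeat(np.arange(n_participants), n_words)
    w_idx = np.tile(np.arange(n_words), n_participants)
    u_p = rng.normal(0.0, sd_participant, n_participants)
    u_w = rng.normal(0.0, sd_word, n_words)
    dv = np.full(p_idx.size, full["intercept"])
    for name in FIXED_EFFECTS:
        if name == "ability":
            dv += full[name] * ability[p_idx]
        else:
            dv += full[name] * cov[name][w_idx]
    dv += u_p[p_idx] + u_w[w_idx] + rng.normal(0.0, sd_resid, p_idx.size)

    df = pd.DataFrame(
        {
            "participant_id": [f"p{i:03d}" for i in p_idx],
            "token_id": w_idx,
            "FFD": dv,
            "ability": ability[p_idx],
            **{name: cov[name][w_idx] for name in cov},
        }
    )
    truth = {"beta": full, "sd_participant": sd_participant, "sd_word": sd_word,
             "sd_resid": sd_resid}
    return df, truth


# ---------------------------------------------------------------------------
# full dataset emission
# ---------------------------------------------------------------------------

def generate_dataset(cfg: GeneratorConfig, out_dir) -> dict[str, Path]:
    """Generate and write the five study input files plus the ground truth.

    Returns the mapping of logical names to paths: text, ngrams, embeddings,
    participants, fixations, ground_truth.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    text = generate_text(cfg, rng)
    table = generate_ngram_counts([t.surface for t in text.tokens])
    emb = generate_embeddings(text, cfg, np.random.default_rng(cfg.seed + 1))
    participants = generate_participants(cfg)
    covs = token_covariates(text, table, emb)
    groups, truth = generate_scanpaths(
        text, covs, participants, cfg, np.random.default_rng(cfg.seed + 2)
    )
    paths = {
        "text": out / "text.tsv",
        "ngrams": out / "ngrams.tsv",
        "embeddings": out / "embeddings.txt",
        "participants": out / "participants.tsv",
        "fixations": out / "fixations.tsv",
        "ground_truth": out / "ground_truth.json",
    }
    text.write(paths["text"])
    table.write(paths["ngrams"])
    emb.write(paths["embeddings"])
    participants.to_csv(paths["participants"], sep="\t", index=False)
    write_fixations(groups, paths["fixations"])
    truth.write(paths["ground_truth"])
    return paths
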