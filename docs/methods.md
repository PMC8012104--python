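# Methods

This note documents the models, the numerical choices, and what the
synthetic-data generator does and does not emulate.

## Viewing-time decomposition

A trial's scanpath is a sequence of fixations, each mapped to the word whose
character span on its display line strictly contains the landing position.
Landings exactly on a span edge are unassignable — a boundary between two
words cannot be attributed to either — and are excluded rather than guessed.

The decomposition replays the retained scanpath once. A word's *first pass*
is the maximal run of consecutive retained fixations on it that begins with
its first arrival from an earlier word (forward saccade). FFD is that run's
first fixation, RFD the rest of the run, and RRD everything else on the word.
Two cases the definitions leave open are resolved as follows:

- **Regressive first entry.** A word whose first fixation arrives from a
  *later* word never acquires a first pass: FFD = RFD = 0 and all its viewing
  time is RRD. This keeps the "incoming forward saccade" part of the FFD
  definition literal; re-visits following such an entry also accrue to RRD.
- **Runs interrupted by removed fixations.** Runs are defined on the retained
  stream, so a first-pass run bridges fixations that the filter removed
  between its members (e.g. a blink on the same word).

Because every retained fixation lands in exactly one bucket, FFD + RFD + RRD
equals the summed retained durations per trial exactly (integer
milliseconds), and GD = FFD + RFD by construction. Words with no retained
fixation are emitted with zero components and a `skipped` flag and never
enter modelling datasets (a zero is an absent observation, not a duration).

## Fixation filtering

Exclusion rules are applied per fixation in a fixed precedence so that the
report is deterministic: blink → trial first/last fixation → line-switch
fixation (display line differs from the previous fixation's) → duration
bounds → first/last word of the display line → boundary/off-text landings.
Duration bounds are strict: exactly 80 ms or 800 ms is retained. The report
partitions the input (`n_input = n_retained + Σ exclusions`, each fixation
under its first matching reason).

The trial-edge and line-switch rules refer to a fixation's *neighbours in the
raw recording*, not to whatever stream happens to be passed in. These
stream-structure facts (trial-first/last flags, previous fixation's line) are
therefore annotated once, when a raw stream is first loaded or grouped, and
the filter evaluates pure per-record predicates thereafter. This makes
re-filtering already-filtered data a no-op, which is the behaviour a
deterministic pipeline needs when stages are re-run.

## Frequency and surprisal

Both are in natural-log units (nats). Word frequency is
`ln(count(w)/total_unigrams)`; unseen words get the floor
`ln(1/(total + V + 1))` (V = vocabulary size), which is strictly below any
seen word's value, keeping frequency increasing in count.

Surprisal is `-ln P(w | context)` with `P = count(context+w)/count(context)`,
estimated at the highest order (trigram, then bigram) at which both the
context and the full n-gram have positive counts; otherwise it falls back to
the (floored) unigram. Backing off when the *n-gram* is unseen — not only
when the context is — is what guarantees a finite value for every query, in
the spirit of stupid backoff (order reduction without interpolation
weights). Consequences worth knowing:

- surprisal is always finite and ≥ 0, and for a seen word with empty context
  equals minus its log frequency;
- monotonicity in the n-gram count holds *within* a resolved order; raising a
  trigram count from zero to one can jump the estimate across orders (a known
  discontinuity of count-threshold backoff);
- conditioning contexts never cross sentence boundaries: sentence-initial
  words are scored with a shorter (or empty) context. The count table itself
  may count n-grams across boundaries; only the conditioning is truncated.

## Similarity measures

Cosine similarity of unit-keyed embeddings (any dimension; 128 by default in
the generator, matching common sentence encoders). Per token: word vs. its
sentence; sentence vs. the preceding sentence *in document order* (a
paragraph-initial sentence is compared with the last sentence of the previous
paragraph — chosen so the measure is defined for every non-initial sentence);
sentence vs. its paragraph; paragraph vs. the preceding paragraph. The
document-initial sentence and first paragraph have no predecessor; those
values are emitted as missing and the affected rows are dropped from
modelling datasets rather than imputed. Sentence- and paragraph-level values
are constant across a sentence's tokens by construction.

## Mixed model

Each viewing-time component (raw ms) is regressed on seven fixed effects
(log frequency, surprisal, the four similarities, reading ability coded
−1/0/+1 for poor/average/good; optional ability × similarity interactions)
with crossed random intercepts for participant and word. Estimation is REML,
profiled over the residual variance and fixed effects, leaving a 2-d
optimisation over the variance ratios γ_p, γ_w. All linear algebra runs
through the q × q system M = Z′Z + G⁻¹ (q = participants + words) via
V⁻¹ = I − Z M⁻¹ Z′ and log|V| = log|M| + log|G|, so a fit costs a few
Cholesky factorisations of a small matrix regardless of the number of
observations — the property that makes the replicated calibration studies
(hundreds of fits at 24,000 observations) affordable. The implementation is
cross-checked in the test suite against statsmodels' `MixedLM`
one-group variance-component formulation on a small fixture.

Numerical choices: the optimiser is Nelder-Mead on log-ratios (restarted from
two fallback points if the first start fails); ratios are clamped to
`[e^-20, e^15]` and a fit touching either bound is flagged `singular` (with a
warning) rather than raised, since boundary variance estimates are a routine
outcome in small cells. Wald t-statistics use residual degrees of freedom
n − p; the results object records `df_method = "residual"`. At the scales the
package targets this is indistinguishable from more elaborate df corrections,
and the type-I calibration is verified by simulation (rejection rate ≈ 5%,
checked to lie in [2%, 9%] over 500 null replicates). With the variance
components at the lower bound the fixed estimates reduce to OLS (tested to
1e-6 relative). No multiple-testing correction is applied anywhere; tables
report raw p-values and say so by omission — consumers applying corrections
should do so per family of interest.

## Path analysis

A recursive system over observed variables ordered coarse-to-fine:
para_para → sent_para → sent_sent → word_sent → DV, with frequency and
surprisal exogenous in every equation. The ordering follows the hierarchy of
the measures (paragraph-level context is causally prior to sentence- and
word-level similarity from the reader's perspective). Each endogenous
variable is regressed by OLS on all predecessors; variables are z-scored
first so coefficients are standardized and comparable across measures
(ddof = 1; constant columns are a rank error, as is any exact collinearity,
reported with the offending equation). Writing the system as x = Bx + e with
B strictly lower-triangular, total effects are (I − B)⁻¹ − I, the direct
effect on the DV is its equation coefficient, and the indirect effect is the
difference — identical to the sum over all multi-edge directed paths of
coefficient products (an enumeration helper exposes the per-path terms).
total = direct + indirect therefore holds to machine precision, and the
single-equation case reproduces OLS exactly. Per-equation SEs and p-values
are classical OLS ones; the refixation component is excluded from path
analysis throughout the reporting grid (sparse observations make its
equations unstable), mirroring standard practice for this measure.

## Synthetic-data generator

The generator's defaults describe a small developmental reading study: 2
grades × 3 ability groups × 10 participants (60 total), a document of 12
paragraphs × 6 sentences × 6 words from a 500-word Zipf(1.1) vocabulary of
1–5-character words, wrapped onto 20-character display lines without
inter-word spaces (as in Chinese text), embeddings of dimension 128.

- **Embeddings** form a topic hierarchy on the unit sphere: paragraph vectors
  drawn near a topic vector, sentence vectors near their paragraph, word
  vectors near their sentence, with `unit(κ·parent + z)` perturbations
  (z standard normal). κ = ∞ reproduces the parent exactly; κ = 0 gives
  independent directions with near-zero expected cosine at dimension 128.
  Expected parent–child cosine is ≈ κ/√(κ² + d), so κ must dominate √d for
  strong similarity structure; the defaults (κ = 4) deliberately produce the
  moderate, noisy similarities real encoders give.
- **Scanpaths**: each paragraph is a trial read left-to-right; interior words
  are skipped with probability 0.10; the latent log-duration linear predictor
  η = β′x + u_participant + u_word (x the z-scored covariates) drives a
  lognormal first fixation, rounded to integer ms and clipped to [81, 799] so
  informative fixations always survive the duration filter; refixations occur
  with probability 0.25 and within-line regressions with probability 0.15.
  Default effect sizes are a few percent of duration per covariate SD with
  random-effect SDs (0.08, 0.05) and residual SD 0.15 on the log scale —
  magnitudes in line with developmental reading-time data.
- **Contaminants** (blinks, sub-80 ms and over-800 ms durations,
  exact-boundary landings) are opt-in extra fixations inserted at
  configurable rates, so the filter removes exactly them and, at rate zero,
  the pipeline's output equals the recorded ground truth *exactly* for every
  line-interior token (verified per-cell in the tests).

Deliberate simplifications, and what they mean for the tests: line-edge
words are always fixated and regressions stay within a display line, so the
structural exclusions (trial edges, line-first/last words, line switches)
never touch interior tokens — this is what makes exact round-trip recovery a
well-defined property. The generator makes no attempt at oculomotor realism
(no landing-position distributions, no parafoveal preview, no saccade-length
model); passing tests certify the *pipeline algebra and estimators*, not any
claim about human reading. Likewise the scanpath generator's β lives on the
log-duration scale (durations are positive and right-skewed), while the
estimator-calibration studies use a separate feature-level generator
(`simulate_lmm_dataset`) that is additive-Gaussian on the ms scale — there
the generating model is exactly the fitted one, which is the correct design
for coverage and type-I checks. Calibration study sizes: 60 participants ×
400 fully crossed words, 100 recovery replicates (coverage of ±2 SE
intervals, nominal 95%, required ≥ 90% per term) and 500 null replicates
(per-term rejection at |t| ≥ 1.96 required within [2%, 9%]).

## Determinism and provenance

Every stage is deterministic under (seed, config): reruns produce
byte-identical input files, measures, and report bundles. `run_pipeline`
writes a manifest with the seed, a config hash, SHA-256 digests of the five
input files and per-stage row counts; the manifest's timestamp is the single
non-reproducible field and lives only there. Effect plots are derived
artifacts of a report and are never read back into any statistic.

## Known limitations

- The mapping of fixations to words is 1-D (character units on a line);
  there is no pixel geometry, calibration drift handling, or vertical error
  correction.
- Surprisal requires an externally supplied count table; the package never
  builds web-scale counts, and smoothing is the minimal floor described
  above, not Kneser-Ney.
- Embeddings are consumed, never trained; similarity quality inherits
  whatever encoder produced the file.
- The path model is a recursive system over observed variables (no latent
  factors, no covariance-based SEM estimator); with a single fixed ordering,
  alternative orderings are the user's responsibility to justify.
- Residual-df p-values are anti-conservative in principle for small
  participant samples; the simulation calibration above bounds the effect at
  the package's target scales.
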