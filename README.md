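# fixread

Viewing-time decomposition and predictability/similarity modelling of reading
eye movements.

`fixread` is for researchers analysing eye-tracking reading corpora — in
particular developmental studies of connected-text reading — who want to link
how long readers look at each word to (a) the word's local predictability and
(b) the semantic cohesion of the text around it.

## What it computes

**Viewing-time components.** The total time a reader spends on a word is
split additively into three components:

- **FFD** (first fixation duration): the first fixation of the word's first
  pass, where the first pass begins with the word's first arrival from an
  earlier word (a forward saccade);
- **RFD** (refixation duration): the remaining first-pass fixations before
  the eyes leave the word;
- **RRD** (re-reading duration): all later fixations on the word
  (regressions in and re-visits). Gaze duration GD = FFD + RFD, and
  FFD + RFD + RRD conserves the retained fixation time exactly.

Raw fixation logs are filtered first (blinks, trial-edge fixations,
line-switch fixations, durations < 80 ms or > 800 ms, first/last words of a
display line, landings exactly on word boundaries), with a report that
partitions every input fixation into retained-or-one-reason.

**Word predictability.** Per-word surprisal in nats from a Google-style
n-gram count table,

    s(w_i) = -ln P(w_i | w_{i-2} w_{i-1}),   P = count(context + w) / count(context),

with trigram → bigram → smoothed-unigram backoff and contexts truncated at
sentence boundaries, plus log relative word frequency.

**Multi-scale similarity.** Four cosine similarities from an embedding file
(word2vec text format): word–sentence, sentence–preceding sentence,
sentence–paragraph, paragraph–preceding paragraph.

**Inference.** Each component is modelled with a linear mixed model with
crossed random intercepts for participant and word,

    DV ~ freq + surprisal + word_sent + sent_sent + sent_para + para_para
         + ability,   (1 | participant) + (1 | word)

fitted by REML (`CrossedLMM(...).fit()` returns a results object with
estimates, SEs, t/p values, variance components and `summary()`). The
interdependence of the similarity measures is unpacked with a recursive path
analysis ordered coarse-to-fine (`para_para → sent_para → sent_sent →
word_sent → DV`, frequency and surprisal exogenous in every equation), giving
standardized direct, indirect (product-of-paths) and total effects with
`total = direct + indirect` holding identically.

**Synthetic study generator.** Because raw eye-tracking corpora are rarely
shareable, the package includes a generator that emits the five study inputs
(token table, n-gram counts, embeddings, participant table, fixation logs)
with known injected effect structure and a recorded ground truth, so the
whole pipeline is testable end to end: with contaminant rates at zero the
gaze pipeline recovers the generated components *exactly*.

## Worked example

```python
from fixread import GeneratorConfig, run_pipeline
import json

cfg = GeneratorConfig(seed=42, n_per_group=4, n_paragraphs=8)
out = run_pipeline(cfg, "demo_run")     # writes inputs, measures, report.json
report = json.load(open(out / "report.json"))
ffd = report["lmm"]["FFD"]["overall"]["result"]
```

The overall FFD mixed model on this synthetic study (24 participants, 8
paragraphs, 3,602 modelled word viewings) prints:

```
term          estimate       SE       t        p
Intercept      233.550    7.696   30.35  2.7e-180
freq            -5.327    0.713   -7.47   9.8e-14
surprisal        7.087    0.780    9.08   1.7e-19
word_sent      -25.939   12.148   -2.14    0.033
sent_sent      -92.500   12.594   -7.34   2.5e-13
sent_para      -57.928   18.921   -3.06    0.0022
para_para      -47.805   16.869   -2.83    0.0046
ability        -12.767    3.343   -3.82   0.00014
variance components: participant 171.2, word 133.1, residual 1135.6
```

Higher frequency, higher text similarity and higher reading ability shorten
first fixations; higher surprisal lengthens them — the directions injected by
the generator. The matching path analysis decomposes each similarity
measure's standardized influence on FFD, e.g.

```
source       direct    indirect   total
para_para   -0.0726    -0.0307   -0.1034
sent_para   -0.0811    -0.0580   -0.1390
sent_sent   -0.1937    -0.0077   -0.2013
```

so roughly a third of the paragraph-level effect on FFD is mediated through
finer-grained similarity. The same grid runs per grade and per ability group
(`report["lmm"][dv]["grade4"]`, `report["path"][dv]["good"]`, ...), and
`fixread.plots.plot_effects` draws partial-effect plots with participant and
word random intercepts removed.

A command-line interface mirrors the stages:

```bash
fixread all --seed 42 --out-dir demo_run          # end to end
fixread generate|features|gaze|fit ...            # stagewise
```

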