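# Methods

## Problem and decomposition

`belex` extracts causal BEL statements — `p(HGNC:AKAP11) decreases
act(p(HGNC:PPP1CC))` — from single sentences with known, typed entity
mentions.  The task is decomposed into two independent classification
subtasks plus a merging step:

1. **Relation extraction (RE).**  Every unordered pair of entity mentions in
   a sentence is a candidate (a sentence with *n* mentions yields
   *n*(*n*−1)/2 instances).  A classifier assigns each pair `none`,
   `increases` or `decreases`.
2. **Function detection (FD).**  Each entity participating in a predicted
   relation may carry one unary function (`act`, `deg`, `pmod`, `sec`) or
   none.  A second classifier predicts the function from a context window of
   at most 15 tokens centered on the entity.
3. **Merging.**  Each positive relation becomes a statement; each argument
   is wrapped by its predicted function, unless the function prediction was
   filtered out (below).

Nested relations and the multi-argument `complex()` function are out of
scope: `complex()` parses (so corpora containing it load), but it is never a
function-detection target and never generated.

## Preprocessing

Entity mentions are anonymized to typed placeholders (`GENE_1`, `CHEM_1`,
`DIS_1`, `BP_1`), numbered per class left to right.  This removes surface-
name variability; a per-sentence placeholder table restores
`namespace:identifier` pairs at merge time.  Tokenization is whitespace
splitting followed by stripping leading/trailing punctuation; this
convention reproduces the worked position-feature example (distance of
"inhibitor" to "AKAP220" = 5, to "PP1c" = −2) and is used everywhere.

When mention spans are not given, `align_identifiers` performs a dictionary
search: each identifier is aligned to the contiguous token run (length 1–5)
minimizing normalized Levenshtein distance to any lexicon synonym, subject
to a cutoff (default 0.3, i.e. at most ~a third of the longer string
edited), with greedy best-score-first assignment and non-overlapping spans.
Identifiers with no span under the cutoff are reported unaligned and the
caller decides whether to drop their statements.

## Model

Both classifiers share one architecture, an attention-based bidirectional
LSTM:

* **Embedding layer.**  Token *i* is represented as the concatenation of a
  trainable word vector (dimension *d_w*) with one (FD) or two (RE)
  trainable position vectors (dimension *d_p*) indexed by the signed
  distance *i* − *e* to the marked entity position(s), clipped to ±50.
  Clipping bounds the position vocabulary; sentences rarely approach 50
  tokens of separation, so the bound is not binding in practice.
* **BiLSTM layer.**  Standard LSTM recurrences run in both directions; the
  directional states are combined by element-wise sum, h_t = h⃗_t ⊕ h⃖_t,
  so the combined state keeps the LSTM width.
* **Attention layer.**  ε_i = w_a·tanh(h_i), α = softmax(ε),
  r = Σ_i α_i h_i.  The attention vector w_a has the LSTM width.  (A
  plausible alternative ties the attention dimension to *d_w*; that is
  inconsistent with element-wise-summed states of width `lstm_units`, so the
  LSTM width is used.)
* **Output layer.**  h\* = tanh(r); p(y|s) = softmax(W h\* + b).

Training minimizes the mean negative log-likelihood of the gold labels plus
λ‖θ‖² over **all** parameters (embeddings included; word vectors are
randomly initialized and adjusted during training, not pre-trained), with
Adam.  Reference hyperparameters: *d_w* = 200, *d_p* = 64, 600 LSTM units,
learning rate 10⁻³, λ = 10⁻⁴.  Epochs (30), batch size (32) and seed are
configurable; no early stopping or re-sampling of the imbalanced classes is
applied.

Implementation notes: the forward pass and backpropagation are written
directly in NumPy (float64).  Batches are padded to the batch maximum;
padded positions are masked out of both recurrences (state reset to zero)
and receive −∞ attention scores, so padding can never receive weight — a
padded forward pass is bit-comparable to an unpadded one, and the batched
encoder is tested against an unbatched straight-line transcription of the
equations.  Gradients are verified against central differences.  Training
is deterministic given the seed (instance shuffling and initialization both
derive from it); instances are length-sorted before shuffling so padding
work is stable.  Forget-gate biases initialize at 1, weights
Glorot-uniform, embeddings uniform ±0.1.

### Argument order

A BEL statement is ordered, but a mention pair is not.  The RE label set is
therefore extended internally to directional labels (`increases>`,
`increases<`, `decreases>`, `decreases<`, `none`), where `>` marks the
left-hand mention as subject.  Externally labels collapse to the two
canonical relations plus a subject-first flag.  This is a design extension:
order must be predicted somehow, and folding it into the label space lets
one classifier learn it jointly with the relation type.

### Threshold filtering

FD precision, not recall, limits statement quality: a wrong function wrapper
spoils an otherwise correct statement.  Before merging, any FD prediction
whose top-class probability is **strictly below** a threshold τ is relabeled
`none` (ties at exactly τ are kept).  τ = 0 is naive merging; τ = 1 keeps
only relations.  The retained-function set shrinks monotonically in τ, so
FD recall is non-increasing in τ.  The default τ = 0.8 favors precision;
`sweep_tau` re-scores cached unfiltered predictions over a τ grid to pick
the value empirically on held-out data.

## Canonicalization

Scoring and training both operate on a canonical label space:
`directlyIncreases`/`directlyDecreases` fold into
`increases`/`decreases`, and activity-family functions (`kin`, `tscript`,
`cat`, `phos`, `pep`, `gtp`, `ribo`, `tport`, `chap`) fold into `act`.  The
activity-family set is configurable; the default covers the common OpenBEL
1.0 activity functions.  Whether `tloc` belongs in the FD label set is
genuinely open; the label set is configuration, defaulting to
`{none, act, deg, pmod, sec}`.

## Evaluation

Six micro-averaged P/R/F1 levels, from coarse to strict, computed per
sentence on canonicalized statements and pooled over the corpus:

| level | unit | match rule |
|---|---|---|
| T | bare term `ns:id` (2 per statement) | equality |
| FS | (function, term), function ≠ none | term equality (function free) |
| Fun | (function, term), function ≠ none | full equality |
| RS | (subject, relation, object), functions stripped | ≥ 2 of 3 components |
| Rel | same triple | full equality (order matters) |
| Stat | full canonical statement | full equality |

Units are matched one-to-one within each sentence.  Exact levels use
multiset intersection, which is already optimal.  For the partial levels
(FS, RS) a greedy matching can be suboptimal — a pairing chosen early can
block two later pairings — so a maximum bipartite matching
(`scipy.optimize.linear_sum_assignment`) is used, with a tie-break
preferring fully equal pairs; the reported counts are therefore the best
achievable pairing, and the scorer is tested against exhaustive assignment
enumeration.  Each match rule lives in one predicate function so an
alternative scorer convention can be swapped in.  Functions are scored
within emitted statements (the entity-level alternative — scoring FD
predictions regardless of whether their relation was found — is noted but
not used).  Empty-denominator conventions: precision, recall and F1 are 0.

By construction Stat-tp ≤ Rel-tp ≤ RS-tp: strictly coarser matching.

## Synthetic corpus generator

The generator makes the pipeline trainable and testable without a curated
corpus.  Each sentence draws 2–5 entities (default mix 45/30/15/10 %),
mostly gene/protein (85 %, with bioprocess 9 %, chemical 4 %, disease 2 %).
Entities are shuffled and paired disjointly; each pair is related with
probability 0.75.  A related pair renders as an active clause
(`GP12 elevates GP13`) or a passive one (`GP13 is elevated by GP12`) —
passive voice reverses argument order, so both directional labels occur.
Relation cue words come from disjoint per-label lexicons (defaults:
increases 72 %, decreases 28 %).  Entity functions are drawn with
`none` = 58 % and act:pmod:deg:sec ≈ 65:19:8:8 among the rest (so ~42 % of
statement arguments carry a function, ~65 % of functions are `act`); each
non-none function places a cue word within three tokens of its entity
(`degradation of GP12`, `GP12 phosphorylation`), always inside the 15-token
FD window.  Identifiers live in a synthetic `SYN` namespace with integer
identifiers — no real gene symbols are implied — and the emitted lexicon
(surface + lowercase variant per identifier) doubles as dictionary-search
input.

With `cue_noise = 0` the cue→label map is deterministic and in-window, so
the Bayes error of both subtasks is zero: a correct implementation must be
able to reach near-perfect accuracy, which is what the parameter-recovery
tests assert (micro-F1 ≥ 0.95 at word dim 32, 64 LSTM units, 15 epochs,
1000 training sentences, three seeds).  `cue_noise > 0` replaces cue words
by distractors to study degradation.

What the generator does **not** emulate: real biomedical syntax (anaphora,
coordination, long-distance dependencies), entities shared across multiple
statements in one sentence, nested relations, `complex()`, or functions
inferable only from domain knowledge.  Passing tests on synthetic data show
the machinery is correct and learnable signal is recovered; they do not
predict corpus-level accuracy on curated data, where all of these
difficulties apply at once.

## Numerical and degenerate-input choices

* Attention over a single token is exactly [1.0]; empty sequences are
  rejected.
* Probabilities are clipped by +1e-12 inside the log only.
* One-class training data is rejected (no decision boundary to learn).
* Duplicate FD training instances (an entity in several statements) are
  kept — the instance count is exactly 2*m* for *m* positive relations.
* Conflicting gold relation labels for one pair keep the first statement in
  corpus order and warn.
* Merged statements are deduplicated after canonicalization, per sentence,
  preserving first-occurrence order.

## Known limitations

* The FD training set contains only statement participants; corpora whose
  negative function instances include non-participating entities will have
  a different negative/positive ratio than this rule produces.
* The NumPy trainer is single-threaded BLAS-bound; the reference-size
  configuration (600 units) trains slowly compared to a GPU framework —
  the architecture is faithful, the throughput is not.
* Dictionary search is surface-based; it inherits the usual edit-distance
  misalignment failure modes on short or generic names.
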