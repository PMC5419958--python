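# Methods

## Task and model

The tagger locates gene/protein mentions as contiguous token spans using
per-token B/I/O labels. The core model is a second-order linear-chain CRF:
the score of a labeling `y` of a sentence with per-token feature sets
`x_1..x_n` is

```
score(y | x) = Σ_i Σ_{f ∈ x_i} W[f, y_i]  +  Σ_{i≥1} T[y_{i−2}, y_{i−1}, y_i]
P(y | x)     = exp(score(y|x) − log Z(x))
```

with `y_{−1} = START` at the second position. Transition parameters are
label trigrams only (they are not conditioned on token features); all
lexical information enters through the state weights `W`. Position 0
carries state features only, so a single-token sentence is scored purely
by its state features and its log-partition is the log-sum-exp of the
three state scores. Inference (Viterbi, partition function, marginals)
runs on the lattice of (previous label, current label) pairs; Viterbi ties
break by the fixed label order B < I < O so decoding is reproducible.

Training maximizes the conditional log-likelihood minus `c2 · ‖θ‖²`
(default `c2 = 1.0`) with batch L-BFGS; gradients come from
forward–backward over the pair lattice. The optimizer is an implementation
detail — the contract is the objective — and training is deterministic
given the data order and hyperparameters. The implementation was checked
against brute-force enumeration (Viterbi and log-partition on all `3^n`
sequences, `n ≤ 5`) and against numerical differentiation of the
objective.

## Directional models and combination

The backward model is trained on reversed token sequences. Reversal
re-encodes the labels (each mention's first token in the new reading order
takes B) because verbatim-reversed labels would violate the B/I/O grammar,
and mirrors the positional prefixes of conjunction features
(`@-k:` ↔ `@+k:`).

Combination modes:

* **union / intersection** of the two directional mention sets —
  union trades precision for recall, intersection the reverse;
* **mira**: the backward weights are mapped into forward orientation —
  state features keep their (feature, label) weight under the mirrored
  identifier; a transition trigram `(a,b,c)` maps to `(c,b,a)`. Trigrams
  whose two-back context is START describe the start of the reversed
  order, i.e. the *end* of the forward order, which the forward
  parameterization does not model; they are dropped during mapping. The
  mapped and forward weights are summed over the union feature space, then
  1-best MIRA refines the vector: for each training sentence in corpus
  order, if Viterbi under the current weights reproduces the gold labels
  nothing happens; otherwise

  ```
  τ = max(0, [L(y, ŷ) − (score(x,y) − score(x,ŷ))] / ‖Φ(x,y) − Φ(x,ŷ)‖²)
  ω ← ω + τ · (Φ(x,y) − Φ(x,ŷ))
  ```

  with `L` the Hamming label loss and `Φ` the sentence-level
  feature-context count vector. After an update with `τ > 0` the gold
  labeling outscores the decoded one by exactly its loss. Defaults: 5
  epochs, corpus order, no shuffling, no weight averaging (the final
  vector is the last iterate). The loss is token-level Hamming rather than
  mention-level error count; with exact-match decoding as the no-update
  test this is the minimal consistent reading of a margin "at least as
  large as the number of errors".

## Features

Exactly 32 basic feature types are registered. The registry names only
exemplify classes of surfaces, so the predicate definitions are fixed
here: INITCAPS = first character uppercase and the remaining alphabetic
characters not all uppercase; ALLCAPS = all alphabetic characters
uppercase, length ≥ 2; ENDCAPS = terminal uppercase run preceded by a
lowercase letter; UPPER-LOWER = uppercase initial followed by all-lowercase
letters; TWOCAPS / THREECAPS / MORECAPS = exactly 2 / exactly 3 / ≥ 4
uppercase letters; MIXEDCAPS = a lowercase letter immediately followed by
an uppercase one (`EcoRI`); LOWERCASE = all-alphabetic lowercase;
NUMBERS_LETTERS = letter/digit mix whose letters are all uppercase (`UR2`);
GREEK / ROMAN = the whole surface is a Greek-letter word / Roman numeral;
HASGREEK / HASROMAN = a hyphen- or space-delimited part is one;
PUNCTUATION = entirely punctuation. Predicates are pure functions of the
surface and are not mutually exclusive (`p53` fires ALPHANUMERIC, HASDIGIT
and ENDDIGIT together). Affix features carry values (`3PREFIX=fib`).

Character N-grams use a sliding window of 4: every contiguous 4-character
substring, the whole surface for shorter tokens (so a token of length
n ≥ 4 yields exactly n − 3 distinct windows, fewer when windows repeat).
The window reading of the sliding-window description was chosen over a
prefixes-of-length-1..4 reading; the latter is available as
`ngram_mode="prefix"`. N-grams are suppressed for single-character and
pure-punctuation tokens as noise control. Offset conjunctions copy the
basic features of tokens at relative positions −2, −1, +1, +2 with
positional prefixes; out-of-range offsets contribute an `EDGE` marker, so
sentence boundaries are visible to the model.

The corpus-frequency feature counts how often each mention surface occurs
in the training annotations (full surface, case-sensitive) and fires
`CORPUS_FREQ` for noun tokens whose surface count lies in `[1, θ_freq]`
(default θ_freq = 10). The band deliberately flags *rare* names — names
the lexical features have little evidence for — so they are tagged
consistently wherever they recur; the inverse band is available as a
config switch for experimentation. A `POS=<tag>` indicator from the
annotation backend is included by default.

PCA feature selection operates on the sentence × feature binary occurrence
matrix (sentence-level rather than token-level rows keeps the matrix small
and emphasizes cross-sentence co-occurrence): columns are mean-centered,
the covariance eigendecomposition is taken, each feature is scored by its
maximum absolute loading over the first L components, and the top K
features are retained *as original sparse indicators*. Selection — not
projection — is used because CRF training needs sparse indicator features.
Selection is off by default (no L/K values are prescribed); it is wired
into the pipeline via `pca_components` / `pca_keep`.

## Preprocessing

Tokenization splits on whitespace, then isolates brackets, commas,
periods, double quotes, slashes and hyphens as single-character tokens.
Exceptions: alphanumeric slash compounds (`P42/44`) stay whole, a period
between digits stays (decimals), apostrophes stay attached (`C'`).
Hyphenated names (`HNF-3`) therefore span three tokens and mentions may
cover several tokens. Tokens carry dual offsets: raw character (half-open)
and non-space character (inclusive), the latter being the corpus
annotation coordinate system; the non-space map is a bijection onto
non-whitespace positions.

POS/lemma/chunk annotation is a pluggable backend (token surfaces in,
equal-length tag lists out). The built-in default is a deliberately
simple suffix-rule tagger — closed-class lookup, verb suffixes, digits,
punctuation, noun otherwise, plural-stripping lemmas, a naive NP chunker.
It is approximate by design; its one load-bearing property is that
gene-like and unknown tokens default to noun, which the corpus-frequency
feature requires. Any real NLP toolchain can be slotted in through the
backend contract.

Sentence splitting cuts after `.`/`!`/`?` followed by whitespace and a
capital (or opening quote/parenthesis), with an abbreviation stop-list
(`e.g.`, `et al.`, `Fig.` …).

## Post-processing rules

Fixed order: contextual clues → parenthesis repair → abbreviation
propagation (→ optional disambiguation). Every rule is idempotent.

* **Contextual clues.** Two passes — connective words (`and`, `or`) first,
  then relation keywords. For each keyword occurrence the nearest
  non-punctuation neighbor on each side is looked up in the post-keyword
  list (mention surfaces seen ≥ 3 times in training); a hit labeled O
  becomes a single-token B. Existing labels are never removed, and only
  single tokens are added (no span growing). The keyword-neighbor reading
  is used for both passes; "previous/next word" is interpreted as one
  non-punctuation token. The shipped relation-keyword list is a seed
  (~50 interaction verbs/nominals); a full list can be supplied as a
  one-keyword-per-line file.
* **Parenthesis repair.** Brackets are matched within the sentence per
  type. A bracket inside a predicted mention whose partner is outside the
  same mention (or absent) is relabeled O; if it headed the mention the
  next token is promoted to B. Iterated to a fixpoint, after which no
  mention contains an unbalanced bracket. A pair fully inside one mention
  (`( BAT )`) is untouched.
* **Abbreviation handling.** Parenthesized candidates with ≤ 10 non-space
  characters and ≥ 1 letter are paired with a long form by the classical
  right-to-left character-matching test (every alphanumeric SF character
  in order, the SF's first character word-initial, search window
  min(|SF|+5, 2·|SF|) tokens); the constants are exposed as arguments.
  When exactly one member of a pair overlaps a mention, the other member's
  span is tagged B I…I; consistent pairs are untouched, and the rule never
  creates mentions from nothing. Disambiguation of ambiguous short forms
  (e.g. two expansions of `ACE`) ranks the senses of a user-supplied
  inventory by context-term overlap after stop-word removal, with a
  long-form-in-sentence override and ties resolved by inventory order.
  Concept-identifier/MeSH-based disambiguation is out of scope (licensed
  resources); the inventory file format is documented in the module.

## Evaluation

Exact span match on non-space offsets; no partial credit. With an
alternate-annotation set, a prediction matching any acceptable alternate
of a gold mention credits that mention; each gold mention is credited at
most once, so TP + FN = |gold| always, and TP + FP = |predictions| in the
alternate-free mode. P, R and F carry zero-denominator guards.

## Synthetic corpus

The generator emulates the corpus formats and the *shape* of the task:
gene surfaces drawn from a generated lexicon covering the orthographic
styles of real symbols (all-caps, letter+digit, mixed caps, Greek and
Roman compounds, trailing `+`/`-`/apostrophe, slash compounds, two-word
names), lowercase common-word filler, and templated sentences with
abbreviation constructs, parenthesized mentions, relation keywords and
connective coordinations (default mixture: 15% abbreviation, 20%
parenthesized, 30% relation, ~20% connective, remainder plain). Train/test
splits share 80% of gene surfaces by default; the held-out 20% are fresh,
so test scores reflect orthographic generalization rather than
memorization. Generation is a pure function of the config; identical
configs give byte-identical files.

What the toy language does **not** emulate: real sentence grammar,
annotation-boundary ambiguity (no alternate spans are generated), nested
or discontinuous mentions, vocabulary overlap between gene and common
words, and realistic n-gram statistics. A high F-score here shows the
pipeline is correct and learnable end to end, not that it would reach any
particular score on a real corpus — benchmark-scale evaluation requires
the external gene-mention corpus and is out of scope.

Default study sizes — 300 training sentences, 100 held-out sentences, a
200-surface lexicon — keep a full train/combine/tag/evaluate cycle within
a few minutes on one CPU while leaving every stage (both directional
models, MIRA, the rules) exercised.

## Numerical and design notes

* Log-space lattice computations use a large finite floor (−1e30) instead
  of −inf so invalid states never produce NaNs.
* Empty sentences decode to empty label sequences; `log Z` of an empty
  sentence is 0.
* Orphan I labels (I after O or at sentence start) are healed to B during
  decoding so that every label sequence — including rule-edited ones —
  decodes to mentions.
* Mention offsets are 0-based inclusive non-space indices, the corpus
  convention; whether they are inclusive or half-open is not derivable
  from the method description itself and was fixed from the corpus format.
* MIRA skips (with a warning) the degenerate case where gold and decoded
  labelings have identical feature vectors: the update direction is
  uninformative.
* Model files are JSON dumps of (direction, feature → three label
  weights, trigram → weight); round-tripping is bit-exact because floats
  serialize at full precision.
* Union/intersection at the label level resolve overlapping spans
  deterministically (longer span first, remaining overlaps dropped).

## Known limitations

* The default POS tagger is rule-based and approximate; corpus-frequency
  gating inherits its noun/verb mistakes.
* Second order only; no higher-order or semi-Markov variants.
* No nested or discontinuous mentions; one annotation per token.
* The relation-keyword seed list is small compared with operational lists;
  contextual-rule recall on real text depends on supplying a fuller list.
* Dictionary/lexicon membership features and word embeddings are
  deliberately absent from the feature set.
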