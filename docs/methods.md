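# Methods

This note documents the models, conventions and numerical choices behind
`corpus-fidelity`: what each metric measures, what the synthetic-note
generator does and does not emulate, and where the design was genuinely open.

## Text model and units

All metrics operate on `Document.normalized_text`: NFC-normalized Unicode
with Markdown syntax stripped (headings, emphasis, link/image syntax, fenced
code blocks; table rows become their cell texts). Stripping isolates
linguistic content from markup; `--no-strip` retains raw text for
sensitivity analysis. Encoding is fixed to UTF-8, and NFC normalization
guarantees that Dutch diacritics (`patiënt` composed vs decomposed) compare
stably. Stripping is applied repeatedly until a fixed point, which exists
because each pass can only shorten the text; this makes `strip_markdown`
idempotent on arbitrary input by construction.

Word tokens are lowercased maximal runs of letters (including diacritics)
and digits with internal hyphens/apostrophes retained — chosen for Dutch
clinical text with hyphenated compounds (`fysio-oefening`); no sentence
segmentation, lemmatization or stopword removal is performed. Character
sequences preserve case, whitespace and punctuation (a `lowercase_chars`
option folds case first). Bigrams never cross document boundaries: a
corpus-level bigram table is the sum of per-document tables, the
conservative choice when documents are independent notes.

## Information-theoretic metrics

All logarithms are base 2, so entropies are in bits and the Jensen–Shannon
divergence lies in [0, 1] (0 iff the distributions are equal, 1 iff their
supports are disjoint). Probabilities are empirical counts over the observed
support; absent tokens are absent, never zero-probability entries.

* **Shannon entropy** H = −Σ p log₂ p. Corpus ("pooled") entropy is computed
  on summed per-document count tables — *not* as a mean of per-document
  entropies; both quantities are reported separately because they answer
  different questions (corpus-level diversity vs typical document
  diversity).
* **Jensen–Shannon divergence** JSD = H(M) − ½[H(P) + H(Q)], M = (P+Q)/2
  over the union support. The default report carries the divergence; a
  `jsd_sqrt` option emits the metric distance √JSD instead. Per-document JSD
  is measured against the pooled word distribution of *both* corpora when
  comparing, and against the corpus's own pool when profiling a single
  corpus.
* **Average bigram PMI**: PMI(a,b) = log₂[(c(a,b)/N) / (p(a)p(b))] with N
  the number of bigram tokens; the reported value is the *unweighted mean
  over bigram types* with count ≥ min_freq (a token-weighted mean is
  available as an option). The frequency floor defaults to 3 at corpus level
  and 1 per document; documents with no qualifying bigram contribute
  "absent" and are excluded from per-document means, with the exclusion
  count echoed in the report configuration.

## Surface and semantic similarity

**Corpus BLEU** is implemented from its definition: clipped modified n-gram
precisions summed over candidates (each n-gram clipped at its maximum count
in any single reference), geometric mean over n = 1..4 with uniform weights,
and the closest-reference-length brevity penalty. The study design never
pairs specific synthetic notes to specific reference notes, so every
reference document serves as part of the multi-reference set for every
candidate (a `best_match` pairing is provided as an alternative — the
pairing changes the number and is always recorded). Zero precisions are
floored at ε = 1e-9 before the logarithm rather than smoothed
exponentially; with fully disjoint vocabularies the score is therefore near,
not exactly, zero.

**Greedy embedding matching** scores a candidate/reference token-list pair
by S[i][j] = cos(ref_i, cand_j): recall is the mean over reference tokens of
the row maximum, precision the mean over candidate tokens of the column
maximum, F1 their harmonic mean, no IDF weighting by default. The embedder
is a contract (unit-norm vector per token); the shipped default is a
deterministic seeded hash embedder — each distinct token maps to a fixed
isotropic-Gaussian unit vector keyed by a BLAKE2 hash — so the pipeline runs
offline and bit-reproducibly. This embedder is context-free: it measures
lexical overlap in embedding space, not meaning, and its absolute scores are
not comparable to those of a contextual transformer. Scores are labeled with
the embedder name and must never be mixed across embedders. Corpus
aggregation defaults to the mean over all document pairs (`all_pairs`);
`best_match` keeps, per synthetic document, the reference pair with maximal
F1.

## Machine discernibility

The discernibility test asks whether a simple classifier can tell the
corpora apart. Features are word-unigram TF-IDF vectors (raw term counts,
idf = ln((1+N)/(1+df)) + 1, L2-normalized rows — the scikit-learn
convention) concatenated with a z-scored log₁₀ character length. The
explicit length feature is essential: L2 normalization largely erases
length, yet unrealistic document length is precisely the kind of
document-level artifact that betrays synthetic corpora, so length-only and
TF-IDF-only ablations are always reported to make any length attribution
testable. The classifier is L2-regularized logistic regression (C = 1) —
linear, so its weights are interpretable — evaluated by stratified 5-fold
cross-validation with a fixed seed; out-of-fold probability scores are
pooled before computing ROC AUC and average-precision AUPRC with the
synthetic class as positive. Precision/recall/F1 use a 0.5 probability
threshold. With class sizes of 13 and 20, five stratified folds keep both
classes in every fold. AUC ≈ 0.5 means the corpora are statistically
indistinguishable to this model family; AUC = 1.0 means trivially separable.

## Statistical comparison

Per-document metric lists are compared with the Mann–Whitney U test,
reporting U of the first (reference) sample — so U = n₁·n₂ = 260 for 13
vs 20 documents signals complete dominance by the reference and U = 0
complete dominance by the synthetic corpus. p-values are two-sided: exact
(scipy's exact method) when the pooled samples are tie-free and n₁+n₂ ≤ 40,
otherwise the normal approximation with tie and continuity corrections. The
fully degenerate all-ties case returns p = 1 with the method flagged rather
than erroring. No multiple-testing correction is applied by default; a
Holm-adjusted column is opt-in, since the metric families are strongly
dependent and the report is descriptive.

## Synthetic-note generator

`generate_corpus` emulates the *statistical signature* of Dutch
physiotherapy notes, not their clinical content:

* **Vocabulary**: deterministic pseudo-Dutch words built from a fixed
  syllable inventory; a configurable fraction (default 0.3) carries one
  Dutch diacritic so character-level transforms have something to act on.
  Word *i* is sampled with probability ∝ i^(−s) (Zipf, default s = 1.1).
* **Document lengths**: target word counts are lognormal with mean
  `mean_doc_words` (default 2,000 words ≈ 13–14k characters, matching
  long-form clinical dossiers) and log-scale sd `sd_log_words`
  (default 0.3).
* **Structure**: a two-line fictive header (dossier number, date) and the
  four SOEP sections (Subjectief, Objectief, Evaluatie, Plan), each
  non-empty; sentences are 6–18 i.i.d. words.
* **Redundancy** (`redundancy_rate`): with this probability a sentence
  repeats one of the document's first five sentences. Repeating from a
  small boilerplate pool — rather than uniformly from all previous
  sentences — mirrors how real notes repeat standard phrases, and is what
  makes redundancy measurably depress pooled word entropy and inflate
  bigram PMI; uniform repetition merely rescales counts and leaves both
  nearly unchanged.
* **Collocations** (`collocation_rate`): bound word pairs from a dedicated
  lexicon outside the Zipf vocabulary, giving controllable high-PMI bigrams
  without disturbing the analytic entropy oracle.

`expected_word_entropy` returns the closed-form Zipf entropy
−Σ pᵢ log₂ pᵢ; with redundancy and collocations off, sampled pooled word
entropy converges to it (the handful of header tokens per document perturbs
the value at the hundredth-of-a-bit level; the generator-validity test uses
a 0.15-bit band at 50 documents × 600 words).

What the generator does **not** emulate: Dutch grammar or clinical
semantics, topical structure, abbreviations, or any contextual dependence
beyond bound pairs. Consequently, passing tests demonstrate that the
*measurement pipeline* behaves correctly under controlled conditions — they
say nothing about the clinical quality of any particular synthetic dataset.

## Corpus transforms and the emulation preset

`transform_corpus` applies, in order: sentence-level length truncation
(keeping the leading fraction — sentence granularity keeps tokenization
valid, emulating shorter notes rather than clipped words), vocabulary swap,
sentence deduplication, and diacritic folding (NFD mark removal).

The vocabulary swap replaces a fraction of word *types* with fresh tokens
consistently **within** each document while cycling among four variants
**across** documents. The variants are character rotations/reversals of the
original word, so length and character statistics are preserved exactly.
The cross-document cycling is deliberate: a single corpus-wide bijective
renaming provably leaves every entropy unchanged (entropy is invariant under
relabeling), whereas per-document variants broaden the corpus vocabulary the
way generative models do when they paraphrase inconsistently across
documents — raising pooled word entropy and inter-corpus JSD while leaving
per-document statistics intact.

`emulation_preset` packages the reference-vs-synthetic contrast: a
13-document reference corpus with boilerplate redundancy 0.15, collocation
rate 0.1 and a diacritic-rich vocabulary (fraction 0.5), versus a
20-document independently seeded, redundancy-free generation truncated to
70% of its sentences, with a quarter of its vocabulary swapped,
deduplicated, and diacritic-folded. The synthetic base is generated
*without* redundancy (synthetic generators tend not to reproduce clinical
boilerplate), which keeps the mean-length ratio at ≈ 0.70; a preset-specific
length sd of 0.08 keeps that ratio stable at these small corpus sizes. The
preset yields, robustly across seeds: lower synthetic character entropy
(folding), higher synthetic word entropy (swap variants + absent
redundancy), lower synthetic corpus PMI (no repeated boilerplate bigrams),
and ~30% shorter synthetic documents.

## Pseudonymization stand-in

`pseudonymize_text` is a transparent rule-based de-identification stage:
regex detection of e-mails, Dutch phone-like digit runs, dates, and
nine-digit runs passing the BSN elfproef (Σ dᵢ·(10−i) − d₉ ≡ 0 mod 11,
all-zeros excluded), plus gazetteer person names replaced by seed-chosen
fictive names, consistent within a document. Offsets are 0-based half-open
Unicode character spans; the audit log replays exactly, and re-running the
rules on their own output is a fixed point. Rule-based recall on free text
is necessarily below that of statistical or neural NER — a documented
limitation; the module exists to make the pipeline runnable and testable
offline, not to certify GDPR compliance.

## Problem sizes and numerical choices

* Benchmark and calibration runs use 50-document corpora of ~600 words from
  a 500-type vocabulary — large enough that pooled entropy estimates are
  stable to a few hundredths of a bit and cross-validated AUC to a few
  hundredths, small enough to run in seconds.
* JSD values are clamped to [0, 1] against floating-point residue; BLEU's
  ε-floor is 1e-9; degenerate zero-variance features in the classifier's
  length z-score fall back to unit scale.
* File sizes are reported in MiB (bytes / 1,048,576).
* Documents are sorted by filename on loading, all generators and transforms
  take explicit seeds, and the full configuration (including derived
  quantities such as PMI exclusion counts) is echoed into `report.json`, so
  every report is bit-reproducible from its inputs.

## Known limitations

* The greedy-match scores under the hash embedder quantify lexical, not
  semantic, alignment; plugging in a contextual embedder changes the scale
  of the scores entirely.
* BLEU's multi-reference pairing is a convention choice; with 20 candidates
  against 13 pooled references the absolute score is not comparable to
  pairwise-aligned BLEU setups.
* The Mann–Whitney exact method is used only in tie-free small-sample
  cases; per-document metrics that produce exact ties (e.g. identical
  documents) fall back to the tie-corrected normal approximation.
* The generator's i.i.d. Zipf words cannot exhibit syntax-driven long-range
  structure; metrics sensitive to such structure (e.g. higher-order n-gram
  overlap) are exercised only near their degenerate ranges.
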