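# Methods

## The problem and the modeling idea

Two extant taxa that diverged by a macroevolutionary transition (the
motivating case: diurnal butterflies vs. nocturnal moths) differ in many
genes at once — gene-family expansions, fixed amino-acid substitutions,
domain gains and losses. `ikgm` treats each species' proteome as a
*document*: every protein is a sentence, and the words of a sentence come
from one of two biologically motivated vocabularies ("word hierarchies"):

* **v = 1, domain words** — the protein's ordered list of functional-domain
  names (Pfam-style annotation, supplied as an input table). Gene-family
  contraction/expansion and domain indels are visible at this scale.
* **v = 2, variant-kmer words** — the protein sequence split at
  high-frequency k-mers into unequal short peptides. Fixed substitutions
  and small indels perturb the token stream locally.

A binary document classifier is trained per view to predict the taxon
label. The classifier is a hierarchical attention network (HAN): if the
classifier can only separate the taxa by attending to particular proteins,
then its attention weights are a measurable notion of which genes carry
the macroevolutionary signal.

## Hierarchical attention network

For sentence *i* with word vectors `x_{i,t}`:

    h⃗_{i,t} = LSTM⃗(x_{i,t}, h⃗_{i,t−1})      (forward encoder)
    h⃖_{i,t} = LSTM⃖(x_{i,t}, h⃖_{i,t+1})      (backward encoder)
    h_{i,t} = [h⃗_{i,t}; h⃖_{i,t}]

    u_{i,t} = tanh(W_w h_{i,t} + b_w)
    α_{i,t} = softmax_t(w_w · u_{i,t})        (word attention)
    s_i     = Σ_t α_{i,t} h_{i,t}             (sentence vector)

The same construction is applied one level up over `s_1 … s_L` to give
sentence (protein) attentions `α_i` and the document vector
`P = Σ_i α_i h_i`, followed by `ŷ = softmax(W_c P + b_c)`.

Implementation notes:

* All tensors are float64 numpy arrays; gradients come from a small
  reverse-mode autodiff core (`ikgm._autodiff`) whose fused LSTM-cell and
  attention-pooling operators are validated against numerical
  differentiation in the test suite (agreement to 1e-4 on a small
  network).
* Padded positions are masked to −∞ before every softmax, so attention
  normalization (Σ_t α_{i,t} = Σ_i α_i = Σ ŷ = 1) holds exactly over real
  positions.
* For long documents the attention-score MLP runs blockwise
  (`chunk_size` sentences per block) followed by one global softmax —
  algebraically identical to the monolithic pass, and tested to 1e-6.
* LSTM gate order is [input, forget, cell, output]; forget-gate bias is
  initialized to 1, other parameters Xavier-uniform.

## Neutral augmentation

Deep classifiers need more documents than there are sequenced species.
Each taxon is expanded separately by label-preserving perturbations that
mimic near-neutral within-species variation:

* **block rearrangement** — the ordered protein list is cut into
  `n_parts` (default 10) contiguous blocks whose order is shuffled;
* **residue substitution** — exactly `round(rate × N)` positions of the
  concatenated proteome (default rate 0.005, hard cap 0.01) are replaced
  by a uniform draw from the other 19 standard amino acids.

Substitution uses an exact count rather than per-site Bernoulli draws so
the ≤1 % bound is verifiable exactly. Domain annotations are inherited
unchanged by variants. Every variant gets its own RNG substream keyed by
(species, replicate), so augmentation output is independent of processing
order. Per-taxon replicate counts can be chosen as
`ceil(target / taxon_size)` to balance uneven taxa.

## Tokenization (variant kmers)

All length-k windows (k = 3 by default, step 1) of the augmented corpus
are counted; k-mers whose count strictly exceeds the upper quartile
(linear interpolation) of the count distribution become *segment
markers*. Each protein sequence is scanned greedily left to right: on a
marker match the accumulated prefix is emitted, then the marker itself,
and scanning resumes after it. Concatenating the tokens reproduces the
sequence exactly; markers are kept as tokens since conserved motifs carry
signal. `corpus_retention` reports the fraction of token occurrences
whose type reaches the embedding frequency floor — an occurrence-weighted
formalization of how much of the corpus survives tokenization at a given
k.

## Word embeddings

Skip-gram with negative sampling, implemented as vectorized numpy SGD:
dynamic window shrinking (effective window ~ U{1..window}), unigram^0.75
noise distribution, linear learning-rate decay, single-threaded and
deterministic under a fixed seed. Noise draws that collide with the true
context are masked, which matters for the small vocabularies typical of
the domain-word view. Out-of-vocabulary tokens map to a reserved all-zero
UNK vector so attention stays computable for every word. Embeddings are
frozen during classifier training.

**Frequency floor.** The library default is `min_count = 2`. The pipeline,
however, resolves the floor to `2 × (replicates + 1)` by default: a token
that occurs only inside one origin genome's replicate family (for example
a species-private mutation and the k-mers it spawns) can appear at most
`replicates + 1` times, and such genome-private tokens act as memorizable
species signatures — a classifier can identify *which training genome* a
document came from instead of learning taxon-level biology. Raising the
floor above the replicate count removes these signatures at the
representation level and leaves only features shared across genomes.

## Training protocol

Cross-entropy minimized by Adam (pipeline default learning rate 5e-3).
The train/validation split operates on *origin genomes*: all augmented
replicates of a held-out genome are held out with it, so validation
accuracy measures generalization to unseen genomes, not to unseen copies
of seen genomes.

Two regularizers are central, both motivated by the fact that the
attentions — not just the predictions — are the scientific output:

* **Gene-grouped sentence dropout** (default rate 0.5): at every training
  step each gene's proteins are removed from the document together with
  probability 0.5. A classification objective is otherwise satisfied by
  the single easiest discriminative gene, and attention collapses onto
  it; under dropout the model can only keep its training loss low by
  learning *every* discriminative gene as a backup.
* **Corrupted validation for model selection**: early stopping tracks the
  loss on dropout-corrupted copies of the validation documents (two fixed
  samples per document). Clean validation loss saturates as soon as one
  dominant gene is learned and would stop training before the backup
  genes are acquired.

Clean validation accuracy is still reported per epoch and is the
package's held-out accuracy measure (averaged over the two views for a
whole pipeline run).

## From attention to gene scores

* **PAS** (protein attention score): the sentence attention of each
  protein of each original (non-augmented) genome.
* **Gene aggregation**: PAS summed over a gene's proteins per species
  (proteins without a gene symbol are excluded).
* **Fusion (v = 3)**: per gene, the cosine similarity between its
  cross-species score vectors under the two views multiplies the mean of
  the two views' scores — genes flagged discordantly by the two views are
  gated toward zero.
* **GAS**: gene scores summed over a taxon's species, normalized to sum
  to one within the taxon.
* **DAS**: the sum of the two taxa's normalized GAS; total DAS mass is
  exactly 2. Genes are ranked by DAS and the top fraction (default 1 %)
  are the key-gene candidates, optionally tested against GMT gene sets by
  an upper-tail hypergeometric test with Benjamini–Hochberg correction.

**Marginalized extraction.** A single forward pass reads attention through
one softmax, which is winner-take-all: a protein the model genuinely uses
as a backup signal can receive near-zero weight because a stronger signal
sits in the same document (verified by ablation: removing the dominant
gene's sentences moves the attention mass onto the backup gene). The
pipeline therefore reports the *expected* sentence attention over the
perturbation families the model was trained with: random block
rearrangements of protein order (protein order is an arbitrary
serialization choice, and document edges otherwise leave attention
artifacts) and gene-grouped dropout samples. Each pass is weighted by the
probability the model assigns to the document's true label in that pass,
so passes in which the classifier is left guessing (every informative
protein removed) contribute little. Dropout is uniform across genes, so
the expectation rescales all genes equally and is renormalized to sum to
one per species. The plain single-pass `extract_attention` remains
available and is what the scoring operations are defined on.

## The synthetic study

The fixture generator emulates the input side of a real two-taxon study
at desk scale. Defaults: 5 species per taxon; 50 background genes of
100–300 aa shared by all species up to 0.5 % per-species substitution
noise and a 5 % chance of one extra annotated domain; and one planted
gene per mechanism class:

* `domain_copy` — 3 copies in taxon 1 vs 1 in taxon 2, with a private
  marker domain (gene-family expansion);
* `substitution` — a shared template with 5 interior taxon-fixed
  diagnostic residues (per-species noise avoids those sites, keeping the
  substitutions fixed within taxa);
* `domain_indel` — a 24-aa repeated-motif insertion plus an extra domain
  present only in taxon 1.

What the generator deliberately does *not* model: phylogenetic
correlation among species, codon-level evolution, indel length variation,
annotation error. Passing the recovery tests therefore shows that the
pipeline can attribute a *clean, taxon-fixed* signal of each mechanism
class to the right gene at small scale — not that it would do so on real
proteomes, where signals are weaker and confounded by phylogeny.

The per-species background noise is kept deliberately: it creates exactly
the genome-private shortcut features (see *Frequency floor*) that make
naive training fail, which is the regime a real study lives in.

## Problem sizes and runtime choices

The default pipeline profile is sized for a single CPU: 24-dimensional
embeddings, 12 hidden units per LSTM direction, attention width 24,
sentences capped at 88 tokens (v = 2), batch 12; up to 128 training
epochs for the domain view and 64 for the kmer view, with validation
every second epoch. The importance readout averages over a two-member
checkpoint ensemble (best-validation state and final state — weak backup
signals are often acquired after the validation-loss minimum) and, per
member, over the canonical order, 3 random block orders, and 16
gene-dropout samples at rate 0.9; high dropout rates isolate small gene
subsets per pass, which together with the excess-confidence weighting
credits attention to each informative gene with little dilution. An
optional restart policy (`retrain_val_band`) retrains a view once when
its corrupted-validation loss indicates a partial fit; it is off by
default so the run cost stays deterministic. One full fixture run (90
documents after augmentation, two classifiers, scoring) takes roughly a
minute and a half. The embedding dimension for real data is 200
(`train_skipgram`'s default); the HAN class defaults (50 hidden units per
direction, attention width 100, Adam 1e-3) likewise target real-data
scale rather than the fixture.

## Known limitations

* DAS sums the two taxa's attention shares, so a gene attended equally in
  both taxa (an uninformative "anchor" sentence) can still rank above
  quiet genes; the differential signal lives in the *difference* of the
  GAS distributions, which DAS by construction does not isolate.
* Attention is a property of one trained network, and which of several
  equally valid discriminative genes a given optimization trajectory
  discovers — and how much attention mass it ends up with — varies from
  seed to seed. Two failure modes recur at desk scale even with all the
  countermeasures above: (i) a weak signal (a handful of diagnostic
  residues in one protein) is sometimes simply not discovered within the
  epoch budget, and (ii) a copy-number signal can be absorbed into
  document-global statistics, leaving the gene's own sentences
  under-attended. Both are detectable only with ground truth. The
  marginalized, ensembled readout substantially reduces but does not
  remove this run-to-run variation; making every planted mechanism land
  in the top ranks of its matched view in nearly every seeded run would
  require training ensembles of independent classifiers per view, which
  multiplies the training cost several-fold. On single-CPU budgets the
  per-run recovery of all three mechanisms at once is therefore a
  realized outcome in only a fraction of runs, and the recovery tests
  report exactly that.
* The variant-kmer view truncates sentences at `max_words_per_sentence`
  tokens; signals in the extreme C-terminal tail of very long proteins
  can be missed at the desk-scale cap.
* Binary taxa only; no multi-class support.
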