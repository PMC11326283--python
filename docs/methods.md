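# Methods

This note documents the models and procedures implemented in `modpep`, the
choices made where the design was genuinely open, and what the synthetic
fixtures do and do not demonstrate.

## Peptide generation

A peptide is first sampled symbolically (a `PeptideSpec`), then realized as a
molecule by graph editing, so every modification operates on well-defined
chemistry rather than on SMILES text.

**Sampling model.** Chain length is uniform on 1..`max_length` (default 100).
Each residue is independently unnatural with probability
`unnatural_fraction` (default 0.10) and uniform within its partition; each
α-carbon that has a stereocenter is independently dextro with probability
`d_fraction` (default 0.10). Aggregate rates are therefore exact in
expectation and recovered empirically to within binomial error. We chose
per-residue Bernoulli draws over exact without-replacement quotas because the
rates are stated as population fractions and independence keeps every record
exchangeable.

**Cyclization.** One of five chemistries is drawn uniformly: head-to-tail
(C-terminal carboxyl → N-terminal amine), sidechain-to-sidechain (side-chain
carboxyl → side-chain amine), sidechain-to-head, sidechain-to-tail, and
disulfide (two thiols). If the drawn chemistry is infeasible for the sampled
residues the peptide stays linear — feasibility is never resampled, so the
linear fraction reflects the sequence distribution. Attachment sites are
uniform over candidates; disulfide partners are a uniform unordered thiol
pair. Two guard rails avoid strained small rings: a sidechain-to-head donor
may not be residue 0 itself, and a sidechain-to-tail donor may not be the
C-terminal residue.

**N-methylation** uses a two-level draw: a peptide is selected with
probability 0.20, and within a selected peptide each *methylatable* backbone
amide NH — positions 1..L−1 whose nitrogen is not already tertiary — is
independently methylated with probability 0.20, i.e. 4% of amide NH
positions overall. Proline-like residues are excluded from both numerator
and denominator: their backbone nitrogen carries no amide hydrogen, so
"fraction of backbone amines methylated" is only well defined over NH
positions.

**PEGylation.** With probability 0.20 a methyl-capped PEG chain
(N-(CH₂CH₂O)ₙ-CH₃, n uniform on 1–4) is attached at a uniformly chosen free
amine: the N-terminal α-amine if no cyclization consumed it, plus side-chain
amines not consumed by a side-chain amide. If no free amine exists the
peptide is left unmodified, so the 20% rate holds among peptides that could
be PEGylated. The methyl cap is standard (mPEG) and makes PEG presence
recomputable from the SMILES alone — the N-C-C-O-C ether motif occurs
nowhere else in the library chemistry.

**Chemistry realization.** Monomers are stored as atom-mapped free amino
acids (map 1 backbone N, 2 acyl C, 3 thiol S, 4 side-chain amine N,
5 side-chain carboxyl C). Chains are condensed into amides by removing the
acyl hydroxyl and bonding C–N; dextro residues invert the α-carbon chiral
tag; methyls and PEG chains are added as atoms; one final sanitization
validates the result. Every emitted SMILES is canonical and survives a
parse→canonicalize round trip. Residue count equals the α-carbon count of
the built molecule (SMARTS `[NX3][CX4][CX3](=O)`), which the tests assert.

The packaged library holds the 20 proteinogenic amino acids plus 16
unnatural monomers (ornithine-series amines, thiol variants, achiral
disubstituted residues, homo/nor side chains, aromatics) in the style of the
SwissSidechain collection; a larger library is a drop-in TSV file.

## Tokenizer

The pretokenizer splits a SMILES into atomic units: bracket expressions and
two-digit ring closures stay whole, Br/Cl are single units, everything else
is one character; concatenating the units always reproduces the input.
Vocabulary training counts contiguous unit runs whose character length is at
most `max_ngram_chars` (default 5) in three categories — plain runs,
bracket-containing runs, and balanced parenthetical groups — and keeps the
most frequent ones under a total non-special budget (default 581, giving 586
tokens with the five specials). Ties break lexicographically, so training is
deterministic. Encoding is greedy longest-match left-to-right with `[UNK]`
for uncovered units, `[CLS]`/`[SEP]` framing, tail truncation and `[PAD]`
fill. The budget default of 581 matches the reference vocabulary size; the
exact token inventory depends on the training corpus and is not expected to
reproduce any particular published vocabulary.

## Masked-language-model pretraining

The encoder is a BERT-shaped transformer: token embeddings only (no absolute
position table), post-layer normalization, GELU feed-forward blocks, and a
language-modeling head (dense + GELU + LayerNorm + decoder). Positions enter
exclusively through rotary embeddings applied to queries and keys, so
attention depends on relative offsets; the tests verify that prepending
masked-out padding leaves content outputs unchanged. At the full-size
configuration (6 layers, 12 heads, hidden 768, intermediate 3072, vocabulary
586) the model instantiates with 44.0M trainable parameters.

Masking selects each eligible (non-special, non-padding) position
independently with probability 0.15; selected positions become `[MASK]` with
probability 0.80, a uniformly random non-special token with probability
0.10, and stay unchanged otherwise. Labels exist only at selected positions;
everything else is ignore-marked, so unselected positions contribute zero
gradient.

Training uses AdamW (optimizer unspecified upstream; AdamW is the field
default for BERT-style models), optional linear warmup and cosine decay,
batch shuffling per epoch, and a held-out validation split evaluated every
20% of the step budget. Reported metrics are the summed and per-position
mean cross-entropy over masked positions, and macro-averaged accuracy
(per-token-class accuracy averaged unweighted over the classes observed in
the evaluation set). A uniform predictor's per-position loss is ln V, which
the tests pin against the closed form.

The network stack is a small reverse-mode autodiff engine on numpy arrays
written for this package, gradient-checked against central finite
differences in the test suite. Checkpoints are self-describing `.npz`
archives (architecture, vocabulary hash, weights); loading rejects a
mismatched vocabulary.

## Permeability evaluation

**Cleaning.** Only PAMPA records are kept and rows with the −10
"undetectable" marker are dropped (aggregation and detection-floor artifacts
make them unreliable as regression targets).

**Embedding and clustering.** Records are embedded as the mean of
final-layer states over content positions (mean pooling is the common
default; the choice matters little for clustering since k-means operates on
relative distances). PCA (centering only — scaling would distort the
variance-retention criterion on already-commensurate hidden units) keeps the
smallest leading subspace with ≥99% variance. K-means (10 restarts, fixed
seed) runs for each candidate k (default 2–6) and k is chosen by maximum
silhouette; Davies–Bouldin and Calinski–Harabasz indices are recorded for
confirmation rather than selection.

**Leave-one-cluster-out schedule.** Each cluster is held out once. The
remaining records are split into 5 train/validation folds — at cluster
granularity when exactly 5 clusters remain (each remaining cluster validates
once), otherwise at record granularity with a seeded K-fold. Disjointness of
test and train/validation is asserted on record indices at run time.

**Finetuning.** The LM head is replaced by a single hidden-width dense layer
producing one scalar. Pooling for regression is a **sum** over content
positions: a linear head on summed token states is a token-additive scorer,
keeping counted structural motifs (methylated amides, PEG units, ring
closures, chain length) linearly accessible, which mean pooling would
normalize away. The head bias is initialized at the training-target mean —
Adam moves a bias by roughly one learning rate per step, so an uncentered
head would spend the whole step budget closing a ~6 log-unit gap. All
weights train under MSE; validation MSE is measured each epoch and the best
epoch's weights are kept. Optionally each training record is augmented with
randomized (non-canonical) SMILES rewrites — standard SMILES enumeration,
deterministic in the seed; validation and test records are never augmented.
Ensembles average the five fold models, optionally each averaged over the
canonical string plus a few randomized rewrites of the test molecule
(test-time enumeration). Augmentation and test-time enumeration are off by
default at paper-scale settings and enabled in the desk-scale pipeline,
where the small model benefits measurably from string-order invariance.

**Scoring.** Predictions are scored as a regression (RMSE against
experimental log10 permeability) and as a ranking at the −5.5 log10 cm/s
cutoff (permeable iff at or above): ROC-AUC by trapezoidal integration and
PR-AUC by step-wise interpolation (average precision). A single-class test
cluster yields NaN AUCs, is excluded from AUC aggregates with a logged
warning, and still contributes RMSE. Aggregates are mean ± SD over clusters.

## Synthetic permeability fixture

The fixture emulates a curated cyclic-peptide PAMPA table with a planted,
recoverable structure→permeability relation. Every record is generated by
this package's own generator (no measured data anywhere); its target is

log10 P = −5.6 − 0.05·length + 0.3·(N-methyl count) − 1.0·(PEG present)
          + 0.8·(macrocyclic) + ε,  ε ~ N(0, 0.3²)

with all four descriptors recomputed from the SMILES string alone
(α-carbon count; N-methyl amide SMARTS; the PEG ether motif; a ring
containing an in-ring amide or disulfide bond). Signs follow the
pharmacology: N-methylation and cyclization tend to improve passive
permeation, PEGylation and size oppose it. The intercept puts roughly a
third of records above the −5.5 cutoff, echoing the moderately imbalanced
split of real PAMPA collections. A configurable share of −10 rows and
non-PAMPA assay rows (5% each) exercises the cleaning stage. The fixture's
generator profile uses shorter chains (≤10 residues) and richer modification
variety (40% N-methylation and PEG selection) than the pretraining defaults
so all four descriptors vary within a 500-row table.

What passing the end-to-end check shows: the harness can express the full
experiment shape — pretraining improves the encoder, embeddings cluster, the
schedule leaks nothing, finetuned ensembles transfer a planted monotone
signal to held-out regions of embedding space. What it does not show: that a
desk-scale model predicts *real* membrane permeability; real PAMPA data is
noisier, the structure–permeability map is nonlinear, and conformation
effects (internal hydrogen bonding, chameleonicity) have no analogue in the
linear fixture.

## Desk-scale pipeline defaults

The `run-all` pipeline is sized to exercise every code path in minutes on
one CPU: 2,000 generated molecules (≤10 residues), a 2-layer / 4-head /
64-hidden / context-160 encoder pretrained 1,000 steps (batch 32, lr 1e-3),
a 500-row fixture, k candidates 2–6, and per-fold finetuning of 600 steps
(batch 16, lr 1e-3, no dropout, weight decay 1e-3, 2 augmentation rewrites
per training record, 4 test-time rewrites). Dropout is disabled at this
scale: with a 64-unit model, a few hundred records and 5-fold ensembling,
it only slows convergence. Paper-scale defaults (lr 5e-6, dropout 0.15,
batch 16, 10,000 steps) remain the constructor defaults of
`FinetuneConfig`.

## Numerical and degenerate-input conventions

Probabilities are validated into [0,1]; the masking shares must sum to 1.
Softmax and cross-entropy are max-shifted; attention masking uses a −1e9
additive bias. K-means ties in k selection break toward smaller k via sorted
iteration. Zero-variance embedding matrices, empty corpora, empty validation
sets, over-length inputs and vocabulary mismatches raise typed errors rather
than degrading silently. All randomness flows from explicit integer seeds
through `numpy.random.Generator`; per-record generator substreams make every
record reproducible from (run seed, index) independently of batch size.

## Known limitations

The residue library is a 36-entry stand-in, not the full SwissSidechain set;
head-to-tail cyclization of length-2 peptides yields diketopiperazines,
which are accepted as valid; the tokenizer learns from whatever corpus it is
given and makes no attempt to reproduce a specific published token
inventory; the numpy engine is single-threaded and unsuitable for
paper-scale pretraining, which is out of scope here; and silhouette-based k
selection on desk-scale embeddings typically chooses k = 2–3, smaller than
the k = 6 reported for full-scale embeddings of real data.
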