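# Methods

## Model

`synfuse` classifies drug-pair/cell-line triples as synergistic or
antagonistic. The pipeline has four stages.

**SMILES encoding.** A bidirectional transformer (token + position
embeddings, post-norm attention/FFN blocks, CLS-position pooling by
default, mean pooling available) embeds each drug's SMILES string. It is
fine-tuned with the SimCSE contrastive objective: each string is encoded
twice under independent dropout masks; the pair forms the positive, the
other batch members' second views are negatives; similarities are cosine,
scaled by a temperature τ (default 0.05). Dropout is the only
augmentation. No pretrained weights are used anywhere: the encoder starts
from a seeded random initialization and trains only on the working corpus.
This keeps the mechanism intact at single-CPU scale; the embeddings are
correspondingly weaker than a pretrained chemical language model's, which
matters for the ablation behavior discussed below. After contrastive
fine-tuning the encoder is frozen and per-drug embeddings are cached; the
supervised stage does not backpropagate into it.

**Featurization.** Each drug also contributes a 2048-bit hashed atom-pair
fingerprint (RDKit), computed on the molecular graph and therefore
identical for every SMILES spelling of one molecule. Cell lines contribute
their gene-expression vector. Invalid SMILES anywhere reject the whole
dataset file — silently dropping rows would corrupt split bookkeeping.

**Dual fusion.** The five inputs are projected by learned affine maps to a
shared width d and concatenated in the fixed order (fp A, fp B,
expression, SMILES A, SMILES B). The vector-level path treats the
concatenation as a 5-token sequence and applies multi-head scaled
dot-product attention (per-head d_k = d/h, no projection biases, head
outputs concatenated, no extra output projection by default), adds a
*projected* residual l·W^R — not an identity skip — and applies ReLU, so
the path output is non-negative. The bit-level path feeds the flat
5d-vector through highway layers g ⊙ t(l) + (1−g) ⊙ q(l); the gate
pre-activation is a learned affine map of the input passed through a
sigmoid (a gate without parameters could not learn what to carry), t is a
ReLU-activated affine transform and q a linear carry. Alignment weights
are shared between drug A and drug B within each modality so both drugs
are featurized identically; the concatenation order still makes the
network order-sensitive. An optional both-orders augmentation is exposed
but off by default. The head sums the two path outputs, layer-normalizes,
and applies a single linear unit with a sigmoid; with two classes a
sigmoid and a 2-way softmax are equivalent.

**Training.** Every batch is passed through the network twice under
independent dropout masks. The loss is the two-pass averaged binary
cross-entropy plus α times the symmetric Bernoulli KL divergence between
the two predictions (R-drop). Both terms are computed from logits via
softplus identities (log p = −softplus(−z)), never from clamped
probabilities. The optimizer is Adam with a constant learning rate.
Probability 0.5 binarizes to the positive class — a stated, testable
convention.

All networks run on an in-package reverse-mode autodiff engine over
float64 numpy arrays. Vector-Jacobian products are verified against
central finite differences in the test suite; float64 keeps the oracle
comparisons (1e-8…1e-10) meaningful. At the package's problem sizes
(feature widths ≤ a few hundred, thousands of records) this is fast
enough that no compiled framework is needed.

## Evaluation

Nine metrics with explicit degenerate-case conventions: precision, recall
and F1 fall back to 0 when undefined; MCC falls back to 0 when a factor
under its root is 0 (these arise in leave-one-entity-out folds with skewed
classes). ROC-AUC is computed as the Mann-Whitney pair statistic with
midranks (exact under ties, equivalent to the probabilistic definition);
average precision is the uninterpolated step sum over descending-score
thresholds; Cohen's κ uses chance agreement from the actual and predicted
class marginals. All agree with scikit-learn to 1e-10 on random tables
where both are defined.

One upstream formula ambiguity is worth recording: the printed definition
of TPR in the source material equals the TNR formula while its prose calls
TPR the recall. The standard TPR = TP/(TP+FN) and TNR = TN/(TN+FP) are
implemented; balanced accuracy is their mean.

## Cross-validation schemes

Four protocols: stratified random k-fold over records, and grouped k-fold
over unordered drug pairs, single drugs, or cell lines. Grouping uses the
canonical molecule, so two spellings of one compound cannot leak across
the train/test boundary. True one-entity-at-a-time splitting is the k =
number-of-entities special case; grouped k-fold (default k = 5) has the
same leakage semantics at tractable cost. In the drug scheme, a fold's
test set contains every record touching a held-out drug — including
records pairing two held-out drugs, which are kept, not discarded — so
test sets may overlap across folds while each fold's train/test pair
remains disjoint. An `audit_leakage` scan re-derives the guarantee
exhaustively from raw records and is asserted on 5,000-record corpora in
the tests. Stratification deals each class round-robin (continuing the
deal across classes), which bounds both per-fold class counts and fold
sizes within one of each other even when a class is smaller than k.

## Synthetic screens

The generator emulates the *structure* of a public combination screen
joined with expression profiles: a SMILES library, a dense cell-line ×
gene matrix, and labeled (drug A, drug B, cell line) records at a
configurable synergistic:antagonistic ratio (the two published regimes,
0.4 and 1.5, are both supported and tested).

**Library.** Molecules form a congeneric analog series: shared scaffolds
with three substitution sites drawn from a 12-substituent pool. This is a
deliberate design: in such a series any two SMILES strings differ in only
a few token positions, so a from-scratch sequence encoder sees weak
discriminative signal, while hashed atom-pair fingerprints resolve the
substituent combinations sharply. That asymmetry — fingerprints carrying
more usable chemical information than desk-scale string embeddings — is
what gives the ablation switches a testable direction: zeroing the
fingerprint input costs far more held-out AUC (≈ 0.67 vs ≈ 0.85) than
zeroing any other single component. An earlier library of structurally
diverse backbones failed to produce this direction because string
similarity then tracked fingerprint similarity almost perfectly and the
network recovered the pair signal equally well through either input.

**Planted rule.** score(i, j, c) = w_fp·z[Tanimoto(fp_i, fp_j)] +
w_expr·z[⟨u_c, v⟩] + ε, with z[·] standardization over the sampled
records, v a fixed random unit gene-weight vector, ε Gaussian
(sd 0.3), and weights (2, 1) so that structure carries more signal than
context but both matter. Labels threshold the score and are then flipped
independently with probability ε_label (default 0.05). The threshold is
set by rank so the *post-flip expected* positive fraction matches the
target ratio (flips on imbalanced classes otherwise bias the realized
ratio upward); the realized ratio is checked within the larger of 10 %
relative or 3 binomial standard deviations plus the half-record
quantization floor.

**Default sizes.** 20 drugs × 12 cell lines × 60 genes, 2,000 records —
100 records per drug, matching the per-drug record density of the real
screens after their expression join. Expression profiles are i.i.d.
standard Gaussian per line; the model consumes expression as dense reals,
so count-level realism is deliberately not simulated.

**What passing tests do and do not show.** The synthetic screens share
the real data's shape, not its biology: no dose-response surfaces, no
drug-frequency imbalance, no correlated gene modules, and a label rule
far simpler than cell-line pharmacology. Results on them validate the
mechanism (the architecture can extract a planted fingerprint + expression
signal; splits leak nothing; training is reproducible), not clinical
performance.

## Study configuration and observed behavior

The "tiny" study model is: encoder 2 layers / 2 heads / D = 32, fusion
d = 32 / 2 heads / 2 highway layers / dropout 0.1, trained 20 epochs at
batch 64. Two training hyperparameters were selected by cross-validation
on synthetic data: learning rate 3e-3 (1e-3 leaves the model visibly
underconverged after 20 epochs) and α = 2 (at α ≤ 1 the training
cross-entropy falls below the Bayes floor implied by 5 % label flips —
i.e. the network memorizes flipped labels — and the R-drop penalty is the
architecture's own remedy). Package-wide defaults remain α = 1, lr = 1e-3,
d = 256.

Under these conditions the held-out ROC-AUC on a 400-record stratified
fold is ≈ 0.86 against a flip-limited oracle ceiling of ≈ 0.92, with a
fold-level sampling sd of ≈ 0.025; across library draws single-fold
estimates range roughly 0.80–0.88. A label-permuted control trains to
≈ 0.5. The residual gap to the oracle is a genuine property of the
architecture at this scale: the pair term of the planted rule must be
read out of fingerprint interactions, and the fusion paths express such
bilinear structure only indirectly (through attention weights and ReLU
kinks), so the network relies partly on per-pair interpolation.

## Numerical and design choices

* Cosine similarity for the contrastive objective and τ = 0.05 follow the
  SimCSE convention; neither is forced by the architecture.
* CLS pooling default, mean pooling configurable.
* Softmax and log-sum-exp computations subtract detached row maxima;
  gradients are exact.
* Tokenization is longest-match over a fixed symbol table (two-letter
  halogens and bracket atoms are single tokens); unknown symbols raise
  with the offending span, and over-long inputs raise rather than
  truncate, because a clipped SMILES denotes a different molecule.
* A fingerprint with a single heavy atom is all-zero (no atom pairs
  exist); Tanimoto of two empty fingerprints is defined as 1.
* Checkpoints are an `.npz` weight blob plus a JSON config sidecar with a
  format version; gene-count mismatches are detected at load time.
* Unknown configuration keys are rejected rather than ignored.

## Known limitations

* Binary labels only; continuous synergy scores (Loewe, Bliss, ZIP) are
  out of scope.
* The encoder is frozen during supervised training; joint fine-tuning is
  not implemented.
* Predictions are not invariant to swapping drug A and drug B (the
  concatenation order is fixed); a both-orders training augmentation is
  exposed but off by default.
* Single CPU, float64, no batching tricks: intended for corpora of
  thousands of records, not the hundreds of thousands in real screens.
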