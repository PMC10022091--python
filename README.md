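# synfuse

Dual-feature-fusion prediction of synergistic drug combinations.

Anticancer drug pairs can act synergistically (their combined effect
exceeds additivity) or antagonistically, and which of the two happens
depends on the cellular context. `synfuse` is a small, fully self-contained
implementation of a deep synergy classifier for researchers who want to
study the *architecture* — contrastive SMILES encoding, two-granularity
feature fusion, R-drop regularization, leakage-free cross-validation — on
seeded synthetic screens, without GPU-scale training or external dataset
downloads. Everything, including a reverse-mode autodiff engine, runs on
numpy; chemistry goes through RDKit.

## The model

Each record is a triple (drug A, drug B, cell line) with a binary label
(1 = synergistic). Five feature vectors are built per record:

* $x_A, x_B \in \mathbb{R}^D$ — embeddings of the two SMILES strings from a
  small bidirectional transformer fine-tuned with the SimCSE contrastive
  objective, in which two dropout-perturbed encodings of the same string
  form a positive pair against in-batch negatives:
  $\ell_i = -\log \frac{e^{\mathrm{sim}(h_i, h_i')/\tau}}
  {\sum_j e^{\mathrm{sim}(h_i, h_j')/\tau}}$
* $f_A, f_B \in \{0,1\}^{2048}$ — hashed atom-pair fingerprints
* $z \in \mathbb{R}^{g}$ — the cell line's gene-expression profile

All five are projected to a shared width $d$ by affine maps $g(x) = Wx + b$
and concatenated, $l = (f_A', f_B', z', x_A', x_B')$. Two parallel paths
re-weight $l$ at different granularities:

* **vector level** — $l$ as a 5-token sequence through multi-head scaled
  dot-product attention, $\mathrm{softmax}(QK^\top/\sqrt{d_k})V$, plus a
  projected residual $lW^R$, then ReLU → $m_{vec}$;
* **bit level** — the flat $5d$ vector through highway layers
  $m = g \odot t(l) + (1-g) \odot q(l)$ with sigmoid gate $g$, ReLU
  transform $t$ and linear carry $q$ → $m_{bit}$.

The head computes $m_x = m_{vec} + m_{bit}$, layer-normalizes, and maps to
a synergy probability $\hat y = \sigma(w^\top \mathrm{LN}(m_x))$. Training
passes every batch through the network twice under independent dropout
masks and minimizes

$$L = \tfrac12\left(L_{ce}(\hat y_1, y) + L_{ce}(\hat y_2, y)\right)
      + \alpha \cdot \tfrac12\left(D_{KL}(\hat y_1 \| \hat y_2)
      + D_{KL}(\hat y_2 \| \hat y_1)\right),$$

the R-drop objective: cross-entropy averaged over the two passes plus the
symmetric KL divergence between their Bernoulli predictions.

Evaluation reports nine metrics (ACC, BACC, Prec, Rec, F1, ROC-AUC, MCC,
Cohen's κ, AP); splits come in four leakage-audited flavors — stratified
random k-fold and grouped k-fold over drug pairs, single drugs or cell
lines.

## Worked example

```python
from synfuse import *
from synfuse.synth import SyntheticConfig, generate_dataset
from synfuse.splits import stratified_kfold

records, expr, truth = generate_dataset(SyntheticConfig(seed=7))
plan = stratified_kfold(records, 5, seed=7)
train = [records[i] for i in plan.folds[0][0]]
test = [records[i] for i in plan.folds[0][1]]

model = DrugSynergyModel(
    train, expr,
    encoder_config=EncoderConfig(n_layers=2, n_heads=2, d_model=32,
                                 d_ff=64, max_len=64),
    fusion_config=FusionConfig(d=32, n_heads=2),
    train_config=TrainConfig(epochs=20, batch_size=64, lr=3e-3,
                             alpha=2.0, encoder_epochs=2),
)
results = model.fit(seed=7)
print(results.summary(eval_records=test))
```

```
Drug synergy dual-fusion model
==============================================
records:            1600 (455 synergistic / 1145 antagonistic)
drugs / cell lines: 20 / 12
genes:              60
encoder:            2 layers, 2 heads, D=32, tau=0.05
fusion:             d=32, 2 heads, 2 highway layers
training:           20 epochs, batch 64, lr 0.003, alpha 2.0, seed 7
final epoch loss:   0.2023
contrastive loss:   3.7071 -> 1.4581 over 4 steps

Held-out evaluation
----------------------------------------------
     ACC      BACC      Prec       Rec        F1   ROC_AUC       MCC     Kappa        AP
  0.8600    0.8203    0.7685    0.7281    0.7477    0.8618    0.6514    0.6510    0.7800
```

The synthetic screen plants a synergy rule (fingerprint Tanimoto similarity
plus a linear cell-line factor; see `docs/methods.md`), so a held-out
ROC-AUC of 0.86 against a label-flip ceiling of roughly 0.92 means the
network recovered most of the planted signal; the same pipeline trained on
permuted labels scores ≈ 0.5.

The same pipeline is scriptable from the shell:

```bash
synfuse simulate  --config cfg.yaml --seed 0 --out run/
synfuse split     --dataset run/dataset.csv --scheme stratified --k 5 --seed 0 --out run/plan.json
synfuse train     --dataset run/dataset.csv --expression run/expression.csv \
                  --config cfg.yaml --seed 0 --plan run/plan.json --out run/model/
synfuse evaluate  --checkpoint run/model/checkpoint --dataset run/dataset.csv \
                  --expression run/expression.csv --plan run/plan.json --out run/metrics.json
```

Ablation switches (`--no-attention`, `--no-highway`, `--no-smiles`,
`--no-fingerprint`, `--no-rdrop`, `--no-finetune`) zero out one component
or input at a time.

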