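"""The drug-synergy model: a statsmodels-style Model/Results pair wrapping
the contrastive SMILES encoder, the dual-fusion network and R-drop training.

``DrugSynergyModel`` is built from labeled (drug A, drug B, cell line)
records plus a cell-line expression table; ``fit`` fine-tunes the SMILES
encoder with the contrastive objective, freezes it, precomputes per-drug
features, and trains the fusion network. Each training batch is passed
through the network twice under independent dropout masks; the objective is
the averaged two-pass cross-entropy plus alpha times the symmetric KL
between the two predicted Bernoulli distributions (R-drop). ``fit`` returns
a ``DrugSynergyResults`` carrying the trained networks, the per-step loss
trace, prediction and evaluation methods, and a text summary.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd

from .autograd import Adam
from .chem import DEFAULT_N_BITS, atom_pair_fingerprint, canonical_smiles, tokenize_smiles
from .encoder import EncoderConfig, SmilesEncoder, finetune
from .fusion import DualFusionNetwork, FusionConfig, PredictionHead  # noqa: F401
from .losses import LossBreakdown, total_loss_from_logits
from .metrics import MetricReport, evaluate_predictions
from .splits import SplitPlan, SynergyRecord


@dataclass
class TrainConfig:
    """Supervised-stage settings.

    alpha weighs the R-drop KL penalty (0 disables it, the "without
    R-drop" ablation); finetune_encoder=False skips the contrastive
    fine-tuning stage and uses the randomly initialized encoder (the
    "without fine-tuning" ablation).
    """

    alpha: float = 1.0
    lr: float = 1e-3
    batch_size: int = 64
    epochs: int = 20
    swap_augment: bool = False  # also train on (B, A) order per record
    finetune_encoder: bool = True
    encoder_epochs: int = 3
    encoder_batch_size: int = 16
    encoder_lr: float = 1e-3

    def validate(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.epochs < 0 or self.encoder_epochs < 0:
            raise ValueError("epoch counts must be >= 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be positive")


def _derived_seed(seed: int, tag: int) -> int:
    return int(np.random.SeedSequence([seed, tag]).generate_state(1)[0] % (2**31))


class DrugSynergyModel:
    """Synergy classifier over drug pairs in cell-line context."""

    def __init__(self, records: list[SynergyRecord], expression: pd.DataFrame,
                 encoder_config: EncoderConfig | None = None,
                 fusion_config: FusionConfig | None = None,
                 train_config: TrainConfig | None = None,
                 n_bits: int = DEFAULT_N_BITS):
        if not records:
            raise ValueError("no training records")
        self.records = list(records)
        self.expression = expression
        self.encoder_config = encoder_config or EncoderConfig()
        self.fusion_config = fusion_config or FusionConfig()
        self.train_config = train_config or TrainConfig()
        self.n_bits = n_bits
        self.encoder_config.validate()
        self.fusion_config.validate()
        self.train_config.validate()

        missing = sorted(
            {r.cell_line for r in records} - set(expression.index)
        )
        if missing:
            raise ValueError(f"cell lines absent from the expression table: {missing}")
        # fail fast on any invalid SMILES: silent row loss corrupts splits
        for r in records:
            canonical_smiles(r.drug_a)
            canonical_smiles(r.drug_b)

    @classmethod
    def from_dataframes(cls, combos: pd.DataFrame, expression: pd.DataFrame,
                        **kwargs) -> "DrugSynergyModel":
        """Build from a combos table with columns drug_a_smiles,
        drug_b_smiles, cell_line, label."""
        required = ["drug_a_smiles", "drug_b_smiles", "cell_line", "label"]
        for col in required:
            if col not in combos.columns:
                raise ValueError(f"combos table is missing column {col!r}")
        records = [
            SynergyRecord(drug_a=row.drug_a_smiles, drug_b=row.drug_b_smiles,
                          cell_line=row.cell_line, label=int(row.label))
            for row in combos.itertuples(index=False)
        ]
        return cls(records, expression, **kwargs)

    # -- fitting -----------------------------------------------------------

    def fit(self, seed: int = 0, encoder: SmilesEncoder | None = None,
            ) -> "DrugSynergyResults":
        tc = self.train_config
        corpus = sorted({r.drug_a for r in self.records} | {r.drug_b for r in self.records})
        enc_cfg = replace(self.encoder_config, seed=_derived_seed(seed, 0xE))
        simcse_trace: list[float] = []
        if encoder is None:
            if tc.finetune_encoder and tc.encoder_epochs > 0:
                encoder, simcse_trace = finetune(
                    corpus, enc_cfg, epochs=tc.encoder_epochs,
                    batch_size=tc.encoder_batch_size, lr=tc.encoder_lr,
                )
            else:
                encoder = SmilesEncoder(enc_cfg)

        fus_cfg = replace(self.fusion_config, seed=_derived_seed(seed, 0xF))
        net = DualFusionNetwork(
            fus_cfg, n_bits=self.n_bits, n_genes=self.expression.shape[1],
            d_smiles=encoder.cfg.d_model,
        )
        results = DrugSynergyResults(
            model=self, encoder=encoder, net=net, seed=seed,
            simcse_trace=simcse_trace,
        )
        results._train(self.records, seed)
        return results


class DrugSynergyResults:
    """Fitted model: trained networks, loss traces, prediction and metrics."""

    def __init__(self, model: DrugSynergyModel, encoder: SmilesEncoder,
                 net: DualFusionNetwork, seed: int,
                 simcse_trace: list[float] | None = None):
        self.model = model
        self.encoder = encoder
        self.net = net
        self.seed = seed
        self.simcse_trace = simcse_trace or []
        self.loss_trace: list[LossBreakdown] = []
        self.epoch_loss: list[float] = []
        self._drug_cache: dict[str, tuple[np.ndarray, np.ndarray]] = {}

    # -- feature assembly --------------------------------------------------

    def _drug_features(self, smiles: str) -> tuple[np.ndarray, np.ndarray]:
        key = canonical_smiles(smiles)
        if key not in self._drug_cache:
            fp = atom_pair_fingerprint(smiles, self.model.n_bits)
            emb = self.encoder.encode_smiles([smiles])[0]
            self._drug_cache[key] = (fp, emb)
        return self._drug_cache[key]

    def _batch_features(self, records: list[SynergyRecord]):
        expr = self.model.expression
        missing = sorted({r.cell_line for r in records} - set(expr.index))
        if missing:
            raise ValueError(f"unknown cell lines: {missing}")
        fa = np.stack([self._drug_features(r.drug_a)[0] for r in records])
        fb = np.stack([self._drug_features(r.drug_b)[0] for r in records])
        xa = np.stack([self._drug_features(r.drug_a)[1] for r in records])
        xb = np.stack([self._drug_features(r.drug_b)[1] for r in records])
        z = expr.loc[[r.cell_line for r in records]].to_numpy(dtype=np.float64)
        y = np.array([r.label for r in records], dtype=np.float64)
        return fa, fb, z, xa, xb, y

    # -- training ----------------------------------------------------------

    def _train(self, records: list[SynergyRecord], seed: int) -> None:
        tc = self.model.train_config
        if tc.swap_augment:
            # the network is order-sensitive by construction; optionally
            # show it both drug orders of every training record
            records = records + [
                SynergyRecord(r.drug_b, r.drug_a, r.cell_line, r.label)
                for r in records
            ]
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0x7271]))
        opt = Adam(self.net.parameters(), lr=tc.lr)
        fa, fb, z, xa, xb, y = self._batch_features(records)
        n = len(records)
        idx = np.arange(n)
        for _ in range(tc.epochs):
            rng.shuffle(idx)
            epoch_losses = []
            for start in range(0, n, tc.batch_size):
                b = idx[start : start + tc.batch_size]
                out1 = self.net(fa[b], fb[b], z[b], xa[b], xb[b], rng=rng, train=True)
                out2 = self.net(fa[b], fb[b], z[b], xa[b], xb[b], rng=rng, train=True)
                loss, breakdown = total_loss_from_logits(
                    out1.logit, out2.logit, y[b], tc.alpha
                )
                if not np.isfinite(loss.data):
                    raise FloatingPointError(
                        f"non-finite loss at step {len(self.loss_trace)}"
                    )
                opt.zero_grad()
                loss.backward()
                opt.step()
                self.loss_trace.append(breakdown)
                epoch_losses.append(breakdown.total)
            if epoch_losses:
                self.epoch_loss.append(float(np.mean(epoch_losses)))

    # -- inference ---------------------------------------------------------

    def predict(self, records: list[SynergyRecord]) -> np.ndarray:
        """Deterministic eval-mode synergy probabilities."""
        if not records:
            raise ValueError("no records to predict")
        fa, fb, z, xa, xb, _ = self._batch_features(records)
        probs = []
        for start in range(0, len(records), 256):
            sl = slice(start, start + 256)
            out = self.net(fa[sl], fb[sl], z[sl], xa[sl], xb[sl], train=False)
            probs.append(out.prob.data)
        return np.concatenate(probs)

    def evaluate(self, records: list[SynergyRecord],
                 threshold: float = 0.5) -> MetricReport:
        probs = self.predict(records)
        y = np.array([r.label for r in records])
        return evaluate_predictions(y, probs, threshold)

    # -- reporting ---------------------------------------------------------

    def summary(self, eval_records: list[SynergyRecord] | None = None) -> str:
        m, tc = self.model, self.model.train_config
        n = len(m.records)
        n_pos = sum(r.label for r in m.records)
        lines = [
            "Drug synergy dual-fusion model",
            "=" * 46,
            f"records:            {n} ({n_pos} synergistic / {n - n_pos} antagonistic)",
            f"drugs / cell lines: {len({canonical_smiles(r.drug_a) for r in m.records} | {canonical_smiles(r.drug_b) for r in m.records})}"
            f" / {len({r.cell_line for r in m.records})}",
            f"genes:              {m.expression.shape[1]}",
            f"encoder:            {m.encoder_config.n_layers} layers, "
            f"{m.encoder_config.n_heads} heads, D={m.encoder_config.d_model}, "
            f"tau={m.encoder_config.tau}",
            f"fusion:             d={m.fusion_config.d}, "
            f"{m.fusion_config.n_heads} heads, "
            f"{m.fusion_config.highway_layers} highway layers",
            f"training:           {tc.epochs} epochs, batch {tc.batch_size}, "
            f"lr {tc.lr}, alpha {tc.alpha}, seed {self.seed}",
        ]
        if self.epoch_loss:
            lines.append(f"final epoch loss:   {self.epoch_loss[-1]:.4f}")
        if self.simcse_trace:
            lines.append(
                f"contrastive loss:   {self.simcse_trace[0]:.4f} -> "
                f"{self.simcse_trace[-1]:.4f} over {len(self.simcse_trace)} steps"
            )
        if eval_records is not None:
            report = self.evaluate(eval_records)
            lines += ["", "Held-out evaluation", "-" * 46, report.table()]
        return "\n".join(lines)

    # -- persistence -------------------------------------------------------

    def save(self, stem: str) -> None:
        """Write <stem>.npz (weights) and <stem>.json (config sidecar)."""
        import json
        from pathlib import Path

        enc_state = {f"enc_{k}": v for k, v in self.encoder.state_arrays().items()}
        net_state = {f"net_{k}": v for k, v in self.net.state_arrays().items()}
        np.savez(f"{stem}.npz", **enc_state, **net_state)
        sidecar = {
            "format_version": 1,
            "seed": self.seed,
            "n_bits": self.model.n_bits,
            "n_genes": int(self.model.expression.shape[1]),
            "encoder_config": asdict(self.encoder.cfg),
            "fusion_config": asdict(self.net.cfg),
            "train_config": asdict(self.model.train_config),
        }
        Path(f"{stem}.json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, stem: str, records: list[SynergyRecord],
             expression: pd.DataFrame) -> "DrugSynergyResults":
        import json
        from pathlib import Path

        sidecar = json.loads(Path(f"{stem}.json").read_text())
        if sidecar.get("format_version") != 1:
            raise ValueError("unrecognized checkpoint format")
        if int(sidecar["n_genes"]) != expression.shape[1]:
            raise ValueError(
                f"checkpoint was trained with {sidecar['n_genes']} genes but the "
                f"expression table has {expression.shape[1]}"
            )
        enc_cfg = EncoderConfig(**sidecar["encoder_config"])
        fus_cfg = FusionConfig(**sidecar["fusion_config"])
        model = DrugSynergyModel(
            records, expression, encoder_config=enc_cfg, fusion_config=fus_cfg,
            train_config=TrainConfig(**sidecar["train_config"]),
            n_bits=int(sidecar["n_bits"]),
        )
        encoder = SmilesEncoder(enc_cfg)
        net = DualFusionNetwork(fus_cfg, n_bits=model.n_bits,
                                n_genes=expression.shape[1],
                                d_smiles=enc_cfg.d_model)
        with np.load(f"{stem}.npz") as data:
            encoder.load_state_arrays(
                {k[4:]: data[k] for k in data.files if k.startswith("enc_")}
            )
            net.load_state_arrays(
                {k[4:]: data[k] for k in data.files if k.startswith("net_")}
            )
        return cls(model=model, encoder=encoder, net=net, seed=int(sidecar["seed"]))


def cross_validate(records: list[SynergyRecord], expression: pd.DataFrame,
                   plan: SplitPlan, seed: int = 0,
                   **model_kwargs) -> list[MetricReport]:
    """Train and evaluate one model per fold of a split plan."""
    reports = []
    for fold_i, (train_idx, test_idx) in enumerate(plan.folds):
        train = [records[i] for i in train_idx]
        test = [records[i] for i in test_idx]
        model = DrugSynergyModel(train, expression, **model_kwargs)
        results = model.fit(seed=_derived_seed(seed, fold_i))
        reports.append(results.evaluate(test))
    return reports
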