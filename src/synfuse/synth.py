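"""Seeded synthetic corpora emulating the structure of public drug
combination screens joined with cell-line expression profiles: a library of
valid small-molecule SMILES, a dense cell-line x gene expression matrix,
and labeled (drug A, drug B, cell line) records.

The labels follow a planted, recoverable rule

    score(i, j, c) = w_fp * z[Tanimoto(fp_i, fp_j)] + w_expr * z[<u_c, v>] + noise,

where fp are hashed atom-pair fingerprints, u_c is the cell line's
expression profile, v a fixed random gene weighting, z[.] standardization
over the sampled records, and noise is Gaussian. A record is synergistic
when its score exceeds a threshold calibrated so the positive:negative
ratio matches the configured value; labels are then flipped independently
with the label-noise probability. Both drug structure and expression carry
signal, with the fingerprint term weighted heavier, so ablating the
fingerprint input should hurt a trained model more than ablating any other
single input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chem import DEFAULT_N_BITS, atom_pair_fingerprint, canonical_smiles, tanimoto
from .splits import SynergyRecord

# Congeneric series: every molecule is one of a few shared scaffolds with
# substituents drawn for each of three fixed sites. This mimics a medicinal
# chemistry analog series and gives the two drug representations sharply
# different information content at small scale: the SMILES strings of any
# two library members differ in only a few token positions (weak signal for
# a from-scratch sequence encoder), while hashed atom-pair fingerprints
# resolve the substituent combinations distinctly.
_SCAFFOLDS = [
    "CC({0})CC({1})CC({2})C",
    "C1CC({0})CC({1})C1{2}",
    "{0}CC({1})C1CCC({2})CC1",
]
_SUBSTITUENTS = [
    "F", "Cl", "Br", "O", "N", "C", "S", "OC", "NC", "C#N", "CO", "CC",
]


@dataclass
class SyntheticConfig:
    """Generator settings; the defaults are the package's study conditions.

    ratio is the target synergistic:antagonistic class ratio (0.4 and 1.5
    are the two published screen regimes); label_noise is the independent
    flip probability epsilon in [0, 0.5).
    """

    n_drugs: int = 20
    n_cell_lines: int = 12
    n_genes: int = 60
    n_records: int = 2000
    ratio: float = 0.4
    label_noise: float = 0.05
    n_bits: int = DEFAULT_N_BITS
    w_fingerprint: float = 2.0
    w_expression: float = 1.0
    noise_sd: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_drugs, self.n_cell_lines, self.n_genes, self.n_records) < 1:
            raise ValueError("all counts must be positive")
        if self.ratio <= 0:
            raise ValueError("class ratio must be positive")
        if not (0.0 <= self.label_noise < 0.5):
            raise ValueError("label_noise must lie in [0, 0.5)")
        if self.n_drugs < 2:
            raise ValueError("need at least two drugs to form a pair")


def generate_molecules(n: int, seed: int) -> list[str]:
    """n distinct valid SMILES forming a congeneric analog series: shared
    scaffolds decorated with halogen / hydroxyl / amine / nitrile / alkyl
    substituents at three sites. Deterministic in seed; all outputs parse
    and are distinct as canonical molecules."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x30D]))
    out: list[str] = []
    seen: set[str] = set()
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > 200 * n + 2000:
            raise RuntimeError("molecule grammar exhausted before reaching n")
        # draw scaffolds in order so small libraries stay single-scaffold
        scaffold = _SCAFFOLDS[min(len(_SCAFFOLDS) - 1, attempts // 2000)]
        subs = rng.choice(_SUBSTITUENTS, size=3)
        smiles = scaffold.format(*subs)
        try:
            canon = canonical_smiles(smiles)
        except ValueError:
            continue
        if canon in seen:
            continue
        seen.add(canon)
        out.append(smiles)
    return out


def generate_expression(n_cell_lines: int, n_genes: int, seed: int) -> pd.DataFrame:
    """Cell line x gene matrix; each line is its own Gaussian signature."""
    if n_cell_lines < 1 or n_genes < 1:
        raise ValueError("counts must be positive")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xE42]))
    values = rng.normal(0.0, 1.0, size=(n_cell_lines, n_genes))
    lines = [f"CL{i:03d}" for i in range(n_cell_lines)]
    genes = [f"G{j:04d}" for j in range(n_genes)]
    return pd.DataFrame(values, index=pd.Index(lines, name="cell_line"), columns=genes)


def generate_dataset(cfg: SyntheticConfig) -> tuple[list[SynergyRecord], pd.DataFrame, dict]:
    """Records + expression + ground-truth rule description.

    The threshold is calibrated by rank so the pre-noise positive count
    matches the target ratio exactly; after label flips the realized ratio
    must stay within 10% (relative) of the target or generation fails.
    """
    cfg.validate()
    molecules = generate_molecules(cfg.n_drugs, cfg.seed)
    expr = generate_expression(cfg.n_cell_lines, cfg.n_genes, cfg.seed)
    n_pairs = cfg.n_drugs * (cfg.n_drugs - 1) // 2
    capacity = n_pairs * cfg.n_cell_lines
    if cfg.n_records > capacity:
        raise ValueError(
            f"n_records={cfg.n_records} exceeds the {capacity} distinct "
            "(pair, cell line) triples available"
        )
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xDA7A]))

    pairs = [(i, j) for i in range(cfg.n_drugs) for j in range(i + 1, cfg.n_drugs)]
    triple_ids = rng.choice(capacity, size=cfg.n_records, replace=False)
    fps = [atom_pair_fingerprint(s, cfg.n_bits) for s in molecules]
    v = rng.normal(0.0, 1.0, size=cfg.n_genes)
    v /= np.linalg.norm(v)
    expr_scores = expr.to_numpy() @ v

    sim = np.empty(cfg.n_records)
    cell_term = np.empty(cfg.n_records)
    triples = []
    for t, tid in enumerate(triple_ids):
        pair_idx, line_idx = divmod(int(tid), cfg.n_cell_lines)
        i, j = pairs[pair_idx]
        triples.append((i, j, line_idx))
        sim[t] = tanimoto(fps[i], fps[j])
        cell_term[t] = expr_scores[line_idx]

    def z(x: np.ndarray) -> np.ndarray:
        sd = x.std()
        if sd == 0:
            return np.zeros_like(x)
        return (x - x.mean()) / sd

    score = (cfg.w_fingerprint * z(sim) + cfg.w_expression * z(cell_term)
             + rng.normal(0.0, cfg.noise_sd, size=cfg.n_records))
    pos_frac = cfg.ratio / (1.0 + cfg.ratio)
    # pre-flip count chosen so the post-flip expectation hits the target:
    # E[pos] = n_pos (1 - eps) + (n - n_pos) eps
    n_pos = int(round(
        cfg.n_records * (pos_frac - cfg.label_noise) / (1.0 - 2.0 * cfg.label_noise)
    ))
    n_pos = min(max(n_pos, 1), cfg.n_records - 1)
    order = np.argsort(-score, kind="mergesort")
    theta = 0.5 * (score[order[n_pos - 1]] + score[order[n_pos]])
    labels = (score > theta).astype(np.int64)
    flips = rng.random(cfg.n_records) < cfg.label_noise
    labels = np.where(flips, 1 - labels, labels)

    realized_pos = int(labels.sum())
    realized_neg = max(cfg.n_records - realized_pos, 1)
    realized_ratio = realized_pos / realized_neg
    # tolerance: 10% relative, widened by the flip-noise sd (3 sigma) and
    # by the half-record quantization floor that rank calibration cannot
    # beat, so small datasets are not rejected for unavoidable granularity
    sd_pos = np.sqrt(cfg.n_records * cfg.label_noise * (1.0 - cfg.label_noise))
    per_record = cfg.n_records / (realized_neg**2)
    tol = max(0.10 * cfg.ratio, (3.0 * sd_pos + 0.5) * per_record)
    if abs(realized_ratio - cfg.ratio) > tol:
        raise RuntimeError(
            f"realized class ratio {realized_ratio:.3f} drifted beyond tolerance "
            f"from the target {cfg.ratio}"
        )

    lines = list(expr.index)
    records = [
        SynergyRecord(drug_a=molecules[i], drug_b=molecules[j],
                      cell_line=lines[c], label=int(labels[t]))
        for t, (i, j, c) in enumerate(triples)
    ]
    truth = {
        "w_fingerprint": cfg.w_fingerprint,
        "w_expression": cfg.w_expression,
        "noise_sd": cfg.noise_sd,
        "gene_weights": v.tolist(),
        "threshold": float(theta),
        "label_noise": cfg.label_noise,
        "realized_ratio": realized_ratio,
        "n_positive": realized_pos,
        "molecules": molecules,
    }
    return records, expr, truth
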