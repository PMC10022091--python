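"""Cross-validation protocols with machine-checkable no-leakage guarantees.

Four schemes: stratified random k-fold over records, and grouped k-fold
over unordered drug pairs, over single drugs, or over cell lines. Grouping
by an entity means no test record's entity ever appears in the same fold's
training set; drug identity is the canonical molecule, so two SMILES
spellings of one compound cannot leak across the boundary.

The leave-one-drug-out scheme partitions *drugs* into k groups; a record
is tested in every fold that holds out one of its two drugs and trained on
only in folds that hold out neither, so test sets may overlap across folds
(a record with both drugs held out stays in the test set). The pair and
cell-line schemes partition the records.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chem import canonical_smiles


@dataclass(frozen=True)
class SynergyRecord:
    """One labeled drug-pair / cell-line observation."""

    drug_a: str
    drug_b: str
    cell_line: str
    label: int

    def __post_init__(self):
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")


@dataclass
class SplitPlan:
    scheme: str
    seed: int
    folds: list[tuple[np.ndarray, np.ndarray]]  # (train_idx, test_idx)

    def to_dict(self) -> dict:
        return {
            "scheme": self.scheme,
            "seed": self.seed,
            "folds": [
                {"train": tr.tolist(), "test": te.tolist()} for tr, te in self.folds
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SplitPlan":
        return cls(
            scheme=d["scheme"],
            seed=int(d["seed"]),
            folds=[
                (np.asarray(f["train"], dtype=np.int64),
                 np.asarray(f["test"], dtype=np.int64))
                for f in d["folds"]
            ],
        )


def _canonical_map(records: list[SynergyRecord]) -> dict[str, str]:
    return {s: canonical_smiles(s)
            for s in {r.drug_a for r in records} | {r.drug_b for r in records}}


def _partition_entities(entities: list, k: int, rng: np.random.Generator) -> list[list]:
    """Shuffle entities and deal them round-robin into k groups."""
    order = sorted(entities)  # sort first: stable across input orderings
    perm = rng.permutation(len(order))
    groups: list[list] = [[] for _ in range(k)]
    for pos, idx in enumerate(perm):
        groups[pos % k].append(order[idx])
    return groups


def stratified_kfold(records: list[SynergyRecord], k: int, seed: int) -> SplitPlan:
    """Random k-fold whose test folds partition the records with per-fold
    class counts within one of each other."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(records) < k:
        raise ValueError(f"only {len(records)} records for k={k} folds")
    labels = np.array([r.label for r in records])
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5F]))
    fold_of = np.empty(len(records), dtype=np.int64)
    dealt = int(rng.integers(0, k))  # random starting fold
    for cls in (0, 1):
        idx = np.flatnonzero(labels == cls)
        if idx.size == 0:
            raise ValueError(f"class {cls} has no records; cannot stratify")
        idx = idx[rng.permutation(idx.size)]
        # continue the round-robin across classes: class counts per fold
        # differ by <= 1 and so do total fold sizes
        fold_of[idx] = (np.arange(idx.size) + dealt) % k
        dealt += idx.size
    folds = []
    all_idx = np.arange(len(records))
    for f in range(k):
        test = all_idx[fold_of == f]
        train = all_idx[fold_of != f]
        folds.append((train, test))
    return SplitPlan(scheme="stratified_kfold", seed=seed, folds=folds)


def _grouped_kfold(records: list[SynergyRecord], k: int, seed: int,
                   key_of: list, scheme: str, salt: int) -> SplitPlan:
    keys = sorted(set(key_of))
    if len(keys) < k:
        raise ValueError(f"{scheme}: only {len(keys)} groups for k={k} folds")
    rng = np.random.default_rng(np.random.SeedSequence([seed, salt]))
    groups = _partition_entities(keys, k, rng)
    folds = []
    all_idx = np.arange(len(records))
    for held_out in groups:
        held = set(held_out)
        in_test = np.array([key in held for key in key_of])
        folds.append((all_idx[~in_test], all_idx[in_test]))
    return SplitPlan(scheme=scheme, seed=seed, folds=folds)


def leave_drug_pair_out(records: list[SynergyRecord], k: int, seed: int) -> SplitPlan:
    """Grouped k-fold over unordered canonical drug pairs."""
    canon = _canonical_map(records)
    key_of = [frozenset((canon[r.drug_a], canon[r.drug_b])) for r in records]
    # frozensets are not orderable; tag with a sortable surrogate
    key_of = [tuple(sorted(key)) for key in key_of]
    return _grouped_kfold(records, k, seed, key_of, "leave_drug_pair_out", 0xDA1)


def leave_cell_line_out(records: list[SynergyRecord], k: int, seed: int) -> SplitPlan:
    """Grouped k-fold over cell lines."""
    key_of = [r.cell_line for r in records]
    return _grouped_kfold(records, k, seed, key_of, "leave_cell_line_out", 0xCE11)


def leave_drug_out(records: list[SynergyRecord], k: int, seed: int) -> SplitPlan:
    """Partition drugs into k groups; each fold tests every record touching
    a held-out drug and trains on records touching none."""
    canon = _canonical_map(records)
    drugs = sorted({canon[r.drug_a] for r in records} | {canon[r.drug_b] for r in records})
    if len(drugs) < k:
        raise ValueError(f"only {len(drugs)} distinct drugs for k={k} folds")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xD06]))
    groups = _partition_entities(drugs, k, rng)
    folds = []
    all_idx = np.arange(len(records))
    for held_out in groups:
        held = set(held_out)
        in_test = np.array(
            [canon[r.drug_a] in held or canon[r.drug_b] in held for r in records]
        )
        train = all_idx[~in_test]
        if train.size == 0:
            raise ValueError(
                f"leave_drug_out: holding out {sorted(held)} empties the training set"
            )
        folds.append((train, all_idx[in_test]))
    return SplitPlan(scheme="leave_drug_out", seed=seed, folds=folds)


SCHEMES = {
    "stratified": stratified_kfold,
    "leave-pair-out": leave_drug_pair_out,
    "leave-drug-out": leave_drug_out,
    "leave-cell-line-out": leave_cell_line_out,
}


def make_split(scheme: str, records: list[SynergyRecord], k: int, seed: int) -> SplitPlan:
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; choose from {sorted(SCHEMES)}")
    return SCHEMES[scheme](records, k, seed)


def audit_leakage(plan: SplitPlan, records: list[SynergyRecord]) -> int:
    """Exhaustive scan: number of (fold, test record) leakage violations.

    A violation is a test record whose grouping entity (pair, drug or cell
    line, per the plan's scheme) also occurs in that fold's training set.
    Always 0 for plans produced by this module; exposed so synthetic-data
    pipelines can assert it.
    """
    canon = _canonical_map(records)
    violations = 0
    for train, test in plan.folds:
        if plan.scheme == "stratified_kfold":
            overlap = set(train.tolist()) & set(test.tolist())
            violations += len(overlap)
            continue
        train_pairs = {tuple(sorted((canon[records[i].drug_a], canon[records[i].drug_b])))
                       for i in train}
        train_drugs = {d for p in train_pairs for d in p}
        train_lines = {records[i].cell_line for i in train}
        for i in test:
            r = records[i]
            pair = tuple(sorted((canon[r.drug_a], canon[r.drug_b])))
            if plan.scheme == "leave_drug_pair_out" and pair in train_pairs:
                violations += 1
            elif plan.scheme == "leave_drug_out" and (
                pair[0] in train_drugs and pair[1] in train_drugs
            ):
                violations += 1
            elif plan.scheme == "leave_cell_line_out" and r.cell_line in train_lines:
                violations += 1
    return violations
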