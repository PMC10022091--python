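"""Delimited-text dataset and expression formats, the run configuration
file, and run logging.

Datasets are CSV/TSV (delimiter chosen by extension) with header columns
drug_a_smiles, drug_b_smiles, cell_line, label; expression matrices have a
cell-line identifier first column and one column per gene. Every row is
validated on read — an invalid SMILES or label anywhere rejects the whole
file, because silently dropping rows would corrupt split accounting.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .chem import SmilesParseError, canonical_smiles
from .encoder import EncoderConfig
from .fusion import FusionConfig
from .model import TrainConfig
from .splits import SynergyRecord
from .synth import SyntheticConfig

DATASET_COLUMNS = ["drug_a_smiles", "drug_b_smiles", "cell_line", "label"]


def _sep_for(path: str | Path) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab")) else ","


def read_dataset(path: str | Path) -> list[SynergyRecord]:
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    for col in DATASET_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        row_no = i + 2  # header is line 1
        if row.label not in ("0", "1"):
            raise ValueError(
                f"{path}: row {row_no}: label must be 0 or 1, got {row.label!r}"
            )
        for col, smiles in (("drug_a_smiles", row.drug_a_smiles),
                            ("drug_b_smiles", row.drug_b_smiles)):
            try:
                canonical_smiles(smiles)
            except (SmilesParseError, TypeError) as exc:
                raise ValueError(f"{path}: row {row_no}: {col}: {exc}") from exc
        if not isinstance(row.cell_line, str) or not row.cell_line:
            raise ValueError(f"{path}: row {row_no}: empty cell_line")
        records.append(SynergyRecord(drug_a=row.drug_a_smiles,
                                     drug_b=row.drug_b_smiles,
                                     cell_line=row.cell_line,
                                     label=int(row.label)))
    return records


def write_dataset(records: list[SynergyRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [(r.drug_a, r.drug_b, r.cell_line, r.label) for r in records],
        columns=DATASET_COLUMNS,
    )
    df.to_csv(path, sep=_sep_for(path), index=False)


def read_expression(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    if df.index.has_duplicates:
        dupes = sorted(df.index[df.index.duplicated()].unique())
        raise ValueError(f"{path}: duplicate cell-line identifiers: {dupes}")
    if df.shape[1] < 1:
        raise ValueError(f"{path}: no gene columns")
    values = df.apply(pd.to_numeric, errors="coerce")
    if values.isna().any().any():
        bad = values.index[values.isna().any(axis=1)].tolist()
        raise ValueError(f"{path}: non-numeric or missing expression in rows {bad}")
    values.index.name = "cell_line"
    return values


def write_expression(expr: pd.DataFrame, path: str | Path) -> None:
    expr.to_csv(path, sep=_sep_for(path))


def write_fingerprints(records: list[SynergyRecord], path: str | Path,
                       n_bits: int) -> None:
    """Dense 0/1 fingerprint matrix keyed by canonical molecule."""
    from .chem import atom_pair_fingerprint

    molecules = sorted({canonical_smiles(r.drug_a) for r in records}
                       | {canonical_smiles(r.drug_b) for r in records})
    rows = [atom_pair_fingerprint(m, n_bits).astype(int) for m in molecules]
    df = pd.DataFrame(rows, columns=[f"bit{i}" for i in range(n_bits)])
    df.insert(0, "molecule", molecules)
    df.to_csv(path, sep=_sep_for(path), index=False)


# -- run configuration ------------------------------------------------------


@dataclass
class RunConfig:
    """Typed view of the YAML run configuration."""

    seed: int = 0
    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    fusion: FusionConfig = field(default_factory=FusionConfig)
    training: TrainConfig = field(default_factory=TrainConfig)
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    split_scheme: str = "stratified"
    split_k: int = 5

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "encoder": dataclasses.asdict(self.encoder),
            "fusion": dataclasses.asdict(self.fusion),
            "training": dataclasses.asdict(self.training),
            "synthetic": dataclasses.asdict(self.synthetic),
            "split": {"scheme": self.split_scheme, "k": self.split_k},
        }


def _build_section(cls, data: dict, section: str):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"config section {section!r}: unknown keys {sorted(unknown)}")
    return cls(**data)


def load_run_config(path: str | Path | None) -> RunConfig:
    """Load and validate a YAML config; unknown keys are rejected."""
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config root must be a mapping")
    known = {"seed", "encoder", "fusion", "training", "synthetic", "split"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown top-level keys {sorted(unknown)}")
    split = raw.get("split", {})
    bad_split = set(split) - {"scheme", "k"}
    if bad_split:
        raise ValueError(f"{path}: unknown split keys {sorted(bad_split)}")
    return RunConfig(
        seed=int(raw.get("seed", 0)),
        encoder=_build_section(EncoderConfig, raw.get("encoder", {}), "encoder"),
        fusion=_build_section(FusionConfig, raw.get("fusion", {}), "fusion"),
        training=_build_section(TrainConfig, raw.get("training", {}), "training"),
        synthetic=_build_section(SyntheticConfig, raw.get("synthetic", {}), "synthetic"),
        split_scheme=split.get("scheme", "stratified"),
        split_k=int(split.get("k", 5)),
    )


def write_run_log(out_dir: str | Path, seed: int, config: RunConfig) -> Path:
    """Echo the materialized config, its hash and versions to the run dir."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config_dict = config.to_dict()
    blob = json.dumps(config_dict, sort_keys=True).encode()
    log = {
        "seed": seed,
        "config": config_dict,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    path = out / "run_log.json"
    path.write_text(json.dumps(log, indent=2))
    return path
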