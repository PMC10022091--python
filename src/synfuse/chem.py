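"""SMILES featurization: tokenization for the sequence encoder and hashed
atom-pair fingerprints for the bit-level path.

The tokenizer is a deterministic longest-match scanner over a fixed symbol
table (multi-character halogens and bracket atoms are single tokens), so
``detokenize(tokenize(s)) == s`` for every accepted string. Fingerprints are
RDKit hashed atom-pair bit vectors computed on the parsed molecular graph,
hence identical for every SMILES spelling of the same molecule.
"""

from __future__ import annotations

import re

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import rdMolDescriptors

RDLogger.DisableLog("rdApp.*")

DEFAULT_N_BITS = 2048


class SmilesParseError(ValueError):
    """Raised when a SMILES string does not parse to a molecule."""


class UnknownTokenError(ValueError):
    """Raised when a SMILES string contains a symbol outside the vocabulary."""


def mol_from_smiles(smiles: str) -> Chem.Mol:
    if not smiles:
        raise SmilesParseError("empty SMILES string")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None or mol.GetNumAtoms() == 0:
        raise SmilesParseError(f"invalid SMILES: {smiles!r}")
    return mol


def canonical_smiles(smiles: str) -> str:
    """Canonical form; two spellings of one molecule map to one string."""
    return Chem.MolToSmiles(mol_from_smiles(smiles))


# Fixed symbol table. Order matters only for readability; matching is
# longest-first. Bracket atoms are closed-class: the common charged /
# protonated organic-subset atoms. Anything else raises UnknownTokenError.
_ORGANIC_ATOMS = [
    "Cl", "Br", "B", "C", "N", "O", "P", "S", "F", "I",
    "b", "c", "n", "o", "p", "s",
]
_BRACKET_ATOMS = [
    "[nH]", "[NH]", "[N+]", "[N-]", "[n+]", "[NH+]", "[NH2+]", "[NH3+]",
    "[O-]", "[OH]", "[O+]", "[S-]", "[S+]", "[C@H]", "[C@@H]", "[C@]",
    "[C@@]", "[P+]", "[Se]", "[Si]", "[H]",
]
_STRUCTURE = [
    "(", ")", "=", "#", "-", "+", "/", "\\", ".", ":", "~", "@",
    "%10", "%11", "%12", "%13", "%14", "%15",
    "0", "1", "2", "3", "4", "5", "6", "7", "8", "9",
]

PAD, BOS, EOS = "<pad>", "<bos>", "<eos>"


class SmilesVocab:
    """Token table with longest-match scanning."""

    def __init__(self, symbols: list[str] | None = None):
        if symbols is None:
            symbols = _BRACKET_ATOMS + _ORGANIC_ATOMS + _STRUCTURE
        self.tokens = [PAD, BOS, EOS] + list(symbols)
        self.index = {t: i for i, t in enumerate(self.tokens)}
        # longest symbols first so e.g. "Cl" wins over "C"
        alternates = sorted(symbols, key=len, reverse=True)
        self._pattern = re.compile("|".join(re.escape(s) for s in alternates))

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def pad_id(self) -> int:
        return self.index[PAD]

    @property
    def bos_id(self) -> int:
        return self.index[BOS]

    @property
    def eos_id(self) -> int:
        return self.index[EOS]

    def scan(self, smiles: str) -> list[str]:
        out: list[str] = []
        pos = 0
        while pos < len(smiles):
            m = self._pattern.match(smiles, pos)
            if m is None:
                span = smiles[pos : pos + 4]
                raise UnknownTokenError(
                    f"unknown symbol at position {pos} ({span!r}) in {smiles!r}"
                )
            out.append(m.group(0))
            pos = m.end()
        return out


DEFAULT_VOCAB = SmilesVocab()


def tokenize_smiles(smiles: str, vocab: SmilesVocab = DEFAULT_VOCAB,
                    max_len: int = 128) -> np.ndarray:
    """SMILES -> [BOS, tokens..., EOS] index array.

    Truncation is deliberately forbidden: a clipped SMILES denotes a
    different molecule, so over-long input raises instead.
    """
    if not smiles:
        raise SmilesParseError("empty SMILES string")
    symbols = vocab.scan(smiles)
    ids = [vocab.bos_id] + [vocab.index[s] for s in symbols] + [vocab.eos_id]
    if len(ids) > max_len:
        raise ValueError(
            f"SMILES of {len(symbols)} tokens exceeds max_len={max_len}: {smiles!r}"
        )
    return np.asarray(ids, dtype=np.int64)


def detokenize(token_ids: np.ndarray, vocab: SmilesVocab = DEFAULT_VOCAB) -> str:
    special = {vocab.pad_id, vocab.bos_id, vocab.eos_id}
    return "".join(vocab.tokens[i] for i in token_ids if i not in special)


def pad_batch(sequences: list[np.ndarray], vocab: SmilesVocab = DEFAULT_VOCAB
              ) -> tuple[np.ndarray, np.ndarray]:
    """Right-pad to a (batch, max_len) index matrix plus a 0/1 key mask."""
    n = len(sequences)
    if n == 0:
        raise ValueError("empty batch")
    width = max(len(s) for s in sequences)
    ids = np.full((n, width), vocab.pad_id, dtype=np.int64)
    mask = np.zeros((n, width), dtype=np.float64)
    for i, s in enumerate(sequences):
        ids[i, : len(s)] = s
        mask[i, : len(s)] = 1.0
    return ids, mask


def atom_pair_fingerprint(smiles: str, n_bits: int = DEFAULT_N_BITS) -> np.ndarray:
    """Hashed atom-pair fingerprint as a dense 0/1 vector of length n_bits.

    A pair is (atom type, atom type, topological distance); a single heavy
    atom therefore yields the all-zero vector.
    """
    mol = mol_from_smiles(smiles)
    fp = rdMolDescriptors.GetHashedAtomPairFingerprintAsBitVect(mol, nBits=n_bits)
    arr = np.zeros(n_bits, dtype=np.float64)
    for bit in fp.GetOnBits():
        arr[bit] = 1.0
    return arr


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Tanimoto similarity of two 0/1 fingerprints (1.0 for two empty sets)."""
    inter = float(np.minimum(a, b).sum())
    union = float(np.maximum(a, b).sum())
    if union == 0.0:
        return 1.0
    return inter / union
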