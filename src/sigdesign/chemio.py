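"""SMILES handling, molecular fingerprints, Tanimoto similarity, and the
SMILES <-> one-hot codec used by the generative model.

All chemistry goes through RDKit. Fingerprints default to Morgan (circular
substructure) fingerprints, radius 2, 1024 bits — a standard binary
presence/absence encoding of local substructures. Tokenization of SMILES is
character-level: the vocabulary is the set of unique characters in the
corpus plus one padding token, and a string is encoded as a
(seq_len x vocab) one-hot matrix, optionally with a condition vector
appended to every row.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import rdFingerprintGenerator

RDLogger.DisableLog("rdApp.*")

#: Padding token: a space, which can never occur inside a SMILES string.
PAD_TOKEN = " "

DEFAULT_N_BITS = 1024
DEFAULT_RADIUS = 2


class SmilesParseError(ValueError):
    """Raised when a SMILES string does not parse to a valid molecule."""


class VocabularyError(KeyError):
    """Raised when a string contains characters absent from a vocabulary."""


@dataclass(frozen=True)
class SmilesRecord:
    """A compound: an opaque identifier plus a canonical SMILES string."""

    compound_id: str
    smiles: str


@dataclass(frozen=True)
class Fingerprint:
    """Fixed-length binary substructure fingerprint.

    Attributes
    ----------
    bits : np.ndarray
        Boolean vector of length ``n_bits``.
    n_bits : int
        Fingerprint length.
    """

    bits: np.ndarray
    n_bits: int

    def __post_init__(self) -> None:
        if self.bits.shape != (self.n_bits,):
            raise ValueError(
                f"fingerprint bits have shape {self.bits.shape}, expected ({self.n_bits},)"
            )

    @property
    def popcount(self) -> int:
        return int(self.bits.sum())


def _mol_from_smiles(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"invalid SMILES: {smiles!r}")
    return mol


def canonicalize_smiles(smiles: str) -> str:
    """Return RDKit's canonical form; equal molecules map to equal strings."""
    return Chem.MolToSmiles(_mol_from_smiles(smiles))


def is_valid_smiles(smiles: str) -> bool:
    return Chem.MolFromSmiles(smiles) is not None


def fingerprint(
    smiles: str,
    n_bits: int = DEFAULT_N_BITS,
    radius: int = DEFAULT_RADIUS,
) -> Fingerprint:
    """Morgan (circular substructure) fingerprint of a SMILES string.

    Deterministic: the same molecule, however spelled, yields the same bits.
    """
    if n_bits < 8:
        raise ValueError(f"n_bits must be >= 8, got {n_bits}")
    mol = _mol_from_smiles(smiles)
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    arr = np.zeros(n_bits, dtype=bool)
    for bit in gen.GetFingerprint(mol).GetOnBits():
        arr[bit] = True
    return Fingerprint(bits=arr, n_bits=n_bits)


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto coefficient |a & b| / |a | b|; 0.0 when both are empty."""
    if a.n_bits != b.n_bits:
        raise ValueError(f"fingerprint length mismatch: {a.n_bits} vs {b.n_bits}")
    union = int(np.logical_or(a.bits, b.bits).sum())
    if union == 0:
        return 0.0
    inter = int(np.logical_and(a.bits, b.bits).sum())
    return inter / union


@dataclass(frozen=True)
class SmilesVocabulary:
    """Character vocabulary with a padding token at a recorded position.

    Tokens are the sorted unique characters of the corpus plus ``PAD_TOKEN``;
    the sort puts the pad (space) first, so ``pad_index`` is 0 in practice,
    but it is recorded explicitly rather than assumed.
    """

    tokens: tuple[str, ...]
    seq_len: int
    index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(set(self.tokens)) != len(self.tokens):
            raise ValueError("vocabulary tokens must be unique")
        if PAD_TOKEN not in self.tokens:
            raise ValueError("vocabulary must contain the padding token")
        object.__setattr__(self, "index", {t: i for i, t in enumerate(self.tokens)})

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def pad_index(self) -> int:
        return self.index[PAD_TOKEN]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"tokens": list(self.tokens), "seq_len": self.seq_len})
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "SmilesVocabulary":
        d = json.loads(Path(path).read_text())
        return cls(tokens=tuple(d["tokens"]), seq_len=int(d["seq_len"]))


def build_vocabulary(
    corpus: Sequence[SmilesRecord], seq_len: int
) -> SmilesVocabulary:
    """Character vocabulary over a corpus, sorted for reproducibility."""
    if not corpus:
        raise ValueError("cannot build a vocabulary from an empty corpus")
    chars: set[str] = set()
    for rec in corpus:
        if len(rec.smiles) > seq_len:
            raise ValueError(
                f"record {rec.compound_id!r}: SMILES length {len(rec.smiles)} "
                f"exceeds seq_len {seq_len}"
            )
        chars.update(rec.smiles)
    chars.add(PAD_TOKEN)
    return SmilesVocabulary(tokens=tuple(sorted(chars)), seq_len=seq_len)


def one_hot_encode(
    smiles: str,
    vocab: SmilesVocabulary,
    seq_len: int | None = None,
    condition: np.ndarray | None = None,
) -> np.ndarray:
    """One-hot encode a SMILES string as a (seq_len x width) matrix.

    Rows past the end of the string are the padding token. When a condition
    vector is given it is appended to every row, so
    width = |vocab| + len(condition).
    """
    if seq_len is None:
        seq_len = vocab.seq_len
    if len(smiles) > seq_len:
        raise ValueError(
            f"SMILES length {len(smiles)} exceeds seq_len {seq_len}: {smiles!r}"
        )
    width = len(vocab) + (0 if condition is None else len(condition))
    mat = np.zeros((seq_len, width), dtype=np.float64)
    padded = smiles + PAD_TOKEN * (seq_len - len(smiles))
    for pos, ch in enumerate(padded):
        try:
            mat[pos, vocab.index[ch]] = 1.0
        except KeyError:
            raise VocabularyError(
                f"character {ch!r} at position {pos} not in vocabulary"
            ) from None
    if condition is not None:
        mat[:, len(vocab):] = np.asarray(condition, dtype=np.float64)
    return mat


def one_hot_decode(probabilities: np.ndarray, vocab: SmilesVocabulary) -> str:
    """Decode per-position token probabilities to a string by row argmax.

    Decoding truncates at the first padding token. Ties break to the lowest
    vocabulary index (numpy argmax convention), which is deterministic.
    """
    probs = np.asarray(probabilities)
    if probs.ndim != 2 or probs.shape[1] != len(vocab):
        raise ValueError(
            f"probability matrix width {probs.shape} incompatible with "
            f"vocabulary of size {len(vocab)}"
        )
    out: list[str] = []
    for row in probs:
        idx = int(np.argmax(row))
        if idx == vocab.pad_index:
            break
        out.append(vocab.tokens[idx])
    return "".join(out)


def read_smi(path: str | Path) -> list[SmilesRecord]:
    """Read a .smi file: one ``SMILES<TAB>compound_id`` per line, '#' comments."""
    records = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected 'SMILES<TAB>id', got {line!r}")
        records.append(SmilesRecord(compound_id=parts[1], smiles=parts[0]))
    return records


def write_smi(records: Iterable[SmilesRecord], path: str | Path) -> None:
    lines = [f"{r.smiles}\t{r.compound_id}" for r in records]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
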