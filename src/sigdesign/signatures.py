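"""Compound-proteome interaction signatures.

The interaction score between a compound and a protein is a ligand-homology
proxy for binding: the maximum Tanimoto coefficient between the compound's
binary fingerprint and the fingerprints of all ligands associated with any
of the protein's predicted binding sites. A protein with no site ligands
scores zero for every compound. The vector of scores over a fixed, ordered
protein library is the compound's interaction signature — its
proteome-scale behavioral proxy. Signatures are compared by RMSD.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .chemio import Fingerprint, SmilesRecord, fingerprint, tanimoto


@dataclass
class BindingSite:
    """One predicted binding site: its known/co-crystallized ligand fingerprints."""

    protein_id: str
    site_id: str
    ligands: list[Fingerprint]


@dataclass
class ProteomeLibrary:
    """An ordered protein library; order defines signature coordinate order."""

    proteins: list[str]
    sites: dict[str, list[BindingSite]]
    n_bits: int
    # stacked ligand bit matrix plus per-protein row slices, built lazily
    _ligand_matrix: np.ndarray | None = field(default=None, repr=False)
    _ligand_slices: list[tuple[int, int]] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if len(set(self.proteins)) != len(self.proteins):
            raise ValueError("protein_ids must be unique")
        for pid, sites in self.sites.items():
            for site in sites:
                for fp in site.ligands:
                    if fp.n_bits != self.n_bits:
                        raise ValueError(
                            f"ligand fingerprint length {fp.n_bits} != library "
                            f"n_bits {self.n_bits} (protein {pid})"
                        )

    def __len__(self) -> int:
        return len(self.proteins)

    def _build_ligand_matrix(self) -> None:
        rows, slices = [], []
        start = 0
        for pid in self.proteins:
            for site in self.sites.get(pid, []):
                rows.extend(fp.bits for fp in site.ligands)
            end = len(rows)
            slices.append((start, end))
            start = end
        self._ligand_matrix = (
            np.array(rows, dtype=bool) if rows else np.zeros((0, self.n_bits), bool)
        )
        self._ligand_slices = slices

    @property
    def ligand_matrix(self) -> np.ndarray:
        if self._ligand_matrix is None:
            self._build_ligand_matrix()
        return self._ligand_matrix

    @property
    def ligand_slices(self) -> list[tuple[int, int]]:
        if self._ligand_slices is None:
            self._build_ligand_matrix()
        return self._ligand_slices

    def to_tsv(self, path: str | Path, ligand_smiles: dict[str, list[tuple[str, str]]]) -> None:
        """Write the site-ligand table (requires the original ligand SMILES)."""
        rows = []
        for pid in self.proteins:
            for site_id, smi in ligand_smiles.get(pid, []):
                rows.append((pid, site_id, smi))
        pd.DataFrame(rows, columns=["protein_id", "site_id", "ligand_smiles"]).to_csv(
            path, sep="\t", index=False
        )


def proteome_from_tsv(
    path: str | Path, n_bits: int = 1024, radius: int = 2
) -> ProteomeLibrary:
    """Load a proteome from a site-ligand TSV.

    Columns: protein_id, site_id, ligand_smiles (one ligand per row; header
    required). Protein order is first-appearance order in the file.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"protein_id", "site_id", "ligand_smiles"}
    if not required.issubset(df.columns):
        raise ValueError(f"proteome TSV must have columns {sorted(required)}")
    proteins: list[str] = []
    sites: dict[str, list[BindingSite]] = {}
    site_lookup: dict[tuple[str, str], BindingSite] = {}
    for _, row in df.iterrows():
        pid, sid = row["protein_id"], row["site_id"]
        if pid not in sites:
            proteins.append(pid)
            sites[pid] = []
        key = (pid, sid)
        if key not in site_lookup:
            site = BindingSite(protein_id=pid, site_id=sid, ligands=[])
            site_lookup[key] = site
            sites[pid].append(site)
        site_lookup[key].ligands.append(
            fingerprint(row["ligand_smiles"], n_bits=n_bits, radius=radius)
        )
    return ProteomeLibrary(proteins=proteins, sites=sites, n_bits=n_bits)


@dataclass
class InteractionSignature:
    """Per-protein interaction scores in [0, 1] for one compound."""

    compound_id: str
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("signature scores must be finite")
        if self.scores.min(initial=0.0) < 0 or self.scores.max(initial=0.0) > 1:
            raise ValueError("signature scores must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.scores)


@dataclass
class SignatureMatrix:
    """Signatures of many compounds over one shared proteome."""

    compound_ids: list[str]
    values: np.ndarray  # (n_compounds, n_proteins)
    protein_ids: list[str]

    def __post_init__(self) -> None:
        if len(set(self.compound_ids)) != len(self.compound_ids):
            raise ValueError("compound_ids must be unique")
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.compound_ids), len(self.protein_ids)):
            raise ValueError("signature matrix shape mismatch")

    def __len__(self) -> int:
        return len(self.compound_ids)

    def row(self, compound_id: str) -> InteractionSignature:
        i = self.compound_ids.index(compound_id)
        return InteractionSignature(compound_id=compound_id, scores=self.values[i])

    def rows(self) -> list[InteractionSignature]:
        return [
            InteractionSignature(cid, self.values[i])
            for i, cid in enumerate(self.compound_ids)
        ]

    def subset(self, compound_ids: Sequence[str]) -> "SignatureMatrix":
        idx = [self.compound_ids.index(c) for c in compound_ids]
        return SignatureMatrix(
            compound_ids=list(compound_ids),
            values=self.values[idx],
            protein_ids=self.protein_ids,
        )

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.values, columns=self.protein_ids)
        df.insert(0, "compound_id", self.compound_ids)
        df.to_csv(path, sep="\t", index=False, float_format="%.6f")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SignatureMatrix":
        df = pd.read_csv(path, sep="\t")
        return cls(
            compound_ids=df["compound_id"].astype(str).tolist(),
            values=df.drop(columns="compound_id").to_numpy(dtype=np.float64),
            protein_ids=[str(c) for c in df.columns[1:]],
        )


def _tanimoto_to_rows(query: Fingerprint, matrix: np.ndarray) -> np.ndarray:
    """Tanimoto of one query fingerprint against each row of a bit matrix."""
    if matrix.shape[0] == 0:
        return np.zeros(0)
    q = query.bits
    inter = matrix @ q.astype(np.int64)
    union = matrix.sum(axis=1) + q.sum() - inter
    with np.errstate(invalid="ignore"):
        scores = np.where(union > 0, inter / np.maximum(union, 1), 0.0)
    return scores


def score_interaction(query: Fingerprint, sites: Sequence[BindingSite]) -> float:
    """Max Tanimoto between the query and any ligand of any site; 0 if none."""
    best = 0.0
    for site in sites:
        for lig in site.ligands:
            if lig.n_bits != query.n_bits:
                raise ValueError(
                    f"fingerprint length mismatch: query {query.n_bits}, "
                    f"ligand {lig.n_bits}"
                )
            best = max(best, tanimoto(query, lig))
    return best


def compute_signature(
    compound: SmilesRecord, proteome: ProteomeLibrary, radius: int = 2
) -> InteractionSignature:
    """Interaction signature of one compound over the proteome library."""
    fp = fingerprint(compound.smiles, n_bits=proteome.n_bits, radius=radius)
    return signature_from_fingerprint(compound.compound_id, fp, proteome)


def signature_from_fingerprint(
    compound_id: str, fp: Fingerprint, proteome: ProteomeLibrary
) -> InteractionSignature:
    if fp.n_bits != proteome.n_bits:
        raise ValueError("fingerprint length does not match proteome n_bits")
    all_scores = _tanimoto_to_rows(fp, proteome.ligand_matrix)
    sig = np.zeros(len(proteome))
    for i, (start, end) in enumerate(proteome.ligand_slices):
        if end > start:
            sig[i] = all_scores[start:end].max()
    return InteractionSignature(compound_id=compound_id, scores=sig)


def compute_signature_matrix(
    corpus: Sequence[SmilesRecord], proteome: ProteomeLibrary, radius: int = 2
) -> SignatureMatrix:
    """One signature row per compound, order preserved, deterministic."""
    ids = [r.compound_id for r in corpus]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate compound_ids in corpus")
    values = np.zeros((len(corpus), len(proteome)))
    for i, rec in enumerate(corpus):
        values[i] = compute_signature(rec, proteome, radius=radius).scores
    return SignatureMatrix(
        compound_ids=ids, values=values, protein_ids=list(proteome.proteins)
    )


def signature_rmsd(a: InteractionSignature, b: InteractionSignature) -> float:
    """Root-mean-squared deviation between two equal-length signatures."""
    if len(a) != len(b):
        raise ValueError(f"signature length mismatch: {len(a)} vs {len(b)}")
    return float(np.sqrt(np.mean((a.scores - b.scores) ** 2)))


def rank_by_signature_similarity(
    objective: InteractionSignature, library: SignatureMatrix, n: int
) -> list[tuple[str, float]]:
    """The n library compounds closest to the objective by signature RMSD.

    Ascending RMSD, ties broken by compound_id; returns min(n, |library|)
    entries.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if len(objective) != len(library.protein_ids):
        raise ValueError("objective signature length does not match library")
    diffs = library.values - objective.scores[None, :]
    rmsds = np.sqrt(np.mean(diffs**2, axis=1))
    order = sorted(range(len(library)), key=lambda i: (rmsds[i], library.compound_ids[i]))
    return [(library.compound_ids[i], float(rmsds[i])) for i in order[:n]]
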