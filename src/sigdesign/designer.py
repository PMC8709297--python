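"""End-to-end design loop: objective compound -> full interaction
signature -> reduced condition vector -> prior-sampled designs ->
validity/uniqueness filter -> re-scored signatures -> ranking by RMSD.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .chemio import (
    SmilesRecord,
    canonicalize_smiles,
    fingerprint,
    is_valid_smiles,
    tanimoto,
    write_smi,
)
from .cvae import CvaeModel, sample_designs
from .reducer import TrainedReducer, reduce_signature
from .signatures import (
    InteractionSignature,
    ProteomeLibrary,
    compute_signature,
    signature_rmsd,
)

logger = logging.getLogger(__name__)


@dataclass
class DesignRequest:
    objective: SmilesRecord
    n_designs: int = 100
    oversample_factor: float = 3.0
    max_rounds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_designs < 0:
            raise ValueError("n_designs must be >= 0")
        if self.oversample_factor < 1:
            raise ValueError("oversample_factor must be >= 1")


@dataclass
class DesignEntry:
    record: SmilesRecord
    signature: InteractionSignature
    rmsd_to_objective: float
    tanimoto_to_objective: float


@dataclass
class DesignSet:
    """Generated designs for one objective, sorted ascending by RMSD."""

    objective_id: str
    objective_signature: InteractionSignature
    designs: list[DesignEntry]
    provenance: dict = field(default_factory=dict)
    status: str = "ok"  # "ok", "short" (fewer than requested), or "empty"

    def __len__(self) -> int:
        return len(self.designs)

    @property
    def rmsds(self) -> np.ndarray:
        return np.array([d.rmsd_to_objective for d in self.designs])

    @property
    def tanimotos(self) -> np.ndarray:
        return np.array([d.tanimoto_to_objective for d in self.designs])

    def top(self, k: int) -> list[DesignEntry]:
        return self.designs[:k]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "objective_id": self.objective_id,
                    "status": self.status,
                    "provenance": self.provenance,
                    "designs": [
                        {
                            "compound_id": d.record.compound_id,
                            "smiles": d.record.smiles,
                            "rmsd_to_objective": d.rmsd_to_objective,
                            "tanimoto_to_objective": d.tanimoto_to_objective,
                        }
                        for d in self.designs
                    ],
                },
                indent=2,
            )
        )

    def to_smi(self, path: str | Path) -> None:
        write_smi([d.record for d in self.designs], path)


def filter_valid_unique(
    raw: list[str], id_prefix: str = "design"
) -> list[SmilesRecord]:
    """Keep parseable SMILES, canonicalize, deduplicate (first occurrence).

    Drops are logged, never fatal.
    """
    seen: set[str] = set()
    kept: list[SmilesRecord] = []
    n_invalid = 0
    for s in raw:
        if not is_valid_smiles(s):
            n_invalid += 1
            continue
        canon = canonicalize_smiles(s)
        if canon in seen or not canon:
            continue
        seen.add(canon)
        kept.append(SmilesRecord(compound_id=f"{id_prefix}{len(kept):04d}", smiles=canon))
    logger.info(
        "filter_valid_unique: %d raw -> %d kept (%d invalid, %d duplicate/empty)",
        len(raw), len(kept), n_invalid, len(raw) - len(kept) - n_invalid,
    )
    return kept


def design_for_objective(
    request: DesignRequest,
    reducer: TrainedReducer,
    model: CvaeModel,
    proteome: ProteomeLibrary,
) -> DesignSet:
    """Generate, filter, score, and rank designs for one objective.

    Draws ceil(n * oversample_factor) raw strings per round, up to
    ``max_rounds`` rounds, until n valid unique designs are collected (or
    returns fewer, with status "short"/"empty" and a logged warning).
    """
    if not reducer.trained or not model.trained:
        raise ValueError("reducer and CVAE must be trained before designing")
    objective_sig = compute_signature(request.objective, proteome)
    condition = reduce_signature(reducer, objective_sig).values

    unique: dict[str, SmilesRecord] = {}
    n_raw_total = 0
    rounds = 0
    if request.n_designs > 0:
        per_round = math.ceil(request.n_designs * request.oversample_factor)
        for rnd in range(request.max_rounds):
            rounds = rnd + 1
            raw = sample_designs(
                model, condition, per_round, seed=request.seed + 7919 * rnd
            )
            n_raw_total += len(raw)
            for rec in filter_valid_unique(raw):
                if rec.smiles not in unique:
                    unique[rec.smiles] = rec
            if len(unique) >= request.n_designs:
                break

    records = list(unique.values())[: request.n_designs]
    status = "ok"
    if request.n_designs > 0 and not records:
        status = "empty"
        logger.warning(
            "objective %s: no valid designs after %d raw samples",
            request.objective.compound_id, n_raw_total,
        )
    elif len(records) < request.n_designs:
        status = "short"
        logger.warning(
            "objective %s: only %d/%d valid unique designs",
            request.objective.compound_id, len(records), request.n_designs,
        )

    obj_fp = fingerprint(request.objective.smiles, n_bits=proteome.n_bits)
    entries = []
    for i, rec in enumerate(records):
        rec = SmilesRecord(
            compound_id=f"{request.objective.compound_id}_d{i:04d}", smiles=rec.smiles
        )
        sig = compute_signature(rec, proteome)
        entries.append(
            DesignEntry(
                record=rec,
                signature=sig,
                rmsd_to_objective=signature_rmsd(sig, objective_sig),
                tanimoto_to_objective=tanimoto(
                    fingerprint(rec.smiles, n_bits=proteome.n_bits), obj_fp
                ),
            )
        )
    entries.sort(key=lambda e: (e.rmsd_to_objective, e.record.compound_id))
    return DesignSet(
        objective_id=request.objective.compound_id,
        objective_signature=objective_sig,
        designs=entries,
        provenance={
            "seed": request.seed,
            "n_designs_requested": request.n_designs,
            "n_raw_sampled": n_raw_total,
            "n_valid_unique": len(unique),
            "rounds": rounds,
            "oversample_factor": request.oversample_factor,
        },
        status=status,
    )


def expand_designs(
    request: DesignRequest,
    reducer: TrainedReducer,
    model: CvaeModel,
    proteome: ProteomeLibrary,
) -> DesignSet:
    """Same contract as design_for_objective at larger n; the top-k subset
    of the returned (sorted) set is the best-k by signature RMSD."""
    return design_for_objective(request, reducer, model, proteome)
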