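"""Benchmarking protocol for the design pipeline.

For each objective compound the generated designs are compared against
three control sets by the distribution of full-signature RMSDs to the
objective:

* **random** — a seeded uniform sample of library compounds (naive
  control);
* **top-100** — the library compounds with the smallest signature RMSD to
  the objective (the structural-analog-biased, hardest control);
* **same indication** — library compounds sharing an indication with the
  objective (phenotype control).

Distributions are compared with two-sample Kolmogorov-Smirnov tests, and
per-design relative gains over the naive control are summarized as
*proximity*: P = (<RMSD_control> - RMSD_redesign) / <RMSD_control>.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.manifold import TSNE

from .chemio import SmilesRecord
from .cvae import CvaeModel
from .designer import DesignRequest, DesignSet, design_for_objective
from .reducer import TrainedReducer
from .signatures import (
    InteractionSignature,
    ProteomeLibrary,
    SignatureMatrix,
    rank_by_signature_similarity,
    signature_rmsd,
)
from .synthdata import IndicationMap

logger = logging.getLogger(__name__)


@dataclass
class ControlSet:
    kind: str  # "random" | "top100" | "same_indication"
    compounds: list[SmilesRecord]
    signatures: SignatureMatrix
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in {"random", "top100", "same_indication"}:
            raise ValueError(f"unknown control kind {self.kind!r}")

    def __len__(self) -> int:
        return len(self.compounds)

    def rmsds_to(self, objective: InteractionSignature) -> np.ndarray:
        diffs = self.signatures.values - objective.scores[None, :]
        return np.sqrt(np.mean(diffs**2, axis=1))


def make_random_control(
    corpus: Sequence[SmilesRecord],
    n: int,
    seed: int,
    signatures: SignatureMatrix,
) -> ControlSet:
    """Uniform sample of n corpus compounds without replacement, seeded."""
    if n > len(corpus):
        raise ValueError(f"cannot sample {n} from a corpus of {len(corpus)}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(corpus), size=n, replace=False)
    chosen = [corpus[i] for i in idx]
    return ControlSet(
        kind="random",
        compounds=chosen,
        signatures=signatures.subset([r.compound_id for r in chosen]),
        seed=seed,
    )


def make_top_control(
    objective: InteractionSignature,
    library: SignatureMatrix,
    n: int,
    corpus_by_id: dict[str, SmilesRecord],
) -> ControlSet:
    """The n library compounds most similar to the objective by signature
    RMSD, excluding the objective itself when present."""
    ranked = rank_by_signature_similarity(objective, library, n + 1)
    chosen_ids = [cid for cid, _ in ranked if cid != objective.compound_id][:n]
    return ControlSet(
        kind="top100",
        compounds=[corpus_by_id[c] for c in chosen_ids],
        signatures=library.subset(chosen_ids),
    )


def make_same_indication_control(
    objective_id: str,
    indication_map: IndicationMap,
    corpus: Sequence[SmilesRecord],
    signatures: SignatureMatrix,
) -> ControlSet:
    """All corpus compounds sharing an indication with the objective,
    objective excluded."""
    inds = indication_map.indications_of(objective_id)
    if not inds:
        raise ValueError(f"objective {objective_id!r} has no indication in the map")
    members: set[str] = set()
    for ind in inds:
        members.update(indication_map.members(ind))
    members.discard(objective_id)
    chosen = [r for r in corpus if r.compound_id in members]
    if not chosen:
        logger.warning(
            "objective %s is the sole member of its indication(s); empty control",
            objective_id,
        )
    return ControlSet(
        kind="same_indication",
        compounds=chosen,
        signatures=signatures.subset([r.compound_id for r in chosen]),
    )


def ks_two_sample(
    a: Sequence[float], b: Sequence[float], exact: bool = False
) -> tuple[float, float]:
    """Two-sided two-sample Kolmogorov-Smirnov test.

    Asymptotic p-value by default; exact small-sample p behind the flag.
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("K-S test requires non-empty samples")
    res = stats.ks_2samp(a, b, method="exact" if exact else "asymp")
    return float(res.statistic), float(res.pvalue)


def proximity(mean_control_rmsd: float, redesign_rmsd: float) -> float:
    """Relative improvement over the naive control:
    (<RMSD_control> - RMSD_redesign) / <RMSD_control>."""
    if mean_control_rmsd <= 0:
        raise ValueError("mean control RMSD must be positive")
    return (mean_control_rmsd - redesign_rmsd) / mean_control_rmsd


@dataclass
class ProximityStats:
    mean_control_rmsd: float
    per_design_proximity: list[float]

    @property
    def mean_proximity(self) -> float:
        return float(np.mean(self.per_design_proximity))


def proximity_stats(
    control_rmsds: Sequence[float], design_rmsds: Sequence[float]
) -> ProximityStats:
    mean_control = float(np.mean(control_rmsds))
    return ProximityStats(
        mean_control_rmsd=mean_control,
        per_design_proximity=[proximity(mean_control, r) for r in design_rmsds],
    )


def subset_proximity_compare(
    subset_a: Sequence[float], subset_b: Sequence[float]
) -> dict:
    """Compare two pooled proximity lists: per-subset means + two-sample K-S."""
    if len(subset_a) == 0 or len(subset_b) == 0:
        raise ValueError("both proximity lists must be non-empty")
    stat, p = ks_two_sample(subset_a, subset_b)
    return {
        "mean_a": float(np.mean(subset_a)),
        "mean_b": float(np.mean(subset_b)),
        "ks_statistic": stat,
        "ks_pvalue": p,
    }


def structural_diversity(designs: DesignSet) -> dict:
    """Mean/median/max Tanimoto of designs to their objective."""
    if len(designs) == 0:
        raise ValueError("empty design set")
    t = designs.tanimotos
    return {
        "mean_tanimoto": float(np.mean(t)),
        "median_tanimoto": float(np.median(t)),
        "max_tanimoto": float(np.max(t)),
        "n": int(len(t)),
    }


def box_stats(values: Sequence[float]) -> dict:
    """Box-plot order statistics: quartiles, median, 1.5*IQR whiskers,
    outliers beyond the whiskers."""
    v = np.sort(np.asarray(values, dtype=np.float64))
    if v.size == 0:
        raise ValueError("empty sample")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inliers = v[(v >= lo_fence) & (v <= hi_fence)]
    return {
        "q1": float(q1),
        "median": float(med),
        "q3": float(q3),
        "whisker_low": float(inliers.min()),
        "whisker_high": float(inliers.max()),
        "outliers": [float(x) for x in v[(v < lo_fence) | (v > hi_fence)]],
    }


def tsne_embed(
    signatures: SignatureMatrix,
    perplexity: float | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """2-D t-SNE embedding of signatures; deterministic for a fixed seed."""
    n = len(signatures)
    if n < 4:
        raise ValueError("t-SNE needs at least 4 signatures")
    if perplexity is None:
        perplexity = min(30.0, n // 4)
    if perplexity >= n:
        raise ValueError(f"perplexity {perplexity} must be < n {n}")
    coords = TSNE(
        n_components=2, perplexity=perplexity, random_state=seed, init="pca"
    ).fit_transform(signatures.values)
    return pd.DataFrame(
        {"compound_id": signatures.compound_ids, "x": coords[:, 0], "y": coords[:, 1]}
    )


@dataclass
class BenchmarkConfig:
    n_designs: int = 100
    n_random: int = 100
    n_top: int = 100
    include_tsne: bool = False
    tsne_perplexity: float | None = None
    seed: int = 0


@dataclass
class ObjectiveResult:
    objective_id: str
    design_set: DesignSet
    controls: dict[str, ControlSet]
    rmsd_distributions: dict[str, list[float]]
    ks: dict[str, tuple[float, float]]
    proximity: ProximityStats | None
    diversity: dict | None
    box: dict[str, dict]
    tsne: pd.DataFrame | None = None

    def median_beats(self, control_kind: str) -> bool:
        """Whether the design median RMSD is below the control's median."""
        d = self.rmsd_distributions
        if not d["design"] or not d[control_kind]:
            return False
        return float(np.median(d["design"])) < float(np.median(d[control_kind]))


@dataclass
class BenchmarkResult:
    config: BenchmarkConfig
    per_objective: dict[str, ObjectiveResult] = field(default_factory=dict)

    def median_win_count(self, control_kind: str) -> int:
        return sum(
            r.median_beats(control_kind) for r in self.per_objective.values()
        )

    def pooled_tanimoto_mean(self) -> float:
        vals = np.concatenate(
            [r.design_set.tanimotos for r in self.per_objective.values()]
        )
        return float(np.mean(vals))

    def pooled_proximities(self, objective_ids: Sequence[str] | None = None) -> list[float]:
        out: list[float] = []
        for oid, r in self.per_objective.items():
            if objective_ids is not None and oid not in objective_ids:
                continue
            if r.proximity is not None:
                out.extend(r.proximity.per_design_proximity)
        return out

    def to_json(self, path: str | Path) -> None:
        payload = {
            "config": {
                "n_designs": self.config.n_designs,
                "n_random": self.config.n_random,
                "n_top": self.config.n_top,
                "seed": self.config.seed,
            },
            "summary": {
                "n_objectives": len(self.per_objective),
                "median_wins_vs_random": self.median_win_count("random"),
                "median_wins_vs_top100": self.median_win_count("top100"),
                "median_wins_vs_same_indication": self.median_win_count(
                    "same_indication"
                ),
                "pooled_mean_tanimoto": self.pooled_tanimoto_mean(),
            },
            "objectives": {
                oid: {
                    "status": r.design_set.status,
                    "rmsd_distributions": r.rmsd_distributions,
                    "ks": {k: list(v) for k, v in r.ks.items()},
                    "mean_proximity": (
                        r.proximity.mean_proximity if r.proximity else None
                    ),
                    "diversity": r.diversity,
                    "box": r.box,
                }
                for oid, r in self.per_objective.items()
            },
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def run_benchmark(
    objectives: Sequence[SmilesRecord],
    corpus: Sequence[SmilesRecord],
    proteome: ProteomeLibrary,
    reducer: TrainedReducer,
    model: CvaeModel,
    signatures: SignatureMatrix,
    indication_map: IndicationMap | None = None,
    config: BenchmarkConfig | None = None,
) -> BenchmarkResult:
    """Run the full protocol: per objective, a design set, three controls,
    four RMSD distributions, K-S per design-control pair, proximity,
    diversity, box statistics, and (optionally) a t-SNE embedding."""
    config = config or BenchmarkConfig()
    corpus_by_id = {r.compound_id: r for r in corpus}
    result = BenchmarkResult(config=config)
    for i, objective in enumerate(objectives):
        oid = objective.compound_id
        try:
            design_set = design_for_objective(
                DesignRequest(
                    objective=objective,
                    n_designs=config.n_designs,
                    seed=config.seed + 104729 * (i + 1),
                ),
                reducer,
                model,
                proteome,
            )
            obj_sig = design_set.objective_signature
            controls: dict[str, ControlSet] = {
                "random": make_random_control(
                    corpus, config.n_random, config.seed + 15485863 * (i + 1), signatures
                ),
                "top100": make_top_control(
                    obj_sig, signatures, config.n_top, corpus_by_id
                ),
            }
            if indication_map is not None:
                controls["same_indication"] = make_same_indication_control(
                    oid, indication_map, corpus, signatures
                )
        except Exception as exc:
            raise RuntimeError(f"benchmark failed at objective {oid!r}: {exc}") from exc

        dists: dict[str, list[float]] = {
            "design": [float(x) for x in design_set.rmsds]
        }
        for kind, ctl in controls.items():
            dists[kind] = [float(x) for x in ctl.rmsds_to(obj_sig)]
        ks = {
            kind: ks_two_sample(dists["design"], dists[kind])
            for kind in controls
            if dists["design"] and dists[kind]
        }
        prox = (
            proximity_stats(dists["random"], dists["design"])
            if dists["design"] and dists["random"]
            else None
        )
        diversity = structural_diversity(design_set) if len(design_set) else None
        box = {k: box_stats(v) for k, v in dists.items() if v}
        tsne = None
        if config.include_tsne:
            ids: list[str] = [oid]
            rows: list[np.ndarray] = [obj_sig.scores]
            for d in design_set.designs:
                ids.append(d.record.compound_id)
                rows.append(d.signature.scores)
            for ctl in controls.values():
                for cid, row in zip(ctl.signatures.compound_ids, ctl.signatures.values):
                    if cid not in ids:  # controls may overlap
                        ids.append(cid)
                        rows.append(row)
            all_sigs = SignatureMatrix(
                compound_ids=ids,
                values=np.vstack(rows),
                protein_ids=signatures.protein_ids,
            )
            tsne = tsne_embed(
                all_sigs, perplexity=config.tsne_perplexity, seed=config.seed
            )
        result.per_objective[oid] = ObjectiveResult(
            objective_id=oid,
            design_set=design_set,
            controls=controls,
            rmsd_distributions=dists,
            ks=ks,
            proximity=prox,
            diversity=diversity,
            box=box,
            tsne=tsne,
        )
        logger.info(
            "objective %s: design median %.4f, random median %.4f",
            oid,
            np.median(dists["design"]) if dists["design"] else np.nan,
            np.median(dists["random"]),
        )
    return result
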