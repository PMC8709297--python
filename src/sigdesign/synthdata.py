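"""Seeded generators for synthetic proteomes, SMILES corpora, indication
maps, and complete benchmark scenarios.

The generators emulate the three inputs of the real pipeline without any
downloads:

* a **compound corpus** of valence-valid SMILES, built compositionally from
  a safe fragment grammar (chain units over C/N/O/S with double/triple
  bonds, branches, and simple rings) so every emitted string parses;
* a **proteome** whose binding sites hold ligand fingerprints drawn from a
  shared ligand pool — sharing induces correlated signature columns, the
  low-rank structure the autoencoder must exploit;
* an **indication map** derived from signature clusters, so the
  same-indication control groups behaviorally related compounds.

Chemotype structure: compounds are sampled from a mixture of *families*,
each family favoring its own subset of grammar units, and each protein's
pool draws are biased toward one family's ligands. Real compound libraries
are likewise clustered into chemotype series with correlated target
profiles; this is the structure that makes the condition vector
informative about which region of chemical space to generate in.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.cluster import KMeans

from .chemio import (
    Fingerprint,
    SmilesRecord,
    fingerprint,
    is_valid_smiles,
    tanimoto,
    write_smi,
)
from .signatures import (
    BindingSite,
    ProteomeLibrary,
    SignatureMatrix,
    compute_signature_matrix,
)

#: Chain units: every unit can take a single bond on each end without
#: exceeding any atom's valence, so arbitrary concatenations stay valid.
GRAMMAR_UNITS: tuple[str, ...] = (
    "C",
    "CC",
    "CCC",
    "N",
    "O",
    "S",
    "C(C)",
    "C(O)",
    "C(N)",
    "C(C)(C)",
    "C(=O)",
    "C(=O)N",
    "C=C",
    "C#C",
    "C(C#N)",
    "C1CCCCC1",
    "C1CCCC1",
    "c1ccccc1",
    "c1ccncc1",
    "C1CCNCC1",
    "C1CCOCC1",
)


@dataclass
class SynthConfig:
    n_proteins: int = 100
    sites_per_protein: tuple[int, int] = (1, 3)
    ligands_per_site: tuple[int, int] = (1, 3)
    ligand_pool_size: int = 60
    pool_sharing: float = 0.8
    corpus_size: int = 2000
    max_smiles_len: int = 40
    n_indications: int = 8
    n_families: int = 8
    n_objectives: int = 20
    holdout_threshold: float = 0.9
    n_bits: int = 1024
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_proteins",
            "ligand_pool_size",
            "corpus_size",
            "max_smiles_len",
            "n_indications",
            "n_families",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 <= self.pool_sharing <= 1):
            raise ValueError("pool_sharing must lie in [0, 1]")
        if self.corpus_size <= self.n_objectives:
            raise ValueError("corpus_size must exceed n_objectives")


@dataclass
class IndicationMap:
    """(compound_id, indication_id) association table."""

    pairs: list[tuple[str, str]]
    _by_compound: dict[str, list[str]] = field(init=False, repr=False)
    _by_indication: dict[str, list[str]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._by_compound = {}
        self._by_indication = {}
        for cid, ind in self.pairs:
            self._by_compound.setdefault(cid, []).append(ind)
            self._by_indication.setdefault(ind, []).append(cid)

    def indications_of(self, compound_id: str) -> list[str]:
        return self._by_compound.get(compound_id, [])

    def members(self, indication_id: str) -> list[str]:
        return self._by_indication.get(indication_id, [])

    def to_tsv(self, path: str | Path) -> None:
        lines = ["compound_id\tindication_id"] + [
            f"{c}\t{i}" for c, i in self.pairs
        ]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "IndicationMap":
        lines = Path(path).read_text().splitlines()
        pairs = [tuple(l.split("\t")) for l in lines[1:] if l.strip()]
        return cls(pairs=[(c, i) for c, i in pairs])


def _family_profiles(n_families: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-sampling weights per family: each family concentrates on its
    own subset of grammar units, with a little mass everywhere."""
    n_units = len(GRAMMAR_UNITS)
    profiles = np.full((n_families, n_units), 0.02)
    for f in range(n_families):
        favored = rng.choice(n_units, size=6, replace=False)
        profiles[f, favored] += rng.dirichlet(np.ones(6)) * 1.0
    return profiles / profiles.sum(axis=1, keepdims=True)


def make_compound(
    rng: np.random.Generator,
    max_smiles_len: int = 40,
    unit_weights: np.ndarray | None = None,
    compound_id: str = "synth",
) -> SmilesRecord:
    """Draw one valence-valid SMILES from the fragment grammar.

    Units are concatenated with single bonds until a length budget drawn in
    [10, max_smiles_len] would be exceeded. The grammar guarantees
    validity by construction; the string is parse-checked anyway, with
    internal retries.
    """
    if unit_weights is None:
        unit_weights = np.full(len(GRAMMAR_UNITS), 1.0 / len(GRAMMAR_UNITS))
    for _ in range(100):
        budget = int(rng.integers(10, max_smiles_len + 1))
        parts: list[str] = []
        length = 0
        while True:
            unit = GRAMMAR_UNITS[int(rng.choice(len(GRAMMAR_UNITS), p=unit_weights))]
            if length + len(unit) > budget:
                break
            parts.append(unit)
            length += len(unit)
        smiles = "".join(parts)
        if smiles and is_valid_smiles(smiles):
            return SmilesRecord(compound_id=compound_id, smiles=smiles)
    raise RuntimeError("fragment grammar failed to produce a valid SMILES")


def make_corpus(
    config: SynthConfig, rng: np.random.Generator, profiles: np.ndarray
) -> tuple[list[SmilesRecord], dict[str, int]]:
    """Corpus of corpus_size compounds from the family mixture."""
    records: list[SmilesRecord] = []
    family_of: dict[str, int] = {}
    seen: set[str] = set()
    i = 0
    while len(records) < config.corpus_size:
        fam = int(rng.integers(config.n_families))
        rec = make_compound(
            rng,
            config.max_smiles_len,
            unit_weights=profiles[fam],
            compound_id=f"c{i:05d}",
        )
        i += 1
        if rec.smiles in seen:
            continue
        seen.add(rec.smiles)
        records.append(rec)
        family_of[rec.compound_id] = fam
    return records, family_of


def make_proteome(
    config: SynthConfig,
    rng: np.random.Generator | None = None,
    profiles: np.ndarray | None = None,
    return_ligand_smiles: bool = False,
):
    """Synthetic proteome with site ligands drawn from a shared pool.

    Each site ligand is a pooled ligand with probability ``pool_sharing``
    (biased toward the protein's own family's pool members), otherwise a
    freshly drawn compound. Higher sharing means more proteins respond to
    the same substructures, hence more correlated signature columns.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if profiles is None:
        profiles = _family_profiles(config.n_families, rng)

    pool: list[SmilesRecord] = []
    pool_family: list[int] = []
    for j in range(config.ligand_pool_size):
        fam = j % config.n_families
        pool.append(
            make_compound(
                rng, config.max_smiles_len, profiles[fam], compound_id=f"pool{j:04d}"
            )
        )
        pool_family.append(fam)
    pool_fps = [fingerprint(r.smiles, n_bits=config.n_bits) for r in pool]
    pool_family_arr = np.array(pool_family)

    proteins: list[str] = []
    sites: dict[str, list[BindingSite]] = {}
    ligand_smiles: dict[str, list[tuple[str, str]]] = {}
    lo_s, hi_s = config.sites_per_protein
    lo_l, hi_l = config.ligands_per_site
    for p in range(config.n_proteins):
        pid = f"p{p:04d}"
        proteins.append(pid)
        ligand_smiles[pid] = []
        fam = p % config.n_families
        fam_pool_idx = np.flatnonzero(pool_family_arr == fam)
        protein_sites: list[BindingSite] = []
        n_sites = int(rng.integers(lo_s, hi_s + 1))
        for s in range(n_sites):
            sid = f"{pid}_s{s}"
            ligands: list[Fingerprint] = []
            for _ in range(int(rng.integers(lo_l, hi_l + 1))):
                if rng.random() < config.pool_sharing and len(pool) > 0:
                    # pooled ligand, biased toward the protein's family
                    if len(fam_pool_idx) > 0 and rng.random() < 0.8:
                        k = int(rng.choice(fam_pool_idx))
                    else:
                        k = int(rng.integers(len(pool)))
                    ligands.append(pool_fps[k])
                    ligand_smiles[pid].append((sid, pool[k].smiles))
                else:
                    fresh = make_compound(rng, config.max_smiles_len, profiles[fam])
                    ligands.append(fingerprint(fresh.smiles, n_bits=config.n_bits))
                    ligand_smiles[pid].append((sid, fresh.smiles))
            protein_sites.append(
                BindingSite(protein_id=pid, site_id=sid, ligands=ligands)
            )
        sites[pid] = protein_sites
    proteome = ProteomeLibrary(proteins=proteins, sites=sites, n_bits=config.n_bits)
    if return_ligand_smiles:
        return proteome, pool, ligand_smiles
    return proteome, pool


def make_indication_map(
    corpus: list[SmilesRecord],
    signatures: SignatureMatrix,
    n_indications: int,
    seed: int = 0,
) -> IndicationMap:
    """Cluster compounds by signature similarity into indication groups.

    Compounds with similar interaction signatures are assumed to behave
    similarly, so indications are taken to be signature clusters (k-means,
    seeded). Every compound gets exactly one indication.
    """
    if not corpus:
        raise ValueError("empty corpus")
    sub = signatures.subset([r.compound_id for r in corpus])
    n_clusters = min(n_indications, len(corpus))
    km = KMeans(n_clusters=n_clusters, random_state=seed, n_init=10)
    labels = km.fit_predict(sub.values)
    pairs = [
        (rec.compound_id, f"ind{int(lab):03d}")
        for rec, lab in zip(corpus, labels)
    ]
    return IndicationMap(pairs=pairs)


def holdout_filter(
    corpus: list[SmilesRecord],
    objectives: list[SmilesRecord],
    threshold: float = 0.9,
    n_bits: int = 1024,
) -> list[SmilesRecord]:
    """Drop corpus compounds with Tanimoto >= threshold to any objective.

    Objectives themselves always have Tanimoto 1.0 to themselves and are
    therefore removed whenever present.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must lie in (0, 1]")
    obj_fps = [fingerprint(o.smiles, n_bits=n_bits) for o in objectives]
    kept = []
    for rec in corpus:
        fp = fingerprint(rec.smiles, n_bits=n_bits)
        if all(tanimoto(fp, ofp) < threshold for ofp in obj_fps):
            kept.append(rec)
    return kept


@dataclass
class BenchmarkScenario:
    """A complete desk-scale study: proteome, corpus, held-out objectives,
    precomputed signatures, and an indication map, all from one seed."""

    config: SynthConfig
    proteome: ProteomeLibrary
    ligand_pool: list[SmilesRecord]
    corpus: list[SmilesRecord]
    training: list[SmilesRecord]
    objectives: list[SmilesRecord]
    signatures: SignatureMatrix
    indications: IndicationMap
    family_of: dict[str, int]
    proteome_ligand_smiles: dict[str, list[tuple[str, str]]] | None = None

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_smi(self.corpus, out / "corpus.smi")
        write_smi(self.training, out / "training.smi")
        write_smi(self.objectives, out / "objectives.smi")
        self.signatures.to_tsv(out / "signatures.tsv")
        self.indications.to_tsv(out / "indications.tsv")
        if self.proteome_ligand_smiles is not None:
            self.proteome.to_tsv(out / "proteome.tsv", self.proteome_ligand_smiles)
        manifest = {
            "config": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in vars(self.config).items()
            },
            "counts": {
                "corpus": len(self.corpus),
                "training": len(self.training),
                "objectives": len(self.objectives),
                "proteins": len(self.proteome),
            },
            "files": [
                "corpus.smi", "training.smi", "objectives.smi",
                "signatures.tsv", "indications.tsv", "proteome.tsv",
            ],
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def make_benchmark_scenario(
    config: SynthConfig, profiles: np.ndarray | None = None
) -> BenchmarkScenario:
    """Generate a reproducible desk-scale twin of the benchmark study.

    Objectives are drawn from the corpus (spread over families) and then
    excluded from the training corpus together with everything >= the
    holdout threshold in Tanimoto similarity to them. Family unit profiles
    are drawn from the seed unless given explicitly (n_families rows of
    unit weights), e.g. to construct well-separated chemotype clusters.
    """
    rng = np.random.default_rng(config.seed)
    if profiles is None:
        profiles = _family_profiles(config.n_families, rng)
    elif profiles.shape != (config.n_families, len(GRAMMAR_UNITS)):
        raise ValueError(
            f"profiles must have shape ({config.n_families}, {len(GRAMMAR_UNITS)})"
        )
    proteome, pool, ligand_smiles = make_proteome(
        config, rng, profiles, return_ligand_smiles=True
    )
    corpus, family_of = make_corpus(config, rng, profiles)
    signatures = compute_signature_matrix(corpus, proteome)

    # objectives spread across families: round-robin over family buckets
    by_family: dict[int, list[SmilesRecord]] = {}
    for rec in corpus:
        by_family.setdefault(family_of[rec.compound_id], []).append(rec)
    objectives: list[SmilesRecord] = []
    fam_order = sorted(by_family)
    k = 0
    while len(objectives) < config.n_objectives:
        fam = fam_order[k % len(fam_order)]
        bucket = by_family[fam]
        if bucket:
            idx = int(rng.integers(len(bucket)))
            objectives.append(bucket.pop(idx))
        k += 1
    objective_ids = {o.compound_id for o in objectives}

    non_objectives = [r for r in corpus if r.compound_id not in objective_ids]
    training = holdout_filter(
        non_objectives, objectives, config.holdout_threshold, config.n_bits
    )
    indications = make_indication_map(
        corpus, signatures, config.n_indications, seed=config.seed
    )
    return BenchmarkScenario(
        config=config,
        proteome=proteome,
        ligand_pool=pool,
        corpus=corpus,
        training=training,
        objectives=objectives,
        signatures=signatures,
        indications=indications,
        family_of=family_of,
        proteome_ligand_smiles=ligand_smiles,
    )


_KNOWN_DRUGS = [
    ("aspirin", "CC(=O)Oc1ccccc1C(=O)O"),
    ("caffeine", "Cn1cnc2c1c(=O)n(C)c(=O)n2C"),
    ("ibuprofen", "CC(C)Cc1ccc(C(C)C(=O)O)cc1"),
    ("paracetamol", "CC(=O)Nc1ccc(O)cc1"),
    ("naproxen", "COc1ccc2cc(C(C)C(=O)O)ccc2c1"),
    ("nicotine", "CN1CCCC1c1cccnc1"),
    ("benzocaine", "CCOC(=O)c1ccc(N)cc1"),
    ("procaine", "CCN(CC)CCOC(=O)c1ccc(N)cc1"),
    ("lidocaine", "CCN(CC)CC(=O)Nc1c(C)cccc1C"),
    ("metformin", "CN(C)C(=N)NC(=N)N"),
    ("phenobarbital", "CCC1(c2ccccc2)C(=O)NC(=O)NC1=O"),
    ("valproate", "CCCC(CCC)C(=O)O"),
    ("warfarin", "CC(=O)CC(c1ccccc1)c1c(O)c2ccccc2oc1=O"),
    ("diazepam", "CN1c2ccc(Cl)cc2C(c2ccccc2)=NCC1=O"),
    ("fluoxetine", "CNCCC(Oc1ccc(C(F)(F)F)cc1)c1ccccc1"),
    ("sertraline", "CNC1CCC(c2ccc(Cl)c(Cl)c2)c2ccccc21"),
    ("atenolol", "CC(C)NCC(O)COc1ccc(CC(N)=O)cc1"),
    ("propranolol", "CC(C)NCC(O)COc1cccc2ccccc12"),
    ("salbutamol", "CC(C)(C)NCC(O)c1ccc(O)c(CO)c1"),
    ("amphetamine", "CC(N)Cc1ccccc1"),
    ("ephedrine", "CNC(C)C(O)c1ccccc1"),
    ("chlorpromazine", "CN(C)CCCN1c2ccccc2Sc2ccc(Cl)cc21"),
    ("haloperidol", "O=C(CCCN1CCC(O)(c2ccc(Cl)cc2)CC1)c1ccc(F)cc1"),
    ("ketamine", "CNC1(c2ccccc2Cl)CCCCC1=O"),
    ("tramadol", "COc1cccc(C2(O)CCCCC2CN(C)C)c1"),
    ("codeine", "COc1ccc2CC3C4C=CC(O)C5Oc1c2C45CCN3C"),
    ("atropine", "CN1C2CCC1CC(OC(=O)C(CO)c1ccccc1)C2"),
    ("cocaine", "COC(=O)C1C(OC(=O)c2ccccc2)CC2CCC1N2C"),
    ("quinine", "COc1ccc2nccc(C(O)C3CC4CCN3CC4C=C)c2c1"),
    ("chloroquine", "CCN(CC)CCCC(C)Nc1ccnc2cc(Cl)ccc12"),
    ("isoniazid", "NNC(=O)c1ccncc1"),
    ("metronidazole", "Cc1ncc([N+](=O)[O-])n1CCO"),
    ("sulfamethoxazole", "Cc1cc(NS(=O)(=O)c2ccc(N)cc2)no1"),
    ("trimethoprim", "COc1cc(Cc2cnc(N)nc2N)cc(OC)c1OC"),
    ("ciprofloxacin", "O=C(O)c1cn(C2CC2)c2cc(N3CCNCC3)c(F)cc2c1=O"),
    ("penicillin_g", "CC1(C)SC2C(NC(=O)Cc3ccccc3)C(=O)N2C1C(=O)O"),
    ("cephalexin", "CC1=C(C(=O)O)N2C(=O)C(NC(=O)C(N)c3ccccc3)C2SC1"),
    ("zidovudine", "Cc1cn(C2CC(N=[N+]=[N-])C(CO)O2)c(=O)[nH]c1=O"),
    ("acyclovir", "Nc1nc2c(c(=O)[nH]1)ncn2COCCO"),
    ("allopurinol", "O=c1[nH]cnc2[nH]ncc12"),
    ("theophylline", "Cn1c(=O)c2[nH]cnc2n(C)c1=O"),
    ("omeprazole", "COc1ccc2[nH]c(S(=O)Cc3ncc(C)c(OC)c3C)nc2c1"),
    ("ranitidine", "CNC(=CN(=O)=O)NCCSCc1ccc(CN(C)C)o1"),
    ("cimetidine", "CC1=C(CSCCNC(=NC)NC#N)N=CN1"),
    ("captopril", "CC(CS)C(=O)N1CCCC1C(=O)O"),
    ("enalapril", "CCOC(=O)C(CCc1ccccc1)NC(C)C(=O)N1CCCC1C(=O)O"),
    ("losartan", "CCCCc1nc(Cl)c(CO)n1Cc1ccc(-c2ccccc2-c2nnn[nH]2)cc1"),
    ("nifedipine", "COC(=O)C1=C(C)NC(C)=C(C(=O)OC)C1c1ccccc1[N+](=O)[O-]"),
    ("simvastatin", "CCC(C)(C)C(=O)OC1CC(C)C=C2C=CC(C)C(CCC3CC(O)CC(=O)O3)C21"),
    ("gabapentin", "NCC1(CC(=O)O)CCCCC1"),
]


def load_known_drugs() -> list[SmilesRecord]:
    """A small bundled list of well-known drug SMILES for smoke tests."""
    return [SmilesRecord(compound_id=name, smiles=smi) for name, smi in _KNOWN_DRUGS]
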