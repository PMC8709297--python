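from dataclasses import dataclass

import numpy as np
import pytest

from sigdesign.chemio import Fingerprint, SmilesRecord, build_vocabulary, fingerprint
from sigdesign.cvae import CvaeConfig, CvaeModel, build_cvae, train_cvae
from sigdesign.reducer import (
    ReducerConfig,
    TrainedReducer,
    build_reducer,
    reduce_matrix,
    train_reducer,
)
from sigdesign.signatures import BindingSite, ProteomeLibrary
from sigdesign.synthdata import BenchmarkScenario, SynthConfig, make_benchmark_scenario


def fp_from_bits(on_bits, n_bits=16):
    bits = np.zeros(n_bits, dtype=bool)
    bits[list(on_bits)] = True
    return Fingerprint(bits=bits, n_bits=n_bits)


@pytest.fixture
def tiny_corpus():
    return [
        SmilesRecord("a", "CCO"),
        SmilesRecord("b", "CC=O"),
        SmilesRecord("c", "c1ccccc1"),
        SmilesRecord("d", "CCN"),
    ]


@pytest.fixture
def tiny_vocab(tiny_corpus):
    return build_vocabulary(tiny_corpus, seq_len=12)


def toy_proteome(ligand_smiles_by_protein, n_bits=1024):
    """Build a proteome from {protein_id: [[site1 ligand smiles...], ...]}."""
    proteins, sites = [], {}
    for pid, site_lists in ligand_smiles_by_protein.items():
        proteins.append(pid)
        sites[pid] = [
            BindingSite(
                protein_id=pid,
                site_id=f"{pid}_s{i}",
                ligands=[fingerprint(s, n_bits=n_bits) for s in ligs],
            )
            for i, ligs in enumerate(site_lists)
        ]
    return ProteomeLibrary(proteins=proteins, sites=sites, n_bits=n_bits)


@dataclass
class Pipeline:
    """A trained desk-scale pipeline shared across tests."""

    scenario: BenchmarkScenario
    reducer: TrainedReducer
    model: CvaeModel


def train_pipeline(
    synth: SynthConfig,
    reducer_epochs: int = 20,
    cvae_epochs: int = 20,
    latent: int = 8,
    hidden: int = 48,
    seed: int = 7,
    profiles: np.ndarray | None = None,
) -> Pipeline:
    scenario = make_benchmark_scenario(synth, profiles=profiles)
    train_ids = [r.compound_id for r in scenario.training]
    train_sigs = scenario.signatures.subset(train_ids)
    reducer = train_reducer(
        build_reducer(
            ReducerConfig.desk(
                input_dim=len(scenario.proteome),
                latent_dim=latent,
                epochs_max=reducer_epochs,
                seed=seed,
            )
        ),
        train_sigs,
    )
    latents = reduce_matrix(reducer, train_sigs)
    cfg = CvaeConfig(
        seq_len=synth.max_smiles_len,
        latent_dim=latent,
        condition_dim=latent,
        hidden_width=hidden,
        epochs_max=cvae_epochs,
        learning_rate=3e-3,
        seed=seed,
    )
    vocab = build_vocabulary(scenario.training, cfg.seq_len)
    model = train_cvae(
        build_cvae(cfg, vocab),
        [(rec, latents[i]) for i, rec in enumerate(scenario.training)],
    )
    return Pipeline(scenario=scenario, reducer=reducer, model=model)


@pytest.fixture(scope="session")
def mini_pipeline():
    """Small trained pipeline: 30 proteins, 200-compound corpus, 3 objectives."""
    return train_pipeline(
        SynthConfig(
            n_proteins=30,
            ligand_pool_size=24,
            corpus_size=200,
            n_indications=4,
            n_families=4,
            n_objectives=3,
            seed=7,
        )
    )


@pytest.fixture
def small_proteome():
    return toy_proteome(
        {
            "p1": [["CCO", "CCC"]],
            "p2": [["c1ccccc1"], ["CCN", "CCCN"]],
            "p3": [[]],
            "p4": [["CC(=O)O"]],
        }
    )
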