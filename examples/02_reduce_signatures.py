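"""Compress interaction signatures with the dense autoencoder.

Signature columns are correlated (proteins share binding-site ligands), so
a short latent code captures most of the variance. The script trains a
desk-scale autoencoder on a synthetic signature matrix and reports the
reconstruction RMSD against an untrained model of the same architecture.
The latent vectors are the condition vectors used by the generative model.
"""

from sigdesign.reducer import (
    ReducerConfig, build_reducer, reduce_matrix, reducer_loss, train_reducer,
)
from sigdesign.synthdata import SynthConfig, make_benchmark_scenario

scenario = make_benchmark_scenario(
    SynthConfig(n_proteins=100, corpus_size=500, n_objectives=5, seed=8)
)
matrix = scenario.signatures

config = ReducerConfig.desk(input_dim=100, latent_dim=16, epochs_max=25, seed=8)
trained = train_reducer(build_reducer(config), matrix)
untrained = build_reducer(config)

x = matrix.values
print(f"signature matrix: {x.shape[0]} compounds x {x.shape[1]} proteins")
print(f"encoder widths: {config.encoder_widths} (latent {config.latent_dim})")
print(f"epochs run: {len(trained.training_log)}")
print(f"reconstruction RMSD untrained: {reducer_loss(x, untrained.autoencode_array(x)):.4f}")
print(f"reconstruction RMSD trained:   {reducer_loss(x, trained.autoencode_array(x)):.4f}")
latents = reduce_matrix(trained, matrix)
print(f"condition vectors: {latents.shape} — 100-dim signatures captured in "
      f"{latents.shape[1]} numbers per compound")
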