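# Methods

## Overview

`sigdesign` implements a proteome-conditioned generative design pipeline in
four stages:

1. **Interaction signatures.** A compound's predicted proteome-scale
   behavior is summarized as a vector of per-protein interaction scores.
   The score against a protein is a ligand-homology proxy for binding: the
   maximum Tanimoto coefficient between the compound's binary substructure
   fingerprint and the fingerprints of all ligands associated with any of
   the protein's predicted binding sites. A protein with no site ligands
   contributes 0 (no evidence of interaction) and is retained in the
   vector so coordinate order always matches the library manifest.
2. **Signature reduction.** A dense autoencoder compresses the full
   signature to a short latent code (the *condition vector*). Signature
   columns are strongly correlated — proteins share binding-site ligands —
   so a short code captures most of the variance.
3. **Conditional generation.** A conditional variational autoencoder
   (CVAE) over one-hot-encoded SMILES strings learns
   P(compound | condition). Generation samples the latent prior under the
   objective's condition vector and decodes greedily.
4. **Benchmarking.** Designs are re-scored against the proteome and their
   RMSD-to-objective distribution is compared against three controls
   (random, top-100 nearest by signature, same indication) with
   two-sample Kolmogorov–Smirnov tests, proximity summaries, box
   statistics, and optional t-SNE embeddings.

## Interaction scoring

* Fingerprints: Morgan (circular substructure) fingerprints, radius 2,
  1024 bits (RDKit). The scoring rule only assumes a binary
  presence/absence encoding; scheme, radius and length are configurable
  and recorded in outputs.
* Tanimoto of two empty fingerprints is defined as 0: an empty fingerprint
  carries no evidence of similarity, and this avoids 0/0.
* Multi-site proteins use the strongest site ligand match ("the strongest
  interaction is used"); signature entries therefore lie in [0, 1].
* Signatures are compared by RMSD over all coordinates. Benchmark RMSDs
  are always computed on full-length signatures; the reduced code is a
  training device only.

## Signature autoencoder

Architecture: densely connected encoder with ReLU hidden activations and
a linear latent layer; the decoder mirrors the encoder, with a linear
output (signatures live in [0,1], but clamping is never applied inside the
loss). Two presets:

* `paper2021`: input 14606, encoder widths
  10000/7750/5500/2250/2000/1250/1000/500/250/200 (latent 200) — the
  full-scale schedule, retained for completeness.
* `desk` (default for tests and the acceptance run): geometric schedule
  from the input dimension down to a configurable latent (100 → 64 → 32 →
  16 by default).

Training: Adam (lr 1e-3 default), minibatches of 32, loss = RMSD between
input and reconstruction. A validation fraction of 1/6 mirrors a
250k/50k-style split; training stops when validation loss has risen for
`patience = 2` consecutive epochs ("until over-fitting is observed") and
the best-validation checkpoint is restored. All initialization and
shuffling is driven by the config seed, so training logs are bit-stable
per platform.

## Conditional VAE

Tokenization is character-level: the vocabulary is the sorted set of
unique characters in the training corpus plus one padding token (a space,
which cannot occur in SMILES). Two-character element symbols (Cl, Br)
would be split under this scheme — a known fidelity trade-off of
character-level tokenization; the synthetic grammar avoids such elements.

* **Encoder**: the one-hot SMILES matrix with the condition vector
  appended to every row runs through a stack of LSTM cells; the final
  hidden state feeds two parallel dense heads for the posterior mean and
  standard deviation (σ parameterized as exp(log σ)).
* **Latent**: z = μ + σ⊙ε with seeded ε (reparameterization).
* **Decoder**: an autoregressive LSTM stack. Step t's input is the
  previous token's one-hot vector with [z, c] re-appended — the latent and
  condition are repeated at every time step. Training uses teacher forcing
  (ground-truth previous token); generation feeds back the argmax token.
  A per-position softmax head emits token probabilities; decoding takes
  the argmax per slot, truncating at the first padding token, with ties
  broken toward the lowest vocabulary index. No beam search.
* **Loss**: per-token cross-entropy reconstruction error plus
  `kl_weight` × KL(N(μ, σ²) ‖ N(0, I)), averaged over the batch. The KL
  is taken against the standard-normal prior over z — the conventional
  conditional ELBO. `kl_weight` defaults to 1.0 with a linear warm-up over
  the first 10% of epochs, which stabilizes small-corpus training.
* **Conditions** are standardized (per-dimension z-score against training
  statistics, recorded in the model) before entering either network; raw
  autoencoder latents are unbounded and poorly scaled otherwise.
* Training stops at `epochs_max` or when the relative epoch-loss
  improvement stays below 1e-4 for `patience = 3` consecutive epochs.

An earlier design fed the decoder only the constant [z, c] pair at every
step, with no token feedback. At desk scale that decoder collapses to
degenerate low-entropy strings (long carbon chains); the autoregressive
decoder above is the design this package ships.

Generation-time z is sampled from the standard-normal prior; the condition
is the reduced signature of the objective compound. Desk defaults: hidden
width 64, latent 16, sequence length 40, one LSTM cell per side. The
`paper2021` preset keeps latent/condition 200 and three cells per side.

## Design loop

For an objective compound: compute its full signature, reduce it to the
condition vector, sample ⌈n × oversample⌉ raw strings from the prior
(oversample factor 3, up to 5 retry rounds), keep parseable SMILES,
canonicalize, deduplicate, truncate to n (status "short"/"empty" with a
logged warning when fewer survive), re-score every design against the
proteome, and rank ascending by signature RMSD (ties broken by compound
id). Each design also records its Morgan-Tanimoto similarity to the
objective, the structural-diversity readout.

## Benchmark protocol

Per objective: 100 designs and three controls — (a) a seeded uniform
random sample of library compounds, (b) the library compounds with
smallest signature RMSD to the objective (objective excluded), (c) all
library compounds sharing an indication with the objective. Design and
control RMSD distributions are compared with two-sided two-sample K-S
tests (asymptotic p by default, exact behind a flag). Proximity,
P = (⟨RMSD_random⟩ − RMSD_design)/⟨RMSD_random⟩, summarizes each design's
relative gain over the naive control; subset comparisons pool proximities
and compare means plus a K-S test. Box statistics use quartiles and
1.5×IQR whiskers with explicit outliers. t-SNE embeddings (seeded,
PCA-initialized, perplexity min(30, ⌊n/4⌋) by default) visualize the
objective/design/control geometry.

The same-indication control is a direct indication-map lookup. (The
original protocol used a full indication-prediction pipeline; the lookup
preserves the phenotype-control semantics at desk scale.) No size cap is
applied to same-indication sets.

## Synthetic data generator

The generator emulates the pipeline's three inputs with no downloads:

* **Compounds** are built from a fragment grammar: chain units over
  C/N/O/S (including branches, double/triple bonds, carbonyl/amide units,
  and simple carbo-/heterocycles) concatenated by single bonds. Every
  unit tolerates a single bond on each end within valence limits, so all
  emitted strings are valence-valid by construction (and parse-checked
  anyway). Compound length budgets are drawn in [10, max_smiles_len]
  (default 40 characters).
* **Chemotype families**: compounds are sampled from a mixture of
  families, each favoring its own subset of ~6 grammar units. Real
  libraries are likewise clustered into chemotype series; this structure
  is what makes the condition vector informative about which region of
  chemical space to generate in.
* **Proteome**: each protein holds 1–3 binding sites with 1–3 ligands
  each. A site ligand is drawn from a shared ligand pool with probability
  `pool_sharing` (default 0.8; biased 80/20 toward the protein's own
  family's pool members), otherwise freshly generated. Pool sharing
  induces correlated signature columns — the low-rank structure the
  autoencoder exploits; the family bias makes protein blocks respond to
  chemotypes.
* **Indications** are k-means clusters of signatures (seeded), so the
  same-indication control groups behaviorally related compounds, matching
  the premise that similar signatures imply similar behavior.
* **Holdout**: objectives and every corpus compound with Tanimoto ≥ 0.9
  to any objective are removed from the training corpus.
* A bundled list of 50 well-known drug SMILES supports smoke tests with
  realistic chemistry.

What the generator does **not** emulate: realistic medicinal-chemistry
property distributions, stereochemistry, multi-character element symbols,
ring-system complexity beyond single 5/6-membered rings, binding-site
geometry, or affinity scales. Passing tests therefore demonstrate that the
pipeline recovers structure of this kind when it exists — not performance
on any real proteome or compound library.

## Problem sizes

The default study conditions (used by `scripts/acceptance.py`) are a
100-protein proteome, a 2000-compound corpus, 8 chemotype
families/indications, and 20 held-out objectives with 100 designs and a
100-compound random control each; the reducer uses latent 16 (30 epochs
max) and the CVAE hidden width 64, latent 16 (40 epochs max). Test
fixtures use smaller twins of the same construction (200–800 compounds,
30–100 proteins). These sizes run the full pipeline end-to-end on a single
CPU core in a few minutes.

## Numerical and reproducibility choices

* All neural components run in float64 on a small reverse-mode autodiff
  engine (`sigdesign.nn`) written on NumPy, gradient-checked against
  finite differences; training is exactly reproducible for a fixed seed on
  one platform.
* Every stochastic step (scenario generation, parameter init, shuffling,
  ε draws, prior sampling, control sampling, t-SNE) takes an explicit
  seed; orchestration code derives child seeds from one master seed.
* Argmax ties in decoding break to the lowest token index; ranking ties
  break by compound id.
* σ heads are parameterized on the log scale, so σ > 0 always holds;
  `cvae_loss` rejects non-positive σ passed directly.
* Degenerate inputs: empty design sets propagate an explicit
  "empty" status rather than silent success; empty samples are rejected
  by the statistical functions; tanimoto(∅, ∅) = 0.

## Known limitations

* Character-level tokenization cannot emit two-character elements.
* Greedy argmax decoding yields limited diversity per condition: distinct
  prior draws can decode to the same string, so valid-unique design sets
  are sometimes smaller than requested (the design loop oversamples and
  reports shortfalls).
* The full-scale `paper2021` presets are architectural echoes; training
  them requires resources far beyond the desk-scale scope of this package.
* The ligand-homology score is a similarity proxy, not a physical binding
  model; conclusions transfer to real systems only insofar as the proxy
  does.
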