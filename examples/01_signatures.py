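"""Compute compound-proteome interaction signatures and compare them.

Builds a small synthetic proteome (each protein's binding sites hold
ligand fingerprints), scores two real drugs against it, and compares the
resulting signatures by RMSD. Each signature entry is the maximum Tanimoto
coefficient between the compound and any site ligand of that protein, so
values near 1 mean a close substructure match to a known binder and 0
means no shared substructure evidence at all.
"""

import numpy as np

from sigdesign import SmilesRecord, compute_signature, signature_rmsd
from sigdesign.synthdata import SynthConfig, load_known_drugs, make_proteome

proteome, pool = make_proteome(
    SynthConfig(n_proteins=40, ligand_pool_size=25, corpus_size=30, n_objectives=2, seed=3)
)

drugs = {r.compound_id: r for r in load_known_drugs()}
ibuprofen = drugs["ibuprofen"]
naproxen = drugs["naproxen"]      # structurally related profen
metformin = drugs["metformin"]    # unrelated biguanide

sig_ibu = compute_signature(ibuprofen, proteome)
sig_nap = compute_signature(naproxen, proteome)
sig_met = compute_signature(metformin, proteome)

print(f"proteome: {len(proteome)} proteins, fingerprint length {proteome.n_bits}")
print(f"ibuprofen signature: min {sig_ibu.scores.min():.3f}, "
      f"max {sig_ibu.scores.max():.3f}, mean {sig_ibu.scores.mean():.3f}")
print(f"RMSD(ibuprofen, naproxen)  = {signature_rmsd(sig_ibu, sig_nap):.4f}")
print(f"RMSD(ibuprofen, metformin) = {signature_rmsd(sig_ibu, sig_met):.4f}")
print("lower RMSD = more similar predicted proteome-scale behavior; the two "
      "profens should sit closer to each other than to the biguanide")
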