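"""Mutational-signature refitting of simulated novel singletons.

Simulates per-sample singleton SNVs from a known 3-signature mixture,
filters them (unique carrier, >=11 supporting reads, absent from the known
set), tallies the 96 trinucleotide contexts, and refits exposures by NNLS.
"""

import numpy as np

from popvar.mutsig import (
    SignatureMatrix,
    build_context_matrix,
    extract_novel_singletons,
    refit_exposures,
)
from popvar.simulate import SimConfig, simulate_singletons

# three synthetic signatures with disjoint context support

profiles = np.zeros((96, 3))
profiles[:32, 0] = 1 / 32
profiles[32:64, 1] = 1 / 32
profiles[64:, 2] = 1 / 32
signatures = SignatureMatrix(["sigA", "sigB", "sigC"], profiles)

weights = [0.5, 0.3, 0.2]
cfg = SimConfig(seed=11, mutations_per_sample=1000)
calls, reference, known, truth = simulate_singletons(cfg, signatures, weights, n_samples=5)

singles = extract_novel_singletons(calls, known)
counts = build_context_matrix(singles, reference)
expo = refit_exposures(counts, signatures)

print("true mixture weights:", weights)
print("recovered mean exposure proportions:", np.round(expo.proportions.mean(axis=0), 3))
# NNLS attributes each sample's 96-context counts to the reference
# signatures; the mean recovered proportions track the generating mixture.
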