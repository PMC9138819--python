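"""Encode a protein sequence as a fixed-length PsePSSM descriptor.

Builds a deterministic BLOSUM62 fallback profile for a short sequence (no
database or external aligner needed), z-scores each profile row, and prints
the descriptor blocks: 20 column means plus 20 lag-correlation terms per lag.
"""

import numpy as np

from dtiforest import fallback_profile, psepssm_descriptor

sequence = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQAPILSRVGDGTQDNLSGAEKAVQVKVKALPDAQFEVVHSLAKWKR"
pssm = fallback_profile(sequence, protein_id="demo")
print(f"profile: {pssm.length} residues x 20 amino-acid columns")

desc = psepssm_descriptor(pssm, lag_max=10)
print(f"descriptor length: {desc.vector.size}  (= 20 * (lag_max + 1) = 20 * 11)")
print("mean block (first 5):", np.round(desc.vector[:5], 3))
print("lag-1 block (first 5):", np.round(desc.vector[20:25], 3))
print("all lag terms non-negative:", bool((desc.vector[20:] >= 0).all()))
# The mean block summarizes average evolutionary preference per amino acid;
# the lag blocks measure how fast that preference changes along the sequence.
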