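"""Transcript-region annotation and sequence-context analysis of m5C sites.

Classifies each planted site into 5'UTR / CDS / 3'UTR / intron against the
fixture's transcript models, then extracts the strand-aware 5-mer context
around each methylated cytosine and ranks the enriched contexts.
"""

from morgan5c import (
    classify_sites,
    context_frequencies,
    extract_contexts,
    region_distribution,
    simulate_site_fixture,
)

genome, annotation, tables, truth, _ = simulate_site_fixture(seed=0)
table = tables[0]

calls = classify_sites(table, annotation)
print("region distribution:")
print(region_distribution(calls).to_string(index=False))

contexts = extract_contexts(table, genome)
top, pfm, ngg = context_frequencies(contexts, top_k=10)
print("\ntop sequence contexts (methylated C + 4 downstream bases):")
print(top.to_string(index=False))
print(f"\nfraction with the G-rich NGGG signature: {ngg:.2f}")
print("\nposition frequency matrix (rows = positions 1..5):")
print(pfm.to_string())
# The NGGG signature (a GGG triplet right after the methylated C, as in
# CGGGA or CAGGG) marks substrates of the NSUN2 methyltransferase; the PFM
# is the count matrix a sequence logo would be drawn from.
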