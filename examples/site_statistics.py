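"""Descriptive m5C methylome statistics on a synthetic site-level cohort.

Builds the bundled site fixture (genome + transcripts + per-sample site
tables for 2 tumors and 2 normals), summarizes each sample, and compares
the groups: Welch t tests on the per-sample summaries and a Wilcoxon
rank-sum test on the pooled per-site methylation rates.
"""

from morgan5c import compare_groups, simulate_site_fixture
from morgan5c.site_stats import summarize_samples

genome, annotation, tables, truth, metadata = simulate_site_fixture(seed=0)

summaries = summarize_samples(tables, annotation.gene_names, annotation)
print("per-sample summaries:")
print(summaries.round(3).to_string(index=False))

comparison = compare_groups(summaries, tables, metadata)
print("\ncancer vs normal:")
print(comparison.round(4).to_string(index=False))
# n_sites / n_modified_genes / pct count the called sites and the genes they
# fall in; density is sites per exonic kilobase of the modified genes. The
# rank-sum row pools every site's methylation rate per group -- the fixture
# plants higher rates in tumors, so its p-value is small.
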