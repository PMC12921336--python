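# morgan5c

Tools for finding genes whose expression is driven by RNA 5-methylcytosine
(m⁵C), by integrating RNA bisulfite-sequencing methylation profiles with
RNA-seq expression across a paired cancer/normal cohort. The package is
aimed at epitranscriptomics groups who have per-sample m⁵C site calls (e.g.
meRanCall-style tables) and a raw count matrix, and want a ranked list of
candidate m⁵C-activated genes plus the standard descriptive analyses of an
m⁵C methylome: per-sample site statistics, transcript-region distribution,
and sequence-context (motif) summaries.

## The screen

For each gene, methylation is aggregated from site level to a per-sample
level m ∈ [0, 1] (coverage-weighted by default). Expression counts are
CPM-normalized, genes with zero counts in more than 25% of samples are
removed, and the two matrices are strictly matched by gene name and sample
id. The screen then proceeds in three stages:

1. **Correlation screen.** Pearson's r between methylation and CPM
   expression across all samples; genes with |r| > 0.6 (and r > 0 by
   default) become candidates.
2. **Methylation states.** Each candidate's per-sample methylation levels
   are fit with univariate Gaussian mixtures for G = 1, 2, 3 components;
   the component count is chosen by minimizing BIC = −2·logL + (3G−1)·ln n,
   and each sample is MAP-assigned to a state. States are ordered by mean
   (low / medium / high).
3. **Differential Methylation (DM) value.** With C_i samples in state i,
   occupancy p_i = C_i/N, and per-state group means μ_cancer,i and
   μ_normal,i,

   DM = Σᵢ Oᵢ·Cᵢ·ln(μ_cancer,i − μ_normal,i + 1) / Σᵢ Oᵢ·Cᵢ,

   with the complexity weight Oᵢ = −pᵢ·ln pᵢ (sample counts take over as
   weights in the single-state case, where every entropy weight vanishes).
   The log-shift emphasizes hypermethylated states. Candidates are ranked
   by descending DM.

A synthetic-cohort generator (Beta-mixture methylation states with
group-specific occupancy, negative-binomial counts whose log-mean rises
with methylation for planted driver genes) makes every stage testable
without access to patient data.

## Worked example

```
python examples/run_driver_screen.py
```

simulates 200 genes (10 planted drivers) over 14 tumors + 8 normals and
runs the full screen:

```
matched genes: 200
candidates passing the |r| > 0.6 screen: 10

top candidates by DM value:
   gene        r  G  dm_value  rank
gene006 0.820126  2  0.577276     1
gene010 0.890059  2  0.346527     2
gene008 0.874921  2  0.318520     3
gene009 0.811290  2  0.293838     4
gene003 0.814842  3  0.212727     5
gene001 0.862408  2  0.015470     6
gene002 0.819186  2  0.012809     7
gene004 0.862857  2  0.004845     8
gene007 0.853026  3 -0.000576     9
gene005 0.931646  2 -0.026905    10

planted driver genes recovered in the top 10: 10/10
```

`r` is the methylation–expression correlation, `G` the BIC-selected number
of methylation states, and `dm_value` the score above: genes whose
high-methylation state is specific to tumors score high (gene006), while
genes whose states are populated by both groups score near zero even when
the correlation is strong (gene005). Other examples cover per-sample site
statistics (`site_statistics.py`), region/motif analysis
(`region_and_motif.py`) and single-gene state modeling
(`methylation_states.py`).

A `morgan` command-line interface wraps the same workflow
(`morgan run`, `simulate`, `sitestats`, `annotate`, `motif`); run
`morgan --help` for the options and `morgan run --config config.yaml` to
override any default (all keys are namespaced per module; unknown keys are
rejected).

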