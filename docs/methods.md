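# Methods

## Scope and data model

The package consumes three tables: per-sample m⁵C site calls (chromosome,
1-based position of the methylated cytosine, strand, read coverage,
methylated-read count, methylation rate, gene assignment), a gene × sample
raw-count expression matrix, and a sample sheet labeling each sample
`cancer` or `normal`. Optional inputs are an Ensembl-dialect GTF (transcript
models for region annotation and density) and a genome FASTA (sequence
contexts). Coordinates are 1-based inclusive throughout; any half-open
convention is converted at the parse boundary. Sites are assumed to have
passed the caller's coverage filter upstream (typically ≥ 10×); readers
validate invariants (methylated ≤ coverage, rates in [0, 1], unique site
keys, unique sample ids) at parse time and fail loudly rather than
propagating malformed rows. Sites without a gene assignment are retained in
per-sample site totals but excluded from gene-level aggregation.

## Preprocessing

Gene-level methylation is the coverage-weighted (pooled) rate
Σ methylated / Σ coverage over a gene's covered sites in a sample; an
unweighted per-site mean is available by configuration, and the two agree
exactly when all sites share one coverage. Pooling is the default because
it is robust to shallow sites. Expression is CPM-normalized
(counts / column-sum × 10⁶) after removing genes with zero counts in
strictly more than 25% of samples — a gene at exactly the boundary is kept.
Matching keeps the intersection of gene names and sample ids in
lexicographic order and logs the attrition.

The built-in differential-expression screen is intentionally simple — CPM
fold change (pseudocount 1) with a two-sided rank-sum p per gene — and
thresholds on the raw p (< 0.01) with fold ≥ 2, reporting
Benjamini–Hochberg adjusted values alongside (an option switches the cut to
the adjusted p). It exists so synthetic end-to-end runs need no external
tool; externally produced DE gene lists are the preferred way to restrict
the screen, and the restriction stage is off by default.

## Correlation screen

Pearson's r (with the classical t-based two-sided p) is computed per gene
over pooled cancer + normal samples; a configuration switch restricts to
one group for sensitivity analysis. Missing methylation entries are
pairwise-deleted and the effective n reported; genes with fewer than 5
pairs (configurable) or a zero-variance vector are flagged undefined and
excluded rather than silently assigned r = 0. Selection keeps |r| strictly
above 0.6, positive-side only by default (the negative side can be
screened with `sign="both"`); no multiple-testing control is applied
because the screen thresholds on r, not p.

## Methylation-state model

Each candidate gene's methylation levels are modeled as a univariate
Gaussian mixture with free per-component variances. EM starts from a
deterministic initialization — component means at the i/(G+1) quantiles,
variances at the pooled sample variance, equal weights — so fits are
seed-free and bit-stable, and iterates to |Δ logL| < 1e−8 (at most 500
iterations). Component counts G = 1..3 are fit (G is skipped when
n < 3G — with cohort-scale n ≈ 20, three states are admissible but fragile,
and refusal is preferred to a degenerate fit); the minimal
BIC = −2·logL + (3G−1)·ln n wins, ties (within 1e−9) going to the smaller
G. States are re-ordered by ascending mean and samples MAP-assigned
(responsibility ties to the lower-mean state).

The likelihood of a free-variance mixture is unbounded: a component can
collapse onto a few near-identical points with vanishing variance and
arbitrarily large likelihood, and at n ≈ 22 such singular solutions corrupt
BIC selection in 10–15% of unimodal samples (the reference mclust "V"
family exhibits the same behavior). The estimator therefore computes a
constrained maximum likelihood: every component variance is bounded below
by max(1e−6, 0.01 · var(x)), i.e. no state may be narrower than one tenth
of the sample's overall spread. Because the floored update is the exact
maximizer of the constrained M-step, EM's monotone-likelihood guarantee is
preserved. With this constraint, BIC selection recovers the true component
count in ≥ 90% of seeded 22-sample genes in each of the one-, two- and
three-state scenarios the test suite runs. Truly degenerate inputs
(all-identical values) are fit only with G = 1, at the absolute floor.

## DM value

For state i with C_i assigned samples (occupancy p_i = C_i/N), let
μ_cancer,i and μ_normal,i be the within-state group means of methylation
(hard MAP membership, matching the categorical state assignment) and
Δ_i their difference. The score is the weighted mean

    DM = Σᵢ wᵢ · ln(max(Δᵢ + 1, ε)) / Σᵢ wᵢ,  wᵢ = Oᵢ·Cᵢ,

with complexity weight Oᵢ = −pᵢ ln pᵢ by default (an alternative mode uses
the mean posterior-assignment entropy of the state's members). Every
entropy weight vanishes for a single-state gene (p = 1), so the sample
counts take over as weights; without that fallback single-state genes would
be unscorable. The clamp ε = 1e−6 guards ln 0 at Δ = −1; such fully
reversed genes receive a large negative score and sink in the ranking. One
caveat is documented rather than resolved: the source description of the
weighting calls C_i both a sample count and a "cluster-specific methylation
mean" in adjacent sentences; the explicit symbol definition (sample count)
is implemented.

Chosen properties, all enforced by tests: DM is exactly 0 when every state's
group means coincide; it is bounded by the extreme per-state contributions;
changing the logarithm base rescales all scores by one positive constant,
so the ranking is base-invariant (natural log is used); and raising every
cancer sample's methylation never decreases it. A state lacking one group
borrows that group's gene-wide mean (flagged in the output); a
`drop_state` policy removes such states and renormalizes instead. Ranking
is by descending DM, ties by descending r then gene name.

## Descriptive statistics

Per sample: site count, modified-gene count, modified-gene percentage
against a stated universe (annotated genes by default, the expressed-gene
set by configuration), mean/median site methylation rate, and density.
"Density" has no single standard definition; the primary definition is
sites per exonic kilobase of the modified genes (union of exon intervals
per gene), with sites-per-modified-gene as the annotation-free fallback —
when an annotation is present both are reported under explicit column
names. Group comparisons use Welch's unequal-variance two-sided t test on
each summary metric and a two-sided Wilcoxon rank-sum test on the pooled
per-site rates (recurring sites contribute once per sample by default; a
flag deduplicates by site key). The rank-sum p is exact for groups of ≤ 8
(scipy's exact null distribution when tie-free, full enumeration of all
group assignments when ties are present) and otherwise uses the normal
approximation with tie and continuity corrections.

## Region annotation and sequence contexts

A site is classified against same-strand transcripts overlapping its
position: exonic positions sub-classify against the CDS span in transcript
orientation (5'UTR upstream, 3'UTR downstream, otherwise CDS), non-exonic
positions within the transcript span are intronic. Verdicts from multiple
transcripts aggregate by priority CDS > 3'UTR > 5'UTR > intron
(configurable); one call per site, no overlap → unassigned. Transcripts
without CDS cannot vote on their exonic positions (the region vocabulary
has no non-coding exon class) but still contribute intron calls. Site
strand always comes from the site table — bisulfite calls are
strand-resolved — never from the transcript.

The sequence context is the methylated C plus 4 downstream bases on the
site's strand (minus-strand contexts are reverse-complemented), N-padded at
contig edges. The window is fixed by the convention that published m⁵C
contexts are written C-first (e.g. CGGGA, CGGGG); its width is
configurable. Context summaries report per-5-mer counts and percentages of
all sites, a 5 × 4 position count matrix (N excluded per position, suitable
for logo rendering), and the fraction carrying the G-rich signature of
NSUN2 substrates — defined here as a C followed by a GGG triplet anywhere
in the 4 downstream bases, which covers both CNGGG (CAGGG, CGGGG) and
CGGGN (CGGGA) variants.

## Synthetic cohorts

The generator emulates the cohort structure the screen assumes, defaulting
to 14 cancer + 8 normal samples and 200 genes with 10 drivers. Driver genes
draw a latent low/high methylation state per sample with group-specific
high-state occupancy (0.9 in tumors vs 0.1 in normals by default) and a
Beta emission per state (Beta(2,20) low, Beta(20,2) high — Beta respects
the [0,1] support of methylation rates); their counts are negative binomial
(dispersion 0.1, var = μ + 0.1μ²) with log-mean baseline + 2·methylation,
scaled by a log-uniform library size in [0.5, 2] so CPM normalization is
non-trivial. Null genes draw methylation from one (70%) or two (30%)
Beta states with no group difference and counts independently of
methylation, with per-gene log-uniform baselines in [ln 5, ln 500] so the
zero-count filter is exercised. Each gene consumes a child random stream
keyed by its index (library sizes use a reserved key), so identical
configurations are bit-reproducible and extending the panel never perturbs
earlier genes.

What the generator does not emulate: read-level bisulfite conversion error,
coverage heterogeneity across sites, within-state group mean shifts,
batch structure, or correlated genes. In particular, planted drivers differ
between groups only in state *occupancy* — both groups share each state's
Beta — so a driver in which both groups happen to populate both states has
near-zero within-state differences and a DM value near zero. Tests passing
on these cohorts demonstrate the pipeline's correctness and its behavior
under the stated generative assumptions, not performance on real tumors,
where state emissions themselves typically shift between groups.

The site-level fixture plants sites with hand-specified region labels and
5-mer contexts (including CGGGA, CGGGG, CAGAG and related variants) into a
random genome with hand-traced transcript models, validating that planted
windows are in-bounds, non-overlapping, and inside their stated
transcripts; cancer samples draw higher site methylation rates than
normals so group comparisons have signal.

## Numerical and interface conventions

Tables are TSV (tab-separated, UTF-8, `#` comments; a tab-containing first
`#` line is treated as a meRanCall-style header), optionally gzipped;
floats are written at 7 significant digits so write→read round-trips within
1e−6 relative. The CLI exits 0 on success, 2 on usage/input errors, 3 on
computation-stage errors; every run echoes its effective configuration and
a config digest into a manifest, writes all intermediate tables by default
for auditability, and is deterministic given identical inputs.

## Known limitations

- Single-state genes are scored by their overall group difference only;
  the entropy weighting is uninformative there by construction.
- Occupancy-only differences between groups (state composition shifts with
  identical state emissions) are invisible to the DM value, which measures
  within-state mean differences; such drivers are screened by correlation
  but may rank low.
- G is capped at 3 states; cohorts with more structure are summarized
  coarsely.
- The mixture assumes Gaussian emissions on [0, 1] data; with levels piled
  near the boundaries a logit or Beta-mixture model would be more faithful.
- The region classifier assigns one region per site; per-transcript
  multiplicity is collapsed by a fixed priority.
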