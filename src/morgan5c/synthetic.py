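"""Synthetic cohorts with planted m5C-driven genes, and site-level fixtures
(genome + transcript models + site tables) with known region labels and
sequence contexts, so every pipeline stage is testable without external data.

The cohort generator emulates the structure the driver screen assumes: a
paired cancer/normal cohort (default 14 + 8 samples), per-gene methylation
drawn from Beta mixtures over latent low/high states (Beta respects the
[0, 1] support of methylation rates), group-specific high-state occupancy for
driven genes, and negative-binomial RNA-seq counts whose log-mean rises with
methylation for driven genes (overdispersed counts, log-uniform library
sizes so CPM normalization is non-trivial). Null genes have methylation and
counts drawn independently. Every gene consumes its own child random stream
keyed by gene index, so enlarging the panel never perturbs earlier genes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import (
    ExpressionMatrix,
    GeneMethylationMatrix,
    GenomeSequence,
    MorganError,
    SampleSheet,
    SiteTable,
    Transcript,
    TranscriptAnnotation,
    reverse_complement,
)

_LIBRARY_STREAM_KEY = 2**20  # spawn key reserved for cohort-level draws


@dataclass
class CohortConfig:
    """Generative settings for one synthetic cohort.

    ``pi_cancer``/``pi_normal`` are the high-methylation-state occupancies of
    driven genes per group; ``coupling`` is the log-mean expression shift per
    unit methylation (beta); ``dispersion`` the NB overdispersion
    (var = mu + dispersion * mu^2).
    """

    seed: int
    n_cancer: int = 14
    n_normal: int = 8
    n_genes: int = 200
    n_driven: int = 10
    beta_low: tuple[float, float] = (2.0, 20.0)    # low-state Beta(a, b)
    beta_high: tuple[float, float] = (20.0, 2.0)   # high-state Beta(a, b)
    pi_cancer: float = 0.9
    pi_normal: float = 0.1
    coupling: float = 2.0
    baseline_log_mean: float = math.log(100.0)
    null_baseline_range: tuple[float, float] = (math.log(5.0), math.log(500.0))
    dispersion: float = 0.1
    library_size_range: tuple[float, float] = (0.5, 2.0)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise MorganError("a seed is mandatory")
        if not (0.0 <= self.pi_cancer <= 1.0 and 0.0 <= self.pi_normal <= 1.0):
            raise MorganError("state occupancies must lie in [0, 1]")
        if self.n_driven > self.n_genes:
            raise MorganError("n_driven cannot exceed n_genes")
        for a, b in (self.beta_low, self.beta_high):
            if a <= 0 or b <= 0:
                raise MorganError("Beta parameters must be positive")
        if self.dispersion <= 0:
            raise MorganError("dispersion must be positive")
        lo, hi = self.library_size_range
        if not (0 < lo <= hi):
            raise MorganError("invalid library size range")


def _gene_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(index,)))


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    shape = 1.0 / dispersion
    p = shape / (shape + mean)
    return rng.negative_binomial(shape, p)


def simulate_cohort(config: CohortConfig):
    """Draw one cohort.

    Returns ``(methylation, raw_counts, metadata, truth)`` where ``truth`` is
    a DataFrame with one row per gene: driven flag, true state count, true
    per-group high-state occupancy, and the true expression coupling.
    Identical config (including seed) reproduces bit-identical output.
    """
    n = config.n_cancer + config.n_normal
    samples = [f"cancer_{i + 1:02d}" for i in range(config.n_cancer)] + [
        f"normal_{i + 1:02d}" for i in range(config.n_normal)
    ]
    groups = ["cancer"] * config.n_cancer + ["normal"] * config.n_normal
    metadata = SampleSheet(dict(zip(samples, groups)))
    is_cancer = np.array([g == "cancer" for g in groups])

    lib_rng = np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(_LIBRARY_STREAM_KEY,))
    )
    lo, hi = config.library_size_range
    lib = np.exp(lib_rng.uniform(math.log(lo), math.log(hi), size=n))

    width = len(str(config.n_genes))
    genes = [f"gene{i + 1:0{width}d}" for i in range(config.n_genes)]
    meth = np.empty((config.n_genes, n))
    counts = np.empty((config.n_genes, n), dtype=np.int64)
    truth_rows = []
    for idx, gene in enumerate(genes):
        rng = _gene_rng(config.seed, idx)
        driven = idx < config.n_driven
        if driven:
            pi = np.where(is_cancer, config.pi_cancer, config.pi_normal)
            high = rng.random(n) < pi
            m = np.where(
                high,
                rng.beta(*config.beta_high, size=n),
                rng.beta(*config.beta_low, size=n),
            )
            mu = lib * np.exp(config.baseline_log_mean + config.coupling * m)
            c = _nb_draw(rng, mu, config.dispersion)
            truth_rows.append((gene, True, 2, config.pi_cancer, config.pi_normal,
                               config.coupling))
        else:
            g_null = 1 if rng.random() < 0.7 else 2
            if g_null == 1:
                m0 = rng.uniform(0.05, 0.6)
                m = rng.beta(m0 * 20.0, (1.0 - m0) * 20.0, size=n)
                occ = 0.0
            else:
                high = rng.random(n) < 0.5
                m = np.where(
                    high,
                    rng.beta(*config.beta_high, size=n),
                    rng.beta(*config.beta_low, size=n),
                )
                occ = 0.5
            base = rng.uniform(*config.null_baseline_range)
            mu = lib * np.exp(base)
            c = _nb_draw(rng, mu, config.dispersion)
            truth_rows.append((gene, False, g_null, occ, occ, 0.0))
        meth[idx] = m
        counts[idx] = c

    methylation = GeneMethylationMatrix(
        pd.DataFrame(meth, index=genes, columns=samples)
    )
    expression = ExpressionMatrix(
        pd.DataFrame(counts.astype(float), index=genes, columns=samples),
        scale="raw_counts",
    )
    truth = pd.DataFrame(
        truth_rows,
        columns=["gene", "driven", "G_true", "pi_cancer", "pi_normal", "coupling"],
    )
    return methylation, expression, metadata, truth


# ---------------------------------------------------------------------------
# Site-level fixture: genome + transcripts + planted sites with known truth
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedSite:
    """A site planted into the synthetic genome with a known region label and
    a known 5-mer context (first character the methylated C on the site's
    strand)."""

    chrom: str
    pos: int
    strand: str
    context: str
    region: str   # expected region call, or "unassigned"
    gene: str


@dataclass
class SiteFixtureConfig:
    chrom_lengths: dict[str, int]
    transcripts: list[Transcript]
    sites: list[PlantedSite]
    samples: dict[str, str] = field(
        default_factory=lambda: {
            "tumor_1": "cancer", "tumor_2": "cancer",
            "norm_1": "normal", "norm_2": "normal",
        }
    )


def default_site_fixture_config() -> SiteFixtureConfig:
    """A hand-traced two-chromosome fixture covering every region class and
    the printed NSUN2-style contexts (CGGGA, CGGGG, CAGAG, CAGGG, CCAGG)."""
    transcripts = [
        Transcript("tx1", "GA", "chr1", "+",
                   exons=((101, 400), (601, 900)),
                   cds=((201, 400), (601, 700))),
        Transcript("tx2", "GB", "chr1", "-",
                   exons=((1201, 1500), (1701, 2000)),
                   cds=((1301, 1500), (1701, 1900))),
        Transcript("tx3", "GC", "chr2", "+",
                   exons=((101, 1000),),
                   cds=((301, 800),)),
    ]
    sites = [
        PlantedSite("chr1", 150, "+", "CGGGA", "five_prime_utr", "GA"),
        PlantedSite("chr1", 250, "+", "CGGGG", "cds", "GA"),
        PlantedSite("chr1", 500, "+", "CAGAG", "intron", "GA"),
        PlantedSite("chr1", 800, "+", "CAGGG", "three_prime_utr", "GA"),
        PlantedSite("chr1", 1950, "-", "CCAGG", "five_prime_utr", "GB"),
        PlantedSite("chr1", 1400, "-", "CGGGA", "cds", "GB"),
        PlantedSite("chr1", 1600, "-", "CTGGG", "intron", "GB"),
        PlantedSite("chr1", 1250, "-", "CGGGG", "three_prime_utr", "GB"),
        PlantedSite("chr2", 400, "+", "CGGGA", "cds", "GC"),
        PlantedSite("chr2", 1500, "+", "CGGGG", "unassigned", ""),
    ]
    return SiteFixtureConfig(
        chrom_lengths={"chr1": 2200, "chr2": 1800},
        transcripts=transcripts,
        sites=sites,
    )


def _validate_fixture(config: SiteFixtureConfig) -> None:
    spans = {}
    for site in config.sites:
        if len(site.context) != 5 or site.context[0] != "C":
            raise MorganError(
                f"planted context must be a C-leading 5-mer, got {site.context!r}"
            )
        length = config.chrom_lengths.get(site.chrom)
        if length is None:
            raise MorganError(f"planted site on unknown chromosome {site.chrom!r}")
        lo, hi = (site.pos, site.pos + 4) if site.strand == "+" else (site.pos - 4, site.pos)
        if lo < 1 or hi > length:
            raise MorganError(f"planted context window out of bounds at {site.chrom}:{site.pos}")
        for (c2, lo2, hi2) in spans.get(site.chrom, []):
            if lo <= hi2 and lo2 <= hi:
                raise MorganError(
                    f"planted context windows overlap on {site.chrom} near {site.pos}"
                )
        spans.setdefault(site.chrom, []).append((site.chrom, lo, hi))
        if site.region != "unassigned":
            covering = [
                tx for tx in config.transcripts
                if tx.chrom == site.chrom and tx.strand == site.strand
                and tx.span[0] <= site.pos <= tx.span[1]
            ]
            if not covering:
                raise MorganError(
                    f"planted site {site.chrom}:{site.pos} ({site.region}) lies "
                    f"outside every same-strand transcript"
                )


def simulate_site_fixture(config: SiteFixtureConfig | None = None, seed: int = 0):
    """Build (genome, annotation, site tables, truth) for the fixture.

    The genome is random A/C/G/T with every planted 5-mer written in at its
    coordinates (reverse-complemented for minus-strand sites). Site coverage
    is drawn in [10, 100]; cancer samples draw higher methylation rates than
    normals so the descriptive group comparisons have signal.
    """
    if config is None:
        config = default_site_fixture_config()
    _validate_fixture(config)
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0,)))
    sequences = {}
    for chrom, length in config.chrom_lengths.items():
        sequences[chrom] = rng.choice(list("ACGT"), size=length)
    for site in config.sites:
        if site.strand == "+":
            start, planted = site.pos, site.context
        else:
            start, planted = site.pos - 4, reverse_complement(site.context)
        sequences[site.chrom][start - 1 : start + 4] = list(planted)
    genome = GenomeSequence({c: "".join(s) for c, s in sequences.items()})
    annotation = TranscriptAnnotation({tx.transcript_id: tx for tx in config.transcripts})

    tables = []
    for sample_index, (sample_id, group) in enumerate(config.samples.items()):
        srng = np.random.default_rng(
            np.random.SeedSequence(seed, spawn_key=(1, sample_index))
        )
        rows = []
        for site in config.sites:
            cov = int(srng.integers(10, 101))
            a, b = (6.0, 2.0) if group == "cancer" else (2.0, 6.0)
            rate = srng.beta(a, b)
            methylated = int(round(rate * cov))
            rows.append(
                (site.chrom, site.pos, site.strand, cov, methylated,
                 methylated / cov, site.gene)
            )
        df = pd.DataFrame(
            rows,
            columns=["chrom", "pos", "strand", "coverage", "methylated",
                     "meth_rate", "gene"],
        )
        tables.append(SiteTable(sample_id, df))
    truth = pd.DataFrame(
        [(s.chrom, s.pos, s.strand, s.region, s.context, s.gene) for s in config.sites],
        columns=["chrom", "pos", "strand", "region", "context", "gene"],
    )
    metadata = SampleSheet(dict(config.samples))
    return genome, annotation, tables, truth, metadata
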