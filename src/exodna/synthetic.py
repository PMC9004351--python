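"""Seeded synthetic inputs for the exocellular-DNA analysis pipeline.

Real inputs are ~20-L ocean metagenomes mapped against a depth-resolved
gene catalog, plus capillary-electrophoresis traces of free-DNA fragment
sizes.  Neither is practical to bundle, so this module generates inputs
with the statistical structure the analysis assumes:

* a gene catalog whose taxa have depth-localized abundance profiles
  (Dirichlet over a 0-4,000 m depth grid), with an optional fraction of
  depth-exclusive "marker" genes that make the depth-of-origin problem
  identifiable, and a fraction of unannotated genes;
* samples formed as mixtures over depth origins with multinomial counting
  noise at a fixed sequencing effort;
* electropherograms as Gaussian peaks on the log10(bp) axis plus an
  exponential degradation smear.

Every operation takes an explicit integer seed and touches no global
random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .count_io import DOMAINS, GeneCatalog, SampleCoverageTable
from .size_spectrum import SIZE_RANGE_BP, Electropherogram

#: Depth grid (m) mirroring typical water-column sampling at an open-ocean
#: time-series station, surface through 4,000 m.
DEFAULT_DEPTH_GRID = (5.0, 25.0, 45.0, 75.0, 100.0, 125.0, 150.0, 175.0,
                      200.0, 250.0, 500.0, 750.0, 1000.0, 2000.0, 3000.0, 4000.0)

#: Dirichlet concentration for taxon depth profiles; < 1 gives the patchy,
#: depth-localized taxa the attribution needs.
DEFAULT_DIRICHLET_ALPHA = 0.3

# Plausible marine taxa to draw annotations from: (domain, family, tag).
# Families echo the dominant groups in open-ocean exocellular DNA; tags mark
# Prochlorococcus ecotypes (HL/LL) and viral known-host groups.
_TAXON_POOL = [
    ("bacteria", "Pelagibacteraceae", None),
    ("bacteria", "Prochlorococcus", "HL"),
    ("bacteria", "Prochlorococcus", "LL"),
    ("bacteria", "Rhodospirillaceae", None),
    ("bacteria", "Rhodobacteraceae", None),
    ("bacteria", "Flavobacteriaceae", None),
    ("bacteria", "Synechococcaceae", None),
    ("virus", "Myoviridae", "host:Prochlorococcus"),
    ("virus", "Myoviridae", "host:Synechococcus"),
    ("virus", "Podoviridae", "host:Pelagibacter"),
    ("virus", "Podoviridae", "host:SAR116"),
    ("virus", "Siphoviridae", "host:Vibrio"),
    ("archaea", "Nitrosopumilaceae", None),
    ("eukaryote", "Pelagomonadaceae", None),
    ("eukaryote", "Noelaerhabdaceae", None),
    ("eukaryote", "Bathycoccaceae", None),
]


@dataclass
class CommunityProfile:
    """Taxon relative abundances on a depth grid; columns sum to 1."""

    depth_grid: np.ndarray
    taxa: list[tuple]  # (domain, family, tag)
    abundance: np.ndarray  # taxon x depth

    def __post_init__(self) -> None:
        self.depth_grid = np.asarray(self.depth_grid, dtype=float)
        if not (np.diff(self.depth_grid) > 0).all():
            raise ValueError("depth grid must be strictly increasing")
        if (self.abundance < 0).any():
            raise ValueError("abundances must be non-negative")
        colsums = self.abundance.sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=1e-9):
            raise ValueError("each depth column must sum to 1")


@dataclass
class MixtureSpec:
    """How to synthesise one sample: a mixture over depth origins.

    Encodes the hypothesis that a sample collected at ``collection_depth``
    carries both autochthonous DNA (weight at its own depth) and
    allochthonous DNA transported from other depths.
    """

    sample_id: str
    fraction_type: str
    collection_depth: float
    weights: dict[float, float]
    read_depth: int
    seed: int

    def __post_init__(self) -> None:
        w = np.array(list(self.weights.values()), dtype=float)
        if (w < 0).any():
            raise ValueError("mixture weights must be non-negative")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError(f"mixture weights sum to {w.sum()}, expected 1")
        if self.read_depth < 1:
            raise ValueError("read_depth must be >= 1")


def make_catalog(n_genes: int, n_taxa: int,
                 depth_grid: tuple[float, ...] = DEFAULT_DEPTH_GRID,
                 depth_exclusive_frac: float = 0.0,
                 unannotated_frac: float = 0.25,
                 alpha: float = DEFAULT_DIRICHLET_ALPHA,
                 seed: int = 0) -> GeneCatalog:
    """Generate a synthetic depth-resolved gene catalog.

    Each gene belongs to one taxon whose depth profile is drawn from a
    Dirichlet(alpha) over the depth grid.  A fraction
    ``depth_exclusive_frac`` of genes get coverage at exactly one depth
    (drawn from their taxon's profile) -- marker genes that make depth
    attribution identifiable.  A fraction ``unannotated_frac`` of genes
    carry no taxonomy (domain "unknown", no family), emulating the large
    unannotated portion of environmental metagenomes.  Coverage columns
    are normalized so every depth column sums to 1.
    """
    if n_genes < 1 or n_taxa < 1:
        raise ValueError("n_genes and n_taxa must be positive")
    if n_genes < n_taxa:
        raise ValueError("need n_genes >= n_taxa")
    if not 0.0 <= depth_exclusive_frac <= 1.0:
        raise ValueError("depth_exclusive_frac must be in [0, 1]")
    if not 0.0 <= unannotated_frac <= 1.0:
        raise ValueError("unannotated_frac must be in [0, 1]")
    depth_grid = np.asarray(depth_grid, dtype=float)
    if depth_grid.size == 0:
        raise ValueError("depth grid is empty")
    if not (np.diff(depth_grid) > 0).all():
        raise ValueError("depth grid must be strictly increasing")

    rng = np.random.default_rng(seed)
    n_depths = depth_grid.size

    taxa = [_TAXON_POOL[i % len(_TAXON_POOL)] for i in range(n_taxa)]
    # disambiguate families when the pool is reused
    taxa = [
        (d, f if i < len(_TAXON_POOL) else f"{f}_{i // len(_TAXON_POOL)}", t)
        for i, (d, f, t) in enumerate(taxa)
    ]
    profiles = rng.dirichlet(np.full(n_depths, alpha), size=n_taxa)

    # every taxon gets at least one gene, the rest are assigned uniformly
    taxon_of_gene = np.concatenate([
        np.arange(n_taxa), rng.integers(0, n_taxa, size=n_genes - n_taxa)
    ])
    rng.shuffle(taxon_of_gene)

    gene_factor = rng.lognormal(mean=0.0, sigma=1.0, size=n_genes)
    coverage = profiles[taxon_of_gene] * gene_factor[:, None]

    n_exclusive = int(round(depth_exclusive_frac * n_genes))
    exclusive = rng.choice(n_genes, size=n_exclusive, replace=False)
    for g in exclusive:
        p = profiles[taxon_of_gene[g]]
        d = rng.choice(n_depths, p=p / p.sum())
        row = np.zeros(n_depths)
        row[d] = gene_factor[g]
        coverage[g] = row

    # per-depth normalization: each depth column sums to 1
    colsum = coverage.sum(axis=0)
    colsum[colsum == 0] = 1.0
    coverage = coverage / colsum

    gene_ids = pd.Index([f"gene_{i:06d}" for i in range(n_genes)], name="gene_id")
    n_unann = int(round(unannotated_frac * n_genes))
    unannotated = np.zeros(n_genes, dtype=bool)
    unannotated[rng.choice(n_genes, size=n_unann, replace=False)] = True

    dom = np.array([taxa[t][0] for t in taxon_of_gene], dtype=object)
    fam = np.array([taxa[t][1] for t in taxon_of_gene], dtype=object)
    tag = np.array([taxa[t][2] for t in taxon_of_gene], dtype=object)
    dom[unannotated] = "unknown"
    fam[unannotated] = None
    tag[unannotated] = None

    annotations = pd.DataFrame(
        {"domain": dom, "family": fam, "tag": tag}, index=gene_ids
    )
    cov = pd.DataFrame(coverage, index=gene_ids, columns=depth_grid)
    return GeneCatalog(annotations=annotations, coverage=cov)


def make_sample(catalog: GeneCatalog, spec: MixtureSpec) -> SampleCoverageTable:
    """Draw a synthetic count table from a depth-mixture of catalog columns.

    The expected per-gene coverage is the weight-mixture of the catalog's
    depth columns; realized counts are a single multinomial draw with
    ``spec.read_depth`` trials, so totals equal the sequencing effort
    exactly.  Deterministic under ``spec.seed``.
    """
    depths = list(catalog.coverage.columns)
    expectation = np.zeros(len(catalog), dtype=float)
    for d, w in spec.weights.items():
        if float(d) not in depths:
            raise ValueError(f"mixture weight on depth {d} m absent from catalog grid")
        expectation += w * catalog.coverage[float(d)].to_numpy()
    total = expectation.sum()
    if total <= 0:
        raise ValueError("mixture has zero expected coverage")
    rng = np.random.default_rng(spec.seed)
    counts = rng.multinomial(spec.read_depth, expectation / total)
    return SampleCoverageTable(
        sample_id=spec.sample_id,
        fraction_type=spec.fraction_type,
        collection_depth=spec.collection_depth,
        counts=pd.Series(counts, index=catalog.gene_ids),
    )


def expected_sample_proportions(catalog: GeneCatalog, weights: dict[float, float]) -> pd.Series:
    """Noise-free expectation of :func:`make_sample` proportions (analytic oracle)."""
    expectation = np.zeros(len(catalog), dtype=float)
    for d, w in weights.items():
        expectation += w * catalog.coverage[float(d)].to_numpy()
    return pd.Series(expectation / expectation.sum(), index=catalog.gene_ids)


def make_electropherogram(peaks: list[tuple[float, float, float]],
                          smear_fraction: float = 0.0,
                          smear_scale_bp: float = 2000.0,
                          n_points: int = 2000,
                          noise_rfu: float = 0.0,
                          seed: int = 0) -> Electropherogram:
    """Synthesise a capillary-electrophoresis trace with known band masses.

    ``peaks`` is a list of ``(center_bp, width_log10, mass_fraction)``;
    each peak is Gaussian on the log10(bp) axis (CE sizing is roughly
    log-linear).  ``smear_fraction`` of the mass goes into an exponential
    degradation smear (scale ``smear_scale_bp`` on the linear bp axis).
    The trace is sampled at ``n_points`` log-spaced sizes across the
    instrument range and returned as signal per bp, so that trapezoidal
    integration over size recovers the component mass fractions.  Each
    component is renormalized to unit mass on the sampled grid, so edge
    truncation does not bias band fractions.
    """
    lo, hi = SIZE_RANGE_BP
    fractions = [f for _, _, f in peaks] + [smear_fraction]
    if any(f < 0 for f in fractions):
        raise ValueError("mass fractions must be non-negative")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"peak + smear mass fractions sum to {sum(fractions)}, expected 1")
    for center, width, _ in peaks:
        if not lo <= center <= hi:
            raise ValueError(f"peak center {center} bp outside [{lo}, {hi}]")
        if width <= 0:
            raise ValueError("peak width_log10 must be positive")
    if n_points < 10:
        raise ValueError("need at least 10 trace points")

    size = np.logspace(np.log10(lo), np.log10(hi), n_points)
    rfu = np.zeros_like(size)
    u = np.log10(size)

    def add_component(density: np.ndarray, mass: float) -> None:
        area = np.trapezoid(density, size)
        if area > 0 and mass > 0:
            rfu[:] += mass * density / area

    for center, width, mass in peaks:
        dens = np.exp(-0.5 * ((u - np.log10(center)) / width) ** 2) / size
        add_component(dens, mass)
    if smear_fraction > 0:
        add_component(np.exp(-(size - lo) / smear_scale_bp), smear_fraction)

    if noise_rfu > 0:
        rng = np.random.default_rng(seed)
        rfu = np.clip(rfu + rng.normal(0.0, noise_rfu, size=rfu.size), 0.0, None)

    if rfu.sum() <= 0:
        raise ValueError("generated trace has no signal")
    return Electropherogram(size=size, rfu=rfu)
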