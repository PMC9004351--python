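"""Count-table and gene-catalog I/O plus taxonomic composition bookkeeping.

Exocellular-DNA metagenomes arrive as per-sample gene count tables produced
by mapping reads against a depth-resolved reference gene catalog.  This
module holds the in-memory containers for those tables, TSV round-trip I/O,
count normalization, and the aggregation logic used to summarise samples:
domain-level composition (with unannotated sequences as an explicit
category), family-level composition over annotated counts, major-taxon
selection at a relative-abundance cutoff, and tag-level composition
(e.g. high-light vs low-light *Prochlorococcus* ecotypes, or known viral
host groups).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The five domain categories used throughout; "unknown" collects
#: unannotated genes and genes absent from the catalog.
DOMAINS = ("bacteria", "archaea", "eukaryote", "virus", "unknown")

#: Sample fraction types: the three exocellular DNA pools plus the
#: cellular (particulate) reference community.
FRACTION_TYPES = ("vesicle", "virus", "free", "cellular")

#: Default major-taxon cutoff: a taxon is "major" if it contributes
#: strictly more than 0.5% in at least one sample.
MAJOR_TAXON_CUTOFF = 0.005


@dataclass
class GeneCatalog:
    """A depth-resolved reference gene catalog.

    Parameters
    ----------
    annotations
        DataFrame indexed by ``gene_id`` with columns ``domain``
        (one of :data:`DOMAINS`), ``family`` (str or NaN) and ``tag``
        (str or NaN; ecotype or known-host label).
    coverage
        Gene x depth coverage matrix; DataFrame indexed by ``gene_id``
        with one float column per depth (m).  Non-negative.
    """

    annotations: pd.DataFrame
    coverage: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.annotations.index.is_unique:
            dupes = self.annotations.index[self.annotations.index.duplicated()]
            raise ValueError(f"duplicate gene_ids in catalog: {list(dupes[:5])}")
        if not self.annotations.index.equals(self.coverage.index):
            raise ValueError("annotation and coverage gene_ids differ")
        if (self.coverage.to_numpy() < 0).any():
            raise ValueError("catalog coverage must be non-negative")
        if not np.isfinite(self.coverage.to_numpy()).all():
            raise ValueError("catalog coverage must be finite")
        bad = set(self.annotations["domain"]) - set(DOMAINS)
        if bad:
            raise ValueError(f"unrecognised domains: {sorted(bad)}")
        self.coverage.columns = self.coverage.columns.astype(float)

    @property
    def gene_ids(self) -> pd.Index:
        return self.annotations.index

    @property
    def depths(self) -> np.ndarray:
        return self.coverage.columns.to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.annotations)


@dataclass
class SampleCoverageTable:
    """Per-sample gene counts with collection metadata.

    ``counts`` is a Series indexed by gene_id; integer counts from read
    mapping, or float coverages if working downstream of normalization.
    """

    sample_id: str
    fraction_type: str
    collection_depth: float
    counts: pd.Series

    def __post_init__(self) -> None:
        if self.fraction_type not in FRACTION_TYPES:
            raise ValueError(
                f"fraction_type {self.fraction_type!r} not in {FRACTION_TYPES}"
            )
        if not self.counts.index.is_unique:
            dupes = self.counts.index[self.counts.index.duplicated()]
            raise ValueError(f"duplicate gene_id in counts: {list(dupes[:5])}")
        if (self.counts < 0).any():
            bad = self.counts.index[self.counts < 0][0]
            raise ValueError(f"negative count for gene {bad!r}")

    @property
    def total(self) -> float:
        return float(self.counts.sum())


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def write_count_table(table: SampleCoverageTable, path: str | Path) -> None:
    """Write a count table as TSV (gene_id, count) plus a JSON metadata sidecar."""
    path = Path(path)
    df = pd.DataFrame({"gene_id": table.counts.index, "count": table.counts.to_numpy()})
    df.to_csv(path, sep="\t", index=False)
    meta = {
        "sample_id": table.sample_id,
        "fraction_type": table.fraction_type,
        "collection_depth": table.collection_depth,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def read_count_table(path: str | Path) -> SampleCoverageTable:
    """Read a TSV count table written by :func:`write_count_table`.

    Raises ``ValueError`` on duplicate gene ids or negative counts, naming
    the offending gene.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    if list(df.columns[:2]) != ["gene_id", "count"]:
        raise ValueError(f"{path}: expected header gene_id<TAB>count, got {list(df.columns)}")
    if df["gene_id"].duplicated().any():
        dupe = df["gene_id"][df["gene_id"].duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicate gene_id {dupe!r}")
    if df["count"].isna().any() or not np.isfinite(df["count"].to_numpy(float)).all():
        raise ValueError(f"{path}: malformed count values")
    meta = json.loads(_sidecar_path(path).read_text())
    counts = pd.Series(df["count"].to_numpy(), index=pd.Index(df["gene_id"], name="gene_id"))
    return SampleCoverageTable(
        sample_id=meta["sample_id"],
        fraction_type=meta["fraction_type"],
        collection_depth=float(meta["collection_depth"]),
        counts=counts,
    )


def write_catalog(catalog: GeneCatalog, annotations_path: str | Path,
                  coverage_path: str | Path) -> None:
    """Write a catalog as two TSVs: annotations and gene x depth coverage."""
    ann = catalog.annotations.reset_index()
    ann.columns = ["gene_id", "domain", "family", "tag"]
    ann.to_csv(annotations_path, sep="\t", index=False)
    cov = catalog.coverage.reset_index()
    cov = cov.rename(columns={cov.columns[0]: "gene_id"})
    cov.to_csv(coverage_path, sep="\t", index=False)


def read_catalog(annotations_path: str | Path, coverage_path: str | Path) -> GeneCatalog:
    ann = pd.read_csv(annotations_path, sep="\t", dtype={"gene_id": str}).set_index("gene_id")
    cov = pd.read_csv(coverage_path, sep="\t", dtype={"gene_id": str}).set_index("gene_id")
    cov.columns = cov.columns.astype(float)
    return GeneCatalog(annotations=ann, coverage=cov)


# ---------------------------------------------------------------------------
# Normalization and composition
# ---------------------------------------------------------------------------

def normalize_counts(table: SampleCoverageTable) -> pd.Series:
    """Per-gene proportions: counts divided by the total mapped count.

    Raises ``ValueError`` for an all-zero table.
    """
    total = table.total
    if total <= 0:
        raise ValueError(f"sample {table.sample_id!r} has no mapped counts")
    return table.counts / total


def _gene_domains(table: SampleCoverageTable, catalog: GeneCatalog) -> pd.Series:
    """Domain per gene in the table; genes absent from the catalog -> unknown."""
    domains = catalog.annotations["domain"].reindex(table.counts.index)
    missing = domains.isna()
    if missing.any():
        logger.info(
            "sample %s: %d genes absent from catalog treated as unknown",
            table.sample_id, int(missing.sum()),
        )
        domains = domains.fillna("unknown")
    return domains


def domain_composition(table: SampleCoverageTable, catalog: GeneCatalog) -> pd.Series:
    """Domain-level proportions over ALL mapped counts.

    Unannotated genes (no taxonomy in the catalog, or absent from the
    catalog entirely) appear as the explicit "unknown" category, so the
    five proportions sum to 1.
    """
    props = normalize_counts(table)
    domains = _gene_domains(table, catalog)
    comp = props.groupby(domains.to_numpy()).sum()
    return comp.reindex(DOMAINS, fill_value=0.0).rename(table.sample_id)


def family_composition(table: SampleCoverageTable, catalog: GeneCatalog,
                       annotated_only: bool = True) -> pd.Series:
    """Family-level proportions.

    With ``annotated_only`` (the default) the denominator is the count mass
    on genes carrying a family annotation, matching how family-level
    percentages are usually reported; otherwise the denominator is all
    mapped counts and the proportions need not sum to 1.
    """
    props = normalize_counts(table)
    families = catalog.annotations["family"].reindex(table.counts.index)
    has_family = families.notna()
    if annotated_only:
        denom = float(props[has_family.to_numpy()].sum())
        if denom <= 0:
            raise ValueError(f"sample {table.sample_id!r} has no family-annotated counts")
        props = props / denom
    comp = props[has_family.to_numpy()].groupby(families[has_family].to_numpy()).sum()
    return comp.rename(table.sample_id)


def tag_composition(table: SampleCoverageTable, catalog: GeneCatalog,
                    tag_universe: list[str] | tuple[str, ...]) -> pd.Series:
    """Proportions over a tag universe among counts carrying any such tag.

    Used for ecotype splits (HL vs LL *Prochlorococcus*) and viral
    known-host groups; the denominator is the count mass on genes whose
    tag lies in ``tag_universe``.
    """
    props = normalize_counts(table)
    tags = catalog.annotations["tag"].reindex(table.counts.index)
    in_universe = tags.isin(tag_universe)
    denom = float(props[in_universe.to_numpy()].sum())
    if denom <= 0:
        raise ValueError(
            f"sample {table.sample_id!r} has no counts tagged in {list(tag_universe)}"
        )
    comp = props[in_universe.to_numpy()].groupby(tags[in_universe].to_numpy()).sum() / denom
    return comp.reindex(tag_universe, fill_value=0.0).rename(table.sample_id)


def composition_table(tables: list[SampleCoverageTable], catalog: GeneCatalog,
                      level: str = "family", annotated_only: bool = True) -> pd.DataFrame:
    """Taxon x sample composition matrix at ``level`` ("domain"|"family"|"tag").

    Columns are samples, rows taxa; missing taxa filled with 0.
    """
    cols = []
    for t in tables:
        if level == "domain":
            cols.append(domain_composition(t, catalog))
        elif level == "family":
            cols.append(family_composition(t, catalog, annotated_only=annotated_only))
        elif level == "tag":
            universe = sorted(catalog.annotations["tag"].dropna().unique())
            cols.append(tag_composition(t, catalog, universe))
        else:
            raise ValueError(f"unknown level {level!r}")
    return pd.concat(cols, axis=1).fillna(0.0)


def major_taxa(comp: pd.DataFrame | pd.Series, cutoff: float = MAJOR_TAXON_CUTOFF) -> set[str]:
    """Taxa whose proportion strictly exceeds ``cutoff`` in at least one sample.

    The comparison is strict (default: >0.5%); taxa sitting exactly at the
    cutoff in every sample are excluded.
    """
    if isinstance(comp, pd.Series):
        comp = comp.to_frame()
    mask = (comp > cutoff).any(axis=1)
    return set(comp.index[mask])
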