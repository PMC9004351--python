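"""Count-table I/O, normalization and composition bookkeeping."""

import numpy as np
import pandas as pd
import pytest

from exodna.count_io import (
    DOMAINS,
    SampleCoverageTable,
    domain_composition,
    family_composition,
    major_taxa,
    normalize_counts,
    read_catalog,
    read_count_table,
    tag_composition,
    write_catalog,
    write_count_table,
)
from exodna.synthetic import make_catalog
from tests.conftest import random_sample


def brute_force_tally(table, catalog, column, annotated_only=False):
    """Independent per-gene loop oracle for composition aggregation."""
    totals: dict[str, float] = {}
    for gene, count in table.counts.items():
        if gene in catalog.annotations.index:
            label = catalog.annotations.loc[gene, column]
        else:
            label = "unknown" if column == "domain" else None
        if pd.isna(label):
            label = "unknown" if column == "domain" else None
        if label is None:
            continue
        totals[label] = totals.get(label, 0.0) + count
    denom = sum(totals.values()) if annotated_only else table.total
    return {k: v / denom for k, v in totals.items()}


class TestIO:
    def test_count_table_round_trip(self, tmp_path, tiny_sample):
        path = tmp_path / "t.tsv"
        write_count_table(tiny_sample, path)
        back = read_count_table(path)
        assert back.sample_id == tiny_sample.sample_id
        assert back.fraction_type == tiny_sample.fraction_type
        assert back.collection_depth == tiny_sample.collection_depth
        pd.testing.assert_series_equal(back.counts, tiny_sample.counts,
                                       check_dtype=False)

    def test_random_round_trip(self, tmp_path):
        cat = make_catalog(80, 6, seed=2)
        table = random_sample(cat, seed=3)
        path = tmp_path / "r.tsv"
        write_count_table(table, path)
        pd.testing.assert_series_equal(read_count_table(path).counts, table.counts,
                                       check_dtype=False)

    def test_duplicate_gene_id_names_offender(self, tmp_path):
        path = tmp_path / "dup.tsv"
        path.write_text("gene_id\tcount\ngA\t3\ngA\t4\n")
        path.with_suffix(".tsv.meta.json").write_text(
            '{"sample_id": "x", "fraction_type": "free", "collection_depth": 75}')
        with pytest.raises(ValueError, match="gA"):
            read_count_table(path)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            SampleCoverageTable("s", "free", 75.0,
                                pd.Series({"g1": 5, "g2": -1}))

    def test_catalog_round_trip(self, tmp_path, tiny_catalog):
        write_catalog(tiny_catalog, tmp_path / "ann.tsv", tmp_path / "cov.tsv")
        back = read_catalog(tmp_path / "ann.tsv", tmp_path / "cov.tsv")
        pd.testing.assert_frame_equal(back.coverage, tiny_catalog.coverage)
        assert list(back.annotations["domain"]) == list(tiny_catalog.annotations["domain"])


class TestNormalize:
    def test_simple_proportions(self):
        t = SampleCoverageTable("s", "free", 75.0, pd.Series({"a": 2, "b": 3, "c": 5}))
        assert normalize_counts(t).to_dict() == {"a": 0.2, "b": 0.3, "c": 0.5}

    def test_single_gene_is_unity(self):
        t = SampleCoverageTable("s", "free", 75.0, pd.Series({"g": 7}))
        assert normalize_counts(t).to_dict() == {"g": 1.0}

    def test_random_table_sums_to_one(self):
        cat = make_catalog(120, 6, seed=8)
        t = random_sample(cat, seed=9)
        assert normalize_counts(t).sum() == pytest.approx(1.0, abs=1e-12)

    def test_all_zero_rejected(self):
        t = SampleCoverageTable("s", "free", 75.0, pd.Series({"a": 0, "b": 0}))
        with pytest.raises(ValueError):
            normalize_counts(t)


class TestDomainComposition:
    def test_half_unannotated(self, tiny_catalog):
        t = SampleCoverageTable("s", "free", 75.0,
                                pd.Series({"g1": 50, "g5": 50}, name=None))
        comp = domain_composition(t, tiny_catalog)
        assert comp["unknown"] == pytest.approx(0.5)
        assert comp["bacteria"] == pytest.approx(0.5)

    def test_columns_sum_to_one(self, tiny_catalog, tiny_sample):
        assert domain_composition(tiny_sample, tiny_catalog).sum() == pytest.approx(1.0)

    def test_catalog_absent_gene_counts_as_unknown(self, tiny_catalog):
        t = SampleCoverageTable("s", "free", 75.0,
                                pd.Series({"g1": 30, "not_in_catalog": 70}))
        assert domain_composition(t, tiny_catalog)["unknown"] == pytest.approx(0.7)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force(self, seed):
        cat = make_catalog(150, 10, unannotated_frac=0.3, seed=seed)
        t = random_sample(cat, seed=seed + 100)
        comp = domain_composition(t, cat)
        oracle = brute_force_tally(t, cat, "domain")
        for d in DOMAINS:
            assert comp[d] == pytest.approx(oracle.get(d, 0.0), abs=1e-12)


class TestFamilyComposition:
    def test_denominator_contract(self, tiny_catalog):
        # half the counts unannotated, the rest one family
        t = SampleCoverageTable("s", "free", 75.0, pd.Series({"g1": 50, "g5": 50}))
        annotated = family_composition(t, tiny_catalog, annotated_only=True)
        overall = family_composition(t, tiny_catalog, annotated_only=False)
        assert annotated["Pelagibacteraceae"] == pytest.approx(1.0)
        assert overall["Pelagibacteraceae"] == pytest.approx(0.5)

    @pytest.mark.parametrize("annotated_only", [True, False])
    def test_matches_brute_force(self, annotated_only):
        cat = make_catalog(150, 10, unannotated_frac=0.3, seed=4)
        t = random_sample(cat, seed=40)
        comp = family_composition(t, cat, annotated_only=annotated_only)
        oracle = brute_force_tally(t, cat, "family", annotated_only=annotated_only)
        assert set(comp.index) == set(oracle)
        for fam, v in oracle.items():
            assert comp[fam] == pytest.approx(v, abs=1e-12)


class TestTagComposition:
    def test_ecotype_split(self, tiny_catalog):
        t = SampleCoverageTable("s", "free", 75.0, pd.Series({"g1": 100, "g2": 850}))
        # only g2 carries an ecotype tag (HL)
        comp = tag_composition(t, tiny_catalog, ["HL", "LL"])
        assert comp["HL"] == pytest.approx(1.0)
        assert comp["LL"] == 0.0

    def test_matches_brute_force(self):
        cat = make_catalog(200, 16, unannotated_frac=0.2, seed=6)
        t = random_sample(cat, seed=60)
        universe = sorted(cat.annotations["tag"].dropna().unique())
        comp = tag_composition(t, cat, universe)
        oracle = brute_force_tally(t, cat, "tag", annotated_only=True)
        # brute force over tag labels restricted to the universe
        denom = sum(v for k, v in oracle.items() if k in universe)
        for tag in universe:
            assert comp[tag] == pytest.approx(oracle.get(tag, 0.0) / denom, abs=1e-12)
        assert comp.sum() == pytest.approx(1.0)


class TestMajorTaxa:
    def test_strict_cutoff_boundary(self):
        comp = pd.DataFrame({"s1": [0.006, 0.005, 0.989]},
                            index=["above", "at_cutoff", "big"])
        taxa = major_taxa(comp, cutoff=0.005)
        assert "above" in taxa and "big" in taxa
        assert "at_cutoff" not in taxa

    def test_included_if_major_in_any_sample(self):
        comp = pd.DataFrame({"s1": [0.001, 0.999], "s2": [0.2, 0.8]},
                            index=["sometimes", "always"])
        assert major_taxa(comp) == {"sometimes", "always"}

    def test_monotone_in_cutoff(self):
        rng = np.random.default_rng(0)
        comp = pd.DataFrame(rng.dirichlet(np.ones(30), size=4).T)
        cuts = [0.001, 0.005, 0.02, 0.1]
        sets = [major_taxa(comp, cutoff=c) for c in cuts]
        for small, big in zip(sets[1:], sets[:-1]):
            assert small <= big

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(1)
        comp = pd.DataFrame(rng.dirichlet(np.ones(50), size=6).T)
        expected = {i for i in comp.index
                    if any(comp.loc[i, c] > 0.005 for c in comp.columns)}
        assert major_taxa(comp, cutoff=0.005) == expected
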