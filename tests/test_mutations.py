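import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st
from scipy import stats

import netcontrast as nc
from netcontrast.errors import (
    CatalogFormatError,
    EmptyCatalogError,
    InsufficientDataError,
)
from netcontrast.mutations import parse_protein_change

from conftest import make_catalog


@pytest.mark.parametrize(
    "change, expected",
    [
        ("R130Q", ("R", 130, "Q")),
        ("p.R130*", ("R", 130, "*")),
        ("A1B", ("A", 1, "B")),
        ("p.?", None),
        ("R130fs", None),
        ("130Q", None),
        ("R130del", None),
        ("", None),
    ],
)
def test_protein_change_grammar(change, expected):
    assert parse_protein_change(change) == expected


class TestParseCatalog:
    def _write(self, tmp_path, rows, header="sample\tgene\tprotein_change"):
        p = tmp_path / "cat.tsv"
        p.write_text("\n".join([header] + rows) + "\n")
        return p

    def test_point_only_drops_unparseable(self, tmp_path):
        p = self._write(
            tmp_path, ["s1\tPTEN\tR130Q", "s2\tPTEN\tp.?", "s3\tTP53\tR175H"]
        )
        cat = nc.parse_catalog(p, "x", point_only=True)
        assert len(cat) == 2
        assert cat.parse_report.n_dropped_nonpoint == 1
        cat_all = nc.parse_catalog(p, "x", point_only=False)
        assert len(cat_all) == 3

    def test_duplicate_rows_collapse(self, tmp_path):
        p = self._write(tmp_path, ["s1\tPTEN\tR130Q", "s1\tPTEN\tR130Q"])
        cat = nc.parse_catalog(p, "x")
        assert len(cat) == 1
        assert cat.parse_report.n_duplicates == 1

    def test_missing_column_names_the_column(self, tmp_path):
        p = self._write(tmp_path, ["s1\tPTEN"], header="sample\tgene")
        with pytest.raises(CatalogFormatError, match="protein_change"):
            nc.parse_catalog(p, "x")

    def test_empty_file_raises(self, tmp_path):
        p = self._write(tmp_path, [])
        with pytest.raises(EmptyCatalogError):
            nc.parse_catalog(p, "x")

    def test_pathogenicity_bounds_enforced(self, tmp_path):
        p = tmp_path / "cat.tsv"
        p.write_text(
            "sample\tgene\tprotein_change\tpathogenicity\ns1\tPTEN\tR130Q\t1.5\n"
        )
        with pytest.raises(CatalogFormatError):
            nc.parse_catalog(p, "x")


@pytest.mark.parametrize("n_carriers, expected", [(0, 0.0), (9, 1.0), (99, 2.0)])
def test_mutation_frequency_log_scale(n_carriers, expected):
    rows = [(f"s{i}", "PTEN", "R130Q") for i in range(n_carriers)]
    cat = make_catalog(rows or [("s0", "OTHER", "A1B")])
    assert nc.mutation_frequency(cat, ("PTEN", "R130Q")) == pytest.approx(expected)


def test_mutation_frequency_counts_distinct_samples():
    # duplicate records of one carrier count once
    cat = make_catalog([("s1", "G", "A1B"), ("s1", "G", "A1B"), ("s2", "G", "A1B")])
    assert nc.mutation_frequency(cat, ("G", "A1B")) == pytest.approx(math.log10(3))


class TestWelch:
    def test_identical_groups(self):
        r = nc.welch_t_test([1, 2, 3], [1, 2, 3])
        assert r.statistic == 0 and r.p_value == 1

    def test_degenerate_variances(self):
        r = nc.welch_t_test([0, 0], [1, 1])
        assert r.p_value == 0 and math.isinf(r.statistic)

    def test_closed_form_oracle(self):
        # hand evaluation of the Welch formula for (1,2,3,4) vs (2,3,4,5):
        # means 2.5 / 3.5, s^2 = 5/3 each, se = sqrt(5/6),
        # t = -1/sqrt(5/6), df = 6
        x, y = [1, 2, 3, 4], [2, 3, 4, 5]
        t_exp = -1.0 / math.sqrt(5.0 / 6.0)
        p_exp = 2.0 * stats.t.sf(abs(t_exp), 6.0)
        r = nc.welch_t_test(x, y)
        assert r.statistic == pytest.approx(t_exp, abs=1e-10)
        assert r.p_value == pytest.approx(p_exp, abs=1e-10)

    def test_matches_scipy_on_random_data(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            x = rng.normal(0, 1, size=int(rng.integers(3, 30)))
            y = rng.normal(0.3, 2, size=int(rng.integers(3, 30)))
            r = nc.welch_t_test(x, y)
            ref = stats.ttest_ind(x, y, equal_var=False)
            assert r.statistic == pytest.approx(ref.statistic, abs=1e-10)
            assert r.p_value == pytest.approx(ref.pvalue, abs=1e-10)

    def test_too_small_group_raises(self):
        with pytest.raises(InsufficientDataError):
            nc.welch_t_test([1], [1, 2])

    @settings(derandomize=True, max_examples=30)
    @given(
        x=st.lists(st.floats(-5, 5), min_size=2, max_size=10),
        y=st.lists(st.floats(-5, 5), min_size=2, max_size=10),
    )
    def test_symmetric_under_group_swap(self, x, y):
        a = nc.welch_t_test(x, y)
        b = nc.welch_t_test(y, x)
        assert a.p_value == pytest.approx(b.p_value, abs=1e-12)
        assert a.statistic == pytest.approx(-b.statistic, abs=1e-12)


class TestCompareCatalogs:
    def test_set_partition_example(self):
        a = make_catalog([("s1", "G1", "A1B"), ("s2", "G2", "C2D")] * 2)
        b = make_catalog([("t1", "G2", "C2D"), ("t2", "G3", "E3F")] * 2)
        cmp_ = nc.compare_catalogs(a, b, frequency_source=b, include_absent=True)
        assert cmp_.shared_mutations == {("G2", "C2D")}
        assert cmp_.a_specific_mutations == {("G1", "A1B")}
        assert cmp_.b_specific_mutations == {("G3", "E3F")}

    def test_identical_catalogs_give_null_test(self):
        a = make_catalog([("s1", "G1", "A1B"), ("s2", "G2", "C2D")])
        cmp_ = nc.compare_catalogs(a, a, frequency_source=a)
        assert not cmp_.a_specific_mutations and not cmp_.b_specific_mutations
        assert cmp_.frequency_test.statistic == 0
        assert cmp_.frequency_test.p_value == 1

    def test_insufficient_overlap_raises(self):
        a = make_catalog([("s1", "G1", "A1B"), ("s2", "G2", "C2D")])
        b = make_catalog([("t1", "G9", "E3F"), ("t2", "G8", "F4G")])
        with pytest.raises(InsufficientDataError):
            nc.compare_catalogs(a, b, frequency_source=b)  # no a-mut in b

    def test_welch_on_planted_shift_matches_independent_computation(
        self, small_dataset
    ):
        d = small_dataset
        cmp_ = nc.compare_catalogs(
            d.catalog_a, d.catalog_b, frequency_source=d.catalog_b
        )
        # independent recomputation: scipy Welch on directly counted
        # log10(N + 1) recurrence values
        src = d.catalog_b
        fx = [
            math.log10(len(src.carriers(m)) + 1)
            for m in d.catalog_a.unique_mutations
            if src.carriers(m)
        ]
        fy = [
            math.log10(len(src.carriers(m)) + 1)
            for m in d.catalog_b.unique_mutations
            if src.carriers(m)
        ]
        ref = stats.ttest_ind(fx, fy, equal_var=False)
        assert cmp_.frequency_test.p_value == pytest.approx(ref.pvalue, abs=1e-10)
        # the planted shared mutations are rare among the cancer cohort
        assert cmp_.frequency_test.statistic < 0
        assert cmp_.frequency_test.p_value < 0.01

    @settings(derandomize=True, max_examples=25)
    @given(data=st.data())
    def test_partition_property(self, data):
        genes = ["G1", "G2", "G3"]
        changes = ["A1B", "C2D", "E3F"]
        mk = st.lists(
            st.tuples(
                st.sampled_from(["s1", "s2", "s3"]),
                st.sampled_from(genes),
                st.sampled_from(changes),
            ),
            min_size=2,
            max_size=12,
        )
        a = make_catalog(data.draw(mk))
        b = make_catalog(data.draw(mk))
        assume(len(a.unique_mutations) >= 2 and len(b.unique_mutations) >= 2)
        cmp_ = nc.compare_catalogs(a, b, frequency_source=b, include_absent=True)
        union = a.unique_mutations | b.unique_mutations
        parts = [
            cmp_.shared_mutations,
            cmp_.a_specific_mutations,
            cmp_.b_specific_mutations,
        ]
        assert sum(len(p) for p in parts) == len(union)
        assert frozenset().union(*parts) == union


def test_gene_class_counts():
    ann = pd.DataFrame(
        {
            "gene": ["A", "B", "D"],
            "is_tf": [True, False, True],
            "is_tsg": [False, True, False],
            "is_oncogene": [False, False, True],
        }
    )
    cat = make_catalog(
        [("s1", "A", "A1B"), ("s2", "B", "A1B"), ("s3", "C", "A1B"),
         ("s4", "D", "A1B")]
    )
    counts = nc.annotate_gene_classes(cat, ann)
    assert counts.marginal == {"tf": 2, "tsg": 1, "oncogene": 1, "none": 1}
    assert counts.combinations[("oncogene", "tf")] == 1  # dual-class gene D
    assert counts.combinations[()] == 1
    assert counts.n_genes == 4


def test_gene_class_counts_empty_catalog():
    counts = nc.annotate_gene_classes(
        make_catalog([]), pd.DataFrame({"gene": [], "is_tf": []})
    )
    assert counts.n_genes == 0
    assert all(v == 0 for v in counts.marginal.values())


def test_phenotype_overlap_network():
    cat = make_catalog(
        [
            ("s1", "A", "A1B", "P1"), ("s1", "B", "A1B", "P1"),
            ("s2", "B", "A1B", "P2"), ("s2", "C", "A1B", "P2"),
            ("s3", "D", "A1B", "P3"),
        ]
    )
    g = nc.phenotype_overlap_network(cat)
    assert set(g.nodes) == {"P1", "P2", "P3"}
    assert g["P1"]["P2"]["weight"] == 1  # gene B shared
    assert not g.has_edge("P1", "P3") and not g.has_edge("P2", "P3")
    assert g.nodes["P1"]["n_samples"] == 1
    assert g.nodes["P1"]["n_mutated_genes"] == 2


class TestResidueProfile:
    def test_counts_and_shared_flag(self):
        a = make_catalog(
            [("s1", "PTEN", "R130*"), ("s2", "PTEN", "R130*")]
        )
        b = make_catalog(
            [("t1", "PTEN", "R130*")]
            + [(f"t{i}", "PTEN", "R130Q") for i in range(2, 7)]
        )
        prof = nc.residue_profile(a, b, "PTEN")
        stop = prof[(prof.position == 130) & (prof.alt == "*")].iloc[0]
        assert (stop.count_a, stop.count_b, stop.shared) == (2, 1, True)
        mis = prof[(prof.position == 130) & (prof.alt == "Q")].iloc[0]
        assert (mis.count_a, mis.count_b, mis.shared) == (0, 5, False)

    def test_absent_gene_warns_and_returns_empty(self):
        a = make_catalog([("s1", "PTEN", "R130Q")])
        with pytest.warns(UserWarning, match="absent"):
            prof = nc.residue_profile(a, a, "NOPE")
        assert prof.empty

    def test_matches_brute_force_scan(self):
        d = nc.generate_all(nc.GeneratorParams(
            n_genes=200, n_ndd_genes=40, n_ndd_mutations=120, rng_seed=3,
        ))
        a, b = d.catalog_a, d.catalog_b
        for gene in sorted(a.mutated_genes | b.mutated_genes):
            prof = nc.residue_profile(a, b, gene)
            for row in prof.itertuples():
                for cat, col in ((a, row.count_a), (b, row.count_b)):
                    naive = {
                        r.sample_id
                        for r in cat.records
                        if r.gene == gene
                        and parse_protein_change(r.protein_change)[1:]
                        == (row.position, row.alt)
                    }
                    assert len(naive) == col


class TestSeedSelection:
    def test_at_least_boundary_is_inclusive(self):
        rows = [(f"s{i}", "G3", "A1B") for i in range(3)]
        rows += [(f"s{i}", "G2", "A1B") for i in range(2)]
        cat = make_catalog(rows)
        assert nc.select_seed_genes(cat, 3) == ["G3"]
        assert nc.select_seed_genes(cat, 1) == ["G3", "G2"]

    def test_invariant_to_record_order(self, small_dataset):
        cat = small_dataset.catalog_a
        rev = nc.MutationCatalog(cat.cohort_name, list(reversed(cat.records)))
        assert nc.select_seed_genes(cat, 3) == nc.select_seed_genes(rev, 3)

    def test_min_patients_validated(self):
        with pytest.raises(ValueError):
            nc.select_seed_genes(make_catalog([("s", "G", "A1B")]), 0)
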