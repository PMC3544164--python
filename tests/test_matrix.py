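"""Core mutation-matrix data model: primitives, invariants and file I/O."""

import io
import logging

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from driverpath import (
    MatrixFormatError,
    MutationMatrix,
    UnknownLabelError,
    as_gene_set,
    coverage,
    coverage_overlap,
    read_matrix,
    support,
    weight,
    write_matrix,
)
from driverpath.matrix import matrix_to_string

T1_DENSE = (
    "patient\tg1\tg2\tg3\tg4\n"
    "p1\t1\t1\t0\t0\n"
    "p2\t0\t1\t0\t0\n"
    "p3\t0\t0\t1\t0\n"
)

T1_PAIRS = "p1\tg1\np1\tg2\np2\tg2\np3\tg3\n"


class TestConstruction:
    def test_rejects_non_binary_entries(self):
        with pytest.raises(ValueError, match="0 or 1"):
            MutationMatrix([[0, 2]], ["p1"], ["g1", "g2"])

    @pytest.mark.parametrize("patients,genes", [(["p", "p"], ["a", "b"]),
                                                (["p", "q"], ["a", "a"])])
    def test_rejects_duplicate_labels(self, patients, genes):
        with pytest.raises(ValueError, match="duplicate"):
            MutationMatrix([[0, 1], [1, 0]], patients, genes)

    def test_rejects_empty_axes(self):
        with pytest.raises(ValueError):
            MutationMatrix(np.zeros((0, 3), dtype=int), [], ["a", "b", "c"])

    def test_all_zero_patient_rows_are_legal(self):
        mat = MutationMatrix([[0, 0], [1, 0]], ["p1", "p2"], ["g1", "g2"])
        assert weight(mat, ["g1", "g2"]) == 1

    def test_gene_set_rejects_duplicates(self):
        with pytest.raises(ValueError, match="duplicate"):
            as_gene_set(["g1", "g1"])


class TestPrimitives:
    def test_support_reads_off_columns(self, toy_matrix):
        assert support(toy_matrix, "g2") == {"p1", "p2"}
        assert support(toy_matrix, "g4") == set()

    def test_support_unknown_gene(self, toy_matrix):
        with pytest.raises(UnknownLabelError):
            support(toy_matrix, "nope")

    @pytest.mark.parametrize(
        "genes,expected",
        [(["g1", "g2"], {"p1", "p2"}), (["g2", "g3"], {"p1", "p2", "p3"}), ([], set())],
    )
    def test_coverage_union(self, toy_matrix, genes, expected):
        assert coverage(toy_matrix, genes) == expected

    @pytest.mark.parametrize(
        "genes,omega", [(["g2", "g3"], 0), (["g1", "g2"], 1), ([], 0)]
    )
    def test_coverage_overlap(self, toy_matrix, genes, omega):
        assert coverage_overlap(toy_matrix, genes) == omega

    def test_identical_columns_overlap_fully(self):
        col = [[1], [1], [1], [1], [1]]
        mat = MutationMatrix(np.hstack([col, col]), [f"p{i}" for i in range(5)],
                             ["a", "b"])
        assert coverage_overlap(mat, ["a", "b"]) == 5

    @pytest.mark.parametrize(
        "genes,w",
        [(["g2", "g3"], 3), (["g1", "g2"], 1), (["g2"], 2), ([], 0)],
    )
    def test_weight_examples(self, toy_matrix, genes, w):
        assert weight(toy_matrix, genes) == w

    def test_singleton_weight_is_support_size(self, toy_matrix):
        for g in toy_matrix.gene_ids:
            assert weight(toy_matrix, [g]) == len(support(toy_matrix, g))


class TestInvariants:
    """Properties checked against brute-force oracles on random matrices."""

    @pytest.mark.parametrize("seed", range(10))
    def test_support_size_equals_column_sum(self, random_matrix_factory, seed):
        mat = random_matrix_factory(20, 8, seed=seed)
        for j, g in enumerate(mat.gene_ids):
            assert len(support(mat, g)) == mat.entries[:, j].sum()

    @pytest.mark.parametrize("seed", range(10))
    def test_coverage_matches_row_scan(self, random_matrix_factory, seed):
        mat = random_matrix_factory(15, 6, seed=seed)
        rng = np.random.default_rng(seed)
        genes = list(rng.choice(mat.gene_ids, size=3, replace=False))
        idx = [mat.gene_index(g) for g in genes]
        expected = {
            p for i, p in enumerate(mat.patient_ids)
            if any(mat.entries[i, j] for j in idx)
        }
        assert coverage(mat, genes) == expected

    @pytest.mark.parametrize("seed", range(10))
    def test_weight_identity_two_code_paths(self, random_matrix_factory, seed):
        # W(M) = 2|Γ(M)| − Σ|Γ(g)| recomputed from the label-level primitives
        mat = random_matrix_factory(25, 10, seed=seed)
        rng = np.random.default_rng(seed + 1)
        genes = list(rng.choice(mat.gene_ids, size=4, replace=False))
        direct = weight(mat, genes)
        rebuilt = 2 * len(coverage(mat, genes)) - sum(
            len(support(mat, g)) for g in genes
        )
        assert direct == rebuilt
        assert direct == len(coverage(mat, genes)) - coverage_overlap(mat, genes)

    @pytest.mark.parametrize("seed", range(5))
    def test_overlap_zero_iff_mutually_exclusive(self, random_matrix_factory, seed):
        mat = random_matrix_factory(12, 5, density=0.2, seed=seed)
        genes = list(mat.gene_ids[:3])
        idx = [mat.gene_index(g) for g in genes]
        per_patient = mat.entries[:, idx].sum(axis=1)
        assert (coverage_overlap(mat, genes) == 0) == bool((per_patient <= 1).all())

    def test_coverage_monotone_under_superset(self, random_matrix_factory):
        mat = random_matrix_factory(20, 8, seed=3)
        small = list(mat.gene_ids[:2])
        for extra in mat.gene_ids[2:]:
            assert coverage(mat, small) <= coverage(mat, small + [extra])


class TestIO:
    def test_dense_parse(self, toy_matrix):
        mat = read_matrix(io.StringIO(T1_DENSE))
        assert mat == toy_matrix

    def test_pair_list_with_universe_matches_dense(self, toy_matrix):
        mat = read_matrix(
            io.StringIO(T1_PAIRS), "pair-list",
            gene_universe=["g1", "g2", "g3", "g4"],
        )
        assert mat == toy_matrix

    def test_non_binary_cell_rejected(self):
        with pytest.raises(MatrixFormatError, match="non-binary"):
            read_matrix(io.StringIO("patient\tg1\np1\t2\n"))

    def test_empty_file_rejected(self):
        with pytest.raises(MatrixFormatError, match="empty"):
            read_matrix(io.StringIO(""))

    def test_duplicate_patient_rejected(self):
        bad = "patient\tg1\np1\t1\np1\t0\n"
        with pytest.raises(MatrixFormatError, match="duplicate patient"):
            read_matrix(io.StringIO(bad))

    def test_duplicate_gene_header_rejected(self):
        with pytest.raises(MatrixFormatError, match="duplicate gene"):
            read_matrix(io.StringIO("patient\tg1\tg1\np1\t1\t0\n"))

    def test_duplicate_pair_collapses_with_warning(self, caplog):
        pairs = "p1\tg1\np1\tg1\n"
        with caplog.at_level(logging.WARNING, logger="driverpath.matrix"):
            mat = read_matrix(io.StringIO(pairs), "pair-list")
        assert mat.entry("p1", "g1") == 1
        assert "duplicate mutation event" in caplog.text

    def test_pair_gene_outside_universe_rejected(self):
        with pytest.raises(MatrixFormatError, match="universe"):
            read_matrix(io.StringIO("p1\tgX\n"), "pair-list", gene_universe=["g1"])

    @pytest.mark.parametrize("fmt", ["dense-tsv", "pair-list"])
    def test_round_trip_toy(self, toy_matrix, fmt):
        text = matrix_to_string(toy_matrix, fmt)
        back = read_matrix(io.StringIO(text), fmt,
                           gene_universe=toy_matrix.gene_ids)
        assert back == toy_matrix

    @pytest.mark.parametrize("seed", range(10))
    def test_round_trip_random_dense(self, random_matrix_factory, seed):
        mat = random_matrix_factory(18, 7, seed=seed)
        buf = io.StringIO()
        write_matrix(mat, buf)
        buf.seek(0)
        assert read_matrix(buf) == mat


@settings(max_examples=40, derandomize=True)
@given(
    data=st.lists(
        st.lists(st.integers(0, 1), min_size=4, max_size=4),
        min_size=1, max_size=12,
    )
)
def test_round_trip_property_dense(data):
    """Any binary matrix survives a dense-TSV write/read cycle exactly."""
    mat = MutationMatrix(
        np.array(data, dtype=np.uint8),
        patient_ids=[f"p{i}" for i in range(len(data))],
        gene_ids=["a", "b", "c", "d"],
    )
    buf = io.StringIO()
    write_matrix(mat, buf)
    buf.seek(0)
    assert read_matrix(buf) == mat


class TestRestriction:
    def test_subset_and_drop(self, toy_matrix):
        sub = toy_matrix.drop_genes(["g4"])
        assert sub.gene_ids == ("g1", "g2", "g3")
        assert sub.patient_ids == toy_matrix.patient_ids
        assert weight(sub, ["g2", "g3"]) == 3

    def test_drop_unknown_gene(self, toy_matrix):
        with pytest.raises(UnknownLabelError):
            toy_matrix.drop_genes(["zz"])

    def test_cannot_drop_everything(self, toy_matrix):
        with pytest.raises(ValueError):
            toy_matrix.drop_genes(toy_matrix.gene_ids)
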