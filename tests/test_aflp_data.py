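"""Genotype-matrix container, flat-file round trips, and error-rate checks."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from isopop import (
    AFLPMatrix,
    ReplicatePairs,
    genotyping_error_rate,
    read_aflp_matrix,
    write_aflp_matrix,
)
from isopop.aflp import AFLPFormatError

from conftest import make_matrix

WELL_FORMED = (
    "sample\tpopulation\tregion\tL1\tL2\tL3\n"
    "s1\tA\tR1\t1\t0\t1\n"
    "s2\tA\tR1\t0\t0\t1\n"
    "s3\tB\tR1\t1\t1\t0\n"
    "s4\tB\tR1\t0\t1\t0\n"
)


class TestReadWrite:
    def test_well_formed_file(self, tmp_path):
        path = tmp_path / "g.tsv"
        path.write_text(WELL_FORMED)
        m = read_aflp_matrix(path)
        assert m.genotypes.shape == (4, 3)
        assert m.sample_ids == ("s1", "s2", "s3", "s4")  # row order preserved
        assert m.locus_ids == ("L1", "L2", "L3")
        assert m.population_of("s3") == "B"

    def test_non_binary_cell_names_row_and_locus(self, tmp_path):
        path = tmp_path / "g.tsv"
        path.write_text(WELL_FORMED.replace("s3\tB\tR1\t1\t1\t0", "s3\tB\tR1\t1\t2\t0"))
        with pytest.raises(AFLPFormatError, match=r"s3.*L2"):
            read_aflp_matrix(path)

    def test_duplicate_sample_id_rejected(self, tmp_path):
        path = tmp_path / "g.tsv"
        path.write_text(WELL_FORMED.replace("s2", "s1"))
        with pytest.raises(AFLPFormatError, match="duplicate"):
            read_aflp_matrix(path)

    def test_genalex_dialect(self, tmp_path):
        text = (
            "3\t4\t2\t2\t2\n"
            "synthetic export\t\t\tA\tB\n"
            "sample\tpop\tL1\tL2\tL3\n"
            "s1\tA\t1\t0\t1\n"
            "s2\tA\t0\t0\t1\n"
            "s3\tB\t1\t1\t0\n"
            "s4\tB\t0\t1\t0\n"
        )
        path = tmp_path / "g.genalex.txt"
        path.write_text(text)
        m = read_aflp_matrix(path, dialect="genalex")
        assert m.genotypes.shape == (4, 3)
        assert set(m.region_of.values()) == {"ALL"}

    def test_roundtrip_random_matrices(self, tmp_path, rng):
        for rep in range(100):
            m = make_matrix(
                rng,
                n_pops=int(rng.integers(2, 5)) * 2,
                n_per_pop=int(rng.integers(2, 5)),
                n_loci=int(rng.integers(1, 15)),
            )
            path = tmp_path / f"m{rep}.tsv"
            write_aflp_matrix(m, path)
            m2 = read_aflp_matrix(path)
            assert np.array_equal(m.genotypes, m2.genotypes)
            assert m.sample_ids == m2.sample_ids
            assert m.populations == m2.populations
            assert m.region_of == dict(m2.region_of)
            assert m.locus_ids == m2.locus_ids
            # writer emits the same dialect bit-exactly
            path2 = tmp_path / f"m{rep}b.tsv"
            write_aflp_matrix(m2, path2)
            assert path.read_bytes() == path2.read_bytes()


class TestValidation:
    def test_rejects_non_binary_entries(self):
        with pytest.raises(ValueError, match="0 or 1"):
            AFLPMatrix(
                np.array([[0, 2], [1, 0], [0, 1], [1, 1]]),
                ["a", "b", "c", "d"],
                ["P1", "P1", "P2", "P2"],
                {"P1": "R", "P2": "R"},
                ["L1", "L2"],
            )

    def test_rejects_undersized_population(self):
        with pytest.raises(ValueError, match="fewer than 2 individuals"):
            AFLPMatrix(
                np.zeros((3, 2), dtype=int),
                ["a", "b", "c"],
                ["P1", "P1", "P2"],
                {"P1": "R", "P2": "R"},
                ["L1", "L2"],
            )

    def test_rejects_single_population_region(self):
        with pytest.raises(ValueError, match="fewer than 2 populations"):
            AFLPMatrix(
                np.zeros((4, 2), dtype=int),
                ["a", "b", "c", "d"],
                ["P1", "P1", "P2", "P2"],
                {"P1": "R1", "P2": "R2"},
                ["L1", "L2"],
            )

    def test_replicate_pair_uniqueness(self):
        with pytest.raises(ValueError, match="more than one pair"):
            ReplicatePairs([("a", "b"), ("b", "c")])


class TestErrorRate:
    def test_identical_replicates_give_zero(self, rng):
        row = rng.integers(0, 2, 8)
        X = np.vstack([row, row, rng.integers(0, 2, 8), rng.integers(0, 2, 8)])
        m = AFLPMatrix(
            X, ["o", "r", "x", "y"], ["P1", "P1", "P2", "P2"],
            {"P1": "R", "P2": "R"}, [f"L{i}" for i in range(8)],
        )
        assert genotyping_error_rate(m, ReplicatePairs([("o", "r")])) == 0.0

    def test_hand_counted_mismatches(self):
        X = np.zeros((4, 10), dtype=int)
        X[1, [2, 7]] = 1  # replicate of row 0 with 2 discordant loci
        m = AFLPMatrix(
            X, ["o1", "r1", "o2", "r2"], ["P1", "P1", "P2", "P2"],
            {"P1": "R", "P2": "R"}, [f"L{i}" for i in range(10)],
        )
        pairs = ReplicatePairs([("o1", "r1"), ("o2", "r2")])
        assert genotyping_error_rate(m, pairs) == pytest.approx(2 / 20)

    def test_all_loci_flipped_gives_one(self):
        X = np.vstack([np.zeros(6), np.ones(6), np.zeros(6), np.zeros(6)]).astype(int)
        m = AFLPMatrix(
            X, ["o", "r", "x", "y"], ["P1", "P1", "P2", "P2"],
            {"P1": "R", "P2": "R"}, [f"L{i}" for i in range(6)],
        )
        assert genotyping_error_rate(m, ReplicatePairs([("o", "r")])) == 1.0

    def test_empty_pairs_error(self, small_matrix):
        with pytest.raises(ValueError, match="at least one"):
            genotyping_error_rate(small_matrix, ReplicatePairs([]))

    @given(st.integers(0, 2**32 - 1))
    def test_invariant_to_locus_and_pair_order(self, seed):
        rng = np.random.default_rng(seed)
        m = make_matrix(rng, n_pops=2, n_per_pop=4, n_loci=12, two_regions=False)
        pairs = ReplicatePairs([("s0", "s1"), ("s2", "s3")])
        base = genotyping_error_rate(m, pairs)
        perm = rng.permutation(m.n_loci)
        shuffled = AFLPMatrix(
            m.genotypes[:, perm], m.sample_ids, m.populations, m.region_of,
            [m.locus_ids[j] for j in perm],
        )
        assert genotyping_error_rate(shuffled, pairs) == base
        swapped = ReplicatePairs([("s2", "s3"), ("s1", "s0")])
        assert genotyping_error_rate(m, swapped) == base
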