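"""Weighted Chaos Game Representation: expansion, addressing, matrix build."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lacunaseq import (
    Call,
    CallTable,
    IUPAC_CODES,
    NucleotideSequence,
    SequenceError,
    apply_calls,
    cgr_matrix,
    expand_ambiguous,
    mutation_report,
    random_sequence,
    SequenceSimSpec,
    substring_position,
)
from lacunaseq.cgr import read_matrix_csv, read_pgm, write_matrix_csv, write_pgm

from _oracles import naive_kmer_counts, quadrant_position

iupac_string = st.text(alphabet=sorted(IUPAC_CODES), min_size=1, max_size=8)


class TestExpandAmbiguous:
    @pytest.mark.parametrize(
        "substring, expected",
        [
            ("tamcg", [("taacg", 0.5), ("taccg", 0.5)]),
            ("tavcg", [("taacg", 1 / 3), ("taccg", 1 / 3), ("tagcg", 1 / 3)]),
            ("acgta", [("acgta", 1.0)]),
        ],
    )
    def test_worked_examples(self, substring, expected):
        got = expand_ambiguous(substring)
        assert [s for s, _ in got] == [s for s, _ in expected]
        assert [w for _, w in got] == pytest.approx([w for _, w in expected])

    def test_double_n_full_product(self):
        got = expand_ambiguous("nn")
        assert len(got) == 16
        assert {s for s, _ in got} == {
            a + b for a in "acgt" for b in "acgt"
        }
        assert all(w == pytest.approx(1 / 16) for _, w in got)

    def test_illegal_symbol(self):
        with pytest.raises(SequenceError):
            expand_ambiguous("acq")

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(s=iupac_string)
    def test_weights_sum_to_one_and_strings_pure(self, s):
        got = expand_ambiguous(s)
        assert sum(w for _, w in got) == pytest.approx(1.0, abs=1e-12)
        degeneracy = int(np.prod([len(IUPAC_CODES[ch]) for ch in s]))
        assert len(got) == degeneracy
        assert all(set(p) <= set("acgt") for p, _ in got)


class TestSubstringPosition:
    @pytest.mark.parametrize(
        "s, expected",
        [("aaaaa", (0, 0)), ("ttttt", (31, 31)), ("ca", (0, 2))],
    )
    def test_corner_and_hand_derived_cells(self, s, expected):
        assert substring_position(s) == expected

    def test_degenerate_symbol_rejected(self):
        with pytest.raises(SequenceError):
            substring_position("am")

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(s=st.text(alphabet="acgt", min_size=1, max_size=7))
    def test_matches_interval_halving_oracle(self, s):
        assert substring_position(s) == quadrant_position(s)

    def test_all_cells_distinct_at_l3(self):
        cells = {
            substring_position(a + b + c)
            for a in "acgt" for b in "acgt" for c in "acgt"
        }
        assert len(cells) == 64


class TestCGRMatrix:
    def test_homopolymer_single_cell(self):
        m = cgr_matrix(NucleotideSequence("aaaa"), 2)
        assert m.values[0, 0] == 3.0
        assert m.values.sum() == 3.0

    def test_weighted_worked_example(self):
        m = cgr_matrix(NucleotideSequence("tamcg"), 5)
        nz = {tuple(ix): m.values[tuple(ix)] for ix in np.argwhere(m.values > 0)}
        assert nz == {
            substring_position("taacg"): pytest.approx(0.5),
            substring_position("taccg"): pytest.approx(0.5),
        }
        assert m.total_mass == pytest.approx(1.0, abs=1e-12)

    def test_l1_counts_symbols(self):
        m = cgr_matrix(NucleotideSequence("acgtacgt"), 1)
        assert np.all(m.values == 2.0)

    def test_frame_length_validation(self):
        with pytest.raises(ValueError):
            cgr_matrix(NucleotideSequence("acg"), 4)
        with pytest.raises(ValueError):
            cgr_matrix(NucleotideSequence("acgt"), 0)
        with pytest.raises(ValueError):
            cgr_matrix(NucleotideSequence("a" * 20), 13)

    def test_expansion_cap(self):
        with pytest.raises(SequenceError, match="cap"):
            cgr_matrix(NucleotideSequence("n" * 7), 7)

    def test_circular_adds_wraparound_windows(self):
        seq = NucleotideSequence("acgt")
        linear = cgr_matrix(seq, 2)
        circular = cgr_matrix(seq, 2, circular=True)
        assert linear.total_mass == 3.0
        assert circular.total_mass == 4.0
        # the extra window is "ta"
        extra = circular.values - linear.values
        assert extra[substring_position("ta")] == 1.0

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(data=st.data())
    def test_mass_conservation_with_ambiguity(self, data):
        symbols = data.draw(
            st.text(alphabet=sorted(IUPAC_CODES), min_size=10, max_size=120)
        )
        L = data.draw(st.sampled_from([2, 3, 5]))
        try:
            m = cgr_matrix(NucleotideSequence(symbols), L)
        except SequenceError:  # expansion cap on pathological all-n windows
            return
        assert m.total_mass == pytest.approx(len(symbols) - L + 1, abs=1e-9)

    @pytest.mark.parametrize("L", [1, 2, 4, 6])
    def test_pure_sequence_equals_kmer_count_oracle(self, L, rng):
        symbols = "".join(rng.choice(list("acgt"), size=400))
        m = cgr_matrix(NucleotideSequence(symbols), L)
        expected = np.zeros_like(m.values)
        for kmer, count in naive_kmer_counts(symbols, L).items():
            expected[substring_position(kmer)] = count
        np.testing.assert_array_equal(m.values, expected)

    def test_consistency_across_frame_lengths(self, rng):
        """Summing the four child cells of an (L-1)-mer recovers its count
        up to the boundary effect of the final window."""
        symbols = "".join(rng.choice(list("acgt"), size=600))
        L = 4
        coarse = cgr_matrix(NucleotideSequence(symbols), L - 1).values
        fine = cgr_matrix(NucleotideSequence(symbols), L).values
        for kmer in set(
            symbols[i : i + L - 1] for i in range(len(symbols) - L + 2)
        ):
            child_sum = sum(
                fine[substring_position(kmer + x)] for x in "acgt"
            )
            assert abs(child_sum - coarse[substring_position(kmer)]) <= 1.0

    def test_cpg_depleted_sequence_empties_cg_cells(self):
        """CpG suppression produces the recursively empty (Sierpinski-like)
        cell pattern: every cell whose substring contains "cg" is zero."""
        seq = random_sequence(
            SequenceSimSpec(length=20000, forbidden_dinucleotides=("cg",), seed=5)
        )
        L = 4
        m = cgr_matrix(seq, L)
        for i in range(4 ** L):
            kmer = "".join("acgt"[(i >> (2 * k)) & 3] for k in range(L))
            if "cg" in kmer:
                assert m.values[substring_position(kmer)] == 0.0


class TestMutationReport:
    def test_pure_reference_counts(self, acgt):
        rep = mutation_report(acgt, CallTable([]), acgt)
        assert rep.counts == {"a": 1, "c": 1, "g": 1, "t": 1}
        assert rep.n_homoplasmic == 0 and rep.n_heteroplasmic == 0

    def test_heteroplasmic_fractional_counts(self, acgt):
        calls = CallTable([Call(2, "c", "m")])
        mutated = apply_calls(acgt, calls)
        rep = mutation_report(acgt, calls, mutated)
        assert rep.counts["a"] == pytest.approx(1.5)
        assert rep.counts["c"] == pytest.approx(0.5)
        assert sum(rep.counts.values()) == pytest.approx(rep.sequence_length)
        assert rep.heteroplasmic == [(2, "c", "m")]

    def test_homoplasmic_counting(self, acgt):
        calls = CallTable([Call(1, "a", "g"), Call(4, "t", "c")])
        mutated = apply_calls(acgt, calls)
        rep = mutation_report(acgt, calls, mutated)
        assert rep.n_homoplasmic == 2
        assert rep.n_heteroplasmic == 0


class TestSerialisation:
    def test_matrix_csv_round_trip(self, tmp_path):
        m = cgr_matrix(NucleotideSequence("tamcgtacg"), 3)
        p = tmp_path / "m.csv"
        write_matrix_csv(m, p)
        np.testing.assert_allclose(read_matrix_csv(p), m.values, atol=1e-10)

    def test_pgm_round_trip_scaling(self, tmp_path):
        values = np.array([[0.0, 2.0], [4.0, 8.0]])
        p = tmp_path / "m.pgm"
        write_pgm(values, p)
        back = read_pgm(p)
        np.testing.assert_allclose(back / back.max(), values / values.max(), atol=1e-4)
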