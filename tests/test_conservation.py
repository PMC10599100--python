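import random
from collections import Counter

import pytest

from wxlsurvey.conservation import (
    Alignment,
    AlignmentFormatError,
    column_conservation,
    map_to_reference,
    read_alignment,
)
from wxlsurvey.synthetic_data import generate_msa


def _aln(rows, ids=None):
    ids = ids or tuple(f"s{i}" for i in range(len(rows)))
    return Alignment(ids=tuple(ids), rows=tuple(rows))


class TestReadAlignment:
    def test_fasta(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">a\nMKLV-AAAAA\n>b\nMKLV-AAAAA\n")
        aln = read_alignment(p)
        assert (aln.n_seqs, aln.n_cols) == (2, 10)

    def test_ragged_names_offender(self, tmp_path):
        p = tmp_path / "r.fa"
        p.write_text(">good\nMKLV\n>short\nMK\n")
        with pytest.raises(AlignmentFormatError, match="short"):
            read_alignment(p)

    def test_clustal_equals_fasta(self, tmp_path):
        rows = {"seq1": "MKL-V", "seq2": "MKLAV"}
        fa = tmp_path / "a.fa"
        fa.write_text("".join(f">{k}\n{v}\n" for k, v in rows.items()))
        cl = tmp_path / "a.aln"
        cl.write_text(
            "CLUSTAL W (1.82) multiple sequence alignment\n\n"
            "seq1   MKL-V\nseq2   MKLAV\n")
        assert read_alignment(fa) == read_alignment(cl)


class TestColumnConservation:
    def test_invariant_count_boundary(self):
        """60 identical residues of 175 is conserved; 59 is not."""
        background = "ACDEFGHIKLMNPQRSTVY"  # spread thin, never majority

        def make(count):
            return ["W"] * count + [background[i % 19] for i in range(175 - count)]

        p60 = column_conservation(_aln(make(60)), threshold=60)
        assert p60.columns[0].conserved
        assert (p60.columns[0].majority_residue, p60.columns[0].majority_count) \
            == ("W", 60)
        p59 = column_conservation(_aln(make(59)), threshold=60)
        assert not p59.columns[0].conserved
        assert p59.columns[0].majority_count == 59

    def test_gaps_never_count(self):
        rows = ["-"] * 3 + ["W"] * 2
        profile = column_conservation(_aln(rows), threshold=2)
        col = profile.columns[0]
        assert (col.majority_residue, col.majority_count) == ("W", 2)

    def test_all_gap_column(self):
        profile = column_conservation(_aln(["-", "-"]), threshold=1)
        col = profile.columns[0]
        assert col.majority_count == 0 and not col.conserved

    def test_tie_broken_alphabetically(self):
        profile = column_conservation(_aln(["W", "A"]), threshold=3)
        assert profile.columns[0].majority_residue == "A"

    def test_bad_threshold(self):
        with pytest.raises(ValueError):
            column_conservation(_aln(["A"]), threshold=0)

    def test_fractional_threshold(self):
        rows = ["W"] * 7 + ["A"] * 13
        assert column_conservation(_aln(rows), fraction=0.343).threshold == 7

    def test_counts_match_bruteforce_tally(self, rng):
        for _ in range(30):
            n, m = rng.randint(1, 30), rng.randint(1, 20)
            rows = ["".join(rng.choice("AW-L.") for _ in range(m))
                    for _ in range(n)]
            profile = column_conservation(_aln(rows), threshold=rng.randint(1, n))
            for j, col in enumerate(profile.columns):
                tally = Counter(r[j] for r in rows if r[j] not in "-.")
                assert col.majority_count == (max(tally.values()) if tally else 0)

    def test_threshold_monotonicity(self, rng):
        rows = ["".join(rng.choice("AWL-") for _ in range(40)) for _ in range(50)]
        prev = None
        for t in range(1, 52):
            conserved = set(
                column_conservation(_aln(rows), threshold=t).conserved_columns())
            if prev is not None:
                assert conserved <= prev
            prev = conserved

    def test_permutation_invariance(self, rng):
        rows = ["".join(rng.choice("AWLK") for _ in range(25)) for _ in range(30)]
        base = column_conservation(_aln(rows), threshold=10)
        shuffled = rows[:]
        rng.shuffle(shuffled)
        assert column_conservation(_aln(shuffled), threshold=10) == base


class TestMapToReference:
    def test_gap_arithmetic(self):
        aln = _aln(["A-CD", "A-CD", "AGCD"], ids=["ref", "b", "c"])
        profile = column_conservation(aln, threshold=3)
        assert profile.conserved_columns() == [0, 2, 3]
        positions, gap_cols = map_to_reference(profile, aln, "ref")
        assert positions == [1, 2, 3]
        assert gap_cols == []

    def test_conserved_column_at_reference_gap(self):
        aln = _aln(["A-C", "AGC", "AGC"], ids=["ref", "b", "c"])
        profile = column_conservation(aln, threshold=2)
        positions, gap_cols = map_to_reference(profile, aln, "ref")
        assert positions == [1, 2]
        assert gap_cols == [1]

    def test_no_conserved_columns(self):
        aln = _aln(["AC", "GT"], ids=["ref", "b"])
        profile = column_conservation(aln, threshold=2)
        assert map_to_reference(profile, aln, "ref") == ([], [])

    def test_ungapped_reference_identity(self):
        aln = _aln(["ACDE", "ACDE"], ids=["ref", "b"])
        profile = column_conservation(aln, threshold=2)
        positions, _ = map_to_reference(profile, aln, "ref")
        assert positions == [c + 1 for c in profile.conserved_columns()]

    def test_unknown_reference(self):
        aln = _aln(["AC"], ids=["a"])
        profile = column_conservation(aln, threshold=1)
        with pytest.raises(KeyError):
            map_to_reference(profile, aln, "nope")


class TestPlantedMsa:
    def test_planted_columns_recovered_exactly(self, rng):
        aln, truth = generate_msa(175, 40, [3, 7], 60, rng)
        profile = column_conservation(aln, threshold=60)
        assert set(profile.conserved_columns()) == truth == {3, 7}

    def test_subthreshold_plant_not_recovered(self, rng):
        aln, _ = generate_msa(175, 30, [5], 59, rng)
        profile = column_conservation(aln, threshold=60)
        assert profile.conserved_columns() == []

    def test_seeded_determinism(self):
        a1, _ = generate_msa(50, 20, [2], 20, random.Random(5))
        a2, _ = generate_msa(50, 20, [2], 20, random.Random(5))
        assert a1 == a2

    def test_infeasible_configuration_rejected(self):
        with pytest.raises(ValueError):
            generate_msa(200, 10, [1], 3, random.Random(0))
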