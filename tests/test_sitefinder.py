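"""Column profiles, conserved windows, discriminative 3' anchors."""

import random
from collections import Counter

import pytest

from taxoprimer import iupac
from taxoprimer.align import Msa
from taxoprimer.sitefinder import (
    column_profile,
    conserved_windows,
    discriminative_anchors,
    repeat_screen,
)


def _msa_from_columns(columns):
    n = len(columns[0])
    rows = tuple("".join(col[i] for col in columns) for i in range(n))
    return Msa(tuple(f"s{i}" for i in range(n)), rows)


class TestColumnProfile:
    def test_uniform_column(self):
        prof = column_profile(_msa_from_columns(["AAAA"]), 0)
        assert prof.conservation == 1.0
        assert prof.entropy_bits == 0.0
        assert prof.majority_base == "A"

    def test_mixed_column_entropy(self):
        prof = column_profile(_msa_from_columns(["AACG"]), 0)
        assert prof.majority_base == "A"
        assert prof.conservation == pytest.approx(0.5)
        assert prof.entropy_bits == pytest.approx(1.5)

    def test_gaps_excluded_from_conservation(self):
        prof = column_profile(_msa_from_columns(["AA--"]), 0)
        assert prof.gap_fraction == pytest.approx(0.5)
        assert prof.conservation == pytest.approx(1.0)

    def test_counts_partition_the_column(self):
        prof = column_profile(_msa_from_columns(["AC-R"]), 0)
        assert sum(prof.base_counts.values()) + prof.gap_count + prof.ambiguous_count == 4


class TestConservedWindows:
    def test_fully_identical_alignment_is_one_window(self):
        msa = Msa(("a", "b", "c"), ("A" * 100,) * 3)
        assert conserved_windows(msa, 10, 0.9) == [(0, 100)]

    def test_variable_column_splits_the_run(self):
        rows = ["A" * 100, "A" * 100, "A" * 50 + "C" + "A" * 49]
        # column 50 has conservation 2/3 < 0.9 -> run splits there
        msa = Msa(("a", "b", "c"), tuple(r[:100] for r in rows))
        assert conserved_windows(msa, 10, 0.9) == [(0, 50), (51, 100)]

    def test_matches_column_by_column_brute_force(self):
        rng = random.Random(17)
        for _ in range(200):
            n, cols = 5, 40
            rows = [
                "".join(rng.choice("ACGT-") for _ in range(cols)) for _ in range(n)
            ]
            msa = Msa(tuple(f"s{i}" for i in range(n)), tuple(rows))
            min_len, min_cons, gap_cap = 3, 0.75, 0.25
            got = conserved_windows(msa, min_len, min_cons, gap_cap)

            def col_ok(c):
                col = [r[c] for r in rows]
                gaps = col.count("-")
                nongap = [x for x in col if x != "-"]
                if gaps / n > gap_cap or not nongap:
                    return False
                top = Counter(x for x in nongap if x in "ACGT").most_common(1)
                return bool(top) and top[0][1] / len(nongap) >= min_cons

            expected, start = [], None
            for c in range(cols + 1):
                ok = c < cols and col_ok(c)
                if ok and start is None:
                    start = c
                elif not ok and start is not None:
                    if c - start >= min_len:
                        expected.append((start, c))
                    start = None
            assert got == expected

    def test_windows_are_maximal_and_disjoint(self):
        rng = random.Random(23)
        rows = tuple(
            "".join(rng.choice("AACGT") for _ in range(200)) for _ in range(6)
        )
        msa = Msa(tuple(f"s{i}" for i in range(6)), rows)
        windows = conserved_windows(msa, 2, 0.8)
        for (s1, e1), (s2, e2) in zip(windows, windows[1:]):
            assert e1 <= s2  # disjoint, ordered


class TestDiscriminativeAnchors:
    def test_planted_divergent_column_is_reported_on_both_strands(self):
        rows = ("CCACCCC", "CCACCCC", "CCGCCCC", "CCGCCCC")
        msa = Msa(("t1", "t2", "n1", "n2"), rows)
        sites = discriminative_anchors(msa, ["t1", "t2"])
        assert {(s.column, s.strand, s.target_base) for s in sites} == {
            (2, "plus", "A"),
            (2, "minus", "T"),
        }
        assert all(s.margin == 2 for s in sites)

    def test_polymorphic_targets_disqualify_the_column(self):
        msa = Msa(("t1", "t2", "n1"), ("A", "G", "C"))
        assert discriminative_anchors(msa, ["t1", "t2"]) == []

    def test_nontarget_ambiguity_overlapping_target_base_blocks_the_site(self):
        msa = Msa(("t1", "n1"), ("A", "R"))  # R could be A -> not safely different
        assert discriminative_anchors(msa, ["t1"]) == []

    def test_all_sequences_as_targets_returns_empty(self):
        msa = Msa(("a", "b"), ("AC", "AC"))
        assert discriminative_anchors(msa, ["a", "b"]) == []

    def test_matches_exhaustive_per_column_check(self):
        rng = random.Random(31)
        for _ in range(200):
            n, cols = 12, 30
            rows = [
                "".join(rng.choice("AC-G") for _ in range(cols)) for _ in range(n)
            ]
            ids = tuple(f"s{i}" for i in range(n))
            msa = Msa(ids, tuple(rows))
            k = rng.randint(1, n - 1)
            targets = list(ids[:k])
            got = {(s.column, s.strand, s.target_base) for s in discriminative_anchors(msa, targets)}
            expected = set()
            for c in range(cols):
                tchars = {rows[i][c] for i in range(k)}
                if len(tchars) != 1:
                    continue
                base = tchars.pop()
                if base not in "ACGT":
                    continue
                if all(
                    rows[i][c] == "-" or base not in iupac.CODE_TO_BASES[rows[i][c]]
                    for i in range(k, n)
                ):
                    expected.add((c, "plus", base))
                    expected.add((c, "minus", iupac.COMPLEMENT[base]))
            assert got == expected

    def test_sites_map_to_valid_positions_for_every_target(self, mock_db):
        from taxoprimer.align import align_sequences
        from taxoprimer.pipeline import consensus_by_species, species_taxonomy

        sp_tax = species_taxonomy(mock_db.taxonomy)
        members = sorted(s for s, t in sp_tax.items() if t.genus == "GenB")
        fam = sorted(s for s, t in sp_tax.items() if t.family == sp_tax[members[0]].family)
        cons = consensus_by_species(
            [r for r in mock_db.records if sp_tax[r.taxon].family == sp_tax[members[0]].family],
            mock_db.taxonomy,
        )
        msa = align_sequences({s: cons[s].sequence for s in fam}, center=members[0])
        sites = discriminative_anchors(msa, members)
        assert sites, "planted genus signature should yield anchors"
        for site in sites:
            for m in members:
                assert msa.position_in(m, site.column) is not None


class TestRepeatScreen:
    def test_repeated_three_prime_flank_is_discarded(self):
        repeat = "ACGTTGCAGGCA"  # 12-mer, planted twice
        rng = random.Random(41)
        filler = "".join(rng.choice("ACGT") for _ in range(40))
        seq = repeat + filler + repeat
        msa = Msa(("t", "n"), (seq, "T" * len(seq)))
        sites = discriminative_anchors(msa, ["t"])
        anchor_col = len(repeat) - 1  # 3' flank == the repeated 12-mer
        kept = repeat_screen(
            [s for s in sites if s.column == anchor_col and s.strand == "plus"],
            msa,
            ["t"],
        )
        assert kept == []
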