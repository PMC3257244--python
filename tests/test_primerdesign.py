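"""Candidate enumeration, physicochemical screening, and pairing."""

import random
from dataclasses import replace

from taxoprimer.align import Msa
from taxoprimer.iupac import reverse_complement
from taxoprimer.primerdesign import (
    DesignConstraints,
    enumerate_candidates,
    hairpin_score,
    make_candidate,
    max_homopolymer,
    pair_candidates,
    physchem_screen,
    self_dimer_score,
    verify_specific_anchor,
)
from taxoprimer.sitefinder import DiscriminativeSite


class TestPhyschemScreen:
    def test_homopolymer_and_gc_violations_are_all_listed(self):
        cand = make_candidate("g20", "G" * 20, "plus", (0, 20))
        result = physchem_screen(cand)
        assert not result.passed
        assert any("homopolymer" in r for r in result.reasons)
        assert any("gc" in r for r in result.reasons)

    def test_balanced_primer_passes(self):
        cand = make_candidate("ok", "ACTGACCTGAAGCTGATCCA", "plus", (0, 20))
        assert physchem_screen(cand).passed

    def test_palindromic_primer_fails_self_dimer(self):
        seq = "GAATTCGAATTCGAATTC"
        assert reverse_complement(seq) == seq
        cand = make_candidate("pal", seq, "plus", (0, len(seq)))
        result = physchem_screen(cand)
        assert not result.passed
        assert any("self-dimer" in r for r in result.reasons)
        # full-length duplex anchored at the 3' end, weighted double
        assert cand.self_dimer_score == 2 * len(seq)

    def test_length_bounds(self):
        short = make_candidate("s", "ACGTACGTAC", "plus", (0, 10))
        assert any("length" in r for r in physchem_screen(short).reasons)


def test_scores_are_order_independent_of_strand_convention():
    seq = "ACTGACCTGAAGCTGATCCA"
    assert self_dimer_score(seq) == self_dimer_score(reverse_complement(seq))
    assert max_homopolymer("AAACCCCTG") == 4
    assert hairpin_score("ACGTACGTACGT") >= 0


class TestEnumerate:
    def _toy(self, rng, n=120):
        target = "".join(rng.choice("ACGT") for _ in range(n))
        nontarget = "".join(
            c if rng.random() > 0.3 else rng.choice("ACGT".replace(c, ""))
            for c in target
        )
        return target, Msa(("t", "n"), (target, nontarget))

    def test_specific_candidates_end_on_the_anchor(self):
        rng = random.Random(3)
        target, msa = self._toy(rng)
        pos = 50
        sites = [
            DiscriminativeSite(pos, target[pos], frozenset("-"), "plus", 1),
            DiscriminativeSite(pos, reverse_complement(target[pos]), frozenset("-"), "minus", 1),
        ]
        cands = enumerate_candidates(
            target, sites=sites, msa=msa, reference_id="t", mode="specific"
        )
        assert cands
        for c in cands:
            assert c.three_prime_position == pos
            if c.strand == "plus":
                assert c.sequence == target[c.template_span[0] : c.template_span[1]]
            else:
                assert c.sequence == reverse_complement(
                    target[c.template_span[0] : c.template_span[1]]
                )

    def test_no_sites_no_candidates(self):
        rng = random.Random(4)
        target, msa = self._toy(rng)
        assert enumerate_candidates(target, sites=[], msa=msa, reference_id="t") == []

    def test_specific_enumeration_matches_exhaustive_window_scan(self):
        rng = random.Random(5)
        target, msa = self._toy(rng)
        constraints = DesignConstraints(min_len=18, max_len=20)
        pos = 70
        sites = [DiscriminativeSite(pos, target[pos], frozenset("-"), "plus", 1)]
        got = {(c.template_span, c.strand) for c in enumerate_candidates(
            target, sites=sites, msa=msa, reference_id="t",
            constraints=constraints, mode="specific",
        )}
        expected = set()
        for length in range(18, 21):
            start, end = pos - length + 1, pos + 1
            if start < 0:
                continue
            cand = make_candidate("x", target[start:end], "plus", (start, end))
            if physchem_screen(cand, constraints).passed:
                expected.add(((start, end), "plus"))
        assert got == expected

    def test_group_candidates_stay_inside_windows(self):
        rng = random.Random(6)
        target, msa = self._toy(rng)
        window = (20, 60)
        cands = enumerate_candidates(
            target, windows=[window], msa=msa, reference_id="t", mode="group"
        )
        for c in cands:
            assert window[0] <= c.template_span[0] and c.template_span[1] <= window[1]


def _placed(seq, strand, span, tm=60.0):
    return replace(make_candidate("p", seq, strand, span), tm_celsius=tm)


class TestPairing:
    def test_expected_length_arithmetic(self):
        f = _placed("ACTGACCTGAAGCTGATCCA", "plus", (10, 30))
        r = _placed("ACTGACCTGAAGCTGATCCA", "minus", (140, 160))
        pairs = pair_candidates([f], [r])
        assert len(pairs) == 1
        assert pairs[0].expected_length_bp == 150
        assert pairs[0].tm_difference == 0.0

    def test_oversized_amplicon_is_excluded(self):
        f = _placed("ACTGACCTGAAGCTGATCCA", "plus", (0, 20))
        r = _placed("ACTGACCTGAAGCTGATCCA", "minus", (480, 500))
        assert pair_candidates([f], [r]) == []

    def test_tm_difference_cap(self):
        f = _placed("ACTGACCTGAAGCTGATCCA", "plus", (10, 30), tm=58.0)
        r = _placed("ACTGACCTGAAGCTGATCCA", "minus", (140, 160), tm=64.0)
        assert pair_candidates([f], [r]) == []

    def test_pairing_is_symmetric_under_strand_flip(self):
        rng = random.Random(7)
        forwards, reverses = [], []
        for k in range(5):
            seq = "".join(rng.choice("ACGT") for _ in range(20))
            forwards.append(_placed(seq, "plus", (10 + 7 * k, 30 + 7 * k), tm=59 + 0.3 * k))
        for k in range(5):
            seq = "".join(rng.choice("ACGT") for _ in range(20))
            reverses.append(_placed(seq, "minus", (150 + 9 * k, 170 + 9 * k), tm=59 + 0.4 * k))
        direct = {
            (p.forward.template_span, p.reverse.template_span)
            for p in pair_candidates(forwards, reverses)
        }

        L = 400  # mirror the template axis when flipping strand convention

        def flip(c):
            start, end = c.template_span
            return replace(
                c,
                strand="minus" if c.strand == "plus" else "plus",
                sequence=reverse_complement(c.sequence),
                template_span=(L - end, L - start),
            )

        flipped = {
            ((L - p.reverse.template_span[1], L - p.reverse.template_span[0]),
             (L - p.forward.template_span[1], L - p.forward.template_span[0]))
            for p in pair_candidates([flip(r) for r in reverses], [flip(f) for f in forwards])
        }
        assert direct == flipped


def test_specific_candidates_discriminate_at_their_anchor(mock_db):
    """ARMS re-verification: every emitted candidate's 3' column separates
    the target from every non-target in its family alignment."""
    from taxoprimer.align import align_sequences
    from taxoprimer.pipeline import consensus_by_species, species_taxonomy
    from taxoprimer.sitefinder import discriminative_anchors

    sp_tax = species_taxonomy(mock_db.taxonomy)
    target = "GenA_sp1"
    fam = sorted(s for s, t in sp_tax.items() if t.family == sp_tax[target].family)
    cons = consensus_by_species(
        [r for r in mock_db.records if sp_tax[r.taxon].family == sp_tax[target].family],
        mock_db.taxonomy,
    )
    msa = align_sequences({s: cons[s].sequence for s in fam}, center=target)
    sites = discriminative_anchors(msa, [target])
    cands = enumerate_candidates(
        cons[target].sequence, sites=sites, msa=msa, reference_id=target,
        mode="specific", name_prefix=target,
    )
    assert cands
    assert all(verify_specific_anchor(c, msa, [target]) for c in cands)
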