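"""Conservation profiles, conserved windows, and discriminative 3' anchors.

Specific primers discriminate by their 3'-terminal base (ARMS logic): a
mismatch under the polymerase's 3' end blocks extension.  The search for
such anchors is purely columnar — find alignment columns where every
target sequence carries one identical concrete base and every non-target
differs.  Group (genus/family) primers instead need windows conserved
across the whole group; their specificity against outgroups is checked
downstream by in-silico PCR rather than per column.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from . import iupac

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ColumnProfile:
    """Composition summary of one alignment column.

    ``conservation`` is the fraction of non-gap symbols equal to the
    majority base (ambiguity codes count as non-gap symbols that never
    equal the majority); ``entropy_bits`` is the Shannon entropy of the
    concrete-base frequencies.  ``majority_base`` is None on a tie.
    """

    position: int
    base_counts: dict
    gap_count: int
    ambiguous_count: int
    n_seqs: int
    majority_base: str | None
    conservation: float
    entropy_bits: float

    @property
    def gap_fraction(self) -> float:
        return self.gap_count / self.n_seqs if self.n_seqs else 0.0


@dataclass(frozen=True)
class DiscriminativeSite:
    """A column suitable for a specific primer's 3'-terminal base.

    ``target_base``/``nontarget_bases`` are reported on the site's strand
    (minus-strand entries carry complemented symbols; gaps stay ``-``).
    ``margin`` counts the non-targets that differ — by construction all of
    them.
    """

    column: int
    target_base: str
    nontarget_bases: frozenset
    strand: str  # plus | minus
    margin: int


def column_profile(msa, position: int) -> ColumnProfile:
    """Exact counts, majority conservation and entropy for one column."""
    col = msa.column(position)  # raises on out-of-range / ragged alignment
    counts = {b: 0 for b in "ACGT"}
    gaps = ambiguous = 0
    for ch in col:
        if ch in iupac.GAP_CHARS:
            gaps += 1
        elif ch in counts:
            counts[ch] += 1
        else:
            ambiguous += 1
    n_nongap = len(col) - gaps
    top = max(counts.values()) if n_nongap else 0
    leaders = [b for b, c in counts.items() if c == top and c > 0]
    majority = leaders[0] if len(leaders) == 1 else None
    conservation = (top / n_nongap) if n_nongap else 0.0

    total_concrete = sum(counts.values())
    entropy = 0.0
    if total_concrete:
        for c in counts.values():
            if c:
                p = c / total_concrete
                entropy -= p * math.log2(p)
    return ColumnProfile(
        position=position,
        base_counts=counts,
        gap_count=gaps,
        ambiguous_count=ambiguous,
        n_seqs=len(col),
        majority_base=majority,
        conservation=conservation,
        entropy_bits=entropy,
    )


def conserved_windows(msa, min_len: int, min_conservation: float, max_gap_fraction: float = 0.1) -> list[tuple[int, int]]:
    """Maximal runs of conserved columns, as [start, end) spans.

    A column qualifies when conservation >= ``min_conservation`` and its
    gap fraction <= ``max_gap_fraction``; runs shorter than ``min_len``
    are dropped.  Windows are disjoint and maximal by construction.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    if not 0 < min_conservation <= 1:
        raise ValueError("min_conservation must be in (0, 1]")
    good = []
    for col in range(msa.n_cols):
        prof = column_profile(msa, col)
        good.append(
            prof.conservation >= min_conservation and prof.gap_fraction <= max_gap_fraction
        )
    windows = []
    start = None
    for col, ok in enumerate(good + [False]):
        if ok and start is None:
            start = col
        elif not ok and start is not None:
            if col - start >= min_len:
                windows.append((start, col))
            start = None
    return windows


def discriminative_anchors(msa, target_ids) -> list[DiscriminativeSite]:
    """Columns where all targets agree and every non-target differs.

    Targets must share one concrete base (an ambiguity code in a target —
    an uncertain consensus position — disqualifies the column).  A
    non-target "differs" when it has a gap or a code that cannot represent
    the target base; an ambiguity code overlapping the target base counts
    as not differing, erring on the side of specificity.  Each qualifying
    column is reported on both strands.
    """
    target_ids = list(dict.fromkeys(target_ids))
    if not target_ids:
        raise ValueError("target_ids is empty")
    unknown = [t for t in target_ids if t not in msa.ids]
    if unknown:
        raise ValueError(f"target ids not in alignment: {unknown}")
    nontarget_ids = [i for i in msa.ids if i not in set(target_ids)]
    if not nontarget_ids:
        logger.warning("discriminative_anchors: every sequence is a target; no sites possible")
        return []

    t_rows = [msa.row(t) for t in target_ids]
    n_rows = [msa.row(n) for n in nontarget_ids]
    sites: list[DiscriminativeSite] = []
    for col in range(msa.n_cols):
        base = t_rows[0][col]
        if base not in iupac.CONCRETE:
            continue
        if any(r[col] != base for r in t_rows):
            continue
        observed = frozenset(r[col] for r in n_rows)
        if not all(
            ch in iupac.GAP_CHARS or base not in iupac.CODE_TO_BASES.get(ch, frozenset())
            for ch in observed
        ):
            continue
        margin = len(nontarget_ids)
        sites.append(DiscriminativeSite(col, base, observed, "plus", margin))
        comp = frozenset("-" if ch in iupac.GAP_CHARS else iupac.COMPLEMENT[ch] for ch in observed)
        sites.append(
            DiscriminativeSite(col, iupac.COMPLEMENT[base], comp, "minus", margin)
        )
    return sites


def repeat_screen(sites, msa, target_ids, k: int = 12) -> list[DiscriminativeSite]:
    """Drop sites whose 3'-flanking k-mer repeats in any target sequence.

    cpDNA spacers are riddled with repeats on both strands and at shifted
    positions; a primer whose 3' flank recurs elsewhere in the template is
    unreliable.  For each site the k-mer that would form the primer's 3'
    end is looked up in every target sequence (both strands); more than
    one hit anywhere discards the site, as does a flank too short to form
    the k-mer.
    """
    kept = []
    targets = [(t, msa.ungapped(t)) for t in target_ids]
    for site in sites:
        ok = True
        for tid, seq in targets:
            pos = msa.position_in(tid, site.column)
            if pos is None:
                ok = False
                break
            if site.strand == "plus":
                if pos - k + 1 < 0:
                    ok = False
                    break
                kmer = seq[pos - k + 1 : pos + 1]
            else:
                if pos + k > len(seq):
                    ok = False
                    break
                kmer = iupac.reverse_complement(seq[pos : pos + k])
            hits = _count_occurrences(seq, kmer) + _count_occurrences(
                seq, iupac.reverse_complement(kmer)
            )
            if hits > 1:
                ok = False
                break
        if ok:
            kept.append(site)
    return kept


def _count_occurrences(haystack: str, needle: str) -> int:
    count = start = 0
    while True:
        idx = haystack.find(needle, start)
        if idx < 0:
            return count
        count += 1
        start = idx + 1
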