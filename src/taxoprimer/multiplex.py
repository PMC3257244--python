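"""Primer-dimer scoring, assay compatibility, and multiplex panel assembly.

Assays multiplex cleanly when their products are separable on a
capillary/gel trace (size gap), their primers work at one annealing
temperature (Tm spread), and no 3'-terminal cross-dimers form.  Panels are
built as an exact minimal partition for small assay sets and greedily
above that.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations

from . import iupac

_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


@dataclass(frozen=True)
class PanelParams:
    """Compatibility thresholds for co-resident assays.

    ``min_size_gap_bp``: smallest resolvable difference between expected
    product sizes (range-valued assays occupy their whole interval);
    ``max_tm_spread_celsius``: allowed Tm range across all primers in a
    panel; ``dimer_score_cap``: maximum tolerated 3'-anchored cross-dimer
    run; ``max_assays_per_panel`` bounds panel size.  The defaults are
    calibrated against published multiplexes known to co-amplify cleanly
    (their worst within-panel values: size gap 19 bp, Tm spread 6.35 C
    under this package's Tm model, 3'-dimer run 6); ``group_singleplex``
    keeps genus/family screening assays in their own reactions, matching
    two-step screening practice.
    """

    min_size_gap_bp: int = 15
    max_tm_spread_celsius: float = 7.0
    dimer_score_cap: int = 6
    max_assays_per_panel: int = 6
    group_singleplex: bool = True

    def __post_init__(self):
        for name in ("min_size_gap_bp", "max_tm_spread_celsius", "dimer_score_cap", "max_assays_per_panel"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class PanelCertificate:
    """Recomputable evidence that a panel satisfies its constraints."""

    pairwise_gaps_bp: tuple
    min_gap_bp: int | None
    tm_spread_celsius: float
    max_dimer_score: int


@dataclass(frozen=True)
class MultiplexPanel:
    name: str
    assays: tuple
    certificate: PanelCertificate


def duplex_runs(a: str, b: str):
    """Ungapped complementary runs between a (5'->3') and b (5'->3').

    Models annealing of ``a`` against ``b`` in antiparallel orientation at
    every register.  Yields ``(length, a_end, b_end)`` for every maximal
    complementary run, where ``a_end``/``b_end`` flag whether the run
    covers the respective primer's 3'-terminal base.
    """
    br = b[::-1]  # now index k pairs a[i] with b's base b[len(b)-1-k]
    la, lb = len(a), len(br)
    # register r: a[i] faces br[i - r]
    for r in range(-(lb - 1), la):
        run = 0
        start_i = None
        lo = max(0, r)
        hi = min(la, lb + r)
        for i in range(lo, hi + 1):
            paired = i < hi and (a[i], br[i - r]) in _PAIRS
            if paired:
                if run == 0:
                    start_i = i
                run += 1
            elif run:
                end_i = i - 1
                a_end = end_i == la - 1
                # br index i-r-... b's 3' terminus is br[0]
                b_end = (start_i - r) == 0
                yield run, a_end, b_end
                run = 0


@lru_cache(maxsize=65536)
def dimer_score(primer_a: str, primer_b: str) -> int:
    """Longest complementary run that includes a 3' terminus of either primer.

    Symmetric in its arguments; 0 when no complementary duplex touches a
    3' end.  Pure and memoised — panel search scores the same oligo pairs
    repeatedly.
    """
    a = iupac.normalize(primer_a)
    b = iupac.normalize(primer_b)
    best = 0
    for run, a_end, b_end in duplex_runs(a, b):
        if a_end or b_end:
            best = max(best, run)
    return best


def _expected_interval(assay) -> tuple[int, int]:
    """Expected product size(s) of an assay as a closed interval."""
    sizes = getattr(assay, "expected_sizes", None)
    if sizes is None:
        size = getattr(assay, "expected_length_bp")
        sizes = size if isinstance(size, (list, tuple)) else [size]
    return (min(sizes), max(sizes))


def _primers(assay):
    return [assay.forward, assay.reverse]


def _primer_seq(p) -> str:
    return p if isinstance(p, str) else p.sequence


def _primer_tm(p) -> float:
    return p.tm_celsius


def size_gap(assay_a, assay_b) -> int:
    lo_a, hi_a = _expected_interval(assay_a)
    lo_b, hi_b = _expected_interval(assay_b)
    return max(0, max(lo_a - hi_b, lo_b - hi_a))


@dataclass(frozen=True)
class CompatibilityDecision:
    compatible: bool
    reasons: tuple = ()


def compatible(assay_a, assay_b, params: PanelParams = PanelParams()) -> CompatibilityDecision:
    """Pairwise co-residency decision with every failed rule listed."""
    reasons = []
    gap = size_gap(assay_a, assay_b)
    if gap < params.min_size_gap_bp:
        reasons.append(f"size-gap {gap} < {params.min_size_gap_bp}")
    tms = [_primer_tm(p) for p in _primers(assay_a) + _primers(assay_b)]
    spread = max(tms) - min(tms)
    if spread > params.max_tm_spread_celsius:
        reasons.append(f"tm-spread {spread:.2f} > {params.max_tm_spread_celsius}")
    seen = set()
    for pa in _primers(assay_a):
        for pb in _primers(assay_b):
            sa, sb = _primer_seq(pa), _primer_seq(pb)
            if sa == sb:
                continue  # shared oligo, not a cross interaction
            key = tuple(sorted((sa, sb)))
            if key in seen:
                continue
            seen.add(key)
            score = dimer_score(sa, sb)
            if score > params.dimer_score_cap:
                reasons.append(f"dimer {_pname(pa)}x{_pname(pb)} score {score} > {params.dimer_score_cap}")
    return CompatibilityDecision(not reasons, tuple(reasons))


def _pname(p) -> str:
    return getattr(p, "name", "primer")


def self_incompatible(assay, params: PanelParams) -> bool:
    f, r = _primers(assay)
    return dimer_score(_primer_seq(f), _primer_seq(r)) > params.dimer_score_cap


def panel_certificate(assays, params: PanelParams = PanelParams()) -> PanelCertificate:
    gaps = tuple(size_gap(a, b) for a, b in combinations(assays, 2))
    tms = [_primer_tm(p) for a in assays for p in _primers(a)]
    spread = max(tms) - min(tms) if tms else 0.0
    seqs = sorted({_primer_seq(p) for a in assays for p in _primers(a)})
    max_dimer = 0
    for sa, sb in combinations(seqs, 2):
        max_dimer = max(max_dimer, dimer_score(sa, sb))
    return PanelCertificate(gaps, min(gaps) if gaps else None, spread, max_dimer)


def panel_valid(assays, params: PanelParams = PanelParams()) -> bool:
    if len(assays) > params.max_assays_per_panel:
        return False
    return all(
        compatible(a, b, params).compatible for a, b in combinations(assays, 2)
    )


def _assay_name(a) -> str:
    return getattr(a, "name", None) or getattr(a, "target", "assay")


def _panel_name(assays) -> str:
    """Initial letters of the target taxa, largest expected size first."""
    ordered = sorted(assays, key=lambda a: (-_expected_interval(a)[1], _assay_name(a)))
    letters = []
    for a in ordered:
        target = getattr(a, "target", None) or _assay_name(a)
        letters.append(target[:1].upper())
    return "".join(letters)


def build_panels(assays, params: PanelParams = PanelParams()) -> list[MultiplexPanel]:
    """Partition assays into the fewest valid panels.

    Exact minimal partition (dynamic programming over subsets, ties broken
    lexicographically by member assay names) for up to 12 assays; greedy
    largest-first above that, flagged in the log.  An assay whose own two
    primers dimerise above the cap cannot sit in any reaction and is an
    error.
    """
    assays = sorted(assays, key=_assay_name)
    if not assays:
        raise ValueError("no assays")
    for a in assays:
        if self_incompatible(a, params):
            raise ValueError(f"assay {_assay_name(a)} is self-incompatible (internal dimer above cap)")

    singles: list = []
    if params.group_singleplex:
        singles = [a for a in assays if getattr(a, "level", "species") in ("genus", "family")]
        assays = [a for a in assays if a not in singles]

    if not assays:
        groups = []
    elif len(assays) <= 12:
        groups = _exact_partition(assays, params)
    else:
        import logging

        logging.getLogger(__name__).warning(
            "more than 12 assays: falling back to greedy largest-first panel assembly"
        )
        groups = _greedy_partition(assays, params)

    panels = []
    for members in groups + [[a] for a in singles]:
        cert = panel_certificate(members, params)
        panels.append(MultiplexPanel(_panel_name(members), tuple(members), cert))
    return panels


def _exact_partition(assays, params):
    n = len(assays)
    valid = {}
    full = (1 << n) - 1

    def subset_valid(mask: int) -> bool:
        if mask not in valid:
            members = [assays[i] for i in range(n) if mask >> i & 1]
            valid[mask] = panel_valid(members, params)
        return valid[mask]

    from functools import lru_cache

    @lru_cache(maxsize=None)
    def best(mask: int) -> int:
        if mask == 0:
            return 0
        low = (mask & -mask).bit_length() - 1
        rest = mask & ~(1 << low)
        best_count = n + 1
        sub = rest
        while True:
            cand = sub | (1 << low)
            if subset_valid(cand):
                best_count = min(best_count, 1 + best(mask & ~cand))
            if sub == 0:
                break
            sub = (sub - 1) & rest
        return best_count

    # Reconstruct canonically: for the lowest uncovered assay pick the
    # lexicographically smallest (by member names) optimal subset.
    groups = []
    mask = full
    while mask:
        low = (mask & -mask).bit_length() - 1
        rest = mask & ~(1 << low)
        target = best(mask)
        choices = []
        sub = rest
        while True:
            cand = sub | (1 << low)
            if subset_valid(cand) and 1 + best(mask & ~cand) == target:
                names = tuple(_assay_name(assays[i]) for i in range(n) if cand >> i & 1)
                choices.append((names, cand))
            if sub == 0:
                break
            sub = (sub - 1) & rest
        choices.sort()
        chosen = choices[0][1]
        groups.append([assays[i] for i in range(n) if chosen >> i & 1])
        mask &= ~chosen
    return groups


def _greedy_partition(assays, params):
    remaining = list(assays)
    groups = []
    while remaining:
        panel = [remaining.pop(0)]
        rest = []
        for a in remaining:
            if len(panel) < params.max_assays_per_panel and panel_valid(panel + [a], params):
                panel.append(a)
            else:
                rest.append(a)
        remaining = rest
        groups.append(panel)
    return groups
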