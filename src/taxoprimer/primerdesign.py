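"""ARMS-style primer candidate enumeration, screening, and pairing.

Specific (species/genus) candidates put their 3'-terminal base exactly on
a discriminative site so that every non-target template carries a
3'-terminal mismatch — the classic amplification-refractory (ARMS) setup.
Group candidates for genus/family assays instead lie wholly inside
windows conserved across the group; their outgroup specificity is
established downstream by in-silico PCR.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import iupac
from .multiplex import duplex_runs
from .thermo import ThermoParams, melting_temperature

reverse_complement = iupac.reverse_complement


@dataclass(frozen=True)
class DesignConstraints:
    """Physicochemical and pairing bounds for candidate oligos.

    Length and GC bounds follow common practice for diagnostic endpoint
    PCR (oligos of 18-29 nt, GC 25-65%); amplicons are capped at 400 bp so
    degraded template DNA stays amplifiable, with an 80 bp floor to keep
    products distinguishable from dimer artifacts.
    """

    min_len: int = 18
    max_len: int = 29
    min_gc: float = 0.25
    max_gc: float = 0.65
    max_homopolymer: int = 4
    hairpin_cap: int = 8
    self_dimer_cap: int = 12
    tm_difference_cap: float = 3.0
    min_amplicon_bp: int = 80
    max_amplicon_bp: int = 400


@dataclass(frozen=True)
class PrimerCandidate:
    """One concrete oligo placed on a reference taxon's sequence.

    ``template_span`` is 0-based half-open on the reference (plus strand);
    for a minus-strand primer the sequence is the reverse complement of
    that span.  ``anchor_column`` is the alignment column of the
    3'-terminal base for specific primers, None for group primers.
    """

    name: str
    sequence: str
    strand: str  # plus | minus
    template_span: tuple
    tm_celsius: float
    gc_fraction: float
    max_homopolymer: int
    hairpin_score: int
    self_dimer_score: int
    anchor_column: int | None = None

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def three_prime_position(self) -> int:
        """Template position (plus-strand coords) under the 3' base."""
        start, end = self.template_span
        return end - 1 if self.strand == "plus" else start


@dataclass(frozen=True)
class Oligo:
    """A bare named oligo (no template placement), e.g. from a panel table."""

    name: str
    sequence: str
    tm_celsius: float

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PrimerPair:
    forward: PrimerCandidate
    reverse: PrimerCandidate
    expected_length_bp: int
    tm_difference: float
    level: str = "species"  # species | genus | family

    def __post_init__(self):
        expected = self.reverse.template_span[1] - self.forward.template_span[0]
        if expected != self.expected_length_bp:
            raise ValueError("expected_length_bp inconsistent with primer spans")


@dataclass(frozen=True)
class AssayDefinition:
    """A named diagnostic assay: primer pair, targets, expected sizes.

    ``expected_sizes`` lists every size the assay may legitimately
    produce (group assays can span a range across member taxa);
    ``metadata`` carries wet-lab fields (primer concentration, annealing
    temperature, MgCl2, multiplex affiliation) that no computation here
    consumes.
    """

    name: str
    target: str
    level: str
    forward: PrimerCandidate
    reverse: PrimerCandidate
    expected_sizes: tuple
    metadata: dict = field(default_factory=dict)

    @property
    def expected_length_bp(self):
        return self.expected_sizes[0] if len(self.expected_sizes) == 1 else tuple(self.expected_sizes)


# ---------------------------------------------------------------------------
# Physicochemical screening


def gc_fraction(sequence: str) -> float:
    return sum(1 for c in sequence if c in "GCS") / len(sequence)


def max_homopolymer(sequence: str) -> int:
    best = run = 1
    for a, b in zip(sequence, sequence[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def self_dimer_score(sequence: str) -> int:
    """Max ungapped self-complementary run; 3'-anchored runs count double."""
    best = 0
    for run, a_end, b_end in duplex_runs(sequence, sequence):
        best = max(best, run * (2 if (a_end or b_end) else 1))
    return best


def hairpin_score(sequence: str, min_loop: int = 3) -> int:
    """Longest intramolecular stem (loop >= ``min_loop``); 3' stems x2."""
    s = sequence
    n = len(s)
    pairs = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}
    best = 0
    for i in range(n):
        for j in range(n - 1, i + min_loop, -1):
            length = 0
            while (
                i + length < j - length
                and (j - length) - (i + length) - 1 >= min_loop
                and (s[i + length], s[j - length]) in pairs
            ):
                length += 1
            if length:
                weight = 2 if j == n - 1 else 1
                best = max(best, length * weight)
    return best


@dataclass(frozen=True)
class ScreenResult:
    passed: bool
    reasons: tuple = ()


def physchem_screen(candidate: PrimerCandidate, constraints: DesignConstraints = DesignConstraints()) -> ScreenResult:
    """Check every physicochemical rule; failures list all violations."""
    c = constraints
    reasons = []
    n = len(candidate.sequence)
    if not c.min_len <= n <= c.max_len:
        reasons.append(f"length {n} outside [{c.min_len}, {c.max_len}]")
    if not c.min_gc <= candidate.gc_fraction <= c.max_gc:
        reasons.append(f"gc {candidate.gc_fraction:.2f} outside [{c.min_gc}, {c.max_gc}]")
    if candidate.max_homopolymer > c.max_homopolymer:
        reasons.append(f"homopolymer run {candidate.max_homopolymer} > {c.max_homopolymer}")
    if candidate.hairpin_score > c.hairpin_cap:
        reasons.append(f"hairpin score {candidate.hairpin_score} > {c.hairpin_cap}")
    if candidate.self_dimer_score > c.self_dimer_cap:
        reasons.append(f"self-dimer score {candidate.self_dimer_score} > {c.self_dimer_cap}")
    return ScreenResult(not reasons, tuple(reasons))


def make_candidate(
    name: str,
    sequence: str,
    strand: str,
    template_span: tuple,
    anchor_column: int | None = None,
    thermo: ThermoParams | None = None,
) -> PrimerCandidate:
    """Compute all derived scores for a concrete oligo."""
    if not iupac.is_concrete(sequence):
        raise ValueError(f"candidate {name}: ambiguity codes are disqualifying")
    return PrimerCandidate(
        name=name,
        sequence=sequence,
        strand=strand,
        template_span=tuple(template_span),
        tm_celsius=melting_temperature(sequence, thermo),
        gc_fraction=gc_fraction(sequence),
        max_homopolymer=max_homopolymer(sequence),
        hairpin_score=hairpin_score(sequence),
        self_dimer_score=self_dimer_score(sequence),
        anchor_column=anchor_column,
    )


# ---------------------------------------------------------------------------
# Enumeration


def enumerate_candidates(
    reference_sequence: str,
    sites=None,
    windows=None,
    msa=None,
    reference_id: str | None = None,
    constraints: DesignConstraints = DesignConstraints(),
    mode: str = "specific",
    thermo: ThermoParams | None = None,
    name_prefix: str = "cand",
) -> list[PrimerCandidate]:
    """Enumerate screened candidates in deterministic order.

    Specific mode: for every discriminative site (alignment columns mapped
    through ``msa``/``reference_id``) and every length in range, the
    window whose 3'-terminal base sits exactly on the site.  Group mode:
    every window position/length/strand wholly inside the conserved
    alignment windows.  Candidates containing ambiguity codes or failing
    the physicochemical screen are dropped.
    """
    if thermo is None:
        thermo = ThermoParams.default()
    seq = reference_sequence
    out: list[PrimerCandidate] = []
    specs: list[tuple] = []  # (template_pos3prime_or_start, length, strand, anchor_col)

    if mode == "specific":
        if sites is None or msa is None or reference_id is None:
            raise ValueError("specific mode needs sites, msa and reference_id")
        for site in sites:
            pos = msa.position_in(reference_id, site.column)
            if pos is None:
                continue
            for length in range(constraints.min_len, constraints.max_len + 1):
                if site.strand == "plus":
                    start, end = pos - length + 1, pos + 1
                else:
                    start, end = pos, pos + length
                if start < 0 or end > len(seq):
                    continue
                specs.append((pos, length, site.strand, site.column, start, end))
        specs.sort(key=lambda t: (t[0], t[1], t[2]))
    elif mode == "group":
        if windows is None:
            raise ValueError("group mode needs conserved windows")
        if msa is not None and reference_id is not None:
            mapped = []
            for wstart, wend in windows:
                ps = [msa.position_in(reference_id, c) for c in range(wstart, wend)]
                ps = [p for p in ps if p is not None]
                if ps:
                    mapped.append((min(ps), max(ps) + 1))
        else:
            mapped = list(windows)
        for wstart, wend in mapped:
            for start in range(wstart, wend):
                for length in range(constraints.min_len, constraints.max_len + 1):
                    end = start + length
                    if end > wend:
                        break
                    for strand in ("plus", "minus"):
                        pos3 = end - 1 if strand == "plus" else start
                        specs.append((pos3, length, strand, None, start, end))
        specs.sort(key=lambda t: (t[4], t[1], t[2]))
    else:
        raise ValueError(f"unknown mode {mode!r}")

    seen = set()
    for pos3, length, strand, anchor_col, start, end in specs:
        key = (start, end, strand)
        if key in seen:
            continue
        seen.add(key)
        window = seq[start:end]
        if not iupac.is_concrete(window):
            continue
        primer = window if strand == "plus" else iupac.reverse_complement(window)
        cand = make_candidate(
            f"{name_prefix}-{strand[0]}{pos3}-L{length}",
            primer,
            strand,
            (start, end),
            anchor_column=anchor_col,
            thermo=thermo,
        )
        if physchem_screen(cand, constraints).passed:
            out.append(cand)
    return out


def pair_candidates(
    forwards,
    reverses,
    constraints: DesignConstraints = DesignConstraints(),
    level: str = "species",
) -> list[PrimerPair]:
    """All valid convergent pairings, best first.

    Keeps pairs whose expected amplicon (both primers included) lies in
    the configured size range, whose primers do not overlap on the
    template, and whose Tm difference is within the cap.  Sorted by Tm
    difference, then amplicon length, then names.
    """
    pairs = []
    for f in forwards:
        if f.strand != "plus":
            continue
        for r in reverses:
            if r.strand != "minus":
                continue
            if r.template_span[0] < f.template_span[1]:
                continue
            length = r.template_span[1] - f.template_span[0]
            if not constraints.min_amplicon_bp <= length <= constraints.max_amplicon_bp:
                continue
            dtm = abs(f.tm_celsius - r.tm_celsius)
            if dtm > constraints.tm_difference_cap:
                continue
            pairs.append(PrimerPair(f, r, length, dtm, level))
    pairs.sort(key=lambda p: (p.tm_difference, p.expected_length_bp, p.forward.name, p.reverse.name))
    return pairs


def verify_specific_anchor(candidate: PrimerCandidate, msa, target_ids) -> bool:
    """Post-hoc ARMS check: every non-target differs at the 3' column."""
    if candidate.anchor_column is None:
        return False
    col = candidate.anchor_column
    targets = set(target_ids)
    plus_base = (
        candidate.sequence[-1]
        if candidate.strand == "plus"
        else iupac.COMPLEMENT[candidate.sequence[-1]]
    )
    for sid in msa.ids:
        ch = msa.row(sid)[col]
        if sid in targets:
            if ch != plus_base:
                return False
        else:
            if ch not in iupac.GAP_CHARS and plus_base in iupac.CODE_TO_BASES.get(ch, frozenset()):
                return False
    return True
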