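"""IUPAC nucleotide code arithmetic.

Every sequence in this package is a plain upper-case string over the 15
IUPAC DNA codes (plus gap characters where alignments are involved).  This
module centralises the code <-> base-set mapping, the minimal-cover merge
used for consensus building, complementation, and the "can this template
code represent that primer base" test used by the in-silico PCR scanner.
"""

from __future__ import annotations

#: IUPAC code -> frozenset of concrete bases it covers.
CODE_TO_BASES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

#: Base-set -> minimal covering IUPAC code (inverse of CODE_TO_BASES).
BASES_TO_CODE: dict[frozenset[str], str] = {v: k for k, v in CODE_TO_BASES.items()}

COMPLEMENT: dict[str, str] = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "D": "H", "H": "D", "V": "B", "N": "N",
    "-": "-",
}

GAP_CHARS = frozenset("-.")

CONCRETE = frozenset("ACGT")


class InvalidBaseError(ValueError):
    """A character outside the IUPAC DNA alphabet, with its position."""

    def __init__(self, char: str, position: int):
        self.char = char
        self.position = position
        super().__init__(f"invalid IUPAC DNA character {char!r} at position {position}")


def validate(sequence: str, allow_gaps: bool = False) -> None:
    """Raise :class:`InvalidBaseError` on the first non-IUPAC character."""
    allowed = set(CODE_TO_BASES)
    if allow_gaps:
        allowed |= GAP_CHARS
    for i, ch in enumerate(sequence):
        if ch not in allowed:
            raise InvalidBaseError(ch, i)


def normalize(sequence: str) -> str:
    """Upper-case and map U->T; validation is the caller's concern."""
    return sequence.upper().replace("U", "T")


def merge_codes(codes) -> str:
    """Minimal IUPAC code covering every base representable by ``codes``.

    This is the consensus merge rule: N appears only when all four bases
    were observed.
    """
    bases: set[str] = set()
    for c in codes:
        bases |= CODE_TO_BASES[c]
    return BASES_TO_CODE[frozenset(bases)]


def complement(sequence: str) -> str:
    try:
        return "".join(COMPLEMENT[c] for c in sequence)
    except KeyError as exc:  # report the offending position
        bad = str(exc.args[0])
        raise InvalidBaseError(bad, sequence.index(bad)) from None


def reverse_complement(sequence: str) -> str:
    """Reverse complement over the full IUPAC alphabet."""
    return complement(sequence)[::-1]


def is_concrete(sequence: str) -> bool:
    """True when the sequence contains only A/C/G/T."""
    return all(c in CONCRETE for c in sequence)


def can_represent(template_code: str, primer_base: str) -> bool:
    """Whether a template IUPAC code could stand for ``primer_base``.

    Used by the binding-site scanner when ambiguity overlap is allowed: an
    R in the template matches a primer A (the underlying chloroplast base
    may be A), while it never matches a primer C.
    """
    if template_code in GAP_CHARS or primer_base in GAP_CHARS:
        return False
    return primer_base in CODE_TO_BASES[template_code] or bool(
        CODE_TO_BASES[template_code] & CODE_TO_BASES[primer_base]
    )
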