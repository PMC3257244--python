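"""Copy-number calculus for assay sensitivity characterisation.

Detection limits of a diagnostic PCR are expressed in template copies per
reaction.  Converting a measured DNA concentration (ng/uL) of a purified
product into copies requires the product's molecular weight; dividing a
nanogram by the weight of one mole gives copies per nanogram.  Serial
dilution then spans a copy ladder, and the detection limit is read off the
lowest positive rung whose entire upper tail is positive.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import iupac

AVOGADRO = 6.02214076e23

#: Average double-stranded weight per base pair and per-molecule terminal
#: term (g/mol): MW(ds, L bp) = 617.96 * L + 36.04.  The per-base-pair
#: constant is the conventional average-composition value (the mean of the
#: A:T and G:C pair residue weights below is 617.90, within 0.01%); the
#: additive term is two water molecules (one per strand's free end).
AVG_BP_WEIGHT = 617.96
TERMINAL_WEIGHT = 36.04

#: Monophosphate residue weights (g/mol) within a DNA strand.
RESIDUE_WEIGHTS = {"A": 313.21, "C": 289.18, "G": 329.21, "T": 304.20}

WATER_WEIGHT = 18.02


@dataclass(frozen=True)
class AmpliconMass:
    """Molecular weight and derived copies-per-ng of one product."""

    length_bp: int
    molecular_weight_g_per_mol: float
    copies_per_ng: float
    concentration_ng_per_ul: float | None = None

    @property
    def copies_per_ul(self) -> float | None:
        if self.concentration_ng_per_ul is None:
            return None
        return self.concentration_ng_per_ul * self.copies_per_ng


@dataclass(frozen=True)
class DilutionSeries:
    start_copies: float
    factor: float
    copies_per_step: tuple

    @property
    def steps(self) -> int:
        return len(self.copies_per_step)


@dataclass(frozen=True)
class ReadoutRecord:
    """One dilution rung's readout: fluorescence signal and the call.

    A rung is positive when the signal exceeds the relative-fluorescence
    threshold (default 0.1 RFU) and the observed fragment size matched the
    assay's expectation (size matching is decided upstream; ``size_ok``
    carries the verdict).
    """

    assay: str
    copies: float
    signal_rfu: float
    size_ok: bool = True
    rfu_threshold: float = 0.1

    @property
    def positive(self) -> bool:
        return self.signal_rfu > self.rfu_threshold and self.size_ok


def ds_molecular_weight(length_bp: int | None = None, sequence: str | None = None) -> float:
    """Double-stranded molecular weight (g/mol).

    Length mode applies the average-composition formula
    ``617.96 * L + 36.04``; sequence mode sums residue weights over both
    strands and adds the same terminal water terms, so the two modes agree
    for average-composition fragments.
    """
    if (length_bp is None) == (sequence is None):
        raise ValueError("give exactly one of length_bp or sequence")
    if sequence is not None:
        seq = iupac.normalize(sequence)
        iupac.validate(seq)
        if not iupac.is_concrete(seq):
            raise ValueError("sequence mode needs a concrete sequence (no ambiguity codes)")
        top = sum(RESIDUE_WEIGHTS[c] for c in seq)
        bottom = sum(RESIDUE_WEIGHTS[iupac.COMPLEMENT[c]] for c in seq)
        return top + bottom + 2 * WATER_WEIGHT
    if length_bp < 1:
        raise ValueError("length_bp must be >= 1")
    return AVG_BP_WEIGHT * length_bp + TERMINAL_WEIGHT


def copies_per_ng(molecular_weight: float) -> float:
    """Template copies in one nanogram of product: N_A * 1e-9 / MW."""
    if molecular_weight <= 0:
        raise ValueError("molecular weight must be positive")
    return AVOGADRO * 1e-9 / molecular_weight


def amplicon_mass(length_bp: int | None = None, sequence: str | None = None, concentration_ng_per_ul: float | None = None) -> AmpliconMass:
    mw = ds_molecular_weight(length_bp, sequence)
    n = length_bp if length_bp is not None else len(sequence)
    return AmpliconMass(n, mw, copies_per_ng(mw), concentration_ng_per_ul)


def dilution_series(start_copies: float, factor: float, floor_copies: float) -> DilutionSeries:
    """Divide by ``factor`` until the next step would fall below the floor."""
    if factor <= 1:
        raise ValueError("dilution factor must be > 1")
    if not start_copies >= floor_copies > 0:
        raise ValueError("need start_copies >= floor_copies > 0")
    steps = [start_copies]
    while steps[-1] / factor >= floor_copies:
        steps.append(steps[-1] / factor)
    return DilutionSeries(start_copies, factor, tuple(steps))


def detection_limit(readouts) -> float | None:
    """Smallest copy number positive with all larger copy numbers positive.

    The monotone-envelope rule: an isolated positive below a negative rung
    does not count (stochastic detection at the limit).  Returns None when
    no rung qualifies.  Conflicting duplicate copy levels are an error.
    """
    by_copies: dict[float, bool] = {}
    for r in readouts:
        pos = r.positive if hasattr(r, "positive") else bool(r[1])
        copies = r.copies if hasattr(r, "copies") else r[0]
        if copies in by_copies and by_copies[copies] != pos:
            raise ValueError(f"conflicting calls at {copies} copies")
        by_copies[copies] = pos
    limit = None
    for copies in sorted(by_copies, reverse=True):
        if by_copies[copies]:
            limit = copies
        else:
            break
    return limit
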