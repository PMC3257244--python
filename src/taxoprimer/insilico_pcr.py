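"""In-silico PCR: binding-site search, amplicon prediction, assay evaluation.

The binding model is deliberately simple and fully documented: a primer
binds wherever an ungapped comparison shows at most ``max_total_mismatches``
mismatches and a perfect match over the protected 3'-terminal window (the
extension-blocking positions of ARMS discrimination).  Convergent
plus/minus site pairs within a length cap yield amplicons; single-primer
(same-orientation) artifacts are ignored, matching how diagnostic gels
are read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from . import iupac

_CODES = "ACGTRYSWKMBDHVN"
_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _c in enumerate(_CODES):
    _LUT[ord(_c)] = _i

_MATCH_OVERLAP = np.zeros((len(_CODES), len(_CODES)), dtype=bool)
_MATCH_EXACT = np.eye(len(_CODES), dtype=bool)
for _i, _a in enumerate(_CODES):
    for _j, _b in enumerate(_CODES):
        _MATCH_OVERLAP[_i, _j] = bool(iupac.CODE_TO_BASES[_a] & iupac.CODE_TO_BASES[_b])


def _encode(seq: str) -> np.ndarray:
    arr = _LUT[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if (arr == 255).any():
        bad = int(np.argmax(arr == 255))
        raise iupac.InvalidBaseError(seq[bad], bad)
    return arr


@dataclass(frozen=True)
class MismatchPolicy:
    """Binding tolerance used for cross-amplification screening.

    ``protected_3prime_nt`` positions at the 3' end admit zero mismatches;
    elsewhere up to ``max_total_mismatches`` are allowed.  With
    ``allow_ambiguity_overlap`` a template ambiguity code counts as a
    match when it can represent the primer base.
    """

    max_total_mismatches: int = 2
    protected_3prime_nt: int = 2
    allow_ambiguity_overlap: bool = True

    def relaxed_from(self, other: "MismatchPolicy") -> bool:
        return (
            self.max_total_mismatches >= other.max_total_mismatches
            and self.protected_3prime_nt <= other.protected_3prime_nt
        )


@dataclass(frozen=True)
class BindingSite:
    """One primer placement; ``span`` is plus-strand 0-based half-open.

    ``mismatch_positions`` are primer coordinates counted from the 3'
    terminus (3'-most base = 0).
    """

    template_id: str
    strand: str  # plus | minus
    span: tuple
    mismatch_positions: tuple
    n_mismatches: int


@dataclass(frozen=True)
class Amplicon:
    """Predicted product spanning both primers."""

    template_id: str
    forward_site: BindingSite
    reverse_site: BindingSite
    length_bp: int
    sequence: str


def _primer_seq(primer) -> str:
    seq = primer if isinstance(primer, str) else primer.sequence
    seq = iupac.normalize(seq)
    if not iupac.is_concrete(seq):
        raise ValueError("primer must be a concrete sequence")
    return seq


def find_binding_sites(primer, template, policy: MismatchPolicy = MismatchPolicy(), template_id: str | None = None) -> list[BindingSite]:
    """All policy-satisfying placements of the primer on both strands.

    A primer longer than the template simply has no sites.  Sites are
    sorted by span start, plus strand before minus at equal position.
    """
    pseq = _primer_seq(primer)
    tseq = iupac.normalize(template if isinstance(template, str) else template.sequence)
    tid = template_id or (getattr(template, "record_id", None) or getattr(template, "taxon", "template"))
    m, n = len(pseq), len(tseq)
    sites: list[BindingSite] = []
    if m > n:
        return sites
    table = _MATCH_OVERLAP if policy.allow_ambiguity_overlap else _MATCH_EXACT
    tarr = _encode(tseq)
    windows = np.lib.stride_tricks.sliding_window_view(tarr, m)
    for strand, probe in (("plus", pseq), ("minus", iupac.reverse_complement(pseq))):
        parr = _encode(probe)
        match = table[windows, parr[None, :]]
        mm_counts = m - match.sum(axis=1)
        for i in np.flatnonzero(mm_counts <= policy.max_total_mismatches):
            js = np.flatnonzero(~match[i])
            if strand == "plus":
                # primer reads 5'->3' along the plus strand; 3' base at i+m-1
                positions = tuple(sorted(int(m - 1 - j) for j in js))
            else:
                # reverse complement along the plus strand; 3' base faces i
                positions = tuple(int(j) for j in js)
            if positions and positions[0] < policy.protected_3prime_nt:
                continue
            sites.append(BindingSite(tid, strand, (int(i), int(i) + m), positions, len(positions)))
    sites.sort(key=lambda s: (s.span[0], 0 if s.strand == "plus" else 1))
    return sites


def predict_amplicons(pair, template, policy: MismatchPolicy = MismatchPolicy(), max_len: int = 1000, template_id: str | None = None) -> list[Amplicon]:
    """Products from every convergent forward/reverse site combination.

    Either oligo of the pair may act in either orientation; only
    opposite-orientation convergent combinations within ``max_len`` count.
    The amplicon sequence is the plus-strand template slice spanning both
    primers.
    """
    fseq = _primer_seq(pair.forward)
    rseq = _primer_seq(pair.reverse)
    if max_len < len(fseq) + len(rseq):
        raise ValueError("max_len shorter than the two primers combined")
    tseq = iupac.normalize(template if isinstance(template, str) else template.sequence)
    tid = template_id or (getattr(template, "record_id", None) or getattr(template, "taxon", "template"))

    f_sites = find_binding_sites(fseq, tseq, policy, template_id=tid)
    r_sites = find_binding_sites(rseq, tseq, policy, template_id=tid)

    combos = [(f_sites, r_sites)]
    if rseq != fseq:
        combos.append((r_sites, f_sites))
    seen = set()
    out: list[Amplicon] = []
    for lefts, rights in combos:
        for fs in lefts:
            if fs.strand != "plus":
                continue
            for rs in rights:
                if rs.strand != "minus":
                    continue
                if rs.span[0] < fs.span[1]:
                    continue
                length = rs.span[1] - fs.span[0]
                if length > max_len:
                    continue
                key = (fs.span, rs.span)
                if key in seen:
                    continue
                seen.add(key)
                out.append(Amplicon(tid, fs, rs, length, tseq[fs.span[0] : rs.span[1]]))
    out.sort(key=lambda a: (a.forward_site.span[0], a.length_bp))
    return out


# ---------------------------------------------------------------------------
# Assay evaluation


@dataclass(frozen=True)
class AssayEvaluation:
    """Specificity matrix plus summary flags for one assay."""

    assay_name: str
    table: pd.DataFrame = field(repr=False)
    sensitivity: float
    violations: tuple

    @property
    def n_violations(self) -> int:
        return len(self.violations)


def _target_species(assay, taxonomy) -> set[str]:
    level = getattr(assay, "level", "species")
    target = getattr(assay, "target")
    species = set()
    for ref in taxonomy.values():
        if (
            (level == "species" and ref.species == target)
            or (level == "genus" and ref.genus == target)
            or (level == "family" and ref.family == target)
        ):
            species.add(ref.species)
    if not species and level == "species":
        species = {target}
    return species


def evaluate_assay(
    assay,
    db: Iterable,
    taxonomy: dict,
    policy: MismatchPolicy = MismatchPolicy(),
    size_tolerance_bp: int = 4,
    max_len: int = 1000,
) -> AssayEvaluation:
    """Cross-amplification screen of one assay against a whole database.

    Per species: did any record amplify, and is any product within
    ``size_tolerance_bp`` of an expected size (making a non-target product
    confusable on a sizing trace)?  Sensitivity is the fraction of target
    species producing an expected-size product.
    """
    expected = getattr(assay, "expected_sizes", None)
    if expected is None:
        size = assay.expected_length_bp
        expected = tuple(size) if isinstance(size, (list, tuple)) else (size,)
    lo, hi = min(expected), max(expected)
    targets = _target_species(assay, taxonomy)

    by_species: dict[str, list] = {}
    for rec in db:
        ref = taxonomy.get(getattr(rec, "record_id", None)) or taxonomy.get(rec.taxon)
        species = ref.species if ref is not None else rec.taxon
        by_species.setdefault(species, []).append(rec)

    rows = []
    violations = []
    for species in sorted(by_species):
        lengths: set[int] = set()
        for rec in by_species[species]:
            for amp in predict_amplicons(assay, rec, policy, max_len):
                lengths.add(amp.length_bp)
        is_target = species in targets
        expected_hit = any(lo - size_tolerance_bp <= L <= hi + size_tolerance_bp for L in lengths)
        confusable = expected_hit and not is_target
        if confusable:
            for L in sorted(lengths):
                if lo - size_tolerance_bp <= L <= hi + size_tolerance_bp:
                    violations.append((species, L))
        rows.append(
            {
                "species": species,
                "is_target": is_target,
                "amplified": bool(lengths),
                "product_lengths": tuple(sorted(lengths)),
                "expected_size_hit": expected_hit,
                "confusable": confusable,
            }
        )
    table = pd.DataFrame(rows).set_index("species")
    n_targets = sum(1 for r in rows if r["is_target"])
    sensitivity = (
        sum(1 for r in rows if r["is_target"] and r["expected_size_hit"]) / n_targets
        if n_targets
        else float("nan")
    )
    return AssayEvaluation(
        assay_name=getattr(assay, "name", "assay"),
        table=table,
        sensitivity=sensitivity,
        violations=tuple(violations),
    )


def amplicons_to_tsv(amplicons: Iterable[Amplicon], assay_name: str = "assay") -> pd.DataFrame:
    rows = [
        {
            "assay": assay_name,
            "template": a.template_id,
            "length": a.length_bp,
            "start": a.forward_site.span[0],
            "end": a.reverse_site.span[1],
            "strand_info": f"F:{a.forward_site.strand}/R:{a.reverse_site.strand}",
        }
        for a in amplicons
    ]
    return pd.DataFrame(rows)


def binding_sites_to_bed(sites: Iterable[BindingSite], name: str = "site") -> str:
    lines = [
        f"{s.template_id}\t{s.span[0]}\t{s.span[1]}\t{name}\t{s.n_mismatches}\t{'+' if s.strand == 'plus' else '-'}"
        for s in sites
    ]
    return "\n".join(lines) + ("\n" if lines else "")
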