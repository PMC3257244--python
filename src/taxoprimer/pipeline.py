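"""End-to-end assay design: database -> alignment -> candidates -> screen.

Mirrors the three-step development of diagnostic plant assays: build
per-species consensus sequences, find design positions on within-group
alignments (discriminative 3' anchors for species/genus targets,
fully-conserved windows for family targets), enumerate and pair ARMS
candidates, and keep only pairs that in-silico PCR confirms amplify every
target taxon at the expected size with no confusable non-target product.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .align import align_sequences
from .insilico_pcr import AssayEvaluation, MismatchPolicy, evaluate_assay, predict_amplicons
from .markerdb import ConsensusRecord, TaxonRef, build_species_consensus
from .multiplex import PanelParams, build_panels
from .primerdesign import (
    AssayDefinition,
    DesignConstraints,
    PrimerPair,
    enumerate_candidates,
    pair_candidates,
)
from .sitefinder import conserved_windows, discriminative_anchors, repeat_screen
from .thermo import ThermoParams

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DesignedAssay:
    assay: AssayDefinition
    evaluation: AssayEvaluation
    n_nontarget_amplified: int


@dataclass(frozen=True)
class DesignResult:
    target: str
    level: str
    assays: tuple  # DesignedAssay, best first

    @property
    def best(self):
        return self.assays[0] if self.assays else None


def consensus_by_species(records, taxonomy: dict[str, TaxonRef]) -> dict[str, ConsensusRecord]:
    by_species: dict[str, list] = {}
    for rec in records:
        ref = taxonomy.get(getattr(rec, "record_id", None))
        species = ref.species if ref else rec.taxon
        by_species.setdefault(species, []).append(rec)
    out = {}
    for species, recs in sorted(by_species.items()):
        # records are keyed to the species; rebadge before merging
        out[species] = build_species_consensus(
            [type(r)(r.record_id, species, r.sequence, r.source) if r.taxon != species else r for r in recs]
        )
    return out


def species_taxonomy(taxonomy: dict[str, TaxonRef]) -> dict[str, TaxonRef]:
    """Collapse a record-level taxonomy to one entry per species."""
    return {ref.species: ref for ref in taxonomy.values()}


def _group_members(target: str, level: str, sp_tax: dict[str, TaxonRef]) -> list[str]:
    if level == "species":
        members = [s for s in sp_tax if s == target]
    elif level == "genus":
        members = [s for s, t in sp_tax.items() if t.genus == target]
    elif level == "family":
        members = [s for s, t in sp_tax.items() if t.family == target]
    else:
        raise ValueError(f"unknown level {level!r}")
    if not members:
        raise ValueError(f"no species for {level} target {target!r}")
    return sorted(members)


def design_assays(
    records,
    taxonomy: dict[str, TaxonRef],
    target: str,
    level: str = "species",
    constraints: DesignConstraints = DesignConstraints(),
    policy: MismatchPolicy = MismatchPolicy(),
    thermo: ThermoParams | None = None,
    size_tolerance_bp: int = 4,
    preferred_size: int | None = None,
    max_pairs_screened: int = 40,
    max_assays: int = 3,
    max_candidates_per_strand: int = 400,
) -> DesignResult:
    """Design validated assays for one target taxon.

    Species and genus targets use discriminative 3' anchors against the
    other members of their family (ARMS logic); family targets use
    windows fully conserved across the family, with outgroup specificity
    established purely by the in-silico PCR screen.  ``preferred_size``
    ranks surviving pairs toward a requested amplicon length, the knob
    used to compose size-multiplexed ladders.
    """
    if thermo is None:
        thermo = ThermoParams.default()
    sp_tax = species_taxonomy(taxonomy)
    consensi = consensus_by_species(records, taxonomy)
    members = _group_members(target, level, sp_tax)
    family = sp_tax[members[0]].family
    family_species = sorted(s for s, t in sp_tax.items() if t.family == family)

    if level in ("species", "genus"):
        scope = family_species
        msa = align_sequences({s: consensi[s].sequence for s in scope}, center=members[0])
        sites = discriminative_anchors(msa, members)
        sites = repeat_screen(sites, msa, members)
        ref = members[0]
        candidates = enumerate_candidates(
            consensi[ref].sequence,
            sites=sites,
            msa=msa,
            reference_id=ref,
            constraints=constraints,
            mode="specific",
            thermo=thermo,
            name_prefix=target,
        )
    else:
        scope = members
        msa = align_sequences({s: consensi[s].sequence for s in scope}, center=members[0])
        windows = conserved_windows(msa, min_len=constraints.min_len, min_conservation=1.0, max_gap_fraction=0.0)
        windows.sort(key=lambda w: (w[0] - w[1], w[0]))  # longest first
        ref = members[0]
        # Fill the candidate budget window by window, longest first: long
        # fully-conserved windows are where group primers live.
        candidates = []
        for window in windows[:8]:
            if len(candidates) >= 2 * max_candidates_per_strand:
                break
            candidates.extend(
                enumerate_candidates(
                    consensi[ref].sequence,
                    windows=[window],
                    msa=msa,
                    reference_id=ref,
                    constraints=constraints,
                    mode="group",
                    thermo=thermo,
                    name_prefix=target,
                )
            )

    forwards = _subsample([c for c in candidates if c.strand == "plus"], max_candidates_per_strand)
    reverses = _subsample([c for c in candidates if c.strand == "minus"], max_candidates_per_strand)
    pairs = pair_candidates(forwards, reverses, constraints, level)
    if preferred_size is not None:
        pairs.sort(key=lambda p: (abs(p.expected_length_bp - preferred_size), p.tm_difference))
    logger.info("%s (%s): %d sites/windows-derived candidates, %d pairs", target, level, len(candidates), len(pairs))

    db = [c.as_record() for c in consensi.values()]
    accepted: list[DesignedAssay] = []
    for pair in pairs[:max_pairs_screened]:
        expected = _expected_sizes(pair, consensi, members, policy)
        if expected is None:
            continue
        assay = AssayDefinition(
            name=f"{target}_{min(expected)}",
            target=target,
            level=level,
            forward=pair.forward,
            reverse=pair.reverse,
            expected_sizes=expected,
        )
        ev = evaluate_assay(assay, db, sp_tax, policy, size_tolerance_bp)
        if ev.sensitivity == 1.0 and not ev.violations:
            n_off = int(
                ev.table[~ev.table.index.isin(members)]["amplified"].sum()
            )
            accepted.append(DesignedAssay(assay, ev, n_off))
            if len(accepted) >= max_assays:
                break
    accepted.sort(
        key=lambda d: (
            d.n_nontarget_amplified,
            abs(min(d.assay.expected_sizes) - preferred_size) if preferred_size else 0,
        )
    )
    return DesignResult(target, level, tuple(accepted))


def _subsample(items: list, cap: int) -> list:
    """Deterministic even subsample preserving positional coverage."""
    if len(items) <= cap:
        return items
    step = len(items) / cap
    return [items[int(k * step)] for k in range(cap)]


def _expected_sizes(pair: PrimerPair, consensi, members, policy) -> tuple | None:
    """Per-member product sizes; None when any member fails to amplify."""
    sizes = set()
    for sp in members:
        amps = predict_amplicons(pair, consensi[sp].as_record(), policy, max_len=1000)
        if not amps:
            return None
        sizes.update(a.length_bp for a in amps)
    return tuple(sorted(sizes))


def design_and_panel(records, taxonomy, targets, panel_params: PanelParams = PanelParams(), **kwargs):
    """Design one best assay per (target, level, preferred_size) and panel them."""
    assays = []
    results = []
    for spec in targets:
        target, level = spec[0], spec[1]
        preferred = spec[2] if len(spec) > 2 else None
        res = design_assays(records, taxonomy, target, level, preferred_size=preferred, **kwargs)
        results.append(res)
        if res.best is not None:
            assays.append(res.best.assay)
    panels = build_panels(assays, panel_params) if assays else []
    return results, panels
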