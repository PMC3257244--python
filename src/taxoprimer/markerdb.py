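"""Marker-region sequence database: loading, consensus building, annotation.

The marker this package was built around is the chloroplast trnT-F region:
two short conserved exons of the trnL (UAA) gene (trnL-E1, trnL-E2)
embedded in three variable non-coding segments — the trnT/trnL-E1
intergenic spacer (IS1), the trnL intron between the exons, and the
trnL-E2/trnF spacer (IS2).  Records for a species are frequently partial
(a single sequencing read covers only part of the region), so the module
merges all available records for a species into an IUPAC consensus and
annotates segment boundaries by locating the conserved exon anchors.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import Align, SeqIO

from . import iupac

#: Canonical segment order across the marker, 5' -> 3'.
SEGMENT_ORDER = ("IS1", "trnL-E1", "trnL-intron", "trnL-E2", "IS2")

# Packaged default exon anchor motifs.  These are synthetic stand-ins with
# the length and conserved character of the real trnL exons (the bundled
# mock-database generator emits exactly these sequences); override them
# with the true exon sequences of whatever marker you are annotating.
TRNL_E1_ANCHOR = "ATGGGCAATCCTGAGCCAAATCTTGTTTCGAAAACA"
TRNL_E2_ANCHOR = "GGACTCGAACCGATGACCTTCTGCGTTATCAGGCGAACGCTCTAACCA"

DEFAULT_ANCHORS = (TRNL_E1_ANCHOR, TRNL_E2_ANCHOR)


class DuplicateRecordError(ValueError):
    pass


class AnchorAmbiguityError(ValueError):
    """An anchor motif has two equally good best matches."""

    def __init__(self, anchor: str, positions: Sequence[int]):
        self.positions = tuple(positions)
        super().__init__(
            f"anchor {anchor[:12]}... matches equally well at positions {list(positions)}"
        )


class ConsensusAnchorError(ValueError):
    """Records that cannot be anchored to the species reference."""

    def __init__(self, outliers: Sequence[str], floor: float):
        self.outliers = tuple(outliers)
        super().__init__(
            f"records failed to anchor (pairwise identity < {floor}): {list(outliers)}"
        )


@dataclass(frozen=True)
class SequenceRecord:
    """One marker-region sequence for one taxon."""

    record_id: str
    taxon: str
    sequence: str
    source: str = "database"  # database | generated | consensus

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"record {self.record_id}: empty sequence")
        iupac.validate(self.sequence)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class TaxonRef:
    """species -> genus -> family placement plus habitat flags."""

    species: str
    genus: str
    family: str
    habitat_flags: frozenset = frozenset()


@dataclass(frozen=True)
class MarkerAnnotation:
    """Segment coordinates (0-based half-open) with per-segment presence.

    ``segments`` maps each canonical segment name to a (start, end) span or
    ``None`` when the segment could not be located (missing anchor or
    zero-length flank); annotation never silently truncates.
    """

    segments: dict

    def __post_init__(self):
        prev_end = None
        for name in SEGMENT_ORDER:
            span = self.segments.get(name)
            if span is None:
                continue
            start, end = span
            if not start < end:
                raise ValueError(f"segment {name}: start {start} >= end {end}")
            if prev_end is not None and start < prev_end:
                raise ValueError(f"segment {name} overlaps its predecessor")
            prev_end = end

    def present(self, name: str) -> bool:
        return self.segments.get(name) is not None

    def span(self, name: str):
        return self.segments.get(name)

    def length(self, name: str):
        span = self.segments.get(name)
        return None if span is None else span[1] - span[0]


@dataclass(frozen=True)
class ConsensusRecord:
    """Per-species IUPAC consensus over all available records."""

    taxon: str
    sequence: str
    n_records: int
    conflict_positions: tuple = ()

    def __len__(self) -> int:
        return len(self.sequence)

    def as_record(self, record_id: str | None = None) -> SequenceRecord:
        return SequenceRecord(
            record_id=record_id or f"consensus|{self.taxon}",
            taxon=self.taxon,
            sequence=self.sequence,
            source="consensus",
        )


# ---------------------------------------------------------------------------
# Loading


def load_records(path, format: str = "fasta", taxon_map: dict | None = None) -> list[SequenceRecord]:
    """Read a multi-FASTA or GenBank flat file into SequenceRecords.

    Sequences are upper-cased with U->T normalisation; record order is
    preserved.  ``taxon_map`` (record_id -> species) overrides the taxon
    guessed from the record itself (GenBank organism, else the id).
    """
    if format not in ("fasta", "genbank"):
        raise ValueError(f"unsupported format {format!r}")
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), format):
        if entry.id in seen:
            raise DuplicateRecordError(f"duplicate record id {entry.id!r}")
        seen.add(entry.id)
        seq = iupac.normalize(str(entry.seq))
        iupac.validate(seq)  # raises with position
        if taxon_map and entry.id in taxon_map:
            taxon = taxon_map[entry.id]
        elif format == "genbank":
            taxon = entry.annotations.get("organism", entry.id)
        else:
            taxon = entry.id
        records.append(SequenceRecord(entry.id, taxon, seq))
    return records


def write_fasta(records: Iterable, path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            rid = rec.record_id if hasattr(rec, "record_id") else f"consensus|{rec.taxon}"
            fh.write(f">{rid}\n")
            seq = rec.sequence
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def load_taxonomy(path) -> dict[str, TaxonRef]:
    """Taxonomy TSV with header ``record_id species genus family habitat``."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = ["record_id", "species", "genus", "family"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"taxonomy table missing columns: {missing}")
    out: dict[str, TaxonRef] = {}
    species_family: dict[str, tuple[str, str]] = {}
    for row in df.itertuples(index=False):
        flags = frozenset(f for f in str(getattr(row, "habitat", "")).split(",") if f)
        ref = TaxonRef(row.species, row.genus, row.family, flags)
        prev = species_family.get(ref.species)
        if prev is not None and prev != (ref.genus, ref.family):
            raise ValueError(f"species {ref.species!r} mapped to two placements")
        species_family[ref.species] = (ref.genus, ref.family)
        out[row.record_id] = ref
    return out


def write_taxonomy(taxonomy: dict[str, TaxonRef], path) -> None:
    rows = [
        {
            "record_id": rid,
            "species": t.species,
            "genus": t.genus,
            "family": t.family,
            "habitat": ",".join(sorted(t.habitat_flags)),
        }
        for rid, t in taxonomy.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Consensus


def _pairwise_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -4
    aligner.extend_gap_score = -1
    # Free end gaps: records are partial reads of one template, so
    # overhangs carry no penalty.
    aligner.open_end_insertion_score = 0
    aligner.extend_end_insertion_score = 0
    aligner.open_end_deletion_score = 0
    aligner.extend_end_deletion_score = 0
    return aligner


def build_species_consensus(records: Sequence, identity_floor: float = 0.70) -> ConsensusRecord:
    """Merge all records of one species into an IUPAC consensus.

    The longest record (ties broken by record id) is the anchoring
    reference; every other record is aligned to it with affine gaps and
    free end gaps.  Overlapping columns merge to the minimal covering
    IUPAC code — disagreements are recorded, never majority-voted away —
    and non-overlapping flanks are concatenated.  A record whose aligned
    identity to the reference falls below ``identity_floor`` cannot be
    anchored and is reported as an outlier.
    """
    records = list(records)
    if not records:
        raise ValueError("no records")
    taxa = {getattr(r, "taxon") for r in records}
    if len(taxa) != 1:
        raise ValueError(f"records span multiple species: {sorted(taxa)}")
    taxon = taxa.pop()
    if len(records) == 1:
        rec = records[0]
        conflicts = getattr(rec, "conflict_positions", ())
        return ConsensusRecord(taxon, rec.sequence, getattr(rec, "n_records", 1), tuple(conflicts))

    ordered = sorted(records, key=lambda r: (-len(r.sequence), _rid(r)))
    ref = ordered[0]
    aligner = _pairwise_aligner()

    # Frame: reference coordinates, extendable on both flanks.  Insertions
    # internal to the reference span cannot be placed on the frame and are
    # dropped (rare within a species; documented behaviour).
    observations: dict[int, list[str]] = {i: [ref.sequence[i]] for i in range(len(ref.sequence))}
    outliers: list[str] = []
    for rec in ordered[1:]:
        aln = aligner.align(ref.sequence, rec.sequence)[0]
        ref_aln, rec_aln = str(aln[0]), str(aln[1])
        matches = compared = 0
        pairs: list[tuple[int, str]] = []  # (frame position, observed code)
        left_over: list[str] = []
        right_over: list[str] = []
        rpos = -1
        for a, b in zip(ref_aln, rec_aln):
            if a != "-":
                rpos += 1
                if b != "-":
                    compared += 1
                    if a == b:
                        matches += 1
                    pairs.append((rpos, b))
            elif b != "-":
                if rpos < 0:
                    left_over.append(b)
                elif rpos == len(ref.sequence) - 1:
                    right_over.append(b)
        if compared == 0 or matches / compared < identity_floor:
            outliers.append(_rid(rec))
            continue
        for k, code in enumerate(left_over):
            pairs.append((k - len(left_over), code))  # negative frame coords
        for k, code in enumerate(right_over):
            pairs.append((len(ref.sequence) + k, code))
        for pos, code in pairs:
            observations.setdefault(pos, []).append(code)
    if outliers:
        raise ConsensusAnchorError(sorted(outliers), identity_floor)

    positions = sorted(observations)
    consensus_chars: list[str] = []
    conflicts: list[int] = []
    for out_idx, pos in enumerate(positions):
        codes = observations[pos]
        merged = iupac.merge_codes(codes)
        consensus_chars.append(merged)
        if len(set(codes)) > 1:
            conflicts.append(out_idx)
    return ConsensusRecord(taxon, "".join(consensus_chars), len(records), tuple(conflicts))


def _rid(rec) -> str:
    return getattr(rec, "record_id", getattr(rec, "taxon", ""))


# ---------------------------------------------------------------------------
# Annotation


def _best_ungapped_match(sequence: str, motif: str, max_mismatch: int):
    """(position, mismatches) of the best ungapped motif placement, or None.

    A template ambiguity code that can represent the motif base counts as a
    match.  Two equally scoring best placements raise
    :class:`AnchorAmbiguityError`.
    """
    n, m = len(sequence), len(motif)
    if m > n:
        return None
    best: list[int] = []
    best_mm = max_mismatch + 1
    for i in range(n - m + 1):
        mm = 0
        for j in range(m):
            if not iupac.can_represent(sequence[i + j], motif[j]):
                mm += 1
                if mm > best_mm:
                    break
        if mm < best_mm:
            best_mm = mm
            best = [i]
        elif mm == best_mm:
            best.append(i)
    if best_mm > max_mismatch:
        return None
    if len(best) > 1:
        raise AnchorAmbiguityError(motif, best)
    return best[0], best_mm


def annotate_marker_regions(
    record,
    anchors: tuple[str, str] = DEFAULT_ANCHORS,
    mismatch_budget: float = 0.10,
) -> MarkerAnnotation:
    """Locate the two exon anchors and derive segment coordinates.

    Each anchor is placed at its best ungapped match with at most
    ``mismatch_budget`` * len(anchor) mismatches (rounded down).  A missing
    anchor flags every segment that depends on it as absent.
    """
    seq = record.sequence
    e1_motif, e2_motif = (iupac.normalize(a) for a in anchors)
    e1 = _best_ungapped_match(seq, e1_motif, int(mismatch_budget * len(e1_motif)))
    e2 = _best_ungapped_match(seq, e2_motif, int(mismatch_budget * len(e2_motif)))

    segments: dict = {name: None for name in SEGMENT_ORDER}
    if e1 is not None:
        e1s, e1e = e1[0], e1[0] + len(e1_motif)
        segments["trnL-E1"] = (e1s, e1e)
        if e1s > 0:
            segments["IS1"] = (0, e1s)
    if e2 is not None:
        e2s, e2e = e2[0], e2[0] + len(e2_motif)
        segments["trnL-E2"] = (e2s, e2e)
        if e2e < len(seq):
            segments["IS2"] = (e2e, len(seq))
    if e1 is not None and e2 is not None:
        e1e = segments["trnL-E1"][1]
        e2s = segments["trnL-E2"][0]
        if e2s < e1e:
            raise ValueError("exon anchors found in inverted order")
        if e2s > e1e:
            segments["trnL-intron"] = (e1e, e2s)
    return MarkerAnnotation(segments)


# ---------------------------------------------------------------------------
# Coverage


def coverage_report(annotated_db: Sequence[tuple], taxonomy: dict[str, TaxonRef] | None = None) -> pd.DataFrame:
    """Per-segment coverage across species.

    ``annotated_db`` is a sequence of (record, MarkerAnnotation) pairs;
    records of one species are pooled (a segment counts as covered for the
    species when any of its records carries it).  Returns a DataFrame with
    coverage percentage and min/max observed segment length per segment.
    """
    per_species: dict[str, dict[str, list[int]]] = {}
    for rec, ann in annotated_db:
        if taxonomy is not None and _rid(rec) in taxonomy:
            species = taxonomy[_rid(rec)].species
        else:
            species = rec.taxon
        seg_map = per_species.setdefault(species, {})
        for name in SEGMENT_ORDER:
            if ann.present(name):
                seg_map.setdefault(name, []).append(ann.length(name))
    n_species = len(per_species)
    rows = []
    for name in SEGMENT_ORDER:
        lengths = [
            max(v[name]) for v in per_species.values() if name in v
        ]  # per-species representative length: longest observation
        covered = sum(1 for v in per_species.values() if name in v)
        rows.append(
            {
                "segment": name,
                "n_species": covered,
                "coverage_pct": 100.0 * covered / n_species if n_species else 0.0,
                "min_len": min(lengths) if lengths else None,
                "max_len": max(lengths) if lengths else None,
            }
        )
    return pd.DataFrame(rows).set_index("segment")


def annotation_to_bed(record, annotation: MarkerAnnotation, path=None) -> str:
    """BED (0-based half-open) lines for the present segments."""
    lines = []
    for name in SEGMENT_ORDER:
        span = annotation.span(name)
        if span is not None:
            lines.append(f"{_rid(record)}\t{span[0]}\t{span[1]}\t{name}")
    text = "\n".join(lines) + ("\n" if lines else "")
    if path is not None:
        Path(path).write_text(text)
    return text
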