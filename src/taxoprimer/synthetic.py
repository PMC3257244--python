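"""Seeded mock marker databases with trnT-F-like architecture.

The generator emulates the structure primer design depends on — two
conserved exon anchors separated and flanked by three variable non-coding
segments (IS1, intron, IS2) with realistic length ranges — via a
hierarchical simulation: one global ancestor, per-family ancestors with
redrawn segment lengths, then genus- and species-level substitution and
indel divergence, and finally per-record within-species noise (including
truncated partial records, as real databases have them).

Designated targets receive planted signatures: a target-exclusive
insertion ``F-motif + filler + revcomp(R-motif)`` of exactly the requested
amplicon length, identical in every member of the target group and absent
everywhere else — the ground truth against which the whole design
pipeline is validated.  It is a test harness, not an evolution simulator:
no substitution-model or coalescent realism is attempted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import iupac
from .markerdb import SEGMENT_ORDER, TRNL_E1_ANCHOR, TRNL_E2_ANCHOR, SequenceRecord, TaxonRef

NONCODING = ("IS1", "trnL-intron", "IS2")

#: Segment length ranges (bp) for family ancestors.
DEFAULT_SEGMENT_LENGTHS = {
    "IS1": (541, 991),
    "trnL-intron": (241, 588),
    "IS2": (75, 692),
}

MOTIF_LEN = 25


@dataclass(frozen=True)
class PlantedSignature:
    """One designed-in diagnostic: a unique insertion in a target group.

    ``amplicon_bp`` is the exact length of the planted block (forward
    motif, filler, reverse-complemented reverse motif), hence of the
    amplicon a primer pair anchored on the motif ends produces.
    """

    target: str
    level: str  # species | genus | family
    amplicon_bp: int
    segment: str = "trnL-intron"

    def __post_init__(self):
        if self.amplicon_bp < 2 * MOTIF_LEN + 5:
            raise ValueError(f"amplicon_bp {self.amplicon_bp} too short for two {MOTIF_LEN}-nt motifs")
        if self.segment not in NONCODING:
            raise ValueError(f"signatures go in non-coding segments, not {self.segment}")


@dataclass(frozen=True)
class MockDbSpec:
    """Study conditions for the mock database.

    Defaults: 30 species in 8 genera and 5 families; substitution rates
    per divergence level and indel rates (geometric lengths, p=0.5, max
    12, non-coding segments only); exons never mutate.  ``seed`` is
    mandatory — one named PRNG stream drives the whole simulation.
    """

    seed: int
    taxa: tuple = ()  # TaxonRef per species; default built when empty
    segment_lengths: dict = field(default_factory=lambda: dict(DEFAULT_SEGMENT_LENGTHS))
    sub_rate_between_family: float = 0.12
    sub_rate_genus: float = 0.05
    sub_rate_species: float = 0.02
    sub_rate_within_species: float = 0.003
    indel_rate_between_family: float = 0.02
    indel_rate_genus: float = 0.008
    indel_rate_species: float = 0.003
    indel_max_len: int = 12
    indel_geom_p: float = 0.5
    records_per_species: int = 2
    partial_record_fraction: float = 0.3
    planted_signatures: tuple = ()
    signature_retry_cap: int = 20

    def __post_init__(self):
        for name in (
            "sub_rate_between_family",
            "sub_rate_genus",
            "sub_rate_species",
            "sub_rate_within_species",
            "indel_rate_between_family",
            "indel_rate_genus",
            "indel_rate_species",
            "partial_record_fraction",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


def default_taxa() -> tuple:
    """30 species, 8 genera, 5 families, with alternating habitat flags."""
    layout = {
        "Fam01": {"GenA": 4, "GenB": 3, "GenC": 3},
        "Fam02": {"GenD": 4, "GenE": 4},
        "Fam03": {"GenF": 5},
        "Fam04": {"GenG": 4},
        "Fam05": {"GenH": 3},
    }
    taxa = []
    i = 0
    for family, genera in layout.items():
        for genus, n in genera.items():
            for k in range(1, n + 1):
                habitat = "maize_field" if i % 2 == 0 else "grassland"
                taxa.append(TaxonRef(f"{genus}_sp{k}", genus, family, frozenset({habitat})))
                i += 1
    return tuple(taxa)


def default_design_targets() -> tuple:
    """The standard design-recovery experiment: 6 targets, ladder-spaced sizes."""
    return (
        PlantedSignature("GenA_sp1", "species", 116, "trnL-intron"),
        PlantedSignature("GenD_sp2", "species", 203, "trnL-intron"),
        PlantedSignature("GenF_sp3", "species", 254, "IS2"),
        PlantedSignature("GenB", "genus", 151, "IS2"),
        PlantedSignature("GenE", "genus", 194, "trnL-intron"),
        PlantedSignature("Fam04", "family", 306, "IS2"),
    )


@dataclass(frozen=True)
class MockDb:
    """Generated records plus taxonomy and machine-readable ground truth."""

    spec: MockDbSpec
    records: tuple
    taxonomy: dict
    truth: dict

    def records_for(self, species: str) -> list:
        return [r for r in self.records if r.taxon == species]

    def write(self, outdir) -> dict:
        from .markerdb import write_fasta, write_taxonomy

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / "records.fasta",
            "taxonomy": outdir / "taxonomy.tsv",
            "truth": outdir / "truth.json",
        }
        write_fasta(self.records, paths["fasta"])
        write_taxonomy(self.taxonomy, paths["taxonomy"])
        paths["truth"].write_text(json.dumps(self.truth, indent=1, sort_keys=True) + "\n")
        return paths


# ---------------------------------------------------------------------------
# Sequence evolution primitives

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return bytes(_BASES[rng.integers(0, 4, size=length)]).decode()


def _mutate_subs(rng: np.random.Generator, seq: str, rate: float, protected=()) -> str:
    if rate <= 0 or not seq:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    n_sub = rng.binomial(len(arr), rate)
    if n_sub == 0:
        return seq
    blocked = np.zeros(len(arr), dtype=bool)
    for start, end in protected:
        blocked[start:end] = True
    free = np.flatnonzero(~blocked)
    if len(free) == 0:
        return seq
    n_sub = min(n_sub, len(free))
    pos = rng.choice(free, size=n_sub, replace=False)
    for p in pos:
        choices = _BASES[_BASES != arr[p]]
        arr[p] = choices[rng.integers(0, len(choices))]
    return bytes(arr).decode()


def _mutate_indels(rng: np.random.Generator, seq: str, rate: float, geom_p: float, max_len: int) -> str:
    if rate <= 0 or not seq:
        return seq
    n_events = rng.binomial(len(seq), rate)
    for _ in range(n_events):
        length = min(int(rng.geometric(geom_p)), max_len)
        if rng.random() < 0.5 and len(seq) > length + 1:  # deletion
            pos = int(rng.integers(0, len(seq) - length))
            seq = seq[:pos] + seq[pos + length :]
        else:  # insertion
            pos = int(rng.integers(0, len(seq) + 1))
            seq = seq[:pos] + _random_seq(rng, length) + seq[pos:]
    return seq


def _evolve_segments(rng, segments: dict, sub_rate: float, indel_rate: float, spec: MockDbSpec) -> dict:
    out = {}
    for name, seq in segments.items():
        if name in NONCODING:
            seq = _mutate_subs(rng, seq, sub_rate)
            seq = _mutate_indels(rng, seq, indel_rate, spec.indel_geom_p, spec.indel_max_len)
        out[name] = seq
    return out


def _resize(rng, seq: str, target_len: int) -> str:
    if target_len <= len(seq):
        return seq[:target_len]
    return seq + _random_seq(rng, target_len - len(seq))


def _balanced_motif(rng: np.random.Generator, length: int = MOTIF_LEN) -> str:
    """A concrete motif with moderate GC and no long homopolymer."""
    while True:
        s = _random_seq(rng, length)
        gc = sum(1 for c in s if c in "GC") / length
        longest_run = max(len(run) for run in _runs(s))
        if 0.35 <= gc <= 0.6 and longest_run <= 3:
            return s


def _runs(s: str):
    out = []
    cur = s[0]
    for c in s[1:]:
        if c == cur[-1]:
            cur += c
        else:
            out.append(cur)
            cur = c
    out.append(cur)
    return out


# ---------------------------------------------------------------------------
# Generation


def generate_mock_db(spec: MockDbSpec) -> MockDb:
    """Simulate the database; identical spec (incl. seed) => identical output."""
    rng = np.random.default_rng(spec.seed)
    taxa = spec.taxa or default_taxa()
    families: dict[str, list[TaxonRef]] = {}
    for t in taxa:
        families.setdefault(t.family, []).append(t)

    # global ancestor (non-coding segments only; exons are fixed constants)
    global_anc = {
        name: _random_seq(rng, int(np.mean(spec.segment_lengths[name])))
        for name in NONCODING
    }
    global_anc["trnL-E1"] = TRNL_E1_ANCHOR
    global_anc["trnL-E2"] = TRNL_E2_ANCHOR

    species_segments: dict[str, dict] = {}
    for family in sorted(families):
        fam_anc = dict(global_anc)
        for name in NONCODING:
            lo, hi = spec.segment_lengths[name]
            fam_anc[name] = _resize(rng, fam_anc[name], int(rng.integers(lo, hi + 1)))
        fam_anc = _evolve_segments(
            rng, fam_anc, spec.sub_rate_between_family, spec.indel_rate_between_family, spec
        )
        genera: dict[str, list[TaxonRef]] = {}
        for t in families[family]:
            genera.setdefault(t.genus, []).append(t)
        for genus in sorted(genera):
            gen_anc = _evolve_segments(
                rng, fam_anc, spec.sub_rate_genus, spec.indel_rate_genus, spec
            )
            for t in sorted(genera[genus], key=lambda t: t.species):
                species_segments[t.species] = _evolve_segments(
                    rng, gen_anc, spec.sub_rate_species, spec.indel_rate_species, spec
                )

    taxon_by_species = {t.species: t for t in taxa}
    signature_truth, protected = _plant_signatures(rng, spec, species_segments, taxon_by_species)

    # assemble species base sequences and segment boundaries
    base_seqs: dict[str, str] = {}
    boundaries: dict[str, dict] = {}
    for species, segs in species_segments.items():
        seq = ""
        bounds = {}
        for name in SEGMENT_ORDER:
            start = len(seq)
            seq += segs[name]
            bounds[name] = [start, len(seq)]
        base_seqs[species] = seq
        boundaries[species] = bounds

    # per-record within-species noise and partial truncation
    records: list[SequenceRecord] = []
    taxonomy: dict[str, TaxonRef] = {}
    record_truth: dict[str, dict] = {}
    for species in sorted(base_seqs):
        seq = base_seqs[species]
        prot = _protected_spans(species, boundaries[species], protected)
        for ridx in range(1, spec.records_per_species + 1):
            rid = f"{species}|r{ridx}"
            rseq = _mutate_subs(rng, seq, spec.sub_rate_within_species, protected=prot)
            offset = 0
            if ridx > 1 and rng.random() < spec.partial_record_fraction:
                # partial record: drop most of IS1, as real databases do
                is1 = boundaries[species]["IS1"]
                offset = int(rng.integers(is1[0], is1[1] - 10))
                rseq = rseq[offset:]
            records.append(SequenceRecord(rid, species, rseq, source="generated"))
            taxonomy[rid] = taxon_by_species[species]
            record_truth[rid] = {
                "offset": offset,
                "segments": {
                    name: [max(0, b[0] - offset), b[1] - offset]
                    for name, b in boundaries[species].items()
                    if b[1] - offset > 0 and (b[0] >= offset or name == "IS1")
                },
            }

    truth = {
        "seed": spec.seed,
        "species_segments": boundaries,
        "records": record_truth,
        "signatures": signature_truth,
    }
    return MockDb(spec, tuple(records), taxonomy, truth)


def _protected_spans(species: str, bounds: dict, protected: dict) -> list[tuple[int, int]]:
    """Absolute spans no record-level substitution may touch.

    Exons stay pristine (their mutation rate is zero by default) and
    planted signature blocks are real fixed differences of the taxon, not
    sequencing noise.
    """
    spans = [tuple(bounds["trnL-E1"]), tuple(bounds["trnL-E2"])]
    for segment, start, end in protected.get(species, ()):
        seg_start = bounds[segment][0]
        spans.append((seg_start + start, seg_start + end))
    return spans


def _members(signature: PlantedSignature, taxon_by_species: dict) -> list[str]:
    if signature.level == "species":
        members = [signature.target] if signature.target in taxon_by_species else []
    elif signature.level == "genus":
        members = [s for s, t in taxon_by_species.items() if t.genus == signature.target]
    elif signature.level == "family":
        members = [s for s, t in taxon_by_species.items() if t.family == signature.target]
    else:
        raise ValueError(f"unknown level {signature.level!r}")
    if not members:
        raise ValueError(f"signature target {signature.target!r} matches no species")
    return sorted(members)


def _plant_signatures(rng, spec: MockDbSpec, species_segments: dict, taxon_by_species: dict):
    """Insert each signature block into every member; verify uniqueness."""
    truth: dict[str, dict] = {}
    protected: dict[str, list] = {}  # species -> [(segment, start, end)]
    planted_blocks: list[tuple[set, str]] = []  # (member set, block)
    for sig in spec.planted_signatures:
        members = _members(sig, taxon_by_species)
        nonmembers = [s for s in species_segments if s not in members]
        for attempt in range(spec.signature_retry_cap):
            fwd = _balanced_motif(rng)
            rev = _balanced_motif(rng)
            filler = _random_seq(rng, sig.amplicon_bp - 2 * MOTIF_LEN)
            block = fwd + filler + iupac.reverse_complement(rev)
            if _block_unique(block, nonmembers, species_segments, planted_blocks, members):
                break
        else:
            raise RuntimeError(
                f"could not plant a unique signature for {sig.target} "
                f"after {spec.signature_retry_cap} attempts"
            )
        offsets = {}
        for sp in members:
            seg = species_segments[sp][sig.segment]
            pos = min(30 + 5 * (hash_stable(sp) % 20), max(0, len(seg) - 1))
            species_segments[sp][sig.segment] = seg[:pos] + block + seg[pos:]
            offsets[sp] = pos
            protected.setdefault(sp, []).append((sig.segment, pos, pos + len(block)))
        planted_blocks.append((set(members), block))
        truth[f"{sig.level}:{sig.target}"] = {
            "target": sig.target,
            "level": sig.level,
            "members": members,
            "segment": sig.segment,
            "amplicon_bp": sig.amplicon_bp,
            "forward_motif": fwd,
            "reverse_motif": rev,
            "block": block,
            "offsets_in_segment": offsets,
        }
    return truth, protected


def hash_stable(s: str) -> int:
    """Deterministic small hash (python's hash() is salted per process)."""
    h = 0
    for ch in s:
        h = (h * 131 + ord(ch)) % 1_000_003
    return h


def _block_unique(block, nonmembers, species_segments, planted_blocks, members) -> bool:
    probes = [
        block[:MOTIF_LEN],
        block[-MOTIF_LEN:],
        iupac.reverse_complement(block[:MOTIF_LEN]),
        iupac.reverse_complement(block[-MOTIF_LEN:]),
    ]
    for sp in nonmembers:
        joined = "|".join(species_segments[sp][n] for n in NONCODING)
        if any(p in joined for p in probes):
            return False
    for other_members, other_block in planted_blocks:
        if other_members & set(members):
            continue
        if any(p in other_block or p in iupac.reverse_complement(other_block) for p in probes):
            return False
    return True


# ---------------------------------------------------------------------------


def load_packaged_panel():
    """Re-export of the published-panel fixture loader (see panel module)."""
    from .panel import load_packaged_panel as _load

    return _load()
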