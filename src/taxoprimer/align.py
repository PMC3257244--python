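"""Deterministic multiple alignment for marker-region sequences.

Hand-curated alignments cannot be reproduced programmatically, so the
package ships a small deterministic center-star progressive aligner: the
center sequence (minimal summed edit distance to all others) is aligned
pairwise to every other sequence with affine gap scores (match +1,
mismatch -1, gap open -4, extend -1) and the pairwise alignments are
merged under the usual "once a gap, always a gap" rule.  Adequate for the
within-family and full-length alignments primer design needs; any external
aligner's aligned FASTA is accepted interchangeably.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
from Bio import Align, SeqIO


@dataclass(frozen=True)
class Msa:
    """An alignment: parallel ids and equal-length gapped rows."""

    ids: tuple
    rows: tuple

    def __post_init__(self):
        if len(self.ids) != len(self.rows):
            raise ValueError("ids/rows length mismatch")
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("ragged alignment: rows differ in length")

    @property
    def n_seqs(self) -> int:
        return len(self.ids)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, seq_id: str) -> str:
        return self.rows[self.ids.index(seq_id)]

    def column(self, col: int) -> str:
        if not 0 <= col < self.n_cols:
            raise IndexError(f"column {col} out of range")
        return "".join(r[col] for r in self.rows)

    def position_in(self, seq_id: str, col: int):
        """Unaligned position of ``col`` in ``seq_id``, or None on a gap."""
        row = self.row(seq_id)
        if row[col] == "-":
            return None
        return sum(1 for c in row[:col] if c != "-")

    def ungapped(self, seq_id: str) -> str:
        return self.row(seq_id).replace("-", "")


def _pairwise_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -4
    aligner.extend_gap_score = -1
    return aligner


def _merge(master_rows: list[str], master_center: str, pair_center: str, pair_new: str):
    """Merge one pairwise alignment into the master under once-a-gap rules."""
    out_rows = [[] for _ in master_rows]
    out_center: list[str] = []
    out_new: list[str] = []
    i = j = 0
    while i < len(master_center) or j < len(pair_center):
        if i < len(master_center) and master_center[i] == "-":
            for k, row in enumerate(master_rows):
                out_rows[k].append(row[i])
            out_center.append("-")
            out_new.append("-")
            i += 1
        elif j < len(pair_center) and pair_center[j] == "-":
            for k in range(len(master_rows)):
                out_rows[k].append("-")
            out_center.append("-")
            out_new.append(pair_new[j])
            j += 1
        else:
            for k, row in enumerate(master_rows):
                out_rows[k].append(row[i])
            out_center.append(master_center[i])
            out_new.append(pair_new[j])
            i += 1
            j += 1
    return ["".join(r) for r in out_rows], "".join(out_center), "".join(out_new)


def align_sequences(sequences: dict[str, str], center: str | None = None) -> Msa:
    """Center-star progressive alignment of ``{id: sequence}``.

    Deterministic: the center is the sequence minimising the summed edit
    distance to all others (ties by id), remaining sequences join in id
    order.  Pass ``center`` explicitly when a particular sequence must
    anchor the column space — a center-star alignment only aligns
    insertions *present in the center* consistently across sequences, so
    design scans focused on one taxon group should center on a member.
    """
    ids = sorted(sequences)
    if not ids:
        raise ValueError("no sequences to align")
    if len(ids) == 1:
        return Msa((ids[0],), (sequences[ids[0]],))

    if center is None:
        dist_sum = {
            a: sum(
                edlib.align(sequences[a], sequences[b], task="distance")["editDistance"]
                for b in ids
                if b != a
            )
            for a in ids
        }
        center = min(ids, key=lambda a: (dist_sum[a], a))
    elif center not in sequences:
        raise ValueError(f"center {center!r} not among the sequences")
    others = [a for a in ids if a != center]

    aligner = _pairwise_aligner()
    master_rows: list[str] = []
    member_ids: list[str] = [center]
    master_center = sequences[center]
    master_rows = [master_center]
    for sid in others:
        aln = aligner.align(sequences[center], sequences[sid])[0]
        pair_center, pair_new = str(aln[0]), str(aln[1])
        # master_center may already carry gaps; merge on center bases
        master_rows, master_center, new_row = _merge(
            master_rows, master_center, pair_center, pair_new
        )
        master_rows.append(new_row)
        member_ids.append(sid)

    order = {sid: k for k, sid in enumerate(member_ids)}
    rows = tuple(master_rows[order[sid]] for sid in ids)
    return Msa(tuple(ids), rows)


def read_aligned_fasta(path) -> Msa:
    ids, rows = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        rows.append(str(rec.seq).upper().replace(".", "-"))
    return Msa(tuple(ids), tuple(rows))


def write_aligned_fasta(msa: Msa, path) -> None:
    with open(path, "w") as fh:
        for sid, row in zip(msa.ids, msa.rows):
            fh.write(f">{sid}\n{row}\n")
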