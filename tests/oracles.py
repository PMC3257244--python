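"""Independent brute-force oracles used by the property tests.

Everything here is written directly from the documented definitions —
offset-by-offset scans, exhaustive register/partition enumeration — and
deliberately shares no code with the package implementation it checks.
"""

from itertools import combinations

from taxoprimer.iupac import CODE_TO_BASES, COMPLEMENT, reverse_complement

_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


def brute_binding_sites(primer, template, policy):
    """Offset-by-offset scan on both strands."""
    m, n = len(primer), len(template)
    out = []
    for strand in ("plus", "minus"):
        probe = primer if strand == "plus" else reverse_complement(primer)
        for i in range(n - m + 1):
            mm = []
            for j in range(m):
                t, p = template[i + j], probe[j]
                ok = (t == p) or (
                    policy.allow_ambiguity_overlap
                    and bool(CODE_TO_BASES.get(t, set()) & CODE_TO_BASES.get(p, set()))
                )
                if not ok:
                    mm.append(m - 1 - j if strand == "plus" else j)
            if len(mm) <= policy.max_total_mismatches and all(
                x >= policy.protected_3prime_nt for x in mm
            ):
                out.append((strand, i, i + m, tuple(sorted(mm))))
    return sorted(out, key=lambda s: (s[1], s[0] != "plus"))


def brute_amplicons(fwd, rev, template, policy, max_len):
    """Exhaustive convergent pairing of independently found sites."""
    spans = set()
    probes = [(fwd, rev)] if fwd == rev else [(fwd, rev), (rev, fwd)]
    for left, right in probes:
        lefts = [s for s in brute_binding_sites(left, template, policy) if s[0] == "plus"]
        rights = [s for s in brute_binding_sites(right, template, policy) if s[0] == "minus"]
        for _, fs, fe, _mm in lefts:
            for _, rs, re_, _mm2 in rights:
                if rs >= fe and re_ - fs <= max_len:
                    spans.add(((fs, fe), (rs, re_)))
    return spans


def brute_anchors(rows, ids, target_ids):
    """Exhaustive per-column discriminative-site check, both strands."""
    k = len(target_ids)
    index = {sid: i for i, sid in enumerate(ids)}
    t_idx = [index[t] for t in target_ids]
    n_idx = [i for i in range(len(ids)) if ids[i] not in set(target_ids)]
    expected = set()
    if not n_idx:
        return expected
    for c in range(len(rows[0])):
        tchars = {rows[i][c] for i in t_idx}
        if len(tchars) != 1:
            continue
        base = tchars.pop()
        if base not in "ACGT":
            continue
        if all(
            rows[i][c] in "-." or base not in CODE_TO_BASES[rows[i][c]] for i in n_idx
        ):
            expected.add((c, "plus", base))
            expected.add((c, "minus", COMPLEMENT[base]))
    return expected


def brute_dimer(a, b):
    """Every duplex register, every complementary run, 3'-inclusive only."""
    best = 0
    la, lb = len(a), len(b)
    for shift in range(-(lb - 1), la):
        cells = []
        for i in range(la):
            k = lb - 1 - (i - shift)  # antiparallel pairing index into b
            cells.append((i, k) if 0 <= k < lb and (a[i], b[k]) in _PAIRS else None)
        i = 0
        while i < la:
            if cells[i] is None:
                i += 1
                continue
            j = i
            while j < la and cells[j] is not None:
                j += 1
            run = cells[i:j]
            if any(c[0] == la - 1 for c in run) or any(c[1] == lb - 1 for c in run):
                best = max(best, len(run))
            i = j
    return best


def min_partition_size(assays, params, compat):
    """Exhaustive set-partition search with a precomputed pairwise matrix."""

    def partitions(items):
        if not items:
            yield []
            return
        first, rest = items[0], items[1:]
        for part in partitions(rest):
            for i, block in enumerate(part):
                yield part[:i] + [[first] + block] + part[i + 1 :]
            yield [[first]] + part

    def block_ok(block):
        if len(block) > params.max_assays_per_panel:
            return False
        return all(
            compat[frozenset((a.name, b.name))] for a, b in combinations(block, 2)
        )

    best = len(assays)
    for part in partitions(list(assays)):
        if all(block_ok(block) for block in part):
            best = min(best, len(part))
    return best
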