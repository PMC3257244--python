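# taxoprimer

Design and in-silico validation of taxon-specific diagnostic PCR assays on
plant chloroplast marker regions.

## The problem

Plants often cannot be identified morphologically — roots growing in
mixture, decaying litter, or the semi-digested tissue in an herbivore's
gut. Diagnostic endpoint PCR solves this cheaply: a primer pair is
designed so that only one species (or genus, or family) yields a product,
and the product's *size* identifies the taxon on a capillary or gel
trace, so several assays can run together in one multiplex reaction.

The marker of choice here is the chloroplast trnT–trnF region: two short,
highly conserved exons of the trnL (UAA) gene (trnL-E1, trnL-E2) embedded
in three variable non-coding segments — the trnT/trnL spacer (IS1), the
trnL intron, and the trnL/trnF spacer (IS2). The exons anchor annotation
and group-level primers; the non-coding segments carry the taxon-specific
differences that specific primers exploit.

## What the package does

- **markerdb** — load FASTA/GenBank records, merge all records of a
  species into an IUPAC consensus (conflicts become ambiguity codes, never
  majority votes), annotate the five marker segments by locating the exon
  anchors, and report per-segment coverage.
- **sitefinder** — per-column conservation profiles, conserved windows,
  and discriminative 3'-anchor columns: positions where every target
  shares one base and every non-target differs. Specific primers place
  their 3'-terminal base exactly there (ARMS logic: a 3' mismatch blocks
  extension), so non-targets fail to amplify.
- **primerdesign** — enumerate candidate oligos anchored on those sites
  (or inside conserved windows for group assays), screen length, GC,
  homopolymers, hairpins and self-dimers, estimate nearest-neighbor
  melting temperatures (unified parameter set, salt-corrected), and pair
  primers under amplicon-size and ΔTm constraints.
- **insilico_pcr** — find primer binding sites under a documented
  mismatch policy (≤2 mismatches, zero in the protected 2-nt 3' window,
  by default), predict amplicons from convergent site pairs, and evaluate
  whole assays against a database: sensitivity (all targets amplify at
  the expected size) and specificity (no non-target product within sizing
  tolerance of an expected size).
- **multiplex** — 3'-anchored primer-dimer scores, pairwise assay
  compatibility (size gap, Tm spread, cross-dimers), and minimal panel
  partitioning (exact for ≤12 assays, greedy above).
- **quantify** — the copy-number calculus used for sensitivity testing:
  double-stranded molecular weight (617.96·L + 36.04, or per-base
  summation), copies per nanogram (N_A·10⁻⁹/MW), serial-dilution
  ladders, and detection-limit calling under a monotone-envelope rule.
- **synthetic** — a seeded generator of mock trnT-F databases with
  planted, target-exclusive signatures, so the entire pipeline is testable
  without any download; plus a packaged fixture of a published 15-assay
  panel (27 oligos, four multiplex groups) used as a regression standard.

## Worked example

Design a species assay on a generated database with a 116-bp signature
planted in the target:

```python
from taxoprimer import (MockDbSpec, generate_mock_db, design_assays,
                        ds_molecular_weight, copies_per_ng)
from taxoprimer.synthetic import default_design_targets

spec = MockDbSpec(seed=1, planted_signatures=default_design_targets())
db = generate_mock_db(spec)
result = design_assays(db.records, db.taxonomy, "GenA_sp1",
                       level="species", preferred_size=116)

best = result.best
print(f"validated assays: {len(result.assays)}")
print(f"forward  5'-{best.assay.forward.sequence}-3'  (Tm {best.assay.forward.tm_celsius:.1f} C)")
print(f"reverse  5'-{best.assay.reverse.sequence}-3'  (Tm {best.assay.reverse.tm_celsius:.1f} C)")
print(f"expected amplicon: {best.assay.expected_sizes[0]} bp")
print(f"in-silico sensitivity: {best.evaluation.sensitivity:.1f}")
print(f"non-target taxa amplified: {best.n_nontarget_amplified}")

mw = ds_molecular_weight(best.assay.expected_sizes[0])
print(f"product molecular weight: {mw:.2f} g/mol")
print(f"template copies per ng: {copies_per_ng(mw):.3e}")
```

prints

```
validated assays: 3
forward  5'-AATGTGGACGCTACAGAGATATAAAAGGG-3'  (Tm 52.7 C)
reverse  5'-GGCCGATCAGTATACTGACTAACCAAAA-3'  (Tm 52.7 C)
expected amplicon: 116 bp
in-silico sensitivity: 1.0
non-target taxa amplified: 0
product molecular weight: 71719.40 g/mol
template copies per ng: 8.397e+09
```

The designed pair ends on the planted discriminative region, amplifies
the target species only, at exactly the planted 116 bp; one nanogram of
that product holds ~8.4×10⁹ template copies — the conversion used when
expressing an assay's detection limit in copies per reaction.

The same workflow is available from the shell:

```sh
taxoprimer simulate --seed 1 --out mockdb/
taxoprimer design --records mockdb/records.fasta --taxonomy mockdb/taxonomy.tsv \
    --target GenA_sp1 --level species --preferred-size 116 --out assays.tsv
taxoprimer panel --out panels.json          # packaged published panel
taxoprimer quantify --length 116
```

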