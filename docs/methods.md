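# Methods

This note documents the models and numerical choices behind taxoprimer:
what each component computes, the defaults and why, what the synthetic
databases emulate (and deliberately do not), and the known limitations.

## Marker model and coordinates

All sequences are treated as linear excerpts of the chloroplast trnT–trnF
region with five canonical segments in fixed order: IS1, trnL-E1,
trnL-intron, trnL-E2, IS2. Coordinates are 0-based half-open everywhere
internally; only human-readable reports and BED exports follow their own
conventions (BED is natively 0-based half-open). Circular templates are
not supported.

Exon anchors are packaged as configurable defaults. The shipped anchor
strings are synthetic stand-ins with the length and conserved character
of the real trnL exons — they are exactly what the bundled database
generator emits, so annotation and generation agree by construction.
Anyone annotating real data should supply the true exon sequences of
their marker; every entry point accepts an `anchors` override. Anchor
placement is the best ungapped match with at most 10% mismatches
(IUPAC-overlap aware); two equally good placements raise an ambiguity
error rather than guessing, and a missing anchor flags dependent segments
absent rather than silently truncating.

## Species consensus

All records of a species are merged into one IUPAC consensus. The longest
record anchors the coordinate frame; every other record is aligned to it
with affine gaps (match +1, mismatch −1, open −4, extend −1) and free end
gaps, via Biopython's PairwiseAligner. A record whose aligned identity to
the reference falls below 0.70 (configurable) is reported as an
unanchorable outlier. Overlapping columns merge to the minimal covering
IUPAC code — disagreements are recorded as conflict positions and
surface as ambiguity codes, never majority-voted away, because the primer
designer must see uncertainty (a candidate containing any ambiguity code
is disqualified). Insertions internal to the reference frame cannot be
placed on reference coordinates and are dropped; within a species these
are rare, and the generator's record-level noise model is substitution
only, matching this behaviour.

## Multiple alignment

Hand-curated alignments cannot be reproduced programmatically, so design
runs on a deterministic center-star progressive aligner: pairwise
alignments of every sequence to a center sequence (chosen by minimal
summed edit distance, or pinned by the caller), merged under "once a gap,
always a gap", with the same scoring as above. A center-star alignment
only places insertions consistently across sequences when the center
itself carries them, so design scans center on a member of the target
group. Any externally produced aligned FASTA is accepted
interchangeably.

## Site discovery

Specific (species/genus) primers use discriminative 3' anchors: alignment
columns where every target carries one identical concrete base and every
non-target differs (different base or gap). A non-target ambiguity code
that *could* represent the target base counts as not differing —
conservative for specificity. Columns are reported on both strands.
Because chloroplast spacers are repeat-rich, a repeat screen then
discards any site whose 3'-flanking 12-mer occurs more than once (either
strand) in any target sequence.

Group (family) primers instead use windows fully conserved across the
group (conservation 1.0, no gaps, at least one primer length long);
their outgroup specificity is established downstream by in-silico PCR
rather than per-column discrimination, which tolerates the internal
length variation group assays legitimately show.

## Primer candidates and pairing

Defaults: length 18–29 nt, GC 0.25–0.65, homopolymer runs ≤4, amplicons
80–400 bp, ΔTm ≤3 °C. Short amplicons maximise detection of degraded
DNA; the floor keeps products distinguishable from dimer artifacts.
Hairpins and self-dimers are scored as the maximum ungapped
self-complementary run, with runs touching a 3' terminus weighted ×2
(caps 8 and 12); thermodynamic folding is deliberately out of scope — the
run score is deterministic and oracle-checkable.

Melting temperatures come from the unified nearest-neighbor parameter set
(enthalpy/entropy per dinucleotide stack plus terminal initiation terms),
with Tm(K) = 1000·ΔH/(ΔS + R·ln(C_T/x)) and the Schildkraut
16.6·log₁₀[Na⁺] salt correction; defaults 50 mM monovalent salt, 250 nM
total oligo. Parameters ship as JSON and are swappable. The symmetry
entropy term for self-complementary oligos is not applied (x switches to
1 instead); real primers are never self-complementary after the self-dimer
screen.

Pairing keeps convergent candidates within the size range and ΔTm cap,
sorted by ΔTm then product length; a `preferred_size` re-ranks surviving
pairs toward a requested amplicon length — the knob used to compose
size-multiplexed ladders. To bound the pairing search, candidate lists
are evenly subsampled to 400 per strand (positional coverage preserved),
and the 40 best-ranked pairs are screened by in-silico PCR; all four
numbers are arguments.

## In-silico PCR

A primer binds wherever an ungapped comparison shows at most 2 mismatches
with none in the 2-nt protected 3' window (both configurable); template
ambiguity codes count as matches when they can represent the primer base.
This is the package's operational definition of cross-amplification —
every specificity claim is relative to the policy used. Products come
from convergent opposite-orientation site pairs only (either oligo may
act in either orientation); same-orientation artifacts are ignored,
matching how diagnostic traces are read. Assay evaluation reports, per
taxon, whether anything amplified and whether any product lies within ±4
bp (capillary sizing error, configurable) of an expected size; a
non-target product inside that window is a confusability violation.

## Multiplex panels

Assays co-reside when their expected sizes are separable, their primers
share a working temperature, and no strong 3' cross-dimer forms.
Defaults: minimum size gap 15 bp, Tm spread ≤7 °C, dimer run ≤6,
≤6 assays per panel. The gap default sits just below the smallest gap
(19 bp) in published multiplexes that demonstrably resolved cleanly; the
Tm-spread and dimer caps are calibrated the same way — the packaged
published panels reach a 6.35 °C spread (under this package's Tm model)
and 3'-anchored runs of 6, and panels that co-amplified in the wet lab
must validate under the defaults. Tighter thresholds are available to
anyone wanting more conservative designs. Range-valued group assays
occupy their whole size interval for gap computation, which is why such
assays end up singleplex; the builder additionally keeps genus- and
family-level screening assays in their own reactions by default
(`group_singleplex`), mirroring two-step screening practice (group
pre-selection first, species multiplexes second). Partitioning is an
exact minimal partition by subset dynamic programming for ≤12 assays,
with lexicographic tie-breaking; above that a greedy largest-first
heuristic is used and flagged. Shared oligos across assays are
deduplicated before dimer scoring — a primer never scores against itself
as a cross-interaction.

## Copy-number calculus

Double-stranded molecular weight: length mode 617.96·L + 36.04 g/mol;
sequence mode sums monophosphate residue weights (A 313.21, C 289.18,
G 329.21, T 304.20) over both strands plus one water per strand end.
These constants are conventional averages; the two modes agree within
1.5% for GC fractions 0.3–0.7 (asserted by test). Copies per nanogram is
N_A·10⁻⁹/MW. Serial dilutions divide by the factor until the next step
would fall below the floor. The detection limit is the smallest copy
number that is positive with every larger copy number positive (the
monotone-envelope rule): an isolated positive below a negative rung
reflects stochastic detection at the limit and does not count. A readout
is positive when its fluorescence signal exceeds 0.1 RFU and its observed
size matched the expectation.

## The synthetic database generator

The generator is a test harness, not an evolution simulator. It emulates
the features design depends on: fixed conserved exons; per-family
non-coding segment lengths drawn from realistic ranges (IS1 541–991,
intron 241–588, IS2 75–692 bp); hierarchical divergence (global ancestor
→ family → genus → species → records) with substitution rates 0.12 /
0.05 / 0.02 / 0.003 per level and indels (geometric lengths, p = 0.5,
capped at 12 nt) confined to non-coding segments; and partial records
(30% of extra records truncated into IS1), echoing the incomplete
coverage real marker databases show. One seeded NumPy generator drives
everything; identical spec and seed give byte-identical output files.

Designated targets receive planted signatures: a target-exclusive
insertion `F-motif (25 nt) + filler + revcomp(R-motif) (25 nt)` of
exactly the requested amplicon length, identical in every member of the
target group, uniqueness-checked against all other taxa (with a retry
cap). Planting signatures as insertions rather than substitutions makes
the ground truth sharp: non-targets show gaps across every signature
column, so discriminative anchors provably exist and the planted amplicon
length is exactly recoverable. The standard experiment plants six targets
(3 species, 2 genus, 1 family) at ladder-spaced sizes 116–306 bp.

What passing on this generator does *not* show: robustness to alignment
ambiguity in deep cross-family comparisons, to signatures that are single
substitutions rather than indel blocks, or to real sequencing artifacts.
The published-panel fixture and the optional real-record check cover the
bridge to real data.

## Problem sizes

The standard validation runs use 30-taxon databases (60 records,
sequences ~1–2.3 kb), three seeds, six targets each; brute-force oracle
comparisons use 100–200 randomized small instances per primitive. A full
validation pass completes in about a minute on one CPU.

## Known limitations

- No thermodynamic secondary-structure or PCR-kinetics modelling; dimer
  and hairpin scores are combinatorial run lengths.
- No degenerate-primer or probe (TaqMan) design; candidates must be
  concrete.
- Center-star alignment is crude for deeply diverged sequence sets; for
  serious cross-family work, align externally and feed the aligned FASTA
  in.
- Amplification efficiency, inhibition (e.g. co-extracted predator DNA)
  and plate-reader calibration are out of scope; wet-lab reaction
  metadata is carried but never interpreted.
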