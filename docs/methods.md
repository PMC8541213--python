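# Methods

## Scope and model

`lampdiag` finds genome positions that are invariant within one target
species and different in every record of every other species in a
panel, designs six-primer LAMP sets anchored on those positions, and
predicts amplification of any primer set on any genome.  All
coordinates are 0-based, half-open.  Circular templates (mitogenomes)
are handled by virtual doubling, so every search and every verdict is
invariant under rotation of the sequence.

## Alignment

Panels of interest are 93–99 % identical, so a banded global aligner is
both adequate and fast.  `global_align` is a Gotoh affine-gap
Needleman–Wunsch restricted to a diagonal band (numba-compiled):
match +1, mismatch −1, and a gap of length L costs 4 + L.  The band
half-width defaults to `max(200, 2·|len(a) − len(b)|)`; mitogenome
pairs differ by under 100 bp, so the optimum is comfortably inside the
band, and for sequences short relative to the band the result equals
the unbanded optimum (verified against Biopython's `PairwiseAligner`
with identical scores).  Percent identity uses the alignment-length
convention: matches over all columns, gap columns included in the
denominator.

The multiple alignment is center-star: every record is pairwise-aligned
to a designated reference and projected onto reference columns;
insertions relative to the reference are counted but excluded from
profiling.  This is deterministic, adequate at these identity levels,
and keeps a one-to-one column↔reference-position mapping.  Records
below 85 % identity to the reference are rejected by name — the model
assumes near-identical panels, and silently profiling a mis-labeled or
wrong-species record would corrupt every downstream call.  Progressive
MSA was deliberately not used: determinism and a fixed reference frame
matter more here than optimal gap placement.

## Site profiling

For a target species, each column gets: the single base shared by all
target rows (columns where the target is polymorphic, gapped or
ambiguous can never be diagnostic), and the set of non-target species
none of whose rows equals that base.  A non-target species may be
polymorphic at a column and still be discriminated, as long as no row
matches; conversely one matching row anywhere blocks discrimination.
Gaps and N never match anything.  A column is *fully diagnostic* when
it discriminates every non-target species; `find_windows` clusters
such columns into maximal windows (default: ≥ 3 sites within ≤ 500 bp
— window parameters are toolkit choices, as no numeric criterion is
fixed by the underlying study).  Indel columns are never diagnostic;
substitution sites only.

## Thermodynamics

Melting temperatures use the unified nearest-neighbor parameter set
with the entropic salt correction, via Biopython's `MeltingTemp`
(defaults: 50 mM monovalent salt, 250 nM primer, primer-in-excess
concentration term).  The test suite checks the wrapper against an
independently coded NN table lookup.  GC fraction and a
longest-self-complementary-run screen complete the physical layer; the
run screen is a crude proxy for hairpin/dimer potential and is treated
accordingly (below).

## Primer set design

A LAMP set occupies eight regions, on the reference in the order
F3 F2 (LF) F1 B1 (LB) B2 B3.  Stored orientations: F3/F2/B1/LB are the
forward-strand sequence of their region, F1c/B2c/B3/LF the reverse
complement, so FIP = F1c·F2 and BIP = B1·B2c are literal string
concatenations and the priming 3′ halves (F2 on +, B2c on −) anneal
convergently.

Candidate enumeration is exhaustive within a diagnostic window
(widened by the maximal outer-primer length): every substring passing
role-specific length and Tm windows, GC bounds, the structure screen,
and — for F3/B3 — at least `min_specific_3prime` (default 2) fully
diagnostic columns within the 3′-terminal 3 bases.  Primers must also
sit where the target species shows no within-species variation at
their 3′ end (last 4 columns) and at most 2 variable columns overall,
so every intra-species variant still binds under the default mismatch
model.  Sets are assembled outer-pair-first (pairs ranked by total
diagnostic 3′ sites), inner primers filled greedily by Tm closeness to
role targets under the geometry bounds (F3→F2 gap 0–40 bp, F2-start→
B2-end span 120–260 bp, outer product ≤ 500 bp), loop primers attached
when a compliant candidate exists between F2–F1 / B1–B2 and omitted
otherwise (sets without loop primers are still emitted — the field
assay itself runs on four primers for three of the four species).
Every emitted set is re-checked by an independent validator
(`validate_set`), and ranking is a deterministic total order:
diagnostic 3′ sites ↓, summed Tm distance from role targets ↑,
worst self-complementary run ↑, product span ↑, F3 start ↑.  When no
outer pair reaches 2 diagnostic 3′ bases the requirement relaxes to 1
before giving up — the published marker set itself contains one species
where only a single terminal diagnostic base was available.

### Constraint defaults and AT-rich calibration

The published four-species diagnostic set is the calibration anchor
for the defaults: computed over those 24 primers, lengths reach 30 nt,
GC drops to 0.11, and NN Tm spans 46.1–57.2 °C — far outside textbook
PrimerExplorer windows (55–65 °C, GC ≥ 25 %), which would reject every
one of them.  Defaults are therefore: lengths 18–30 (inner parts
18–28), Tm 46–63 °C for priming roles (46–66 °C for F1c/B1, 43–60 °C
for loops) with ranking targets at 55–58 °C, GC 0.02–0.60 (the floor
only excludes zero-GC primers; on 80 % AT templates the Tm floor is
the real stability criterion and a higher GC floor merely duplicates
it), and a self-complementary-run cap of 16 with the run length used
as a ranking penalty.  The cap is deliberately loose: AT-rich genomes
carry 10–14-base AT palindromes in ordinary flanks, and such duplexes
are far weaker than the 6-base GC runs a length cutoff is usually
tuned to; hard-rejecting them empties whole windows.  5′ G padding
(≤ 3 bases, minimal count to reach the role's Tm floor) mirrors the
published assay's own practice of appending 5′ G's to adjust Tm;
padded bases are non-genomic, are recorded per primer
(`padded_5prime`), and are excluded from binding-model searches and
from PCR product arithmetic.

A reverse-complement design pass was prototyped and removed: with
symmetric per-role constraints, every outer-primer screen (Tm, GC,
self-complementarity, 3′ diagnostic window) is strand-invariant over
the same physical flank, so the mirror frame cannot rescue a window
the forward frame rejects.

## In-silico PCR and LAMP

Binding is mismatch counting with a mandatory exact match over the
primer's 3′-terminal window (default 2 bases) and at most 2 total
mismatches, searched on both strands over the doubled circular
sequence.  This is intentionally not a thermodynamic duplex model: it
encodes the qualitative design rule that two or more species-specific
3′ bases confer specificity while single internal differences may
cross-react, and its two parameters are exposed for recalibration.
How many mismatches abolish LAMP in practice is not quantified by the
underlying study; the defaults are a toolkit calibration.

`predict_pcr` reports convergent site pairs with the 5′-to-5′
inclusive length convention (matching gel-size expectations), both
role assignments considered, circular products allowed to wrap the
origin.  `predict_lamp` is positive iff all six core regions bind with
correct strand and order within the product cap; both template
orientations are checked, so reverse-complemented genome files give
identical verdicts.  FIP/BIP are decomposed into their stored parts;
for primers read from a table, where the split point is unknown, every
admissible split is tried (`predict_lamp_components`).  Loop primers
never make a call positive: when LF/LB binds a genome whose core call
is negative the call carries a `loop_risk` flag (matrix cell
`-!loop`), reflecting that loop primers are an amplification
accelerant with a documented tendency to cross-react in close
relatives, not a specificity element.

## Synthetic panels

`simulate_panel` draws an ancestral sequence at a given AT fraction
(default 0.80), derives each species by independent substitutions on a
star phylogeny (substitutions only; planted windows are always
indel-free), adds low intra-species polymorphism (default 0.002/site)
on disjoint positions per record — a species with a single record gets
none, as within-species variation is undefined there — and plants
diagnostic windows whose positions are returned as ground truth.  Two
construction rules make the truth table exact rather than
approximate: at a planted column the target keeps its base and all
other species share one different base (so the column is diagnostic
for its owner and nobody else), and species-level substitutions that
would accidentally create a fully diagnostic column for a
marker-carrying species are neutralised by copying the target base
into one species without planted windows.  Sinks are restricted to
non-marker species so the pairwise identity structure among the
marker-carrying species stays undistorted.  Planted sites are laid out
as two tight clusters ~190 bp apart so outer primers can terminate on
them at both ends of a compact LAMP amplicon, the geometry the real
markers exhibit (a run of bolded diagnostic bases at the 3′ end of
each outer primer).

The canonical test panel emulates the study system's printed identity
structure: seven species, 15 kb circular genomes at 80 % AT, one
reference-like species at ~93.3–94.4 % identity to everything else,
one near-identical pair at ~97.7–98.2 % (the hardest discrimination
case), three more distant relatives standing in for other noctuid
genera, two records per marker-carrying species with 0.002
polymorphism.  Per-lineage divergences (0.047, 0.0119, 0.0081, 0.0081,
0.020, 0.022, 0.018) were calibrated once, empirically, so that
*realized record-level* identities land in those bands after
polymorphism and the cleanup pass; the bands are verified by
`global_align` in the tests.

What the generator does **not** emulate: indels and rearrangements,
rate heterogeneity along the genome, tree-structured (non-star)
divergence, sequencing error, and base-composition skew between
species.  Passing tests therefore demonstrate correctness of the
algorithms under the stated panel regime, not performance on arbitrary
real data; in particular real panels contain *many* species-unique
substitutions outside any marker window, which the canonical panel
deliberately suppresses so planted-site recovery can be asserted
exactly.

## Validation against public records

The sequence-derived numbers of the source study (mitogenome lengths
15,378 / 15,361 bp, 13 CDS + 22 tRNA features, 94.21 % pairwise
identity, single sub-500 bp in-silico PCR amplicons of the published
outer pairs) are encoded in `lampdiag.validation` and the
`lampdiag validate` subcommand, which run on user-supplied GenBank
files for MZ603870 and MT702982.  The records are not redistributed
with the package and nothing in the test suite depends on network
access.  The identity check uses the alignment-length denominator
stated above, with a ±0.5 percentage-point tolerance.

## Numerical and degenerate-input choices

Ambiguity base N is legal in genomes (never matching anything in
profiling or binding) and illegal in primers.  Empty candidate lists,
single-species panels and profiles without diagnostic columns return
empty results rather than raising.  Tm is undefined below 8 nt and for
sequences containing N.  All randomness flows through
`numpy.random.default_rng(seed)`; same spec + seed reproduces panels
byte-for-byte.  Problem sizes in the test and acceptance suites
(15 kb genomes, 20 panel replicates, 100 aligner/invariant trials)
were chosen as the smallest sizes at which the statistical assertions
are stable.
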