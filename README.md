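# lampdiag

Species-diagnostic LAMP marker discovery and in-silico validation for
panels of near-identical genomes.

## The problem

Closely related insect pests — the motivating case is the *Spodoptera*
armyworm/cutworm complex — are morphologically indistinguishable as
larvae but must be told apart for quarantine and field monitoring.
Loop-mediated isothermal amplification (LAMP) gives a field-deployable
answer: a six-primer reaction that amplifies only when all of its
recognition regions match the target species.  Designing such an assay
against mitochondrial genomes is hard for two reasons: the candidate
species are 93–99 % identical, so discriminating positions are scarce;
and the templates are ~80 % AT, so conventional primer-design
constraints reject nearly everything.

`lampdiag` implements the full marker workflow:

1. **Profile** a labeled genome panel: every record is aligned to a
   designated reference with a banded affine-gap Needleman–Wunsch
   aligner and each reference column is scored as *diagnostic* when it
   is invariant within the target species and differs from **every**
   record of every other species.
2. **Design** complete LAMP sets (F3/F2/F1c/B1/B2c/B3 plus optional
   LF/LB loop primers; FIP = F1c·F2, BIP = B1·B2c) over clusters of
   diagnostic sites, requiring ≥ 2 diagnostic bases at the 3′ ends of
   the outer primers, nearest-neighbor Tm and geometry constraints, a
   ≤ 500 bp outer product, and optional 5′ G padding to lift the Tm of
   AT-rich primers.
3. **Check** any primer set in silico against any genome with a
   3′-anchored mismatch binding model (exact 3′-terminal match, bounded
   total mismatches) — per-set amplification calls, predicted PCR
   amplicons, loop-primer cross-reaction risk flags, and full
   cross-species specificity matrices.
4. **Simulate** seeded synthetic panels (star phylogeny, AT-rich,
   low intra-species polymorphism, planted diagnostic sites with a
   ground-truth table) so that every stage is testable end to end
   without downloads.

## Worked example

```bash
# 1. a seeded synthetic panel: 3 species, one planted marker window
lampdiag simulate-panel --out demo --seed 99 --n-species 3 \
    --genome-length 2500 --divergence 0.03 --plant sp1:800

# 2. profile the panel for species sp1
lampdiag scan --input demo/panel.fasta --target sp1 --out demo
# -> sp1: 6 diagnostic sites, 1 windows

# 3. design primer sets
lampdiag design --input demo/panel.fasta --target sp1 --out demo --top-k 1
# -> sp1: 1 primer set(s), best span 245 bp

# 4. cross-species specificity matrix
lampdiag matrix --primers demo/sp1_primers.tsv \
    --input demo/panel.fasta --out demo/matrix.tsv
# ->     sp1_1 sp2_1   sp3_1
# -> sp1     +     -  -!loop
```

The `+` on the target genome and `-` elsewhere is the desired diagonal
pattern: the set amplifies its own species only.  The `-!loop` cell
means the core reaction is negative on sp3 but a loop primer still
binds that genome — the situation in which loop primers are known to
cause non-specific amplification in close relatives, reported as a
risk flag rather than a positive call.

The package also bundles (as `lampdiag.seq_io.bundled_primer_table()`)
the published 26-primer diagnostic table for the four *Spodoptera*
species (24 LAMP primers + the universal mtCO1 PCR pair), usable
directly with `check`/`matrix`.

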