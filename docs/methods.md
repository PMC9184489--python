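# Methods

This note documents the models, algorithms, parameter choices and numerical
details behind `larixsed`, and what the synthetic-data tests do and do not
establish about real sedimentary ancient DNA (sedaDNA).

## Diagnostic-site discovery (`refpanel`)

**Model.** Two congeneric species groups of chloroplast genomes are assumed
collinear (no rearrangements — true for *Larix* chloroplasts). One genome is
the *anchor* and defines all coordinates. A position is *diagnostic* when,
in a column of the anchor-based multi-alignment, (i) the column maps to an
anchor position (not an insertion), (ii) no genome carries a gap or N, and
(iii) the two groups are each fixed for a different base. Indel differences
are deliberately excluded: the consumers of the table are reads as short as
30 bp, on which point differences are the only robustly callable signal.

**Anchoring algorithm.** Each genome is aligned to the anchor pairwise:

1. circular genomes are first rotated to the anchor's origin — the candidate
   offset is the modal difference of unique shared k-mer positions (k = 21,
   unique in ~120 kb chloroplasts), and the rotation is applied only if it
   lengthens the collinear chain (small modal offsets are indel shifts, not
   origin differences);
2. unique shared k-mers are chained by longest strictly-increasing
   subsequence (patience sorting; the already-increasing common case is
   detected and short-circuited);
3. stretches between chained anchors are closed by global edit-distance
   alignment (edlib; internally banded by edit distance, so memory stays
   bounded);
4. pairwise alignments are merged on anchor coordinates. Insertions of
   different genomes at the same anchor gap are left-aligned and padded, not
   aligned to each other — they can never satisfy the site criteria, so
   their internal alignment is irrelevant to the output.

A genome with fewer than 10 chained anchors fails loudly with its name.

**Tie-breaking.** Unit-cost alignment does not distinguish two adjacent
substitutions from an equal-cost indel arrangement. Where a closed gap
segment has equal lengths on both sides and its Hamming distance equals the
optimal edit distance, the substitution-only (columnwise) form is used.
Without this rule, adjacent implanted differences occasionally surfaced as
spurious one-base indel columns and were lost to criterion (ii).

**Coordinates.** 0-based half-open internally; all emitted tables are
1-based (GenBank convention). Output is TSV, LF line endings, with the
transition flag ({C,T} or {A,G}) carried per site because deamination can
mimic exactly those alleles.

## Synthetic data (`simulate`)

The generator produces every input the pipeline consumes, with truth labels
down to the per-fragment damage counts. Defaults reflect the study
conditions the pipeline targets:

| parameter | default | rationale |
|---|---|---|
| fragment length | lognormal, median 75 bp, sd(log) 0.35, truncated [20, 500] | typical sedaDNA insert-size scale; the usable minimum downstream is 30 bp |
| damage `d0` | 0.3 | terminal C→T amplitude of a clearly ancient sample |
| damage `λ` | 0.3 /base | decay reaching background within ~15 bp |
| damage `e` | 0.01 | background substitution floor |
| read length | 250 (paired) | 2×250 bp paired-end chemistry |
| satellite motif | 173 bp | EulaSat1-class period |
| confidence threshold | 0.8 | the conservative genus-filter setting |

Damage model: each C at distance *i* from the 5' end of the molecule becomes
T with probability `e + d0·exp(−λ·i)`; G→A mirrors from the 3' end. This is
a single-exponential per-strand approximation, not the full
overhang/nick-frequency likelihood — the pipeline authenticates by terminal
frequency only, so nothing downstream depends on the richer model.
Sequencing error is a uniform substitution applied to positions not already
deaminated. Paired reads are cut from the damaged fragment with a fixed,
documented adapter constant padding short inserts, so read-through is
deterministically detectable. PCR duplicates re-emit molecules verbatim
under new ids. All stages draw from labelled child streams of one master
seed (`SeedSequence([seed, crc32(label)])`), so any stage can be regenerated
independently and a fixed seed yields byte-identical FASTQ and truth tables.

**What the simulator does not emulate:** capture-efficiency and bait-tiling
bias, GC bias, polymerase-specific error spectra, chimeras, and the real
taxonomic breadth of sediment background (background reads are random or
drawn from one off-target genome). Green tests therefore demonstrate
correctness of the computation under the stated statistical model, not
robustness to every artefact of real libraries.

## K-mer classification (`taxfilter`)

Canonical k-mers (lexicographic min of k-mer and reverse complement,
k odd so no k-mer is its own complement; default k = 25) of the labelled
reference set are assigned to the lowest common ancestor of the genomes
containing them, in a small user-supplied rooted taxonomy. A read's
candidate label maximises summed k-mer support along the root-to-node path;
ties collapse to the LCA of the tied nodes (conservative: genus rather than
an arbitrary leaf). Confidence is path support divided by *all* queried
k-mers, hit or miss, and calls below the threshold are unclassified.

This is intentionally not a KRAKEN2 clone (no minimizers, no spaced seeds,
and KRAKEN2's denominator treats ambiguous k-mers subtly differently). The
pipeline depends on the confidence-threshold semantics — monotonicity of
the kept set in the threshold, reverse-complement invariance, and rejection
of half-support chimeras at 0.8 — all of which are property-tested.

## Mapping and species assignment (`assign`)

Merged fragments (overlap merger with exact-adapter trimming; partial
terminal adapter handled by longest suffix-prefix match) are aligned
semi-globally — free end-gaps on the reference — against the anchor, both
strands, best edit distance kept. Defaults: `min_len` 30 bp (the study's
bioinformatic minimum), `max_div` 0.1 (admits terminal damage plus residual
divergence on short reads). Reads with optimal hits at more than one locus
are flagged ambiguous and excluded from site calling, since chloroplast
repeats would otherwise inject false calls.

**Terminal re-anchoring.** Under free end-gaps, a substitution at the very
first or last read base ties in cost with treating that base as an
insertion and shifting the reference span (or pairing it with a matching
neighbour while deleting the true reference base). Aligners may return
either form; the insertion form removes exactly the terminal substitutions
that the damage profile measures, and depressed the measured terminal
C→T frequency by ~20 % relative to truth. Every imperfect hit is therefore
realigned globally against candidate windows with the span ends jittered by
±1, choosing minimal (edit distance, indel columns, jitter). Global scoring
makes the mismatch form strictly cheaper, restoring unbiased terminal
counts at negligible cost.

Duplicates are collapsed on (span, strand, sequence), keeping the first
representative (idempotent). Each alignment's bases at diagnostic sites are
observed via the CIGAR (deletions emit nothing); each observation records
its distance to the nearer fragment terminus. The optional damage filter
(off by default — the upstream study does not mask) drops transition-site
observations within `mask_m` = 5 bp of a terminus; the test suite
demonstrates that masking strictly reduces species-B miscalls on an
all-species-A, heavily damaged, C/T-diagnostic simulation.

Per-read species is the majority over that read's informative calls
("other" bases are not votes); ties and zero informative calls leave the
read unassigned. The per-read rule is this artifact's definition — the
upstream presentation defines per-site percentages and per-sample totals
but not a per-read rule — and majority voting was chosen for robustness to
a single damage or error hit. Per-site percentages are over A+B+other
coverage, rounded half-up to two decimals. Negative-control screening
offers a report mode (overlap counts only) and a subtract mode (per-site
counts reduced by the control's, floor at zero).

## Damage estimation (`damage`)

`profile_damage` tallies, per distance *i* from the read end (window
w = 25), the fraction of reference-C positions read as T (5') and
reference-G read as A (3'), strand-resolved on the mapped orientation. The
simulator and the profiler share one geometry (the single-stranded-library
convention: both raw-read ends damaged), so profiles pooled over mapping
strands follow the model exactly; library chemistry itself is not modelled.

`fit_damage` runs weighted nonlinear least squares of
`f(i) = e + d0·exp(−λ·i)` with weights √(denominator), bounds
d0, e ∈ [0,1], λ ∈ [0,5], initialisation e = min f, d0 = f(0) − e, λ = 0.3,
tolerances 1e-8. A flat profile returns d0 = 0 with a `degenerate` flag
rather than raising. `authenticate` reports a read-resampling bootstrap
interval on d0 (200 replicates by default; per-read terminal counts are
cached so resampling is cheap), a Spearman decay check, and a verdict:
"consistent with ancient" requires d0 ≥ 0.05 and a negative trend;
fewer than 100 terminal observations give "insufficient data". The 0.05
amplitude is this artifact's default and is surfaced in the API.

## Satellite profiling (`repeatprof`)

Reads from a tandem array start at an arbitrary motif phase and span copy
junctions, so each read is aligned semi-globally against the motif
concatenated ⌈len/P⌉+1 times (both strands); the alignment start modulo P
is the phase. `max_div` defaults to 0.2 here — looser than genome mapping
because satellite copies diverge from their consensus. Profiles tally every
aligned base at (target position mod P); positions with zero coverage carry
undefined frequencies and are excluded from distances. Cross-sample
constancy is summarised as the mean, over positions covered in both
samples, of the total-variation distance between base-frequency vectors —
the constancy statistic is this artifact's definition, chosen because it is
bounded, symmetric, and directly interpretable as maximal frequency
disagreement.

A sampling subtlety the tests respect: with a finite array of C copies at
divergence δ, each position's true consensus frequency is itself
Binomial(C, δ)-distributed, so the standard error of an observed frequency
is √(δ(1−δ)(1/C + 1/coverage)), not the read-level term alone.

## Pipeline and reproducibility

`pipeline.run_all` executes panel → sites → (simulated or loaded) reads →
merge → classify → map → dedup → observe → aggregate, with damage and
repeat profiling as parallel branches, writing TSV/JSON/SAM outputs and a
manifest of per-stage counts and SHA-256 checksums. Unmergeable pairs fall
back to mate 1. Runs with the same config and seed are byte-identical
(verified by checksum in the tests). All tables are 1-based, tab-separated,
UTF-8, LF.

## Problem sizes used in tests and the acceptance script

Chosen once as realistic desk-scale study conditions: the full 120 kb ×
10-genome × 157-site panel across 20 seeds for exact truth recovery; an
8 kb anchor carrying the full 157-site panel for mixture recovery (2600
fragments ≈ 2000 informative reads at this site density, with a 50-seed
mean check at 400 fragments); 50,000 fragments for damage-parameter
recovery with a 20,000-fragment zero-damage control; 300-copy satellite
arrays at 5 % divergence with 5000-read samples.

## Known limitations

- The site caller reports substitutions only; a panel whose groups differ
  by indels would under-report those differences by design.
- Anchoring assumes collinearity; rearranged genomes fail the chained-anchor
  minimum rather than being aligned rearrangement-aware.
- The classifier is a teaching-sized LCA filter; it is not optimised for
  multi-gigabase databases.
- The damage fit treats both ends as exchangeable; libraries with genuinely
  asymmetric end chemistry should be fitted per end (`fit_damage(end=...)`).
- Ambiguity detection uses non-overlapping optimal-hit spans; near-identical
  long repeats shorter than a read would not be flagged.
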