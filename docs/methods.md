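# Methods

## Scope and model

`orthocis` operationalises identity-based conserved noncoding element
discovery for a *pair* of orthologous loci: a baseline species (whose
coordinates anchor every report) and a target species. Multi-species
screens are handled as independent baseline-vs-target pairs; no
sum-of-pairs multiple alignment is attempted, because every downstream
statistic (windowed identity, region calling, site pairing) is defined
against the baseline and pairwise comparison exercises it fully. Published
per-region "conservation" percentages from multi-species figures are
therefore reproduced here as pairwise-vs-baseline identities and labelled
as such.

Coordinates are 0-based half-open everywhere inside the package. Published
binding-site tables use 1-based inclusive From–to pairs; conversion happens
only in report writers/parsers (`to_report_coords` and its inverse), so
off-by-one drift cannot accumulate internally.

## Alignment

Whole-locus screens historically used anchored aligners over ~100-kb loci.
At the segment scale this package targets, an exact global affine-gap
aligner is preferable: a three-state Gotoh dynamic program (match state
plus one gap state per sequence), numba-jitted, with optional banding
(`|i − j| ≤ band`). A gap of length *k* costs `open + (k−1)·extend`;
terminal gaps are charged like internal ones. Defaults — match +1,
mismatch −1, open 4, extend 1 — are declared in `AlignParams` and
overridable everywhere; no published parameterisation exists for this
screen, so the defaults are deliberately conventional and visible.

Determinism: at equal score the traceback prefers a match/mismatch column,
then a gap in the target, then a gap in the baseline, and the same
predecessor order applies within each state. Swapping the input roles
therefore preserves the score always, and mirrors the alignment whenever
the optimum is unique.

`N` is never a match (it scores as a mismatch in alignment and counts as
non-identity in conservation) — ambiguity is treated conservatively
throughout.

Precomputed alignments can be imported from aligned FASTA (exactly two
records) or MAF. MAF blocks are sorted by baseline start and must be
contiguous on both sequences; non-contiguous MAF is rejected rather than
silently concatenated, because the column↔residue coordinate maps that
drive interval projection would otherwise be wrong.

## Conservation calling

The windowed statistic is percent identity over alignment columns: for a
window of `window` (default 100) consecutive baseline residues, identity is
100 × (columns in the window's column span where both species carry the
same unambiguous residue) / (total columns in the span). Gap and N columns
stay in the denominator and never match, so indels register as dips in the
profile. The span is measured in baseline residues, not columns, matching
the convention of reporting region lengths per species as ungapped bp.

Windows with identity strictly above `min_identity` (default 70 — the
strict inequality follows the usual "more than 70%" phrasing) merge when
their baseline spans overlap or abut. A merged run's identity is recomputed
over its full column span (averaging window values would double-count
overlapping columns). Because the edge windows of a run can dilute a strong
core with low-identity flanks, a run whose recomputed identity fails the
threshold is not discarded outright: the weaker edge window (by its own
window identity; ties drop the left one) is trimmed and the run
re-evaluated, so the emitted region is the maximal high-identity core.
Regions shorter than `min_span` (default 100 bp, ≥ window) are dropped.
Emitted regions always satisfy both thresholds and are disjoint on the
baseline.

Each region is scored `percent_identity + length/60` (identity 0–100,
length in baseline bp) and ranked descending; ties break by greater
length, then smaller baseline start. The divisor 60 makes 60 bp of extra
span worth one identity point, favouring long blocks among equally
conserved candidates.

## Motif model and scanning

Two representations: an IUPAC degenerate consensus (hit iff every position
is compatible; an N in the *sequence* is compatible only with an N in the
motif) and a position-count matrix scored as

    similarity = Σ_k counts[k, observed base] / Σ_k max(counts[k, ·])

with a hit threshold (default 0.85). Commercial TFBS scanners use
proprietary core/matrix similarity weightings; this transparent surrogate
preserves their ranking behaviour, is exactly reproducible, and its
threshold is a per-motif field. Consensus scanning coincides with matrix
scanning of the consensus's indicator matrix at threshold 1.0 (verified as
a property test).

Both strands are always scanned. Hits are reported in plus-strand
coordinates; the motif-strand word of a minus hit is the reverse complement
of the plus-strand segment, which is what published tables print in their
`(−)` rows. A near-palindromic motif such as the AP-1 heptamer `TGASTCA`
matches one locus on both strands — the inverted-repeat double listing.
All overlapping hits are reported; no greedy non-overlap filter is applied,
since published site tables themselves list overlapping entries.

Every motif designates a contiguous *core* (default: the whole motif for
the built-in AP-1 consensus, the `GGGR` head for the NFκB decamer),
rendered upper-case in site sequences. `delete_core` excises the core from
the sequence (the in-silico counterpart of site-directed deletion
mutagenesis); `disrupted_sites` returns the hits whose core a sequence
variant intersects, with flank-only contacts reported separately.

## TFBS conservation

A site is conserved when the same matrix hits orthologous positions: the
target hit is projected through the alignment onto the baseline and paired
with the baseline hit of the same matrix it overlaps best, requiring
reciprocal overlap ≥ `min_overlap` (default 0.5, a visible choice — no
published value exists) and, by default, strand agreement. Pairing is
greedy by descending overlap (ties by smaller baseline, then target,
start), one pair per hit. Conservation is positional by design: sequence
agreement is already enforced by the motif match itself. Table coordinates
are rendered relative to the containing region's start, with absolute
coordinates kept in machine columns.

Published tables of this kind occasionally contain a row out of coordinate
order; `orthocis` always sorts by baseline start, so such a row is a
layout discrepancy of the source, not reproduced.

## Synthetic data

The generator emulates exactly the statistical structure the screen
assumes: a uniform-random baseline; a target derived by per-base
substitution at rate (1 − identity), uniform over the three alternatives
(identity, not evolutionary distance, is the controlled quantity, because
the detection criterion is raw identity); indels started at `indel_rate`
per base with geometric lengths; planted blocks of elevated identity; and
planted motif words written verbatim. Indels are suppressed inside planted
motif spans, and scope-"both" motifs are exempt from substitution, so truth
site coordinates stay exact. One RNG stream, seeded once, drives all
randomness; identical config + seed yields byte-identical FASTA.

Defaults (the package's study conditions): 3000 bp baseline, background
identity 0.45, indel rate 0.02/bp with mean length 2, planted blocks of
250 bp/85%, 400 bp/80% and 300 bp/90%, and an AP-1 inverted-repeat pair
plus an NFκB decamer inside the middle block. These mirror a realistic
human–mouse noncoding locus: ~40–60% alignable background identity, with
conserved elements a few hundred bp long standing 25–45 points above it.
The demo adds a 150 bp coding interval at the locus start so noncoding
extraction is exercised end to end.

What the simulator does *not* emulate: repeats and their ambiguous
alignment, regional mutation-rate and GC heterogeneity, large
rearrangements, and real TFBS degeneracy (planted sites are exact words).
Passing recovery tests therefore demonstrates correctness of the
computation under the stated model, not performance on real genomes —
where alignability, assembly quality and repeat masking dominate.

Recovery scoring matches calls to truth blocks at reciprocal overlap
≥ 0.5 (greedy, one-to-one); precision and recall follow that matching, and
boundary error is the mean absolute difference of matched start/end
coordinates. At the default settings the align→call pipeline attains
recall 1.0 and precision ≥ 0.9 with mean boundary error ≈ 35–40 bp over 20
replicate seeds (recomputed by `scripts/acceptance.py` and the test suite;
the 20×3000 bp problem size keeps a full replicate sweep comfortably
interactive).

## Numerical and degenerate-input choices

- Alignment scores are float64; the DP uses −10¹⁸ as the unreachable-cell
  sentinel. Banding requires `band ≥ |len(a) − len(b)|`, otherwise a
  `BandError` suggests the minimal viable band.
- Empty sequences cannot be aligned or scanned; a baseline shorter than one
  window is an explicit error in profiling.
- An interval projected entirely into a gap run has an empty projection
  (`None`) and coverage 0; callers treat such hits/regions as unpairable.
- Annotation strand is ignored for masking: coding sequence is masked on
  both strands.
- Lower-case (soft-masked) residues can optionally be excluded from
  noncoding extraction (`mask_lowercase`), default off — whether repeat
  masking belongs in this screen is left to the user.
- Writers emit deterministic ordering and no timestamps, so reruns are
  byte-identical; every output file states its coordinate convention in a
  header comment.

## Known limitations

- Pairwise only; no ≥3-way site conservation or phylogenetic scoring
  (phastCons/phyloP-style models are out of scope — the criterion here is
  purely identity-based).
- The exact DP is quadratic; loci beyond a few tens of kb should be
  aligned externally and imported (aligned FASTA/MAF).
- The matrix-similarity surrogate is not numerically comparable to
  proprietary scanner scores; published "number of putative TFBSs" counts
  from such scanners are scanner- and threshold-specific and are not
  reproduction targets.
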