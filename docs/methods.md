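# Methods

## Overview

`spliceseek` locates exon–exon junctions from RNA-Seq reads that fail
contiguous genome alignment.  The procedure has two ingredients: a
combinatorial one (patterned fragment-pair alignment with mismatch-minimizing
boundary refinement) that proposes candidate introns, and a statistical one
(a logistic regression over intron context features, trained per organism)
that arbitrates among candidates and decides which predictions to keep.
This note records the model, its assumptions, the parameters that matter,
and the design decisions taken where the design was genuinely open.

Coordinates are 0-based half-open throughout; an intron is
`[donor_end, acceptor_start)` over intronic bases.

## Read routing

Reads are first aligned contiguously with the built-in seed-and-verify
aligner (`max_mismatches` = 2 by default).  A read with any contiguous
placement is reported in the SAM output and contributes no junction
evidence.  A read whose best placement (within a budget of
`min_local − 1` mismatches) has all its mismatches confined to one terminal
stub shorter than `min_local` is also treated as contiguous: an overhang
below `min_local` is by definition beneath the resolution of the local
placement step, and feeding such reads to the rescue path only produces
unplaceable 3–5-nt fragments whose "placements" are noise.  Everything else
enters the patterned-alignment path.

## Patterned alignment

For a read of length *n*, cutoffs lie on the arithmetic grid
`p = m + i·s` restricted to `min(p, n−p) ≥ min_local` (defaults m = 14,
s = 4, min_local = 6).  Cutoffs with both sides ≥ m give double-alignable
pairs; the extension below m and above n−m gives one-alignable pairs for
the single-match path.

**Double matches.**  Both fragments must place *uniquely* (no second hit
with equal or fewer mismatches); hits must share chromosome and strand,
with the right fragment downstream in read orientation and an implied
intron length within `[min_intron, max_intron]` (defaults 20 bp, 500 kb).
Minus-strand placements are canonicalized by reverse-complementing the
read, so all downstream geometry is forward-strand.

**Boundary refinement.**  Around a detected cutoff p, cutoffs
p′ ∈ [p−adjust, p+adjust] (default adjust = 2) are evaluated with the left
fragment anchored at its hit start and the right fragment anchored at its
hit end; the intron *length* is invariant under the shift, only its
position moves.  The p′ minimizing total mismatches wins; ties prefer a
recognized splice signal (ranked GT-AG, GC-AG, AT-AC), then the smallest
shift, then the smaller p′.

**Single-match rescue.**  The longest uniquely aligned fragment anchors a
local ungapped search for the complementary fragment in a window of
`window` bp (default 100 kb) on the intron-side flank, clipped by the mate
span for paired-end reads (the clip is ignored when it would leave no room
for the fragment, which happens when the mate lies on the other side of
the anchor).  Two deliberate departures from a "single best placement"
design, both forced by short remainders:

* *All* minimal-mismatch placements (capped at 50) become candidates and
  the junction model arbitrates.  A 6-nt remainder has several exact
  matches in any 100-kb window, so a nearest-placement rule would
  regularly lose the true acceptor to a random match; scoring by splice
  signal, size and branch-point context recovers it.
* Remainder cutoffs within ±adjust of the anchor's grid cutoff are also
  tried.  Junctions whose offset falls between grid cutoffs otherwise have
  remainders that straddle the junction and can never be placed.

**Fast-path guard.**  A read overlapping the junction by fewer than m
nucleotides on one side has no clean double-alignable cutoff; its double
matches are *mis-cut* pairs whose spanning fragment aligned within a lucky
mismatch budget, and the true boundary can sit beyond the adjustment
radius.  The double-match fast path is therefore trusted only when some
candidate refines to zero mismatches with a recognized splice signal;
otherwise the rescue also runs and the model chooses.

Per read, the highest-scoring candidate is kept (ties: fewer mismatches,
then leftmost).  A read crossing two introns reports only its best-scoring
one.

## The junction model

A candidate intron is summarized by the feature vector **Z**:

| feature | meaning | source |
| --- | --- | --- |
| `sig_gtag`, `sig_gcag`, `sig_atac`, `sig_other` | one-hot splice-signal class, strand-aware (GT-AG on the minus strand appears as CT..AC) | genome |
| `pareto_logpdf` | ln f(size) under the organism's Pareto intron-size law | trained |
| `log_intron_size` | ln(size) | genome |
| `mismatch_frac` | alignment mismatches / read length | alignment |
| `bps_score` | best branch-point PWM log-odds 18–40 bp upstream of the 3′ splice site (intron side, strand-aware; strand-symmetric background) | genome |
| `anchor_len` | shorter exonic fragment length | alignment |

The score is `1/(1+exp(−(β₀+βZ)))`, clamped away from exact 0/1.

**Intron sizes** follow a Pareto law f(x) = αx_mᵅ/x^(α+1), x ≥ x_m, with
organism-dependent parameters; the shape is fitted by the closed-form MLE
α̂ = N / Σ ln(xᵢ/x_m) with x_m the smallest annotated size (≥30 sizes
required; identical sizes raise a degenerate-fit error).  Sizes below x_m
score the density at x_m minus a fixed 5-nat penalty.  "Posterior
probability of the size" is implemented as the log density — the monotone
equivalent that needs no prior.

**Branch points.**  The default PWM is a 7-nt mammalian-consensus-derived
matrix (branch A at position 4), overridable per organism.  The feature is
the maximum log-odds over motif positions fully inside the 18–40-bp
acceptor-proximal intronic window, against the genome's strand-symmetric
base composition; windows without a single N-free motif position take a
floor of −10.

**Training.**  Positives are the introns of the supplied annotation.
Decoys (equal count, seeded RNG) are half *shifted* (one boundary moved by
±[3, 50] nt: plausible position, scrambled signal) and half *spurious* (an
anchor a few nt off a real boundary paired with a random acceptor within
the search span — what a wrong local placement looks like; half of the
spurious sizes are bootstrapped from the annotated sizes, half uniform over
the span, so that both the signal/branch-point contrast and the size law of
random placements are represented).  Earlier versions also used
donor/acceptor *mispairing* across introns; this was removed because such
decoys differ from positives only by size and trained the model to reject
genuine mid-size introns, while the error mode they represent is already
excluded by the uniqueness requirement on double matches.

Three coefficient groups are estimated differently, for cause:

* **Signal classes** use smoothed count log-odds with partial pooling: the
  three splice classes are shrunk toward their common log-odds with weight
  `n_pos/(n_pos+20)`.  Free ML coefficients misbehave here — a class with
  a handful of positives already explained by context gets a coefficient
  near 0, and under separation the coefficient diverges; meanwhile decoys
  reach the minor patterns by chance (~1/256 per boundary, doubled by the
  strand-flip check), so raw minor-class counts are noise-dominated.  All
  three classes are genuine spliceosomal signals; pooling encodes that.
* **Continuous features** (size, branch point, anchor) are standardized
  and fitted by binomial GLM with the class log-odds as a fixed offset
  (statsmodels IRLS; ridge fallback under instability).
* **The mismatch coefficient** is not identifiable from annotation-derived
  training (every training intron has zero read mismatches) and is fixed
  from the error model instead: under the true-junction hypothesis a
  mismatch is a sequencing error or polymorphism (~1% per base combined),
  under a spurious placement it occurs with probability 3/4, so each
  mismatch costs ln(0.01/0.75) ≈ −4.3 log-units.  Without this, a shadow
  boundary 1–2 nt off the truth with 1–2 mismatches can outscore the exact
  placement.

Zero-variance features keep σ = 1 and coefficient 0.  Models serialize to
versioned plain-text JSON (coefficients, standardization constants, Pareto
parameters, PWM, background).

`fit_logistic` (plain penalized ML, λ = 10⁻⁴, used for the general-purpose
fits and the recovery tests) logs a warning when the classes are perfectly
separated.

## Clustering and prediction

Per-read junctions sharing chromosome and strand are grouped by
single-linkage when donor *and* acceptor each differ by ≤ 5 nt (absorbing
the ±2 refinement slack plus alignment jitter; exposed as
`--cluster-tolerance`).  The highest-scoring member fixes the predicted
position (ties: most mismatch-free exact support, then leftmost donor);
the member count is the junction coverage.  Known/novel annotation is by
exact coordinate match — refinement is expected to land exactly, and fuzzy
matching would inflate "known" counts.

Predictions scoring below `--min-score` (default 0.5) are dropped.  The
score is a calibrated probability against the decoy model, so 0.5 reads as
"more likely real than decoy"; clusters below threshold are still counted
in the run statistics.  There is deliberately *no* coverage filter —
singleton clusters with high scores are retained.

## Built-in aligner

A k-mer index (default k = 8) stores every offset under its forward k-mer
(strand +) and the reverse-complement k-mer (strand −); palindromic k-mers
naturally hold both entries under one key; k-mers containing N are skipped.
Fragment placement is seed-and-verify with pigeonhole seeds: with
`max_mismatches+1` disjoint seeds, any placement within budget contains an
exact seed, so the hit set is complete.  Fragments too short for that many
seeds fall back to a vectorized scan of every genome position — the
reported hit set is therefore *exactly* the brute-force set at every
fragment length (property-tested against an independent sliding-window
oracle).  Fragments overlapping N runs never produce hits.  Local
alignment is ungapped (the boundary search absorbs positional slack;
indels are out of scope) with a mismatch ceiling of ⌊length/7⌋.

## Synthetic data

The generator emulates the standard junction benchmark: uniform-random
background sequence; non-overlapping multi-exon genes (3–7 exons of
100–300 bp by default); intron lengths Pareto(α = 1.5, x_m = 60) truncated
at 10 kb; splice signals written at 96% GT-AG / 3% GC-AG / 1% AT-AC;
a PWM-sampled branch-point motif planted 26–37 bp upstream of every
acceptor (every spliced intron has a branch point — what varies is motif
strength, which sampling provides); strand per gene at random.  Reads are
drawn uniformly along transcripts at `depth` coverage
(reads = depth·length/read_length), with SNPs applied once per gene
haplotype at 5/1000 bp and sequencing errors per read base at 1/1000 bp.
Read names encode the source transcript and offset; the truth set records,
per junction, the number of reads overlapping both flanks by ≥ 6 nt
(junctions without such a read are excluded from sensitivity denominators —
they are undetectable in principle).  Everything is byte-deterministic
under a fixed seed.

What the simulation does *not* model: positional/GC coverage bias, quality
profiles, indels, repeats and paralogy, alternative isoforms sharing
junctions, and realistic exon/intron sequence composition (background is
i.i.d. uniform).  Passing tests therefore demonstrate the combinatorial
and statistical machinery under clean mappability, not performance on real
libraries — in particular, real genomes' repeats would reduce unique
placements, and real splice-site context carries information (pyrimidine
tracts, extended donor consensus) this feature set ignores.

## Numerical and degenerate-input choices

* Overflow in the logistic is clamped (|f| ≤ 700; scores in
  [10⁻¹², 1−10⁻¹²]).
* Reads shorter than 2·min_local are skipped with a warning.
* Refinement cutoffs that would leave the chromosome are skipped; if all
  are invalid the unrefined cutoff is kept with a saturated mismatch
  count.
* Ties everywhere break deterministically (documented per operation);
  output is invariant to input order and to the worker count (reads are
  processed independently and merged in input order).
* Empty inputs produce empty outputs and exit code 0.

## Known limitations

* A ~6-nt rescue remainder can match several window positions exactly;
  when a junk placement happens to read GT-AG while the true junction is a
  minor class, the calibrated score genuinely prefers the junk (observed
  at a rate of roughly one coverage-1 false junction per few hundred
  junction-spanning reads on the synthetic benchmark).  Coverage-aware
  post-filtering would remove these at the cost of the single-read
  sensitivity the method is designed for.
* Minor-class calibration needs annotation scale: with fewer than ~20
  GC-AG/AT-AC training examples the pooled prior dominates.
* One junction per read: reads crossing two introns report the better one.
* Trans-splicing (fragments on different chromosomes or strands) is not
  predicted.
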