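# Methods

Conventions, algorithms, defaults and limitations of the `irscape`
pipeline. All internal coordinates are 0-based half-open; annotation TSVs
carry 1-based anchor positions; BED is 0-based half-open and GFF3 1-based
inclusive.

## IR scanning

An IR is `(start, end, R, S)` with left arm `[start, start+R)`, spacer of
length `S`, right arm `[end-R, end)`, and the right arm equal to the
reverse complement of the left. Reported IRs satisfy `R >= 5`,
`0 <= S <= 8`, `2R + S >= 13`.

* **Pairing**: `A:T` and `G:C` only. `N` is encoded with a sentinel
  complement so it never pairs: arms cannot cross an `N`, but an `N` inside
  the spacer is legal (spacer bases do not pair).
* **Maximality**: an IR is reported only if the flanking bases
  `(start-1, end)` do not pair (or the sequence ends). This is checked on
  the interval, so every reported IR is outward-maximal.
* **Equal intervals**: one interval can be read with several `(R, S)`
  decompositions (e.g. `A7T7` as R7S0, R6S2, R5S4). The largest arm, then
  the smallest spacer, is kept.
* **Containment pruning**: an IR whose interval lies strictly inside
  another reported IR's interval is dropped; only outermost IRs remain.
* **Center**: `start + (end - start - 1) // 2` — for even-length IRs the
  left of the two middle bases.

The production scanner is vectorized (per-spacer index compaction,
~0.6 s/Mb); the test suite checks it exhaustively against an independent
brute-force enumeration of every `(start, R, S)` triple
(`tests/reference.py`), plus strand-symmetry and arm-complementarity
properties.

## Sequence-type classification

Only one arm needs classifying (the other is its reverse complement, and
the label is invariant — tested). Features of an arm of length `L`:

* `at_content` — fraction of A/T bases; AT-rich iff `>= 0.6`.
* `tract_occupancy` — length of the longest run of `A{3,}` or `T{3,}`
  divided by `L`; tract-rich iff `>= 0.5`. Runs shorter than 3 score 0.
* `alt_occupancy` — length of the longest `(AT)+` or `(TA)+` match
  divided by `L`, counted in complete dinucleotide units (always even;
  `"ATA"` scores 2); alternating-rich iff `>= 0.5`.

Flag triple `(at, tract, alt)` to type: TTT→I, TTF→II, TFT→III, TFF→IV,
FTF→V, FTT→VI, FFT→VI, FFF→VII. The mapping is total and exclusive: every
arm gets exactly one type.

## Genome partition

A protein-coding gene is four anchors: TSS, start codon (first base), stop
codon (third base), poly(A) site. In gene orientation: 5'-UTR
`[tss, start_codon)`, ORF `[start_codon, stop_codon]`, 3'-UTR
`(stop_codon, polya]`. Genes lacking TSS or poly(A) ("no clear ends") keep
their ORF but are excluded from UTR profiling and intergenic construction.

* **OUR regions**: pairwise UTR–UTR overlaps of adjacent genes — OUR1
  (5'/5'), OUR2 (3'/5'), OUR3 (3'/3'). Plain UTR regions are trimmed so
  OUR segments replace the overlapped parts.
* **Intergenic regions**: between the facing transcript ends of adjacent
  clear-ended genes, excluding both anchor bases (which belong to the
  UTRs). Labels by flanking strands: (+,+) and (−,−) → TAN (tandem),
  (+,−) → CON (convergent), (−,+) → DIV (divergent). Intergenic stretches
  overlapping a user-supplied excluded feature (tRNA/rRNA genes,
  pseudogenes, …) are dropped.
* **Offsets**: `relative_offset(pos, anchor, gene)` is `pos - anchor` for
  `+` genes and `anchor - pos` for `-` genes; positive = downstream.
* **Length groups**: regions sorted by length into `k = 5` equal-count
  groups (remainder spread over the shortest groups); the shortest group is
  dropped and the rest named Q1..Q4.

## Positional enrichment

IR centers are counted in 10-bp bins of anchored offset across all
same-kind regions. Two span regimes:

* **Variable-span kinds** (UTR5, UTR3, OUR*): the window equals the kind's
  mean length (rounded up to the bin width), placed on the region side of
  the anchor (for poly(A) anchors the window is `(-width, +10)` so the
  anchor bin is included); only regions *longer than the mean* are
  retained, so every retained region covers the full span.
* **Fixed-window kinds** (ORF, TAN, DIV, CON): a 200-bp window from the
  bounding anchor into the region, all regions retained. Intergenic panels
  are anchored by side (`left`/`right` bounding anchor).

**Null model**: each chromosome is tiled into merged-ORF (coding) and
complementary (noncoding) segments; bases are permuted uniformly within
each segment. Boundaries, lengths and per-segment base counts are
conserved exactly, so annotations carry over. 100 control genomes
(seeds `seed+1 .. seed+100`) are each re-scanned and binned identically.

**Significance**: the real bin count is pooled with its 100 controls
(N = 101) and tested with the Grubbs statistic
`G = |x_test - mean| / sd` (sd with `ddof=1`) against
`G_crit = ((N-1)/sqrt(N)) * sqrt(t^2 / (N-2+t^2))`,
`t = t_{1-alpha/N, N-2}`, at α = 0.01 and 0.001; the call direction is the
sign of the deviation, and an all-equal bin (sd = 0) is not significant.
The worked identity: count 10 against 100 zero controls gives G = 9.9504,
significant at 0.001. No multiple-testing correction is applied across
bins. Note that `G_crit` is the one-sided critical value: it calibrates
the *extreme studentized deviate* (sample maximum) at rate ≈ α, which is
what the Monte-Carlo calibration test checks; a designated i.i.d. datum
tested against the same threshold would reject at ≈ 2α/N.

## Nucleosome occupancy (nNuOc)

Calls from any source (MNase-seq, chemical cleavage) are consumed as BED
intervals and reduced to union-coverage binary tracks. For each IR center:
take the ±200 bp window, skip it if truncated by a chromosome end or if
the chromosome mean occupancy is zero, divide by the chromosome mean,
flip if the owning gene is on `-`, and average per offset. IRs are
attributed to genes via the region partition (default: IRs whose center
lies in a 3'-UTR); an optional filter keeps only genes flanking a CON
intergenic region, avoiding promoter-proximal depletion of downstream
tandem genes in the average. Grouping by type, arm length or Q group is
done by filtering the classified IR table first.

## Synthetic genomes

`default_config(seed)` gives 2 chromosomes × 100 genes (~0.9 Mb):
truncated-normal lengths, 5'-UTR (70 ± 20, min 25), ORF (1536 ± 400, min
300), 3'-UTR (120 ± 35, min 70), intergenic gaps (2800 ± 700, min 400),
i.i.d. background at AT fraction 0.62, orientation weights TAN/DIV/CON =
0.5/0.25/0.25 realized as a strand Markov chain. The intergenic mean is
chosen so 200 genes fill ~1 Mb; real yeast is gene-denser, so the
synthetic intergenic fraction is deliberately larger than yeast's.

Planted IRs (defaults: type III R8S0 at poly(A) −60..−31 in 70% of genes,
type II R7S0 at −20..−10 in 50%, type VII R6S3 at start codon +30..+60 in
50%) are written so the scanner must recover them exactly:

* arms come from per-type recipes validated against the classifier at
  generation time — arithmetically infeasible `(type, length)` combos
  raise (e.g. type I at R=5; type VI at R=10, where the shortest
  half-covering alternation already makes the arm AT-rich);
* plant configs must satisfy the scanner thresholds including
  `2R + S >= 13` — a shorter plant could never be reported;
* the flanking bases are redrawn until non-pairing (outward maximality)
  and the outermost spacer pair until non-pairing (blocks a larger-arm
  reading of the same interval);
* each locus is re-scanned locally after planting; if a chance background
  IR contains the plant, the flanks are redrawn (up to 60 attempts —
  homopolymer arms merge with an adjacent background A/T into a containing
  IR roughly half the time per attempt).

Planted loci keep >= 90 bp apart, so a type II plant is silently skipped
when a type III plant already sits nearby; truth tables record exactly
what was planted. Nucleosome calls are phased 147-bp intervals with 20-bp
linkers, per-condition Gaussian start jitter, and depletion windows
(anchored on planted IRs of selected types, or on gene anchors) that
remove any overlapping call with a configurable probability; realization
is recorded per window and condition in the truth table.

## Numerical and reproducibility choices

* Sequences are uint8 code arrays (A,C,G,T,N = 0..4); complementation is a
  table lookup with a non-pairing sentinel for N.
* All randomness flows through `numpy.random.default_rng(seed)`; control
  genome `i` uses seed `seed + i`. Identical configs give byte-identical
  outputs, and every CLI stage writes a manifest with config, seeds and
  SHA-256 checksums.
* CLI configs are strict YAML: unknown keys are rejected rather than
  ignored. An absent `simulate` section means the canonical default
  conditions (including plants); pass `plants: []` for an unplanted
  genome.

## Limitations

* Only perfect (mismatch-free) IRs are found; bulged or mismatched stems
  are out of scope.
* The synthetic background is i.i.d.; real genomes have dinucleotide and
  isochore structure, so absolute IR densities differ from real data even
  at matched AT content.
* Types IV–VI are rare under the default background (few arms are
  tract-rich or alternating without being AT-rich), so type-resolved
  panels for them need targeted planting.
* Per-bin significance is uncorrected across bins by design; interpret
  panel-wide patterns, not isolated single-bin calls.
* Analyses of real genomes require externally produced annotation
  (anchors incl. TSS/poly(A)) and nucleosome-call files; no downloader is
  included.
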