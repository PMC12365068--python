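# Methods

This note documents the models, conventions and numerical choices behind
`splitprobe`, and what its synthetic data can and cannot show about real
libraries.

## Library structure and coordinate conventions

All coordinates are 0-based, half-open. The read-1 barcode layout is
defined in *reverse-complement space* — the orientation in which the three
well barcodes read 5'→3':

```
PAD(s) + CATTCG + BC1 + revcomp(linker1) + BC2 + revcomp(linker2) + BC3 + TAIL(3-s)
```

with `linker1 = CTCAAGCACGTGGATAGTCGTACGCCGATG` (30 nt) and
`linker2 = CGAAACATCGGCCAC` (15 nt); the sequenced read 1 (75 nt) is the
reverse complement of this, and `s ∈ {0..3}` is the stagger that
diversifies base composition during sequencing. The construction pins the
anchors at reverse-complement positions `s+1` (ATTCG), `s+35` (TGCTTGAG,
the last 8 nt of revcomp(linker1)) and `s+59` (GTTTCG, the last 6 nt of
revcomp(linker2)); after trimming the `s+6`-base prefix the barcodes sit at
the fixed slices [0,7), [37,44), [59,66). Read 2 is
`left 30-mer + right 30-mer + UMI(8) + handle(7)`. The handle standing in
for the round-1 ligation handle is arbitrary and configurable; the
pipeline never reads past the UMI.

The cell barcode (CBC) is the 21-nt concatenation BC1+BC2+BC3 in
reverse-complement-space orientation, for every strategy, so strategies
are directly comparable. Three rounds of 96 barcodes give 96³ = 884,736
possible paths.

## Demultiplexing strategies

**anchor** searches each anchor in its window ([0,25), [35,57), [57,end)
on the reverse-complemented read), takes the 9 (rounds 1–2) or 7 (round 3)
bases after it, and requires exactly one *distinct* whitelist 7-mer among
the scanned offsets — the same entry found at two offsets counts once,
since exclusion is meant for ambiguity between candidate barcodes.
Leftmost anchor occurrence wins (tie-break chosen here; the true anchor
always precedes any coincidental match in the constructed layout).
**fixed** trims the stagger by locating CATTCG in the first 10 bases of
the reverse complement, slices the fixed positions, and matches each
slice against its whitelist within edit distance 2, requiring a strictly
unique best match. **linker** aligns the two linkers as infixes of the
native read (edit budgets 4 and 2, leftmost best location) and accepts
only exact whitelist membership of the flanking 7-mers. Edit distances use
edlib (NW mode for whitelist matching, HW infix mode for linker location).

A consequence worth knowing: at a 1% substitution rate the fixed strategy
calls the most reads (~94%) because only 6 context bases must be exact;
the linker strategy (~79%) requires the 21 barcode bases exact but absorbs
linker errors in its alignment budgets; the anchor strategy (~67%)
requires ~40 bases (19 anchor + 21 barcode) to be error-free. On
error-free reads all three agree exactly.

## Probe matching and specificity

Read-2 targeting regions are matched independently against the panel's
left and right 30-mer whitelists within Hamming distance 2 (unique best
match; indel errors therefore fall to unmatched). This enumerates the same
left × right combination space as aligning against an index of every
combination, so nonspecific ligations — combinations not designed
adjacent — remain countable. UMI collapse deduplicates on
(CBC, left id, right id, UMI) exactly; no UMI error clustering is
attempted.

The specificity index considers only the 30 nt centered on the ligation
junction (last 15 of the left probe + first 15 of the right probe),
enumerates its 16 overlapping 15-mers, and counts occurrences of their
RNA-side sequences across all transcripts with every transcript weighted
1, overlaps and multiple sites per transcript included. The 16 window
counts are aggregated as a ratio of sums rather than a mean of ratios,
which is robust to zero-count windows. A probe whose center window occurs
nowhere is flagged unevaluable rather than scored. Melting temperature is
deliberately not modeled; CG content over the 60-mer is the proxy. Panel
selection keeps candidates passing the junction rule (first two bases of
the right target in {A,T} — SplintR ligase disfavors C/G at the junction),
a CG window and a specificity threshold, then picks k probes at maximal
spacing (exhaustive max–min-gap search with larger-span then lexicographic
tie-breaks up to 5000 combinations, evenly-spaced-position heuristic
beyond).

## Synthetic data: what it emulates and what it does not

The generator draws per-cell transcript counts T ~ Poisson(N) per gene and
per-copy, per-probe Bernoulli(e) detections (mechanistic mode), or
per-probe counts ~ Poisson(N·e) directly (model-faithful mode, under which
mean = variance = N n e exactly). Doublets are modeled as the split-pool
collision mechanism: a configured fraction of barcode paths host two
complete cells (D groups with D/(#CBCs) equal to the configured fraction).
Barcode hopping replaces one round's barcode on a read with a different
whitelist entry. Nonspecific ligation replaces a molecule's left/right
combination with a random non-adjacent one at the configured rate.
Sequencing errors are independent per-base substitutions; qualities are
constant because the pipeline never uses them. Stagger pads are random
bases, redrawn when a draw would create a spurious anchor occurrence ahead
of the real one. The generator reports reads whose extraction window
coincidentally contains a second whitelist 7-mer (an unavoidable whitelist
collision the extractor must reject as multi-match), so round-trip checks
can exclude exactly those.

Not modeled: indels in sequencing, PCR chimeras, ambient RNA, quality
score structure, cell-size variation beyond Poisson sampling, or the
library variant with five extra random nucleotides 3' of the well barcode
(representable only via custom window offsets in `BarcodeSchema`).
Passing round-trip tests therefore demonstrates the pipeline's logic and
bookkeeping, not robustness to every artifact of real libraries.

## Detection-noise model

With N transcripts/cell, n detection chances and efficiency e:
C = N n e, Noise_C = √C, SNR = √C; M = C/n = N e, Noise_M = √(M/n) + b,
SNR_M = M/Noise_M. The √(Nne) noise treats per-probe detections as
independent Poisson events; the mechanistic compound-binomial variance is
N n e (1 − e + n e), larger for n > 1. Both simulation modes are exposed
so either assumption can be tested; the model-faithful mode satisfies the
equations exactly.

`min_detectable_N` solves √(N n e) = threshold, N* = threshold²/(n e).
Two conventions are exposed because N* is generally fractional: `truncate`
takes the integer part (e = 0.45 → N* = 8.89 → 8, matching the commonly
quoted limit) and `strict` returns the smallest integer whose SNR actually
reaches the threshold (9). Truncation is the default.

`fit_baseline_b` holds M at its experimentally determined value (the
through-origin slope of UMIs/cell versus n) and fits only b ≥ 0 by least
squares. The objective is quadratic in b, so the constrained optimum is
the mean residual clipped at zero; a bounded scalar minimization is run as
a cross-check and any disagreement is logged.

`subsample_snr` first scales every cell by median(total)/total over the
*whole panel* (isolating measurement noise from cell-size differences),
then for each n draws n probes with replacement, sums their per-cell
counts, and records mean (signal), SD across cells (noise) and their
ratio (the expression SNR: mean expression UMIs/cell/n over the SD of
expression, which equals mean/SD of the sums). Default 10,000 replicates;
tests and examples use a few hundred with fixed seeds. Two caveats
follow from the procedure itself: with-replacement draws can repeat a
probe, inflating the variance of the sum by ≈ (1 + (n−1)/P) for P
available probes, and normalization anticorrelates the normalized counts
at n near the panel size — so model agreement is evaluated through the
fitted M and b and the low-n SNR rather than point-wise at large n.

## Cell calling and QC conventions

The percentile rule takes the top `expected_cells` CBCs by UMI total
("top set" is not defined more precisely by the protocol, so it is the
expected cell count by default and configurable to all CBCs), computes
10% of their 99th percentile, and retains CBCs at or above it. The knee
alternative automates "visually setting the threshold at the first knee"
as the largest drop of log-total against log-rank.

Mixing statistics call a CBC cross-species when it has ≥ 2 UMIs from each
species ("multiple probes", threshold configurable). With exactly two
approximately equal populations the doublet rate is 2× the cross-species
fraction; otherwise the general correction cross/(1 − Σp²) is applied and
logged as an extension. Sequencing saturation is 1 − UMIs/reads, the
standard definition. Bulk tiling replicates are each scaled to sum exactly
200; per-cell tiling scales each cell to the population median total, which
preserves within-cell probe proportions exactly. Collision probability for
n cells over B paths is 1 − (1 − 1/B)^(n−1).

## Problem sizes

Defaults in tests and examples are chosen to exercise every code path at
interactive speed: 48–96 barcodes per round, panels of 3–18 probe pairs,
200–800 simulated cells (500 for the round-trip suite), 10⁵ cells for
moment checks of the count distributions, and 200–500 bootstrap
replicates. All stochastic steps take explicit seeds and are reproducible
byte-for-byte, including gzipped FASTQ output (fixed gzip mtime).

## Known limitations

Probe matching assumes substitution-only errors in targeting regions;
reads with indels there are dropped. The specificity index uses exact
15-mer occurrence counts, not the penalty-weighted lookup of full-genome
design pipelines, and toy transcriptomes only — it is not a genome-scale
designer. The knee caller picks the single largest log-drop and can be
unstable on small or flat rank curves; the percentile rule is the default
for simulations. The linker strategy takes the leftmost best alignment;
adversarial reads with two equally good linker placements are resolved
arbitrarily rather than excluded.
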