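# splitprobe

A toolkit for split-pool barcoded split-probe ligation sequencing — a
targeted, microfluidics-free approach to single-cell RNA profiling in which
pairs of ssDNA half-probes hybridize adjacently on a transcript, are joined
by SplintR ligase (active on DNA–RNA hybrids), and are then labeled with a
three-round combinatorial cell barcode by split-pool ligation and PCR.

The package implements the complete computational side of such an
experiment:

- **Probe design** — tile transcripts with 60-nt split-probe windows and
  score candidates by the junction base rule, CG content, and a
  junction-centered 15-mer **specificity index** (on-target occurrences /
  total occurrences across the transcriptome, all transcripts weighted
  equally).
- **Read simulation** — ground-truthed paired FASTQ generation with the
  exact library layout (75-nt read 1: stagger + anchors + linkers + three
  7-nt well barcodes; 75-nt read 2: left/right 30-mers + 8-nt UMI),
  including doublets, barcode hopping, nonspecific ligations and
  sequencing errors.
- **Demultiplexing** — three interchangeable cell-barcode strategies:
  anchor search, fixed-position slicing with edit-distance-2 rescue, and
  linker alignment with exact whitelist matching.
- **Counting** — Hamming-distance probe matching on read 2, ligation
  specificity classification (left/right combinations not designed to be
  adjacent are nonspecific), UMI collapse on (cell, probe pair, UMI), sparse
  MatrixMarket output, and percentile/knee cell calling.
- **QC** — barnyard mixing/doublet statistics, barcode-collision
  arithmetic, nonspecific-ligation rate, sequencing saturation, tiling
  normalization, probe-subsampling correlation, k-mer coverage profiles.
- **Noise model** — the multi-probe detection model and its bootstrap.

## The detection-noise model

Detection of each transcript by each probe is a binomial trial. With N
transcripts per cell (Poisson), n detection chances (probes) per
transcript, and per-chance efficiency e, the expected UMI count is

    C = N n e,    Noise_C = √(N n e),    SNR = √(N n e)

and on the expression scale M = C/n = N e,

    Noise_M = √(M/n) + b,    SNR_M = M / (√(M/n) + b)

where b is a constant baseline SD absorbing biological cell-to-cell
heterogeneity. Because signal grows linearly with n while noise grows as
√n, multiple probes per transcript linearly amplify the signal: at
e = 0.45 and an SNR threshold of 2 a single detection chance reliably
detects ≥ 8 RNAs/cell, at e = 0.10 only ≥ 40, while three probes at
e = 0.2 already reach ≥ 7.

## Worked example

`examples/` contains one narrative script per capability. For instance the
barnyard QC example simulates an equal human/mouse mix with 5% of barcode
paths shared by two cells and recovers the doublet rate from the
cross-species fraction:

```
$ python examples/04_species_mixing_qc.py
cells with UMIs: 742
cross-species fraction: 0.030
estimated doublet rate: 0.059 (injected 0.05)
median single-cell purity: 1.000
nonspecific ligations: 0.20% of UMIs per cell (injected 0.20%)
expected collision rate, 22k cells / 884736 paths: 0.0246
```

In an equal two-species mix only half the doublets are cross-species, so
the doublet rate is twice the cross-species fraction; 96³ = 884,736
possible barcode paths give ~22k cells a 2.46% chance of sharing a path.
The model example prints the detection limits and the two simulation
modes:

```
$ python examples/05_snr_model.py
e=0.45, single detection chance -> >= 8 RNAs/cell
e=0.10, single detection chance -> >= 40 RNAs/cell
e=0.20 with 3 probes -> >= 7 RNAs/cell (linear amplification)
poisson    : mean=8.01 var=8.09
mechanistic: mean=8.00 var=12.82
...
fitted M = 2.00 (truth N*e = 2.0), baseline b = 0.000
```

A thin CLI mirrors the stages (`splitprobe design|simulate|extract|count|
qc|model|run`); see `splitprobe --help`.

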