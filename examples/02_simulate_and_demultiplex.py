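"""Simulate a sequencing run and compare the three barcode strategies.

Generates 200 cells of ground-truthed paired reads at a 0.5% per-base
substitution error rate, then demultiplexes read 1 with the anchor-search,
fixed-position and linker-alignment strategies.
"""

import numpy as np

import splitprobe as sp

rng = np.random.default_rng(1)
schema = sp.default_schema(rng, n_per_round=96)

manifest = []
for g in range(4):
    seq = "".join(rng.choice(list("ACGT"), 180))
    manifest += sp.tile_transcript(f"t{g}", f"gene{g}", seq)

config = sp.SimConfig(
    populations=[sp.Population("cells", manifest, n_cells=200,
                               mean_transcripts=5.0)],
    schema=schema,
    efficiency=0.3,
    error_rate=0.005,
    seed=7,
)
reads, truths, stats = sp.simulate_reads(config)
print(f"simulated {stats['n_reads']} reads from {stats['n_cells']} cells")

report = sp.compare_strategies(reads, schema)
for strategy, row in report["strategies"].items():
    print(
        f"  {strategy:6s}: {row['pct_reads_called']:5.1f}% reads called, "
        f"{row['n_unique_cbc']} unique cell barcodes"
    )
# the fixed strategy rescues barcodes within edit distance 2, so it calls
# the most reads; the two exact-barcode strategies lose reads with errors
# in the bases each requires to be error-free.
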