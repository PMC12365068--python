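"""Full counting pipeline: probe matching, UMI collapse, cell calling.

Takes an error-free simulation through barcode extraction, probe/UMI
identification, UMI deduplication, matrix construction and the
10%-of-99th-percentile cell-calling rule.
"""

import numpy as np

import splitprobe as sp

rng = np.random.default_rng(2)
schema = sp.default_schema(rng, n_per_round=96)
manifest = []
for g in range(3):
    seq = "".join(rng.choice(list("ACGT"), 240))
    manifest += sp.tile_transcript(f"t{g}", f"gene{g}", seq)

config = sp.SimConfig(
    populations=[sp.Population("cells", manifest, 300, 6.0)],
    schema=schema, efficiency=0.4,
    mean_reads_per_molecule=2.0,  # PCR duplicates so saturation is nonzero
    seed=11,
)
reads, truths, stats = sp.simulate_reads(config)

calls = sp.extract_barcodes(reads, schema, "anchor")
matcher = sp.ProbeMatcher(manifest)
records, funnel = sp.reads_to_molecules(reads, calls, matcher)
molecules = sp.collapse_umis(records)
probe_matrix = sp.build_matrices(molecules, manifest, mode="tiling")
gene_matrix = sp.aggregate_genes(probe_matrix, manifest)

print(f"reads: {funnel['n_reads']}, barcode called: "
      f"{funnel['pct_barcode_called']:.1f}%, probe matched: "
      f"{funnel['pct_probe_matched']:.1f}%")
print(f"molecules after UMI collapse: {len(molecules)}")
print(f"saturation: {sp.saturation(funnel['n_probe_matched'], len(molecules)):.2f}")

totals = dict(zip(probe_matrix.cell_barcodes, probe_matrix.total_umis_per_cell()))
retained, threshold = sp.call_cells(totals, expected_cells=300)
print(f"cell threshold {threshold:.1f} UMIs -> {len(retained)} cells retained")
print(f"probe matrix {probe_matrix.shape}, gene matrix {gene_matrix.shape}")
# saturation = 1 - UMIs/reads: the fraction of reads that were duplicates
# of molecules already seen.
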