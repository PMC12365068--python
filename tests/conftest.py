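from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import splitprobe as sp

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def schema() -> sp.BarcodeSchema:
    """Default-layout schema with three 48-entry whitelists."""
    rng = np.random.default_rng(2024)
    return sp.default_schema(rng, n_per_round=48)


def make_manifest(tag: str, n_genes: int, rng, transcript_len: int = 180):
    """Toy manifest: n_genes random transcripts, fully tiled (3 pairs each)."""
    pairs = []
    for g in range(n_genes):
        seq = "".join(rng.choice(list("ACGT"), size=transcript_len))
        pairs.extend(sp.tile_transcript(f"{tag}T{g}", f"{tag}G{g}", seq))
    return pairs


@pytest.fixture(scope="session")
def toy_manifest():
    rng = np.random.default_rng(5)
    return make_manifest("hs", 3, rng)


@pytest.fixture(scope="session")
def clean_sim(schema):
    """Error-free two-population simulation shared across extraction and
    counting round-trip tests."""
    rng = np.random.default_rng(99)
    pops = [
        sp.Population("human", make_manifest("hs", 3, rng), 40, 4.0),
        sp.Population("mouse", make_manifest("mm", 3, rng), 40, 4.0),
    ]
    config = sp.SimConfig(
        populations=pops,
        schema=schema,
        efficiency=0.5,
        error_rate=0.0,
        seed=7,
    )
    reads, truths, stats = sp.simulate_reads(config)
    return config, reads, truths, stats
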