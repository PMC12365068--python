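"""Mixing/doublet statistics, collision arithmetic, saturation,
tiling normalization, probe subsampling and k-mer coverage."""

from __future__ import annotations

import numpy as np
import pytest
import scipy.sparse as sps
from hypothesis import given
from hypothesis import strategies as st

import splitprobe as sp


def species_matrix(n_single_a, n_single_b, n_cross, umis=10):
    """Toy two-species matrix: pure cells plus cross-species cells."""
    features = ["ha", "hb", "ma", "mb"]
    smap = {"ha": "human", "hb": "human", "ma": "mouse", "mb": "mouse"}
    rows = []
    for _ in range(n_single_a):
        rows.append([umis, umis, 0, 0])
    for _ in range(n_single_b):
        rows.append([0, 0, umis, umis])
    for _ in range(n_cross):
        rows.append([umis, 0, umis, 0])
    barcodes = [f"c{i:05d}" for i in range(len(rows))]
    m = sp.CountMatrix(barcodes, features, sps.csr_matrix(np.array(rows)))
    return m, smap


class TestMixingStats:
    def test_cross_fraction_doubles_to_doublet_rate(self):
        m, smap = species_matrix(491, 491, 18)  # 18/1000 cross
        rep = sp.mixing_stats(m, smap)
        assert rep.cross_species_fraction == pytest.approx(0.018)
        assert rep.doublet_rate == pytest.approx(0.036)

    def test_zero_cross(self):
        m, smap = species_matrix(50, 50, 0)
        rep = sp.mixing_stats(m, smap)
        assert rep.cross_species_fraction == 0.0
        assert rep.median_purity == 1.0

    def test_min_umi_threshold(self):
        # one stray UMI from the other species is not "multiple probes"
        features = ["h", "m"]
        smap = {"h": "human", "m": "mouse"}
        counts = sps.csr_matrix(np.array([[10, 1], [10, 2]]))
        m = sp.CountMatrix(["c1", "c2"], features, counts)
        rep = sp.mixing_stats(m, smap, min_umis_per_species=2)
        assert rep.cross_species_fraction == pytest.approx(0.5)

    def test_single_species_raises(self):
        features = ["h1", "h2"]
        m = sp.CountMatrix(
            ["c1"], features, sps.csr_matrix(np.array([[1, 2]]))
        )
        with pytest.raises(ValueError, match="two species"):
            sp.mixing_stats(m, {"h1": "human", "h2": "human"})

    @pytest.mark.parametrize("seed", range(5))
    def test_recovers_injected_doublet_fraction(self, schema, seed):
        """Cross-species doubling recovers the generator's doublet fraction."""
        rng = np.random.default_rng(100 + seed)
        mk = lambda tag: [
            p
            for g in range(2)
            for p in sp.tile_transcript(
                f"{tag}T{g}", f"{tag}G{g}",
                "".join(rng.choice(list("ACGT"), 120)),
            )
        ]
        pops = [
            sp.Population("human", mk("hs"), 300, 6.0),
            sp.Population("mouse", mk("mm"), 300, 6.0),
        ]
        cfg = sp.SimConfig(
            pops, schema, efficiency=0.6, doublet_fraction=0.06,
            seed=1000 + seed,
        )
        reads, _truths, _stats = sp.simulate_reads(cfg)
        manifest = pops[0].manifest + pops[1].manifest
        matcher = sp.ProbeMatcher(manifest)
        calls = sp.extract_barcodes(reads, schema, "anchor")
        records, _ = sp.reads_to_molecules(reads, calls, matcher)
        pm = sp.build_matrices(sp.collapse_umis(records), manifest, "tiling")
        smap = {
            p.probe_pair_id: pop.name for pop in pops for p in pop.manifest
        }
        rep = sp.mixing_stats(pm, smap)
        d = 0.06
        n = rep.n_cells
        se = np.sqrt((d / 2) * (1 - d / 2) / n)
        assert abs(rep.cross_species_fraction - d / 2) < 3 * se


class TestCollisionRate:
    def test_single_cell_zero(self):
        assert sp.expected_collision_rate(1, 884736) == 0.0

    def test_barnyard_scale(self):
        # 96^3 barcode paths; ~22k cells give ~2.46% expected multiples
        assert sp.expected_collision_rate(22000, 96**3) == pytest.approx(
            0.0246, abs=2e-4
        )

    @given(
        n=st.integers(min_value=1, max_value=10_000),
        b=st.integers(min_value=2, max_value=10**6),
    )
    def test_monotonicity(self, n, b):
        r = sp.expected_collision_rate
        assert r(n + 1, b) >= r(n, b)
        assert r(n, b + 1) <= r(n, b)


class TestNonspecificFraction:
    def _panel_matrix(self, ns_count, sp_count):
        features = ["p1", "ns:a/L|b/R"]
        counts = sps.csr_matrix(np.array([[sp_count, ns_count]]))
        return sp.CountMatrix(["c" * 21], features, counts)

    def test_all_nonspecific(self):
        rep = sp.nonspecific_fraction(self._panel_matrix(5, 0))
        assert rep["mean_pct"] == 100.0

    def test_zero_rate(self):
        rep = sp.nonspecific_fraction(self._panel_matrix(0, 5))
        assert rep["mean_pct"] == 0.0 and rep["fold_specific_over_nonspecific"] == np.inf

    def test_recovers_injected_rate(self, schema, toy_manifest):
        pop = sp.Population("s", toy_manifest, 400, 8.0)
        rate = 0.02
        cfg = sp.SimConfig(
            [pop], schema, efficiency=0.6,
            nonspecific_ligation_rate=rate, seed=70,
        )
        reads, _, stats = sp.simulate_reads(cfg)
        calls = sp.extract_barcodes(reads, schema, "anchor")
        matcher = sp.ProbeMatcher(toy_manifest)
        records, _ = sp.reads_to_molecules(reads, calls, matcher)
        pm = sp.build_matrices(sp.collapse_umis(records), toy_manifest, "panel")
        rep = sp.nonspecific_fraction(pm)
        n_mol = stats["n_molecules"]
        se = 100 * np.sqrt(rate * (1 - rate) / n_mol)
        assert abs(rep["mean_pct"] - 100 * rate) < 3 * se + 0.2


class TestSaturation:
    @pytest.mark.parametrize(
        "reads,umis,expected", [(1000, 200, 0.8), (100, 100, 0.0), (50, 0, 1.0)]
    )
    def test_values(self, reads, umis, expected):
        assert sp.saturation(reads, umis) == pytest.approx(expected)

    def test_zero_reads_raises(self):
        with pytest.raises(ValueError):
            sp.saturation(0, 0)


class TestTilingNormalization:
    def test_cell_scale_factors(self):
        counts = sps.csr_matrix(np.array([[50, 50], [150, 150]]))
        m = sp.CountMatrix(["c1", "c2"], ["p1", "p2"], counts)
        out = sp.tiling_normalize_cells(m, ["p1", "p2"])
        # totals 100 and 300, median 200 -> factors 2.0 and 2/3
        assert np.allclose(out["traces"][0], [100, 100])
        assert np.allclose(out["traces"][1], [100, 100])
        assert out["median_total"] == 200

    def test_proportions_preserved(self, schema, clean_sim):
        cfg, reads, _t, _s = clean_sim
        manifest = [p for pop in cfg.populations for p in pop.manifest]
        matcher = sp.ProbeMatcher(manifest)
        calls = sp.extract_barcodes(reads, schema, "anchor")
        records, _ = sp.reads_to_molecules(reads, calls, matcher)
        pm = sp.build_matrices(sp.collapse_umis(records), manifest, "tiling")
        probes = [p.probe_pair_id for p in manifest if p.transcript_id == "hsT0"]
        out = sp.tiling_normalize_cells(pm, probes)
        raw = pm.counts[:, [pm.features.index(p) for p in probes]].toarray()
        raw = raw[raw.sum(axis=1) > 0].astype(float)
        props_raw = raw / raw.sum(axis=1, keepdims=True)
        props_norm = out["traces"] / out["traces"].sum(axis=1, keepdims=True)
        assert np.allclose(props_raw, props_norm)

    def test_single_cell_keeps_own_total(self):
        m = sp.CountMatrix(
            ["c1"], ["p1", "p2"], sps.csr_matrix(np.array([[30, 10]]))
        )
        out = sp.tiling_normalize_cells(m, ["p1", "p2"])
        assert out["traces"].sum() == pytest.approx(40)

    def test_bulk_sums_to_200_exactly(self):
        reps = np.array([[100.0, 300.0], [40.0, 60.0], [1.0, 3.0]])
        out = sp.tiling_normalize_bulk(reps)
        assert np.allclose(out["normalized"].sum(axis=1), 200.0)

    def test_bulk_halves_a_400_sum(self):
        out = sp.tiling_normalize_bulk(np.array([[100.0, 300.0]]))
        assert np.allclose(out["normalized"], [[50.0, 150.0]])

    def test_identical_replicates_zero_sd(self):
        reps = np.array([[10.0, 30.0]] * 3)
        out = sp.tiling_normalize_bulk(reps)
        assert np.allclose(out["probe_sd"], 0.0)

    def test_zero_sum_replicate_raises(self):
        with pytest.raises(ValueError):
            sp.tiling_normalize_bulk(np.array([[0.0, 0.0]]))


@pytest.fixture(scope="module")
def counted(schema):
    """Simulated five-gene tiling panel, counted through the pipeline."""
    rng = np.random.default_rng(80)
    pairs = []
    means = {}
    for g, mean in enumerate([2.0, 5.0, 9.0, 14.0, 20.0]):
        seq = "".join(rng.choice(list("ACGT"), 180))
        pairs.extend(sp.tile_transcript(f"T{g}", f"G{g}", seq))
        means[f"G{g}"] = mean
    pop = sp.Population("s", pairs, 200, means)
    cfg = sp.SimConfig([pop], schema, efficiency=0.5, seed=81)
    reads, _, _ = sp.simulate_reads(cfg)
    calls = sp.extract_barcodes(reads, schema, "anchor")
    matcher = sp.ProbeMatcher(pairs)
    records, _ = sp.reads_to_molecules(reads, calls, matcher)
    pm = sp.build_matrices(sp.collapse_umis(records), pairs, "tiling")
    return pm, pairs, means


class TestProbeSubsampling:
    def test_full_panel_r_is_deterministic(self, counted):
        pm, pairs, means = counted
        rs = sp.probe_subsample_correlation(pm, pairs, k=3, reference=means, reps=5)
        assert np.allclose(rs, rs[0])  # k = all probes -> every rep identical

    def test_median_r_increases_with_k(self, counted):
        pm, pairs, means = counted
        medians = [
            float(np.median(
                sp.probe_subsample_correlation(
                    pm, pairs, k=k, reference=means, reps=200, seed=7
                )
            ))
            for k in (1, 2, 3)
        ]
        assert medians[0] <= medians[1] + 1e-6 <= medians[2] + 2e-6

    def test_same_seed_identical(self, counted):
        pm, pairs, means = counted
        a = sp.probe_subsample_correlation(pm, pairs, 2, means, reps=50, seed=3)
        b = sp.probe_subsample_correlation(pm, pairs, 2, means, reps=50, seed=3)
        assert np.array_equal(a, b)


class TestKmerCoverage:
    def test_full_length_reads_cover_everything(self):
        t = "ACGTACGTACGTACGTACGTACGTA"
        prof = sp.kmer_coverage_profile(t, [t, t], k=20)
        assert np.allclose(prof, 1.0)

    def test_truncated_reads_zero_at_three_prime(self):
        rng = np.random.default_rng(90)
        t = "".join(rng.choice(list("ACGT"), 100))
        reads = [t[:50]] * 10  # only the 5' half sequenced
        prof = sp.kmer_coverage_profile(t, reads, k=20)
        assert np.allclose(prof[:31], 1.0)  # k-mers fully inside [0,50)
        assert np.allclose(prof[50:], 0.0)

    def test_k_longer_than_transcript_raises(self):
        with pytest.raises(ValueError):
            sp.kmer_coverage_profile("ACGT", ["ACGT"], k=20)

    def test_empty_reads_raise(self):
        with pytest.raises(ValueError):
            sp.kmer_coverage_profile("A" * 30, [], k=20)
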