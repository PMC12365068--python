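"""Cell-barcode calling: anchor, fixed-position and linker strategies."""

from __future__ import annotations

import numpy as np
import pytest

import splitprobe as sp
from splitprobe.extract import STRATEGIES


def make_read(schema, stagger=1):
    bc1, bc2, bc3 = (
        sorted(schema.whitelist1)[0],
        sorted(schema.whitelist2)[0],
        sorted(schema.whitelist3)[0],
    )
    return bc1 + bc2 + bc3, sp.layout_read1(bc1, bc2, bc3, stagger, schema)


class TestAnchorStrategy:
    @pytest.mark.parametrize("stagger", [0, 1, 2, 3])
    def test_recovers_true_cbc(self, schema, stagger):
        cbc, read1 = make_read(schema, stagger)
        call = sp.extract_anchor(read1, schema)
        assert call.called and call.cbc == cbc

    def test_destroyed_anchor_excluded(self, schema):
        _, read1 = make_read(schema)
        rc = sp.reverse_complement(read1)
        pos = rc.index(schema.anchor1)
        broken = rc[:pos] + "GGGGG" + rc[pos + 5 :]
        call = sp.extract_anchor(sp.reverse_complement(broken), schema)
        assert not call.called and call.failure_reason == "no_anchor"

    def test_multi_match_window_excluded(self):
        """Two overlapping whitelist 7-mers inside one 9-base window."""
        rng = np.random.default_rng(50)
        wl2 = sp.random_whitelist(8, rng)
        wl3 = sp.random_whitelist(8, rng)
        # window 1 is BC1 + "CA" (first two bases of the reverse-complemented
        # linker); with BC1=AAAAAAA both AAAAAAA and AAAAAAC are present
        schema = sp.BarcodeSchema(
            whitelist1=frozenset({"AAAAAAA", "AAAAAAC"}),
            whitelist2=wl2,
            whitelist3=wl3,
        )
        read1 = sp.layout_read1(
            "AAAAAAA", sorted(wl2)[0], sorted(wl3)[0], 0, schema
        )
        call = sp.extract_anchor(read1, schema)
        assert not call.called and call.failure_reason == "multi_match"

    def test_never_returns_off_whitelist_barcode(self, schema, toy_manifest):
        pop = sp.Population("s", toy_manifest, 30, 3.0)
        cfg = sp.SimConfig(
            [pop], schema, efficiency=0.5, error_rate=0.02, seed=51
        )
        reads, _, _ = sp.simulate_reads(cfg)
        for rp in reads:
            call = sp.extract_anchor(rp.read1, schema)
            if call.called:
                assert call.bc1 in schema.whitelist1
                assert call.bc2 in schema.whitelist2
                assert call.bc3 in schema.whitelist3

    def test_short_read_excluded(self, schema):
        call = sp.extract_anchor("ACGT" * 10, schema)
        assert call.failure_reason == "no_anchor"


class TestTrimStagger:
    def test_removes_pad_and_context(self, schema):
        cbc, read1 = make_read(schema, stagger=3)
        trimmed = sp.trim_stagger(read1, schema)
        assert trimmed == sp.reverse_complement(read1)[9:]
        assert trimmed[0:7] == cbc[0:7]

    def test_scrambled_read_untrimmable(self, schema):
        rng = np.random.default_rng(52)
        junk = "".join(rng.choice(list("ACGT"), size=75))
        assert sp.trim_stagger(junk, schema) is None or "CATTCG" in sp.reverse_complement(junk)[:10]


class TestFixedStrategy:
    def test_recovers_true_cbc(self, schema):
        cbc, read1 = make_read(schema, 2)
        call = sp.extract_fixed(read1, schema)
        assert call.cbc == cbc

    def test_one_substitution_corrected(self):
        """Edit-distance-2 matching is unambiguous when whitelist entries are
        at least Hamming distance 5 apart."""
        rng = np.random.default_rng(53)
        schema = sp.BarcodeSchema(
            whitelist1=sp.random_whitelist(8, rng, min_dist=5),
            whitelist2=sp.random_whitelist(8, rng, min_dist=5),
            whitelist3=sp.random_whitelist(8, rng, min_dist=5),
        )
        cbc, read1 = make_read(schema, 1)
        rc = sp.reverse_complement(read1)
        # substitute inside BC2 (revcomp-space positions [44, 51) at stagger 1)
        pos = 1 + 43 + 3
        sub = "A" if rc[pos] != "A" else "C"
        mutated = sp.reverse_complement(rc[:pos] + sub + rc[pos + 1 :])
        call = sp.extract_fixed(mutated, schema)
        assert call.cbc == cbc

    def test_equidistant_whitelist_entries_ambiguous(self):
        rng = np.random.default_rng(54)
        wl2 = sp.random_whitelist(4, rng, min_dist=5)
        wl3 = sp.random_whitelist(4, rng, min_dist=5)
        schema = sp.BarcodeSchema(
            whitelist1=frozenset({"AAAAAAA", "CCAAAAA"}),
            whitelist2=wl2,
            whitelist3=wl3,
        )
        # ACAAAAA is edit distance 1 from both whitelist entries
        read1 = sp.layout_read1(
            "AAAAAAA", sorted(wl2)[0], sorted(wl3)[0], 0, schema
        )
        rc = sp.reverse_complement(read1)
        rc = rc[:6] + "ACAAAAA" + rc[13:]
        call = sp.extract_fixed(sp.reverse_complement(rc), schema)
        assert not call.called and call.failure_reason == "multi_match"

    def test_untrimmable_excluded(self, schema):
        call = sp.extract_fixed("G" * 75, schema)
        assert not call.called and call.failure_reason == "no_anchor"


class TestLinkerStrategy:
    def test_recovers_true_cbc(self, schema):
        cbc, read1 = make_read(schema, 2)
        call = sp.extract_linker(read1, schema)
        assert call.cbc == cbc

    def test_linker_budget_exceeded(self, schema):
        """Six spread substitutions in linker 1 exceed the budget of 4."""
        cbc, read1 = make_read(schema, 0)
        start = read1.index(schema.linker1_read1)
        region = list(read1[start : start + 30])
        flip = {"A": "C", "C": "A", "G": "T", "T": "G"}
        for i in (0, 5, 10, 15, 20, 25):
            region[i] = flip[region[i]]
        mutated = read1[:start] + "".join(region) + read1[start + 30 :]
        call = sp.extract_linker(mutated, schema)
        assert not call.called

    def test_barcode_substitution_not_rescued(self, schema):
        """Linker strategy accepts exact whitelist matches only."""
        cbc, read1 = make_read(schema, 0)
        start = read1.index(schema.linker1_read1)
        end = start + len(schema.linker1_read1)
        bc1_slice = read1[end : end + 7]  # revcomp(BC1) in native orientation
        sub = "A" if bc1_slice[3] != "A" else "C"
        mutated = read1[: end + 3] + sub + read1[end + 4 :]
        call = sp.extract_linker(mutated, schema)
        assert not call.called


class TestCrossStrategy:
    def test_all_strategies_agree_on_clean_reads(self, schema, clean_sim):
        _cfg, reads, truths, _stats = clean_sim
        subset = reads[:300]
        truth_subset = truths[:300]
        for rp, t in zip(subset, truth_subset):
            if t.ambiguous_window:
                continue
            calls = {s: sp.extract_barcodes([rp], schema, s)[0] for s in STRATEGIES}
            assert all(c.called for c in calls.values()), calls
            assert {c.cbc for c in calls.values()} == {t.cbc}

    def test_compare_strategies_clean(self, schema, clean_sim):
        _cfg, reads, _truths, stats = clean_sim
        report = sp.compare_strategies(reads[:200], schema)
        if stats["ambiguous_window_reads"] == 0:
            for s in STRATEGIES:
                assert report["strategies"][s]["pct_reads_called"] == 100.0
            sizes = {report["strategies"][s]["n_unique_cbc"] for s in STRATEGIES}
            assert len(sizes) == 1

    def test_call_rate_ordering_with_errors(self, schema, toy_manifest):
        """Substitution errors: the fixed strategy's edit-distance-2 barcode
        rescue calls the most reads; the two exact-barcode strategies lose
        reads roughly in proportion to the bases they require error-free."""
        pop = sp.Population("s", toy_manifest, 150, 4.0)
        cfg = sp.SimConfig(
            [pop], schema, efficiency=0.5, error_rate=0.01, seed=55
        )
        reads, _, _ = sp.simulate_reads(cfg)
        report = sp.compare_strategies(reads, schema)
        rates = {s: report["strategies"][s]["pct_reads_called"] for s in STRATEGIES}
        assert rates["fixed"] >= rates["anchor"]
        assert rates["fixed"] >= rates["linker"]
        # anchor demands ~40 error-free bases (19 anchor + 21 barcode);
        # linker only the 21 barcode bases, its alignment budgets absorbing
        # linker errors, so anchor loses more reads at this error rate
        assert rates["linker"] >= rates["anchor"]

    def test_empty_input(self, schema):
        report = sp.compare_strategies([], schema)
        assert report["n_reads"] == 0
        for s in STRATEGIES:
            assert report["strategies"][s]["pct_reads_called"] == 0.0
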