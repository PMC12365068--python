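"""Three interchangeable strategies for calling the three-round cell barcode
from read 1.

``anchor``  — search each anchor sequence in its window on the reverse
              complement of the read and scan the bases after it for exactly
              one whitelist 7-mer (the pipeline's native strategy).
``fixed``   — trim the stagger by locating the CATTCG context, then slice
              the barcodes at fixed positions and match each against its
              whitelist within edit distance 2 (unique best).
``linker``  — locate the two linkers by infix alignment on the native read
              (edit budgets 4 and 2) and take the flanking 7-mers; exact
              whitelist membership only.

All strategies emit the same reverse-complement-space CBC so their outputs
are directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import edlib

from .schema import BarcodeSchema, ReadPair, reverse_complement

STRATEGIES = ("anchor", "fixed", "linker")


@dataclass(frozen=True)
class BarcodeCall:
    cbc: str | None
    bc1: str | None = None
    bc2: str | None = None
    bc3: str | None = None
    strategy: str = "anchor"
    failure_reason: str = "none"  # no_anchor | no_match | multi_match | none

    @property
    def called(self) -> bool:
        return self.cbc is not None


def _find_anchor(seq: str, anchor: str, window: tuple[int, int]) -> int:
    """Leftmost anchor start within [window[0], window[1]); -1 if absent."""
    start, stop = window
    if stop == -1:
        stop = len(seq)
    # python find's end bound is the slice end; allow starts < stop
    return seq.find(anchor, start, stop - 1 + len(anchor))


def _scan_whitelist(window: str, whitelist: frozenset[str], bc_len: int) -> tuple[str | None, str]:
    """Scan the 7-mer substrings of a window; require exactly one distinct
    whitelist entry (the same entry at two offsets counts once)."""
    hits = {
        window[o : o + bc_len]
        for o in range(len(window) - bc_len + 1)
    } & whitelist
    if len(hits) == 1:
        return next(iter(hits)), "none"
    if not hits:
        return None, "no_match"
    return None, "multi_match"


def extract_anchor(read1: str, schema: BarcodeSchema) -> BarcodeCall:
    """Anchor-search barcode extraction on the reverse complement of read 1."""
    if len(read1) < 66:
        return BarcodeCall(None, strategy="anchor", failure_reason="no_anchor")
    rc = reverse_complement(read1)
    spec = (
        (schema.anchor1, schema.search_window1, schema.extract_len1, schema.whitelist1),
        (schema.anchor2, schema.search_window2, schema.extract_len2, schema.whitelist2),
        (schema.anchor3, schema.search_window3, schema.extract_len3, schema.whitelist3),
    )
    bcs: list[str] = []
    for anchor, window, extract_len, whitelist in spec:
        pos = _find_anchor(rc, anchor, window)
        if pos == -1:
            return BarcodeCall(None, strategy="anchor", failure_reason="no_anchor")
        chunk = rc[pos + len(anchor) : pos + len(anchor) + extract_len]
        if extract_len == schema.barcode_len:
            # round 3: the extracted bases must themselves be a whitelist entry
            if chunk in whitelist:
                bc, reason = chunk, "none"
            else:
                bc, reason = None, "no_match"
        else:
            bc, reason = _scan_whitelist(chunk, whitelist, schema.barcode_len)
        if bc is None:
            return BarcodeCall(None, strategy="anchor", failure_reason=reason)
        bcs.append(bc)
    return BarcodeCall("".join(bcs), *bcs, strategy="anchor")


def trim_stagger(read1: str, schema: BarcodeSchema) -> str | None:
    """Reverse-complement read 1 and drop the stagger pad plus the CATTCG
    context (emulating 3' adapter trimming); None when untrimmable."""
    rc = reverse_complement(read1)
    ctx = schema.trim_context
    pos = rc.find(ctx, 0, 10)
    if pos == -1:
        return None
    return rc[pos + len(ctx) :]


def _match_edit(
    query: str, whitelist: Sequence[str], max_dist: int = 2
) -> tuple[str | None, str]:
    """Unique best whitelist match within edit distance ``max_dist``.

    Strictly-smaller-than-runner-up required; ties are excluded."""
    if query in whitelist:
        # an exact hit can still tie with another entry at distance 0 only if
        # whitelist entries are duplicated, which the schema forbids
        return query, "none"
    best: str | None = None
    best_d = max_dist + 1
    tie = False
    for entry in whitelist:
        d = edlib.align(query, entry, mode="NW", k=max_dist)["editDistance"]
        if d == -1:
            continue
        if d < best_d:
            best, best_d, tie = entry, d, False
        elif d == best_d:
            tie = True
    if best is None:
        return None, "no_match"
    if tie:
        return None, "multi_match"
    return best, "none"


def extract_fixed(read1: str, schema: BarcodeSchema) -> BarcodeCall:
    """Fixed-position extraction with edit-distance-2 whitelist matching."""
    trimmed = trim_stagger(read1, schema)
    if trimmed is None:
        return BarcodeCall(None, strategy="fixed", failure_reason="no_anchor")
    slices = (schema.fixed_bc1, schema.fixed_bc2, schema.fixed_bc3)
    whitelists = schema.whitelists
    bcs: list[str] = []
    for (lo, hi), whitelist in zip(slices, whitelists):
        if len(trimmed) < hi:
            return BarcodeCall(None, strategy="fixed", failure_reason="no_anchor")
        bc, reason = _match_edit(trimmed[lo:hi], sorted(whitelist))
        if bc is None:
            return BarcodeCall(None, strategy="fixed", failure_reason=reason)
        bcs.append(bc)
    return BarcodeCall("".join(bcs), *bcs, strategy="fixed")


def _locate_linker(read: str, linker: str, budget: int) -> tuple[int, int] | None:
    """Best infix alignment of a linker (edit distance <= budget); returns
    (start, end_exclusive) of the leftmost best hit, or None."""
    res = edlib.align(linker, read, mode="HW", task="locations", k=budget)
    if res["editDistance"] == -1 or not res["locations"]:
        return None
    start, end = res["locations"][0]
    if start is None:
        start = 0
    return start, end + 1


def extract_linker(read1: str, schema: BarcodeSchema) -> BarcodeCall:
    """Linker-alignment extraction on the native read orientation.

    BC2/BC1 flank linker 1 (upstream/downstream), BC3 sits upstream of
    linker 2; extracted 7-mers are reverse-complemented into whitelist
    orientation and must match exactly.
    """
    loc1 = _locate_linker(read1, schema.linker1_read1, budget=4)
    if loc1 is None:
        return BarcodeCall(None, strategy="linker", failure_reason="no_anchor")
    start1, end1 = loc1
    loc2 = _locate_linker(read1, schema.linker2_read1, budget=2)
    if loc2 is None:
        return BarcodeCall(None, strategy="linker", failure_reason="no_anchor")
    start2, _end2 = loc2
    bl = schema.barcode_len
    if start1 < bl or end1 + bl > len(read1) or start2 < bl:
        return BarcodeCall(None, strategy="linker", failure_reason="no_match")
    bc2 = reverse_complement(read1[start1 - bl : start1])
    bc1 = reverse_complement(read1[end1 : end1 + bl])
    bc3 = reverse_complement(read1[start2 - bl : start2])
    if (
        bc1 not in schema.whitelist1
        or bc2 not in schema.whitelist2
        or bc3 not in schema.whitelist3
    ):
        return BarcodeCall(None, strategy="linker", failure_reason="no_match")
    return BarcodeCall(bc1 + bc2 + bc3, bc1, bc2, bc3, strategy="linker")


_EXTRACTORS = {
    "anchor": extract_anchor,
    "fixed": extract_fixed,
    "linker": extract_linker,
}


def extract_barcodes(
    reads: Iterable[ReadPair], schema: BarcodeSchema, strategy: str = "anchor"
) -> list[BarcodeCall]:
    try:
        fn = _EXTRACTORS[strategy]
    except KeyError:
        raise ValueError(f"unknown strategy {strategy!r}") from None
    return [fn(rp.read1, schema) for rp in reads]


def compare_strategies(
    reads: Sequence[ReadPair], schema: BarcodeSchema
) -> dict:
    """Per-strategy call rate, unique-CBC count, and pairwise CBC overlap."""
    calls = {s: extract_barcodes(reads, schema, s) for s in STRATEGIES}
    n = len(reads)
    report: dict = {"n_reads": n, "strategies": {}, "pairwise_cbc_overlap": {}}
    cbc_sets: dict[str, set[str]] = {}
    for s, cs in calls.items():
        called = [c for c in cs if c.called]
        cbc_sets[s] = {c.cbc for c in called}
        report["strategies"][s] = {
            "pct_reads_called": 100.0 * len(called) / n if n else 0.0,
            "n_unique_cbc": len(cbc_sets[s]),
        }
    for i, a in enumerate(STRATEGIES):
        for b in STRATEGIES[i + 1 :]:
            report["pairwise_cbc_overlap"][f"{a}~{b}"] = len(
                cbc_sets[a] & cbc_sets[b]
            )
    return report
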