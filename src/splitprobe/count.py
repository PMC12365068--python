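"""Probe-pair identification on read 2, ligation-specificity classification,
UMI collapse, count-matrix construction, and cell calling.

Read 2 carries the ligated probe: bases [0,30) are the left targeting
region, [30,60) the right targeting region, [60,68) the 8-nt UMI.  The two
30-mers are matched independently against the panel's left/right target
whitelists within Hamming distance 2 (unique best match); this enumerates
the same left x right combination space as aligning to an index of every
combination, so nonspecific ligations (combinations not designed to be
adjacent) remain countable.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import scipy.sparse as sp

from .extract import BarcodeCall
from .schema import CountMatrix, ReadPair, SplitProbePair

logger = logging.getLogger("splitprobe")

NONSPECIFIC_PREFIX = "ns:"


@dataclass(frozen=True)
class MoleculeRecord:
    cbc: str
    left_id: str
    right_id: str
    pair_class: str  # specific | nonspecific
    umi: str


class ProbeMatcher:
    """Hamming-distance matcher for the two 30-nt targeting regions."""

    def __init__(self, manifest: Sequence[SplitProbePair], max_dist: int = 2):
        self.max_dist = max_dist
        self.manifest = list(manifest)
        self.adjacency = {(p.left_id, p.right_id) for p in self.manifest}
        self._left = self._build([(p.left_target, p.left_id) for p in self.manifest])
        self._right = self._build(
            [(p.right_target, p.right_id) for p in self.manifest]
        )

    @staticmethod
    def _build(entries: list[tuple[str, str]]):
        exact: dict[str, str | None] = {}
        seqs, ids = [], []
        for seq, pid in entries:
            if seq in exact:
                if exact[seq] != pid:
                    exact[seq] = None  # same 30-mer shared by two probes: ambiguous
                continue
            exact[seq] = pid
            seqs.append(seq)
            ids.append(pid)
        mat = np.frombuffer("".join(seqs).encode(), dtype="S1").reshape(
            len(seqs), -1
        )
        return exact, mat, ids

    def _match_side(self, query: str, side) -> str | None:
        exact, mat, ids = side
        if query in exact:
            return exact[query]
        q = np.frombuffer(query.encode(), dtype="S1")
        if q.shape[0] != mat.shape[1]:
            return None
        dists = (mat != q).sum(axis=1)
        best = int(dists.min(initial=self.max_dist + 1))
        if best > self.max_dist:
            return None
        hits = np.nonzero(dists == best)[0]
        if len(hits) != 1:
            return None  # ambiguous: two targets at equal minimal distance
        return ids[int(hits[0])]

    def match_left(self, seq30: str) -> str | None:
        return self._match_side(seq30, self._left)

    def match_right(self, seq30: str) -> str | None:
        return self._match_side(seq30, self._right)


def match_targeting_regions(
    read2: str, matcher: ProbeMatcher, umi_length: int = 8
) -> tuple[str, str, str] | None:
    """(left_id, right_id, umi) from read 2, or None when unmatched."""
    if len(read2) < 60 + umi_length:
        return None
    left = matcher.match_left(read2[0:30])
    if left is None:
        return None
    right = matcher.match_right(read2[30:60])
    if right is None:
        return None
    return left, right, read2[60 : 60 + umi_length]


def classify_ligation(
    left_id: str, right_id: str, adjacency: set[tuple[str, str]]
) -> str:
    return "specific" if (left_id, right_id) in adjacency else "nonspecific"


def reads_to_molecules(
    reads: Iterable[ReadPair],
    calls: Iterable[BarcodeCall],
    matcher: ProbeMatcher,
    umi_length: int = 8,
) -> tuple[list[MoleculeRecord], dict]:
    """Join barcode calls with probe/UMI identification; returns raw
    (pre-collapse) molecule records plus a funnel summary."""
    records: list[MoleculeRecord] = []
    n_reads = n_called = n_matched = 0
    for rp, call in zip(reads, calls):
        n_reads += 1
        if not call.called:
            continue
        n_called += 1
        hit = match_targeting_regions(rp.read2, matcher, umi_length)
        if hit is None:
            continue
        n_matched += 1
        left, right, umi = hit
        records.append(
            MoleculeRecord(
                call.cbc, left, right,
                classify_ligation(left, right, matcher.adjacency), umi,
            )
        )
    stats = {
        "n_reads": n_reads,
        "n_barcode_called": n_called,
        "n_probe_matched": n_matched,
        "pct_barcode_called": 100.0 * n_called / n_reads if n_reads else 0.0,
        "pct_probe_matched": 100.0 * n_matched / n_reads if n_reads else 0.0,
    }
    return records, stats


def collapse_umis(records: Iterable[MoleculeRecord]) -> list[MoleculeRecord]:
    """Deduplicate on (cbc, left_id, right_id, umi); idempotent."""
    seen: dict[tuple[str, str, str, str], MoleculeRecord] = {}
    for r in records:
        seen.setdefault((r.cbc, r.left_id, r.right_id, r.umi), r)
    return list(seen.values())


def build_matrices(
    molecules: Iterable[MoleculeRecord],
    manifest: Sequence[SplitProbePair],
    mode: str = "tiling",
) -> CountMatrix:
    """Probe-level UMI count matrix.

    ``tiling`` mode drops nonspecific molecules; ``panel`` mode keeps them
    as extra ``ns:left|right`` features so the nonspecific-ligation rate can
    be computed downstream.
    """
    if mode not in ("tiling", "panel"):
        raise ValueError(f"unknown mode {mode!r}")
    pair_of = {(p.left_id, p.right_id): p.probe_pair_id for p in manifest}
    counts: Counter[tuple[str, str]] = Counter()
    for m in molecules:
        if m.pair_class == "specific":
            feature = pair_of[(m.left_id, m.right_id)]
        elif mode == "panel":
            feature = f"{NONSPECIFIC_PREFIX}{m.left_id}|{m.right_id}"
        else:
            continue
        counts[(m.cbc, feature)] += 1
    features = [p.probe_pair_id for p in manifest]
    if mode == "panel":
        extra = sorted(
            {f for (_, f) in counts if f.startswith(NONSPECIFIC_PREFIX)}
        )
        features = features + extra
    barcodes = sorted({cbc for (cbc, _) in counts})
    f_idx = {f: j for j, f in enumerate(features)}
    b_idx = {b: i for i, b in enumerate(barcodes)}
    if counts:
        rows, cols, data = zip(
            *((b_idx[b], f_idx[f], c) for (b, f), c in counts.items())
        )
    else:
        rows = cols = data = ()
    mat = sp.coo_matrix(
        (data, (rows, cols)), shape=(len(barcodes), len(features)), dtype=np.int64
    )
    return CountMatrix(barcodes, features, mat, level="probe")


def aggregate_genes(
    matrix: CountMatrix, manifest: Sequence[SplitProbePair]
) -> CountMatrix:
    """Gene-level matrix: sum of each gene's specific probe-pair columns."""
    gene_of = {p.probe_pair_id: p.gene_id for p in manifest}
    genes = sorted({p.gene_id for p in manifest})
    g_idx = {g: j for j, g in enumerate(genes)}
    indicator = sp.lil_matrix((len(matrix.features), len(genes)), dtype=np.int64)
    for j, f in enumerate(matrix.features):
        if f in gene_of:
            indicator[j, g_idx[gene_of[f]]] = 1
    gene_counts = matrix.counts @ indicator.tocsr()
    return CountMatrix(list(matrix.cell_barcodes), genes, gene_counts, level="gene")


def call_cells(
    umi_totals: Mapping[str, int],
    expected_cells: int | None = None,
    method: str = "percentile",
    top_set: str = "expected",
) -> tuple[set[str], float]:
    """Select real-cell barcodes from per-CBC UMI totals.

    ``percentile``: threshold = 10% of the 99th percentile of the top-set
    totals, where the top set is the highest-``expected_cells`` CBCs
    (``top_set='expected'``) or every CBC (``top_set='all'``).  ``knee``:
    automated largest drop of log-total against log-rank.
    Returns (retained CBCs, threshold).
    """
    items = sorted(umi_totals.items(), key=lambda kv: (-kv[1], kv[0]))
    if not items:
        return set(), 0.0
    totals = np.array([v for _, v in items], dtype=float)
    if method == "percentile":
        if top_set == "all" or expected_cells is None:
            top = totals
        else:
            if expected_cells > len(totals):
                logger.warning(
                    "expected %d cells but only %d CBCs observed; using all",
                    expected_cells,
                    len(totals),
                )
            top = totals[:expected_cells]
        threshold = 0.10 * float(np.percentile(top, 99))
    elif method == "knee":
        if len(totals) < 2:
            threshold = 0.0
        else:
            pos = totals > 0
            t = totals[pos]
            ranks = np.arange(1, len(t) + 1, dtype=float)
            slopes = np.diff(np.log10(t)) / np.diff(np.log10(ranks + 0.0) + 1e-12)
            with np.errstate(invalid="ignore"):
                knee = int(np.nanargmin(slopes))
            threshold = float(t[knee])
    else:
        raise ValueError(f"unknown method {method!r}")
    retained = {cbc for cbc, v in items if v >= threshold}
    return retained, threshold
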