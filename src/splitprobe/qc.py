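"""Quality-control analyses: species-mixing/doublet statistics, barcode
collision arithmetic, nonspecific-ligation rate, sequencing saturation,
tiling normalization, probe-subsampling correlation, and k-mer coverage
profiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import scipy.stats

from .count import NONSPECIFIC_PREFIX
from .schema import CountMatrix, SplitProbePair

logger = logging.getLogger("splitprobe")


@dataclass(frozen=True)
class MixingReport:
    n_cells: int
    cross_species_fraction: float
    doublet_rate: float
    median_purity: float
    species_fractions: dict


def mixing_stats(
    matrix: CountMatrix,
    species_map: Mapping[str, str],
    min_umis_per_species: int = 2,
) -> MixingReport:
    """Species-mixing statistics for a barnyard-style experiment.

    A CBC is cross-species when it carries at least ``min_umis_per_species``
    UMIs from each species.  With exactly two species in (approximately)
    equal proportions the doublet rate is twice the cross-species fraction —
    same-species doublets are invisible; otherwise the general correction
    cross_fraction / (1 - sum p_i^2) is applied.
    """
    species = sorted(set(species_map.values()))
    if len(species) < 2:
        raise ValueError("mixing statistics require at least two species")
    s_idx = {s: i for i, s in enumerate(species)}
    col_species = np.array(
        [s_idx.get(species_map.get(f, ""), -1) for f in matrix.features]
    )
    dense_by_species = np.zeros((matrix.shape[0], len(species)))
    for i, s in enumerate(species):
        cols = np.nonzero(col_species == i)[0]
        dense_by_species[:, i] = np.asarray(
            matrix.counts[:, cols].sum(axis=1)
        ).ravel()
    totals = dense_by_species.sum(axis=1)
    keep = totals > 0
    dense_by_species = dense_by_species[keep]
    totals = totals[keep]
    n_cells = int(keep.sum())
    if n_cells == 0:
        raise ValueError("no cells with UMIs")
    cross = np.all(dense_by_species >= min_umis_per_species, axis=1)
    cross_fraction = float(cross.mean())
    majority = dense_by_species.argmax(axis=1)
    p = np.bincount(majority, minlength=len(species)) / n_cells
    if len(species) == 2 and abs(p[0] - 0.5) < 0.1:
        doublet_rate = 2.0 * cross_fraction
    else:
        denom = 1.0 - float((p**2).sum())
        doublet_rate = cross_fraction / denom if denom > 0 else float("nan")
        logger.info(
            "unequal/multi-species mix: using general collision correction "
            "1/(1 - sum p^2) = %.3f", 1.0 / denom if denom > 0 else float("nan")
        )
    purity = dense_by_species.max(axis=1) / totals
    return MixingReport(
        n_cells=n_cells,
        cross_species_fraction=cross_fraction,
        doublet_rate=doublet_rate,
        median_purity=float(np.median(purity)),
        species_fractions={s: float(p[i]) for s, i in s_idx.items()},
    )


def expected_collision_rate(n_cells: int, n_barcodes: int) -> float:
    """Probability a given cell shares its barcode path with >= 1 other cell
    when ``n_cells`` cells draw uniformly from ``n_barcodes`` paths."""
    if n_cells < 1 or n_barcodes < 1:
        raise ValueError("n_cells and n_barcodes must be >= 1")
    return 1.0 - (1.0 - 1.0 / n_barcodes) ** (n_cells - 1)


def nonspecific_fraction(matrix: CountMatrix) -> dict:
    """Per-cell nonspecific-ligation UMI fraction from a panel-mode matrix.

    Nonspecific features carry the ``ns:`` prefix.  Cells with zero UMIs are
    skipped.  Also reports the aggregate specific:nonspecific fold ratio.
    """
    is_ns = np.array(
        [f.startswith(NONSPECIFIC_PREFIX) for f in matrix.features]
    )
    ns_umis = np.asarray(
        matrix.counts[:, np.nonzero(is_ns)[0]].sum(axis=1)
    ).ravel()
    totals = matrix.total_umis_per_cell()
    keep = totals > 0
    frac = ns_umis[keep] / totals[keep]
    total_ns = float(ns_umis[keep].sum())
    total_specific = float(totals[keep].sum() - total_ns)
    return {
        "per_cell_pct": 100.0 * frac,
        "mean_pct": float(100.0 * frac.mean()) if frac.size else 0.0,
        "fold_specific_over_nonspecific": (
            total_specific / total_ns if total_ns > 0 else float("inf")
        ),
        "n_cells": int(keep.sum()),
    }


def saturation(total_reads: int, total_umis: int) -> float:
    """Sequencing saturation, 1 - UMIs/reads."""
    if total_reads <= 0:
        raise ValueError("total_reads must be > 0")
    if total_umis > total_reads:
        raise ValueError("more UMIs than reads")
    return 1.0 - total_umis / total_reads


def tiling_normalize_cells(
    matrix: CountMatrix, probe_ids: Sequence[str]
) -> dict:
    """Per-cell median normalization of one transcript's tiling probes.

    Each cell's probe vector is scaled so its sum equals the population
    median total; scaling preserves within-cell probe proportions exactly.
    Returns normalized traces plus per-probe mean and SD across cells.
    """
    cols = [matrix.features.index(p) for p in probe_ids]
    sub = matrix.counts[:, cols].toarray().astype(float)
    totals = sub.sum(axis=1)
    n_zero = int((totals == 0).sum())
    if n_zero:
        logger.info("excluding %d all-zero cells from tiling normalization", n_zero)
    sub = sub[totals > 0]
    totals = totals[totals > 0]
    if sub.shape[0] == 0:
        raise ValueError("no cells with counts on these probes")
    median_total = float(np.median(totals))
    traces = sub * (median_total / totals)[:, None]
    ddof = 1 if traces.shape[0] > 1 else 0
    return {
        "traces": traces,
        "probe_mean": traces.mean(axis=0),
        "probe_sd": traces.std(axis=0, ddof=ddof),
        "median_total": median_total,
        "n_cells": traces.shape[0],
        "n_zero_cells": n_zero,
    }


def tiling_normalize_bulk(replicate_counts: np.ndarray, target: float = 200.0) -> dict:
    """Bulk tiling normalization: each replicate scaled to sum ``target``
    (200 by convention); per-probe SD across replicates."""
    reps = np.asarray(replicate_counts, dtype=float)
    if reps.ndim == 1:
        reps = reps[None, :]
    sums = reps.sum(axis=1)
    if np.any(sums == 0):
        raise ValueError("zero-sum replicate cannot be normalized")
    normalized = reps * (target / sums)[:, None]
    ddof = 1 if reps.shape[0] > 1 else 0
    return {
        "normalized": normalized,
        "probe_mean": normalized.mean(axis=0),
        "probe_sd": normalized.std(axis=0, ddof=ddof),
    }


def probe_subsample_correlation(
    matrix: CountMatrix,
    manifest: Sequence[SplitProbePair],
    k: int,
    reference: Mapping[str, float],
    reps: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Pearson r between per-gene mean UMIs/cell from ``k`` subsampled
    probes per gene and a per-gene reference, over ``reps`` replicates."""
    rng = np.random.default_rng(seed)
    probes_by_gene: dict[str, list[int]] = {}
    for p in manifest:
        if p.probe_pair_id in matrix.features:
            probes_by_gene.setdefault(p.gene_id, []).append(
                matrix.features.index(p.probe_pair_id)
            )
    genes = [g for g in probes_by_gene if g in reference]
    usable = [g for g in genes if len(probes_by_gene[g]) >= k]
    skipped = set(genes) - set(usable)
    if skipped:
        logger.warning("skipping genes with < %d probes: %s", k, sorted(skipped))
    if len(usable) < 3:
        raise ValueError("need >= 3 usable genes for a correlation")
    ref = np.array([reference[g] for g in usable])
    dense = matrix.counts.toarray().astype(float)
    rs = np.empty(reps)
    for r in range(reps):
        means = np.empty(len(usable))
        for gi, g in enumerate(usable):
            cols = rng.choice(probes_by_gene[g], size=k, replace=False)
            means[gi] = dense[:, cols].sum(axis=1).mean()
        rs[r] = scipy.stats.pearsonr(means, ref)[0]
    return rs


def kmer_coverage_profile(
    transcript_seq: str, read_seqs: Sequence[str], k: int = 20
) -> np.ndarray:
    """Fraction of reads containing each k-mer of the transcript verbatim.

    Entry i covers transcript positions [i, i+k).
    """
    if k > len(transcript_seq):
        raise ValueError("k longer than the transcript")
    if not read_seqs:
        raise ValueError("empty read set")
    n = len(read_seqs)
    profile = np.zeros(len(transcript_seq) - k + 1)
    for i in range(len(profile)):
        kmer = transcript_seq[i : i + k]
        profile[i] = sum(kmer in r for r in read_seqs) / n
    return profile
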