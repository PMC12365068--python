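"""Split-probe panel design: transcript tiling, junction rule, CG content
and the junction-centered k-mer specificity index.

A split probe covers a 60-nt RNA window.  The right probe hybridizes to the
5'-most 30 nt (its 5'-phosphate sits at the ligation junction) and the left
probe to the 3'-most 30 nt; both targeting sequences are reverse complements
of the RNA.  Specificity is scored on the 30 nt centered on the junction
(last 15 nt of the left probe + first 15 nt of the right probe) by counting
how often each of its 16 overlapping 15-mers occurs across the whole
transcriptome, with every transcript weighted equally (abundance 1):

    specificity = on-target-gene occurrences / total occurrences

summed over the 16 windows.  Melting temperature is deliberately not
modeled; CG content is the proxy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

from .schema import SplitProbePair, reverse_complement

logger = logging.getLogger("splitprobe")

SPECIFICITY_K = 15  # window length for the k-mer specificity index


@dataclass(frozen=True)
class Transcriptome:
    """transcript_id -> (gene_id, RNA sequence in DNA alphabet); abundance 1 each."""

    transcripts: dict[str, tuple[str, str]]

    def __post_init__(self) -> None:
        for tid, (gid, seq) in self.transcripts.items():
            if not seq:
                raise ValueError(f"empty sequence for transcript {tid}")
            if not gid:
                raise ValueError(f"transcript {tid} has no gene id")

    def genes(self) -> set[str]:
        return {gid for gid, _ in self.transcripts.values()}

    def transcripts_of(self, gene_id: str) -> list[str]:
        return [
            tid for tid, (gid, _) in self.transcripts.items() if gid == gene_id
        ]


@dataclass(frozen=True)
class ProbeScore:
    probe_pair_id: str
    specificity: float | None  # None: no occurrences anywhere -> unevaluable
    cg_content: float
    junction_ok: bool

    @property
    def evaluable(self) -> bool:
        return self.specificity is not None


def tile_transcript(
    transcript_id: str,
    gene_id: str,
    sequence: str,
    window: int = 60,
    step: int | None = None,
) -> list[SplitProbePair]:
    """Tile a transcript with 60-nt split-probe windows.

    ``step`` defaults to ``window`` (non-overlapping, complete tiling).
    Transcripts shorter than one window yield an empty list with a warning.
    """
    step = window if step is None else step
    if step < 1:
        raise ValueError("step must be >= 1")
    if window % 2 != 0:
        raise ValueError("window must be even (two half-probes)")
    half = window // 2
    if len(sequence) < window:
        logger.warning(
            "transcript %s (%d nt) shorter than window %d; no probes",
            transcript_id,
            len(sequence),
            window,
        )
        return []
    pairs = []
    tile_index = 0
    for rna_start in range(0, len(sequence) - window + 1, step):
        rna = sequence[rna_start : rna_start + window]
        right = reverse_complement(rna[:half])
        left = reverse_complement(rna[half:])
        pairs.append(
            SplitProbePair(
                probe_pair_id=f"{transcript_id}:t{tile_index}",
                gene_id=gene_id,
                transcript_id=transcript_id,
                tile_index=tile_index,
                left_target=left,
                right_target=right,
                rna_start=rna_start,
            )
        )
        tile_index += 1
    return pairs


def junction_rule(pair: SplitProbePair) -> bool:
    """SplintR ligase prefers A/T in the first two bases 3' of the junction."""
    return pair.right_target[0] in "AT" and pair.right_target[1] in "AT"


def cg_content(pair: SplitProbePair) -> float:
    seq = pair.left_target + pair.right_target
    return (seq.count("C") + seq.count("G")) / len(seq)


def count_occurrences(text: str, pattern: str) -> int:
    """Overlapping occurrence count of ``pattern`` in ``text``."""
    count = 0
    pos = text.find(pattern)
    while pos != -1:
        count += 1
        pos = text.find(pattern, pos + 1)
    return count


def specificity_index(
    pair: SplitProbePair, transcriptome: Transcriptome, target_gene: str
) -> float | None:
    """Junction-centered 15-mer specificity index in [0, 1].

    Enumerates the 16 overlapping 15-mers of the junction-centered 30-mer,
    counts occurrences of their RNA-side sequences (reverse complements)
    across all transcripts — overlaps and multiple sites per transcript
    included, every transcript weighted 1 — and returns the ratio of
    on-target-gene occurrences to total occurrences (ratio of sums).
    Returns None when the total count is zero (unevaluable probe).
    """
    if target_gene not in transcriptome.genes():
        raise ValueError(f"gene {target_gene!r} not in transcriptome")
    rna_center = reverse_complement(pair.center30)
    kmers = [
        rna_center[i : i + SPECIFICITY_K]
        for i in range(len(rna_center) - SPECIFICITY_K + 1)
    ]
    on_target = 0
    total = 0
    for _tid, (gid, seq) in transcriptome.transcripts.items():
        hits = sum(count_occurrences(seq, k) for k in kmers)
        total += hits
        if gid == target_gene:
            on_target += hits
    if total == 0:
        return None
    return on_target / total


def score_probe(
    pair: SplitProbePair, transcriptome: Transcriptome
) -> ProbeScore:
    return ProbeScore(
        probe_pair_id=pair.probe_pair_id,
        specificity=specificity_index(pair, transcriptome, pair.gene_id),
        cg_content=cg_content(pair),
        junction_ok=junction_rule(pair),
    )


def _select_spaced(
    candidates: list[SplitProbePair], k: int, max_combos: int = 5000
) -> list[SplitProbePair]:
    """Pick k candidates spaced maximally along the transcript.

    Exhaustive max-min-gap search (ties: larger span, then lexicographically
    smaller index tuple) while the combination count is small; otherwise an
    evenly-spaced-position heuristic.
    """
    m = len(candidates)
    if k >= m:
        return list(candidates)
    if k == 1:
        return [candidates[(m - 1) // 2]]
    positions = [p.rna_start for p in candidates]

    def n_combos() -> int:
        c = 1
        for i in range(k):
            c = c * (m - i) // (i + 1)
            if c > max_combos:
                return c
        return c

    if n_combos() <= max_combos:
        best = None
        best_key = None
        for idx in combinations(range(m), k):
            gaps = [positions[b] - positions[a] for a, b in zip(idx, idx[1:])]
            key = (min(gaps), positions[idx[-1]] - positions[idx[0]],
                   tuple(-i for i in idx))
            if best_key is None or key > best_key:
                best_key = key
                best = idx
        return [candidates[i] for i in best]
    # heuristic: nearest candidate to each evenly spaced position
    lo, hi = positions[0], positions[-1]
    chosen: list[int] = []
    for i in range(k):
        target = lo + i * (hi - lo) / (k - 1)
        j = min(
            (j for j in range(m) if j not in chosen),
            key=lambda j: abs(positions[j] - target),
        )
        chosen.append(j)
    return [candidates[i] for i in sorted(chosen)]


def design_panel(
    transcriptome: Transcriptome,
    genes: list[str],
    k_probes: int,
    min_specificity: float = 0.9,
    cg_range: tuple[float, float] = (0.0, 1.0),
    window: int = 60,
    step: int | None = None,
    enforce_junction: bool = True,
) -> list[SplitProbePair]:
    """Design up to ``k_probes`` split-probe pairs per transcript.

    Candidates are tiled, filtered by the junction base rule, CG range and
    specificity threshold, then spaced maximally along the transcript.
    Deterministic given inputs; emits fewer than ``k_probes`` with a warning
    when not enough candidates pass.
    """
    missing = set(genes) - transcriptome.genes()
    if missing:
        raise ValueError(f"genes not in transcriptome: {sorted(missing)}")
    panel: list[SplitProbePair] = []
    for gene in genes:
        for tid in transcriptome.transcripts_of(gene):
            _gid, seq = transcriptome.transcripts[tid]
            candidates = []
            for pair in tile_transcript(tid, gene, seq, window=window, step=step):
                if enforce_junction and not junction_rule(pair):
                    continue
                cg = cg_content(pair)
                if not (cg_range[0] <= cg <= cg_range[1]):
                    continue
                spec = specificity_index(pair, transcriptome, gene)
                if spec is None or spec < min_specificity:
                    continue
                candidates.append(pair)
            if len(candidates) < k_probes:
                logger.warning(
                    "transcript %s: only %d/%d candidates pass filters",
                    tid,
                    len(candidates),
                    k_probes,
                )
            panel.extend(_select_spaced(candidates, k_probes))
    return panel
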