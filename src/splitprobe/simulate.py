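"""Synthetic paired-read generator with ground truth.

Emulates the sequencing library structure of split-pool barcoded probe
ligation: read 1 (75 nt) carries the three-round cell barcode embedded in
anchor/linker scaffold with a 0–3 nt stagger; read 2 (75 nt) carries the
ligated probe (left 30-mer + right 30-mer), an 8-nt UMI and a constant
handle.  The generator models per-cell Poisson transcript sampling,
per-probe Bernoulli detection (or a model-faithful Poisson shortcut),
doublets (two cells sharing one barcode path), barcode hopping,
nonspecific ligations, and per-base substitution errors — all under one
seed, byte-reproducibly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import write_fastq_pairs, write_json_report
from .schema import BarcodeSchema, ReadPair, SplitProbePair, reverse_complement

BASES = np.frombuffer(b"ACGT", dtype="S1")

# constant handle 3' of the UMI on read 2 (round-1 ligation handle stand-in;
# arbitrary because the pipeline never reads past the UMI)
DEFAULT_READ2_FILLER = "GGCCACT"


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one emitted read pair."""

    read_id: str
    cbc: str
    cell_id: int
    species: str
    probe_pair_id: str  # designed pair id, or "nonspecific" for mispairings
    left_id: str
    right_id: str
    umi: str
    doublet: bool
    hopped: bool
    stagger: int
    ambiguous_window: bool


@dataclass
class Population:
    """One cell population sharing a probe panel (e.g. one species)."""

    name: str
    manifest: list[SplitProbePair]
    n_cells: int
    mean_transcripts: float | dict[str, float] = 5.0

    def genes(self) -> list[str]:
        seen: dict[str, list[SplitProbePair]] = {}
        for p in self.manifest:
            seen.setdefault(p.gene_id, []).append(p)
        return list(seen)

    def probes_of(self, gene: str) -> list[SplitProbePair]:
        return [p for p in self.manifest if p.gene_id == gene]

    def gene_mean(self, gene: str) -> float:
        if isinstance(self.mean_transcripts, dict):
            return float(self.mean_transcripts[gene])
        return float(self.mean_transcripts)


@dataclass
class SimConfig:
    populations: list[Population]
    schema: BarcodeSchema
    efficiency: float = 0.2
    doublet_fraction: float = 0.0
    barcode_hop_rate: float = 0.0
    nonspecific_ligation_rate: float = 0.0
    stagger_weights: tuple[float, ...] = (0.25, 0.25, 0.25, 0.25)
    error_rate: float = 0.0
    detection_mode: str = "mechanistic"  # or "poisson" (model-faithful)
    mean_reads_per_molecule: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "efficiency",
            "doublet_fraction",
            "barcode_hop_rate",
            "nonspecific_ligation_rate",
            "error_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.efficiency == 0.0:
            raise ValueError("efficiency must be > 0")
        if self.detection_mode not in ("mechanistic", "poisson"):
            raise ValueError(f"unknown detection_mode {self.detection_mode!r}")
        if not self.populations:
            raise ValueError("at least one population required")
        for pop in self.populations:
            if not pop.manifest:
                raise ValueError(f"population {pop.name!r} has an empty probe panel")
        if len(self.stagger_weights) != len(self.schema.stagger_range):
            raise ValueError("stagger_weights must match schema.stagger_range")


def random_whitelist(
    n: int, rng: np.random.Generator, length: int = 7, min_dist: int = 3
) -> frozenset[str]:
    """Random barcode whitelist with minimum pairwise Hamming distance.

    Greedy rejection sampling; raises if the space cannot accommodate n
    entries at the requested distance within the attempt budget.
    """
    kept: list[str] = []
    attempts = 0
    max_attempts = 200_000
    while len(kept) < n:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"could not place {n} barcodes at min Hamming distance {min_dist}"
            )
        cand = "".join(rng.choice(["A", "C", "G", "T"], size=length))
        if all(
            sum(a != b for a, b in zip(cand, k)) >= min_dist for k in kept
        ):
            kept.append(cand)
    return frozenset(kept)


def default_schema(rng: np.random.Generator, n_per_round: int = 96) -> BarcodeSchema:
    """Schema with three freshly drawn 96-entry whitelists (default layout)."""
    return BarcodeSchema(
        whitelist1=random_whitelist(n_per_round, rng),
        whitelist2=random_whitelist(n_per_round, rng),
        whitelist3=random_whitelist(n_per_round, rng),
    )


def layout_read1(
    bc1: str,
    bc2: str,
    bc3: str,
    stagger: int,
    schema: BarcodeSchema,
    pad: str = "",
    tail: str = "",
) -> str:
    """Build one read-1 sequence from three round barcodes and a stagger.

    The reverse-complement-space layout is
    ``PAD(s) + CATTCG + BC1 + revcomp(linker1) + BC2 + revcomp(linker2) +
    BC3 + TAIL(3-s)``; the returned read 1 is its reverse complement.
    ``pad``/``tail`` default to all-A filler of the right lengths.
    """
    for bc in (bc1, bc2, bc3):
        if len(bc) != schema.barcode_len:
            raise ValueError(f"barcode {bc!r} is not {schema.barcode_len} nt")
    max_s = max(schema.stagger_range)
    if stagger not in schema.stagger_range:
        raise ValueError(f"stagger {stagger} outside {schema.stagger_range}")
    pad = pad or "A" * stagger
    tail = tail or "A" * (max_s - stagger)
    if len(pad) != stagger or len(tail) != max_s - stagger:
        raise ValueError("pad/tail lengths inconsistent with stagger")
    revspace = (
        pad
        + schema.trim_context
        + bc1
        + reverse_complement(schema.linker1_read1)
        + bc2
        + reverse_complement(schema.linker2_read1)
        + bc3
        + tail
    )
    assert len(revspace) == schema.read_length
    return reverse_complement(revspace)


def layout_read2(
    pair_left_target: str,
    pair_right_target: str,
    umi: str,
    schema: BarcodeSchema | None = None,
    filler: str = DEFAULT_READ2_FILLER,
) -> str:
    """Read 2: left 30-mer + right 30-mer + 8-nt UMI + constant handle."""
    umi_len = schema.umi_length if schema else 8
    if len(umi) != umi_len:
        raise ValueError(f"UMI {umi!r} is not {umi_len} nt")
    read2 = pair_left_target + pair_right_target + umi + filler
    return read2


def _random_pad(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(["A", "C", "G", "T"], size=length)) if length else ""


def _spurious_anchor(revspace: str, stagger: int, schema: BarcodeSchema) -> bool:
    """True if a pad/tail draw created an anchor occurrence before the real one."""
    w1 = schema.search_window1
    first = revspace.find(schema.anchor1, w1[0], w1[1] + len(schema.anchor1))
    return first != stagger + 1


def _ambiguous_windows(schema: BarcodeSchema) -> tuple[set[str], set[str]]:
    """Round-1/2 barcodes whose 9-base extraction window contains a second
    distinct whitelist 7-mer at scan offsets 1 or 2 (an unavoidable
    whitelist collision the extractor must reject as multi-match)."""
    rc_l1 = reverse_complement(schema.linker1_read1)
    rc_l2 = reverse_complement(schema.linker2_read1)
    ambiguous1 = set()
    for bc in schema.whitelist1:
        window = bc + rc_l1[:2]
        hits = {window[o : o + 7] for o in (0, 1, 2)} & schema.whitelist1
        if len(hits) > 1:
            ambiguous1.add(bc)
    ambiguous2 = set()
    for bc in schema.whitelist2:
        window = bc + rc_l2[:2]
        hits = {window[o : o + 7] for o in (0, 1, 2)} & schema.whitelist2
        if len(hits) > 1:
            ambiguous2.add(bc)
    return ambiguous1, ambiguous2


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate == 0.0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hit = rng.random(len(arr)) < rate
    for i in np.nonzero(hit)[0]:
        choices = BASES[BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode()


def _assign_cbcs(
    cells: list[tuple[int, Population]],
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[dict[int, str], dict[int, bool]]:
    """Assign barcode paths: unique per cell except doublet pairs that share."""
    schema = config.schema
    wl1 = sorted(schema.whitelist1)
    wl2 = sorted(schema.whitelist2)
    wl3 = sorted(schema.whitelist3)
    n_total = len(cells)
    d = config.doublet_fraction
    # D groups of two cells per CBC, so that D / (#CBCs) equals d
    n_doublet_groups = int(round(d * n_total / (1.0 + d)))
    n_cbcs = n_total - n_doublet_groups
    space = len(wl1) * len(wl2) * len(wl3)
    if n_cbcs > space:
        raise ValueError("more cells than possible barcode paths")
    codes = rng.choice(space, size=n_cbcs, replace=False)
    cbcs = []
    for c in codes:
        i, rem = divmod(int(c), len(wl2) * len(wl3))
        j, k = divmod(rem, len(wl3))
        cbcs.append(wl1[i] + wl2[j] + wl3[k])
    order = rng.permutation(n_total)
    cbc_of: dict[int, str] = {}
    is_doublet: dict[int, bool] = {}
    # first 2*D shuffled cells are paired two-per-CBC
    for g in range(n_doublet_groups):
        a, b = order[2 * g], order[2 * g + 1]
        for cell_idx in (a, b):
            cbc_of[cells[cell_idx][0]] = cbcs[g]
            is_doublet[cells[cell_idx][0]] = True
    for offset, cell_idx in enumerate(order[2 * n_doublet_groups :]):
        cbc_of[cells[cell_idx][0]] = cbcs[n_doublet_groups + offset]
        is_doublet[cells[cell_idx][0]] = False
    return cbc_of, is_doublet


def simulate_reads(
    config: SimConfig,
) -> tuple[list[ReadPair], list[TruthRecord], dict]:
    """Run the generator; returns reads, per-read truth, and summary stats."""
    rng = np.random.default_rng(config.seed)
    schema = config.schema
    ambiguous1, ambiguous2 = _ambiguous_windows(schema)
    wl_sorted = [sorted(w) for w in schema.whitelists]

    cells: list[tuple[int, Population]] = []
    cell_id = 0
    for pop in config.populations:
        for _ in range(pop.n_cells):
            cells.append((cell_id, pop))
            cell_id += 1
    cbc_of, is_doublet = _assign_cbcs(cells, config, rng)

    stagger_vals = list(schema.stagger_range)
    weights = np.asarray(config.stagger_weights, dtype=float)
    weights = weights / weights.sum()

    reads: list[ReadPair] = []
    truths: list[TruthRecord] = []
    n_molecules = 0
    n_nonspecific = 0
    n_ambiguous = 0
    read_no = 0
    e = config.efficiency

    for cid, pop in cells:
        cbc = cbc_of[cid]
        molecules: list[tuple[SplitProbePair | tuple, str]] = []
        for gene in pop.genes():
            probes = pop.probes_of(gene)
            mean_n = pop.gene_mean(gene)
            if config.detection_mode == "poisson":
                # model-faithful: per-probe counts ~ Poisson(N*e)
                for probe in probes:
                    k = rng.poisson(mean_n * e)
                    molecules.extend((probe, "") for _ in range(k))
            else:
                t = rng.poisson(mean_n)
                for _ in range(t):
                    detected = rng.random(len(probes)) < e
                    molecules.extend(
                        (probes[i], "") for i in np.nonzero(detected)[0]
                    )
        for probe, _ in molecules:
            n_molecules += 1
            umi = "".join(rng.choice(["A", "C", "G", "T"], size=schema.umi_length))
            # nonspecific ligation: swap in a nonadjacent left/right combination
            if (
                config.nonspecific_ligation_rate > 0.0
                and len(pop.manifest) > 1
                and rng.random() < config.nonspecific_ligation_rate
            ):
                i, j = rng.choice(len(pop.manifest), size=2, replace=False)
                left_probe, right_probe = pop.manifest[int(i)], pop.manifest[int(j)]
                pair_id = "nonspecific"
                left_id, right_id = left_probe.left_id, right_probe.right_id
                left_seq, right_seq = (
                    left_probe.left_target,
                    right_probe.right_target,
                )
                n_nonspecific += 1
            else:
                pair_id = probe.probe_pair_id
                left_id, right_id = probe.left_id, probe.right_id
                left_seq, right_seq = probe.left_target, probe.right_target

            if config.mean_reads_per_molecule <= 1.0:
                n_reads = 1
            else:
                n_reads = 1 + rng.poisson(config.mean_reads_per_molecule - 1.0)
            for _ in range(n_reads):
                stagger = int(rng.choice(stagger_vals, p=weights))
                bcs = [cbc[0:7], cbc[7:14], cbc[14:21]]
                hopped = False
                if (
                    config.barcode_hop_rate > 0.0
                    and rng.random() < config.barcode_hop_rate
                ):
                    rd = int(rng.integers(3))
                    others = [b for b in wl_sorted[rd] if b != bcs[rd]]
                    if others:
                        bcs[rd] = others[int(rng.integers(len(others)))]
                        hopped = True
                max_s = max(schema.stagger_range)
                for _try in range(100):
                    pad = _random_pad(rng, stagger)
                    tail = _random_pad(rng, max_s - stagger)
                    r1 = layout_read1(
                        bcs[0], bcs[1], bcs[2], stagger, schema, pad=pad, tail=tail
                    )
                    if not _spurious_anchor(
                        reverse_complement(r1), stagger, schema
                    ):
                        break
                r2 = layout_read2(left_seq, right_seq, umi, schema)
                r1 = _apply_errors(r1, config.error_rate, rng)
                r2 = _apply_errors(r2, config.error_rate, rng)
                ambiguous = bcs[0] in ambiguous1 or bcs[1] in ambiguous2
                if ambiguous:
                    n_ambiguous += 1
                rid = f"read{read_no:08d}"
                read_no += 1
                reads.append(
                    ReadPair(rid, r1, r2, "I" * len(r1), "I" * len(r2))
                )
                truths.append(
                    TruthRecord(
                        read_id=rid,
                        cbc=bcs[0] + bcs[1] + bcs[2] if not hopped else cbc,
                        cell_id=cid,
                        species=pop.name,
                        probe_pair_id=pair_id,
                        left_id=left_id,
                        right_id=right_id,
                        umi=umi,
                        doublet=is_doublet[cid],
                        hopped=hopped,
                        stagger=stagger,
                        ambiguous_window=ambiguous,
                    )
                )

    stats = {
        "n_cells": len(cells),
        "n_cbcs": len(set(cbc_of.values())),
        "n_molecules": n_molecules,
        "n_reads": len(reads),
        "n_nonspecific_molecules": n_nonspecific,
        "ambiguous_window_reads": n_ambiguous,
        "doublet_cells": int(sum(is_doublet.values())),
    }
    return reads, truths, stats


def write_truth(truths: list[TruthRecord], path) -> None:
    import pandas as pd

    pd.DataFrame([t.__dict__ for t in truths]).to_csv(path, sep="\t", index=False)


def simulate_run(config: SimConfig, out_dir: str | Path) -> dict:
    """Simulate and write R1/R2 FASTQ.gz, truth.tsv and a stats JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    reads, truths, stats = simulate_reads(config)
    write_fastq_pairs(reads, out_dir / "R1.fastq.gz", out_dir / "R2.fastq.gz")
    write_truth(truths, out_dir / "truth.tsv")
    write_json_report(stats, out_dir / "sim_stats.json")
    return stats
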