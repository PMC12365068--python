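"""Readers and writers for the formats the pipeline touches.

FASTQ (phred+33, transparently gzipped), barcode whitelists (one 7-mer per
line), the probe-pair manifest (TSV), and MatrixMarket count-matrix trios
(matrix.mtx + barcodes.tsv + features.tsv).
"""

from __future__ import annotations

import gzip
import json
import logging
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .schema import CountMatrix, ReadPair, SplitProbePair

logger = logging.getLogger("splitprobe")

MANIFEST_COLUMNS = [
    "probe_pair_id",
    "gene_id",
    "transcript_id",
    "tile_index",
    "left_target",
    "right_target",
    "rna_start",
]


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        if "w" in mode:
            # fixed mtime so identical content gives identical bytes
            import io as _io

            gz = gzip.GzipFile(path, "wb", mtime=0)
            return _io.TextIOWrapper(gz, encoding="ascii")
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq_pairs(path1: str | Path, path2: str | Path) -> Iterator[ReadPair]:
    """Stream paired FASTQ records in file order.

    Record IDs (up to the first ``/`` or whitespace) must agree pairwise;
    desynchronized or truncated files raise ``ValueError``.
    """
    with _open_text(path1) as h1, _open_text(path2) as h2:
        it1 = FastqGeneralIterator(h1)
        it2 = FastqGeneralIterator(h2)
        n = 0
        while True:
            rec1 = next(it1, None)
            rec2 = next(it2, None)
            if rec1 is None and rec2 is None:
                return
            if rec1 is None or rec2 is None:
                raise ValueError(
                    f"FASTQ files desynchronized after {n} records: "
                    f"{'read1' if rec1 is None else 'read2'} file exhausted first"
                )
            id1 = rec1[0].split()[0].split("/")[0]
            id2 = rec2[0].split()[0].split("/")[0]
            if id1 != id2:
                raise ValueError(
                    f"FASTQ record {n}: mismatched ids {id1!r} vs {id2!r}"
                )
            n += 1
            yield ReadPair(id1, rec1[1].upper(), rec2[1].upper(), rec1[2], rec2[2])


def write_fastq_pairs(
    pairs: Iterable[ReadPair], path1: str | Path, path2: str | Path
) -> int:
    """Write paired reads to two FASTQ files (gzipped iff the name ends .gz)."""
    n = 0
    with _open_text(path1, "wt") as h1, _open_text(path2, "wt") as h2:
        for rp in pairs:
            q1 = rp.qual1 or "I" * len(rp.read1)
            q2 = rp.qual2 or "I" * len(rp.read2)
            h1.write(f"@{rp.read_id}\n{rp.read1}\n+\n{q1}\n")
            h2.write(f"@{rp.read_id}\n{rp.read2}\n+\n{q2}\n")
            n += 1
    return n


def read_whitelist(path: str | Path, barcode_len: int = 7) -> frozenset[str]:
    entries = set()
    with _open_text(path) as fh:
        for i, line in enumerate(fh):
            bc = line.strip().upper()
            if not bc:
                continue
            if len(bc) != barcode_len or not set(bc) <= set("ACGT"):
                raise ValueError(f"{path}:{i + 1}: invalid barcode {bc!r}")
            entries.add(bc)
    return frozenset(entries)


def write_whitelist(whitelist: Iterable[str], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for bc in sorted(whitelist):
            fh.write(bc + "\n")


def load_probe_manifest(
    path: str | Path,
) -> tuple[list[SplitProbePair], set[tuple[str, str]]]:
    """Load a probe manifest TSV and derive the predicted-adjacency map.

    Returns the validated pairs plus the set of (left_id, right_id)
    combinations predicted adjacent — i.e. the left and right halves of one
    designed pair.  Every other left x right combination in the panel is a
    nonspecific ligation product.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.empty:
        raise ValueError(f"{path}: empty probe manifest")
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing manifest columns {sorted(missing)}")
    pairs = manifest_from_frame(df)
    return pairs, adjacency_map(pairs)


def manifest_from_frame(df: pd.DataFrame) -> list[SplitProbePair]:
    pairs = []
    seen_ids: set[str] = set()
    seen_tiles: set[tuple[str, int]] = set()
    for row in df.itertuples(index=False):
        pid = str(row.probe_pair_id)
        if pid in seen_ids:
            raise ValueError(f"duplicate probe_pair_id {pid!r}")
        seen_ids.add(pid)
        pair = SplitProbePair(
            probe_pair_id=pid,
            gene_id=str(row.gene_id),
            transcript_id=str(row.transcript_id),
            tile_index=int(row.tile_index),
            left_target=str(row.left_target).upper(),
            right_target=str(row.right_target).upper(),
            rna_start=int(row.rna_start),
        )
        key = (pair.transcript_id, pair.tile_index)
        if key in seen_tiles:
            raise ValueError(f"duplicate (transcript_id, tile_index) {key}")
        seen_tiles.add(key)
        pairs.append(pair)
    return pairs


def adjacency_map(pairs: list[SplitProbePair]) -> set[tuple[str, str]]:
    return {(p.left_id, p.right_id) for p in pairs}


def write_probe_manifest(pairs: Iterable[SplitProbePair], path: str | Path) -> None:
    rows = [
        {
            "probe_pair_id": p.probe_pair_id,
            "gene_id": p.gene_id,
            "transcript_id": p.transcript_id,
            "tile_index": p.tile_index,
            "left_target": p.left_target,
            "right_target": p.right_target,
            "rna_start": p.rna_start,
        }
        for p in pairs
    ]
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(path, sep="\t", index=False)


def write_count_matrix(matrix: CountMatrix, out_dir: str | Path) -> None:
    """Write a MatrixMarket trio (matrix.mtx, barcodes.tsv, features.tsv)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(
        out_dir / "matrix.mtx", sp.coo_matrix(matrix.counts), field="integer"
    )
    (out_dir / "barcodes.tsv").write_text(
        "".join(bc + "\n" for bc in matrix.cell_barcodes)
    )
    (out_dir / "features.tsv").write_text(
        "".join(f + "\n" for f in matrix.features)
    )
    (out_dir / "level.txt").write_text(matrix.level + "\n")


def read_count_matrix(in_dir: str | Path) -> CountMatrix:
    in_dir = Path(in_dir)
    for name in ("matrix.mtx", "barcodes.tsv", "features.tsv"):
        if not (in_dir / name).exists():
            raise FileNotFoundError(in_dir / name)
    counts = sp.csr_matrix(scipy.io.mmread(in_dir / "matrix.mtx")).astype(np.int64)
    barcodes = (in_dir / "barcodes.tsv").read_text().split()
    features = (in_dir / "features.tsv").read_text().split()
    level_file = in_dir / "level.txt"
    level = level_file.read_text().strip() if level_file.exists() else "probe"
    if counts.shape[0] != len(barcodes):
        raise ValueError(
            f"{in_dir}: matrix has {counts.shape[0]} rows but "
            f"{len(barcodes)} barcodes"
        )
    if counts.shape[1] != len(features):
        raise ValueError(
            f"{in_dir}: matrix has {counts.shape[1]} columns but "
            f"{len(features)} features"
        )
    return CountMatrix(barcodes, features, counts, level=level)


def read_transcriptome_fasta(path: str | Path) -> dict[str, tuple[str, str]]:
    """Read transcripts from FASTA with header convention ``transcript_id|gene_id``.

    Returns transcript_id -> (gene_id, sequence).  A header without ``|``
    uses the transcript id as its own gene id.
    """
    from Bio import SeqIO

    transcripts: dict[str, tuple[str, str]] = {}
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if "|" in rec.id:
                tid, gid = rec.id.split("|", 1)
            else:
                tid = gid = rec.id
            seq = str(rec.seq).upper().replace("U", "T")
            if not seq:
                raise ValueError(f"{path}: empty sequence for {tid}")
            if tid in transcripts:
                raise ValueError(f"{path}: duplicate transcript {tid}")
            transcripts[tid] = (gid, seq)
    if not transcripts:
        raise ValueError(f"{path}: no FASTA records")
    return transcripts


def write_json_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
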