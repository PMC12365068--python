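"""Core data model for split-pool barcoded split-probe sequencing.

The read-1 barcode layout is defined in *reverse-complement space*: the
orientation in which the three well barcodes read 5'→3' as they appear in
the barcode oligos.  A sequenced read 1 is the reverse complement of that
layout, optionally preceded by a 0–3 nt stagger pad that diversifies base
composition during sequencing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

DNA_ALPHABET = frozenset("ACGTN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string; N maps to N.

    Raises ``ValueError`` on characters outside {A,C,G,T,N}.
    """
    if not set(seq) <= DNA_ALPHABET:
        bad = sorted(set(seq) - DNA_ALPHABET)
        raise ValueError(f"non-DNA characters in sequence: {bad}")
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class BarcodeSchema:
    """Anchors, linkers, windows and whitelists defining the read-1 layout.

    Coordinates are 0-based half-open and refer to the reverse complement of
    read 1.  ``search_window*`` bound the *start* position of each anchor;
    ``fixed_*`` are barcode slices in stagger-trimmed coordinates (the
    coordinates after the stagger pad and the 6-base CATTCG context have
    been removed).
    """

    anchor1: str = "ATTCG"
    anchor2: str = "TGCTTGAG"
    anchor3: str = "GTTTCG"
    linker1_read1: str = "CTCAAGCACGTGGATAGTCGTACGCCGATG"
    linker2_read1: str = "CGAAACATCGGCCAC"
    whitelist1: frozenset[str] = frozenset()
    whitelist2: frozenset[str] = frozenset()
    whitelist3: frozenset[str] = frozenset()
    search_window1: tuple[int, int] = (0, 25)
    search_window2: tuple[int, int] = (35, 57)
    search_window3: tuple[int, int] = (57, -1)  # -1: to end of read
    extract_len1: int = 9
    extract_len2: int = 9
    extract_len3: int = 7
    barcode_len: int = 7
    fixed_bc1: tuple[int, int] = (0, 7)
    fixed_bc2: tuple[int, int] = (37, 44)
    fixed_bc3: tuple[int, int] = (59, 66)
    stagger_range: tuple[int, ...] = (0, 1, 2, 3)
    trim_context: str = "CATTCG"
    read_length: int = 75
    umi_length: int = 8

    def __post_init__(self) -> None:
        for name in ("whitelist1", "whitelist2", "whitelist3"):
            wl = getattr(self, name)
            if not isinstance(wl, frozenset):
                object.__setattr__(self, name, frozenset(wl))
        for name in ("whitelist1", "whitelist2", "whitelist3"):
            for bc in getattr(self, name):
                if len(bc) != self.barcode_len or not set(bc) <= set("ACGT"):
                    raise ValueError(
                        f"{name} entry {bc!r} is not a {self.barcode_len}-mer over ACGT"
                    )
        if not reverse_complement(self.linker1_read1).endswith(self.anchor2):
            raise ValueError("revcomp(linker1_read1) must end with anchor2")
        if not reverse_complement(self.linker2_read1).endswith(self.anchor3):
            raise ValueError("revcomp(linker2_read1) must end with anchor3")
        if self.anchor1 not in self.trim_context:
            raise ValueError("anchor1 must be contained in the trim context")

    @property
    def whitelists(self) -> tuple[frozenset[str], ...]:
        return (self.whitelist1, self.whitelist2, self.whitelist3)

    @property
    def n_possible_cbcs(self) -> int:
        """Size of the combinatorial barcode space (product of round sizes)."""
        return len(self.whitelist1) * len(self.whitelist2) * len(self.whitelist3)


@dataclass(frozen=True)
class SplitProbePair:
    """One ligatable left/right split-probe pair.

    ``left_target`` and ``right_target`` are the probe-side (DNA) 30-mers;
    the right probe hybridizes to the 5'-most 30 nt of the targeted RNA
    window so that its 5'-phosphate sits at the ligation junction.
    ``rna_start`` is the 0-based transcript coordinate of the 60-nt window.
    """

    probe_pair_id: str
    gene_id: str
    transcript_id: str
    tile_index: int
    left_target: str
    right_target: str
    rna_start: int = 0

    def __post_init__(self) -> None:
        for name in ("left_target", "right_target"):
            t = getattr(self, name)
            if len(t) != 30:
                raise ValueError(
                    f"{self.probe_pair_id}: {name} must be 30 nt, got {len(t)}"
                )
            if not set(t) <= set("ACGT"):
                raise ValueError(f"{self.probe_pair_id}: non-DNA {name}")
        if self.tile_index < 0:
            raise ValueError("tile_index must be >= 0")

    @property
    def left_id(self) -> str:
        return f"{self.probe_pair_id}/L"

    @property
    def right_id(self) -> str:
        return f"{self.probe_pair_id}/R"

    @property
    def center30(self) -> str:
        """Junction-centered 30-mer: last 15 nt of left + first 15 nt of right."""
        return self.left_target[15:30] + self.right_target[0:15]


@dataclass(frozen=True)
class ReadPair:
    """A paired sequencing read (read 1 = barcode side, read 2 = probe side)."""

    read_id: str
    read1: str
    read2: str
    qual1: str = ""
    qual2: str = ""

    def __post_init__(self) -> None:
        if self.qual1 and len(self.qual1) != len(self.read1):
            raise ValueError(f"{self.read_id}: qual1 length mismatch")
        if self.qual2 and len(self.qual2) != len(self.read2):
            raise ValueError(f"{self.read_id}: qual2 length mismatch")


@dataclass
class CountMatrix:
    """Sparse UMI counts, cells x features.

    ``level`` records whether features are probe-pair ids or gene ids.
    """

    cell_barcodes: list[str]
    features: list[str]
    counts: sp.spmatrix
    level: str = "probe"

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        n, m = self.counts.shape
        if n != len(self.cell_barcodes):
            raise ValueError("row count does not match number of cell barcodes")
        if m != len(self.features):
            raise ValueError("column count does not match number of features")
        if len(set(self.cell_barcodes)) != n:
            raise ValueError("duplicate cell barcodes")
        if len(set(self.features)) != m:
            raise ValueError("duplicate features")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("negative counts")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def total_umis_per_cell(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=1)).ravel()

    def dense(self) -> np.ndarray:
        return self.counts.toarray()
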