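"""Mismatch-tolerant demultiplexing of inline cell barcodes.

Reads carry a UMI and a cell barcode at fixed positions. Each observed
barcode is matched against a predefined set allowing ``max_mismatch``
substitutions (two for a 384-adapter set, one for a 96-adapter set);
reads whose nearest barcode is not unique at the minimal distance are left
unassigned, as are reads shorter than the layout. The UMI is extracted
verbatim (no error correction) and both are appended to the read name as
``_{barcode}_{umi}`` so downstream deduplication can parse them back.

N bases count as a mismatch against every nucleotide.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator


class LayoutError(ValueError):
    pass


class FastqFormatError(ValueError):
    pass


@dataclass(frozen=True)
class ReadLayout:
    """Positions (0-based) and lengths of UMI, barcode and optional anchor."""

    umi_start: int = 0
    umi_len: int = 8
    bc_start: int = 8
    bc_len: int = 8
    anchor_seq: str = "CATG"

    def __post_init__(self):
        if min(self.umi_start, self.umi_len, self.bc_start, self.bc_len) < 0:
            raise LayoutError("negative layout coordinates")
        u = (self.umi_start, self.umi_start + self.umi_len)
        b = (self.bc_start, self.bc_start + self.bc_len)
        if max(u[0], b[0]) < min(u[1], b[1]):
            raise LayoutError("UMI and barcode intervals overlap")

    @property
    def min_read_len(self) -> int:
        return max(self.umi_start + self.umi_len, self.bc_start + self.bc_len)


@dataclass(frozen=True)
class BarcodeSet:
    """Equal-length unique barcodes plus the mismatch tolerance."""

    barcodes: tuple[str, ...]
    max_mismatch: int = 2

    def __post_init__(self):
        if not self.barcodes:
            raise LayoutError("empty barcode set")
        if len(set(self.barcodes)) != len(self.barcodes):
            raise LayoutError("duplicate barcodes")
        L = len(self.barcodes[0])
        if any(len(b) != L for b in self.barcodes):
            raise LayoutError("barcodes must have equal length")
        if self.max_mismatch < 0:
            raise LayoutError("max_mismatch must be >= 0")

    @property
    def length(self) -> int:
        return len(self.barcodes[0])

    def matrix(self) -> np.ndarray:
        return np.frombuffer("".join(self.barcodes).encode(), dtype=np.uint8
                             ).reshape(len(self.barcodes), self.length)


def hamming(a: str, b: str) -> int:
    """Hamming distance; any position containing N mismatches."""
    if len(a) != len(b):
        raise ValueError("length mismatch")
    return sum(1 for x, y in zip(a, b) if x != y or x == "N" or y == "N")


def assign_barcode(observed: str, barcode_set: BarcodeSet) -> int | None:
    """Index of the unique barcode within ``max_mismatch`` of ``observed``,
    or None when no barcode is close enough or >=2 tie at the minimum."""
    if len(observed) != barcode_set.length:
        raise ValueError(
            f"observed barcode length {len(observed)} != {barcode_set.length}")
    dists = _batch_distances(
        np.frombuffer(observed.encode(), dtype=np.uint8)[None, :],
        barcode_set.matrix())[0]
    return _pick(dists, barcode_set.max_mismatch)


def _batch_distances(reads: np.ndarray, bcs: np.ndarray) -> np.ndarray:
    """(n_reads x n_barcodes) Hamming distances; N in either sequence counts
    as a mismatch even against another N."""
    n = ord("N")
    out = np.empty((reads.shape[0], bcs.shape[0]), dtype=np.int16)
    read_is_n = reads == n
    for j in range(bcs.shape[0]):
        mism = (reads != bcs[j]) | read_is_n | (bcs[j] == n)
        out[:, j] = mism.sum(axis=1)
    return out


def _pick(dists: np.ndarray, max_mismatch: int) -> int | None:
    best = int(dists.argmin())
    d = int(dists[best])
    if d > max_mismatch:
        return None
    if (dists == d).sum() > 1:
        return None
    return best


def parse_read_name(name: str) -> tuple[str, str, str]:
    """Invert the demultiplexer's naming: -> (original name, barcode, umi)."""
    base, bc, umi = name.rsplit("_", 2)
    return base, bc, umi


def _iter_fastq(source) -> Iterator[tuple[str, str, str]]:
    if isinstance(source, (str, Path)):
        opener = gzip.open if str(source).endswith(".gz") else open
        with opener(source, "rt") as fh:
            yield from FastqGeneralIterator(fh)
    else:
        yield from source


@dataclass
class DemuxStats:
    per_cell: pd.DataFrame      # index barcode; column n_reads
    n_total: int
    n_assigned: int
    n_unassigned: int
    n_short: int

    @property
    def assignment_rate(self) -> float:
        return self.n_assigned / self.n_total if self.n_total else float("nan")


def demultiplex(
    fastq,
    layout: ReadLayout,
    barcode_set: BarcodeSet,
    out_dir: str | Path | None = None,
    gzip_output: bool = False,
    chunk_size: int = 20000,
) -> tuple[DemuxStats, pd.DataFrame]:
    """Split reads into per-cell sets by barcode.

    ``fastq`` is a path (optionally .gz) or an iterable of (name, seq, qual)
    tuples. Every input read lands in exactly one output: a cell file or the
    unassigned pool. Returns per-cell statistics plus an assignment table
    (read name, assigned barcode or None, reason for unassigned reads).
    """
    bc_mat = barcode_set.matrix()
    counts: dict[str, int] = {b: 0 for b in barcode_set.barcodes}
    assignments: list[tuple[str, str | None, str]] = []
    n_total = n_short = n_assigned = 0

    handles = {}

    def _write(barcode_key: str, name: str, seq: str, qual: str) -> None:
        if out_dir is None:
            return
        if barcode_key not in handles:
            ext = ".fastq.gz" if gzip_output else ".fastq"
            path = Path(out_dir) / f"{barcode_key}{ext}"
            handles[barcode_key] = (gzip.open(path, "wt") if gzip_output
                                    else open(path, "w"))
        handles[barcode_key].write(f"@{name}\n{seq}\n+\n{qual}\n")

    if out_dir is not None:
        Path(out_dir).mkdir(parents=True, exist_ok=True)

    try:
        chunk: list[tuple[str, str, str]] = []

        def _flush(chunk):
            nonlocal n_assigned
            obs = np.frombuffer(
                "".join(s[layout.bc_start:layout.bc_start + layout.bc_len]
                        for _, s, _ in chunk).encode(),
                dtype=np.uint8).reshape(len(chunk), layout.bc_len)
            dists = _batch_distances(obs, bc_mat)
            best = dists.argmin(axis=1)
            dmin = np.take_along_axis(dists, best[:, None], axis=1)[:, 0]
            n_at_min = (dists == dmin[:, None]).sum(axis=1)
            ok = (dmin <= barcode_set.max_mismatch) & (n_at_min == 1)
            for i, (name, seq, qual) in enumerate(chunk):
                umi = seq[layout.umi_start:layout.umi_start + layout.umi_len]
                if ok[i]:
                    bc = barcode_set.barcodes[best[i]]
                    counts[bc] += 1
                    n_assigned += 1
                    assignments.append((name, bc, "assigned"))
                    _write(bc, f"{name}_{bc}_{umi}", seq, qual)
                else:
                    reason = ("ambiguous" if dmin[i] <= barcode_set.max_mismatch
                              else "no_match")
                    assignments.append((name, None, reason))
                    _write("unassigned", name, seq, qual)

        source = iter(_iter_fastq(fastq))
        idx = -1
        while True:
            idx += 1
            try:
                rec = next(source)
            except StopIteration:
                break
            except ValueError as exc:
                raise FastqFormatError(
                    f"malformed FASTQ record at index {idx}") from exc
            try:
                name, seq, qual = rec
            except (TypeError, ValueError) as exc:
                raise FastqFormatError(f"malformed record at index {idx}") from exc
            n_total += 1
            if len(seq) < layout.min_read_len:
                n_short += 1
                assignments.append((name, None, "short"))
                _write("unassigned", name, seq, qual)
                continue
            chunk.append((name, seq, qual))
            if len(chunk) >= chunk_size:
                _flush(chunk)
                chunk = []
        if chunk:
            _flush(chunk)
    finally:
        for fh in handles.values():
            fh.close()

    per_cell = pd.DataFrame(
        {"n_reads": pd.Series(counts)}).rename_axis("barcode")
    stats = DemuxStats(
        per_cell=per_cell,
        n_total=n_total,
        n_assigned=n_assigned,
        n_unassigned=n_total - n_assigned,
        n_short=n_short,
    )
    table = pd.DataFrame(assignments, columns=["read", "barcode", "status"])
    return stats, table
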