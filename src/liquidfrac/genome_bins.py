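"""Fixed-width genomic bin lattices and per-sample bin counts.

Low-pass WGS copy-number analysis starts from read counts over a fixed
lattice of genomic intervals (here 500 kb by default). This module builds
the lattice, assigns aligned read start positions to bins, and round-trips
the annotated count tables through plain-text formats (TSV, fixed-step WIG).

Coordinates are 0-based half-open throughout (BED convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

DEFAULT_BIN_SIZE = 500_000

#: GRCh38 autosome lengths (bp); the default lattice for simulations.
GRCH38_AUTOSOMES: dict[str, int] = {
    "chr1": 248_956_422, "chr2": 242_193_529, "chr3": 198_295_559,
    "chr4": 190_214_555, "chr5": 181_538_259, "chr6": 170_805_979,
    "chr7": 159_345_973, "chr8": 145_138_636, "chr9": 138_394_717,
    "chr10": 133_797_422, "chr11": 135_086_622, "chr12": 133_275_309,
    "chr13": 114_364_328, "chr14": 107_043_718, "chr15": 101_991_189,
    "chr16": 90_338_345, "chr17": 83_257_441, "chr18": 80_373_285,
    "chr19": 58_617_616, "chr20": 64_444_167, "chr21": 46_709_983,
    "chr22": 50_818_468,
}


def _chrom_sort_key(name: str) -> tuple:
    body = name[3:] if name.lower().startswith("chr") else name
    return (0, int(body)) if body.isdigit() else (1, body)


@dataclass
class BinGrid:
    """An ordered lattice of fixed-width genomic bins with annotation.

    Attributes
    ----------
    chromosome, start, end :
        Parallel arrays defining 0-based half-open intervals, sorted by
        (chromosome, start) and non-overlapping.
    gc :
        GC fraction per bin in [0, 1]; NaN when unknown.
    centromere_flag :
        True for bins overlapping a centromere annotation.
    mask_flag :
        True for bins excluded from modelling (short terminal bins,
        invalid GC, user blacklist).
    bin_size :
        Nominal bin width in bp; every bin except possibly the last of a
        chromosome has exactly this width.
    """

    chromosome: np.ndarray
    start: np.ndarray
    end: np.ndarray
    gc: np.ndarray
    centromere_flag: np.ndarray
    mask_flag: np.ndarray
    bin_size: int = DEFAULT_BIN_SIZE

    def __post_init__(self) -> None:
        self.chromosome = np.asarray(self.chromosome, dtype=object)
        self.start = np.asarray(self.start, dtype=np.int64)
        self.end = np.asarray(self.end, dtype=np.int64)
        self.gc = np.asarray(self.gc, dtype=float)
        self.centromere_flag = np.asarray(self.centromere_flag, dtype=bool)
        self.mask_flag = np.asarray(self.mask_flag, dtype=bool)
        n = len(self.start)
        for name in ("chromosome", "end", "gc", "centromere_flag", "mask_flag"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"grid field {name!r} has wrong length")
        if np.any(self.end <= self.start):
            raise ValueError("empty or inverted bin interval")
        ok = ~self.mask_flag & np.isfinite(self.gc)
        if np.any((self.gc[ok] < 0) | (self.gc[ok] > 1)):
            raise ValueError("gc outside [0,1] for an unmasked bin")

    def __len__(self) -> int:
        return len(self.start)

    @property
    def n_bins(self) -> int:
        return len(self.start)

    def chromosomes(self) -> list[str]:
        """Distinct chromosome labels in grid order."""
        seen: dict[str, None] = {}
        for c in self.chromosome:
            seen.setdefault(c, None)
        return list(seen)

    def chrom_slices(self) -> dict[str, slice]:
        """Map each chromosome to its contiguous slice of bin indices."""
        out: dict[str, slice] = {}
        idx = 0
        for c in self.chromosomes():
            n = int(np.sum(self.chromosome == c))
            out[c] = slice(idx, idx + n)
            idx += n
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "chrom": self.chromosome, "start": self.start, "end": self.end,
            "gc": self.gc, "centromere": self.centromere_flag.astype(int),
            "mask": self.mask_flag.astype(int),
        })


@dataclass
class BinCounts:
    """Raw read counts for one sample, index-aligned with a :class:`BinGrid`."""

    sample_id: str
    counts: np.ndarray
    dropped: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if not np.issubdtype(self.counts.dtype, np.integer):
            if np.any(self.counts != np.floor(self.counts)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            raise ValueError("negative count")

    @property
    def total_reads(self) -> int:
        return int(self.counts.sum())

    def __len__(self) -> int:
        return len(self.counts)


def make_bin_grid(
    chrom_sizes: Mapping[str, int],
    bin_size: int = DEFAULT_BIN_SIZE,
    gc: Mapping[str, Sequence[float]] | None = None,
    centromeres: Mapping[str, tuple[int, int]] | None = None,
) -> BinGrid:
    """Tile each chromosome left to right into fixed-width bins.

    A trailing partial bin is created whenever the chromosome length is not
    a multiple of ``bin_size``; it is masked when shorter than half a bin so
    downstream depth models never see systematically under-covered bins.

    Parameters
    ----------
    chrom_sizes :
        Chromosome label -> length in bp.
    bin_size :
        Bin width in bp (default 500 kb).
    gc :
        Optional per-chromosome GC fractions, one per bin; NaN if absent.
    centromeres :
        Optional chromosome -> (start, end) centromere interval; bins
        overlapping it are flagged.
    """
    if not chrom_sizes:
        raise ValueError("no chromosomes")
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    chroms, starts, ends, gcs, cents, masks = [], [], [], [], [], []
    for chrom in sorted(chrom_sizes, key=_chrom_sort_key):
        size = int(chrom_sizes[chrom])
        if size <= 0:
            raise ValueError(f"non-positive size for {chrom}")
        bin_starts = np.arange(0, size, bin_size, dtype=np.int64)
        bin_ends = np.minimum(bin_starts + bin_size, size)
        n = len(bin_starts)
        chroms.extend([chrom] * n)
        starts.append(bin_starts)
        ends.append(bin_ends)
        chrom_gc = np.full(n, np.nan) if gc is None else np.asarray(gc[chrom], float)
        if len(chrom_gc) != n:
            raise ValueError(f"gc vector for {chrom} has wrong length")
        gcs.append(chrom_gc)
        cent = np.zeros(n, dtype=bool)
        if centromeres and chrom in centromeres:
            c0, c1 = centromeres[chrom]
            cent = (bin_starts < c1) & (bin_ends > c0)
        cents.append(cent)
        mask = np.zeros(n, dtype=bool)
        mask[-1] = (bin_ends[-1] - bin_starts[-1]) < bin_size / 2
        masks.append(mask)
    return BinGrid(
        chromosome=np.array(chroms, dtype=object),
        start=np.concatenate(starts), end=np.concatenate(ends),
        gc=np.concatenate(gcs), centromere_flag=np.concatenate(cents),
        mask_flag=np.concatenate(masks), bin_size=bin_size,
    )


def count_reads_in_bins(
    read_starts: Iterable[tuple[str, int]],
    grid: BinGrid,
    sample_id: str = "sample",
) -> BinCounts:
    """Assign each aligned read start to the unique bin containing it.

    Reads on chromosomes absent from the grid are counted as ``dropped``
    and logged; reads past the end of the last bin of a chromosome are
    likewise dropped.
    """
    slices = grid.chrom_slices()
    counts = np.zeros(grid.n_bins, dtype=np.int64)
    dropped = 0
    for chrom, pos in read_starts:
        pos = int(pos)
        if pos < 0:
            raise ValueError(f"negative read position {chrom}:{pos}")
        sl = slices.get(chrom)
        if sl is None:
            dropped += 1
            continue
        offset = pos // grid.bin_size
        idx = sl.start + offset
        if idx >= sl.stop or pos >= grid.end[idx]:
            dropped += 1
            continue
        counts[idx] += 1
    if dropped:
        log.info("count_reads_in_bins: dropped %d reads outside the grid", dropped)
    return BinCounts(sample_id=sample_id, counts=counts, dropped=dropped)


# ---------------------------------------------------------------------------
# plain-text serialization

_TSV_COLUMNS = ["chrom", "start", "end", "gc", "centromere", "count"]


def write_bin_table(path: str | Path, grid: BinGrid, counts: BinCounts,
                    dialect: str = "tsv") -> None:
    """Write a grid + counts pair as a TSV bin table or fixed-step WIG.

    The WIG dialect carries counts only (one ``fixedStep`` block per
    chromosome with ``step == span == bin_size``); the TSV dialect is a
    full round-trip of coordinates, GC, centromere flags and counts.
    """
    path = Path(path)
    if len(counts) != grid.n_bins:
        raise ValueError("counts not aligned with grid")
    if dialect == "tsv":
        df = grid.to_frame().drop(columns="mask")
        df["count"] = counts.counts
        df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    elif dialect == "wig":
        with open(path, "w") as fh:
            for chrom, sl in grid.chrom_slices().items():
                fh.write(f"fixedStep chrom={chrom} start=1 "
                         f"step={grid.bin_size} span={grid.bin_size}\n")
                for v in counts.counts[sl]:
                    fh.write(f"{int(v)}\n")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_bin_table(path: str | Path, dialect: str = "tsv",
                   bin_size: int | None = None,
                   sample_id: str | None = None) -> tuple[BinGrid, BinCounts]:
    """Read a bin table written by :func:`write_bin_table`.

    Raises a ``ValueError`` naming the offending line on ragged rows,
    non-integer counts, or unsorted bins.
    """
    path = Path(path)
    sample_id = sample_id or path.stem
    if dialect == "tsv":
        return _read_tsv(path, sample_id)
    if dialect == "wig":
        return _read_wig(path, sample_id, bin_size)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_tsv(path: Path, sample_id: str) -> tuple[BinGrid, BinCounts]:
    rows = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _TSV_COLUMNS:
            raise ValueError(f"{path}:1: expected columns {_TSV_COLUMNS}, got {header}")
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(_TSV_COLUMNS):
                raise ValueError(f"{path}:{lineno}: expected "
                                 f"{len(_TSV_COLUMNS)} fields, got {len(parts)}")
            chrom, start, end, gc, cent, count = parts
            try:
                start_i, end_i = int(start), int(end)
                gc_f = float(gc)
                cent_i = int(cent)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            try:
                count_i = int(count)
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: non-integer count {count!r}") from None
            if count_i < 0:
                raise ValueError(f"{path}:{lineno}: negative count")
            rows.append((chrom, start_i, end_i, gc_f, cent_i, count_i))
    if not rows:
        raise ValueError(f"{path}: empty bin table")
    widths = [r[2] - r[1] for r in rows]
    bin_size = max(widths)
    prev: tuple | None = None
    for i, r in enumerate(rows):
        if prev is not None and r[0] == prev[0] and r[1] < prev[2]:
            raise ValueError(f"{path}:{i + 2}: bins unsorted or overlapping")
        prev = r
    n = len(rows)
    grid = BinGrid(
        chromosome=np.array([r[0] for r in rows], dtype=object),
        start=np.array([r[1] for r in rows]),
        end=np.array([r[2] for r in rows]),
        gc=np.array([r[3] for r in rows]),
        centromere_flag=np.array([bool(r[4]) for r in rows]),
        mask_flag=np.array([w < bin_size / 2 for w in widths]),
        bin_size=bin_size,
    )
    counts = BinCounts(sample_id=sample_id,
                       counts=np.array([r[5] for r in rows]))
    return grid, counts


def _read_wig(path: Path, sample_id: str,
              bin_size: int | None) -> tuple[BinGrid, BinCounts]:
    chrom_counts: dict[str, list[int]] = {}
    current: list[int] | None = None
    step = span = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("track", "#")):
                continue
            if line.startswith("fixedStep"):
                fields = dict(kv.split("=") for kv in line.split()[1:])
                step, span = int(fields["step"]), int(fields.get("span", fields["step"]))
                if step != span:
                    raise ValueError(f"{path}:{lineno}: step != span")
                if bin_size is not None and step != bin_size:
                    raise ValueError(f"{path}:{lineno}: step {step} != bin_size {bin_size}")
                current = chrom_counts.setdefault(fields["chrom"], [])
            else:
                if current is None:
                    raise ValueError(f"{path}:{lineno}: data before fixedStep header")
                try:
                    current.append(int(line))
                except ValueError:
                    raise ValueError(
                        f"{path}:{lineno}: non-integer count {line!r}") from None
    if not chrom_counts:
        raise ValueError(f"{path}: empty WIG")
    assert step is not None
    sizes = {c: len(v) * step for c, v in chrom_counts.items()}
    grid = make_bin_grid(sizes, bin_size=step)
    counts = np.concatenate([
        np.asarray(chrom_counts[c], dtype=np.int64) for c in grid.chromosomes()
    ])
    return grid, BinCounts(sample_id=sample_id, counts=counts)
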