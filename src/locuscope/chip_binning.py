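"""Binned ChIP-seq peak enrichment over a genomic window.

Parses ENCODE narrowPeak peak calls and summarizes them as bins x samples
fold-enrichment matrices: a window is tiled with fixed-size bins (default
500 bp), each bin receives the highest signalValue among peaks overlapping
it by at least one base, and replicate experiments on the same cell type
are averaged. A bin with no overlapping peak call holds exactly 0 — "no
called peak", which may mean either no signal or signal insufficient for
the upstream peak caller.

All coordinates are 0-based half-open, the native narrowPeak/BED
convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

MARKS_ACTIVATING = ("H3K4me1", "H3K4me3", "H3K27ac")


@dataclass(frozen=True)
class GenomicWindow:
    """A genomic interval [start, end) on one chromosome."""

    chrom: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"invalid region {self.chrom}:{self.start}-{self.end}: start must be < end"
            )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GenomicBin:
    """One tile of a binned window, [start, end) in genome coordinates."""

    window: GenomicWindow
    index: int
    start: int
    end: int

    @property
    def bin_id(self) -> str:
        return f"{self.window.chrom}:{self.start}-{self.end}"


@dataclass(frozen=True)
class NarrowPeakRecord:
    """One ENCODE narrowPeak (BED6+4) peak call; signalValue is fold-enrichment."""

    chrom: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0
    strand: str = "."
    signal_value: float = 0.0
    p_value: float = -1.0
    q_value: float = -1.0
    peak: int = -1

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"peak {self.chrom}:{self.start}-{self.end}: start must be < end")
        if self.signal_value < 0:
            raise ValueError(f"peak {self.name}: negative signalValue {self.signal_value}")


@dataclass
class BinEnrichmentMatrix:
    """Bins x cell types matrix of per-bin peak fold-enrichment for one mark."""

    mark: str
    bins: list[GenomicBin]
    samples: list[str]
    values: np.ndarray  # shape (n_bins, n_samples), >= 0; 0 = no called peak

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.bins), len(self.samples)):
            raise ValueError(
                f"values shape {self.values.shape} != ({len(self.bins)}, {len(self.samples)})"
            )
        if (self.values < 0).any():
            raise ValueError("fold-enrichment values must be >= 0")

    @property
    def bin_ids(self) -> list[str]:
        return [b.bin_id for b in self.bins]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.bin_ids, name="bin_id"),
                            columns=self.samples)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path, mark: str) -> "BinEnrichmentMatrix":
        df = pd.read_csv(path, sep="\t", index_col="bin_id")
        bins = []
        window = None
        for i, bin_id in enumerate(df.index):
            chrom, span = bin_id.rsplit(":", 1)
            start, end = (int(x) for x in span.split("-"))
            if window is None:
                win_end = int(str(df.index[-1]).rsplit(":", 1)[1].split("-")[1])
                window = GenomicWindow(chrom, start, win_end)
            bins.append(GenomicBin(window, i, start, end))
        return cls(mark=mark, bins=bins, samples=[str(c) for c in df.columns],
                   values=df.to_numpy(dtype=float))


def bin_window(window: GenomicWindow, bin_size: int) -> list[GenomicBin]:
    """Tile ``window`` with ``bin_size``-bp bins; the final bin may be shorter.

    Bin i covers [start + i*bin_size, min(start + (i+1)*bin_size, end)); the
    bins partition the window exactly (no gaps, no overlap).
    """
    if bin_size < 1:
        raise ValueError(f"bin_size must be >= 1, got {bin_size}")
    n = math.ceil(len(window) / bin_size)
    return [
        GenomicBin(window, i,
                   window.start + i * bin_size,
                   min(window.start + (i + 1) * bin_size, window.end))
        for i in range(n)
    ]


def read_narrowpeak(path: str | Path) -> list[NarrowPeakRecord]:
    """Parse a narrowPeak file (BED6+4, tab-separated, no header)."""
    records: list[NarrowPeakRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 7:
                raise ValueError(
                    f"{path}: line {lineno}: expected >= 7 narrowPeak columns, got {len(fields)}"
                )
            try:
                records.append(NarrowPeakRecord(
                    chrom=fields[0],
                    start=int(fields[1]),
                    end=int(fields[2]),
                    name=fields[3],
                    score=float(fields[4]),
                    strand=fields[5],
                    signal_value=float(fields[6]),
                    p_value=float(fields[7]) if len(fields) > 7 else -1.0,
                    q_value=float(fields[8]) if len(fields) > 8 else -1.0,
                    peak=int(fields[9]) if len(fields) > 9 else -1,
                ))
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: malformed narrowPeak record: {exc}") from exc
    return records


def max_enrichment_per_bin(peaks: Iterable[NarrowPeakRecord],
                           bins: Sequence[GenomicBin]) -> np.ndarray:
    """Per-bin maximum peak signalValue; 0 where no peak overlaps the bin.

    A peak is assigned to every bin it overlaps by >= 1 bp (half-open
    intersection). Peaks on other chromosomes are ignored. If several peaks
    overlap one bin, the highest signalValue wins.
    """
    if not bins:
        return np.zeros(0)
    window = bins[0].window
    bin_size = bins[0].end - bins[0].start
    out = np.zeros(len(bins))
    for p in peaks:
        if p.chrom != window.chrom or p.end <= window.start or p.start >= window.end:
            continue
        first = max(0, (p.start - window.start) // bin_size)
        last = min(len(bins), math.ceil((p.end - window.start) / bin_size))
        for i in range(first, last):
            if out[i] < p.signal_value:
                out[i] = p.signal_value
    return out


def average_replicates(vectors: Mapping[str, Sequence[np.ndarray]],
                       bins: Sequence[GenomicBin],
                       mark: str) -> BinEnrichmentMatrix:
    """Average per-sample bin vectors within each cell type.

    ``vectors`` maps cell-type label -> replicate enrichment vectors (one per
    ChIP experiment). Zeros participate in the mean: an absent peak in one
    replicate pulls the average down rather than being treated as missing.
    """
    n_bins = len(bins)
    samples = list(vectors)
    cols = []
    for cell_type in samples:
        reps = [np.asarray(v, dtype=float) for v in vectors[cell_type]]
        if not reps:
            raise ValueError(f"cell type {cell_type!r} has zero replicates")
        for v in reps:
            if v.shape != (n_bins,):
                raise ValueError(
                    f"cell type {cell_type!r}: replicate vector length {v.shape} != {n_bins} bins"
                )
        cols.append(np.mean(reps, axis=0))
    return BinEnrichmentMatrix(mark=mark, bins=list(bins), samples=samples,
                               values=np.column_stack(cols) if cols else np.zeros((n_bins, 0)))


def bin_peak_files(window: GenomicWindow, bin_size: int, mark: str,
                   peak_files: Mapping[str, Sequence[str | Path]]) -> BinEnrichmentMatrix:
    """End-to-end: narrowPeak files grouped by cell type -> averaged matrix."""
    bins = bin_window(window, bin_size)
    vectors = {
        cell_type: [max_enrichment_per_bin(read_narrowpeak(f), bins) for f in files]
        for cell_type, files in peak_files.items()
    }
    return average_replicates(vectors, bins, mark)
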