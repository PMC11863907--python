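"""Windowed cfDNA occupancy tracks and region-level confounder checks.

Occupancy here means the mean per-bp coverage of nucleosome-protected
(120-180 bp) cfDNA fragments within fixed genomic windows (10 kb by
default). Tracks are normalized by the sample's genome-wide mean coverage
so that samples sequenced to different depths are directly comparable:
a normalized track has width-weighted mean exactly 1.

GC content and copy-number-overlap utilities support post-hoc checks that
differential-occupancy regions are not explained by base composition or by
amplified segments.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .fragments import FragmentSet

DEFAULT_BIN_SIZE = 10_000

Region = tuple  # (chrom, start, end), 0-based half-open


@dataclasses.dataclass
class GenomeBins:
    """Fixed windows tiling each chromosome (0-based half-open).

    With ``step == bin_size`` (default) windows are consecutive,
    non-overlapping tiles; the last window of each chromosome may be
    shorter than ``bin_size``. ``step < bin_size`` produces true sliding
    windows for sensitivity analyses.
    """

    bin_size: int
    step: int
    chrom_order: tuple
    chrom_sizes: dict
    bin_chrom: np.ndarray
    bin_start: np.ndarray
    bin_end: np.ndarray
    chrom_slices: dict

    @property
    def n_bins(self) -> int:
        return len(self.bin_start)

    @property
    def widths(self) -> np.ndarray:
        return self.bin_end - self.bin_start

    @property
    def is_tiling(self) -> bool:
        return self.step == self.bin_size

    def regions(self) -> list:
        return list(zip(self.bin_chrom, self.bin_start, self.bin_end))

    def same_bins(self, other: "GenomeBins") -> bool:
        return (
            self.bin_size == other.bin_size
            and self.step == other.step
            and self.chrom_order == other.chrom_order
            and np.array_equal(self.bin_start, other.bin_start)
            and np.array_equal(self.bin_end, other.bin_end)
        )


def tile_genome(
    chrom_sizes: Mapping[str, int],
    bin_size: int = DEFAULT_BIN_SIZE,
    step: Optional[int] = None,
) -> GenomeBins:
    """Tile the genome into fixed windows, chromosome by chromosome.

    Each chromosome of size S yields ceil(S / step) windows starting at
    multiples of ``step`` and truncated at the chromosome end. Chromosomes
    are emitted in the input order of the sizes table.
    """
    if step is None:
        step = bin_size
    if bin_size < 1 or step < 1 or step > bin_size:
        raise ValueError("need 1 <= step <= bin_size")
    chroms, starts, ends = [], [], []
    slices: dict = {}
    order = tuple(chrom_sizes)
    for chrom in order:
        size = int(chrom_sizes[chrom])
        if size < 1:
            raise ValueError(f"chromosome {chrom!r} has nonpositive size {size}")
        first = len(starts)
        pos = 0
        while pos < size:
            chroms.append(chrom)
            starts.append(pos)
            ends.append(min(pos + bin_size, size))
            pos += step
        slices[chrom] = slice(first, len(starts))
    return GenomeBins(
        bin_size=bin_size,
        step=step,
        chrom_order=order,
        chrom_sizes={c: int(chrom_sizes[c]) for c in order},
        bin_chrom=np.array(chroms, dtype=object),
        bin_start=np.array(starts, dtype=np.int64),
        bin_end=np.array(ends, dtype=np.int64),
        chrom_slices=slices,
    )


@dataclasses.dataclass
class OccupancyTrack:
    """Per-window mean per-bp coverage for one sample.

    ``depth_constant`` holds the normalization divisor (the width-weighted
    genome-wide mean coverage) once ``normalized`` is True.
    """

    sample_id: str
    condition: str
    bins: GenomeBins
    values: np.ndarray
    normalized: bool = False
    depth_constant: float = float("nan")

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if len(self.values) != self.bins.n_bins:
            raise ValueError("values length must equal number of bins")


@dataclasses.dataclass
class CnvSegment:
    chrom: str
    start: int
    end: int
    log2_ratio: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("segment end must exceed start")


def per_base_coverage(
    fs: FragmentSet, chrom_sizes: Mapping[str, int]
) -> dict:
    """Per-bp fragment coverage arrays, one per chromosome.

    Fragments are clipped to chromosome bounds. Intended for toy genomes
    and the simulated cohorts (tens of Mb); windowed occupancy itself does
    not require per-bp arrays.
    """
    known = set(chrom_sizes)
    for chrom in np.unique(fs.chroms.astype(str)):
        if chrom not in known:
            raise ValueError(f"fragment on unknown chromosome {chrom!r}")
    cov = {}
    for chrom, size in chrom_sizes.items():
        size = int(size)
        diff = np.zeros(size + 1)
        mask = fs.chroms == chrom
        s = np.clip(fs.starts[mask], 0, size)
        e = np.clip(fs.ends[mask], 0, size)
        keep = e > s
        np.add.at(diff, s[keep], 1.0)
        np.add.at(diff, e[keep], -1.0)
        cov[chrom] = np.cumsum(diff[:-1])
    return cov


def genome_mean_coverage(fs: FragmentSet, chrom_sizes: Mapping[str, int]) -> float:
    """Genome-wide mean per-bp coverage (fragment bases / genome length)."""
    known = set(chrom_sizes)
    for chrom in np.unique(fs.chroms.astype(str)):
        if chrom not in known:
            raise ValueError(f"fragment on unknown chromosome {chrom!r}")
    total = 0
    for chrom, size in chrom_sizes.items():
        mask = fs.chroms == chrom
        if not mask.any():
            continue
        s = np.clip(fs.starts[mask], 0, int(size))
        e = np.clip(fs.ends[mask], 0, int(size))
        total += int(np.maximum(e - s, 0).sum())
    genome = sum(int(s) for s in chrom_sizes.values())
    return total / genome


def compute_occupancy(fs: FragmentSet, bins: GenomeBins) -> OccupancyTrack:
    """Mean per-bp coverage of ``fs`` within each window (unnormalized).

    A fragment contributes to every window it overlaps, proportionally to
    the overlap length; each window's total overlap is divided by the
    window width. The caller is expected to have applied the
    nucleosome-protection length filter already when the track feeds
    occupancy analyses.
    """
    values = np.zeros(bins.n_bins)
    known = set(bins.chrom_order)
    for chrom in np.unique(fs.chroms.astype(str)):
        if chrom not in known:
            raise ValueError(f"fragment on unknown chromosome {chrom!r}")
    if bins.is_tiling:
        bs = bins.bin_size
        for chrom in bins.chrom_order:
            sl = bins.chrom_slices[chrom]
            mask = fs.chroms == chrom
            if not mask.any():
                continue
            size = bins.chrom_sizes[chrom]
            s = np.clip(fs.starts[mask], 0, size)
            e = np.clip(fs.ends[mask], 0, size)
            keep = e > s
            s, e = s[keep], e[keep]
            b0 = s // bs
            b1 = (e - 1) // bs
            local = np.zeros(sl.stop - sl.start)
            one = b0 == b1
            np.add.at(local, b0[one], (e - s)[one].astype(np.float64))
            two = b1 == b0 + 1
            if two.any():
                boundary = (b0[two] + 1) * bs
                np.add.at(local, b0[two], (boundary - s[two]).astype(np.float64))
                np.add.at(local, b1[two], (e[two] - boundary).astype(np.float64))
            multi = b1 > b0 + 1
            for si, ei, bi0, bi1 in zip(s[multi], e[multi], b0[multi], b1[multi]):
                for b in range(bi0, bi1 + 1):
                    lo = max(si, b * bs)
                    hi = min(ei, (b + 1) * bs)
                    local[b] += hi - lo
            values[sl] = local
        return OccupancyTrack(
            fs.sample_id, fs.condition, bins, values / bins.widths, normalized=False
        )
    # overlapping windows: exact segment sums from a per-bp cumulative array
    cov = per_base_coverage(fs, bins.chrom_sizes)
    for chrom in bins.chrom_order:
        sl = bins.chrom_slices[chrom]
        csum = np.concatenate([[0.0], np.cumsum(cov[chrom])])
        starts = bins.bin_start[sl]
        ends = bins.bin_end[sl]
        values[sl] = csum[ends] - csum[starts]
    return OccupancyTrack(
        fs.sample_id, fs.condition, bins, values / bins.widths, normalized=False
    )


def normalize_track(track: OccupancyTrack) -> OccupancyTrack:
    """Divide by the width-weighted genome-wide mean so the mean becomes 1."""
    if track.normalized:
        raise ValueError("track is already normalized")
    widths = track.bins.widths.astype(np.float64)
    depth = float(np.sum(track.values * widths) / np.sum(widths))
    if depth <= 0:
        raise ValueError("no coverage: cannot normalize an all-zero track")
    return OccupancyTrack(
        track.sample_id,
        track.condition,
        track.bins,
        track.values / depth,
        normalized=True,
        depth_constant=depth,
    )


def gc_content(
    regions: Sequence[Region], fasta_path: str | Path
) -> tuple[np.ndarray, float]:
    """Per-region GC fraction and the width-weighted region-set mean.

    GC fraction is (#G + #C) / (#A + #C + #G + #T), case-insensitive;
    N and other ambiguity codes are excluded from the denominator. A region
    with no unambiguous bases gets NaN and is excluded from the mean.
    """
    from pyfaidx import Fasta

    fasta = Fasta(str(fasta_path), sequence_always_upper=True)
    fracs = np.empty(len(regions))
    widths = np.empty(len(regions))
    for i, (chrom, start, end) in enumerate(regions):
        if chrom not in fasta:
            raise ValueError(f"region chromosome {chrom!r} absent from FASTA")
        seqlen = len(fasta[chrom])
        if end > seqlen or start < 0 or end <= start:
            raise ValueError(
                f"region {chrom}:{start}-{end} outside sequence bounds (length {seqlen})"
            )
        seq = str(fasta[chrom][start:end])
        gc = seq.count("G") + seq.count("C")
        at = seq.count("A") + seq.count("T")
        fracs[i] = gc / (gc + at) if gc + at > 0 else np.nan
        widths[i] = end - start
    ok = np.isfinite(fracs)
    mean = float(np.sum(fracs[ok] * widths[ok]) / np.sum(widths[ok])) if ok.any() else float("nan")
    return fracs, mean


def region_cnv_overlap(
    regions: Sequence[Region],
    segments: Iterable[CnvSegment],
    log2_min: float = 1.0,
) -> float:
    """Fraction of regions overlapping (>= 1 bp) an amplified CNV segment.

    A segment qualifies when its log2 ratio strictly exceeds ``log2_min``.
    Returns 0.0 when no segment qualifies; an empty region list is an error
    (the fraction is undefined).
    """
    from intervaltree import IntervalTree

    regions = list(regions)
    if not regions:
        raise ValueError("no regions: overlap fraction undefined")
    trees: dict = {}
    for seg in segments:
        if seg.log2_ratio > log2_min:
            trees.setdefault(seg.chrom, IntervalTree()).addi(seg.start, seg.end)
    hit = 0
    for chrom, start, end in regions:
        tree = trees.get(chrom)
        if tree is not None and tree.overlap(start, end):
            hit += 1
    return hit / len(regions)


def read_chrom_sizes(path: str | Path) -> dict:
    """Read a two-column (name, length) chromosome-sizes TSV."""
    sizes: dict = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected name and length")
            try:
                size = int(fields[1])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer length") from exc
            if size < 1:
                raise ValueError(f"{path}:{lineno}: nonpositive chromosome size")
            sizes[fields[0]] = size
    return sizes


def read_cnv_segments(path: str | Path) -> list:
    """Read CNV segments from a headered TSV (chrom, start, end, log2_ratio)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "start", "end", "log2_ratio"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing CNV columns {sorted(missing)}")
    return [
        CnvSegment(str(r.chrom), int(r.start), int(r.end), float(r.log2_ratio))
        for r in df.itertuples()
    ]


def write_bedgraph(track: OccupancyTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, value in zip(
            track.bins.bin_chrom, track.bins.bin_start, track.bins.bin_end, track.values
        ):
            fh.write(f"{chrom}\t{start}\t{end}\t{value:.6g}\n")


def read_bedgraph(
    path: str | Path,
    bins: GenomeBins,
    sample_id: str = "sample",
    condition: str = "unknown",
    normalized: bool = True,
) -> OccupancyTrack:
    """Read a bedGraph written on exactly the given bins."""
    values = np.zeros(bins.n_bins)
    i = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 bedGraph columns")
            if i >= bins.n_bins:
                raise ValueError(f"{path}:{lineno}: more intervals than bins")
            if (
                fields[0] != bins.bin_chrom[i]
                or int(fields[1]) != bins.bin_start[i]
                or int(fields[2]) != bins.bin_end[i]
            ):
                raise ValueError(f"{path}:{lineno}: interval does not match bin {i}")
            values[i] = float(fields[3])
            i += 1
    if i != bins.n_bins:
        raise ValueError(f"{path}: expected {bins.n_bins} intervals, found {i}")
    return OccupancyTrack(sample_id, condition, bins, values, normalized=normalized)


def write_bins_bed(bins: GenomeBins, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in zip(bins.bin_chrom, bins.bin_start, bins.bin_end):
            fh.write(f"{chrom}\t{start}\t{end}\n")
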