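"""Fragment-level I/O and fragment-size statistics for cfDNA samples.

cfDNA fragments are double-stranded DNA intervals recovered from aligned
sequencing data. Coordinates are 0-based half-open throughout the package;
BED dialect conversion happens only at the I/O boundary (BED is already
0-based half-open, so no shift is applied on read or write).

Fragment sizes carry chromatin information: ~165 bp fragments reflect
chromatosome protection (nucleosome core + linker histone), ~150 bp the
nucleosome core particle, and ~50 bp transcription-factor-bound DNA.
Nucleosome-level occupancy analyses restrict to 120-180 bp fragments.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

CONDITIONS = ("pre", "post", "progression", "unknown")

#: inclusive nucleosome-protection length bounds applied before occupancy analyses
DEFAULT_LENGTH_BOUNDS = (120, 180)

#: 1-bp histogram support; lengths above the upper bound go to an overflow tail
#: that is excluded from peak searches
HISTOGRAM_SUPPORT = (1, 500)

DEFAULT_TF_PEAK_WINDOW = (30, 80)
DEFAULT_CORE_PEAK_WINDOW = (140, 157)
DEFAULT_CHROMATOSOME_PEAK_WINDOW = (158, 180)


@dataclasses.dataclass
class FragmentSet:
    """Sequenced cfDNA fragments of one plasma sample.

    Records are kept as parallel numpy arrays sorted by (chrom, start).
    Strand is intentionally absent: cfDNA fragments are double-stranded.
    """

    sample_id: str
    condition: str
    chroms: np.ndarray
    starts: np.ndarray
    ends: np.ndarray

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"unknown condition {self.condition!r}; expected one of {CONDITIONS}"
            )
        self.chroms = np.asarray(self.chroms, dtype=object)
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        if not (len(self.chroms) == len(self.starts) == len(self.ends)):
            raise ValueError("chroms/starts/ends must have equal length")
        if np.any(self.ends <= self.starts):
            bad = int(np.argmax(self.ends <= self.starts))
            raise ValueError(
                f"fragment {bad}: end ({self.ends[bad]}) must exceed start ({self.starts[bad]})"
            )

    @property
    def lengths(self) -> np.ndarray:
        return self.ends - self.starts

    @property
    def total_count(self) -> int:
        return len(self.starts)

    def sort(self) -> "FragmentSet":
        """Return a copy sorted by (chrom, start)."""
        order = np.lexsort((self.starts, self.chroms.astype(str)))
        return FragmentSet(
            self.sample_id,
            self.condition,
            self.chroms[order],
            self.starts[order],
            self.ends[order],
        )

    def subset(self, mask: np.ndarray) -> "FragmentSet":
        return FragmentSet(
            self.sample_id,
            self.condition,
            self.chroms[mask],
            self.starts[mask],
            self.ends[mask],
        )

    @classmethod
    def empty(cls, sample_id: str, condition: str = "unknown") -> "FragmentSet":
        z = np.array([], dtype=np.int64)
        return cls(sample_id, condition, np.array([], dtype=object), z, z)


@dataclasses.dataclass
class SizeDistribution:
    """1-bp fragment-length histogram over the closed support [1, 500].

    ``counts[L]`` is the number of fragments of length L (index 0 unused).
    Lengths above the support accumulate in ``n_overflow`` and are excluded
    from peak searches. ``sum(counts) + n_overflow == n``.
    """

    counts: np.ndarray
    n: int
    n_overflow: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (HISTOGRAM_SUPPORT[1] + 1,):
            raise ValueError(
                f"counts must have shape ({HISTOGRAM_SUPPORT[1] + 1},), one bin per bp"
            )
        if int(self.counts.sum()) + self.n_overflow != self.n:
            raise ValueError("histogram mass does not equal n")


@dataclasses.dataclass
class PeakRatioMetrics:
    """Fragment-size peak positions and peak-height ratios.

    Peaks are histogram argmaxes inside disjoint search windows for the
    chromatosome (~165 bp), nucleosome core particle (~150 bp) and
    TF-protected (~50 bp) components. A window with no counts leaves its
    peak (and any dependent ratio) as None rather than zero.
    """

    chromatosome_peak_bp: Optional[int]
    nucleosome_peak_bp: Optional[int]
    tf_peak_bp: Optional[int]
    ratio_chromatosome_nucleosome: Optional[float]
    ratio_chromatosome_tf: Optional[float]

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _check_chrom(chrom: str, chrom_sizes: Optional[Mapping[str, int]], where: str) -> None:
    if chrom_sizes is not None and chrom not in chrom_sizes:
        raise ValueError(f"{where}: chromosome {chrom!r} absent from chromosome-sizes table")


def _read_bed_like(
    path: Path,
    sample_id: str,
    condition: str,
    chrom_sizes: Optional[Mapping[str, int]],
    header: bool,
) -> FragmentSet:
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            if header and lineno == 1:
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 columns, got {len(fields)}")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if end <= start:
                raise ValueError(f"{path}:{lineno}: end ({end}) must exceed start ({start})")
            _check_chrom(chrom, chrom_sizes, f"{path}:{lineno}")
            chroms.append(chrom)
            starts.append(start)
            ends.append(end)
    fs = FragmentSet(
        sample_id,
        condition,
        np.array(chroms, dtype=object),
        np.array(starts, dtype=np.int64),
        np.array(ends, dtype=np.int64),
    )
    return fs.sort()


def _read_bam(
    path: Path,
    sample_id: str,
    condition: str,
    chrom_sizes: Optional[Mapping[str, int]],
    min_mapq: int,
) -> FragmentSet:
    import pysam

    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    with pysam.AlignmentFile(str(path), "rb") as bam:
        for read in bam.fetch(until_eof=True):
            if (
                read.is_unmapped
                or read.is_secondary
                or read.is_supplementary
                or read.is_duplicate
                or read.is_qcfail
            ):
                continue
            if not read.is_proper_pair:
                continue
            if read.mapping_quality < min_mapq:
                continue
            tlen = read.template_length
            if tlen <= 0:  # count each template once, from its leftmost mate
                continue
            chrom = read.reference_name
            _check_chrom(chrom, chrom_sizes, str(path))
            chroms.append(chrom)
            starts.append(read.reference_start)
            ends.append(read.reference_start + tlen)
    fs = FragmentSet(
        sample_id,
        condition,
        np.array(chroms, dtype=object),
        np.array(starts, dtype=np.int64),
        np.array(ends, dtype=np.int64),
    )
    return fs.sort()


def read_fragments(
    path: str | Path,
    fmt: str = "auto",
    sample_id: str = "sample",
    condition: str = "unknown",
    chrom_sizes: Optional[Mapping[str, int]] = None,
    min_mapq: int = 20,
) -> FragmentSet:
    """Read aligned cfDNA fragments from BAM, BED or headered TSV.

    BAM input yields one fragment per properly paired template (leftmost
    mate start + template length), excluding duplicate, secondary,
    supplementary, unmapped and low-MAPQ reads. BED/TSV input yields one
    fragment per data line. Fragments are returned sorted by
    (chrom, start). An empty file yields an empty FragmentSet.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt == "auto":
        suffix = path.suffix.lower()
        fmt = {"bam": "bam", ".bam": "bam", ".bed": "bed", ".tsv": "tsv"}.get(suffix, "bed")
    if fmt == "bam":
        return _read_bam(path, sample_id, condition, chrom_sizes, min_mapq)
    if fmt == "bed":
        return _read_bed_like(path, sample_id, condition, chrom_sizes, header=False)
    if fmt == "tsv":
        return _read_bed_like(path, sample_id, condition, chrom_sizes, header=True)
    raise ValueError(f"unknown fragment format {fmt!r}; expected bam, bed or tsv")


def filter_by_length(
    fs: FragmentSet,
    lo: int = DEFAULT_LENGTH_BOUNDS[0],
    hi: int = DEFAULT_LENGTH_BOUNDS[1],
) -> FragmentSet:
    """Keep fragments with lo <= length <= hi (both bounds inclusive)."""
    if lo > hi:
        raise ValueError(f"lower bound {lo} exceeds upper bound {hi}")
    lengths = fs.lengths
    return fs.subset((lengths >= lo) & (lengths <= hi))


def size_histogram(fs: FragmentSet) -> SizeDistribution:
    """Tabulate fragment lengths into a 1-bp histogram on [1, 500]."""
    return length_histogram(fs.lengths)


def length_histogram(lengths: np.ndarray) -> SizeDistribution:
    lengths = np.asarray(lengths, dtype=np.int64)
    if np.any(lengths < 1):
        raise ValueError("fragment lengths must be >= 1")
    hi = HISTOGRAM_SUPPORT[1]
    in_support = lengths <= hi
    counts = np.bincount(lengths[in_support], minlength=hi + 1)
    return SizeDistribution(
        counts=counts, n=len(lengths), n_overflow=int((~in_support).sum())
    )


def _window_peak(counts: np.ndarray, window: tuple[int, int]) -> Optional[int]:
    lo, hi = window
    seg = counts[lo : hi + 1]
    if seg.size == 0 or seg.max() == 0:
        return None
    return lo + int(np.argmax(seg))  # first occurrence -> smallest length on ties


def peak_ratio_metrics(
    dist: SizeDistribution,
    tf_window: tuple[int, int] = DEFAULT_TF_PEAK_WINDOW,
    core_window: tuple[int, int] = DEFAULT_CORE_PEAK_WINDOW,
    chromatosome_window: tuple[int, int] = DEFAULT_CHROMATOSOME_PEAK_WINDOW,
) -> PeakRatioMetrics:
    """Locate the three protection-mode peaks and form their height ratios.

    Each peak is the argmax of the histogram within its (inclusive) search
    window, ties resolved toward the smallest length. Ratios are
    chromatosome/nucleosome-core and chromatosome/TF peak heights.
    """
    windows = sorted([tf_window, core_window, chromatosome_window])
    for (a_lo, a_hi), (b_lo, b_hi) in zip(windows, windows[1:]):
        if b_lo <= a_hi:
            raise ValueError("peak search windows must be disjoint")
    lo_support, hi_support = HISTOGRAM_SUPPORT
    for lo, hi in windows:
        if lo < lo_support or hi > hi_support or lo > hi:
            raise ValueError(f"window ({lo}, {hi}) outside histogram support")

    chrom_peak = _window_peak(dist.counts, chromatosome_window)
    core_peak = _window_peak(dist.counts, core_window)
    tf_peak = _window_peak(dist.counts, tf_window)

    def _ratio(num: Optional[int], den: Optional[int]) -> Optional[float]:
        if num is None or den is None:
            return None
        return float(dist.counts[num]) / float(dist.counts[den])

    return PeakRatioMetrics(
        chromatosome_peak_bp=chrom_peak,
        nucleosome_peak_bp=core_peak,
        tf_peak_bp=tf_peak,
        ratio_chromatosome_nucleosome=_ratio(chrom_peak, core_peak),
        ratio_chromatosome_tf=_ratio(chrom_peak, tf_peak),
    )


def write_fragments_bed(fs: FragmentSet, path: str | Path) -> None:
    """Write fragments as 3-column BED (0-based half-open)."""
    with open(path, "w") as fh:
        for chrom, start, end in zip(fs.chroms, fs.starts, fs.ends):
            fh.write(f"{chrom}\t{start}\t{end}\n")


def write_size_tsv(dist: SizeDistribution, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("length\tcount\n")
        for length in range(HISTOGRAM_SUPPORT[0], HISTOGRAM_SUPPORT[1] + 1):
            fh.write(f"{length}\t{dist.counts[length]}\n")


def write_metrics_json(metrics: PeakRatioMetrics, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(metrics.to_dict(), fh, indent=2)
        fh.write("\n")


def write_fragments_bam(
    fs: FragmentSet,
    path: str | Path,
    chrom_sizes: Mapping[str, int],
    read_length: int = 75,
) -> None:
    """Write fragments as a coordinate-sorted, indexed BAM of proper pairs.

    Each fragment becomes one read pair: read 1 on the forward strand at the
    fragment start, read 2 reversed at the fragment end. Intended for
    generating test inputs and interoperating with alignment-based tools.
    """
    import pysam

    path = Path(path)
    names = list(chrom_sizes)
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": name, "LN": int(chrom_sizes[name])} for name in names],
    }
    tid = {name: i for i, name in enumerate(names)}
    reads = []
    for i, (chrom, start, end) in enumerate(zip(fs.chroms, fs.starts, fs.ends)):
        start, end = int(start), int(end)
        rlen = min(read_length, end - start)
        for is_read2 in (False, True):
            a = pysam.AlignedSegment()
            a.query_name = f"frag{i}"
            a.reference_id = tid[chrom]
            a.mapping_quality = 60
            a.query_sequence = "A" * rlen
            a.query_qualities = pysam.qualitystring_to_array("I" * rlen)
            a.cigarstring = f"{rlen}M"
            a.next_reference_id = tid[chrom]
            if not is_read2:
                a.reference_start = start
                a.next_reference_start = end - rlen
                a.template_length = end - start
                a.flag = 0x1 | 0x2 | 0x20 | 0x40  # paired, proper, mate reverse, read1
            else:
                a.reference_start = end - rlen
                a.next_reference_start = start
                a.template_length = -(end - start)
                a.flag = 0x1 | 0x2 | 0x10 | 0x80  # paired, proper, reverse, read2
            reads.append(a)
    reads.sort(key=lambda a: (a.reference_id, a.reference_start))
    with pysam.AlignmentFile(str(path), "wb", header=header) as bam:
        for a in reads:
            bam.write(a)
    pysam.index(str(path))
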