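"""Aggregate cfDNA occupancy profiles and activity scores at TF binding sites.

A transcription factor bound at its site displaces nucleosome-sized cfDNA
fragments from the site center, so the normalized read depth at TFBS
centers is an *inverse* proxy for TF binding: higher center depth means
less binding, predicting lower expression of the factor's program.

Two read-outs are computed from length-filtered (120-180 bp) fragments:

* aggregate profiles — the per-condition mean normalized coverage as a
  function of distance from the site center, strand-oriented;
* activity scores — one value per sample per TF, the mean normalized
  coverage within +/- ``half_width`` bp of the site centers.

Scores are related to matched tumor expression (Spearman/Pearson), tumor
fraction (Pearson) and clinical groups (Mann-Whitney U).
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .fragments import FragmentSet
from .occupancy import genome_mean_coverage, per_base_coverage

DEFAULT_HALF_WIDTH = 15
DEFAULT_FLANK = 2000
DEFAULT_STEP = 10


@dataclasses.dataclass
class BindingSiteSet:
    """TF binding sites with centers, strands and optional strengths.

    ``center = floor((start + end) / 2)``; strand "." is treated as "+"
    in strand-oriented computations; ``strengths`` is NaN where absent.
    """

    tf_name: str
    chroms: np.ndarray
    starts: np.ndarray
    ends: np.ndarray
    strands: np.ndarray
    strengths: np.ndarray
    source: str = "database"

    def __post_init__(self) -> None:
        if not self.tf_name:
            raise ValueError("tf_name must be nonempty")
        self.chroms = np.asarray(self.chroms, dtype=object)
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        self.strands = np.asarray(self.strands, dtype=object)
        self.strengths = np.asarray(self.strengths, dtype=np.float64)
        n = len(self.starts)
        if not all(len(a) == n for a in (self.chroms, self.ends, self.strands, self.strengths)):
            raise ValueError("site arrays must have equal length")
        if np.any(self.ends <= self.starts):
            raise ValueError("site end must exceed start")

    @property
    def n_sites(self) -> int:
        return len(self.starts)

    @property
    def centers(self) -> np.ndarray:
        return (self.starts + self.ends) // 2

    def subset(self, idx: np.ndarray) -> "BindingSiteSet":
        return BindingSiteSet(
            self.tf_name,
            self.chroms[idx],
            self.starts[idx],
            self.ends[idx],
            self.strands[idx],
            self.strengths[idx],
            self.source,
        )

    def sort(self) -> "BindingSiteSet":
        order = np.lexsort((self.starts, self.chroms.astype(str)))
        return self.subset(order)


@dataclasses.dataclass
class AggregateProfile:
    """Mean normalized coverage around site centers, one curve per condition.

    ``offsets`` are multiples of ``step`` in [-flank, flank], symmetric
    about 0; each value averages the per-bp curve within floor(step/2) bp
    of the offset. ``curves`` maps condition -> per-offset mean over the
    condition's samples (each sample itself averages sites with equal
    weight per site).
    """

    tf_name: str
    offsets: np.ndarray
    curves: dict
    n_sites: int
    flank: int
    step: int


@dataclasses.dataclass
class ActivityScore:
    """Per-sample TF activity read-out: mean normalized center depth.

    Higher score = more center coverage = less TF binding.
    """

    sample_id: str
    tf_name: str
    score: float
    condition: str = "unknown"


@dataclasses.dataclass
class CorrelationResult:
    coefficient: float  # NaN when undefined (constant input)
    p_value: float
    n: int
    method: str


@dataclasses.dataclass
class GroupComparison:
    u_statistic: float
    p_value: float
    medians: dict
    n: dict


def load_sites(
    path: str | Path,
    tf_name: str,
    strength_col: Optional[int] = None,
    source: str = "database",
) -> BindingSiteSet:
    """Load TF binding sites from BED.

    Strand is read from column 6 when present (else "."). Strength is read
    from 0-based column ``strength_col``; when None, the BED score column
    (index 4) is used if the line has >= 5 fields.
    """
    chroms, starts, ends, strands, strengths = [], [], [], [], []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if end <= start:
                raise ValueError(f"{path}:{lineno}: end must exceed start")
            col = strength_col if strength_col is not None else 4
            strength = math.nan
            if col < len(fields):
                try:
                    strength = float(fields[col])
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: non-numeric strength") from exc
            strand = fields[5] if len(fields) >= 6 and fields[5] in ("+", "-") else "."
            chroms.append(fields[0])
            starts.append(start)
            ends.append(end)
            strands.append(strand)
            strengths.append(strength)
    sites = BindingSiteSet(
        tf_name,
        np.array(chroms, dtype=object),
        np.array(starts, dtype=np.int64),
        np.array(ends, dtype=np.int64),
        np.array(strands, dtype=object),
        np.array(strengths, dtype=np.float64),
        source=source,
    )
    return sites.sort()


def write_sites_bed(sites: BindingSiteSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i in range(sites.n_sites):
            strength = sites.strengths[i]
            score = "0" if math.isnan(strength) else f"{strength:g}"
            fh.write(
                f"{sites.chroms[i]}\t{sites.starts[i]}\t{sites.ends[i]}\t"
                f"{sites.tf_name}_{i}\t{score}\t{sites.strands[i]}\n"
            )


def select_top_fraction(sites: BindingSiteSet, fraction: float = 0.5) -> BindingSiteSet:
    """Keep the ceil(fraction * n) strongest sites.

    Ties are broken by (chrom, start) ascending so the selection is
    deterministic; the result is sorted genomically.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if sites.n_sites == 0:
        return sites
    if np.any(~np.isfinite(sites.strengths)):
        raise ValueError("all sites need a strength to rank by")
    k = math.ceil(fraction * sites.n_sites)
    order = sorted(
        range(sites.n_sites),
        key=lambda i: (-sites.strengths[i], str(sites.chroms[i]), int(sites.starts[i])),
    )
    return sites.subset(np.array(order[:k], dtype=np.intp)).sort()


def _usable_site_indices(
    sites: BindingSiteSet, chrom_sizes: Mapping[str, int], flank: int
) -> np.ndarray:
    centers = sites.centers
    keep = []
    for i in range(sites.n_sites):
        chrom = sites.chroms[i]
        if chrom not in chrom_sizes:
            continue
        c = int(centers[i])
        if c - flank >= 0 and c + flank < int(chrom_sizes[chrom]):
            keep.append(i)
    return np.array(keep, dtype=np.intp)


def _normalized_coverage(
    fs: FragmentSet, chrom_sizes: Mapping[str, int]
) -> tuple[dict, float]:
    cov = per_base_coverage(fs, chrom_sizes)
    mean = genome_mean_coverage(fs, chrom_sizes)
    if mean <= 0:
        raise ValueError(f"sample {fs.sample_id!r} has no coverage")
    return {c: a / mean for c, a in cov.items()}, mean


def _sample_site_curve(
    cov: Mapping[str, np.ndarray], sites: BindingSiteSet, usable: np.ndarray, flank: int
) -> np.ndarray:
    """Equal-weight mean over sites of the per-bp coverage in [-flank, flank]."""
    total = np.zeros(2 * flank + 1)
    centers = sites.centers
    for i in usable:
        c = int(centers[i])
        window = cov[sites.chroms[i]][c - flank : c + flank + 1]
        if sites.strands[i] == "-":
            window = window[::-1]
        total += window
    return total / len(usable)


def _bin_curve(curve: np.ndarray, flank: int, step: int) -> tuple[np.ndarray, np.ndarray]:
    if step == 1:
        return np.arange(-flank, flank + 1), curve
    half = step // 2
    offsets = np.arange(-(flank // step) * step, (flank // step) * step + 1, step)
    values = np.empty(len(offsets))
    for j, off in enumerate(offsets):
        lo = max(off - half, -flank) + flank
        hi = min(off + half, flank) + flank
        values[j] = curve[lo : hi + 1].mean()
    return offsets, values


def aggregate_profile(
    samples: Sequence[FragmentSet],
    sites: BindingSiteSet,
    chrom_sizes: Mapping[str, int],
    flank: int = DEFAULT_FLANK,
    step: int = DEFAULT_STEP,
) -> AggregateProfile:
    """Per-condition aggregate normalized-coverage profile around site centers.

    Fragments are expected to be length-filtered already. Per sample, the
    per-bp coverage (normalized to genome mean 1) is extracted around each
    usable center, orientation-flipped for "-" sites, and averaged with
    equal weight per site; per condition, sample curves are averaged with
    equal weight per sample. Sites whose flanks cross a chromosome edge
    are dropped.
    """
    if sites.n_sites == 0:
        raise ValueError("no binding sites given")
    usable = _usable_site_indices(sites, chrom_sizes, flank)
    if len(usable) == 0:
        raise ValueError("no usable sites: all flanks cross chromosome edges")
    by_condition: dict = {}
    for fs in samples:
        cov, _ = _normalized_coverage(fs, chrom_sizes)
        curve = _sample_site_curve(cov, sites, usable, flank)
        by_condition.setdefault(fs.condition, []).append(curve)
    offsets = None
    curves = {}
    for condition, sample_curves in by_condition.items():
        mean_curve = np.mean(sample_curves, axis=0)
        offsets, binned = _bin_curve(mean_curve, flank, step)
        curves[condition] = binned
    return AggregateProfile(
        tf_name=sites.tf_name,
        offsets=offsets,
        curves=curves,
        n_sites=len(usable),
        flank=flank,
        step=step,
    )


def tfbs_center_depth(
    fs: FragmentSet,
    sites: BindingSiteSet,
    chrom_sizes: Mapping[str, int],
    half_width: int = DEFAULT_HALF_WIDTH,
) -> ActivityScore:
    """Mean normalized coverage in [center - half_width, center + half_width].

    Coverage is normalized to genome-wide mean 1 before averaging, first
    within each site's center window, then with equal weight across sites.
    ``half_width`` 0 reads the single center base.
    """
    if sites.n_sites == 0:
        raise ValueError("no binding sites given")
    usable = _usable_site_indices(sites, chrom_sizes, half_width)
    if len(usable) == 0:
        raise ValueError("no usable sites for center-depth scoring")
    mean_cov = genome_mean_coverage(fs, chrom_sizes)
    if mean_cov <= 0:
        raise ValueError(f"sample {fs.sample_id!r} has no coverage")
    # window coverage = sum of fragment overlaps with [c-hw, c+hw], computed
    # directly from the (chrom, start)-sorted fragment arrays — no per-bp
    # genome array is needed for center scoring
    centers = sites.centers
    max_len = int(fs.lengths.max()) if fs.total_count else 0
    width = 2 * half_width + 1
    by_chrom = {}
    for chrom in np.unique(fs.chroms.astype(str)):
        mask = fs.chroms == chrom
        by_chrom[chrom] = (fs.starts[mask], fs.ends[mask])
    site_means = np.empty(len(usable))
    for j, i in enumerate(usable):
        c = int(centers[i])
        lo_pos, hi_pos = c - half_width, c + half_width + 1
        arrs = by_chrom.get(str(sites.chroms[i]))
        if arrs is None:
            site_means[j] = 0.0
            continue
        starts, ends = arrs
        lo = np.searchsorted(starts, lo_pos - max_len, "left")
        hi = np.searchsorted(starts, hi_pos, "left")
        s, e = starts[lo:hi], ends[lo:hi]
        overlap = np.minimum(e, hi_pos) - np.maximum(s, lo_pos)
        site_means[j] = overlap[overlap > 0].sum() / width
    site_means /= mean_cov
    return ActivityScore(
        sample_id=fs.sample_id,
        tf_name=sites.tf_name,
        score=float(site_means.mean()),
        condition=fs.condition,
    )


def _paired(
    a: Mapping[str, float], b: Mapping[str, float]
) -> tuple[np.ndarray, np.ndarray, int]:
    shared = [
        s
        for s in a
        if s in b and np.isfinite(a[s]) and np.isfinite(b[s])
    ]
    x = np.array([a[s] for s in shared])
    y = np.array([b[s] for s in shared])
    return x, y, len(shared)


def correlate_activity_expression(
    scores: Mapping[str, float],
    expression: Mapping[str, float],
    method: str = "spearman",
) -> CorrelationResult:
    """Correlate per-sample center-depth scores with matched expression.

    Pairs with missing values are dropped. A constant vector leaves the
    coefficient (and p) as NaN — the "undefined" marker.
    """
    if method not in ("spearman", "pearson"):
        raise ValueError("method must be 'spearman' or 'pearson'")
    x, y, n = _paired(scores, expression)
    if n < 3:
        raise ValueError(f"need >= 3 paired samples, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(float("nan"), float("nan"), n, method)
    if method == "spearman":
        rho, p = stats.spearmanr(x, y)
    else:
        rho, p = stats.pearsonr(x, y)
    return CorrelationResult(float(rho), float(p), n, method)


def correlate_with_tumor_fraction(
    scores: Mapping[str, float], tumor_fraction: Mapping[str, float]
) -> CorrelationResult:
    """Pearson correlation of center-depth scores with tumor fraction."""
    x, y, n = _paired(scores, tumor_fraction)
    if n < 3:
        raise ValueError(f"need >= 3 paired samples, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(float("nan"), float("nan"), n, "pearson")
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(float(r), float(p), n, "pearson")


def compare_groups(
    scores: Mapping[str, float], groups: Mapping[str, str]
) -> GroupComparison:
    """Two-sided Mann-Whitney U test between two labeled score groups.

    ``groups`` maps sample_id to a label; exactly two labels must be
    present among the scored samples. The U statistic is reported for the
    lexicographically first label's group; tie correction is applied.
    """
    labels = sorted({groups[s] for s in scores if s in groups})
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 groups, got {labels}")
    a = [scores[s] for s in scores if groups.get(s) == labels[0]]
    b = [scores[s] for s in scores if groups.get(s) == labels[1]]
    if not a or not b:
        raise ValueError("each group needs >= 1 sample")
    u, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    return GroupComparison(
        u_statistic=float(u),
        p_value=float(p),
        medians={labels[0]: float(np.median(a)), labels[1]: float(np.median(b))},
        n={labels[0]: len(a), labels[1]: len(b)},
    )


def write_profile_tsv(profile: AggregateProfile, path: str | Path) -> None:
    conditions = sorted(profile.curves)
    with open(path, "w") as fh:
        fh.write("offset\t" + "\t".join(conditions) + "\n")
        for j, off in enumerate(profile.offsets):
            row = "\t".join(f"{profile.curves[c][j]:.6g}" for c in conditions)
            fh.write(f"{off}\t{row}\n")


def write_scores_tsv(scores: Sequence[ActivityScore], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tcondition\ttf_name\tscore\n")
        for s in scores:
            fh.write(f"{s.sample_id}\t{s.condition}\t{s.tf_name}\t{s.score:.6g}\n")
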