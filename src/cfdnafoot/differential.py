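"""Stability-filtered differential-occupancy calling between conditions.

The procedure is purely threshold-based, with two criteria applied to
depth-normalized 10-kb occupancy tracks:

1. *Stability*: within each condition, a window is stable when the relative
   deviation (sample standard deviation / mean, RSD) of the normalized
   occupancies across samples is strictly below ``rsd_max`` (default 0.5).
2. *Change*: for windows stable in both conditions, the signed relative
   change of the condition means, (mean_post - mean_pre) / mean_pre, must
   strictly exceed ``change_min`` (default 0.4) in magnitude.

Windows passing both criteria are "gained-nucleosome" regions when
occupancy increases post-treatment and "lost-nucleosome" regions when it
decreases. No p-values or multiple-testing control are involved.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .occupancy import GenomeBins, OccupancyTrack

DEFAULT_RSD_MAX = 0.5
DEFAULT_CHANGE_MIN = 0.4


@dataclasses.dataclass
class ConditionGroup:
    """Two or more normalized occupancy tracks sharing one condition label."""

    condition: str
    tracks: Sequence[OccupancyTrack]

    def __post_init__(self) -> None:
        if len(self.tracks) < 2:
            raise ValueError("a condition group needs >= 2 samples (RSD undefined for 1)")
        bins = self.tracks[0].bins
        for t in self.tracks:
            if not t.normalized:
                raise ValueError(f"track {t.sample_id!r} is not normalized")
            if not t.bins.same_bins(bins):
                raise ValueError("tracks in a group must share identical bins")

    @property
    def bins(self) -> GenomeBins:
        return self.tracks[0].bins

    def matrix(self) -> np.ndarray:
        return np.vstack([t.values for t in self.tracks])


@dataclasses.dataclass
class StabilityResult:
    rsd: np.ndarray  # NaN marks "undefined" (zero-mean windows)
    stable_mask: np.ndarray
    rsd_max: float


@dataclasses.dataclass
class DifferentialRegion:
    chrom: str
    start: int
    end: int
    mean_pre: float
    mean_post: float
    rel_change: float
    direction: str  # "gained" | "lost"


@dataclasses.dataclass
class DifferentialRegionSet:
    regions: list
    n_gained: int
    n_lost: int
    rsd_max: float
    change_min: float
    stats: pd.DataFrame  # per-bin table: rsd_pre, rsd_post, means, rel_change, call
    no_stable_bins: bool = False


def relative_deviation(values: Sequence[float]) -> float:
    """Sample standard deviation (n-1 denominator) divided by the mean.

    Returns NaN (the "undefined" marker) when the mean is zero.
    """
    arr = np.asarray(values, dtype=np.float64)
    if arr.size < 2:
        raise ValueError("relative deviation requires >= 2 values")
    mean = arr.mean()
    if mean == 0:
        return float("nan")
    return float(arr.std(ddof=1) / mean)


def stable_bins(group: ConditionGroup, rsd_max: float = DEFAULT_RSD_MAX) -> StabilityResult:
    """Per-bin RSD across the group's samples and the stability mask.

    A bin is stable when its RSD is defined (positive mean) and strictly
    below ``rsd_max``.
    """
    mat = group.matrix()
    means = mat.mean(axis=0)
    sds = mat.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        rsd = np.where(means > 0, sds / means, np.nan)
    mask = np.isfinite(rsd) & (rsd < rsd_max) & (means > 0)
    return StabilityResult(rsd=rsd, stable_mask=mask, rsd_max=rsd_max)


def call_differential(
    pre: ConditionGroup,
    post: ConditionGroup,
    rsd_max: float = DEFAULT_RSD_MAX,
    change_min: float = DEFAULT_CHANGE_MIN,
    denominator: str = "pre",
) -> DifferentialRegionSet:
    """Call gained-/lost-nucleosome windows between two condition groups.

    Only windows stable (RSD < rsd_max) in *both* conditions are compared.
    ``denominator`` controls the relative-change definition: ``"pre"``
    (default) divides by the pre-treatment mean; ``"symmetric"`` divides by
    the average of the two condition means. Calls require the magnitude to
    strictly exceed ``change_min``; regions are single windows (no merging)
    emitted in genomic order.
    """
    if not pre.bins.same_bins(post.bins):
        raise ValueError("pre and post groups must share identical bins")
    if denominator not in ("pre", "symmetric"):
        raise ValueError("denominator must be 'pre' or 'symmetric'")
    bins = pre.bins
    s_pre = stable_bins(pre, rsd_max)
    s_post = stable_bins(post, rsd_max)
    mean_pre = pre.matrix().mean(axis=0)
    mean_post = post.matrix().mean(axis=0)
    both = s_pre.stable_mask & s_post.stable_mask
    den = mean_pre if denominator == "pre" else 0.5 * (mean_pre + mean_post)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel_change = np.where(den > 0, (mean_post - mean_pre) / den, np.nan)
    call = np.full(bins.n_bins, "", dtype=object)
    gained = both & np.isfinite(rel_change) & (rel_change > change_min)
    lost = both & np.isfinite(rel_change) & (rel_change < -change_min)
    call[gained] = "gained"
    call[lost] = "lost"

    regions = [
        DifferentialRegion(
            chrom=str(bins.bin_chrom[b]),
            start=int(bins.bin_start[b]),
            end=int(bins.bin_end[b]),
            mean_pre=float(mean_pre[b]),
            mean_post=float(mean_post[b]),
            rel_change=float(rel_change[b]),
            direction=str(call[b]),
        )
        for b in np.flatnonzero(gained | lost)
    ]
    stats = pd.DataFrame(
        {
            "chrom": bins.bin_chrom,
            "start": bins.bin_start,
            "end": bins.bin_end,
            "rsd_pre": s_pre.rsd,
            "rsd_post": s_post.rsd,
            "mean_pre": mean_pre,
            "mean_post": mean_post,
            "rel_change": rel_change,
            "stable_both": both,
            "call": call,
        }
    )
    return DifferentialRegionSet(
        regions=regions,
        n_gained=int(gained.sum()),
        n_lost=int(lost.sum()),
        rsd_max=rsd_max,
        change_min=change_min,
        stats=stats,
        no_stable_bins=not bool(both.any()),
    )


def export_regions(drs: DifferentialRegionSet, path: str | Path) -> None:
    """Write calls as BED6: name = direction, score = 1000 * min(|change|, 1)."""
    with open(path, "w") as fh:
        for r in drs.regions:
            score = int(round(1000 * min(abs(r.rel_change), 1.0)))
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.direction}\t{score}\t.\n")


def read_regions_bed(path: str | Path) -> list:
    """Round-trip reader for :func:`export_regions` output (coords + direction)."""
    out = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}:{lineno}: expected BED6")
            out.append((fields[0], int(fields[1]), int(fields[2]), fields[3]))
    return out


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Read a sample sheet TSV; requires sample_id, condition and path columns."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "condition"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing sample-sheet columns {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"{path}: duplicate sample_id {dupes}")
    return df
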