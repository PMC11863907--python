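import numpy as np
import pytest

from cfdnafoot import (
    compute_occupancy,
    default_cohort_config,
    filter_by_length,
    normalize_track,
    simulate_cohort,
    tile_genome,
)
from cfdnafoot.fragments import FragmentSet


def make_fragments(records, sample_id="s", condition="unknown"):
    """Build a FragmentSet from (chrom, start, end) tuples."""
    if not records:
        return FragmentSet.empty(sample_id, condition)
    chroms, starts, ends = zip(*records)
    fs = FragmentSet(
        sample_id,
        condition,
        np.array(chroms, dtype=object),
        np.array(starts, dtype=np.int64),
        np.array(ends, dtype=np.int64),
    )
    return fs.sort()


def brute_force_bin_coverage(records, chrom_sizes, bin_size):
    """Per-bin mean coverage via an explicit per-bp count (oracle)."""
    depth = {c: [0] * size for c, size in chrom_sizes.items()}
    for chrom, start, end in records:
        for pos in range(max(start, 0), min(end, chrom_sizes[chrom])):
            depth[chrom][pos] += 1
    values = []
    for chrom, size in chrom_sizes.items():
        pos = 0
        while pos < size:
            stop = min(pos + bin_size, size)
            values.append(sum(depth[chrom][pos:stop]) / (stop - pos))
            pos = stop
    return np.array(values)


@pytest.fixture(scope="session")
def default_cohort():
    cfg = default_cohort_config(seed=17)
    frags, truth, sites = simulate_cohort(cfg)
    return cfg, frags, truth, sites


@pytest.fixture(scope="session")
def default_tracks(default_cohort):
    cfg, frags, _, _ = default_cohort
    bins = tile_genome(cfg.chrom_sizes, cfg.window_size)
    tracks = {
        sid: normalize_track(compute_occupancy(filter_by_length(fs), bins))
        for sid, fs in frags.items()
    }
    return bins, tracks
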