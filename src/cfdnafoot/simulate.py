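"""Synthetic cfDNA cohort generator with ground-truth tables.

The generator emulates the statistical structure that the occupancy and
TFBS analyses assume, on a small flat genome (two 10-Mb chromosomes by
default):

* fragment lengths from a three-component nucleosome-protection mixture —
  chromatosome (~165 bp), nucleosome core particle (~150 bp) and
  TF-protected (~50 bp) fragments;
* per-sample sequencing depth around a 0.1x target, with controllable
  window-to-window multiplicative noise;
* planted condition-level occupancy shifts in selected 10-kb windows
  (treatment-level chromatin remodelling of the plasma pool: gained
  windows rise post-treatment, lost windows fall, progression reverts
  halfway);
* TF binding-site footprints carried by the tumor-derived fraction of
  fragments: at sites "open" in the tumor, nucleosome-sized tumor
  fragments overlapping the footprint are replaced by short TF-protected
  fragments flanking the center, so the center dip deepens with
  tumor_fraction x activity;
* expression linked negatively to the expected TFBS center depth.

Every planted quantity is emitted in a :class:`SimulationTruth` so that
downstream assertions can compare recovered values against ground truth.
All randomness flows from a single seed through one spawned child stream
per sample, so adding a sample does not perturb the others.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .fragments import FragmentSet
from .occupancy import tile_genome

DEFAULT_CHROM_SIZES = {"chr1": 10_000_000, "chr2": 10_000_000}
DEFAULT_WINDOW_SIZE = 10_000

#: per-window multiplicative depth noise (relative sd across samples); this is
#: the generator's stand-in for biological + technical variability left after
#: depth normalization, and sets the RSD seen by the stability filter
DEFAULT_WINDOW_NOISE_RSD = 0.1

#: fraction of a planted effect retained at disease progression (gained
#: regions decline at progression but stay above pre-treatment level)
PROGRESSION_EFFECT_RETENTION = 0.5


@dataclasses.dataclass
class SizeMixture:
    """Three-component fragment-length mixture, truncated to ``support``.

    Component order: chromatosome, nucleosome core particle, TF-protected.
    """

    weights: tuple = (0.55, 0.35, 0.10)
    means: tuple = (165.0, 150.0, 50.0)
    sds: tuple = (5.0, 5.0, 10.0)
    support: tuple = (30, 400)

    def validate(self) -> None:
        if len(self.weights) != 3 or len(self.means) != 3 or len(self.sds) != 3:
            raise ValueError("size mixture needs exactly 3 components")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError(f"mixture weights must sum to 1, got {sum(self.weights)}")
        if any(w < 0 for w in self.weights):
            raise ValueError("mixture weights must be nonnegative")
        if self.support[0] < 1 or self.support[1] <= self.support[0]:
            raise ValueError("invalid length support")

    @property
    def mean_length(self) -> float:
        return float(sum(w * m for w, m in zip(self.weights, self.means)))


@dataclasses.dataclass
class SampleSpec:
    sample_id: str
    condition: str
    tumor_fraction: float
    platinum_status: str = "unknown"
    target_mean_coverage: float = 0.1

    def validate(self) -> None:
        if not 0 <= self.tumor_fraction <= 1:
            raise ValueError(
                f"sample {self.sample_id!r}: tumor_fraction {self.tumor_fraction} not in [0, 1]"
            )
        if self.target_mean_coverage <= 0:
            raise ValueError(f"sample {self.sample_id!r}: nonpositive target coverage")


@dataclasses.dataclass
class TFSpec:
    """A simulated transcription factor: site count and per-condition activity.

    ``activity`` is the probability that a site is open (TF-bound) in the
    tumor compartment under each condition.
    """

    name: str
    n_sites: int = 500
    activity: dict = dataclasses.field(
        default_factory=lambda: {"pre": 0.5, "post": 0.5, "progression": 0.5}
    )
    footprint_half_width: int = 25
    site_length: int = 20

    def validate(self) -> None:
        if self.n_sites < 1:
            raise ValueError(f"TF {self.name!r}: need >= 1 site")
        for cond, a in self.activity.items():
            if not 0 <= a <= 1:
                raise ValueError(f"TF {self.name!r}: activity {a} not in [0, 1] ({cond})")


@dataclasses.dataclass
class SimulationConfig:
    seed: int = 17
    chrom_sizes: dict = dataclasses.field(default_factory=lambda: dict(DEFAULT_CHROM_SIZES))
    window_size: int = DEFAULT_WINDOW_SIZE
    nucleosome_repeat: int = 200
    phased: bool = False
    samples: list = dataclasses.field(default_factory=list)
    size_mixture: SizeMixture = dataclasses.field(default_factory=SizeMixture)
    planted_windows: list = dataclasses.field(default_factory=list)  # (index, effect)
    tfs: list = dataclasses.field(default_factory=list)
    expression_link: tuple = (10.0, 10.0, 1.0)  # intercept, slope, noise sd
    window_noise_rsd: float = DEFAULT_WINDOW_NOISE_RSD

    def validate(self) -> None:
        self.size_mixture.validate()
        if not self.samples:
            raise ValueError("config has no samples")
        seen = set()
        for s in self.samples:
            s.validate()
            if s.sample_id in seen:
                raise ValueError(f"duplicate sample_id {s.sample_id!r}")
            seen.add(s.sample_id)
        for tf in self.tfs:
            tf.validate()
        bins = tile_genome(self.chrom_sizes, self.window_size)
        for idx, effect in self.planted_windows:
            if not 0 <= idx < bins.n_bins:
                raise ValueError(f"planted window index {idx} out of range")
            if effect <= -1:
                raise ValueError(f"planted effect {effect} must exceed -1")
        if self.window_noise_rsd < 0:
            raise ValueError("window_noise_rsd must be >= 0")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["size_mixture"] = dataclasses.asdict(self.size_mixture)
        d["samples"] = [dataclasses.asdict(s) for s in self.samples]
        d["tfs"] = [dataclasses.asdict(tf) for tf in self.tfs]
        d["planted_windows"] = [[int(i), float(e)] for i, e in self.planted_windows]
        d["expression_link"] = list(self.expression_link)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        if "size_mixture" in d:
            m = d["size_mixture"]
            d["size_mixture"] = SizeMixture(
                weights=tuple(m["weights"]),
                means=tuple(m["means"]),
                sds=tuple(m["sds"]),
                support=tuple(m["support"]),
            )
        d["samples"] = [SampleSpec(**s) for s in d.get("samples", [])]
        d["tfs"] = [TFSpec(**tf) for tf in d.get("tfs", [])]
        d["planted_windows"] = [(int(i), float(e)) for i, e in d.get("planted_windows", [])]
        if "expression_link" in d:
            d["expression_link"] = tuple(d["expression_link"])
        return cls(**d)


@dataclasses.dataclass
class SimulationTruth:
    """Ground truth emitted alongside a simulated cohort."""

    planted: list  # dicts: window_index, chrom, start, end, effect, direction
    samples: list  # dicts: sample_id, condition, tumor_fraction, ...
    tf_activity: dict  # tf -> condition -> activity
    sites_open: dict  # tf -> condition -> list[bool] per site
    expected_center_depth: dict  # tf -> sample_id -> expected normalized depth
    expression_link: tuple

    def gained_indices(self) -> list:
        return [p["window_index"] for p in self.planted if p["direction"] == "gained"]

    def lost_indices(self) -> list:
        return [p["window_index"] for p in self.planted if p["direction"] == "lost"]

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationTruth":
        with open(path) as fh:
            d = json.load(fh)
        d["expression_link"] = tuple(d["expression_link"])
        return cls(**d)


def default_cohort_config(seed: int = 17) -> SimulationConfig:
    """The reference differential-occupancy cohort.

    Six pre- and six post-treatment samples at 0.1x target coverage on a
    2 x 10 Mb genome; 30 gained (+0.6) and 30 lost (-0.6) 10-kb windows at
    fixed, well-separated positions; tumor fractions evenly covering
    0.3-0.5 in each arm; three TFs whose activity shifts with treatment.
    """
    tf_pre = np.linspace(0.3, 0.5, 6)
    samples = []
    for i in range(6):
        samples.append(
            SampleSpec(f"PRE{i:02d}", "pre", float(tf_pre[i]),
                       platinum_status="sensitive" if i % 2 == 0 else "resistant")
        )
    for i in range(6):
        samples.append(
            SampleSpec(f"POST{i:02d}", "post", float(tf_pre[i]),
                       platinum_status="sensitive" if i % 2 == 0 else "resistant")
        )
    gained = [(10 + 33 * k, 0.6) for k in range(30)]       # chr1 windows
    lost = [(1010 + 33 * k, -0.6) for k in range(30)]      # chr2 windows
    tfs = [
        TFSpec("TFA", n_sites=500, activity={"pre": 0.9, "post": 0.4, "progression": 0.6}),
        TFSpec("TFB", n_sites=500, activity={"pre": 0.5, "post": 0.5, "progression": 0.5}),
        TFSpec("TFC", n_sites=500, activity={"pre": 0.1, "post": 0.3, "progression": 0.2}),
    ]
    return SimulationConfig(seed=seed, samples=samples,
                            planted_windows=gained + lost, tfs=tfs)


def footprint_cohort_config(seed: int = 17, n_samples: int = 30) -> SimulationConfig:
    """A single-condition cohort for footprint / expression calibration.

    Thirty pre-treatment samples whose tumor fractions span 0.1-0.6 (the
    broad range a liquid-biopsy cohort shows), three TFs with activities
    0.1 / 0.5 / 0.9 and no planted windows: all structure at TFBS comes
    from tumor-borne footprints, so recovered center-depth scores can be
    compared against the activity and tumor-fraction ground truth.
    """
    fractions = np.linspace(0.1, 0.6, n_samples)
    samples = [
        SampleSpec(f"S{i:02d}", "pre", float(fractions[i])) for i in range(n_samples)
    ]
    tfs = [
        TFSpec("LOWTF", n_sites=500, activity={"pre": 0.1, "post": 0.1, "progression": 0.1}),
        TFSpec("MIDTF", n_sites=500, activity={"pre": 0.5, "post": 0.5, "progression": 0.5}),
        TFSpec("HIGHTF", n_sites=500, activity={"pre": 0.9, "post": 0.9, "progression": 0.9}),
    ]
    return SimulationConfig(seed=seed, samples=samples, tfs=tfs)


def simulate_fragment_lengths(
    n: int, mixture: SizeMixture, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` integer fragment lengths from the protection-mode mixture.

    Component draws are normal, rounded to 1 bp, and redrawn while outside
    the truncation support.
    """
    mixture.validate()
    comp = rng.choice(3, size=n, p=np.asarray(mixture.weights, dtype=float))
    means = np.asarray(mixture.means)[comp]
    sds = np.asarray(mixture.sds)[comp]
    lengths = np.rint(rng.normal(means, sds)).astype(np.int64)
    lo, hi = mixture.support
    bad = (lengths < lo) | (lengths > hi)
    while bad.any():
        redraw = rng.normal(means[bad], sds[bad])
        lengths[bad] = np.rint(redraw).astype(np.int64)
        bad = (lengths < lo) | (lengths > hi)
    return lengths


def _place_sites(cfg: SimulationConfig, rng: np.random.Generator):
    """Uniformly place each TF's sites, with strengths and open/closed states."""
    chroms = list(cfg.chrom_sizes)
    sizes = np.array([cfg.chrom_sizes[c] for c in chroms], dtype=np.float64)
    margin = 5000  # keep full flanks inside the chromosome
    sites = {}
    for tf in cfg.tfs:
        chrom_idx = rng.choice(len(chroms), size=tf.n_sites, p=sizes / sizes.sum())
        centers = np.empty(tf.n_sites, dtype=np.int64)
        for i, ci in enumerate(chrom_idx):
            centers[i] = rng.integers(margin, int(sizes[ci]) - margin)
        strengths = rng.random(tf.n_sites)
        strands = rng.choice(np.array(["+", "-"], dtype=object), size=tf.n_sites)
        order = np.lexsort((centers, chrom_idx))
        chrom_idx, centers = chrom_idx[order], centers[order]
        strengths, strands = strengths[order], strands[order]
        open_status = {
            cond: (rng.random(tf.n_sites) < tf.activity.get(cond, 0.0)).tolist()
            for cond in ("pre", "post", "progression")
        }
        sites[tf.name] = {
            "chroms": np.array([chroms[i] for i in chrom_idx], dtype=object),
            "centers": centers,
            "strengths": strengths,
            "strands": strands,
            "open": open_status,
            "spec": tf,
        }
    return sites


def _window_multipliers(cfg: SimulationConfig, condition: str, n_windows: int) -> np.ndarray:
    w = np.ones(n_windows)
    for idx, effect in cfg.planted_windows:
        if condition == "post":
            w[idx] *= 1.0 + effect
        elif condition == "progression":
            w[idx] *= 1.0 + PROGRESSION_EFFECT_RETENTION * effect
    return w


def _simulate_sample(
    cfg: SimulationConfig,
    spec: SampleSpec,
    sites: dict,
    rng: np.random.Generator,
) -> FragmentSet:
    bins = tile_genome(cfg.chrom_sizes, cfg.window_size)
    genome = sum(cfg.chrom_sizes.values())
    mix = cfg.size_mixture
    n_frags = int(round(spec.target_mean_coverage * genome / mix.mean_length))

    # Two channels: nucleosome-protected fragments carry the window structure
    # (they are what the 120-180 bp occupancy analysis sees), while short
    # TF-protected fragments form an unstructured genome-wide background.
    # This keeps the realized per-window RSD at ~window_noise_rsd instead of
    # adding binomial thinning noise from the length filter.
    w_short = mix.weights[2]
    n_nuc = int(round(n_frags * (1.0 - w_short)))
    n_short = n_frags - n_nuc
    mult = _window_multipliers(cfg, spec.condition, bins.n_bins)
    lam = n_nuc * mult / mult.sum()
    noise = rng.normal(0.0, cfg.window_noise_rsd, bins.n_bins)
    counts = np.clip(np.rint(lam * (1.0 + noise)), 0, None).astype(np.int64)

    total = int(counts.sum())
    win_start = np.repeat(bins.bin_start, counts)
    win_width = np.repeat((bins.bin_end - bins.bin_start), counts)
    chroms = np.repeat(bins.bin_chrom, counts)
    if cfg.phased:
        repeat = cfg.nucleosome_repeat
        dyads = rng.integers(0, np.maximum(win_width // repeat, 1)) * repeat
        jitter = np.rint(rng.normal(0.0, repeat / 10.0, total)).astype(np.int64)
        midpoints = win_start + np.clip(dyads + jitter, 0, win_width - 1)
    else:
        midpoints = win_start + rng.integers(0, win_width)
    nuc_mix = SizeMixture(
        weights=(mix.weights[0] / (1.0 - w_short), mix.weights[1] / (1.0 - w_short), 0.0),
        means=mix.means, sds=mix.sds, support=mix.support,
    )
    lengths = simulate_fragment_lengths(total, nuc_mix, rng)

    # genome-wide short-fragment background (TF-protected everywhere)
    if n_short > 0:
        chrom_names = list(cfg.chrom_sizes)
        sizes_arr = np.array([cfg.chrom_sizes[c] for c in chrom_names], dtype=np.float64)
        ci = rng.choice(len(chrom_names), size=n_short, p=sizes_arr / sizes_arr.sum())
        short_mid = rng.integers(0, sizes_arr[ci].astype(np.int64))
        short_mix = SizeMixture(weights=(0.0, 0.0, 1.0), means=mix.means,
                                sds=mix.sds, support=mix.support)
        short_len = simulate_fragment_lengths(n_short, short_mix, rng)
        chroms = np.concatenate([chroms, np.array(chrom_names, dtype=object)[ci]])
        midpoints = np.concatenate([midpoints, short_mid])
        lengths = np.concatenate([lengths, short_len])
        total += n_short
    starts = midpoints - lengths // 2
    ends = starts + lengths
    # keep fragments inside their chromosome without changing their length
    for chrom, size in cfg.chrom_sizes.items():
        on = chroms == chrom
        starts[on] = np.clip(starts[on], 0, size - lengths[on])
        ends[on] = starts[on] + lengths[on]
    is_tumor = rng.random(total) < spec.tumor_fraction

    # tumor-borne TF footprints: nucleosome-sized tumor fragments overlapping
    # an open site's footprint are replaced by short TF-protected fragments
    # flanking the center, conserving fragment count
    for tf_name, info in sites.items():
        fw = info["spec"].footprint_half_width
        open_now = np.asarray(info["open"].get(spec.condition, [False] * len(info["centers"])))
        for chrom in cfg.chrom_sizes:
            on_chrom = np.flatnonzero(chroms == chrom)
            if len(on_chrom) == 0:
                continue
            order = on_chrom[np.argsort(starts[on_chrom], kind="stable")]
            s_sorted = starts[order]
            site_sel = (info["chroms"] == chrom) & open_now
            for c in info["centers"][site_sel]:
                c = int(c)
                lo = np.searchsorted(s_sorted, c - fw - cfg.size_mixture.support[1], "left")
                hi = np.searchsorted(s_sorted, c + fw, "right")
                cand = order[lo:hi]
                cand = cand[(ends[cand] > c - fw) & is_tumor[cand]]
                if len(cand) == 0:
                    continue
                new_len = np.clip(
                    np.rint(rng.normal(50.0, 10.0, len(cand))), 30, 80
                ).astype(np.int64)
                left = rng.random(len(cand)) < 0.5
                new_start = np.where(left, c - fw - new_len, c + fw + 1)
                new_start = np.clip(new_start, 0, None)
                starts[cand] = new_start
                ends[cand] = new_start + new_len
                lengths[cand] = new_len
    fs = FragmentSet(spec.sample_id, spec.condition, chroms, starts, ends)
    return fs.sort()


def simulate_cohort(cfg: SimulationConfig):
    """Generate one FragmentSet per sample plus the ground-truth tables.

    Returns ``(fragments, truth)`` where ``fragments`` maps sample_id to
    FragmentSet. Deterministic given ``cfg.seed``.
    """
    cfg.validate()
    root = np.random.default_rng(cfg.seed)
    streams = root.spawn(1 + len(cfg.samples))
    sites = _place_sites(cfg, streams[0])
    fragments = {}
    for spec, rng in zip(cfg.samples, streams[1:]):
        fragments[spec.sample_id] = _simulate_sample(cfg, spec, sites, rng)

    bins = tile_genome(cfg.chrom_sizes, cfg.window_size)
    planted = [
        {
            "window_index": int(idx),
            "chrom": str(bins.bin_chrom[idx]),
            "start": int(bins.bin_start[idx]),
            "end": int(bins.bin_end[idx]),
            "effect": float(effect),
            "direction": "gained" if effect > 0 else "lost",
        }
        for idx, effect in cfg.planted_windows
    ]
    expected_depth = {
        tf.name: {
            s.sample_id: 1.0 - s.tumor_fraction * tf.activity.get(s.condition, 0.0)
            for s in cfg.samples
        }
        for tf in cfg.tfs
    }
    truth = SimulationTruth(
        planted=planted,
        samples=[
            {
                "sample_id": s.sample_id,
                "condition": s.condition,
                "platinum_status": s.platinum_status,
                "tumor_fraction": s.tumor_fraction,
                "target_mean_coverage": s.target_mean_coverage,
                "n_fragments": int(fragments[s.sample_id].total_count),
            }
            for s in cfg.samples
        ],
        tf_activity={tf.name: dict(tf.activity) for tf in cfg.tfs},
        sites_open={name: dict(info["open"]) for name, info in sites.items()},
        expected_center_depth=expected_depth,
        expression_link=cfg.expression_link,
    )
    return fragments, truth, sites


def binding_site_sets(sites: dict):
    """Convert the generator's site tables into BindingSiteSet objects."""
    from .tfbs import BindingSiteSet

    out = {}
    for name, info in sites.items():
        half = info["spec"].site_length // 2
        out[name] = BindingSiteSet(
            tf_name=name,
            chroms=info["chroms"],
            starts=info["centers"] - half,
            ends=info["centers"] + (info["spec"].site_length - half),
            strands=info["strands"],
            strengths=info["strengths"],
            source="motif_scan",
        )
    return out


def simulate_expression(
    truth: SimulationTruth, cfg: SimulationConfig
) -> pd.DataFrame:
    """Expression table (TF gene x sample) linked to expected center depth.

    ``expression = max(0, a - b * expected_center_depth + Normal(0, sd))``
    with (a, b, sd) = ``cfg.expression_link``. Deterministic given the
    config seed (its own child stream, independent of the cohort's).
    """
    a, b, sd = cfg.expression_link
    rng = np.random.default_rng([cfg.seed, 0xE0F])
    genes = sorted(truth.expected_center_depth)
    sample_ids = [s["sample_id"] for s in truth.samples]
    data = np.empty((len(genes), len(sample_ids)))
    for gi, gene in enumerate(genes):
        depths = np.array(
            [truth.expected_center_depth[gene][sid] for sid in sample_ids]
        )
        noise = rng.normal(0.0, sd, len(sample_ids)) if sd > 0 else np.zeros(len(sample_ids))
        data[gi] = np.maximum(0.0, a - b * depths + noise)
    return pd.DataFrame(data, index=pd.Index(genes, name="gene"), columns=sample_ids)


def write_cohort(out_dir: str | Path, cfg: SimulationConfig) -> dict:
    """Simulate and write a full cohort to ``out_dir``.

    Writes per-sample fragment BEDs, per-TF site BEDs, a sample sheet,
    the expression table, the truth JSON, a chromosome-sizes table and a
    copy of the config. Returns the paths written. Byte-identical across
    reruns with the same config.
    """
    from .fragments import write_fragments_bed
    from .tfbs import write_sites_bed

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fragments, truth, sites = simulate_cohort(cfg)
    paths = {"fragments": {}, "sites": {}}

    for sid, fs in fragments.items():
        p = out_dir / f"{sid}.frags.bed"
        write_fragments_bed(fs, p)
        paths["fragments"][sid] = str(p)
    for name, bss in binding_site_sets(sites).items():
        p = out_dir / f"sites_{name}.bed"
        write_sites_bed(bss, p)
        paths["sites"][name] = str(p)

    sheet = out_dir / "samples.tsv"
    with open(sheet, "w") as fh:
        fh.write("sample_id\tcondition\tplatinum_status\ttumor_fraction\tpath\n")
        for s in cfg.samples:
            # paths are relative to the sheet's own directory
            fh.write(
                f"{s.sample_id}\t{s.condition}\t{s.platinum_status}\t"
                f"{s.tumor_fraction:g}\t{Path(paths['fragments'][s.sample_id]).name}\n"
            )
    paths["samples"] = str(sheet)

    expr = simulate_expression(truth, cfg)
    expr_path = out_dir / "expression.tsv"
    expr.to_csv(expr_path, sep="\t", float_format="%.6g")
    paths["expression"] = str(expr_path)

    sizes_path = out_dir / "chrom.sizes"
    with open(sizes_path, "w") as fh:
        for chrom, size in cfg.chrom_sizes.items():
            fh.write(f"{chrom}\t{size}\n")
    paths["chrom_sizes"] = str(sizes_path)

    tf_path = out_dir / "tumor_fractions.tsv"
    with open(tf_path, "w") as fh:
        fh.write("sample_id\ttumor_fraction\n")
        for s in cfg.samples:
            fh.write(f"{s.sample_id}\t{s.tumor_fraction:g}\n")
    paths["tumor_fractions"] = str(tf_path)

    truth_path = out_dir / "truth.json"
    truth.to_json(truth_path)
    paths["truth"] = str(truth_path)

    cfg_path = out_dir / "config.yaml"
    with open(cfg_path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
    paths["config"] = str(cfg_path)
    return paths
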