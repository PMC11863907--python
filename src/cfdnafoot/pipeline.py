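"""End-to-end orchestration: fragments -> occupancy -> differential regions
-> TFBS scoring -> report, driven by one YAML config.

The run config gathers every analysis threshold (window size, the 120-180
bp nucleosome-protection bounds, the RSD < 0.5 stability criterion and the
|relative change| > 0.4 differential criterion) so nothing is hard-coded.
Condition labels are fixed to {pre, post, progression}: the differential
caller contrasts pre vs post; progression samples contribute only to
aggregate profiles and activity-score tracking.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import differential as diff
from . import fragments as frag
from . import occupancy as occ
from . import tfbs

logger = logging.getLogger("cfdnafoot")


@dataclasses.dataclass
class TFConfig:
    name: str
    sites: str
    top_fraction: Optional[float] = None
    half_width: int = tfbs.DEFAULT_HALF_WIDTH
    flank: int = tfbs.DEFAULT_FLANK
    step: int = tfbs.DEFAULT_STEP
    strength_col: Optional[int] = None


@dataclasses.dataclass
class RunConfig:
    samples: str
    chrom_sizes: str
    out_dir: str
    bin_size: int = occ.DEFAULT_BIN_SIZE
    length_bounds: tuple = frag.DEFAULT_LENGTH_BOUNDS
    rsd_max: float = diff.DEFAULT_RSD_MAX
    change_min: float = diff.DEFAULT_CHANGE_MIN
    tfs: list = dataclasses.field(default_factory=list)
    expression: Optional[str] = None
    tumor_fractions: Optional[str] = None
    cnv_segments: Optional[str] = None
    fasta: Optional[str] = None
    seed: int = 0
    allow_missing: bool = False


def validate_config(path: str | Path) -> RunConfig:
    """Load and schema-check a YAML run config, resolving defaults.

    Raises ValueError naming the offending field; referenced files must
    exist at validation time.
    """
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    for field in ("samples", "chrom_sizes", "out_dir"):
        if field not in raw:
            raise ValueError(f"{path}: missing required field {field!r}")
    tf_cfgs = [TFConfig(**tf) for tf in raw.pop("tfs", [])]
    if "length_bounds" in raw:
        raw["length_bounds"] = tuple(raw["length_bounds"])
    cfg = RunConfig(tfs=tf_cfgs, **raw)
    if cfg.bin_size < 1:
        raise ValueError("bin_size: must be >= 1")
    if cfg.rsd_max <= 0:
        raise ValueError("rsd_max: must be positive")
    if cfg.change_min <= 0:
        raise ValueError("change_min: must be positive")
    lo, hi = cfg.length_bounds
    if lo > hi or lo < 1:
        raise ValueError("length_bounds: need 1 <= lo <= hi")
    base = path.parent
    def _resolve(p: Optional[str], field: str, required: bool) -> Optional[str]:
        if p is None:
            if required:
                raise ValueError(f"{field}: missing")
            return None
        rp = Path(p) if Path(p).is_absolute() else base / p
        if not rp.exists():
            raise ValueError(f"{field}: file not found: {rp}")
        return str(rp)

    cfg.samples = _resolve(cfg.samples, "samples", True)
    cfg.chrom_sizes = _resolve(cfg.chrom_sizes, "chrom_sizes", True)
    cfg.expression = _resolve(cfg.expression, "expression", False)
    cfg.tumor_fractions = _resolve(cfg.tumor_fractions, "tumor_fractions", False)
    cfg.cnv_segments = _resolve(cfg.cnv_segments, "cnv_segments", False)
    cfg.fasta = _resolve(cfg.fasta, "fasta", False)
    for tf in cfg.tfs:
        tf.sites = _resolve(tf.sites, f"tfs[{tf.name}].sites", True)
        if tf.top_fraction is not None and not 0 < tf.top_fraction <= 1:
            raise ValueError(f"tfs[{tf.name}].top_fraction: must be in (0, 1]")
    sheet = diff.read_sample_sheet(cfg.samples)
    for cond in sheet["condition"]:
        if cond not in frag.CONDITIONS:
            raise ValueError(f"samples: unknown condition label {cond!r}")
    if "path" not in sheet.columns:
        raise ValueError("samples: sample sheet needs a 'path' column")
    return cfg


@dataclasses.dataclass
class RunReport:
    parameters: dict
    samples: list
    n_gained: int
    n_lost: int
    tf_results: dict
    peak_ratios: dict
    qc: dict
    output_hashes: dict

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)
            fh.write("\n")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(cfg: RunConfig) -> RunReport:
    """Execute the full analysis described by ``cfg`` and write all artifacts.

    Stages: read + length-filter fragments; windowed normalized occupancy
    (bedGraph per sample); pre-vs-post differential calling (BED + per-bin
    stats); per-TF aggregate profiles, center-depth activity scores and
    score-based statistics; fragment-size peak ratios; optional GC and
    CNV-overlap checks on the called regions. Fails fast on the first
    stage error unless ``allow_missing``.
    """
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    chrom_sizes = occ.read_chrom_sizes(cfg.chrom_sizes)
    sheet = diff.read_sample_sheet(cfg.samples)
    bins = occ.tile_genome(chrom_sizes, cfg.bin_size)
    lo, hi = cfg.length_bounds

    logger.info("stage=fragments n_samples=%d", len(sheet))
    outputs: list[Path] = []
    filtered: dict[str, frag.FragmentSet] = {}
    peak_ratios: dict[str, dict] = {}
    for row in sheet.itertuples():
        p = Path(row.path)
        if not p.is_absolute():
            p = Path(cfg.samples).parent / p
        if not p.exists():
            msg = f"stage=fragments sample={row.sample_id}: missing {p}"
            if cfg.allow_missing:
                logger.warning("%s (skipped)", msg)
                continue
            raise FileNotFoundError(msg)
        fs = frag.read_fragments(
            p, sample_id=str(row.sample_id), condition=str(row.condition),
            chrom_sizes=chrom_sizes,
        )
        dist = frag.size_histogram(fs)
        if fs.total_count:
            peak_ratios[fs.sample_id] = frag.peak_ratio_metrics(dist).to_dict()
        filtered[fs.sample_id] = frag.filter_by_length(fs, lo, hi)

    logger.info("stage=occupancy bin_size=%d", cfg.bin_size)
    tracks: dict[str, occ.OccupancyTrack] = {}
    for sid, fs in filtered.items():
        track = occ.normalize_track(occ.compute_occupancy(fs, bins))
        tracks[sid] = track
        bg = out_dir / f"{sid}.occupancy.bedgraph"
        occ.write_bedgraph(track, bg)
        outputs.append(bg)

    logger.info("stage=differential rsd_max=%g change_min=%g", cfg.rsd_max, cfg.change_min)
    pre_tracks = [t for t in tracks.values() if t.condition == "pre"]
    post_tracks = [t for t in tracks.values() if t.condition == "post"]
    drs = None
    if len(pre_tracks) >= 2 and len(post_tracks) >= 2:
        drs = diff.call_differential(
            diff.ConditionGroup("pre", pre_tracks),
            diff.ConditionGroup("post", post_tracks),
            rsd_max=cfg.rsd_max,
            change_min=cfg.change_min,
        )
        regions_bed = out_dir / "differential_regions.bed"
        diff.export_regions(drs, regions_bed)
        stats_tsv = out_dir / "per_bin_stats.tsv"
        drs.stats.to_csv(stats_tsv, sep="\t", index=False, float_format="%.6g")
        outputs += [regions_bed, stats_tsv]
    else:
        logger.warning("stage=differential skipped: need >= 2 samples per condition")

    qc: dict = {}
    if drs is not None and drs.regions:
        regions = [(r.chrom, r.start, r.end) for r in drs.regions]
        if cfg.fasta:
            _, region_gc = occ.gc_content(regions, cfg.fasta)
            _, genome_gc = occ.gc_content(
                [(c, 0, s) for c, s in chrom_sizes.items()], cfg.fasta
            )
            qc["region_gc"] = region_gc
            qc["genome_gc"] = genome_gc
        if cfg.cnv_segments:
            segments = occ.read_cnv_segments(cfg.cnv_segments)
            qc["cnv_overlap_fraction"] = occ.region_cnv_overlap(regions, segments)

    expression = None
    if cfg.expression:
        expression = pd.read_csv(cfg.expression, sep="\t", index_col=0)
    tumor_fractions = None
    if cfg.tumor_fractions:
        tf_table = pd.read_csv(cfg.tumor_fractions, sep="\t")
        tumor_fractions = dict(
            zip(tf_table["sample_id"].astype(str), tf_table["tumor_fraction"])
        )
    platinum = None
    if "platinum_status" in sheet.columns:
        platinum = dict(zip(sheet["sample_id"].astype(str), sheet["platinum_status"]))

    tf_results: dict = {}
    if not cfg.tfs:
        logger.info("stage=tfbs skipped: no TF site files configured")
        tf_results["skipped"] = True
    for tf_cfg in cfg.tfs:
        logger.info("stage=tfbs tf=%s", tf_cfg.name)
        sites = tfbs.load_sites(tf_cfg.sites, tf_cfg.name, strength_col=tf_cfg.strength_col)
        if tf_cfg.top_fraction is not None:
            sites = tfbs.select_top_fraction(sites, tf_cfg.top_fraction)
            sel_bed = out_dir / f"{tf_cfg.name}.selected_sites.bed"
            tfbs.write_sites_bed(sites, sel_bed)
            outputs.append(sel_bed)
        profile = tfbs.aggregate_profile(
            list(filtered.values()), sites, chrom_sizes,
            flank=tf_cfg.flank, step=tf_cfg.step,
        )
        prof_tsv = out_dir / f"{tf_cfg.name}.profile.tsv"
        tfbs.write_profile_tsv(profile, prof_tsv)
        outputs.append(prof_tsv)
        scores = [
            tfbs.tfbs_center_depth(fs, sites, chrom_sizes, half_width=tf_cfg.half_width)
            for fs in filtered.values()
        ]
        scores_tsv = out_dir / f"{tf_cfg.name}.scores.tsv"
        tfbs.write_scores_tsv(scores, scores_tsv)
        outputs.append(scores_tsv)

        entry: dict = {"n_sites": profile.n_sites,
                       "scores": {s.sample_id: s.score for s in scores}}
        score_map = {s.sample_id: s.score for s in scores}
        if expression is not None and tf_cfg.name in expression.index:
            expr_row = expression.loc[tf_cfg.name].to_dict()
            try:
                corr = tfbs.correlate_activity_expression(score_map, expr_row)
                entry["expression_spearman"] = dataclasses.asdict(corr)
            except ValueError as exc:
                entry["expression_spearman"] = {"error": str(exc)}
        if tumor_fractions is not None:
            try:
                corr = tfbs.correlate_with_tumor_fraction(score_map, tumor_fractions)
                entry["tumor_fraction_pearson"] = dataclasses.asdict(corr)
            except ValueError as exc:
                entry["tumor_fraction_pearson"] = {"error": str(exc)}
        if platinum is not None:
            try:
                comp = tfbs.compare_groups(score_map, platinum)
                entry["platinum_mannwhitney"] = dataclasses.asdict(comp)
            except ValueError as exc:
                entry["platinum_mannwhitney"] = {"error": str(exc)}
        tf_results[tf_cfg.name] = entry

    report = RunReport(
        parameters={
            "bin_size": cfg.bin_size,
            "length_bounds": list(cfg.length_bounds),
            "rsd_max": cfg.rsd_max,
            "change_min": cfg.change_min,
            "seed": cfg.seed,
        },
        samples=[
            {"sample_id": sid, "condition": fs.condition,
             "n_fragments_filtered": fs.total_count,
             "depth_constant": tracks[sid].depth_constant}
            for sid, fs in filtered.items()
        ],
        n_gained=drs.n_gained if drs is not None else 0,
        n_lost=drs.n_lost if drs is not None else 0,
        tf_results=tf_results,
        peak_ratios=peak_ratios,
        qc=qc,
        output_hashes={p.name: _sha256(p) for p in outputs},
    )
    report.to_json(out_dir / "report.json")
    logger.info("stage=report n_gained=%d n_lost=%d", report.n_gained, report.n_lost)
    return report
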