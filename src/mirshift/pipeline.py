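"""End-to-end pipeline: DE calling -> seed scan -> CDF shift -> prioritization.

The stage order mirrors the analysis it reproduces: normalize and call
differential miRNAs (reference-miRNA normalization, mean count > 100,
fold > 1.70, p < 0.05), normalize and call differential mRNAs (total-count
normalization, FPKM > 2, fold > 2.0, p < 0.05), scan 3'UTRs for seed
sites of the significantly upregulated miRNAs, stratify genes by site
count and test each stratum's fold-change distribution against the
zero-site background (KS), annotate and rank sites by Ago2 overlap and
conservation, and optionally compute calcium-transient and PSI readouts.

All thresholds default to the published cut-offs; every run writes TSV
stage outputs, a machine-readable JSON summary, and logs each threshold
and seed to standard error.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import association, clip, diffexpr, io, readouts, seedscan, synthetic
from .errors import MirshiftError, PipelineError

log = logging.getLogger("mirshift")


@dataclass
class PipelineConfig:
    """Paths, thresholds and seeds for a full pipeline run.

    Threshold defaults are the published cut-offs: FPKM > 2 and mean
    count > 100 abundance filters, fold-change cut-offs 2.0 (mRNA) and
    1.70 (miRNA), alpha 0.05, conservation threshold 0.6.
    """

    # inputs
    mirna_counts: str = "mirna_counts.tsv"
    mirna_groups: str = "mirna_groups.tsv"
    mrna_counts: str = "mrna_counts.tsv"
    mrna_groups: str = "mrna_groups.tsv"
    mrna_lengths: str = "mrna_lengths.tsv"
    mirna_fasta: str = "mirnas.fasta"
    utr_fasta: str = "utrs.fasta"
    ago2_bed: str = "ago2_peaks.bed"
    conservation_bedgraph: str = "conservation.bedgraph"
    # thresholds (defaults = the published cut-offs)
    fpkm_min: float = 2.0
    mirna_count_min: float = 100.0
    mrna_fc: float = 2.0
    mirna_fc: float = 1.70
    alpha: float = 0.05
    cons_threshold: float = 0.6
    pseudocount: float = 0.5
    bins: tuple = association.DEFAULT_BINS
    include_6mer: bool = False
    ref_mirnas: tuple = synthetic.REFERENCE_MIRNAS
    # bookkeeping
    seed: int = 0
    out_dir: str = "results"

    def __post_init__(self):
        for name in ("fpkm_min", "mirna_count_min", "mrna_fc", "mirna_fc",
                     "cons_threshold", "pseudocount"):
            if getattr(self, name) <= 0:
                raise PipelineError(f"threshold {name} must be positive")
        if not 0 < self.alpha < 1:
            raise PipelineError("alpha must lie in (0, 1)")
        self.bins = tuple(tuple(b) for b in self.bins)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["bins"] = [list(b) for b in self.bins]
        d["ref_mirnas"] = list(self.ref_mirnas)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "bins" in d:
            d["bins"] = tuple(
                (int(lo), None if hi is None else int(hi)) for lo, hi in d["bins"]
            )
        if "ref_mirnas" in d:
            d["ref_mirnas"] = tuple(d["ref_mirnas"])
        return cls(**d)


def _stage(name):
    """Decorator: re-raise stage errors with the stage name attached."""

    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except MirshiftError as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        inner.__name__ = fn.__name__
        return inner

    return wrap


@_stage("de-mirna")
def run_mirna_de(cfg: PipelineConfig, base: Path):
    groups = io.read_group_map(base / cfg.mirna_groups)
    m = io.read_counts(base / cfg.mirna_counts, groups)
    m = diffexpr.normalize_by_references(m, list(cfg.ref_mirnas))
    de = diffexpr.call_de(
        m,
        filter_metric="count",
        filter_threshold=cfg.mirna_count_min,
        fc_threshold=cfg.mirna_fc,
        alpha=cfg.alpha,
        pseudocount=cfg.pseudocount,
    )
    log.info(
        "miRNA DE: %d features, filter mean count > %g, fold > %g, alpha %g",
        len(de), cfg.mirna_count_min, cfg.mirna_fc, cfg.alpha,
    )
    return de


@_stage("de-mrna")
def run_mrna_de(cfg: PipelineConfig, base: Path):
    groups = io.read_group_map(base / cfg.mrna_groups)
    lengths = io.read_lengths(base / cfg.mrna_lengths)
    m = io.read_counts(base / cfg.mrna_counts, groups, lengths)
    m = diffexpr.normalize_total_counts(m)
    de = diffexpr.call_de(
        m,
        filter_metric="FPKM",
        filter_threshold=cfg.fpkm_min,
        fc_threshold=cfg.mrna_fc,
        alpha=cfg.alpha,
        pseudocount=cfg.pseudocount,
    )
    log.info(
        "mRNA DE: %d features, filter FPKM > %g, fold > %g, alpha %g",
        len(de), cfg.fpkm_min, cfg.mrna_fc, cfg.alpha,
    )
    return de


@_stage("scan")
def run_scan(cfg: PipelineConfig, base: Path, up_mirnas: set[str]):
    mirna_seqs = io.read_fasta(base / cfg.mirna_fasta)
    utrs = io.read_fasta(base / cfg.utr_fasta)
    mirnas = [seedscan.MatureMiRNA(k, v) for k, v in mirna_seqs.items()]
    types = seedscan.MATCH_TYPES if cfg.include_6mer else seedscan.STRONG_TYPES
    sites = [
        s
        for s in seedscan.scan_all(utrs, mirnas, restrict_to=up_mirnas)
        if s.match_type in types
    ]
    counts = seedscan.count_sites(utrs, mirnas, restrict_to=up_mirnas, types=types)
    log.info("seed scan: %d sites over %d UTRs (%d up-miRNAs)",
             len(sites), len(utrs), len(up_mirnas))
    return utrs, sites, counts


@_stage("associate")
def run_association(cfg: PipelineConfig, mrna_de, counts: seedscan.SiteCounts):
    tested = mrna_de[mrna_de["status"] != "filtered"]
    genes = [g for g in tested.index if g in counts.total]
    lfc = tested.loc[genes, "log2fc"].to_numpy()
    site_counts = np.array([counts.total[g] for g in genes])
    result = association.cdf_shift(lfc, site_counts, bins=cfg.bins)
    log.info(
        "CDF shift: %d genes, targeted %.1f%%, multi-site %.1f%%",
        len(genes), 100 * result.targeted_fraction, 100 * result.multi_fraction,
    )
    return result


@_stage("prioritize")
def run_prioritization(cfg: PipelineConfig, base: Path, utrs, sites):
    peaks = io.read_bed(base / cfg.ago2_bed)
    track = io.read_bedgraph(
        base / cfg.conservation_bedgraph,
        lengths={k: len(v) for k, v in utrs.items()},
    )
    annotated = clip.overlap_sites_peaks(sites, peaks, valid_refs=set(utrs))
    clip.annotate_conservation(annotated, track, threshold=cfg.cons_threshold)
    ranked = clip.rank_candidates(annotated)
    log.info("prioritize: %d sites, %d Ago2-overlapped",
             len(ranked), sum(a.ago2 for a in ranked))
    return ranked


def run_pipeline(cfg: PipelineConfig, base_dir=".") -> dict:
    """Execute every stage and write TSV outputs plus a JSON summary.

    Returns the summary dict; raises :class:`PipelineError` naming the
    failing stage on any error.
    """
    base = Path(base_dir)
    out = io.ensure_dir(base / cfg.out_dir)
    log.info("pipeline start: seed %d, output %s", cfg.seed, out)

    mirna_de = run_mirna_de(cfg, base)
    up_mirnas = set(mirna_de.index[mirna_de["status"] == "up"])
    mirna_de.to_csv(out / "mirna_de.tsv", sep="\t")

    mrna_de = run_mrna_de(cfg, base)
    mrna_de.to_csv(out / "mrna_de.tsv", sep="\t")
    n_up, n_down, ratio = diffexpr.asymmetry_summary(mrna_de)

    utrs, sites, counts = run_scan(cfg, base, up_mirnas)
    shift = run_association(cfg, mrna_de, counts)
    shift.to_frame().to_csv(out / "cdf_shift.tsv", sep="\t", index=False)

    ranked = run_prioritization(cfg, base, utrs, sites)
    io.write_sites(ranked, out / "annotated_sites.tsv")

    summary = {
        "seed": cfg.seed,
        "n_mirna_up": int((mirna_de["status"] == "up").sum()),
        "n_mirna_down": int((mirna_de["status"] == "down").sum()),
        "n_mrna_up": n_up,
        "n_mrna_down": n_down,
        "mrna_down_up_ratio": ratio,
        "targeted_fraction": shift.targeted_fraction,
        "multi_fraction": shift.multi_fraction,
        "strata": [
            {
                "stratum": s.label,
                "n": s.n,
                "ks_d": s.d,
                "p_value": s.p,
                "median_shift": s.median_shift,
            }
            for s in shift.strata
        ],
        "n_sites": len(ranked),
        "n_sites_ago2": int(sum(a.ago2 for a in ranked)),
        "top_sites": [
            {
                "utr_id": a.site.utr_id,
                "start": a.site.start,
                "match_type": a.site.match_type,
                "mirna_id": a.site.mirna_id,
                "peak_height": a.peak_height,
                "cons_score": round(a.cons_score, 4),
                "cons_class": a.cons_class,
            }
            for a in ranked[:10]
        ],
        "thresholds": {
            "fpkm_min": cfg.fpkm_min,
            "mirna_count_min": cfg.mirna_count_min,
            "mrna_fc": cfg.mrna_fc,
            "mirna_fc": cfg.mirna_fc,
            "alpha": cfg.alpha,
            "cons_threshold": cfg.cons_threshold,
        },
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(_json_safe(summary), fh, indent=2, sort_keys=True)
        fh.write("\n")
    log.info("pipeline done: %d up-miRNAs, %d/%d mRNA up/down",
             summary["n_mirna_up"], n_up, n_down)
    return summary


def _json_safe(x):
    """Recursively replace non-finite floats (NaN medians of empty strata,
    infinite ratios) with null so the summary is strict JSON."""
    if isinstance(x, dict):
        return {k: _json_safe(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_json_safe(v) for v in x]
    if isinstance(x, (float, np.floating)):
        return float(x) if np.isfinite(x) else None
    if isinstance(x, np.integer):
        return int(x)
    return x


@dataclass
class SimulationParams:
    """Generator settings for `simulate_inputs` (the study conditions)."""

    n_mirna: int = 150
    n_mirna_per_group: int = 4  # quadruplicate miRNA libraries
    frac_up: float = 0.35
    mirna_fold_mean: float = 2.5
    mirna_dispersion: float = 0.05
    mirna_baseline: float = 500.0
    n_scan_mirnas: int = 10
    n_genes: int = 400
    utr_len_mean: int = 800
    max_sites_per_gene: int = 5
    delta_per_site: float = -0.2
    mrna_noise_sd: float = 0.25
    n_mrna_per_group: int = 2  # duplicate mRNA libraries
    base_fpkm_mean: float = 20.0
    ago2_site_recall: float = 0.7
    ago2_decoy_rate: float = 1.0
    ago2_height_mean: float = 50.0
    cons_high: float = 0.9
    cons_low: float = 0.2


def simulate_inputs(
    params: SimulationParams, cfg: PipelineConfig, base_dir="."
) -> synthetic.SimTruth:
    """Generate every pipeline input file with planted truth.

    The scanned miRNA set is the first ``n_scan_mirnas`` planted-up
    miRNAs (sites are planted for upregulated miRNAs so the association
    stage has a signal to find); writes FASTA/BED/bedGraph/TSV inputs at
    the paths in ``cfg`` and returns the truth record.
    """
    base = Path(base_dir)
    base.mkdir(parents=True, exist_ok=True)
    seed = cfg.seed

    mirna_m, mirna_truth = synthetic.generate_mirna_counts(
        n_mirna=params.n_mirna,
        n_per_group=params.n_mirna_per_group,
        frac_up=params.frac_up,
        fold_mean=params.mirna_fold_mean,
        dispersion=params.mirna_dispersion,
        baseline_mean=params.mirna_baseline,
        seed=seed,
    )
    io.write_counts(mirna_m, base / cfg.mirna_counts)
    io.write_group_map(mirna_m.groups, base / cfg.mirna_groups)

    up_ids = sorted(mirna_truth.mirna_up_ids)[: params.n_scan_mirnas]
    if len(up_ids) < params.n_scan_mirnas:
        raise PipelineError("not enough planted-up miRNAs for the scan set")
    scan_mirnas = synthetic.random_mirnas(
        len(up_ids), seed=seed + 1, ids=up_ids
    )
    io.write_fasta(
        {m.id: m.sequence for m in scan_mirnas}, base / cfg.mirna_fasta
    )

    utrs, truth = synthetic.generate_utrs_with_sites(
        n_genes=params.n_genes,
        utr_len_mean=params.utr_len_mean,
        mirnas=scan_mirnas,
        max_sites_per_gene=params.max_sites_per_gene,
        seed=seed + 2,
    )
    truth.mirna_up_ids = mirna_truth.mirna_up_ids
    truth.mirna_fold = mirna_truth.mirna_fold
    io.write_fasta(utrs, base / cfg.utr_fasta)

    mrna_m = synthetic.generate_mrna_expression(
        truth,
        up_mirnas=set(up_ids),
        delta_per_site=params.delta_per_site,
        noise_sd=params.mrna_noise_sd,
        n_per_group=params.n_mrna_per_group,
        base_fpkm_mean=params.base_fpkm_mean,
        seed=seed + 3,
    )
    io.write_counts(mrna_m, base / cfg.mrna_counts)
    io.write_group_map(mrna_m.groups, base / cfg.mrna_groups)
    io.write_lengths(mrna_m.lengths, base / cfg.mrna_lengths)

    peaks = synthetic.generate_ago2_peaks(
        truth,
        site_recall=params.ago2_site_recall,
        decoy_rate=params.ago2_decoy_rate,
        height_mean=params.ago2_height_mean,
        seed=seed + 4,
    )
    io.write_bed(peaks, base / cfg.ago2_bed)

    track = synthetic.generate_conservation(
        utrs, truth, high=params.cons_high, low=params.cons_low, seed=seed + 5
    )
    io.write_bedgraph(track, base / cfg.conservation_bedgraph)

    cfg.to_yaml(base / "config.yaml")
    log.info("simulated inputs in %s (seed %d)", base, seed)
    return truth
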