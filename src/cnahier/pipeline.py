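"""End-to-end orchestration: RD profile -> CN reference -> blocks -> FAs.

`run_pipeline` ties the stages together on in-memory per-chromosome
profiles; file-level plumbing (BAM/bedGraph in, TSV/JSON out) lives in the
CLI and in `write_results`.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import calibration
from .blocks import IsoCopyBlock, merge_to_ibs
from .focal import detect_focal_alterations
from .rd import RDProfile
from .reference import CNReference, estimate_cn_reference, model_weights
from .segmentation import build_primary_segments, sg_smooth, varri_change_points

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All tunable parameters of one run, serialisable to/from JSON.

    ``amp_threshold``, ``del_threshold`` and ``resolution_bp`` default to
    None = AUTO: evaluated from the coverage-calibration curves at the
    sample's estimated fold-coverage.
    """

    bin_size: int = 1000
    ploidy: str = "free"
    weight_sign: str = "decreasing"
    min_ib_size: int = 1_000_000
    sg_window: int = 51
    sg_order: int = 3
    varri_w: int = 30
    varri_k: float = 4.0
    fine_w: int = 10
    fine_k: float = 3.0
    amp_threshold: float | None = None
    del_threshold: float | None = None
    resolution_bp: float | None = None
    low_map_frac_limit: float = 0.5
    alpha: float = 0.05
    fdr_method: str = "fdr_bh"
    min_mapq: int = 1
    mappability_threshold: float = 0.5
    seed: int = 0

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class PipelineResult:
    reference: CNReference
    coverage: float
    params: dict[str, float]
    ibs_by_chrom: dict[str, list[IsoCopyBlock]]
    ib_table: pd.DataFrame
    lcv_table: pd.DataFrame
    fa_calls: pd.DataFrame
    fa_audit: pd.DataFrame
    stage_counts: dict[str, int] = field(default_factory=dict)


def _ib_frame(ibs_by_chrom: dict[str, list[IsoCopyBlock]],
              bin_size: int) -> pd.DataFrame:
    rows = []
    for chrom, ibs in ibs_by_chrom.items():
        for b in ibs:
            rows.append({
                "chromosome": chrom, "start": b.start_bin * bin_size,
                "end": b.end_bin * bin_size, "cn_state": b.cn_state,
                "mean_cn": b.mean_cn, "width_bp": b.width_bp,
                "is_lcv": b.is_lcv, "block_id": b.block_id,
            })
    cols = ["chromosome", "start", "end", "cn_state", "mean_cn",
            "width_bp", "is_lcv", "block_id"]
    return pd.DataFrame(rows, columns=cols)


def run_pipeline(profiles: dict[str, RDProfile],
                 config: RunConfig | None = None) -> PipelineResult:
    """Run CN-reference estimation, segmentation, block assembly and FA
    calling on per-chromosome RD profiles."""
    cfg = config or RunConfig()
    if not profiles:
        raise ValueError("no profiles supplied")
    ploidy = model_weights(cfg.ploidy, weight_sign=cfg.weight_sign)
    ref = estimate_cn_reference(list(profiles.values()), ploidy)
    log.info("CN reference (2N) at RD %.4f, score %.3f, sigma %.3f",
             ref.rd_2n, ref.fit_score, ref.sigma)

    # coverage over all unmasked bins, then AUTO parameters
    pooled = np.concatenate([p.values for p in profiles.values()])
    coverage = float(np.nanmean(pooled))
    auto = calibration.params_for_coverage(coverage, bin_size=cfg.bin_size)
    params = {
        "amp_threshold_cn": cfg.amp_threshold or auto["amp_threshold_cn"],
        "del_threshold_cn": cfg.del_threshold or auto["del_threshold_cn"],
        "resolution_bp": cfg.resolution_bp or auto["resolution_bp"],
    }
    log.info("coverage %.2fx -> amp/del thresholds %.3f/%.3f CN, "
             "resolution %.0f bp", coverage, params["amp_threshold_cn"],
             params["del_threshold_cn"], params["resolution_bp"])

    ibs_by_chrom: dict[str, list[IsoCopyBlock]] = {}
    n_segments = 0
    for chrom, profile in profiles.items():
        n = profile.bins.n_bins
        win = min(cfg.sg_window, (n - 2) | 1)
        if win <= cfg.sg_order:
            ibs_by_chrom[chrom] = []
            continue
        smoothed = sg_smooth(profile.values, window=win, order=cfg.sg_order)
        cps = varri_change_points(smoothed, window_w=cfg.varri_w,
                                  threshold_k=cfg.varri_k,
                                  raw=profile.values, chromosome=chrom,
                                  mask=profile.mask)
        segments = build_primary_segments(profile, cps, ref)
        n_segments += len(segments)
        ibs_by_chrom[chrom] = merge_to_ibs(segments, ref, profile=profile,
                                           min_ib_size=cfg.min_ib_size,
                                           bin_size=profile.bins.bin_size)

    ib_table = _ib_frame(ibs_by_chrom, cfg.bin_size)
    lcv_table = ib_table[ib_table["is_lcv"]].reset_index(drop=True)

    fa_calls, fa_audit = detect_focal_alterations(
        profiles, ibs_by_chrom, ref,
        amp_threshold=params["amp_threshold_cn"],
        del_threshold=params["del_threshold_cn"],
        resolution_bp=params["resolution_bp"],
        low_map_frac_limit=cfg.low_map_frac_limit,
        alpha=cfg.alpha, fdr_method=cfg.fdr_method,
        fine_w=cfg.fine_w, fine_k=cfg.fine_k)

    counts = {
        "chromosomes": len(profiles),
        "primary_segments": n_segments,
        "blocks": int(len(ib_table)),
        "lcvs": int(len(lcv_table)),
        "fa_candidates": int(len(fa_audit)),
        "fa_calls": int(len(fa_calls)),
    }
    log.info("stage counts: %s", counts)
    return PipelineResult(ref, coverage, params, ibs_by_chrom, ib_table,
                          lcv_table, fa_calls, fa_audit, counts)


def write_results(result: PipelineResult, outdir: str,
                  config: RunConfig | None = None) -> None:
    """Write reference JSON + IB/LCV/FA tables (TSV, 0-based half-open bp;
    1-based inclusive columns added for human reading)."""
    import os

    os.makedirs(outdir, exist_ok=True)
    ref = result.reference
    report = {
        "ploidy_model": ref.ploidy.name,
        "rd_2n": ref.rd_2n,
        "sigma_cn": ref.sigma,
        "fit_score": ref.fit_score,
        "coverage": result.coverage,
        "params": result.params,
        "state_centers_rd": {int(s): ref.state_center(s) for s in range(1, 7)},
        "state_intervals_rd": {int(s): list(ref.state_interval(s))
                               for s in range(1, 7)},
        "stage_counts": result.stage_counts,
    }
    with open(os.path.join(outdir, "cn_reference.json"), "w") as fh:
        json.dump(report, fh, indent=2)
    for name, tbl in [("blocks", result.ib_table),
                      ("lcv_calls", result.lcv_table),
                      ("fa_calls", result.fa_calls),
                      ("fa_audit", result.fa_audit)]:
        t = tbl.copy()
        if {"start", "end"}.issubset(t.columns):
            t.insert(3, "start_1based", t["start"] + 1)
            t.insert(4, "end_1based", t["end"])
        t.to_csv(os.path.join(outdir, f"{name}.tsv"), sep="\t", index=False)
    if config is not None:
        config.to_json(os.path.join(outdir, "run_config.json"))
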