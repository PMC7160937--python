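"""Focal alteration (FA) calling inside iso-copy-number blocks.

Each block is the *local* reference population for the focal events nested
inside it: a candidate sub-region is compared against the block's other bins,
never against the global 2N level, so a focal deletion inside a segmental
amplification (and vice versa) is called correctly.

Two call classes, as in the hierarchical caller's design:

* **Class 1** (statistically significant): Welch two-sample t-test of the
  candidate's bins against the rest of the block, Benjamini-Hochberg
  corrected across all candidates genome-wide, q < 0.05.
* **Class 2** (high confidence): the amplitude shift |delta CN| between the
  candidate and its parent block exceeds a coverage-calibrated threshold.
  At high coverage the theoretical threshold is 0.5N (the next CN state);
  at low coverage overdispersion demands larger shifts.

Calls are then filtered by width (the coverage-dependent resolution) and by
overlap with blacklist/gap/repeat masks; deletions are additionally screened
by their fraction of low-mappability bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .blocks import IsoCopyBlock
from .rd import RDProfile
from .reference import CNReference
from .segmentation import sg_smooth, varri_change_points

MIN_CAND_BINS = 5       # below this no t-test is attempted
MIN_IB_BINS = 100       # blocks smaller than this are not searched


@dataclass
class FocalAlteration:
    chromosome: str
    start_bin: int
    end_bin: int
    parent_ib: int
    mean_cn: float
    delta_cn: float
    direction: str              # "amplification" | "deletion"
    p_value: float
    q_value: float
    class1: bool
    class2: bool
    n_unmasked_bins: int
    filters_failed: list[str] = field(default_factory=list)

    @property
    def width_bins(self) -> int:
        return self.end_bin - self.start_bin


def propose_candidates(ib: IsoCopyBlock, profile: RDProfile,
                       fine_w: int = 10, fine_k: float = 3.0,
                       sg_window: int = 11, sg_order: int = 3
                       ) -> list[tuple[int, int]]:
    """Fine-scale candidate regions (half-open bin ranges) inside one block.

    A second, fine-scale smoothing + amplitude-shift pass runs on the block's
    own signal; regions between consecutive change points are the candidates.
    Runs absorbed during block assembly are appended (deduplicated).  A flat
    block yields no candidates.  All candidates are clipped to the block.
    """
    s, e = ib.start_bin, ib.end_bin
    regions: list[tuple[int, int]] = []
    sl = profile.values[s:e]
    n_obs = int(np.isfinite(sl).sum())
    if n_obs >= MIN_IB_BINS and np.isfinite(sl).any():
        win = min(sg_window, (e - s - 2) | 1)
        if win > sg_order:
            smoothed = sg_smooth(sl, window=win, order=sg_order)
            cps = varri_change_points(
                smoothed, window_w=fine_w, threshold_k=fine_k, raw=sl,
                chromosome=ib.chromosome,
                mask=profile.mask[s:e])
            if cps.positions.size:
                cuts = [0] + list(cps.positions) + [e - s]
                regions = [(s + a, s + b)
                           for a, b in zip(cuts[:-1], cuts[1:]) if b > a]
    for run in ib.embedded:
        rs, re = max(run.start_bin, s), min(run.end_bin, e)
        if re <= rs:
            continue
        covered = any(min(re, b) - max(rs, a) > 0.5 * (re - rs)
                      for a, b in regions)
        if not covered:
            regions.append((rs, re))
    regions.sort()
    return regions


def _candidate_stats(profile: RDProfile, ref: CNReference,
                     ib: IsoCopyBlock, region: tuple[int, int]):
    """(candidate CN values, background CN values) for one region."""
    v = profile.values
    cn = ref.cn_of(v)
    inside = np.zeros(profile.bins.n_bins, dtype=bool)
    inside[region[0]:region[1]] = True
    block = np.zeros_like(inside)
    block[ib.start_bin:ib.end_bin] = True
    obs = np.isfinite(v)
    cand = cn[inside & block & obs]
    bg = cn[block & ~inside & obs]
    return cand, bg


def test_class1(cand: np.ndarray, bg: np.ndarray) -> float:
    """Welch t-test p-value of candidate vs background bins (NaN if the
    candidate has too few bins or either side is degenerate)."""
    if cand.size < MIN_CAND_BINS or bg.size < MIN_CAND_BINS:
        return np.nan
    if np.ptp(cand) == 0 and np.ptp(bg) == 0:
        return 1.0 if cand.mean() == bg.mean() else 0.0
    return float(stats.ttest_ind(cand, bg, equal_var=False).pvalue)


def test_class2(delta_cn: float, amp_threshold: float,
                del_threshold: float) -> bool:
    """High-confidence flag: amplitude shift beyond the calibrated threshold."""
    if amp_threshold <= 0 or del_threshold <= 0:
        raise ValueError("thresholds must be positive")
    return bool(delta_cn >= amp_threshold or -delta_cn >= del_threshold)


def evaluate_candidates(profile: RDProfile, ref: CNReference,
                        ib: IsoCopyBlock, regions: list[tuple[int, int]],
                        amp_threshold: float, del_threshold: float
                        ) -> list[FocalAlteration]:
    """Score each candidate region of one block (q-values filled later)."""
    out = []
    for (a, b) in regions:
        cand, bg = _candidate_stats(profile, ref, ib, (a, b))
        if cand.size == 0 or bg.size == 0:
            continue
        mean_cn = float(cand.mean())
        # the parent block's robust centre (median CN) is the local
        # reference: the mean of the remaining bins would be dragged toward
        # other focal events sharing the block
        local_ref = ib.mean_cn if np.isfinite(ib.mean_cn) \
            else float(np.median(bg))
        delta = mean_cn - local_ref
        p = test_class1(cand, bg)
        fa = FocalAlteration(
            chromosome=ib.chromosome, start_bin=a, end_bin=b,
            parent_ib=ib.block_id, mean_cn=mean_cn, delta_cn=delta,
            direction="amplification" if delta >= 0 else "deletion",
            p_value=p, q_value=np.nan, class1=False,
            class2=test_class2(delta, amp_threshold, del_threshold),
            n_unmasked_bins=int(cand.size),
        )
        if cand.size < MIN_CAND_BINS:
            fa.filters_failed.append("too few bins")
        out.append(fa)
    return out


def apply_fdr(calls: list[FocalAlteration], alpha: float = 0.05,
              method: str = "fdr_bh") -> None:
    """Fill q-values and class-1 flags across all candidates genome-wide."""
    testable = [fa for fa in calls if np.isfinite(fa.p_value)]
    if not testable:
        return
    pvals = np.array([fa.p_value for fa in testable])
    if method == "none":
        qvals = pvals
        rej = pvals < alpha
    else:
        rej, qvals, _, _ = multipletests(pvals, alpha=alpha, method=method)
    for fa, q, r in zip(testable, qvals, rej):
        fa.q_value = float(q)
        fa.class1 = bool(r)


def filter_fas(calls: list[FocalAlteration], bins_by_chrom: dict,
               resolution_bp: float, low_map_frac_limit: float = 0.5,
               region_overlap_limit: float = 0.5) -> None:
    """Populate ``filters_failed`` on every call (calls are never deleted;
    reporting selects on an empty filter list).

    Drops: width below the coverage resolution; >50% overlap with
    blacklist/gap/repeat masks; deletions whose low-mappability bin fraction
    exceeds ``low_map_frac_limit``.
    """
    for fa in calls:
        gb = bins_by_chrom[fa.chromosome]
        width_bp = fa.width_bins * gb.bin_size
        if width_bp < resolution_bp:
            fa.filters_failed.append("below resolution")
        sl = slice(fa.start_bin, fa.end_bin)
        n = fa.width_bins
        region_frac = (gb.masks["blacklist"][sl] | gb.masks["gap"][sl]
                       | gb.masks["repeat"][sl]).sum() / n
        if region_frac > region_overlap_limit:
            fa.filters_failed.append("masked region overlap")
        if fa.direction == "deletion":
            lm_frac = gb.masks["low_mappability"][sl].sum() / n
            if lm_frac > low_map_frac_limit:
                fa.filters_failed.append("low mappability")


def calls_to_frame(calls: list[FocalAlteration], bin_size: int = 1000
                   ) -> pd.DataFrame:
    rows = []
    for fa in calls:
        rows.append({
            "chromosome": fa.chromosome,
            "start": fa.start_bin * bin_size,
            "end": fa.end_bin * bin_size,
            "parent_ib": fa.parent_ib,
            "mean_cn": fa.mean_cn,
            "delta_cn": fa.delta_cn,
            "direction": fa.direction,
            "p_value": fa.p_value,
            "q_value": fa.q_value,
            "class1": fa.class1,
            "class2": fa.class2,
            "filters": ";".join(fa.filters_failed),
        })
    cols = ["chromosome", "start", "end", "parent_ib", "mean_cn", "delta_cn",
            "direction", "p_value", "q_value", "class1", "class2", "filters"]
    return pd.DataFrame(rows, columns=cols)


def detect_focal_alterations(profiles: dict[str, RDProfile],
                             ibs_by_chrom: dict[str, list[IsoCopyBlock]],
                             ref: CNReference,
                             amp_threshold: float, del_threshold: float,
                             resolution_bp: float,
                             low_map_frac_limit: float = 0.5,
                             alpha: float = 0.05,
                             fdr_method: str = "fdr_bh",
                             fine_w: int = 10, fine_k: float = 3.0
                             ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full FA stage genome-wide.

    Returns ``(calls, audit)``: *calls* are class-2 FAs passing every filter
    (annotated with their class-1 status); *audit* lists every evaluated
    candidate with flags and failure reasons.
    """
    all_calls: list[FocalAlteration] = []
    for chrom, profile in profiles.items():
        for ib in ibs_by_chrom.get(chrom, []):
            if ib.n_unmasked_bins < MIN_IB_BINS:
                continue
            regions = propose_candidates(ib, profile, fine_w=fine_w,
                                         fine_k=fine_k)
            all_calls.extend(evaluate_candidates(
                profile, ref, ib, regions, amp_threshold, del_threshold))
    apply_fdr(all_calls, alpha=alpha, method=fdr_method)
    bins_by_chrom = {c: p.bins for c, p in profiles.items()}
    filter_fas(all_calls, bins_by_chrom, resolution_bp,
               low_map_frac_limit=low_map_frac_limit)
    bin_size = next(iter(profiles.values())).bins.bin_size if profiles else 1000
    audit = calls_to_frame(all_calls, bin_size)
    reported = [fa for fa in all_calls if fa.class2 and not fa.filters_failed]
    calls = calls_to_frame(reported, bin_size)
    return calls, audit
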