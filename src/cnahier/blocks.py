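"""Assembly of primary segments into iso-copy-number blocks (IBs).

Segmentation alone over- and under-cuts: neighbouring primary segments often
share a copy-number state (false segmentation), and focal events inside a
large aneuploid region fragment it (oversegmentation).  The assembly step
merges adjacent segments with equal integer CN state and absorbs runs shorter
than the minimum block size into the flank whose copy number is closer,
iterating to a fixed point.  Absorbed short runs are retained as focal-
alteration candidates for the downstream detector.  Blocks whose state
differs from 2N are the large-scale copy variations (LCVs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .reference import CNReference
from .segmentation import Segment

log = logging.getLogger(__name__)

MIN_IB_SIZE = 1_000_000  # bp; user-tunable


@dataclass
class EmbeddedRun:
    """A sub-minimum-size run absorbed into an IB; kept as an FA candidate."""

    start_bin: int
    end_bin: int
    mean_rd: float
    mean_cn: float
    n_unmasked_bins: int


@dataclass
class IsoCopyBlock:
    chromosome: str
    start_bin: int
    end_bin: int
    cn_state: int
    mean_cn: float
    mean_rd: float
    n_unmasked_bins: int
    width_bp: int
    is_lcv: bool
    member_segments: list[int] = field(default_factory=list)
    embedded: list[EmbeddedRun] = field(default_factory=list)
    block_id: int = -1

    @property
    def n_bins(self) -> int:
        return self.end_bin - self.start_bin


def assign_cn_state(segment: Segment, ref: CNReference) -> int:
    """Integer CN state of a segment's mean RD (half-integer boundaries,
    half-open upward: mean CN 2.5 -> state 3)."""
    if segment.n_unmasked_bins < 1:
        raise ValueError("segment has no unmasked bins")
    return int(ref.state_of(segment.mean_rd))


def _state_of_cn(mean_cn: float) -> int:
    if not np.isfinite(mean_cn):
        return -1
    return max(int(np.floor(mean_cn + 0.5)), 0)


def merge_to_ibs(segments: list[Segment], ref: CNReference,
                 profile=None, min_ib_size: int = MIN_IB_SIZE,
                 bin_size: int = 1000) -> list[IsoCopyBlock]:
    """Merge primary segments into iso-copy-number blocks.

    Excluded segments (assembly gaps / fully masked territory) are hard
    barriers: merging never bridges them and they yield no block.  Within
    each gap-free run the procedure iterates (1) merge adjacent equal-state
    items, (2) absorb the narrowest item below ``min_ib_size`` into the
    flank whose copy number is closer (ties leftward), recording it as an
    embedded FA candidate, until a fixed point.  Idempotent.

    Each working item's copy number is the **median** bin CN over its
    territory (recomputed from ``profile`` when given, else from the
    segments' means), so a block's state always reflects its majority
    territory - absorbed focal runs can never drift or fake a block's state
    no matter how densely they cluster.
    """
    if profile is not None:
        cn_bins = ref.cn_of(profile.values)
        rd_bins = profile.values
        n_bins_total = profile.bins.n_bins
    else:
        n_bins_total = max(s.end_bin for s in segments) if segments else 0
        cn_bins = np.full(n_bins_total, np.nan)
        rd_bins = np.full(n_bins_total, np.nan)
        for s in segments:
            if s.n_unmasked_bins > 0:
                cn = s.mean_cn if np.isfinite(s.mean_cn) \
                    else float(2.0 * s.mean_rd / ref.rd_2n)
                cn_bins[s.start_bin:s.end_bin] = cn
                rd_bins[s.start_bin:s.end_bin] = s.mean_rd

    blocks: list[IsoCopyBlock] = []
    run: list[Segment] = []
    for seg in segments:
        if seg.excluded:
            if run:
                blocks.extend(_merge_run(run, cn_bins, rd_bins,
                                         min_ib_size, bin_size))
                run = []
        else:
            run.append(seg)
    if run:
        blocks.extend(_merge_run(run, cn_bins, rd_bins, min_ib_size,
                                 bin_size))
    for i, b in enumerate(blocks):
        b.block_id = i
    return blocks


def _merge_run(segments: list[Segment], cn_bins: np.ndarray,
               rd_bins: np.ndarray, min_ib_size: int,
               bin_size: int) -> list[IsoCopyBlock]:
    """Anchor-and-bridge assembly of one gap-free segment run.

    Segments at least ``min_ib_size`` wide are *anchors* (their state is
    certain).  Each inter-anchor gap - a stretch of sub-minimum segments,
    typically focal events interleaved with backbone slivers - is resolved
    as a whole: bridged into same-state flanking anchors, split between
    different-state anchors at the cut minimising the copy-number
    misassignment cost, or promoted to a block of its own when its median
    state matches no flank and it is wide enough.  Sub-minimum segments
    whose state differs from their final block are retained as embedded
    focal-alteration candidates.
    """
    min_bins = max(min_ib_size // bin_size, 1)

    def center(s: int, e: int) -> float:
        v = cn_bins[s:e]
        v = v[np.isfinite(v)]
        return float(np.median(v)) if v.size else np.nan

    def item_of(seg: Segment) -> dict:
        c = center(seg.start_bin, seg.end_bin)
        return {"start": seg.start_bin, "end": seg.end_bin, "cn": c,
                "state": _state_of_cn(c), "members": [seg.segment_id]}

    items = [item_of(seg) for seg in segments]
    chrom = segments[0].chromosome

    def run_pieces() -> list[dict]:
        """Resolve items into block pieces: {start, end, state, members,
        absorbed (sub-min items)}."""
        anchors = [i for i, it in enumerate(items)
                   if it["end"] - it["start"] >= min_bins]
        if not anchors:
            s, e = items[0]["start"], items[-1]["end"]
            c = center(s, e)
            if (e - s) < min_bins:
                log.warning("run on %s shorter than min_ib_size (%d bp); "
                            "emitting a single block", chrom, min_ib_size)
            return [{"start": s, "end": e, "state": _state_of_cn(c),
                     "cn": c,
                     "members": sum((it["members"] for it in items), []),
                     "absorbed": [it for it in items
                                  if it["state"] != _state_of_cn(c)]}]

        pieces = []
        for ai in anchors:
            a = items[ai]
            pieces.append({"start": a["start"], "end": a["end"],
                           "state": a["state"], "cn": a["cn"],
                           "members": list(a["members"]), "absorbed": []})
        # gaps: before the first anchor, between anchors, after the last
        gaps = []
        prev_end = 0
        for ai in anchors:
            gaps.append(items[prev_end:ai])
            prev_end = ai + 1
        gaps.append(items[prev_end:])

        out_pieces: list[dict] = []
        for j, gap in enumerate(gaps):
            left = pieces[j - 1] if j > 0 else None
            right = pieces[j] if j < len(pieces) else None
            for part, host in _resolve_gap(gap, left, right, center,
                                           min_bins):
                if host is None:
                    out_pieces.append(part)
                else:
                    host["start"] = min(host["start"], part["start"])
                    host["end"] = max(host["end"], part["end"])
                    host["members"].extend(part["members"])
                    host["absorbed"].extend(part["absorbed"])
            if right is not None:
                out_pieces.append(right)
        out_pieces.sort(key=lambda p: p["start"])
        return out_pieces

    pieces = run_pieces()

    # merge adjacent same-state pieces, refresh robust centres
    merged: list[dict] = []
    for p in pieces:
        if merged and merged[-1]["state"] == p["state"]:
            merged[-1]["end"] = p["end"]
            merged[-1]["members"].extend(p["members"])
            merged[-1]["absorbed"].extend(p["absorbed"])
        else:
            merged.append(p)

    out = []
    for p in merged:
        s, e = p["start"], p["end"]
        c = center(s, e)
        state = max(p["state"], 0)
        rd_obs = rd_bins[s:e]
        rd_obs = rd_obs[np.isfinite(rd_obs)]
        embedded = []
        for it in p["absorbed"]:
            ocn = cn_bins[it["start"]:it["end"]]
            ocn = ocn[np.isfinite(ocn)]
            ord_ = rd_bins[it["start"]:it["end"]]
            ord_ = ord_[np.isfinite(ord_)]
            if ocn.size:
                embedded.append(EmbeddedRun(
                    it["start"], it["end"],
                    float(np.mean(ord_)) if ord_.size else np.nan,
                    float(np.mean(ocn)), int(ocn.size)))
        out.append(IsoCopyBlock(
            chromosome=chrom, start_bin=s, end_bin=e,
            cn_state=state, mean_cn=c,
            mean_rd=float(np.median(rd_obs)) if rd_obs.size else np.nan,
            n_unmasked_bins=int(rd_obs.size),
            width_bp=(e - s) * bin_size,
            is_lcv=state != 2, member_segments=p["members"],
            embedded=embedded,
        ))
    return out


def _resolve_gap(gap: list[dict], left: dict | None, right: dict | None,
                 center, min_bins: int):
    """Assign a stretch of sub-minimum items to flanking anchors, or promote
    it to its own block.

    Yields ``(piece, host)`` pairs where ``host`` is the flanking anchor
    piece to extend, or None when ``piece`` stands alone.  ``piece`` carries
    the assigned items' members and the minority items as ``absorbed``.
    """
    gap = list(gap)
    if not gap:
        return

    def bundle(its: list[dict], state: int) -> dict:
        return {"start": its[0]["start"], "end": its[-1]["end"],
                "state": state,
                "cn": np.nan,
                "members": sum((it["members"] for it in its), []),
                "absorbed": [it for it in its if it["state"] != state]}

    # trim: leading/trailing items already matching a flank's state belong
    # to that flank outright
    while gap and left is not None and gap[0]["state"] == left["state"]:
        yield bundle([gap.pop(0)], left["state"]), left
    while gap and right is not None and gap[-1]["state"] == right["state"]:
        yield bundle([gap.pop()], right["state"]), right
    if not gap:
        return

    g0, g1 = gap[0]["start"], gap[-1]["end"]
    med_state = _state_of_cn(center(g0, g1))
    flank_states = {p["state"] for p in (left, right) if p is not None}

    if (g1 - g0) >= min_bins and med_state not in flank_states:
        # a coherent block in its own right (e.g. an aneuploid region so
        # dense with focal events that no single backbone segment reaches
        # the minimum width)
        yield bundle(gap, med_state), None
        return

    if left is not None and right is not None \
            and left["state"] != right["state"]:
        # split at the cut minimising width-weighted CN misassignment
        widths = np.array([it["end"] - it["start"] for it in gap], float)
        dl = np.array([abs(it["cn"] - left["cn"]) if np.isfinite(it["cn"])
                       else 0.0 for it in gap])
        dr = np.array([abs(it["cn"] - right["cn"]) if np.isfinite(it["cn"])
                       else 0.0 for it in gap])
        costs = [float((widths[:j] * dl[:j]).sum()
                       + (widths[j:] * dr[j:]).sum())
                 for j in range(len(gap) + 1)]
        cut = int(np.argmin(costs))
        if cut > 0:
            yield bundle(gap[:cut], left["state"]), left
        if cut < len(gap):
            yield bundle(gap[cut:], right["state"]), right
    else:
        # same-state flanks (bridge) or a single flank: absorb everything
        # into the nearer available anchor
        host = left if left is not None else right
        if left is not None and right is not None:
            g_cn = center(g0, g1)
            if np.isfinite(g_cn) and \
                    abs(right["cn"] - g_cn) < abs(left["cn"] - g_cn):
                host = right
        yield bundle(gap, host["state"]), host


def call_lcvs(ibs: list[IsoCopyBlock]):
    """Split blocks into (LCV rows, CN-neutral rows) as record dicts."""
    lcvs, neutral = [], []
    for b in ibs:
        row = {
            "chromosome": b.chromosome, "start_bin": b.start_bin,
            "end_bin": b.end_bin, "cn_state": b.cn_state,
            "mean_cn": b.mean_cn, "width_bp": b.width_bp,
            "block_id": b.block_id,
        }
        (lcvs if b.is_lcv else neutral).append(row)
    return lcvs, neutral
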