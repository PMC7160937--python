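"""Ground-truth CNA simulation: read spike-in and fully synthetic profiles.

Two complementary generators back the test harness and benchmarks:

* **Read spike-in** edits an existing read set.  To move a region from copy
  number C1 to C2 it adds or removes ``round(X * (C2/C1 - 1))`` reads, where
  X is the region's observed read count; added reads are copies of randomly
  chosen originals with their coordinates jittered by 10-500 bp, so the local
  coverage texture is preserved.  FA placement follows the protocol's
  constraints: inside one LCV, mask-clean, non-overlapping, and with a read
  count within 5% of the chromosome's typical count at that width.

* **Synthetic profiles** draw per-bin base counts from Poisson
  (coverage * cn/2 * bin_size) over a planted piecewise-constant copy-number
  truth, optionally modulated by a low-frequency sinusoidal wave artifact and
  a GC bias, giving the caller's assumed statistical structure with known
  ground truth at desk scale.

Evaluation follows the benchmark's matching rules: an FA counts as detected
when a single call covers > 75% of it, an LCV when a single block covers
>= 90% of it (with matching integer state); precision counts false
amplifications only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bins import GenomeBins
from .rd import RDProfile

FA_OVERLAP = 0.75
LCV_OVERLAP = 0.90


def _round_half_away(v: float) -> int:
    """Nearest integer, halves away from zero."""
    return int(np.sign(v) * np.floor(abs(v) + 0.5))


# ---------------------------------------------------------------------------
# Truth bookkeeping


@dataclass(frozen=True)
class TruthRegion:
    chromosome: str
    start: int          # bp, 0-based half-open
    end: int
    kind: str           # "LCV" | "FA"
    original_cn: int
    target_cn: int

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass
class TruthSet:
    regions: list[TruthRegion] = field(default_factory=list)
    fa_overlap: float = FA_OVERLAP
    lcv_overlap: float = LCV_OVERLAP

    def of_kind(self, kind: str) -> list[TruthRegion]:
        return [r for r in self.regions if r.kind == kind]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "chromosome": r.chromosome, "start": r.start, "end": r.end,
            "kind": r.kind, "original_cn": r.original_cn,
            "target_cn": r.target_cn} for r in self.regions])


# ---------------------------------------------------------------------------
# LCV / FA planning


def plan_lcvs(chrom_length: int, m: int, rng,
              cn_choices=(1, 2, 3, 4), min_segment: int = 1_000_000
              ) -> list[tuple[int, int, int]]:
    """Partition a chromosome into ``m`` contiguous segments with target CNs.

    Cut points are uniform conditional on every segment reaching
    ``min_segment``: the cuts are drawn uniformly in the slack space
    (chromosome length minus the reserved minimum widths) and the minima are
    re-inserted, so the draw always succeeds.  Returns ``(start, end, cn)``
    tuples covering [0, length).
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if chrom_length / m < 2 * min_segment:
        raise ValueError("chromosome too short for m segments of this size")
    rng = np.random.default_rng(rng)
    slack = chrom_length - m * min_segment
    if m == 1:
        cuts = np.array([], dtype=np.int64)
    else:
        free = np.sort(rng.integers(0, slack + 1, size=m - 1))
        cuts = free + min_segment * np.arange(1, m)
    edges = np.concatenate([[0], cuts, [chrom_length]]).astype(int)
    cns = rng.choice(cn_choices, size=m)
    return [(int(s), int(e), int(c))
            for s, e, c in zip(edges[:-1], edges[1:], cns)]


def plan_benchmark_chromosome(chrom_length: int, n_lcv: int, rng,
                              lcv_cn_choices=(1, 3, 4),
                              min_segment: int = 1_000_000,
                              lcv_share: float = 3.0
                              ) -> list[tuple[int, int, int]]:
    """Plan a chromosome of alternating diploid background and ``n_lcv``
    aberrant segments (the planted LCVs).

    Segment lengths follow a Dirichlet draw weighting LCV segments
    ``lcv_share`` times the background, so LCVs are roomy enough to nest
    focal events; every segment is at least ``min_segment`` wide by
    construction (the Dirichlet distributes only the slack above the
    reserved minima).
    """
    rng = np.random.default_rng(rng)
    m = 2 * n_lcv + 1
    if chrom_length < m * min_segment:
        raise ValueError("chromosome too short for this many segments")
    alpha = np.where(np.arange(m) % 2 == 1, lcv_share, 1.0)
    slack = chrom_length - m * min_segment
    lengths = min_segment + rng.dirichlet(alpha * 2.0) * slack
    edges = np.concatenate([[0], np.cumsum(lengths)]).astype(int)
    edges[-1] = chrom_length
    plan = []
    for i, (s, e) in enumerate(zip(edges[:-1], edges[1:])):
        cn = 2 if i % 2 == 0 else int(rng.choice(lcv_cn_choices))
        plan.append((int(s), int(e), cn))
    return plan


def _fa_target_cn(parent_cn: int, rng) -> int:
    choices = [c for c in range(max(parent_cn - 3, 0),
                                min(parent_cn + 3, 6) + 1) if c != parent_cn]
    return int(rng.choice(choices))


def plan_fa_regions(plan: list[tuple[int, int, int]], n_fa: int, rng,
                    size_range=(50_000, 100_000), margin: int = 10_000,
                    spacing: int = 2_000, mask_intervals=(),
                    max_tries: int = 50_000,
                    only_in_lcvs: bool = True) -> list[tuple[int, int, int, int]]:
    """Place ``n_fa`` non-overlapping focal regions strictly inside LCVs.

    Returns ``(start, end, parent_cn, target_cn)`` tuples.  Regions keep
    ``margin`` bp from LCV boundaries, ``spacing`` bp from each other, avoid
    ``mask_intervals`` and change the copy number by at least one state.
    """
    rng = np.random.default_rng(rng)
    hosts = [(s, e, c) for s, e, c in plan
             if (c != 2 or not only_in_lcvs)
             and (e - s) > 2 * margin + size_range[1]]
    if not hosts:
        raise RuntimeError("no segment can host focal regions")
    # uniform placement over the eligible territory = width-weighted hosts
    host_p = np.array([e - s for s, e, _ in hosts], dtype=float)
    host_p /= host_p.sum()
    placed: list[tuple[int, int, int, int]] = []
    tries = 0
    while len(placed) < n_fa and tries < max_tries:
        tries += 1
        hs, he, hc = hosts[rng.choice(len(hosts), p=host_p)]
        width = int(rng.integers(size_range[0], size_range[1] + 1))
        lo, hi = hs + margin, he - margin - width
        if hi <= lo:
            continue
        start = int(rng.integers(lo, hi))
        end = start + width
        if any(start < pe + spacing and ps - spacing < end
               for ps, pe, _, _ in placed):
            continue
        if any(start < me and ms < end for _, ms, me in mask_intervals):
            continue
        placed.append((start, end, hc, _fa_target_cn(hc, rng)))
    if len(placed) < n_fa:
        raise RuntimeError(
            f"could only place {len(placed)} of {n_fa} focal regions")
    return sorted(placed)


# ---------------------------------------------------------------------------
# Read-interval records and spike-in


@dataclass
class ReadSet:
    """Lightweight read records: per-read start (bp) and length."""

    chromosome: str
    starts: np.ndarray
    lengths: np.ndarray

    def __post_init__(self):
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.lengths = np.asarray(self.lengths, dtype=np.int64)
        if self.starts.shape != self.lengths.shape:
            raise ValueError("starts and lengths must align")

    @property
    def n_reads(self) -> int:
        return self.starts.size

    def in_region(self, start: int, end: int) -> np.ndarray:
        """Indices of reads starting inside [start, end)."""
        return np.nonzero((self.starts >= start) & (self.starts < end))[0]

    def to_rd(self, bins: GenomeBins) -> RDProfile:
        """Base-count-frequency RD profile of this read set."""
        bases = np.zeros(bins.n_bins)
        bs = bins.bin_size
        short = self.lengths <= bs
        if short.any():  # vectorised: a short read spans at most two bins
            s = self.starts[short]
            e = np.minimum(s + self.lengths[short], bins.chrom_length)
            first = s // bs
            ov1 = np.minimum(e, (first + 1) * bs) - s
            np.add.at(bases, first, np.maximum(ov1, 0))
            rest = (e - s) - ov1
            sel = rest > 0
            second = np.minimum(first[sel] + 1, bins.n_bins - 1)
            np.add.at(bases, second, rest[sel])
        for s, ln in zip(self.starts[~short], self.lengths[~short]):
            e = min(s + ln, bins.chrom_length)
            if e <= s:
                continue
            first, last = s // bs, (e - 1) // bs
            for b in range(first, min(last, bins.n_bins - 1) + 1):
                b0, b1 = b * bs, (b + 1) * bs
                bases[b] += min(e, b1) - max(s, b0)
        profile = RDProfile(bins, bases / bs)
        profile.rd[bins.combined_mask()] = np.nan
        return profile


def uniform_reads(chrom_length: int, coverage: float, read_length: int,
                  rng, chromosome: str = "chr1") -> ReadSet:
    """Uniform random read set at the requested fold-coverage."""
    rng = np.random.default_rng(rng)
    n = int(round(coverage * chrom_length / read_length))
    starts = rng.integers(0, chrom_length - read_length, size=n)
    return ReadSet(chromosome, np.sort(starts),
                   np.full(n, read_length, dtype=np.int64))


def spike_plan_delta(x: int, c1: int, c2: int) -> int:
    """Reads to add (positive) or remove (negative): round(X*(C2/C1 - 1))."""
    if c1 <= 0:
        raise ValueError("original copy number C1 must be positive")
    if c2 < 0:
        raise ValueError("target copy number C2 must be non-negative")
    return _round_half_away(x * (c2 / c1 - 1.0))


def spike_reads(reads: ReadSet, region: tuple[int, int], c1: int, c2: int,
                rng, shift_range=(10, 500)) -> ReadSet:
    """Spike a region from copy number ``c1`` to ``c2``.

    Adds duplicates of randomly chosen in-region reads with starts shifted by
    a uniform offset in +/-[10, 500] bp (clipped to stay inside the region),
    or removes randomly chosen reads.  Reads outside the region are conserved
    exactly.
    """
    rng = np.random.default_rng(rng)
    r0, r1 = region
    idx = reads.in_region(r0, r1)
    x = idx.size
    delta = spike_plan_delta(x, c1, c2)
    if delta == 0:
        return ReadSet(reads.chromosome, reads.starts.copy(),
                       reads.lengths.copy())
    if delta > 0:
        src = rng.choice(idx, size=delta, replace=True)
        sign = rng.choice([-1, 1], size=delta)
        off = sign * rng.integers(shift_range[0], shift_range[1] + 1,
                                  size=delta)
        new_starts = reads.starts[src] + off
        hi = np.maximum(r1 - reads.lengths[src], r0)
        new_starts = np.clip(new_starts, r0, hi)
        starts = np.concatenate([reads.starts, new_starts])
        lengths = np.concatenate([reads.lengths, reads.lengths[src]])
    else:
        n_rm = min(-delta, x)
        rm = rng.choice(idx, size=n_rm, replace=False)
        keep = np.ones(reads.n_reads, dtype=bool)
        keep[rm] = False
        starts, lengths = reads.starts[keep], reads.lengths[keep]
    order = np.argsort(starts, kind="stable")
    return ReadSet(reads.chromosome, starts[order], lengths[order])


def select_fa_regions(reads: ReadSet, plan: list[tuple[int, int, int]],
                      n: int, rng, size_range=(50_000, 100_000),
                      mask_intervals=(), cutoff: float = 0.05,
                      margin: int = 10_000, spacing: int = 2_000,
                      max_tries: int = 50_000
                      ) -> list[tuple[int, int, int, int]]:
    """FA placement on a real read set, with the read-count similarity rule.

    Besides the geometric constraints (inside one LCV, mask-clean,
    non-overlapping), each region's read count RC must satisfy
    |Med - RC| / Med <= ``cutoff``, where Med is the chromosome's median
    read count over windows of the same width - i.e. candidate regions sit
    on typical-coverage territory.
    """
    rng = np.random.default_rng(rng)
    hosts = [(s, e, c) for s, e, c in plan
             if (e - s) > 2 * margin + size_range[1]]
    if not hosts or n < 1:
        raise ValueError("no host segments or n < 1")
    host_p = np.array([e - s for s, e, _ in hosts], dtype=float)
    host_p /= host_p.sum()
    chrom_length = int(plan[-1][1])

    def window_median(width: int) -> float:
        starts = np.arange(0, chrom_length - width, max(width // 2, 1))
        counts = [reads.in_region(int(s), int(s + width)).size
                  for s in starts]
        return float(np.median(counts))

    med_cache: dict[int, float] = {}
    placed: list[tuple[int, int, int, int]] = []
    tries = 0
    while len(placed) < n and tries < max_tries:
        tries += 1
        hs, he, hc = hosts[rng.choice(len(hosts), p=host_p)]
        width = int(rng.integers(size_range[0], size_range[1] + 1))
        lo, hi = hs + margin, he - margin - width
        if hi <= lo:
            continue
        start = int(rng.integers(lo, hi))
        end = start + width
        if any(start < pe + spacing and ps - spacing < end
               for ps, pe, _, _ in placed):
            continue
        if any(start < me and ms < end for _, ms, me in mask_intervals):
            continue
        wkey = int(round(width, -4))  # cache medians per 10-kb width class
        if wkey not in med_cache:
            med_cache[wkey] = window_median(wkey)
        med = med_cache[wkey]
        rc = reads.in_region(start, end).size * (wkey / width)
        if med <= 0 or abs(med - rc) / med > cutoff:
            continue
        placed.append((start, end, hc, _fa_target_cn(hc, rng)))
    if len(placed) < n:
        raise RuntimeError(
            f"could only place {len(placed)} of {n} focal regions under the "
            f"read-count cutoff")
    return sorted(placed)


def spike_truth(reads: ReadSet, plan, fas, rng) -> tuple[ReadSet, TruthSet]:
    """Apply the full spike-in protocol (LCVs then FAs) to a read set."""
    rng = np.random.default_rng(rng)
    truth = TruthSet()
    out = reads
    for s, e, cn in plan:
        if cn != 2:
            out = spike_reads(out, (s, e), 2, cn, rng)
            truth.regions.append(TruthRegion(reads.chromosome, s, e, "LCV",
                                             2, cn))
    for s, e, c1, c2 in fas:
        out = spike_reads(out, (s, e), c1, c2, rng)
        truth.regions.append(TruthRegion(reads.chromosome, s, e, "FA",
                                         c1, c2))
    return out, truth


# ---------------------------------------------------------------------------
# Fully synthetic profiles


def profile_from_cn(cn: np.ndarray, coverage: float, rng,
                    bin_size: int = 1000, chromosome: str = "chr1",
                    wave: dict | None = None) -> RDProfile:
    """Poisson RD profile from an explicit per-bin copy-number vector."""
    rng = np.random.default_rng(rng)
    cn = np.asarray(cn, dtype=float)
    mean = coverage * cn / 2.0 * bin_size
    if wave:
        period = float(wave.get("period", 2000))
        amp = float(wave.get("amplitude", 0.1))
        mean = mean * (1.0 + amp * np.sin(2 * np.pi * np.arange(cn.size)
                                          / period))
    counts = rng.poisson(np.maximum(mean, 0.0))
    gb = GenomeBins(chromosome, cn.size * bin_size, bin_size)
    return RDProfile(gb, counts / bin_size)


def synth_profile(chrom_length: int = 20_000_000, coverage: float = 1.5,
                  bin_size: int = 1000, n_lcv: int = 2, n_fa: int = 40,
                  fa_size_range=(50_000, 100_000),
                  lcv_cn_choices=(1, 3, 4),
                  wave: dict | None = None, gc_bias: float = 0.0,
                  rng=None, chromosome: str = "chr1"
                  ) -> tuple[RDProfile, TruthSet, np.ndarray]:
    """Generate one synthetic chromosome with planted LCVs and FAs.

    Per-bin base counts are Poisson(coverage * cn/2 * bin_size) over the
    planted truth.  ``wave`` = {"amplitude": A, "period": bins} superimposes
    a multiplicative sinusoid (1 + A sin(2 pi i / period)); ``gc_bias`` b
    multiplies expectations by (1 + b (gc - 0.5)) over a smooth random GC
    field assigned at the 100-kb isochore scale.  Returns the profile, the
    truth set and the per-bin true copy number.
    """
    rng = np.random.default_rng(rng)
    gb = GenomeBins(chromosome, chrom_length, bin_size)
    n_bins = gb.n_bins

    if n_lcv > 0:
        plan = plan_benchmark_chromosome(chrom_length, n_lcv, rng,
                                         lcv_cn_choices=lcv_cn_choices)
    else:
        plan = [(0, chrom_length, 2)]
    truth = TruthSet()
    cn = np.full(n_bins, 2.0)
    for s, e, c in plan:
        cn[s // bin_size: -(-e // bin_size)] = c
        if c != 2:
            truth.regions.append(TruthRegion(chromosome, s, e, "LCV", 2, c))
    if n_fa > 0:
        fas = plan_fa_regions(plan, n_fa, rng, size_range=fa_size_range)
        for s, e, c1, c2 in fas:
            cn[s // bin_size: -(-e // bin_size)] = c2
            truth.regions.append(TruthRegion(chromosome, s, e, "FA", c1, c2))

    mean = coverage * cn / 2.0 * bin_size
    if wave:
        period = float(wave.get("period", 2000))
        amp = float(wave.get("amplitude", 0.1))
        mean = mean * (1.0 + amp * np.sin(2 * np.pi * np.arange(n_bins)
                                          / period))
    if gc_bias:
        n_iso = -(-chrom_length // 100_000)
        iso_gc = rng.uniform(0.3, 0.7, size=n_iso)
        gc = np.repeat(iso_gc, 100_000 // bin_size)[:n_bins]
        gb.gc_fraction = gc
        mean = mean * (1.0 + gc_bias * (gc - 0.5))
    counts = rng.poisson(np.maximum(mean, 0.0))
    profile = RDProfile(gb, counts / bin_size)
    return profile, truth, cn


def synth_genome(n_chrom: int = 5, chrom_length: int = 20_000_000,
                 coverage: float = 1.5, n_lcv_range=(1, 4), n_fa: int = 40,
                 fa_size_range=(50_000, 100_000), rng=None, **kwargs
                 ) -> tuple[dict[str, RDProfile], TruthSet]:
    """Multi-chromosome synthetic genome mirroring the benchmark layout:
    per chromosome, 1-4 LCVs with 40 nested FAs of 50-100 kb."""
    rng = np.random.default_rng(rng)
    profiles: dict[str, RDProfile] = {}
    truth = TruthSet()
    for i in range(n_chrom):
        chrom = f"chr{i + 1}"
        n_lcv = int(rng.integers(n_lcv_range[0], n_lcv_range[1] + 1))
        p, t, _ = synth_profile(chrom_length=chrom_length, coverage=coverage,
                                n_lcv=n_lcv, n_fa=n_fa,
                                fa_size_range=fa_size_range, rng=rng,
                                chromosome=chrom, **kwargs)
        profiles[chrom] = p
        truth.regions.extend(t.regions)
    return profiles, truth


# ---------------------------------------------------------------------------
# Evaluation


def _best_single_cover(call_rows, region: TruthRegion) -> tuple[float, dict | None]:
    best, best_row = 0.0, None
    for row in call_rows:
        if row["chromosome"] != region.chromosome:
            continue
        ov = min(row["end"], region.end) - max(row["start"], region.start)
        frac = max(ov, 0) / region.width
        if frac > best:
            best, best_row = frac, row
    return best, best_row


def evaluate_calls(fa_calls: pd.DataFrame | None,
                   lcv_calls: pd.DataFrame | None,
                   truth: TruthSet,
                   require_lcv_state_match: bool = True) -> dict:
    """Precision/recall/f-measure and CN accuracy against a truth set.

    An FA is detected when one call covers > 75% of it; an LCV when one
    called block covers >= 90% of it (and, by default, carries the planted
    integer state).  Precision counts *false amplifications* only.  With zero
    calls precision is reported as 1.0 and flagged ``no_calls``.
    """
    out: dict[str, dict] = {}
    specs = []
    if fa_calls is not None:
        specs.append(("FA", fa_calls, truth.fa_overlap, False, "gt"))
    if lcv_calls is not None:
        specs.append(("LCV", lcv_calls, truth.lcv_overlap,
                      require_lcv_state_match, "ge"))
    for kind, calls, min_ov, state_match, cmp_mode in specs:
        regions = truth.of_kind(kind)
        rows = calls.to_dict("records") if len(calls) else []
        matched_rows = set()
        n_matched = 0
        cn_err = []
        for reg in regions:
            frac, row = _best_single_cover(rows, reg)
            hit = frac > min_ov if cmp_mode == "gt" else frac >= min_ov
            if hit and state_match:
                state = row.get("cn_state",
                                int(np.floor(row["mean_cn"] + 0.5)))
                hit = int(state) == reg.target_cn
            if hit:
                n_matched += 1
                matched_rows.add(id(row))
                cn_err.append(abs(row["mean_cn"] - reg.target_cn))
        # false positives: amplification calls not attributable to any truth
        # region (a call is attributable when >= 50% of its own width lies
        # inside truth territory of this kind)
        def is_amp(row):
            if "direction" in row and isinstance(row["direction"], str):
                return row["direction"] == "amplification"
            return row.get("cn_state", 3) > 2

        def attributable(row):
            width = row["end"] - row["start"]
            cov = sum(max(0, min(row["end"], r.end) - max(row["start"], r.start))
                      for r in regions if r.chromosome == row["chromosome"])
            return width > 0 and cov >= 0.5 * width

        false_amp = sum(1 for row in rows
                        if id(row) not in matched_rows and is_amp(row)
                        and not attributable(row))
        recall = n_matched / len(regions) if regions else np.nan
        n_calls = len(rows)
        if n_calls == 0:
            precision, no_calls = 1.0, True
        else:
            denom = n_matched + false_amp
            precision = n_matched / denom if denom else 1.0
            no_calls = False
        f = (2 * precision * recall / (precision + recall)
             if precision + recall > 0 else 0.0)
        out[kind] = {
            "n_truth": len(regions), "n_matched": n_matched,
            "n_calls": n_calls, "false_amplifications": false_amp,
            "recall": recall, "precision": precision, "f_measure": f,
            "mean_abs_cn_error": float(np.mean(cn_err)) if cn_err else np.nan,
            "no_calls": no_calls,
        }
    return out
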