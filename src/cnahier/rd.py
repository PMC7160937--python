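"""Read-depth (RD) signal on fixed bins, with GC and mappability correction.

The RD signal is the *base count frequency*: total aligned reference bases
overlapping a bin divided by the bin width.  On this scale a genome sequenced
at fold-coverage ``c`` has mean RD ``c`` over copy-number-2 territory, so RD
maps linearly to copy number once the 2N reference level is known.

Masked bins carry NaN and are excluded from every statistic downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .bins import GenomeBins

log = logging.getLogger(__name__)


@dataclass
class RDProfile:
    """Per-chromosome RD vector on a :class:`GenomeBins` grid.

    ``rd`` is non-negative where observed and NaN on masked bins.  The
    ``corrected`` dict records which bias corrections have been applied.
    """

    bins: GenomeBins
    rd: np.ndarray
    corrected: dict[str, bool] = field(
        default_factory=lambda: {"gc": False, "mappability": False}
    )

    def __post_init__(self) -> None:
        self.rd = np.asarray(self.rd, dtype=float)
        if self.rd.shape != (self.bins.n_bins,):
            raise ValueError("rd length does not match bin grid")
        obs = np.isfinite(self.rd)
        if np.any(self.rd[obs] < 0):
            raise ValueError("rd must be non-negative")

    @property
    def chromosome(self) -> str:
        return self.bins.chromosome

    @property
    def mask(self) -> np.ndarray:
        """True where the bin is excluded (mask set or rd missing)."""
        return self.bins.combined_mask() | ~np.isfinite(self.rd)

    @property
    def values(self) -> np.ndarray:
        """RD with masked bins forced to NaN."""
        out = self.rd.copy()
        out[self.mask] = np.nan
        return out

    @property
    def coverage(self) -> float:
        """Estimated fold-coverage: mean RD over unmasked bins."""
        v = self.values
        return float(np.nanmean(v))

    def masked_copy(self, extra_mask: np.ndarray | None = None) -> "RDProfile":
        out = replace(self, rd=self.rd.copy(),
                      corrected=dict(self.corrected))
        if extra_mask is not None:
            out.rd[extra_mask] = np.nan
        return out


# ---------------------------------------------------------------------------
# RD computation from alignments


def _read_passes(read, min_mapq: int, drop_duplicates: bool) -> bool:
    if read.is_unmapped or read.is_secondary or read.is_supplementary:
        return False
    if drop_duplicates and read.is_duplicate:
        return False
    if read.mapping_quality < min_mapq:
        return False
    return True


def compute_rd(alignments, bins: GenomeBins, min_mapq: int = 1,
               drop_duplicates: bool = True) -> RDProfile:
    """Compute the RD signal from coordinate-sorted alignments.

    Every aligned reference-consuming base of each passing read contributes
    1/bin_size to the bin it falls in, so a read straddling a bin boundary is
    split proportionally.  ``alignments`` is a pysam.AlignmentFile or a path
    to a SAM/BAM file.

    Raises
    ------
    KeyError
        If the bin grid's chromosome is absent from the alignment header.
    ValueError
        If the file is not coordinate-sorted.
    """
    import pysam

    own = False
    if isinstance(alignments, str):
        alignments = pysam.AlignmentFile(alignments)
        own = True
    try:
        header = alignments.header.to_dict()
        so = header.get("HD", {}).get("SO", "unknown")
        if so not in ("coordinate", "unknown"):
            raise ValueError(f"alignments must be coordinate-sorted (SO={so})")
        if bins.chromosome not in alignments.references:
            raise KeyError(
                f"chromosome {bins.chromosome!r} not present in alignment "
                f"header (contigs: {list(alignments.references)[:5]}...)"
            )
        bases = np.zeros(bins.n_bins)
        bs = bins.bin_size
        try:
            it = alignments.fetch(bins.chromosome)
        except ValueError:
            # no index: stream the whole file and filter by contig
            it = (r for r in alignments if r.reference_name == bins.chromosome)
        for read in it:
            if not _read_passes(read, min_mapq, drop_duplicates):
                continue
            for s, e in read.get_blocks():
                e = min(e, bins.chrom_length)
                if e <= s:
                    continue
                first, last = s // bs, (e - 1) // bs
                if first == last:
                    bases[first] += e - s
                else:
                    for b in range(first, last + 1):
                        b0, b1 = b * bs, (b + 1) * bs
                        bases[b] += min(e, b1) - max(s, b0)
        rd = bases / bs
    finally:
        if own:
            alignments.close()
    profile = RDProfile(bins, rd)
    profile.rd[bins.combined_mask()] = np.nan
    return profile


# ---------------------------------------------------------------------------
# Bias corrections


def gc_correct(profile: RDProfile, n_strata: int = 100,
               min_stratum_bins: int = 20) -> RDProfile:
    """Isochore-style GC normalisation by stratified median matching.

    Bins are grouped into GC quantile strata (default 1% bands over the
    isochore-window GC values) and each stratum is rescaled so its median RD
    matches the global median:  rd' = rd * median(all) / median(stratum).
    Strata with fewer than ``min_stratum_bins`` unmasked bins are left
    untouched.  Scale-equivariant: multiplying rd by k multiplies the output
    by k.
    """
    gc = profile.bins.gc_fraction
    if gc is None:
        raise ValueError("bins carry no gc_fraction; load a FASTA first")
    v = profile.values
    obs = np.isfinite(v) & np.isfinite(gc)
    if obs.sum() < min_stratum_bins:
        raise ValueError("too few unmasked bins for GC correction")
    global_med = np.median(v[obs])
    if global_med <= 0:
        raise ValueError("global median RD is zero; nothing to normalise")

    # quantile band edges over observed GC values
    qs = np.quantile(gc[obs], np.linspace(0, 1, n_strata + 1))
    qs = np.unique(qs)
    stratum = np.full(profile.bins.n_bins, -1, dtype=int)
    stratum[obs] = np.clip(np.searchsorted(qs, gc[obs], side="right") - 1,
                           0, len(qs) - 2)
    out = profile.rd.copy()
    n_skipped = 0
    for s in range(len(qs) - 1):
        idx = obs & (stratum == s)
        n = int(idx.sum())
        if n == 0:
            continue
        if n < min_stratum_bins:
            n_skipped += 1
            continue
        med = np.median(v[idx])
        if med > 0:
            out[idx] = profile.rd[idx] * (global_med / med)
    if n_skipped:
        log.info("gc_correct: %d strata below %d bins left uncorrected",
                 n_skipped, min_stratum_bins)
    corrected = dict(profile.corrected)
    corrected["gc"] = True
    return RDProfile(profile.bins, out, corrected)


def apply_mappability_mask(profile: RDProfile, threshold: float,
                           track: np.ndarray | None = None) -> RDProfile:
    """Mask (not zero) bins whose mappability falls below ``threshold``.

    ``track`` overrides the per-bin mappability stored on the bin grid.
    Returns a new profile; the ``low_mappability`` mask on the shared bin
    grid is extended (masks only grow).
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    mp = track if track is not None else profile.bins.mappability
    if mp is None:
        raise ValueError("no mappability track available")
    mp = np.asarray(mp, dtype=float)
    if mp.shape != (profile.bins.n_bins,):
        raise ValueError("mappability track does not cover all bins")
    new = (mp < threshold) & ~profile.bins.masks["low_mappability"]
    profile.bins.masks["low_mappability"] |= mp < threshold
    log.info("mappability mask at %.2f: %d newly masked bins",
             threshold, int(new.sum()))
    out = profile.masked_copy()
    out.rd[profile.bins.masks["low_mappability"]] = np.nan
    out.corrected["mappability"] = True
    return out


# ---------------------------------------------------------------------------
# Pre-binned input / output


def load_binned(path: str, bins: GenomeBins | None = None,
                chromosome: str | None = None,
                bin_size: int = 1000) -> RDProfile:
    """Load a pre-binned RD vector so the caller runs without alignments.

    Accepts either a two-column TSV ``bin_index<TAB>rd`` or a bedGraph
    ``chrom start end rd`` (constant-width intervals).  When ``bins`` is not
    given a grid is inferred from the records.
    """
    idx_vals: list[tuple[int, float]] = []
    chrom = chromosome
    inferred_end = 0
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) >= 4:
                c, s, e, v = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
                if chrom is None:
                    chrom = c
                if c != chrom:
                    continue
                if bins is not None:
                    bin_size = bins.bin_size
                idx_vals.append((s // bin_size, v))
                inferred_end = max(inferred_end, e)
            else:
                idx_vals.append((int(parts[0]), float(parts[1])))
    if not idx_vals:
        raise ValueError(f"no usable records in {path}")
    if bins is None:
        n = max(i for i, _ in idx_vals) + 1
        length = max(inferred_end, n * bin_size)
        bins = GenomeBins(chrom or "chr1", length, bin_size)
    rd = np.full(bins.n_bins, np.nan)
    for i, v in idx_vals:
        if 0 <= i < bins.n_bins:
            rd[i] = v
    return RDProfile(bins, rd)


def write_bedgraph(profile: RDProfile, path: str) -> None:
    """Write the unmasked RD values as bedGraph (0-based half-open)."""
    v = profile.values
    starts, ends = profile.bins.starts, profile.bins.ends
    with open(path, "w") as fh:
        for i in range(profile.bins.n_bins):
            if np.isfinite(v[i]):
                fh.write(f"{profile.chromosome}\t{starts[i]}\t{ends[i]}"
                         f"\t{v[i]:.6g}\n")
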