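"""Fixed-width genome bins with per-bin annotation and exclusion masks.

Bins are 0-based, half-open ``[start, start + bin_size)`` and tile one
chromosome without overlap.  Every downstream signal (read depth, GC,
mappability) lives on this grid.  Masks mark bins that must never enter a
statistic: assembly gaps, blacklisted intervals, repeat-associated regions
and low-mappability territory.  Masks only ever grow; no operation unmasks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MASK_NAMES = ("gap", "blacklist", "low_mappability", "repeat")

#: isochore window (bp) over which GC is computed; bins inherit the GC of
#: the window they fall in (window-level "isochore" normalisation).
ISOCHORE_WINDOW = 100_000


@dataclass
class GenomeBins:
    """Bin grid for one chromosome.

    Parameters
    ----------
    chromosome
        Contig name, as it appears in alignment headers.
    chrom_length
        Contig length in bp; the last bin may be partial.
    bin_size
        Bin width in bp (default 1000).
    """

    chromosome: str
    chrom_length: int
    bin_size: int = 1000
    gc_fraction: np.ndarray | None = None
    mappability: np.ndarray | None = None
    masks: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.chrom_length <= 0:
            raise ValueError("chrom_length must be positive")
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        for name in MASK_NAMES:
            self.masks.setdefault(
                name, np.zeros(self.n_bins, dtype=bool)
            )
        if self.gc_fraction is not None:
            self.gc_fraction = np.asarray(self.gc_fraction, dtype=float)
            if self.gc_fraction.shape != (self.n_bins,):
                raise ValueError("gc_fraction length mismatch")
            finite = np.isfinite(self.gc_fraction)
            if np.any((self.gc_fraction[finite] < 0) | (self.gc_fraction[finite] > 1)):
                raise ValueError("gc_fraction outside [0, 1]")
        if self.mappability is not None:
            self.mappability = np.asarray(self.mappability, dtype=float)
            if self.mappability.shape != (self.n_bins,):
                raise ValueError("mappability length mismatch")
            if np.any((self.mappability < 0) | (self.mappability > 1)):
                raise ValueError("mappability outside [0, 1]")

    @property
    def n_bins(self) -> int:
        return -(-self.chrom_length // self.bin_size)

    @property
    def starts(self) -> np.ndarray:
        return np.arange(self.n_bins, dtype=np.int64) * self.bin_size

    @property
    def ends(self) -> np.ndarray:
        return np.minimum(self.starts + self.bin_size, self.chrom_length)

    def combined_mask(self) -> np.ndarray:
        """Union of all exclusion masks (True = excluded)."""
        out = np.zeros(self.n_bins, dtype=bool)
        for arr in self.masks.values():
            out |= arr
        return out

    def add_bed_mask(self, name: str, intervals, min_overlap: float = 1e-9) -> int:
        """Mark bins overlapping BED-style intervals under mask ``name``.

        ``intervals`` is an iterable of ``(chrom, start, end)`` 0-based
        half-open records; records on other chromosomes are ignored.  A bin is
        masked when the overlapping fraction of the bin exceeds
        ``min_overlap`` (any overlap by default).  Idempotent: re-applying the
        same intervals changes nothing.  Returns the number of newly masked
        bins.
        """
        if name not in self.masks:
            self.masks[name] = np.zeros(self.n_bins, dtype=bool)
        mask = self.masks[name]
        before = int(mask.sum())
        for rec in intervals:
            chrom, start, end = rec[0], int(rec[1]), int(rec[2])
            if chrom != self.chromosome or end <= start:
                continue
            first = max(start // self.bin_size, 0)
            last = min((end - 1) // self.bin_size, self.n_bins - 1)
            for b in range(first, last + 1):
                b0 = b * self.bin_size
                b1 = min(b0 + self.bin_size, self.chrom_length)
                ov = min(end, b1) - max(start, b0)
                if ov / (b1 - b0) > min_overlap:
                    mask[b] = True
        return int(mask.sum()) - before

    def set_gc_from_sequence(self, sequence: str,
                             isochore_window: int = ISOCHORE_WINDOW) -> None:
        """Compute per-bin GC from a chromosome sequence.

        GC is computed over ``isochore_window``-bp windows and each bin is
        assigned its window's GC; windows that are all-N yield NaN GC and the
        affected bins are gap-masked.
        """
        seq = np.frombuffer(sequence.upper().encode("ascii"), dtype="S1")
        if seq.size < self.chrom_length:
            raise ValueError("sequence shorter than chrom_length")
        is_gc = (seq == b"G") | (seq == b"C")
        is_base = is_gc | (seq == b"A") | (seq == b"T")
        gc = np.full(self.n_bins, np.nan)
        n_windows = -(-self.chrom_length // isochore_window)
        for w in range(n_windows):
            s, e = w * isochore_window, min((w + 1) * isochore_window, self.chrom_length)
            nb = int(is_base[s:e].sum())
            val = is_gc[s:e].sum() / nb if nb > 0 else np.nan
            first = s // self.bin_size
            last = (e - 1) // self.bin_size
            gc[first:last + 1] = val
        self.gc_fraction = gc
        self.masks["gap"] |= ~np.isfinite(gc)

    def set_gc_from_fasta(self, fasta_path: str,
                          isochore_window: int = ISOCHORE_WINDOW) -> None:
        """Load the chromosome from an indexed FASTA and compute per-bin GC."""
        from pyfaidx import Fasta

        with Fasta(fasta_path, as_raw=True) as fa:
            if self.chromosome not in fa:
                raise KeyError(
                    f"chromosome {self.chromosome!r} not in {fasta_path}"
                )
            seq = str(fa[self.chromosome][:])
        self.set_gc_from_sequence(seq, isochore_window=isochore_window)

    def set_mappability(self, values: np.ndarray) -> None:
        values = np.asarray(values, dtype=float)
        if values.shape != (self.n_bins,):
            raise ValueError("mappability track does not cover all bins")
        if np.any((values < 0) | (values > 1)):
            raise ValueError("mappability outside [0, 1]")
        self.mappability = values

    def set_mappability_from_bedgraph(self, records) -> None:
        """Average bedGraph ``(chrom, start, end, value)`` records into bins.

        Uncovered bp count as mappability 0.
        """
        acc = np.zeros(self.n_bins)
        for rec in records:
            chrom, start, end, val = rec[0], int(rec[1]), int(rec[2]), float(rec[3])
            if chrom != self.chromosome or end <= start:
                continue
            end = min(end, self.chrom_length)
            first, last = start // self.bin_size, (end - 1) // self.bin_size
            for b in range(first, min(last, self.n_bins - 1) + 1):
                b0 = b * self.bin_size
                b1 = min(b0 + self.bin_size, self.chrom_length)
                ov = min(end, b1) - max(start, b0)
                if ov > 0:
                    acc[b] += val * ov / (b1 - b0)
        self.set_mappability(np.clip(acc, 0.0, 1.0))


def read_bed(path: str):
    """Yield ``(chrom, start, end)`` from a BED file (0-based half-open)."""
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            yield parts[0], int(parts[1]), int(parts[2])


def read_bedgraph(path: str):
    """Yield ``(chrom, start, end, value)`` from a bedGraph file."""
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            yield parts[0], int(parts[1]), int(parts[2]), float(parts[3])
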