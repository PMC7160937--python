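"""Static copy-number profile plots.

One figure style: per-bin copy number as a scatter coloured by call class
(red = focally amplified, black = focally deleted, grey = neutral), a stepped
blue line at each block's copy number, and a box outlining every block.
"""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def plot_profile(profile, ref, ibs, fa_calls=None, region=None, path=None,
                 max_points: int = 50_000):
    """Plot one chromosome's CN profile with blocks and focal calls.

    ``region`` is an optional (start_bp, end_bp) window; ``fa_calls`` the FA
    call table restricted to this chromosome.  Returns the figure; saves to
    ``path`` when given.
    """
    bs = profile.bins.bin_size
    n = profile.bins.n_bins
    lo, hi = region if region is not None else (0, n * bs)
    if hi <= lo:
        raise ValueError("empty region")
    b0, b1 = lo // bs, min(-(-hi // bs), n)
    v = profile.values[b0:b1]
    cn = ref.cn_of(v)
    pos = (np.arange(b0, b1) * bs + bs // 2) / 1e6

    color = np.full(cn.size, "0.6", dtype=object)
    if fa_calls is not None and len(fa_calls):
        for _, row in fa_calls.iterrows():
            if row["chromosome"] != profile.chromosome:
                continue
            s, e = int(row["start"]) // bs, -(-int(row["end"]) // bs)
            s, e = max(s - b0, 0), min(e - b0, cn.size)
            if e > s:
                color[s:e] = ("red" if row["direction"] == "amplification"
                              else "black")

    stride = max(cn.size // max_points, 1)
    fig, ax = plt.subplots(figsize=(12, 4))
    ax.scatter(pos[::stride], cn[::stride], s=2, c=list(color[::stride]),
               rasterized=True)
    for ib in ibs:
        x0, x1 = ib.start_bin * bs / 1e6, ib.end_bin * bs / 1e6
        if x1 * 1e6 < lo or x0 * 1e6 > hi:
            continue
        ax.plot([x0, x1], [ib.cn_state, ib.cn_state], color="tab:blue", lw=2)
        ax.add_patch(plt.Rectangle((x0, ib.cn_state - 0.45), x1 - x0, 0.9,
                                   fill=False, edgecolor="tab:blue",
                                   lw=0.8, alpha=0.6))
    ax.set_xlabel(f"{profile.chromosome} position (Mb)")
    ax.set_ylabel("copy number")
    ax.set_ylim(-0.3, max(6.5, np.nanmax(cn) + 0.5 if np.isfinite(cn).any()
                          else 6.5))
    ax.set_title(f"{profile.chromosome}: 2N at RD {ref.rd_2n:.3f}")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_histogram_fit(profile, ref, path=None, dx: float = 0.02):
    """RD histogram in CN units with the fitted multimodal density."""
    from .reference import multimodal_pdf

    if hasattr(profile, "values"):
        vals = profile.values
    else:
        vals = np.concatenate([p.values for p in profile])
    vals = vals[np.isfinite(vals)]
    x = 2.0 * vals / ref.rd_2n
    fig, ax = plt.subplots(figsize=(7, 4))
    edges = np.arange(0, 7 + dx, dx)
    ax.hist(x[x <= 7], bins=edges, density=False, color="0.7",
            weights=np.full((x <= 7).sum(), 1.0 / (vals.size * dx)))
    grid = np.linspace(0, 7, 700)
    ax.plot(grid, multimodal_pdf(grid, ref.ploidy, ref.sigma), "r-",
            label=f"fit ({ref.ploidy.name}, score {ref.fit_score:.2f})")
    ax.set_xlabel("copy number (RD / 2N reference x 2)")
    ax.set_ylabel("density")
    ax.legend()
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
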