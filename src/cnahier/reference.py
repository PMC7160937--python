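"""Absolute copy-number reference from the multimodal RD distribution.

A cancer genome's read-depth histogram is multimodal: each iso-copy-number
block contributes a near-Gaussian peak centred at its copy-number state.  The
global median therefore tracks the *dominant* state, which in aneuploid
genomes need not be 2N — using it as the diploid reference misclassifies
every block (a triploid-dominant genome would see its 3N territory called
neutral).  Instead we model the RD density, rescaled to copy-number units, as
a mixture of Gaussians at integer states 2..6,

    f(x) = sum_i  c * w_i * N(x; mean=i, sd=sigma),      c = 1 / sum_i w_i,

and slide a candidate 2N level ``g`` over a grid: RD is mapped to CN units
via ``x = 2 * rd / g`` and the candidate maximising the overlap between the
empirical density r(x) and f(x) is the CN reference.  Ploidy models reweight
the states: the *free* model is flat (w_i = 1), while diploid / triploid /
tetraploid put geometrically decaying weight around the main state n,
w_i = 2^(-|i - n|).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .rd import RDProfile

log = logging.getLogger(__name__)

STATES = np.arange(2, 7)  # modelled CN states
#: bins scaled beyond this CN are excluded from the fit (states above 6
#: are outside the mixture's support)
FIT_CN_MAX = 6.5


@dataclass(frozen=True)
class PloidyModel:
    """State weighting of the multimodal mixture."""

    name: str
    main_state: int | None
    weights: np.ndarray  # over STATES = 2..6

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.shape != STATES.shape or np.any(w <= 0):
            raise ValueError("weights must be positive, one per state 2..6")
        object.__setattr__(self, "weights", w)

    @property
    def c(self) -> float:
        """Normalisation constant, 1 / sum of weights."""
        return 1.0 / float(self.weights.sum())


_MAIN_STATE = {"diploid": 2, "triploid": 3, "tetraploid": 4}


def model_weights(ploidy_name: str, weight_sign: str = "decreasing") -> PloidyModel:
    """Build the ploidy model for one of free/diploid/triploid/tetraploid.

    ``weight_sign="decreasing"`` uses w_i = 2^(-|i-n|), so the main ploidy
    state carries the largest weight (majority of the genome near n).  The
    variant ``"printed"`` uses 2^(+|i-n|) instead.
    """
    if ploidy_name == "free":
        return PloidyModel("free", None, np.ones_like(STATES, dtype=float))
    if ploidy_name not in _MAIN_STATE:
        raise ValueError(
            f"unknown ploidy model {ploidy_name!r}; "
            "allowed: free, diploid, triploid, tetraploid"
        )
    n = _MAIN_STATE[ploidy_name]
    expo = np.abs(STATES - n).astype(float)
    if weight_sign == "decreasing":
        w = 2.0 ** (-expo)
    elif weight_sign == "printed":
        w = 2.0 ** expo
    else:
        raise ValueError("weight_sign must be 'decreasing' or 'printed'")
    return PloidyModel(ploidy_name, n, w)


def multimodal_pdf(x, ploidy: PloidyModel, sigma: float) -> np.ndarray:
    """Mixture density f(x) over CN units; integrates to 1 on (-inf, inf)."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    x = np.atleast_1d(np.asarray(x, dtype=float))
    dens = np.zeros_like(x)
    c = ploidy.c
    for i, w in zip(STATES, ploidy.weights):
        dens += c * w * norm.pdf(x, loc=i, scale=sigma)
    return dens


@dataclass(frozen=True)
class CNReference:
    """The fitted 2N RD level and the induced RD -> CN mapping."""

    rd_2n: float
    ploidy: PloidyModel
    sigma: float
    fit_score: float

    def __post_init__(self):
        if self.rd_2n <= 0:
            raise ValueError("rd_2n must be positive")

    def state_center(self, state: int) -> float:
        """RD value at the centre of an integer CN state."""
        return self.rd_2n * state / 2.0

    def state_interval(self, state: int) -> tuple[float, float]:
        """Half-open RD interval [lo, hi) assigned to an integer state."""
        lo = self.rd_2n * (state - 0.5) / 2.0
        hi = self.rd_2n * (state + 0.5) / 2.0
        return (max(lo, 0.0), hi)

    def cn_of(self, rd) -> np.ndarray:
        """Continuous copy number 2*rd/rd_2n (NaN passes through)."""
        rd = np.asarray(rd, dtype=float)
        if np.any(rd[np.isfinite(rd)] < 0):
            raise ValueError("rd must be non-negative")
        return 2.0 * rd / self.rd_2n

    def state_of(self, rd) -> np.ndarray:
        """Integer CN state; boundaries at half-integers, half-open upward
        (cn = 2.5 belongs to state 3)."""
        cn = self.cn_of(rd)
        return np.floor(cn + 0.5).astype(int)


def rd_to_cn(rd: float, ref: CNReference) -> tuple[float, int]:
    """Map one RD value to (continuous CN, integer state)."""
    cn = float(ref.cn_of(rd))
    return cn, int(ref.state_of(rd))


# ---------------------------------------------------------------------------
# Fitting


def _pooled_values(profile) -> np.ndarray:
    """Unmasked RD values from a profile, a sequence of profiles, or a raw
    array of RD values."""
    if isinstance(profile, RDProfile):
        profiles = [profile]
    elif isinstance(profile, np.ndarray):
        vals = np.asarray(profile, dtype=float).ravel()
        return vals[np.isfinite(vals)]
    else:
        profiles = list(profile)
    vals = np.concatenate([p.values for p in profiles])
    return vals[np.isfinite(vals)]


def _sigma_for_candidate(x: np.ndarray, lo: float = 0.01, hi: float = 0.5) -> float:
    """Robust per-state spread (CN units) at a candidate scaling.

    Residuals to the nearest modelled state, restricted to |resid| <= 0.25,
    scaled by 1.4826 * MAD; clamped to [lo, hi].
    """
    state = np.clip(np.floor(x + 0.5), STATES[0], STATES[-1])
    resid = x - state
    resid = resid[np.abs(resid) <= 0.25]
    if resid.size < 20:
        return 0.1
    mad = np.median(np.abs(resid - np.median(resid)))
    return float(np.clip(1.4826 * mad, lo, hi))


def _overlap_score(x: np.ndarray, n_total: int, ploidy: PloidyModel,
                   sigma: float, dx: float = 0.01) -> float:
    """Histogram-intersection overlap between r(x) and f(x) in [0, 1].

    The empirical density is normalised by the *total* number of unmasked
    bins, so probability mass scaled outside the modelled CN range
    [0, FIT_CN_MAX] is lost, penalising scalings that push real peaks out of
    the mixture's support.
    """
    edges = np.arange(0.0, FIT_CN_MAX + dx, dx)
    counts, _ = np.histogram(x, bins=edges)
    r_hat = counts / (n_total * dx)
    centers = 0.5 * (edges[:-1] + edges[1:])
    f = multimodal_pdf(centers, ploidy, sigma)
    return float(np.minimum(r_hat, f).sum() * dx)


def estimate_cn_reference(profile, ploidy: PloidyModel | str = "free",
                          grid: np.ndarray | None = None,
                          n_grid: int = 500,
                          min_bins: int = 10_000,
                          refine: bool = True,
                          tie_tol: float = 0.15) -> CNReference:
    """Estimate the 2N RD level by maximum density overlap.

    Parameters
    ----------
    profile
        An :class:`RDProfile` or a sequence of them (whole genome).
    ploidy
        A :class:`PloidyModel` or one of its names.
    grid
        Candidate 2N RD values.  Default: ``n_grid`` log-spaced points over
        [0.25, 2] x the global RD median.
    refine
        After the grid argmax, refine with a second, finer log-spaced pass
        over +/- 2 grid steps around the winner (resolves the coarse-grid
        quantisation of rd_2n).

    Near-ties on the score (within ``tie_tol`` of the maximum, relative) are
    broken toward the **larger** candidate - the lower-ploidy interpretation
    of the same histogram.  Under the free model a unimodal histogram scores
    identically for every state its mode could sit on (up to sampling noise),
    so the tie rule must act at noise scale, not only on exact equality.
    """
    if isinstance(ploidy, str):
        ploidy = model_weights(ploidy)
    vals = _pooled_values(profile)
    if vals.size < min_bins:
        raise ValueError(
            f"need >= {min_bins} unmasked bins to fit the CN reference, "
            f"got {vals.size}"
        )
    med = float(np.median(vals))
    if med <= 0 or not np.isfinite(med):
        raise ValueError("degenerate RD histogram (non-positive median)")
    if grid is None:
        grid = np.geomspace(0.25 * med, 2.0 * med, n_grid)
    grid = np.asarray(grid, dtype=float)

    def score_of(g: float) -> float:
        x = 2.0 * vals / g
        sigma = _sigma_for_candidate(x)
        return _overlap_score(x[x <= FIT_CN_MAX], vals.size, ploidy, sigma)

    scores = np.array([score_of(g) for g in grid])
    if scores.max() - scores.min() < 1e-3:
        log.warning("flat overlap landscape; falling back to global median "
                    "as the 2N reference")
        best_g = med
        best_score = score_of(med)
    else:
        # local maxima of the score landscape are the distinct scale
        # interpretations; among those within tie_tol of the best, take the
        # largest candidate, then refine within that peak by pure argmax
        interior = np.arange(1, len(grid) - 1)
        is_peak = (scores[interior] >= scores[interior - 1]) \
            & (scores[interior] >= scores[interior + 1])
        peaks = interior[is_peak]
        if peaks.size == 0:
            peaks = np.array([int(np.argmax(scores))])
        eligible = peaks[scores[peaks] >= scores.max() * (1.0 - tie_tol)]
        best_idx = int(eligible[np.argmax(grid[eligible])])
        best_g, best_score = float(grid[best_idx]), float(scores[best_idx])
        if refine and len(grid) > 2:
            lo = grid[max(best_idx - 2, 0)]
            hi = grid[min(best_idx + 2, len(grid) - 1)]
            fine = np.geomspace(lo, hi, 81)
            fscores = np.array([score_of(g) for g in fine])
            fi = int(np.argmax(fscores))
            if fscores[fi] >= best_score:
                best_g, best_score = float(fine[fi]), float(fscores[fi])
            # polish: when the intersection saturates, the score is flat over
            # a ~sigma-wide band of scales; centre the modes on integer
            # states instead (median of x/round(x) near states is an exact
            # multiplicative correction for all states at once)
            g = best_g
            for _ in range(3):
                x = 2.0 * vals / g
                near = np.round(x)
                sel = (np.abs(x - near) <= 0.25) & (near >= 1) \
                    & (near <= STATES[-1])
                if sel.sum() < 100:
                    break
                g *= float(np.median(x[sel] / near[sel]))
            polished = score_of(g)
            if polished >= best_score * (1.0 - tie_tol):
                best_g, best_score = float(g), float(polished)

    sigma = _sigma_for_candidate(2.0 * vals / best_g)
    return CNReference(rd_2n=best_g, ploidy=ploidy, sigma=sigma,
                       fit_score=best_score)
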