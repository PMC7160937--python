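"""Ploidy models, the multimodal density, and CN-reference estimation."""

import numpy as np
import pytest
from scipy.integrate import quad

from cnahier.reference import (CNReference, estimate_cn_reference,
                               model_weights, multimodal_pdf, rd_to_cn)


def sample_from_mixture(ploidy, sigma, rd_2n, n, rng):
    """Draw RD values from the multimodal model itself (test oracle)."""
    states = np.arange(2, 7)
    probs = ploidy.weights / ploidy.weights.sum()
    s = rng.choice(states, size=n, p=probs)
    x = rng.normal(s, sigma)
    return np.maximum(x, 0.01) * rd_2n / 2.0


class TestModelWeights:
    def test_free_model_flat_weights(self):
        m = model_weights("free")
        np.testing.assert_array_equal(m.weights, np.ones(5))
        assert m.c == pytest.approx(1 / 5)

    def test_diploid_weights_halve_per_state(self):
        m = model_weights("diploid")
        np.testing.assert_allclose(m.weights / m.weights[0],
                                   [1, 0.5, 0.25, 0.125, 0.0625])

    def test_triploid_max_weight_at_main_state(self):
        m = model_weights("triploid")
        assert np.argmax(m.weights) == 1  # state 3

    def test_printed_variant_increases_with_distance(self):
        m = model_weights("diploid", weight_sign="printed")
        assert np.all(np.diff(m.weights) > 0)

    def test_unknown_name_lists_allowed(self):
        with pytest.raises(ValueError, match="free, diploid"):
            model_weights("pentaploid")


class TestMultimodalPDF:
    def test_density_at_state_center(self):
        m = model_weights("free")
        sigma = 0.1
        got = multimodal_pdf(2.0, m, sigma)[0]
        expected = m.c / np.sqrt(2 * np.pi * sigma ** 2)
        assert got == pytest.approx(expected, rel=1e-6)

    def test_integrates_to_one(self):
        for name in ("free", "diploid", "tetraploid"):
            m = model_weights(name)
            total, _ = quad(lambda x: multimodal_pdf(x, m, 0.2)[0], 0, 12,
                            limit=200)
            assert total == pytest.approx(1.0, abs=1e-6)

    def test_gaussian_symmetry_around_states(self):
        m = model_weights("free")
        assert multimodal_pdf(3.1, m, 0.05)[0] == pytest.approx(
            multimodal_pdf(2.9, m, 0.05)[0], rel=1e-9)

    def test_nonpositive_sigma_raises(self):
        with pytest.raises(ValueError):
            multimodal_pdf(2.0, model_weights("free"), 0.0)


class TestRdToCn:
    @pytest.fixture
    def ref(self):
        return CNReference(1.0, model_weights("free"), 0.1, 0.9)

    @pytest.mark.parametrize("rd,cn,state", [
        (1.0, 2.0, 2),
        (1.5, 3.0, 3),
        (1.26, 2.52, 3),    # boundary at 2.5 is half-open upward
        (1.249, 2.498, 2),
        (0.1, 0.2, 0),
    ])
    def test_mapping_and_boundaries(self, ref, rd, cn, state):
        got_cn, got_state = rd_to_cn(rd, ref)
        assert got_cn == pytest.approx(cn)
        assert got_state == state

    def test_exact_boundary_goes_up(self, ref):
        assert rd_to_cn(1.25, ref)[1] == 3   # cn 2.5 -> state 3

    def test_negative_rd_raises(self, ref):
        with pytest.raises(ValueError):
            rd_to_cn(-0.1, ref)

    def test_intervals_partition(self, ref):
        for s in range(1, 6):
            lo, hi = ref.state_interval(s)
            assert hi == pytest.approx(ref.state_interval(s + 1)[0])


def brute_force_reference(vals, ploidy, grid):
    """Independent coarse-grid maximiser of the same overlap objective."""
    from cnahier.reference import (_overlap_score, _sigma_for_candidate,
                                   FIT_CN_MAX)
    best, best_g = -1.0, None
    for g in grid:
        x = 2.0 * vals / g
        s = _overlap_score(x[x <= FIT_CN_MAX], vals.size, ploidy,
                           _sigma_for_candidate(x))
        if s >= best:
            best, best_g = s, g
    return best_g


class TestEstimateCNReference:
    def test_three_mode_histogram_free_model(self, rng):
        # modes at RD 50/75/100 with mass .2/.5/.3 -> these are CN 2,3,4
        vals = np.concatenate([
            rng.normal(50, 2.0, 20_000),
            rng.normal(75, 2.0, 50_000),
            rng.normal(100, 2.0, 30_000)])
        ref = estimate_cn_reference(vals, "free")
        assert ref.rd_2n == pytest.approx(50.0, rel=0.02)
        # the global median sits on the CN-3 mode: ~50% off the reference
        med = np.median(vals)
        assert abs(med - ref.rd_2n) / ref.rd_2n > 0.3
        # brute-force oracle over a coarse grid agrees
        coarse = np.linspace(30, 120, 181)
        g = brute_force_reference(vals, model_weights("free"), coarse)
        assert abs(g - ref.rd_2n) <= (coarse[1] - coarse[0]) + 0.02 * 50

    def test_unimodal_free_matches_diploid_model(self, rng):
        vals = rng.normal(10.0, 0.4, 60_000)
        free = estimate_cn_reference(vals, "free")
        dip = estimate_cn_reference(vals, "diploid")
        step = (2.0 / 0.25) ** (1 / 499)  # default grid ratio
        assert abs(free.rd_2n - dip.rd_2n) / dip.rd_2n < 2 * (step - 1) + 0.01

    @pytest.mark.parametrize("ploidy,sigma", [
        ("free", 0.05), ("free", 0.3),
        ("diploid", 0.1), ("triploid", 0.15), ("tetraploid", 0.2)])
    def test_recovery_within_one_percent(self, ploidy, sigma):
        rng = np.random.default_rng(hash((ploidy, sigma)) % 2**31)
        model = model_weights(ploidy)
        vals = sample_from_mixture(model, sigma, rd_2n=4.2, n=60_000, rng=rng)
        ref = estimate_cn_reference(vals, model)
        assert ref.rd_2n == pytest.approx(4.2, rel=0.01)

    def test_scale_equivariance(self, rng):
        model = model_weights("diploid")
        vals = sample_from_mixture(model, 0.1, 2.0, 50_000, rng)
        r1 = estimate_cn_reference(vals, model)
        r2 = estimate_cn_reference(vals * 7.0, model)
        assert r2.rd_2n == pytest.approx(7.0 * r1.rd_2n, rel=0.005)

    def test_too_few_bins_raises(self, rng):
        with pytest.raises(ValueError, match="10000"):
            estimate_cn_reference(rng.normal(2, 0.1, 500), "free")

    def test_deterministic(self, rng):
        vals = sample_from_mixture(model_weights("free"), 0.1, 3.0,
                                   30_000, rng)
        a = estimate_cn_reference(vals, "free")
        b = estimate_cn_reference(vals, "free")
        assert a.rd_2n == b.rd_2n and a.fit_score == b.fit_score
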