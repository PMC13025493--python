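"""Uncertainty metrics, Platt calibration, and the error-correlation analysis."""

import math

import numpy as np
import pytest

from musclequant.ensemble import ProbabilityMap, aggregate
from musclequant.uncertainty import (
    CalibrationModel,
    apply_platt,
    binary_entropy,
    compute_metrics,
    correlate,
    cov_of_areas,
    fit_platt,
)


def pmap(values, spacing=(1.0, 1.0), provenance="m"):
    return ProbabilityMap(grid=np.asarray(values, dtype=float), pixel_spacing=spacing, provenance=provenance)


class TestComputeMetrics:
    def test_confident_unanimous_ensemble(self):
        grid = np.array([[1.0, 0.0], [1.0, 0.0]])
        rep = compute_metrics(aggregate([pmap(grid), pmap(grid)]))
        assert rep.avg_probability == 1.0
        assert rep.avg_variance == 0.0
        assert rep.avg_variance_sm == 0.0
        assert rep.cov_pixelwise == 0.0
        assert rep.cov_sma == 0.0
        assert rep.avg_entropy == 0.0
        assert rep.expected_entropy == 0.0

    def test_symmetric_two_member_disagreement_closed_forms(self):
        # every pixel sees members {0.4, 0.6}: mean 0.5, population var 0.01
        rep = compute_metrics(aggregate([pmap(np.full((3, 3), 0.4)), pmap(np.full((3, 3), 0.6))]))
        assert rep.avg_entropy == pytest.approx(1.0)
        h04 = -(0.4 * math.log2(0.4) + 0.6 * math.log2(0.6))
        assert rep.expected_entropy == pytest.approx(h04)  # ≈ 0.9710 bits
        assert rep.avg_variance == pytest.approx(0.01)
        assert math.isnan(rep.avg_probability_sm)  # empty consensus: undefined, not zero
        assert math.isnan(rep.avg_variance_sm)

    def test_two_pixel_toy_matches_hand_computation(self):
        # members: pixel A sees {0.9, 0.2}, pixel B sees {0.7, 0.4}
        m1 = pmap([[0.9, 0.7]])
        m2 = pmap([[0.2, 0.4]])
        rep = compute_metrics(aggregate([m1, m2]))

        def h2(p):
            return 0.0 if p in (0, 1) else -(p * math.log2(p) + (1 - p) * math.log2(1 - p))

        pix = [(0.9, 0.2), (0.7, 0.4)]
        means = [sum(v) / 2 for v in pix]
        variances = [np.var(v) for v in pix]
        sds = [math.sqrt(v) for v in variances]
        assert rep.avg_probability == pytest.approx(np.mean([max(m, 1 - m) for m in means]))
        sm = [m > 0.5 for m in means]
        assert rep.avg_probability_sm == pytest.approx(np.mean([m for m, s in zip(means, sm) if s]))
        assert rep.avg_variance == pytest.approx(np.mean(variances))
        assert rep.avg_variance_sm == pytest.approx(np.mean([v for v, s in zip(variances, sm) if s]))
        assert rep.cov_pixelwise == pytest.approx(np.mean([s / m for s, m in zip(sds, means)]))
        areas = [sum(p > 0.5 for p in m.grid.ravel()) for m in (m1, m2)]  # {2, 0}
        assert rep.cov_sma == pytest.approx(np.std(areas, ddof=1) / np.mean(areas))
        assert rep.avg_entropy == pytest.approx(np.mean([h2(m) for m in means]))
        assert rep.expected_entropy == pytest.approx(np.mean([(h2(a) + h2(b)) / 2 for a, b in pix]))
        assert math.isnan(rep.avg_calibrated_probability)  # no calibration model supplied

    def test_metrics_invariant_to_member_order(self, member_factory):
        members = member_factory(k=5, shape=(12, 12))
        a = compute_metrics(aggregate(members))
        b = compute_metrics(aggregate(members[::-1]))
        for k, v in a.as_dict().items():
            other = b.as_dict()[k]
            assert (math.isnan(v) and math.isnan(other)) or v == pytest.approx(other)

    def test_calibrated_probability_present_with_model(self):
        grid = np.array([[0.8, 0.3]])
        rep = compute_metrics(
            aggregate([pmap(grid), pmap(grid)]), calibration=CalibrationModel(a=1.0, b=0.0)
        )
        # identity calibration: calibrated metric equals the raw one
        assert rep.avg_calibrated_probability == pytest.approx(rep.avg_probability)


class TestCovOfAreas:
    def test_equal_areas_zero(self):
        assert cov_of_areas([100, 100, 100]) == 0.0

    def test_sample_sd_convention(self):
        assert cov_of_areas([90, 100, 110]) == pytest.approx(0.10)

    def test_single_area_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            cov_of_areas([100])

    def test_zero_mean_undefined(self):
        assert math.isnan(cov_of_areas([0, 0]))


class TestPlatt:
    def test_recovers_identity_on_calibrated_probabilities(self):
        rng = np.random.default_rng(99)
        p = rng.uniform(0.02, 0.98, size=100_000)
        y = rng.random(p.size) < p
        model = fit_platt(p, y)
        grid = np.linspace(0.1, 0.9, 17)
        cal = apply_platt(model, pmap(grid[None, :])).grid.ravel()
        assert np.abs(cal - grid).max() < 0.02

    def test_overconfident_inputs_compress_toward_half(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(0.02, 0.98, size=100_000)
        y = rng.random(p.size) < (0.5 * p + 0.25)  # true rate milder than stated
        model = fit_platt(p, y)
        cal = apply_platt(model, pmap(np.array([[0.05, 0.95]]))).grid.ravel()
        assert cal[0] > 0.05
        assert cal[1] < 0.95

    def test_monotone(self):
        model = CalibrationModel(a=0.7, b=0.2)
        grid = np.linspace(0.01, 0.99, 50)
        cal = apply_platt(model, pmap(grid[None, :])).grid.ravel()
        assert (np.diff(cal) >= 0).all()

    def test_single_class_labels_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            fit_platt(np.array([0.2, 0.8]), np.array([1, 1]))

    def test_negative_slope_rejected(self):
        with pytest.raises(ValueError, match="slope"):
            CalibrationModel(a=-0.5, b=0.0)


def vector_with_exact_r(r, n, seed):
    """Construct (x, y) whose sample Pearson r is exactly ``r`` (Gram-Schmidt)."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    z = rng.standard_normal(n)
    x = (x - x.mean()) / x.std()
    z = z - z.mean()
    z -= (z @ x) / (x @ x) * x
    z /= z.std()
    return x, r * x + math.sqrt(1 - r**2) * z


class TestCorrelate:
    def test_weak_band_at_r_0296(self):
        x, y = vector_with_exact_r(0.296, 40, seed=1)
        res = correlate(x, y)
        assert res.r == pytest.approx(0.296)
        assert res.band == "weak"

    def test_exact_linear_is_perfect(self):
        x = np.arange(10.0)
        res = correlate(x, 3 * x + 1)
        assert res.r == pytest.approx(1.0)
        assert res.band == "perfect"

    def test_t_transform_p_value(self):
        # r just inside the moderate band; the 1e-9 offset leaves t and p
        # unchanged at the asserted precision
        x, y = vector_with_exact_r(0.5 - 1e-9, 25, seed=2)
        res = correlate(x, y)
        # t = r·sqrt((n−2)/(1−r²)) = 0.5·sqrt(23/0.75) ≈ 2.7689, df = 23
        t = 0.5 * math.sqrt((25 - 2) / (1 - 0.25))
        assert t == pytest.approx(2.7689, abs=5e-4)
        assert res.p_value == pytest.approx(0.01092, abs=2e-4)
        assert res.p_value < 0.05
        assert res.band == "moderate"

    @pytest.mark.parametrize(
        "r,band",
        [
            (0.15, "weak"),
            # boundary checks offset by 1e-6: the construction is exact only
            # up to floating roundoff, far below the offset
            (0.3 - 1e-6, "weak"),
            (0.3 + 1e-6, "moderate"),
            (0.45, "moderate"),
            (0.5 - 1e-6, "moderate"),
            (0.5 + 1e-6, "strong"),
            (0.65, "strong"),
            (0.7 + 1e-6, "very strong"),
            (0.8, "very strong"),
        ],
    )
    def test_band_cutpoints(self, r, band):
        x, y = vector_with_exact_r(r, 60, seed=3)
        assert correlate(x, y).band == band

    def test_zero_variance_flagged_undefined(self):
        res = correlate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert math.isnan(res.r)
        assert res.band == "undefined"

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            correlate([1, 2], [3, 4])


def test_binary_entropy_conventions():
    assert binary_entropy(np.array([0.0, 1.0])).tolist() == [0.0, 0.0]
    assert binary_entropy(np.array([0.5]))[0] == pytest.approx(1.0)
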