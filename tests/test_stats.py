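"""Wing scores, dose-dependency testing, and constrained sigmoid fitting."""

import numpy as np
import pandas as pd
import pytest

from wingspot import (
    DoseResponse,
    MwhGrouping,
    SigmoidParams,
    compute_wing_scores,
    dose_dependency_test,
    fit_sigmoid,
    generate_dose_scores,
    scale_measures,
    two_sample_test,
)
from wingspot.stats import _sigmoid


def drc_from_means(doses, means, n=5):
    """A DoseResponse whose per-dose means equal ``means`` exactly."""
    rows = [
        (i * n + k, float(d), float(m))
        for i, (d, m) in enumerate(zip(doses, means))
        for k in range(n)
    ]
    return DoseResponse.from_table(
        pd.DataFrame(rows, columns=["wing_id", "dose_mM", "score"])
    )


class TestWingScores:
    def test_clean_wing_scores_zero(self):
        ws = compute_wing_scores(MwhGrouping(0, 0, 0), analyzed_area_um2=1e6)
        assert (ws.score_hairs_per_mm2, ws.score_cells, ws.score_spots) == (0, 0, 0)
        assert ws.score_dichotomous is False

    def test_single_three_hair_cell(self):
        ws = compute_wing_scores(MwhGrouping(3, 1, 1), analyzed_area_um2=2e6)
        assert ws.score_cells == 1
        assert ws.score_spots == 1
        assert ws.score_dichotomous is True          # 3 > 2
        assert ws.score_hairs_per_mm2 == pytest.approx(1.5)

    def test_two_hairs_is_not_dichotomous_positive(self):
        ws = compute_wing_scores(MwhGrouping(2, 1, 1), analyzed_area_um2=1e6)
        assert ws.score_dichotomous is False         # boundary: needs > 2

    def test_zero_area_with_hairs_raises(self):
        with pytest.raises(ValueError, match="area"):
            compute_wing_scores(MwhGrouping(3, 1, 1), analyzed_area_um2=0.0)


class TestDoseDependency:
    doses = [0.0, 0.6, 1.25, 2.5, 5.0, 10.0]

    def test_increasing_means_are_genotoxic(self):
        slope, p, verdict = dose_dependency_test(
            drc_from_means(self.doses, [1, 2, 3, 5, 8, 12])
        )
        assert verdict == "genotoxic"
        assert slope > 0
        assert p < 0.01

    def test_decreasing_means_are_non_genotoxic_one_sided(self):
        _, p, verdict = dose_dependency_test(
            drc_from_means(self.doses, [12, 8, 5, 3, 2, 1])
        )
        assert verdict == "non-genotoxic"
        assert p > 0.95

    def test_fewer_than_three_doses_raises(self):
        with pytest.raises(ValueError, match="insufficient"):
            dose_dependency_test(drc_from_means([0.0, 1.0], [1, 2]))

    def test_null_rejection_rate_is_near_alpha(self):
        # quick calibration check; the full 1000-run version is in acceptance
        from wingspot import simulate_null_rejection_rate

        rate = simulate_null_rejection_rate(n_sim=400, seed=77)
        assert 0.02 <= rate <= 0.08


class TestTwoSample:
    def test_identical_zero_variance_groups_return_one(self):
        assert two_sample_test([2, 2, 2], [2, 2, 2]) == 1.0

    def test_three_sd_shift_is_highly_significant(self, rng):
        a = rng.normal(10.0, 1.0, 60)
        b = rng.normal(7.0, 1.0, 60)
        assert two_sample_test(a, b) < 1e-3

    def test_type_one_error_within_binomial_band(self, rng):
        hits = sum(
            two_sample_test(rng.normal(5, 1, 30), rng.normal(5, 1, 30)) < 0.05
            for _ in range(1000)
        )
        assert 23 <= hits <= 77  # binomial 95% band around 50/1000

    def test_rank_alternative_available(self, rng):
        a = rng.normal(10.0, 1.0, 40)
        b = rng.normal(7.0, 1.0, 40)
        assert two_sample_test(a, b, method="ranksum") < 1e-3


class TestSigmoidFit:
    doses = [0.0, 0.3, 0.6, 1.25, 2.5, 5.0, 10.0]

    def test_noiseless_data_recovered_exactly(self):
        top, offset = 12.0, 0.0
        truth = (1.2, 2.5, 1.3)  # bottom, ec50, slope
        means = _sigmoid(np.array(self.doses), top, offset, *truth)
        fit = fit_sigmoid(drc_from_means(self.doses, means), top=top)
        assert fit.bottom == pytest.approx(truth[0], rel=1e-6)
        assert fit.ec50_mM == pytest.approx(truth[1], rel=1e-6)
        assert fit.slope == pytest.approx(truth[2], rel=1e-6)
        assert fit.ci_ec50[0] <= fit.ec50_mM <= fit.ci_ec50[1]

    def test_fit_needs_four_doses_and_a_control(self):
        with pytest.raises(ValueError, match=">= 4"):
            fit_sigmoid(drc_from_means([0, 1, 2], [1, 2, 3]), top=5.0)
        bad = drc_from_means([1, 2, 4, 8], [1, 2, 3, 4])
        with pytest.raises(ValueError, match="control"):
            fit_sigmoid(bad, top=5.0)

    def test_curve_never_exceeds_enforced_top(self):
        curve = SigmoidParams(bottom=1.0, top=10.0, ec50_mM=2.0, slope=1.5)
        means = curve.mean_at(np.array(self.doses))
        fit = fit_sigmoid(drc_from_means(self.doses, means), top=10.0)
        grid = np.linspace(0, 10, 50)
        assert (fit.predict(grid) <= 10.0 + 1e-9).all()

    def test_far_extrapolated_ec50_is_flagged(self):
        # nearly-linear shallow data: EC50 lands far beyond the dose range
        means = 1.0 + 0.001 * np.asarray(self.doses)
        fit = fit_sigmoid(drc_from_means(self.doses, means), top=50.0)
        if fit.ec50_mM > 1e3 * max(self.doses):
            assert fit.extrapolated

    def test_envelope_brackets_the_fit(self):
        curve = SigmoidParams()
        table = generate_dose_scores(curve, self.doses, n_wings=40, seed=3)
        fit = fit_sigmoid(DoseResponse.from_table(table), top=curve.top)
        grid = np.linspace(0, 10, 25)
        lo, hi = fit.envelope(grid)
        mid = fit.predict(grid)
        assert (lo <= mid + 1e-9).all() and (mid <= hi + 1e-9).all()

    def test_wald_ci_overlaps_bootstrap_ci(self, rng):
        curve = SigmoidParams()
        table = generate_dose_scores(curve, self.doses, n_wings=60, seed=9)
        drc = DoseResponse.from_table(table)
        fit = fit_sigmoid(drc, top=curve.top)
        boot = []
        for b in range(200):
            res = {
                d: rng.choice(s, size=len(s), replace=True)
                for d, s in drc.scores.items()
            }
            bdrc = DoseResponse(compound="b", measure="auto", scores=res)
            try:
                boot.append(fit_sigmoid(bdrc, top=curve.top).ec50_mM)
            except Exception:
                continue
        blo, bhi = np.percentile(boot, [2.5, 97.5])
        assert max(blo, fit.ci_ec50[0]) <= min(bhi, fit.ci_ec50[1])


class TestScaling:
    doses = [0.0, 0.3, 0.6, 1.25, 2.5, 5.0, 10.0]

    def _fit(self, bottom, top, ec50=2.5, slope=1.2):
        means = SigmoidParams(bottom, top, ec50, slope).mean_at(np.array(self.doses))
        return fit_sigmoid(drc_from_means(self.doses, means), top=top)

    def test_identical_measures_have_unit_ec50_ratio(self):
        a = self._fit(1.0, 10.0)
        cmp = scale_measures(a, self._fit(1.0, 10.0))
        assert cmp["ec50_ratio"] == pytest.approx(1.0, rel=1e-6)
        assert cmp["ec50_verdict"] == "consistent"

    def test_affine_score_transform_leaves_ec50_and_slope(self):
        # manual = 2 x auto + 5: absorbed entirely by bottom and range
        a = self._fit(1.0, 10.0)
        m = self._fit(2 * 1.0 + 5, 2 * 10.0 + 5)
        assert m.ec50_mM == pytest.approx(a.ec50_mM, rel=1e-6)
        assert m.slope == pytest.approx(a.slope, rel=1e-6)
        assert m.bottom == pytest.approx(2 * a.bottom + 5, rel=1e-6)

    def test_degenerate_range_rejected(self):
        flat = self._fit(1.0, 10.0)
        object.__setattr__(flat, "bottom", flat.top)
        with pytest.raises(ValueError, match="degenerate"):
            scale_measures(flat, flat)
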