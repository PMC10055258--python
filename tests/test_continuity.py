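"""Scott binning, density cutoffs, bootstrapped splines, transition metrics,
and the continuity decision rules."""

import numpy as np
import pytest

from damfretkit.continuity import (
    ContinuityAbstention,
    GRID_SIZE,
    SplineProfile,
    classify_continuity,
    classify_continuous_subtype,
    classify_well,
    density_filter,
    fit_spline_profile,
    majority_classification,
    scott_bins,
    transition_metrics,
)
from damfretkit.synth import PhenotypeSpec, simulate_events


class TestScottBins:
    def test_formula(self):
        rng = np.random.default_rng(0)
        v = rng.normal(0, 1, 1000)
        v = (v - v.mean()) / v.std(ddof=1)  # force sd exactly 1
        v = v / (v.max() - v.min()) * 4  # and range exactly 4
        sd = v.std(ddof=1)
        width = 3.49 * sd * 1000 ** (-1 / 3)
        expected = int(np.ceil(4 / width))
        assert len(scott_bins(v)) - 1 == expected

    def test_bin_count_scaling(self):
        rng = np.random.default_rng(1)
        v = rng.normal(size=4000)
        n1 = len(scott_bins(v[:2000])) - 1
        n2 = len(scott_bins(v)) - 1
        assert n2 / n1 == pytest.approx(2 ** (1 / 3), rel=0.2)

    def test_constant_data(self):
        with pytest.raises(ValueError):
            scott_bins(np.ones(100))


class TestDensityFilter:
    def test_rules(self):
        rng = np.random.default_rng(2)
        bins = [
            rng.normal(0, 0.01, 19),  # too few cells
            rng.normal(0, 0.5, 100) * 0.5 / 0.5,  # density 100/IQR(~0.67) < 500
            rng.normal(0, 0.01, 1000),  # eligible
            np.zeros(50),  # IQR 0 -> infinite density, eligible
        ]
        mask, reasons = density_filter(bins)
        assert list(mask) == [False, False, True, True]
        assert reasons[0] == "too_few_cells"
        assert reasons[1] == "low_density"

    def test_outlier_rule(self):
        rng = np.random.default_rng(11)
        # tight core (high density) with 30% far beyond the Tukey fences
        base = np.concatenate(
            [rng.normal(0, 0.005, 700), np.full(150, 5.0), np.full(150, -5.0)]
        )
        mask, reasons = density_filter([base])
        assert not mask[0] and reasons[0] == "outlier_heavy"


def synthetic_well(behavior="discontinuous", n=30_000, seed=0, **kw):
    ev = simulate_events(PhenotypeSpec(behavior=behavior, **kw), n, seed)
    return np.log10(ev["acceptor"].to_numpy()), (ev["fret"] / ev["acceptor"]).to_numpy()


class TestSpline:
    def test_deterministic_for_fixed_seed(self):
        lx, am = synthetic_well(n=10_000)
        a = fit_spline_profile(lx, am, n_boot=3, rng_seed=9)
        b = fit_spline_profile(lx, am, n_boot=3, rng_seed=9)
        assert np.array_equal(a.spline, b.spline)

    def test_constant_profile_stays_constant(self):
        rng = np.random.default_rng(3)
        lx = rng.uniform(1, 4, 20_000)
        am = np.full(20_000, 0.2)
        prof = fit_spline_profile(lx, am, n_boot=5)
        assert np.allclose(prof.spline, 0.2, atol=1e-9)

    def test_step_plateaus_preserved(self):
        rng = np.random.default_rng(4)
        lx = rng.uniform(1, 4, 200_000)
        am = np.where(lx > 2.5, 0.30, 0.0) + rng.normal(0, 0.005, lx.size)
        prof = fit_spline_profile(lx, am, n_boot=5)
        low = prof.spline[prof.grid < 2.0]
        high = prof.spline[prof.grid > 3.0]
        assert np.all(np.abs(low) < 0.02 * 0.30)
        assert np.all(np.abs(high - 0.30) < 0.02 * 0.30)

    def test_abstains_below_four_eligible_bins(self):
        rng = np.random.default_rng(5)
        lx = rng.uniform(1, 4, 60)  # far too sparse for the density rule
        am = rng.normal(0, 0.05, 60)
        with pytest.raises(ContinuityAbstention):
            fit_spline_profile(lx, am)


def profile_from_curve(curve, grid=None):
    grid = np.linspace(0, 4, GRID_SIZE) if grid is None else grid
    return SplineProfile(
        bin_edges=np.array([0, 4.0]),
        bin_centers=grid[:: GRID_SIZE // 8],
        median_amfret=curve[:: GRID_SIZE // 8],
        eligible=np.ones(8, bool),
        reasons=["eligible"] * 8,
        grid=grid,
        spline=curve,
        replicate_splines=curve[None, :],
    )


class TestTransitionMetrics:
    def test_logistic_inflection_found(self):
        grid = np.linspace(0, 4, GRID_SIZE)
        c0 = 2.3
        curve = 0.3 / (1 + np.exp(-6 * (grid - c0)))
        summ = transition_metrics(profile_from_curve(curve, grid))
        step = grid[1] - grid[0]
        assert abs(summ.transition_point - c0) <= step + 1e-9
        assert summ.transition_start < c0 < summ.transition_end
        assert not summ.degenerate

    def test_flat_spline_degenerate(self):
        curve = np.full(GRID_SIZE, 0.1)
        assert transition_metrics(profile_from_curve(curve)).degenerate

    def test_linear_ramp_ties_leftmost(self):
        # unit-spaced grid keeps the derivative of an exact ramp exactly tied
        grid = np.arange(GRID_SIZE, dtype=float)
        summ = transition_metrics(profile_from_curve(0.5 * grid, grid))
        assert summ.transition_point == pytest.approx(grid[0])


class TestDecisionRules:
    @pytest.mark.parametrize(
        "p, label",
        [(0.049, "discontinuous"), (0.05, "continuous"), (0.9, "continuous")],
    )
    def test_dip_cutoff(self, p, label):
        assert classify_continuity(p) == label

    @pytest.mark.parametrize(
        "mn, end, expected",
        [
            (0.01, 0.02, "low"),
            (0.2, 0.3, "high"),
            (0.01, 0.3, "low_to_high"),
        ],
    )
    def test_subtype(self, mn, end, expected):
        spline = np.linspace(mn, end, 50) if end >= mn else None
        assert classify_continuous_subtype(spline, 0.1) == expected

    def test_subtype_needs_reference(self):
        with pytest.raises(ValueError):
            classify_continuous_subtype(np.zeros(5), float("nan"))

    @pytest.mark.parametrize(
        "labels, expected",
        [
            (["discontinuous", "discontinuous", "continuous"], "discontinuous"),
            (["discontinuous", "continuous"], "unresolved"),
            (["low", "low", "low"], "low"),
        ],
    )
    def test_majority(self, labels, expected):
        assert majority_classification(labels) == expected


class TestEndToEnd:
    def test_each_behavior_classified(self):
        cases = {
            "discontinuous": "discontinuous",
            "continuous_low_to_high": "continuous",
            "one_state_low": "continuous",
            "one_state_high": "continuous",
        }
        subtype = {"one_state_low": "low", "one_state_high": "high",
                   "continuous_low_to_high": "low_to_high"}
        for behavior, expected in cases.items():
            lx, am = synthetic_well(behavior, n=60_000, seed=42)
            res = classify_well(lx, am, rng_seed=1, n_null=500)
            assert res.label == expected, behavior
            if behavior in subtype:
                assert res.subtype == subtype[behavior], behavior

    def test_bootstrap_medians_order_invariant(self):
        lx, am = synthetic_well(n=20_000, seed=8)
        prof = fit_spline_profile(lx, am, n_boot=8, rng_seed=0)
        summ1 = transition_metrics(prof)
        prof.replicate_splines = prof.replicate_splines[::-1].copy()
        summ2 = transition_metrics(prof)
        assert summ1.transition_point == summ2.transition_point
        assert summ1.transition_start == summ2.transition_start
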