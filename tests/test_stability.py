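import math

import numpy as np
import pytest

from togglekit import (
    ParameterDomainError,
    ReducedParams,
    ToggleParams,
    balanced_threshold,
    bistable_numeric,
    constraint_residual,
    find_fixed_points,
    nullclines,
    stability_diagram,
    sufficient_monostable,
    toggle_from_reduced,
)


class TestNullclines:
    def test_closed_form_without_competition(self):
        p = ToggleParams(10, 10, 0, 0)
        zs = np.linspace(0, 12, 25)
        for z, roots in zip(zs, nullclines(p, "y", zs)):
            assert len(roots) == 1
            assert roots[0] == pytest.approx(10 / (1 + z * z), rel=1e-9)

    def test_roots_are_nullcline_points(self, balanced_bistable):
        from togglekit import rhs

        zs = np.linspace(0, 8, 33)
        for z, roots in zip(zs, nullclines(balanced_bistable, "y", zs)):
            for y in roots:
                fy, _ = rhs((y, z), balanced_bistable)
                assert abs(fy) < 1e-9

    def test_fixed_points_lie_on_both_nullclines(self, balanced_bistable):
        res = find_fixed_points(balanced_bistable)
        for fp in res.fixed_points:
            y_roots = nullclines(balanced_bistable, "y", [fp.z])[0]
            z_roots = nullclines(balanced_bistable, "z", [fp.y])[0]
            assert min(abs(y_roots - fp.y)) < 1e-6
            assert min(abs(z_roots - fp.z)) < 1e-6


class TestConstraint:
    @pytest.mark.parametrize("y, z", [(1.0, 1.0), (4.0, 0.25)])
    def test_balanced_manifold_branches(self, y, z):
        # for a = 1 the manifold degenerates to y = z union y z = 1
        assert constraint_residual(y, z, 1.0) == pytest.approx(0.0, abs=1e-12)

    def test_all_fixed_points_satisfy_constraint(self):
        for p in [ToggleParams(10, 10, 1, 1), ToggleParams(25, 20, 1, 1.5),
                  ToggleParams(9.33, 10.72, 0, 0)]:
            a = p.alpha_y / p.alpha_z
            for fp in find_fixed_points(p).fixed_points:
                assert abs(constraint_residual(fp.y, fp.z, a)) < 1e-8


class TestFindFixedPoints:
    def test_sequestered_bistable_reference(self, balanced_bistable):
        res = find_fixed_points(balanced_bistable)
        assert res.label == "bistable"
        assert len(res.fixed_points) == 3
        # off-diagonal stable pair from the quadratic 2y^2 - 10y + 2 = 0
        y_hi = (5 + math.sqrt(21)) / 2
        ys = sorted(fp.y for fp in res.stable_points)
        assert ys == pytest.approx([1 / y_hi, y_hi], rel=1e-9)
        # the unstable point sits on the diagonal: root of y^3 + 3y - 10
        saddle = [fp for fp in res.fixed_points if not fp.stable][0]
        y_star = float(np.real(
            [r for r in np.roots([1, 0, 3, -10]) if abs(r.imag) < 1e-12][0]
        ))
        assert saddle.y == pytest.approx(y_star, rel=1e-9)
        assert saddle.z == pytest.approx(y_star, rel=1e-9)

    def test_strong_sequestration_is_monostable(self, balanced_monostable):
        res = find_fixed_points(balanced_monostable)
        assert res.label == "monostable"
        assert res.n_stable == 1

    def test_silent_switch_decays_to_origin(self):
        res = find_fixed_points(ToggleParams(0, 0))
        assert res.label == "monostable"
        fp = res.fixed_points[0]
        assert (fp.y, fp.z) == (0.0, 0.0) and fp.stable

    def test_residuals_below_solver_tolerance(self, unbalanced_free):
        from togglekit import rhs

        for fp in find_fixed_points(unbalanced_free).fixed_points:
            fy, fz = rhs((fp.y, fp.z), unbalanced_free)
            assert abs(fy) < 1e-9 and abs(fz) < 1e-9


class TestMonteCarloClassifier:
    def test_printed_reference_labels(self, balanced_bistable, balanced_monostable):
        assert bistable_numeric(balanced_bistable, seed=7).label == "bistable"
        assert bistable_numeric(balanced_monostable, seed=7).label == "monostable"

    def test_reproducible_given_seed(self, balanced_bistable):
        a = bistable_numeric(balanced_bistable, seed=42)
        b = bistable_numeric(balanced_bistable, seed=42)
        assert [(fp.y, fp.z) for fp in a.fixed_points] == [
            (fp.y, fp.z) for fp in b.fixed_points
        ]

    def test_agreement_with_analytic_classifier(self):
        # random realizable reduced draws; rare disagreements happen only for
        # near-degenerate systems at the mono/bistable boundary
        rng = np.random.default_rng(12345)
        n, agree = 200, 0
        for k in range(n):
            alpha0 = rng.uniform(1, 15)
            a = rng.uniform(1, 3)
            beta0 = rng.uniform(1, 16)
            b = math.exp(rng.uniform(math.log(1 / beta0), math.log(beta0)))
            p = toggle_from_reduced(ReducedParams(alpha0, a, beta0, b))
            if find_fixed_points(p).label == bistable_numeric(p, seed=1000 + k).label:
                agree += 1
        assert agree >= 0.99 * n

    def test_requires_at_least_two_trajectories(self, balanced_bistable):
        with pytest.raises(ValueError):
            bistable_numeric(balanced_bistable, n_traj=1)


class TestAnalyticConditions:
    def test_balanced_threshold_values(self):
        assert balanced_threshold(1) == 2.0
        assert balanced_threshold(4) == 4.0
        with pytest.raises(ParameterDomainError):
            balanced_threshold(0.5)

    def test_printed_parameters_straddle_threshold(self):
        # alpha0 = 10 against thresholds 4 (beta0 = 4) and 22 (beta0 = 121)
        assert find_fixed_points(ToggleParams(10, 10, 1, 1)).label == "bistable"
        assert find_fixed_points(ToggleParams(10, 10, 10, 10)).label == "monostable"

    def test_certificate_is_silent_for_bistable_reference(self):
        assert not sufficient_monostable(ReducedParams(10, 1, 4, 1))

    def test_certificate_fires_for_strongly_sequestered_switch(self):
        red = ReducedParams(10, 1, 121, 1)
        assert sufficient_monostable(red)
        assert bistable_numeric(toggle_from_reduced(red), seed=5).label == "monostable"

    def test_certificate_never_contradicts_numeric_label(self):
        rng = np.random.default_rng(777)
        for k in range(60):
            alpha0 = rng.uniform(1, 20)
            a = rng.uniform(1, 3)
            beta0 = rng.uniform(1, 30)
            b = math.exp(rng.uniform(math.log(1 / beta0), math.log(beta0)))
            red = ReducedParams(alpha0, a, beta0, b)
            if sufficient_monostable(red):
                p = toggle_from_reduced(red)
                assert bistable_numeric(p, seed=k).label == "monostable"


class TestStabilityDiagram:
    def test_balanced_slice_boundary_independent_of_b(self):
        alpha0s = np.linspace(2, 8, 7)
        labels = {}
        for b in (1.0, 2.0):
            df = stability_diagram("alpha0", "beta0", alpha0s, [4.0],
                                   {"a": 1.0, "b": b}, seed=9)
            labels[b] = list(df["label"])
        assert labels[1.0] == labels[2.0]
        # threshold at alpha0 = 2 sqrt(4) = 4
        df = stability_diagram("alpha0", "beta0", alpha0s, [4.0],
                               {"a": 1.0, "b": 1.0}, seed=9)
        for _, row in df.iterrows():
            expected = "bistable" if row["alpha0"] > 4 else "monostable"
            assert row["label"] == expected

    def test_unrealizable_cells_marked(self):
        df = stability_diagram("beta0", "b", [2.0], [8.0], {"alpha0": 10, "a": 1},
                               seed=1)
        assert list(df["label"]) == ["unrealizable"]

    def test_asymmetry_never_rescues_bistability(self):
        # increasing a at fixed (alpha0, beta0, b) must not flip mono -> bi
        df = stability_diagram("a", "alpha0", np.linspace(1, 2.5, 6),
                               np.linspace(3, 9, 4), {"beta0": 4.0, "b": 1.0},
                               seed=31, method="analytic-roots")
        for alpha0, grp in df.groupby("alpha0"):
            seq = [l == "bistable" for l in grp.sort_values("a")["label"]]
            # once bistability is lost along increasing a it never returns
            assert seq == sorted(seq, reverse=True)
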