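import json
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from togglekit import (
    BiophysicalParams,
    ParameterDomainError,
    ReducedParams,
    State,
    ToggleParams,
    UnrealizableParametersError,
    context_rescale,
    expand_parameters,
    integrate_trajectory,
    load_params,
    lump_constants,
    reduce_parameters,
    save_params,
)


class TestReduceExpand:
    def test_reduction_of_printed_unbalanced_pair(self):
        r = reduce_parameters(9.33, 10.72, 0, 0)
        assert r.swapped  # the z side is the stronger one here
        assert r.a == pytest.approx(1.15, abs=0.005)
        assert r.alpha0 == pytest.approx(10.0, abs=0.05)
        assert r.beta0 == 1.0 and r.b == 1.0

    @pytest.mark.parametrize(
        "args, expected",
        [
            ((10, 10, 0, 0), (10.0, 1.0, 1.0, 1.0)),
            ((25, 20, 1, 1.5), (math.sqrt(500), 1.25, 5.0, 0.8)),
        ],
    )
    def test_reduction_arithmetic(self, args, expected):
        r = reduce_parameters(*args)
        assert (r.alpha0, r.a, r.beta0, r.b) == pytest.approx(expected)

    def test_expansion_of_printed_pair(self):
        ay, az, by, bz = expand_parameters(ReducedParams(10, 1.15, 1, 1))
        assert ay == pytest.approx(10.72, abs=0.01)
        assert az == pytest.approx(9.33, abs=0.01)
        assert by == bz == 0.0

    def test_expansion_balanced_identity(self):
        assert expand_parameters(ReducedParams(10, 1, 1, 1)) == (10, 10, 0, 0)

    def test_unrealizable_b_rejected(self):
        with pytest.raises(UnrealizableParametersError):
            expand_parameters(ReducedParams(10, 1, 4, 8))

    def test_nonpositive_alpha_rejected(self):
        with pytest.raises(ParameterDomainError):
            reduce_parameters(0.0, 10.0)

    @given(
        ay=st.floats(0.1, 100), az=st.floats(0.1, 100),
        by=st.floats(0, 10), bz=st.floats(0, 10),
    )
    @settings(max_examples=200, deadline=None)
    def test_reduce_expand_round_trip(self, ay, az, by, bz):
        r = reduce_parameters(ay, az, by, bz)
        assert r.a >= 1.0 and r.realizable
        back = expand_parameters(r)
        assert back == pytest.approx((ay, az, by, bz), rel=1e-12, abs=1e-12)

    @given(
        alpha0=st.floats(0.5, 50), a=st.floats(1, 10),
        beta0=st.floats(1, 100), frac=st.floats(0, 1),
    )
    @settings(max_examples=200, deadline=None)
    def test_expand_reduce_round_trip(self, alpha0, a, beta0, frac):
        # b drawn inside the realizable band [1/beta0, beta0]
        b = (1 / beta0) ** (1 - frac) * beta0**frac
        red = ReducedParams(alpha0, a, beta0, b)
        back = reduce_parameters(*expand_parameters(red))
        assert (back.alpha0, back.a, back.beta0, back.b) == pytest.approx(
            (alpha0, a, beta0, b), rel=1e-9
        )


class TestContextRescale:
    def test_no_context_is_identity(self):
        p = ToggleParams(10, 8, 1, 2, beta_c=0)
        assert context_rescale(p) == p

    def test_rescaling_formula(self):
        p = ToggleParams(10, 10, 2, 0, beta_c=1)
        q = context_rescale(p)
        assert q.alpha_y == 5 and q.beta_y == 1 and q.beta_c == 0

    def test_trajectories_agree_pointwise(self):
        p = ToggleParams(10, 8, 1, 0.5, beta_c=2)
        q = context_rescale(p)
        t_eval = np.linspace(0, 30, 40)
        a = integrate_trajectory(p, 3.0, 4.0, t_max=30, t_eval=t_eval)
        b = integrate_trajectory(q, 3.0, 4.0, t_max=30, t_eval=t_eval)
        np.testing.assert_allclose(a.y, b.y, rtol=1e-6, atol=1e-8)


class TestLumpedConstants:
    def test_vanishing_transcription_leaves_promoter_sequestration(self):
        p = BiophysicalParams(lam_tx=0, lam_tl=1000, D=1000, delta=10,
                              kappa=1, k=10)
        assert lump_constants(p)["beta"] == pytest.approx(1.0)  # D/kappa in uM

    def test_typical_values_land_in_design_range(self):
        p = BiophysicalParams(lam_tx=100, lam_tl=1000, D=1000, delta=10,
                              kappa=1, k=10)
        assert 0.1 <= lump_constants(p)["beta"] <= 10

    def test_linearity_in_dna_concentration(self):
        kw = dict(lam_tx=100, lam_tl=1000, delta=10, kappa=1, k=10)
        lo = lump_constants(BiophysicalParams(D=500, **kw))
        hi = lump_constants(BiophysicalParams(D=1000, **kw))
        assert hi["alpha_dim"] == pytest.approx(2 * lo["alpha_dim"])
        assert hi["beta_dim"] == pytest.approx(2 * lo["beta_dim"])

    def test_positivity_enforced(self):
        with pytest.raises(ParameterDomainError):
            BiophysicalParams(lam_tx=100, lam_tl=1000, D=1000, delta=0,
                              kappa=1, k=10)


class TestTypesAndIO:
    def test_negative_state_rejected(self):
        with pytest.raises(ParameterDomainError):
            State(-1.0, 0.0)

    def test_nonstandard_hill_coefficient_rejected(self):
        with pytest.raises(ParameterDomainError):
            ToggleParams(10, 10, theta=3)

    @pytest.mark.parametrize("suffix", [".json", ".toml"])
    def test_config_round_trip(self, tmp_path, suffix):
        p = ToggleParams(10.5, 8.25, 1.5, 0.25, beta_c=0.5)
        path = tmp_path / f"params{suffix}"
        save_params(p, path)
        assert load_params(path) == p

    def test_reduced_config_is_expanded(self, tmp_path):
        path = tmp_path / "reduced.json"
        path.write_text(json.dumps({"alpha0": 10, "a": 1, "beta0": 4, "b": 1}))
        p = load_params(path)
        assert p.alpha_y == pytest.approx(10) and p.beta_y == pytest.approx(1)
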