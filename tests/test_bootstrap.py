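"""Bootstrap CIs, circular phase handling, condition comparison, classification."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import two_condition_config
from oracles import percentile_ci_oracle
from rhythmkit import (
    bootstrap_params,
    circular_mean,
    classify_change,
    compare_conditions,
    generate_dataset,
    param_ci,
    wrap_phase_difference,
)

ZT = np.array([3.0, 9.0, 15.0, 21.0])


def series(noise=1.0, m=5.0, a=2.0, phi=8.0, reps=5, seed=0):
    r = np.random.default_rng(seed)
    t = np.repeat(ZT, reps)
    y = m + a * np.cos(2 * np.pi * (t - phi) / 24.0) + r.normal(0, noise, t.size)
    return t, y


class TestBootstrapParams:
    @pytest.mark.parametrize("scheme", ["stratified", "residual"])
    def test_noise_free_draws_collapse_to_point(self, scheme):
        t, y = series(noise=0.0)
        dist = bootstrap_params(t, y, B=300, scheme=scheme, seed=1)
        ci = param_ci(dist, "amplitude")
        assert ci.upper - ci.lower == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(dist.draws[:, 0], dist.point.mesor, atol=1e-9)

    def test_deterministic_under_fixed_seed(self):
        t, y = series(seed=3)
        a = bootstrap_params(t, y, B=250, seed=42)
        b = bootstrap_params(t, y, B=250, seed=42)
        np.testing.assert_array_equal(a.draws, b.draws)

    def test_minimum_draws_enforced(self):
        t, y = series()
        with pytest.raises(ValueError, match="200"):
            bootstrap_params(t, y, B=100)

    def test_amplitude_ci_contains_point_estimate(self):
        t, y = series(seed=7)
        dist = bootstrap_params(t, y, B=500, seed=7)
        ci = param_ci(dist, "amplitude")
        assert ci.lower <= ci.point <= ci.upper

    def test_linear_ci_matches_percentile_oracle(self):
        t, y = series(seed=5)
        dist = bootstrap_params(t, y, B=400, seed=11)
        for which, col in (("mesor", 0), ("amplitude", 1)):
            ci = param_ci(dist, which)
            lo, hi = percentile_ci_oracle(dist.draws[:, col], 0.95)
            assert ci.lower == pytest.approx(lo, abs=1e-12)
            assert ci.upper == pytest.approx(hi, abs=1e-12)

    def test_draws_are_canonical(self):
        t, y = series(noise=2.0, a=0.5, seed=9)
        dist = bootstrap_params(t, y, B=400, seed=2)
        assert (dist.draws[:, 1] >= 0).all()
        assert ((dist.draws[:, 2] >= 0) & (dist.draws[:, 2] < 24)).all()


class TestCircularPhase:
    def test_circular_mean_wraps_midnight(self):
        # draws straddling midnight average to ~ZT0 on the circle, not ZT12
        phis = np.array([23.5, 0.5] * 150)
        cm = circular_mean(phis)
        assert abs(wrap_phase_difference(cm - 0.0)) == pytest.approx(0.0, abs=1e-9)

    def test_acrophase_ci_covers_wrap(self):
        t, y = series(phi=0.2, noise=1.0, seed=13)
        dist = bootstrap_params(t, y, B=500, seed=13)
        ci = param_ci(dist, "acrophase")
        assert ci.circular
        assert ci.upper - ci.lower < 24.0
        assert ci.contains(dist.point.acrophase)

    def test_undefined_phase_ci_is_error(self):
        t, y = series(noise=0.0, a=0.0)
        dist = bootstrap_params(t, y, B=300, seed=1)
        with pytest.raises(ValueError, match="arrhythmic"):
            param_ci(dist, "acrophase")

    @given(delta=st.floats(-40, 40))
    def test_wrap_phase_difference_range(self, delta):
        w = wrap_phase_difference(delta)
        assert -12.0 < w <= 12.0
        assert (w - delta) % 24.0 == pytest.approx(0.0, abs=1e-9) or (
            (delta - w) % 24.0 == pytest.approx(0.0, abs=1e-9)
        )


class TestCompareConditions:
    def test_self_comparison_finds_nothing(self):
        t, y = series(seed=21)
        dist = bootstrap_params(t, y, B=300, seed=21)
        cmp = compare_conditions(dist, dist)
        assert cmp.delta_mesor.point == 0.0
        assert cmp.amplitude_ratio.point == 1.0
        assert cmp.delta_phi.point == 0.0
        assert not any(cmp.significant.values())
        assert cmp.change_class == "unchanged"

    def test_time_shift_of_both_conditions_preserves_delta_phi(self):
        ta, ya = series(phi=20.0, seed=31)
        tb, yb = series(phi=17.0, seed=32)
        base = compare_conditions(
            bootstrap_params(ta, ya, B=400, seed=1),
            bootstrap_params(tb, yb, B=400, seed=2),
        )
        shifted = compare_conditions(
            bootstrap_params(ta + 5.0, ya, B=400, seed=1),
            bootstrap_params(tb + 5.0, yb, B=400, seed=2),
        )
        assert shifted.delta_phi.point == pytest.approx(base.delta_phi.point, abs=1e-9)

    def test_arrhythmic_side_suppresses_phase_and_amplitude(self):
        t, y = series(seed=41)
        ta, ya = series(a=0.0, noise=1.0, seed=42)
        cmp = compare_conditions(
            bootstrap_params(t, y, B=300, seed=1),
            bootstrap_params(ta, ya, B=300, seed=2),
            call_a="rhythmic",
            call_b="nsr",
        )
        assert cmp.amplitude_ratio is None
        assert cmp.delta_phi is None
        assert cmp.significant["amplitude"] is None
        assert cmp.change_class == "lost"

    def test_overlap_mode_is_more_conservative(self):
        # a modest mesor shift: difference-CI flags it more readily than
        # demanding the two marginal CIs be disjoint
        ta, ya = series(m=5.0, seed=51)
        tb, yb = series(m=6.0, seed=52)
        da = bootstrap_params(ta, ya, B=400, seed=3)
        db = bootstrap_params(tb, yb, B=400, seed=4)
        diff = compare_conditions(da, db, mode="difference")
        over = compare_conditions(da, db, mode="overlap")
        if over.significant["mesor"]:
            assert diff.significant["mesor"]


class TestClassifyChange:
    @pytest.mark.parametrize(
        "call_a,call_b,sig,expected",
        [
            ("nsr", "rhythmic", {}, "gained"),
            ("rhythmic", "nsr", {}, "lost"),
            ("nsr", "nsr", {}, "both_arrhythmic"),
            ("nd", "rhythmic", {}, "indeterminate"),
            ("rhythmic", "nd", {}, "indeterminate"),
            ("rhythmic", "rhythmic", {"phase": True}, "phase_shifted"),
            ("rhythmic", "rhythmic", {"amplitude": True}, "amplitude_modulated"),
            ("rhythmic", "rhythmic", {"mesor": True}, "mesor_shifted"),
            ("rhythmic", "rhythmic", {"mesor": True, "phase": True}, "compound"),
            ("rhythmic", "rhythmic", {}, "unchanged"),
        ],
    )
    def test_change_taxonomy(self, call_a, call_b, sig, expected):
        significant = {"mesor": False, "amplitude": False, "phase": False, **sig}
        assert classify_change(call_a, call_b, significant) == expected


class TestCalibration:
    def test_phase_shift_power_is_monotone(self):
        """Detection rate of a phase shift grows with the shift size.

        100 simulated two-condition studies per shift level at the sparse
        design; one inversion within Monte-Carlo error (5 points) allowed.
        """
        rates = []
        for shift in (0.0, 1.5, 3.0, 6.0):
            hits = 0
            for i in range(100):
                cfg = two_condition_config(phi_b=20.0 - shift, noise=1.0, seed=10_000 + i)
                ds = generate_dataset(cfg)
                dists = {}
                for j, cond in enumerate(("CD", "MCDD")):
                    g = ds[ds["condition"] == cond]
                    dists[cond] = bootstrap_params(
                        g["zt"].to_numpy(), g["value"].to_numpy(), B=200,
                        seed=2 * i + j,
                    )
                cmp = compare_conditions(dists["CD"], dists["MCDD"])
                hits += bool(cmp.significant["phase"])
            rates.append(hits / 100.0)
        inversions = sum(
            1 for lo, hi in zip(rates, rates[1:]) if hi < lo - 0.05
        )
        assert inversions == 0, rates
        assert rates[-1] > rates[0]

    def test_null_comparison_flag_rate_bounded(self):
        """Same rhythmic model in both conditions: each contrast's flag
        fires in at most 10% of 200 studies at the 95% CI level, with the
        default number of bootstrap draws."""
        counts = {"mesor": 0, "amplitude": 0, "phase": 0}
        for i in range(200):
            cfg = two_condition_config(phi_b=20.0, noise=1.0, seed=20_000 + i)
            ds = generate_dataset(cfg)
            dists = []
            for j, cond in enumerate(("CD", "MCDD")):
                g = ds[ds["condition"] == cond]
                dists.append(
                    bootstrap_params(
                        g["zt"].to_numpy(), g["value"].to_numpy(), B=1000,
                        seed=2 * i + j,
                    )
                )
            cmp = compare_conditions(*dists)
            for k in counts:
                counts[k] += bool(cmp.significant[k])
        for k, c in counts.items():
            assert c / 200.0 <= 0.10, (k, counts)
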