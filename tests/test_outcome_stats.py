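"""Outcome-statistics tests: the printed 2x2 worked examples, rank tests,
Cox screening/ENTER modelling and variance inflation factors."""

import numpy as np
import pandas as pd
import pytest

import fqrs
from fqrs.errors import (
    DegenerateTableError,
    EmptyModelError,
    InestimableError,
    InvalidParameterError,
)
from fqrs.outcome_stats import cox_univariable


def simulate_ph(n, log_hr, rng, p_exposed=0.5, censor_scale=3.0):
    """Minimal exponential proportional-hazards data with one binary
    covariate -- the independent oracle generator for Cox recovery."""
    x = (rng.uniform(size=n) < p_exposed).astype(float)
    t_event = rng.exponential(1.0 / np.exp(log_hr * x))
    t_cens = rng.exponential(censor_scale, size=n)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    return pd.DataFrame({"time": time, "event": event, "x": x})


class TestChiSquare2x2:
    def test_identical_proportions(self):
        chi2, p = fqrs.chi_square_2x2(50, 100, 50, 100)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_crtd_worked_example(self):
        """Device-type contrast: 182/538 vs 185/704 rounds to p = 0.004."""
        _, p = fqrs.chi_square_2x2(182, 538, 185, 704)
        assert round(p, 3) == 0.004

    def test_ihd_worked_example(self):
        """Etiology contrast: 326/538 vs 472/704 rounds to p = 0.019."""
        _, p = fqrs.chi_square_2x2(326, 538, 472, 704)
        assert round(p, 3) == 0.019

    def test_zero_margin_rejected(self):
        with pytest.raises(DegenerateTableError):
            fqrs.chi_square_2x2(0, 100, 0, 100)

    def test_invalid_counts_rejected(self):
        with pytest.raises(InvalidParameterError):
            fqrs.chi_square_2x2(120, 100, 10, 100)


class TestMannWhitney:
    def test_identical_groups(self):
        a = np.arange(30.0)
        u, p = fqrs.mann_whitney(a, a[::-1])
        assert u == pytest.approx(30 * 30 / 2)
        assert p > 0.95

    def test_complete_separation(self):
        u, p = fqrs.mann_whitney(np.arange(1, 21), np.arange(101, 121))
        assert u in (0.0, 400.0)
        assert p < 1e-6

    def test_type_one_error_rate(self):
        rng = np.random.default_rng(8)
        rejections = 0
        reps = 1000
        for _ in range(reps):
            a = rng.standard_normal(50)
            b = rng.standard_normal(50)
            _, p = fqrs.mann_whitney(a, b)
            rejections += p < 0.05
        assert 0.035 <= rejections / reps <= 0.065

    def test_empty_group_rejected(self):
        with pytest.raises(InvalidParameterError):
            fqrs.mann_whitney([], [1.0, 2.0])


class TestCoxUnivariable:
    def test_binary_hr_recovery(self):
        rng = np.random.default_rng(21)
        df = simulate_ph(3000, np.log(2.0), rng)
        res = cox_univariable(df, "x", "time", "event")[0]
        assert 1.8 <= res.hazard_ratio <= 2.2
        assert res.ci_lower <= 2.0 <= res.ci_upper

    def test_rescaled_covariate_identity(self):
        """Doubling a covariate halves the log-hazard per unit but leaves
        the p-value unchanged (log-linearity)."""
        rng = np.random.default_rng(22)
        df = simulate_ph(800, np.log(1.8), rng)
        df["x2"] = 2.0 * df["x"]
        r1 = cox_univariable(df, "x", "time", "event")[0]
        r2 = cox_univariable(df, "x2", "time", "event")[0]
        assert r2.p_value == pytest.approx(r1.p_value, abs=1e-8)
        assert r2.hazard_ratio**2 == pytest.approx(r1.hazard_ratio, rel=1e-6)

    def test_constant_covariate_rejected(self):
        rng = np.random.default_rng(23)
        df = simulate_ph(200, 0.0, rng)
        df["c"] = 1.0
        with pytest.raises(InestimableError):
            cox_univariable(df, "c", "time", "event")

    def test_requires_ten_events(self):
        df = pd.DataFrame({
            "time": np.arange(1.0, 21.0),
            "event": [1] * 5 + [0] * 15,
            "x": np.r_[np.zeros(10), np.ones(10)],
        })
        with pytest.raises(InestimableError):
            cox_univariable(df, "x", "time", "event")


@pytest.fixture(scope="module")
def screening_frame():
    rng = np.random.default_rng(31)
    n = 1500
    x = (rng.uniform(size=n) < 0.5).astype(float)
    noise1 = rng.standard_normal(n)
    noise2 = (rng.uniform(size=n) < 0.3).astype(float)
    t_event = rng.exponential(1.0 / np.exp(np.log(2.0) * x))
    t_cens = rng.exponential(3.0, size=n)
    return pd.DataFrame({
        "time": np.minimum(t_event, t_cens),
        "event": (t_event <= t_cens).astype(int),
        "x": x, "noise1": noise1, "noise2": noise2,
    })


class TestCoxMultivariableEnter:
    def test_only_signal_retained(self, screening_frame):
        res = fqrs.cox_multivariable_enter(
            screening_frame, "time", "event", ["x", "noise1", "noise2"],
        )
        assert [r.covariate for r in res] == ["x"]
        uni = cox_univariable(screening_frame, "x", "time", "event")[0]
        assert res[0].hazard_ratio == pytest.approx(uni.hazard_ratio, rel=0.05)

    def test_screening_disabled_retains_all(self, screening_frame):
        res = fqrs.cox_multivariable_enter(
            screening_frame, "time", "event", ["x", "noise1", "noise2"],
            screen_alpha=1.01,
        )
        assert {r.covariate for r in res} == {"x", "noise1", "noise2"}
        assert all(r.model == "multivariable" for r in res)

    def test_enter_is_one_joint_fit(self, screening_frame):
        """Retained coefficients come from a single simultaneous fit:
        dropping a retained covariate changes the others' estimates."""
        full = fqrs.cox_multivariable_enter(
            screening_frame, "time", "event", ["x", "noise1", "noise2"],
            screen_alpha=1.01,
        )
        reduced = fqrs.cox_multivariable_enter(
            screening_frame, "time", "event", ["x", "noise1"],
            screen_alpha=1.01,
        )
        hr_full = {r.covariate: r.hazard_ratio for r in full}
        hr_red = {r.covariate: r.hazard_ratio for r in reduced}
        assert hr_full["x"] != hr_red["x"]

    def test_force_include_reports_exposure(self, screening_frame):
        df = screening_frame.assign(exposure=0.0)
        df.loc[df.index[:700], "exposure"] = 1.0
        res = fqrs.cox_multivariable_enter(
            df, "time", "event", ["x", "exposure"],
            force_include=("exposure",),
        )
        assert "exposure" in {r.covariate for r in res}

    def test_no_survivor_of_screening(self, screening_frame):
        with pytest.raises(EmptyModelError):
            fqrs.cox_multivariable_enter(
                screening_frame, "time", "event", ["noise1", "noise2"],
                screen_alpha=1e-12,
            )

    def test_categorical_expanded_against_reference(self):
        rng = np.random.default_rng(33)
        n = 1200
        nyha = rng.choice([1.0, 2.0, 3.0], size=n, p=[0.4, 0.4, 0.2])
        t_event = rng.exponential(1.0 / np.exp(0.5 * (nyha - 1)))
        df = pd.DataFrame({
            "time": np.minimum(t_event, 3.0),
            "event": (t_event <= 3.0).astype(int),
            "nyha": nyha,
        })
        res = fqrs.cox_multivariable_enter(
            df, "time", "event", ["nyha"], categorical=("nyha",),
        )
        names = [r.covariate for r in res]
        assert names == ["nyha_2", "nyha_3"]
        assert res[1].hazard_ratio > res[0].hazard_ratio > 1.0


class TestVif:
    def test_independent_covariates(self):
        rng = np.random.default_rng(41)
        X = pd.DataFrame(rng.standard_normal((5000, 4)),
                         columns=list("abcd"))
        vif = fqrs.compute_vif(X)
        assert ((vif >= 1.0) & (vif <= 1.1)).all()

    def test_duplicate_column_flags_infinity(self):
        rng = np.random.default_rng(42)
        x = rng.standard_normal(200)
        X = pd.DataFrame({"x1": x, "x2": x, "y": rng.standard_normal(200)})
        vif = fqrs.compute_vif(X)
        assert np.isinf(vif["x1"]) and np.isinf(vif["x2"])
        assert np.isfinite(vif["y"])

    def test_vif_decays_with_noise(self):
        rng = np.random.default_rng(43)
        x1 = rng.standard_normal(2000)
        x2 = rng.standard_normal(2000)
        vifs = []
        for sigma in (0.5, 2.0, 20.0):
            x3 = x1 + x2 + sigma * rng.standard_normal(2000)
            vifs.append(
                fqrs.compute_vif(pd.DataFrame({"a": x1, "b": x2, "c": x3}))["c"]
            )
        assert vifs[0] > vifs[1] > vifs[2]
        assert vifs[2] == pytest.approx(1.0, abs=0.05)


class TestBaselineTable:
    def test_group_denominators_echoed(self):
        rng = np.random.default_rng(51)
        n0, n1 = 704, 538
        df = pd.DataFrame({
            "group": np.r_[np.zeros(n0), np.ones(n1)],
            "age": rng.normal(62, 11, n0 + n1),
            "ihd": (rng.uniform(size=n0 + n1) < 0.64).astype(float),
        })
        rows = fqrs.baseline_table(df, "group", ["age"], ["ihd"])
        for row in rows:
            assert (row.n_a, row.n_b) == (n0, n1)

    def test_identical_groups_yield_null_pvalues(self):
        rng = np.random.default_rng(52)
        half = pd.DataFrame({
            "age": rng.normal(60, 10, 400),
            "dm": (rng.uniform(size=400) < 0.2).astype(float),
        })
        df = pd.concat(
            [half.assign(group=0.0), half.assign(group=1.0)],
            ignore_index=True,
        )
        rows = fqrs.baseline_table(df, "group", ["age"], ["dm"])
        for row in rows:
            assert row.p_value > 0.95

    def test_injected_difference_detected_only_where_present(self):
        rng = np.random.default_rng(53)
        n = 1000
        df = pd.DataFrame({
            "group": np.r_[np.zeros(n), np.ones(n)],
            "same": rng.standard_normal(2 * n),
            "shifted": np.r_[rng.standard_normal(n),
                             rng.standard_normal(n) + 0.5],
        })
        rows = {r.variable: r for r in
                fqrs.baseline_table(df, "group", ["same", "shifted"], [])}
        assert rows["shifted"].p_value < 0.001
        assert rows["same"].p_value > 0.05
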