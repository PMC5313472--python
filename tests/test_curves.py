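import numpy as np
import pandas as pd
import pytest

from herdfap.curves import (
    MilkCurveParams,
    SccCurveParams,
    eval_milk_curve,
    eval_scc_curve,
    fit_cow_level,
    fit_herd_curve,
    invert_milk_level,
    invert_scc_level,
)
from herdfap.errors import DomainError, InsufficientDataError

MILK = MilkCurveParams(a=16.0, b=0.17, c=0.002, d=3e-6, parity_group="1")
SCC = SccCurveParams(a=2.3, b=0.0005, c=-2.8, d=1.5, parity_group="1")


def _frame(dim, ecm=None, tscc=None, pregnant=False, dim_p=np.nan):
    n = len(dim)
    return pd.DataFrame({
        "dim": dim,
        "ecm_kg": ecm if ecm is not None else np.zeros(n),
        "tscc": tscc if tscc is not None else np.ones(n),
        "pregnant": np.full(n, pregnant),
        "dim_p": np.full(n, dim_p, dtype=float),
        "cow_id": ["C1"] * n,
        "parity": [1] * n,
    })


class TestMilkCurve:
    def test_open_cow_reduces_to_wood_form(self):
        t = np.array([10.0, 100.0, 300.0])
        expected = MILK.a * t**MILK.b * np.exp(-MILK.c * t)
        np.testing.assert_allclose(eval_milk_curve(MILK, 1.0, t), expected)

    def test_strictly_proportional_to_level(self):
        t = np.arange(1, 400, 7, dtype=float)
        np.testing.assert_allclose(
            eval_milk_curve(MILK, 2.0, t, True, 80.0),
            2.0 * eval_milk_curve(MILK, 1.0, t, True, 80.0),
        )

    def test_pregnancy_never_raises_yield(self):
        t = np.arange(1, 500, dtype=float)
        preg = eval_milk_curve(MILK, 1.0, t, True, 100.0)
        open_ = eval_milk_curve(MILK, 1.0, t)
        assert (preg <= open_ + 1e-12).all()
        assert (preg[t > 101] < open_[t > 101]).all()

    def test_zero_dim_with_negative_b_is_domain_error(self):
        bad = MilkCurveParams(a=16.0, b=-0.1, c=0.002, d=0.0)
        with pytest.raises(DomainError):
            eval_milk_curve(bad, 1.0, 0)

    def test_additive_parse_differs_only_when_pregnant(self):
        lit = MilkCurveParams(a=16.0, b=0.17, c=0.002, d=1e-3, parse="literal")
        add = MilkCurveParams(a=16.0, b=0.17, c=0.002, d=1e-3, parse="additive")
        t = np.array([50.0, 200.0])
        np.testing.assert_allclose(eval_milk_curve(lit, 1, t), eval_milk_curve(add, 1, t))
        assert not np.allclose(
            eval_milk_curve(lit, 1, t, True, 40.0), eval_milk_curve(add, 1, t, True, 40.0)
        )


class TestSccCurve:
    def test_positive_for_finite_params(self):
        t = np.arange(0, 600, 13, dtype=float)
        assert (eval_scc_curve(SCC, 1.0, t) > 0).all()

    def test_monotone_in_level(self):
        t = np.array([5.0, 50.0, 250.0])
        lo = eval_scc_curve(SCC, 0.9, t)
        mid = eval_scc_curve(SCC, 1.0, t)
        hi = eval_scc_curve(SCC, 1.1, t)
        assert (lo < mid).all() and (mid < hi).all()

    def test_inversion_recovers_level(self):
        t = np.array([20.0, 100.0, 280.0])
        for alpha in (0.93, 1.0, 1.05):
            vals = eval_scc_curve(SCC, alpha, t)
            np.testing.assert_allclose(invert_scc_level(SCC, vals, t), alpha, rtol=1e-9)

    def test_extreme_exponent_is_clamped_finite(self):
        assert np.isfinite(eval_scc_curve(SCC, 3.0, 600.0))


class TestHerdCurveFit:
    def test_noise_free_recovery_milk(self):
        rng = np.random.default_rng(5)
        dim = rng.integers(5, 300, 300).astype(float)
        df = _frame(dim, ecm=eval_milk_curve(MILK, 1.0, dim))
        df["cow_id"] = [f"C{i % 25}" for i in range(len(df))]
        params, diag = fit_herd_curve(df, "milk", min_lactations=20, seed=0)
        t = np.array([10.0, 100.0, 300.0])
        np.testing.assert_allclose(
            eval_milk_curve(params, 1.0, t), eval_milk_curve(MILK, 1.0, t), rtol=1e-4
        )
        assert diag.residual_sd < 1e-3

    def test_noise_free_recovery_scc(self):
        rng = np.random.default_rng(6)
        dim = rng.integers(5, 300, 300).astype(float)
        df = _frame(dim, tscc=eval_scc_curve(SCC, 1.0, dim))
        df["cow_id"] = [f"C{i % 25}" for i in range(len(df))]
        params, _ = fit_herd_curve(df, "scc", min_lactations=20, seed=0)
        t = np.array([10.0, 100.0, 300.0])
        np.testing.assert_allclose(
            eval_scc_curve(params, 1.0, t), eval_scc_curve(SCC, 1.0, t), rtol=1e-3
        )

    def test_too_few_lactations_raises(self):
        dim = np.arange(5.0, 100.0, 5.0)
        df = _frame(dim, ecm=eval_milk_curve(MILK, 1.0, dim))
        df["cow_id"] = [f"C{i % 5}" for i in range(len(df))]
        with pytest.raises(InsufficientDataError):
            fit_herd_curve(df, "milk", min_lactations=20)

    def test_fixed_pregnancy_rate_is_respected(self):
        rng = np.random.default_rng(7)
        dim = rng.integers(5, 300, 240).astype(float)
        df = _frame(dim, ecm=eval_milk_curve(MILK, 1.0, dim))
        df["cow_id"] = [f"C{i % 25}" for i in range(len(df))]
        params, _ = fit_herd_curve(df, "milk", min_lactations=20, fixed_d=5e-6)
        assert params.d == 5e-6


class TestCowLevel:
    def test_exact_herd_average_cow_has_level_one(self):
        dim = np.arange(10.0, 220.0, 30.0)
        df = _frame(dim, ecm=eval_milk_curve(MILK, 1.0, dim))
        lvl = fit_cow_level(df, MILK, "milk")
        assert lvl.fittable and lvl.alpha == pytest.approx(1.0, abs=1e-12)

    def test_proportional_cow_recovers_exact_ratio(self):
        dim = np.arange(10.0, 220.0, 30.0)
        df = _frame(dim, ecm=1.10 * eval_milk_curve(MILK, 1.0, dim))
        assert fit_cow_level(df, MILK, "milk").alpha == pytest.approx(1.10, abs=1e-12)

    def test_five_point_lactation_defaults_to_one(self):
        dim = np.arange(10.0, 160.0, 30.0)
        assert len(dim) == 5
        df = _frame(dim, ecm=1.3 * eval_milk_curve(MILK, 1.0, dim))
        lvl = fit_cow_level(df, MILK, "milk")
        assert not lvl.fittable and lvl.alpha == 1.0

    def test_scc_level_recovered_from_exact_curve(self):
        dim = np.arange(10.0, 300.0, 30.0)
        df = _frame(dim, tscc=eval_scc_curve(SCC, 1.07, dim))
        lvl = fit_cow_level(df, SCC, "scc")
        assert lvl.alpha == pytest.approx(1.07, abs=1e-4)

    def test_all_zero_milk_raises(self):
        dim = np.arange(10.0, 220.0, 30.0)
        df = _frame(dim, ecm=np.zeros(len(dim)))
        with pytest.raises(DomainError):
            fit_cow_level(df, MILK, "milk")


def test_level_recovery_from_noisy_herd(sim):
    """Full two-stage fit: herd curves then per-cow levels correlate > 0.9
    with the generator's true milk levels at the stated noise scales."""
    from herdfap.io import derive_records, filter_fittable
    from herdfap.model import FitConfig, _fit_cow_levels

    records, truth = sim
    df = filter_fittable(derive_records(records))
    milk, scc = {}, {}
    for pg in ("1", "2", "3+"):
        sub = df[df["parity_group"] == pg]
        milk[pg], _ = fit_herd_curve(sub, "milk", seed=1, parity_group=pg)
        scc[pg], _ = fit_herd_curve(sub, "scc", seed=1, parity_group=pg)
    levels = _fit_cow_levels(df, milk, scc, FitConfig())
    key = truth.lactations.set_index(["cow_id", "parity"])
    fit = levels[levels["fittable"]]
    true_am = [key.loc[(r.cow_id, r.parity), "alpha_m"] for r in fit.itertuples()]
    true_lc = [key.loc[(r.cow_id, r.parity), "log_level_c"] for r in fit.itertuples()]
    assert np.corrcoef(fit["alpha_m"], true_am)[0, 1] > 0.9
    assert np.corrcoef(fit["alpha_c"], true_lc)[0, 1] > 0.9
    # the "relative to the average cow" normalization: mean fitted level ~ 1
    assert fit["alpha_m"].mean() == pytest.approx(1.0, abs=0.05)
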