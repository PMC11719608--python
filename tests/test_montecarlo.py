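"""Distribution sampling, the Monte Carlo engine and percentile reporting."""

import math

import numpy as np
import pytest

from chocrisk.deterministic import cr, hq
from chocrisk.distributions import DistributionSpec, sample
from chocrisk.domain import PopulationGroup, ToxicologyConstants
from chocrisk.errors import DomainError, SpecError
from chocrisk.montecarlo import (
    ModelSpec,
    SpreadConfig,
    build_group_model,
    percentile,
    run_mcs,
)

CONSTS = ToxicologyConstants()
ADULTS = PopulationGroup("adults", 0.00259, 0.00154, 30.0, 70.0)


def _point_model(endpoint="HQ", c_milk=0.028, c_dark=0.057, mode="per_bw",
                 iterations=100, seed=0, **overrides):
    dists = {
        "C_milk": DistributionSpec.point(c_milk),
        "C_dark": DistributionSpec.point(c_dark),
        "IngR_milk": DistributionSpec.point(0.37),
        "IngR_dark": DistributionSpec.point(0.22),
        "EF": DistributionSpec.point(350.0),
        "ED": DistributionSpec.point(30.0),
        "CF": DistributionSpec.point(1e-3),
    }
    if endpoint == "HQ":
        dists["RfD"] = DistributionSpec.point(1e-3)
    else:
        dists["CSF"] = DistributionSpec.point(6.1)
        dists["AT"] = DistributionSpec.point(25550.0)
    if mode == "absolute":
        dists["BW"] = DistributionSpec.point(70.0)
    dists.update(overrides)
    return ModelSpec(endpoint=endpoint, group="adults", dists=dists,
                     mode=mode, iterations=iterations, seed=seed)


class TestDistributionSpec:
    def test_point_degenerate(self):
        rng = np.random.default_rng(0)
        draws = sample(DistributionSpec.point(6.1), 5, rng)
        assert np.array_equal(draws, np.full(5, 6.1))

    def test_triangular_mean_matches_closed_form(self):
        rng = np.random.default_rng(1)
        draws = sample(DistributionSpec.triangular(1, 2, 3), 100_000, rng)
        analytic_mean = (1 + 2 + 3) / 3.0
        analytic_sd = math.sqrt((1 + 4 + 9 - 2 - 3 - 6) / 18.0)
        se = analytic_sd / math.sqrt(draws.size)
        assert abs(draws.mean() - analytic_mean) < 3 * se
        assert draws.min() >= 1.0 and draws.max() <= 3.0

    def test_lognormal_from_mean_median_closed_form(self):
        spec = DistributionSpec.lognormal_from_mean_median(0.057, 0.042)
        assert spec.params["log_mean"] == pytest.approx(math.log(0.042))
        assert spec.params["log_sd"] == pytest.approx(
            math.sqrt(2 * math.log(0.057 / 0.042)), rel=1e-12
        )

    def test_lognormal_from_mean_cv_recovers_mean(self):
        spec = DistributionSpec.lognormal_from_mean_cv(70.0, 0.2)
        assert spec.mean() == pytest.approx(70.0, rel=1e-12)

    @pytest.mark.parametrize(
        "kind,params",
        [
            ("triangular", {"min": 3.0, "mode": 2.0, "max": 1.0}),
            ("lognormal", {"log_mean": 0.0, "log_sd": -1.0}),
            ("point", {"value": float("inf")}),
            ("weird", {"value": 1.0}),
        ],
    )
    def test_invalid_specs_rejected(self, kind, params):
        with pytest.raises(SpecError):
            DistributionSpec(kind, params)


class TestPercentile:
    def test_odd_length_median(self):
        assert percentile([1, 2, 3, 4, 5], 50) == 3.0

    def test_linear_interpolation_oracle(self):
        assert percentile([0.0, 10.0], 90) == pytest.approx(9.0)

    def test_extremes(self):
        vals = [3.0, 1.0, 2.0]
        assert percentile(vals, 0) == 1.0
        assert percentile(vals, 100) == 3.0

    def test_monotone_in_p(self):
        rng = np.random.default_rng(3)
        vals = rng.lognormal(0, 1, 500)
        ps = np.linspace(0, 100, 41)
        qs = [percentile(vals, p) for p in ps]
        assert all(a <= b for a, b in zip(qs, qs[1:]))

    def test_errors(self):
        with pytest.raises(DomainError):
            percentile([], 50)
        with pytest.raises(DomainError):
            percentile([1.0], 101)


class TestRunMcs:
    def test_collapse_to_deterministic_value(self):
        """All-point specs reproduce the deterministic HQ/CR exactly."""
        res = run_mcs(_point_model("HQ"))
        expected = hq(0.028, 0.37, CONSTS, 30.0) + hq(0.057, 0.22, CONSTS, 30.0)
        assert np.all(res.output == res.output[0])
        assert res.output[0] == pytest.approx(expected, rel=1e-12)

        res = run_mcs(_point_model("CR"))
        expected = cr(0.028, 0.37, CONSTS, 30.0) + cr(0.057, 0.22, CONSTS, 30.0)
        assert res.output[0] == pytest.approx(expected, rel=1e-12)

    def test_linear_in_concentration(self):
        base = run_mcs(_point_model("HQ"))
        doubled = run_mcs(_point_model("HQ", c_milk=0.056, c_dark=0.114))
        np.testing.assert_allclose(doubled.output, 2 * base.output, rtol=1e-12)

    def test_seed_contract_bit_identical(self):
        spec = _point_model(
            "CR", iterations=10_000, seed=42,
            C_dark=DistributionSpec.lognormal_from_mean_median(0.057, 0.042),
            EF=DistributionSpec.triangular(300, 350, 365),
        )
        a, b = run_mcs(spec), run_mcs(spec)
        assert np.array_equal(a.output, b.output)
        assert a.draws.equals(b.draws)

    def test_missing_symbol_is_spec_error(self):
        dists = dict(_point_model("HQ").dists)
        del dists["RfD"]
        with pytest.raises(SpecError, match="RfD"):
            ModelSpec("HQ", "adults", dists, iterations=10)

    def test_at_not_accepted_for_hq(self):
        dists = dict(_point_model("HQ").dists)
        dists["AT"] = DistributionSpec.point(25550.0)
        with pytest.raises(SpecError):
            ModelSpec("HQ", "adults", dists, iterations=10)

    def test_lognormal_concentration_propagates_log_sd(self):
        """With only C_dark lognormal the output is lognormal with the same log-sd."""
        sigma = math.sqrt(2 * math.log(0.057 / 0.042))
        spec = _point_model(
            "HQ", iterations=10_000, seed=7,
            C_milk=DistributionSpec.point(0.0),
            IngR_milk=DistributionSpec.point(0.0),
            C_dark=DistributionSpec.lognormal(math.log(0.042), sigma),
        )
        res = run_mcs(spec)
        log_sd = np.log(res.output).std(ddof=1)
        se = sigma / math.sqrt(2 * (res.output.size - 1))
        assert abs(log_sd - sigma) < 3 * se

    def test_draw_matrix_shape_and_percentiles(self):
        res = run_mcs(_point_model("HQ", iterations=250), (5, 50, 95))
        assert res.draws.shape == (250, 8)
        assert list(res.percentiles) == [5.0, 50.0, 95.0]
        values = list(res.percentiles.values())
        assert values == sorted(values)


class TestBuildGroupModel:
    def test_absolute_mode_includes_bw(self):
        conc = {"milk": DistributionSpec.point(0.028),
                "dark": DistributionSpec.point(0.057)}
        spec = build_group_model(ADULTS, "HQ", conc, CONSTS, mode="absolute")
        assert "BW" in spec.dists
        assert spec.dists["BW"].kind == "lognormal"
        # IngR nominal is the per-bw daily rate scaled by nominal body weight
        nominal = 0.00259 / 7 * 1000 * 70.0
        assert spec.dists["IngR_milk"].params["mode"] == pytest.approx(nominal)

    def test_per_bw_mode_omits_bw(self):
        conc = {"milk": DistributionSpec.point(0.028),
                "dark": DistributionSpec.point(0.057)}
        spec = build_group_model(ADULTS, "CR", conc, CONSTS, mode="per_bw")
        assert "BW" not in spec.dists
        assert spec.dists["AT"].params["value"] == 25550.0

    def test_zero_rate_becomes_point_zero(self):
        group = PopulationGroup("g", 0.0, 0.002, 5.0, 20.0)
        conc = {"milk": DistributionSpec.point(0.028),
                "dark": DistributionSpec.point(0.057)}
        spec = build_group_model(group, "HQ", conc, CONSTS)
        assert spec.dists["IngR_milk"].kind == "point"
        assert spec.dists["IngR_milk"].params["value"] == 0.0

    def test_invalid_spread_rejected(self):
        with pytest.raises(SpecError):
            SpreadConfig(ingr_rel=(1.1, 1.0, 0.9))
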