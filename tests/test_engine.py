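"""Monte Carlo engine: assigned share, caps, twins, and the full protocol."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import radpoc as rp
from radpoc.modelset import ModelGroup, ModelSet
from radpoc.mmi import WeightTree


def single_model_set(model_set, mid, group_name="G"):
    """A one-model set reusing a model from the example set."""
    model = model_set.models[mid]
    return ModelSet(
        id=f"single-{mid}",
        models={mid: model},
        groups={group_name: ModelGroup(group_name, model.disease_class,
                                       WeightTree(model_ids=[mid], aics=[0.0]))},
    )


class TestAssignedShare:
    @pytest.mark.parametrize("h, lam0, expected",
                             [(0.0, 1e-4, 0.0),
                              (1e-4, 1e-4, 0.5),
                              (1e-4, 2e-4, 1 / 3)])
    def test_values(self, h, lam0, expected):
        assert rp.assigned_share(h, lam0) == pytest.approx(expected)

    def test_negative_excess_floored_at_zero(self):
        assert rp.assigned_share(-1e-4, 1e-4) == 0.0

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(rp.InputError):
            rp.assigned_share(1e-4, 0.0)

    @given(h=st.floats(0, 1e3), lam0=st.floats(1e-8, 1e-2))
    @settings(deadline=None, max_examples=80)
    def test_always_in_unit_interval(self, h, lam0):
        assert 0.0 <= rp.assigned_share(h, lam0) < 1.0


class TestTimeCaps:
    @pytest.mark.parametrize("cls, t, expected",
                             [("solid", 60, 53), ("solid", 20, 20), ("solid", 0, 0),
                              ("hematopoietic", 3, 5), ("hematopoietic", 60, 56),
                              ("hematopoietic", 30, 30)])
    def test_caps(self, cls, t, expected):
        assert rp.capped_time_since_exposure(cls, t) == expected

    def test_unknown_class_rejected(self):
        with pytest.raises(rp.ConfigurationError):
            rp.capped_time_since_exposure("benign", 10)


class TestCombineExposures:
    def test_single_exposure_unit_ratio_reduces_to_plain_share(self):
        h_m = 2e-4
        z = rp.combine_exposures([h_m], [1.0], f=0.7, lambda0=1e-3)
        assert z == pytest.approx(rp.assigned_share(h_m, 1e-3))

    def test_two_equal_exposures_additive(self):
        z = rp.combine_exposures([1e-4, 1e-4], [2.0, 2.0], f=0.0, lambda0=1e-3)
        assert z == pytest.approx(2e-4 / (1e-3 + 2e-4))

    def test_negative_clipping_modes(self):
        # mixed-sign excess: summing first retains cancellation
        z_sum = rp.combine_exposures([-1e-4, 2e-4], [1.0, 1.0], 0.5, 1e-3)
        z_clip = rp.combine_exposures([-1e-4, 2e-4], [1.0, 1.0], 0.5, 1e-3,
                                      clip="per_exposure")
        assert z_sum == pytest.approx(1e-4 / (1e-3 + 1e-4))
        assert z_clip == pytest.approx(2e-4 / (1e-3 + 2e-4))

    @given(
        h=st.lists(st.floats(0, 1e-3), min_size=1, max_size=4),
        B=st.lists(st.floats(0.1, 5.0), min_size=4, max_size=4),
        f=st.floats(0, 1),
    )
    @settings(deadline=None, max_examples=60)
    def test_monotone_in_each_excess(self, h, B, f):
        B = B[: len(h)]
        z0 = rp.combine_exposures(h, B, f, 1e-3)
        h2 = list(h)
        h2[0] += 1e-4
        assert rp.combine_exposures(h2, B, f, 1e-3) >= z0


class TestTwinAndMaxRules:
    def test_twin_rule_is_max(self):
        assert rp.twin_rule(0.2, 0.5) == 0.5
        assert rp.twin_rule(0.5, 0.5) == 0.5

    def test_max_err_rule_pointwise(self):
        out = rp.max_err_rule([[0.1, 0.9], [0.5, 0.2]])
        assert list(out) == [0.5, 0.9]

    def test_max_err_rule_empty_rejected(self):
        with pytest.raises(rp.InputError):
            rp.max_err_rule([])

    def test_linear_twin_dominates_at_low_dose(self, model_set, population,
                                               frozen_config):
        """Quadratic leukaemia model with equal 1-Gy excess: below 1 Gy the
        linear twin's Z must win."""
        case = rp.CaseSpec("HEMSYN", "m", 1950, 2010,
                           [rp.ExposureEvent(1980, {"type": "fixed", "value": 100.0})])
        dist = rp.run_case(case, model_set, population, frozen_config, seed=1)
        lam0 = population.baseline_rate("m", 60, 2010)
        model = model_set.models["HEMSYN-L"]
        lam0m = rp.model_baseline(model, model.params, -1, 60, 1975)
        fl = rp.latency_factor(30, rp.LatencyParams(1.5, 7.66))
        h_m = lam0m * 1.0 * 0.1 * fl  # linear twin at 0.1 Gy
        B = lam0 / lam0m
        z_twin = rp.combine_exposures([h_m], [B], 0.5, lam0)
        assert np.allclose(dist.values, z_twin)


class TestSummarize:
    def test_constant_sample(self):
        s = rp.summarize(np.full(100, 0.3))
        assert s["mean"] == s["median"] == 0.3
        assert s["ci95"] == (0.3, 0.3)

    def test_uniform_tail_percentile(self, rng):
        sample = rng.uniform(size=100_000)
        s = rp.summarize(sample)
        assert s["percentiles"][97.5] == pytest.approx(0.975, abs=0.005)

    def test_empty_rejected(self):
        with pytest.raises(rp.InputError):
            rp.summarize([])


class TestRunCase:
    def test_zero_dose_gives_identically_zero(self, model_set, population):
        case = rp.CaseSpec("DIG", "f", 1950, 2010,
                           [rp.ExposureEvent(1980, {"type": "fixed", "value": 0.0})])
        dist = rp.run_case(case, model_set, population,
                           rp.RunConfig(iterations=200), seed=2)
        assert np.all(dist.values == 0.0)

    def test_reproducible_under_seed(self, model_set, population, simple_case):
        cfg = rp.RunConfig(iterations=300)
        a = rp.run_case(simple_case, model_set, population, cfg, seed=5)
        b = rp.run_case(simple_case, model_set, population, cfg, seed=5)
        assert np.array_equal(a.values, b.values)

    def test_values_in_unit_interval(self, model_set, population, simple_case):
        dist = rp.run_case(simple_case, model_set, population,
                           rp.RunConfig(iterations=500), seed=3)
        assert np.all((dist.values >= 0) & (dist.values < 1))

    def test_stratified_allocation_matches_worked_example(self, model_set,
                                                          population, simple_case):
        ms = ModelSet(
            id="two",
            models={mid: model_set.models[mid] for mid in ("DIG-ERR", "DIG-EAR")},
            groups={"DIG": ModelGroup(
                "DIG", "solid",
                WeightTree(model_ids=["DIG-ERR", "DIG-EAR"],
                           leaf_weights=[0.6, 0.4]))},
        )
        dist = rp.run_case(simple_case, ms, population,
                           rp.RunConfig(iterations=10_000, sample_parameters=False),
                           seed=0)
        assert dist.metadata["model_counts"] == {"DIG-ERR": 6000, "DIG-EAR": 4000}

    def test_frozen_run_equals_closed_form(self, model_set, population,
                                           frozen_config):
        """With every sampling source frozen the run must reproduce the
        closed-form mixed-transfer value exactly."""
        ms = single_model_set(model_set, "DIG-ERR", "DIG")
        case = rp.CaseSpec("DIG", "m", 1950, 2010,
                           [rp.ExposureEvent(1980, {"type": "fixed", "value": 500.0})])
        dist = rp.run_case(case, ms, population, frozen_config, seed=0)
        # independent arithmetic: ERR model, a=60, e=30, t=30
        p = model_set.models["DIG-ERR"].params
        err = p["beta"] * 0.5 * (60 / 70) ** p["phi"]
        lam0m = np.exp(p["b0"] + p["b_sex"] * (-1) + p["b_age"] * np.log(60 / 70))
        fl = 1.0 / (1.0 + (30 / 3.5) ** (-6.25))
        h_m = lam0m * err * fl
        lam0 = population.baseline_rate("m", 60, 2010)
        B = lam0 / lam0m
        num = 0.5 * h_m + 0.5 * h_m * B
        expected = num / (lam0 + num)
        assert np.allclose(dist.values, expected, rtol=1e-12)

    def test_dref_median_invariance_under_frozen_everything_else(
            self, model_set, population, frozen_config):
        """DREF has geometric mean 1: switching it on (only the percentile
        varies) must not move the median Z."""
        ms = single_model_set(model_set, "DIG-ERR", "DIG")
        case = rp.CaseSpec("DIG", "m", 1950, 2010,
                           [rp.ExposureEvent(1980, {"type": "fixed", "value": 100.0},
                                             duration_hours=1000.0)])
        cfg_off = frozen_config
        z_off = rp.run_case(case, ms, population, cfg_off, seed=0).values[0]
        cfg_on = rp.RunConfig(**{**frozen_config.__dict__,
                                 "iterations": 10_000, "dref_enabled": True})
        dist_on = rp.run_case(case, ms, population, cfg_on, seed=0)
        assert np.median(dist_on.values) == pytest.approx(z_off, rel=0.02)
        # and the spread genuinely widens
        assert dist_on.values.std() > 0

    def test_max_err_group_takes_larger_model(self, population, frozen_config):
        base = dict(kind="ERR", disease_class="solid",
                    baseline_spec=rp.BaselineSpec(),
                    params={"b0": np.log(2e-4), "beta": 0.5})
        lo = rp.RiskModel(id="lo", **base)
        hi = rp.RiskModel(id="hi", **{**base, "params": {"b0": np.log(2e-4), "beta": 1.0}})
        ms = ModelSet(
            id="maxgrp", models={"lo": lo, "hi": hi},
            groups={"L": ModelGroup("L", "solid",
                                    WeightTree(model_ids=["lo", "hi"],
                                               leaf_weights=[0.5, 0.5]),
                                    max_group=["lo", "hi"])},
        )
        case = rp.CaseSpec("L", "m", 1950, 2010,
                           [rp.ExposureEvent(1980, {"type": "fixed", "value": 500.0})])
        dist = rp.run_case(case, ms, population, frozen_config, seed=0)
        # every iteration must equal the Z of the larger-ERR model
        lam0 = population.baseline_rate("m", 60, 2010)
        lam0m = 2e-4
        fl = 1.0 / (1.0 + (30 / 3.5) ** (-6.25))
        h_hi = lam0m * 1.0 * 0.5 * fl
        z_hi = rp.combine_exposures([h_hi], [lam0 / lam0m], 0.5, lam0)
        assert np.allclose(dist.values, z_hi)

    def test_unknown_group_rejected(self, model_set, population):
        case = rp.CaseSpec("NOPE", "m", 1950, 2010, [])
        with pytest.raises(rp.ConfigurationError):
            rp.run_case(case, model_set, population)

    def test_iteration_bounds_enforced(self):
        with pytest.raises(rp.ConfigurationError):
            rp.RunConfig(iterations=60_000)
        with pytest.raises(rp.ConfigurationError):
            rp.RunConfig(iterations=0)

    def test_inconsistent_years_rejected(self):
        with pytest.raises(rp.InputError):
            rp.CaseSpec("DIG", "m", 1950, 1940, [])
        with pytest.raises(rp.InputError):
            rp.CaseSpec("DIG", "m", 1950, 2010,
                        [rp.ExposureEvent(1940, {"type": "fixed", "value": 1.0})])


class TestFractionation:
    """Dose-splitting behaviour: exact invariance for linear models, exact
    1/k scaling for pure quadratic models."""

    def _combined_excess(self, model, doses_gy):
        return sum(
            rp.excess(model, model.params, d, s=-1, a=60, e=30) for d in doses_gy
        )

    def test_linear_model_fraction_invariant(self, model_set):
        model = model_set.models["URI-ERR"]
        single = self._combined_excess(model, [1.0])
        for k in (2, 10, 100):
            split = self._combined_excess(model, [1.0 / k] * k)
            assert split == pytest.approx(single, rel=1e-12)

    def test_quadratic_model_scales_inverse_k(self, model_set):
        model = model_set.models["HEMSYN-Q"]
        single = self._combined_excess(model, [1.0])
        for k in (10, 100):
            split = self._combined_excess(model, [1.0 / k] * k)
            assert single / split == pytest.approx(k, rel=1e-12)


class TestSmoking:
    def _lung_like_set(self, prevalence):
        model = rp.RiskModel(
            id="LUNG-ERR", kind="ERR", disease_class="solid",
            baseline_spec=rp.BaselineSpec(),
            modifier_spec=rp.ModifierSpec(smoking=True),
            params={"b0": np.log(3e-4), "beta": 0.8, "theta1": 0.5, "theta2": -0.2},
        )
        return ModelSet(
            id="lung", models={"LUNG-ERR": model},
            groups={"LUNG": ModelGroup("LUNG", "solid",
                                       WeightTree(model_ids=["LUNG-ERR"], aics=[0.0]))},
            smoking_prevalence=prevalence,
        )

    def test_unknown_status_sampled_from_prevalence(self, population):
        ms = self._lung_like_set(rp.generate_smoking_prevalence())
        case = rp.CaseSpec("LUNG", "m", 1950, 2010,
                           [rp.ExposureEvent(1980, {"type": "fixed", "value": 500.0})],
                           smoking={"status": "unknown"})
        dist = rp.run_case(case, ms, population, rp.RunConfig(iterations=300), seed=4)
        assert np.all((dist.values >= 0) & (dist.values < 1))
        assert dist.values.std() > 0

    def test_degenerate_all_never_table_matches_never_smoker(self, population,
                                                             frozen_config):
        never_table = {s: {"never": 1.0, "past": 0.0, "current": 0.0,
                           "intensity_lognormal": {"gm": 10.0, "gsd": 1.5}}
                       for s in ("m", "f")}
        ms = self._lung_like_set(never_table)
        exposures = [rp.ExposureEvent(1980, {"type": "fixed", "value": 500.0})]
        unknown = rp.CaseSpec("LUNG", "m", 1950, 2010, exposures,
                              smoking={"status": "unknown"})
        never = rp.CaseSpec("LUNG", "m", 1950, 2010, exposures,
                            smoking={"status": "never"})
        z_u = rp.run_case(unknown, ms, population, frozen_config, seed=1).values
        z_n = rp.run_case(never, ms, population, frozen_config, seed=1).values
        assert np.array_equal(z_u, z_n)

    def test_missing_prevalence_table_rejected(self, population):
        ms = self._lung_like_set(None)
        case = rp.CaseSpec("LUNG", "m", 1950, 2010,
                           [rp.ExposureEvent(1980, {"type": "fixed", "value": 1.0})],
                           smoking={"status": "unknown"})
        with pytest.raises(rp.ConfigurationError):
            rp.run_case(case, ms, population, rp.RunConfig(iterations=5), seed=0)


class TestDoseDistributions:
    @pytest.mark.parametrize("dose, check", [
        ({"type": "normal", "mean": 100.0, "sd": 300.0}, lambda d: d >= 0),
        ({"type": "lognormal", "gm": 100.0, "gsd": 2.0}, lambda d: d > 0),
        ({"type": "uniform", "low": 50.0, "high": 150.0},
         lambda d: 50 <= d <= 150),
        ({"type": "triangular", "low": 0.0, "mode": 100.0, "high": 300.0},
         lambda d: 0 <= d <= 300),
    ])
    def test_support(self, dose, check, rng):
        ex = rp.ExposureEvent(1980, dose)
        assert all(check(ex.sample_dose(rng)) for _ in range(500))

    def test_unknown_type_rejected(self):
        with pytest.raises(rp.InputError):
            rp.ExposureEvent(1980, {"type": "gamma", "shape": 2})

    def test_indoor_radon_requires_duration(self):
        with pytest.raises(rp.InputError):
            rp.ExposureEvent(1980, {"type": "fixed", "value": 200.0},
                             radiation_class="radon_indoor")
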