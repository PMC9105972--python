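import numpy as np
import pytest

from tdikin.assays import NoiseModel, gal_design, generate_curves, to_concentration
from tdikin.fitting import (
    FitCurve,
    FitParameter,
    FitSpec,
    fit_curves_from_progress,
    fit_stage1,
    fit_stage2,
    global_fit,
    profile_uncertainty,
)
from tdikin.mechanisms import Mechanism, Step, build_scheme


def rel_err(a, b):
    return abs(a - b) / abs(b)


class TestGlobalFitBasics:
    def test_truth_start_converges_immediately(self, product_series_fit_curves, tcache_rates):
        res = fit_stage1(
            product_series_fit_curves,
            guesses={k: tcache_rates[k] for k in ("k1", "k2", "k4")},
        )
        assert res.converged
        assert res.rss < 1e-12
        for k in ("k1", "k2", "k4"):
            assert rel_err(res.estimates[k], tcache_rates[k]) < 1e-6

    def test_determinism(self, product_series_fit_curves, tcache_rates):
        g = {"k1": tcache_rates["k1"] * 2, "k2": tcache_rates["k2"] / 2, "k4": tcache_rates["k4"]}
        a = fit_stage1(product_series_fit_curves, guesses=g)
        b = fit_stage1(product_series_fit_curves, guesses=g)
        assert a.to_dict() == b.to_dict()

    def test_spec_validation(self, product_series_fit_curves):
        mech = build_scheme("slyke_cullen_product")
        with pytest.raises(ValueError, match="free and fixed"):
            FitSpec(
                mechanism=mech,
                fixed_rates={"k1": 1e8, "k2": 1e3, "k3": 2e8, "k4": 1e3},
                parameters=[FitParameter("k1", 1e8)],
                curves=product_series_fit_curves,
            )
        with pytest.raises(ValueError, match="neither free nor fixed"):
            FitSpec(
                mechanism=mech,
                fixed_rates={"k3": 2e8},
                parameters=[FitParameter("k1", 1e8)],
                curves=product_series_fit_curves,
            )
        with pytest.raises(ValueError, match="at least one curve"):
            FitSpec(mechanism=mech, fixed_rates={}, parameters=[], curves=[])

    def test_parameter_validation(self):
        with pytest.raises(ValueError, match="bounds"):
            FitParameter("k1", 1.0, lower=2.0, upper=1.0)
        with pytest.raises(ValueError, match="outside bounds"):
            FitParameter("k1", 10.0, lower=0.1, upper=1.0)


class TestStage1:
    def test_round_trip_from_perturbed_guesses(self, product_series_fit_curves, tcache_rates):
        """Noiseless sequential-addition data regenerate k1, k2 and the
        product Ki to well under 0.5% from x3 / /3 perturbed guesses."""
        res = fit_stage1(
            product_series_fit_curves,
            guesses={
                "k1": tcache_rates["k1"] * 3,
                "k2": tcache_rates["k2"] / 3,
                "k4": tcache_rates["k4"] * 3,
            },
        )
        assert res.converged and not res.rank_deficient
        for k in ("k1", "k2", "k4"):
            assert rel_err(res.estimates[k], tcache_rates[k]) < 5e-3
        d = res.derived()
        assert rel_err(d["Ki_product_M"], 21.54e-6) < 5e-3

    def test_round_trip_with_absorbance_noise(self, tcache_rates):
        from dataclasses import replace

        design = replace(gal_design("product_series"), sample_dt_s=5.0)
        mech = build_scheme("slyke_cullen_product")
        curves = generate_curves(design, mech, tcache_rates, NoiseModel(sd_abs=0.01, seed=11))
        fcs = fit_curves_from_progress(curves, design)
        res = fit_stage1(
            fcs,
            guesses={
                "k1": tcache_rates["k1"] * 3,
                "k2": tcache_rates["k2"] / 3,
                "k4": tcache_rates["k4"] * 3,
            },
        )
        for k in ("k1", "k2"):
            assert rel_err(res.estimates[k], tcache_rates[k]) < 0.05
        assert rel_err(res.derived()["Ki_product_M"], 21.54e-6) < 0.05
        # noise now propagates into finite standard errors
        assert res.standard_errors["k2"] > 0

    def test_product_ki_invariant_to_assumed_on_rate(self, product_series_fit_curves, tcache_rates):
        """Near-equilibrium product binding identifies only k4/k3: fixing
        k3 five-fold higher shifts the fitted Ki by < 0.2%."""
        g = {"k1": tcache_rates["k1"] * 2, "k2": tcache_rates["k2"] / 2, "k4": tcache_rates["k4"]}
        a = fit_stage1(product_series_fit_curves, k3_fixed=2e8, guesses=g)
        b = fit_stage1(product_series_fit_curves, k3_fixed=1e9, guesses=g)
        assert rel_err(a.derived()["Ki_product_M"], b.derived()["Ki_product_M"]) < 2e-3

    def test_omitting_product_inhibition_leaves_systematic_residuals(
        self, product_series_fit_curves, tcache_rates
    ):
        """A hydrolysis-only model cannot reproduce the progressively slower
        later additions: its best-fit RMS is far above the full model's."""
        full = fit_stage1(
            product_series_fit_curves,
            guesses={k: tcache_rates[k] for k in ("k1", "k2", "k4")},
        )
        bare = Mechanism(
            "slyke_cullen_bare",
            ("E", "S", "EA", "P", "A"),
            (
                Step({"E": 1, "S": 1}, {"EA": 1, "P": 1}, "k1"),
                Step({"EA": 1}, {"E": 1, "A": 1}, "k2"),
            ),
        )
        spec = FitSpec(
            mechanism=bare,
            fixed_rates={},
            parameters=[
                FitParameter("k1", tcache_rates["k1"], 1e4, 1e12),
                FitParameter("k2", tcache_rates["k2"], 1e-2, 1e8),
            ],
            curves=product_series_fit_curves,
        )
        res = global_fit(spec)
        assert max(res.per_curve_rms) >= 5 * max(max(full.per_curve_rms), 1e-12)
        assert res.rss > 100 * full.rss + 1e-9


class TestStage2:
    GUESSES = {"k5": 1.9e6 * 3, "k6": 1.9e6 * 8.45e-9 / 3}

    def test_round_trip_recovers_ki_and_kon(
        self, gal_series_fit_curves, stage1_truth, tcache_rates
    ):
        res = fit_stage2(gal_series_fit_curves, stage1_truth, guesses=self.GUESSES)
        assert res.converged
        d = res.derived()
        assert rel_err(d["Ki_M"], 8.45e-9) < 0.01
        assert rel_err(d["kon_M_per_s"], 1.9e6) < 0.01
        # Ki is derived from k6/k5 exactly, never fitted separately
        assert d["Ki_M"] == res.estimates["k6"] / res.estimates["k5"]

    def test_concentration_scales_stay_near_nominal(
        self, gal_series_fit_curves, stage1_truth
    ):
        res = fit_stage2(gal_series_fit_curves, stage1_truth, guesses=self.GUESSES)
        scales = [v for k, v in res.estimates.items() if k == "e0" or k.startswith("s0:")]
        assert len(scales) == 7  # shared e0 + six per-curve s0
        assert np.allclose(scales, 1.0, atol=1e-3)

    def test_uninhibited_curves_alone_are_rejected(self, gal_series_fit_curves, stage1_truth):
        only0 = [fc for fc in gal_series_fit_curves if fc.i0 == 0.0]
        with pytest.raises(ValueError, match="unidentifiable"):
            fit_stage2(only0, stage1_truth)

    def test_missing_stage1_constants(self, gal_series_fit_curves):
        with pytest.raises(ValueError, match="stage-1 constants missing"):
            fit_stage2(gal_series_fit_curves, {"k1": 1e8})

    def test_slow_onset_of_inhibition_in_enzyme_initiated_curves(self, gal_series_curves):
        """Slow second-order EI formation: just after mixing every curve
        runs at nearly the uninhibited rate, the inhibition then develops
        over tens of seconds, and the early-time inhibition (rate relative
        to the i0 = 0 curve at the same instant, before substrate depletion
        matters) deepens monotonically with galantamine because the onset
        rate k5*[I] + k6 and the equilibrium occupancy both grow with [I]."""
        design, curves = gal_series_curves

        def rate_at(c, t):
            cc = to_concentration(c)
            r = np.gradient(cc.signal, cc.time_s)
            return r[np.argmin(np.abs(cc.time_s - t))]

        ref = next(c for c in curves if c.i0 == 0.0)
        inhibited = sorted((c for c in curves if c.i0 > 0), key=lambda c: c.i0)
        early = [rate_at(c, 0.0) / rate_at(ref, 0.0) for c in inhibited]
        later = [rate_at(c, 40.0) / rate_at(ref, 40.0) for c in inhibited]
        # initial rates substantially unaffected even at 180 nM (the first
        # 10 s average retains ~80% of the uninhibited rate)
        assert min(early) > 0.75
        # inhibition has developed by ~40 s and deepens with concentration
        assert all(l < e for e, l in zip(early, later))
        assert all(a > b for a, b in zip(later, later[1:]))

    def test_loss_invariance_between_signal_scales(self, gal_series_curves, stage1_truth):
        """Fitting the same curves in absorbance or concentration units
        gives identical parameter estimates."""
        design, curves = gal_series_curves
        fcs_abs = fit_curves_from_progress(curves, design)
        conc = [to_concentration(c) for c in curves]
        from dataclasses import replace

        fcs_conc = fit_curves_from_progress(conc, replace(design, detection="concentration"))
        a = fit_stage2(fcs_abs, stage1_truth, guesses=self.GUESSES, fit_s0=False, fit_e0=False)
        b = fit_stage2(fcs_conc, stage1_truth, guesses=self.GUESSES, fit_s0=False, fit_e0=False)
        for k in ("k5", "k6"):
            assert rel_err(a.estimates[k], b.estimates[k]) < 1e-6


class TestProfile:
    def test_profile_minimum_at_optimum_and_convex(self, gal_series_fit_curves, stage1_truth):
        # uninhibited, 60 nM and 180 nM curves
        srt = sorted(gal_series_fit_curves, key=lambda fc: fc.i0)
        fcs = [srt[0], srt[3], srt[5]]
        assert fcs[1].i0 > 0 and fcs[2].i0 > 0
        spec = FitSpec(
            mechanism=build_scheme("slyke_cullen_product_inhibitor"),
            fixed_rates=dict(stage1_truth),
            parameters=[
                FitParameter("k5", 1.9e6, 1e2, 1e10),
                FitParameter("k6", 1.6055e-2, 1e-7, 1e3),
            ],
            curves=fcs,
        )
        res = global_fit(spec)
        grid = [1.9e6 * f for f in (0.8, 1.0, 1.25)]
        prof = profile_uncertainty(spec, res, "k5", grid)
        rss = [r for _, r in prof]
        assert rss[1] == pytest.approx(res.rss, abs=1e-12)
        assert rss[0] > rss[1] and rss[2] > rss[1]

    def test_unknown_parameter_rejected(self, gal_series_fit_curves, stage1_truth):
        spec = FitSpec(
            mechanism=build_scheme("slyke_cullen_product_inhibitor"),
            fixed_rates=dict(stage1_truth),
            parameters=[
                FitParameter("k5", 1.9e6, 1e2, 1e10),
                FitParameter("k6", 1.6e-2, 1e-7, 1e3),
            ],
            curves=gal_series_fit_curves,
        )
        res = global_fit(spec)
        with pytest.raises(ValueError, match="not a free parameter"):
            profile_uncertainty(spec, res, "k1", [1.0])
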