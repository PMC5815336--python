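"""Diversity-area curves, model fitting, ranking and random-placement nulls."""

import numpy as np
import pytest

import steppediv as sd
from steppediv.sar import FAMILIES, family_predict

from conftest import make_dataset

AREAS = np.array([(k * 0.5) ** 2 for k in range(1, 11)])

TRUE_PARAMS = {
    "power_multiplicative": (8.5, 0.35),
    "power_additive": (7.0, 0.55),
    "exponential": (3.0, 5.0),
    "logistic": (2.0, 26.0, 0.1),
    "parabolic": (-0.4, 3.0, 10.0),
    "linear": (0.8, 9.0),
}


def noise_free_curve(family, params):
    return sd.SARCurve(
        metric="richness", areas=AREAS, values=family_predict(family, params, AREAS)
    )


class TestFitModel:
    @pytest.mark.parametrize("family", sorted(FAMILIES))
    def test_noise_free_parameter_recovery(self, family):
        params = TRUE_PARAMS[family]
        fit = sd.fit_model(noise_free_curve(family, params), family)
        np.testing.assert_allclose(fit.params, params, atol=1e-6, rtol=1e-6)
        assert fit.ssr < 1e-12

    def test_logistic_self_consistency(self):
        fit = sd.fit_model(noise_free_curve("logistic", (2.0, 26.0, 0.1)), "logistic")
        np.testing.assert_allclose(fit.params, (2.0, 26.0, 0.1), atol=1e-6)
        assert fit.ssr < 1e-12

    def test_exponential_closed_form(self):
        # linear in parameters: exact recovery of S = 3 ln A + 5
        fit = sd.fit_model(noise_free_curve("exponential", (3.0, 5.0)), "exponential")
        np.testing.assert_allclose(fit.params, (3.0, 5.0), atol=1e-10)

    def test_noise_bias_shrinks_with_sigma(self):
        rng = np.random.default_rng(0)
        errs = []
        for sigma in (0.5, 0.05):
            recovered = []
            for _ in range(20):
                vals = family_predict("exponential", (3.0, 5.0), AREAS)
                curve = sd.SARCurve("richness", AREAS, vals + rng.normal(0, sigma, len(AREAS)))
                recovered.append(sd.fit_model(curve, "exponential").params)
            errs.append(np.abs(np.mean(recovered, axis=0) - (3.0, 5.0)).max())
        assert errs[1] < errs[0]

    def test_ci_halfwidths_nonnegative_and_cover_truth_mostly(self):
        rng = np.random.default_rng(1)
        cover = 0
        n = 50
        for _ in range(n):
            vals = family_predict("exponential", (3.0, 5.0), AREAS)
            curve = sd.SARCurve("richness", AREAS, vals + rng.normal(0, 0.3, len(AREAS)))
            fit = sd.fit_model(curve, "exponential")
            assert (fit.ci_halfwidths >= 0).all()
            lo, hi = fit.params - fit.ci_halfwidths, fit.params + fit.ci_halfwidths
            cover += bool((lo <= (3.0, 5.0)).all() and ((3.0, 5.0) <= hi).all())
        assert cover >= 0.8 * n  # nominal 95% joint-ish coverage

    def test_flat_curve_flat_families_and_logistic_error(self):
        flat = sd.SARCurve("richness", AREAS, np.full(len(AREAS), 4.0))
        with pytest.warns(UserWarning, match="constant"):
            fit = sd.fit_model(flat, "exponential")
        assert fit.ssr == 0 and fit.params[0] == 0
        with pytest.raises(ValueError, match="flat"):
            sd.fit_model(flat, "logistic")

    def test_too_few_points_rejected(self):
        curve = sd.SARCurve("richness", AREAS[:3], np.array([1.0, 2.0, 3.0]))
        with pytest.raises(ValueError, match="points"):
            sd.fit_model(curve, "logistic")


class TestCompareModels:
    def _fits(self, curve, families):
        return [sd.fit_model(curve, f) for f in families]

    def test_lowest_ssr_first_on_logistic_truth(self):
        curve = noise_free_curve("logistic", (2.0, 26.0, 0.1))
        ranking = sd.compare_models(
            self._fits(curve, ["exponential", "power_multiplicative", "logistic"])
        )
        assert ranking[0].family == "logistic"
        assert ranking[0].ssr <= ranking[1].ssr <= ranking[2].ssr

    def test_tie_broken_by_fewer_parameters(self):
        flat = sd.SARCurve("richness", AREAS, np.full(len(AREAS), 4.0))
        with pytest.warns(UserWarning):
            fits = self._fits(flat, ["parabolic", "exponential"])
        ranking = sd.compare_models(fits)
        assert ranking[0].family == "exponential"  # 2 params beats 3 at equal SSR

    def test_ranking_invariant_to_input_order(self):
        curve = noise_free_curve("logistic", (2.0, 26.0, 0.1))
        fits = self._fits(curve, ["exponential", "logistic", "power_multiplicative"])
        r1 = [f.family for f in sd.compare_models(fits)]
        r2 = [f.family for f in sd.compare_models(fits[::-1])]
        assert r1 == r2

    def test_fits_of_different_curves_rejected(self):
        c1 = noise_free_curve("exponential", (3.0, 5.0))
        c2 = noise_free_curve("exponential", (2.0, 5.0))
        with pytest.raises(ValueError, match="different curves"):
            sd.compare_models([sd.fit_model(c1, "exponential"), sd.fit_model(c2, "exponential")])


class TestEmpiricalCurve:
    def test_area_axis(self, grazed):
        curve = sd.empirical_curve(grazed, "richness", ks=[1, 10])
        np.testing.assert_allclose(curve.areas, [0.25, 25.0])

    def test_richness_curve_monotone(self, grazed):
        curve = sd.empirical_curve(grazed, "richness")
        assert np.all(np.diff(curve.values) >= -1e-9)

    def test_single_ubiquitous_species_gives_constant_one(self):
        ds = make_dataset(np.ones((6, 6, 1), dtype=int))
        curve = sd.empirical_curve([ds], "richness")
        np.testing.assert_allclose(curve.values, 1.0)


class TestColeman:
    def test_full_area_equals_whole_subplot_richness(self, grazed):
        d = grazed[0]
        exp = sd.expected_sar_coleman(d, ks=[10])
        whole = sd.richness(d.abundance.sum(axis=0).to_numpy())
        assert exp.values[0] == pytest.approx(whole)

    def test_single_individual_linear_in_area(self):
        counts = np.zeros((4, 4, 1), dtype=int)
        counts[0, 0, 0] = 1
        ds = make_dataset(counts)
        exp = sd.expected_sar_coleman(ds, ks=[1, 2, 4])
        np.testing.assert_allclose(exp.values, [1 / 16, 4 / 16, 1.0])

    def test_concave_nondecreasing(self, grazed):
        exp = sd.expected_sar_coleman(grazed)
        diffs = np.diff(exp.values)
        assert np.all(diffs >= -1e-9)
        assert np.all(np.diff(diffs) <= 1e-9)  # concavity in a

    def test_matches_randomization_mean(self, grazed):
        # closed form vs Monte Carlo oracle, 3 standard errors of the mean;
        # near saturation a species-miss is so rare that no replicate shows it
        # and the empirical SE collapses, so allow the rule-of-three bound on
        # an unobserved event rate (3/n_reps) as absolute slack
        d = grazed[0]
        exp = sd.expected_sar_coleman(d)
        null = sd.randomization_sar(d, n_reps=300, seed=3)
        se = null.rep_sd / np.sqrt(null.n_reps)
        tol = 3 * se + 3.0 / null.n_reps
        assert np.all(np.abs(null.curve.values - exp.values) <= tol)


class TestRandomization:
    def test_seeded_reproducibility(self, grazed):
        a = sd.randomization_sar(grazed[0], n_reps=5, seed=7)
        b = sd.randomization_sar(grazed[0], n_reps=5, seed=7)
        np.testing.assert_array_equal(a.curve.values, b.curve.values)
        np.testing.assert_array_equal(a.lower, b.lower)

    def test_uniform_data_inside_envelope(self):
        # data that IS random placement should sit inside its own 95% envelope
        rng = np.random.default_rng(2)
        hits, total = 0, 0
        for rep in range(5):
            counts = rng.multinomial(400, np.full(36, 1 / 36), size=8).T.reshape(6, 6, 8)
            ds = make_dataset(counts)
            obs = sd.empirical_curve([ds], "richness", ks=[1, 2, 3, 6])
            null = sd.randomization_sar(ds, ks=[1, 2, 3, 6], n_reps=199, seed=rep)
            inside = (obs.values >= null.lower - 1e-9) & (obs.values <= null.upper + 1e-9)
            hits += int(inside.sum())
            total += len(inside)
        assert hits >= 0.9 * total

    def test_clustered_data_below_expectation_at_small_areas(self):
        # all individuals of each species piled into one quadrat
        counts = np.zeros((6, 6, 6), dtype=int)
        for s in range(6):
            counts[s, s, s] = 30
        ds = make_dataset(counts)
        obs = sd.empirical_curve([ds], "richness", ks=[1, 2])
        exp = sd.expected_sar_coleman(ds, ks=[1, 2])
        assert np.all(obs.values < exp.values)


class TestCurvesDiffer:
    def _fit_with(self, params, ci):
        return sd.ModelFit(
            family="exponential", params=np.asarray(params, float),
            ci_halfwidths=np.asarray(ci, float), ssr=0.0, converged=True,
            n_points=10, curve_digest="x",
        )

    def test_disjoint_intervals_flagged(self):
        f1 = self._fit_with([1.5, 3.5], [0.5, 0.5])
        f2 = self._fit_with([3.5, 3.6], [0.5, 0.5])
        verdict = sd.curves_differ(f1, f2)
        assert verdict == {"alpha": True, "beta": False}

    def test_identical_fits_never_differ(self):
        f = self._fit_with([1.0, 2.0], [0.1, 0.1])
        assert set(sd.curves_differ(f, f).values()) == {False}

    def test_family_mismatch_rejected(self):
        f1 = self._fit_with([1.0, 2.0], [0.1, 0.1])
        f2 = sd.ModelFit("linear", np.array([1.0, 2.0]), np.array([0.1, 0.1]),
                         0.0, True, 10, "x")
        with pytest.raises(ValueError, match="mismatch"):
            sd.curves_differ(f1, f2)

    def test_grazed_vs_fenced_logistic_fits_comparable(self, grazed, fenced):
        cg = sd.empirical_curve(grazed, "richness")
        cf = sd.empirical_curve(fenced, "richness")
        fg = sd.fit_model(cg, "logistic")
        ff = sd.fit_model(cf, "logistic")
        verdict = sd.curves_differ(fg, ff)
        assert set(verdict) == {"alpha", "beta", "delta"}
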