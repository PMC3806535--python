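"""Parameter estimation: (a, b) regressions, capacity RSS fits, r2, normalization."""

from dataclasses import replace

import numpy as np
import pytest

from isoflux import (
    EnergeticIsoParams,
    DatasetDesign,
    G93Params,
    LeafEnvironment,
    GasExchangeRecord,
    PhotoParams,
    UndefinedStatisticError,
    electron_transport,
    fit_ab_from_ci_response,
    fit_ab_from_light_response,
    fit_photo_params,
    generate_dataset,
    jv_required,
    kinetics_at,
    r_squared,
    standard_emission,
)
from isoflux.io import records_from_table


def _records(table):
    return records_from_table(table)


def _light_design(photo, iso, cv=0.0, seed=0, n=20):
    return DatasetDesign(
        kind="light_response", grid=np.linspace(150.0, 2000.0, n),
        photo=photo, iso=iso, fixed=LeafEnvironment(1000.0, 30.0, 273.0),
        cv_a=cv, cv_iso=cv, seed=seed,
    )


def _ci_design(photo, iso, cv=0.0, seed=0, n=20):
    return DatasetDesign(
        kind="ci_response", grid=np.linspace(60.0, 800.0, n),
        photo=photo, iso=iso, fixed=LeafEnvironment(1000.0, 30.0, 273.0),
        cv_a=cv, cv_iso=cv, seed=seed,
    )


class TestRSquared:
    def test_perfect_prediction(self):
        assert r_squared([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 1.0

    def test_mean_prediction_scores_zero(self):
        obs = np.array([1.0, 2.0, 3.0, 10.0])
        assert r_squared(obs, np.full(4, obs.mean())) == pytest.approx(0.0)

    def test_hand_arithmetic_triple(self):
        assert r_squared([1.0, 2.0, 3.0], [1.0, 2.0, 4.0]) == pytest.approx(0.5)

    def test_can_be_negative_for_bad_models(self):
        assert r_squared([1.0, 2.0, 3.0], [6.0, 6.0, 6.0]) < 0

    def test_zero_variance_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            r_squared([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])


class TestLightResponseAB:
    def test_hand_collinear_points(self, reference_photo):
        # iso constructed as exactly 2*J - 50: slope 2, intercept -50,
        # hence b = 50/Jv and a = 2 - b
        par = [400.0, 900.0, 1600.0]
        t_k = 303.15
        jmax = reference_photo.jmax_at(t_k)
        recs = []
        for q in par:
            j = float(electron_transport(q, jmax, reference_photo.alpha,
                                         reference_photo.theta))
            recs.append(GasExchangeRecord(
                env=LeafEnvironment(q, 30.0, 273.0),
                a_net_obs=10.0, iso_obs=2.0 * j - 50.0,
            ))
        res = fit_ab_from_light_response(recs, reference_photo)
        gs, km = kinetics_at(t_k, 210.0, reference_photo)
        jv = jv_required(reference_photo.vcmax_at(t_k), 273.0, gs, km)
        assert res.estimates["slope"] == pytest.approx(2.0, abs=1e-10)
        assert res.estimates["intercept"] == pytest.approx(-50.0, abs=1e-7)
        assert res.estimates["b"] == pytest.approx(50.0 / jv, rel=1e-9)
        assert res.estimates["a"] == pytest.approx(2.0 - 50.0 / jv, rel=1e-9)
        assert res.r_squared == pytest.approx(1.0)

    def test_noiseless_exact_recovery(self, reference_photo, iso_params):
        table, _ = generate_dataset(_light_design(reference_photo, iso_params))
        res = fit_ab_from_light_response(_records(table), reference_photo)
        assert res.estimates["a"] == pytest.approx(iso_params.a, rel=1e-9)
        assert res.estimates["b"] == pytest.approx(iso_params.b, rel=1e-9)

    def test_reorder_invariance(self, reference_photo, iso_params):
        table, _ = generate_dataset(_light_design(reference_photo, iso_params,
                                                  cv=0.05, seed=3))
        recs = _records(table)
        res1 = fit_ab_from_light_response(recs, reference_photo)
        res2 = fit_ab_from_light_response(list(reversed(recs)), reference_photo)
        assert res1.estimates["a"] == pytest.approx(res2.estimates["a"])
        assert res1.estimates["b"] == pytest.approx(res2.estimates["b"])

    def test_varying_ci_rejected(self, reference_photo):
        recs = [
            GasExchangeRecord(LeafEnvironment(q, 30.0, ci), 10.0, 20.0)
            for q, ci in [(300.0, 200.0), (800.0, 273.0), (1500.0, 350.0)]
        ]
        with pytest.raises(ValueError, match="fixed ci"):
            fit_ab_from_light_response(recs, reference_photo)

    def test_degenerate_light_spread_rejected(self, reference_photo):
        recs = [
            GasExchangeRecord(LeafEnvironment(1000.0, 30.0, 273.0), 10.0, 20.0)
            for _ in range(4)
        ]
        with pytest.raises(np.linalg.LinAlgError):
            fit_ab_from_light_response(recs, reference_photo)


class TestCiResponseAB:
    def test_noiseless_exact_recovery(self, reference_photo, iso_params):
        table, _ = generate_dataset(_ci_design(reference_photo, iso_params))
        res = fit_ab_from_ci_response(_records(table), reference_photo)
        assert res.estimates["a"] == pytest.approx(iso_params.a, rel=1e-9)
        assert res.estimates["b"] == pytest.approx(iso_params.b, rel=1e-9)

    def test_positive_b_gives_negative_slope(self, reference_photo, iso_params):
        table, _ = generate_dataset(_ci_design(reference_photo, iso_params))
        res = fit_ab_from_ci_response(_records(table), reference_photo)
        assert res.estimates["slope"] < 0
        assert res.estimates["b"] == pytest.approx(-res.estimates["slope"])

    def test_cross_design_consistency(self, reference_photo, iso_params):
        # the same leaf measured two ways yields the same coefficients at CV=0
        light, _ = generate_dataset(_light_design(reference_photo, iso_params))
        ci, _ = generate_dataset(_ci_design(reference_photo, iso_params))
        res_l = fit_ab_from_light_response(_records(light), reference_photo)
        res_c = fit_ab_from_ci_response(_records(ci), reference_photo)
        assert res_l.estimates["a"] == pytest.approx(res_c.estimates["a"], rel=1e-8)
        assert res_l.estimates["b"] == pytest.approx(res_c.estimates["b"], rel=1e-8)

    def test_below_compensation_records_excluded(self, reference_photo, iso_params):
        design = replace(_ci_design(reference_photo, iso_params),
                         grid=np.concatenate([[5.0, 20.0], np.linspace(80, 800, 18)]))
        table, _ = generate_dataset(design)
        res = fit_ab_from_ci_response(_records(table), reference_photo)
        assert res.n_obs == 18  # the two sub-compensation points were dropped
        assert res.estimates["a"] == pytest.approx(iso_params.a, rel=1e-9)


class TestPhotoFit:
    def test_noiseless_recovery(self, reference_photo, iso_params):
        table, _ = generate_dataset(_light_design(reference_photo, iso_params))
        res = fit_photo_params(_records(table), PhotoParams(rd25=0.5))
        assert res.estimates["vcmax25"] == pytest.approx(70.0, rel=1e-3)
        assert res.estimates["jmax25"] == pytest.approx(130.0, rel=1e-3)
        assert res.notes["spans_both_regimes"]

    def test_grid_search_oracle(self, reference_photo, iso_params):
        table, _ = generate_dataset(_light_design(reference_photo, iso_params,
                                                  cv=0.05, seed=11))
        recs = _records(table)
        bounds = ((40.0, 110.0), (80.0, 200.0))
        res = fit_photo_params(recs, PhotoParams(rd25=0.5), bounds=bounds)
        from isoflux.fitting import _photo_rss_function

        rss, _ = _photo_rss_function(recs, PhotoParams(rd25=0.5))
        vg = np.linspace(*bounds[0], 200)
        jg = np.linspace(*bounds[1], 200)
        grid_best = min(
            (rss((v, j)), v, j) for v in vg for j in jg
        )
        dv = vg[1] - vg[0]
        dj = jg[1] - jg[0]
        assert res.rss <= grid_best[0] + 1e-9
        assert abs(res.estimates["vcmax25"] - grid_best[1]) <= dv
        assert abs(res.estimates["jmax25"] - grid_best[2]) <= dj

    def test_local_optimality_probe(self, reference_photo, iso_params):
        table, _ = generate_dataset(_light_design(reference_photo, iso_params,
                                                  cv=0.05, seed=7))
        recs = _records(table)
        res = fit_photo_params(recs, PhotoParams(rd25=0.5))
        from isoflux.fitting import _photo_rss_function

        rss, _ = _photo_rss_function(recs, PhotoParams(rd25=0.5))
        v, j = res.estimates["vcmax25"], res.estimates["jmax25"]
        for dv, dj in [(1.1, 1.0), (0.9, 1.0), (1.0, 1.1), (1.0, 0.9)]:
            assert rss((v * dv, j * dj)) > res.rss

    def test_multistart_trace_is_recorded(self, reference_photo, iso_params):
        table, _ = generate_dataset(_light_design(reference_photo, iso_params))
        res = fit_photo_params(_records(table), PhotoParams(rd25=0.5))
        assert len(res.trace) == 5
        assert res.rss <= min(t["rss"] for t in res.trace) + 1e-12


class TestStandardEmission:
    def test_normalizing_by_itself_gives_unity(self, reference_photo, iso_params):
        is_ = standard_emission("energetic", iso_params, reference_photo)
        assert is_ > 0
        assert is_ / is_ == 1.0

    def test_homogeneous_in_ab(self, reference_photo):
        p1 = EnergeticIsoParams(a=0.3, b=0.1)
        p2 = EnergeticIsoParams(a=0.6, b=0.2)
        is1 = standard_emission("energetic", p1, reference_photo)
        is2 = standard_emission("energetic", p2, reference_photo)
        assert is2 == pytest.approx(2 * is1, rel=1e-12)

    def test_normalized_curves_invariant_to_common_scaling(self, reference_photo):
        from isoflux import sweep

        grid = np.arange(100.0, 2000.0, 100.0)
        fixed = LeafEnvironment(1000.0, 30.0, 273.0)
        c1 = sweep("par", grid, fixed, reference_photo,
                   {"energetic": EnergeticIsoParams(a=0.3, b=0.1)}, normalize=True)
        c2 = sweep("par", grid, fixed, reference_photo,
                   {"energetic": EnergeticIsoParams(a=0.6, b=0.2)}, normalize=True)
        assert np.allclose(c1.data["iso_energetic_norm"],
                           c2.data["iso_energetic_norm"], rtol=1e-12)

    def test_g93_standard_condition(self, reference_photo):
        p = G93Params(i_s=30.0)
        is_ = standard_emission("g93", p, reference_photo)
        assert is_ > 0

    def test_unknown_model_rejected(self, reference_photo, iso_params):
        with pytest.raises(ValueError, match="unknown model"):
            standard_emission("megan", iso_params, reference_photo)
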