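import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from shapely.geometry import LineString, Point

from fernfusion import (CovariateStandardizer, distance_surface,
                        extrapolate_climate, filter_occurrences,
                        generate_domain, gvif, ilr_inverse, ilr_transform,
                        rao_q, select_covariates, standardize)


# --- Rao's Q ----------------------------------------------------------------

class TestRaoQ:
    def test_equal_values_give_zero(self):
        assert rao_q([5, 5, 5], [1 / 3] * 3) == 0.0

    def test_two_class_closed_form(self):
        # two classes one meter apart, equal weight: 2 * 0.25 * 1 = 0.5
        assert rao_q([3, 4], [0.5, 0.5]) == pytest.approx(0.5, abs=1e-15)

    def test_matches_double_sum_oracle(self):
        rng = np.random.default_rng(42)
        v = rng.integers(0, 30, 12).astype(float)
        p = rng.dirichlet(np.ones(12))
        brute = sum(abs(v[i] - v[j]) * p[i] * p[j]
                    for i in range(12) for j in range(12))
        assert rao_q(v, p) == pytest.approx(brute, abs=1e-12)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.permutations(list(range(6))))
    def test_permutation_invariant(self, perm):
        v = np.array([1.0, 4.0, 2.0, 9.0, 3.0, 7.0])
        p = np.array([0.1, 0.2, 0.25, 0.05, 0.15, 0.25])
        idx = np.array(perm)
        assert rao_q(v[idx], p[idx]) == pytest.approx(rao_q(v, p), abs=1e-12)

    def test_rejects_mismatched_lengths(self):
        with pytest.raises(ValueError):
            rao_q([1, 2, 3], [0.5, 0.5])


# --- ILR --------------------------------------------------------------------

class TestILR:
    def test_barycenter_maps_to_zero(self):
        assert np.allclose(ilr_transform([0.25] * 4), 0.0, atol=1e-14)

    def test_scale_invariance(self):
        x = np.array([0.1, 0.4, 0.2, 0.3])
        assert np.allclose(ilr_transform(x), ilr_transform(7.3 * x),
                           atol=1e-12)

    def test_round_trip(self):
        rng = np.random.default_rng(0)
        x = rng.dirichlet(np.ones(5), size=20)
        back = ilr_inverse(ilr_transform(x))
        assert np.allclose(back, x, atol=1e-12)

    def test_matches_skbio_oracle(self):
        from skbio.stats.composition import ilr as skbio_ilr
        rng = np.random.default_rng(1)
        x = rng.dirichlet(np.ones(4), size=10)
        ours = np.abs(np.sort(np.abs(ilr_transform(x)), axis=1))
        # bases may differ by orthogonal rotation/sign; compare norms exactly
        theirs = skbio_ilr(x)
        assert np.allclose(np.linalg.norm(ours, axis=1),
                           np.linalg.norm(theirs, axis=1), atol=1e-10)

    def test_zero_parts_rejected_with_guidance(self):
        with pytest.raises(ValueError, match="zero-replacement"):
            ilr_transform([0.5, 0.5, 0.0])


# --- collinearity screening -------------------------------------------------

class TestSelectCovariates:
    def test_duplicate_keeps_one(self):
        rng = np.random.default_rng(2)
        a = rng.standard_normal(50)
        t = pd.DataFrame({"a": a, "b": a.copy(), "c": rng.standard_normal(50)})
        kept, diag = select_covariates(t)
        assert sorted(kept) in (["a", "c"], ["b", "c"])
        assert len(kept) == 2

    def test_orthogonal_all_kept_unit_gvif(self):
        n = 64
        t = pd.DataFrame({
            "x1": np.tile([1.0, -1.0], n // 2),
            "x2": np.repeat([1.0, -1.0], n // 2),
            "x3": np.concatenate([np.tile([1.0, -1.0], n // 4),
                                  np.tile([-1.0, 1.0], n // 4)]),
        })
        kept, diag = select_covariates(t)
        assert kept == ["x1", "x2", "x3"]
        assert np.allclose(gvif(t), 1.0, atol=1e-10)

    def test_correlated_triple_matches_subset_oracle(self):
        rng = np.random.default_rng(3)
        a = rng.standard_normal(200)
        b = 0.75 * a + np.sqrt(1 - 0.75 ** 2) * rng.standard_normal(200)
        c = rng.standard_normal(200)
        t = pd.DataFrame({"a": a, "b": b, "c": c})
        abundance = a + 0.1 * rng.standard_normal(200)
        kept, _ = select_covariates(t, abundance=abundance)
        # brute force: the largest subset with all |r| <= 0.7 that keeps the
        # member more correlated with abundance
        from itertools import combinations
        best = None
        for k in (3, 2, 1):
            for sub in combinations(t.columns, k):
                R = t[list(sub)].corr().abs().to_numpy()
                np.fill_diagonal(R, 0)
                if R.max() <= 0.7:
                    score = max(abs(np.corrcoef(t[c_], abundance)[0, 1])
                                for c_ in sub)
                    if best is None or (len(sub) > len(best[0])) or \
                       (len(sub) == len(best[0]) and score > best[1]):
                        best = (sub, score)
            if best:
                break
        assert set(kept) == set(best[0])

    def test_constant_column_flagged(self):
        t = pd.DataFrame({"a": np.arange(10.0), "b": np.ones(10),
                          "c": np.arange(10.0)[::-1]})
        kept, diag = select_covariates(t)
        assert "b" in diag["constant"]
        assert "b" not in kept

    def test_order_invariance(self):
        rng = np.random.default_rng(4)
        t = pd.DataFrame(rng.standard_normal((100, 4)),
                         columns=list("abcd"))
        t["e"] = 0.9 * t["a"] + 0.1 * rng.standard_normal(100)
        kept1, _ = select_covariates(t)
        kept2, _ = select_covariates(t[["e", "d", "c", "b", "a"]])
        assert set(kept1) == set(kept2)


# --- standardization --------------------------------------------------------

class TestStandardize:
    def test_zero_mean_unit_sd_and_round_trip(self):
        rng = np.random.default_rng(5)
        t = pd.DataFrame({"a": rng.normal(3, 2, 40),
                          "b": rng.normal(-1, 0.5, 40)})
        z, st_ = standardize(t)
        assert np.allclose(z.mean(), 0.0, atol=1e-9)
        assert np.allclose(z.std(ddof=0), 1.0, atol=1e-9)
        assert np.allclose(st_.inverse_transform(z), t, atol=1e-12)

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            CovariateStandardizer().fit(pd.DataFrame({"a": np.ones(5)}))


# --- climate extrapolation --------------------------------------------------

class TestExtrapolateClimate:
    series = pd.Series([1, 2, 3, 4, 5, 6], index=range(2014, 2020))

    def test_linear_extends_exact_line(self):
        out = extrapolate_climate(self.series, [2020], method="linear")
        assert out.loc[2020] == pytest.approx(7.0)

    def test_last_year_repeats_final_value(self):
        out = extrapolate_climate(self.series, range(2020, 2024),
                                  method="last_year")
        assert (out == 6.0).all()

    def test_mean_repeats_average(self):
        out = extrapolate_climate(self.series, range(2020, 2024),
                                  method="mean")
        assert np.allclose(out, 3.5)

    def test_single_year_linear_rejected(self):
        with pytest.raises(ValueError):
            extrapolate_climate(pd.Series([1.0], index=[2014]), [2015],
                                method="linear")


# --- distance surfaces ------------------------------------------------------

class TestDistanceSurface:
    def test_point_feature_pythagoras(self):
        d = generate_domain(0, 200, 100, 2)
        # centroid (150, 150); feature at (150-30, 150-40) -> distance 50
        out = distance_surface([Point(120.0, 110.0)], d)
        assert out[3] == pytest.approx(50.0)

    def test_centroid_on_feature_zero(self):
        d = generate_domain(0, 200, 100, 2)
        line = LineString([(0, 50), (200, 50)])
        assert distance_surface([line], d)[0] == pytest.approx(0.0)

    def test_matches_brute_force_segment_oracle(self):
        rng = np.random.default_rng(6)
        d = generate_domain(0, 500, 100, 2)
        segs = [LineString(rng.uniform(0, 500, (2, 2))) for _ in range(3)]
        out = distance_surface(segs, d)

        def seg_dist(p, a, b):
            ab = b - a
            t = np.clip(np.dot(p - a, ab) / np.dot(ab, ab), 0, 1)
            return np.linalg.norm(p - (a + t * ab))

        for i, c in enumerate(d.centroids):
            brute = min(seg_dist(c, np.array(s.coords[0]),
                                 np.array(s.coords[1])) for s in segs)
            assert out[i] == pytest.approx(brute, abs=1e-9)

    def test_log_floor_avoids_log_zero(self):
        d = generate_domain(0, 200, 100, 2)
        line = LineString([(50, 50), (150, 50)])
        out = distance_surface([line], d, log=True)
        assert np.isfinite(out).all()
        assert out[0] == pytest.approx(np.log(50.0))  # floor = cell/2

    def test_empty_features_rejected(self):
        d = generate_domain(0, 200, 100, 2)
        with pytest.raises(ValueError):
            distance_surface([], d)


# --- occurrence filters -----------------------------------------------------

def _records():
    rows = []
    # 8 clean records (one with absent uncertainty metadata)
    for i in range(8):
        rows.append({"longitude": -5.5 + i * 0.01, "latitude": 36.2,
                     "basis_of_record": "HUMAN_OBSERVATION",
                     "coordinate_uncertainty_m": 200.0 if i else np.nan,
                     "coordinate_resolution_deg": 0.0001})
    # 3 invalid coordinates
    for _ in range(3):
        rows.append({"longitude": np.nan, "latitude": 36.2,
                     "basis_of_record": "HUMAN_OBSERVATION",
                     "coordinate_uncertainty_m": 100.0,
                     "coordinate_resolution_deg": 0.0001})
    # 2 fossils
    for _ in range(2):
        rows.append({"longitude": -5.5, "latitude": 36.2,
                     "basis_of_record": "FOSSIL_SPECIMEN",
                     "coordinate_uncertainty_m": 100.0,
                     "coordinate_resolution_deg": 0.0001})
    # 3 placeholder uncertainties
    for u in (301.0, 3036.0, 9999.0):
        rows.append({"longitude": -5.5, "latitude": 36.2,
                     "basis_of_record": "HUMAN_OBSERVATION",
                     "coordinate_uncertainty_m": u,
                     "coordinate_resolution_deg": 0.0001})
    # 2 coarse resolution
    for _ in range(2):
        rows.append({"longitude": -5.5, "latitude": 36.2,
                     "basis_of_record": "HUMAN_OBSERVATION",
                     "coordinate_uncertainty_m": 100.0,
                     "coordinate_resolution_deg": 0.05})
    # 2 uncertainty above 1000 m
    for _ in range(2):
        rows.append({"longitude": -5.5, "latitude": 36.2,
                     "basis_of_record": "HUMAN_OBSERVATION",
                     "coordinate_uncertainty_m": 2500.0,
                     "coordinate_resolution_deg": 0.0001})
    return pd.DataFrame(rows)


class TestFilterOccurrences:
    def test_enumerated_batch(self):
        recs = _records()
        kept, counts = filter_occurrences(recs)
        assert len(kept) == 8
        assert counts == {"invalid_coordinates": 3, "basis_of_record": 2,
                          "placeholder_uncertainty": 3,
                          "coarse_resolution": 2, "uncertainty_above_max": 2}

    def test_rejections_sum_to_removed(self):
        recs = _records()
        kept, counts = filter_occurrences(recs)
        assert sum(counts.values()) == len(recs) - len(kept)

    def test_placeholder_9999_rejected(self):
        rec = pd.DataFrame([{"longitude": 1.0, "latitude": 1.0,
                             "coordinate_uncertainty_m": 9999.0}])
        kept, counts = filter_occurrences(rec)
        assert len(kept) == 0 and counts["placeholder_uncertainty"] == 1

    def test_absent_uncertainty_retained(self):
        rec = pd.DataFrame([{"longitude": 1.0, "latitude": 1.0,
                             "coordinate_uncertainty_m": np.nan}])
        kept, _ = filter_occurrences(rec)
        assert len(kept) == 1
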