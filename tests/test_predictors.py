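import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from kinscape import (
    AssociationLookup,
    SampleTable,
    ValidationError,
    combined_environment_distance,
    community_distance,
    geographic_distances,
    kinship_matrix,
    per_variable_distances,
    standardize_predictors,
    vif_screen,
    wind_exposure,
)
from kinscape.model_averaging import unfold
from kinscape.predictors import PredictorSet


def _samples(n, rng, n_env=3):
    return SampleTable(pd.DataFrame({
        "id": [f"i{k}" for k in range(n)],
        "lon": rng.uniform(-1, 1, n),
        "lat": rng.uniform(-1, 1, n),
        "association": rng.choice(["u", "v"], n),
        **{f"e{j}": rng.normal(size=n) for j in range(n_env)},
    }))


class TestGeographicDistances:
    def test_one_degree_of_latitude(self):
        st_ = SampleTable(pd.DataFrame({
            "id": ["a", "b"], "lon": [0.0, 0.0], "lat": [0.0, 1.0],
            "association": ["x", "x"],
        }))
        d = geographic_distances(st_).values
        assert d[1, 0] == pytest.approx(111194.93, abs=0.01)
        assert d[0, 0] == 0.0

    def test_symmetry_and_zero_diagonal(self):
        rng = np.random.default_rng(2)
        d = geographic_distances(_samples(8, rng)).values
        np.testing.assert_array_equal(d, d.T)
        np.testing.assert_array_equal(np.diag(d), 0.0)

    def test_planar_approximation_close_at_small_extent(self):
        rng = np.random.default_rng(3)
        s = _samples(6, rng)
        s.data["lon"] = s.data["lon"] * 0.01
        s.data["lat"] = s.data["lat"] * 0.01
        dh = geographic_distances(s, method="haversine").values
        de = geographic_distances(s, method="euclidean").values
        off = np.tril_indices(6, -1)
        np.testing.assert_allclose(dh[off], de[off], rtol=1e-3)


class TestWindExposure:
    def test_southwest_aspect_scores_zero(self):
        assert wind_exposure(225.0) == pytest.approx(0.0)

    def test_northeast_aspect_scores_180(self):
        assert wind_exposure(45.0) == pytest.approx(180.0)

    def test_perpendicular_aspect_scores_90(self):
        assert wind_exposure(135.0) == pytest.approx(90.0)
        assert wind_exposure(315.0) == pytest.approx(90.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            wind_exposure(360.0)

    @given(st.floats(min_value=0, max_value=359.999))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_bounded_and_symmetric_about_northeast(self, a):
        e = wind_exposure(a)
        assert 0.0 <= e <= 180.0
        mirror = (90.0 - a) % 360.0  # reflection through the 45-degree axis
        assert wind_exposure(mirror) == pytest.approx(e, abs=1e-9)


class TestPerVariableDistances:
    def test_absolute_difference(self):
        s = SampleTable(pd.DataFrame({
            "id": ["a", "b"], "lon": [0, 0], "lat": [0, 0],
            "association": ["x", "x"], "altitude": [100.0, 350.0],
        }))
        d = per_variable_distances(s).matrices["altitude"].values
        assert d[1, 0] == 250.0

    def test_missing_value_names_individual(self):
        s = SampleTable(pd.DataFrame({
            "id": ["a", "b"], "lon": [0, 0], "lat": [0, 0],
            "association": ["x", "x"], "altitude": [100.0, np.nan],
        }))
        with pytest.raises(ValidationError, match="altitude.*'b'"):
            per_variable_distances(s)


class TestCombinedEnvironmentDistance:
    def test_equals_euclidean_on_standardized_table(self):
        rng = np.random.default_rng(4)
        for trial in range(20):
            s = _samples(rng.integers(5, 15), rng, n_env=int(rng.integers(2, 6)))
            d = combined_environment_distance(s).values
            z = s.env.to_numpy()
            z = (z - z.mean(0)) / z.std(0, ddof=1)
            direct = np.sqrt(((z[:, None, :] - z[None, :, :]) ** 2).sum(-1))
            np.testing.assert_allclose(d, direct, atol=1e-10)

    def test_identical_environments_give_zero(self):
        s = SampleTable(pd.DataFrame({
            "id": ["a", "b", "c"], "lon": [0, 0, 0], "lat": [0, 0, 0],
            "association": ["x"] * 3,
            "e1": [0.0, 3.0, 0.0], "e2": [0.0, 4.0, 0.0],
        }))
        d = combined_environment_distance(s).values
        assert d[2, 0] == pytest.approx(0.0, abs=1e-12)
        assert d[1, 0] == pytest.approx(d[2, 1], abs=1e-12)
        # 3-4-5 structure: scaling by the column sds, distances stay equal
        assert d[1, 0] > 0

    def test_zero_variance_variable_rejected(self):
        s = SampleTable(pd.DataFrame({
            "id": ["a", "b"], "lon": [0, 0], "lat": [0, 0],
            "association": ["x", "x"], "e1": [1.0, 1.0], "e2": [0.0, 1.0],
        }))
        with pytest.raises(ValidationError, match="zero-variance"):
            combined_environment_distance(s)


class TestCommunityDistance:
    LOOKUP = AssociationLookup({
        "u": {"A", "B", "C"}, "v": {"B", "C", "D"}, "w": {"X", "Y"},
    })

    def _samples_with(self, assocs):
        n = len(assocs)
        return SampleTable(pd.DataFrame({
            "id": [f"i{k}" for k in range(n)], "lon": [0.0] * n,
            "lat": [0.0] * n, "association": assocs,
        }))

    def test_jaccard_values(self):
        d = community_distance(self._samples_with(["u", "u", "v", "w"]), self.LOOKUP).values
        assert d[1, 0] == 0.0                      # same association
        assert d[2, 0] == pytest.approx(0.5)       # 1 - 2/4
        assert d[3, 0] == 1.0                      # disjoint species sets

    def test_triangle_inequality_over_association_triples(self):
        d = community_distance(self._samples_with(["u", "v", "w"]), self.LOOKUP).values
        for i in range(3):
            for j in range(3):
                for k in range(3):
                    assert d[i, j] <= d[i, k] + d[k, j] + 1e-12

    def test_unknown_association_rejected(self):
        with pytest.raises(ValidationError, match="zzz"):
            community_distance(self._samples_with(["u", "zzz"]), self.LOOKUP)


class TestStandardize:
    def _setup(self, n=8, seed=0):
        rng = np.random.default_rng(seed)
        s = _samples(n, rng)
        pset = per_variable_distances(s)
        vals = rng.integers(0, 2, size=(n, 60)).astype(float)
        from kinscape import GenotypeMatrix
        from kinscape.io_formats import drop_monomorphic
        gm, _ = drop_monomorphic(GenotypeMatrix(s.ids, [f"L{k}" for k in range(60)], vals))
        K = kinship_matrix(gm)
        return pset, K

    def test_unit_scale_and_idempotence(self):
        pset, K = self._setup()
        vectors, y, pset2 = standardize_predictors(pset, K)
        for v in vectors.values():
            assert abs(v.mean()) < 1e-12
            assert v.std(ddof=1) == pytest.approx(1.0)
        assert abs(y.mean()) < 1e-12 and y.std(ddof=1) == pytest.approx(1.0)
        assert pset2.standardized
        # standardizing an already standardized vector changes nothing
        v = vectors["e0"]
        np.testing.assert_allclose((v - v.mean()) / v.std(ddof=1), v, atol=1e-12)

    def test_constant_predictor_rejected(self):
        pset, K = self._setup()
        const = pset.matrices["e0"]
        const.values[:] = 0.0
        with pytest.raises(ValidationError, match="e0"):
            standardize_predictors(pset, K)


class TestVifScreen:
    def test_orthogonal_predictors_all_kept(self):
        rng = np.random.default_rng(0)
        q, _ = np.linalg.qr(rng.standard_normal((50, 3)))
        vectors = {f"x{j}": q[:, j] for j in range(3)}
        kept, removed = vif_screen(vectors)
        assert list(kept) == ["x0", "x1", "x2"] and removed == {}

    def test_duplicated_predictor_removes_later_copy(self):
        rng = np.random.default_rng(1)
        v = rng.standard_normal(40)
        w = rng.standard_normal(40)
        kept, removed = vif_screen({"a": v, "b": w, "a_copy": v.copy()})
        assert "a_copy" in removed and list(kept) == ["a", "b"]
        assert len(removed) == 1

    def test_correlation_point_nine_crosses_threshold_five(self):
        # r = 0.9 -> VIF = 1/(1-0.81) = 5.263 > 5 -> one of two removed
        rng = np.random.default_rng(2)
        x = rng.standard_normal(5000)
        y = 0.9 * x + np.sqrt(1 - 0.81) * rng.standard_normal(5000)
        x = (x - x.mean()) / x.std(ddof=1)
        y = (y - y.mean()) / y.std(ddof=1)
        r = float(x @ y / (len(x) - 1))
        assert abs(r - 0.9) < 0.02
        kept, removed = vif_screen({"x": x, "y": y}, threshold=5.0)
        assert len(kept) == 1 and len(removed) == 1
        assert next(iter(removed.values())) == pytest.approx(1 / (1 - r**2), rel=1e-6)

    def test_single_predictor_never_removed(self):
        rng = np.random.default_rng(3)
        kept, removed = vif_screen({"only": rng.standard_normal(30)})
        assert list(kept) == ["only"] and removed == {}


class TestPredictorSet:
    def test_mismatched_ids_rejected(self):
        rng = np.random.default_rng(0)
        a = geographic_distances(_samples(4, rng))
        b = geographic_distances(_samples(4, np.random.default_rng(1)))
        b.individual_ids = ["x1", "x2", "x3", "x4"]
        with pytest.raises(ValidationError, match="different individual order"):
            PredictorSet({"a": a, "b": b})
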