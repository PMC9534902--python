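"""Feature assembly, z-scoring, Euclidean RSA distance, matrix IO."""

import math

import numpy as np
import pandas as pd
import pytest

from rsaphylo import (
    DistanceMatrix,
    FeatureVector,
    build_features,
    pairwise_distance,
    scale_features,
)
from rsaphylo.distance import DistanceError, features_frame
from rsaphylo.models import PLNParams, RSAFit


def _fit(mu=-3.0, sigma2=4.0, converged=True, model="PLN"):
    return RSAFit(
        model=model, params=PLNParams(mu, sigma2), loglik=-10.0, aic=24.0,
        r2=0.95, n_species=100, converged=converged,
    )


class TestBuildFeatures:
    def test_complete_inputs(self):
        fits = {g: _fit() for g in ("a", "b", "c")}
        dens = {g: 0.001 for g in ("a", "b", "c")}
        feats, dropped = build_features(fits, dens)
        assert len(feats) == 3 and dropped == []

    def test_missing_density_dropped_with_reason(self):
        fits = {g: _fit() for g in ("a", "b", "c")}
        feats, dropped = build_features(fits, {"a": 0.001, "b": 0.001})
        assert len(feats) == 2
        assert dropped == [("c", "no density")]

    def test_nonconverged_fit_dropped(self):
        fits = {"a": _fit(), "b": _fit(converged=False)}
        feats, dropped = build_features(fits, {"a": 0.001, "b": 0.001})
        assert [f.genome_id for f in feats] == ["a"]
        assert dropped[0][0] == "b"

    def test_sigma_is_sqrt_of_sigma2(self):
        feats, _ = build_features({"a": _fit(sigma2=4.0)}, {"a": 0.001})
        assert feats[0].sigma == 2.0

    def test_empty_intersection_errors(self):
        with pytest.raises(DistanceError):
            build_features({"a": _fit(converged=False)}, {"a": 0.001})


class TestScaleFeatures:
    def _features(self, n=5, seed=0):
        rng = np.random.default_rng(seed)
        return [
            FeatureVector(f"g{i}", rng.normal(-3, 1), rng.uniform(1, 3),
                          rng.uniform(1e-4, 1e-3))
            for i in range(n)
        ]

    def test_zero_mean_unit_sd(self):
        scaled, _ = scale_features(self._features())
        np.testing.assert_allclose(scaled.mean(), 0.0, atol=1e-12)
        np.testing.assert_allclose(scaled.std(ddof=1), 1.0, atol=1e-12)

    def test_two_genomes_symmetric(self):
        scaled, _ = scale_features(self._features(n=2))
        # with the n-1 sd convention two points scale to +/- 1/sqrt(2)
        np.testing.assert_allclose(np.abs(scaled.to_numpy()),
                                   math.sqrt(0.5), atol=1e-12)

    def test_scaling_constants_round_trip(self):
        feats = self._features()
        scaled, scaling = scale_features(feats)
        again = scaling.apply(features_frame(feats))
        pd.testing.assert_frame_equal(scaled, again)

    def test_zero_variance_dimension_named(self):
        feats = [FeatureVector(f"g{i}", -3.0, 2.0, 1e-3 * (i + 1)) for i in range(4)]
        with pytest.raises(DistanceError, match="mu"):
            scale_features(feats)


class TestPairwiseDistance:
    def test_identical_rows_zero(self):
        df = pd.DataFrame([[1.0, 2.0, 3.0]] * 2, index=["a", "b"])
        dm = pairwise_distance(df)
        assert dm.values[0, 1] == 0.0

    def test_hand_computed_345(self):
        df = pd.DataFrame([[0.0, 0.0, 0.0], [1.0, 2.0, 2.0]], index=["a", "b"])
        assert pairwise_distance(df).values[0, 1] == pytest.approx(3.0)

    def test_metric_axioms_on_random_input(self):
        rng = np.random.default_rng(42)
        df = pd.DataFrame(rng.normal(size=(8, 3)), index=[f"g{i}" for i in range(8)])
        dm = pairwise_distance(df)
        v = dm.values
        assert np.allclose(v, v.T) and np.all(np.diag(v) == 0) and np.all(v >= 0)
        for i in range(8):
            for j in range(8):
                for k in range(8):
                    assert v[i, j] <= v[i, k] + v[k, j] + 1e-12

    def test_scale_invariance_of_final_distances(self):
        """Multiplying a raw feature column by a constant changes nothing
        after z-scoring."""
        rng = np.random.default_rng(3)
        feats = [
            FeatureVector(f"g{i}", rng.normal(-3, 1), rng.uniform(1, 3),
                          rng.uniform(1e-4, 1e-3))
            for i in range(6)
        ]
        scaled1, _ = scale_features(feats)
        boosted = [
            FeatureVector(f.genome_id, f.mu, f.sigma, 1000.0 * f.density)
            for f in feats
        ]
        scaled2, _ = scale_features(boosted)
        d1 = pairwise_distance(scaled1).values
        d2 = pairwise_distance(scaled2).values
        np.testing.assert_allclose(d1, d2, atol=1e-9)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(rng.normal(size=(5, 3)), index=list("abcde"))
        dm = pairwise_distance(df)
        perm = ["c", "a", "e", "b", "d"]
        dm_p = pairwise_distance(df.loc[perm])
        sub = dm.subset(perm)
        np.testing.assert_allclose(dm_p.values, sub.values, atol=1e-12)


class TestDistanceMatrixIO:
    def _dm(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(4, 3))
        d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        return DistanceMatrix(list("wxyz"), d)

    def test_phylip_square_round_trip(self, tmp_path):
        dm = self._dm()
        path = tmp_path / "m.dist"
        dm.to_phylip(path)
        back = DistanceMatrix.from_phylip(path)
        assert back.ids == dm.ids
        np.testing.assert_allclose(back.values, dm.values, atol=1e-9)

    def test_phylip_lower_triangle(self, tmp_path):
        dm = self._dm()
        path = tmp_path / "m.dist"
        with open(path, "w") as fh:
            fh.write("4\n")
            for i, gid in enumerate(dm.ids):
                row = "\t".join(f"{v:.10g}" for v in dm.values[i, :i])
                fh.write(f"{gid}\t{row}\n" if row else f"{gid}\n")
        back = DistanceMatrix.from_phylip(path)
        np.testing.assert_allclose(back.values, dm.values, atol=1e-9)

    def test_long_tsv(self, tmp_path):
        dm = self._dm()
        path = tmp_path / "m.tsv"
        dm.to_tsv(path)
        df = pd.read_csv(path, sep="\t")
        assert len(df) == 6  # upper triangle of 4x4
        row = df[(df.id1 == "w") & (df.id2 == "x")].iloc[0]
        assert row.distance == pytest.approx(dm.values[0, 1])

    @pytest.mark.parametrize(
        "mutate",
        [
            lambda v: v + np.diag([1.0, 0, 0, 0]),          # nonzero diagonal
            lambda v: np.triu(v) * 2 - np.triu(v).T + v * 0,  # asymmetry
        ],
    )
    def test_invalid_matrices_rejected(self, mutate):
        dm = self._dm()
        with pytest.raises(DistanceError):
            DistanceMatrix(dm.ids, mutate(dm.values))
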