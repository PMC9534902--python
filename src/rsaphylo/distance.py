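"""The RSA model-based distance between genomes.

Each genome is a point in the 3D space (mu, sigma, density): the fitted
Poisson Log-Normal location and standard deviation of log abundance,
plus the protein-domain density (domain instances per bp).  Each
dimension is z-scored across genomes and the distance is plain Euclidean
in the scaled space, so the triangle inequality holds by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .models import RSAFit

FEATURE_COLUMNS = ("mu", "sigma", "density")


class DistanceError(ValueError):
    pass


@dataclass(frozen=True)
class FeatureVector:
    """A genome's coordinates in RSA space."""

    genome_id: str
    mu: float
    sigma: float
    density: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise DistanceError(f"{self.genome_id}: sigma must be > 0")
        if self.density <= 0:
            raise DistanceError(f"{self.genome_id}: density must be > 0")


@dataclass(frozen=True)
class FeatureScaling:
    """Column means/sds used for z-scoring (n-1 denominator)."""

    mean: tuple[float, float, float]
    std: tuple[float, float, float]

    def apply(self, raw: pd.DataFrame) -> pd.DataFrame:
        return (raw[list(FEATURE_COLUMNS)] - np.array(self.mean)) / np.array(self.std)


class DistanceMatrix:
    """Symmetric non-negative distance matrix with zero diagonal."""

    def __init__(self, ids: Sequence[str], values: np.ndarray):
        values = np.asarray(values, dtype=float)
        n = len(ids)
        if values.shape != (n, n):
            raise DistanceError(f"matrix shape {values.shape} does not match {n} ids")
        if len(set(ids)) != n:
            raise DistanceError("duplicate ids in distance matrix")
        if np.any(~np.isfinite(values)):
            raise DistanceError("non-finite distances")
        if not np.allclose(values, values.T, atol=1e-12):
            raise DistanceError("distance matrix is not symmetric")
        if np.any(np.abs(np.diag(values)) > 1e-12):
            raise DistanceError("nonzero diagonal")
        if np.any(values < -1e-12):
            raise DistanceError("negative distances")
        vals = np.clip((values + values.T) / 2.0, 0.0, None)
        np.fill_diagonal(vals, 0.0)
        self.ids = list(ids)
        self.values = vals

    def __len__(self) -> int:
        return len(self.ids)

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)

    def subset(self, ids: Sequence[str]) -> "DistanceMatrix":
        idx = [self.ids.index(i) for i in ids]
        return DistanceMatrix(list(ids), self.values[np.ix_(idx, idx)])

    # --- IO -------------------------------------------------------------
    def to_phylip(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.ids)}\n")
            for gid, row in zip(self.ids, self.values):
                fh.write(gid + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")

    @classmethod
    def from_phylip(cls, path: str | Path) -> "DistanceMatrix":
        with open(path) as fh:
            n = int(fh.readline().split()[0])
            ids, rows = [], []
            for _ in range(n):
                parts = fh.readline().split()
                ids.append(parts[0])
                vals = [float(v) for v in parts[1:]]
                rows.append(vals)
        m = np.zeros((n, n))
        for i, vals in enumerate(rows):
            if len(vals) == n:            # square
                m[i, :] = vals
            elif len(vals) == i:          # lower triangle
                m[i, :i] = vals
                m[:i, i] = vals
            else:
                raise DistanceError(f"{path}: row {ids[i]} has {len(vals)} values")
        return cls(ids, m)

    def to_tsv(self, path: str | Path) -> None:
        """Long format: id1, id2, distance (upper triangle)."""
        rows = []
        for i, a in enumerate(self.ids):
            for j in range(i + 1, len(self.ids)):
                rows.append((a, self.ids[j], self.values[i, j]))
        pd.DataFrame(rows, columns=["id1", "id2", "distance"]).to_csv(
            path, sep="\t", index=False
        )


def build_features(
    fits: Mapping[str, RSAFit], densities: Mapping[str, float]
) -> tuple[list[FeatureVector], list[tuple[str, str]]]:
    """Assemble (mu, sigma, density) per genome from converged PLN fits.

    sigma is the square root of the fitted sigma^2.  Genomes missing a
    converged PLN fit or a density are returned in the dropped list with
    a reason, so downstream comparisons can use the identical genome set.
    """
    features: list[FeatureVector] = []
    dropped: list[tuple[str, str]] = []
    for gid in list(fits) + [g for g in densities if g not in fits]:
        fit = fits.get(gid)
        if fit is None:
            dropped.append((gid, "no PLN fit"))
            continue
        if fit.model != "PLN" or not fit.converged:
            dropped.append((gid, "no converged PLN fit"))
            continue
        if gid not in densities:
            dropped.append((gid, "no density"))
            continue
        features.append(
            FeatureVector(
                genome_id=gid, mu=fit.params.mu,
                sigma=math.sqrt(fit.params.sigma2), density=densities[gid],
            )
        )
    if not features:
        raise DistanceError("no genome has both a converged PLN fit and a density")
    return features, dropped


def features_frame(features: Sequence[FeatureVector]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "mu": [f.mu for f in features],
            "sigma": [f.sigma for f in features],
            "density": [f.density for f in features],
        },
        index=[f.genome_id for f in features],
    )


def scale_features(
    features: Sequence[FeatureVector] | pd.DataFrame,
) -> tuple[pd.DataFrame, FeatureScaling]:
    """Z-score each feature column (mean 0, sd 1; n-1 denominator)."""
    raw = features if isinstance(features, pd.DataFrame) else features_frame(features)
    if len(raw) < 2:
        raise DistanceError("need at least 2 genomes to scale features")
    mean = raw[list(FEATURE_COLUMNS)].mean()
    std = raw[list(FEATURE_COLUMNS)].std(ddof=1)
    for col in FEATURE_COLUMNS:
        if std[col] == 0 or not np.isfinite(std[col]):
            raise DistanceError(f"zero variance in feature {col!r}; cannot z-score")
    scaling = FeatureScaling(mean=tuple(mean), std=tuple(std))
    return scaling.apply(raw), scaling


def pairwise_distance(scaled: pd.DataFrame) -> DistanceMatrix:
    """Euclidean distances between rows of the scaled 3-column table."""
    if scaled.shape[1] != 3:
        raise DistanceError(f"expected 3 feature columns, got {scaled.shape[1]}")
    d = squareform(pdist(scaled.to_numpy(), metric="euclidean"))
    return DistanceMatrix(list(scaled.index), d)


def rsa_distance_matrix(
    fits: Mapping[str, RSAFit], densities: Mapping[str, float]
) -> tuple[DistanceMatrix, list[tuple[str, str]]]:
    """build_features -> scale_features -> pairwise_distance in one call."""
    features, dropped = build_features(fits, densities)
    scaled, _ = scale_features(features)
    return pairwise_distance(scaled), dropped
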