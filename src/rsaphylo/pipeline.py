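"""End-to-end RSA phylogeny: model object over (matrix, metadata).

`RSAPhylogeny` is the front door of the package: construct it from a
domain-count matrix and genome metadata, call `fit()` to run per-genome
zero-truncated MLE fits, AIC model selection, feature assembly and the
scaled 3D Euclidean distance.  The returned `RSAPhylogenyResults` holds
the per-genome fit table, the distance matrix, dendrograms under either
linkage, and a text `summary()`.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import compare, distance, models, profiles


class RSAPhylogeny:
    """RSA model-based phylogeny of a set of genomes."""

    def __init__(
        self,
        matrix: profiles.DomainMatrix,
        records: Sequence[profiles.GenomeRecord],
        min_species: int = 10,
        nodes: int = 801,
    ):
        self.matrix = matrix
        self.records = {r.genome_id: r for r in records}
        missing = [g for g in matrix.genome_ids if g not in self.records]
        if missing:
            raise profiles.ProfileError(
                f"{len(missing)} genome(s) lack metadata, e.g. {missing[:3]}"
            )
        self.min_species = min_species
        self.nodes = nodes

    @classmethod
    def from_files(
        cls, matrix_path: str | Path, metadata_path: str | Path, **kw
    ) -> "RSAPhylogeny":
        return cls(
            profiles.read_domain_matrix(matrix_path),
            profiles.read_metadata(metadata_path),
            **kw,
        )

    def fit(
        self,
        candidate_models: Sequence[str] = models.MODEL_ORDER,
        compute_se: bool = False,
    ) -> "RSAPhylogenyResults":
        """Fit candidate RSA models per genome and build the RSA distance."""
        rows = []
        pln_fits: dict[str, models.RSAFit] = {}
        densities: dict[str, float] = {}
        excluded: list[tuple[str, str]] = []
        for gid in self.matrix.genome_ids:
            try:
                rsa = profiles.compute_rsa(self.matrix, gid)
            except profiles.ProfileError as exc:
                excluded.append((gid, str(exc)))
                continue
            try:
                fits = models.fit_all(
                    rsa, candidate_models, min_species=self.min_species,
                    nodes=self.nodes, compute_se=compute_se,
                )
            except models.UnfittableRSAError as exc:
                excluded.append((gid, str(exc)))
                continue
            try:
                best = models.select_model(fits)
            except models.ModelError as exc:
                excluded.append((gid, str(exc)))
                continue
            row: dict[str, object] = {
                "genome_id": gid,
                "selected": best.model,
                "S": rsa.n_species,
                "N": rsa.n_individuals,
            }
            for f in fits:
                row[f"aic_{f.model}"] = f.aic
                row[f"loglik_{f.model}"] = f.loglik
                row[f"converged_{f.model}"] = f.converged
                if f.model == "PLN":
                    row["mu"] = f.params.mu
                    row["sigma2"] = f.params.sigma2
                    row["r2_PLN"] = f.r2
                    if f.converged:
                        pln_fits[gid] = f
                elif f.model == "NB":
                    row["nb_dispersion"] = f.params.dispersion
                    row["nb_q"] = f.params.q
            rows.append(row)
            densities[gid] = rsa.n_individuals / self.records[gid].genome_length
        if not pln_fits:
            raise models.ModelError("no genome produced a converged PLN fit")
        dm, dropped = distance.rsa_distance_matrix(pln_fits, densities)
        excluded.extend(dropped)
        return RSAPhylogenyResults(
            model=self,
            fit_table=pd.DataFrame(rows).set_index("genome_id"),
            distance_matrix=dm,
            excluded=excluded,
        )


class RSAPhylogenyResults:
    """Fitted RSA phylogeny: per-genome fits, features and distances."""

    def __init__(
        self,
        model: RSAPhylogeny,
        fit_table: pd.DataFrame,
        distance_matrix: distance.DistanceMatrix,
        excluded: list[tuple[str, str]],
    ):
        self.model = model
        self.fit_table = fit_table
        self.distance_matrix = distance_matrix
        self.excluded = excluded

    @property
    def genome_ids(self) -> list[str]:
        return list(self.distance_matrix.ids)

    def features(self) -> pd.DataFrame:
        """Raw (mu, sigma, density) per genome kept in the distance matrix."""
        tab = self.fit_table.loc[self.genome_ids]
        lengths = {g: self.model.records[g].genome_length for g in self.genome_ids}
        return pd.DataFrame(
            {
                "mu": tab["mu"],
                "sigma": np.sqrt(tab["sigma2"]),
                "density": tab["N"] / pd.Series(lengths),
            }
        )

    def dendrogram(self, linkage: str = "ward") -> compare.Dendrogram:
        return compare.hclust(self.distance_matrix, linkage=linkage)

    def clusters(self, k: int, linkage: str = "ward") -> dict[str, int]:
        return self.dendrogram(linkage=linkage).cut_to_k(k)

    def selected_fraction(self, model_name: str = "PLN") -> float:
        return float((self.fit_table["selected"] == model_name).mean())

    def summary(self) -> str:
        tab = self.fit_table
        n = len(tab)
        frac = {m: float((tab["selected"] == m).mean()) for m in models.MODEL_ORDER}
        r2 = tab["r2_PLN"].dropna()
        lines = [
            "RSA phylogeny fit",
            f"  genomes fitted:     {n} (excluded: {len(self.excluded)})",
            "  selected by AIC:    "
            + ", ".join(f"{m} {100 * frac[m]:.1f}%" for m in models.MODEL_ORDER),
            f"  PLN Preston R^2:    mean {r2.mean():.3f}, min {r2.min():.3f}",
            f"  mu range:           [{tab['mu'].min():.3f}, {tab['mu'].max():.3f}]",
            f"  sigma2 range:       [{tab['sigma2'].min():.3f}, {tab['sigma2'].max():.3f}]",
            f"  distance matrix:    {len(self.distance_matrix)} genomes",
        ]
        return "\n".join(lines)
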