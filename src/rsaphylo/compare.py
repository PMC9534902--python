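"""Comparison of clustering solutions and dendrograms.

The RSA distance matrix is clustered hierarchically (Ward linkage; the
16S matrix, not being Euclidean, uses average linkage), trees are cut at
a fixed number of clusters k (the number of taxa at the chosen rank),
and partitions are compared by normalized mutual information against a
simulated random-assignment baseline, plus taxonomy purity.  Pairs of
dendrograms are compared by cophenetic correlation and by the fraction
of internal nodes with identical leaf sets.  The subsampling protocol
re-runs the whole RSA pipeline on random domain-family subsets to gauge
the stability of the inferred phylogeny.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.stats import pearsonr
from sklearn.metrics import normalized_mutual_info_score

from .distance import DistanceMatrix
from .profiles import DomainMatrix, GenomeRecord, ProfileError, compute_rsa

LINKAGES = ("ward", "average")


class CompareError(ValueError):
    pass


class Dendrogram:
    """Rooted binary merge tree over genome leaves (scipy linkage matrix)."""

    def __init__(self, linkage_matrix: np.ndarray, ids: Sequence[str]):
        self.Z = np.asarray(linkage_matrix, dtype=float)
        self.ids = list(ids)
        if self.Z.shape != (len(self.ids) - 1, 4):
            raise CompareError("linkage matrix does not match the leaf count")

    @property
    def n_leaves(self) -> int:
        return len(self.ids)

    def heights(self) -> np.ndarray:
        return self.Z[:, 2].copy()

    def cut_to_k(self, k: int) -> dict[str, int]:
        """Exactly k clusters by undoing the k-1 last merges (merge order).

        Ties in merge heights are resolved by merge order, so cuts are
        deterministic.
        """
        if not 1 <= k <= self.n_leaves:
            raise CompareError(f"k={k} out of range 1..{self.n_leaves}")
        labels = hierarchy.cut_tree(self.Z, n_clusters=k).ravel()
        return {gid: int(lab) for gid, lab in zip(self.ids, labels)}

    def cophenetic(self) -> np.ndarray:
        """Condensed cophenetic distance vector (leaf-id order of self.ids)."""
        return hierarchy.cophenet(self.Z)

    def internal_leaf_sets(self) -> set[frozenset]:
        """Leaf-id sets of all internal nodes (the root included)."""
        n = self.n_leaves
        sets: list[frozenset] = [frozenset([gid]) for gid in self.ids]
        out: set[frozenset] = set()
        for a, b in self.Z[:, :2].astype(int):
            merged = sets[a] | sets[b]
            sets.append(merged)
            out.add(merged)
        return out

    def to_newick(self) -> str:
        """Newick string with branch lengths derived from merge heights."""
        tree = hierarchy.to_tree(self.Z)

        def rec(node, parent_height: float) -> str:
            length = max(parent_height - (0.0 if node.is_leaf() else node.dist), 0.0)
            if node.is_leaf():
                length = parent_height
                return f"{self.ids[node.id]}:{length:.10g}"
            left = rec(node.left, node.dist)
            right = rec(node.right, node.dist)
            return f"({left},{right}):{length:.10g}"

        left = rec(tree.left, tree.dist)
        right = rec(tree.right, tree.dist)
        return f"({left},{right});"


def hclust(dm: DistanceMatrix, linkage: str = "ward") -> Dendrogram:
    """Agglomerative clustering of a distance matrix.

    Ward uses the squared-Euclidean Lance-Williams update applied to the
    distance input (the Ward.D2-style convention); average is UPGMA.
    """
    if linkage not in LINKAGES:
        raise CompareError(f"linkage must be one of {LINKAGES}, got {linkage!r}")
    if len(dm) < 2:
        raise CompareError("need at least 2 genomes to cluster")
    cond = dm.condensed()
    if np.any(~np.isfinite(cond)):
        raise CompareError("NaN/inf in distance matrix")
    Z = hierarchy.linkage(cond, method=linkage)
    return Dendrogram(Z, dm.ids)


# ---------------------------------------------------------------------------
# partition comparison
# ---------------------------------------------------------------------------

def _aligned_labels(
    a: Mapping[str, object], b: Mapping[str, object]
) -> tuple[np.ndarray, np.ndarray]:
    if set(a) != set(b):
        raise CompareError("clusterings cover different genome sets")
    keys = sorted(a)
    la = pd.factorize(pd.Series([a[k] for k in keys]))[0]
    lb = pd.factorize(pd.Series([b[k] for k in keys]))[0]
    return la, lb


def _entropy(labels: np.ndarray) -> float:
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    return float(-np.sum(p * np.log(p)))


def nmi(a: Mapping[str, object], b: Mapping[str, object],
        average_method: str = "arithmetic") -> float:
    """Normalized mutual information between two partitions.

    Normalization is the arithmetic mean of the entropies by default
    (sqrt/min/max configurable).  If either partition has a single
    cluster (zero entropy) the score is 0 by convention.
    """
    la, lb = _aligned_labels(a, b)
    if _entropy(la) == 0.0 or _entropy(lb) == 0.0:
        return 0.0
    return float(normalized_mutual_info_score(la, lb, average_method=average_method))


def nmi_baseline(reference: Mapping[str, object] | Sequence[object], k: int,
                 n_sims: int = 1000, seed: int = 0,
                 average_method: str = "arithmetic") -> np.ndarray:
    """Random-assignment NMI baseline against a reference partition.

    Each simulation assigns every point an independent uniform label in
    1..k and scores NMI against the reference; the full sample is
    returned (box-plot-ready).  Deterministic under seed.
    """
    if isinstance(reference, Mapping):
        ref = pd.factorize(pd.Series([reference[g] for g in sorted(reference)]))[0]
    else:
        ref = pd.factorize(pd.Series(list(reference)))[0]
    n = len(ref)
    if not 1 <= k <= max(n, 1):
        raise CompareError(f"k={k} out of range for n={n}")
    rng = np.random.default_rng(seed)
    ref_entropy = _entropy(ref)
    out = np.empty(n_sims)
    for i in range(n_sims):
        rand = rng.integers(0, k, size=n)
        if ref_entropy == 0.0 or _entropy(rand) == 0.0:
            out[i] = 0.0
        else:
            out[i] = normalized_mutual_info_score(
                ref, rand, average_method=average_method
            )
    return out


def purity(clusters: Mapping[str, object], taxonomy: Mapping[str, object]) -> float:
    """Size-weighted average over clusters of the majority-taxon fraction."""
    if set(clusters) != set(taxonomy):
        raise CompareError("clusters and taxonomy cover different genome sets")
    df = pd.DataFrame(
        {"cluster": [clusters[g] for g in sorted(clusters)],
         "taxon": [taxonomy[g] for g in sorted(clusters)]}
    )
    if df["taxon"].isna().any():
        raise CompareError("missing taxonomy label; filter genomes first")
    n = len(df)
    correct = sum(
        grp["taxon"].value_counts().iloc[0] for _, grp in df.groupby("cluster")
    )
    return float(correct / n)


# ---------------------------------------------------------------------------
# dendrogram comparison
# ---------------------------------------------------------------------------

def _match_leaf_order(t1: Dendrogram, t2: Dendrogram) -> Dendrogram:
    if set(t1.ids) != set(t2.ids):
        raise CompareError("dendrograms have different leaf sets")
    return t2


def cophenetic_corr(t1: Dendrogram, t2: Dendrogram) -> float:
    """Pearson correlation of the two cophenetic distance vectors.

    Returns nan if either vector is constant (correlation undefined).
    """
    _match_leaf_order(t1, t2)
    if t1.n_leaves < 3:
        raise CompareError("cophenetic correlation needs at least 3 leaves")
    c1 = t1.cophenetic()
    # reorder t2's condensed vector to t1's leaf order
    idx = [t2.ids.index(g) for g in t1.ids]
    from scipy.spatial.distance import squareform

    m2 = squareform(t2.cophenetic())[np.ix_(idx, idx)]
    c2 = squareform(m2, checks=False)
    if np.allclose(c1, c1[0]) or np.allclose(c2, c2[0]):
        return float("nan")
    return float(pearsonr(c1, c2)[0])


def common_nodes_corr(t1: Dendrogram, t2: Dendrogram) -> float:
    """Shared internal-node fraction: 2*|common leaf sets| / (m1 + m2).

    Internal nodes only; the root is always common, so the value is
    strictly positive.
    """
    _match_leaf_order(t1, t2)
    s1 = t1.internal_leaf_sets()
    s2 = t2.internal_leaf_sets()
    return 2.0 * len(s1 & s2) / (len(s1) + len(s2))


# ---------------------------------------------------------------------------
# subsampling robustness protocol
# ---------------------------------------------------------------------------

def _pipeline_dendrogram(
    matrix: DomainMatrix,
    records: Sequence[GenomeRecord],
    genome_ids: Sequence[str],
    linkage: str = "ward",
    min_species: int = 10,
) -> tuple[Dendrogram, list[str]]:
    """RSA -> PLN fit -> features -> distances -> tree for one family set.

    Returns the tree plus the genomes dropped (empty proteome after
    subsampling, unfittable RSA, or non-converged fit).
    """
    from .distance import rsa_distance_matrix
    from .models import UnfittableRSAError, fit_mle

    lengths = {r.genome_id: r.genome_length for r in records}
    fits, densities, dropped = {}, {}, []
    for gid in genome_ids:
        try:
            rsa = compute_rsa(matrix, gid)
            fit = fit_mle("PLN", rsa, min_species=min_species, compute_se=False)
        except (ProfileError, UnfittableRSAError):
            dropped.append(gid)
            continue
        if not fit.converged:
            dropped.append(gid)
            continue
        fits[gid] = fit
        densities[gid] = rsa.n_individuals / lengths[gid]
    if len(fits) < 3:
        raise CompareError("fewer than 3 genomes survived the pipeline")
    dm, _ = rsa_distance_matrix(fits, densities)
    return hclust(dm, linkage=linkage), dropped


def subsample_robustness(
    matrix: DomainMatrix,
    records: Sequence[GenomeRecord],
    genome_ids: Sequence[str] | None = None,
    proportions: Sequence[float] = tuple(np.round(np.arange(0.1, 1.0, 0.1), 1)),
    n_reps: int = 50,
    seed: int = 0,
    linkage: str = "ward",
    min_species: int = 10,
) -> pd.DataFrame:
    """Stability of the RSA phylogeny under domain-family subsampling.

    For each proportion p and repeat: draw a uniform random subset of
    round(p * F) domain families (among families present in at least one
    selected genome), rerun the RSA pipeline, and record the cophenetic
    and common-nodes correlations against the all-family tree (restricted
    to the genomes retained in both).  Returns a tidy table with columns
    (proportion, repeat, measure, value, n_dropped); deterministic under
    seed.
    """
    if genome_ids is None:
        genome_ids = matrix.genome_ids
    for p in proportions:
        if not 0.0 < p <= 1.0:
            raise CompareError(f"proportion {p} outside (0, 1]")
    sub = matrix.subset(genome_ids=genome_ids)
    present = [f for f, tot in sub.counts.sum(axis=0).items() if tot > 0]
    base_tree, base_dropped = _pipeline_dendrogram(
        sub, records, genome_ids, linkage=linkage, min_species=min_species
    )
    rng = np.random.default_rng(seed)
    rows = []
    for p in proportions:
        n_fam = max(int(round(p * len(present))), 1)
        for rep in range(n_reps):
            fams = (
                present
                if p == 1.0
                else list(rng.choice(present, size=n_fam, replace=False))
            )
            try:
                tree, dropped = _pipeline_dendrogram(
                    sub.subset(family_ids=fams), records,
                    [g for g in genome_ids if g not in base_dropped],
                    linkage=linkage, min_species=min_species,
                )
            except CompareError:
                continue
            keep = [g for g in base_tree.ids if g in tree.ids]
            if len(keep) < 3:
                continue
            b = _restrict_tree(base_tree, keep, linkage)
            t = _restrict_tree(tree, keep, linkage)
            for measure, value in (
                ("cophenetic", cophenetic_corr(b, t)),
                ("common_nodes", common_nodes_corr(b, t)),
            ):
                rows.append(
                    {"proportion": p, "repeat": rep, "measure": measure,
                     "value": value, "n_dropped": len(dropped)}
                )
    return pd.DataFrame(rows)


def _restrict_tree(tree: Dendrogram, keep: Sequence[str], linkage: str) -> Dendrogram:
    """Re-cluster the cophenetic distances restricted to `keep` leaves."""
    if list(keep) == tree.ids:
        return tree
    from scipy.spatial.distance import squareform

    full = squareform(tree.cophenetic())
    idx = [tree.ids.index(g) for g in keep]
    dm = DistanceMatrix(list(keep), full[np.ix_(idx, idx)])
    return hclust(dm, linkage="average")


def robustness_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Per (proportion, measure) mean and sd of the correlation values."""
    return (
        table.groupby(["proportion", "measure"])["value"]
        .agg(["mean", "std", "count"])
        .reset_index()
    )
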