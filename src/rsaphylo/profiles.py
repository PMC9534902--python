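"""Genome x protein-domain-family abundance profiles.

The raw input of the pipeline is an integer count matrix (one row per
genome, one column per protein-domain family, e.g. InterPro identifiers)
plus a metadata table carrying genome lengths and the six-rank taxonomy.
From a genome's row we derive its Relative Species Abundance (RSA)
histogram: for every abundance value x >= 1, the number of domain
families observed exactly x times in that genome.  Families with zero
copies are unobservable and never enter the histogram.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

RANKS = ("phylum", "class", "order", "family", "genus", "species")


class ProfileError(ValueError):
    """Malformed or degenerate domain-profile input."""


@dataclass(frozen=True)
class GenomeRecord:
    """Per-genome metadata: length in bp and (possibly partial) taxonomy."""

    genome_id: str
    genome_length: int
    taxonomy: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.genome_length <= 0:
            raise ProfileError(
                f"genome {self.genome_id!r}: genome_length must be > 0, "
                f"got {self.genome_length}"
            )
        unknown = set(self.taxonomy) - set(RANKS)
        if unknown:
            raise ProfileError(
                f"genome {self.genome_id!r}: unknown taxonomy ranks {sorted(unknown)}"
            )


@dataclass(frozen=True)
class RSAHistogram:
    """Empirical RSA: mapping abundance x (>=1) -> number of families n_x."""

    counts: Mapping[int, int]

    def __post_init__(self) -> None:
        for x, n in self.counts.items():
            if x < 1:
                raise ProfileError(f"RSA histogram contains abundance {x} < 1")
            if n < 1:
                raise ProfileError(f"RSA histogram has non-positive count at x={x}")

    @property
    def n_species(self) -> int:
        """S: number of observed domain families."""
        return int(sum(self.counts.values()))

    @property
    def n_individuals(self) -> int:
        """N: total number of domain instances."""
        return int(sum(x * n for x, n in self.counts.items()))

    @property
    def abundances(self) -> np.ndarray:
        """Sorted distinct abundance values."""
        return np.array(sorted(self.counts), dtype=int)

    def expand(self) -> np.ndarray:
        """Per-family abundance vector of length S."""
        return np.repeat(self.abundances, [self.counts[x] for x in self.abundances])

    @classmethod
    def from_abundances(cls, values: Iterable[int]) -> "RSAHistogram":
        vals = np.asarray(list(values), dtype=int)
        vals = vals[vals > 0]
        if vals.size == 0:
            raise ProfileError("empty proteome: no family with positive abundance")
        uniq, cnt = np.unique(vals, return_counts=True)
        return cls({int(x): int(n) for x, n in zip(uniq, cnt)})


class DomainMatrix:
    """Validated genome x domain-family count table."""

    def __init__(self, data: pd.DataFrame):
        if data.shape[0] == 0:
            raise ProfileError("no genomes in domain matrix")
        if data.shape[1] == 0:
            raise ProfileError("no domain families in domain matrix")
        dup_g = data.index[data.index.duplicated()].unique().tolist()
        if dup_g:
            raise ProfileError(f"duplicated genome id(s): {dup_g}")
        dup_f = data.columns[data.columns.duplicated()].unique().tolist()
        if dup_f:
            raise ProfileError(f"duplicated family id(s): {dup_f}")
        arr = data.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ProfileError("non-numeric cells in domain matrix")
        if np.any(~np.isfinite(arr.astype(float))):
            raise ProfileError("non-finite cells in domain matrix")
        if np.any(arr < 0):
            i, j = np.argwhere(arr < 0)[0]
            raise ProfileError(
                f"negative count at genome {data.index[i]!r}, family {data.columns[j]!r}"
            )
        frac = arr.astype(float) % 1
        if np.any(frac != 0):
            i, j = np.argwhere(frac != 0)[0]
            raise ProfileError(
                f"non-integer count at genome {data.index[i]!r}, "
                f"family {data.columns[j]!r}"
            )
        self._df = data.astype(np.int64)

    @property
    def genome_ids(self) -> list[str]:
        return list(self._df.index)

    @property
    def family_ids(self) -> list[str]:
        return list(self._df.columns)

    @property
    def counts(self) -> pd.DataFrame:
        return self._df

    @property
    def shape(self) -> tuple[int, int]:
        return self._df.shape

    def row(self, genome_id: str) -> np.ndarray:
        if genome_id not in self._df.index:
            raise KeyError(f"genome {genome_id!r} not in matrix")
        return self._df.loc[genome_id].to_numpy()

    def subset(self, genome_ids: Sequence[str] | None = None,
               family_ids: Sequence[str] | None = None) -> "DomainMatrix":
        df = self._df
        if genome_ids is not None:
            df = df.loc[list(genome_ids)]
        if family_ids is not None:
            df = df[list(family_ids)]
        return DomainMatrix(df.copy())

    def to_tsv(self, path: str | Path) -> None:
        self._df.to_csv(path, sep="\t", index_label="genome_id")


def read_domain_matrix(path: str | Path, sep: str = "\t") -> DomainMatrix:
    """Read a TSV/CSV count matrix: first column genome ids, header family ids."""
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except pd.errors.EmptyDataError as exc:
        raise ProfileError(f"{path}: empty file") from exc
    if df.shape[0] == 0:
        raise ProfileError(f"{path}: no genomes (header only)")
    # locate non-numeric cells precisely before the bulk validation
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            raise ProfileError(
                f"{path}: non-numeric cell at genome {bad[0]!r}, family {col!r}"
            )
        df[col] = coerced
    return DomainMatrix(df)


def read_metadata(path: str | Path, sep: str = "\t") -> list[GenomeRecord]:
    """Read the metadata TSV (genome_id, genome_length, phylum..species)."""
    df = pd.read_csv(path, sep=sep, dtype={"genome_id": str})
    if "genome_id" not in df.columns or "genome_length" not in df.columns:
        raise ProfileError(f"{path}: metadata needs genome_id and genome_length columns")
    records = []
    for _, row in df.iterrows():
        tax = {
            r: str(row[r])
            for r in RANKS
            if r in df.columns and pd.notna(row[r]) and str(row[r]) != ""
        }
        records.append(
            GenomeRecord(str(row["genome_id"]), int(row["genome_length"]), tax)
        )
    ids = [r.genome_id for r in records]
    if len(set(ids)) != len(ids):
        raise ProfileError(f"{path}: duplicated genome ids in metadata")
    return records


def write_metadata(records: Sequence[GenomeRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        row = {"genome_id": r.genome_id, "genome_length": r.genome_length}
        for rank in RANKS:
            row[rank] = r.taxonomy.get(rank, "")
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def compute_rsa(matrix: DomainMatrix, genome_id: str) -> RSAHistogram:
    """RSA histogram for one genome: abundance x -> number of families n_x."""
    row = matrix.row(genome_id)
    if not np.any(row > 0):
        raise ProfileError(f"genome {genome_id!r}: empty proteome (all counts zero)")
    return RSAHistogram.from_abundances(row)


def compute_density(matrix: DomainMatrix, record: GenomeRecord) -> float:
    """Protein-domain density: total domain instances / genome length (per bp)."""
    row = matrix.row(record.genome_id)
    n = int(row.sum())
    if n == 0:
        raise ProfileError(f"genome {record.genome_id!r}: empty proteome")
    return n / record.genome_length


def filter_taxa(
    records: Sequence[GenomeRecord], level: str, min_members: int = 10
) -> tuple[list[GenomeRecord], list[str]]:
    """Keep genomes with a known label at `level` shared by >= min_members.

    Returns the surviving records (input order preserved) and the list of
    surviving taxon labels (sorted).
    """
    if level not in RANKS:
        raise ProfileError(f"unknown taxonomic rank {level!r}")
    if min_members < 1:
        raise ProfileError("min_members must be >= 1")
    labelled = [r for r in records if level in r.taxonomy]
    sizes: dict[str, int] = {}
    for r in labelled:
        sizes[r.taxonomy[level]] = sizes.get(r.taxonomy[level], 0) + 1
    keep_taxa = {t for t, n in sizes.items() if n >= min_members}
    kept = [r for r in labelled if r.taxonomy[level] in keep_taxa]
    return kept, sorted(keep_taxa)
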