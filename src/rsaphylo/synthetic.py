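"""Synthetic data with the statistical structure the method assumes.

Communities are parameterized directly in (mu, sigma2, density) space -
the space in which the RSA method operates - with genome groups playing
the role of species.  Per-genome family abundances are i.i.d. draws from
the zero-truncated candidate distributions; group-specific feature
centres plus within-group jitter produce the striped clouds the fitted
parameters form for real taxa.  A 16S-like generator mutates copies of
a shared ancestor at within- and between-group per-site rates, and an
Euler-Maruyama integrator simulates the underlying stochastic growth
equation dx = [r - g(x)] x dt + x sigma_r(x) dB.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .models import LSParams, ModelError, NBParams, PLNParams
from .profiles import DomainMatrix, GenomeRecord

BASES = np.array(list("ACGT"))


class SyntheticError(ValueError):
    pass


@dataclass(frozen=True)
class GroupSpec:
    """One genome group: PLN centre, density, size and within-group jitter."""

    label: str
    pln: PLNParams
    density: float
    genome_length: int
    n_genomes: int
    n_families: int
    jitter: float = 0.0

    def __post_init__(self) -> None:
        if self.n_genomes < 1:
            raise SyntheticError("n_genomes must be >= 1")
        if self.n_families < 10:
            raise SyntheticError("n_families must be >= 10")
        if self.jitter < 0:
            raise SyntheticError("jitter must be >= 0")
        if self.density <= 0 or self.genome_length <= 0:
            raise SyntheticError("density and genome_length must be > 0")


@dataclass(frozen=True)
class SDETrajectory:
    """One realized abundance path of the stochastic growth equation."""

    t: np.ndarray
    x: np.ndarray
    seed: int
    n_reflections: int
    x_min: float


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def _sample_untruncated(model: str, params, n: int, rng: np.random.Generator):
    if model == "PLN":
        lam = rng.lognormal(mean=params.mu, sigma=params.sigma, size=n)
        return rng.poisson(lam)
    if model == "NB":
        # numpy negative_binomial(n, p): p is the NB's 1 - q
        return rng.negative_binomial(params.dispersion, 1.0 - params.q, size=n)
    raise ModelError(f"unknown model {model!r}")


def sample_zt(model: str, params, n: int, seed: int | np.random.Generator = 0,
              max_batches: int = 200) -> np.ndarray:
    """n i.i.d. draws from the zero-truncated distribution.

    PLN and NB sample by rejection of zeros; LS is already zero-free and
    samples directly via its quantile function.  Deterministic under
    seed.  Errors out if the zero class soaks up essentially all mass.
    """
    if n < 1:
        raise SyntheticError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if model == "LS":
        if not isinstance(params, LSParams):
            raise ModelError("LS sampling requires LSParams")
        return stats.logser.rvs(params.q, size=n, random_state=rng).astype(np.int64)
    out = np.empty(n, dtype=np.int64)
    filled = 0
    for _ in range(max_batches):
        batch = _sample_untruncated(model, params, max(2 * (n - filled), 64), rng)
        batch = batch[batch >= 1]
        take = min(len(batch), n - filled)
        out[filled:filled + take] = batch[:take]
        filled += take
        if filled == n:
            return out
    raise SyntheticError(
        f"zero-truncated sampling failed: P(X=0) too close to 1 for {model}"
    )


# ---------------------------------------------------------------------------
# community generator
# ---------------------------------------------------------------------------

def _group_family_weights(
    n_groups: int, family_pool: int, rng: np.random.Generator, bias: float = 0.7
) -> np.ndarray:
    """Group-biased family-sampling weights: each group concentrates a
    fraction `bias` of its mass on a group-specific block of the pool."""
    blocks = np.array_split(np.arange(family_pool), n_groups)
    w = np.full((n_groups, family_pool), (1.0 - bias) / family_pool)
    for g, block in enumerate(blocks):
        w[g, block] += bias / len(block)
    return w / w.sum(axis=1, keepdims=True)


def generate_population(
    groups: Sequence[GroupSpec],
    family_pool: int,
    seed: int = 0,
    bias: float = 0.7,
) -> tuple[DomainMatrix, list[GenomeRecord], dict[str, str]]:
    """Synthetic genome x family matrix with group structure.

    Per genome the group's (mu, sigma2, density) centre is perturbed by
    Gaussian jitter, n_families abundances are drawn from the
    zero-truncated PLN and assigned to families sampled from the pool
    with group-biased weights; genome_length is set so the realized
    density equals the (jittered) target.  Taxonomy carries the group
    label at species level; the returned dict is the ground truth.
    """
    if family_pool < max(g.n_families for g in groups):
        raise SyntheticError("family_pool smaller than the largest n_families")
    rng = np.random.default_rng(seed)
    weights = _group_family_weights(len(groups), family_pool, rng, bias=bias)
    family_ids = [f"FAM{k:05d}" for k in range(family_pool)]
    rows, gids, records, labels = [], [], [], {}
    for g, spec in enumerate(groups):
        for i in range(spec.n_genomes):
            gid = f"{spec.label}_{i:03d}"
            mu = spec.pln.mu + spec.jitter * rng.standard_normal()
            sigma2 = max(spec.pln.sigma2 + spec.jitter * rng.standard_normal(), 0.05)
            density = max(
                spec.density * (1.0 + spec.jitter * rng.standard_normal()), 1e-6
            )
            abund = sample_zt("PLN", PLNParams(mu, sigma2), spec.n_families, rng)
            fams = rng.choice(
                family_pool, size=spec.n_families, replace=False, p=weights[g]
            )
            row = np.zeros(family_pool, dtype=np.int64)
            row[fams] = abund
            length = max(int(round(row.sum() / density)), 1)
            rows.append(row)
            gids.append(gid)
            records.append(
                GenomeRecord(gid, length, {"species": spec.label, "genus": spec.label})
            )
            labels[gid] = spec.label
    matrix = DomainMatrix(
        pd.DataFrame(np.vstack(rows), index=gids, columns=family_ids)
    )
    return matrix, records, labels


# ---------------------------------------------------------------------------
# 16S-like sequences
# ---------------------------------------------------------------------------

def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    if rate == 0.0:
        return seq.copy()
    out = seq.copy()
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    for k in hits:
        choices = BASES[BASES != out[k]]
        out[k] = rng.choice(choices)
    return out


def generate_16s_set(
    n_genomes: int,
    length: int = 300,
    mutation_rate_within: float = 0.005,
    mutation_rate_between: float = 0.05,
    groups: Sequence[str] | None = None,
    seed: int = 0,
    copies_per_genome: int = 2,
) -> dict[str, list[str]]:
    """16S-like gene sets: per-site mutation from a shared ancestor.

    A random ancestor is mutated at the between rate once per group, and
    each genome's copies are mutated from its group ancestor at the
    within rate, so inter-group distances exceed intra-group distances
    in expectation.  Genome ids follow `<group>_<i>`; deterministic
    under seed.
    """
    for rate in (mutation_rate_within, mutation_rate_between):
        if not 0.0 <= rate <= 0.5:
            raise SyntheticError("mutation rates must lie in [0, 0.5]")
    rng = np.random.default_rng(seed)
    if groups is None:
        groups = ["G0"] * n_genomes
    if len(groups) != n_genomes:
        raise SyntheticError("groups must have one label per genome")
    ancestor = rng.choice(BASES, size=length)
    group_anc = {
        g: _mutate(ancestor, mutation_rate_between, rng) for g in dict.fromkeys(groups)
    }
    counter: dict[str, int] = {}
    genes: dict[str, list[str]] = {}
    for g in groups:
        i = counter.get(g, 0)
        counter[g] = i + 1
        gid = f"{g}_{i:03d}"
        genes[gid] = [
            "".join(_mutate(group_anc[g], mutation_rate_within, rng))
            for _ in range(copies_per_genome)
        ]
    return genes


# ---------------------------------------------------------------------------
# stochastic growth equation
# ---------------------------------------------------------------------------

def simulate_sde(
    eco,
    regulation: str | None = None,
    x0: float = 1.0,
    dt: float = 1e-3,
    t_max: float = 10.0,
    seed: int = 0,
    x_min: float = 1e-6,
) -> SDETrajectory:
    """Euler-Maruyama integration of the stochastic growth equation.

    The abundance follows dx = m(x) dt + x sigma_r(x) dB with
    m(x) = [r - g(x)] x + sigma_d^2/2 + sigma_e^2 x / 2 and
    sigma_r^2(x) = sigma_e^2 + sigma_d^2/x; g(x) = gamma ln(x+eps)
    (Gompertz) or eta x (linear).  With this drift, ln x under Gompertz
    regulation is an Ornstein-Uhlenbeck process with stationary mean
    r/gamma and variance sigma_e^2/(2 gamma) as eps -> 0.  Positivity is
    kept by reflection at x_min (count recorded).
    """
    regulation = regulation or eco.regulation
    if regulation != eco.regulation:
        raise ModelError("regulation mode does not match parameters")
    if dt <= 0 or x0 <= 0:
        raise SyntheticError("dt and x0 must be > 0")
    rng = np.random.default_rng(seed)
    n_steps = int(round(t_max / dt))
    t = np.linspace(0.0, n_steps * dt, n_steps + 1)
    x = np.empty(n_steps + 1)
    x[0] = x0
    eps = eco.epsilon
    sqdt = np.sqrt(dt)
    n_reflect = 0
    for k in range(n_steps):
        xc = x[k]
        g = eco.gamma * np.log(xc + eps) if regulation == "gompertz" else eco.eta * xc
        drift = (eco.r - g) * xc + 0.5 * eco.sigma_d2 + 0.5 * eco.sigma_e2 * xc
        diff = xc * np.sqrt(eco.sigma_e2 + eco.sigma_d2 / xc)
        xn = xc + drift * dt + diff * sqdt * rng.standard_normal()
        if xn < x_min:
            xn = 2.0 * x_min - xn if xn > 0 else x_min
            xn = max(xn, x_min)
            n_reflect += 1
        if not np.isfinite(xn) or xn > 1e12:
            raise SyntheticError(
                f"SDE diverged at t={t[k + 1]:.4g} (x={xn:.3g}); reduce dt or rates"
            )
        x[k + 1] = xn
    return SDETrajectory(t=t, x=x, seed=seed, n_reflections=n_reflect, x_min=x_min)
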