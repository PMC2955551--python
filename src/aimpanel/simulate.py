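"""Synthetic multi-allelic genotype data with known ancestry structure.

The generator follows the Balding–Nichols construction: ancestral allele
frequencies at each locus are drawn from a symmetric Dirichlet(gamma), and
each population's frequencies drift around them as
Dirichlet(p_anc * (1 - F) / F), so F is the expected fixation index of that
population relative to the ancestral pool.  Individuals are diploid mosaics:
every gene copy first draws an ancestral population from the individual's
ancestry proportions q, then an allele from that population's frequencies —
the generative twin of the admixture model used for inference.

Reference individuals carry one-hot q; query cohorts draw q either from a
fixed vector or from a Dirichlet law, emulating self-declared groups whose
labels need not match genetic ancestry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .genotype_io import DEFAULT_MISSING_CODE, GenotypeMatrix


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class Cohort:
    """A self-declared query group: ``n`` individuals whose true ancestry is
    drawn either as a fixed vector ``q`` or as Dirichlet(``alpha``)."""

    label: str
    n: int
    q: tuple[float, ...] | None = None
    alpha: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if (self.q is None) == (self.alpha is None):
            raise SimulationError(
                f"cohort {self.label!r}: specify exactly one of q or alpha"
            )
        if self.q is not None and abs(sum(self.q) - 1.0) > 1e-9:
            raise SimulationError(f"cohort {self.label!r}: q must sum to 1")


@dataclass
class SimulationConfig:
    """Study-design parameters of the generator.

    ``F`` may be a scalar (shared divergence) or one value per population;
    ``n_alleles`` likewise scalar or per-locus.  ``gamma`` is the
    concentration of the ancestral Dirichlet (1.0 = uniform over the
    simplex).  The ``paper_like`` preset mirrors the scale of a continental
    ancestry panel: 5 populations, 36 microsatellites with 10 alleles each,
    divergence F = 0.2 and 50 reference individuals per population.
    """

    k_true: int = 5
    n_loci: int = 36
    n_alleles: int | Sequence[int] = 10
    F: float | Sequence[float] = 0.2
    gamma: float = 1.0
    n_ref: int = 50
    cohorts: tuple[Cohort, ...] = ()
    missing_rate: float = 0.0
    seed: int = 0

    @classmethod
    def paper_like(cls, seed: int = 0, cohorts: tuple[Cohort, ...] = ()) -> "SimulationConfig":
        return cls(k_true=5, n_loci=36, n_alleles=10, F=0.2, n_ref=50,
                   cohorts=cohorts, seed=seed)

    def f_values(self) -> np.ndarray:
        F = np.broadcast_to(np.asarray(self.F, dtype=float), (self.k_true,)).copy()
        if np.any((F <= 0) | (F >= 1)):
            raise SimulationError("F values must lie in (0, 1)")
        return F

    def allele_numbers(self) -> np.ndarray:
        A = np.broadcast_to(np.asarray(self.n_alleles, dtype=int), (self.n_loci,)).copy()
        if np.any(A < 2):
            raise SimulationError("every locus needs at least 2 alleles")
        return A

    def validate(self) -> None:
        if self.k_true < 1 or self.n_loci < 1:
            raise SimulationError("k_true and n_loci must be positive")
        if not (0.0 <= self.missing_rate < 1.0):
            raise SimulationError("missing_rate must be in [0, 1)")
        if self.gamma <= 0:
            raise SimulationError("gamma must be positive")
        self.f_values()
        self.allele_numbers()
        for c in self.cohorts:
            law = c.q if c.q is not None else c.alpha
            if len(law) != self.k_true:
                raise SimulationError(
                    f"cohort {c.label!r}: ancestry law has {len(law)} components, "
                    f"expected {self.k_true}"
                )


@dataclass
class SimulatedDataset:
    """Genotypes plus the ground truth that generated them."""

    genotypes: GenotypeMatrix
    metadata: pd.DataFrame
    p_anc: np.ndarray  # (L, A_max), rows padded with 0
    P_true: np.ndarray  # (K, L, A_max)
    Q_true: np.ndarray  # (N, K)
    config: SimulationConfig


def allele_code(index: int) -> int:
    """Fragment-size-like allele code for allele ``index`` (0-based)."""
    return 100 + 2 * index


def draw_frequencies(
    cfg: SimulationConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw ancestral and per-population allele frequencies.

    p_anc[l] ~ Dirichlet(gamma, ..., gamma) over the locus's alleles;
    P_true[k, l] ~ Dirichlet(p_anc[l] * (1 - F_k) / F_k).  Padded allele
    slots (beyond a locus's allele count) are zero.
    """
    cfg.validate()
    A = cfg.allele_numbers()
    F = cfg.f_values()
    a_max = int(A.max())
    L, K = cfg.n_loci, cfg.k_true
    p_anc = np.zeros((L, a_max))
    P_true = np.zeros((K, L, a_max))
    for l in range(L):
        a_l = int(A[l])
        p = rng.dirichlet(np.full(a_l, cfg.gamma))
        p_anc[l, :a_l] = p
        for k in range(K):
            scale = (1.0 - F[k]) / F[k]
            P_true[k, l, :a_l] = rng.dirichlet(np.maximum(p * scale, 1e-12))
    return p_anc, P_true


def simulate_individual(
    q: np.ndarray,
    P_true: np.ndarray,
    rng: np.random.Generator,
    missing_rate: float = 0.0,
    allele_numbers: np.ndarray | None = None,
) -> np.ndarray:
    """Draw one diploid genotype row: (L, 2) array of allele codes, with
    both entries set to the missing code where the locus drops out.

    For each locus and copy the ancestral population is Categorical(q) and
    the allele is drawn from that population's frequencies.
    """
    K, L, a_max = P_true.shape
    q = np.asarray(q, dtype=float)
    z = rng.choice(K, size=(L, 2), p=q)
    calls = np.empty((L, 2), dtype=np.int64)
    u = rng.random((L, 2))
    for l in range(L):
        for c in range(2):
            cum = np.cumsum(P_true[z[l, c], l])
            idx = int(np.searchsorted(cum, u[l, c] * cum[-1], side="right"))
            idx = min(idx, a_max - 1)
            calls[l, c] = allele_code(idx)
    if missing_rate > 0:
        drop = rng.random(L) < missing_rate
        calls[drop, :] = DEFAULT_MISSING_CODE
    return calls


def simulate_dataset(cfg: SimulationConfig) -> SimulatedDataset:
    """Generate a full dataset: reference panels plus query cohorts.

    References get role ``reference``, one-hot true ancestry and population
    labels ``pop1..popK``; cohort members get role ``query`` and
    ``declared_group`` equal to the cohort label.  Deterministic per seed.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    p_anc, P_true = draw_frequencies(cfg, rng)
    K, L = cfg.k_true, cfg.n_loci
    A = cfg.allele_numbers()

    sample_ids: list[str] = []
    pop_labels: list[str | None] = []
    declared: list[str | None] = []
    roles: list[str] = []
    qs: list[np.ndarray] = []

    for k in range(K):
        for i in range(cfg.n_ref):
            sample_ids.append(f"ref_pop{k + 1}_{i + 1:03d}")
            pop_labels.append(f"pop{k + 1}")
            declared.append(None)
            roles.append("reference")
            q = np.zeros(K)
            q[k] = 1.0
            qs.append(q)
    for cohort in cfg.cohorts:
        for i in range(cohort.n):
            sample_ids.append(f"{cohort.label}_{i + 1:03d}")
            pop_labels.append(None)
            declared.append(cohort.label)
            roles.append("query")
            if cohort.q is not None:
                qs.append(np.asarray(cohort.q, dtype=float))
            else:
                qs.append(rng.dirichlet(np.asarray(cohort.alpha, dtype=float)))

    N = len(sample_ids)
    if N == 0:
        raise SimulationError("configuration yields no individuals")
    Q_true = np.vstack(qs)
    calls = np.empty((N, L, 2), dtype=np.int64)
    for i in range(N):
        calls[i] = simulate_individual(Q_true[i], P_true, rng, cfg.missing_rate, A)
    locus_names = [f"msat{l + 1:03d}" for l in range(L)]
    g = GenotypeMatrix.from_calls(sample_ids, locus_names, calls)
    meta = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "population_label": pop_labels,
            "declared_group": declared,
            "role": roles,
        }
    )
    return SimulatedDataset(g, meta, p_anc, P_true, Q_true, cfg)
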