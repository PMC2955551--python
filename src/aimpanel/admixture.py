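"""Bayesian admixture clustering by Gibbs sampling.

The model: each of K clusters has its own allele-frequency vectors
p_{k,l,.} per locus (symmetric Dirichlet(lambda) prior); each individual
has ancestry proportions q_i on the K-simplex (Dirichlet(alpha) prior);
each gene copy independently draws its cluster of origin z from q_i and
its allele from that cluster's frequencies.  Inference is unsupervised —
no prior population assignment is used — and runs a Gibbs sweep

    z  |  P, Q      (per gene copy, categorical)
    P  |  z         (per cluster-locus, Dirichlet)
    Q  |  z, alpha  (per individual, Dirichlet)
    alpha | Q       (Metropolis step, uniform prior on (0, alpha_max])

with the admixture parameter alpha optionally inferred, either shared or
one per cluster.  The model score lnP(D) is estimated from the kept
samples' data log-likelihoods as mean - variance/2, the estimator the
clustering literature uses for this harmonic-style approximation, so that
rate-of-change model selection (Evanno delta-K) can be applied downstream.

Missing genotypes contribute nothing to any update: they are masked out of
all counts and of the likelihood, never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .genotype_io import MISSING, GenotypeMatrix

_TINY = 1e-300


class AdmixtureError(ValueError):
    pass


@dataclass(frozen=True)
class AdmixtureConfig:
    """Sampler settings.

    ``burn_in``/``iterations`` default to desk-scale values (5,000/5,000);
    production-scale runs (e.g. 400,000/350,000) are a config change.
    ``lam`` is the symmetric Dirichlet prior on cluster allele frequencies
    (1.0 = uniform).  With ``infer_alpha``, alpha takes Metropolis steps
    with a normal proposal (sd ``alpha_proposal_sd``) under a uniform prior
    on (0, ``alpha_max``]; ``separate_alpha`` gives each cluster its own
    alpha.
    """

    k: int
    burn_in: int = 5000
    iterations: int = 5000
    lam: float = 1.0
    infer_alpha: bool = True
    separate_alpha: bool = True
    alpha_init: float = 1.0
    alpha_proposal_sd: float = 0.025
    alpha_max: float = 10.0
    seed: int = 0
    thin: int = 1

    def __post_init__(self) -> None:
        if self.k < 1:
            raise AdmixtureError("k must be >= 1")
        if self.burn_in < 1 or self.iterations < 1:
            raise AdmixtureError("burn_in and iterations must be >= 1")
        if self.lam <= 0:
            raise AdmixtureError("lambda must be positive")
        if self.alpha_init <= 0 or self.alpha_max <= 0 or self.alpha_proposal_sd <= 0:
            raise AdmixtureError("alpha parameters must be positive")
        if self.thin < 1:
            raise AdmixtureError("thin must be >= 1")


@dataclass
class EncodedGenotypes:
    """Genotypes re-indexed for the sampler.

    ``alleles[i, l, c]`` is the per-locus allele index (0-based) of copy
    ``c``, 0 where missing; ``valid[i, l]`` marks non-missing calls;
    ``a_l`` the allele count per locus (padded arrays use ``a_max``).
    """

    alleles: np.ndarray  # (N, L, 2) int
    valid: np.ndarray  # (N, L) bool
    a_l: np.ndarray  # (L,) int
    locus_names: list[str]
    individuals: list[str]

    @property
    def n_individuals(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_loci(self) -> int:
        return self.alleles.shape[1]

    @property
    def a_max(self) -> int:
        return int(self.a_l.max())

    @property
    def n_gene_copies(self) -> int:
        return int(2 * self.valid.sum())

    @classmethod
    def from_matrix(cls, g: GenotypeMatrix) -> "EncodedGenotypes":
        N, L = g.n_individuals, g.n_loci
        alleles = np.zeros((N, L, 2), dtype=np.int64)
        valid = ~g.missing_mask
        for l, locus in enumerate(g.loci):
            lookup = {code: u for u, code in enumerate(locus.allele_codes)}
            col = g.calls[:, l, :]
            for i in range(N):
                if valid[i, l]:
                    alleles[i, l, 0] = lookup[int(col[i, 0])]
                    alleles[i, l, 1] = lookup[int(col[i, 1])]
        a_l = np.array([locus.n_alleles for locus in g.loci], dtype=np.int64)
        return cls(alleles, valid, a_l, g.locus_names, list(g.individuals))


@dataclass
class AdmixtureState:
    """Current sampler state.

    ``z``: (N, L, 2) cluster of origin per gene copy (content at missing
    positions is irrelevant); ``p``: (K, L, A_max) cluster allele
    frequencies, zero in padded slots; ``q``: (N, K) ancestry proportions;
    ``alpha``: (K,) admixture parameter (all entries equal when shared).
    """

    z: np.ndarray
    p: np.ndarray
    q: np.ndarray
    alpha: np.ndarray
    loglik: float = float("nan")


@dataclass
class AdmixtureRun:
    """Posterior summaries of one MCMC run."""

    q_mean: np.ndarray  # (N, K)
    p_mean: np.ndarray  # (K, L, A_max)
    alpha_mean: np.ndarray  # (K,)
    ln_prob: float  # lnP(D) = mean - var/2 of kept log-likelihoods
    loglik_mean: float
    loglik_var: float
    n_kept: int
    config: AdmixtureConfig
    individuals: list[str]
    locus_names: list[str]

    def q_frame(self) -> pd.DataFrame:
        cols = [f"cluster{k + 1}" for k in range(self.q_mean.shape[1])]
        return pd.DataFrame(self.q_mean, index=self.individuals, columns=cols)


# ---------------------------------------------------------------------------
# Gibbs updates (module-level so each can be exercised in isolation)


def _gather_weights(state: AdmixtureState, data: EncodedGenotypes) -> np.ndarray:
    """(N, L, 2, K) unnormalized assignment weights q_{i,k} p_{k,l,j}."""
    L = data.n_loci
    # P gathered at the observed alleles: (K, N, L, 2) -> (N, L, 2, K)
    pg = state.p[:, np.arange(L)[None, :, None], data.alleles]
    return np.moveaxis(pg, 0, -1) * state.q[:, None, None, :]


def update_z(state: AdmixtureState, data: EncodedGenotypes, rng: np.random.Generator) -> AdmixtureState:
    """Resample every gene copy's cluster of origin.

    P(z = k) is proportional to q_{i,k} p_{k,l,j} for the observed allele j;
    missing copies are resampled from q alone (they touch no later update).
    """
    w = _gather_weights(state, data)
    if not data.valid.all():
        rows = np.nonzero(~data.valid)[0]
        w[~data.valid] = state.q[rows][:, None, :]
    total = w.sum(axis=-1, keepdims=True)
    if not np.all(total > 0):
        raise AdmixtureError("zero total assignment probability (corrupt state)")
    cum = np.cumsum(w, axis=-1)
    u = rng.random(cum.shape[:-1])[..., None] * total
    z = (u >= cum).sum(axis=-1)
    state.z = z.astype(np.int64)
    return state


def _assignment_counts(state: AdmixtureState, data: EncodedGenotypes, k: int) -> tuple[np.ndarray, np.ndarray]:
    """n_{k,l,j} gene-copy counts per cluster-locus-allele and m_{i,k} per
    individual-cluster, over non-missing copies only."""
    N, L = data.n_individuals, data.n_loci
    a_max = data.a_max
    vmask = np.repeat(data.valid[:, :, None], 2, axis=2)
    z = state.z[vmask]
    l_idx = np.broadcast_to(np.arange(L)[None, :, None], (N, L, 2))[vmask]
    a_idx = data.alleles[vmask]
    n_kla = np.bincount(
        (z * L + l_idx) * a_max + a_idx, minlength=k * L * a_max
    ).reshape(k, L, a_max)
    i_idx = np.broadcast_to(np.arange(N)[:, None, None], (N, L, 2))[vmask]
    m_ik = np.bincount(i_idx * k + z, minlength=N * k).reshape(N, k)
    return n_kla, m_ik


def update_p(
    state: AdmixtureState, data: EncodedGenotypes, rng: np.random.Generator, lam: float = 1.0
) -> AdmixtureState:
    """Resample cluster allele frequencies from Dirichlet(lambda + counts).

    The Dirichlet draw is realized as normalized gamma variates; padded
    allele slots (beyond a locus's allele count) get shape 0 and stay 0.
    """
    K = state.q.shape[1]
    n_kla, _ = _assignment_counts(state, data, K)
    valid_allele = np.arange(data.a_max)[None, :] < data.a_l[:, None]  # (L, A_max)
    shape = n_kla + np.where(valid_allele, lam, 0.0)
    draws = rng.gamma(shape)
    draws[:, valid_allele] = np.maximum(draws[:, valid_allele], _TINY)
    draws[:, ~valid_allele] = 0.0
    state.p = draws / draws.sum(axis=2, keepdims=True)
    return state


def update_q(state: AdmixtureState, data: EncodedGenotypes, rng: np.random.Generator) -> AdmixtureState:
    """Resample each individual's ancestry from Dirichlet(alpha + m_i)."""
    K = state.q.shape[1]
    _, m_ik = _assignment_counts(state, data, K)
    draws = rng.gamma(state.alpha[None, :] + m_ik)
    draws = np.maximum(draws, _TINY)
    state.q = draws / draws.sum(axis=1, keepdims=True)
    return state


def _dirichlet_logpdf_sum(q: np.ndarray, alpha: np.ndarray) -> float:
    """Sum over rows of q of the Dirichlet(alpha) log density."""
    n = q.shape[0]
    logq = np.log(np.clip(q, _TINY, None))
    return float(
        n * (gammaln(alpha.sum()) - gammaln(alpha).sum())
        + ((alpha - 1.0) * logq.sum(axis=0)).sum()
    )


def update_alpha(
    state: AdmixtureState,
    rng: np.random.Generator,
    proposal_sd: float = 0.025,
    alpha_max: float = 10.0,
    separate: bool = True,
) -> AdmixtureState:
    """Metropolis update of the admixture parameter(s).

    Symmetric normal proposal; uniform prior on (0, alpha_max] with
    out-of-range proposals auto-rejected.  With ``separate`` each cluster's
    alpha_k is updated in turn; otherwise one shared value is updated.  The
    rng is consumed in a fixed order (proposal, then acceptance uniform) per
    update so runs are reproducible.
    """
    K = state.alpha.size
    logq_sums = np.log(np.clip(state.q, _TINY, None)).sum(axis=0)
    n = state.q.shape[0]
    if separate:
        for k in range(K):
            prop = state.alpha[k] + rng.normal(0.0, proposal_sd)
            u = rng.random()
            if prop <= 0.0 or prop > alpha_max:
                continue
            new = state.alpha.copy()
            new[k] = prop
            log_ratio = (
                n * (gammaln(new.sum()) - gammaln(state.alpha.sum())
                     - gammaln(prop) + gammaln(state.alpha[k]))
                + (prop - state.alpha[k]) * logq_sums[k]
            )
            if np.log(u) < log_ratio:
                state.alpha = new
    else:
        cur = state.alpha[0]
        prop = cur + rng.normal(0.0, proposal_sd)
        u = rng.random()
        if prop <= 0.0 or prop > alpha_max:
            return state
        log_ratio = (
            n * (gammaln(K * prop) - K * gammaln(prop)
                 - gammaln(K * cur) + K * gammaln(cur))
            + (prop - cur) * logq_sums.sum()
        )
        if np.log(u) < log_ratio:
            state.alpha = np.full(K, prop)
    return state


def log_likelihood(state: AdmixtureState, data: EncodedGenotypes) -> float:
    """Data log-likelihood with assignments integrated out:
    Sigma over non-missing gene copies of ln Sigma_k q_{i,k} p_{k,l,j}."""
    w = _gather_weights(state, data)
    per_copy = w.sum(axis=-1)
    vmask = np.repeat(data.valid[:, :, None], 2, axis=2)
    vals = per_copy[vmask]
    if np.any(vals <= 0):
        return float("-inf")
    return float(np.log(vals).sum())


# ---------------------------------------------------------------------------
# the full sampler


def run_mcmc(data: GenotypeMatrix | EncodedGenotypes, cfg: AdmixtureConfig) -> AdmixtureRun:
    """Run the Gibbs sampler and return posterior means and lnP(D).

    The chain is initialized with uniform-random assignments, alpha at
    ``alpha_init``, and P and Q drawn from their full conditionals; each
    step cycles z, P, Q and (optionally) alpha.  Posterior means are taken
    over post-burn-in samples at the configured thinning; two runs with the
    same config and seed are bit-identical.
    """
    enc = data if isinstance(data, EncodedGenotypes) else EncodedGenotypes.from_matrix(data)
    K = cfg.k
    if K > enc.n_gene_copies:
        raise AdmixtureError(
            f"K = {K} exceeds the number of non-missing gene copies ({enc.n_gene_copies})"
        )
    rng = np.random.default_rng(cfg.seed)
    N, L, a_max = enc.n_individuals, enc.n_loci, enc.a_max

    state = AdmixtureState(
        z=rng.integers(0, K, size=(N, L, 2)),
        p=np.zeros((K, L, a_max)),
        q=np.full((N, K), 1.0 / K),
        alpha=np.full(K, cfg.alpha_init),
    )
    update_p(state, enc, rng, cfg.lam)
    update_q(state, enc, rng)

    q_sum = np.zeros_like(state.q)
    p_sum = np.zeros_like(state.p)
    alpha_sum = np.zeros_like(state.alpha)
    logliks: list[float] = []

    total = cfg.burn_in + cfg.iterations
    for step in range(total):
        update_z(state, enc, rng)
        update_p(state, enc, rng, cfg.lam)
        update_q(state, enc, rng)
        if cfg.infer_alpha:
            update_alpha(
                state, rng, cfg.alpha_proposal_sd, cfg.alpha_max, cfg.separate_alpha
            )
        kept = step >= cfg.burn_in and (step - cfg.burn_in) % cfg.thin == 0
        if kept:
            ll = log_likelihood(state, enc)
            if not np.isfinite(ll):
                raise AdmixtureError(
                    f"non-finite log-likelihood at step {step}; "
                    f"alpha={state.alpha}, seed={cfg.seed}"
                )
            logliks.append(ll)
            q_sum += state.q
            p_sum += state.p
            alpha_sum += state.alpha

    n_kept = len(logliks)
    ll_arr = np.asarray(logliks)
    ll_mean = float(ll_arr.mean())
    ll_var = float(ll_arr.var())
    return AdmixtureRun(
        q_mean=q_sum / n_kept,
        p_mean=p_sum / n_kept,
        alpha_mean=alpha_sum / n_kept,
        ln_prob=ll_mean - ll_var / 2.0,
        loglik_mean=ll_mean,
        loglik_var=ll_var,
        n_kept=n_kept,
        config=cfg,
        individuals=list(enc.individuals),
        locus_names=list(enc.locus_names),
    )


# ---------------------------------------------------------------------------
# anchoring clusters to reference groups


@dataclass
class ClusterLabeling:
    """Cluster -> reference-group name map.

    ``labels[k]`` is the reference population group with the largest mean
    membership in cluster k; ``tied[k]`` flags a tie broken lexicographically.
    """

    labels: list[str]
    tied: list[bool]
    mean_membership: pd.DataFrame  # groups x clusters

    def as_dict(self) -> dict[int, str]:
        return {k: lab for k, lab in enumerate(self.labels)}


def label_clusters_by_reference(
    q: np.ndarray | pd.DataFrame, metadata: pd.DataFrame, individuals: list[str] | None = None
) -> ClusterLabeling:
    """Name each cluster after the reference group dominating it.

    For every cluster k the label is the reference population group with
    the largest mean membership q[., k]; ties break to the
    lexicographically smallest group name and are flagged.
    """
    if isinstance(q, pd.DataFrame):
        individuals = list(q.index)
        qm = q.to_numpy()
    else:
        qm = np.asarray(q, dtype=float)
        if individuals is None:
            raise AdmixtureError("individuals required when q is a bare array")
    refs = metadata[metadata["role"] == "reference"]
    if len(refs) == 0:
        raise AdmixtureError("no reference samples in metadata")
    pos = {s: i for i, s in enumerate(individuals)}
    groups = sorted(set(refs["population_label"]))
    K = qm.shape[1]
    mm = np.zeros((len(groups), K))
    for gi, grp in enumerate(groups):
        ids = refs.loc[refs["population_label"] == grp, "sample_id"]
        rows = [pos[s] for s in ids if s in pos]
        if not rows:
            raise AdmixtureError(f"reference group {grp!r} absent from the Q matrix")
        mm[gi] = qm[rows].mean(axis=0)
    labels, tied = [], []
    for k in range(K):
        col = mm[:, k]
        best = float(col.max())
        winners = [groups[i] for i in np.flatnonzero(col == best)]
        labels.append(min(winners))
        tied.append(len(winners) > 1)
    frame = pd.DataFrame(mm, index=groups, columns=[f"cluster{k + 1}" for k in range(K)])
    return ClusterLabeling(labels, tied, frame)


def labeled_q_frame(run_q: pd.DataFrame, labeling: ClusterLabeling) -> pd.DataFrame:
    """Collapse a cluster-indexed Q matrix to ancestry labels, summing
    clusters that share a label."""
    out = pd.DataFrame(0.0, index=run_q.index, columns=sorted(set(labeling.labels)))
    for k, lab in enumerate(labeling.labels):
        out[lab] += run_q.iloc[:, k]
    return out
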