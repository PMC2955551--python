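"""Choosing the number of clusters K by the rate-of-change (delta-K) rule.

Replicate runs at each K in a contiguous sweep yield lnP(D) values; the
second difference of the mean lnP(D) across K, scaled by the replicate
standard deviation, peaks at the uppermost K the data can clearly resolve:

    L'(K)  = mean L(K) - mean L(K-1)
    L''(K) = L'(K+1) - L'(K)
    deltaK = |L''(K)| / sd L(K)

deltaK is defined only at interior K values of the sweep.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .admixture import AdmixtureConfig, AdmixtureRun, EncodedGenotypes, run_mcmc
from .genotype_io import GenotypeMatrix


class KSelectionError(ValueError):
    pass


@dataclass
class KSweep:
    """lnP(D) values across a contiguous K range, R replicates each."""

    k_values: list[int]
    ln_prob: dict[int, list[float]]  # K -> replicate lnP(D)
    seeds: dict[tuple[int, int], int] = field(default_factory=dict)
    runs: dict[tuple[int, int], AdmixtureRun] = field(default_factory=dict)

    def validate(self) -> None:
        ks = self.k_values
        if sorted(ks) != list(range(min(ks), max(ks) + 1)):
            raise KSelectionError(f"K values {ks} are not a contiguous range")
        reps = {len(self.ln_prob[k]) for k in ks}
        if len(reps) != 1:
            raise KSelectionError("every K needs the same replicate count")


@dataclass
class DeltaKTable:
    """The delta-K table and the selected K.

    ``best_k`` is the argmax of deltaK over interior K (ties broken toward
    the larger K and flagged); None when no curvature exists anywhere
    (``unresolved``).  Interior rows with zero replicate sd have deltaK NaN
    and are flagged in ``undefined_at``.
    """

    table: pd.DataFrame  # index K; columns mean_l, sd_l, l_prime, l_double_prime_abs, delta_k
    best_k: int | None
    tie: bool
    unresolved: bool
    undefined_at: list[int]


def delta_k(sweep: KSweep | dict[int, list[float]]) -> DeltaKTable:
    """Compute the delta-K table and select K.

    Accepts a :class:`KSweep` or a bare {K: [lnP(D) replicates]} mapping.
    Needs a contiguous range of at least 3 K values with >= 2 replicates
    each.
    """
    lnpd = sweep.ln_prob if isinstance(sweep, KSweep) else dict(sweep)
    ks = sorted(lnpd)
    if len(ks) < 3:
        raise KSelectionError(f"delta-K needs >= 3 consecutive K values, got {len(ks)}")
    if ks != list(range(ks[0], ks[-1] + 1)):
        raise KSelectionError(f"K values {ks} are not contiguous")
    reps = {len(lnpd[k]) for k in ks}
    if min(reps) < 2:
        raise KSelectionError("delta-K needs >= 2 replicates per K for a defined sd")

    mean_l = np.array([np.mean(lnpd[k]) for k in ks])
    sd_l = np.array([np.std(lnpd[k], ddof=1) for k in ks])
    l_prime = np.full(len(ks), np.nan)
    l_prime[1:] = np.diff(mean_l)
    l_dd = np.full(len(ks), np.nan)
    dk = np.full(len(ks), np.nan)
    undefined: list[int] = []
    for i in range(1, len(ks) - 1):
        l_dd[i] = abs(l_prime[i + 1] - l_prime[i])
        if sd_l[i] > 0:
            dk[i] = l_dd[i] / sd_l[i]
        else:
            undefined.append(ks[i])
    table = pd.DataFrame(
        {
            "mean_l": mean_l,
            "sd_l": sd_l,
            "l_prime": l_prime,
            "l_double_prime_abs": l_dd,
            "delta_k": dk,
        },
        index=pd.Index(ks, name="K"),
    )
    interior = table["delta_k"].iloc[1:-1]
    finite = interior.dropna()
    unresolved = bool(len(finite) == 0 or np.all(finite.to_numpy() == 0.0))
    best_k: int | None = None
    tie = False
    if not unresolved:
        best = finite.max()
        winners = [int(k) for k, v in finite.items() if v == best]
        best_k = max(winners)  # prefer the larger K on exact ties
        tie = len(winners) > 1
    return DeltaKTable(table, best_k, tie, unresolved, undefined)


def replicate_seed(master_seed: int, k: int, replicate: int) -> int:
    """Deterministic per-run seed: master seed plus a stable hash of
    (K, replicate), kept below 2**31."""
    h = zlib.crc32(f"k={k}:rep={replicate}".encode())
    return int((master_seed + h) % (2**31))


def run_k_sweep(
    data: GenotypeMatrix | EncodedGenotypes,
    base_cfg: AdmixtureConfig,
    k_values: range | list[int],
    replicates: int,
    master_seed: int = 0,
    keep_runs: bool = True,
) -> KSweep:
    """One admixture run per (K, replicate) with derived seeds.

    ``base_cfg.k`` and ``base_cfg.seed`` are overridden per run; everything
    else (burn-in, iterations, priors) is shared.  The same master seed
    reproduces the sweep exactly.
    """
    enc = data if isinstance(data, EncodedGenotypes) else EncodedGenotypes.from_matrix(data)
    ks = sorted(k_values)
    if replicates < 1:
        raise KSelectionError("need at least 1 replicate")
    sweep = KSweep(k_values=ks, ln_prob={k: [] for k in ks})
    from dataclasses import replace as _replace

    for k in ks:
        for rep in range(replicates):
            seed = replicate_seed(master_seed, k, rep)
            cfg = _replace(base_cfg, k=k, seed=seed)
            run = run_mcmc(enc, cfg)
            sweep.ln_prob[k].append(run.ln_prob)
            sweep.seeds[(k, rep)] = seed
            if keep_runs:
                sweep.runs[(k, rep)] = run
    return sweep
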