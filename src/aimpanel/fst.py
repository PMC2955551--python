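"""Multi-allelic Weir–Cockerham F_st (theta) estimation.

The estimator decomposes allele-frequency variance at each locus into three
components per allele: ``a`` (among populations), ``b`` (among individuals
within populations) and ``c`` (within individuals, i.e. half the
heterozygote frequency).  theta is always combined as a ratio of sums —
over alleles within a locus, and over loci for the multi-locus estimate —
never as a mean of per-locus ratios.  The moment estimator is unbiased but
not range-constrained, so small negative estimates are reported as-is.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genotype_io import AlleleCounts, GenotypeError, GenotypeMatrix, allele_counts


class FstError(ValueError):
    """Invalid input for theta estimation."""


@dataclass
class FstComponents:
    """Per-allele variance components and intermediates at one locus.

    Arrays are indexed by allele (length = number of observed alleles);
    ``r`` is the number of populations entering the estimate.
    """

    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    n_bar: float
    n_c: float
    p_bar: np.ndarray
    s2: np.ndarray
    h_bar: np.ndarray
    r: int


@dataclass
class FstResult:
    """Per-locus and multi-locus theta.

    ``per_locus`` holds theta_l per locus name (NaN where undefined);
    ``theta`` is Sigma a / Sigma (a+b+c) over all informative loci and
    alleles; ``loci_used`` lists the loci entering the sums.
    """

    per_locus: pd.Series
    theta: float
    loci_used: list[str]
    excluded: list[str]


def locus_theta(
    n_i: np.ndarray, p_i: np.ndarray, h_i: np.ndarray
) -> tuple[FstComponents, float]:
    """Variance components and theta_l for one locus.

    Parameters
    ----------
    n_i
        (r,) non-missing sample sizes per population.
    p_i
        (r, A) sample allele frequencies per population.
    h_i
        (r, A) per-allele observed heterozygote frequencies (fraction of
        individuals carrying exactly one copy of the allele).

    Returns the components and theta_l = Sigma_u a_u / Sigma_u (a_u+b_u+c_u).
    theta_l is NaN when the locus is monomorphic across all populations
    (zero denominator).
    """
    n_i = np.asarray(n_i, dtype=float)
    p_i = np.asarray(p_i, dtype=float)
    h_i = np.asarray(h_i, dtype=float)
    r = n_i.size
    if r < 2:
        raise FstError(f"need at least 2 populations, got {r}")
    if np.any(n_i < 1):
        raise FstError("every population needs at least 2 gene copies (n_i >= 1)")
    n_bar = n_i.sum() / r
    if n_bar <= 1:
        raise FstError("mean sample size n_bar must exceed 1")
    n_c = (r * n_bar - (n_i**2).sum() / (r * n_bar)) / (r - 1)
    w = n_i[:, None]  # sample-size weights
    p_bar = (w * p_i).sum(axis=0) / (r * n_bar)
    s2 = (w * (p_i - p_bar) ** 2).sum(axis=0) / ((r - 1) * n_bar)
    h_bar = (w * h_i).sum(axis=0) / (r * n_bar)

    pq = p_bar * (1.0 - p_bar)
    inner = pq - s2 * (r - 1) / r
    a = (n_bar / n_c) * (s2 - (inner - h_bar / 4.0) / (n_bar - 1.0))
    b = (n_bar / (n_bar - 1.0)) * (inner - h_bar * (2.0 * n_bar - 1.0) / (4.0 * n_bar))
    c = h_bar / 2.0

    comp = FstComponents(a, b, c, float(n_bar), float(n_c), p_bar, s2, h_bar, r)
    denom = (a + b + c).sum()
    theta = float(a.sum() / denom) if denom != 0.0 else float("nan")
    return comp, theta


def _locus_inputs(counts: AlleleCounts, l: int) -> tuple[np.ndarray, np.ndarray, np.ndarray] | None:
    """Assemble (n_i, p_i, h_i) at locus ``l``, dropping all-missing
    populations; None when fewer than 2 populations remain informative."""
    n = counts.n[:, l].astype(float)
    keep = n >= 1
    if keep.sum() < 2:
        return None
    A = counts.loci[l].n_alleles
    n_i = n[keep]
    sub_counts = counts.counts[keep, l, :A].astype(float)
    sub_het = counts.het[keep, l, :A].astype(float)
    p_i = sub_counts / (2.0 * n_i[:, None])
    h_i = sub_het / n_i[:, None]
    return n_i, p_i, h_i


def theta_from_counts(counts: AlleleCounts) -> FstResult:
    """Multi-locus theta (ratio of sums) from pre-computed allele counts."""
    num = 0.0
    den = 0.0
    per_locus: dict[str, float] = {}
    used: list[str] = []
    excluded: list[str] = []
    for l, locus in enumerate(counts.loci):
        inputs = _locus_inputs(counts, l)
        if inputs is None:
            per_locus[locus.name] = float("nan")
            excluded.append(locus.name)
            continue
        n_i, p_i, h_i = inputs
        if np.asarray(n_i).mean() <= 1:
            per_locus[locus.name] = float("nan")
            excluded.append(locus.name)
            continue
        comp, theta_l = locus_theta(n_i, p_i, h_i)
        per_locus[locus.name] = theta_l
        if np.isnan(theta_l):  # monomorphic in this comparison
            excluded.append(locus.name)
            continue
        num += comp.a.sum()
        den += (comp.a + comp.b + comp.c).sum()
        used.append(locus.name)
    if not used:
        raise FstError("no informative loci: every locus monomorphic or data-free")
    return FstResult(pd.Series(per_locus), float(num / den), used, excluded)


def multilocus_theta(
    g: GenotypeMatrix, grouping: Mapping[str, Sequence[str]]
) -> FstResult:
    """Weir–Cockerham theta over all loci for the given population grouping."""
    return theta_from_counts(allele_counts(g, grouping))


def pairwise_fst(
    g: GenotypeMatrix, grouping: Mapping[str, Sequence[str]]
) -> pd.DataFrame:
    """Symmetric population x population matrix of multi-locus theta.

    Entry (A, B) is :func:`multilocus_theta` restricted to populations
    {A, B}; the diagonal is NaN.  Loci monomorphic within a pair are
    skipped in that pair's sums.
    """
    pops = sorted(grouping)
    if len(pops) < 2:
        raise FstError("pairwise theta needs at least 2 populations")
    counts = allele_counts(g, grouping)
    if np.any(counts.n.sum(axis=1) == 0):
        empty = [pops[i] for i in np.flatnonzero(counts.n.sum(axis=1) == 0)]
        raise FstError(f"populations with no genotype data at any locus: {empty}")
    mat = pd.DataFrame(np.nan, index=pops, columns=pops, dtype=float)
    for i in range(len(pops)):
        for j in range(i + 1, len(pops)):
            sub = AlleleCounts(
                [pops[i], pops[j]],
                counts.loci,
                counts.counts[[i, j]],
                counts.het[[i, j]],
                counts.n[[i, j]],
            )
            theta = theta_from_counts(sub).theta
            mat.iloc[i, j] = theta
            mat.iloc[j, i] = theta
    return mat
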