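"""False-SNP recoding of multi-allelic genotypes and PCA of the result.

Each (locus, allele) pair becomes one binary column scoring the presence
or absence of that allele in the individual's genotype, turning L
multi-allelic markers into Sigma_l A_l pseudo-SNP columns.  PCA of the
mean-centered (optionally frequency-normalized) matrix then exposes
population structure as the top axes of variation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import GenotypeError, GenotypeMatrix


class PcaError(ValueError):
    pass


@dataclass
class FalseSnpMatrix:
    """N x M binary presence/absence matrix with per-locus missing masking.

    ``values`` holds 0/1 floats with NaN across all of a locus's columns
    where that individual's call is missing.  ``columns`` pairs each column
    with its (locus name, allele code).
    """

    values: np.ndarray
    columns: list[tuple[str, int]]
    individuals: list[str]

    def frame(self) -> pd.DataFrame:
        names = [f"{loc}:{al}" for loc, al in self.columns]
        return pd.DataFrame(self.values, index=self.individuals, columns=names)


@dataclass
class PcaResult:
    """Coordinates, eigenvalues and variance fractions of the decomposition.

    ``var_frac`` covers every principal axis (it sums to 1); ``coords``
    holds the top ``n_pcs`` coordinates per individual.
    """

    coords: np.ndarray
    eigenvalues: np.ndarray
    var_frac: np.ndarray
    individuals: list[str]

    def frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.coords.shape[1])]
        return pd.DataFrame(self.coords, index=self.individuals, columns=cols)


def recode_false_snp(g: GenotypeMatrix, dosage: bool = False) -> FalseSnpMatrix:
    """Binary presence/absence encoding of every (locus, allele) pair.

    With ``dosage`` the column instead counts copies (0/1/2), the coding
    used by SNP-style PCA; presence/absence is the default.
    """
    N = g.n_individuals
    cols: list[tuple[str, int]] = []
    blocks: list[np.ndarray] = []
    miss = g.missing_mask
    for l, locus in enumerate(g.loci):
        block = np.zeros((N, locus.n_alleles))
        calls = g.calls[:, l, :]
        for u, code in enumerate(locus.allele_codes):
            hits = (calls == code).sum(axis=1).astype(float)
            block[:, u] = hits if dosage else (hits > 0).astype(float)
        block[miss[:, l], :] = np.nan
        blocks.append(block)
        cols.extend((locus.name, code) for code in locus.allele_codes)
    return FalseSnpMatrix(np.hstack(blocks), cols, list(g.individuals))


def run_pca(x: FalseSnpMatrix, normalize: bool = False, n_pcs: int = 10) -> PcaResult:
    """PCA of the false-SNP matrix.

    Columns are mean-centered with missing entries imputed to the column
    mean; with ``normalize`` each column is further divided by
    sqrt(p(1-p)) where p is the column frequency (monomorphic columns are
    dropped).  Coordinates and eigenvalues come from the spectral
    decomposition of the individual x individual covariance; the variance
    fraction of each axis is its eigenvalue over the trace.
    """
    v = np.array(x.values, dtype=float)
    n, m = v.shape
    if n < 2 or m < 1:
        raise PcaError("PCA needs at least 2 individuals and 1 column")
    col_mean = np.nanmean(v, axis=0)
    inds = np.where(np.isnan(v))
    v[inds] = np.take(col_mean, inds[1])
    centered = v - col_mean
    if normalize:
        p = col_mean if np.nanmax(x.values) <= 1.0 else col_mean / 2.0
        keep = (p > 0) & (p < 1)
        if not np.any(keep):
            raise PcaError("every column is monomorphic")
        centered = centered[:, keep] / np.sqrt(p[keep] * (1.0 - p[keep]))
    if not np.any(np.abs(centered) > 0):
        raise PcaError("every column is monomorphic")
    # SVD of the centered matrix <=> eigendecomposition of the N x N covariance
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    eig = s**2 / max(n - 1, 1)
    var_frac = eig / eig.sum()
    k = min(n_pcs, s.size)
    coords = u[:, :k] * s[:k]
    return PcaResult(coords, eig, var_frac, list(x.individuals))
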