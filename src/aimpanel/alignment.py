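"""Label-switching alignment and averaging of replicate membership matrices.

Cluster labels are arbitrary across MCMC runs: the same partition can come
back with columns permuted.  Before replicate Q matrices can be averaged,
each run is aligned to a reference run (the first) by the column
permutation maximizing the pairwise similarity

    G(Qa, Qb) = 1 - ||Qa - Qb||_F / sqrt(2 N),

which is 1 iff the matrices agree and 0 when their rows are disjoint
one-hot vectors.  For K <= 8 the K! permutations are searched exhaustively;
for larger K the optimal assignment on the column cross-product cost gives
the same maximizer of G.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment


class AlignmentError(ValueError):
    pass


@dataclass
class Alignment:
    """Per-run permutations, scores against the reference, and the average.

    ``permutations[r]`` is the column order ``perm`` such that
    ``runs[r][:, perm]`` best matches the reference; ``scores[r]`` the
    post-alignment similarity; ``average`` the mean of the aligned runs
    (rows sum to 1).
    """

    permutations: list[tuple[int, ...]]
    scores: list[float]
    average: np.ndarray


def similarity(qa: np.ndarray, qb: np.ndarray) -> float:
    """Pairwise similarity G in [0, 1] between two membership matrices."""
    qa = np.asarray(qa, dtype=float)
    qb = np.asarray(qb, dtype=float)
    if qa.shape != qb.shape:
        raise AlignmentError(f"shape mismatch: {qa.shape} vs {qb.shape}")
    n = qa.shape[0]
    return float(1.0 - np.linalg.norm(qa - qb) / np.sqrt(2.0 * n))


def _best_permutation_exhaustive(ref: np.ndarray, q: np.ndarray) -> tuple[int, ...]:
    k = ref.shape[1]
    best_perm, best_score = None, -np.inf
    for perm in itertools.permutations(range(k)):
        s = similarity(ref, q[:, perm])
        if s > best_score:
            best_perm, best_score = perm, s
    return tuple(best_perm)


def _best_permutation_assignment(ref: np.ndarray, q: np.ndarray) -> tuple[int, ...]:
    # maximizing G is minimizing ||q[:, perm] - ref||^2, i.e. maximizing
    # sum_j ref[:, j] . q[:, perm_j] — a linear assignment problem
    cost = -(ref.T @ q)  # (K, K): cost[j, c] for placing column c at slot j
    _, cols = linear_sum_assignment(cost)
    return tuple(int(c) for c in cols)


def best_permutation(ref: np.ndarray, q: np.ndarray, method: str = "auto") -> tuple[int, ...]:
    """Column order of ``q`` maximizing similarity to ``ref``.

    ``method``: 'exhaustive' (K! search), 'assignment' (Hungarian), or
    'auto' (exhaustive for K <= 8).
    """
    if ref.shape != q.shape:
        raise AlignmentError(f"shape mismatch: {ref.shape} vs {q.shape}")
    k = ref.shape[1]
    if method == "auto":
        method = "exhaustive" if k <= 8 else "assignment"
    if method == "exhaustive":
        return _best_permutation_exhaustive(ref, q)
    if method == "assignment":
        return _best_permutation_assignment(ref, q)
    raise AlignmentError(f"unknown method {method!r}")


def align_to_reference(runs: list[np.ndarray], method: str = "auto") -> Alignment:
    """Align replicate membership matrices to the first run and average.

    All runs must share N and K.  The average is the elementwise mean of
    the permuted runs; its rows sum to 1 because each aligned run's do.
    """
    if not runs:
        raise AlignmentError("no runs to align")
    mats = [np.asarray(q, dtype=float) for q in runs]
    ref = mats[0]
    for i, m in enumerate(mats[1:], start=2):
        if m.shape != ref.shape:
            raise AlignmentError(
                f"run {i} has shape {m.shape}, reference has {ref.shape}"
            )
    perms: list[tuple[int, ...]] = []
    scores: list[float] = []
    aligned = []
    for m in mats:
        perm = best_permutation(ref, m, method=method)
        am = m[:, perm]
        perms.append(perm)
        scores.append(similarity(ref, am))
        aligned.append(am)
    average = np.mean(aligned, axis=0)
    return Alignment(perms, scores, average)
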