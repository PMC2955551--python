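"""Marker-panel selection by F_st informativeness.

The cascade: estimate per-locus theta across reference populations,
keep loci at or above a threshold (the ancestry-informative candidates),
then reduce the panel stepwise to smaller target sizes, re-ranking by
global theta recomputed on each intermediate panel.  Panels can be
evaluated by pairwise F_st, a clustering K sweep, and PCA.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .admixture import AdmixtureConfig
from .fst import FstError, multilocus_theta, pairwise_fst
from .genotype_io import GenotypeMatrix
from .k_selection import delta_k, run_k_sweep
from .pca_falsesnp import recode_false_snp, run_pca


class PanelError(ValueError):
    pass


@dataclass
class PanelCandidate:
    """An ordered marker panel with its per-locus theta ranking."""

    loci: list[str]
    theta: pd.Series  # per-locus theta, same order as loci
    provenance: str

    @property
    def size(self) -> int:
        return len(self.loci)


@dataclass
class PanelReport:
    """Evaluation of one panel: pairwise F_st plus optional clustering/PCA."""

    size: int
    pairwise: pd.DataFrame
    best_k: int | None = None
    pca_var_frac: np.ndarray | None = None


@dataclass
class PanelEvalConfig:
    """What :func:`evaluate_panel` runs beyond pairwise F_st."""

    run_clustering: bool = False
    run_pca: bool = False
    k_values: Sequence[int] = (1, 2, 3, 4, 5, 6)
    replicates: int = 3
    mcmc: AdmixtureConfig | None = None
    seed: int = 0
    normalize_pca: bool = False


def _sorted_by_theta(theta: pd.Series) -> pd.Series:
    """Descending by theta, ties broken by locus name for determinism."""
    frame = theta.rename("theta").rename_axis("locus").reset_index()
    frame = frame.sort_values(["theta", "locus"], ascending=[False, True])
    return frame.set_index("locus")["theta"]


def threshold_filter(per_locus_theta: pd.Series, threshold: float) -> PanelCandidate:
    """Loci with theta >= threshold (inclusive), sorted descending.

    An empty result is returned (not raised) so callers can react.
    """
    theta = per_locus_theta.dropna()
    kept = _sorted_by_theta(theta[theta >= threshold])
    return PanelCandidate(
        list(kept.index), kept, provenance=f"threshold>={threshold}"
    )


def stepwise_reduce(
    panel: PanelCandidate,
    target_sizes: Sequence[int],
    g: GenotypeMatrix,
    grouping: Mapping[str, Sequence[str]],
) -> list[PanelCandidate]:
    """Reduce a panel to successively smaller sizes.

    At each step the global per-locus theta is recomputed on the current
    panel's loci and the top-N are retained, so each panel is a subset of
    the previous one and sizes match ``target_sizes`` exactly.
    """
    sizes = list(target_sizes)
    if any(b >= a for a, b in zip([panel.size] + sizes, sizes)):
        raise PanelError(
            f"target sizes {sizes} must be strictly decreasing and < {panel.size}"
        )
    out: list[PanelCandidate] = []
    current = panel
    for target in sizes:
        result = multilocus_theta(g.subset_loci(current.loci), grouping)
        ranked = _sorted_by_theta(result.per_locus.dropna())
        kept = ranked.iloc[:target]
        current = PanelCandidate(
            list(kept.index), kept, provenance=f"reduced-to-{target}"
        )
        out.append(current)
    return out


def evaluate_panel(
    panel: PanelCandidate,
    g: GenotypeMatrix,
    grouping: Mapping[str, Sequence[str]],
    cfg: PanelEvalConfig = PanelEvalConfig(),
) -> PanelReport:
    """Pairwise F_st on the panel, plus a K sweep and PCA when enabled."""
    if len(grouping) < 2:
        raise PanelError("panel evaluation needs at least 2 populations")
    sub = g.subset_loci(panel.loci)
    report = PanelReport(size=panel.size, pairwise=pairwise_fst(sub, grouping))
    if cfg.run_clustering:
        base = cfg.mcmc or AdmixtureConfig(k=2, burn_in=500, iterations=500)
        sweep = run_k_sweep(
            sub, base, list(cfg.k_values), cfg.replicates, master_seed=cfg.seed,
            keep_runs=False,
        )
        report.best_k = delta_k(sweep).best_k
    if cfg.run_pca:
        result = run_pca(recode_false_snp(sub), normalize=cfg.normalize_pca)
        report.pca_var_frac = result.var_frac
    return report
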