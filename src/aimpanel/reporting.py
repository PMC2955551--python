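"""Cohort-level ancestry reporting and end-to-end orchestration.

Given per-individual ancestry proportions labeled by reference-anchored
ancestry names, this module summarizes each self-declared group
(mean, sd, median, quartiles, 10th/90th percentiles), compares groups by
Welch two-sample t-tests on a named ancestry, and flags individuals whose
dominant inferred ancestry contradicts their declared group.  A pipeline
driver chains simulation/loading, F_st, optional panel selection, the K
sweep, replicate alignment, reference labeling, PCA and the summaries
under one master seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .admixture import (
    AdmixtureConfig,
    label_clusters_by_reference,
    labeled_q_frame,
)
from .alignment import align_to_reference
from .fst import multilocus_theta, pairwise_fst
from .genotype_io import GenotypeMatrix, grouping_from_metadata
from .k_selection import delta_k, run_k_sweep
from .panel_selection import PanelCandidate, stepwise_reduce, threshold_filter
from .pca_falsesnp import recode_false_snp, run_pca
from .simulate import SimulationConfig, simulate_dataset


class ReportingError(ValueError):
    pass


SUMMARY_COLUMNS = [
    "declared_group", "ancestry", "mean", "sd", "median",
    "q25", "q75", "p10", "p90", "n",
]


def summarize_groups(q_labeled: pd.DataFrame, metadata: pd.DataFrame) -> pd.DataFrame:
    """Per (declared group, ancestry) distribution summary of proportions.

    ``q_labeled`` is individuals x ancestry labels (rows sum to 1);
    individuals without a declared group are skipped.  sd is the sample
    standard deviation (ddof=1; 0 for singleton groups).
    """
    declared = dict(zip(metadata["sample_id"], metadata["declared_group"]))
    rows = []
    groups: dict[str, list[str]] = {}
    for sid in q_labeled.index:
        grp = declared.get(sid)
        if grp is None or (isinstance(grp, float) and np.isnan(grp)):
            continue
        groups.setdefault(str(grp), []).append(sid)
    for grp in sorted(groups):
        block = q_labeled.loc[groups[grp]]
        for ancestry in q_labeled.columns:
            v = block[ancestry].to_numpy(dtype=float)
            rows.append(
                {
                    "declared_group": grp,
                    "ancestry": ancestry,
                    "mean": float(v.mean()),
                    "sd": float(v.std(ddof=1)) if v.size > 1 else 0.0,
                    "median": float(np.median(v)),
                    "q25": float(np.percentile(v, 25)),
                    "q75": float(np.percentile(v, 75)),
                    "p10": float(np.percentile(v, 10)),
                    "p90": float(np.percentile(v, 90)),
                    "n": int(v.size),
                }
            )
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)


def compare_groups(
    q_labeled: pd.DataFrame,
    metadata: pd.DataFrame,
    group_a: str,
    group_b: str,
    ancestry: str,
) -> tuple[float, float]:
    """Welch two-sample t-test on one ancestry's proportions between two
    declared groups; returns (t, p).

    Two degenerate groups (zero variance in both) with equal means give
    (0.0, 1.0) by convention.
    """
    declared = dict(zip(metadata["sample_id"], metadata["declared_group"]))
    va, vb = [], []
    for sid in q_labeled.index:
        grp = declared.get(sid)
        if grp == group_a:
            va.append(float(q_labeled.at[sid, ancestry]))
        elif grp == group_b:
            vb.append(float(q_labeled.at[sid, ancestry]))
    if len(va) < 2 or len(vb) < 2:
        raise ReportingError(
            f"both groups need n >= 2 (got {len(va)} and {len(vb)})"
        )
    a, b = np.asarray(va), np.asarray(vb)
    if a.var() == 0.0 and b.var() == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float("inf") if a.mean() > b.mean() else float("-inf"), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


@dataclass(frozen=True)
class DiscordanceFlag:
    """An individual whose dominant inferred ancestry contradicts the
    ancestry expected for their declared group."""

    sample_id: str
    declared_group: str
    dominant_ancestry: str
    dominant_proportion: float


def flag_discordant(
    q_labeled: pd.DataFrame,
    metadata: pd.DataFrame,
    expected: Mapping[str, str],
    cutoff: float = 0.95,
) -> list[DiscordanceFlag]:
    """Flag individuals with dominant proportion >= cutoff whose dominant
    ancestry label differs from the one their declared group maps to.

    ``expected`` maps declared group -> ancestry label; groups absent from
    the map are never flagged.
    """
    declared = dict(zip(metadata["sample_id"], metadata["declared_group"]))
    flags: list[DiscordanceFlag] = []
    for sid in q_labeled.index:
        grp = declared.get(sid)
        if grp is None or grp not in expected:
            continue
        row = q_labeled.loc[sid]
        dominant = str(row.idxmax())
        prop = float(row.max())
        if prop >= cutoff and dominant != expected[grp]:
            flags.append(DiscordanceFlag(str(sid), str(grp), dominant, prop))
    return flags


# ---------------------------------------------------------------------------
# pipeline orchestration


@dataclass
class PipelineConfig:
    """End-to-end run settings.

    Either ``simulation`` (generate data) or pre-built inputs passed to
    :func:`run_pipeline` directly.  ``k_values``/``replicates`` drive the
    model-selection sweep; ``panel_threshold``/``panel_targets`` enable the
    marker-selection cascade; ``expected_ancestry`` maps declared groups to
    reference population labels for discordance flagging.  All randomness
    derives from ``master_seed``.
    """

    simulation: SimulationConfig | None = None
    mcmc: AdmixtureConfig = field(
        default_factory=lambda: AdmixtureConfig(k=2, burn_in=1000, iterations=1000)
    )
    k_values: Sequence[int] = (1, 2, 3, 4, 5, 6)
    replicates: int = 3
    panel_threshold: float | None = None
    panel_targets: Sequence[int] = ()
    run_pca: bool = True
    discordance_cutoff: float = 0.95
    expected_ancestry: Mapping[str, str] = field(default_factory=dict)
    master_seed: int = 0
    outdir: str | None = None


@dataclass
class PipelineResult:
    """Everything one pipeline run computed."""

    genotypes: GenotypeMatrix
    metadata: pd.DataFrame
    fst_per_locus: pd.Series
    fst_global: float
    pairwise: pd.DataFrame
    panels: list[PanelCandidate]
    delta_k_table: pd.DataFrame
    best_k: int | None
    q_average: pd.DataFrame  # individuals x clusters, replicate-averaged
    labeling: list[str]
    q_labeled: pd.DataFrame  # individuals x ancestry labels
    pca_var_frac: np.ndarray | None
    pca_coords: pd.DataFrame | None
    summary: pd.DataFrame
    flags: list[DiscordanceFlag]
    manifest: dict


def run_pipeline(
    config: PipelineConfig,
    genotypes: GenotypeMatrix | None = None,
    metadata: pd.DataFrame | None = None,
) -> PipelineResult:
    """Execute the full workflow on simulated or supplied data.

    Stages: data -> F_st (global, per-locus, pairwise) -> optional panel
    reduction -> K sweep + delta-K -> alignment of the best-K replicates ->
    reference labeling -> optional PCA -> group summaries and discordance
    flags.  Deterministic for a fixed config and master seed.
    """
    stage = "input"
    try:
        if genotypes is None:
            if config.simulation is None:
                raise ReportingError("supply genotypes+metadata or a simulation config")
            sim_cfg = replace(config.simulation, seed=config.master_seed)
            sim = simulate_dataset(sim_cfg)
            genotypes, metadata = sim.genotypes, sim.metadata
        if metadata is None:
            raise ReportingError("metadata required alongside genotypes")

        stage = "fst"
        grouping = grouping_from_metadata(metadata)
        fst = multilocus_theta(genotypes, grouping)
        pw = pairwise_fst(genotypes, grouping)

        stage = "panel_selection"
        panels: list[PanelCandidate] = []
        working = genotypes
        if config.panel_threshold is not None:
            cand = threshold_filter(fst.per_locus, config.panel_threshold)
            panels.append(cand)
            if config.panel_targets:
                panels.extend(
                    stepwise_reduce(cand, config.panel_targets, genotypes, grouping)
                )
            working = genotypes.subset_loci(panels[-1].loci)

        stage = "k_sweep"
        sweep = run_k_sweep(
            working, config.mcmc, list(config.k_values), config.replicates,
            master_seed=config.master_seed,
        )
        dk = delta_k(sweep)
        best_k = dk.best_k if dk.best_k is not None else max(config.k_values)

        stage = "alignment"
        reps = [
            sweep.runs[(best_k, r)].q_mean for r in range(config.replicates)
        ]
        aligned = align_to_reference(reps)
        q_avg = pd.DataFrame(
            aligned.average,
            index=genotypes.individuals,
            columns=[f"cluster{k + 1}" for k in range(best_k)],
        )

        stage = "labeling"
        labeling = label_clusters_by_reference(q_avg, metadata)
        q_labeled = labeled_q_frame(q_avg, labeling)

        stage = "pca"
        pca_var, pca_coords = None, None
        if config.run_pca:
            res = run_pca(recode_false_snp(working))
            pca_var = res.var_frac
            pca_coords = res.frame()

        stage = "reporting"
        summary = summarize_groups(q_labeled, metadata)
        flags = flag_discordant(
            q_labeled, metadata, config.expected_ancestry, config.discordance_cutoff
        )
    except Exception as exc:
        raise ReportingError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "master_seed": config.master_seed,
        "k_values": list(config.k_values),
        "replicates": config.replicates,
        "best_k": best_k,
        "delta_k_unresolved": dk.unresolved,
        "fst_global": fst.theta,
        "n_individuals": genotypes.n_individuals,
        "n_loci": genotypes.n_loci,
        "panel_sizes": [p.size for p in panels],
        "replicate_seeds": {f"{k}:{r}": s for (k, r), s in sweep.seeds.items()},
    }
    result = PipelineResult(
        genotypes=genotypes,
        metadata=metadata,
        fst_per_locus=fst.per_locus,
        fst_global=fst.theta,
        pairwise=pw,
        panels=panels,
        delta_k_table=dk.table,
        best_k=best_k,
        q_average=q_avg,
        labeling=labeling.labels,
        q_labeled=q_labeled,
        pca_var_frac=pca_var,
        pca_coords=pca_coords,
        summary=summary,
        flags=flags,
        manifest=manifest,
    )
    if config.outdir:
        write_artifacts(result, Path(config.outdir))
    return result


def write_artifacts(result: PipelineResult, outdir: Path) -> None:
    """Write the run's tables and manifest as CSV/JSON under ``outdir``."""
    outdir.mkdir(parents=True, exist_ok=True)
    result.fst_per_locus.rename("theta").to_csv(outdir / "fst_per_locus.csv")
    result.pairwise.to_csv(outdir / "fst_pairwise.csv")
    result.delta_k_table.to_csv(outdir / "delta_k.csv")
    result.q_average.to_csv(outdir / "q_average.csv")
    result.q_labeled.to_csv(outdir / "q_labeled.csv")
    result.summary.to_csv(outdir / "group_summary.csv", index=False)
    if result.pca_coords is not None:
        result.pca_coords.to_csv(outdir / "pca_coords.csv")
    flags = [vars(f) for f in result.flags]
    (outdir / "discordance_flags.json").write_text(json.dumps(flags, indent=2))
    (outdir / "manifest.json").write_text(json.dumps(result.manifest, indent=2))


# ---------------------------------------------------------------------------
# minimal inspection plots


def stacked_bar_plot(q_labeled: pd.DataFrame, path: str | Path) -> None:
    """One stacked bar of ancestry proportions per individual."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(max(6, len(q_labeled) * 0.05), 3))
    bottom = np.zeros(len(q_labeled))
    xs = np.arange(len(q_labeled))
    for col in q_labeled.columns:
        vals = q_labeled[col].to_numpy()
        ax.bar(xs, vals, bottom=bottom, width=1.0, label=col)
        bottom += vals
    ax.set_xlim(-0.5, len(q_labeled) - 0.5)
    ax.set_ylim(0, 1)
    ax.set_ylabel("ancestry proportion")
    ax.legend(fontsize="small", ncol=min(len(q_labeled.columns), 5))
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def pc_scatter_plot(
    coords: pd.DataFrame, metadata: pd.DataFrame, path: str | Path,
    pcs: tuple[int, int] = (1, 2),
) -> None:
    """Scatter of two principal components, colored by population label."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = dict(zip(metadata["sample_id"], metadata["population_label"]))
    fig, ax = plt.subplots(figsize=(5, 4))
    cx, cy = f"PC{pcs[0]}", f"PC{pcs[1]}"
    series = pd.Series([labels.get(s) or "query" for s in coords.index], index=coords.index)
    for grp in sorted(set(series)):
        sel = series == grp
        ax.scatter(coords.loc[sel, cx], coords.loc[sel, cy], s=10, label=grp)
    ax.set_xlabel(cx)
    ax.set_ylabel(cy)
    ax.legend(fontsize="small")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
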