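"""Canonical-panel co-expression scoring of phasic structure.

In unsorted cycling populations, genes regulated at the same cell-cycle
transition co-vary across cells once phasic expression is established.
This module scores that structure with pairwise Pearson correlations of
the canonical G1/S and G2/M gene panels within random same-stage cell
cohorts: within-panel correlations rise and between-panel correlations
turn negative as phasing emerges over developmental stages.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .containers import CountMatrix, ValidationError
from .stats import cpm

logger = logging.getLogger(__name__)


def load_panels() -> dict[str, list[str]]:
    """The canonical G1/S and G2/M phase gene panels (mouse symbols)."""
    with resources.files("phasic.data").joinpath("phase_panels.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    return {name: sub["gene"].tolist() for name, sub in df.groupby("panel")}


@dataclass
class CohortCorrelation:
    """Pairwise panel-gene correlations within one random cell cohort."""

    stage: str
    group: str
    cohort_cells: list[str]
    genes: list[str]
    corr: np.ndarray
    mean_within_G1S: float
    mean_within_G2M: float
    mean_between: float


def _offdiag_mean(corr: np.ndarray, rows, cols) -> float:
    rows = np.asarray(rows)
    cols = np.asarray(cols)
    vals = []
    for i in rows:
        for j in cols:
            if i == j:
                continue
            v = corr[i, j]
            if np.isfinite(v):
                vals.append(v)
    return float(np.mean(vals)) if vals else np.nan


def cohort_correlation(counts: CountMatrix, annotations: pd.DataFrame,
                       stage: str, group: str,
                       panels: dict[str, list[str]] | None = None,
                       cohort_size: int = 50,
                       rng: np.random.Generator | None = None
                       ) -> CohortCorrelation:
    """Panel-gene Pearson correlations in one random same-stage cohort.

    Draws ``cohort_size`` cells without replacement from the given stage
    and group, computes pairwise Pearson correlations of log2(CPM+1) over
    the panel genes, and summarizes within- and between-panel means over
    off-diagonal entries.  Genes absent from the matrix are dropped with a
    warning; zero-variance genes are excluded from the summaries.
    """
    panels = panels or load_panels()
    rng = rng or np.random.default_rng(0)
    ann = annotations.set_index("unit_id").loc[counts.unit_ids].reset_index()
    sel = (ann["stage"].astype(str) == str(stage)) & \
          (ann["lineage"].astype(str) == str(group))
    ids = ann.loc[sel, "unit_id"].to_numpy()
    if ids.size < cohort_size:
        raise ValidationError(
            f"group {group!r} at stage {stage!r} has {ids.size} cells "
            f"< cohort size {cohort_size}")
    cohort = rng.choice(ids, size=cohort_size, replace=False)
    sub = counts.subset_units(np.isin(counts.unit_ids, cohort))

    present = set(sub.gene_ids)
    genes, labels = [], []
    for panel_name in ("G1S", "G2M"):
        for g in panels[panel_name]:
            if g in present:
                genes.append(g)
                labels.append(panel_name)
            else:
                logger.warning("panel gene %s absent from matrix; dropped", g)
    if len(genes) < 2:
        raise ValidationError("fewer than 2 panel genes present")
    expr = cpm(sub, log2=True)
    idx = {g: i for i, g in enumerate(sub.gene_ids)}
    mat = expr[[idx[g] for g in genes], :]
    sd = mat.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(mat)
    corr[sd == 0, :] = np.nan
    corr[:, sd == 0] = np.nan
    np.fill_diagonal(corr, 1.0)
    labels = np.asarray(labels)
    g1s = np.flatnonzero(labels == "G1S")
    g2m = np.flatnonzero(labels == "G2M")
    return CohortCorrelation(
        stage=str(stage), group=str(group),
        cohort_cells=[str(c) for c in cohort], genes=genes, corr=corr,
        mean_within_G1S=_offdiag_mean(corr, g1s, g1s),
        mean_within_G2M=_offdiag_mean(corr, g2m, g2m),
        mean_between=_offdiag_mean(corr, g1s, g2m),
    )


def coexpression_trend(counts: CountMatrix, annotations: pd.DataFrame,
                       stages, group: str,
                       panels: dict[str, list[str]] | None = None,
                       n_cohorts: int = 20, cohort_size: int = 50,
                       seed: int = 1) -> pd.DataFrame:
    """Per-stage distributions of cohort correlation summaries.

    Repeats :func:`cohort_correlation` ``n_cohorts`` times per stage and
    returns a long table with one row per (stage, cohort) holding the
    within- and between-panel summary means, suitable for testing an
    increasing trend of phasic co-expression across stages.
    """
    panels = panels or load_panels()
    rows = []
    for s_idx, stage in enumerate(stages):
        for c in range(n_cohorts):
            rng = np.random.default_rng([seed, s_idx, c])
            cc = cohort_correlation(counts, annotations, stage, group,
                                    panels, cohort_size, rng)
            rows.append({
                "stage": str(stage), "group": str(group), "cohort": c,
                "mean_within_G1S": cc.mean_within_G1S,
                "mean_within_G2M": cc.mean_within_G2M,
                "mean_between": cc.mean_between,
            })
    return pd.DataFrame(rows)
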