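"""Single-cell phasic-expression pipeline.

QC filters, pseudobulk construction, the permutation median-FDR phasic
caller with its fold-change gate, the scrambled-lineage interaction null,
equal-phase down-sampling and genotype comparisons.

The caller works on pseudobulk aggregates (sums of ``pseudobulk_size``
cells sharing phase, and lineage unless scrambled) to mitigate dropout.
Because no block of cells recapitulates a real cell, the blocking is
re-randomized ``n_permutations`` times and each gene's call is the median
of its BH-adjusted hurdle p-values across permutations, gated by an
absolute fold-change of ``fc_threshold`` (a ratio; the gate on the log2
scale is ``|log2fc| > log2(fc_threshold)``).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CountMatrix, PipelineConfig, ValidationError, compute_qc_fields
from .hurdle import build_design, interaction_contrasts_batch, lrt_term_batch
from .stats import bh_adjust, cpm

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# QC filters
# ---------------------------------------------------------------------------

def qc_filter_cells(counts: CountMatrix, annotations: pd.DataFrame,
                    config: PipelineConfig) -> tuple[CountMatrix, pd.DataFrame]:
    """Remove low-quality cells: UMI floor, mito ceiling, relative detection.

    Filters are applied in order — total UMI >= ``min_umi``, mitochondrial
    fraction < ``max_mito_fraction``, then detected genes >= ``min_rel_detection``
    of the maximum among cells surviving the first two filters.  The
    detection fraction is recomputed on the survivors.
    """
    ann = compute_qc_fields(counts, annotations, config.mito_prefix)
    keep = ann["total_umi"].to_numpy() >= config.min_umi
    keep &= ann["mito_fraction"].to_numpy() < config.max_mito_fraction
    det = ann["n_detected_genes"].to_numpy()
    if keep.any():
        rel = det / det[keep].max()
        keep &= rel >= config.min_rel_detection
    if not keep.any():
        raise ValidationError("no cells survive QC; review thresholds")
    out = counts.subset_units(keep)
    ann = compute_qc_fields(out, annotations, config.mito_prefix)
    return out, ann


def filter_genes_sc(counts: CountMatrix, config: PipelineConfig) -> CountMatrix:
    """Keep genes detected (count > 0) in at least ``min_gene_cell_fraction``
    of all cells."""
    frac = (counts.counts > 0).mean(axis=1)
    return counts.subset_genes(frac >= config.min_gene_cell_fraction)


# ---------------------------------------------------------------------------
# pseudobulk
# ---------------------------------------------------------------------------

@dataclass
class PseudobulkSet:
    """One permutation of pseudobulk aggregates.

    ``counts`` holds the exact column sums of each sample's member cells;
    ``samples`` records phase, lineage and the member cell ids; cells left
    over after blocking are listed in ``dropped_cells``.
    """

    counts: CountMatrix
    samples: pd.DataFrame          # sample_id, phase, lineage, member_cell_ids
    dropped_cells: list[str]
    permutation_index: int = 0


def make_pseudobulk(counts: CountMatrix, annotations: pd.DataFrame,
                    group_by=("phase",), size: int = 10,
                    rng: np.random.Generator | None = None,
                    permutation_index: int = 0) -> PseudobulkSet:
    """Sum disjoint random blocks of ``size`` cells sharing the group keys.

    Within each group (phase, or phase and lineage), cells are shuffled and
    partitioned into blocks of exactly ``size``; leftover cells are dropped
    and recorded.  Groups smaller than ``size`` are skipped with a warning.
    """
    rng = rng or np.random.default_rng(0)
    ann = annotations.set_index("unit_id").loc[counts.unit_ids]
    group_by = list(group_by)
    pos = {u: i for i, u in enumerate(counts.unit_ids)}
    samples, cols, dropped = [], [], []
    sid = 0
    for key, sub in ann.groupby(group_by, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        ids = sub.index.to_numpy()
        if ids.size < size:
            logger.warning("group %s has %d cells < pseudobulk size %d; skipped",
                           key, ids.size, size)
            dropped.extend(ids.tolist())
            continue
        perm = rng.permutation(ids.size)
        n_blocks = ids.size // size
        for b in range(n_blocks):
            members = ids[perm[b * size:(b + 1) * size]]
            idx = [pos[m] for m in members]
            cols.append(counts.counts[:, idx].sum(axis=1))
            rec = {"sample_id": f"pb{sid:04d}",
                   "member_cell_ids": ",".join(members.tolist())}
            rec.update(dict(zip(group_by, key)))
            samples.append(rec)
            sid += 1
        dropped.extend(ids[perm[n_blocks * size:]].tolist())
    if not samples:
        raise ValidationError("no group is large enough for pseudobulk")
    sample_df = pd.DataFrame(samples)
    pb = CountMatrix(counts.gene_ids, sample_df["sample_id"].to_numpy(),
                     np.column_stack(cols), counts.layer_name)
    return PseudobulkSet(pb, sample_df, dropped, permutation_index)


def scramble_lineage_pseudobulk(counts: CountMatrix, annotations: pd.DataFrame,
                                size: int = 10,
                                rng: np.random.Generator | None = None,
                                permutation_index: int = 0) -> PseudobulkSet:
    """Pseudobulk from same-phase cells of mixed lineages (negative control).

    Blocks are drawn within phase ignoring lineage, then assigned lineage
    labels so that every (phase, lineage) stratum holds exactly as many
    pseudobulk samples as the matched-lineage construction would.
    """
    rng = rng or np.random.default_rng(0)
    ann = annotations.set_index("unit_id").loc[counts.unit_ids]
    pos = {u: i for i, u in enumerate(counts.unit_ids)}
    samples, cols, dropped = [], [], []
    sid = 0
    for phase, sub in ann.groupby("phase", sort=True):
        # matched-construction sample counts per lineage
        lineage_counts = sub.groupby("lineage").size().sort_index()
        blocks_per_lineage = (lineage_counts // size)
        labels = np.repeat(blocks_per_lineage.index.to_numpy(),
                           blocks_per_lineage.to_numpy())
        ids = sub.index.to_numpy()
        perm = rng.permutation(ids.size)
        n_blocks = labels.size
        if ids.size < n_blocks * size:  # pragma: no cover - arithmetic guard
            n_blocks = ids.size // size
            labels = labels[:n_blocks]
        for b in range(n_blocks):
            members = ids[perm[b * size:(b + 1) * size]]
            idx = [pos[m] for m in members]
            cols.append(counts.counts[:, idx].sum(axis=1))
            samples.append({"sample_id": f"pb{sid:04d}", "phase": phase,
                            "lineage": labels[b],
                            "member_cell_ids": ",".join(members.tolist())})
            sid += 1
        dropped.extend(ids[perm[n_blocks * size:]].tolist())
    if not samples:
        raise ValidationError("no group is large enough for pseudobulk")
    sample_df = pd.DataFrame(samples)
    pb = CountMatrix(counts.gene_ids, sample_df["sample_id"].to_numpy(),
                     np.column_stack(cols), counts.layer_name)
    return PseudobulkSet(pb, sample_df, dropped, permutation_index)


def _pseudobulk_expression(pb: PseudobulkSet) -> tuple[np.ndarray, pd.DataFrame]:
    """log2(CPM + 1) of pseudobulk counts plus the detection covariate."""
    expr = cpm(pb.counts, log2=True)
    det = (pb.counts.counts > 0).sum(axis=0)
    ann = pb.samples.copy()
    ann["detection_fraction"] = det / max(det.max(), 1)
    return expr, ann


# ---------------------------------------------------------------------------
# permutation median-FDR phasic caller
# ---------------------------------------------------------------------------

def _median_with_na(values: np.ndarray) -> np.ndarray:
    """Row-wise median ignoring NAs, unless more than half are NA."""
    n = values.shape[1]
    n_na = np.isnan(values).sum(axis=1)
    med = np.full(values.shape[0], np.nan)
    ok = n_na < n
    if ok.any():
        with np.errstate(all="ignore"):
            med[ok] = np.nanmedian(values[ok], axis=1)
    med[n_na > n / 2] = np.nan
    return med


def permuted_phasic_test(counts: CountMatrix, annotations: pd.DataFrame,
                         config: PipelineConfig,
                         terms=("cell_cycle_phase", "fraction_of_detected_genes"),
                         group_by=("phase",),
                         alpha: float | None = None,
                         n_permutations: int | None = None,
                         seed: int | None = None) -> pd.DataFrame:
    """Permutation median-FDR phasic caller on pseudobulk hurdle tests.

    For each permutation the pseudobulk blocks are re-randomized, expression
    is log2(CPM+1), the hurdle LRT of the phase term (with the detection
    covariate) is BH-adjusted within the permutation, and per-gene medians
    of adjusted p and log2 fold-change are taken across permutations.
    Calls require ``median_adj_p < alpha`` and ``|median_log2fc| >
    log2(fc_threshold)``.
    """
    alpha = config.alpha_sc if alpha is None else alpha
    n_perm = config.n_permutations if n_permutations is None else n_permutations
    seed = config.rng_seed if seed is None else seed
    G = counts.n_genes
    adj = np.full((G, n_perm), np.nan)
    lfc = np.full((G, n_perm), np.nan)
    for k in range(n_perm):
        rng = np.random.default_rng([seed, k])
        pb = make_pseudobulk(counts, annotations, group_by,
                             config.pseudobulk_size, rng, k)
        expr, ann = _pseudobulk_expression(pb)
        design = build_design(ann, terms)
        res = lrt_term_batch(expr, design, "cell_cycle_phase")
        ok = res["testable"].to_numpy() & np.isfinite(res["p_value"].to_numpy())
        if ok.any():
            adj[ok, k] = bh_adjust(res.loc[ok, "p_value"].to_numpy())
        lfc[:, k] = res["log2fc"].to_numpy()
    median_adj = _median_with_na(adj)
    median_lfc = _median_with_na(lfc)
    passes_fc = np.abs(median_lfc) > np.log2(config.fc_threshold)
    passes_fc &= np.isfinite(median_lfc)
    call = (median_adj < alpha) & passes_fc
    call &= np.isfinite(median_adj)
    n_used = np.sum(~np.isnan(adj), axis=1)
    return pd.DataFrame({
        "gene_id": counts.gene_ids,
        "log2fc": median_lfc,
        "adj_p": median_adj,
        "passes_fc": passes_fc,
        "phasic_call": call,
        "n_permutations_used": n_used,
    })


def interaction_phasic_test(counts: CountMatrix, annotations: pd.DataFrame,
                            config: PipelineConfig,
                            reference_lineage: str,
                            alpha: float | None = None,
                            n_permutations: int | None = None,
                            seed: int | None = None,
                            scrambled: bool = False) -> pd.DataFrame:
    """Phase-by-lineage interaction caller with a scrambled-lineage null.

    Cells are first down-sampled to equal phase counts within each lineage.
    Each permutation builds pseudobulk matched on (phase, lineage) — or
    phase-only with matched lineage label counts when ``scrambled`` — and
    tests each non-reference lineage's interaction contrast with the hurdle
    LRT, BH-adjusted across genes within the permutation and lineage.  The
    table holds per-lineage median adjusted p and interaction effects; a
    gene is called when any lineage's median FDR falls below ``alpha``.
    """
    alpha = config.alpha_sc if alpha is None else alpha
    n_perm = config.n_permutations if n_permutations is None else n_permutations
    seed = config.rng_seed if seed is None else seed
    lineages = sorted(set(annotations["lineage"].astype(str)))
    if len(lineages) < 2:
        raise ValidationError("interaction test needs at least 2 lineages")
    if reference_lineage not in lineages:
        raise ValidationError(f"reference lineage {reference_lineage!r} absent")

    rng_ds = np.random.default_rng([seed, 999_983])
    keep_ids = downsample_equal_phase(annotations, rng_ds)
    counts = counts.subset_units(np.isin(counts.unit_ids, keep_ids))
    annotations = annotations[annotations["unit_id"].isin(keep_ids)]

    others = [l for l in lineages if l != reference_lineage]
    G = counts.n_genes
    adj = {l: np.full((G, n_perm), np.nan) for l in others}
    eff = {l: np.full((G, n_perm), np.nan) for l in others}
    terms = ("cell_cycle_phase", "lineage", "cell_cycle_phase:lineage",
             "fraction_of_detected_genes")
    for k in range(n_perm):
        rng = np.random.default_rng([seed, k])
        if scrambled:
            pb = scramble_lineage_pseudobulk(counts, annotations,
                                             config.pseudobulk_size, rng, k)
        else:
            pb = make_pseudobulk(counts, annotations, ("phase", "lineage"),
                                 config.pseudobulk_size, rng, k)
        expr, ann = _pseudobulk_expression(pb)
        design = build_design(ann, terms, reference_lineage)
        contrasts = interaction_contrasts_batch(expr, design)
        for l, res in contrasts.items():
            ok = res["testable"].to_numpy() & np.isfinite(res["p_value"].to_numpy())
            if ok.any():
                adj[l][ok, k] = bh_adjust(res.loc[ok, "p_value"].to_numpy())
            eff[l][:, k] = res["log2fc"].to_numpy()
    out = pd.DataFrame({"gene_id": counts.gene_ids})
    any_call = np.zeros(G, dtype=bool)
    for l in others:
        med = _median_with_na(adj[l])
        out[f"adj_p_{l}"] = med
        out[f"log2fc_{l}"] = _median_with_na(eff[l])
        call = np.isfinite(med) & (med < alpha)
        out[f"call_{l}"] = call
        any_call |= call
    out["phasic_call"] = any_call
    return out


def downsample_equal_phase(annotations: pd.DataFrame,
                           rng: np.random.Generator,
                           lineage_col: str = "lineage") -> np.ndarray:
    """Per lineage, random subset so both phases have min(|G1|, |G2M|) cells.

    Lineages missing a phase entirely are dropped with a warning.
    """
    kept: list[str] = []
    for lineage, sub in annotations.groupby(lineage_col, sort=True):
        sizes = sub.groupby("phase").size()
        if sizes.get("G1", 0) == 0 or sizes.get("G2M", 0) == 0:
            logger.warning("lineage %s lacks a phase; dropped", lineage)
            continue
        m = int(sizes.min())
        for phase in ("G1", "G2M"):
            ids = sub.loc[sub["phase"] == phase, "unit_id"].to_numpy()
            pick = rng.choice(ids, size=m, replace=False) if ids.size > m else ids
            kept.extend(pick.tolist())
    return np.array(kept, dtype=str)


# ---------------------------------------------------------------------------
# genotype comparison
# ---------------------------------------------------------------------------

def compare_genotype_phasic(control: tuple[CountMatrix, pd.DataFrame],
                            mutant: tuple[CountMatrix, pd.DataFrame],
                            config: PipelineConfig,
                            lineage: str | None = None,
                            n_resamples: int | None = None,
                            alpha: float | None = None,
                            seed: int | None = None) -> dict:
    """Compare phasic gene counts between genotypes within one lineage.

    In each of ``n_resamples`` rounds the same number of cells per phase is
    drawn from each genotype (the minimum across genotype x phase), one
    pseudobulk pass of the hurdle phase test is run per genotype, and
    BH-adjusted p-values are collected; a gene's evidence per genotype is
    the median adjusted p across rounds, gated by the fold-change rule.
    Returns per-genotype call counts and call tables.
    """
    alpha = config.alpha_bulk if alpha is None else alpha
    n_res = config.genotype_resamples if n_resamples is None else n_resamples
    seed = config.rng_seed if seed is None else seed
    data = {"control": control, "mutant": mutant}
    subs = {}
    for name, (cm, ann) in data.items():
        if lineage is not None:
            ann = ann[ann["lineage"].astype(str) == str(lineage)]
            cm = cm.subset_units(np.isin(cm.unit_ids, ann["unit_id"].to_numpy()))
        subs[name] = (cm, ann)
    common = np.intersect1d(subs["control"][0].gene_ids, subs["mutant"][0].gene_ids)
    n_per_phase = min(
        int((ann["phase"] == ph).sum())
        for (_, ann) in subs.values() for ph in ("G1", "G2M"))
    if n_per_phase < 2 * config.pseudobulk_size:
        raise ValidationError(
            f"lineage too small: {n_per_phase} cells per phase available")

    out = {}
    for gi, (name, (cm, ann)) in enumerate(subs.items()):
        cm = cm.subset_genes(common)
        G = cm.n_genes
        adj = np.full((G, n_res), np.nan)
        lfc = np.full((G, n_res), np.nan)
        for k in range(n_res):
            rng = np.random.default_rng([seed, gi, k])
            pick = []
            for ph in ("G1", "G2M"):
                ids = ann.loc[ann["phase"] == ph, "unit_id"].to_numpy()
                pick.extend(rng.choice(ids, size=n_per_phase, replace=False))
            sub_cm = cm.subset_units(np.isin(cm.unit_ids, np.array(pick)))
            sub_ann = ann[ann["unit_id"].isin(pick)]
            pb = make_pseudobulk(sub_cm, sub_ann, ("phase",),
                                 config.pseudobulk_size, rng, k)
            expr, pb_ann = _pseudobulk_expression(pb)
            design = build_design(
                pb_ann, ("cell_cycle_phase", "fraction_of_detected_genes"))
            res = lrt_term_batch(expr, design, "cell_cycle_phase")
            ok = res["testable"].to_numpy() & np.isfinite(res["p_value"].to_numpy())
            if ok.any():
                adj[ok, k] = bh_adjust(res.loc[ok, "p_value"].to_numpy())
            lfc[:, k] = res["log2fc"].to_numpy()
        med_adj = _median_with_na(adj)
        med_lfc = _median_with_na(lfc)
        passes_fc = np.isfinite(med_lfc) & \
            (np.abs(med_lfc) > np.log2(config.fc_threshold))
        call = np.isfinite(med_adj) & (med_adj < alpha) & passes_fc
        out[name] = pd.DataFrame({
            "gene_id": cm.gene_ids,
            "log2fc": med_lfc,
            "adj_p": med_adj,
            "passes_fc": passes_fc,
            "phasic_call": call,
        })
    return {
        "n_cells_per_phase": n_per_phase,
        "counts": {name: int(tab["phasic_call"].sum()) for name, tab in out.items()},
        "tables": out,
        "gene_lists": {name: tab.loc[tab["phasic_call"], "gene_id"].tolist()
                       for name, tab in out.items()},
    }


# ---------------------------------------------------------------------------
# phase-separation sanity check
# ---------------------------------------------------------------------------

def panel_phase_clustering_check(counts: CountMatrix, annotations: pd.DataFrame,
                                 phasic_gene_set, seed: int = 0) -> float:
    """Fraction of cells whose 2-means expression cluster matches their phase.

    Clusters cells on log2(CPM+1) of the supplied phasic gene set and
    returns the agreement with the sorted phase labels, maximized over the
    two possible cluster-to-phase mappings.
    """
    from sklearn.cluster import KMeans

    genes = [g for g in phasic_gene_set if g in set(counts.gene_ids)]
    if not genes:
        raise ValidationError("phasic gene set is empty or absent from matrix")
    ann = annotations.set_index("unit_id").loc[counts.unit_ids]
    phases = ann["phase"].to_numpy()
    for ph in ("G1", "G2M"):
        if (phases == ph).sum() < 2:
            raise ValidationError("need at least 2 cells per phase")
    expr = cpm(counts, log2=True)
    sub = counts.subset_genes(np.isin(counts.gene_ids, genes))
    idx = {g: i for i, g in enumerate(counts.gene_ids)}
    expr = expr[[idx[g] for g in sub.gene_ids], :]
    km = KMeans(n_clusters=2, n_init=10, random_state=seed)
    labels = km.fit_predict(expr.T)
    is_g2m = (phases == "G2M").astype(int)
    match = max(np.mean(labels == is_g2m), np.mean(labels == 1 - is_g2m))
    return float(match)
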