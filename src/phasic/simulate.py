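"""Synthetic phase-sorted count data with planted ground truth.

The generators emulate the structure of DNA-content-sorted expression data:

* **single-cell**: NB-distributed UMI counts (variance = mu + phi mu^2)
  with log-normal library sizes, dropout arising naturally from low means,
  a configurable fraction of genes carrying multiplicative phase effects
  (globally or restricted to one lineage), lineage baseline effects,
  mitochondrial genes named with a ``mt-`` prefix, and planted low-quality
  cells that the QC filters should remove;
* **bulk exon/intron**: paired layers where a phase effect can act on
  transcription (intron and exon move together) and/or on transcript
  stability (exon moves, intron flat), exploiting rapid intron turnover;
* **activity scores**: Gaussian per-cell scores with a phase shift, inputs
  for the KS phase-preference test.

Phase effects are split symmetrically (x 2^(+beta/2) in G2/M, x 2^(-beta/2)
in G1) so a gene's average expression across the cycle stays constant while
the differential between phases grows.  Every generator returns a truth
table recording the planted per-gene effects.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .containers import CountMatrix, ValidationError

DRIVER_CLASSES = ("TRANSCRIPTION", "STABILITY", "BOTH", "NONE")


@dataclass
class SimParams:
    """Parameters of the single-cell generator.

    Library sizes are log-normal with median ~8000 UMI (comfortably above
    the 5000-UMI QC floor); per-gene baselines are log-normal so that a
    realistic majority of genes clear the 20%-of-cells detection filter at
    Drop-seq-like capture; the NB dispersion of 0.2 gives the heavy
    dropout regime of shallow UMI data.
    """

    n_genes: int = 2000
    n_cells_per_phase_per_lineage: int = 300
    lineages: tuple[str, ...] = ("A",)
    reference_lineage: str | None = None
    genotype: str = "control"
    stage: str = "E9.5"
    baseline_mean_log: tuple[float, float] = (0.0, 1.5)   # loc/scale of ln baseline
    libsize_log: tuple[float, float] = (np.log(8000.0), 0.35)
    nb_dispersion: float = 0.2
    libsize_floor: float = 6500.0   # healthy cells stay above the QC floor
    frac_phasic: float = 0.0
    effect_log2fc: float = 1.0
    frac_interaction: float = 0.0      # fraction of phasic genes lineage-specific
    interaction_lineage: str | None = None
    lineage_effect_sd: float = 0.0     # sd of per-lineage ln baseline multipliers
    n_mito_genes: int = 13
    mito_expr_frac: float = 0.02
    frac_low_quality_cells: float = 0.0
    seed: int = 1

    def __post_init__(self) -> None:
        for name in ("frac_phasic", "frac_interaction", "mito_expr_frac",
                     "frac_low_quality_cells"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValidationError(f"{name} must lie in [0, 1]")
        if self.nb_dispersion < 0:
            raise ValidationError("nb_dispersion must be non-negative")
        if not self.lineages:
            raise ValidationError("need at least one lineage")
        if self.reference_lineage is None:
            self.reference_lineage = self.lineages[0]
        if self.reference_lineage not in self.lineages:
            raise ValidationError("reference lineage not in lineages")
        if self.interaction_lineage is not None and \
                self.interaction_lineage not in self.lineages:
            raise ValidationError("interaction lineage not in lineages")

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["lineages"] = list(self.lineages)
        d["baseline_mean_log"] = list(self.baseline_mean_log)
        d["libsize_log"] = list(self.libsize_log)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


def _nb_sample(rng: np.random.Generator, mean: np.ndarray,
               dispersion: float) -> np.ndarray:
    """NB draw with variance = mu + phi mu^2 via the gamma-Poisson mixture."""
    mean = np.maximum(mean, 1e-12)
    if dispersion <= 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam)


def simulate_sc(params: SimParams) -> tuple[CountMatrix, pd.DataFrame, pd.DataFrame]:
    """Simulate phase-sorted single-cell UMI counts with planted effects.

    For a cell in phase p and lineage l, gene g has relative mean
    ``mu_g * lambda_gl * 2^(s_p * beta_gl)`` with ``s_G1 = -1/2`` and
    ``s_G2M = +1/2``; counts are NB around that mean scaled to the cell's
    library size.  Returns ``(counts, annotations, truth)``.
    """
    rng = np.random.default_rng(params.seed)
    G = params.n_genes
    lineages = list(params.lineages)
    n_mito = min(params.n_mito_genes, G)

    gene_ids = np.array([f"gene{g:05d}" for g in range(G)], dtype=object)
    gene_ids[:n_mito] = [f"mt-gene{g:05d}" for g in range(n_mito)]
    gene_ids = gene_ids.astype(str)
    is_mito = np.zeros(G, dtype=bool)
    is_mito[:n_mito] = True

    loc, scale = params.baseline_mean_log
    base = rng.lognormal(loc, scale, size=G)
    if n_mito and params.mito_expr_frac > 0:
        # give mito genes a fixed share of the transcriptome
        non_mito_total = base[~is_mito].sum()
        target = params.mito_expr_frac / (1 - params.mito_expr_frac) * non_mito_total
        base[is_mito] = target / n_mito

    # planted phase effects: global or lineage-specific
    n_phasic = int(round(params.frac_phasic * G))
    eligible = np.flatnonzero(~is_mito)
    phasic_idx = rng.choice(eligible, size=min(n_phasic, eligible.size),
                            replace=False)
    n_inter = int(round(params.frac_interaction * phasic_idx.size))
    inter_idx = phasic_idx[:n_inter]          # lineage-specific subset
    signs = rng.choice([-1.0, 1.0], size=phasic_idx.size)
    beta = np.zeros((G, len(lineages)))       # log2FC per lineage
    inter_lineage = params.interaction_lineage or (
        lineages[1] if len(lineages) > 1 else lineages[0])
    li = lineages.index(inter_lineage)
    for j, (g, s) in enumerate(zip(phasic_idx, signs)):
        if g in set(inter_idx):
            beta[g, li] = s * params.effect_log2fc
        else:
            beta[g, :] = s * params.effect_log2fc

    # per-lineage baseline multipliers
    lam = np.ones((G, len(lineages)))
    if params.lineage_effect_sd > 0 and len(lineages) > 1:
        lam = np.exp(rng.normal(0.0, params.lineage_effect_sd,
                                size=(G, len(lineages))))

    n_cell = params.n_cells_per_phase_per_lineage
    cells, phases, lins = [], [], []
    counts_cols = []
    low_quality: list[bool] = []
    mu_loc, mu_scale = params.libsize_log
    cid = 0
    for l, lineage in enumerate(lineages):
        for phase, s_p in (("G1", -0.5), ("G2M", +0.5)):
            rel = base * lam[:, l] * np.exp2(s_p * beta[:, l])
            rel = rel / rel.sum()
            for _ in range(n_cell):
                lib = rng.lognormal(mu_loc, mu_scale)
                while lib < params.libsize_floor:   # truncated: healthy
                    lib = rng.lognormal(mu_loc, mu_scale)
                lq = rng.random() < params.frac_low_quality_cells
                rel_c = rel
                if lq:
                    if rng.random() < 0.5:
                        lib = rng.uniform(500, 4000)      # below UMI floor
                    else:
                        # inflate mitochondrial share well above 5%
                        rel_c = rel.copy()
                        rel_c[is_mito] *= 10.0
                        rel_c = rel_c / rel_c.sum()
                mean = rel_c * lib
                counts_cols.append(_nb_sample(rng, mean, params.nb_dispersion))
                cells.append(f"cell{cid:05d}")
                phases.append(phase)
                lins.append(lineage)
                low_quality.append(lq)
                cid += 1

    counts = CountMatrix(gene_ids, np.array(cells),
                         np.column_stack(counts_cols), "umi")
    ann = pd.DataFrame({
        "unit_id": cells,
        "phase": phases,
        "lineage": lins,
        "genotype": params.genotype,
        "stage": params.stage,
        "replicate": "r1",
        "planted_low_quality": low_quality,
    })
    truth = pd.DataFrame({
        "gene_id": gene_ids,
        "is_phasic": beta.any(axis=1),
        "is_mito": is_mito,
        "driver_class": "NONE",
    })
    for l, lineage in enumerate(lineages):
        truth[f"log2fc_{lineage}"] = beta[:, l]
    return counts, ann, truth


@dataclass
class BulkDataset:
    """Paired exon/intron bulk layers with shared labels and annotations."""

    exon: CountMatrix
    intron: CountMatrix | None
    annotations: pd.DataFrame

    def __post_init__(self) -> None:
        if self.intron is not None:
            if not (np.array_equal(self.exon.gene_ids, self.intron.gene_ids)
                    and np.array_equal(self.exon.unit_ids, self.intron.unit_ids)):
                raise ValidationError("exon and intron layers must share labels")


def simulate_bulk_exon_intron(
        n_genes: int = 2000,
        n_replicates: int = 3,
        n_transcription: int = 50,
        n_stability: int = 50,
        n_both: int = 20,
        effect_log2fc: float = 1.0,
        libsize: float = 2e6,
        nb_dispersion: float = 0.02,
        intron_fraction: float = 0.35,
        stage: str = "E9.5",
        seed: int = 1) -> tuple[BulkDataset, pd.DataFrame]:
    """Simulate a phase-sorted bulk dataset with exon and intron layers.

    Each gene has a transcription rate T and stability S per phase; intron
    abundance is proportional to T, exon abundance to T*S.  TRANSCRIPTION
    genes carry the phase effect on T only, STABILITY genes on S only, BOTH
    genes on both, split symmetrically around the baseline.
    """
    rng = np.random.default_rng(seed)
    G = n_genes
    n_planted = n_transcription + n_stability + n_both
    if n_planted > G:
        raise ValidationError(
            f"{n_planted} planted driver genes exceed {G} genes")
    gene_ids = np.array([f"gene{g:05d}" for g in range(G)])
    classes = np.array(["NONE"] * G, dtype=object)
    picks = rng.choice(G, size=n_planted, replace=False)
    classes[picks[:n_transcription]] = "TRANSCRIPTION"
    classes[picks[n_transcription:n_transcription + n_stability]] = "STABILITY"
    classes[picks[n_transcription + n_stability:]] = "BOTH"
    signs = np.zeros(G)
    signs[picks] = rng.choice([-1.0, 1.0], size=picks.size)

    baseT = rng.lognormal(0.0, 1.2, size=G)
    exon_cols, intron_cols, units, phases, reps = [], [], [], [], []
    for phase, s_p in (("G1", -0.5), ("G2M", +0.5)):
        dT = np.where(np.isin(classes, ["TRANSCRIPTION", "BOTH"]),
                      np.exp2(s_p * signs * effect_log2fc), 1.0)
        dS = np.where(np.isin(classes, ["STABILITY", "BOTH"]),
                      np.exp2(s_p * signs * effect_log2fc), 1.0)
        T = baseT * dT
        exon_rel = T * dS
        intron_rel = T * intron_fraction
        exon_mean = exon_rel / exon_rel.sum() * libsize
        intron_mean = intron_rel / intron_rel.sum() * libsize
        for r in range(n_replicates):
            exon_cols.append(_nb_sample(rng, exon_mean, nb_dispersion))
            intron_cols.append(_nb_sample(rng, intron_mean, nb_dispersion))
            units.append(f"{stage}_{phase}_r{r + 1}")
            phases.append(phase)
            reps.append(f"r{r + 1}")

    exon = CountMatrix(gene_ids, np.array(units), np.column_stack(exon_cols),
                       "exon")
    intron = CountMatrix(gene_ids, np.array(units),
                         np.column_stack(intron_cols), "intron")
    ann = pd.DataFrame({"unit_id": units, "phase": phases, "stage": stage,
                        "replicate": reps})
    truth = pd.DataFrame({
        "gene_id": gene_ids,
        "is_phasic": classes != "NONE",
        "driver_class": classes.astype(str),
        "log2fc": signs * effect_log2fc * (classes != "NONE"),
    })
    # STABILITY acts on exon only; TRANSCRIPTION and BOTH change both layers
    return BulkDataset(exon, intron, ann), truth


def simulate_activity_scores(n_cells_per_phase: int, shift: float,
                             seed: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian per-cell activity scores with the G2/M mean shifted."""
    if n_cells_per_phase < 2:
        raise ValidationError("need at least 2 cells per phase")
    rng = np.random.default_rng(seed)
    g1 = rng.normal(0.0, 1.0, size=n_cells_per_phase)
    g2m = rng.normal(shift, 1.0, size=n_cells_per_phase)
    scores = np.concatenate([g1, g2m])
    phases = np.array(["G1"] * n_cells_per_phase + ["G2M"] * n_cells_per_phase)
    return scores, phases


def simulate_unsorted_panels(
        n_cells: int = 2000,
        amplitude: float = 1.0,
        n_background_genes: int = 200,
        libsize_log: tuple[float, float] = (np.log(8000.0), 0.35),
        nb_dispersion: float = 0.2,
        stage: str = "E8.5",
        lineage: str = "ectoderm",
        seed: int = 1) -> tuple[CountMatrix, pd.DataFrame]:
    """Unsorted cycling cells with a latent phase driving the panel genes.

    Each cell carries a hidden phase indicator s in {-1/2, +1/2}; the
    canonical G2/M panel genes scale by ``2^(s * amplitude)`` and the G1/S
    panel genes by ``2^(-s * amplitude)`` (opposite directions), on top of
    background genes with no phase structure.  With ``amplitude = 0`` the
    panels are independent.  Used for the co-expression cohort analysis of
    atlas-style data, where phase labels are unavailable.
    """
    from .coexpression import load_panels

    rng = np.random.default_rng(seed)
    panels = load_panels()
    g1s, g2m = panels["G1S"], panels["G2M"]
    bg = [f"bg{g:04d}" for g in range(n_background_genes)]
    gene_ids = np.array(g1s + g2m + bg)
    G = gene_ids.size
    base = np.concatenate([
        np.full(len(g1s), 30.0),      # panel genes well-expressed
        np.full(len(g2m), 30.0),
        rng.lognormal(0.0, 1.0, size=n_background_genes) * 5.0,
    ])
    direction = np.concatenate([
        -np.ones(len(g1s)), np.ones(len(g2m)), np.zeros(n_background_genes)])
    cols, cells = [], []
    s_latent = rng.choice([-0.5, 0.5], size=n_cells)
    mu_loc, mu_scale = libsize_log
    for c in range(n_cells):
        rel = base * np.exp2(s_latent[c] * amplitude * direction)
        rel = rel / rel.sum()
        lib = rng.lognormal(mu_loc, mu_scale)
        cols.append(_nb_sample(rng, rel * lib, nb_dispersion))
        cells.append(f"cell{c:05d}")
    counts = CountMatrix(gene_ids, np.array(cells), np.column_stack(cols), "umi")
    ann = pd.DataFrame({
        "unit_id": cells,
        "phase": np.where(s_latent > 0, "G2M", "G1"),
        "lineage": lineage,
        "stage": stage,
    })
    return counts, ann


# ---------------------------------------------------------------------------
# named presets: the study conditions exercised by the analysis scripts
# ---------------------------------------------------------------------------

def preset_params(name: str, seed: int = 1) -> SimParams | dict:
    """Named generator settings for the standard experiments."""
    if name == "sc-null":
        return SimParams(n_genes=2000, n_cells_per_phase_per_lineage=300,
                         frac_phasic=0.0, seed=seed)
    if name == "sc-phasic":
        return SimParams(n_genes=2000, n_cells_per_phase_per_lineage=500,
                         frac_phasic=0.10, effect_log2fc=1.0, seed=seed)
    if name == "sc-interaction":
        return SimParams(n_genes=1000, n_cells_per_phase_per_lineage=120,
                         lineages=("A", "B", "C"), reference_lineage="A",
                         frac_phasic=0.04, effect_log2fc=1.5,
                         frac_interaction=1.0, interaction_lineage="B",
                         lineage_effect_sd=0.3, seed=seed)
    if name == "genotype-pair":
        return {
            "control": SimParams(n_genes=1500, n_cells_per_phase_per_lineage=300,
                                 frac_phasic=0.02, effect_log2fc=1.0,
                                 genotype="control", seed=seed),
            "mutant": SimParams(n_genes=1500, n_cells_per_phase_per_lineage=300,
                                frac_phasic=0.02 + 50 / 1500, effect_log2fc=1.0,
                                genotype="mutant", seed=seed + 10_000),
        }
    if name == "bulk-decomp":
        return dict(n_genes=2000, n_replicates=3, n_transcription=50,
                    n_stability=50, n_both=20, effect_log2fc=1.0, seed=seed)
    raise ValidationError(f"unknown preset {name!r}")
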