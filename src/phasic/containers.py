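"""Core data containers shared by every pipeline.

The in-memory convention is genes-as-rows, units-as-columns, where a "unit"
is a cell (single-cell data), a sample (bulk data) or a pseudobulk aggregate.
Counts are non-negative integers (UMIs or reads); all validation happens at
construction so downstream code can assume a well-formed matrix.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

PHASES = ("G1", "G2M")

#: accepted spellings of the two cell-cycle phase labels (case-insensitive)
_PHASE_ALIASES = {
    "g1": "G1",
    "g1/s": "G1",
    "g2m": "G2M",
    "g2/m": "G2M",
    "g2-m": "G2M",
}


class ValidationError(ValueError):
    """Raised when an input violates a structural invariant."""


def normalize_phase(values: Iterable[str]) -> np.ndarray:
    """Map phase labels to the canonical {G1, G2M} pair.

    "G2/M", "G2M" and "g2m" all normalize to "G2M".  Unknown labels raise a
    :class:`ValidationError` listing the offending rows.
    """
    values = np.asarray(list(values), dtype=object)
    out = np.empty(values.shape, dtype=object)
    bad: list[int] = []
    for i, v in enumerate(values):
        key = str(v).strip().lower()
        if key in _PHASE_ALIASES:
            out[i] = _PHASE_ALIASES[key]
        else:
            bad.append(i)
    if bad:
        shown = ", ".join(f"row {i}: {values[i]!r}" for i in bad[:10])
        raise ValidationError(f"unknown phase label(s): {shown}")
    return out.astype(str)


@dataclass
class CountMatrix:
    """Gene x unit matrix of non-negative integer counts with string labels.

    Parameters
    ----------
    gene_ids
        Unique gene identifiers (opaque strings), one per row.
    unit_ids
        Unique unit (cell/sample) identifiers, one per column.
    counts
        Integer matrix, shape ``(len(gene_ids), len(unit_ids))``.
    layer_name
        Tag describing what was counted: ``"umi"``, ``"exon"`` or ``"intron"``.
    """

    gene_ids: np.ndarray
    unit_ids: np.ndarray
    counts: np.ndarray
    layer_name: str = "umi"

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids, dtype=str)
        self.unit_ids = np.asarray(self.unit_ids, dtype=str)
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValidationError("counts must be a 2-D matrix")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.isfinite(counts)) or np.any(counts != np.floor(counts)):
                raise ValidationError("counts contain non-integer entries")
            counts = counts.astype(np.int64)
        if counts.min(initial=0) < 0:
            raise ValidationError("counts contain negative entries")
        if counts.shape != (self.gene_ids.size, self.unit_ids.size):
            raise ValidationError(
                f"counts shape {counts.shape} does not match "
                f"{self.gene_ids.size} genes x {self.unit_ids.size} units"
            )
        for name, labels in (("gene", self.gene_ids), ("unit", self.unit_ids)):
            if len(set(labels.tolist())) != labels.size:
                raise ValidationError(f"duplicated {name} identifiers")
        self.counts = counts.astype(np.int64)

    @property
    def n_genes(self) -> int:
        return self.gene_ids.size

    @property
    def n_units(self) -> int:
        return self.unit_ids.size

    def library_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def subset_genes(self, mask_or_ids) -> "CountMatrix":
        idx = self._index(self.gene_ids, mask_or_ids)
        return CountMatrix(self.gene_ids[idx], self.unit_ids,
                           self.counts[idx, :], self.layer_name)

    def subset_units(self, mask_or_ids) -> "CountMatrix":
        idx = self._index(self.unit_ids, mask_or_ids)
        return CountMatrix(self.gene_ids, self.unit_ids[idx],
                           self.counts[:, idx], self.layer_name)

    @staticmethod
    def _index(labels: np.ndarray, mask_or_ids) -> np.ndarray:
        arr = np.asarray(mask_or_ids)
        if arr.dtype == bool:
            if arr.size != labels.size:
                raise ValidationError("boolean mask length mismatch")
            return np.flatnonzero(arr)
        pos = {lab: i for i, lab in enumerate(labels)}
        try:
            return np.array([pos[str(x)] for x in arr], dtype=int)
        except KeyError as e:  # pragma: no cover - defensive
            raise ValidationError(f"unknown identifier {e.args[0]!r}") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.unit_ids)


def compute_qc_fields(counts: CountMatrix, annotations: pd.DataFrame,
                      mito_prefix: str = "mt-") -> pd.DataFrame:
    """Attach derived per-unit QC columns to an annotation table.

    Adds ``total_umi``, ``n_detected_genes``, ``mito_fraction`` (fraction of
    counts on genes whose id starts with *mito_prefix*, case-insensitive) and
    ``detection_fraction`` (detected genes relative to the unit with the most
    detected genes).  Annotation rows are aligned to the matrix columns.
    """
    ann = annotations.set_index("unit_id").loc[counts.unit_ids].reset_index()
    total = counts.library_sizes()
    detected = (counts.counts > 0).sum(axis=0)
    is_mito = np.char.startswith(np.char.lower(counts.gene_ids), mito_prefix.lower())
    mito = counts.counts[is_mito, :].sum(axis=0) if is_mito.any() else np.zeros_like(total)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(total > 0, mito / np.maximum(total, 1), 0.0)
    max_det = detected.max() if detected.size else 0
    ann["total_umi"] = total
    ann["n_detected_genes"] = detected
    ann["mito_fraction"] = mito_frac
    ann["detection_fraction"] = detected / max(max_det, 1)
    return ann


@dataclass
class PipelineConfig:
    """All tunable thresholds of the analysis pipelines, with defaults.

    Defaults follow the published procedure: a 5000-UMI floor and 5%
    mitochondrial ceiling per cell, a 40% relative-detection floor, genes
    kept when detected in at least 20% of cells, pseudobulk aggregates of 10
    cells, 100 pseudobulk permutations, a 1.1 fold-change gate on the log2
    scale, a 5-CPM bulk expression floor, bulk calls at adjusted P < 0.1 and
    single-cell calls at adjusted P < 0.05.
    """

    min_umi: int = 5000
    max_mito_fraction: float = 0.05
    min_rel_detection: float = 0.40
    min_gene_cell_fraction: float = 0.20
    pseudobulk_size: int = 10
    n_permutations: int = 100
    fc_threshold: float = 1.1
    bulk_min_cpm: float = 5.0
    alpha_bulk: float = 0.1
    alpha_sc: float = 0.05
    genotype_resamples: int = 100
    cohort_size: int = 50
    ks_threshold: float = 1e-12
    min_lineage_cells: int = 50
    mito_prefix: str = "mt-"
    rng_seed: int = 1

    def __post_init__(self) -> None:
        for name in ("min_umi", "pseudobulk_size", "n_permutations",
                     "genotype_resamples", "cohort_size", "min_lineage_cells"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be strictly positive")
        for name in ("max_mito_fraction", "min_rel_detection",
                     "min_gene_cell_fraction", "alpha_bulk", "alpha_sc"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValidationError(f"{name} must lie in (0, 1)")
        if self.fc_threshold <= 1:
            raise ValidationError("fc_threshold must exceed 1")
        if self.bulk_min_cpm <= 0 or self.ks_threshold <= 0:
            raise ValidationError("thresholds must be strictly positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
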