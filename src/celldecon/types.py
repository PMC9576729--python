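"""Shared domain types for the deconvolution pipeline.

The pipeline flows through these containers: annotated single-cell
reference datasets are aggregated into pseudo-bulk samples, pseudo-bulks
are batch-corrected and distilled into cell-type expression profiles,
profile sets are ranked by training, and bulk query samples are decomposed
against the kept sets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Platform",
    "ReferenceDataset",
    "BulkSample",
    "PseudoBulkSample",
    "CellTypeProfile",
    "ProfileSet",
    "ProfileBundle",
    "SingleSetFit",
    "DeconvolutionResult",
    "SimulationConfig",
    "TrainingConfig",
    "EnsembleConfig",
    "BatchDesign",
    "normalize_gene_id",
]

LIBRARY_SIZE = 1_000_000.0


def normalize_gene_id(gene: str) -> str:
    """Canonical gene identifier: upper-cased, stripped symbol string.

    Applied identically at every read site so that datasets from different
    sources match on symbols; collisions are collapsed by summation at read
    time.
    """
    return str(gene).strip().upper()


class Platform(str, Enum):
    """Sequencing protocol of a reference dataset.

    Full-length protocols are quantified in TPM, 3' UMI protocols in UMI
    counts; both are normalized to one million downstream.
    ``bulk_as_pseudobulk`` marks bulk RNA-seq of purified cells (e.g.
    isolated muscle fibers) used directly as pure pseudo-bulk replicates.
    """

    FULL_LENGTH = "full_length"
    THREE_PRIME_UMI = "three_prime_umi"
    BULK_AS_PSEUDOBULK = "bulk_as_pseudobulk"


@dataclass
class ReferenceDataset:
    """One annotated gene-by-cell count matrix from a single source study."""

    dataset_id: str
    counts: np.ndarray  # genes x cells, non-negative
    gene_ids: list[str]
    cell_ids: list[str]
    cell_types: list[str]  # one label per cell
    platform: Platform = Platform.THREE_PRIME_UMI
    diseased_flags: np.ndarray | None = None  # per-cell bool
    gene_lengths: np.ndarray | None = None  # kb, for TPM on full-length data

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if len(self.cell_types) != len(self.cell_ids):
            raise ValueError("one cell-type label required per cell")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        norm = [normalize_gene_id(g) for g in self.gene_ids]
        if len(set(norm)) != len(norm):
            raise ValueError("gene_ids not unique after case-normalization")
        self.gene_ids = norm
        if self.diseased_flags is not None:
            self.diseased_flags = np.asarray(self.diseased_flags, dtype=bool)
            if self.diseased_flags.shape[0] != len(self.cell_ids):
                raise ValueError("diseased_flags length must match cell count")

    @property
    def present_cell_types(self) -> list[str]:
        return sorted(set(self.cell_types))

    def cells_of_type(self, cell_type: str, include_diseased: bool = False) -> np.ndarray:
        """Column indices of usable cells carrying the given label."""
        mask = np.array([ct == cell_type for ct in self.cell_types])
        if self.diseased_flags is not None and not include_diseased:
            mask &= ~self.diseased_flags
        return np.flatnonzero(mask)


@dataclass
class BulkSample:
    """A query bulk expression vector, optionally with known composition."""

    sample_id: str
    expression: pd.Series  # gene-indexed, non-negative
    known_composition: dict[str, float] | None = None

    def __post_init__(self) -> None:
        # gene ids are case-normalized at read sites (ReferenceDataset, io
        # readers); vectors passed in memory are taken as-is
        self.expression = self.expression.astype(float)
        if (self.expression < 0).any():
            raise ValueError("bulk expression must be non-negative")
        if self.known_composition is not None:
            vals = list(self.known_composition.values())
            if any(v < 0 or v > 1 for v in vals):
                raise ValueError("known composition fractions must lie in [0, 1]")
            if sum(vals) > 1 + 1e-6:
                raise ValueError("known composition fractions must sum to <= 1")


@dataclass
class PseudoBulkSample:
    """Expression vector summed over a random subset of annotated cells."""

    sample_id: str
    source_dataset_id: str
    kind: str  # "pure" | "mixed"
    counts: pd.Series  # gene-indexed
    cell_type: str | None = None  # pure only
    composition: dict[str, float] | None = None  # mixed only
    n_cells_used: int = 0
    total_counts: float = 0.0
    below_floor: bool = False  # count floor unreachable even using all cells

    def __post_init__(self) -> None:
        if self.kind not in ("pure", "mixed"):
            raise ValueError("kind must be 'pure' or 'mixed'")
        if self.kind == "pure":
            if self.cell_type is None:
                raise ValueError("pure pseudo-bulk requires cell_type")
            self.composition = {self.cell_type: 1.0}
        elif self.composition is None:
            raise ValueError("mixed pseudo-bulk requires a composition map")


@dataclass
class CellTypeProfile:
    """Expression profile of one pure cell type over a bundle's gene universe."""

    cell_type: str
    values: pd.Series  # gene-indexed, 1M-normalized, non-negative
    profile_genes: list[str]
    source: tuple[str, int]  # (dataset_id, replicate index)

    def __post_init__(self) -> None:
        missing = set(self.profile_genes) - set(self.values.index)
        if missing:
            raise ValueError(f"profile_genes outside gene universe: {sorted(missing)[:5]}")


@dataclass
class ProfileSet:
    """One candidate signature matrix: exactly one profile per cell type."""

    set_id: str
    profiles: dict[str, CellTypeProfile]
    training_score: float = math.nan
    rank: int = -1

    def __post_init__(self) -> None:
        universes = {tuple(p.values.index) for p in self.profiles.values()}
        if len(universes) > 1:
            raise ValueError("all member profiles must share one gene universe")
        for ct, prof in self.profiles.items():
            if prof.cell_type != ct:
                raise ValueError(f"profile keyed {ct!r} is labelled {prof.cell_type!r}")

    @property
    def cell_types(self) -> list[str]:
        return list(self.profiles)

    @property
    def gene_universe(self) -> list[str]:
        first = next(iter(self.profiles.values()))
        return list(first.values.index)

    def matrix(self) -> pd.DataFrame:
        """Genes x cell-types signature matrix (the P vectors, column-stacked)."""
        return pd.DataFrame({ct: p.values for ct, p in self.profiles.items()})


@dataclass
class ProfileBundle:
    """A named, ranked collection of profile sets sharing one gene universe."""

    group_name: str
    cell_types: list[str]
    gene_universe: list[str]
    profile_sets: list[ProfileSet]
    config_snapshot: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        scores = [s.training_score for s in self.profile_sets]
        finite = [s for s in scores if not math.isnan(s)]
        if any(b < a - 1e-12 for a, b in zip(finite, finite[1:])):
            raise ValueError("profile_sets must be sorted ascending by training_score")
        for i, s in enumerate(self.profile_sets):
            s.rank = i
        for s in self.profile_sets:
            if sorted(s.cell_types) != sorted(self.cell_types):
                raise ValueError(f"set {s.set_id} does not cover the bundle cell types")

    def profile_genes(self) -> dict[str, list[str]]:
        """Per-type profile gene lists (identical across member sets)."""
        first = self.profile_sets[0]
        return {ct: list(p.profile_genes) for ct, p in first.profiles.items()}


@dataclass
class SingleSetFit:
    """NNLS fit of one bulk sample against one profile set."""

    set_id: str
    raw_coefficients: dict[str, float]
    fitted_expression: pd.Series
    fit_rmse: float  # goodness-of-fit RMSE over genes
    coefficient_pvalues: dict[str, float] = field(default_factory=dict)

    @property
    def proportions(self) -> dict[str, float]:
        """Coefficients rescaled to sum to one."""
        total = sum(self.raw_coefficients.values())
        if total <= 0:
            n = len(self.raw_coefficients)
            return {ct: 1.0 / n for ct in self.raw_coefficients}
        return {ct: v / total for ct, v in self.raw_coefficients.items()}


@dataclass
class DeconvolutionResult:
    """Ensemble composition estimate for one bulk sample.

    ``proportions`` holds the full weighted-ensemble estimate for every cell
    type; types whose ensemble p-value is not below alpha contribute their
    mass to ``undetermined`` and are zeroed in ``significant_proportions``.
    """

    sample_id: str
    proportions: dict[str, float]
    pvalues: dict[str, float]
    undetermined: float
    fit_rmse: list[float]
    weights: list[float]
    used_set_ids: list[str]
    alpha: float = 0.05

    @property
    def significant_proportions(self) -> dict[str, float]:
        return {
            ct: (v if self.pvalues.get(ct, 1.0) < self.alpha else 0.0)
            for ct, v in self.proportions.items()
        }


@dataclass
class SimulationConfig:
    """Parameters of the synthetic reference-collection generator.

    Counts are negative binomial around a per-gene baseline, scaled by a
    planted cell-type signature effect and a per-(dataset, gene) log-normal
    batch effect. ``presence`` optionally restricts which datasets carry
    which cell types, emulating reference collections with non-identical
    repertoires; each type should remain present in at least
    ``min_datasets_per_type`` datasets.
    """

    n_datasets: int = 5
    cell_types: Sequence[str] = ("astrocyte", "neuron", "oligodendrocyte", "microglia")
    n_genes: int = 1000
    n_signature_genes_per_type: int = 40
    signature_log2fc: float = 2.5
    nb_dispersion: float = 0.3
    batch_gene_sigma: float = 0.3
    cells_per_type: tuple[int, int] = (200, 400)
    depth_per_cell: tuple[int, int] = (2000, 6000)
    presence: Mapping[str, Sequence[int]] | None = None  # type -> dataset indices
    min_datasets_per_type: int = 3
    gene_length_bias_sigma: float = 0.0  # >0 emulates full-length length bias
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_datasets", "n_genes", "n_signature_genes_per_type"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.cells_per_type[0] <= 0 or self.depth_per_cell[0] <= 0:
            raise ValueError("cell and depth ranges must be positive")
        if self.n_signature_genes_per_type * len(self.cell_types) > self.n_genes:
            raise ValueError("not enough genes for the requested signature genes")


@dataclass
class TrainingConfig:
    """Knobs of the two-step iterative profile-set ranking."""

    keep_top_k_after_step1: int = 50
    keep_top_k_after_step2: int = 20
    rmse_target: float = 0.1
    max_iterations: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.keep_top_k_after_step1 <= 0 or self.keep_top_k_after_step2 <= 0:
            raise ValueError("keep_top_k values must be positive")
        if self.keep_top_k_after_step2 > self.keep_top_k_after_step1:
            raise ValueError("keep_top_k must be non-increasing across steps")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass
class EnsembleConfig:
    """Ensemble deconvolution settings: number of sets kept and significance."""

    top_n: int = 5
    alpha: float = 0.05
    weight_scheme: str = "as_printed"  # or "inverse_rmse"

    def __post_init__(self) -> None:
        if self.top_n < 1:
            raise ValueError("top_n must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.weight_scheme not in ("as_printed", "inverse_rmse"):
            raise ValueError("weight_scheme must be 'as_printed' or 'inverse_rmse'")


@dataclass
class BatchDesign:
    """Pseudo-bulk batch layout used to pick the correction strategy."""

    samples: list[tuple[str, str, str]]  # (pseudo-bulk id, dataset_id, cell_type)
    strategy: str = "per_cell_type"  # or "all_in_one"

    def overlap_table(self) -> pd.DataFrame:
        """Dataset x cell-type presence matrix."""
        datasets = sorted({d for _, d, _ in self.samples})
        types = sorted({t for _, _, t in self.samples})
        tab = pd.DataFrame(False, index=datasets, columns=types)
        for _, d, t in self.samples:
            tab.loc[d, t] = True
        return tab
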