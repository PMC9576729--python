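"""Pure and mixed pseudo-bulk construction, normalization, and gene filtering.

A pure pseudo-bulk replicate sums counts over a random subset of one cell
type's cells within a single dataset: at least half the available cells,
grown toward the full pool if the 2-million-count floor is not yet met.
Full-length datasets are converted to TPM (counts divided by transcript
length) before normalization; 3' UMI datasets use raw UMI counts. All
samples are then normalized to one million and low-expression genes are
filtered.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import _draw_compositions, mix_from_dataset
from .types import LIBRARY_SIZE, BulkSample, Platform, PseudoBulkSample, ReferenceDataset

__all__ = [
    "make_pure_pseudobulks",
    "make_mixed_pseudobulks",
    "normalize_to_million",
    "filter_low_expression",
    "FilterReport",
]

logger = logging.getLogger(__name__)

COUNT_FLOOR = 2_000_000.0


def _to_expression_metric(summed: np.ndarray, dataset: ReferenceDataset) -> np.ndarray:
    """Summed counts -> the platform's expression metric (TPM or UMI)."""
    if dataset.platform is Platform.FULL_LENGTH and dataset.gene_lengths is not None:
        return summed / np.clip(dataset.gene_lengths, 1e-12, None)
    return summed


def make_pure_pseudobulks(
    dataset: ReferenceDataset,
    replicates_per_type: int = 4,
    seed: int = 0,
    cell_types: list[str] | None = None,
    strict: bool = False,
    count_floor: float = COUNT_FLOOR,
) -> list[PseudoBulkSample]:
    """Pure pseudo-bulk replicates for every (requested) cell type of a dataset.

    Each replicate draws a uniform random subset of at least 50% of the
    type's cells; if its total count is below ``count_floor`` more cells are
    added at random until the floor is met or all cells are used (in which
    case the replicate is flagged ``below_floor``).

    Datasets of platform ``bulk_as_pseudobulk`` bypass cell sampling: every
    column is one bulk sample of purified cells and becomes one replicate of
    its labelled type.
    """
    rng = np.random.default_rng(seed)
    if cell_types is None:
        cell_types = dataset.present_cell_types

    out: list[PseudoBulkSample] = []
    if dataset.platform is Platform.BULK_AS_PSEUDOBULK:
        for ct in cell_types:
            for rep, col in enumerate(dataset.cells_of_type(ct)):
                vec = dataset.counts[:, col].astype(float)
                out.append(
                    PseudoBulkSample(
                        sample_id=f"{dataset.dataset_id}:{ct}:r{rep}",
                        source_dataset_id=dataset.dataset_id,
                        kind="pure",
                        cell_type=ct,
                        counts=pd.Series(vec, index=dataset.gene_ids),
                        n_cells_used=1,
                        total_counts=float(vec.sum()),
                    )
                )
        return out

    for ct in cell_types:
        idx = dataset.cells_of_type(ct)
        if idx.size == 0:
            raise ValueError(f"no cells of type {ct!r} in dataset {dataset.dataset_id}")
        if idx.size < 2:
            msg = f"only {idx.size} cell of type {ct!r} in {dataset.dataset_id}"
            if strict:
                raise ValueError(msg)
            logger.warning("%s; replicates will be identical", msg)
        n_min = math.ceil(0.5 * idx.size)
        for rep in range(replicates_per_type):
            order = rng.permutation(idx)
            n_used = n_min
            summed = dataset.counts[:, order[:n_used]].sum(axis=1)
            while summed.sum() < count_floor and n_used < idx.size:
                extra = min(idx.size - n_used, max(1, n_used // 4))
                summed = summed + dataset.counts[:, order[n_used : n_used + extra]].sum(axis=1)
                n_used += extra
            below = summed.sum() < count_floor
            if below:
                logger.warning(
                    "pure pseudo-bulk %s:%s:r%d below %.0f-count floor (%.0f)",
                    dataset.dataset_id, ct, rep, count_floor, summed.sum(),
                )
            expr = _to_expression_metric(summed.astype(float), dataset)
            out.append(
                PseudoBulkSample(
                    sample_id=f"{dataset.dataset_id}:{ct}:r{rep}",
                    source_dataset_id=dataset.dataset_id,
                    kind="pure",
                    cell_type=ct,
                    counts=pd.Series(expr, index=dataset.gene_ids),
                    n_cells_used=int(n_used),
                    total_counts=float(summed.sum()),
                    below_floor=bool(below),
                )
            )
    return out


def make_mixed_pseudobulks(
    dataset: ReferenceDataset,
    n: int,
    composition_law: str = "dirichlet",
    alpha: float = 1.0,
    seed: int = 0,
    cells_per_type: int = 50,
    grid_step: float = 0.05,
) -> list[PseudoBulkSample]:
    """Mixed pseudo-bulks with known compositions from a single dataset.

    Compositions are restricted to the cell types present in this dataset;
    the exact drawn composition is recorded on each sample.
    """
    if n == 0:
        return []
    rng = np.random.default_rng(seed)
    types = dataset.present_cell_types
    comps = _draw_compositions(types, n, composition_law, alpha, rng, grid_step)
    out = []
    for i, comp in enumerate(comps):
        vec = mix_from_dataset(dataset, comp, rng, cells_per_type)
        out.append(
            PseudoBulkSample(
                sample_id=f"{dataset.dataset_id}:mixed:{i}",
                source_dataset_id=dataset.dataset_id,
                kind="mixed",
                composition={ct: float(f) for ct, f in comp.items()},
                counts=vec,
                n_cells_used=cells_per_type * sum(1 for f in comp.values() if f > 0),
                total_counts=float(vec.sum()),
            )
        )
    return out


def normalize_to_million(sample: PseudoBulkSample | BulkSample):
    """Rescale a sample's expression vector to sum to one million."""
    if isinstance(sample, BulkSample):
        total = float(sample.expression.sum())
        if total <= 0:
            raise ValueError(f"sample {sample.sample_id} has zero total expression")
        return BulkSample(
            sample_id=sample.sample_id,
            expression=sample.expression * (LIBRARY_SIZE / total),
            known_composition=sample.known_composition,
        )
    total = float(sample.counts.sum())
    if total <= 0:
        raise ValueError(f"sample {sample.sample_id} has zero total counts")
    scaled = sample.counts * (LIBRARY_SIZE / total)
    return PseudoBulkSample(
        sample_id=sample.sample_id,
        source_dataset_id=sample.source_dataset_id,
        kind=sample.kind,
        cell_type=sample.cell_type,
        composition=sample.composition,
        counts=scaled,
        n_cells_used=sample.n_cells_used,
        total_counts=sample.total_counts,
        below_floor=sample.below_floor,
    )


@dataclass
class FilterReport:
    """Bookkeeping from the low-expression filter."""

    retained_genes: list[str]
    dropped_genes: list[str]
    removed_count_fraction: dict[str, float]  # per source dataset
    low_flags: pd.DataFrame  # gene x cell-type: low in that type?


def filter_low_expression(
    samples: list[PseudoBulkSample],
    min_count: float = 4.0,
    frac: float = 0.2,
    mode: str = "all_types",
) -> FilterReport:
    """Drop genes that are lowly expressed across pseudo-bulk samples.

    A gene is "low" in a cell type when more than ``frac`` of that type's
    samples carry fewer than ``min_count`` counts. Under the default
    ``all_types`` mode a gene is dropped only when it is low in every cell
    type (keeping genes adequately expressed in at least one type, which
    preserves markers of rare types); ``any_type`` drops a gene as soon as
    one cell type flags it.
    """
    if not samples:
        raise ValueError("no samples supplied to the low-expression filter")
    if mode not in ("all_types", "any_type"):
        raise ValueError("mode must be 'all_types' or 'any_type'")

    genes = samples[0].counts.index
    by_type: dict[str, list[PseudoBulkSample]] = {}
    for s in samples:
        key = s.cell_type if s.cell_type is not None else "__mixed__"
        by_type.setdefault(key, []).append(s)

    low = {}
    for ct, group in by_type.items():
        mat = np.column_stack([s.counts.reindex(genes).to_numpy() for s in group])
        low[ct] = (mat < min_count).mean(axis=1) > frac
    low_flags = pd.DataFrame(low, index=genes)

    if mode == "all_types":
        drop = low_flags.all(axis=1)
    else:
        drop = low_flags.any(axis=1)
    retained = list(genes[~drop.to_numpy()])
    dropped = list(genes[drop.to_numpy()])

    removed_frac = {}
    for s in samples:
        removed_frac.setdefault(s.source_dataset_id, [0.0, 0.0])
        tot = float(s.counts.sum())
        rem = float(s.counts.loc[dropped].sum()) if dropped else 0.0
        removed_frac[s.source_dataset_id][0] += rem
        removed_frac[s.source_dataset_id][1] += tot
    removed_fraction = {d: (r / t if t > 0 else 0.0) for d, (r, t) in removed_frac.items()}
    logger.info(
        "low-expression filter: dropped %d/%d genes (mode=%s)",
        len(dropped), len(genes), mode,
    )
    return FilterReport(
        retained_genes=retained,
        dropped_genes=dropped,
        removed_count_fraction=removed_fraction,
        low_flags=low_flags,
    )
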