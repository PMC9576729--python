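"""Synthetic reference collections and bulk mixtures with known ground truth.

The generator emulates the statistical structure the deconvolution method
assumes: several single-cell reference datasets sharing overlapping (but
possibly non-identical) cell-type repertoires, negative-binomial counts
with planted cell-type signature genes, multiplicative per-(dataset, gene)
batch effects, and bulk mixtures drawn from known Dirichlet compositions.
"""

from __future__ import annotations

import itertools
import logging
import warnings

import numpy as np
import pandas as pd

from .types import LIBRARY_SIZE, BulkSample, Platform, ReferenceDataset, SimulationConfig

__all__ = ["simulate_reference_collection", "simulate_bulk_mixtures"]

logger = logging.getLogger(__name__)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with var = mu + dispersion * mu^2 (Poisson if 0)."""
    mean = np.clip(mean, 1e-12, None)
    if dispersion <= 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def _presence_matrix(config: SimulationConfig) -> dict[str, list[int]]:
    types = list(config.cell_types)
    if config.presence is None:
        return {ct: list(range(config.n_datasets)) for ct in types}
    presence = {ct: sorted(config.presence.get(ct, [])) for ct in types}
    for ct, idx in presence.items():
        if any(i < 0 or i >= config.n_datasets for i in idx):
            raise ValueError(f"presence indices for {ct!r} outside dataset range")
        if len(idx) < config.min_datasets_per_type:
            warnings.warn(
                f"cell type {ct!r} present in only {len(idx)} datasets "
                f"(< {config.min_datasets_per_type}); profiles may be unstable",
                stacklevel=3,
            )
    return presence


def simulate_reference_collection(
    config: SimulationConfig,
    strict: bool = False,
) -> tuple[list[ReferenceDataset], pd.DataFrame]:
    """Generate annotated reference datasets plus a ground-truth marker table.

    Each gene has a log-normal baseline expression shared across datasets.
    Signature genes of a cell type have their mean multiplied by
    ``2 ** signature_log2fc`` in that type. Each dataset applies an
    independent log-normal multiplicative batch effect per gene
    (sd = ``batch_gene_sigma`` on the natural-log scale). Per-cell counts
    are negative binomial around the cell's expected gene fractions times
    its sequencing depth.

    Returns the datasets and a table with columns ``gene``, ``cell_type``
    recording which genes are true markers of which type.
    """
    rng = np.random.default_rng(config.seed)
    types = list(config.cell_types)
    presence = _presence_matrix(config)
    if strict:
        short = [ct for ct, idx in presence.items() if len(idx) < config.min_datasets_per_type]
        if short:
            raise ValueError(f"cell types present in too few datasets: {short}")

    genes = [f"G{i:05d}" for i in range(config.n_genes)]
    baseline = rng.lognormal(mean=1.0, sigma=1.0, size=config.n_genes)

    # plant disjoint signature-gene blocks, one per cell type
    sig_rows = []
    effect = np.ones((config.n_genes, len(types)))
    perm = rng.permutation(config.n_genes)
    for t, ct in enumerate(types):
        block = perm[t * config.n_signature_genes_per_type : (t + 1) * config.n_signature_genes_per_type]
        effect[block, t] = 2.0 ** config.signature_log2fc
        sig_rows.extend({"gene": genes[g], "cell_type": ct} for g in sorted(block))
    signature_table = pd.DataFrame(sig_rows, columns=["gene", "cell_type"])

    datasets: list[ReferenceDataset] = []
    for d in range(config.n_datasets):
        batch = np.exp(rng.normal(0.0, config.batch_gene_sigma, size=config.n_genes))
        gene_lengths = None
        platform = Platform.THREE_PRIME_UMI
        if config.gene_length_bias_sigma > 0 and d % 2 == 0:
            # even-indexed datasets emulate full-length protocols whose raw
            # counts scale with transcript length
            platform = Platform.FULL_LENGTH
            gene_lengths = np.exp(rng.normal(0.0, config.gene_length_bias_sigma, size=config.n_genes))
        blocks, cell_ids, cell_types = [], [], []
        for ct_i, ct in enumerate(types):
            if d not in presence[ct]:
                continue
            n_cells = int(rng.integers(config.cells_per_type[0], config.cells_per_type[1] + 1))
            mean_expr = baseline * effect[:, ct_i] * batch
            if gene_lengths is not None:
                mean_expr = mean_expr * gene_lengths
            frac = mean_expr / mean_expr.sum()
            depths = rng.integers(config.depth_per_cell[0], config.depth_per_cell[1] + 1, size=n_cells)
            mu = frac[:, None] * depths[None, :]
            blocks.append(_nb_draw(rng, mu, config.nb_dispersion))
            cell_ids.extend(f"{ct}_{d}_{i}" for i in range(n_cells))
            cell_types.extend([ct] * n_cells)
        counts = np.concatenate(blocks, axis=1)
        datasets.append(
            ReferenceDataset(
                dataset_id=f"ds{d}",
                counts=counts,
                gene_ids=list(genes),
                cell_ids=cell_ids,
                cell_types=cell_types,
                platform=platform,
                gene_lengths=gene_lengths,
            )
        )
        logger.debug("simulated %s: %d cells, %d types", datasets[-1].dataset_id, len(cell_ids), len(blocks))
    return datasets, signature_table


def _draw_compositions(
    types: list[str],
    n_samples: int,
    composition_law: str,
    alpha: float,
    rng: np.random.Generator,
    grid_step: float = 0.05,
) -> list[dict[str, float]]:
    if composition_law == "dirichlet":
        draws = rng.dirichlet([alpha] * len(types), size=n_samples)
        return [dict(zip(types, row)) for row in draws]
    if composition_law == "fixed_grid":
        steps = int(round(1.0 / grid_step))
        grid = [
            c
            for c in itertools.product(range(steps + 1), repeat=len(types))
            if sum(c) == steps
        ]
        return [{t: g / steps for t, g in zip(types, combo)} for combo in grid]
    raise ValueError(f"unknown composition law: {composition_law!r}")


def mix_from_dataset(
    dataset: ReferenceDataset,
    composition: dict[str, float],
    rng: np.random.Generator,
    cells_per_type: int = 50,
    depth: float = LIBRARY_SIZE,
) -> pd.Series:
    """Draw a mixture vector from one dataset at an exact composition.

    Each contributing type's randomly drawn cells are summed and normalized
    before weighting, so the known composition holds exactly in normalized
    expression space (up to sampling noise in the per-type profile itself).
    """
    total = np.zeros(len(dataset.gene_ids))
    for ct, frac in composition.items():
        if frac <= 0:
            continue
        idx = dataset.cells_of_type(ct)
        if idx.size == 0:
            raise ValueError(f"cell type {ct!r} absent from dataset {dataset.dataset_id}")
        chosen = rng.choice(idx, size=min(cells_per_type, idx.size), replace=False)
        summed = dataset.counts[:, chosen].sum(axis=1)
        total += frac * (summed / summed.sum())
    return pd.Series(total * depth, index=dataset.gene_ids)


def simulate_bulk_mixtures(
    refs: list[ReferenceDataset],
    n_samples: int,
    composition_law: str = "dirichlet",
    alpha: float = 1.0,
    seed: int = 0,
    cell_types: list[str] | None = None,
    cells_per_type: int = 50,
    depth: float = LIBRARY_SIZE,
    grid_step: float = 0.05,
) -> list[BulkSample]:
    """Simulate bulk samples with known compositions from a reference collection.

    For each sample a composition is drawn (Dirichlet(alpha) or an exhaustive
    fixed grid), then for each contributing cell type cells are drawn from a
    random dataset carrying that type. ``known_composition`` records the
    drawn fractions exactly.
    """
    rng = np.random.default_rng(seed)
    if cell_types is None:
        cell_types = sorted({ct for ds in refs for ct in ds.present_cell_types})
    carriers = {ct: [ds for ds in refs if ct in ds.present_cell_types] for ct in cell_types}
    missing = [ct for ct, lst in carriers.items() if not lst]
    if missing:
        raise ValueError(f"requested cell types absent from references: {missing}")

    comps = _draw_compositions(cell_types, n_samples, composition_law, alpha, rng, grid_step)
    gene_index = refs[0].gene_ids
    samples = []
    for i, comp in enumerate(comps):
        total = np.zeros(len(gene_index))
        for ct, frac in comp.items():
            if frac <= 0:
                continue
            ds = carriers[ct][rng.integers(len(carriers[ct]))]
            part = mix_from_dataset(ds, {ct: 1.0}, rng, cells_per_type, depth=1.0)
            total += frac * part.reindex(gene_index, fill_value=0.0).to_numpy()
        samples.append(
            BulkSample(
                sample_id=f"mix{i:03d}",
                expression=pd.Series(total * depth, index=gene_index),
                known_composition={ct: float(f) for ct, f in comp.items()},
            )
        )
    return samples
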