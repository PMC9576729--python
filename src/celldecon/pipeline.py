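"""End-to-end profile-bundle construction from annotated reference datasets.

Ties the stages together: pure and mixed pseudo-bulking per dataset,
1M normalization, low-expression filtering, batch correction across
datasets, one-vs-rest signature-gene selection, candidate profile-set
assembly, and two-step training. The result is a ranked, serializable
profile bundle ready for deconvolution; building it is the expensive
step, and it only needs to run once per reference collection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .combat import choose_strategy, correct_pure_pseudobulks
from .profiles import (
    DEFAULT_MAX_GENES,
    DEFAULT_MIN_GENES,
    assemble_profile_sets,
    de_one_vs_rest,
    select_profile_genes,
)
from .pseudobulk import (
    filter_low_expression,
    make_mixed_pseudobulks,
    make_pure_pseudobulks,
    normalize_to_million,
)
from .training import train
from .types import (
    BatchDesign,
    BulkSample,
    ProfileBundle,
    ReferenceDataset,
    TrainingConfig,
)

__all__ = ["BundleBuildConfig", "build_profile_bundle"]

logger = logging.getLogger(__name__)


@dataclass
class BundleBuildConfig:
    """All thresholds and sizes of the bundle-building pipeline."""

    group_name: str = "bundle"
    replicates_per_type: int = 4
    mixed_per_dataset: int = 20
    mixed_alpha: float = 1.0
    filter_min_count: float = 4.0
    filter_frac: float = 0.2
    filter_mode: str = "all_types"
    combat_strategy: str | None = None  # None -> choose from overlap
    overlap_threshold: float = 0.5
    log2fc_cutoff: float = 1.0
    de_alpha: float = 0.05
    min_genes: int = DEFAULT_MIN_GENES
    max_genes: int = DEFAULT_MAX_GENES
    max_sets: int = 200
    training: TrainingConfig = field(default_factory=TrainingConfig)
    seed: int = 0


def build_profile_bundle(
    datasets: list[ReferenceDataset],
    config: BundleBuildConfig | None = None,
    real_bulk_samples: list[BulkSample] | None = None,
    cell_types: list[str] | None = None,
) -> ProfileBundle:
    """Build a ranked profile bundle from annotated reference datasets.

    ``cell_types`` restricts the bundle to a subset of the collection's
    repertoire; by default every annotated type is profiled. Optional
    ``real_bulk_samples`` with known compositions drive the second
    training step.
    """
    config = config or BundleBuildConfig()
    if not datasets:
        raise ValueError("no reference datasets supplied")

    pure = []
    for i, ds in enumerate(datasets):
        requested = None
        if cell_types is not None:
            requested = [ct for ct in cell_types if ct in ds.present_cell_types]
            if not requested:
                continue
        pure.extend(
            make_pure_pseudobulks(
                ds,
                replicates_per_type=config.replicates_per_type,
                seed=config.seed * 100_003 + i,
                cell_types=requested,
            )
        )
    pure = [normalize_to_million(s) for s in pure]

    report = filter_low_expression(
        pure,
        min_count=config.filter_min_count,
        frac=config.filter_frac,
        mode=config.filter_mode,
    )
    pure = [
        type(s)(
            sample_id=s.sample_id,
            source_dataset_id=s.source_dataset_id,
            kind=s.kind,
            cell_type=s.cell_type,
            composition=s.composition,
            counts=s.counts.loc[report.retained_genes],
            n_cells_used=s.n_cells_used,
            total_counts=s.total_counts,
            below_floor=s.below_floor,
        )
        for s in pure
    ]

    design = BatchDesign(
        samples=[(s.sample_id, s.source_dataset_id, s.cell_type or "") for s in pure]
    )
    strategy = config.combat_strategy or choose_strategy(design, config.overlap_threshold)
    corrected = correct_pure_pseudobulks(pure, strategy=strategy)

    types = sorted({s.cell_type for s in corrected if s.cell_type})
    de = []
    for ct in types:
        de.extend(de_one_vs_rest(corrected, ct))
    profile_genes = select_profile_genes(
        de,
        log2fc_cutoff=config.log2fc_cutoff,
        alpha=config.de_alpha,
        min_genes=config.min_genes,
        max_genes=config.max_genes,
    )

    candidates = assemble_profile_sets(
        corrected, profile_genes, max_sets=config.max_sets, seed=config.seed
    )

    def _mixed(seed: int):
        mixed = []
        for i, ds in enumerate(datasets):
            present = set(ds.present_cell_types) & set(types)
            if len(present) < 2:
                continue
            mixed.extend(
                make_mixed_pseudobulks(
                    ds,
                    n=config.mixed_per_dataset,
                    alpha=config.mixed_alpha,
                    seed=seed + i,
                )
            )
        # restrict known compositions to the bundle's types
        for m in mixed:
            m.composition = {ct: f for ct, f in m.composition.items() if ct in types}
        return [normalize_to_million(m) for m in mixed]

    mixed = _mixed(config.seed * 7_919 + 1)

    def _factory(derived_seed: int):
        # fresh candidates for later training iterations
        return assemble_profile_sets(
            corrected, profile_genes, max_sets=config.max_sets, seed=derived_seed
        )

    bundle = train(
        candidates,
        mixed,
        real_bulk_samples=real_bulk_samples,
        config=config.training,
        group_name=config.group_name,
        candidate_factory=_factory,
    )
    bundle.config_snapshot.update(
        {
            "strategy": strategy,
            "filter": {
                "min_count": config.filter_min_count,
                "frac": config.filter_frac,
                "mode": config.filter_mode,
                "n_retained": len(report.retained_genes),
                "removed_count_fraction": report.removed_count_fraction,
            },
            "de": {
                "log2fc_cutoff": config.log2fc_cutoff,
                "alpha": config.de_alpha,
                "genes_per_type": {ct: len(g) for ct, g in profile_genes.items()},
            },
            "max_sets": config.max_sets,
            "seed": config.seed,
            "group_name": config.group_name,
        }
    )
    return bundle
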