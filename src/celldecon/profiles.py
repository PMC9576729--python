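"""Cell-type profile genes and candidate profile sets.

Signature genes are found by one-vs-rest differential expression on the
batch-corrected pure pseudo-bulks: a negative-binomial score test with
moment-estimated tagwise dispersion (shrunk toward the across-gene
median), Benjamini-Hochberg adjusted within each contrast. Genes passing
log2FC > 1 against the average of the other cell types at adjusted
p < 0.05 become candidates; per-type candidate lists are balanced to a
common size and made disjoint across types. Candidate profile sets then
combine one corrected pure replicate per cell type.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .types import CellTypeProfile, ProfileSet, PseudoBulkSample

__all__ = [
    "DEResult",
    "de_one_vs_rest",
    "select_profile_genes",
    "assemble_profile_sets",
]

logger = logging.getLogger(__name__)

PSEUDOCOUNT = 1.0
DEFAULT_MIN_GENES = 100
DEFAULT_MAX_GENES = 350


@dataclass
class DEResult:
    """One gene's one-vs-rest differential expression outcome."""

    gene: str
    cell_type: str
    log2fc: float
    pvalue: float
    adj_pvalue: float


def _bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    n = len(pvals)
    order = np.argsort(pvals)
    ranked = pvals[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def _moment_dispersion(mat: np.ndarray, groups: list[np.ndarray]) -> np.ndarray:
    """Tagwise NB dispersion by method of moments, shrunk to the median.

    Within-group residual variance is pooled per gene; the moment estimate
    phi = (s2 - mu) / mu^2 is floored at zero and shrunk toward the
    across-gene median with a fixed prior weight, stabilizing genes whose
    few replicates give noisy dispersion estimates.
    """
    n_total = sum(len(g) for g in groups)
    df = n_total - len(groups)
    ss = np.zeros(mat.shape[0])
    for g in groups:
        sub = mat[:, g]
        ss += ((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    s2 = ss / max(df, 1)
    mu = mat.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = np.where(mu > 0, (s2 - mu) / np.maximum(mu, 1e-12) ** 2, 0.0)
    phi = np.clip(phi, 0.0, 100.0)
    prior_df = 10.0
    phi_med = np.median(phi[mu > 0]) if np.any(mu > 0) else 0.0
    return (df * phi + prior_df * phi_med) / (df + prior_df)


def de_one_vs_rest(
    pseudobulks: list[PseudoBulkSample],
    cell_type: str,
) -> list[DEResult]:
    """Test each gene for higher expression in one cell type vs the rest.

    The fold change is log2 of the target type's mean over the average of
    the other cell types' per-type means (with a pseudo-count); the test is
    an NB score test of the target samples against the pooled rest.
    """
    target = [s for s in pseudobulks if s.cell_type == cell_type]
    rest = [s for s in pseudobulks if s.cell_type != cell_type and s.cell_type is not None]
    if len(target) < 2 or len(rest) < 2:
        raise ValueError(
            f"need >= 2 samples per side for {cell_type!r} "
            f"(got {len(target)} vs {len(rest)})"
        )
    genes = target[0].counts.index
    t_mat = np.column_stack([s.counts.reindex(genes).to_numpy() for s in target])
    r_mat = np.column_stack([s.counts.reindex(genes).to_numpy() for s in rest])

    # one-vs-average fold change: average of the OTHER TYPES' means, so a
    # large rest type cannot drown out small ones
    rest_types: dict[str, list[int]] = {}
    for j, s in enumerate(rest):
        rest_types.setdefault(s.cell_type, []).append(j)
    rest_type_means = np.column_stack([r_mat[:, idx].mean(axis=1) for idx in rest_types.values()])
    m_target = t_mat.mean(axis=1)
    m_rest_avg = rest_type_means.mean(axis=1)
    log2fc = np.log2((m_target + PSEUDOCOUNT) / (m_rest_avg + PSEUDOCOUNT))

    # NB score test, target vs pooled rest, under the pooled-mean null
    full = np.column_stack([t_mat, r_mat])
    n1, n2 = t_mat.shape[1], r_mat.shape[1]
    groups = [np.arange(n1), np.arange(n1, n1 + n2)]
    phi = _moment_dispersion(full, groups)
    mu0 = full.mean(axis=1)
    m2 = r_mat.mean(axis=1)
    var0 = mu0 + phi * mu0**2
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = (m_target - m2) ** 2 / (var0 * (1.0 / n1 + 1.0 / n2))
    stat = np.where(var0 > 0, stat, 0.0)
    pvals = stats.chi2.sf(stat, df=1)
    pvals = np.where(var0 > 0, pvals, 1.0)
    adj = _bh_adjust(pvals)

    return [
        DEResult(gene=g, cell_type=cell_type, log2fc=float(fc), pvalue=float(p), adj_pvalue=float(q))
        for g, fc, p, q in zip(genes, log2fc, pvals, adj)
    ]


def select_profile_genes(
    de: list[DEResult],
    target_n_per_type: int | None = None,
    log2fc_cutoff: float = 1.0,
    alpha: float = 0.05,
    min_genes: int = DEFAULT_MIN_GENES,
    max_genes: int = DEFAULT_MAX_GENES,
) -> dict[str, list[str]]:
    """Pick a balanced, disjoint profile-gene list per cell type.

    Candidates pass log2FC > ``log2fc_cutoff`` and BH-adjusted p <
    ``alpha``. A gene significant for several types is kept only where its
    fold change is largest (ties broken by lexicographic type order).
    Per-type lists are ranked by descending fold change and truncated to a
    common target: the smallest per-type candidate count, clamped into
    [``min_genes``, ``max_genes``] (or ``target_n_per_type`` if given).
    """
    cell_types = sorted({r.cell_type for r in de})
    candidates: dict[str, list[DEResult]] = {ct: [] for ct in cell_types}
    best_for_gene: dict[str, tuple[float, str]] = {}
    for r in de:
        if r.log2fc > log2fc_cutoff and r.adj_pvalue < alpha:
            prev = best_for_gene.get(r.gene)
            if prev is None or r.log2fc > prev[0] or (r.log2fc == prev[0] and r.cell_type < prev[1]):
                best_for_gene[r.gene] = (r.log2fc, r.cell_type)
    for r in de:
        if r.log2fc > log2fc_cutoff and r.adj_pvalue < alpha:
            if best_for_gene[r.gene][1] == r.cell_type:
                candidates[r.cell_type].append(r)

    counts = {ct: len(lst) for ct, lst in candidates.items()}
    if target_n_per_type is None:
        target_n = int(np.clip(min(counts.values()), min_genes, max_genes))
    else:
        target_n = target_n_per_type
    short = [ct for ct, c in counts.items() if c < min(target_n, min_genes)]
    if short:
        raise ValueError(
            f"too few profile-gene candidates for {short} "
            f"(counts {counts}); profiles cannot be built"
        )
    out = {}
    for ct, lst in candidates.items():
        ranked = sorted(lst, key=lambda r: (-r.log2fc, r.gene))
        out[ct] = [r.gene for r in ranked[:target_n]]
    logger.info(
        "profile genes per type: target %d from candidate counts %s", target_n, counts
    )
    return out


def assemble_profile_sets(
    pseudobulks: list[PseudoBulkSample],
    profile_genes: dict[str, list[str]],
    max_sets: int = 200,
    seed: int = 0,
) -> list[ProfileSet]:
    """Combine one corrected pure replicate per cell type into candidate sets.

    The gene universe is the union of all profile genes. If the full
    Cartesian product of replicate choices has at most ``max_sets``
    members it is enumerated; otherwise ``max_sets`` distinct combinations
    are sampled uniformly with the given seed.
    """
    cell_types = sorted(profile_genes)
    universe = sorted({g for genes in profile_genes.values() for g in genes})
    replicates: dict[str, list[PseudoBulkSample]] = {ct: [] for ct in cell_types}
    for s in pseudobulks:
        if s.kind == "pure" and s.cell_type in replicates:
            replicates[s.cell_type].append(s)
    empty = [ct for ct, lst in replicates.items() if not lst]
    if empty:
        raise ValueError(f"no pure replicates for cell types: {empty}")
    for lst in replicates.values():
        lst.sort(key=lambda s: s.sample_id)

    sizes = [len(replicates[ct]) for ct in cell_types]
    n_product = int(np.prod(sizes, dtype=object))
    if n_product <= max_sets:
        combos = list(itertools.product(*[range(k) for k in sizes]))
    else:
        rng = np.random.default_rng(seed)
        seen: set[tuple[int, ...]] = set()
        while len(seen) < max_sets:
            seen.add(tuple(int(rng.integers(k)) for k in sizes))
        combos = sorted(seen)

    sets = []
    for combo in combos:
        profiles = {}
        for ct, idx in zip(cell_types, combo):
            rep = replicates[ct][idx]
            values = rep.counts.reindex(universe, fill_value=0.0)
            total = values.sum()
            if total > 0:
                values = values * (1e6 / total)
            profiles[ct] = CellTypeProfile(
                cell_type=ct,
                values=values,
                profile_genes=list(profile_genes[ct]),
                source=(rep.source_dataset_id, idx),
            )
        set_id = "set_" + "_".join(f"{ct}.{i}" for ct, i in zip(cell_types, combo))
        sets.append(ProfileSet(set_id=set_id, profiles=profiles))
    logger.info("assembled %d candidate profile sets (product %d)", len(sets), n_product)
    return sets
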