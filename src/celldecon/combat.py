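"""Empirical-Bayes batch correction of pure pseudo-bulk samples.

Implements parametric ComBat: per-gene standardization against a model
with batch indicators (plus optional biological covariates), empirical-
Bayes shrinkage of per-batch location and scale estimates toward their
across-gene priors, and back-transformation. Two application strategies
are supported, chosen by how much the datasets' cell-type repertoires
overlap: with sparse overlap, correction runs independently within each
cell type (batch = source dataset); with high overlap, a single run over
all samples with cell type as a protected covariate suffices and avoids
removing true cell-type differences.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd

from .types import BatchDesign, PseudoBulkSample

__all__ = [
    "combat_correct",
    "choose_strategy",
    "correct_pure_pseudobulks",
]

logger = logging.getLogger(__name__)


def _design_matrix(labels: list[str], drop_first: bool = False) -> np.ndarray:
    levels = sorted(set(labels))
    if drop_first:
        levels = levels[1:]
    return np.column_stack([[1.0 if l == lev else 0.0 for l in labels] for lev in levels]) \
        if levels else np.empty((len(labels), 0))


def _aprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (2 * s2 + m**2) / s2


def _bprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (m * s2 + m**3) / s2


def _postmean(g_hat, g_bar, n, d_star, t2):
    return (t2 * n * g_hat + d_star * g_bar) / (t2 * n + d_star)


def _postvar(sum2, n, a, b):
    return (0.5 * sum2 + b) / (n / 2.0 + a - 1.0)


def _it_sol(z_batch, g_hat, d_hat, g_bar, t2, a, b, conv=1e-8, max_iter=2000):
    """Iterate the coupled EB posterior equations to their fixed point."""
    n = z_batch.shape[1]
    g_old, d_old = g_hat.copy(), d_hat.copy()
    for _ in range(max_iter):
        g_new = _postmean(g_hat, g_bar, n, d_old, t2)
        sum2 = ((z_batch - g_new[:, None]) ** 2).sum(axis=1)
        d_new = _postvar(sum2, n, a, b)
        change = max(
            np.abs(g_new - g_old).max() / np.abs(g_old).max(),
            np.abs(d_new - d_old).max() / np.abs(d_old).max(),
        )
        g_old, d_old = g_new, d_new
        if change < conv:
            break
    return g_old, d_old


def combat_correct(
    matrix: pd.DataFrame,
    batches: list[str],
    covariates: list[str] | None = None,
) -> pd.DataFrame:
    """Parametric empirical-Bayes batch adjustment of a gene x sample matrix.

    ``matrix`` is log-scale expression (genes in rows). ``batches`` gives the
    per-sample batch label; ``covariates`` an optional per-sample biological
    label (e.g. cell type) protected during standardization. Batches with a
    single sample pass through uncorrected with a warning; genes with zero
    pooled variance pass through unchanged; a single batch returns the input.
    """
    Y = matrix.to_numpy(dtype=float)
    if not np.all(np.isfinite(Y)):
        raise ValueError("non-finite values in expression matrix")
    if len(batches) != Y.shape[1]:
        raise ValueError("one batch label required per sample")

    batch_levels = sorted(set(batches))
    if len(batch_levels) < 2:
        logger.warning("single batch: returning input unchanged")
        return matrix.copy()

    small = {b for b in batch_levels if batches.count(b) < 2}
    if small:
        logger.warning("batches with < 2 samples pass through uncorrected: %s", sorted(small))
        keep = [i for i, b in enumerate(batches) if b not in small]
        sub = combat_correct(
            matrix.iloc[:, keep],
            [batches[i] for i in keep],
            [covariates[i] for i in keep] if covariates is not None else None,
        )
        out = matrix.copy()
        out.iloc[:, keep] = sub.to_numpy()
        return out

    n_genes, n_samples = Y.shape
    batch_design = _design_matrix(batches)  # one column per batch
    n_batches = batch_design.shape[1]
    n_per_batch = batch_design.sum(axis=0)

    X = batch_design
    if covariates is not None:
        cov = _design_matrix(covariates, drop_first=True)
        X = np.column_stack([batch_design, cov])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("confounded design: covariates collinear with batch")

    # standardize each gene against the full model
    B_hat = np.linalg.solve(X.T @ X, X.T @ Y.T)  # coefficients x genes
    grand_mean = (n_per_batch / n_samples) @ B_hat[:n_batches]
    resid = Y - (X @ B_hat).T
    var_pooled = (resid**2).mean(axis=1)
    nonzero = var_pooled > 0

    stand_mean = np.tile(grand_mean[:, None], (1, n_samples))
    if X.shape[1] > n_batches:
        X_cov = X.copy()
        X_cov[:, :n_batches] = 0.0
        stand_mean = stand_mean + (X_cov @ B_hat).T

    sd = np.sqrt(var_pooled[nonzero])[:, None]
    Z = (Y[nonzero] - stand_mean[nonzero]) / sd

    # per-batch location/scale estimates and their EB priors
    gamma_hat = np.linalg.solve(batch_design.T @ batch_design, batch_design.T @ Z.T)
    delta_hat = np.vstack([
        Z[:, np.asarray(batches) == b].var(axis=1, ddof=1) for b in batch_levels
    ])
    gamma_bar = gamma_hat.mean(axis=1)
    t2 = gamma_hat.var(axis=1, ddof=1)

    Z_adj = Z.copy()
    for i, b in enumerate(batch_levels):
        cols = np.asarray(batches) == b
        d_i = delta_hat[i]
        if not np.all(np.isfinite(d_i)) or d_i.var(ddof=1) <= 0 or np.all(d_i <= 0):
            # scale not estimable (e.g. identical replicates within the
            # batch): location-only adjustment
            logger.warning("batch %s: within-batch scale not estimable; "
                           "location-only adjustment", b)
            n_b = int(cols.sum())
            g_star = _postmean(gamma_hat[i], gamma_bar[i], n_b, 1.0, t2[i])
            d_star = np.ones_like(d_i)
        else:
            a, bp = _aprior(d_i), _bprior(d_i)
            g_star, d_star = _it_sol(
                Z[:, cols], gamma_hat[i], d_i, gamma_bar[i], t2[i], a, bp
            )
        Z_adj[:, cols] = (Z[:, cols] - g_star[:, None]) / np.sqrt(d_star)[:, None]

    out = Y.copy()
    out[nonzero] = Z_adj * sd + stand_mean[nonzero]
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def choose_strategy(design: BatchDesign | pd.DataFrame, threshold: float = 0.5) -> str:
    """Pick a correction strategy from cell-type overlap across datasets.

    Overlap score = mean Jaccard similarity of the datasets' cell-type sets
    over all dataset pairs. High overlap (score >= ``threshold``) supports a
    single all-in-one correction; sparse overlap requires correcting within
    each cell type separately.
    """
    table = design.overlap_table() if isinstance(design, BatchDesign) else design
    sets = [frozenset(table.columns[table.loc[d]]) for d in table.index]
    pairs = list(itertools.combinations(sets, 2))
    if not pairs:
        return "all_in_one"
    score = float(np.mean([
        len(a & b) / len(a | b) if (a | b) else 0.0 for a, b in pairs
    ]))
    strategy = "all_in_one" if score >= threshold else "per_cell_type"
    logger.info("cell-type overlap score %.3f -> %s correction", score, strategy)
    return strategy


def correct_pure_pseudobulks(
    samples: list[PseudoBulkSample],
    strategy: str | None = None,
    overlap_threshold: float = 0.5,
) -> list[PseudoBulkSample]:
    """Batch-correct 1M-normalized pure pseudo-bulks across source datasets.

    Correction operates on log2(x + 1); corrected linear values are
    recovered by back-transform and floored at zero. ``per_cell_type``
    corrects each cell type independently (batch = dataset);
    ``all_in_one`` corrects all samples at once with cell type as a
    protected covariate. When ``strategy`` is None it is chosen from the
    overlap structure.
    """
    if not samples:
        raise ValueError("no samples to correct")
    design = BatchDesign(
        samples=[(s.sample_id, s.source_dataset_id, s.cell_type or "") for s in samples]
    )
    if strategy is None:
        strategy = choose_strategy(design, overlap_threshold)
    if strategy not in ("per_cell_type", "all_in_one"):
        raise ValueError(f"unknown strategy {strategy!r}")

    genes = samples[0].counts.index
    mat = pd.DataFrame(
        {s.sample_id: np.log2(s.counts.reindex(genes).to_numpy() + 1.0) for s in samples},
        index=genes,
    )
    batches = [s.source_dataset_id for s in samples]
    types = [s.cell_type or "" for s in samples]

    if strategy == "per_cell_type":
        corrected = mat.copy()
        for ct in sorted(set(types)):
            cols = [i for i, t in enumerate(types) if t == ct]
            sub = combat_correct(mat.iloc[:, cols], [batches[i] for i in cols])
            corrected.iloc[:, cols] = sub.to_numpy()
    else:
        corrected = combat_correct(mat, batches, covariates=types)

    out = []
    for s in samples:
        linear = np.maximum(2.0 ** corrected[s.sample_id].to_numpy() - 1.0, 0.0)
        out.append(
            PseudoBulkSample(
                sample_id=s.sample_id,
                source_dataset_id=s.source_dataset_id,
                kind=s.kind,
                cell_type=s.cell_type,
                composition=s.composition,
                counts=pd.Series(linear, index=genes),
                n_cells_used=s.n_cells_used,
                total_counts=s.total_counts,
                below_floor=s.below_floor,
            )
        )
    return out
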