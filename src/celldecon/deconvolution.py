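"""Ensemble NNLS deconvolution of bulk samples against profile bundles.

Each bulk sample G is decomposed against a profile set's signature matrix
by non-negative least squares,

    G = beta_1 P_1 + beta_2 P_2 + ... + beta_c P_c,   beta_i >= 0,

over the genes shared between query and profiles, both sides normalized
to one million. The N sets with the lowest goodness-of-fit RMSE are
combined into weighted proportions; per-type p-values (from an OLS refit
on the NNLS active set) drive the undetermined fraction: the mass carried
by coefficients whose significance test fails.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .types import (
    LIBRARY_SIZE,
    BulkSample,
    DeconvolutionResult,
    EnsembleConfig,
    ProfileBundle,
    ProfileSet,
    SingleSetFit,
)

__all__ = [
    "nnls_fit",
    "coefficient_pvalues",
    "ensemble_weights",
    "ensemble_combine",
    "deconvolve",
    "stepwise_deconvolve",
    "HierarchyLevel",
    "StepwiseResult",
]

logger = logging.getLogger(__name__)

MIN_GENE_COVERAGE = 0.5


def nnls_fit(bulk: pd.Series | BulkSample, profile_set: ProfileSet) -> SingleSetFit:
    """Fit one bulk sample against one profile set by NNLS.

    Query and profiles are restricted to their shared genes and both
    renormalized to one million over that intersection before fitting.
    Fails with a coverage error when fewer than half the set's profile
    genes are present in the query.
    """
    expr = bulk.expression if isinstance(bulk, BulkSample) else bulk
    P = profile_set.matrix()
    shared = P.index.intersection(expr.index)
    coverage = len(shared) / len(P.index)
    if coverage < MIN_GENE_COVERAGE:
        missing = sorted(set(P.index) - set(expr.index))
        raise ValueError(
            f"gene coverage {coverage:.2f} below {MIN_GENE_COVERAGE}; "
            f"missing e.g. {missing[:10]}"
        )
    g = expr.loc[shared].to_numpy(dtype=float)
    if g.sum() <= 0:
        raise ValueError("query expression is zero over the shared genes")
    A = P.loc[shared].to_numpy(dtype=float)
    g = g * (LIBRARY_SIZE / g.sum())
    col_sums = A.sum(axis=0)
    col_sums[col_sums <= 0] = 1.0
    A = A * (LIBRARY_SIZE / col_sums)

    beta, _ = optimize.nnls(A, g)
    fitted = A @ beta
    rmse = float(np.sqrt(np.mean((g - fitted) ** 2)))
    fit = SingleSetFit(
        set_id=profile_set.set_id,
        raw_coefficients={ct: float(b) for ct, b in zip(P.columns, beta)},
        fitted_expression=pd.Series(fitted, index=shared),
        fit_rmse=rmse,
    )
    fit.coefficient_pvalues = coefficient_pvalues(fit, A=A, g=g, cell_types=list(P.columns))
    return fit


def coefficient_pvalues(
    fit: SingleSetFit,
    A: np.ndarray | None = None,
    g: np.ndarray | None = None,
    cell_types: list[str] | None = None,
) -> dict[str, float]:
    """Two-sided t-tests of the active NNLS coefficients against zero.

    Ordinary least squares is refit on the cell types with strictly
    positive NNLS coefficients; each coefficient is tested with residual
    degrees of freedom (genes - active types). Types at the NNLS boundary
    (coefficient zero) get p = 1 by convention.
    """
    if A is None or g is None:
        raise ValueError("design matrix and query vector required to compute p-values")
    cell_types = cell_types or list(fit.raw_coefficients)
    beta = np.array([fit.raw_coefficients[ct] for ct in cell_types])
    active = beta > 0
    pvals = {ct: 1.0 for ct in cell_types}
    k = int(active.sum())
    n = len(g)
    df = n - k
    if k == 0:
        return pvals
    if df <= 0:
        logger.warning("no residual degrees of freedom; all p-values set to 1")
        return pvals
    Aa = A[:, active]
    coef, res, *_ = np.linalg.lstsq(Aa, g, rcond=None)
    resid = g - Aa @ coef
    sigma2 = float(resid @ resid) / df
    XtX_inv = np.linalg.pinv(Aa.T @ Aa)
    se = np.sqrt(np.maximum(sigma2 * np.diag(XtX_inv), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, coef / se, np.inf)
    p_active = 2.0 * stats.t.sf(np.abs(tvals), df)
    for ct, p in zip(np.array(cell_types)[active], p_active):
        pvals[str(ct)] = float(p)
    return pvals


def ensemble_weights(fit_rmses: list[float], scheme: str = "as_printed") -> np.ndarray:
    """Per-set ensemble weights from goodness-of-fit RMSEs.

    ``as_printed`` uses the absolute deviation from the mean RMSE,
    normalized to sum to one (uniform when all deviations vanish,
    including N = 1). ``inverse_rmse`` weights each set by 1/(RMSE + eps),
    normalized; it guarantees the lowest-RMSE set the largest weight,
    which the deviation-from-mean formula does not for N >= 3.
    """
    r = np.asarray(fit_rmses, dtype=float)
    if np.any(r < 0):
        raise ValueError("RMSE values must be non-negative")
    n = len(r)
    if scheme == "as_printed":
        dev = np.abs(r - r.mean())
        total = dev.sum()
        if total <= 0:
            return np.full(n, 1.0 / n)
        return dev / total
    if scheme == "inverse_rmse":
        inv = 1.0 / (r + 1e-12)
        return inv / inv.sum()
    raise ValueError(f"unknown weight scheme {scheme!r}")


def ensemble_combine(
    sample_id: str,
    fits: list[SingleSetFit],
    config: EnsembleConfig | None = None,
) -> DeconvolutionResult:
    """Combine the top-N single-set fits into one composition estimate.

    Per-fit coefficients are normalized to proportions, then averaged with
    the goodness-of-fit weights; per-type p-values are combined with the
    same weights. Proportions whose combined p-value is not below alpha
    are pooled into the undetermined fraction.
    """
    config = config or EnsembleConfig()
    if not fits:
        raise ValueError("no fits to combine")
    fits = sorted(fits, key=lambda f: f.fit_rmse)[: config.top_n]
    if len(fits) < config.top_n:
        logger.warning("only %d fits available for top_n=%d", len(fits), config.top_n)
    w = ensemble_weights([f.fit_rmse for f in fits], config.weight_scheme)

    cell_types = list(fits[0].raw_coefficients)
    props = {ct: 0.0 for ct in cell_types}
    pvals = {ct: 0.0 for ct in cell_types}
    for f, wj in zip(fits, w):
        fp = f.proportions
        for ct in cell_types:
            props[ct] += wj * fp[ct]
            pvals[ct] += wj * f.coefficient_pvalues.get(ct, 1.0)
    undetermined = sum(v for ct, v in props.items() if pvals[ct] >= config.alpha)
    return DeconvolutionResult(
        sample_id=sample_id,
        proportions=props,
        pvalues=pvals,
        undetermined=float(undetermined),
        fit_rmse=[f.fit_rmse for f in fits],
        weights=[float(x) for x in w],
        used_set_ids=[f.set_id for f in fits],
        alpha=config.alpha,
    )


def deconvolve(
    bulk_samples: list[BulkSample],
    bundle: ProfileBundle,
    config: EnsembleConfig | None = None,
) -> list[DeconvolutionResult]:
    """Ensemble deconvolution of bulk samples against a profile bundle.

    Every profile set in the bundle is fit to each sample; the N fits with
    the lowest goodness-of-fit RMSE (ties broken by set rank) are combined.
    """
    config = config or EnsembleConfig()
    if not bundle.profile_sets:
        raise ValueError("empty profile bundle")
    results = []
    for sample in bulk_samples:
        fits = []
        for pset in bundle.profile_sets:
            fits.append((pset.rank, nnls_fit(sample, pset)))
        fits.sort(key=lambda t: (t[1].fit_rmse, t[0]))
        top = [f for _, f in fits[: config.top_n]]
        results.append(ensemble_combine(sample.sample_id, top, config))
    return results


@dataclass
class HierarchyLevel:
    """One bundle in a coarse-to-fine deconvolution hierarchy."""

    bundle: ProfileBundle
    parent_type: str | None = None  # cell type in the parent bundle gating this level


@dataclass
class StepwiseResult:
    """Nested results of hierarchical deconvolution for one sample."""

    sample_id: str
    coarse: DeconvolutionResult
    refined: dict[str, "StepwiseLevelResult"] = field(default_factory=dict)


@dataclass
class StepwiseLevelResult:
    """A fine bundle's result, raw and rescaled by its parent fraction."""

    parent_type: str
    parent_fraction: float
    result: DeconvolutionResult
    rescaled_proportions: dict[str, float] = field(default_factory=dict)


def _check_acyclic(levels: list[HierarchyLevel]) -> None:
    names = [lv.bundle.group_name for lv in levels]
    if len(set(names)) != len(names):
        raise ValueError("duplicate bundle names in hierarchy")
    child_types = {ct for lv in levels[1:] for ct in lv.bundle.cell_types}
    for lv in levels[1:]:
        if lv.parent_type is None:
            raise ValueError(f"fine bundle {lv.bundle.group_name} lacks a parent type")
        if lv.parent_type in child_types:
            raise ValueError(
                f"cyclic hierarchy: parent type {lv.parent_type!r} is itself a refined type"
            )


def stepwise_deconvolve(
    bulk_samples: list[BulkSample],
    hierarchy: list[HierarchyLevel],
    config: EnsembleConfig | None = None,
    refine_threshold: float = 0.2,
) -> list[StepwiseResult]:
    """Coarse-to-fine deconvolution: refine a type only when it is present.

    The first level runs on every sample; a fine bundle runs only when its
    parent type's significant proportion reaches ``refine_threshold``.
    Fine proportions are reported both raw (summing to one within the
    fine bundle) and rescaled by the parent fraction.
    """
    if not hierarchy:
        raise ValueError("empty hierarchy")
    _check_acyclic(hierarchy)
    config = config or EnsembleConfig()
    coarse_results = deconvolve(bulk_samples, hierarchy[0].bundle, config)
    out = []
    for sample, coarse in zip(bulk_samples, coarse_results):
        node = StepwiseResult(sample_id=sample.sample_id, coarse=coarse)
        sig = coarse.significant_proportions
        for level in hierarchy[1:]:
            parent_frac = sig.get(level.parent_type, 0.0)
            if parent_frac < refine_threshold:
                continue
            fine = deconvolve([sample], level.bundle, config)[0]
            node.refined[level.bundle.group_name] = StepwiseLevelResult(
                parent_type=level.parent_type,
                parent_fraction=parent_frac,
                result=fine,
                rescaled_proportions={
                    ct: v * parent_frac for ct, v in fine.proportions.items()
                },
            )
        out.append(node)
    return out
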