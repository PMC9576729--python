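"""Composition-accuracy metrics: RMSE per sample and per cell type.

The core criterion is the root-mean-square difference between expected
and estimated proportions,

    RMSE = sqrt( sum_i (Exp_i - Est_i)^2 / c ),

computed over the union of cell types appearing in either map (an absent
type counts as zero). The same quantity is aggregated per cell type
across samples, and a target-purity variant scores samples against an
assumed 100% target composition — useful for tracking how closely
differentiating iPSC-derived cultures approach their intended cell type.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import DeconvolutionResult

__all__ = [
    "EvaluationRecord",
    "composition_rmse",
    "records_from_results",
    "rmse_by_cell_type",
    "rmse_by_sample",
    "evaluate_target_purity",
]


@dataclass
class EvaluationRecord:
    """Expected vs estimated composition of one sample."""

    sample_id: str
    expected: dict[str, float]
    estimated: dict[str, float]

    @property
    def rmse_sample(self) -> float:
        return composition_rmse(self.expected, self.estimated)


def composition_rmse(
    expected: dict[str, float],
    estimated: dict[str, float],
    include_undetermined: bool = False,
) -> float:
    """Root-mean-square error between two composition maps.

    The union of keys defines c; a type absent from one map contributes
    its full fraction as error. The undetermined slot is excluded unless
    the expected map declares it (or ``include_undetermined`` is set).
    """
    keys = set(expected) | set(estimated)
    if not keys:
        raise ValueError("both composition maps are empty")
    if not include_undetermined and "undetermined" not in expected:
        keys.discard("undetermined")
    keys = sorted(keys)
    exp = np.array([expected.get(k, 0.0) for k in keys])
    est = np.array([estimated.get(k, 0.0) for k in keys])
    if np.any(exp < 0) or np.any(est < 0):
        raise ValueError("composition fractions must be non-negative")
    return float(np.sqrt(np.mean((exp - est) ** 2)))


def records_from_results(
    results: list[DeconvolutionResult],
    expected: dict[str, dict[str, float]],
) -> list[EvaluationRecord]:
    """Pair deconvolution results with their known compositions."""
    return [
        EvaluationRecord(
            sample_id=r.sample_id,
            expected=expected[r.sample_id],
            estimated=r.proportions,
        )
        for r in results
        if r.sample_id in expected
    ]


def rmse_by_cell_type(records: list[EvaluationRecord]) -> pd.DataFrame:
    """Per-cell-type RMSE across samples, with median and spread columns.

    For each cell type, the RMSE of (expected - estimated) over samples,
    plus the median and interquartile range of the per-sample absolute
    errors for report panels.
    """
    if not records:
        raise ValueError("no evaluation records")
    types = sorted({t for r in records for t in (set(r.expected) | set(r.estimated))} - {"undetermined"})
    rows = []
    for ct in types:
        err = np.array([
            r.expected.get(ct, 0.0) - r.estimated.get(ct, 0.0) for r in records
        ])
        rows.append({
            "cell_type": ct,
            "rmse": float(np.sqrt(np.mean(err**2))),
            "median_abs_error": float(np.median(np.abs(err))),
            "iqr_abs_error": float(np.subtract(*np.percentile(np.abs(err), [75, 25]))),
            "n_samples": len(err),
        })
    return pd.DataFrame(rows).set_index("cell_type")


def rmse_by_sample(records: list[EvaluationRecord]) -> pd.Series:
    """Per-sample composition RMSE across each sample's cell types."""
    if not records:
        raise ValueError("no evaluation records")
    return pd.Series({r.sample_id: r.rmse_sample for r in records}, name="rmse")


def evaluate_target_purity(
    results: list[DeconvolutionResult],
    target_type: str,
) -> pd.DataFrame:
    """Score samples against an assumed 100% target-type composition.

    Intended for samples (e.g. iPSC-derived cultures) whose true
    composition is unknown: the reported RMSE measures similarity to the
    target cell type, not deconvolution accuracy.
    """
    rows = []
    for r in results:
        types = set(r.proportions) | {target_type}
        if target_type not in r.proportions:
            raise ValueError(f"target type {target_type!r} absent from result {r.sample_id}")
        expected = {ct: (1.0 if ct == target_type else 0.0) for ct in types}
        rows.append({
            "sample_id": r.sample_id,
            "target_fraction": r.proportions[target_type],
            "rmse_to_target": composition_rmse(expected, r.proportions),
        })
    return pd.DataFrame(rows).set_index("sample_id")
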