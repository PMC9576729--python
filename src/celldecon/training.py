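"""Ranking and filtering of candidate profile sets on known compositions.

Each candidate set is scored by the mean composition RMSE it achieves
when deconvolving (single-set, no ensemble) samples of known composition.
Training runs two sequential steps per iteration — first on mixed
pseudo-bulk samples, then (when available) on real bulk samples — keeping
the top-k survivors of each step. If the best score misses the target and
iterations remain, a fresh batch of candidates is generated with a seed
derived from the base seed, merged, and re-ranked.
"""

from __future__ import annotations

import logging
import math
from typing import Callable, Sequence

import numpy as np

from .deconvolution import nnls_fit
from .evaluation import composition_rmse
from .types import BulkSample, ProfileBundle, ProfileSet, PseudoBulkSample, TrainingConfig

__all__ = ["score_profile_set", "train"]

logger = logging.getLogger(__name__)


def _as_bulk(sample: PseudoBulkSample | BulkSample) -> BulkSample:
    if isinstance(sample, BulkSample):
        return sample
    return BulkSample(
        sample_id=sample.sample_id,
        expression=sample.counts,
        known_composition=sample.composition,
    )


def score_profile_set(
    profile_set: ProfileSet,
    samples: Sequence[PseudoBulkSample | BulkSample],
) -> float:
    """Mean composition RMSE of single-set deconvolution over known samples.

    A sample covering fewer than half the set's genes scores as failed
    (NaN), as does one with no recorded composition.
    """
    if not samples:
        raise ValueError("no training samples supplied")
    rmses = []
    for s in samples:
        bulk = _as_bulk(s)
        if bulk.known_composition is None:
            raise ValueError(f"sample {bulk.sample_id} lacks a known composition")
        try:
            fit = nnls_fit(bulk, profile_set)
        except ValueError:
            return math.nan
        rmses.append(composition_rmse(bulk.known_composition, fit.proportions))
    return float(np.mean(rmses))


def _rank(
    sets: list[ProfileSet],
    scores: list[float],
    keep: int,
) -> tuple[list[ProfileSet], list[float]]:
    """Keep the top sets by ascending score; NaN scores sort last; ties by id."""
    order = sorted(
        range(len(sets)),
        key=lambda i: (math.isnan(scores[i]), scores[i] if not math.isnan(scores[i]) else 0.0, sets[i].set_id),
    )
    kept = order[:keep]
    return [sets[i] for i in kept], [scores[i] for i in kept]


def train(
    candidate_sets: list[ProfileSet],
    mixed_samples: Sequence[PseudoBulkSample | BulkSample],
    real_bulk_samples: Sequence[BulkSample] | None = None,
    config: TrainingConfig | None = None,
    group_name: str = "bundle",
    candidate_factory: Callable[[int], list[ProfileSet]] | None = None,
) -> ProfileBundle:
    """Two-step iterative training of a ranked profile bundle.

    Step 1 scores every candidate on the mixed pseudo-bulks and keeps the
    top ``keep_top_k_after_step1``; step 2, when real bulk training
    samples are provided, re-scores the survivors and keeps
    ``keep_top_k_after_step2``. When the best score still exceeds
    ``rmse_target`` and iterations remain, ``candidate_factory(seed)``
    supplies fresh candidates (seed derived deterministically from the
    base seed) which are merged with the survivors and re-ranked.
    """
    config = config or TrainingConfig()
    if not candidate_sets:
        raise ValueError("no candidate profile sets")
    if not mixed_samples:
        raise ValueError("no mixed training samples")

    pool = {s.set_id: s for s in candidate_sets}
    kept: list[ProfileSet] = []
    kept_scores: list[float] = []
    history = []
    iteration = 0
    while iteration < config.max_iterations:
        iteration += 1
        sets = sorted(pool.values(), key=lambda s: s.set_id)
        step1 = [score_profile_set(s, mixed_samples) for s in sets]
        if all(math.isnan(x) for x in step1):
            raise ValueError("all candidate sets failed scoring")
        kept, kept_scores = _rank(sets, step1, config.keep_top_k_after_step1)
        step_used = 1
        if real_bulk_samples:
            step2 = [score_profile_set(s, real_bulk_samples) for s in kept]
            kept, kept_scores = _rank(kept, step2, config.keep_top_k_after_step2)
            step_used = 2
        else:
            kept, kept_scores = _rank(kept, kept_scores, config.keep_top_k_after_step2)
        best = kept_scores[0]
        history.append({"iteration": iteration, "best_score": best, "n_candidates": len(sets), "final_step": step_used})
        logger.info("training iteration %d: best RMSE %.4f over %d candidates", iteration, best, len(sets))
        if best <= config.rmse_target or candidate_factory is None:
            break
        if iteration < config.max_iterations:
            derived_seed = (config.seed * 1_000_003 + iteration) % (2**31)
            fresh = candidate_factory(derived_seed)
            pool = {s.set_id: s for s in kept}
            for s in fresh:
                pool.setdefault(s.set_id, s)

    for s, sc in zip(kept, kept_scores):
        s.training_score = sc
    order = sorted(range(len(kept)), key=lambda i: (kept_scores[i], kept[i].set_id))
    ranked = [kept[i] for i in order]
    first = ranked[0]
    return ProfileBundle(
        group_name=group_name,
        cell_types=sorted(first.cell_types),
        gene_universe=first.gene_universe,
        profile_sets=ranked,
        config_snapshot={
            "keep_top_k_after_step1": config.keep_top_k_after_step1,
            "keep_top_k_after_step2": config.keep_top_k_after_step2,
            "rmse_target": config.rmse_target,
            "max_iterations": config.max_iterations,
            "seed": config.seed,
            "iterations_run": iteration,
            "history": history,
        },
    )
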