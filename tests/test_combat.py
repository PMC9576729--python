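import numpy as np
import pandas as pd
import pytest

from celldecon.combat import choose_strategy, combat_correct, correct_pure_pseudobulks
from celldecon.pseudobulk import make_pure_pseudobulks, normalize_to_million
from celldecon.simulate import simulate_reference_collection
from celldecon.types import BatchDesign, SimulationConfig

from reference_combat import reference_combat


def _two_batch_matrix(shift=1.5, n_genes=40, per_batch=6, seed=0, types=None):
    rng = np.random.default_rng(seed)
    base = rng.normal(5, 2, size=(n_genes, 2 * per_batch))
    base[:, per_batch:] += shift
    if types is not None:
        for j, t in enumerate(types):
            if t == "B":
                base[: n_genes // 2, j] += 2.0
    batches = ["b1"] * per_batch + ["b2"] * per_batch
    return pd.DataFrame(base), batches


class TestCombatCorrect:
    def test_location_shift_removed(self):
        """A homogeneous additive batch shift is removed exactly.

        When every gene carries the same standardized batch effect the EB
        posterior coincides with the per-gene estimate, so per-gene batch
        means coincide after adjustment.
        """
        rng = np.random.default_rng(0)
        mu = rng.uniform(3, 8, size=40)
        e = rng.normal(0, 1, size=12)
        Y = mu[:, None] + e[None, :]
        Y[:, 6:] += 1.5
        batches = ["b1"] * 6 + ["b2"] * 6
        out = combat_correct(pd.DataFrame(Y), batches)
        m1 = out.iloc[:, :6].mean(axis=1)
        m2 = out.iloc[:, 6:].mean(axis=1)
        np.testing.assert_allclose(m1, m2, atol=1e-6)

    def test_heterogeneous_shift_strongly_reduced(self):
        """Gene-specific batch shifts shrink toward zero (EB leaves a remnant)."""
        rng = np.random.default_rng(1)
        mat, batches = _two_batch_matrix(seed=1)
        mat.iloc[:, 6:] += rng.normal(0, 1, size=(mat.shape[0], 1))
        before = (mat.iloc[:, 6:].mean(axis=1) - mat.iloc[:, :6].mean(axis=1)).abs()
        out = combat_correct(mat, batches)
        after = (out.iloc[:, 6:].mean(axis=1) - out.iloc[:, :6].mean(axis=1)).abs()
        assert after.mean() < 0.5 * before.mean()

    def test_single_batch_identity(self):
        mat, _ = _two_batch_matrix()
        out = combat_correct(mat, ["b1"] * mat.shape[1])
        np.testing.assert_array_equal(out.to_numpy(), mat.to_numpy())

    def test_matches_independent_reference(self):
        """Vectorized EB adjustment equals a scalar-loop reference transcription."""
        mat, batches = _two_batch_matrix(seed=2)
        out = combat_correct(mat, batches)
        ref = reference_combat(mat.to_numpy(), batches)
        np.testing.assert_allclose(out.to_numpy(), ref, atol=1e-6)

    def test_matches_reference_with_covariate(self):
        types = ["A", "B"] * 6
        mat, batches = _two_batch_matrix(seed=3, types=types)
        out = combat_correct(mat, batches, covariates=types)
        ref = reference_combat(mat.to_numpy(), batches, covariates=types)
        np.testing.assert_allclose(out.to_numpy(), ref, atol=1e-6)

    def test_zero_variance_gene_passes_through(self):
        mat, batches = _two_batch_matrix()
        mat.iloc[0] = 3.0
        out = combat_correct(mat, batches)
        np.testing.assert_array_equal(out.iloc[0].to_numpy(), mat.iloc[0].to_numpy())

    def test_non_finite_rejected(self):
        mat, batches = _two_batch_matrix()
        mat.iloc[1, 1] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            combat_correct(mat, batches)

    def test_singleton_batch_passes_through(self, caplog):
        mat, batches = _two_batch_matrix()
        batches = batches[:-1] + ["b3"]
        with caplog.at_level("WARNING"):
            out = combat_correct(mat, batches)
        np.testing.assert_array_equal(
            out.iloc[:, -1].to_numpy(), mat.iloc[:, -1].to_numpy()
        )
        assert "b3" in caplog.text

    def test_shape_and_universe_preserved(self):
        mat, batches = _two_batch_matrix()
        out = combat_correct(mat, batches)
        assert out.shape == mat.shape
        assert list(out.index) == list(mat.index)


class TestChooseStrategy:
    def test_full_overlap_all_in_one(self):
        tab = pd.DataFrame(True, index=["d1", "d2", "d3"], columns=["A", "B"])
        assert choose_strategy(tab) == "all_in_one"

    def test_zero_overlap_per_cell_type(self):
        tab = pd.DataFrame(
            [[True, False], [False, True]], index=["d1", "d2"], columns=["A", "B"]
        )
        assert choose_strategy(tab) == "per_cell_type"

    def test_sparse_many_dataset_pattern(self):
        """Each type in only 3 of 17 datasets: sparse overlap -> per-type correction."""
        rng = np.random.default_rng(0)
        datasets, types = 17, 9
        tab = pd.DataFrame(False, index=[f"d{i}" for i in range(datasets)],
                           columns=[f"t{j}" for j in range(types)])
        for j in range(types):
            for i in rng.choice(datasets, size=3, replace=False):
                tab.iloc[i, j] = True
        assert choose_strategy(tab) == "per_cell_type"

    def test_batch_design_accepted(self):
        design = BatchDesign(samples=[("s1", "d1", "A"), ("s2", "d2", "A")])
        assert choose_strategy(design) == "all_in_one"


def _corrected_pure(small_collection, strategy):
    refs, _, _ = small_collection
    pure = []
    for i, ds in enumerate(refs):
        pure.extend(make_pure_pseudobulks(ds, replicates_per_type=3, seed=i, count_floor=0.0))
    pure = [normalize_to_million(s) for s in pure]
    return pure, correct_pure_pseudobulks(pure, strategy=strategy)


def _type_dataset_means(samples):
    frames = {}
    for s in samples:
        frames.setdefault((s.cell_type, s.source_dataset_id), []).append(
            np.log2(s.counts.to_numpy() + 1)
        )
    return {k: np.mean(v, axis=0) for k, v in frames.items()}


class TestCorrectPurePseudobulks:
    def test_per_cell_type_shrinks_between_dataset_distance(self, small_collection):
        pure, corrected = _corrected_pure(small_collection, "per_cell_type")
        before, after = _type_dataset_means(pure), _type_dataset_means(corrected)

        def within_type_spread(means):
            dists = []
            types = {ct for ct, _ in means}
            for ct in types:
                vecs = [v for (c, _), v in means.items() if c == ct]
                for i in range(len(vecs)):
                    for j in range(i + 1, len(vecs)):
                        dists.append(np.linalg.norm(vecs[i] - vecs[j]))
            return np.mean(dists)

        assert within_type_spread(after) < 0.5 * within_type_spread(before)

    def test_all_in_one_with_covariate_preserves_type_differences(self, small_collection):
        pure, corrected = _corrected_pure(small_collection, "all_in_one")
        before, after = _type_dataset_means(pure), _type_dataset_means(corrected)

        def between_type_distance(means):
            types = sorted({ct for ct, _ in means})
            centroids = {
                ct: np.mean([v for (c, _), v in means.items() if c == ct], axis=0)
                for ct in types
            }
            return np.mean([
                np.linalg.norm(centroids[a] - centroids[b])
                for i, a in enumerate(types) for b in types[i + 1:]
            ])

        assert abs(between_type_distance(after) - between_type_distance(before)) \
            < 0.1 * between_type_distance(before)

    def test_all_in_one_without_covariate_erodes_separation(self, small_collection):
        """Correcting across everything with no protected covariate removes biology."""
        refs, _, _ = small_collection
        pure = []
        for i, ds in enumerate(refs):
            pure.extend(make_pure_pseudobulks(ds, replicates_per_type=3, seed=i, count_floor=0.0))
        pure = [normalize_to_million(s) for s in pure]
        genes = pure[0].counts.index
        mat = pd.DataFrame(
            {s.sample_id: np.log2(s.counts.to_numpy() + 1.0) for s in pure}, index=genes
        )
        batches = [s.source_dataset_id for s in pure]
        types = [s.cell_type for s in pure]
        no_cov = combat_correct(mat, batches)
        with_cov = combat_correct(mat, batches, covariates=types)

        def separation(m):
            cents = {ct: m.loc[:, [t == ct for t in types]].mean(axis=1) for ct in set(types)}
            keys = sorted(cents)
            return np.mean([
                np.linalg.norm(cents[a] - cents[b])
                for i, a in enumerate(keys) for b in keys[i + 1:]
            ])

        assert separation(no_cov) < separation(with_cov)

    def test_near_identity_on_batch_free_data(self):
        config = SimulationConfig(
            n_datasets=3, cell_types=("A", "B"), n_genes=300,
            n_signature_genes_per_type=20, batch_gene_sigma=0.0,
            cells_per_type=(80, 100), depth_per_cell=(2000, 4000), seed=21,
        )
        refs, _ = simulate_reference_collection(config)
        pure = []
        for i, ds in enumerate(refs):
            pure.extend(make_pure_pseudobulks(ds, replicates_per_type=3, seed=i, count_floor=0.0))
        pure = [normalize_to_million(s) for s in pure]
        corrected = correct_pure_pseudobulks(pure, strategy="all_in_one")
        before = np.column_stack([s.counts.to_numpy() for s in pure])
        after = np.column_stack([s.counts.to_numpy() for s in corrected])
        assert np.abs(after - before).mean() < 0.05 * before.mean()

    def test_sample_count_and_genes_unchanged(self, small_collection):
        pure, corrected = _corrected_pure(small_collection, "per_cell_type")
        assert len(corrected) == len(pure)
        assert all(
            list(a.counts.index) == list(b.counts.index) for a, b in zip(pure, corrected)
        )
        assert all((s.counts >= 0).all() for s in corrected)
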