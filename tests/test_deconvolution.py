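import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from celldecon.deconvolution import (
    HierarchyLevel,
    deconvolve,
    ensemble_combine,
    ensemble_weights,
    nnls_fit,
    stepwise_deconvolve,
)
from celldecon.types import (
    BulkSample,
    EnsembleConfig,
    ProfileBundle,
    ProfileSet,
    SingleSetFit,
)

from conftest import make_toy_profile_set


def _mixture_of(pset, fractions):
    mat = pset.matrix()
    vec = sum(f * mat[ct] for ct, f in fractions.items())
    return BulkSample(sample_id="mix", expression=vec)


def _grid_search_oracle(g, A, step=0.01):
    """Exhaustive simplex search for the best non-negative composition."""
    g = g / g.sum()
    cols = A / A.sum(axis=0)
    best, best_err = None, np.inf
    ticks = int(round(1 / step))
    for combo in itertools.product(range(ticks + 1), repeat=A.shape[1] - 1):
        if sum(combo) > ticks:
            continue
        fracs = np.array(list(combo) + [ticks - sum(combo)]) / ticks
        err = np.sum((g - cols @ fracs) ** 2)
        if err < best_err:
            best, best_err = fracs, err
    return best


class TestNNLSFit:
    def test_self_mixture(self):
        pset = make_toy_profile_set()
        fit = nnls_fit(_mixture_of(pset, {"A": 1.0}), pset)
        assert fit.fit_rmse == pytest.approx(0.0, abs=1e-6)
        props = fit.proportions
        assert props["A"] == pytest.approx(1.0, abs=1e-9)
        assert fit.raw_coefficients["B"] == 0.0
        assert fit.coefficient_pvalues["A"] < 1e-10
        assert fit.coefficient_pvalues["B"] == 1.0

    def test_noiseless_two_type_recovery(self):
        pset = make_toy_profile_set()
        fit = nnls_fit(_mixture_of(pset, {"A": 0.3, "B": 0.7}), pset)
        props = fit.proportions
        assert props["A"] == pytest.approx(0.3, abs=1e-6)
        assert props["B"] == pytest.approx(0.7, abs=1e-6)
        assert props["C"] == pytest.approx(0.0, abs=1e-6)

    def test_matches_grid_search_oracle(self):
        """NNLS compositions agree with an exhaustive simplex search."""
        rng = np.random.default_rng(4)
        pset = make_toy_profile_set(n_genes=21, seed=7)
        mat = pset.matrix()
        for trial in range(3):
            fracs = rng.dirichlet([1, 1, 1])
            noise = rng.normal(0, 0.02, size=len(mat))
            vec = (mat.to_numpy() @ fracs) * (1 + noise)
            bulk = BulkSample(sample_id=f"t{trial}", expression=pd.Series(np.clip(vec, 0, None), index=mat.index))
            fit = nnls_fit(bulk, pset)
            oracle = _grid_search_oracle(bulk.expression.to_numpy(), mat.to_numpy())
            props = fit.proportions
            for k, ct in enumerate(mat.columns):
                assert abs(props[ct] - oracle[k]) <= 0.02

    def test_negative_ols_coefficient_clamped_to_zero(self):
        # 2 genes, 2 types: unconstrained LS solution has a negative coefficient
        genes = ["g0", "g1"]
        from celldecon.types import CellTypeProfile
        p1 = pd.Series([9e5, 1e5], index=genes)
        p2 = pd.Series([5e5, 5e5], index=genes)
        pset = ProfileSet(set_id="toy2", profiles={
            "A": CellTypeProfile("A", p1, ["g0"], ("d", 0)),
            "B": CellTypeProfile("B", p2, ["g1"], ("d", 0)),
        })
        bulk = BulkSample(sample_id="b", expression=pd.Series([1e6, 0.0], index=genes))
        ols = np.linalg.lstsq(
            np.column_stack([p1, p2]), bulk.expression.to_numpy(), rcond=None
        )[0]
        assert ols.min() < 0
        fit = nnls_fit(bulk, pset)
        assert fit.raw_coefficients["B"] == 0.0

    def test_low_coverage_rejected(self):
        pset = make_toy_profile_set(n_genes=30)
        bulk = BulkSample(
            sample_id="b",
            expression=pd.Series([100.0] * 10, index=[f"g{i}" for i in range(10)]),
        )
        with pytest.raises(ValueError, match="coverage"):
            nnls_fit(bulk, pset)

    def test_zero_bulk_rejected(self):
        pset = make_toy_profile_set()
        bulk = BulkSample(
            sample_id="b",
            expression=pd.Series(0.0, index=pset.gene_universe),
        )
        with pytest.raises(ValueError, match="zero"):
            nnls_fit(bulk, pset)


class TestEnsembleWeights:
    def test_two_values_split_evenly(self):
        np.testing.assert_allclose(ensemble_weights([0.1, 0.3]), [0.5, 0.5])

    def test_three_values_middle_zero(self):
        np.testing.assert_allclose(ensemble_weights([0.1, 0.2, 0.3]), [0.5, 0.0, 0.5],
                                   atol=1e-12)

    def test_all_equal_uniform(self):
        np.testing.assert_allclose(ensemble_weights([0.2, 0.2, 0.2, 0.2]), [0.25] * 4)
        np.testing.assert_allclose(ensemble_weights([0.7]), [1.0])

    def test_inverse_scheme_prefers_lowest(self):
        w = ensemble_weights([0.1, 0.2, 0.3], scheme="inverse_rmse")
        assert w[0] > w[1] > w[2]
        assert w.sum() == pytest.approx(1.0)

    def test_negative_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            ensemble_weights([0.1, -0.2])

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0.0, 10.0), min_size=1, max_size=8))
    def test_weights_are_a_distribution(self, rmses):
        for scheme in ("as_printed", "inverse_rmse"):
            w = ensemble_weights(rmses, scheme)
            assert np.all(w >= 0)
            assert w.sum() == pytest.approx(1.0, abs=1e-9)


def _fit(set_id, coeffs, rmse, pvals=None):
    return SingleSetFit(
        set_id=set_id,
        raw_coefficients=coeffs,
        fitted_expression=pd.Series(dtype=float),
        fit_rmse=rmse,
        coefficient_pvalues=pvals or {ct: 0.001 for ct in coeffs},
    )


class TestEnsembleCombine:
    def test_weighted_average_of_proportions(self):
        f1 = _fit("s1", {"A": 1.0, "B": 0.0}, 0.1)
        f2 = _fit("s2", {"A": 0.0, "B": 1.0}, 0.3)
        res = ensemble_combine("x", [f1, f2], EnsembleConfig(top_n=2))
        assert res.proportions["A"] == pytest.approx(0.5)
        assert res.proportions["B"] == pytest.approx(0.5)
        np.testing.assert_allclose(res.weights, [0.5, 0.5])

    def test_single_fit_degenerate(self):
        f1 = _fit("s1", {"A": 0.6, "B": 0.4}, 0.2)
        res = ensemble_combine("x", [f1], EnsembleConfig(top_n=1))
        assert res.proportions == pytest.approx(f1.proportions)
        assert res.weights == [1.0]
        assert res.used_set_ids == ["s1"]

    def test_insignificant_mass_becomes_undetermined(self):
        f1 = _fit("s1", {"A": 0.7, "B": 0.3}, 0.1,
                  pvals={"A": 0.001, "B": 0.5})
        res = ensemble_combine("x", [f1], EnsembleConfig(top_n=1, alpha=0.05))
        assert res.undetermined == pytest.approx(0.3)
        assert res.significant_proportions["B"] == 0.0
        assert sum(res.significant_proportions.values()) + res.undetermined \
            == pytest.approx(1.0, abs=1e-8)

    def test_convex_combination_invariant(self):
        rng = np.random.default_rng(1)
        fits = [
            _fit(f"s{i}", {ct: float(v) for ct, v in
                           zip("ABC", rng.dirichlet([1, 1, 1]))}, float(rng.uniform(0.05, 0.4)))
            for i in range(5)
        ]
        res = ensemble_combine("x", fits, EnsembleConfig(top_n=5))
        mins = {ct: min(f.proportions[ct] for f in fits) for ct in "ABC"}
        maxs = {ct: max(f.proportions[ct] for f in fits) for ct in "ABC"}
        for ct in "ABC":
            assert mins[ct] - 1e-12 <= res.proportions[ct] <= maxs[ct] + 1e-12
        assert sum(res.proportions.values()) == pytest.approx(1.0, abs=1e-8)


def _bundle_from_sets(sets, name="toy"):
    for i, s in enumerate(sets):
        s.training_score = 0.01 * (i + 1)
    return ProfileBundle(
        group_name=name,
        cell_types=sets[0].cell_types,
        gene_universe=sets[0].gene_universe,
        profile_sets=sets,
    )


class TestDeconvolve:
    def test_pure_synthetic_bulk_recovered(self, small_bundle, small_collection):
        """A pure one-type query is assigned predominantly to that type.

        Averaged over source datasets, since each dataset's residual batch
        tilt moves its individual estimate a little.
        """
        refs, _, _ = small_collection
        from celldecon.pseudobulk import make_pure_pseudobulks, normalize_to_million
        fractions = []
        for ds in refs:
            rep = normalize_to_million(
                make_pure_pseudobulks(ds, replicates_per_type=1, seed=99, cell_types=["neuron"])[0]
            )
            bulk = BulkSample(sample_id=f"pure_{ds.dataset_id}", expression=rep.counts)
            [res] = deconvolve([bulk], small_bundle)
            fractions.append(res.proportions["neuron"])
        assert min(fractions) > 0.8
        assert np.mean(fractions) > 0.9

    def test_determinism(self, small_bundle):
        pset = small_bundle.profile_sets[0]
        bulk = _mixture_of(pset, {ct: 1 / len(pset.cell_types) for ct in pset.cell_types})
        r1, r2 = deconvolve([bulk, bulk], small_bundle)
        assert r1.proportions == r2.proportions
        assert r1.weights == r2.weights

    def test_noiseless_bundle_mixture_exact(self):
        sets = [make_toy_profile_set(seed=s, set_id=f"set{s}") for s in range(6)]
        bundle = _bundle_from_sets(sets)
        target = sets[0]
        bulk = _mixture_of(target, {"A": 0.2, "B": 0.5, "C": 0.3})
        [res] = deconvolve([bulk], bundle, EnsembleConfig(top_n=1))
        assert res.used_set_ids == ["set0"]
        assert res.proportions["A"] == pytest.approx(0.2, abs=1e-6)
        assert res.proportions["B"] == pytest.approx(0.5, abs=1e-6)
        assert res.proportions["C"] == pytest.approx(0.3, abs=1e-6)

    def test_missing_type_worsens_fit(self, small_collection, small_bundle):
        """A query containing an unprofiled type fits worse than a covered one."""
        from celldecon.simulate import simulate_bulk_mixtures
        refs, _, _ = small_collection
        covered = simulate_bulk_mixtures(
            refs, 5, seed=31, cell_types=["astro", "neuron", "oligo", "micro"]
        )
        reduced_types = ["astro", "neuron", "oligo"]
        reduced_sets = [
            ProfileSet(
                set_id=s.set_id,
                profiles={ct: p for ct, p in s.profiles.items() if ct in reduced_types},
                training_score=s.training_score,
            )
            for s in small_bundle.profile_sets
        ]
        reduced = ProfileBundle(
            group_name="reduced", cell_types=reduced_types,
            gene_universe=small_bundle.gene_universe, profile_sets=reduced_sets,
        )
        # same mixtures, one branch fully covered and one missing 'micro'
        covered_only = simulate_bulk_mixtures(refs, 5, seed=31, cell_types=reduced_types)
        res_missing = deconvolve(covered, reduced)
        res_covered = deconvolve(covered_only, reduced)
        assert np.mean([np.mean(r.fit_rmse) for r in res_missing]) > \
            np.mean([np.mean(r.fit_rmse) for r in res_covered])

    def test_low_abundance_detected_less_often(self, small_bundle, small_collection):
        """A 5% contribution is flagged significant less often than a 30% one."""
        refs, _, _ = small_collection
        from celldecon.simulate import mix_from_dataset
        rng = np.random.default_rng(17)
        detect = {0.05: 0, 0.30: 0}
        n_trials = 8
        for frac in detect:
            for t in range(n_trials):
                rest = (1 - frac) / 2
                comp = {"micro": frac, "astro": rest, "neuron": rest}
                ds = refs[t % len(refs)]
                expr = mix_from_dataset(ds, comp, rng)
                bulk = BulkSample(sample_id=f"f{frac}_{t}", expression=expr)
                [res] = deconvolve([bulk], small_bundle)
                detect[frac] += int(res.pvalues["micro"] < 0.05)
        assert detect[0.30] >= detect[0.05]
        assert detect[0.30] == n_trials  # strong contributions always found


class TestStepwise:
    def _two_level(self):
        coarse_sets = [make_toy_profile_set(cell_types=("neuron", "glia"), seed=s, set_id=f"c{s}")
                       for s in range(2)]
        fine_sets = [make_toy_profile_set(cell_types=("excitatory", "inhibitory"),
                                          seed=10 + s, set_id=f"f{s}", gene_prefix="fg")
                     for s in range(2)]
        coarse = _bundle_from_sets(coarse_sets, "coarse")
        fine = _bundle_from_sets(fine_sets, "fine_neuron")
        return coarse, fine

    def test_gate_skips_absent_parent(self):
        coarse, fine = self._two_level()
        bulk = _mixture_of(coarse.profile_sets[0], {"glia": 1.0})
        [res] = stepwise_deconvolve(
            [bulk],
            [HierarchyLevel(coarse), HierarchyLevel(fine, parent_type="neuron")],
        )
        assert res.refined == {}

    def test_fine_fractions_rescaled_by_parent(self):
        coarse, fine = self._two_level()
        # a bulk that is pure neuron at the coarse level and 60/40 at fine level
        fine_mat = fine.profile_sets[0].matrix()
        vec = 0.6 * fine_mat["excitatory"] + 0.4 * fine_mat["inhibitory"]
        coarse_mat = coarse.profile_sets[0].matrix()
        bulk = BulkSample(sample_id="b", expression=pd.concat([coarse_mat["neuron"], vec]))
        [res] = stepwise_deconvolve(
            [bulk],
            [HierarchyLevel(coarse), HierarchyLevel(fine, parent_type="neuron")],
            refine_threshold=0.2,
        )
        assert res.coarse.proportions["neuron"] > 0.9
        level = res.refined["fine_neuron"]
        parent = level.parent_fraction
        assert level.result.proportions["excitatory"] == pytest.approx(0.6, abs=0.05)
        assert level.rescaled_proportions["excitatory"] == pytest.approx(0.6 * parent, abs=0.05)

    def test_single_level_equals_deconvolve(self):
        coarse, _ = self._two_level()
        bulk = _mixture_of(coarse.profile_sets[0], {"neuron": 0.5, "glia": 0.5})
        [plain] = deconvolve([bulk], coarse)
        [step] = stepwise_deconvolve([bulk], [HierarchyLevel(coarse)])
        assert step.coarse.proportions == plain.proportions
        assert step.refined == {}

    def test_cyclic_hierarchy_rejected(self):
        coarse, fine = self._two_level()
        with pytest.raises(ValueError, match="cyclic"):
            stepwise_deconvolve(
                [],
                [HierarchyLevel(coarse), HierarchyLevel(fine, parent_type="excitatory")],
            )
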