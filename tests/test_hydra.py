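"""Polytope clustering: solver, initialization, fitting, fusion, stability."""

import dataclasses
import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.svm import LinearSVC

from aba_subtypes import (
    GeneratorConfig,
    PolytopeModel,
    adjusted_rand_index,
    assign_clusters,
    cluster_stability,
    consensus_fuse,
    dpp_initialize,
    fit_hydra,
    fit_polytope,
    generate_cohort,
    residualize_covariates,
)
from aba_subtypes.hydra import (
    HydraError,
    _greedy_kdpp,
    candidate_similarity,
    fit_weighted_sqhinge,
    polytope_objective,
)


def pair_counting_ari(a, b):
    """Independent oracle: ARI from explicit agreement counts over pairs."""
    a, b = np.asarray(a), np.asarray(b)
    s11 = s10 = s01 = s00 = 0
    for i, j in itertools.combinations(range(len(a)), 2):
        same_a, same_b = a[i] == a[j], b[i] == b[j]
        s11 += same_a and same_b
        s10 += same_a and not same_b
        s01 += same_b and not same_a
        s00 += not same_a and not same_b
    num = 2.0 * (s00 * s11 - s01 * s10)
    den = (s00 + s01) * (s01 + s11) + (s00 + s10) * (s10 + s11)
    return 1.0 if den == 0 else num / den


def separable_toy(seed=0, n_targets=12, n_controls=12, gap=6.0):
    """2-D toy: controls at the origin, targets in two well-separated clouds."""
    rng = np.random.default_rng(seed)
    controls = rng.normal(scale=0.5, size=(n_controls, 2))
    half = n_targets // 2
    t1 = rng.normal(scale=0.5, size=(half, 2)) + [gap, 0.0]
    t2 = rng.normal(scale=0.5, size=(n_targets - half, 2)) + [-gap, gap]
    targets = np.vstack([t1, t2])
    X = np.vstack([controls, targets])
    is_target = np.zeros(len(X), dtype=bool)
    is_target[n_controls:] = True
    truth = np.array([0] * half + [1] * (n_targets - half))
    return X, is_target, truth


class TestResidualize:
    def test_exact_covariate_function_vanishes(self):
        rng = np.random.default_rng(0)
        covs = np.column_stack(
            [rng.uniform(45, 83, 50), rng.integers(0, 2, 50), rng.integers(10, 20, 50)]
        )
        feats = np.column_stack([2.0 * covs[:, 0], rng.normal(size=50)])
        ref = np.ones(50, dtype=bool)
        out = residualize_covariates(feats, covs, ref)
        # the age-only feature residualizes to ~0 and is dropped as constant
        assert "f0" in out.dropped_features or np.allclose(out.values[:, 0], 0, atol=1e-8)

    def test_reference_residuals_standardized(self):
        rng = np.random.default_rng(1)
        covs = rng.normal(size=(80, 3))
        feats = rng.normal(size=(80, 5)) + covs @ rng.normal(size=(3, 5))
        ref = np.zeros(80, dtype=bool)
        ref[:50] = True
        out = residualize_covariates(feats, covs, ref)
        assert np.allclose(out.values[ref].mean(axis=0), 0.0, atol=1e-8)
        assert np.allclose(out.values[ref].std(axis=0), 1.0, atol=1e-8)

    def test_collinear_covariates_rejected(self):
        rng = np.random.default_rng(2)
        covs = rng.normal(size=(30, 2))
        covs = np.column_stack([covs, covs[:, 0] * 2.0])
        with pytest.raises(HydraError, match="collinear"):
            residualize_covariates(rng.normal(size=(30, 3)), covs, np.ones(30, bool))

    def test_zero_variance_feature_dropped_with_warning(self):
        rng = np.random.default_rng(3)
        covs = rng.normal(size=(40, 3))
        feats = np.column_stack([np.full(40, 7.0), rng.normal(size=40)])
        with pytest.warns(UserWarning, match="zero-variance"):
            out = residualize_covariates(feats, covs, np.ones(40, bool))
        assert out.n_features == 1


class TestSolver:
    def test_agrees_with_liblinear(self):
        """Independent cross-check against sklearn's squared-hinge SVM."""
        rng = np.random.default_rng(0)
        X = rng.normal(size=(300, 20))
        y = np.where(rng.random(300) < 0.5, 1.0, -1.0)
        X[y > 0] += 0.8
        sw = np.where(y > 0, 1.0, 0.5)
        w, b, _ = fit_weighted_sqhinge(X, y, sw, C=1.0, tol=1e-12)
        ref = LinearSVC(C=1.0, loss="squared_hinge", dual=False, tol=1e-10, max_iter=10000)
        ref.fit(X, y, sample_weight=sw)
        assert np.corrcoef(w, ref.coef_[0])[0, 1] > 0.9999
        assert np.max(np.abs(w - ref.coef_[0])) < 1e-2
        assert b == pytest.approx(ref.intercept_[0], abs=1e-2)

    def test_warm_start_reaches_same_solution(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(100, 5))
        y = np.sign(X[:, 0] + 0.1)
        sw = np.ones(100)
        w1, b1, f1 = fit_weighted_sqhinge(X, y, sw, tol=1e-12)
        w2, b2, f2 = fit_weighted_sqhinge(
            X, y, sw, w0=np.concatenate([w1 + 0.01, [b1]]), tol=1e-12
        )
        assert f2 == pytest.approx(f1, rel=1e-6)


class TestInitialization:
    def test_k1_puts_everyone_in_one_cluster(self):
        X, is_target, _ = separable_toy()
        init = dpp_initialize(X[is_target], X[~is_target], K=1, seed=0)
        assert np.array_equal(init, np.zeros(is_target.sum(), dtype=int))

    def test_antipodal_clouds_separated_exactly(self):
        """Two target clouds on opposite sides of the controls split cleanly."""
        rng = np.random.default_rng(4)
        controls = rng.normal(scale=0.3, size=(20, 2))
        t1 = rng.normal(scale=0.3, size=(15, 2)) + [5.0, 0.0]
        t2 = rng.normal(scale=0.3, size=(15, 2)) - [5.0, 0.0]
        targets = np.vstack([t1, t2])
        init = dpp_initialize(targets, controls, K=2, seed=0)
        truth = np.array([0] * 15 + [1] * 15)
        assert adjusted_rand_index(init, truth) == pytest.approx(1.0)
        # agrees with the sign of the projection on the separating axis
        assert len(set(init[:15])) == 1 and len(set(init[15:])) == 1

    def test_greedy_selection_is_swap_optimal(self):
        rng = np.random.default_rng(5)
        D = rng.normal(size=(20, 6))
        D /= np.linalg.norm(D, axis=1, keepdims=True)
        kernel = candidate_similarity(D)
        selected = _greedy_kdpp(kernel, K=3, first=0)
        base = np.linalg.det(kernel[np.ix_(selected, selected)])
        for i in range(3):
            for c in range(20):
                if c in selected:
                    continue
                trial = list(selected)
                trial[i] = c
                assert np.linalg.det(kernel[np.ix_(trial, trial)]) <= base * (1 + 1e-9)

    def test_too_few_candidates_rejected(self):
        X, is_target, _ = separable_toy(n_targets=2)
        with pytest.raises(HydraError):
            dpp_initialize(X[is_target], X[~is_target], K=5, seed=0)

    def test_deterministic_given_seed(self):
        X, is_target, _ = separable_toy(seed=3)
        a = dpp_initialize(X[is_target], X[~is_target], K=2, seed=9)
        b = dpp_initialize(X[is_target], X[~is_target], K=2, seed=9)
        assert np.array_equal(a, b)


class TestFitPolytope:
    def test_k1_reduces_to_direct_weighted_classifier(self):
        X, is_target, _ = separable_toy(seed=1)
        model = fit_polytope(X, is_target, K=1, C=1.0, solver_tol=1e-12)
        y = np.where(is_target, 1.0, -1.0)
        w, b, _ = fit_weighted_sqhinge(X, y, np.ones(len(X)), C=1.0, tol=1e-12)
        direct = X @ w + b
        assert np.max(np.abs(model.decision_values(X)[:, 0] - direct)) < 1e-6

    def test_assignment_is_argmax_of_decision_values(self):
        model = PolytopeModel(
            K=2,
            hyperplane_weights=np.array([[1.0, 0.0], [0.0, 1.0]]),
            hyperplane_offsets=np.zeros(2),
            assignments=np.array([]),
            objective_trace=[],
            converged=True,
            C=1.0,
        )
        assert assign_clusters(model, np.array([[2.0, 1.0]]))[0] == 0
        # tie -> lowest face index
        assert assign_clusters(model, np.array([[1.0, 1.0]]))[0] == 0
        with pytest.raises(HydraError, match="dimension"):
            model.decision_values(np.ones((1, 3)))

    def test_converged_assignments_are_a_fixed_point(self):
        X, is_target, _ = separable_toy(seed=2)
        model = fit_polytope(X, is_target, K=2, seed=0)
        assert model.converged
        again = assign_clusters(model, X[is_target])
        assert np.array_equal(again, model.assignments)

    def test_objective_trace_non_increasing(self):
        X, is_target, _ = separable_toy(seed=5, n_targets=20, n_controls=20)
        model = fit_polytope(X, is_target, K=2, seed=1)
        trace = np.asarray(model.objective_trace)
        assert np.all(np.diff(trace) <= 1e-6 * (1.0 + np.abs(trace[:-1])))

    def test_controls_inside_polytope_on_separable_toy(self):
        X, is_target, _ = separable_toy(seed=6)
        model = fit_polytope(X, is_target, K=2, seed=0)
        assert np.all(model.decision_values(X[~is_target]) < 0)

    def test_recovers_separated_clouds(self):
        X, is_target, truth = separable_toy(seed=7, n_targets=30, n_controls=30)
        model = fit_polytope(X, is_target, K=2, seed=0)
        assert adjusted_rand_index(model.assignments, truth) == pytest.approx(1.0)

    def test_labels_equivariant_under_rotation(self):
        X, is_target, _ = separable_toy(seed=8)
        model = fit_polytope(X, is_target, K=2, seed=0)
        theta = 0.83
        R = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        rotated = dataclasses.replace(
            model, hyperplane_weights=model.hyperplane_weights @ R.T
        )
        a = assign_clusters(model, X[is_target])
        b = assign_clusters(rotated, X[is_target] @ R.T)
        assert np.array_equal(a, b)

    def test_brute_force_oracle_small(self):
        """Exhaustive enumeration of all assignments on a separable toy:
        the iterative fit lands within 1% of the global optimum."""
        X, is_target, _ = separable_toy(seed=9, n_targets=8, n_controls=10)
        controls, targets = X[~is_target], X[is_target]
        model = fit_polytope(X, is_target, K=2, C=1.0, seed=0, solver_tol=1e-10)
        best = _exhaustive_optimum(controls, targets, C=1.0)
        final = polytope_objective(
            model.hyperplane_weights, model.hyperplane_offsets,
            controls, targets, model.assignments, 1.0,
        )
        assert final <= best * 1.01


def _exhaustive_optimum(controls, targets, C):
    """Score every target-to-face map by refitting both weighted classifiers."""
    n = len(targets)
    y_c = -np.ones(len(controls))
    w_c = np.full(len(controls), 0.5)  # controls carry weight 1/K, K=2
    cache = {}

    def face_obj(mask_bits):
        if mask_bits not in cache:
            members = [i for i in range(n) if mask_bits >> i & 1]
            Xj = np.vstack([controls, targets[members]]) if members else controls
            yj = np.concatenate([y_c, np.ones(len(members))])
            sj = np.concatenate([w_c, np.ones(len(members))])
            _, _, fun = fit_weighted_sqhinge(Xj, yj, sj, C=C, tol=1e-10)
            cache[mask_bits] = fun
        return cache[mask_bits]

    full = (1 << n) - 1
    return min(face_obj(m) + face_obj(full ^ m) for m in range(1 << n))


class TestAri:
    def test_identity_and_permutation_invariance(self):
        assert adjusted_rand_index([1, 1, 2, 2], [1, 1, 2, 2]) == pytest.approx(1.0)
        assert adjusted_rand_index([1, 1, 2, 2], [2, 2, 1, 1]) == pytest.approx(1.0)

    def test_matches_pair_counting_oracle(self):
        a = [1, 1, 1, 2, 2, 2]
        b = [1, 1, 2, 2, 3, 3]
        assert adjusted_rand_index(a, b) == pytest.approx(pair_counting_ari(a, b))

    @settings(derandomize=True, max_examples=40)
    @given(
        st.lists(st.integers(0, 3), min_size=2, max_size=25),
        st.data(),
    )
    def test_oracle_agreement_property(self, a, data):
        b = data.draw(st.lists(st.integers(0, 3), min_size=len(a), max_size=len(a)))
        assert adjusted_rand_index(a, b) == pytest.approx(
            pair_counting_ari(a, b), abs=1e-12
        )
        assert adjusted_rand_index(a, b) == pytest.approx(
            adjusted_rand_index(b, a), abs=1e-12
        )

    def test_length_mismatch_rejected(self):
        with pytest.raises(HydraError):
            adjusted_rand_index([1, 2], [1, 2, 3])


class TestConsensus:
    def test_single_run_returned_unchanged(self):
        labels = np.array([0, 0, 1, 1, 2])
        assert np.array_equal(consensus_fuse([labels], K=3), labels)

    def test_permuted_identical_runs_fuse_to_same_partition(self):
        rng = np.random.default_rng(0)
        base = rng.integers(0, 3, size=60)
        runs = []
        for _ in range(8):
            perm = rng.permutation(3)
            runs.append(perm[base])
        fused = consensus_fuse(runs, K=3)
        assert adjusted_rand_index(fused, base) == pytest.approx(1.0)

    def test_noisy_runs_fuse_at_least_as_well_as_best_single(self):
        rng = np.random.default_rng(1)
        truth = np.repeat([0, 1, 2], 30)
        runs = []
        for _ in range(20):
            noisy = truth.copy()
            flip = rng.random(len(truth)) < 0.10
            noisy[flip] = rng.integers(0, 3, flip.sum())
            runs.append(rng.permutation(3)[noisy])
        fused = consensus_fuse(runs, K=3)
        best_single = max(adjusted_rand_index(r, truth) for r in runs)
        assert adjusted_rand_index(fused, truth) >= best_single - 0.05

    def test_inconsistent_lengths_rejected(self):
        with pytest.raises(HydraError):
            consensus_fuse([np.zeros(3, int), np.zeros(4, int)], K=2)


class TestStability:
    def test_k_below_two_rejected(self):
        X, is_target, _ = separable_toy(n_targets=30, n_controls=30)
        with pytest.raises(HydraError, match="K < 2"):
            cluster_stability(X, is_target, k_range=[1, 2], n_folds=3, n_init=1)

    def test_planted_three_subtypes_selected(self):
        """Stability CV picks the planted K on a well-separated cohort."""
        cfg = GeneratorConfig(
            n_subjects=600,
            block_sizes={"sMRI": 30, "dMRI": 20, "rsfMRI": 20},
            seed=21,
        )
        cohort, truth = generate_cohort(cfg)
        ids = cohort.subject_ids.to_numpy()
        is_target = truth.aba_flag.loc[ids].to_numpy()
        feats = residualize_covariates(
            cohort.idp_matrix(), cohort.covariate_matrix(), ~is_target
        )
        curve = cluster_stability(
            feats, is_target, k_range=(2, 3, 4), n_folds=5, n_init=2, seed=0
        )
        assert curve.selected_k == 3
        assert curve.mean_ari[3] == max(curve.mean_ari.values())
        model = fit_hydra(feats, is_target, K=3, n_init=3, seed=0)
        tl = truth.labels_for(ids[is_target]) - 1
        assert adjusted_rand_index(model.assignments, tl) >= 0.8
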