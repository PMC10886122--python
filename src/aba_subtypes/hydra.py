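"""Semi-supervised max-margin polytope clustering (HYDRA).

Separates a *target* group (here: accelerated brain agers) from a
*reference/control* group (resilient agers) with a convex polytope of K
linear max-margin classifiers.  Each face is a soft-margin linear
classifier that must keep every control on its negative side; each
target is assigned to the face giving it the largest decision value, so
the faces partition the target group into K subtypes, each face
capturing one direction of deviation from the controls.

Fitting alternates (i) estimation — refit each face on all controls
(down-weighted 1/K so total control influence is constant in K) plus
its currently assigned targets — with (ii) assignment — move each
target to its best face.  Both steps monotonically decrease the joint
objective

    sum_j [ 1/2 (||w_j||^2 + b_j^2) + C * sum_i s_i * max(0, 1 - y_i f_j(x_i))^2 ],

the weighted squared-hinge soft-margin objective summed over faces.

Initialization samples diverse candidate aging directions (target minus
control centroid) and picks a mutually diverse K-subset by greedy
determinant maximization of their Gram matrix — a deterministic k-DPP
approximation — polished to single-swap local optimality.  Multiple
initializations are fused through co-assignment (consensus) clustering,
and the number of subtypes is selected by cross-validated clustering
stability measured with the adjusted Rand index (ARI).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import minimize
from scipy.spatial.distance import squareform
from sklearn.metrics import adjusted_rand_score
from sklearn.model_selection import KFold

__all__ = [
    "HydraError",
    "ResidualizedFeatures",
    "residualize_covariates",
    "fit_weighted_sqhinge",
    "dpp_initialize",
    "PolytopeModel",
    "fit_polytope",
    "assign_clusters",
    "adjusted_rand_index",
    "consensus_fuse",
    "fit_hydra",
    "StabilityCurve",
    "cluster_stability",
]


class HydraError(ValueError):
    pass


# ---------------------------------------------------------------------------
# covariate residualization
# ---------------------------------------------------------------------------


@dataclass
class ResidualizedFeatures:
    """Features with nuisance covariates regressed out.

    The per-feature OLS on [1, age, sex, education] is fitted on
    reference-group rows only and applied to everyone, then residuals
    are standardized by the reference-group residual SD — so reference
    residuals have mean 0 and SD 1 per feature by construction.
    """

    values: np.ndarray  # subjects x kept features
    feature_names: tuple[str, ...]
    coefficients: np.ndarray  # (1 + n_covariates) x kept features
    reference_mask: np.ndarray
    reference_sd: np.ndarray
    dropped_features: tuple[str, ...] = ()

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


def residualize_covariates(
    features: np.ndarray,
    covariates: np.ndarray,
    reference_mask: np.ndarray,
    feature_names: Sequence[str] | None = None,
) -> ResidualizedFeatures:
    """Regress covariates out of every feature, reference-group-fitted."""
    X = np.asarray(features, dtype=float)
    Z = np.asarray(covariates, dtype=float)
    mask = np.asarray(reference_mask, dtype=bool)
    if X.ndim != 2 or Z.ndim != 2 or len(X) != len(Z) or len(mask) != len(X):
        raise HydraError("features, covariates and reference_mask are not aligned")
    if np.isnan(X).any() or np.isnan(Z).any():
        raise HydraError("missing values are not allowed; filter complete cases first")
    if not mask.any():
        raise HydraError("reference group is empty")
    names = (
        tuple(feature_names)
        if feature_names is not None
        else tuple(f"f{i}" for i in range(X.shape[1]))
    )
    design = np.column_stack([np.ones(mask.sum()), Z[mask]])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise HydraError("covariates are collinear on the reference group")
    coef, *_ = np.linalg.lstsq(design, X[mask], rcond=None)
    resid = X - np.column_stack([np.ones(len(X)), Z]) @ coef
    ref_sd = resid[mask].std(axis=0, ddof=0)
    keep = ref_sd > 1e-12
    dropped = tuple(n for n, k in zip(names, keep) if not k)
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} zero-variance feature(s) after "
            f"residualization: {dropped[:5]}"
        )
    resid = resid[:, keep] / ref_sd[keep]
    return ResidualizedFeatures(
        values=resid,
        feature_names=tuple(n for n, k in zip(names, keep) if k),
        coefficients=coef[:, keep],
        reference_mask=mask,
        reference_sd=ref_sd[keep],
        dropped_features=dropped,
    )


# ---------------------------------------------------------------------------
# base classifier: weighted squared-hinge soft-margin linear max-margin
# ---------------------------------------------------------------------------


def fit_weighted_sqhinge(
    X: np.ndarray,
    y: np.ndarray,
    sample_weight: np.ndarray,
    C: float = 1.0,
    w0: np.ndarray | None = None,
    tol: float = 1e-9,
) -> tuple[np.ndarray, float, float]:
    """Minimize 1/2(||w||^2 + b^2) + C * sum_i s_i max(0, 1 - y_i(w.x_i + b))^2.

    Smooth (C1) primal solved by L-BFGS; supports warm starts, which the
    alternating polytope optimization exploits heavily.  Returns
    (w, b, objective).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    cs = C * np.asarray(sample_weight, dtype=float)
    n, p = X.shape

    def fun_grad(theta: np.ndarray) -> tuple[float, np.ndarray]:
        w, b = theta[:p], theta[p]
        margin = 1.0 - y * (X @ w + b)
        act = margin > 0.0
        val = 0.5 * (w @ w + b * b) + float(cs[act] @ (margin[act] ** 2))
        coef = np.zeros(n)
        coef[act] = -2.0 * cs[act] * margin[act] * y[act]
        grad = np.empty(p + 1)
        grad[:p] = w + X.T @ coef
        grad[p] = b + coef.sum()
        return val, grad

    x0 = np.zeros(p + 1) if w0 is None else np.asarray(w0, dtype=float)
    res = minimize(
        fun_grad,
        x0,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": 2000, "ftol": tol, "gtol": 1e-8},
    )
    return res.x[:p], float(res.x[p]), float(res.fun)


def _face_objective(
    w: np.ndarray,
    b: float,
    controls: np.ndarray,
    targets_j: np.ndarray,
    C: float,
    K: int,
) -> float:
    """Objective contribution of one face given its current targets."""
    reg = 0.5 * (w @ w + b * b)
    m_c = np.maximum(0.0, 1.0 + (controls @ w + b))  # controls: y = -1
    loss = (C / K) * float(np.sum(m_c**2))
    if len(targets_j):
        m_t = np.maximum(0.0, 1.0 - (targets_j @ w + b))  # targets: y = +1
        loss += C * float(np.sum(m_t**2))
    return reg + loss


def polytope_objective(
    W: np.ndarray,
    b: np.ndarray,
    controls: np.ndarray,
    targets: np.ndarray,
    assignments: np.ndarray,
    C: float,
) -> float:
    """Joint polytope objective for given hyperplanes and target assignments."""
    K = len(W)
    return float(
        sum(
            _face_objective(W[j], b[j], controls, targets[assignments == j], C, K)
            for j in range(K)
        )
    )


# ---------------------------------------------------------------------------
# diverse initialization (greedy k-DPP approximation)
# ---------------------------------------------------------------------------


def _init_subspace(
    targets: np.ndarray, controls: np.ndarray, K: int
) -> tuple[np.ndarray, np.ndarray] | None:
    """Control-whitened metric and dominant target-deviation subspace.

    High-dimensional deviation vectors are noise-dominated, which makes
    raw cosine similarity between candidate aging directions almost
    uninformative.  Whitening by the (shrinkage-regularized) control
    covariance cancels variance directions shared with controls (block
    noise factors), after which the leading principal components of the
    target deviations isolate the directions in which targets actually
    differ from controls.  Returns ``(whiten, project)`` — the p x p
    whitening map and a p x q map from raw deviations to q-dimensional
    whitened scores — or None when the ambient dimension is already small.
    """
    p = targets.shape[1]
    q = min(p, max(K, 2))
    if p <= q or len(controls) < 3:
        return None
    cov = np.cov(controls, rowvar=False)
    evals, evecs = np.linalg.eigh(cov)
    lam = 0.05 * float(evals.mean())
    whiten = evecs @ np.diag(1.0 / np.sqrt(np.maximum(evals, 0.0) + lam)) @ evecs.T
    dev = (targets - controls.mean(axis=0)) @ whiten
    _, _, vt = np.linalg.svd(dev, full_matrices=False)
    return whiten, whiten @ vt[:q].T


def _greedy_kdpp(gram: np.ndarray, K: int, first: int) -> list[int]:
    """Greedy max-determinant K-subset, polished to single-swap optimality."""
    m = len(gram)
    selected = [first]
    while len(selected) < K:
        best_c, best_det = None, -np.inf
        for c in range(m):
            if c in selected:
                continue
            sub = gram[np.ix_(selected + [c], selected + [c])]
            d = np.linalg.det(sub)
            if d > best_det:
                best_c, best_det = c, d
        selected.append(best_c)
    # local search: swap one selected with one unselected while det improves
    improved = True
    while improved:
        improved = False
        cur = np.linalg.det(gram[np.ix_(selected, selected)])
        for i in range(len(selected)):
            for c in range(m):
                if c in selected:
                    continue
                trial = selected.copy()
                trial[i] = c
                d = np.linalg.det(gram[np.ix_(trial, trial)])
                if d > cur * (1 + 1e-12) + 1e-15:
                    selected, cur, improved = trial, d, True
    return selected


def candidate_similarity(directions: np.ndarray) -> np.ndarray:
    """Diversity kernel between unit candidate directions: squared cosine.

    The entrywise square of the Gram matrix (a Schur product, hence
    still PSD) treats a direction and its negation as identical, so
    determinant-maximal subsets favour mutually non-collinear aging
    axes; antipodal subtypes are then separated by the signed-cosine
    assignment rather than wasting two picks on one axis.
    """
    gram = directions @ directions.T
    return gram * gram


def dpp_initialize(
    targets: np.ndarray,
    controls: np.ndarray,
    K: int,
    n_candidates: int = 50,
    seed: int = 0,
    subspace: np.ndarray | None = None,
) -> np.ndarray:
    """Initial target assignments from K mutually diverse aging directions.

    Candidate directions are unit-normalized (target - control centroid)
    vectors for a random candidate pool, measured in a control-whitened
    dominant subspace when the ambient dimension is large (see
    ``_init_subspace``); a diverse K-subset is chosen by greedy
    determinant maximization of their similarity kernel (a k-DPP
    approximation polished to single-swap local optimality), and every
    target joins the direction of largest cosine similarity.
    Deterministic given ``seed``.
    """
    targets = np.asarray(targets, dtype=float)
    controls = np.asarray(controls, dtype=float)
    if K < 1:
        raise HydraError("K must be >= 1")
    if len(targets) == 0:
        raise HydraError("target group is empty")
    rng = np.random.default_rng(seed)
    centroid = controls.mean(axis=0)
    if subspace is None:
        subspace = _init_subspace(targets, controls, K)
    raw_diffs = targets - centroid
    if subspace is not None:
        whiten, project = subspace
        diffs = raw_diffs @ project
        full = raw_diffs @ whiten
    else:
        diffs = raw_diffs
        full = raw_diffs
    norms = np.linalg.norm(diffs, axis=1)
    usable = np.flatnonzero(norms > 1e-12)
    if len(usable) < K:
        raise HydraError(f"fewer than K={K} distinct candidate directions")
    m = min(n_candidates, len(usable))
    cand = rng.choice(usable, size=m, replace=False)
    D = diffs[cand] / norms[cand, None]
    if K == 1:
        return np.zeros(len(targets), dtype=int)
    first = int(np.argmax(norms[cand]))  # farthest target anchors the set
    selected = _greedy_kdpp(candidate_similarity(D), K, first)
    directions = D[selected]
    unit = diffs / np.maximum(norms, 1e-12)[:, None]
    assign = np.argmax(unit @ directions.T, axis=1).astype(int)
    # refine the sampled directions: single candidates are noisy, so a few
    # spherical-mean rounds (direction <- mean of its assigned deviations)
    # denoise them before the polytope fit takes over
    for _ in range(20):
        for j in range(K):
            members = unit[assign == j]
            if len(members):
                d = members.mean(axis=0)
                n = np.linalg.norm(d)
                if n > 1e-12:
                    directions[j] = d / n
        new = np.argmax(unit @ directions.T, axis=1).astype(int)
        if np.array_equal(new, assign):
            break
        assign = new
    # final polish in the full whitened space: the truncated subspace loses
    # part of each deviation direction, so soft (EM-style, unit-variance)
    # centroid/responsibility rounds on the complete whitened deviations
    # recover it — cluster centroids average away subject noise, and soft
    # responsibilities avoid the boundary bias of hard reassignment
    if subspace is not None:
        resp = np.zeros((len(full), K))
        resp[np.arange(len(assign)), assign] = 1.0
        for _ in range(60):
            weights = np.maximum(resp.sum(axis=0), 1e-9)
            centroids = (resp.T @ full) / weights[:, None]
            logits = full @ centroids.T - 0.5 * np.sum(centroids**2, axis=1)
            logits -= logits.max(axis=1, keepdims=True)
            new_resp = np.exp(logits)
            new_resp /= new_resp.sum(axis=1, keepdims=True)
            done = np.abs(new_resp - resp).max() < 1e-6
            resp = new_resp
            if done:
                break
        assign = resp.argmax(axis=1).astype(int)
    return assign


# ---------------------------------------------------------------------------
# polytope fitting
# ---------------------------------------------------------------------------


@dataclass
class PolytopeModel:
    """K max-margin hyperplanes enclosing the controls, one face per subtype."""

    K: int
    hyperplane_weights: np.ndarray  # K x n_features
    hyperplane_offsets: np.ndarray  # K
    assignments: np.ndarray  # per target, 0..K-1
    objective_trace: list[float]
    converged: bool
    C: float
    seed: int = 0
    feature_names: tuple[str, ...] = ()

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.hyperplane_weights.shape[1]:
            raise HydraError(
                f"feature dimension {X.shape[1]} != model dimension "
                f"{self.hyperplane_weights.shape[1]}"
            )
        return X @ self.hyperplane_weights.T + self.hyperplane_offsets

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(
            json.dumps(
                {
                    "K": self.K,
                    "hyperplane_weights": self.hyperplane_weights.tolist(),
                    "hyperplane_offsets": self.hyperplane_offsets.tolist(),
                    "assignments": self.assignments.tolist(),
                    "objective_trace": self.objective_trace,
                    "converged": self.converged,
                    "C": self.C,
                    "seed": self.seed,
                    "feature_names": list(self.feature_names),
                },
                sort_keys=True,
            )
        )
        return path


def _as_matrix(features) -> tuple[np.ndarray, tuple[str, ...]]:
    if isinstance(features, ResidualizedFeatures):
        return features.values, features.feature_names
    X = np.asarray(features, dtype=float)
    return X, tuple(f"f{i}" for i in range(X.shape[1]))


def _reseed_empty_faces(
    assignments: np.ndarray, K: int, decisions: np.ndarray | None
) -> np.ndarray:
    """Give every empty face one target: the worst-fitting target overall."""
    assignments = assignments.copy()
    for j in range(K):
        if np.any(assignments == j):
            continue
        if decisions is None:
            # no hyperplanes yet: steal from the largest face
            donor = np.argmax(np.bincount(assignments, minlength=K))
            idx = np.flatnonzero(assignments == donor)[0]
        else:
            worst = np.min(decisions, axis=1)
            order = np.argsort(worst, kind="stable")
            idx = next(
                i for i in order if np.sum(assignments == assignments[i]) > 1
            )
        assignments[idx] = j
    return assignments


def fit_polytope(
    features,
    is_target: np.ndarray,
    K: int,
    C: float = 1.0,
    init: np.ndarray | None = None,
    max_iter: int = 50,
    seed: int = 0,
    solver_tol: float = 1e-9,
    n_candidates: int = 50,
) -> PolytopeModel:
    """Alternating estimation/assignment optimization of the polytope.

    ``init`` gives initial target assignments (0..K-1); when omitted a
    diverse initialization is drawn with ``seed``.  Controls carry
    weight 1/K in every face's classifier so their total influence does
    not grow with K; targets carry weight 1 in their assigned face only.
    Convergence = an assignment pass changes nothing.
    """
    X, names = _as_matrix(features)
    is_target = np.asarray(is_target, dtype=bool)
    if len(is_target) != len(X):
        raise HydraError("is_target mask does not match features")
    controls, targets = X[~is_target], X[is_target]
    if len(controls) == 0 or len(targets) == 0:
        raise HydraError("both target and control groups must be nonempty")
    if K < 1:
        raise HydraError("K must be >= 1")

    if init is None:
        assignments = dpp_initialize(
            targets, controls, K, n_candidates=n_candidates, seed=seed
        )
    else:
        assignments = np.asarray(init, dtype=int).copy()
        if len(assignments) != len(targets):
            raise HydraError("init length does not match number of targets")
        if assignments.min() < 0 or assignments.max() >= K:
            raise HydraError("init labels outside 0..K-1")
    assignments = _reseed_empty_faces(assignments, K, None)

    n_c = len(controls)
    y_controls = -np.ones(n_c)
    w_controls = np.full(n_c, 1.0 / K)
    p = X.shape[1]
    W = np.zeros((K, p))
    b = np.zeros(K)
    warm: list[np.ndarray | None] = [None] * K
    trace: list[float] = []
    converged = False

    for _ in range(max_iter):
        # (i) estimation: refit each face on controls + its targets
        for j in range(K):
            tj = targets[assignments == j]
            Xj = np.vstack([controls, tj])
            yj = np.concatenate([y_controls, np.ones(len(tj))])
            sj = np.concatenate([w_controls, np.ones(len(tj))])
            W[j], b[j], _ = fit_weighted_sqhinge(
                Xj, yj, sj, C=C, w0=warm[j], tol=solver_tol
            )
            warm[j] = np.concatenate([W[j], [b[j]]])
        trace.append(polytope_objective(W, b, controls, targets, assignments, C))
        # (ii) assignment: each target to the face with the largest decision
        decisions = targets @ W.T + b
        new = np.argmax(decisions, axis=1).astype(int)
        new = _reseed_empty_faces(new, K, decisions)
        if np.array_equal(new, assignments):
            converged = True
            break
        assignments = new

    return PolytopeModel(
        K=K,
        hyperplane_weights=W.copy(),
        hyperplane_offsets=b.copy(),
        assignments=assignments,
        objective_trace=trace,
        converged=converged,
        C=C,
        seed=seed,
        feature_names=names,
    )


def assign_clusters(model: PolytopeModel, features) -> np.ndarray:
    """Face of largest decision value per row; ties -> lowest face index."""
    X, _ = _as_matrix(features)
    return np.argmax(model.decision_values(X), axis=1).astype(int)


# ---------------------------------------------------------------------------
# agreement, fusion, stability
# ---------------------------------------------------------------------------


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Permutation-model adjusted Rand index between two partitions."""
    a = np.asarray(labels_a)
    bb = np.asarray(labels_b)
    if a.shape != bb.shape:
        raise HydraError("label vectors differ in length")
    if a.size < 2:
        raise HydraError("need at least 2 items to compare partitions")
    return float(adjusted_rand_score(a, bb))


def consensus_fuse(
    assignment_list: Sequence[np.ndarray], K: int, seed: int = 0
) -> np.ndarray:
    """Fuse runs through co-assignment (consensus) clustering.

    The co-assignment matrix holds the fraction of runs in which two
    subjects share a cluster; average-linkage hierarchical clustering of
    1 - co-assignment is cut at K groups.  Deterministic given inputs.
    """
    if len(assignment_list) == 0:
        raise HydraError("need at least one assignment vector")
    arrs = [np.asarray(a, dtype=int) for a in assignment_list]
    n = len(arrs[0])
    if any(len(a) != n for a in arrs):
        raise HydraError("assignment vectors differ in length")
    if len(arrs) == 1:
        return arrs[0].copy()
    co = np.zeros((n, n))
    for a in arrs:
        co += a[:, None] == a[None, :]
    co /= len(arrs)
    dist = squareform(1.0 - co, checks=False)
    Z = linkage(dist, method="average")
    return (fcluster(Z, t=K, criterion="maxclust") - 1).astype(int)


def fit_hydra(
    features,
    is_target: np.ndarray,
    K: int,
    C: float = 1.0,
    n_init: int = 10,
    seed: int = 0,
    max_iter: int = 50,
    solver_tol: float = 1e-6,
    n_candidates: int = 50,
) -> PolytopeModel:
    """Multi-initialization polytope fit with consensus fusion.

    Runs ``n_init`` independently initialized fits, fuses their final
    assignments, and refits once from the fused labels.
    """
    X, _ = _as_matrix(features)
    is_target = np.asarray(is_target, dtype=bool)
    subspace = _init_subspace(X[is_target], X[~is_target], K)
    seeds = np.random.SeedSequence(seed).generate_state(n_init) % (2**31)
    runs = [
        fit_polytope(
            features,
            is_target,
            K,
            C=C,
            init=dpp_initialize(
                X[is_target],
                X[~is_target],
                K,
                n_candidates=n_candidates,
                seed=int(s),
                subspace=subspace,
            ),
            seed=int(s),
            max_iter=max_iter,
            solver_tol=solver_tol,
        )
        for s in seeds
    ]
    if n_init == 1:
        return runs[0]
    fused = consensus_fuse([r.assignments for r in runs], K, seed=seed)
    return fit_polytope(
        features,
        is_target,
        K,
        C=C,
        init=fused,
        max_iter=max_iter,
        seed=seed,
        solver_tol=solver_tol,
    )


@dataclass
class StabilityCurve:
    """Cross-validated clustering stability per candidate K."""

    k_values: tuple[int, ...]
    mean_ari: dict[int, float]
    fold_assignments: dict[int, list[dict[int, int]]] = field(repr=False, default_factory=dict)
    selected_k: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "K": list(self.k_values),
                "mean_ari": [self.mean_ari[k] for k in self.k_values],
                "selected": [k == self.selected_k for k in self.k_values],
            }
        )


def cluster_stability(
    features,
    is_target: np.ndarray,
    k_range: Sequence[int] = (2, 3, 4, 5),
    n_folds: int = 5,
    n_init: int = 10,
    C: float = 1.0,
    seed: int = 0,
    max_iter: int = 50,
    solver_tol: float = 1e-6,
) -> StabilityCurve:
    """Select K by cross-validated assignment stability.

    For each K, the target group is split into ``n_folds`` folds; each
    fold's *training* portion (all other folds, plus every control) gets
    a full fused HYDRA fit, and stability is the mean pairwise ARI
    between fold solutions on the targets the two training sets share.
    The selected K maximizes mean ARI; ties break toward smaller K.
    """
    if any(k < 2 for k in k_range):
        raise HydraError("stability is undefined for K < 2 (single-cluster ARI)")
    X, names = _as_matrix(features)
    is_target = np.asarray(is_target, dtype=bool)
    target_pos = np.flatnonzero(is_target)
    if len(target_pos) < n_folds:
        raise HydraError("not enough targets for the requested folds")
    control_pos = np.flatnonzero(~is_target)

    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    fold_train_targets = [target_pos[tr] for tr, _ in kf.split(target_pos)]

    seeds = np.random.SeedSequence(seed).generate_state(len(k_range) * n_folds)
    seeds = seeds % (2**31)
    mean_ari: dict[int, float] = {}
    fold_assignments: dict[int, list[dict[int, int]]] = {}
    for ki, K in enumerate(k_range):
        per_fold: list[dict[int, int]] = []
        for fi, train_targets in enumerate(fold_train_targets):
            rows = np.concatenate([control_pos, train_targets])
            sub_target = np.zeros(len(rows), dtype=bool)
            sub_target[len(control_pos):] = True
            model = fit_hydra(
                X[rows],
                sub_target,
                K,
                C=C,
                n_init=n_init,
                seed=int(seeds[ki * n_folds + fi]),
                max_iter=max_iter,
                solver_tol=solver_tol,
            )
            per_fold.append(
                {int(t): int(l) for t, l in zip(train_targets, model.assignments)}
            )
        aris = []
        for i in range(n_folds):
            for j in range(i + 1, n_folds):
                shared = sorted(per_fold[i].keys() & per_fold[j].keys())
                if len(shared) >= 2:
                    aris.append(
                        adjusted_rand_index(
                            [per_fold[i][t] for t in shared],
                            [per_fold[j][t] for t in shared],
                        )
                    )
        mean_ari[K] = float(np.mean(aris)) if aris else float("nan")
        fold_assignments[K] = per_fold

    best = max(mean_ari.values())
    selected = min(k for k in k_range if mean_ari[k] >= best - 1e-12)
    return StabilityCurve(
        k_values=tuple(k_range),
        mean_ari=mean_ari,
        fold_assignments=fold_assignments,
        selected_k=selected,
    )
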