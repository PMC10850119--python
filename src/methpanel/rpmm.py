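"""Recursively partitioned beta-mixture clustering of tumor methylomes.

Each cancer project's tumor samples are clustered on their most
variable probes by recursive binary splitting. At each node a
two-class mixture is fitted in which, within a class, probes are
independent beta-distributed variables; memberships are initialized
with fuzzy c-means, parameters are re-estimated by weighted method of
moments inside EM, and the split is kept only if a level-weighted BIC
favours it and both children are large enough. Leaves are the
methylation clusters (MCs), relabelled so that MC1 has the highest
mean methylation over the clustering probe set.

Normal-tissue samples are never clustered.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import betaln, logsumexp

from .core import GroupSpec, ValidationError

CLAMP = 1e-4  # beta log-density diverges at the boundary
VAR_FLOOR = 1e-6


@dataclass
class MixtureNode:
    """A fitted (1- or 2-class) beta mixture at one node of the tree."""

    member_weights: np.ndarray  # samples x classes, rows sum to 1
    shape_a: np.ndarray  # classes x probes
    shape_b: np.ndarray  # classes x probes
    mixing: np.ndarray  # class weights
    log_likelihood: float
    depth: int = 0
    loglik_trace: tuple[float, ...] = ()
    collapsed: bool = False

    @property
    def n_classes(self) -> int:
        return self.shape_a.shape[0]

    @property
    def n_free_params(self) -> int:
        # two shapes per probe per class, plus (classes - 1) mixing weights
        return 2 * self.shape_a.size + (self.n_classes - 1)

    def hard_assignment(self) -> np.ndarray:
        return np.argmax(self.member_weights, axis=1)


@dataclass
class SplitDecision:
    accept: bool
    parent_bic: float  # level-weighted
    split_bic: float  # level-weighted
    reason: str


@dataclass
class MCAssignment:
    """Ordered methylation-cluster labels for one project's tumors."""

    project: str
    labels: dict[str, int]  # sample -> 1-based MC index
    cluster_means: dict[int, float]
    probe_set: tuple[str, ...]

    def n_clusters(self) -> int:
        return len(self.cluster_means)

    def members(self, mc: int) -> tuple[str, ...]:
        return tuple(s for s, c in self.labels.items() if c == mc)

    def to_json_dict(self) -> dict:
        return {
            "project": self.project,
            "labels": self.labels,
            "cluster_means": {str(k): v for k, v in self.cluster_means.items()},
            "probe_set": list(self.probe_set),
        }


def top_variable_probes(m: pd.DataFrame, samples: GroupSpec, k: int) -> list[str]:
    """The ``k`` probes most variable across the given samples.

    Ties are broken by lexicographic probe id; ``k`` larger than the
    number of probes returns all probes.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    sub = m[list(samples.sample_ids)]
    variances = sub.var(axis=1, ddof=1)
    order = sorted(zip(-variances.to_numpy(), variances.index))
    return [probe for _, probe in order[: min(k, len(order))]]


def fuzzy_init(
    x: np.ndarray,
    n_classes: int = 2,
    m_exp: float = 2.0,
    rng: np.random.Generator | None = None,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> np.ndarray:
    """Fuzzy c-means memberships (Euclidean distance, seeded start).

    Returns a samples x classes membership grid whose rows sum to 1.
    """
    rng = rng or np.random.default_rng(0)
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    if n < n_classes:
        raise ValidationError(f"{n} samples cannot form {n_classes} fuzzy classes")
    centers = x[rng.choice(n, size=n_classes, replace=False)].copy()
    power = 2.0 / (m_exp - 1.0)
    u = np.full((n, n_classes), 1.0 / n_classes)
    for _ in range(max_iter):
        d = np.linalg.norm(x[:, None, :] - centers[None, :, :], axis=2)
        zero = d < 1e-12
        d = np.where(zero, 1e-12, d)
        inv = d ** (-power)
        u = inv / inv.sum(axis=1, keepdims=True)
        hit = zero.any(axis=1)
        if hit.any():
            u[hit] = zero[hit] / zero[hit].sum(axis=1, keepdims=True)
        um = u**m_exp
        new_centers = (um.T @ x) / um.sum(axis=0)[:, None]
        shift = np.abs(new_centers - centers).max()
        centers = new_centers
        if shift < tol:
            break
    return u


def _moment_shapes(
    x: np.ndarray, w: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Weighted method-of-moments beta shapes for one class.

    ``a = mu*(mu*(1-mu)/v - 1)``, ``b = (1-mu)*(mu*(1-mu)/v - 1)`` from
    the weighted mean and variance per probe, with the variance floored
    and capped below ``mu*(1-mu)`` so both shapes stay positive.
    """
    wsum = w.sum()
    mu = (w @ x) / wsum
    var = (w @ (x - mu) ** 2) / wsum
    cap = mu * (1.0 - mu)
    var = np.clip(var, VAR_FLOOR, cap * (1.0 - 1e-6))
    factor = cap / var - 1.0
    return mu * factor, (1.0 - mu) * factor


def _class_logdensity(
    logx: np.ndarray, log1mx: np.ndarray, a: np.ndarray, b: np.ndarray
) -> np.ndarray:
    """Per-sample joint log-density of independent beta probes."""
    return logx @ (a - 1.0) + log1mx @ (b - 1.0) - betaln(a, b).sum()


def fit_beta_node(
    x: np.ndarray,
    init_weights: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-6,
    depth: int = 0,
    min_class_weight: float = 0.0,
) -> MixtureNode:
    """EM fit of a beta mixture with probe-independent classes.

    The M-step is weighted method of moments (closed form); the E-step
    recomputes responsibilities from the joint log-densities. Because
    moment estimation is not the exact maximum-likelihood M-step, the
    fit keeps the best parameters seen and stops if the log-likelihood
    would decrease, so the reported trace is non-decreasing.

    A class whose total responsibility falls below ``min_class_weight``
    sets ``collapsed=True`` (a signal, not an exception).
    """
    x = np.clip(np.asarray(x, dtype=float), CLAMP, 1.0 - CLAMP)
    w = np.asarray(init_weights, dtype=float)
    n, n_classes = w.shape
    logx, log1mx = np.log(x), np.log1p(-x)

    best: dict = {}
    trace: list[float] = []
    prev_ll = -np.inf
    for _ in range(max_iter):
        shapes_a = np.empty((n_classes, x.shape[1]))
        shapes_b = np.empty_like(shapes_a)
        mixing = w.sum(axis=0) / n
        mixing = np.clip(mixing, 1e-12, None)
        mixing /= mixing.sum()
        for k in range(n_classes):
            shapes_a[k], shapes_b[k] = _moment_shapes(x, w[:, k])
        ll_matrix = np.column_stack(
            [
                np.log(mixing[k])
                + _class_logdensity(logx, log1mx, shapes_a[k], shapes_b[k])
                for k in range(n_classes)
            ]
        )
        total = logsumexp(ll_matrix, axis=1)
        ll = float(total.sum())
        if ll < prev_ll:  # moment M-step overshoot: keep best-so-far
            break
        trace.append(ll)
        w = np.exp(ll_matrix - total[:, None])
        best = dict(a=shapes_a, b=shapes_b, mixing=mixing, w=w, ll=ll)
        if ll - prev_ll < tol and np.isfinite(prev_ll):
            break
        prev_ll = ll

    collapsed = bool((best["w"].sum(axis=0) < min_class_weight).any())
    return MixtureNode(
        member_weights=best["w"],
        shape_a=best["a"],
        shape_b=best["b"],
        mixing=best["mixing"],
        log_likelihood=best["ll"],
        depth=depth,
        loglik_trace=tuple(trace),
        collapsed=collapsed,
    )


def level_weighted_bic(
    parent: MixtureNode,
    split: MixtureNode,
    n: int,
    min_cluster_size: int = 5,
) -> SplitDecision:
    """Decide whether the two-class split improves on the parent.

    ``BIC = -2 logL + p ln(n)`` for the one-class parent and the
    two-class split; both terms carry the common level weight
    ``2^(-depth)`` of the node under consideration. The split is
    accepted iff its weighted BIC is lower AND both children hold at
    least ``min_cluster_size`` samples.
    """
    weight = 2.0 ** (-parent.depth)
    parent_bic = weight * (-2.0 * parent.log_likelihood
                           + parent.n_free_params * np.log(n))
    split_bic = weight * (-2.0 * split.log_likelihood
                          + split.n_free_params * np.log(n))
    hard = split.hard_assignment()
    sizes = np.bincount(hard, minlength=split.n_classes)
    if split.collapsed or (sizes < min_cluster_size).any():
        return SplitDecision(False, parent_bic, split_bic, "child below minimum size")
    if split_bic < parent_bic:
        return SplitDecision(True, parent_bic, split_bic, "BIC improved")
    return SplitDecision(False, parent_bic, split_bic, "BIC not improved")


def _single_class_weights(n: int) -> np.ndarray:
    return np.ones((n, 1))


def rpmm_cluster(
    m: pd.DataFrame,
    tumors: GroupSpec,
    project: str | None = None,
    k: int = 5000,
    max_depth: int = 3,
    min_cluster_size: int = 5,
    seed: int = 0,
    fuzzifier: float = 2.0,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> MCAssignment:
    """Cluster one project's tumors into ordered methylation clusters.

    Selects the ``k`` most variable probes, recursively splits with
    fuzzy-c-means-initialized beta-mixture EM under the level-weighted
    BIC, and relabels leaves MC1..MCn by decreasing mean methylation.
    Projects too small to split return a single-cluster assignment.
    """
    project = project or tumors.name
    probes = top_variable_probes(m, tumors, k)
    sample_ids = list(tumors.sample_ids)
    x = m.loc[probes, sample_ids].T.to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValidationError("clustering input contains missing values")
    x = np.clip(x, CLAMP, 1.0 - CLAMP)

    leaves: list[np.ndarray] = []
    root_ss = np.random.SeedSequence(seed)

    def _recurse(idx: np.ndarray, depth: int, ss: np.random.SeedSequence) -> None:
        if depth >= max_depth or len(idx) < 2 * min_cluster_size:
            leaves.append(idx)
            return
        ss_init, ss_left, ss_right = ss.spawn(3)
        rng = np.random.default_rng(ss_init)
        sub = x[idx]
        init = fuzzy_init(sub, 2, fuzzifier, rng)
        split = fit_beta_node(
            sub, init, max_iter=max_iter, tol=tol, depth=depth,
            min_class_weight=float(min_cluster_size),
        )
        parent = fit_beta_node(
            sub, _single_class_weights(len(idx)), max_iter=max_iter, tol=tol,
            depth=depth,
        )
        decision = level_weighted_bic(parent, split, len(idx), min_cluster_size)
        if not decision.accept:
            leaves.append(idx)
            return
        hard = split.hard_assignment()
        _recurse(idx[hard == 0], depth + 1, ss_left)
        _recurse(idx[hard == 1], depth + 1, ss_right)

    _recurse(np.arange(len(sample_ids)), 0, root_ss)

    raw = [tuple(sample_ids[i] for i in leaf) for leaf in leaves]
    return label_clusters(raw, m, tuple(probes), project=project)


def label_clusters(
    raw: list[tuple[str, ...]],
    m: pd.DataFrame,
    probe_set: tuple[str, ...],
    project: str = "",
) -> MCAssignment:
    """Relabel leaves MC1..MCn by decreasing mean beta over ``probe_set``.

    Ties on the mean are broken by leaf size (descending), then by the
    smallest original leaf index.
    """
    if not raw:
        raise ValidationError("no leaves to label")
    sub = m.loc[list(probe_set)]
    stats = []
    for original_index, members in enumerate(raw):
        mean = float(sub[list(members)].to_numpy(dtype=float).mean())
        stats.append((-round(mean, 12), -len(members), original_index, members, mean))
    stats.sort(key=lambda t: t[:3])
    labels: dict[str, int] = {}
    cluster_means: dict[int, float] = {}
    for mc, (_, _, _, members, mean) in enumerate(stats, start=1):
        cluster_means[mc] = mean
        for s in members:
            labels[s] = mc
    return MCAssignment(
        project=project, labels=labels, cluster_means=cluster_means,
        probe_set=probe_set,
    )
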