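"""Network-based statistic: edge-wise GLM + permutation FWE on components.

The network-based statistic (NBS) is the graph analog of cluster-based
thresholding.  Each edge of the connectome is tested for association with
the outcome in a general linear model adjusting for nuisance covariates;
edges whose |t| exceeds a primary threshold are collected, and connected
components of the resulting graph are the candidate subnetworks.  Family-
wise error is controlled by permuting the outcome across subjects,
recording the maximal component size per permutation, and assigning each
observed component the proportion of permutations whose maximal size was
at least as large.

Defaults follow common practice for this design: primary threshold
|t| > 3.50, 10 000 permutations, corrected alpha 0.010, component size
measured as edge count (extent).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .connectome import EdgeIndex


@dataclass(frozen=True)
class NbsConfig:
    """Parameters of the NBS permutation test.

    ``scheme`` selects the permutation scheme: ``"simple"`` shuffles the
    outcome with covariates fixed; ``"freedman_lane"`` permutes residuals of
    the outcome on the covariates and adds back the fitted nuisance part.
    ``permutations="exhaustive"`` enumerates all n! orderings (small n only)
    and reports exact p values.  ``size_measure`` is ``"extent"`` (edge
    count, default) or ``"intensity"`` (sum of |t| - threshold).
    ``component_mode="pooled"`` forms components from positive- and
    negative-t edges together; ``"by_sign"`` splits them.
    """

    t_threshold: float = 3.50
    n_permutations: int = 10000
    alpha: float = 0.010
    seed: int = 0
    scheme: str = "simple"
    permutations: str = "random"
    size_measure: str = "extent"
    component_mode: str = "pooled"

    def __post_init__(self):
        if self.t_threshold <= 0:
            raise ValueError("t_threshold must be positive")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        if self.scheme not in ("simple", "freedman_lane"):
            raise ValueError(f"unknown permutation scheme {self.scheme!r}")
        if self.permutations not in ("random", "exhaustive"):
            raise ValueError(f"unknown permutations mode {self.permutations!r}")
        if self.size_measure not in ("extent", "intensity"):
            raise ValueError(f"unknown size_measure {self.size_measure!r}")
        if self.component_mode not in ("pooled", "by_sign"):
            raise ValueError(f"unknown component_mode {self.component_mode!r}")


@dataclass
class EdgeStatMap:
    """Per-edge outcome-association t statistics, covariate-adjusted."""

    t_values: np.ndarray = field(repr=False)
    df: int = 0
    outcome_name: str = "outcome"
    covariate_names: tuple = ()

    @property
    def n_edges(self) -> int:
        return self.t_values.shape[0]


@dataclass
class ComponentResult:
    """One connected suprathreshold subnetwork with its FWE p value."""

    edge_list: list                 # (i, j) region pairs, i < j
    edge_indices: np.ndarray = field(repr=False)  # flat edge ids
    n_edges: int = 0
    sign_profile: dict = field(default_factory=dict)  # counts of +/- t edges
    p_fwe: float = 1.0
    significant: bool = False
    size: float = 0.0               # under the configured size measure

    def __post_init__(self):
        if self.n_edges != len(self.edge_list):
            raise ValueError("n_edges inconsistent with edge_list")


def _design_matrix(outcome: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    outcome = np.asarray(outcome, dtype=float).ravel()
    n = outcome.shape[0]
    cols = [np.ones(n), outcome]
    if covariates is not None:
        covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
        if covariates.shape[0] != n:
            covariates = covariates.T
        if covariates.shape[0] != n:
            raise ValueError("covariates do not match number of subjects")
        cols.extend(covariates.T)
    X = np.column_stack(cols)
    return X


def _edge_t_values(X: np.ndarray, E: np.ndarray) -> np.ndarray:
    """t statistic of the outcome column (index 1) for every edge column of E."""
    n, p = X.shape
    xtx = X.T @ X
    try:
        xtx_inv = np.linalg.inv(xtx)
    except np.linalg.LinAlgError as exc:
        raise ValueError("rank-deficient design (collinear covariates?)") from exc
    if np.linalg.matrix_rank(xtx) < p:
        raise ValueError("rank-deficient design (collinear covariates?)")
    coef = xtx_inv @ (X.T @ E)           # p x m
    resid = E - X @ coef
    dof = n - p
    sigma2 = np.einsum("ij,ij->j", resid, resid) / dof
    with np.errstate(divide="ignore", invalid="ignore"):
        t = coef[1] / np.sqrt(sigma2 * xtx_inv[1, 1])
    bad = ~np.isfinite(t)
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} constant edge(s): t set to 0", RuntimeWarning
        )
        t = np.where(bad, 0.0, t)
    return t


def edge_glm(
    edge_table: np.ndarray,
    outcome: np.ndarray,
    covariates: np.ndarray | None = None,
    outcome_name: str = "outcome",
    covariate_names: tuple = (),
) -> EdgeStatMap:
    """Edge-wise GLM: ``edge ~ 1 + outcome + covariates`` by least squares.

    The returned t statistic of the outcome term equals the partial-
    correlation t between each edge and the outcome given the covariates,
    with ``df = n_subjects - (n_covariates + 2)``.
    """
    E = np.asarray(edge_table, dtype=float)
    if E.ndim != 2:
        raise ValueError("edge_table must be subjects x edges")
    outcome = np.asarray(outcome, dtype=float).ravel()
    if outcome.shape[0] != E.shape[0]:
        raise ValueError("outcome length does not match subjects")
    if np.std(outcome) == 0:
        raise ValueError("outcome is constant")
    X = _design_matrix(outcome, covariates)
    if E.shape[0] <= X.shape[1]:
        raise ValueError(
            f"need more subjects ({E.shape[0]}) than design columns ({X.shape[1]})"
        )
    constant = np.ptp(E, axis=0) == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant edge(s): t set to 0", RuntimeWarning
        )
    t = _edge_t_values(X, E)
    t = np.where(constant, 0.0, t)
    return EdgeStatMap(
        t_values=t,
        df=E.shape[0] - X.shape[1],
        outcome_name=outcome_name,
        covariate_names=tuple(covariate_names),
    )


def _n_regions_from_edges(n_edges: int) -> int:
    R = int(round((1 + math.isqrt(1 + 8 * n_edges)) / 2))
    if R * (R - 1) // 2 != n_edges:
        raise ValueError(f"edge count {n_edges} is not R*(R-1)/2 for integer R")
    return R


class _UnionFind:
    __slots__ = ("parent",)

    def __init__(self):
        self.parent = {}

    def find(self, a):
        parent = self.parent
        root = parent.setdefault(a, a)
        while parent[root] != root:
            root = parent[root]
        while parent[a] != root:
            parent[a], a = root, parent[a]
        return root

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def _component_edge_groups(pairs: np.ndarray) -> list:
    """Group edge row-indices of ``pairs`` by connected component."""
    uf = _UnionFind()
    for i, j in pairs:
        uf.union(int(i), int(j))
    groups: dict = {}
    for row, (i, j) in enumerate(pairs):
        groups.setdefault(uf.find(int(i)), []).append(row)
    return list(groups.values())


def _max_component_size(
    pairs: np.ndarray, weights: np.ndarray | None = None
) -> float:
    """Largest component size: edge count, or summed weights if given."""
    if pairs.shape[0] == 0:
        return 0.0
    groups = _component_edge_groups(pairs)
    if weights is None:
        return float(max(len(g) for g in groups))
    return float(max(weights[g].sum() for g in groups))


def suprathreshold_components(
    stats: EdgeStatMap,
    t_threshold: float,
    component_mode: str = "pooled",
) -> list:
    """Connected components of the |t| > threshold graph, as flat-edge arrays.

    Every suprathreshold edge belongs to exactly one component (the result
    partitions the suprathreshold edge set).  With
    ``component_mode="by_sign"``, positive- and negative-t edges form
    separate graphs.
    """
    if t_threshold <= 0:
        raise ValueError("t_threshold must be positive")
    index = EdgeIndex(_n_regions_from_edges(stats.n_edges))
    t = stats.t_values
    masks = [np.abs(t) > t_threshold]
    if component_mode == "by_sign":
        supra = masks[0]
        masks = [supra & (t > 0), supra & (t < 0)]
    components = []
    for mask in masks:
        flat = np.flatnonzero(mask)
        if flat.size == 0:
            continue
        pairs = index.pairs[flat]
        for rows in _component_edge_groups(pairs):
            components.append(np.sort(flat[np.asarray(rows)]))
    components.sort(key=lambda c: (-c.size, c[0]))
    return components


def _permuted_design(
    X: np.ndarray, order: np.ndarray, scheme: str, fl_parts: tuple | None
) -> np.ndarray:
    Xp = X.copy()
    if scheme == "simple":
        Xp[:, 1] = X[order, 1]
    else:  # freedman_lane: permute reduced-model residuals of the outcome
        fitted, resid = fl_parts
        Xp[:, 1] = fitted + resid[order]
    return Xp


def _component_size(flat: np.ndarray, t: np.ndarray, threshold: float, measure: str) -> float:
    if measure == "extent":
        return float(flat.size)
    return float(np.sum(np.abs(t[flat]) - threshold))


def nbs_test(
    edge_table: np.ndarray,
    outcome: np.ndarray,
    covariates: np.ndarray | None = None,
    config: NbsConfig | None = None,
    outcome_name: str = "outcome",
    covariate_names: tuple = (),
) -> list:
    """Full NBS: observed components with permutation FWE-corrected p values.

    For each permutation the outcome is reshuffled across subjects (per
    ``config.scheme``), the edge-wise GLM recomputed, and the maximal
    suprathreshold component size recorded.  In random mode
    ``p_fwe = (1 + #{perm max >= observed}) / (1 + n_permutations)`` (never
    exactly 0); in exhaustive mode all n! orderings are enumerated and the
    exact proportion (identity ordering included) is reported.  Components
    with ``p_fwe < alpha`` are flagged significant.  Deterministic given the
    config seed.
    """
    config = config or NbsConfig()
    E = np.asarray(edge_table, dtype=float)
    stats = edge_glm(E, outcome, covariates, outcome_name, covariate_names)
    index = EdgeIndex(_n_regions_from_edges(stats.n_edges))
    observed = suprathreshold_components(
        stats, config.t_threshold, config.component_mode
    )

    X = _design_matrix(np.asarray(outcome, dtype=float).ravel(), covariates)
    n = X.shape[0]
    fl_parts = None
    if config.scheme == "freedman_lane":
        Z = np.delete(X, 1, axis=1)  # intercept + covariates
        gamma, *_ = np.linalg.lstsq(Z, X[:, 1], rcond=None)
        fitted = Z @ gamma
        fl_parts = (fitted, X[:, 1] - fitted)

    if config.permutations == "exhaustive":
        if n > 9:
            raise ValueError(
                "exhaustive enumeration limited to n <= 9 subjects "
                f"(n! = {math.factorial(n)} orderings)"
            )
        orders = (np.asarray(p) for p in itertools.permutations(range(n)))
        n_perms = math.factorial(n)
    else:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed))
        orders = (rng.permutation(n) for _ in range(config.n_permutations))
        n_perms = config.n_permutations

    def _null_stat(tp: np.ndarray) -> float:
        supra = np.abs(tp) > config.t_threshold
        if config.component_mode == "by_sign":
            masks = [supra & (tp > 0), supra & (tp < 0)]
        else:
            masks = [supra]
        best = 0.0
        for mask in masks:
            flat = np.flatnonzero(mask)
            if flat.size == 0:
                continue
            if config.size_measure == "extent":
                best = max(best, _max_component_size(index.pairs[flat]))
            else:
                best = max(
                    best,
                    _max_component_size(
                        index.pairs[flat], np.abs(tp[flat]) - config.t_threshold
                    ),
                )
        return best

    null_max = np.empty(n_perms)
    for k, order in enumerate(orders):
        Xp = _permuted_design(X, order, config.scheme, fl_parts)
        null_max[k] = _null_stat(_edge_t_values(Xp, E))

    results = []
    for flat in observed:
        size = _component_size(flat, stats.t_values, config.t_threshold, config.size_measure)
        count = int(np.sum(null_max >= size))
        if config.permutations == "exhaustive":
            p_fwe = count / n_perms
        else:
            p_fwe = (1 + count) / (1 + n_perms)
        t_comp = stats.t_values[flat]
        results.append(
            ComponentResult(
                edge_list=[tuple(map(int, index.to_pair(int(f)))) for f in flat],
                edge_indices=flat,
                n_edges=int(flat.size),
                sign_profile={
                    "positive": int(np.sum(t_comp > 0)),
                    "negative": int(np.sum(t_comp < 0)),
                },
                p_fwe=float(p_fwe),
                significant=bool(p_fwe < config.alpha),
                size=size,
            )
        )
    return results


class NetworkBasedStatistic:
    """Scikit-learn-style estimator wrapping the NBS test.

    ``fit(X, y, covariates=...)`` runs the edge-wise GLM and permutation
    test on a subjects x edges table ``X`` against outcome ``y``;
    ``transform(X)`` then returns the mean connectivity over the selected
    component's edges as a single-column feature (the standard input to the
    downstream prediction stage).

    Fitted attributes: ``t_values_``, ``df_``, ``components_`` (all
    observed suprathreshold components, largest first), ``component_``
    (the selected one: the largest significant component, or the largest
    overall if none is significant and ``require_significant=False``)
    and ``n_regions_``.
    """

    def __init__(
        self,
        t_threshold: float = 3.50,
        n_permutations: int = 10000,
        alpha: float = 0.010,
        scheme: str = "simple",
        permutations: str = "random",
        size_measure: str = "extent",
        component_mode: str = "pooled",
        require_significant: bool = True,
        random_state: int = 0,
    ):
        self.t_threshold = t_threshold
        self.n_permutations = n_permutations
        self.alpha = alpha
        self.scheme = scheme
        self.permutations = permutations
        self.size_measure = size_measure
        self.component_mode = component_mode
        self.require_significant = require_significant
        self.random_state = random_state

    def get_params(self, deep: bool = True) -> dict:
        return {
            "t_threshold": self.t_threshold,
            "n_permutations": self.n_permutations,
            "alpha": self.alpha,
            "scheme": self.scheme,
            "permutations": self.permutations,
            "size_measure": self.size_measure,
            "component_mode": self.component_mode,
            "require_significant": self.require_significant,
            "random_state": self.random_state,
        }

    def set_params(self, **params):
        for key, value in params.items():
            if key not in self.get_params():
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    def _config(self) -> NbsConfig:
        return NbsConfig(
            t_threshold=self.t_threshold,
            n_permutations=self.n_permutations,
            alpha=self.alpha,
            seed=self.random_state,
            scheme=self.scheme,
            permutations=self.permutations,
            size_measure=self.size_measure,
            component_mode=self.component_mode,
        )

    def fit(self, X, y, covariates=None):
        X = np.asarray(X, dtype=float)
        stats = edge_glm(X, y, covariates)
        self.t_values_ = stats.t_values
        self.df_ = stats.df
        self.n_regions_ = _n_regions_from_edges(stats.n_edges)
        self.components_ = nbs_test(X, y, covariates, self._config())
        significant = [c for c in self.components_ if c.significant]
        if significant:
            self.component_ = significant[0]
        elif self.components_ and not self.require_significant:
            self.component_ = self.components_[0]
        else:
            self.component_ = None
        return self

    def get_support(self) -> np.ndarray:
        """Boolean mask over edges belonging to the selected component."""
        if not hasattr(self, "t_values_"):
            raise RuntimeError("estimator is not fitted")
        mask = np.zeros(self.t_values_.shape[0], dtype=bool)
        if self.component_ is not None:
            mask[self.component_.edge_indices] = True
        return mask

    def transform(self, X) -> np.ndarray:
        """Mean connectivity over the selected component per subject (n x 1)."""
        if not hasattr(self, "t_values_"):
            raise RuntimeError("estimator is not fitted")
        if self.component_ is None:
            raise RuntimeError("no component selected (none significant)")
        X = np.asarray(X, dtype=float)
        return X[:, self.component_.edge_indices].mean(axis=1, keepdims=True)

    def fit_transform(self, X, y, covariates=None) -> np.ndarray:
        return self.fit(X, y, covariates=covariates).transform(X)
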