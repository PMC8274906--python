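"""ReliefF feature weighting with ranked top-k selection.

ReliefF scores each feature by how well it separates nearby instances of
different classes.  For a visited instance x_i with k nearest hits H_i (same
class) and, per other class C, k nearest misses M_i(C), every feature weight
is updated as

    w[f] -= sum_{x_j in H_i} diff(f, x_i, x_j) / (m * k)
    w[f] += sum_{C != class(x_i)} P(C)/(1 - P(class(x_i)))
            * sum_{x_j in M_i(C)} diff(f, x_i, x_j) / (m * k)

where diff is the 0/1 indicator for nominal features and the range-scaled
absolute difference for continuous features, and the normalizer m is the
number of features ("paper" mode, the default) or the number of visited
instances ("classic" mode).  Both normalizers are uniform positive scalings,
so rankings are identical between modes.

Neighbor distance is the sum of per-feature diff values (Manhattan on
range-scaled features); distance ties break by instance index, which makes
the procedure fully deterministic under the default exhaustive visiting
policy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

SELECTION_SIZES: tuple = (50, 100, 200, 300, 400, 500, 600, "all")


@dataclass
class RelieffConfig:
    """k_neighbors must not exceed (smallest class size - 1)."""

    k_neighbors: int = 10
    iteration_policy: str = "exhaustive"  # or "sampled"
    n_iterations: int | None = None  # only for the sampled policy
    normalizer_mode: str = "paper"  # m = n_features; "classic": m = n_iterations
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if self.iteration_policy not in ("exhaustive", "sampled"):
            raise ValueError(f"unknown iteration_policy {self.iteration_policy!r}")
        if self.normalizer_mode not in ("paper", "classic"):
            raise ValueError(f"unknown normalizer_mode {self.normalizer_mode!r}")


@dataclass
class FeatureWeights:
    names: list[str]
    weights: np.ndarray
    config: RelieffConfig
    n_iterations: int


@dataclass
class RankedFeatures:
    """Features sorted by weight (descending, ties lexicographic by name)."""

    names: list[str]
    weights: np.ndarray
    subsets: dict = field(default_factory=dict)

    def top(self, size) -> list[str]:
        return self.subsets[size]


def infer_feature_kinds(X: np.ndarray, nominal_hint: list[bool] | None = None) -> list[str]:
    """Per-column kind: <= 2 distinct values (or hinted flags) -> nominal."""
    kinds = []
    for j in range(X.shape[1]):
        hinted = nominal_hint[j] if nominal_hint is not None else False
        nominal = hinted or len(np.unique(X[:, j])) <= 2
        kinds.append("nominal" if nominal else "continuous")
    logger.debug(
        "feature kinds: %d nominal, %d continuous",
        sum(k == "nominal" for k in kinds),
        sum(k == "continuous" for k in kinds),
    )
    return kinds


def diff(
    f_value_i: float,
    f_value_j: float,
    kind: str,
    value_range: tuple[float, float] | None = None,
) -> float:
    """Per-feature instance difference in [0, 1].

    Nominal: 0 if equal else 1.  Continuous: |x_i - x_j| / (max - min), with
    0 by convention for a constant feature.
    """
    if kind == "nominal":
        return 0.0 if f_value_i == f_value_j else 1.0
    lo, hi = value_range
    if hi <= lo:
        return 0.0
    return abs(f_value_i - f_value_j) / (hi - lo)


def _transform(X: np.ndarray, kinds: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Scale columns so per-feature diff = |z_i - z_j| (or != for nominal).

    Continuous columns are divided by their range (constant columns zeroed);
    nominal columns keep raw values and are compared by inequality.  Returns
    (Z, nominal_mask).
    """
    Z = np.array(X, dtype=float, copy=True)
    nominal_mask = np.array([k == "nominal" for k in kinds])
    for j, kind in enumerate(kinds):
        if kind == "continuous":
            span = Z[:, j].max() - Z[:, j].min()
            Z[:, j] = Z[:, j] / span if span > 0 else 0.0
        else:
            # Recode binary nominal values to 0/1 so |z_i - z_j| equals the
            # inequality indicator; multi-valued nominal columns keep raw
            # codes and use explicit inequality.
            uniq = np.unique(Z[:, j])
            if len(uniq) <= 2:
                Z[:, j] = np.searchsorted(uniq, Z[:, j]).astype(float)
    return Z, nominal_mask


def _pair_diffs(Z: np.ndarray, nominal_mask: np.ndarray, i: int, js: np.ndarray) -> np.ndarray:
    """diff(f, x_i, x_j) for each j in js and every feature; shape (len(js), m)."""
    block = Z[js]
    out = np.abs(block - Z[i])
    if nominal_mask.any():
        out[:, nominal_mask] = (block[:, nominal_mask] != Z[i, nominal_mask]).astype(float)
    return out


def _distance_matrix(Z: np.ndarray, nominal_mask: np.ndarray) -> np.ndarray:
    """Sum-of-diffs distance between all instance pairs."""
    n = len(Z)
    cont = ~nominal_mask
    D = np.zeros((n, n))
    if cont.any():
        from scipy.spatial.distance import cdist

        D += cdist(Z[:, cont], Z[:, cont], metric="cityblock")
    for j in np.flatnonzero(nominal_mask):
        col = Z[:, j]
        uniq = np.unique(col)
        if len(uniq) <= 2:
            D += np.abs(col[:, None] - col[None, :])
        else:
            D += (col[:, None] != col[None, :]).astype(float)
    return D


def nearest_hits_misses(
    i: int,
    X: np.ndarray,
    y: np.ndarray,
    k: int,
    kinds: list[str] | None = None,
) -> tuple[np.ndarray, dict]:
    """k nearest same-class hits and, per other class, k nearest misses.

    Standalone (recomputes distances); :func:`relieff_weights` uses the same
    logic against a precomputed distance matrix.  Distance ties break by
    instance index order.
    """
    kinds = kinds or infer_feature_kinds(X)
    Z, nominal_mask = _transform(X, kinds)
    D = _distance_matrix(Z, nominal_mask)
    return _neighbors_from_distances(i, D, np.asarray(y), k)


def _neighbors_from_distances(
    i: int, D: np.ndarray, y: np.ndarray, k: int
) -> tuple[np.ndarray, dict]:
    order = np.argsort(D[i], kind="stable")
    order = order[order != i]
    hits = order[y[order] == y[i]][:k]
    if len(hits) < k:
        raise ValueError(
            f"class {y[i]!r} has fewer than k+1={k + 1} members; "
            "reduce k_neighbors or enlarge the class"
        )
    misses = {}
    for c in np.unique(y):
        if c == y[i]:
            continue
        mc = order[y[order] == c][:k]
        if len(mc) < k:
            raise ValueError(
                f"class {c!r} has fewer than k={k} members; "
                "reduce k_neighbors or enlarge the class"
            )
        misses[c] = mc
    return hits, misses


def relieff_weights(
    X: np.ndarray,
    y,
    config: RelieffConfig | None = None,
    feature_names: list[str] | None = None,
    kinds: list[str] | None = None,
) -> FeatureWeights:
    """ReliefF weights for every feature (see module docstring for the update)."""
    config = config or RelieffConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, m = X.shape
    if feature_names is None:
        feature_names = [f"f{j}" for j in range(m)]
    classes, class_counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("relieff_weights requires at least 2 classes")
    k = config.k_neighbors
    if class_counts.min() < k + 1:
        smallest = classes[class_counts.argmin()]
        raise ValueError(
            f"class {smallest!r} has {class_counts.min()} members, "
            f"fewer than k_neighbors+1={k + 1}"
        )

    kinds = kinds or infer_feature_kinds(X)
    Z, nominal_mask = _transform(X, kinds)
    D = _distance_matrix(Z, nominal_mask)

    priors = {c: cnt / n for c, cnt in zip(classes, class_counts)}
    if config.iteration_policy == "exhaustive":
        visit = np.arange(n)
    else:
        rng = np.random.default_rng(config.seed)
        n_iter = config.n_iterations or n
        visit = rng.integers(0, n, size=n_iter)

    m_norm = m if config.normalizer_mode == "paper" else len(visit)
    w = np.zeros(m)
    for i in visit:
        hits, misses = _neighbors_from_distances(int(i), D, y, k)
        w -= _pair_diffs(Z, nominal_mask, int(i), hits).sum(axis=0) / (m_norm * k)
        factor_denom = 1.0 - priors[y[i]]
        for c, mc in misses.items():
            w += (
                priors[c]
                / factor_denom
                * _pair_diffs(Z, nominal_mask, int(i), mc).sum(axis=0)
                / (m_norm * k)
            )
    return FeatureWeights(
        names=list(feature_names), weights=w, config=config, n_iterations=len(visit)
    )


def rank_and_select(
    fw: FeatureWeights, sizes: tuple = SELECTION_SIZES
) -> RankedFeatures:
    """Sort by weight descending (ties lexicographic) and materialize prefixes.

    A requested size larger than the feature count is clamped to all
    features, with a warning.
    """
    order = sorted(range(len(fw.names)), key=lambda j: (-fw.weights[j], fw.names[j]))
    names = [fw.names[j] for j in order]
    weights = fw.weights[order]
    subsets = {}
    for size in sizes:
        if size == "all":
            subsets["all"] = list(names)
            continue
        if size > len(names):
            logger.warning(
                "selection size %d exceeds feature count %d; clamped to all",
                size,
                len(names),
            )
            subsets[size] = list(names)
        else:
            subsets[size] = names[:size]
    return RankedFeatures(names=names, weights=weights, subsets=subsets)


def write_ranking_csv(
    ranked: RankedFeatures, path, families: dict[str, str] | None = None
) -> None:
    """rank, feature, weight and (optionally) family tag per row."""
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["rank", "feature", "weight", "family"])
        for rank, (name, weight) in enumerate(zip(ranked.names, ranked.weights), start=1):
            writer.writerow([rank, name, f"{weight:.10g}", (families or {}).get(name, "")])
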