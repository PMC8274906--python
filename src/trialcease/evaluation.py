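"""Cross-validation folds, the four metrics, and Friedman/Nemenyi comparison.

Model comparison treats each feature-subset size as one dataset: for k
classifiers over n datasets, per-dataset descending ranks (best = 1, ties get
the average rank) give average ranks R_j, the Friedman statistic

    chi2_F = 12n / (k(k+1)) * (sum_j R_j^2 - k(k+1)^2 / 4)

is referred to the chi-square distribution with k-1 degrees of freedom, and
the Nemenyi post-hoc critical difference is

    CD = q_alpha * sqrt(k(k+1) / (6n))

with q_alpha the Studentized range statistic divided by sqrt(2).  Classifiers
whose average ranks differ by less than CD are grouped under one bar in the
critical-difference diagram.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import (
    accuracy_score,
    balanced_accuracy_score,
    f1_score,
    roc_auc_score,
)
from sklearn.model_selection import KFold

METRICS = ("accuracy", "balanced_accuracy", "f1", "auc")

#: Nemenyi q_alpha (Studentized range / sqrt(2)) for k = 2..10 classifiers.
Q_ALPHA: dict[float, dict[int, float]] = {
    0.05: {2: 1.960, 3: 2.343, 4: 2.569, 5: 2.728, 6: 2.850, 7: 2.949,
           8: 3.031, 9: 3.102, 10: 3.164},
    0.10: {2: 1.645, 3: 2.052, 4: 2.291, 5: 2.459, 6: 2.589, 7: 2.693,
           8: 2.780, 9: 2.855, 10: 2.920},
}


@dataclass
class FoldSplit:
    """Assignment of instance positions to folds 1..k."""

    fold_of: np.ndarray
    k: int
    seed: int
    stratified: bool

    def folds(self):
        for f in range(self.k):
            test = np.flatnonzero(self.fold_of == f)
            train = np.flatnonzero(self.fold_of != f)
            yield train, test


def make_folds(labels, k: int = 5, seed: int = 0, stratified: bool = True) -> FoldSplit:
    """Deterministic (stratified) k-fold assignment.

    Stratified mode deals each class's shuffled members across folds so that
    per-fold class counts differ by at most one *and* total fold sizes differ
    by at most one (remainders go to the currently smallest folds).  This
    also covers classes smaller than k: their members simply land in
    different folds.
    """
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("make_folds requires both classes present")
    rng = np.random.default_rng(seed)
    fold_of = np.empty(len(y), dtype=int)
    if not stratified:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        for f, (_, test) in enumerate(splitter.split(np.zeros(len(y)))):
            fold_of[test] = f
        return FoldSplit(fold_of=fold_of, k=k, seed=seed, stratified=False)
    totals = np.zeros(k, dtype=int)
    for cls in classes[np.argsort(-counts, kind="stable")]:  # largest class first
        members = np.flatnonzero(y == cls)
        members = members[rng.permutation(len(members))]
        base, rem = divmod(len(members), k)
        quotas = np.full(k, base)
        # remainders go to the folds that are currently smallest (ties by index)
        for f in sorted(range(k), key=lambda f: (totals[f], f))[:rem]:
            quotas[f] += 1
        pos = 0
        for f in range(k):
            fold_of[members[pos : pos + quotas[f]]] = f
            pos += quotas[f]
        totals += quotas
    return FoldSplit(fold_of=fold_of, k=k, seed=seed, stratified=True)


def compute_metrics(y_true, probabilities, threshold: float = 0.5) -> dict[str, float]:
    """Accuracy, balanced accuracy, F1 (cessation class) and AUC.

    AUC is computed from the probability ranking with midrank tie handling
    (trapezoidal-equivalent); both classes must be present in y_true.
    """
    y_true = np.asarray(y_true).astype(int)
    probabilities = np.asarray(probabilities, dtype=float)
    if len(np.unique(y_true)) < 2:
        raise ValueError("AUC/balanced accuracy undefined: y_true has a single class")
    y_pred = (probabilities >= threshold).astype(int)
    return {
        "accuracy": accuracy_score(y_true, y_pred),
        "balanced_accuracy": balanced_accuracy_score(y_true, y_pred),
        "f1": f1_score(y_true, y_pred, pos_label=1, zero_division=0),
        "auc": roc_auc_score(y_true, probabilities),
    }


def aggregate_fold_metrics(per_fold: list[dict[str, float]]) -> dict[str, float]:
    """Fold-averaged metrics with standard deviations (population SD)."""
    out = {}
    for metric in METRICS:
        values = np.array([fold[metric] for fold in per_fold])
        out[metric] = float(values.mean())
        out[f"{metric}_sd"] = float(values.std())
    return out


def average_ranks(metric_table) -> tuple[np.ndarray, np.ndarray]:
    """Average descending ranks over datasets.

    ``metric_table`` has shape (k classifiers, n datasets), larger metric =
    better.  Per dataset the best classifier gets rank 1; exact ties receive
    the average of the tied ranks.  Returns (R_j of shape (k,), full rank
    matrix of shape (k, n)).
    """
    table = np.asarray(metric_table, dtype=float)
    if table.ndim != 2:
        raise ValueError("metric_table must be 2-D (classifiers x datasets)")
    ranks = np.column_stack(
        [stats.rankdata(-table[:, i], method="average") for i in range(table.shape[1])]
    )
    return ranks.mean(axis=1), ranks


def friedman_chi2(R, n: int, k: int) -> tuple[float, float]:
    """Friedman statistic from average ranks, with its chi-square p-value."""
    if n < 2 or k < 2:
        raise ValueError("friedman_chi2 requires n >= 2 datasets and k >= 2 classifiers")
    R = np.asarray(R, dtype=float)
    chi2 = 12.0 * n / (k * (k + 1)) * (np.sum(R**2) - k * (k + 1) ** 2 / 4.0)
    p = float(stats.chi2.sf(chi2, df=k - 1))
    return float(chi2), p


def friedman_test(metric_table) -> dict:
    """Convenience wrapper: ranks + statistic from a metric table."""
    table = np.asarray(metric_table, dtype=float)
    k, n = table.shape
    R, ranks = average_ranks(table)
    chi2, p = friedman_chi2(R, n, k)
    return {"average_ranks": R, "rank_matrix": ranks, "chi2": chi2, "p": p, "k": k, "n": n}


def nemenyi_cd(k: int, n: int, alpha: float = 0.05, q_alpha: float | None = None) -> float:
    """Critical difference CD = q_alpha * sqrt(k(k+1)/(6n))."""
    if q_alpha is None:
        try:
            q_alpha = Q_ALPHA[alpha][k]
        except KeyError as exc:
            raise ValueError(
                f"no built-in q for alpha={alpha}, k={k}; pass q_alpha explicitly"
            ) from exc
    if q_alpha <= 0:
        raise ValueError("q_alpha must be > 0")
    return q_alpha * np.sqrt(k * (k + 1) / (6.0 * n))


@dataclass
class NemenyiResult:
    names: list[str]
    average_ranks: np.ndarray
    cd: float
    #: boolean matrix, True where |R_a - R_b| >= CD
    significant: np.ndarray = field(default=None)
    #: maximal groups of mutually non-significant classifiers, best rank first
    bars: list[list[str]] = field(default_factory=list)

    def to_json(self, path) -> None:
        payload = {
            "cd": self.cd,
            "average_ranks": dict(zip(self.names, map(float, self.average_ranks))),
            "bars": self.bars,
            "significant_pairs": [
                [self.names[a], self.names[b]]
                for a in range(len(self.names))
                for b in range(a + 1, len(self.names))
                if self.significant[a, b]
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
            fh.write("\n")


def cd_grouping(R, cd: float, names: list[str] | None = None) -> NemenyiResult:
    """Maximal bars of classifiers whose pairwise rank gaps are all below CD."""
    R = np.asarray(R, dtype=float)
    k = len(R)
    names = names or [f"clf{j + 1}" for j in range(k)]
    significant = np.abs(R[:, None] - R[None, :]) >= cd
    order = sorted(range(k), key=lambda j: (R[j], names[j]))
    intervals = []
    for start in range(k):
        end = start
        while end + 1 < k and R[order[end + 1]] - R[order[start]] < cd:
            end += 1
        intervals.append((start, end))
    bars = [
        [names[order[j]] for j in range(s, e + 1)]
        for s, e in intervals
        if not any(o_s <= s and e <= o_e and (o_s, o_e) != (s, e) for o_s, o_e in intervals)
    ]
    # drop duplicates while keeping left-to-right order
    seen = set()
    unique_bars = []
    for bar in bars:
        key = tuple(bar)
        if key not in seen:
            seen.add(key)
            unique_bars.append(bar)
    return NemenyiResult(
        names=names, average_ranks=R, cd=cd, significant=significant, bars=unique_bars
    )


def cd_diagram(result: NemenyiResult, path) -> None:
    """Render the critical-difference diagram to SVG (best ranks at left)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = np.argsort(result.average_ranks, kind="stable")
    fig, ax = plt.subplots(figsize=(7, 2 + 0.3 * len(result.names)))
    lo = np.floor(result.average_ranks.min())
    hi = np.ceil(result.average_ranks.max())
    ax.set_xlim(lo - 0.2, hi + 0.2)
    ax.set_ylim(-len(result.names) - len(result.bars) - 1, 1.5)
    ax.axhline(0, color="black", lw=1)
    for tick in np.arange(lo, hi + 0.5, 0.5):
        ax.plot([tick, tick], [0, 0.15], color="black", lw=1)
        ax.text(tick, 0.3, f"{tick:g}", ha="center", fontsize=8)
    for row, j in enumerate(order, start=1):
        r = result.average_ranks[j]
        ax.plot([r, r], [0, -row], color="black", lw=0.8)
        ax.text(r, -row - 0.15, f"{result.names[j]} ({r:.2f})", ha="center", fontsize=9)
    base = -len(result.names) - 1
    for b, bar in enumerate(result.bars):
        rs = [result.average_ranks[result.names.index(name)] for name in bar]
        y = base - 0.4 * b
        ax.plot([min(rs) - 0.05, max(rs) + 0.05], [y, y], color="black", lw=3)
    ax.text(lo, 1.2, f"CD = {result.cd:.3f}", fontsize=9)
    ax.axis("off")
    fig.savefig(path, format="svg", bbox_inches="tight")
    plt.close(fig)


def bars_text(result: NemenyiResult) -> str:
    """Plain-text description of the critical-difference bars."""
    lines = [f"CD = {result.cd:.3f}"]
    for j in np.argsort(result.average_ranks, kind="stable"):
        lines.append(f"  {result.names[j]}: R = {result.average_ranks[j]:.3f}")
    for bar in result.bars:
        lines.append("  bar: " + " ~ ".join(bar))
    return "\n".join(lines)
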