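"""Boruta all-relevant channel selection over a randomized-tree backend.

Boruta augments the design matrix with *shadow* channels — column-shuffled
copies of the real ones — and repeatedly fits a tree ensemble.  A real
channel scores a *hit* in a run when its importance z-score beats the best
shadow's; accumulated hits are tested against a fair coin (binomial test
with Bonferroni correction) to confirm or reject channels.  Channels still
undecided when the run budget is exhausted are *tentative*.

The importance backend is a bagged ensemble of randomized decision trees
(scikit-learn trees, bootstrap resampling handled here so the per-tree
out-of-bag sample is explicit).  The classic Boruta importance is the
per-tree out-of-bag permutation accuracy decrease; mean-decrease-impurity
is available as a faster alternative, with the caveat that its z-scores
are not comparable to the permutation ones.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from sklearn.tree import DecisionTreeClassifier

from .dataio import ChannelSubset, FMGDataset

#: Boruta keeps at least this many shadow columns in every run.
MIN_SHADOWS = 5


def forest_importance(
    values: np.ndarray,
    labels: Sequence[str],
    n_trees: int = 500,
    seed: int = 0,
    importance: str = "permutation",
    max_features: str | int | float = "sqrt",
) -> np.ndarray:
    """Per-feature importance z-scores from a bagged randomized-tree ensemble.

    Each tree is fit on a bootstrap resample; with
    ``importance="permutation"`` its contribution for feature ``j`` is the
    accuracy drop on the tree's out-of-bag samples when column ``j`` is
    permuted.  The z-score is mean / sd of the per-tree importances
    (``z = 0`` where the sd is zero).  Seeded and deterministic.
    """
    X = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=object).astype(str)
    if X.ndim != 2 or len(y) != X.shape[0]:
        raise ValueError("values must be 2-D with one label per row")
    if len(np.unique(y)) < 2:
        raise ValueError("importance requires at least two classes")
    if importance not in ("permutation", "impurity"):
        raise ValueError(f"unknown importance measure {importance!r}")
    n, d = X.shape
    rng = np.random.default_rng(seed)
    per_tree = np.zeros((n_trees, d))
    for t in range(n_trees):
        boot = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), boot, assume_unique=False)
        tree = DecisionTreeClassifier(
            max_features=max_features,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        tree.fit(X[boot], y[boot])
        if importance == "impurity":
            per_tree[t] = tree.feature_importances_
            continue
        if len(oob) == 0:
            continue
        X_oob = X[oob]
        y_oob = y[oob]
        m = len(oob)
        base_acc = float(np.mean(tree.predict(X_oob) == y_oob))
        # batch the d permuted copies into few predict calls
        chunk = max(1, 200_000 // max(m, 1))
        for j0 in range(0, d, chunk):
            js = range(j0, min(j0 + chunk, d))
            stacked = np.repeat(X_oob[None, :, :], len(js), axis=0)
            for k, j in enumerate(js):
                stacked[k, :, j] = X_oob[rng.permutation(m), j]
            pred = tree.predict(stacked.reshape(-1, d)).reshape(len(js), m)
            per_tree[t, list(js)] = base_acc - np.mean(pred == y_oob[None, :], axis=1)
    mean = per_tree.mean(axis=0)
    sd = per_tree.std(axis=0, ddof=1) if n_trees > 1 else np.zeros(d)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, mean / sd, 0.0)
    return z


@dataclass(frozen=True)
class BorutaResult:
    """Outcome of a Boruta run.

    ``decisions`` partitions the channels into confirmed / rejected /
    tentative; ``importance_history`` is the (n_runs_used, n_channels)
    matrix of per-run z-scores of the real channels (shadows never appear
    in the result); ``final_ranking`` orders all channels by mean z over
    the runs, best first.
    """

    decisions: Mapping[int, str]
    importance_history: np.ndarray
    n_runs_used: int
    final_ranking: tuple[int, ...]
    hit_counts: tuple[int, ...]

    def channels_with(self, decision: str) -> tuple[int, ...]:
        return tuple(sorted(c for c, d in self.decisions.items() if d == decision))

    def selected(self, include_tentative: bool = False) -> tuple[int, ...]:
        keep = {"confirmed", "tentative"} if include_tentative else {"confirmed"}
        return tuple(sorted(c for c, d in self.decisions.items() if d in keep))


def binomial_decisions(
    hits: Sequence[int],
    n_runs: int,
    undecided: Sequence[int],
    alpha: float = 0.01,
) -> dict[int, str]:
    """Bonferroni-corrected two-sided binomial test on shadow-beating hits.

    For each undecided channel the hit count over ``n_runs`` is tested
    against a fair coin; significance with more hits than ``n_runs / 2``
    confirms the channel, significance with fewer rejects it.  The
    Bonferroni divisor is the number of channels still undecided.
    """
    decisions: dict[int, str] = {}
    if not undecided or n_runs == 0:
        return decisions
    corrected = alpha / len(undecided)
    for c in undecided:
        h = int(hits[c])
        p = stats.binomtest(h, n_runs, 0.5).pvalue
        if p < corrected:
            decisions[c] = "confirmed" if h > n_runs / 2 else "rejected"
    return decisions


def boruta_run(
    dataset: FMGDataset,
    reps: Sequence[int] | None = None,
    n_trees: int = 500,
    max_runs: int = 100,
    alpha: float = 0.01,
    importance: str = "permutation",
    seed: int = 0,
) -> BorutaResult:
    """Boruta all-relevant selection on the training repetitions.

    Each run appends independently column-shuffled shadow copies of the
    real channels (padded to at least :data:`MIN_SHADOWS` shadows by
    duplicating shuffled originals), computes tree-ensemble importance
    z-scores, and records for each still-undecided channel whether it
    beat the maximum shadow z.  After every run the accumulated hits are
    tested with :func:`binomial_decisions`; the loop ends when all
    channels are decided or after ``max_runs`` runs, leaving the
    remainder tentative.  Tentative outcomes are a valid result — the
    run count is data-dependent and is always reported.
    """
    if reps is not None:
        mask = np.isin(dataset.repetition, list(reps))
        data = dataset.select_rows(mask)
    else:
        data = dataset
    X = data.values
    y = data.gesture.astype(str)
    n, d = X.shape
    rng = np.random.default_rng(seed)

    n_shadow_copies = max(1, int(np.ceil(MIN_SHADOWS / d)))
    hits = np.zeros(d, dtype=int)
    undecided = set(range(d))
    decisions: dict[int, str] = {}
    history: list[np.ndarray] = []

    run = 0
    while undecided and run < max_runs:
        run += 1
        # shadow block: copies of X with every column shuffled independently
        shadows = np.hstack([X] * n_shadow_copies).copy()
        for j in range(shadows.shape[1]):
            shadows[:, j] = shadows[rng.permutation(n), j]
        design = np.hstack([X, shadows])
        z = forest_importance(
            design,
            y,
            n_trees=n_trees,
            seed=int(rng.integers(0, 2**31 - 1)),
            importance=importance,
        )
        z_real, z_shadow = z[:d], z[d:]
        history.append(z_real)
        best_shadow = float(z_shadow.max())
        for c in undecided:
            if z_real[c] > best_shadow:
                hits[c] += 1
        for c, verdict in binomial_decisions(hits, run, sorted(undecided), alpha).items():
            decisions[c] = verdict
            undecided.discard(c)

    for c in undecided:
        decisions[c] = "tentative"

    mean_z = np.mean(history, axis=0) if history else np.zeros(d)
    order = np.argsort(-mean_z, kind="stable")
    return BorutaResult(
        decisions=decisions,
        importance_history=np.asarray(history),
        n_runs_used=run,
        final_ranking=tuple(int(i) for i in order),
        hit_counts=tuple(int(h) for h in hits),
    )
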