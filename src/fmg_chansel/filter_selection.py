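"""Mutual-information machinery and the mRMR (MIQ) channel ranking.

mRMR is the filter method of the study: it ranks channels by greedily
maximizing the *quotient* of relevance (mutual information between a
candidate channel and the gesture label) over mean redundancy (mean mutual
information between the candidate and the already-selected channels).
It performs no classifier fits at all, which is why it is the fastest
method in the benchmark.

Channels are discretized before MI estimation.  The study's mRMR variant
(MIQ) is recommended for discrete features; the default coding is the
Ding–Peng mean ± sigma 3-state scheme, with n-quantile binning available
as an alternative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .dataio import ChannelSubset, FMGDataset


def discretize(values: np.ndarray, scheme: str = "mean_sigma3", n_bins: int = 3) -> np.ndarray:
    """Per-channel discretization of a sample × channel matrix.

    ``mean_sigma3`` codes each channel into 3 states around its own mean:
    below ``mu - sigma`` → 0, within ``mu ± sigma`` → 1, above
    ``mu + sigma`` → 2.  A zero-variance channel codes as all 1s (not an
    error).  Coding is invariant under affine rescaling of a channel,
    since mu and sigma rescale together.

    ``quantile`` codes each channel into ``n_bins`` equal-frequency bins.
    """
    X = np.asarray(values, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if not np.all(np.isfinite(X)):
        raise ValueError("values must be finite")
    if scheme == "mean_sigma3":
        mu = X.mean(axis=0)
        sigma = X.std(axis=0)
        codes = np.ones(X.shape, dtype=int)
        nz = sigma > 0
        codes[:, nz] += (X[:, nz] > (mu + sigma)[nz]).astype(int)
        codes[:, nz] -= (X[:, nz] < (mu - sigma)[nz]).astype(int)
        return codes
    if scheme == "quantile":
        codes = np.zeros(X.shape, dtype=int)
        qs = np.linspace(0, 1, n_bins + 1)[1:-1]
        for j in range(X.shape[1]):
            edges = np.quantile(X[:, j], qs)
            codes[:, j] = np.searchsorted(edges, X[:, j], side="right")
        return codes
    raise ValueError(f"unknown discretization scheme {scheme!r}")


def mutual_information(x: Sequence, y: Sequence) -> float:
    """Plug-in mutual information of two discrete vectors, in bits.

    ``I(X;Y) = sum_xy p(x,y) log2[p(x,y) / (p(x) p(y))]`` over the
    empirical joint distribution, with ``0 log 0 := 0``.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = len(x)
    _, xi = np.unique(x, return_inverse=True)
    _, yi = np.unique(y, return_inverse=True)
    kx, ky = xi.max() + 1, yi.max() + 1
    joint = np.bincount(xi * ky + yi, minlength=kx * ky).reshape(kx, ky) / n
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    nz = joint > 0
    return float(np.sum(joint[nz] * np.log2(joint[nz] / np.outer(px, py)[nz])))


@dataclass
class MRMRState:
    """mRMR ranking state: relevance, (lazily filled) redundancy, ranking.

    ``relevance[a]`` is I(channel a; gesture label); ``redundancy[a, b]``
    is I(a; b), filled only for pairs involving selected channels (NaN
    elsewhere); ``selected`` is the full greedy ranking, best first;
    ``scores`` the MIQ quotient each channel was selected at (relevance
    for the first pick, ``inf`` for zero-redundancy picks).
    """

    relevance: np.ndarray
    redundancy: np.ndarray
    selected: list[int]
    scores: list[float]
    scheme: str

    def subset(self, k: int | None = None, training_reps: Sequence[int] = ()) -> ChannelSubset:
        """Top-k prefix of the ranking as a :class:`ChannelSubset`."""
        k = len(self.selected) if k is None else k
        return ChannelSubset(
            indices=tuple(self.selected[:k]),
            method="mrmr",
            training_reps=tuple(training_reps),
            rank_scores=tuple(self.scores[:k]),
        )


def mrmr_rank(
    dataset: FMGDataset,
    reps: Sequence[int] | None = None,
    scheme: str = "mean_sigma3",
) -> MRMRState:
    """Full greedy MIQ ranking of all channels on the training repetitions.

    The first channel maximizes relevance I(a; label); each subsequent
    pick maximizes the quotient

        I(a; label) / [ (1/|F|) * sum_{b in F} I(a; b) ]

    over unselected channels ``a``, where ``F`` is the already-selected
    set.  If the mean redundancy of a candidate is exactly zero the
    quotient is treated as +inf, and such candidates are ordered by
    relevance.  All ties break to the lower channel index.  Discretization
    statistics (mu, sigma) are computed on the training repetitions only.
    Deterministic; performs zero classifier fits.
    """
    if dataset.n_channels < 2:
        raise ValueError("mRMR ranking needs at least two channels")
    if reps is not None:
        mask = np.isin(dataset.repetition, list(reps))
        if not mask.any():
            raise ValueError(f"no samples in repetitions {list(reps)}")
        data = dataset.select_rows(mask)
    else:
        data = dataset
        reps = dataset.repetition_ids

    codes = discretize(data.values, scheme=scheme)
    labels = data.gesture.astype(str)
    d = data.n_channels
    relevance = np.array([mutual_information(codes[:, j], labels) for j in range(d)])
    redundancy = np.full((d, d), np.nan)

    def red(a: int, b: int) -> float:
        if np.isnan(redundancy[a, b]):
            v = mutual_information(codes[:, a], codes[:, b])
            redundancy[a, b] = redundancy[b, a] = v
        return redundancy[a, b]

    selected: list[int] = []
    scores: list[float] = []
    remaining = list(range(d))

    first = int(np.argmax(relevance))  # argmax takes the lowest index on ties
    selected.append(first)
    scores.append(float(relevance[first]))
    remaining.remove(first)

    while remaining:
        best, best_key = None, None
        for a in remaining:
            mean_red = float(np.mean([red(a, b) for b in selected]))
            if mean_red == 0.0:
                key = (1, relevance[a])  # +inf quotient tier, ordered by relevance
            else:
                key = (0, relevance[a] / mean_red)
            if best_key is None or key > best_key:
                best, best_key = a, key
        selected.append(best)
        scores.append(float("inf") if best_key[0] == 1 else float(best_key[1]))
        remaining.remove(best)

    return MRMRState(
        relevance=relevance,
        redundancy=redundancy,
        selected=selected,
        scores=scores,
        scheme=scheme,
    )
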