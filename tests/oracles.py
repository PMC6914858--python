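"""Independent brute-force oracles used to check the selection algorithms.

These deliberately re-derive each quantity from its definition with the
plainest possible code (exhaustive loops, direct summation) and share no
logic with the package implementation they check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from fmg_chansel.classification import loocv_accuracy, loocv_error


def mi_bruteforce(x, y, base: float = 2.0) -> float:
    """Mutual information by direct triple-loop summation over the joint."""
    x = list(x)
    y = list(y)
    n = len(x)
    xs, ys = sorted(set(x)), sorted(set(y))
    total = 0.0
    for a in xs:
        for b in ys:
            pxy = sum(1 for xi, yi in zip(x, y) if xi == a and yi == b) / n
            if pxy == 0:
                continue
            px = sum(1 for xi in x if xi == a) / n
            py = sum(1 for yi in y if yi == b) / n
            total += pxy * math.log(pxy / (px * py), base)
    return total


def mrmr_bruteforce(codes: np.ndarray, labels, mi=mi_bruteforce) -> list[int]:
    """Greedy MIQ ranking straight from the definition.

    First pick maximizes relevance; later picks maximize
    relevance / mean-redundancy-over-selected, with +inf when the mean
    redundancy is zero (ordered by relevance) and ties to the lower index.
    """
    d = codes.shape[1]
    relevance = [mi(codes[:, j], labels) for j in range(d)]
    selected = [max(range(d), key=lambda j: (relevance[j], -j))]
    while len(selected) < d:
        best, best_key = None, None
        for a in range(d):
            if a in selected:
                continue
            mean_red = sum(mi(codes[:, a], codes[:, b]) for b in selected) / len(selected)
            key = (1, relevance[a], -a) if mean_red == 0 else (0, relevance[a] / mean_red, -a)
            if best_key is None or key > best_key:
                best, best_key = a, key
        selected.append(best)
    return selected


def sfs_bruteforce(dataset, reps, n_steps: int | None = None) -> tuple[list[int], list[float]]:
    """Greedy forward selection re-evaluating every candidate at every step."""
    n = dataset.n_channels
    n_steps = n if n_steps is None else n_steps
    order: list[int] = []
    path: list[float] = []
    for _ in range(n_steps):
        candidates = [b for b in range(n) if b not in order]
        errs = [loocv_error(dataset, order + [b], reps=reps) for b in candidates]
        best = min(range(len(candidates)), key=lambda i: (errs[i], candidates[i]))
        order.append(candidates[best])
        path.append(errs[best])
    return order, path


def global_max_bruteforce(ranking, dataset, reps) -> list[int]:
    """Prefix sweep straight from the definition: max accuracy, smallest k."""
    accs = [
        loocv_accuracy(dataset, list(ranking[:k]), reps=reps).mean
        for k in range(1, len(ranking) + 1)
    ]
    best_k = max(range(len(accs)), key=lambda i: (accs[i], -i)) + 1
    return list(ranking[:best_k])


def exhaustive_best_subsets(dataset, reps) -> tuple[float, set[frozenset]]:
    """Optimum LOOCV error over every nonempty channel subset."""
    n = dataset.n_channels
    best_err, best_sets = 2.0, set()
    for r in range(1, n + 1):
        for combo in itertools.combinations(range(n), r):
            err = loocv_error(dataset, list(combo), reps=reps)
            if err < best_err - 1e-12:
                best_err, best_sets = err, {frozenset(combo)}
            elif abs(err - best_err) <= 1e-12:
                best_sets.add(frozenset(combo))
    return best_err, best_sets


def binom_two_sided_p(h: int, n: int) -> float:
    """Exact two-sided binomial p-value at p0 = 0.5 by tail symmetry."""
    tail = min(h, n - h)
    p = sum(math.comb(n, k) for k in range(0, tail + 1)) / 2**n
    if h * 2 == n:
        return 1.0
    return min(1.0, 2 * p)


def sign_flip_p(diff: np.ndarray) -> float:
    """Exhaustive sign-flip approximation to the paired t-test p-value."""
    diff = np.asarray(diff, dtype=float)
    n = len(diff)
    t_obs = abs(np.mean(diff) / (np.std(diff, ddof=1) / math.sqrt(n)))
    count = 0
    total = 2**n
    for signs in itertools.product((1, -1), repeat=n):
        d = diff * signs
        sd = np.std(d, ddof=1)
        if sd == 0:
            t = math.inf if np.mean(d) != 0 else 0.0
        else:
            t = abs(np.mean(d) / (sd / math.sqrt(n)))
        if t >= t_obs - 1e-12:
            count += 1
    return count / total
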