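"""Wrapper channel selection: sequential forward selection and a GA.

Both wrappers use the same objective the study prescribes: the
leave-one-repetition-out LDA misclassification error computed over the
*training* repetitions only (the held-out evaluation repetition never
enters the selection objective).

SFS grows a subset greedily, one channel per iteration, and can stop
either on the relative-iterative-improvement (RII) rule or run to a full
ranking for a later global-maximum sweep.  The GA searches channel-subset
space with a real-coded genome: the study names *arithmetic crossover*
and *uniform mutation*, which are real-vector operators — a plain
bitstring genome cannot support arithmetic crossover — so each gene lives
in [0, 1] and a channel is included iff its gene exceeds 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .classification import loocv_error
from .dataio import ChannelSubset, FMGDataset

#: Machine epsilon the RII threshold formula is stated with.
EPS = 2.2204e-16


@dataclass(frozen=True)
class SFSTrace:
    """Record of one SFS run.

    ``order`` lists channels in order of addition; ``criterion_path[i]``
    is the training-repetition LOOCV error after adding ``order[i]``;
    ``stopped_at`` is ``len(order)`` when the RII rule halted the run,
    ``None`` for a full ranking.
    """

    order: tuple[int, ...]
    criterion_path: tuple[float, ...]
    stopped_at: int | None
    training_reps: tuple[int, ...]

    def subset(self) -> ChannelSubset:
        return ChannelSubset(
            indices=self.order,
            method="sfs",
            training_reps=self.training_reps,
            rank_scores=self.criterion_path,
        )


def rii_threshold(old_crit: float, tol_fun: float = 1e-6, quadratic: bool = False) -> float:
    """Relative-iterative-improvement stopping threshold.

    ``threshold = (|old_crit| + sqrt(eps)) * tol_fun`` with
    ``eps = 2.2204e-16``; the iteration stops when the improvement
    ``old_crit - new_crit`` is strictly below the threshold.  The
    ``quadratic`` flag multiplies by a leading ``old_crit`` factor — an
    alternative literal reading of the published formula, off by default.
    """
    if not np.isfinite(old_crit):
        raise ValueError("old_crit must be finite")
    thr = (abs(old_crit) + np.sqrt(EPS)) * tol_fun
    return old_crit * thr if quadratic else thr


def sfs_run(
    dataset: FMGDataset,
    reps: Sequence[int],
    stop: str = "rii",
    tol_fun: float = 1e-6,
    quadratic_threshold: bool = False,
    reg: float = 1e-6,
) -> SFSTrace:
    """Sequential forward selection with LDA-LOOCV error as the objective.

    At each iteration every remaining channel ``b`` is evaluated by the
    leave-one-repetition-out error of ``selected + [b]`` over ``reps``;
    the argmin is added (equivalently, accuracy is maximized).  Ties break
    to the lowest channel index.  ``stop="rii"`` halts when the best
    addition improves the criterion by less than :func:`rii_threshold`
    (the non-improving channel is not added); ``stop="full_ranking"``
    orders all channels.  Deterministic.
    """
    if stop not in ("rii", "full_ranking"):
        raise ValueError(f"unknown stopping rule {stop!r}")
    reps = tuple(int(r) for r in reps)
    n = dataset.n_channels
    selected: list[int] = []
    path: list[float] = []
    remaining = list(range(n))
    old_crit = 1.0  # worst-case error of the empty subset
    stopped_at: int | None = None

    while remaining:
        best_b, best_err = None, None
        for b in remaining:
            err = loocv_error(dataset, selected + [b], reps=reps, reg=reg)
            if best_err is None or err < best_err:  # strict < keeps lowest index on ties
                best_b, best_err = b, err
        if stop == "rii":
            if old_crit - best_err < rii_threshold(old_crit, tol_fun, quadratic_threshold):
                stopped_at = len(selected)
                break
        selected.append(best_b)
        path.append(best_err)
        remaining.remove(best_b)
        old_crit = best_err

    return SFSTrace(
        order=tuple(selected),
        criterion_path=tuple(path),
        stopped_at=stopped_at,
        training_reps=reps,
    )


@dataclass(frozen=True)
class GAConfig:
    """Genetic-algorithm settings.

    Operators follow the study's setup: random initial population,
    tournament selection, arithmetic crossover, uniform mutation, an
    elite count of 2, and the function-tolerance-over-stall-generations
    stopping rule (tolerance 1e-6 over 50 generations).  Population size
    and the per-gene mutation rate are not prescribed by the study; the
    defaults (50; 1/n_channels) are this package's, both configurable.
    A hard ``max_generations`` cap backs the stall rule so termination is
    guaranteed.
    """

    population_size: int = 50
    elite_count: int = 2
    tournament_size: int = 4
    mutation_rate: float | None = None  # None -> 1 / n_channels
    stall_generations: int = 50
    function_tolerance: float = 1e-6
    max_generations: int = 200
    n_restarts: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.elite_count >= self.population_size:
            raise ValueError("elite_count must be smaller than population_size")
        if self.function_tolerance <= 0:
            raise ValueError("function_tolerance must be positive")
        if self.tournament_size < 1 or self.population_size < 2:
            raise ValueError("invalid tournament or population size")
        if self.mutation_rate is not None and not (0 <= self.mutation_rate <= 1):
            raise ValueError("mutation_rate must lie in [0, 1]")
        if self.stall_generations < 1 or self.max_generations < 1:
            raise ValueError("generation counts must be positive")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be positive")


def _decode(genome: np.ndarray) -> tuple[int, ...]:
    return tuple(int(i) for i in np.flatnonzero(genome > 0.5))


def ga_select(
    dataset: FMGDataset,
    reps: Sequence[int],
    config: GAConfig | None = None,
    reg: float = 1e-6,
    rng: np.random.Generator | None = None,
) -> tuple[ChannelSubset, list[float]]:
    """One seeded GA run minimizing the training-repetition LOOCV error.

    Genome: real vector in [0,1]^n_channels, channel included iff its
    gene > 0.5; an empty decode scores the worst possible fitness (error
    1.0) so the search stays total.  Returns the best subset found and
    the per-generation best-fitness history (non-increasing, by elitism).
    Fitness values are memoized per decoded subset, so duplicated genomes
    cost no extra classifier fits.
    """
    cfg = config or GAConfig()
    reps = tuple(int(r) for r in reps)
    n = dataset.n_channels
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    mut_rate = cfg.mutation_rate if cfg.mutation_rate is not None else 1.0 / n

    cache: dict[tuple[int, ...], float] = {}

    def fitness(genome: np.ndarray) -> float:
        subset = _decode(genome)
        if not subset:
            return 1.0
        if subset not in cache:
            cache[subset] = loocv_error(dataset, subset, reps=reps, reg=reg)
        return cache[subset]

    pop = rng.uniform(size=(cfg.population_size, n))
    fits = np.array([fitness(g) for g in pop])
    history: list[float] = []
    best_genome = pop[int(np.argmin(fits))].copy()
    best_fit = float(fits.min())

    for _ in range(cfg.max_generations):
        order = np.argsort(fits, kind="stable")
        elites = pop[order[: cfg.elite_count]].copy()

        def tournament() -> np.ndarray:
            idx = rng.integers(0, cfg.population_size, size=cfg.tournament_size)
            return pop[idx[np.argmin(fits[idx])]]

        children = [*elites]
        while len(children) < cfg.population_size:
            p1, p2 = tournament(), tournament()
            lam = rng.uniform()
            child = lam * p1 + (1.0 - lam) * p2
            mask = rng.uniform(size=n) < mut_rate
            child = np.where(mask, rng.uniform(size=n), child)
            children.append(child)
        pop = np.asarray(children)
        fits = np.array([fitness(g) for g in pop])

        gen_best = int(np.argmin(fits))
        if fits[gen_best] < best_fit:
            best_fit = float(fits[gen_best])
            best_genome = pop[gen_best].copy()
        history.append(best_fit)

        if len(history) > cfg.stall_generations:
            window = history[-cfg.stall_generations - 1 :]
            if (window[0] - window[-1]) / cfg.stall_generations < cfg.function_tolerance:
                break

    subset = ChannelSubset(
        indices=_decode(best_genome),
        method="ga",
        training_reps=reps,
    )
    return subset, history


@dataclass(frozen=True)
class GARepeatSummary:
    """Aggregate of repeated GA runs (the study reports means over 10)."""

    subsets: tuple[ChannelSubset, ...]
    fitnesses: tuple[float, ...]
    sizes: tuple[int, ...]

    @property
    def mean_size(self) -> float:
        return float(np.mean(self.sizes))

    @property
    def sd_size(self) -> float:
        return float(np.std(self.sizes, ddof=1)) if len(self.sizes) > 1 else 0.0

    def format_size(self) -> str:
        """``"m ± s"`` subset-size summary, e.g. ``"11.6 ± 1.3"``."""
        return f"{self.mean_size:.1f} ± {self.sd_size:.1f}"


def ga_repeat(
    dataset: FMGDataset,
    reps: Sequence[int],
    config: GAConfig | None = None,
    reg: float = 1e-6,
) -> GARepeatSummary:
    """Run the GA ``n_restarts`` times with derived seeds and aggregate.

    The GA is stochastic, so the study repeats it (10 times) and reports
    averages; restart seeds are spawned deterministically from
    ``config.seed``.
    """
    cfg = config or GAConfig()
    children = np.random.SeedSequence(cfg.seed).spawn(cfg.n_restarts)
    subsets, fitnesses = [], []
    for ss in children:
        subset, history = ga_select(dataset, reps, cfg, reg=reg, rng=np.random.default_rng(ss))
        subsets.append(subset)
        fitnesses.append(history[-1] if history else 1.0)
    return GARepeatSummary(
        subsets=tuple(subsets),
        fitnesses=tuple(fitnesses),
        sizes=tuple(len(s) for s in subsets),
    )
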