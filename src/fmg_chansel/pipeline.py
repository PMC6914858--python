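"""The channel-selection evaluation protocol.

For every held-out protocol repetition, a selection method picks a channel
subset using the remaining training repetitions only (wrapper objectives
use leave-one-repetition-out CV *within* those training repetitions).  The
five per-fold subsets are then intersected: only channels selected in
every fold make the final subset.  Reported accuracy is the
leave-one-repetition-out accuracy over all five repetitions restricted to
the final subset, compared against the all-channel baseline with a paired
t-test.  Note the protocol's deliberate optimism: the final accuracy is
computed over repetitions that also served in selection — this mirrors
the study design and is documented rather than "fixed".

Also here: the subset-stability experiment (how much the selection churns
as training data shrink), the half-data sensitivity analysis, and
JSON/Markdown report generation.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .classification import CVResult, loocv_accuracy, paired_t_test
from .dataio import GESTURES, ChannelSubset, FMGDataset
from .embedded_selection import boruta_run
from .filter_selection import mrmr_rank
from .wrapper_selection import GAConfig, ga_select, sfs_run

METHODS = ("sfs-rii", "sfs-globalmax", "mrmr", "ga", "boruta")


@dataclass(frozen=True)
class MethodConfig:
    """Knobs for one benchmark run, covering every selection method.

    ``fallback_k``: if the cross-fold intersection comes out empty the
    run normally fails with a diagnostic; with ``fallback_k = N`` the
    final subset instead keeps channels selected in at least N of the
    folds.
    """

    ga: GAConfig = field(default_factory=GAConfig)
    boruta_trees: int = 500
    boruta_max_runs: int = 100
    boruta_alpha: float = 0.01
    boruta_importance: str = "permutation"
    boruta_include_tentative: bool = False
    mrmr_scheme: str = "mean_sigma3"
    reg: float = 1e-6
    fallback_k: int | None = None
    seed: int = 0


class EmptyIntersectionError(RuntimeError):
    """No channel was selected in every fold; see ``fallback_k``."""


@dataclass(frozen=True)
class SelectionResult:
    """Everything the protocol measures for one method on one dataset."""

    method: str
    fold_subsets: tuple[ChannelSubset, ...]
    final_subset: ChannelSubset
    cv: CVResult
    baseline_cv: CVResult
    reduction_pct: float
    runtime_seconds: float
    t_test: tuple[float, float, bool, bool]
    size_summary: tuple[float, float] | None = None  # GA: (mean, sd) over restarts

    def __post_init__(self) -> None:
        final = self.final_subset.as_set()
        for fs in self.fold_subsets:
            if not final <= fs.as_set():
                raise ValueError("final subset must be contained in every fold subset")

    def size_display(self) -> str:
        """Subset count as printed in reports: integer, or ``m ± s`` for GA."""
        if self.size_summary is not None:
            m, s = self.size_summary
            return f"{m:.1f} ± {s:.1f}"
        return str(len(self.final_subset))

    def to_dict(self) -> dict:
        t, p, reject, degenerate = self.t_test
        return {
            "method": self.method,
            "fold_subsets": [list(s.indices) for s in self.fold_subsets],
            "final_subset": list(self.final_subset.indices),
            "n_selected": len(self.final_subset),
            "size_summary": list(self.size_summary) if self.size_summary else None,
            "reduction_pct": self.reduction_pct,
            "cv": self.cv.to_dict(),
            "baseline_cv": self.baseline_cv.to_dict(),
            "worst_gesture": self.cv.worst_gesture(),
            "t_test": {"t": t, "p": p, "reject": reject, "degenerate": degenerate},
            "runtime_seconds": self.runtime_seconds,
        }


@dataclass(frozen=True)
class StabilityResult:
    """Subset turnover as training repetitions shrink (4 → 3 → 2 reps)."""

    method: str
    training_sets: tuple[tuple[int, ...], ...]
    subsets: tuple[ChannelSubset, ...]
    variations: tuple[float, ...]
    average_variation: float

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "training_sets": [list(t) for t in self.training_sets],
            "subsets": [list(s.indices) for s in self.subsets],
            "subset_sizes": [len(s) for s in self.subsets],
            "variations_pct": list(self.variations),
            "average_variation_pct": self.average_variation,
        }


def reduction_pct(n_total: int, n_selected: float) -> float:
    """Percentage decrease in input channels, to one decimal.

    Accepts fractional ``n_selected`` (GA subset counts are means over
    restarts).
    """
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not (0 <= n_selected <= n_total):
        raise ValueError(f"n_selected must lie in [0, {n_total}], got {n_selected}")
    return round(100.0 * (n_total - n_selected) / n_total, 1)


def variation_pct(subset_a: ChannelSubset | Sequence[int], subset_b: ChannelSubset | Sequence[int]) -> float:
    """Subset turnover: ``100 * (|A| - |A ∩ B|) / |A|``.

    ``A`` is the subset from the larger training set, so the statistic
    measures how much of the better-informed selection survives when
    training data shrink.  Identical subsets give 0, disjoint ones 100.
    """
    a = set(subset_a.indices if isinstance(subset_a, ChannelSubset) else subset_a)
    b = set(subset_b.indices if isinstance(subset_b, ChannelSubset) else subset_b)
    if not a:
        raise ValueError("reference subset A must be nonempty")
    return 100.0 * (len(a) - len(a & b)) / len(a)


def global_max_subset(
    ranking: Sequence[int],
    dataset: FMGDataset,
    reps: Sequence[int],
    method: str = "",
    reg: float = 1e-6,
) -> ChannelSubset:
    """Global-maximum stopping rule over a full channel ranking.

    Evaluates the leave-one-repetition-out accuracy (over ``reps``) of
    every ranking prefix of size 1..n and keeps the accuracy-maximizing
    prefix; ties go to the smallest prefix.
    """
    ranking = [int(c) for c in ranking]
    best_k, best_acc = 1, -1.0
    for k in range(1, len(ranking) + 1):
        acc = loocv_accuracy(dataset, ranking[:k], reps=reps, reg=reg).mean
        if acc > best_acc:  # strict > keeps the smallest prefix on ties
            best_k, best_acc = k, acc
    return ChannelSubset(
        indices=tuple(ranking[:best_k]),
        method=method,
        training_reps=tuple(int(r) for r in reps),
    )


def _derived_seed(master: int, *salt: int) -> int:
    return int(np.random.SeedSequence([int(master), *map(int, salt)]).generate_state(1)[0] % (2**31))


def _select_one_fold(
    dataset: FMGDataset,
    method: str,
    train_reps: Sequence[int],
    config: MethodConfig,
    fold: int,
) -> ChannelSubset:
    """Method-specific selection on one training-repetition set."""
    reps = tuple(int(r) for r in train_reps)
    if method == "sfs-rii":
        trace = sfs_run(dataset, reps, stop="rii", reg=config.reg)
        return replace(trace.subset(), method=method)
    if method == "sfs-globalmax":
        trace = sfs_run(dataset, reps, stop="full_ranking", reg=config.reg)
        return global_max_subset(trace.order, dataset, reps, method=method, reg=config.reg)
    if method == "mrmr":
        state = mrmr_rank(dataset, reps, scheme=config.mrmr_scheme)
        return global_max_subset(state.selected, dataset, reps, method=method, reg=config.reg)
    if method == "ga":
        ga_cfg = replace(config.ga, seed=_derived_seed(config.ga.seed, fold))
        subset, _ = ga_select(dataset, reps, ga_cfg, reg=config.reg)
        return subset
    if method == "boruta":
        result = boruta_run(
            dataset,
            reps,
            n_trees=config.boruta_trees,
            max_runs=config.boruta_max_runs,
            alpha=config.boruta_alpha,
            importance=config.boruta_importance,
            seed=_derived_seed(config.seed, 1000 + fold),
        )
        return global_max_subset(result.final_ranking, dataset, reps, method=method, reg=config.reg)
    raise ValueError(f"unknown method {method!r}; choose from {METHODS}")


def _intersect_folds(
    fold_subsets: Sequence[ChannelSubset],
    method: str,
    fallback_k: int | None,
) -> ChannelSubset:
    counts: dict[int, int] = {}
    for fs in fold_subsets:
        for c in fs.indices:
            counts[c] = counts.get(c, 0) + 1
    final = sorted(c for c, k in counts.items() if k == len(fold_subsets))
    if not final:
        if fallback_k is None:
            raise EmptyIntersectionError(
                f"{method}: no channel was selected in all {len(fold_subsets)} folds; "
                "re-run with fallback_k=N to keep channels selected in >= N folds"
            )
        final = sorted(c for c, k in counts.items() if k >= fallback_k)
        if not final:
            raise EmptyIntersectionError(
                f"{method}: no channel reaches fallback threshold {fallback_k}"
            )
    return ChannelSubset(indices=tuple(final), method=method)


def run_method(
    dataset: FMGDataset,
    method: str,
    config: MethodConfig | None = None,
    ga_restarts: int | None = None,
) -> SelectionResult:
    """Run one method through the full cross-fold selection protocol.

    For each held-out repetition the method selects on the remaining
    repetitions; the per-fold subsets are intersected into the final
    subset, whose leave-one-repetition-out accuracy over *all*
    repetitions is compared to the all-channel baseline with a paired
    t-test.  Runtime covers the selection phase only.

    The GA is stochastic, so its subset-size report is aggregated over
    ``ga_restarts`` full selection passes (default ``config.ga.n_restarts``);
    accuracy and the final subset come from the first pass.
    """
    cfg = config or MethodConfig()
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    rep_ids = dataset.repetition_ids
    if len(rep_ids) < 2:
        raise ValueError("protocol needs at least two repetitions")

    n_passes = 1
    if method == "ga":
        n_passes = ga_restarts if ga_restarts is not None else cfg.ga.n_restarts

    t0 = time.perf_counter()
    pass_folds: list[list[ChannelSubset]] = []
    for p in range(n_passes):
        pass_cfg = cfg if p == 0 else replace(cfg, ga=replace(cfg.ga, seed=_derived_seed(cfg.ga.seed, 7000 + p)))
        folds = [
            _select_one_fold(dataset, method, [r for r in rep_ids if r != held], pass_cfg, fold)
            for fold, held in enumerate(rep_ids)
        ]
        pass_folds.append(folds)
    runtime = time.perf_counter() - t0

    fold_subsets = tuple(pass_folds[0])
    final = _intersect_folds(fold_subsets, method, cfg.fallback_k)

    size_summary = None
    if method == "ga" and n_passes > 1:
        sizes = [len(_intersect_folds(folds, method, cfg.fallback_k)) for folds in pass_folds]
        size_summary = (float(np.mean(sizes)), float(np.std(sizes, ddof=1)))

    cv = loocv_accuracy(dataset, final, reg=cfg.reg)
    baseline = ChannelSubset(indices=tuple(range(dataset.n_channels)), method="baseline")
    baseline_cv = loocv_accuracy(dataset, baseline, reg=cfg.reg)
    t_test = paired_t_test(cv.fold_accuracies, baseline_cv.fold_accuracies)

    return SelectionResult(
        method=method,
        fold_subsets=fold_subsets,
        final_subset=final,
        cv=cv,
        baseline_cv=baseline_cv,
        reduction_pct=reduction_pct(dataset.n_channels, len(final)),
        runtime_seconds=runtime,
        t_test=t_test,
        size_summary=size_summary,
    )


def stability_experiment(
    dataset: FMGDataset,
    method: str,
    config: MethodConfig | None = None,
) -> StabilityResult:
    """Subset stability as training data shrink from 4 to 3 to 2 repetitions.

    Selection runs on the first four, first three, and first two
    repetitions (the last repetition is reserved as test data throughout);
    consecutive subsets are compared with :func:`variation_pct`, taking
    the larger training set's subset as the reference.
    """
    cfg = config or MethodConfig()
    rep_ids = dataset.repetition_ids
    if len(rep_ids) < 5:
        raise ValueError("stability experiment needs at least five repetitions")
    training_sets = (tuple(rep_ids[:4]), tuple(rep_ids[:3]), tuple(rep_ids[:2]))
    subsets = tuple(
        _select_one_fold(dataset, method, reps, cfg, fold=100 + i)
        for i, reps in enumerate(training_sets)
    )
    variations = tuple(
        variation_pct(subsets[i], subsets[i + 1]) for i in range(len(subsets) - 1)
    )
    return StabilityResult(
        method=method,
        training_sets=training_sets,
        subsets=subsets,
        variations=variations,
        average_variation=float(np.mean(variations)),
    )


def halve_repetitions(dataset: FMGDataset) -> FMGDataset:
    """Keep the first half of every gesture hold within every repetition.

    Halving is applied per (repetition, gesture) block so that every
    repetition still contains every gesture; block sample counts halve
    (floor, minimum 1).
    """
    keep = np.zeros(dataset.n_samples, dtype=bool)
    rep = dataset.repetition
    gest = dataset.gesture.astype(str)
    for r in dataset.repetition_ids:
        for g in GESTURES:
            idx = np.flatnonzero((rep == r) & (gest == g))
            keep[idx[: max(1, len(idx) // 2)]] = True
    return dataset.select_rows(keep)


def half_data_analysis(
    dataset: FMGDataset,
    selection_results: Sequence[SelectionResult],
    reg: float = 1e-6,
) -> list[dict]:
    """Re-score previously selected subsets on half-size repetitions.

    No re-selection happens: each method's final subset is evaluated by
    leave-one-repetition-out accuracy on the dataset truncated to the
    first half of every gesture hold.  One output row per method with
    mean ± sd accuracy.
    """
    half = halve_repetitions(dataset)
    rows = []
    for res in selection_results:
        cv = loocv_accuracy(half, res.final_subset, reg=reg)
        rows.append(
            {
                "method": res.method,
                "mean_accuracy": cv.mean,
                "sd_accuracy": cv.sd,
                "fold_accuracies": list(cv.fold_accuracies),
            }
        )
    return rows


@dataclass(frozen=True)
class BenchmarkReport:
    """All protocol outputs for one dataset, serializable to JSON/Markdown."""

    dataset_name: str
    n_channels: int
    protocol: str
    methods: tuple[str, ...]
    results: Mapping[str, SelectionResult]
    stability: Mapping[str, StabilityResult]
    half_data: list[dict]
    errors: Mapping[str, str]

    def to_dict(self, include_runtimes: bool = True) -> dict:
        out = {
            "dataset": self.dataset_name,
            "n_channels": self.n_channels,
            "protocol": self.protocol,
            "methods": list(self.methods),
            "results": {m: r.to_dict() for m, r in self.results.items()},
            "stability": {m: s.to_dict() for m, s in self.stability.items()},
            "half_data": self.half_data,
            "errors": dict(self.errors),
        }
        if not include_runtimes:
            for r in out["results"].values():
                r.pop("runtime_seconds", None)
        return out

    def to_json(self, include_runtimes: bool = True) -> str:
        return json.dumps(self.to_dict(include_runtimes=include_runtimes), indent=2, sort_keys=True)

    def to_markdown(self) -> str:
        """Human-readable report mirroring the study's table layouts."""
        lines = [
            f"# Channel-selection benchmark: {self.dataset_name}",
            "",
            f"{self.n_channels} channels, {self.protocol} protocol.",
            "",
        ]
        ms = [m for m in self.methods if m in self.results]
        header = "| | " + " | ".join(ms) + " |"
        rule = "|---" * (len(ms) + 1) + "|"

        lines += ["## Selected channel counts", "", header, rule]
        lines.append("| n selected | " + " | ".join(self.results[m].size_display() for m in ms) + " |")
        lines += ["", "## Hardest gesture (lowest recall)", "", header, rule]
        lines.append("| gesture | " + " | ".join(self.results[m].cv.worst_gesture() for m in ms) + " |")
        lines += ["", "## Channel reduction (%)", "", header, rule]
        lines.append("| reduction | " + " | ".join(f"{self.results[m].reduction_pct:.1f}" for m in ms) + " |")
        lines += ["", "## Selection runtime (s)", "", header, rule]
        lines.append("| runtime | " + " | ".join(f"{self.results[m].runtime_seconds:.1f}" for m in ms) + " |")
        lines += ["", "## Accuracy (mean ± sd over folds)", "", header, rule]
        lines.append(
            "| full data | "
            + " | ".join(f"{100 * self.results[m].cv.mean:.1f} ± {100 * self.results[m].cv.sd:.1f}" for m in ms)
            + " |"
        )
        half = {row["method"]: row for row in self.half_data}
        if half:
            lines.append(
                "| half data | "
                + " | ".join(
                    f"{100 * half[m]['mean_accuracy']:.1f} ± {100 * half[m]['sd_accuracy']:.1f}"
                    if m in half
                    else "—"
                    for m in ms
                )
                + " |"
            )
        if self.stability:
            lines += ["", "## Stability (average subset variation %)", "", header, rule]
            lines.append(
                "| variation | "
                + " | ".join(
                    f"{self.stability[m].average_variation:.1f}" if m in self.stability else "—"
                    for m in ms
                )
                + " |"
            )
        if self.results:
            any_res = next(iter(self.results.values()))
            lines += [
                "",
                f"Baseline (all channels): {100 * any_res.baseline_cv.mean:.1f} ± "
                f"{100 * any_res.baseline_cv.sd:.1f} %",
            ]
        if self.errors:
            lines += ["", "## Failed methods", ""]
            lines += [f"- {m}: {msg}" for m, msg in self.errors.items()]
        return "\n".join(lines) + "\n"


def run_benchmark(
    dataset: FMGDataset,
    methods: Sequence[str] = METHODS,
    config: MethodConfig | None = None,
    dataset_name: str = "dataset",
    with_stability: bool = True,
    with_half_data: bool = True,
) -> BenchmarkReport:
    """Execute the full protocol for every requested method.

    A method failure (e.g. an empty cross-fold intersection without a
    fallback) is recorded in the report's ``errors`` section and does not
    abort the other methods.
    """
    cfg = config or MethodConfig()
    results: dict[str, SelectionResult] = {}
    stability: dict[str, StabilityResult] = {}
    errors: dict[str, str] = {}
    for m in methods:
        try:
            results[m] = run_method(dataset, m, cfg)
            if with_stability:
                stability[m] = stability_experiment(dataset, m, cfg)
        except Exception as exc:  # noqa: BLE001 - failures are reported, not fatal
            errors[m] = str(exc)
    half = half_data_analysis(dataset, list(results.values()), reg=cfg.reg) if with_half_data else []
    return BenchmarkReport(
        dataset_name=dataset_name,
        n_channels=dataset.n_channels,
        protocol=dataset.protocol,
        methods=tuple(methods),
        results=results,
        stability=stability,
        half_data=half,
        errors=errors,
    )
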