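"""Success-rate-driven feature-panel optimisation.

Three wrapper algorithms reduce a ranked discovery list to a compact
classifying panel, all scored by leave-one-out KNN success rate (SR, in
percent) on the training cohort and driven by the increment dSR = SR_new -
SR_previous observed when one feature joins the working panel:

* **Greedy accumulation** — walk down the ranked list starting from the top
  two features; a feature whose addition yields dSR < 0 is permanently
  eliminated, all others are retained.  The accepted-SR trace is
  non-decreasing by construction.
* **Random two-point crossover** — partition the list into fixed-size
  subsets; within each subset score members sequentially by dSR (negative
  members are excluded from subsequent within-subset cross-validations but
  keep their position); evolve by exchanging random two-point segments
  between adjacent subsets; after the final generation take the top ``m``
  features by dSR across the whole population.
* **Fittest-member crossover** — identical except each subset replaces its
  ``q`` weakest members (lowest dSR) with the ``q`` globally best members
  drawn from other subsets (which keep their own copies).

All randomness flows from an explicit seed; ties in every ranking are broken
by (statistic, original discovery rank, probe id), so runs are reproducible
bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import ExpressionDataset
from .knn import loocv_from_distances


@dataclass(frozen=True)
class OptStep:
    probe_id: str
    sr_before: float
    sr_after: float
    delta_sr: float
    accepted: bool


@dataclass
class GenerationRecord:
    generation: int
    subsets: list[list[str]]
    subset_srs: list[float]
    recorded: list[bool]  # subset reached the best SR seen so far


@dataclass
class OptimisationTrace:
    steps: list[OptStep] = field(default_factory=list)
    generations: list[GenerationRecord] = field(default_factory=list)

    def accepted_sr_sequence(self) -> list[float]:
        return [s.sr_after for s in self.steps if s.accepted]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([s.__dict__ for s in self.steps])


@dataclass
class OptimisationResult:
    """Outcome of one optimiser run: the panel, its LOOCV SR, diagnostics."""

    features: list[str]
    sr: float
    trace: OptimisationTrace
    delta_sr: dict[str, float] = field(default_factory=dict)
    truncated: bool = False  # fewer evaluated probes than requested panel size

    def summary(self) -> str:
        lines = [
            f"Optimised panel: {len(self.features)} features, LOOCV SR {self.sr:.1f}%",
            f"  steps evaluated: {len(self.trace.steps)}",
            f"  generations:     {len(self.trace.generations)}",
        ]
        return "\n".join(lines)


class _PanelScorer:
    """Incremental LOOCV scorer over growing/shrinking feature panels.

    Caches each feature's pairwise squared-difference matrix so adding or
    removing one feature from the working panel is an O(n^2) update instead
    of a fresh distance computation.
    """

    def __init__(self, data: ExpressionDataset, k: int = 3):
        self.data = data
        self.k = k
        self.labels = data.labels.to_numpy()
        self.sample_ids = data.sample_ids
        self._cache: dict[str, np.ndarray] = {}
        counts = data.class_counts()
        # chance-level SR: always predicting the majority class
        self.baseline_sr = 100.0 * max(counts.values()) / data.n_samples

    def feature_d2(self, probe: str) -> np.ndarray:
        d2 = self._cache.get(probe)
        if d2 is None:
            x = self.data.values.loc[probe].to_numpy()
            d2 = (x[:, None] - x[None, :]) ** 2
            self._cache[probe] = d2
        return d2

    def panel_d2(self, features: list[str]) -> np.ndarray:
        n = self.data.n_samples
        d2 = np.zeros((n, n))
        for f in features:
            d2 += self.feature_d2(f)
        return d2

    def sr_of(self, d2: np.ndarray) -> float:
        return loocv_from_distances(d2, self.labels, self.sample_ids, k=self.k).sr

    def panel_sr(self, features: list[str]) -> float:
        return self.sr_of(self.panel_d2(features))


def _usable(features, data: ExpressionDataset) -> list[str]:
    if isinstance(features, pd.DataFrame):
        features = features["probe_id"].tolist()
    index = set(data.values.index)
    return [f for f in features if f in index]


# ---------------------------------------------------------------------------
# Optimisation 1: greedy accumulation down the ranked list

def optimise_greedy(ranked, data: ExpressionDataset, k: int = 3) -> OptimisationResult:
    """Greedy dSR walk: keep every feature that does not hurt the LOOCV SR.

    The panel starts as the top two ranked features (never eliminated, no
    dSR defined for them); each further feature is added once, its dSR
    recorded, and eliminated permanently when dSR < 0 (dSR = 0 retains).
    """
    features = _usable(ranked, data)
    if len(features) < 2:
        raise ValueError("greedy optimisation needs >= 2 usable ranked features")
    scorer = _PanelScorer(data, k=k)
    retained = features[:2]
    d2 = scorer.panel_d2(retained)
    sr_prev = scorer.sr_of(d2)
    trace = OptimisationTrace()
    delta: dict[str, float] = {}
    for probe in features[2:]:
        cand = d2 + scorer.feature_d2(probe)
        sr_new = scorer.sr_of(cand)
        dsr = sr_new - sr_prev
        accept = dsr >= 0
        trace.steps.append(OptStep(probe, sr_prev, sr_new, dsr, accept))
        delta[probe] = dsr
        if accept:
            retained.append(probe)
            d2 = cand
            sr_prev = sr_new
    return OptimisationResult(features=retained, sr=sr_prev, trace=trace,
                              delta_sr=delta)


# ---------------------------------------------------------------------------
# subset machinery shared by the evolutionary optimisers

@dataclass
class AnnotatedSubset:
    """A fixed-size subset with per-member dSR and elimination marks.

    Eliminated members are excluded from the working cross-validations but
    keep their place in the subset for the crossover step.
    """

    members: list[str]
    delta_sr: list[float]
    eliminated: list[bool]
    working_sr: float

    def annotations(self) -> list[tuple[str, float]]:
        return list(zip(self.members, self.delta_sr))


def prune_subset(subset: list[str], data: ExpressionDataset, k: int = 3,
                 scorer: _PanelScorer | None = None) -> AnnotatedSubset:
    """Sequential dSR evaluation within one subset.

    The first member's dSR is taken against the chance-level baseline (the
    majority-class success rate); each later member's against the working
    panel's SR.  Negative-dSR members are marked eliminated and excluded
    from subsequent within-subset cross-validations.
    """
    if not subset:
        raise ValueError("empty subset")
    scorer = scorer or _PanelScorer(data, k=k)
    subset = _usable(subset, data)
    n = data.n_samples
    working: list[str] = []
    d2 = np.zeros((n, n))
    sr_prev = scorer.baseline_sr
    deltas, marks = [], []
    for probe in subset:
        cand = d2 + scorer.feature_d2(probe)
        sr_new = scorer.sr_of(cand)
        dsr = sr_new - sr_prev
        deltas.append(dsr)
        if dsr < 0:
            marks.append(True)
        else:
            marks.append(False)
            working.append(probe)
            d2 = cand
            sr_prev = sr_new
    return AnnotatedSubset(members=subset, delta_sr=deltas,
                           eliminated=marks, working_sr=sr_prev)


def select_top(population: list[AnnotatedSubset], data: ExpressionDataset,
               m: int = 25, k: int = 3,
               original_rank: dict[str, int] | None = None,
               scorer: _PanelScorer | None = None) -> OptimisationResult:
    """Global dSR ranking across all subsets; joint LOOCV SR of the top m."""
    original_rank = original_rank or {}
    pool: dict[str, float] = {}
    for sub in population:
        for probe, dsr in sub.annotations():
            if probe not in pool or dsr > pool[probe]:
                pool[probe] = dsr
    ranked = sorted(pool.items(),
                    key=lambda kv: (-kv[1], original_rank.get(kv[0], 10**9), kv[0]))
    chosen = [p for p, _ in ranked[:m]]
    truncated = len(pool) < m
    scorer = scorer or _PanelScorer(data, k=k)
    sr = scorer.panel_sr(chosen)
    return OptimisationResult(features=chosen, sr=sr, trace=OptimisationTrace(),
                              delta_sr={p: pool[p] for p in chosen},
                              truncated=truncated)


def two_point_crossover(a: list[str], b: list[str], seed: int | np.random.Generator,
                        cuts: tuple[int, int] | None = None) -> tuple[list[str], list[str]]:
    """Exchange the segment between two shared cut positions.

    Cut positions are slice boundaries drawn uniformly from 0..len and
    sorted; both parents use the same positions so lengths are preserved.
    """
    if len(a) != len(b):
        raise ValueError("crossover parents must have equal lengths")
    if len(a) < 2:
        raise ValueError("crossover needs lists of length >= 2")
    if cuts is None:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        c1, c2 = sorted(rng.integers(0, len(a) + 1, size=2).tolist())
    else:
        c1, c2 = sorted(cuts)
    a2 = a[:c1] + b[c1:c2] + a[c2:]
    b2 = b[:c1] + a[c1:c2] + b[c2:]
    return a2, b2


def _partition(features: list[str], subset_size: int) -> list[list[str]]:
    return [features[i:i + subset_size] for i in range(0, len(features), subset_size)]


def _evaluate_population(subsets: list[list[str]], scorer: _PanelScorer,
                         data: ExpressionDataset, k: int) -> list[AnnotatedSubset]:
    return [prune_subset(s, data, k=k, scorer=scorer) for s in subsets]


def _record_generation(trace: OptimisationTrace, gen: int,
                       annotated: list[AnnotatedSubset], best_so_far: float) -> float:
    srs = [a.working_sr for a in annotated]
    recorded = []
    for sr in srs:
        if sr >= best_so_far:
            best_so_far = sr
            recorded.append(True)
        else:
            recorded.append(False)
    trace.generations.append(GenerationRecord(
        generation=gen, subsets=[list(a.members) for a in annotated],
        subset_srs=srs, recorded=recorded))
    return best_so_far


def optimise_random_crossover(ranked, data: ExpressionDataset, subset_size: int = 53,
                              n_generations: int = 5, m: int = 25, k: int = 3,
                              seed: int = 0) -> OptimisationResult:
    """Evolve fixed-size subsets by random two-point crossover of adjacent pairs."""
    features = _usable(ranked, data)
    if subset_size < 2:
        raise ValueError("subset_size must be >= 2")
    if len(features) < subset_size:
        raise ValueError("ranked list shorter than subset_size")
    rng = np.random.default_rng(seed)
    original_rank = {p: i for i, p in enumerate(features)}
    scorer = _PanelScorer(data, k=k)
    subsets = _partition(features, subset_size)
    trace = OptimisationTrace()
    annotated = _evaluate_population(subsets, scorer, data, k)
    best = _record_generation(trace, 0, annotated, -np.inf)
    for gen in range(1, n_generations + 1):
        new_subsets = [list(s) for s in subsets]
        for i in range(0, len(subsets) - 1, 2):  # adjacent pairs; odd last sits out
            a, b = subsets[i], subsets[i + 1]
            cut_span = min(len(a), len(b))
            c1, c2 = sorted(rng.integers(0, cut_span + 1, size=2).tolist())
            new_subsets[i] = a[:c1] + b[c1:c2] + a[c2:]
            new_subsets[i + 1] = b[:c1] + a[c1:c2] + b[c2:]
        subsets = new_subsets
        annotated = _evaluate_population(subsets, scorer, data, k)
        best = _record_generation(trace, gen, annotated, best)
    result = select_top(annotated, data, m=m, k=k,
                        original_rank=original_rank, scorer=scorer)
    result.trace = trace
    return result


def optimise_fittest_crossover(ranked, data: ExpressionDataset, subset_size: int = 53,
                               n_generations: int = 5, m: int = 25, q: int = 5,
                               k: int = 3, seed: int = 0) -> OptimisationResult:
    """Evolve subsets by importing the globally fittest members.

    Each generation every subset replaces its ``q`` lowest-dSR members with
    the ``q`` highest-dSR members found in *other* subsets (donors keep
    their own copies); a member already present is skipped in favour of the
    next-best donor.  With a single subset the exchange is a no-op.
    """
    features = _usable(ranked, data)
    if subset_size < 2:
        raise ValueError("subset_size must be >= 2")
    if len(features) < subset_size:
        raise ValueError("ranked list shorter than subset_size")
    if not 1 <= q < subset_size:
        raise ValueError("q must satisfy 1 <= q < subset_size")
    original_rank = {p: i for i, p in enumerate(features)}
    scorer = _PanelScorer(data, k=k)
    subsets = _partition(features, subset_size)
    trace = OptimisationTrace()
    annotated = _evaluate_population(subsets, scorer, data, k)
    best = _record_generation(trace, 0, annotated, -np.inf)
    for gen in range(1, n_generations + 1):
        if len(subsets) > 1:
            new_subsets = []
            for i, sub in enumerate(annotated):
                donors = []
                for j, other in enumerate(annotated):
                    if j != i:
                        donors.extend(other.annotations())
                donors.sort(key=lambda kv: (-kv[1], original_rank.get(kv[0], 10**9), kv[0]))
                order = sorted(range(len(sub.members)),
                               key=lambda idx: (sub.delta_sr[idx],
                                                -original_rank.get(sub.members[idx], 0)))
                weakest = set(order[:min(q, len(sub.members))])
                kept = [mbr for idx, mbr in enumerate(sub.members) if idx not in weakest]
                present = set(kept)
                incoming = []
                for probe, _ in donors:
                    if len(incoming) == len(sub.members) - len(kept):
                        break
                    if probe not in present:
                        incoming.append(probe)
                        present.add(probe)
                new_subsets.append(kept + incoming)
            subsets = new_subsets
        annotated = _evaluate_population(subsets, scorer, data, k)
        best = _record_generation(trace, gen, annotated, best)
    result = select_top(annotated, data, m=m, k=k,
                        original_rank=original_rank, scorer=scorer)
    result.trace = trace
    return result


# ---------------------------------------------------------------------------
# estimator-style front ends

class GreedyPanelOptimizer:
    """Object front end for :func:`optimise_greedy`."""

    def __init__(self, ranked, data: ExpressionDataset, k: int = 3):
        self.ranked, self.data, self.k = ranked, data, k

    def fit(self) -> OptimisationResult:
        return optimise_greedy(self.ranked, self.data, k=self.k)


class RandomCrossoverOptimizer:
    def __init__(self, ranked, data: ExpressionDataset, subset_size: int = 53,
                 n_generations: int = 5, m: int = 25, k: int = 3, seed: int = 0):
        self.args = dict(subset_size=subset_size, n_generations=n_generations,
                         m=m, k=k, seed=seed)
        self.ranked, self.data = ranked, data

    def fit(self) -> OptimisationResult:
        return optimise_random_crossover(self.ranked, self.data, **self.args)


class FittestCrossoverOptimizer:
    def __init__(self, ranked, data: ExpressionDataset, subset_size: int = 53,
                 n_generations: int = 5, m: int = 25, q: int = 5, k: int = 3,
                 seed: int = 0):
        self.args = dict(subset_size=subset_size, n_generations=n_generations,
                         m=m, q=q, k=k, seed=seed)
        self.ranked, self.data = ranked, data

    def fit(self) -> OptimisationResult:
        return optimise_fittest_crossover(self.ranked, self.data, **self.args)
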