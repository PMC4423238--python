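"""Genetic-algorithm band selection with LOOCV-LDA fitness.

Each individual (chromosome) is a set of ``k_segments`` unique segment ids,
held in canonical ascending order.  Fitness is the leave-one-spectrum-out
cross-validated LDA accuracy on the chromosome's expanded variables, so the
GA directly optimizes the diagnostic accuracy of a 30-variable model.

One generation: evaluate -> copy the top quartile over the bottom quartile
(the mating pool) -> random disjoint pairing with single-point crossover
-> per-individual mutation -> elitist reinsertion of the all-time best when
neither its chromosome nor its fitness value survives.  Runs are repeated
independently and the best chromosomes' segments are cumulatively counted;
high-count segments, merged when adjacent, define the consensus diagnostic
bands.

Fitness evaluations are memoized per dataset (keyed by the segment set), so
repeated runs over the same spectra share work.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .lda import loocv
from .spectra import SegmentIndex, SpectraSet, WavenumberGrid, expand_chromosome

Chromosome = tuple[int, ...]  # canonical: ascending, unique


def canonical(segments) -> Chromosome:
    chrom = tuple(sorted(int(s) for s in segments))
    if len(set(chrom)) != len(chrom):
        raise ValueError(f"chromosome has duplicate segments: {chrom}")
    return chrom


def validate_chromosome(chrom: Chromosome, n_segments: int, k: int) -> None:
    if len(chrom) != k:
        raise ValueError(f"chromosome length {len(chrom)} != k_segments {k}")
    if len(set(chrom)) != k:
        raise ValueError(f"duplicate segment ids in {chrom}")
    if any(not 0 <= s < n_segments for s in chrom):
        raise ValueError(f"segment id out of range [0, {n_segments}) in {chrom}")


@dataclass(frozen=True)
class GAConfig:
    population_size: int = 20
    generations: int = 100
    crossover_prob: float = 0.70
    mutation_prob: float = 0.05
    copy_fraction: float = 0.25
    k_segments: int = 6
    n_runs: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("crossover_prob", "mutation_prob", "copy_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.generations < 0:
            raise ValueError("generations must be >= 0")
        if self.k_segments < 1:
            raise ValueError("k_segments must be >= 1")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if self.n_copy < 1:
            raise ValueError(
                "copy_fraction * population_size must round up to >= 1"
            )

    @property
    def n_copy(self) -> int:
        return math.ceil(self.copy_fraction * self.population_size)


@dataclass
class GARunResult:
    best: Chromosome
    best_fitness: float
    history_best: list[float]  # all-time best per generation (non-decreasing)
    history_mean: list[float]  # population mean fitness per generation


@dataclass
class BandCounts:
    """Cumulative segment counts of the best chromosomes over repeated runs."""

    counts: np.ndarray
    n_runs: int
    k_segments: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        total = int(self.counts.sum())
        if total != self.n_runs * self.k_segments:
            raise ValueError(
                f"count sum {total} != n_runs*k_segments = {self.n_runs * self.k_segments}"
            )


@dataclass
class Band:
    """A contiguous run of selected segments, reported as a closed interval."""

    segments: tuple[int, ...]
    lo: float
    hi: float
    total_count: int


class FitnessEvaluator:
    """Memoized LOOCV-LDA fitness for one preprocessed dataset."""

    def __init__(self, data: SpectraSet, idx: SegmentIndex, ridge="auto"):
        data.require_two_classes()
        if idx.n_points != data.grid.n_points:
            raise ValueError("segment index does not match data grid")
        self.data = data
        self.idx = idx
        self.ridge = ridge
        self._cache: dict[Chromosome, float] = {}

    def __call__(self, chrom: Chromosome) -> float:
        key = canonical(chrom)
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        value = self.evaluate_uncached(key)
        self._cache[key] = value
        return value

    def evaluate_uncached(self, chrom: Chromosome) -> float:
        variables = expand_chromosome(chrom, self.idx)
        cv = loocv(self.data.matrix, self.data.labels, variables=variables,
                   ids=self.data.ids, ridge=self.ridge)
        return cv.accuracy

    @property
    def cache_size(self) -> int:
        return len(self._cache)


def fitness(chrom, data: SpectraSet, idx: SegmentIndex, evaluator: FitnessEvaluator | None = None) -> float:
    """LOOCV-LDA overall accuracy of a chromosome's variables, in [0, 1]."""
    if evaluator is None:
        evaluator = FitnessEvaluator(data, idx)
    return evaluator(canonical(chrom))


def init_population(ga: GAConfig, n_segments: int, rng: np.random.Generator) -> list[Chromosome]:
    """Uniform without-replacement initial chromosomes."""
    if ga.k_segments > n_segments:
        raise ValueError(f"k_segments {ga.k_segments} > n_segments {n_segments}")
    return [
        canonical(rng.choice(n_segments, size=ga.k_segments, replace=False))
        for _ in range(ga.population_size)
    ]


def _ranked(population: list[Chromosome], fitnesses: list[float]) -> list[int]:
    # descending fitness; ties broken by canonical chromosome order
    return sorted(range(len(population)),
                  key=lambda i: (-fitnesses[i], population[i]))


def select_copy(population: list[Chromosome], fitnesses, ga: GAConfig) -> list[Chromosome]:
    """Top ``ceil(copy_fraction*N)`` chromosomes overwrite the bottom ones.

    The pool keeps the population's slot order; only the worst slots change,
    and a slot is only overwritten when the replacement is strictly fitter
    (so an all-tied population passes through unchanged).  Ranking ties are
    broken by canonical chromosome order.
    """
    fitnesses = list(fitnesses)
    if len(population) != len(fitnesses):
        raise ValueError("population/fitness length mismatch")
    order = _ranked(population, fitnesses)
    m = ga.n_copy
    pool = list(population)
    for best_i, worst_i in zip(order[:m], order[::-1][:m]):
        if fitnesses[best_i] > fitnesses[worst_i]:
            pool[worst_i] = population[best_i]
    return pool


def crossover(a: Chromosome, b: Chromosome, rng: np.random.Generator,
              n_segments: int) -> tuple[Chromosome, Chromosome]:
    """Single-point crossover on canonically ordered parents, with repair.

    The cut site is uniform in {1..k-1}; tails are swapped; duplicates in a
    child are repaired by redrawing uniformly from the segments it does not
    already hold.
    """
    a, b = canonical(a), canonical(b)
    k = len(a)
    if k < 2:
        return a, b
    cut = int(rng.integers(1, k))
    child1 = list(a[:cut]) + list(b[cut:])
    child2 = list(b[:cut]) + list(a[cut:])
    return (_repair(child1, rng, n_segments), _repair(child2, rng, n_segments))


def _repair(genes: list[int], rng: np.random.Generator, n_segments: int) -> Chromosome:
    seen: set[int] = set()
    out: list[int] = []
    for g in genes:
        if g in seen:
            unused = np.setdiff1d(np.arange(n_segments), genes + out, assume_unique=False)
            g = int(rng.choice(unused))
        seen.add(g)
        out.append(g)
    return canonical(out)


def mutate(chrom: Chromosome, ga: GAConfig, rng: np.random.Generator,
           n_segments: int) -> Chromosome:
    """With probability ``mutation_prob`` replace one gene by an unused id."""
    chrom = canonical(chrom)
    if rng.random() >= ga.mutation_prob:
        return chrom
    unused = np.setdiff1d(np.arange(n_segments), chrom)
    if unused.size == 0:  # chromosome already holds every segment
        return chrom
    pos = int(rng.integers(len(chrom)))
    genes = list(chrom)
    genes[pos] = int(rng.choice(unused))
    return canonical(genes)


def run_ga(
    data: SpectraSet,
    ga: GAConfig,
    idx: SegmentIndex,
    rng: np.random.Generator | None = None,
    evaluator: FitnessEvaluator | None = None,
    log=None,
) -> GARunResult:
    """One independent GA run; best-fitness history is non-decreasing."""
    if rng is None:
        rng = np.random.default_rng(ga.seed)
    if evaluator is None:
        evaluator = FitnessEvaluator(data, idx)
    n_segments = idx.n_segments
    pop = init_population(ga, n_segments, rng)
    fits = [evaluator(c) for c in pop]
    best_i = _ranked(pop, fits)[0]
    best, best_fit = pop[best_i], fits[best_i]
    history_best: list[float] = []
    history_mean: list[float] = []

    for gen in range(ga.generations):
        history_best.append(best_fit)
        history_mean.append(float(np.mean(fits)))
        if log is not None:
            log(gen, best_fit, float(np.mean(fits)))
        pool = select_copy(pop, fits, ga)
        order = rng.permutation(len(pool))
        offspring: list[Chromosome] = [None] * len(pool)  # type: ignore[list-item]
        for j in range(0, len(order) - 1, 2):
            i1, i2 = int(order[j]), int(order[j + 1])
            if rng.random() < ga.crossover_prob:
                c1, c2 = crossover(pool[i1], pool[i2], rng, n_segments)
            else:
                c1, c2 = pool[i1], pool[i2]
            offspring[i1], offspring[i2] = c1, c2
        if len(order) % 2:  # odd population: last one passes through
            i_last = int(order[-1])
            offspring[i_last] = pool[i_last]
        offspring = [mutate(c, ga, rng, n_segments) for c in offspring]
        fits = [evaluator(c) for c in offspring]
        # update the all-time best from the offspring
        cand_i = _ranked(offspring, fits)[0]
        if fits[cand_i] > best_fit:
            best, best_fit = offspring[cand_i], fits[cand_i]
        # elitism: reinsert the best if its chromosome is gone and no
        # individual matches its fitness
        if best not in offspring and not any(f == best_fit for f in fits):
            worst_i = _ranked(offspring, fits)[-1]
            offspring[worst_i] = best
            fits[worst_i] = best_fit
        pop = offspring

    # final bookkeeping (covers generations == 0 as well)
    final_i = _ranked(pop, fits)[0]
    if fits[final_i] > best_fit:
        best, best_fit = pop[final_i], fits[final_i]
    history_best.append(best_fit)
    history_mean.append(float(np.mean(fits)))
    return GARunResult(best=best, best_fitness=best_fit,
                       history_best=history_best, history_mean=history_mean)


def consensus_counts(
    data: SpectraSet,
    ga: GAConfig,
    idx: SegmentIndex,
    evaluator: FitnessEvaluator | None = None,
    log=None,
) -> tuple[BandCounts, list[GARunResult]]:
    """Repeat the GA ``n_runs`` times and cumulatively count best segments.

    Run ``r`` uses the substream ``default_rng([seed, r])``; the fitness
    cache is shared across runs (fitness is a pure function of the data).
    """
    if evaluator is None:
        evaluator = FitnessEvaluator(data, idx)
    counts = np.zeros(idx.n_segments, dtype=int)
    results: list[GARunResult] = []
    for r in range(ga.n_runs):
        rng = np.random.default_rng([ga.seed, r])
        res = run_ga(data, ga, idx, rng=rng, evaluator=evaluator)
        for s in res.best:
            counts[s] += 1
        results.append(res)
        if log is not None:
            log(r, res.best_fitness, evaluator.cache_size)
    return BandCounts(counts=counts, n_runs=ga.n_runs, k_segments=ga.k_segments), results


def top_bands(counts: BandCounts, idx: SegmentIndex, grid: WavenumberGrid,
              k: int = 6) -> list[Band]:
    """Top-count segments merged into ``k`` contiguous wavenumber bands.

    Segments are ranked by count descending (ties -> lower id first) and
    taken greedily; adjacent selected segments merge into one band; the
    process stops as soon as exactly ``k`` bands exist.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    c = counts.counts
    ranked = sorted(range(len(c)), key=lambda s: (-c[s], s))
    selected: set[int] = set()
    for s in ranked:
        if c[s] == 0:
            break
        selected.add(s)
        if len(_merge(selected)) == k:
            return _bands_from(selected, c, idx, grid)
    raise ValueError(
        f"cannot form {k} bands: only {len(_merge(selected))} bands available "
        f"from {int(np.count_nonzero(c))} nonzero-count segments"
    )


def _merge(selected: set[int]) -> list[tuple[int, ...]]:
    runs: list[tuple[int, ...]] = []
    cur: list[int] = []
    for s in sorted(selected):
        if cur and s == cur[-1] + 1:
            cur.append(s)
        else:
            if cur:
                runs.append(tuple(cur))
            cur = [s]
    if cur:
        runs.append(tuple(cur))
    return runs


def _bands_from(selected: set[int], c: np.ndarray, idx: SegmentIndex,
                grid: WavenumberGrid) -> list[Band]:
    bands = []
    for run in _merge(selected):
        lo, _ = idx.interval(run[0], grid)
        _, hi = idx.interval(run[-1], grid)
        bands.append(Band(segments=run, lo=lo, hi=hi,
                          total_count=int(sum(c[s] for s in run))))
    return bands


def band_covers_peaks(bands: list[Band], centers, tolerance: float = 9.0) -> list[bool]:
    """Whether each peak center is covered by some band, within ``tolerance``.

    A band covers a center when its closed interval, widened by ``tolerance``
    cm^-1 on each side (default: the generator's Lorentzian half-width, i.e.
    the region carrying >= 50% of peak height), contains the center.
    """
    out = []
    for center in centers:
        out.append(any(b.lo - tolerance <= center <= b.hi + tolerance for b in bands))
    return out
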