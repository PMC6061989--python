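"""Integer-coded Differential Evolution over candidate feature-index vectors.

Each individual is a vector of ``n`` distinct 1-based indices into the
sorted feature table.  One generation applies, per target slot ``j``:

1. *mutation and scaling* — pick three distinct slots ``a, b, c != j`` and
   form ``trial[k] = v[c][k] + floor(F * (v[a][k] - v[b][k]))``, then wrap
   each element back into ``[1, d]`` (repeatedly adding/subtracting ``d``,
   i.e. modular wrapping);
2. *crossover* — keep trial element ``k`` when the k-th uniform draw is
   <= Cr, else restore the target's element;
3. *duplicate repair* — mutation and crossover can repeat an index, which
   would break the distinctness invariant; each duplicate (scanning left
   to right) is replaced by a uniform draw from the currently unused
   indices;
4. *selection* — the trial survives only on a strict fitness improvement;
5. *elitism* — after selection, if the previous generation's best beats
   the new population's worst, the worst slot is replaced by a copy of it.

Selection plus elitism make the best-fitness history non-decreasing: the
population never deteriorates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


@dataclass
class DEConfig:
    """Differential-evolution settings.

    Defaults: panel length n=10, population I=50, generations phi=50,
    mutation factor F=1.0, crossover rate Cr=0.8, independent runs
    theta=50.
    """

    n: int = 10
    pop_size: int = 50
    generations: int = 50
    mutation_factor: float = 1.0
    crossover_rate: float = 0.8
    runs: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.pop_size < 4:
            raise ValueError("pop_size must be >= 4 (mutation needs j, a, b, c distinct)")
        if self.generations < 0:
            raise ValueError("generations must be >= 0")
        if not 0.0 <= self.mutation_factor <= 2.0:
            raise ValueError("mutation_factor must lie in [0, 2]")
        if not 0.0 <= self.crossover_rate <= 1.0:
            raise ValueError("crossover_rate must lie in [0, 1]")
        if self.runs < 1:
            raise ValueError("runs must be >= 1")


@dataclass
class CandidateVector:
    """A DE individual: distinct 1-based feature indices plus cached fitness."""

    indices: np.ndarray
    fitness: float | None = None

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)

    def validate(self, d: int) -> None:
        v = self.indices
        if len(set(v.tolist())) != v.size:
            raise ValueError(f"indices must be distinct: {v.tolist()}")
        if ((v < 1) | (v > d)).any():
            raise ValueError(f"indices must lie in [1, {d}]: {v.tolist()}")

    def copy(self) -> "CandidateVector":
        return CandidateVector(self.indices.copy(), self.fitness)


@dataclass
class DERunResult:
    """Outcome of one DE run."""

    best: CandidateVector
    history: list[float]  # best fitness per generation, length generations + 1
    n_initial_evaluations: int
    n_trial_evaluations: int
    config: DEConfig = field(repr=False, default=None)


def init_population(d: int, cfg: DEConfig, rng: np.random.Generator) -> list[CandidateVector]:
    """I vectors of n distinct uniform indices from [1, d]."""
    if d < cfg.n:
        raise ValueError(f"cannot draw {cfg.n} distinct indices from {d} features")
    return [
        CandidateVector(rng.choice(d, size=cfg.n, replace=False) + 1)
        for _ in range(cfg.pop_size)
    ]


def mutate_values(vc, va, vb, F: float, d: int) -> np.ndarray:
    """Base-plus-floored-scaled-difference, wrapped into [1, d].

    ``trial[k] = vc[k] + floor(F * (va[k] - vb[k]))`` followed by the range
    correction (add d while < 1, subtract d while > d), applied here as the
    equivalent modular wrap so it also covers |floor(F*diff)| > d.
    """
    vc = np.asarray(vc, dtype=int)
    va = np.asarray(va, dtype=int)
    vb = np.asarray(vb, dtype=int)
    raw = vc + np.floor(F * (va - vb)).astype(int)
    return ((raw - 1) % d) + 1


def repair_duplicates(v: np.ndarray, d: int, rng: np.random.Generator) -> np.ndarray:
    """Restore distinctness: replace repeats (left to right) with unused indices."""
    v = np.asarray(v, dtype=int).copy()
    seen = set()
    dup_slots = []
    for k, x in enumerate(v):
        if x in seen:
            dup_slots.append(k)
        else:
            seen.add(int(x))
    if dup_slots:
        unused = np.setdiff1d(np.arange(1, d + 1), v)
        draw = rng.choice(unused.size, size=len(dup_slots), replace=False)
        v[dup_slots] = unused[draw]
    return v


def mutate_scale(
    pop: list[CandidateVector], j: int, F: float, d: int, rng: np.random.Generator
) -> np.ndarray:
    """Build the trial for target slot j from three other random slots.

    a, b, c are uniform without replacement among slots != j.  The result
    is wrapped into range and duplicate-repaired, so it satisfies the
    candidate invariants.
    """
    if len(pop) < 4:
        raise ValueError("mutation needs a population of at least 4")
    others = [i for i in range(len(pop)) if i != j]
    a, b, c = rng.choice(len(others), size=3, replace=False)
    va, vb, vc = (pop[others[i]].indices for i in (a, b, c))
    trial = mutate_values(vc, va, vb, F, d)
    return repair_duplicates(trial, d, rng)


def crossover(
    trial: np.ndarray,
    target: np.ndarray,
    cr: float,
    d: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Keep trial element k when the k-th uniform draw <= Cr, else the target's.

    Duplicate repair is re-applied afterwards, since mixing two distinct
    vectors can introduce repeats.
    """
    trial = np.asarray(trial, dtype=int)
    target = np.asarray(target, dtype=int)
    if trial.shape != target.shape:
        raise ValueError("trial and target must have equal length")
    keep = rng.random(trial.size) <= cr
    mixed = np.where(keep, trial, target)
    return repair_duplicates(mixed, d, rng)


def select(trial: CandidateVector, target: CandidateVector) -> CandidateVector:
    """Strict-improvement rule: the trial survives only if strictly fitter."""
    if trial.fitness is None or target.fitness is None:
        raise ValueError("both fitnesses must be computed before selection")
    return trial if trial.fitness > target.fitness else target


def apply_elitism(
    prev_best: CandidateVector, next_pop: list[CandidateVector]
) -> list[CandidateVector]:
    """Replace the worst slot with the previous best if strictly better.

    Ties favor the new population (no replacement).  Returns the (mutated)
    population list.
    """
    if prev_best.fitness is None or any(v.fitness is None for v in next_pop):
        raise ValueError("elitism requires computed fitnesses")
    worst = min(range(len(next_pop)), key=lambda i: next_pop[i].fitness)
    if prev_best.fitness > next_pop[worst].fitness:
        next_pop[worst] = prev_best.copy()
    return next_pop


def run_de(d: int, cfg: DEConfig, fitness, rng: np.random.Generator) -> DERunResult:
    """One full DE run.

    Parameters
    ----------
    d : int
        Feature-table size; indices range over [1, d].
    fitness : callable
        Maps a 1-based index array to a real fitness in [0, 1].
    rng : numpy Generator
        Sole source of randomness for the run.

    Returns the best candidate of the final generation and the
    per-generation best-fitness history (length ``generations + 1``,
    non-decreasing by the selection/elitism contract).
    """
    pop = init_population(d, cfg, rng)
    n_init = 0
    for v in pop:
        v.fitness = float(fitness(v.indices))
        n_init += 1
    history = [max(v.fitness for v in pop)]
    n_trials = 0

    for _ in range(cfg.generations):
        prev_best = max(pop, key=lambda v: v.fitness)
        next_pop = []
        for j in range(cfg.pop_size):
            trial = mutate_scale(pop, j, cfg.mutation_factor, d, rng)
            trial = crossover(trial, pop[j].indices, cfg.crossover_rate, d, rng)
            cand = CandidateVector(trial, float(fitness(trial)))
            n_trials += 1
            next_pop.append(select(cand, pop[j]))
        apply_elitism(prev_best, next_pop)
        pop = next_pop
        history.append(max(v.fitness for v in pop))

    best = max(pop, key=lambda v: v.fitness)
    return DERunResult(
        best=best.copy(),
        history=history,
        n_initial_evaluations=n_init,
        n_trial_evaluations=n_trials,
        config=replace(cfg),
    )
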