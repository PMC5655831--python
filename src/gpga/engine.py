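"""Integer-coded genetic search for the position of one exon in a query.

Each individual is a single integer: a candidate start position of the
exon E in the query Q, constrained to [l, u] = [1, q - e].  Selection is
a size-3 tournament; crossover and mutation are "adaptive position
prediction" (APP) operators that narrow the sampling interval to a
window around a parent whose fitness has reached half the maximum
(e/2), and otherwise resample uniformly from the full range.  The
search stops as soon as a perfect placement (F = e) is found, when the
all-time best fitness has not improved for ``stall_generations``
consecutive generations, or at ``max_generations``.

Defaults follow the published parameterization: population 200, up to
3000 generations, stall at 200, tournament size 3, crossover and
mutation probabilities both 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .seqio import N_CODE, Sequence


@dataclass
class SearchParams:
    pop_size: int = 200
    max_generations: int = 3000
    stall_generations: int = 200
    tournament_k: int = 3
    p_cross: float = 1.0
    p_mut: float = 1.0
    suboptimal_fraction: float = 0.5  # the e/2 rule
    narrow_halfwidth_factor: float = 1.0  # window is +- factor*e around a parent
    elite_count: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pop_size < 2:
            raise ValueError("pop_size must be >= 2")
        if self.tournament_k < 1:
            raise ValueError("tournament_k must be >= 1")
        for name in ("p_cross", "p_mut"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if not (0.0 < self.suboptimal_fraction <= 1.0):
            raise ValueError("suboptimal_fraction must lie in (0, 1]")
        if self.stall_generations > self.max_generations:
            raise ValueError("stall_generations must be <= max_generations")


@dataclass
class Individual:
    position: int  # 1-based start, in [1, q - e]
    fitness: int


@dataclass
class SearchTrace:
    best_fitness_per_generation: list[int] = field(default_factory=list)
    generations_run: int = 0
    termination_reason: str = ""  # max_generations | stall | optimum


class _Evaluator:
    """Window-compare fitness with the exon pre-encoded."""

    def __init__(self, exon, query: Sequence):
        self.e_arr = _encode(exon)
        self.q_arr = query.encoded()
        self.e = len(self.e_arr)
        self.valid = self.e_arr != N_CODE

    def __call__(self, p: int) -> int:
        w = self.q_arr[p - 1 : p - 1 + self.e]
        return int(((self.e_arr == w) & self.valid).sum())


def _encode(seq_like) -> np.ndarray:
    from .seqio import _ENCODE

    enc = getattr(seq_like, "encoded", None)
    if enc is not None:
        return enc()
    return _ENCODE[np.frombuffer(seq_like.residues.encode("ascii"), dtype=np.uint8)]


def init_population(
    q: int, e: int, params: SearchParams, rng: np.random.Generator, evaluate
) -> list[Individual]:
    """N positions drawn uniformly from [1, q - e] (all 1 when e = q)."""
    if e > q:
        raise ValueError(f"exon longer than query (e={e} > q={q})")
    u = max(q - e, 1)
    positions = rng.integers(1, u + 1, size=params.pop_size)
    return [Individual(int(p), evaluate(int(p))) for p in positions]


def _better(a: Individual, b: Individual) -> Individual:
    """Higher fitness wins; ties broken by smaller position."""
    if a.fitness != b.fitness:
        return a if a.fitness > b.fitness else b
    return a if a.position <= b.position else b


def tournament_select(
    pop: list[Individual], k: int, rng: np.random.Generator
) -> Individual:
    """Sample k individuals with replacement, return the fittest."""
    if not pop:
        raise ValueError("tournament over an empty population")
    idx = rng.integers(0, len(pop), size=k)
    best = pop[idx[0]]
    for i in idx[1:]:
        best = _better(best, pop[i])
    return best


def _app_offspring_position(
    parent: Individual,
    e: int,
    l: int,
    u: int,
    params: SearchParams,
    rng: np.random.Generator,
) -> int:
    """One offspring position under the APP narrowing rule.

    F = e: the optimum is found, keep the position.  F >= e/2 (the
    suboptimal region): sample from the narrowed window [P-h, P+h]
    clipped to [l, u], h = round(factor * e).  Otherwise sample from
    the unmodified [l, u].
    """
    threshold = params.suboptimal_fraction * e
    if parent.fitness >= e:
        return parent.position
    if parent.fitness >= threshold:
        h = int(round(params.narrow_halfwidth_factor * e))
        lo = max(l, parent.position - h)
        hi = min(u, parent.position + h)
        return int(rng.integers(lo, hi + 1))
    return int(rng.integers(l, u + 1))


def app_crossover(
    pa: Individual,
    pb: Individual,
    e: int,
    l: int,
    u: int,
    params: SearchParams,
    rng: np.random.Generator,
    evaluate,
) -> tuple[Individual, Individual]:
    """APP crossover: each parent independently yields one offspring."""
    ca = _app_offspring_position(pa, e, l, u, params, rng)
    cb = _app_offspring_position(pb, e, l, u, params, rng)
    return Individual(ca, evaluate(ca)), Individual(cb, evaluate(cb))


def app_mutation(
    child: Individual,
    e: int,
    l: int,
    u: int,
    params: SearchParams,
    rng: np.random.Generator,
    evaluate,
) -> Individual:
    """APP mutation: resample within the narrowed window when the child
    has reached the suboptimal region, else from the full range."""
    threshold = params.suboptimal_fraction * e
    if child.fitness >= threshold:
        h = int(round(params.narrow_halfwidth_factor * e))
        lo = max(l, child.position - h)
        hi = min(u, child.position + h)
        p = int(rng.integers(lo, hi + 1))
    else:
        p = int(rng.integers(l, u + 1))
    return Individual(p, evaluate(p))


def search_exon(
    exon,
    query: Sequence,
    params: SearchParams,
    rng_offset: int = 0,
) -> tuple[Individual, SearchTrace]:
    """Run the full genetic search for one exon.

    ``rng_offset`` is a stable per-exon stream offset so that multi-exon
    runs are reproducible and independent of search order.  Returns the
    all-time best individual and the per-generation trace.
    """
    e = len(exon.residues)
    q = len(query.residues)
    if e > q:
        raise ValueError(f"exon longer than query (e={e} > q={q})")

    rng = np.random.default_rng([params.seed, rng_offset])
    evaluate = _Evaluator(exon, query)
    l, u = 1, max(q - e, 1)

    pop = init_population(q, e, params, rng, evaluate)
    best = pop[0]
    for ind in pop[1:]:
        best = _better(best, ind)

    trace = SearchTrace()
    trace.best_fitness_per_generation.append(best.fitness)
    if best.fitness >= e:
        trace.termination_reason = "optimum"
        return best, trace

    stall = 0
    for _gen in range(1, params.max_generations + 1):
        new_pop: list[Individual] = []
        while len(new_pop) < params.pop_size:
            pa = tournament_select(pop, params.tournament_k, rng)
            pb = tournament_select(pop, params.tournament_k, rng)
            if rng.random() < params.p_cross:
                ca, cb = app_crossover(pa, pb, e, l, u, params, rng, evaluate)
            else:
                ca = Individual(pa.position, pa.fitness)
                cb = Individual(pb.position, pb.fitness)
            if rng.random() < params.p_mut:
                ca = app_mutation(ca, e, l, u, params, rng, evaluate)
            if rng.random() < params.p_mut:
                cb = app_mutation(cb, e, l, u, params, rng, evaluate)
            new_pop.append(ca)
            if len(new_pop) < params.pop_size:
                new_pop.append(cb)

        # elitism: the all-time best replaces the worst of the new pool
        if params.elite_count > 0:
            new_pop.sort(key=lambda ind: (ind.fitness, -ind.position))
            for i in range(min(params.elite_count, len(new_pop))):
                new_pop[i] = Individual(best.position, best.fitness)
        pop = new_pop

        gen_best = pop[0]
        for ind in pop[1:]:
            gen_best = _better(gen_best, ind)
        improved = (
            gen_best.fitness > best.fitness
            or (gen_best.fitness == best.fitness and gen_best.position < best.position)
        )
        if gen_best.fitness > best.fitness:
            stall = 0
        else:
            stall += 1
        if improved:
            best = gen_best

        trace.best_fitness_per_generation.append(best.fitness)
        trace.generations_run = _gen

        if best.fitness >= e:
            trace.termination_reason = "optimum"
            return best, trace
        if stall >= params.stall_generations:
            trace.termination_reason = "stall"
            return best, trace

    trace.termination_reason = "max_generations"
    return best, trace
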