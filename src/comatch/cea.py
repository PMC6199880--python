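"""Single-swarm compact EA with crossover-based local search.

The population is a probability vector (PV). Each generation samples one
candidate, mutates it, derives a neighbor of the elite by copying a short
circular fragment of the candidate into the elite, promotes the best of
{candidate, neighbor, elite} (incumbent wins ties), and shifts the PV toward
the winner. At most a constant number of chromosomes is ever held.

By default the PV update fires only in generations where the elite strictly
improved; ``pv_update_always=True`` switches to an unconditional
per-generation update toward the incumbent, which converges the PV much
faster at the cost of exploration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from comatch.config import MatcherConfig
from comatch.encoding import (
    Chromosome,
    DecodedSolution,
    EncodingError,
    EncodingParams,
    ProbabilityVector,
    decode,
    mutate,
    perturb_pv,
    sample,
    uniform_pv,
    update_pv,
)
from comatch.evaluation import solution_scores
from comatch.ontology_io import Ontology
from comatch.similarity import SimilarityMatrix


@dataclass(frozen=True)
class Objective:
    """Deterministic fitness of a decoded solution under one rough metric.

    ``tag`` is one of mr (MatchRatio), mc (MatchCoverage), mf (MatchFmeasure).
    """

    tag: str
    score: Callable[[DecodedSolution], float]

    def __call__(self, sol: DecodedSolution) -> float:
        return self.score(sol)


_METRIC_FIELDS = {
    "mr": "match_ratio",
    "mc": "match_coverage",
    "mf": "match_fmeasure",
}

OBJECTIVE_ORDER = ("mr", "mc", "mf")


def make_objective(tag: str, sim: SimilarityMatrix) -> Objective:
    if tag not in _METRIC_FIELDS:
        raise ValueError(f"unknown objective tag {tag!r}")
    field_name = _METRIC_FIELDS[tag]
    values = sim.values

    def score(sol: DecodedSolution) -> float:
        return getattr(solution_scores(sol.mapping, sol.threshold, values), field_name)

    return Objective(tag=tag, score=score)


def make_objectives(sim: SimilarityMatrix) -> dict[str, Objective]:
    return {tag: make_objective(tag, sim) for tag in OBJECTIVE_ORDER}


@dataclass(frozen=True)
class SwarmState:
    pv: ProbabilityVector
    elite: Chromosome
    elite_fitness: float
    generation: int = 0


def local_search_crossover(
    ind_new: Chromosome, ind_elite: Chromosome, pc: float, rng
) -> Chromosome:
    """Copy a circular fragment of ``ind_new`` into a copy of ``ind_elite``.

    The cut point is uniform over the chromosome; the fragment length L >= 1
    grows while successive uniform draws fall below ``pc`` (truncated
    geometric, capped at the chromosome length). Since both inputs are
    usually sampled from the same PV, the result differs from the elite in
    few positions — an exploitative neighborhood move.
    """
    ind_new = np.asarray(ind_new, dtype=np.uint8)
    ind_elite = np.asarray(ind_elite, dtype=np.uint8)
    if ind_new.shape != ind_elite.shape:
        raise EncodingError("chromosome lengths differ")
    if not 0 < pc < 1:
        raise ValueError("pc must be in (0, 1)")
    length = ind_elite.shape[0]
    cut = int(rng.integers(0, length))
    fragment = 1
    while fragment < length and float(rng.random()) < pc:
        fragment += 1
    result = ind_elite.copy()
    positions = (cut + np.arange(fragment)) % length
    result[positions] = ind_new[positions]
    return result


def init_swarm(params: EncodingParams, obj: Objective, rng) -> SwarmState:
    """Uniform PV; the first sampled chromosome seeds the elite."""
    pv = uniform_pv(params)
    elite = sample(pv, rng)
    fitness = obj(decode(elite, params))
    return SwarmState(pv=pv, elite=elite, elite_fitness=fitness, generation=0)


def cea_generation(
    state: SwarmState,
    obj: Objective,
    params: EncodingParams,
    cfg: MatcherConfig,
    rng,
) -> SwarmState:
    """One compact-EA generation.

    ``cfg.n_candidates`` > 1 widens the per-generation evaluation budget
    (each extra candidate also gets a local-search neighbor); the default 1
    matches the compact model.
    """
    elite = state.elite
    best = elite
    best_fitness = state.elite_fitness
    improved = False
    for _ in range(cfg.n_candidates):
        candidate = mutate(sample(state.pv, rng), cfg.mutation_probability, rng)
        neighbor = local_search_crossover(
            candidate, elite, cfg.crossover_probability, rng
        )
        fit_candidate = obj(decode(candidate, params))
        # incumbent retained on ties: strict improvement required
        if fit_candidate > best_fitness:
            best, best_fitness, improved = candidate, fit_candidate, True
        fit_neighbor = obj(decode(neighbor, params))
        if fit_neighbor > best_fitness:
            best, best_fitness, improved = neighbor, fit_neighbor, True
    if cfg.pv_update_always or improved:
        pv = update_pv(state.pv, best, cfg.update_rate)
    else:
        pv = state.pv
    pv = perturb_pv(pv, cfg.mutation_probability, cfg.mutation_rate, rng)
    return SwarmState(
        pv=pv,
        elite=best,
        elite_fitness=best_fitness,
        generation=state.generation + 1,
    )


def run_cea(
    o1: Ontology,
    o2: Ontology,
    sim: SimilarityMatrix,
    obj: Objective,
    cfg: MatcherConfig,
    rng,
) -> SwarmState:
    """Evolve a single swarm for ``cfg.max_generation`` generations."""
    if sim.n1 != o1.concept_count or sim.n2 != o2.concept_count:
        raise ValueError("similarity matrix does not fit the ontologies")
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    params = EncodingParams(n1=sim.n1, n2=sim.n2, num_accuracy=cfg.numerical_accuracy)
    state = init_swarm(params, obj, rng)
    for _ in range(cfg.max_generation):
        state = cea_generation(state, obj, params, cfg, rng)
    return state
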