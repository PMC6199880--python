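"""Three cooperating compact-EA subswarms.

One subswarm per rough metric (MatchRatio, MatchCoverage, MatchFmeasure).
Each generation every swarm advances one compact-EA step, then the swarms
exchange elites: a foreign elite that strictly beats a swarm's incumbent
under that swarm's own objective replaces it and drags the swarm's PV toward
it. The cooperation is Pareto-safe per objective — no swarm's elite fitness
can drop — and is meant to keep MatchCoverage and MatchRatio improving
jointly instead of trading one for the other. The final alignment is decoded
from the MatchFmeasure swarm's elite.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from comatch.cea import (
    OBJECTIVE_ORDER,
    Objective,
    SwarmState,
    cea_generation,
    init_swarm,
    make_objectives,
)
from comatch.config import MatcherConfig
from comatch.encoding import EncodingParams, decode, update_pv
from comatch.evaluation import Alignment, decode_to_alignment
from comatch.ontology_io import Ontology
from comatch.similarity import SimilarityMatrix, SynonymProvider, similarity_matrix


@dataclass(frozen=True)
class CCEAState:
    """The three subswarm states keyed by objective tag, plus a shared
    generation counter."""

    swarms: dict[str, SwarmState]
    generation: int = 0

    def fitness_triple(self) -> tuple[float, float, float]:
        return tuple(self.swarms[tag].elite_fitness for tag in OBJECTIVE_ORDER)


def exchange_elites(
    state: CCEAState,
    objectives: dict[str, Objective],
    params: EncodingParams,
    cfg: MatcherConfig,
) -> CCEAState:
    """Elite migration with per-objective acceptance.

    Every pre-exchange elite is evaluated under every other objective, in the
    fixed scan order (mr, mc, mf); the best strictly-improving foreign elite
    replaces the incumbent and the local PV is updated toward it. Ties keep
    the incumbent, so after the exchange each swarm's elite fitness equals
    the maximum of its objective over the three pre-exchange elites.
    """
    pre_elites = {tag: state.swarms[tag].elite for tag in OBJECTIVE_ORDER}
    decoded = {tag: decode(elite, params) for tag, elite in pre_elites.items()}
    new_swarms: dict[str, SwarmState] = {}
    for tag in OBJECTIVE_ORDER:
        swarm = state.swarms[tag]
        obj = objectives[tag]
        best_tag = None
        best_fitness = swarm.elite_fitness
        for other in OBJECTIVE_ORDER:
            if other == tag:
                continue
            foreign_fitness = obj(decoded[other])
            if foreign_fitness > best_fitness:
                best_tag, best_fitness = other, foreign_fitness
        if best_tag is None:
            new_swarms[tag] = swarm
        else:
            adopted = pre_elites[best_tag].copy()
            new_swarms[tag] = replace(
                swarm,
                elite=adopted,
                elite_fitness=best_fitness,
                pv=update_pv(swarm.pv, adopted, cfg.update_rate),
            )
    return CCEAState(swarms=new_swarms, generation=state.generation)


def run_ccea_state(
    o1: Ontology,
    o2: Ontology,
    syn: SynonymProvider,
    cfg: MatcherConfig,
    seed: "int | None" = None,
    sim: "SimilarityMatrix | None" = None,
    trace: "list[tuple[int, float, float, float]] | None" = None,
) -> tuple[CCEAState, SimilarityMatrix]:
    """Full coevolutionary run returning the final state and the similarity
    matrix (built once and shared by all three swarms).

    ``seed`` overrides ``cfg.seed``; each swarm consumes its own child stream
    of the seed so runs are reproducible and swarm draws are independent.
    ``trace`` (if given) collects per-generation elite fitness triples,
    generation 0 being the initial elites.
    """
    if sim is None:
        sim = similarity_matrix(o1, o2, syn, cfg.similarity_params())
    params = EncodingParams(n1=sim.n1, n2=sim.n2, num_accuracy=cfg.numerical_accuracy)
    objectives = make_objectives(sim)
    seed = cfg.seed if seed is None else seed
    streams = np.random.SeedSequence(seed).spawn(len(OBJECTIVE_ORDER))
    rngs = {
        tag: np.random.default_rng(stream)
        for tag, stream in zip(OBJECTIVE_ORDER, streams)
    }
    swarms = {
        tag: init_swarm(params, objectives[tag], rngs[tag]) for tag in OBJECTIVE_ORDER
    }
    state = CCEAState(swarms=swarms, generation=0)
    if trace is not None:
        trace.append((0, *state.fitness_triple()))
    for gen in range(1, cfg.max_generation + 1):
        if cfg.help_before_update:
            state = exchange_elites(state, objectives, params, cfg)
        swarms = {
            tag: cea_generation(state.swarms[tag], objectives[tag], params, cfg, rngs[tag])
            for tag in OBJECTIVE_ORDER
        }
        state = CCEAState(swarms=swarms, generation=gen)
        if not cfg.help_before_update:
            state = exchange_elites(state, objectives, params, cfg)
        if trace is not None:
            trace.append((gen, *state.fitness_triple()))
    return state, sim


def run_ccea(
    o1: Ontology,
    o2: Ontology,
    syn: SynonymProvider,
    cfg: MatcherConfig,
    seed: "int | None" = None,
    trace_path: "str | Path | None" = None,
) -> Alignment:
    """Match two ontologies; returns the alignment decoded from the
    MatchFmeasure swarm's elite. Optionally logs the per-generation elite
    fitness triples to a CSV file."""
    trace: "list[tuple[int, float, float, float]] | None" = (
        [] if trace_path is not None else None
    )
    state, sim = run_ccea_state(o1, o2, syn, cfg, seed=seed, trace=trace)
    if trace_path is not None and trace is not None:
        with open(trace_path, "w", newline="") as handle:
            writer = csv.writer(handle)
            writer.writerow(["generation", "match_ratio", "match_coverage", "match_fmeasure"])
            writer.writerows(trace)
    params = EncodingParams(n1=sim.n1, n2=sim.n2, num_accuracy=cfg.numerical_accuracy)
    solution = decode(state.swarms["mf"].elite, params)
    return decode_to_alignment(solution, sim, o1, o2)
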