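"""Run configuration with the matcher's default parameter set.

Defaults: numerical accuracy 0.01, PV update rate 0.1, crossover probability
0.6, mutation probability 0.03, mutation rate 0.05 (magnitude of the
per-element PV perturbation toward 0.5), 3000 generations, delta 0.06.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, fields, replace
from pathlib import Path

from comatch.similarity import SimilarityParams


@dataclass
class MatcherConfig:
    # similarity
    delta: float = 0.06
    element_match_threshold: float = 0.9
    ngram_size: int = 3
    # encoding
    numerical_accuracy: float = 0.01
    # evolution
    update_rate: float = 0.1
    crossover_probability: float = 0.6
    mutation_probability: float = 0.03
    mutation_rate: float = 0.05
    max_generation: int = 3000
    n_candidates: int = 1
    # When False (default) the PV moves toward the elite only in generations
    # where the elite strictly improved; when True it moves every generation.
    # The always-update reading pins the PV to the incumbent within ~1/update_rate
    # generations and stalls the search on multi-bit segment repairs.
    pv_update_always: bool = False
    # cooperation ordering: evolve each swarm first, then exchange elites
    help_before_update: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.numerical_accuracy <= 1:
            raise ValueError("numerical_accuracy must be in (0, 1]")
        if not 0 < self.crossover_probability < 1:
            raise ValueError("crossover_probability must be in (0, 1)")
        if not 0 <= self.mutation_probability <= 1:
            raise ValueError("mutation_probability must be in [0, 1]")
        if self.max_generation < 0:
            raise ValueError("max_generation must be non-negative")
        if self.n_candidates < 1:
            raise ValueError("n_candidates must be positive")

    def similarity_params(self) -> SimilarityParams:
        return SimilarityParams(
            delta=self.delta,
            element_match_threshold=self.element_match_threshold,
            ngram_size=self.ngram_size,
        )

    @classmethod
    def from_toml(cls, path: str | Path) -> "MatcherConfig":
        """Load overrides from a TOML file; unknown keys are rejected."""
        data = tomllib.loads(Path(path).read_text())
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return replace(cls(), **data)
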