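"""Binary chromosome and probability-vector machinery.

A chromosome holds one gene segment of ``segment_bit_length(n2)`` bits per
source concept (big-endian target index, 0 = unmapped) followed by a single
threshold segment of ``threshold_bit_length(num_accuracy)`` bits. Decoded
values exceeding their range are folded with a modulus so every bit pattern
decodes to a valid solution.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from math import ceil, log2

import numpy as np

#: A chromosome is a 1-D uint8 array of 0/1 gene bits.
Chromosome = np.ndarray
#: A probability vector holds, per gene bit, the probability of sampling 1.
ProbabilityVector = np.ndarray


class EncodingError(ValueError):
    """Chromosome/PV length inconsistent with the encoding parameters."""


def segment_bit_length(n2: int) -> int:
    """Bits per gene segment: smallest b with 2**b >= n2 + 1.

    Indices 0 (unmapped) through n2 must all be representable.
    """
    if n2 < 1:
        raise ValueError("n2 must be >= 1")
    return max(1, ceil(log2(n2 + 1)))


def threshold_bit_length(num_accuracy: float) -> int:
    """Bits for the threshold segment: smallest b with
    2**b >= ceil(1 / num_accuracy) + 1."""
    if not 0 < num_accuracy <= 1:
        raise ValueError("num_accuracy must be in (0, 1]")
    levels = ceil(1 / num_accuracy)
    return max(1, ceil(log2(levels + 1)))


@dataclass(frozen=True)
class EncodingParams:
    n1: int
    n2: int
    num_accuracy: float = 0.01

    def __post_init__(self) -> None:
        if self.n1 < 1 or self.n2 < 1:
            raise ValueError("n1 and n2 must be >= 1")
        if not 0 < self.num_accuracy <= 1:
            raise ValueError("num_accuracy must be in (0, 1]")

    @property
    def segment_bits(self) -> int:
        return segment_bit_length(self.n2)

    @property
    def threshold_bits(self) -> int:
        return threshold_bit_length(self.num_accuracy)

    @property
    def threshold_levels(self) -> int:
        return ceil(1 / self.num_accuracy)

    @property
    def length(self) -> int:
        return self.n1 * self.segment_bits + self.threshold_bits


@dataclass(frozen=True)
class DecodedSolution:
    """Per-source-concept target indices (0 = unmapped) plus the filter
    threshold in [0, 1]."""

    mapping: np.ndarray
    threshold: float


@lru_cache(maxsize=None)
def _weights(bits: int) -> np.ndarray:
    # big-endian: most significant bit first
    return (1 << np.arange(bits - 1, -1, -1)).astype(np.int64)


def uniform_pv(params: EncodingParams) -> ProbabilityVector:
    return np.full(params.length, 0.5)


def decode(bits: Chromosome, params: EncodingParams) -> DecodedSolution:
    """Decode a chromosome; total (no bit pattern is invalid).

    Index segments decode big-endian and fold via ``d mod (n2 + 1)``; the
    threshold segment folds via ``d mod (levels + 1)``, is scaled by the
    numerical accuracy and capped at 1.
    """
    bits = np.asarray(bits, dtype=np.uint8)
    if bits.shape != (params.length,):
        raise EncodingError(
            f"chromosome length {bits.shape} does not match encoding length {params.length}"
        )
    seg_bits = params.segment_bits
    segments = bits[: params.n1 * seg_bits].reshape(params.n1, seg_bits)
    mapping = (segments @ _weights(seg_bits)) % (params.n2 + 1)
    raw = int(bits[params.n1 * seg_bits :] @ _weights(params.threshold_bits))
    threshold = min((raw % (params.threshold_levels + 1)) * params.num_accuracy, 1.0)
    return DecodedSolution(mapping=mapping, threshold=threshold)


def encode(sol: DecodedSolution, params: EncodingParams) -> Chromosome:
    """Inverse of :func:`decode` for in-range solutions (test/debug aid)."""
    bits = np.zeros(params.length, dtype=np.uint8)
    seg_bits = params.segment_bits
    for i, target in enumerate(np.asarray(sol.mapping, dtype=np.int64)):
        if not 0 <= target <= params.n2:
            raise EncodingError(f"target index {target} out of range 0..{params.n2}")
        for k in range(seg_bits):
            bits[i * seg_bits + k] = (target >> (seg_bits - 1 - k)) & 1
    level = round(sol.threshold / params.num_accuracy)
    if not 0 <= level <= params.threshold_levels:
        raise EncodingError(f"threshold {sol.threshold} not representable")
    for k in range(params.threshold_bits):
        bits[params.n1 * seg_bits + k] = (level >> (params.threshold_bits - 1 - k)) & 1
    return bits


def sample(pv: ProbabilityVector, rng) -> Chromosome:
    """Draw a chromosome: bit i is 1 iff a uniform draw falls below pv[i]."""
    pv = np.asarray(pv, dtype=float)
    draws = np.asarray(rng.random(pv.shape[0]))
    return (draws < pv).astype(np.uint8)


def update_pv(pv: ProbabilityVector, elite: Chromosome, rate: float) -> ProbabilityVector:
    """Shift each PV element by ``rate`` toward the elite's bit, clamped to
    [0, 1]."""
    pv = np.asarray(pv, dtype=float)
    elite = np.asarray(elite, dtype=np.uint8)
    if pv.shape != elite.shape:
        raise EncodingError("PV and elite lengths differ")
    if not 0 < rate < 1:
        raise ValueError("rate must be in (0, 1)")
    return np.clip(pv + np.where(elite == 1, rate, -rate), 0.0, 1.0)


def perturb_pv(
    pv: ProbabilityVector, probability: float, step: float, rng
) -> ProbabilityVector:
    """Per-element PV perturbation: with the given probability, move the
    element ``step`` toward 0.5 (never past it). Keeps a converged PV from
    freezing completely; disabled when either constant is 0."""
    if probability <= 0 or step <= 0:
        return np.asarray(pv, dtype=float)
    pv = np.asarray(pv, dtype=float).copy()
    mask = np.asarray(rng.random(pv.shape[0])) < probability
    pv[mask] += np.clip(0.5 - pv[mask], -step, step)
    return pv


def mutate(bits: Chromosome, pm: float, rng) -> Chromosome:
    """Flip each bit independently with probability ``pm``."""
    if not 0 <= pm <= 1:
        raise ValueError("pm must be in [0, 1]")
    bits = np.asarray(bits, dtype=np.uint8)
    flips = (np.asarray(rng.random(bits.shape[0])) < pm).astype(np.uint8)
    return bits ^ flips
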