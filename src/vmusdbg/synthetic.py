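"""Simulation of small genomes with planted repeats and error-free reads.

The generator emulates the regime the assembler is designed for: clean,
HiFi-like reads sampled uniformly (with wrap-around on circular genomes)
from a genome that may carry exact planted repeats.  There is no
sequencing-error model by default; a substitution-rate hook exists but is
set to zero, matching the method's assumption of error-free input.

Everything is deterministic under the configured seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mus_core import Read, ReadSet

_BASES = np.array(list("ACGT"))

TOY_GENOME = "ATGCTAGCAC"
_TOY_READS = ["ATGCTA", "GCTAGC", "TAGCAC", "GCACAT", "ACATGC"]


@dataclass
class SimulationConfig:
    genome_length: int = 2000
    circular: bool = True
    repeat_spec: list[tuple[int, int]] = field(default_factory=list)
    coverage: float = 20.0
    read_length: int | tuple[int, int] = 200
    seed: int = 0
    substitution_rate: float = 0.0  # hook; error-free by default

    def read_length_bounds(self) -> tuple[int, int]:
        if isinstance(self.read_length, int):
            return self.read_length, self.read_length
        lo, hi = self.read_length
        return int(lo), int(hi)


def toy_genome() -> str:
    """The 10 bp circular genome of the worked example."""
    return TOY_GENOME


def toy_read_set() -> ReadSet:
    """The five 6 bp reads tiling the toy genome with 2 bp steps."""
    return ReadSet([Read(f"read_{i + 1}", seq) for i, seq in enumerate(_TOY_READS)])


def make_genome(config: SimulationConfig) -> tuple[str, list[tuple[int, int, str]]]:
    """Random genome with planted exact repeats.

    Returns the genome string and a BED-style annotation of the planted
    repeat intervals: (start, end, name) with 0-based half-open coordinates
    (the only place this package departs from 1-based closed intervals).

    Repeat copies are exact duplicates placed at non-overlapping positions;
    placement is retried a bounded number of times before raising.
    """
    rng = np.random.default_rng(config.seed)
    n = config.genome_length
    planted = sum(length * copies for length, copies in config.repeat_spec)
    if n < planted + 1:
        raise ValueError("genome_length too small for the requested repeats")
    genome = rng.choice(_BASES, size=n)
    bed: list[tuple[int, int, str]] = []
    occupied: list[tuple[int, int]] = []
    for r, (length, copies) in enumerate(config.repeat_spec):
        unit = rng.choice(_BASES, size=length)
        for c in range(copies):
            placed = False
            for _ in range(1000):
                start = int(rng.integers(0, n - length + 1))
                if all(start + length <= s or start >= e for s, e in occupied):
                    placed = True
                    break
            if not placed:
                raise ValueError("could not place repeat copies without overlap")
            genome[start : start + length] = unit
            occupied.append((start, start + length))
            bed.append((start, start + length, f"repeat{r}_copy{c}"))
    bed.sort()
    return "".join(genome), bed


def sample_reads(genome: str, config: SimulationConfig) -> ReadSet:
    """Error-free substrings sampled to the requested expected coverage.

    Start positions are uniform over the genome; on circular genomes reads
    wrap across the origin.  Coverage 0 yields an empty read set.
    """
    rng = np.random.default_rng(config.seed + 1)
    n = len(genome)
    lo, hi = config.read_length_bounds()
    if not config.circular and hi > n:
        raise ValueError("read length exceeds linear genome length")
    mean_len = (lo + hi) / 2
    n_reads = int(round(config.coverage * n / mean_len))
    if n_reads <= 0:
        return ReadSet([])
    doubled = genome + genome
    reads: list[Read] = []
    for i in range(n_reads):
        length = int(rng.integers(lo, hi + 1))
        if config.circular:
            start = int(rng.integers(0, n))
            seq = doubled[start : start + length]
        else:
            start = int(rng.integers(0, n - length + 1))
            seq = genome[start : start + length]
        if config.substitution_rate > 0:
            seq = _mutate(seq, config.substitution_rate, rng)
        reads.append(Read(f"read_{i + 1}", seq))
    return ReadSet(reads)


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    arr = np.array(list(seq))
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[int(rng.integers(0, 3))]
    return "".join(arr)
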