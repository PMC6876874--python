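"""Seeded synthetic fixtures: i.i.d. genomes with planted recognition sites,
N-run gaps, toy annotation tracks, and paired-end template files.

The generator stands in for a real assembly in tests: background sequence is
drawn i.i.d. from a configurable base composition, gap runs are overwritten
with N, and recognition motifs are planted last at known coordinates (so
background chance occurrences of the same motifs remain and must be accounted
for by the scanner, not suppressed).  One integer seed drives a single
``numpy.random.default_rng`` stream, so every output is byte-reproducible.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence, Union

import numpy as np

from .annotate import RegionSet
from .motifs import REGISTRY, EnzymeSpec, SiteHit, expand_motif

__all__ = [
    "SimulationConfig",
    "SimulatedGenome",
    "simulate_genome",
    "random_sequence",
    "write_fasta",
    "simulate_fragments_bedpe",
    "write_bedpe",
    "constant_lengths",
    "lognormal_lengths",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: A length sampler: (rng, size) -> int64 array of template lengths.
LengthSampler = Callable[[np.random.Generator, int], np.ndarray]


@dataclass
class SimulationConfig:
    """Parameters of one synthetic chromosome.

    ``gap_runs`` are (start, length) N runs; ``planted_sites`` are
    (enzyme name, position) recognition sites overwritten into the
    background.  Planted sites must fit in the sequence and must not touch a
    gap run, which is validated up front.
    """

    seed: int
    length: int
    composition: Sequence[float] = (0.25, 0.25, 0.25, 0.25)
    gap_runs: Sequence[tuple[int, int]] = ()
    planted_sites: Sequence[tuple[str, int]] = ()
    name: str = "sim"
    registry: Mapping[str, EnzymeSpec] = field(default_factory=lambda: dict(REGISTRY))

    def validate(self) -> None:
        if self.length <= 0:
            raise ValueError("genome length must be positive")
        probs = np.asarray(self.composition, dtype=float)
        if probs.shape != (4,) or np.any(probs < 0) or abs(probs.sum() - 1) > 1e-9:
            raise ValueError("composition must be 4 nonnegative probabilities summing to 1")
        gaps = []
        for start, glen in self.gap_runs:
            if glen <= 0 or start < 0 or start + glen > self.length:
                raise ValueError(f"gap run ({start},{glen}) out of bounds")
            gaps.append((start, start + glen))
        for enzyme, pos in self.planted_sites:
            if enzyme not in self.registry:
                raise ValueError(f"unknown enzyme {enzyme!r} in planted sites")
            mlen = self.registry[enzyme].motif_length
            if pos < 0 or pos + mlen > self.length:
                raise ValueError(f"planted site {enzyme}@{pos} out of bounds")
            for gs, ge in gaps:
                if pos < ge and gs < pos + mlen:
                    raise ValueError(
                        f"planted site {enzyme}@{pos} overlaps gap run [{gs},{ge})"
                    )


@dataclass
class SimulatedGenome:
    """A synthetic chromosome plus its ground truth."""

    name: str
    sequence: str
    planted: list[SiteHit]
    gaps: list[tuple[int, int]]  # half-open [start, end)

    def gap_track(self) -> RegionSet:
        rs = RegionSet("gap")
        for start, end in self.gaps:
            rs.add(self.name, start, end)
        rs.sort()
        return rs


def random_sequence(
    rng: np.random.Generator,
    length: int,
    composition: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
) -> str:
    """i.i.d. DNA string of the given base composition (A,C,G,T order)."""
    probs = np.asarray(composition, dtype=float)
    if np.allclose(probs, 0.25):
        idx = rng.integers(0, 4, size=length)
    else:
        idx = rng.choice(4, size=length, p=probs)
    return _BASES[idx].tobytes().decode("ascii")


def simulate_genome(config: SimulationConfig) -> SimulatedGenome:
    """Generate one chromosome per the config; deterministic given the seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    seq = np.frombuffer(
        random_sequence(rng, config.length, config.composition).encode("ascii"),
        dtype=np.uint8,
    ).copy()
    gaps = []
    for start, glen in config.gap_runs:
        seq[start : start + glen] = ord("N")
        gaps.append((start, start + glen))
    planted = []
    for enzyme, pos in config.planted_sites:
        spec = config.registry[enzyme]
        words = sorted(expand_motif(spec.recognition))
        word = words[rng.integers(len(words))]
        seq[pos : pos + len(word)] = np.frombuffer(word.encode("ascii"), dtype=np.uint8)
        planted.append(SiteHit(config.name, pos, enzyme))
    planted.sort(key=lambda h: (h.pos, h.enzyme))
    return SimulatedGenome(config.name, seq.tobytes().decode("ascii"), planted, gaps)


def write_fasta(
    genomes: Union[SimulatedGenome, Sequence[SimulatedGenome]],
    path: Union[str, Path],
    width: int = 60,
) -> None:
    """Write one or more simulated chromosomes as (optionally gzipped) FASTA."""
    if isinstance(genomes, SimulatedGenome):
        genomes = [genomes]
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as out:
        for g in genomes:
            out.write(f">{g.name}\n")
            for i in range(0, len(g.sequence), width):
                out.write(g.sequence[i : i + width] + "\n")


def constant_lengths(value: int) -> LengthSampler:
    def sample(rng: np.random.Generator, size: int) -> np.ndarray:
        return np.full(size, value, dtype=np.int64)

    return sample


def lognormal_lengths(median: float, sigma: float = 0.35) -> LengthSampler:
    """Log-normal template lengths with the given median (typical for
    size-selected sequencing libraries)."""

    def sample(rng: np.random.Generator, size: int) -> np.ndarray:
        return np.maximum(
            1, rng.lognormal(np.log(median), sigma, size).astype(np.int64)
        )

    return sample


def simulate_fragments_bedpe(
    track: RegionSet,
    length_samplers: Mapping[str, LengthSampler],
    n_per_class: int,
    seed: int,
    read_length: int = 50,
) -> tuple[list[tuple[str, int, int, str, int, int]], dict[str, float]]:
    """Draw paired-end template intervals with midpoints planted per class.

    For each class label, ``n_per_class`` template midpoints are placed
    uniformly over the class's merged intervals (weighted by interval length)
    and lengths drawn from the class's sampler.  Returns BEDPE records
    (outermost read intervals of each pair) and the truth per-class median
    template length actually drawn.
    """
    if n_per_class < 0:
        raise ValueError("n_per_class must be >= 0")
    rng = np.random.default_rng(seed)
    records: list[tuple[str, int, int, str, int, int]] = []
    truth: dict[str, float] = {}
    for label in sorted(length_samplers):
        merged = track.merged(label)
        if not merged:
            raise ValueError(f"class {label!r} has no intervals in track {track.name!r}")
        chroms = sorted(merged)
        spans = []
        for chrom in chroms:
            starts, ends = merged[chrom]
            for s, e in zip(starts, ends):
                spans.append((chrom, int(s), int(e)))
        weights = np.array([e - s for _, s, e in spans], dtype=float)
        weights /= weights.sum()
        lengths = length_samplers[label](rng, n_per_class)
        truth[label] = float(np.median(lengths)) if n_per_class else float("nan")
        span_idx = rng.choice(len(spans), size=n_per_class, p=weights)
        for i in range(n_per_class):
            chrom, s, e = spans[span_idx[i]]
            mid = int(rng.integers(s, e))
            tlen = int(lengths[i])
            start = max(0, mid - tlen // 2)
            end = start + tlen
            rlen = min(read_length, tlen)
            records.append((chrom, start, start + rlen, chrom, end - rlen, end))
    return records, truth


def write_bedpe(
    records: Sequence[tuple[str, int, int, str, int, int]],
    path: Union[str, Path],
) -> None:
    with open(path, "w") as out:
        for c1, s1, e1, c2, s2, e2 in records:
            out.write(f"{c1}\t{s1}\t{e1}\t{c2}\t{s2}\t{e2}\n")
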