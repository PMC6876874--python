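"""Fragmentation statistics from cut-site coordinates.

Cutting a chromosome of length L at n distinct internal coordinates yields
n+1 half-open fragments that tile the chromosome exactly.  Fragment
boundaries are recognition-site START coordinates; the chemical cut offset
within the site is metadata only.  From the fragment set this module derives
the headline assay-design quantities: the fragment-size distribution, the
fraction of the genome cut below a size threshold, the "refractory" fragments
that remain above it, and the analytic expected spacing of a motif panel
under an i.i.d. base model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence, Union

import numpy as np

from .motifs import CutSiteIndex, EnzymeSpec, expand_motif, is_palindromic, \
    reverse_complement_motif

__all__ = [
    "FragmentSet",
    "RefractoryRegion",
    "DigestReport",
    "fragments_from_sites",
    "genome_fraction_below",
    "refractory_regions",
    "expected_site_spacing",
    "fragment_size_histogram",
    "digest_report",
    "write_fragments_bed",
    "write_regions_bed",
]

_BASES = "ACGT"


def fragments_from_sites(
    chrom_length: int, site_positions: Sequence[int] | np.ndarray
) -> list[tuple[int, int]]:
    """Half-open fragment intervals implied by sorted cut coordinates.

    ``n`` distinct positions in ``(0, chrom_length)`` produce ``n + 1``
    fragments ``[0,p1), [p1,p2), ..., [pn, chrom_length)``.  A site at
    coordinate 0 and duplicate coordinates are dropped so zero-length
    fragments cannot occur.
    """
    if chrom_length <= 0:
        raise ValueError(f"chromosome length must be positive, got {chrom_length}")
    pos = np.asarray(site_positions, dtype=np.int64)
    if pos.size:
        if np.any(np.diff(pos) < 0):
            raise ValueError("site positions must be sorted ascending")
        if pos[0] < 0:
            raise ValueError(f"negative site position {pos[0]}")
        if pos[-1] >= chrom_length:
            raise ValueError(
                f"site position {int(pos[-1])} >= chromosome length {chrom_length}"
            )
        pos = np.unique(pos)
        pos = pos[pos > 0]
    edges = np.concatenate(([0], pos, [chrom_length]))
    return [(int(s), int(e)) for s, e in zip(edges[:-1], edges[1:])]


@dataclass
class FragmentSet:
    """Per-chromosome fragment tilings.

    ``boundaries[chrom]`` holds the interior cut coordinates (sorted, distinct,
    excluding 0 and the chromosome end); fragments are reconstructed on the
    fly.  The tiling invariant — fragment lengths sum to the chromosome
    length — holds by construction and is asserted on access.
    """

    chrom_lengths: dict[str, int] = field(default_factory=dict)
    boundaries: dict[str, np.ndarray] = field(default_factory=dict)

    @classmethod
    def from_index(cls, index: CutSiteIndex) -> "FragmentSet":
        fs = cls()
        for chrom, length in index.chrom_lengths.items():
            pos = index.positions(chrom)
            pos = pos[(pos > 0) & (pos < length)]
            fs.chrom_lengths[chrom] = length
            fs.boundaries[chrom] = pos
        return fs

    @classmethod
    def from_sites(cls, chrom_lengths: Mapping[str, int],
                   sites: Mapping[str, Sequence[int]]) -> "FragmentSet":
        fs = cls()
        for chrom, length in chrom_lengths.items():
            frags = fragments_from_sites(length, sites.get(chrom, []))
            fs.chrom_lengths[chrom] = length
            fs.boundaries[chrom] = np.array([s for s, _ in frags[1:]], dtype=np.int64)
        return fs

    def intervals(self, chrom: str) -> list[tuple[int, int]]:
        length = self.chrom_lengths[chrom]
        edges = np.concatenate(([0], self.boundaries[chrom], [length]))
        return [(int(s), int(e)) for s, e in zip(edges[:-1], edges[1:])]

    def iter_intervals(self) -> Iterator[tuple[str, int, int]]:
        for chrom in self.chrom_lengths:
            for start, end in self.intervals(chrom):
                yield chrom, start, end

    def lengths(self, chrom: str | None = None) -> np.ndarray:
        if chrom is not None:
            edges = np.concatenate(
                ([0], self.boundaries[chrom], [self.chrom_lengths[chrom]])
            )
            out = np.diff(edges)
            assert out.sum() == self.chrom_lengths[chrom], "tiling broken"
            return out
        parts = [self.lengths(c) for c in self.chrom_lengths]
        return np.concatenate(parts) if parts else np.empty(0, dtype=np.int64)

    def n_fragments(self) -> int:
        return sum(b.size + 1 for b in self.boundaries.values())

    def total_length(self) -> int:
        return sum(self.chrom_lengths.values())


@dataclass
class RefractoryRegion:
    """A fragment that remains longer than the size cutoff after digestion.

    ``labels`` is filled by the annotation step with the overlapping
    annotation tracks (gap / blacklist / repeat ...); a region with no label
    is a "unique" poorly fragmentable region.
    """

    chrom: str
    start: int
    end: int
    labels: set[str] = field(default_factory=set)

    @property
    def length(self) -> int:
        return self.end - self.start


def genome_fraction_below(
    fragset: FragmentSet,
    threshold: int = 1000,
    denominator: str = "assembly",
    gap_bp: int = 0,
) -> float:
    """Fraction of the genome predicted to be cut into fragments shorter than
    ``threshold`` bp (strict ``<``).

    ``denominator="assembly"`` divides by the full assembly length including
    N runs; ``denominator="nongap"`` divides by assembly length minus
    ``gap_bp`` (total hard-masked bases, e.g. ``CutSiteIndex.total_n_bases()``).
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if not fragset.chrom_lengths:
        raise ValueError("empty fragment set")
    lengths = fragset.lengths()
    below = int(lengths[lengths < threshold].sum())
    total = fragset.total_length()
    if denominator == "assembly":
        denom = total
    elif denominator == "nongap":
        denom = total - gap_bp
        if denom <= 0:
            raise ValueError("gap length exceeds assembly length")
    else:
        raise ValueError(f"unknown denominator mode {denominator!r}")
    return below / denom


def refractory_regions(
    fragset: FragmentSet, min_length: int = 1000
) -> list[RefractoryRegion]:
    """Whole fragments strictly longer than ``min_length`` bp, in BED order.

    These are the regions the digest leaves poorly fragmented; with the
    four-enzyme panel on a real genome they concentrate in assembly gaps,
    blacklist regions and repeats.
    """
    if min_length <= 0:
        raise ValueError("min_length must be positive")
    out = [
        RefractoryRegion(chrom, start, end)
        for chrom, start, end in fragset.iter_intervals()
        if end - start > min_length
    ]
    out.sort(key=lambda r: (r.chrom, r.start))
    return out


def _panel_density(panel: Sequence[EnzymeSpec], probs: np.ndarray,
                   both_strands: bool = True) -> float:
    density = 0.0
    for enzyme in panel:
        words = set(expand_motif(enzyme.recognition))
        if both_strands and not is_palindromic(enzyme.recognition):
            words |= expand_motif(reverse_complement_motif(enzyme.recognition))
        for word in words:
            p = 1.0
            for base in word:
                p *= probs[_BASES.index(base)]
            density += p
    return density


def expected_site_spacing(
    panel: Sequence[EnzymeSpec] | EnzymeSpec,
    composition: Mapping[str, float] | Sequence[float] | None = None,
    both_strands: bool = True,
) -> float:
    """Expected distance in bp between consecutive recognition sites of a
    panel in an i.i.d. sequence with the given base composition.

    By linearity of expectation the per-position match density is
    ``sum over enzymes, over concrete expansions, of prod_i P(base_i)`` and the
    expected spacing is its reciprocal (edge effects ignored).  A single fully
    specified 4-bp cutter under uniform composition gives ``4**4 = 256`` bp.
    """
    if isinstance(panel, EnzymeSpec):
        panel = [panel]
    if not panel:
        raise ValueError("empty enzyme panel")
    if composition is None:
        probs = np.full(4, 0.25)
    elif isinstance(composition, Mapping):
        probs = np.array([float(composition.get(b, 0.0)) for b in _BASES])
    else:
        probs = np.asarray(composition, dtype=float)
        if probs.shape != (4,):
            raise ValueError("composition must give probabilities for A,C,G,T")
    if np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("base composition must be nonnegative and sum to 1")
    density = _panel_density(panel, probs, both_strands)
    if density == 0.0:
        raise ValueError("panel motifs are impossible under this composition")
    return 1.0 / density


def fragment_size_histogram(
    fragset: FragmentSet, bin_edges: Sequence[int]
) -> tuple[np.ndarray, int]:
    """Histogram of fragment lengths over half-open bins ``[e_i, e_{i+1})``
    plus an overflow count for lengths >= the last edge.

    Returns ``(counts, overflow)``; ``counts.sum() + overflow`` equals the
    number of fragments below the first edge subtracted — with edges starting
    at 0 it equals the total fragment count.
    """
    edges = np.asarray(bin_edges, dtype=np.int64)
    if edges.size < 2:
        raise ValueError("need at least two bin edges")
    if np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    lengths = fragset.lengths()
    idx = np.searchsorted(edges, lengths, side="right") - 1
    counts = np.bincount(idx[(idx >= 0) & (idx < edges.size - 1)],
                         minlength=edges.size - 1)
    overflow = int((lengths >= edges[-1]).sum())
    return counts, overflow


@dataclass
class DigestReport:
    """Aggregate digestion statistics for one genome + panel run."""

    total_length: int
    total_sites: int
    n_fragments: int
    mean_fragment_bp: float
    median_fragment_bp: float
    fraction_below_assembly: float
    fraction_below_nongap: float
    threshold_bp: int
    n_at_threshold: int
    refractory: list[RefractoryRegion]
    histogram_edges: list[int]
    histogram_counts: list[int]
    histogram_overflow: int

    def to_dict(self) -> dict:
        return {
            "total_length_bp": self.total_length,
            "total_sites": self.total_sites,
            "n_fragments": self.n_fragments,
            "mean_fragment_bp": round(self.mean_fragment_bp, 3),
            "median_fragment_bp": self.median_fragment_bp,
            "threshold_bp": self.threshold_bp,
            "fraction_below_threshold_assembly": round(self.fraction_below_assembly, 6),
            "fraction_below_threshold_nongap": round(self.fraction_below_nongap, 6),
            "n_fragments_exactly_threshold": self.n_at_threshold,
            "n_refractory_regions": len(self.refractory),
        }

    def to_text(self) -> str:
        lines = [f"{k}\t{v}" for k, v in self.to_dict().items()]
        return "\n".join(lines) + "\n"


def digest_report(
    index: CutSiteIndex,
    threshold: int = 1000,
    min_refractory: int = 1000,
    bin_edges: Sequence[int] = tuple(range(0, 2001, 100)),
) -> tuple[FragmentSet, DigestReport]:
    """Fragment a scanned genome and assemble the standard digest report."""
    fragset = FragmentSet.from_index(index)
    lengths = fragset.lengths()
    counts, overflow = fragment_size_histogram(fragset, bin_edges)
    report = DigestReport(
        total_length=fragset.total_length(),
        total_sites=index.total_sites(),
        n_fragments=fragset.n_fragments(),
        mean_fragment_bp=float(lengths.mean()),
        median_fragment_bp=float(np.median(lengths)),
        fraction_below_assembly=genome_fraction_below(fragset, threshold, "assembly"),
        fraction_below_nongap=genome_fraction_below(
            fragset, threshold, "nongap", gap_bp=index.total_n_bases()
        ),
        threshold_bp=threshold,
        n_at_threshold=int((lengths == threshold).sum()),
        refractory=refractory_regions(fragset, min_refractory),
        histogram_edges=list(bin_edges),
        histogram_counts=[int(c) for c in counts],
        histogram_overflow=overflow,
    )
    return fragset, report


def write_fragments_bed(fragset: FragmentSet, path: Union[str, Path]) -> int:
    """BED4 of all fragments, name = length."""
    n = 0
    with open(path, "w") as out:
        for chrom, start, end in fragset.iter_intervals():
            out.write(f"{chrom}\t{start}\t{end}\t{end - start}\n")
            n += 1
    return n


def write_regions_bed(regions: Iterable[RefractoryRegion],
                      path: Union[str, Path]) -> int:
    """BED4 of refractory regions; name = comma-joined labels or length."""
    n = 0
    with open(path, "w") as out:
        for r in regions:
            name = ",".join(sorted(r.labels)) if r.labels else str(r.length)
            out.write(f"{r.chrom}\t{r.start}\t{r.end}\t{name}\n")
            n += 1
    return n
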