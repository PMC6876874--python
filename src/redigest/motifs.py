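"""Restriction enzymes as IUPAC-degenerate motifs, and recognition-site scanning.

A restriction endonuclease is modelled by its recognition sequence written in
the IUPAC nucleotide alphabet (e.g. MvaI = ``CCWGG`` where W is A or T, HinfI =
``GANTC`` where N is any base).  Scanning reports the 0-based start coordinate
of every occurrence of the motif in a DNA sequence, including overlapping
occurrences; hard-masked ``N`` bases never match, soft-masked lowercase bases
are treated as ordinary sequence.

Coordinates follow the BED convention throughout: 0-based, half-open.
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Iterable, Iterator, Mapping, NamedTuple, Sequence, Union

import numpy as np
from Bio import SeqIO

__all__ = [
    "IUPAC_CODES",
    "IUPAC_COMPLEMENT",
    "EnzymeSpec",
    "SiteHit",
    "CutSiteIndex",
    "REGISTRY",
    "PAPER_PANEL",
    "get_panel",
    "load_enzyme_table",
    "expand_motif",
    "reverse_complement_motif",
    "is_palindromic",
    "scan_sequence",
    "scan_genome",
    "write_sites_bed",
]

#: IUPAC nucleotide code -> set of concrete bases it stands for.
IUPAC_CODES: Mapping[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

#: Complement at the IUPAC-code level; an involution (complement of complement
#: is the identity) because complementation is a bijection on {A,C,G,T}.
IUPAC_COMPLEMENT: Mapping[str, str] = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}

_BASE_TO_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def _validate_motif(recognition: str) -> str:
    """Uppercase and validate an IUPAC motif, naming the first bad position."""
    if not recognition:
        raise ValueError("recognition motif must be non-empty")
    motif = recognition.upper()
    for i, code in enumerate(motif):
        if code not in IUPAC_CODES:
            raise ValueError(
                f"invalid IUPAC code {code!r} at position {i} of motif {recognition!r}"
            )
    return motif


@dataclass(frozen=True)
class EnzymeSpec:
    """A named restriction enzyme.

    Parameters
    ----------
    name:
        Enzyme identifier (e.g. ``"AluI"``).
    recognition:
        Recognition sequence in IUPAC codes, length >= 4.
    cut_offset:
        Optional position of the chemical cut within the top-strand
        recognition site, in ``[0, len(recognition)]``.  Carried as metadata;
        fragmentation uses recognition-site start coordinates by default.
    """

    name: str
    recognition: str
    cut_offset: int | None = None

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("enzyme name must be non-empty")
        motif = _validate_motif(self.recognition)
        if len(motif) < 4:
            raise ValueError(
                f"recognition motif {self.recognition!r} shorter than 4 bp"
            )
        object.__setattr__(self, "recognition", motif)
        if self.cut_offset is not None and not 0 <= self.cut_offset <= len(motif):
            raise ValueError(
                f"cut_offset {self.cut_offset} outside [0, {len(motif)}]"
            )

    @property
    def motif_length(self) -> int:
        return len(self.recognition)

    def is_palindromic(self) -> bool:
        return is_palindromic(self.recognition)


#: Built-in enzyme registry.  The cut offsets are standard enzymology metadata
#: (blunt/sticky cut positions) and are not used for fragmentation by default.
REGISTRY: Mapping[str, EnzymeSpec] = {
    e.name: e
    for e in (
        EnzymeSpec("AluI", "AGCT", 2),
        EnzymeSpec("SaqAI", "TTAA", 1),
        EnzymeSpec("HinfI", "GANTC", 1),
        EnzymeSpec("MvaI", "CCWGG", 2),
        EnzymeSpec("BsuRI", "GGCC", 2),
    )
}

#: The four-enzyme panel used for chromatin fragmentation in RAT-ChIP.
PAPER_PANEL: tuple[str, ...] = ("AluI", "SaqAI", "MvaI", "HinfI")


def get_panel(names: Iterable[str]) -> list[EnzymeSpec]:
    """Resolve enzyme names against the registry."""
    panel = []
    for name in names:
        if name not in REGISTRY:
            known = ", ".join(sorted(REGISTRY))
            raise ValueError(f"unknown enzyme {name!r}; registry has: {known}")
        panel.append(REGISTRY[name])
    if not panel:
        raise ValueError("empty enzyme panel")
    return panel


def load_enzyme_table(path: Union[str, Path]) -> list[EnzymeSpec]:
    """Read an enzyme panel from a whitespace/tab-separated text file.

    Each non-comment line: ``name  recognition  [cut_offset]``.
    """
    panel: list[EnzymeSpec] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) not in (2, 3):
                raise ValueError(
                    f"{path}:{lineno}: expected 'name recognition [cut_offset]'"
                )
            name, recognition = fields[0], fields[1]
            if name in seen:
                raise ValueError(f"{path}:{lineno}: duplicate enzyme {name!r}")
            seen.add(name)
            offset = int(fields[2]) if len(fields) == 3 else None
            panel.append(EnzymeSpec(name, recognition, offset))
    if not panel:
        raise ValueError(f"{path}: no enzymes defined")
    return panel


class SiteHit(NamedTuple):
    """One recognition-site occurrence: 0-based start of the matched window."""

    chrom: str
    pos: int
    enzyme: str
    strand: str = "+"


def expand_motif(recognition: str) -> set[str]:
    """Cartesian expansion of an IUPAC motif into concrete DNA strings.

    ``CCWGG -> {CCAGG, CCTGG}``; the result size is the product of the
    per-position base-set sizes.
    """
    motif = _validate_motif(recognition)
    return {"".join(bases) for bases in product(*(sorted(IUPAC_CODES[c]) for c in motif))}


def reverse_complement_motif(recognition: str) -> str:
    """Reverse complement at the IUPAC-code level; applying twice is identity."""
    motif = _validate_motif(recognition)
    return "".join(IUPAC_COMPLEMENT[c] for c in reversed(motif))


def is_palindromic(recognition: str) -> bool:
    """True iff the motif equals its own reverse complement (IUPAC level).

    All five registry enzymes are palindromic, as is typical for Type II
    restriction sites.
    """
    motif = _validate_motif(recognition)
    return reverse_complement_motif(motif) == motif


def _motif_regex(motif: str) -> re.Pattern[str]:
    # Lookahead so overlapping occurrences are all reported; character classes
    # contain only A/C/G/T, so windows touching an N can never match.
    body = "".join(
        c if len(IUPAC_CODES[c]) == 1 else "[" + "".join(sorted(IUPAC_CODES[c])) + "]"
        for c in motif
    )
    return re.compile(f"(?=({body}))")


_VALID_SEQ = re.compile(r"[^ACGTN]")


def _prepare_sequence(seq: str) -> str:
    folded = seq.upper()
    bad = _VALID_SEQ.search(folded)
    if bad is not None:
        raise ValueError(
            f"non-nucleotide character {bad.group()!r} at position {bad.start()}"
        )
    return folded


def _scan_enzyme(seq: str, enzyme: EnzymeSpec, both_strands: bool) -> list[tuple[int, str]]:
    """(pos, strand) pairs for one enzyme, deduplicated by position."""
    hits = {m.start(): "+" for m in _motif_regex(enzyme.recognition).finditer(seq)}
    if both_strands and not enzyme.is_palindromic():
        rc = reverse_complement_motif(enzyme.recognition)
        for m in _motif_regex(rc).finditer(seq):
            hits.setdefault(m.start(), "-")
    return sorted(hits.items())


def scan_sequence(
    seq: str,
    panel: Sequence[EnzymeSpec],
    both_strands: bool = True,
    chrom: str = "",
) -> list[SiteHit]:
    """Locate every recognition-site occurrence of a panel in one sequence.

    Overlapping occurrences are all reported; windows overlapping an ``N`` are
    never matches; lowercase (soft-masked) input scans identically to its
    uppercase version.  Output is sorted by position, ties broken by enzyme
    name.  For palindromic motifs scanning one strand or both is equivalent
    and each site is emitted once with strand ``+``.
    """
    if not panel:
        raise ValueError("empty enzyme panel")
    folded = _prepare_sequence(seq)
    hits: list[SiteHit] = []
    for enzyme in panel:
        hits.extend(
            SiteHit(chrom, pos, enzyme.name, strand)
            for pos, strand in _scan_enzyme(folded, enzyme, both_strands)
        )
    hits.sort(key=lambda h: (h.pos, h.enzyme))
    return hits


@dataclass
class CutSiteIndex:
    """Per-chromosome recognition-site coordinates for an enzyme panel.

    ``sites[chrom][enzyme]`` is a sorted int64 array of occurrence starts;
    ``strands`` holds the matching strand characters (all ``+`` for
    palindromic motifs).  ``n_bases`` counts hard-masked N bases per
    chromosome so callers can compute gap-excluded denominators.
    """

    chrom_lengths: dict[str, int] = field(default_factory=dict)
    sites: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)
    strands: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)
    motif_lengths: dict[str, int] = field(default_factory=dict)
    n_bases: dict[str, int] = field(default_factory=dict)

    def add_chromosome(self, chrom: str, seq: str, panel: Sequence[EnzymeSpec],
                       both_strands: bool = True) -> None:
        if chrom in self.chrom_lengths:
            raise ValueError(f"duplicate sequence name {chrom!r}")
        folded = _prepare_sequence(seq)
        self.chrom_lengths[chrom] = len(folded)
        self.n_bases[chrom] = folded.count("N")
        per_enzyme: dict[str, np.ndarray] = {}
        per_strand: dict[str, np.ndarray] = {}
        for enzyme in panel:
            pairs = _scan_enzyme(folded, enzyme, both_strands)
            per_enzyme[enzyme.name] = np.fromiter(
                (p for p, _ in pairs), dtype=np.int64, count=len(pairs)
            )
            per_strand[enzyme.name] = np.array([s for _, s in pairs], dtype="U1")
            self.motif_lengths[enzyme.name] = enzyme.motif_length
        self.sites[chrom] = per_enzyme
        self.strands[chrom] = per_strand

    @property
    def enzymes(self) -> list[str]:
        return sorted(self.motif_lengths)

    def total_sites(self) -> int:
        return sum(
            arr.size for per in self.sites.values() for arr in per.values()
        )

    def total_n_bases(self) -> int:
        return sum(self.n_bases.values())

    def total_length(self) -> int:
        return sum(self.chrom_lengths.values())

    def positions(self, chrom: str) -> np.ndarray:
        """Distinct sorted site coordinates on one chromosome, panel-wide."""
        per = self.sites.get(chrom, {})
        if not per:
            return np.empty(0, dtype=np.int64)
        return np.unique(np.concatenate(list(per.values())))

    def iter_hits(self, chrom: str) -> Iterator[SiteHit]:
        """All hits on one chromosome, sorted by pos then enzyme name."""
        per = self.sites.get(chrom, {})
        rows = [
            (int(pos), name, str(strand))
            for name in sorted(per)
            for pos, strand in zip(per[name], self.strands[chrom][name])
        ]
        rows.sort()
        for pos, name, strand in rows:
            yield SiteHit(chrom, pos, name, strand)


def _open_fasta(source: Union[str, Path]):
    path = Path(source)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def scan_genome(
    fasta: Union[str, Path, Mapping[str, str]],
    panel: Sequence[EnzymeSpec],
    both_strands: bool = True,
) -> CutSiteIndex:
    """Scan every sequence of a genome (FASTA path, optionally gzipped, or a
    name->sequence mapping) and build a :class:`CutSiteIndex`.

    Sequences are processed one at a time so memory stays bounded by the
    largest chromosome.  Duplicate sequence names are an error.
    """
    if not panel:
        raise ValueError("empty enzyme panel")
    index = CutSiteIndex()
    if isinstance(fasta, Mapping):
        records: Iterable[tuple[str, str]] = fasta.items()
        for name, seq in records:
            index.add_chromosome(name, seq, panel, both_strands)
    else:
        with _open_fasta(fasta) as handle:
            n = 0
            for record in SeqIO.parse(handle, "fasta"):
                index.add_chromosome(record.id, str(record.seq), panel, both_strands)
                n += 1
        if n == 0:
            raise ValueError(f"{fasta}: no sequences found")
    return index


def write_sites_bed(index: CutSiteIndex, path: Union[str, Path]) -> int:
    """Write all hits as BED6 (start, start+motif length, enzyme, 0, strand).

    Returns the number of records written.
    """
    n = 0
    with open(path, "w") as out:
        for chrom in index.chrom_lengths:
            for hit in index.iter_hits(chrom):
                end = hit.pos + index.motif_lengths[hit.enzyme]
                out.write(
                    f"{hit.chrom}\t{hit.pos}\t{end}\t{hit.enzyme}\t0\t{hit.strand}\n"
                )
                n += 1
    return n
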