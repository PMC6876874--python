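"""Annotation-based classification of digestion results.

Two uses:

* label refractory regions by overlap with annotation tracks (assembly gaps,
  ENCODE blacklist, RepeatMasker repeats) — a region carries every track it
  overlaps by at least 1 bp, so labels are not mutually exclusive, and the
  regions overlapping no track are the "unique" poorly fragmentable genome;
* per-class digestion metrics against a labelled segmentation (e.g. a
  chromHMM chromatin-state BED): recognition sites per kb of class sequence,
  and mean/median predicted or observed (paired-end template) fragment length
  per class.

Sites are assigned to a class interval by their start coordinate; fragments
and sequenced templates by their midpoint, which keeps the assignment total
and single-valued when the classes partition the genome.  All interval
arithmetic is 0-based half-open (BED semantics); chromosome names are
compared verbatim unless ``normalize_chroms`` strips/adds the ``chr`` prefix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .digestion import FragmentSet, RefractoryRegion
from .motifs import CutSiteIndex

logger = logging.getLogger(__name__)

__all__ = [
    "RegionSet",
    "ClassificationSummary",
    "read_bed",
    "read_template_intervals",
    "classify_regions",
    "site_density_per_class",
    "fragment_length_per_class",
    "observed_fragment_lengths",
]


@dataclass
class RegionSet:
    """A named collection of genomic intervals, optionally labelled per
    interval (BED column 4, e.g. a chromHMM state).

    Unlabelled intervals take the set name as their class label.  Overlapping
    intervals within one set are permitted; per-class merged views are
    computed on demand.
    """

    name: str
    intervals: dict[str, list[tuple[int, int, str]]] = field(default_factory=dict)

    def add(self, chrom: str, start: int, end: int, label: str | None = None) -> None:
        if start >= end:
            raise ValueError(f"empty interval {chrom}:{start}-{end}")
        self.intervals.setdefault(chrom, []).append(
            (start, end, label if label is not None else self.name)
        )

    def sort(self) -> None:
        for ivs in self.intervals.values():
            ivs.sort()

    def labels(self) -> list[str]:
        return sorted({lab for ivs in self.intervals.values() for _, _, lab in ivs})

    def chroms(self) -> set[str]:
        return set(self.intervals)

    def is_empty(self) -> bool:
        return not any(self.intervals.values())

    def merged(self, label: str | None = None) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Per-chromosome merged (starts, ends) arrays, optionally for one label."""
        out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, ivs in self.intervals.items():
            picked = sorted(
                (s, e) for s, e, lab in ivs if label is None or lab == label
            )
            if not picked:
                continue
            starts, ends = [picked[0][0]], [picked[0][1]]
            for s, e in picked[1:]:
                if s <= ends[-1]:
                    ends[-1] = max(ends[-1], e)
                else:
                    starts.append(s)
                    ends.append(e)
            out[chrom] = (np.array(starts, dtype=np.int64),
                          np.array(ends, dtype=np.int64))
        return out

    def class_length(self, label: str | None = None) -> int:
        """Total merged bp covered, per label (or the whole set)."""
        return int(
            sum((e - s).sum() for s, e in self.merged(label).values())
        )


def _maybe_normalize(chrom: str, normalize: bool) -> str:
    if not normalize:
        return chrom
    return chrom[3:] if chrom.startswith("chr") else chrom


def read_bed(
    path: Union[str, Path],
    name: str | None = None,
    use_name_column: bool = False,
    normalize_chroms: bool = False,
) -> RegionSet:
    """Read BED3/BED4 into a :class:`RegionSet`.

    With ``use_name_column`` the 4th column becomes the per-interval class
    label (chromHMM-style segmentation); otherwise all intervals carry the
    set name (gap/blacklist/repeat-style track).
    """
    path = Path(path)
    rs = RegionSet(name or path.stem)
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 BED columns")
            chrom = _maybe_normalize(fields[0], normalize_chroms)
            start, end = int(fields[1]), int(fields[2])
            label = fields[3] if use_name_column and len(fields) > 3 else None
            rs.add(chrom, start, end, label)
    rs.sort()
    return rs


@dataclass
class ClassificationSummary:
    """Overlap breakdown of refractory regions against annotation tracks."""

    total: int
    per_label: dict[str, int]
    unique: int

    def to_frame(self) -> pd.DataFrame:
        rows = [("total", self.total)]
        rows += sorted(self.per_label.items())
        rows.append(("unlabelled", self.unique))
        return pd.DataFrame(rows, columns=["class", "n_regions"])


def _track_trees(track: RegionSet) -> dict[str, IntervalTree]:
    return {
        chrom: IntervalTree.from_tuples((s, e) for s, e, _ in ivs)
        for chrom, ivs in track.intervals.items()
        if ivs
    }


def classify_regions(
    regions: Sequence[RefractoryRegion],
    tracks: Mapping[str, RegionSet],
) -> ClassificationSummary:
    """Label each region with every track it overlaps by >= 1 bp.

    Mutates ``regions`` in place (fills ``labels``) and returns the summary:
    per-track overlap counts (non-exclusive, so they may sum to more than the
    number of labelled regions) and the count of regions overlapping no
    track at all.
    """
    if not tracks:
        raise ValueError("no annotation tracks given")
    trees = {name: _track_trees(t) for name, t in tracks.items()}
    region_chroms = {r.chrom for r in regions}
    track_chroms = set().union(*(t.chroms() for t in tracks.values()))
    missing = sorted(region_chroms - track_chroms)
    if missing and track_chroms:
        logger.warning(
            "chromosomes absent from every annotation track: %s",
            ", ".join(missing),
        )
    per_label = {name: 0 for name in tracks}
    unique = 0
    for region in regions:
        region.labels.clear()
        for name, by_chrom in trees.items():
            tree = by_chrom.get(region.chrom)
            if tree is not None and tree.overlaps(region.start, region.end):
                region.labels.add(name)
                per_label[name] += 1
        if not region.labels:
            unique += 1
    return ClassificationSummary(len(regions), per_label, unique)


def _assign_to_merged(
    merged: Mapping[str, tuple[np.ndarray, np.ndarray]],
    chrom: str,
    coords: np.ndarray,
) -> np.ndarray:
    """Boolean mask: which coordinates fall inside a merged interval."""
    if chrom not in merged or coords.size == 0:
        return np.zeros(coords.size, dtype=bool)
    starts, ends = merged[chrom]
    idx = np.searchsorted(starts, coords, side="right") - 1
    ok = idx >= 0
    ok[ok] &= coords[ok] < ends[idx[ok]]
    return ok


def site_density_per_class(
    index: CutSiteIndex,
    track: RegionSet,
    excluded_labels: Iterable[str] = (),
) -> pd.DataFrame:
    """Recognition sites per kb of merged class sequence, per class label.

    A site belongs to a class iff its start coordinate lies inside a class
    interval; density is ``1000 * sites / merged class length``.  Classes in
    ``excluded_labels`` (e.g. repeat-associated chromHMM states) are dropped.
    """
    excluded = set(excluded_labels)
    labels = [lab for lab in track.labels() if lab not in excluded]
    if not labels:
        raise ValueError("no class labels remain after exclusions")
    rows = []
    for label in labels:
        merged = track.merged(label)
        length = int(sum((e - s).sum() for s, e in merged.values()))
        n_sites = 0
        for chrom in index.sites:
            for arr in index.sites[chrom].values():
                n_sites += int(_assign_to_merged(merged, chrom, arr).sum())
        rows.append(
            {
                "class": label,
                "length_bp": length,
                "n_sites": n_sites,
                "sites_per_kb": 1000.0 * n_sites / length if length else 0.0,
            }
        )
    return pd.DataFrame(rows)


def _midpoint_lengths_per_class(
    track: RegionSet,
    excluded: set[str],
    chrom_iter: Iterable[tuple[str, np.ndarray, np.ndarray]],
) -> dict[str, np.ndarray]:
    """Collect interval lengths per class by midpoint membership.

    ``chrom_iter`` yields (chrom, midpoints, lengths) per chromosome.
    """
    labels = [lab for lab in track.labels() if lab not in excluded]
    if not labels:
        raise ValueError("no class labels remain after exclusions")
    merged_by_label = {lab: track.merged(lab) for lab in labels}
    acc: dict[str, list[np.ndarray]] = {lab: [] for lab in labels}
    for chrom, mids, lens in chrom_iter:
        for lab in labels:
            mask = _assign_to_merged(merged_by_label[lab], chrom, mids)
            if mask.any():
                acc[lab].append(lens[mask])
    return {
        lab: (np.concatenate(parts) if parts else np.empty(0, dtype=np.int64))
        for lab, parts in acc.items()
    }


def fragment_length_per_class(
    fragset: FragmentSet,
    track: RegionSet,
    excluded_labels: Iterable[str] = (),
) -> pd.DataFrame:
    """Mean/median predicted fragment length per class label.

    Each fragment is assigned to the class its midpoint falls in.  A class
    whose intervals contain no fragment midpoint is scored by the fragments
    that enclose its interval midpoints (the enclosing-fragment convention),
    so every class reports a length.
    """
    excluded = set(excluded_labels)

    def per_chrom():
        for chrom in fragset.chrom_lengths:
            ivs = np.array(fragset.intervals(chrom), dtype=np.int64)
            mids = (ivs[:, 0] + ivs[:, 1]) // 2
            yield chrom, mids, ivs[:, 1] - ivs[:, 0]

    per_class = _midpoint_lengths_per_class(track, excluded, per_chrom())
    rows = []
    for label, lens in sorted(per_class.items()):
        if lens.size == 0:
            lens = _enclosing_fragment_lengths(fragset, track, label)
        rows.append(
            {
                "class": label,
                "n_fragments": int(lens.size),
                "mean_bp": float(lens.mean()) if lens.size else float("nan"),
                "median_bp": float(np.median(lens)) if lens.size else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def _enclosing_fragment_lengths(
    fragset: FragmentSet, track: RegionSet, label: str
) -> np.ndarray:
    """Lengths of the fragments enclosing each class-interval midpoint."""
    out = []
    for chrom, (starts, ends) in track.merged(label).items():
        if chrom not in fragset.chrom_lengths:
            continue
        edges = np.concatenate(
            ([0], fragset.boundaries[chrom], [fragset.chrom_lengths[chrom]])
        )
        mids = (starts + ends) // 2
        mids = mids[mids < fragset.chrom_lengths[chrom]]
        idx = np.searchsorted(edges, mids, side="right") - 1
        out.append(edges[idx + 1] - edges[idx])
    return np.concatenate(out) if out else np.empty(0, dtype=np.int64)


def read_template_intervals(
    path: Union[str, Path],
    fmt: str = "auto",
    normalize_chroms: bool = False,
    max_malformed_fraction: float = 0.10,
) -> tuple[list[tuple[str, int, int]], int]:
    """Read sequenced-template intervals from BEDPE or 6-column BED.

    BEDPE rows (chrom1 start1 end1 chrom2 start2 end2) are collapsed to the
    outermost coordinates of the pair; inter-chromosomal pairs are malformed.
    BED rows use columns 1-3 directly.  Malformed rows are skipped and
    counted; more than ``max_malformed_fraction`` of them is a hard error.

    Returns ``(templates, n_malformed)``.
    """
    templates: list[tuple[str, int, int]] = []
    malformed = 0
    total = 0
    detected = fmt
    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            total += 1
            fields = line.split("\t")
            if detected == "auto":
                detected = _detect_template_format(fields)
            try:
                if detected == "bedpe":
                    c1, s1, e1, c2, s2, e2 = fields[:6]
                    if c1 != c2:
                        raise ValueError("interchromosomal pair")
                    start = min(int(s1), int(s2))
                    end = max(int(e1), int(e2))
                    chrom = c1
                else:
                    chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                if start >= end:
                    raise ValueError("empty template")
                templates.append(
                    (_maybe_normalize(chrom, normalize_chroms), start, end)
                )
            except (ValueError, IndexError):
                malformed += 1
    if total and malformed / total > max_malformed_fraction:
        raise ValueError(
            f"{path}: {malformed}/{total} malformed records "
            f"(> {max_malformed_fraction:.0%})"
        )
    if malformed:
        logger.warning("%s: skipped %d malformed records", path, malformed)
    return templates, malformed


def _detect_template_format(fields: Sequence[str]) -> str:
    # BEDPE column 6 is an integer end2; BED6 column 6 is a strand character.
    if len(fields) >= 6:
        try:
            int(fields[4]), int(fields[5])
            int(fields[1]), int(fields[2])
            # col 4 must look like a chromosome, not a numeric score
            if not fields[3].isdigit():
                return "bedpe"
        except ValueError:
            pass
    return "bed"


def observed_fragment_lengths(
    templates: Union[str, Path, Sequence[tuple[str, int, int]]],
    track: RegionSet,
    excluded_labels: Iterable[str] = (),
) -> pd.DataFrame:
    """Median observed template (fragment) length per class label.

    ``templates`` is a BEDPE/BED path or an iterable of (chrom, start, end)
    template intervals; template length is ``end - start`` and each template
    is assigned to the class its midpoint falls in.
    """
    if isinstance(templates, (str, Path)):
        templates, _ = read_template_intervals(templates)
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in templates:
        by_chrom.setdefault(chrom, []).append((start, end))

    def per_chrom():
        for chrom, ivs in by_chrom.items():
            arr = np.array(ivs, dtype=np.int64)
            yield chrom, (arr[:, 0] + arr[:, 1]) // 2, arr[:, 1] - arr[:, 0]

    per_class = _midpoint_lengths_per_class(track, set(excluded_labels), per_chrom())
    rows = [
        {
            "class": label,
            "n_templates": int(lens.size),
            "mean_bp": float(lens.mean()) if lens.size else float("nan"),
            "median_bp": float(np.median(lens)) if lens.size else float("nan"),
        }
        for label, lens in sorted(per_class.items())
    ]
    return pd.DataFrame(rows)
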