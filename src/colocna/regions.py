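"""Minimal common regions: recurrent aberrations shared across samples.

A minimal common region (MCR) is a maximal genomic interval over which
the set of samples carrying a same-sign aberration is constant and at
least ``min_support`` strong.  Adjacent intervals with different
supporter sets are kept separate, so the minimal shared core of any
overlap is always its own record.  Regions are confirmed by reciprocal
overlap with consensus regions from an independent second caller, then
filtered to candidate size (here <= 3 Mb, after discarding regions
<= 1 kb), and labelled by the lesion groups (adenoma/carcinoma) of their
supporting samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .segmentation import AberrantSegment

__all__ = [
    "MinimalCommonRegion",
    "find_minimal_common_regions",
    "confirm_regions",
    "filter_candidate_regions",
    "label_group_occurrence",
]

DEFAULT_MIN_SUPPORT = 2
DEFAULT_MIN_SIZE = 1_000  # strict lower bound, bp
DEFAULT_MAX_SIZE = 3_000_000  # inclusive upper bound, bp
DEFAULT_RECIPROCAL_OVERLAP = 0.5

_CLASS_TO_GROUP = {"A": "adenoma", "T": "carcinoma"}


@dataclass(frozen=True)
class MinimalCommonRegion:
    """A recurrent gain or loss interval (1-based inclusive bp)."""

    chromosome: str
    start: int
    end: int
    state: str
    supporting_samples: frozenset[str]
    groups: frozenset[str] = field(default_factory=frozenset)
    confirmed: bool | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("region start > end")
        if self.state not in ("gain", "loss"):
            raise ValueError(f"unknown state {self.state!r}")
        object.__setattr__(
            self, "supporting_samples", frozenset(self.supporting_samples)
        )
        object.__setattr__(self, "groups", frozenset(self.groups))

    @property
    def support(self) -> int:
        return len(self.supporting_samples)

    @property
    def size(self) -> int:
        return self.end - self.start + 1


def find_minimal_common_regions(
    segments: Iterable[AberrantSegment],
    min_support: int = DEFAULT_MIN_SUPPORT,
    min_size: int = DEFAULT_MIN_SIZE,
) -> list[MinimalCommonRegion]:
    """Sweep-line extraction of recurrent same-sign intervals.

    For each (chromosome, state), segment endpoints partition the axis
    into atomic intervals with a constant supporting-sample set; adjacent
    atoms with identical supporter sets are merged, and merged intervals
    with support >= ``min_support`` and size strictly > ``min_size`` are
    emitted, sorted by coordinate.  Permuting input order does not change
    the result.
    """
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    grouped: dict[tuple[str, str], list[AberrantSegment]] = {}
    for seg in segments:
        grouped.setdefault((seg.chromosome, seg.state), []).append(seg)
    out: list[MinimalCommonRegion] = []
    for (chrom, state), segs in grouped.items():
        # breakpoints: interval [b_i, b_{i+1} - 1] has a constant supporter set
        breaks = sorted({s.start for s in segs} | {s.end + 1 for s in segs})
        atoms: list[tuple[int, int, frozenset[str]]] = []
        for lo, nxt in zip(breaks, breaks[1:]):
            hi = nxt - 1
            supporters = frozenset(
                s.sample for s in segs if s.start <= lo and s.end >= hi
            )
            atoms.append((lo, hi, supporters))
        merged: list[tuple[int, int, frozenset[str]]] = []
        for lo, hi, supp in atoms:
            if merged and merged[-1][2] == supp and merged[-1][1] + 1 == lo:
                merged[-1] = (merged[-1][0], hi, supp)
            else:
                merged.append((lo, hi, supp))
        for lo, hi, supp in merged:
            size = hi - lo + 1
            if len(supp) >= min_support and size > min_size:
                out.append(
                    MinimalCommonRegion(
                        chromosome=chrom,
                        start=lo,
                        end=hi,
                        state=state,
                        supporting_samples=supp,
                    )
                )
    out.sort(key=lambda r: (r.chromosome, r.start, r.end, r.state))
    return out


def _reciprocal_overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> float:
    inter = min(a_end, b_end) - max(a_start, b_start) + 1
    if inter <= 0:
        return 0.0
    return min(inter / (a_end - a_start + 1), inter / (b_end - b_start + 1))


def confirm_regions(
    mcrs: Sequence[MinimalCommonRegion],
    second_caller_segments: Iterable[AberrantSegment],
    min_reciprocal_overlap: float = DEFAULT_RECIPROCAL_OVERLAP,
    min_support: int = DEFAULT_MIN_SUPPORT,
) -> list[MinimalCommonRegion]:
    """Cross-caller confirmation by reciprocal overlap.

    Consensus regions are derived from the second caller's segments with
    the same recurrence rule (no size filter); an MCR is marked confirmed
    iff some same-sign second-caller consensus region overlaps it
    reciprocally by at least ``min_reciprocal_overlap``.
    """
    second = find_minimal_common_regions(
        second_caller_segments, min_support=min_support, min_size=0
    )
    out = []
    for mcr in mcrs:
        hit = any(
            r.chromosome == mcr.chromosome
            and r.state == mcr.state
            and _reciprocal_overlap(mcr.start, mcr.end, r.start, r.end)
            >= min_reciprocal_overlap
            for r in second
        )
        out.append(replace(mcr, confirmed=hit))
    return out


def filter_candidate_regions(
    mcrs: Sequence[MinimalCommonRegion], max_size: int = DEFAULT_MAX_SIZE
) -> list[MinimalCommonRegion]:
    """Keep regions of size <= ``max_size`` (inclusive), order preserved."""
    return [m for m in mcrs if m.size <= max_size]


def label_group_occurrence(
    mcr: MinimalCommonRegion, sample_sheet: pd.DataFrame | Mapping[str, str]
) -> frozenset[str]:
    """Lesion groups ({adenoma, carcinoma} subset) of a region's supporters.

    ``sample_sheet`` maps sample ids to tissue classes, either as a
    mapping or as a DataFrame with ``sample_id``/``class`` columns.
    Raises ``KeyError`` for an unknown supporter and ``ValueError`` if a
    supporter is not an adenoma or carcinoma sample.
    """
    if isinstance(sample_sheet, pd.DataFrame):
        classes = dict(
            zip(sample_sheet["sample_id"], sample_sheet["class"])
        )
    else:
        classes = dict(sample_sheet)
    groups = set()
    for sample in mcr.supporting_samples:
        if sample not in classes:
            raise KeyError(f"supporting sample {sample!r} missing from sample sheet")
        cls = classes[sample]
        if cls not in _CLASS_TO_GROUP:
            raise ValueError(
                f"supporting sample {sample!r} has class {cls!r}, expected A or T"
            )
        groups.add(_CLASS_TO_GROUP[cls])
    return frozenset(groups)
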