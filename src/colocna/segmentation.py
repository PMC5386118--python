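"""Per-sample copy-number ratio computation, smoothing, and segment calling.

A test sample is contrasted either against its own matched normal
(pairwise, self-reference) or against a best-fit subset of a healthy
control panel (non-pairwise).  Log2 ratios are smoothed with a centered
moving average over 5 consecutive SNPs and thresholded into gain/loss
segments.  A median-filter variant of the smoother provides an
independent second caller used downstream for confirmation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AberrantSegment",
    "select_best_fit_reference",
    "compute_log2_ratio",
    "smooth_consecutive",
    "median_smooth",
    "call_segments",
    "pairwise_nonpairwise_conservation",
]

logger = logging.getLogger(__name__)

DEFAULT_EPSILON = 1e-6
DEFAULT_WINDOW = 5
DEFAULT_GAIN_THRESHOLD = 0.2
DEFAULT_LOSS_THRESHOLD = -0.2
DEFAULT_MIN_SNPS = 5
DEFAULT_BEST_FIT_K = 10


@dataclass(frozen=True)
class AberrantSegment:
    """One sample's contiguous gain or loss call.

    ``start``/``end`` are the 1-based inclusive positions of the first
    and last supporting SNP; ``n_snps`` counts supporting probes and
    ``mean_log2`` is the mean smoothed ratio over them.
    """

    sample: str
    chromosome: str
    start: int
    end: int
    state: str
    n_snps: int
    mean_log2: float

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("segment start > end")
        if self.state not in ("gain", "loss"):
            raise ValueError(f"unknown state {self.state!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def select_best_fit_reference(
    test_track: np.ndarray | pd.Series,
    control_tracks: pd.DataFrame,
    k: int = DEFAULT_BEST_FIT_K,
    epsilon: float = DEFAULT_EPSILON,
) -> tuple[np.ndarray, list[str]]:
    """Pick the k controls whose ratio to the test sample is least noisy.

    Controls are ranked by the standard deviation of
    ``log2((test+eps)/(control+eps))`` over all probes (greedy
    per-control ranking, stable under ties); the reference profile is the
    probe-wise mean intensity of the chosen k.

    Returns ``(reference_profile, chosen_ids)``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    n_controls = control_tracks.shape[1]
    if n_controls < k:
        raise ValueError(
            f"best-fit reference needs at least k={k} controls, got {n_controls}"
        )
    test = np.asarray(test_track, dtype=float)
    if test.shape[0] != control_tracks.shape[0]:
        raise ValueError("test track and control panel have different probe counts")
    sds = []
    for col in control_tracks.columns:
        ratios = np.log2((test + epsilon) / (control_tracks[col].to_numpy() + epsilon))
        sds.append(float(np.std(ratios)))
    order = np.argsort(sds, kind="stable")[:k]
    chosen = [control_tracks.columns[i] for i in order]
    profile = control_tracks[chosen].to_numpy(dtype=float).mean(axis=1)
    return profile, chosen


def compute_log2_ratio(
    test_track: np.ndarray | pd.Series,
    reference_profile: np.ndarray | pd.Series,
    epsilon: float = DEFAULT_EPSILON,
) -> np.ndarray:
    """Probe-wise ``log2((test + eps) / (reference + eps))``.

    The epsilon floor guards against zero intensities in simulated or
    degenerate input; both tracks must align 1:1 with the probe map.
    """
    test = np.asarray(test_track, dtype=float)
    ref = np.asarray(reference_profile, dtype=float)
    if test.shape != ref.shape:
        raise ValueError(
            f"length mismatch: test has {test.shape[0]} probes, "
            f"reference has {ref.shape[0]}"
        )
    if np.any(test + epsilon <= 0) or np.any(ref + epsilon <= 0):
        raise ValueError("intensities must be positive after epsilon flooring")
    return np.log2((test + epsilon) / (ref + epsilon))


def _per_chromosome_filter(
    track: np.ndarray, snp_map: pd.DataFrame, w: int, reducer
) -> np.ndarray:
    if w < 3 or w % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    values = np.asarray(track, dtype=float)
    if values.shape[0] != len(snp_map):
        raise ValueError("track length does not match the probe map")
    out = np.full(values.shape[0], np.nan)
    half = (w - 1) // 2
    for chrom, grp in snp_map.groupby("chromosome", sort=False):
        idx = grp.index.to_numpy()
        v = values[idx]
        if v.shape[0] < w:
            logger.warning(
                "chromosome %s has %d probes, fewer than window %d: "
                "all smoothed values undefined",
                chrom, v.shape[0], w,
            )
            continue
        windows = np.lib.stride_tricks.sliding_window_view(v, w)
        out[idx[half : len(idx) - half]] = reducer(windows)
    return out


def smooth_consecutive(
    track: np.ndarray | pd.Series, snp_map: pd.DataFrame, w: int = DEFAULT_WINDOW
) -> np.ndarray:
    """Centered moving average over ``w`` consecutive SNPs.

    The window never crosses a chromosome boundary; probes without a full
    centered window are NaN (undefined).  Smoothing is linear and
    shift-equivariant.
    """
    return _per_chromosome_filter(track, snp_map, w, lambda win: win.mean(axis=1))


def median_smooth(
    track: np.ndarray | pd.Series, snp_map: pd.DataFrame, w: int = DEFAULT_WINDOW
) -> np.ndarray:
    """Centered moving median, the second caller's smoother.

    Same window/edge semantics as :func:`smooth_consecutive`; the
    nonlinear reducer makes its segment calls an independent check on the
    moving-average caller.
    """
    return _per_chromosome_filter(track, snp_map, w, lambda win: np.median(win, axis=1))


def call_segments(
    smoothed: np.ndarray | pd.Series,
    snp_map: pd.DataFrame,
    sample: str,
    gain_threshold: float = DEFAULT_GAIN_THRESHOLD,
    loss_threshold: float = DEFAULT_LOSS_THRESHOLD,
    min_snps: int = DEFAULT_MIN_SNPS,
) -> list[AberrantSegment]:
    """Threshold a smoothed track into maximal gain/loss runs.

    A gain segment is a maximal run of >= ``min_snps`` consecutive
    defined probes strictly above ``gain_threshold`` (symmetrically for
    losses below ``loss_threshold``).  An empty call set is a valid
    result.
    """
    if not loss_threshold < 0 < gain_threshold:
        raise ValueError("need loss_threshold < 0 < gain_threshold")
    values = np.asarray(smoothed, dtype=float)
    if values.shape[0] != len(snp_map):
        raise ValueError("track length does not match the probe map")
    segments: list[AberrantSegment] = []
    for chrom, grp in snp_map.groupby("chromosome", sort=False):
        idx = grp.index.to_numpy()
        v = values[idx]
        pos = grp["position"].to_numpy()
        labels = np.zeros(v.shape[0], dtype=int)
        with np.errstate(invalid="ignore"):
            labels[v > gain_threshold] = 1
            labels[v < loss_threshold] = -1
        labels[np.isnan(v)] = 0
        i = 0
        n = labels.shape[0]
        while i < n:
            if labels[i] == 0:
                i += 1
                continue
            j = i
            while j + 1 < n and labels[j + 1] == labels[i]:
                j += 1
            run = j - i + 1
            if run >= min_snps:
                state = "gain" if labels[i] == 1 else "loss"
                segments.append(
                    AberrantSegment(
                        sample=sample,
                        chromosome=str(chrom),
                        start=int(pos[i]),
                        end=int(pos[j]),
                        state=state,
                        n_snps=run,
                        mean_log2=float(np.mean(v[i : j + 1])),
                    )
                )
            i = j + 1
    return segments


def _covered_length(
    seg: AberrantSegment, others: Sequence[AberrantSegment]
) -> int:
    """Base pairs of ``seg`` covered by the union of ``others``."""
    intervals = sorted(
        (max(seg.start, o.start), min(seg.end, o.end))
        for o in others
        if o.start <= seg.end and o.end >= seg.start
    )
    covered = 0
    cursor = None
    for lo, hi in intervals:
        if cursor is None or lo > cursor:
            covered += hi - lo + 1
            cursor = hi
        elif hi > cursor:
            covered += hi - cursor
            cursor = hi
    return covered


def pairwise_nonpairwise_conservation(
    segments_pairwise: Sequence[AberrantSegment],
    segments_nonpairwise: Sequence[AberrantSegment],
    min_coverage: float = 0.5,
) -> float | None:
    """Fraction of pairwise calls conserved in the non-pairwise analysis.

    A pairwise segment counts as conserved when same-sign non-pairwise
    segments of the same sample cover at least ``min_coverage`` of its
    length.  Returns ``None`` (not applicable) for an empty pairwise set.
    """
    if not segments_pairwise:
        return None
    by_key: dict[tuple[str, str, str], list[AberrantSegment]] = {}
    for seg in segments_nonpairwise:
        by_key.setdefault((seg.sample, seg.chromosome, seg.state), []).append(seg)
    conserved = 0
    for seg in segments_pairwise:
        others = by_key.get((seg.sample, seg.chromosome, seg.state), [])
        if _covered_length(seg, others) >= min_coverage * seg.length:
            conserved += 1
    return conserved / len(segments_pairwise)
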