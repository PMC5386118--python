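"""Two-hit evidence scoring: loss of heterozygosity and promoter methylation.

LOH is assessed from paired normal/tumor genotype calls with duplicate
tumor measurements: only heterozygous (AB) normals are informative, and
LOH requires BOTH tumor duplicates to agree on the same homozygote.
Promoter hypermethylation is read from bisulfite-clone matrices: a clone
counts as methylated when a sufficient fraction of its CpGs are
methylated, and the per-sample clone count is binned into
extensive / moderate / unmethylated classes (for ten clones: >= 5,
2-4, <= 1, with the ambiguous count of 5 resolved to extensive).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "GenotypePair",
    "LohCall",
    "MethylationClass",
    "score_loh",
    "loh_frequency",
    "methylated_clone_count",
    "classify_methylation",
    "cohort_methylation_summary",
]

VALID_CALLS = ("AA", "AB", "BB", "NoCall")
LOH_STATUSES = ("LOH", "retention", "non_informative", "non_evaluable")
METHYLATION_CLASSES = ("extensive", "moderate", "unmethylated")

DEFAULT_CLONE_RULE_FRACTION = 0.25
DEFAULT_N_CLONES = 10


@dataclass(frozen=True)
class GenotypePair:
    """Paired genotype calls: one normal, two tumor duplicates."""

    pair_id: str
    marker: str
    normal_call: str
    tumor_calls: tuple[str, str]

    def __post_init__(self) -> None:
        if len(self.tumor_calls) != 2:
            raise ValueError("exactly two tumor duplicate calls are required")


@dataclass(frozen=True)
class LohCall:
    pair_id: str
    marker: str
    status: str


@dataclass(frozen=True)
class MethylationClass:
    sample_id: str
    label: str
    methylated_clone_count: int


def _check_call(token: str) -> None:
    if token not in VALID_CALLS:
        raise ValueError(
            f"unknown genotype call {token!r}; expected one of {VALID_CALLS}"
        )


def score_loh(pair: GenotypePair) -> LohCall:
    """Score one marker of one tumor/normal pair.

    Rules, in order of precedence:

    1. normal not heterozygous (AA, BB or NoCall) -> ``non_informative``;
    2. any tumor duplicate NoCall -> ``non_evaluable``;
    3. both duplicates the same homozygote (AA,AA or BB,BB) -> ``LOH``;
    4. any duplicate heterozygous -> ``retention``;
    5. discordant homozygous duplicates (AA,BB) -> ``non_evaluable``.

    Non-evaluable pairs are excluded from frequency denominators but
    counted separately; only AB normals can ever yield LOH or retention.
    """
    _check_call(pair.normal_call)
    t1, t2 = pair.tumor_calls
    _check_call(t1)
    _check_call(t2)
    if pair.normal_call != "AB":
        status = "non_informative"
    elif "NoCall" in (t1, t2):
        status = "non_evaluable"
    elif t1 == t2 and t1 in ("AA", "BB"):
        status = "LOH"
    elif "AB" in (t1, t2):
        status = "retention"
    else:  # discordant homozygotes
        status = "non_evaluable"
    return LohCall(pair.pair_id, pair.marker, status)


def loh_frequency(calls: Iterable[LohCall]) -> tuple[float | None, int, int]:
    """LOH frequency among informative cases, as an integer percent.

    Informative cases are LOH + retention.  The frequency is rounded
    half-up to a whole percent (5/12 -> 42, 11/19 -> 58); with zero
    informative cases it is undefined and returned as ``None``.

    Returns ``(frequency_percent, n_loh, n_informative)``.
    """
    n_loh = n_ret = 0
    for call in calls:
        if call.status == "LOH":
            n_loh += 1
        elif call.status == "retention":
            n_ret += 1
    n_informative = n_loh + n_ret
    if n_informative == 0:
        return None, 0, 0
    pct = math.floor(100.0 * n_loh / n_informative + 0.5)  # round half up
    return float(pct), n_loh, n_informative


def methylated_clone_count(
    matrix: np.ndarray,
    clone_rule_fraction: float = DEFAULT_CLONE_RULE_FRACTION,
) -> int:
    """Count clones whose methylated-CpG fraction reaches the rule.

    ``matrix`` is clones x CpG sites with binary entries (1 = methylated
    at that site).  A clone is methylated iff
    ``methylated sites / assayed sites >= clone_rule_fraction``.
    """
    if not 0.0 < clone_rule_fraction <= 1.0:
        raise ValueError("clone_rule_fraction must lie in (0, 1]")
    m = np.asarray(matrix)
    if m.size == 0:
        raise ValueError("empty clone matrix")
    if not np.isin(m, (0, 1)).all():
        raise ValueError("clone matrix entries must be 0/1")
    fractions = m.mean(axis=1)
    return int(np.sum(fractions >= clone_rule_fraction))


def classify_methylation(
    count: int, n_clones: int = DEFAULT_N_CLONES, sample_id: str = ""
) -> MethylationClass:
    """Bin a methylated-clone count into the three promoter classes.

    For ten clones: >= 5 extensive, 2-4 moderate, <= 1 unmethylated
    (scattered); the printed class bands overlap at 5, which is resolved
    in favour of extensive.  For other clone totals the cutoffs scale as
    ceil(n/2) and ceil(n/5).
    """
    if not 0 <= count <= n_clones:
        raise ValueError(f"count {count} outside 0..{n_clones}")
    ext_thr = math.ceil(n_clones / 2)
    mod_thr = math.ceil(n_clones / 5)
    if count >= ext_thr:
        label = "extensive"
    elif count >= mod_thr:
        label = "moderate"
    else:
        label = "unmethylated"
    return MethylationClass(sample_id, label, count)


def cohort_methylation_summary(
    classes: Sequence[MethylationClass | str],
) -> dict[str, tuple[int, float]]:
    """Per-class counts and percentages over classified tumors.

    Percentages carry one decimal place, truncated toward zero, so that
    4 of 26 reports as 15.3%.  Raises on empty input.
    """
    labels = [c.label if isinstance(c, MethylationClass) else str(c) for c in classes]
    if not labels:
        raise ValueError("no classified tumors to summarize")
    unknown = set(labels) - set(METHYLATION_CLASSES)
    if unknown:
        raise ValueError(f"unknown methylation classes {sorted(unknown)}")
    total = len(labels)
    out = {}
    for label in METHYLATION_CLASSES:
        n = labels.count(label)
        pct = math.floor(1000.0 * n / total) / 10.0  # one decimal, truncated
        out[label] = (n, pct)
    return out
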