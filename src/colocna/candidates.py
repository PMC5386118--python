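"""Candidate-gene integration: annotation, expression filtering, and qPCR.

Connects recurrent copy-number regions to genes (browser-style
any-overlap queries against a gene-model table), narrows candidates with
a two-group differential-expression test, and quantifies per-patient DNA
or transcript changes with the comparative threshold-cycle scheme.

Sign convention (matters!): the relative quantity is

    ddCT = dCT(normal) - dCT(lesion),      fold = 2**ddCT

so a deficit in the lesion gives a *negative* ddCT and a fold below 1.
This is the mirror image of the common 2**(-ddCT) habit; it follows
directly from forming the difference normal-minus-lesion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .regions import MinimalCommonRegion

__all__ = [
    "AssemblyMismatchError",
    "DdctResult",
    "REFERENCE_GENES",
    "annotate_genes",
    "count_candidate_genes",
    "differential_expression_filter",
    "delta_ct",
    "delta_delta_ct",
    "call_copy_or_expression_status",
    "ddct_report",
]

#: reference gene used for normalization, by template
REFERENCE_GENES = {"genomic": "GAPDH", "cDNA": "DDX5"}

DEFAULT_ALPHA = 0.001
DEFAULT_DECREASE_THRESHOLD = -1.0  # two-fold deficit
DEFAULT_INCREASE_THRESHOLD = 1.0


class AssemblyMismatchError(ValueError):
    """Regions and gene models are tagged with different genome assemblies."""


def _norm_chrom(chrom: str) -> str:
    c = str(chrom)
    return c[3:] if c.lower().startswith("chr") else c


def annotate_genes(
    regions: Sequence[MinimalCommonRegion],
    gene_models: pd.DataFrame,
    region_assembly: str = "hg19",
    gene_assembly: str = "hg19",
) -> list[list[str]]:
    """Assign genes to regions by any-overlap (>= 1 bp).

    ``gene_models`` needs columns ``symbol, chromosome, start, end``
    (1-based inclusive).  Chromosome labels are compared with the "chr"
    prefix stripped.  Returns, for each region in input order, the
    overlapping gene symbols ordered by gene start; an empty list is a
    valid annotation.
    """
    if region_assembly != gene_assembly:
        raise AssemblyMismatchError(
            f"regions are {region_assembly} but gene models are {gene_assembly}"
        )
    models = gene_models.copy()
    models["_chrom"] = models["chromosome"].map(_norm_chrom)
    out: list[list[str]] = []
    for region in regions:
        chrom = _norm_chrom(region.chromosome)
        hits = models[
            (models["_chrom"] == chrom)
            & (models["start"] <= region.end)
            & (models["end"] >= region.start)
        ].sort_values(["start", "end", "symbol"], kind="stable")
        out.append(hits["symbol"].tolist())
    return out


def count_candidate_genes(annotation: Iterable[Iterable[str]]) -> int:
    """Number of distinct gene symbols across all annotated regions."""
    return len({g for genes in annotation for g in genes})


def differential_expression_filter(
    expression_matrix: pd.DataFrame,
    group_labels: Sequence[str],
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Two-sided Welch test per gene; keep genes with p <= alpha.

    ``expression_matrix`` has genes as rows and samples as columns;
    ``group_labels`` assigns each column to one of exactly two groups
    (first-seen group is the baseline for the sign of ``direction``).

    Degenerate zero-variance genes: when both groups are constant and
    equal, p is defined as 1; when constant but different (exact
    separation) p is set to 0 and flagged in the ``degenerate`` column.

    Returns a DataFrame with columns ``gene, direction, p, degenerate``
    restricted to genes passing the threshold.
    """
    labels = list(group_labels)
    if len(labels) != expression_matrix.shape[1]:
        raise ValueError("one group label per expression column is required")
    groups = list(dict.fromkeys(labels))
    if len(groups) != 2:
        raise ValueError(f"exactly two groups required, got {groups}")
    mask_a = np.array([l == groups[0] for l in labels])
    a = expression_matrix.loc[:, mask_a].to_numpy(dtype=float)
    b = expression_matrix.loc[:, ~mask_a].to_numpy(dtype=float)
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("need at least 2 samples per group")
    rows = []
    for i, gene in enumerate(expression_matrix.index):
        xa, xb = a[i], b[i]
        degenerate = False
        if np.var(xa) == 0 and np.var(xb) == 0:
            degenerate = True
            p = 1.0 if np.mean(xa) == np.mean(xb) else 0.0
        else:
            p = float(stats.ttest_ind(xa, xb, equal_var=False).pvalue)
        direction = "up" if np.mean(xb) > np.mean(xa) else "down"
        if p <= alpha:
            rows.append((gene, direction, p, degenerate))
    return pd.DataFrame(rows, columns=["gene", "direction", "p", "degenerate"])


# ---------------------------------------------------------------------------
# comparative CT arithmetic
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DdctResult:
    """Per-patient relative quantity of a target gene in one lesion."""

    patient: str
    gene: str
    template: str
    lesion_class: str
    delta_ct_normal: float
    delta_ct_lesion: float
    ddct: float
    fold_change: float
    status: str


def delta_ct(
    ct_target: float,
    ct_reference: float,
    template: str | None = None,
    reference_template: str | None = None,
) -> float:
    """dCT = CT(target) - CT(reference), within one sample and template.

    If both template tags are given they must match.
    """
    if template is not None and reference_template is not None:
        if template != reference_template:
            raise ValueError(
                f"template mismatch: target is {template!r}, "
                f"reference is {reference_template!r}"
            )
    return ct_target - ct_reference


def delta_delta_ct(dct_normal: float, dct_lesion: float) -> tuple[float, float]:
    """ddCT = dCT(normal) - dCT(lesion); fold change = 2**ddCT.

    Antisymmetric: swapping normal and lesion negates ddCT and inverts
    the fold change.
    """
    ddct = dct_normal - dct_lesion
    return ddct, float(2.0 ** ddct)


def call_copy_or_expression_status(
    ddct: float,
    decrease_threshold: float = DEFAULT_DECREASE_THRESHOLD,
    increase_threshold: float = DEFAULT_INCREASE_THRESHOLD,
) -> str:
    """Ternary call on ddCT; boundaries are inclusive.

    Defaults +-1 correspond to a two-fold change.
    """
    if not decrease_threshold < 0 < increase_threshold:
        raise ValueError("need decrease_threshold < 0 < increase_threshold")
    if ddct <= decrease_threshold:
        return "decreased"
    if ddct >= increase_threshold:
        return "increased"
    return "unchanged"


def ddct_report(
    qpcr: pd.DataFrame,
    reference_genes: Mapping[str, str] = REFERENCE_GENES,
    decrease_threshold: float = DEFAULT_DECREASE_THRESHOLD,
    increase_threshold: float = DEFAULT_INCREASE_THRESHOLD,
) -> pd.DataFrame:
    """Full comparative-CT report from a long-format CT table.

    ``qpcr`` has columns ``patient, tissue_class, gene, template, ct``
    with tissue classes N (matched normal), A and/or T.  For every
    (patient, template, target gene, lesion class) with a matched normal
    measurement, the report carries both dCTs, the ddCT, the fold change
    and the ternary status.  A lesion measurement without a matched
    normal (or without reference-gene rows) is rejected.
    """
    required = {"patient", "tissue_class", "gene", "template", "ct"}
    missing = required - set(qpcr.columns)
    if missing:
        raise ValueError(f"qPCR table lacks columns {sorted(missing)}")
    if (qpcr["ct"] <= 0).any() or not np.isfinite(qpcr["ct"]).all():
        raise ValueError("CT values must be finite and positive")
    ct = {
        (r.patient, r.tissue_class, r.gene, r.template): r.ct
        for r in qpcr.itertuples()
    }
    results = []
    for r in qpcr.sort_values(
        ["patient", "template", "gene", "tissue_class"], kind="stable"
    ).itertuples():
        if r.tissue_class not in ("A", "T"):
            continue
        ref_gene = reference_genes.get(r.template)
        if ref_gene is None:
            raise ValueError(f"no reference gene defined for template {r.template!r}")
        if r.gene == ref_gene:
            continue
        key_ref_lesion = (r.patient, r.tissue_class, ref_gene, r.template)
        key_target_n = (r.patient, "N", r.gene, r.template)
        key_ref_n = (r.patient, "N", ref_gene, r.template)
        for key, what in (
            (key_ref_lesion, f"reference gene {ref_gene} in the lesion"),
            (key_target_n, "matched normal for the target"),
            (key_ref_n, f"reference gene {ref_gene} in the matched normal"),
        ):
            if key not in ct:
                raise ValueError(
                    f"missing {what}: patient {r.patient}, gene {r.gene}, "
                    f"template {r.template}"
                )
        dct_lesion = delta_ct(r.ct, ct[key_ref_lesion])
        dct_normal = delta_ct(ct[key_target_n], ct[key_ref_n])
        ddct, fold = delta_delta_ct(dct_normal, dct_lesion)
        results.append(
            DdctResult(
                patient=r.patient,
                gene=r.gene,
                template=r.template,
                lesion_class=r.tissue_class,
                delta_ct_normal=dct_normal,
                delta_ct_lesion=dct_lesion,
                ddct=ddct,
                fold_change=fold,
                status=call_copy_or_expression_status(
                    ddct, decrease_threshold, increase_threshold
                ),
            )
        )
    return pd.DataFrame([vars(r) for r in results])
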