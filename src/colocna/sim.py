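"""Synthetic cohort generation for the mucosa-adenoma-carcinoma pipeline.

The generators in this module emulate the statistical structure of a
trio-designed copy-number study: matched normal mucosa (N), adenoma (A)
and carcinoma (T) samples per patient, extra unmatched adenomas, and a
panel of healthy blood controls (C).  Every generator is a pure function
of its inputs and a seed, and each returns, alongside the data, a truth
catalog so that downstream stages can be scored for recovery.

Signal model: a planted gain or loss segment shifts the log2 copy-number
ratio of every probe inside it by ``delta`` for each carrier sample;
i.i.d. Gaussian probe noise (default sd 0.15 log2 units) is added on top.
Intensities are emitted as ``baseline * 2**(shift + noise)`` so that the
ratio-computation stage is exercised end to end.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PlantedSegment",
    "QpcrTruth",
    "SimConfig",
    "TruthCatalog",
    "simulate_snp_map",
    "simulate_cohort",
    "simulate_genotypes",
    "simulate_bisulfite_clones",
    "simulate_qpcr",
    "simulate_gene_models",
    "simulate_expression",
    "default_scenario",
]

#: minor-allele frequencies of the two PTPRM SNP markers in Han populations
DEFAULT_MARKER_MAFS: dict[str, float] = {"rs2230601": 0.244, "rs965639": 0.356}

#: baseline array intensity for a diploid probe (arbitrary linear units)
BASELINE_INTENSITY = 2.0

_METHYLATION_CLASSES = ("extensive", "moderate", "unmethylated")


@dataclass(frozen=True)
class PlantedSegment:
    """A ground-truth gain or loss planted into carrier samples.

    Coordinates are 1-based inclusive base pairs on the simulated map.
    ``delta`` is the log2-ratio shift applied to every probe inside the
    segment; its sign must match ``state``.
    """

    chromosome: str
    start: int
    end: int
    state: str  # "gain" | "loss"
    delta: float
    carriers: frozenset[str]

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"segment start {self.start} > end {self.end}")
        if self.state not in ("gain", "loss"):
            raise ValueError(f"unknown segment state {self.state!r}")
        if self.state == "gain" and self.delta <= 0:
            raise ValueError("gain segment requires delta > 0")
        if self.state == "loss" and self.delta >= 0:
            raise ValueError("loss segment requires delta < 0")
        if not self.carriers:
            raise ValueError("segment has no carriers")
        object.__setattr__(self, "carriers", frozenset(self.carriers))


@dataclass(frozen=True)
class QpcrTruth:
    """Planted relative quantity for one patient/gene/lesion combination.

    ``fold_change`` is the abundance of the target in the lesion relative
    to the matched normal; 0.25 means a four-fold deficit.
    """

    patient: str
    gene: str
    tissue_class: str  # "A" | "T"
    fold_change: float
    template: str = "genomic"  # "genomic" | "cDNA"

    def __post_init__(self) -> None:
        if self.tissue_class not in ("A", "T"):
            raise ValueError("lesion tissue class must be A or T")
        if self.fold_change <= 0:
            raise ValueError("fold change must be positive")
        if self.template not in ("genomic", "cDNA"):
            raise ValueError(f"unknown template {self.template!r}")


@dataclass
class SimConfig:
    """Cohort design and noise parameters for :func:`simulate_cohort`.

    Defaults are a desk-scale version of an 8-trio / 6-extra-adenoma /
    95-control study: 4 trios, 3 extra adenomas, 12 controls on two
    500-probe chromosomes.  The full-size design is reachable by setting
    the counts accordingly.
    """

    n_trios: int = 4
    n_extra_adenomas: int = 3
    n_controls: int = 12
    n_chromosomes: int = 2
    snps_per_chromosome: int = 500
    probe_spacing: int = 10_000
    noise_sd: float = 0.15
    planted_segments: list[PlantedSegment] = field(default_factory=list)
    qpcr_truth: list[QpcrTruth] = field(default_factory=list)
    loh_truth: list[tuple[str, str, str]] = field(default_factory=list)
    methylation_truth: list[tuple[str, str]] = field(default_factory=list)
    marker_mafs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MARKER_MAFS)
    )
    qpcr_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_trios", "n_controls", "n_chromosomes", "snps_per_chromosome"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_extra_adenomas < 0:
            raise ValueError("n_extra_adenomas must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")

    # -- sample design ---------------------------------------------------
    @property
    def normals(self) -> list[str]:
        return [f"N{i}" for i in range(1, self.n_trios + 1)]

    @property
    def adenomas(self) -> list[str]:
        return [
            f"A{i}" for i in range(1, self.n_trios + self.n_extra_adenomas + 1)
        ]

    @property
    def tumors(self) -> list[str]:
        return [f"T{i}" for i in range(1, self.n_trios + 1)]

    @property
    def controls(self) -> list[str]:
        return [f"C{i}" for i in range(1, self.n_controls + 1)]

    @property
    def lesions(self) -> list[str]:
        return self.adenomas + self.tumors

    @property
    def samples(self) -> list[str]:
        return self.normals + self.adenomas + self.tumors + self.controls

    def sample_sheet(self) -> pd.DataFrame:
        """Design table: one row per sample with its patient and class."""
        rows = []
        for i in range(1, self.n_trios + 1):
            rows += [
                (f"N{i}", f"P{i}", "N"),
                (f"A{i}", f"P{i}", "A"),
                (f"T{i}", f"P{i}", "T"),
            ]
        for j in range(1, self.n_extra_adenomas + 1):
            i = self.n_trios + j
            rows.append((f"A{i}", f"P{i}", "A"))
        for c in self.controls:
            rows.append((c, c, "C"))
        return pd.DataFrame(rows, columns=["sample_id", "patient_id", "class"])


@dataclass
class TruthCatalog:
    """Everything that was planted, plus derived expectations.

    ``expected_mcrs`` holds the recurrent intervals implied by the planted
    segments at probe resolution, computed by direct per-probe support
    counting (independent of the sweep-line used by the analysis stage).
    Each entry is ``(chromosome, start, end, state, supporting_samples)``.
    """

    planted_segments: list[PlantedSegment]
    expected_mcrs: list[tuple[str, int, int, str, frozenset[str]]]
    qpcr_truth: list[QpcrTruth]
    loh_truth: list[tuple[str, str, str]]
    methylation_truth: list[tuple[str, str]]


# ---------------------------------------------------------------------------
# probe map
# ---------------------------------------------------------------------------

def simulate_snp_map(
    n_chromosomes: int,
    snps_per_chromosome: int,
    probe_spacing: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Lay out an evenly spaced SNP probe map.

    Probe *i* (1-based) on each chromosome sits at ``i * probe_spacing``.
    The layout is deterministic; ``seed`` is accepted for interface
    uniformity with the other generators.

    Returns a DataFrame with columns ``chromosome``, ``position``,
    ``probe_id``, sorted by (chromosome, position).
    """
    if snps_per_chromosome < 5:
        raise ValueError(
            "snps_per_chromosome must be >= 5: the 5-SNP smoothing window "
            "needs at least one full window per chromosome"
        )
    if n_chromosomes < 1 or probe_spacing < 1:
        raise ValueError("n_chromosomes and probe_spacing must be >= 1")
    records = []
    for c in range(1, n_chromosomes + 1):
        chrom = f"chr{c}"
        for i in range(1, snps_per_chromosome + 1):
            records.append((chrom, i * probe_spacing, f"{chrom}_snp{i}"))
    return pd.DataFrame(records, columns=["chromosome", "position", "probe_id"])


# ---------------------------------------------------------------------------
# intensity cohort
# ---------------------------------------------------------------------------

def _expected_mcrs_per_probe(
    snp_map: pd.DataFrame,
    segments: Sequence[PlantedSegment],
    min_support: int = 2,
) -> list[tuple[str, int, int, str, frozenset[str]]]:
    """Recurrent intervals implied by planted truth, by brute-force counting.

    For every probe and aberration sign, tally which carriers cover it;
    maximal probe runs with a constant supporter set of size >= min_support
    become one expected recurrent region (coordinates of the first/last
    probe in the run).
    """
    out: list[tuple[str, int, int, str, frozenset[str]]] = []
    for state in ("gain", "loss"):
        for chrom, grp in snp_map.groupby("chromosome", sort=False):
            pos = grp["position"].to_numpy()
            supporters: list[frozenset[str]] = []
            for p in pos:
                s: set[str] = set()
                for seg in segments:
                    if (
                        seg.state == state
                        and seg.chromosome == chrom
                        and seg.start <= p <= seg.end
                    ):
                        s |= seg.carriers
                supporters.append(frozenset(s))
            i = 0
            while i < len(pos):
                j = i
                while j + 1 < len(pos) and supporters[j + 1] == supporters[i]:
                    j += 1
                if len(supporters[i]) >= min_support:
                    out.append((chrom, int(pos[i]), int(pos[j]), state, supporters[i]))
                i = j + 1
    out.sort(key=lambda r: (r[0], r[1], r[3]))
    return out


def simulate_cohort(
    snp_map: pd.DataFrame, config: SimConfig
) -> tuple[pd.DataFrame, pd.DataFrame, TruthCatalog]:
    """Generate the intensity matrix, sample sheet and truth catalog.

    Planted deltas are applied only to carrier lesion samples (A/T);
    normals and controls carry pure noise.  Intensities are
    ``BASELINE_INTENSITY * 2**(delta + eps)`` with
    ``eps ~ N(0, noise_sd)`` i.i.d. per probe and sample.

    Raises ``ValueError`` if a planted segment lies off the map or names
    a carrier that is not a lesion sample of the design.
    """
    sheet = config.sample_sheet()
    lesion_set = set(config.lesions)
    chrom_span = {
        chrom: (int(g["position"].min()), int(g["position"].max()))
        for chrom, g in snp_map.groupby("chromosome", sort=False)
    }
    for seg in config.planted_segments:
        if seg.chromosome not in chrom_span:
            raise ValueError(f"planted segment on unknown chromosome {seg.chromosome}")
        lo, hi = chrom_span[seg.chromosome]
        if seg.start < lo or seg.end > hi:
            raise ValueError(
                f"planted segment {seg.chromosome}:{seg.start}-{seg.end} "
                f"outside mapped range {lo}-{hi}"
            )
        bad = seg.carriers - lesion_set
        if bad:
            raise ValueError(
                f"carriers {sorted(bad)} are not lesion samples of the design"
            )

    rng = np.random.default_rng(config.seed)
    samples = config.samples
    n_probes = len(snp_map)
    shifts = pd.DataFrame(
        np.zeros((n_probes, len(samples))), columns=samples, index=snp_map.index
    )
    for seg in config.planted_segments:
        mask = (
            (snp_map["chromosome"] == seg.chromosome)
            & (snp_map["position"] >= seg.start)
            & (snp_map["position"] <= seg.end)
        ).to_numpy()
        for carrier in sorted(seg.carriers):
            shifts.loc[mask, carrier] += seg.delta
    noise = rng.normal(0.0, config.noise_sd, size=(n_probes, len(samples)))
    intensities = BASELINE_INTENSITY * np.exp2(shifts.to_numpy() + noise)
    matrix = pd.DataFrame(intensities, columns=samples, index=snp_map.index)
    truth = TruthCatalog(
        planted_segments=list(config.planted_segments),
        expected_mcrs=_expected_mcrs_per_probe(snp_map, config.planted_segments),
        qpcr_truth=list(config.qpcr_truth),
        loh_truth=list(config.loh_truth),
        methylation_truth=list(config.methylation_truth),
    )
    return matrix, sheet, truth


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def simulate_genotypes(
    n_pairs: int,
    marker_mafs: Mapping[str, float] | None = None,
    loh_truth: Iterable[tuple[str, str, str]] = (),
    seed: int = 0,
) -> tuple[pd.DataFrame, int]:
    """Draw paired normal/tumor genotypes with duplicate tumor calls.

    Normal genotypes follow Hardy-Weinberg proportions at each marker's
    minor-allele frequency (defaults: rs2230601 at 0.244, rs965639 at
    0.356).  Tumor duplicates copy the normal call, except where LOH is
    planted on a heterozygous normal: there one allele (chosen at random)
    is removed from BOTH duplicates, yielding concordant AA or BB.

    LOH planted on a homozygous normal is unrealizable; such entries are
    skipped with a warning and counted in the second return value.

    Returns ``(table, n_unrealizable)`` where the table has columns
    ``pair_id, marker, normal_call, tumor_call_1, tumor_call_2``.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    mafs = dict(DEFAULT_MARKER_MAFS if marker_mafs is None else marker_mafs)
    for marker, maf in mafs.items():
        if not 0.0 < maf <= 0.5:
            raise ValueError(f"MAF for {marker} must lie in (0, 0.5], got {maf}")
    planted = {(pair, marker) for pair, marker, status in loh_truth if status == "LOH"}
    rng = np.random.default_rng(seed)
    rows = []
    n_unrealizable = 0
    for i in range(1, n_pairs + 1):
        pair = f"P{i}"
        for marker in sorted(mafs):
            q = mafs[marker]  # minor allele B
            p = 1.0 - q
            normal = rng.choice(
                ["AA", "AB", "BB"], p=[p * p, 2 * p * q, q * q]
            )
            t1 = t2 = normal
            if (pair, marker) in planted:
                if normal == "AB":
                    t1 = t2 = str(rng.choice(["AA", "BB"]))
                else:
                    n_unrealizable += 1
                    warnings.warn(
                        f"planted LOH at {marker} for {pair} is unrealizable: "
                        f"normal genotype {normal} is not heterozygous",
                        stacklevel=2,
                    )
            rows.append((pair, marker, str(normal), t1, t2))
    table = pd.DataFrame(
        rows,
        columns=["pair_id", "marker", "normal_call", "tumor_call_1", "tumor_call_2"],
    )
    return table, n_unrealizable


# ---------------------------------------------------------------------------
# bisulfite clones
# ---------------------------------------------------------------------------

def simulate_bisulfite_clones(
    target_class: str,
    n_clones: int = 10,
    n_cpg: int = 20,
    seed: int = 0,
    clone_rule_fraction: float = 0.25,
) -> np.ndarray:
    """Generate a clones x CpG binary matrix of a given methylation class.

    The number of methylated clones is drawn uniformly inside the target
    class band (for 10 clones: extensive >= 5, moderate 2-4, unmethylated
    <= 1); a methylated clone receives at least ``clone_rule_fraction`` of
    its CpGs methylated, an unmethylated clone strictly fewer (scattered
    background).  By construction the matrix classifies back to
    ``target_class`` under the default classifier parameters.
    """
    if target_class not in _METHYLATION_CLASSES:
        raise ValueError(
            f"unknown methylation class {target_class!r}; "
            f"expected one of {_METHYLATION_CLASSES}"
        )
    if n_clones < 1 or n_cpg < 1:
        raise ValueError("n_clones and n_cpg must be >= 1")
    ext_thr = math.ceil(n_clones / 2)
    mod_thr = math.ceil(n_clones / 5)
    rng = np.random.default_rng(seed)
    if target_class == "extensive":
        n_meth = int(rng.integers(ext_thr, n_clones + 1))
    elif target_class == "moderate":
        if mod_thr >= ext_thr:
            raise ValueError(f"moderate class is empty for n_clones={n_clones}")
        n_meth = int(rng.integers(mod_thr, ext_thr))
    else:
        n_meth = int(rng.integers(0, mod_thr))
    min_meth_cpg = math.ceil(clone_rule_fraction * n_cpg)
    matrix = np.zeros((n_clones, n_cpg), dtype=int)
    meth_clones = rng.choice(n_clones, size=n_meth, replace=False)
    for clone in range(n_clones):
        if clone in meth_clones:
            k = int(rng.integers(min_meth_cpg, n_cpg + 1))
        else:
            k = int(rng.integers(0, max(min_meth_cpg, 1)))
        sites = rng.choice(n_cpg, size=k, replace=False)
        matrix[clone, sites] = 1
    return matrix


# ---------------------------------------------------------------------------
# qPCR
# ---------------------------------------------------------------------------

#: reference gene per template, as used for normalization
REFERENCE_GENES = {"genomic": "GAPDH", "cDNA": "DDX5"}


def simulate_qpcr(
    qpcr_truth: Sequence[QpcrTruth],
    base_ct: float = 24.0,
    seed: int = 0,
    noise_sd: float = 0.0,
    reference_ct: float = 18.0,
) -> pd.DataFrame:
    """Emit threshold-cycle tables that invert the relative-quantity model.

    A planted fold change *f* of the target in the lesion versus the
    matched normal is realized as ``CT_lesion = CT_normal + log2(1/f)``
    with the reference-gene CT held constant, so a noise-free table
    round-trips to ``log2(f)`` exactly through the downstream
    relative-quantity computation.

    Returns a table with columns ``patient, tissue_class, gene, template,
    ct``; reference-gene and matched-normal rows are emitted once per
    patient/template.
    """
    rng = np.random.default_rng(seed)
    rows: dict[tuple[str, str, str, str], float] = {}
    for t in qpcr_truth:
        if t.fold_change <= 0:
            raise ValueError("fold change must be positive")
        ref_gene = REFERENCE_GENES[t.template]
        rows.setdefault((t.patient, "N", ref_gene, t.template), reference_ct)
        rows.setdefault((t.patient, t.tissue_class, ref_gene, t.template), reference_ct)
        rows.setdefault((t.patient, "N", t.gene, t.template), base_ct)
        rows[(t.patient, t.tissue_class, t.gene, t.template)] = base_ct + math.log2(
            1.0 / t.fold_change
        )
    records = []
    for (patient, cls, gene, template), ct in sorted(rows.items()):
        if noise_sd > 0:
            ct = ct + rng.normal(0.0, noise_sd)
        records.append((patient, cls, gene, template, ct))
    return pd.DataFrame(
        records, columns=["patient", "tissue_class", "gene", "template", "ct"]
    )


# ---------------------------------------------------------------------------
# gene models and expression (for the candidate-annotation stages)
# ---------------------------------------------------------------------------

def simulate_gene_models(
    snp_map: pd.DataFrame, genes_per_chromosome: int = 8
) -> pd.DataFrame:
    """Tile deterministic gene models across the simulated genome.

    Genes are evenly spaced intervals covering half of each inter-gene
    stride, named ``G<chrom>_<i>``.  Columns: ``symbol, chromosome,
    start, end`` (1-based inclusive).
    """
    records = []
    for chrom, grp in snp_map.groupby("chromosome", sort=False):
        lo = int(grp["position"].min())
        hi = int(grp["position"].max())
        stride = (hi - lo + 1) // genes_per_chromosome
        for i in range(genes_per_chromosome):
            start = lo + i * stride
            end = start + stride // 2
            records.append((f"G{chrom[3:]}_{i + 1}", chrom, start, min(end, hi)))
    return pd.DataFrame(records, columns=["symbol", "chromosome", "start", "end"])


def simulate_expression(
    gene_symbols: Sequence[str],
    down_genes: Iterable[str] = (),
    n_per_group: int = 10,
    shift: float = 4.0,
    sd: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[str]]:
    """Two-group expression matrix with planted down-regulation.

    Normal-group values are N(0, sd); lesion-group values of genes in
    ``down_genes`` are shifted by ``-shift`` (others unshifted).  Returns
    ``(matrix, labels)`` with genes as rows, samples as columns, and
    labels "normal"/"lesion" per column.
    """
    rng = np.random.default_rng(seed)
    down = set(down_genes)
    cols = [f"norm{i}" for i in range(1, n_per_group + 1)] + [
        f"les{i}" for i in range(1, n_per_group + 1)
    ]
    labels = ["normal"] * n_per_group + ["lesion"] * n_per_group
    data = rng.normal(0.0, sd, size=(len(gene_symbols), 2 * n_per_group))
    for r, g in enumerate(gene_symbols):
        if g in down:
            data[r, n_per_group:] -= shift
    return pd.DataFrame(data, index=list(gene_symbols), columns=cols), labels


# ---------------------------------------------------------------------------
# standard desk-scale scenario
# ---------------------------------------------------------------------------

def default_scenario(seed: int = 0) -> tuple[pd.DataFrame, SimConfig]:
    """The stock desk-scale truth set used by the pipeline and examples.

    Four trios, three extra adenomas and twelve controls on two 500-probe
    chromosomes; three planted segments (one shared loss, one shared
    gain, one private loss), one four-fold genomic deficit per lesion of
    patient P1 for gene G1_2, LOH planted at both markers for a few
    pairs, and one methylation truth per class.
    """
    spacing = 10_000
    snp_map = simulate_snp_map(2, 500, spacing, seed)
    planted = [
        PlantedSegment(
            "chr1", 100 * spacing, 140 * spacing, "loss", -1.0,
            frozenset({"A1", "T1", "T2"}),
        ),
        PlantedSegment(
            "chr2", 200 * spacing, 260 * spacing, "gain", 1.0,
            frozenset({"A2", "T2"}),
        ),
        PlantedSegment(
            "chr2", 400 * spacing, 430 * spacing, "loss", -1.0,
            frozenset({"T4"}),
        ),
    ]
    qpcr = [
        QpcrTruth("P1", "G1_2", "A", 0.25, "genomic"),
        QpcrTruth("P1", "G1_2", "T", 0.25, "genomic"),
        QpcrTruth("P2", "G1_2", "A", 1.0, "genomic"),
        QpcrTruth("P2", "G1_2", "T", 0.5, "genomic"),
        QpcrTruth("P1", "G1_2", "T", 0.25, "cDNA"),
        QpcrTruth("P2", "G1_2", "T", 1.0, "cDNA"),
    ]
    loh = [
        ("P1", "rs2230601", "LOH"),
        ("P2", "rs965639", "LOH"),
        ("P3", "rs965639", "LOH"),
    ]
    methyl = [("P1", "extensive"), ("P2", "moderate"), ("P3", "unmethylated")]
    config = SimConfig(
        planted_segments=planted,
        qpcr_truth=qpcr,
        loh_truth=loh,
        methylation_truth=methyl,
        seed=seed,
    )
    return snp_map, config
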