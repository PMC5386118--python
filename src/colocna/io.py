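"""File formats, the printed region-table fixture, and run configuration.

Conventions: coordinates are 1-based inclusive inside the package; BED
exports are 0-based half-open.  All tabular schemas are headered TSVs;
lines starting with ``#`` are comments and may carry the configuration
hash of the run that produced the file.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

from .regions import MinimalCommonRegion
from .segmentation import AberrantSegment

__all__ = [
    "RegionTableFixture",
    "parse_region_table",
    "PipelineConfig",
    "write_bed",
    "read_bed",
    "write_segments_tsv",
    "read_segments_tsv",
    "write_mcr_tsv",
    "read_mcr_tsv",
    "write_matrix_tsv",
    "read_matrix_tsv",
    "write_table_tsv",
    "read_table_tsv",
]


# ---------------------------------------------------------------------------
# printed region-table fixture
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegionTableFixture:
    """The published table of candidate regions and their genes.

    20 recurrent regions (14 gains, 6 losses) of <= 3 Mb shared by
    adenomas and carcinomas, with the genes each region harbours on the
    hg19 assembly.  ``genes`` is parallel to ``regions``; alias symbols
    printed in parentheses are stripped, composite (fusion-style)
    symbols are single entries, and a dash row yields an empty list.
    """

    regions: tuple[MinimalCommonRegion, ...]
    genes: tuple[tuple[str, ...], ...]
    cytobands: tuple[str, ...]
    assembly: str = "hg19"


def _parse_coordinate(text: str, row: int, column: str) -> int:
    stripped = str(text).replace(",", "").strip()
    if not stripped.isdigit():
        raise ValueError(
            f"malformed {column} coordinate {text!r} in region-table row {row}"
        )
    return int(stripped)


def _parse_gene_cell(cell: str) -> tuple[str, ...]:
    cell = cell.strip()
    if cell in ("-", ""):
        return ()
    symbols = []
    for entry in cell.split(","):
        symbol = entry.strip().split(" (")[0].strip()
        if symbol:
            symbols.append(symbol)
    return tuple(symbols)


def parse_region_table(fixture_path: str | Path | None = None) -> RegionTableFixture:
    """Parse the shipped candidate-region table (or a file of that schema).

    The TSV has columns ``state`` (+/-), ``cytoband``, ``start``, ``end``
    (digit-grouped with commas, 1-based inclusive) and ``genes``
    (comma-separated, "-" for none).  The chromosome is taken from the
    cytoband prefix.
    """
    if fixture_path is None:
        ref = resources.files("colocna.data").joinpath("region_table.tsv")
        with resources.as_file(ref) as path:
            table = pd.read_csv(path, sep="\t", dtype=str)
    else:
        table = pd.read_csv(fixture_path, sep="\t", dtype=str)
    regions: list[MinimalCommonRegion] = []
    genes: list[tuple[str, ...]] = []
    cytobands: list[str] = []
    for i, row in enumerate(table.itertuples(index=False), start=1):
        state = {"+": "gain", "-": "loss"}.get(row.state.strip())
        if state is None:
            raise ValueError(f"unknown state {row.state!r} in region-table row {i}")
        cytoband = row.cytoband.strip()
        chrom = cytoband.split("p")[0].split("q")[0]
        start = _parse_coordinate(row.start, i, "start")
        end = _parse_coordinate(row.end, i, "end")
        regions.append(
            MinimalCommonRegion(
                chromosome=chrom,
                start=start,
                end=end,
                state=state,
                supporting_samples=frozenset(),
                groups=frozenset({"adenoma", "carcinoma"}),
            )
        )
        genes.append(_parse_gene_cell(row.genes))
        cytobands.append(cytoband)
    return RegionTableFixture(
        regions=tuple(regions), genes=tuple(genes), cytobands=tuple(cytobands)
    )


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Every tunable of the end-to-end run, with its default.

    The configuration serializes losslessly to YAML ("key: value" text);
    ``config_hash`` digests the analysis parameters (paths excluded) and
    is embedded in output headers for auditability.
    """

    out_dir: str = "colocna_out"
    intensity_path: str | None = None
    sample_sheet_path: str | None = None
    seed: int = 0
    # cohort scale (used when simulating)
    n_trios: int = 4
    n_extra_adenomas: int = 3
    n_controls: int = 12
    n_chromosomes: int = 2
    snps_per_chromosome: int = 500
    probe_spacing: int = 10_000
    noise_sd: float = 0.15
    # segmentation
    window: int = 5
    gain_threshold: float = 0.2
    loss_threshold: float = -0.2
    min_snps: int = 5
    k_reference: int = 10
    epsilon: float = 1e-6
    # recurrent regions
    min_support: int = 2
    min_size: int = 1_000
    max_size: int = 3_000_000
    reciprocal_overlap: float = 0.5
    conservation_coverage: float = 0.5
    # candidates
    de_alpha: float = 0.001
    decrease_threshold: float = -1.0
    increase_threshold: float = 1.0
    # two-hit
    clone_rule_fraction: float = 0.25
    n_clones: int = 10
    n_cpg: int = 20
    n_loh_pairs: int = 39
    log_level: str = "INFO"

    _PATH_FIELDS = ("out_dir", "intensity_path", "sample_sheet_path")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def config_hash(self) -> str:
        """Short digest of the analysis parameters (paths excluded)."""
        params = {
            k: v for k, v in sorted(asdict(self).items()) if k not in self._PATH_FIELDS
        }
        blob = yaml.safe_dump(params, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


# ---------------------------------------------------------------------------
# BED and TSV writers/readers
# ---------------------------------------------------------------------------

def _header_lines(config_hash: str | None) -> str:
    return f"# colocna config_hash={config_hash}\n" if config_hash else ""


def write_bed(
    records: Iterable[MinimalCommonRegion | AberrantSegment],
    path: str | Path,
    config_hash: str | None = None,
) -> None:
    """Write regions or segments as BED (0-based half-open, no header).

    The name field carries the state and the score field the mean log2
    ratio x 1000 (rounded; 0 for regions, which have no single ratio).
    """
    lines = [_header_lines(config_hash)] if config_hash else []
    for rec in records:
        if rec.start < 1:
            raise ValueError("coordinate < 1 cannot be converted to BED")
        score = (
            round(rec.mean_log2 * 1000) if isinstance(rec, AberrantSegment) else 0
        )
        lines.append(f"{rec.chromosome}\t{rec.start - 1}\t{rec.end}\t{rec.state}\t{score}\n")
    Path(path).write_text("".join(lines))


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED written by :func:`write_bed` back to 1-based records."""
    rows = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        chrom, start, end, name, score = line.split("\t")
        if int(start) < 0:
            raise ValueError("negative BED start")
        rows.append((chrom, int(start) + 1, int(end), name, int(score)))
    return pd.DataFrame(rows, columns=["chromosome", "start", "end", "state", "score"])


def write_table_tsv(
    table: pd.DataFrame, path: str | Path, config_hash: str | None = None
) -> None:
    """Write any headered tabular schema, with an optional # audit line."""
    with open(path, "w") as fh:
        fh.write(_header_lines(config_hash))
        table.to_csv(fh, sep="\t", index=False)


def read_table_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_segments_tsv(
    segments: Iterable[AberrantSegment], path: str | Path, config_hash: str | None = None
) -> None:
    table = pd.DataFrame(
        [
            (s.sample, s.chromosome, s.start, s.end, s.state, s.n_snps, s.mean_log2)
            for s in segments
        ],
        columns=["sample", "chromosome", "start", "end", "state", "n_snps", "mean_log2"],
    )
    write_table_tsv(table, path, config_hash)


def read_segments_tsv(path: str | Path) -> list[AberrantSegment]:
    table = read_table_tsv(path)
    return [
        AberrantSegment(
            sample=str(r.sample),
            chromosome=str(r.chromosome),
            start=int(r.start),
            end=int(r.end),
            state=str(r.state),
            n_snps=int(r.n_snps),
            mean_log2=float(r.mean_log2),
        )
        for r in table.itertuples()
    ]


def write_mcr_tsv(
    mcrs: Sequence[MinimalCommonRegion], path: str | Path, config_hash: str | None = None
) -> None:
    table = pd.DataFrame(
        [
            (
                m.chromosome,
                m.start,
                m.end,
                m.state,
                m.size,
                m.support,
                ",".join(sorted(m.supporting_samples)),
                ",".join(sorted(m.groups)),
                "" if m.confirmed is None else str(bool(m.confirmed)),
            )
            for m in mcrs
        ],
        columns=[
            "chromosome", "start", "end", "state", "size",
            "support", "samples", "groups", "confirmed",
        ],
    )
    write_table_tsv(table, path, config_hash)


def read_mcr_tsv(path: str | Path) -> list[MinimalCommonRegion]:
    table = read_table_tsv(path).fillna({"samples": "", "groups": "", "confirmed": ""})
    out = []
    for r in table.itertuples():
        confirmed = None
        if str(r.confirmed) in ("True", "False"):
            confirmed = str(r.confirmed) == "True"
        out.append(
            MinimalCommonRegion(
                chromosome=str(r.chromosome),
                start=int(r.start),
                end=int(r.end),
                state=str(r.state),
                supporting_samples=frozenset(
                    s for s in str(r.samples).split(",") if s
                ),
                groups=frozenset(g for g in str(r.groups).split(",") if g),
                confirmed=confirmed,
            )
        )
    return out


def write_matrix_tsv(
    matrix: pd.DataFrame,
    snp_map: pd.DataFrame,
    path: str | Path,
    config_hash: str | None = None,
) -> None:
    """Intensity (or ratio) matrix: probe annotation columns then samples."""
    table = pd.concat(
        [snp_map.reset_index(drop=True), matrix.reset_index(drop=True)], axis=1
    )
    write_table_tsv(table, path, config_hash)


def read_matrix_tsv(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Return ``(snp_map, matrix)`` from a file written by write_matrix_tsv."""
    table = read_table_tsv(path)
    map_cols = ["chromosome", "position", "probe_id"]
    snp_map = table[map_cols].copy()
    matrix = table.drop(columns=map_cols)
    return snp_map, matrix
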