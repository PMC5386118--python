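"""Gene annotation, expression filtering and comparative-CT arithmetic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from colocna.candidates import (
    AssemblyMismatchError,
    annotate_genes,
    call_copy_or_expression_status,
    count_candidate_genes,
    ddct_report,
    delta_ct,
    delta_delta_ct,
    differential_expression_filter,
)
from colocna.io import parse_region_table
from colocna.regions import MinimalCommonRegion
from colocna.sim import QpcrTruth, simulate_qpcr


def region(chrom, lo, hi, state="loss"):
    return MinimalCommonRegion(chrom, lo, hi, state, frozenset({"A1", "T1"}))


class TestAnnotateGenes:
    models = pd.DataFrame(
        {
            "symbol": ["PTPRM", "FARAWAY", "EDGE"],
            "chromosome": ["18", "18", "18"],
            "start": [7_750_000, 50_000_000, 7_816_623],
            "end": [8_500_000, 50_100_000, 9_000_000],
        }
    )

    def test_published_loss_region_contains_ptprm(self):
        r = region("18", 7_579_318, 7_816_623)
        assert annotate_genes([r], self.models)[0] == ["PTPRM", "EDGE"]

    def test_single_base_overlap_included(self):
        r = region("18", 7_579_318, 7_750_000)
        assert "PTPRM" in annotate_genes([r], self.models)[0]

    def test_no_overlap_empty_list(self):
        r = region("13", 72_583_695, 73_033_999, "gain")
        assert annotate_genes([r], self.models)[0] == []

    def test_chr_prefix_normalized(self):
        r = region("chr18", 7_579_318, 7_816_623)
        assert "PTPRM" in annotate_genes([r], self.models)[0]

    def test_assembly_mismatch_rejected(self):
        r = region("18", 1, 2)
        with pytest.raises(AssemblyMismatchError):
            annotate_genes([r], self.models, region_assembly="hg17")

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(0)
        models = pd.DataFrame(
            {
                "symbol": [f"g{i}" for i in range(60)],
                "chromosome": rng.choice(["1", "2"], 60),
                "start": rng.integers(1, 100_000, 60),
            }
        )
        models["end"] = models["start"] + rng.integers(1, 30_000, 60)
        regions = [
            region(str(rng.choice(["1", "2"])), int(lo), int(lo + ln))
            for lo, ln in zip(
                rng.integers(1, 100_000, 15), rng.integers(100, 40_000, 15)
            )
        ]
        got = annotate_genes(regions, models)
        for r, genes in zip(regions, got):
            brute = [
                m.symbol
                for m in models.sort_values(["start", "end", "symbol"]).itertuples()
                if m.chromosome == r.chromosome
                and m.start <= r.end
                and m.end >= r.start
            ]
            assert genes == brute

    def test_distinct_gene_count_from_published_table(self):
        fx = parse_region_table()
        assert count_candidate_genes(fx.genes) == 87

    def test_count_deduplicates_and_handles_empty(self):
        assert count_candidate_genes([]) == 0
        assert count_candidate_genes([["A", "B"], ["B", "C"]]) == 3


class TestDifferentialExpression:
    def test_null_distribution_empty_at_strict_alpha(self):
        rng = np.random.default_rng(1)
        expr = pd.DataFrame(rng.normal(0, 1, (50, 20)),
                            index=[f"g{i}" for i in range(50)])
        labels = ["a"] * 10 + ["b"] * 10
        hits = differential_expression_filter(expr, labels, alpha=1e-6)
        assert len(hits) == 0

    def test_planted_eight_sd_shift_retained(self):
        rng = np.random.default_rng(2)
        expr = pd.DataFrame(rng.normal(0, 1, (5, 20)),
                            index=[f"g{i}" for i in range(5)])
        expr.iloc[0, 10:] += 8.0
        labels = ["a"] * 10 + ["b"] * 10
        hits = differential_expression_filter(expr, labels, alpha=0.001)
        assert hits["gene"].tolist() == ["g0"]
        assert hits["direction"].iloc[0] == "up"

    def test_alpha_one_keeps_everything(self):
        rng = np.random.default_rng(3)
        expr = pd.DataFrame(rng.normal(0, 1, (7, 8)))
        hits = differential_expression_filter(expr, ["a"] * 4 + ["b"] * 4, alpha=1.0)
        assert len(hits) == 7

    def test_degenerate_zero_variance(self):
        expr = pd.DataFrame(
            [[1.0, 1, 1, 2, 2, 2], [3.0, 3, 3, 3, 3, 3]], index=["sep", "flat"]
        )
        labels = ["a"] * 3 + ["b"] * 3
        hits = differential_expression_filter(expr, labels, alpha=0.5)
        assert hits["gene"].tolist() == ["sep"]
        assert hits["p"].iloc[0] == 0.0
        assert bool(hits["degenerate"].iloc[0])


class TestCtArithmetic:
    @pytest.mark.parametrize(
        "target,ref,expected", [(20, 18, 2), (18, 18, 0), (15.5, 18.25, -2.75)]
    )
    def test_delta_ct(self, target, ref, expected):
        assert delta_ct(target, ref) == pytest.approx(expected)

    def test_delta_ct_template_mismatch(self):
        with pytest.raises(ValueError, match="template"):
            delta_ct(20, 18, template="genomic", reference_template="cDNA")

    def test_delta_delta_ct_directions(self):
        ddct, fold = delta_delta_ct(2, 5)
        assert (ddct, fold) == (-3, pytest.approx(0.125))
        assert delta_delta_ct(4, 4) == (0, pytest.approx(1.0))

    @given(a=st.floats(-10, 10), b=st.floats(-10, 10))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_antisymmetry(self, a, b):
        d1, f1 = delta_delta_ct(a, b)
        d2, f2 = delta_delta_ct(b, a)
        assert d1 == pytest.approx(-d2)
        assert f1 * f2 == pytest.approx(1.0)

    def test_reference_gene_invariance(self):
        # adding a constant to every CT of one sample cancels in dCT
        base = delta_ct(24.0, 18.0)
        shifted = delta_ct(24.0 + 1.7, 18.0 + 1.7)
        assert base == pytest.approx(shifted)

    @pytest.mark.parametrize(
        "ddct,status",
        [(-3, "decreased"), (0, "unchanged"), (-1, "decreased"),
         (1, "increased"), (0.99, "unchanged"), (-0.99, "unchanged")],
    )
    def test_status_thresholds_inclusive(self, ddct, status):
        assert call_copy_or_expression_status(ddct) == status


class TestDdctReport:
    def test_round_trip_planted_folds(self):
        truth = [
            QpcrTruth("P1", "G", "T", 0.25, "genomic"),
            QpcrTruth("P1", "G", "A", 0.5, "genomic"),
            QpcrTruth("P2", "G", "T", 2.0, "cDNA"),
        ]
        report = ddct_report(simulate_qpcr(truth))
        by = report.set_index(["patient", "lesion_class", "template"])
        assert by.loc[("P1", "T", "genomic"), "ddct"] == pytest.approx(-2.0)
        assert by.loc[("P1", "A", "genomic"), "ddct"] == pytest.approx(-1.0)
        assert by.loc[("P2", "T", "cDNA"), "ddct"] == pytest.approx(1.0)
        assert by.loc[("P1", "T", "genomic"), "status"] == "decreased"

    def test_planted_decrease_recalled_completely(self):
        truth = [
            QpcrTruth(f"P{i}", "G", cls, 0.25)
            for i in range(1, 6)
            for cls in ("A", "T")
        ]
        report = ddct_report(simulate_qpcr(truth))
        assert (report["status"] == "decreased").all()
        assert len(report) == 10

    def test_missing_matched_normal_rejected(self):
        table = pd.DataFrame(
            [
                ("P1", "T", "G", "genomic", 24.0),
                ("P1", "T", "GAPDH", "genomic", 18.0),
            ],
            columns=["patient", "tissue_class", "gene", "template", "ct"],
        )
        with pytest.raises(ValueError, match="matched normal"):
            ddct_report(table)
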