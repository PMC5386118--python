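"""Ratio, smoothing and segment-calling behavior against brute-force oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from colocna import sim
from colocna.segmentation import (
    AberrantSegment,
    call_segments,
    compute_log2_ratio,
    median_smooth,
    pairwise_nonpairwise_conservation,
    select_best_fit_reference,
    smooth_consecutive,
)


def window_mean_oracle(values, snp_map, w):
    """Independent per-probe recomputation of the centered window mean."""
    out = np.full(len(values), np.nan)
    half = (w - 1) // 2
    for _, grp in snp_map.groupby("chromosome"):
        idx = grp.index.to_numpy()
        v = np.asarray(values)[idx]
        for i in range(half, len(v) - half):
            out[idx[i]] = np.mean(v[i - half : i + half + 1])
    return out


@pytest.fixture
def snp_map():
    return sim.simulate_snp_map(2, 100, 1000)


class TestLog2Ratio:
    def test_identity_doubling_halving(self, snp_map):
        ref = np.full(len(snp_map), 4.0)
        assert compute_log2_ratio(ref, ref) == pytest.approx(np.zeros(len(ref)), abs=1e-6)
        assert compute_log2_ratio(2 * ref, ref) == pytest.approx(np.ones(len(ref)), abs=1e-6)
        assert compute_log2_ratio(ref / 2, ref) == pytest.approx(-np.ones(len(ref)), abs=1e-6)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            compute_log2_ratio(np.ones(5), np.ones(6))


class TestBestFitReference:
    def test_identical_control_chosen(self, snp_map):
        rng = np.random.default_rng(0)
        test = np.full(len(snp_map), 2.0)
        panel = pd.DataFrame(
            {
                "noisy1": 2.0 * np.exp2(rng.normal(0, 0.3, len(snp_map))),
                "same": test.copy(),
                "noisy2": 2.0 * np.exp2(rng.normal(0, 0.3, len(snp_map))),
            }
        )
        profile, chosen = select_best_fit_reference(test, panel, k=1)
        assert chosen == ["same"]
        assert compute_log2_ratio(test, profile) == pytest.approx(
            np.zeros(len(snp_map)), abs=1e-6
        )

    def test_k_equals_panel_gives_plain_mean(self, snp_map):
        rng = np.random.default_rng(1)
        panel = pd.DataFrame(
            rng.uniform(1, 3, (len(snp_map), 4)), columns=list("abcd")
        )
        test = np.full(len(snp_map), 2.0)
        profile, chosen = select_best_fit_reference(test, panel, k=4)
        assert sorted(chosen) == list("abcd")
        np.testing.assert_allclose(profile, panel.to_numpy().mean(axis=1))

    def test_matches_exhaustive_search_when_noise_levels_are_nested(self, snp_map):
        # controls = test * noise at strictly increasing noise levels: the
        # greedy ranking and the exhaustive subset search must agree
        rng = np.random.default_rng(2)
        n = len(snp_map)
        test = rng.uniform(1, 3, n)
        sds = [0.01, 0.05, 0.1, 0.2, 0.4, 0.8]
        panel = pd.DataFrame(
            {f"c{i}": test * np.exp2(rng.normal(0, sd, n)) for i, sd in enumerate(sds)}
        )
        k = 3
        _, chosen = select_best_fit_reference(test, panel, k=k)

        def subset_sd(cols):
            profile = panel[list(cols)].to_numpy().mean(axis=1)
            return np.std(np.log2((test + 1e-6) / (profile + 1e-6)))

        best = min(itertools.combinations(panel.columns, k), key=subset_sd)
        assert sorted(chosen) == sorted(best)

    def test_too_few_controls_rejected(self, snp_map):
        panel = pd.DataFrame({"a": np.ones(len(snp_map))})
        with pytest.raises(ValueError, match="controls"):
            select_best_fit_reference(np.ones(len(snp_map)), panel, k=10)


class TestSmoothing:
    def test_constant_track(self, snp_map):
        out = smooth_consecutive(np.full(len(snp_map), 3.5), snp_map)
        defined = ~np.isnan(out)
        assert np.allclose(out[defined], 3.5)

    def test_impulse_center_value(self):
        m = sim.simulate_snp_map(1, 5, 1000)
        out = smooth_consecutive(np.array([0.0, 0, 1, 0, 0]), m, w=5)
        assert out[2] == pytest.approx(0.2)
        assert np.isnan(out[[0, 1, 3, 4]]).all()

    def test_matches_window_oracle_on_random_tracks(self):
        m = sim.simulate_snp_map(2, 100, 1000)
        rng = np.random.default_rng(3)
        for _ in range(20):
            track = rng.normal(0, 1, len(m))
            got = smooth_consecutive(track, m)
            want = window_mean_oracle(track, m, 5)
            np.testing.assert_allclose(got, want, atol=1e-12, equal_nan=True)

    def test_never_crosses_chromosomes(self, snp_map):
        # a huge value at the end of chr1 must not leak into chr2
        track = np.zeros(len(snp_map))
        track[99] = 1000.0
        out = smooth_consecutive(track, snp_map)
        chr2 = snp_map[snp_map["chromosome"] == "chr2"].index
        assert np.nansum(np.abs(out[chr2])) == 0.0

    def test_short_chromosome_all_undefined(self):
        m = sim.simulate_snp_map(1, 5, 1000)
        out = smooth_consecutive(np.zeros(5), m, w=7)
        assert np.isnan(out).all()

    def test_even_window_rejected(self, snp_map):
        with pytest.raises(ValueError, match="odd"):
            smooth_consecutive(np.zeros(len(snp_map)), snp_map, w=4)

    @given(shift=st.floats(-5, 5, allow_nan=False))
    @settings(max_examples=25, derandomize=True, deadline=None)
    def test_shift_equivariance(self, shift):
        m = sim.simulate_snp_map(1, 30, 1000)
        rng = np.random.default_rng(4)
        track = rng.normal(0, 1, 30)
        base = smooth_consecutive(track, m)
        shifted = smooth_consecutive(track + shift, m)
        np.testing.assert_allclose(shifted, base + shift, atol=1e-9, equal_nan=True)

    def test_median_smoother_is_independent_of_mean(self):
        m = sim.simulate_snp_map(1, 9, 1000)
        track = np.array([0.0, 0, 0, 0, 10, 0, 0, 0, 0])
        mean_out = smooth_consecutive(track, m)
        med_out = median_smooth(track, m)
        assert mean_out[4] == pytest.approx(2.0)
        assert med_out[4] == pytest.approx(0.0)  # robust to the outlier


class TestCallSegments:
    def test_all_zero_no_segments(self, snp_map):
        assert call_segments(np.zeros(len(snp_map)), snp_map, "S") == []

    def test_planted_loss_called_with_window_slack(self):
        m = sim.simulate_snp_map(1, 100, 1000)
        ratio = np.zeros(100)
        ratio[30:60] = -1.0  # 30 probes
        smoothed = smooth_consecutive(ratio, m)
        segs = call_segments(smoothed, m, "S")
        assert len(segs) == 1
        seg = segs[0]
        assert seg.state == "loss"
        # transition ramps: boundary within (w-1)/2 = 2 probes
        assert abs(seg.start - 31_000) <= 2_000
        assert abs(seg.end - 60_000) <= 2_000

    def test_short_run_filtered(self):
        m = sim.simulate_snp_map(1, 20, 1000)
        track = np.zeros(20)
        track[5:9] = 1.0  # 4 probes above threshold < min_snps
        assert call_segments(track, m, "S") == []

    def test_invariant_to_probe_relabeling(self, snp_map):
        rng = np.random.default_rng(5)
        track = rng.normal(0, 0.5, len(snp_map))
        relabeled = snp_map.copy()
        relabeled["probe_id"] = [f"x{i}" for i in range(len(snp_map))]
        assert call_segments(track, snp_map, "S") == call_segments(
            track, relabeled, "S"
        )

    def test_state_sign_matches_mean(self, snp_map):
        rng = np.random.default_rng(6)
        track = rng.normal(0, 0.4, len(snp_map))
        for seg in call_segments(track, snp_map, "S"):
            assert (seg.mean_log2 > 0) == (seg.state == "gain")
            assert seg.n_snps >= 5


class TestRecovery:
    def test_noise_free_recovery_exact(self):
        snp_map = sim.simulate_snp_map(2, 200, 1000)
        cfg = sim.SimConfig(
            n_trios=2, n_extra_adenomas=0, n_controls=2, n_chromosomes=2,
            snps_per_chromosome=200, probe_spacing=1000, noise_sd=1e-12,
            planted_segments=[
                sim.PlantedSegment("chr1", 50_000, 80_000, "loss", -1.0,
                                   frozenset({"T1"})),
                sim.PlantedSegment("chr2", 100_000, 150_000, "gain", 1.0,
                                   frozenset({"A2"})),
            ],
        )
        matrix, _, _ = sim.simulate_cohort(snp_map, cfg)
        for sample, chrom, state, lo, hi in [
            ("T1", "chr1", "loss", 50_000, 80_000),
            ("A2", "chr2", "gain", 100_000, 150_000),
        ]:
            ratio = compute_log2_ratio(matrix[sample], matrix["N1"])
            segs = call_segments(smooth_consecutive(ratio, snp_map), snp_map, sample)
            assert len(segs) == 1
            seg = segs[0]
            assert (seg.chromosome, seg.state) == (chrom, state)
            assert abs(seg.start - lo) <= 2_000 and abs(seg.end - hi) <= 2_000

    def test_noisy_recovery_rate(self):
        # sd 0.15, |delta| = 1.0, 20-probe segments: recovery >= 99%
        snp_map = sim.simulate_snp_map(1, 200, 1000)
        hits = 0
        n_seeds = 30
        for seed in range(n_seeds):
            cfg = sim.SimConfig(
                n_trios=1, n_extra_adenomas=0, n_controls=1, n_chromosomes=1,
                snps_per_chromosome=200, probe_spacing=1000, noise_sd=0.15,
                planted_segments=[
                    sim.PlantedSegment("chr1", 90_000, 109_000, "loss", -1.0,
                                       frozenset({"T1"}))
                ],
                seed=seed,
            )
            matrix, _, _ = sim.simulate_cohort(snp_map, cfg)
            ratio = np.log2(matrix["T1"] / sim.BASELINE_INTENSITY)
            segs = call_segments(smooth_consecutive(ratio, snp_map), snp_map, "T1")
            hits += any(
                s.state == "loss" and s.start <= 95_000 and s.end >= 105_000
                for s in segs
            )
        assert hits == n_seeds


class TestConservation:
    def _seg(self, sample, lo, hi, state="loss", chrom="chr1"):
        return AberrantSegment(sample, chrom, lo, hi, state, 10, -1.0 if state == "loss" else 1.0)

    def test_identical_sets(self):
        segs = [self._seg("S", 100, 200), self._seg("S", 500, 900, "gain")]
        assert pairwise_nonpairwise_conservation(segs, segs) == 1.0

    def test_disjoint_sets(self):
        a = [self._seg("S", 100, 200)]
        b = [self._seg("S", 1000, 2000)]
        assert pairwise_nonpairwise_conservation(a, b) == 0.0

    def test_three_of_four_covered(self):
        pairwise = [
            self._seg("S", 100, 199),
            self._seg("S", 300, 399),
            self._seg("S", 500, 599),
            self._seg("S", 700, 799),
        ]
        nonpairwise = [
            self._seg("S", 100, 199),   # full cover
            self._seg("S", 300, 360),   # 61% cover
            self._seg("S", 550, 599),   # 50% cover, boundary inclusive
            self._seg("S", 790, 799),   # 10% cover -> not conserved
        ]
        assert pairwise_nonpairwise_conservation(pairwise, nonpairwise) == 0.75

    def test_sign_must_match(self):
        a = [self._seg("S", 100, 200, "loss")]
        b = [self._seg("S", 100, 200, "gain")]
        assert pairwise_nonpairwise_conservation(a, b) == 0.0

    def test_empty_pairwise_not_applicable(self):
        assert pairwise_nonpairwise_conservation([], [self._seg("S", 1, 9)]) is None
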