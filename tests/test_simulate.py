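"""Generators: determinism, ground-truth bookkeeping, planted-effect recovery."""

import numpy as np
import pandas as pd
import pytest

from cardiomir.refractory import build_schedule
from cardiomir.simulate import (
    APWaveformParams,
    DESimParams,
    ForceSimParams,
    PlantingError,
    UTRSimParams,
    random_family_pool,
    simulate_ap_trace,
    simulate_de_table,
    simulate_expression,
    simulate_force_trace,
    simulate_reporter_cells,
    simulate_two_channel_recording,
    simulate_utrs,
)
from cardiomir.targetome import SeedFamily, count_matrix, scan_sites_bruteforce, top_n_entities


class TestSimulateUTRs:
    def test_no_planted_sites_scan_finds_nothing(self):
        pool = random_family_pool(4, 0)
        utrs, truth = simulate_utrs(
            UTRSimParams(n_genes=5, utr_length=150, family_pool=pool, rng_seed=1)
        )
        assert truth.empty
        fams = [SeedFamily(f, s) for f, s in pool.items()]
        for u in utrs:
            for fam in fams:
                assert scan_sites_bruteforce(u, fam) == []

    def test_single_planted_8mer_recorded(self):
        pool = {"F": "AAUGCCC"}
        utrs, truth = simulate_utrs(
            UTRSimParams(
                n_genes=1, utr_length=60, family_pool=pool,
                planted_sites={"g": [("F", "8mer")]}, rng_seed=2,
            )
        )
        assert len(truth) == 1
        row = truth.iloc[0]
        assert (row["gene_id"], row["family_id"], row["site_type"]) == ("g", "F", "8mer")
        assert utrs[0].sequence[row["start"]: row["end"]] == "GGGCAUUA"

    def test_scanner_counts_equal_ground_truth(self):
        pool = random_family_pool(5, 3)
        rng = np.random.default_rng(7)
        fam_ids = sorted(pool)
        planted = {
            f"g{i:02d}": [
                (fam_ids[int(rng.integers(5))],
                 ["8mer", "7mer-m8", "7mer-A1"][int(rng.integers(3))])
                for _ in range(int(rng.integers(2, 4)))
            ]
            for i in range(20)
        }
        params = UTRSimParams(
            n_genes=20, utr_length=300, family_pool=pool,
            planted_sites=planted, rng_seed=9,
        )
        utrs, truth = simulate_utrs(params)
        fams = [SeedFamily(f, s) for f, s in sorted(pool.items())]
        matrix = count_matrix(utrs, fams)
        planted_counts = truth.groupby(["family_id", "gene_id"]).size()
        for fam in fams:
            for u in utrs:
                expected = int(planted_counts.get((fam.family_id, u.gene_id), 0))
                assert int(matrix.counts.loc[fam.family_id, u.gene_id]) == expected

    def test_infeasible_planting_raises(self):
        pool = {"F": "AAUGCCC"}
        with pytest.raises((PlantingError, ValueError)):
            simulate_utrs(
                UTRSimParams(
                    n_genes=1, utr_length=10, family_pool=pool,
                    planted_sites={"g": [("F", "8mer")] * 3}, rng_seed=0,
                )
            )

    def test_bit_reproducible(self):
        pool = random_family_pool(3, 5)
        params = dict(n_genes=4, utr_length=120, family_pool=pool,
                      planted_sites={"g0": [(sorted(pool)[0], "8mer")]}, rng_seed=42)
        u1, t1 = simulate_utrs(UTRSimParams(**params))
        u2, t2 = simulate_utrs(UTRSimParams(**params))
        assert [x.sequence for x in u1] == [x.sequence for x in u2]
        pd.testing.assert_frame_equal(t1, t2)


class TestSimulateExpression:
    def test_zero_overlap(self):
        a, b = simulate_expression(60, 0, rng_seed=0, n_top=20)
        assert top_n_entities(a, b, 20) == set()

    def test_planted_46_member_intersection(self):
        a, b = simulate_expression(200, 46, rng_seed=3, n_top=100)
        assert len(top_n_entities(a, b, 100)) == 46

    def test_deterministic(self):
        a1, b1 = simulate_expression(100, 10, rng_seed=8, n_top=30)
        a2, b2 = simulate_expression(100, 10, rng_seed=8, n_top=30)
        pd.testing.assert_frame_equal(a1, a2)
        pd.testing.assert_frame_equal(b1, b2)

    def test_overlap_larger_than_top_rejected(self):
        with pytest.raises(ValueError):
            simulate_expression(50, 30, rng_seed=0, n_top=20)


class TestSimulateAPTrace:
    def test_analytic_apd90_of_square_pulse(self, square_ap_params):
        assert square_ap_params.true_apd90 == pytest.approx(380.0)
        _, truth = simulate_ap_trace(square_ap_params)
        assert np.allclose(truth.apd90, 380.0)

    def test_zero_beats_flat_trace(self):
        p = APWaveformParams(n_beats=0, noise_sd=0.0, rng_seed=0)
        trace, truth = simulate_ap_trace(p)
        assert len(truth.onset_times) == 0
        assert np.allclose(trace.signal, p.baseline)

    def test_true_rr_equals_beat_interval(self, square_ap_params):
        _, truth = simulate_ap_trace(square_ap_params)
        assert np.isnan(truth.rr[0])
        assert np.allclose(truth.rr[1:], square_ap_params.beat_interval)

    def test_coarse_sampling_rejected(self):
        with pytest.raises(ValueError):
            APWaveformParams(upstroke_duration=2.0, sampling_interval=5.0)

    def test_noise_added_after_truth(self, square_ap_params):
        noisy = APWaveformParams(**{**square_ap_params.__dict__, "noise_sd": 0.1})
        _, t_clean = simulate_ap_trace(square_ap_params)
        _, t_noisy = simulate_ap_trace(noisy)
        assert np.array_equal(t_clean.apd90, t_noisy.apd90)

    def test_two_channel_ratio_truth(self, square_ap_params):
        time, num, den, truth = simulate_two_channel_recording(square_ap_params)
        assert np.allclose(num / den, truth.signal)


class TestSimulateForceTrace:
    def test_interval_above_rp_two_twitches(self, default_schedule):
        trace, _ = simulate_force_trace(
            ForceSimParams(true_rp=400.0, rng_seed=0), default_schedule
        )
        stim = trace.stimuli
        blk = stim[stim["block"] == default_schedule.intervals.index(600.0)]
        s1 = float(blk.iloc[0]["time_ms"])
        s2 = float(blk.iloc[1]["time_ms"])
        mid = trace.force[(trace.time > s1 + 100) & (trace.time < s2)]
        peak2 = trace.force[(trace.time > s2) & (trace.time < s2 + 200)]
        assert peak2.max() > 0.9  # full second twitch present

    def test_interval_below_rp_suppressed(self, default_schedule):
        trace, _ = simulate_force_trace(
            ForceSimParams(true_rp=400.0, rng_seed=0), default_schedule
        )
        stim = trace.stimuli
        bi = default_schedule.intervals.index(300.0)
        blk = stim[stim["block"] == bi]
        s1, s2 = float(blk.iloc[0]["time_ms"]), float(blk.iloc[1]["time_ms"])
        # force after s2 is only the decaying tail of the S1 twitch
        after = trace.force[(trace.time > s2 + 30) & (trace.time < s2 + 90)]
        tail = np.exp(-(s2 + 30 - s1 - 55) / 120.0)
        assert after.max() < tail + 0.05

    def test_graded_refractory_response(self, default_schedule):
        trace, _ = simulate_force_trace(
            ForceSimParams(true_rp=400.0, refractory_response_fraction=0.5, rng_seed=0),
            default_schedule,
        )
        bi = default_schedule.intervals.index(300.0)
        blk = trace.stimuli[trace.stimuli["block"] == bi]
        s2 = float(blk.iloc[1]["time_ms"])
        resp = trace.force[(trace.time > s2) & (trace.time < s2 + 150)]
        assert 0.3 < resp.max() < 0.9

    def test_deterministic(self, default_schedule):
        p = ForceSimParams(true_rp=500.0, noise_sd=0.05, rng_seed=4)
        t1, _ = simulate_force_trace(p, default_schedule)
        t2, _ = simulate_force_trace(p, default_schedule)
        assert np.array_equal(t1.force, t2.force)


class TestSimulateDETable:
    def test_no_targets_all_negative_labels(self):
        _, labels = simulate_de_table(DESimParams(n_genes=50, n_targets=0, rng_seed=0))
        assert not labels.any()

    def test_labels_match_planted_count_and_shift(self):
        table, labels = simulate_de_table(
            DESimParams(n_genes=2000, n_targets=400, target_shift=-0.5,
                        sd_log2fc=0.2, rng_seed=1)
        )
        assert labels.sum() == 400
        assert table["log2fc"][labels].mean() == pytest.approx(-0.5, abs=0.05)
        assert table["log2fc"][~labels].mean() == pytest.approx(0.0, abs=0.05)
        # FDR ordering: shifted targets get smaller FDR on average
        assert table["fdr"][labels].mean() < table["fdr"][~labels].mean()

    def test_null_exchangeability(self):
        table, labels = simulate_de_table(
            DESimParams(n_genes=1000, n_targets=100, target_shift=0.0,
                        sd_log2fc=0.2, rng_seed=2)
        )
        t = table["log2fc"][labels]
        b = table["log2fc"][~labels]
        assert abs(t.mean() - b.mean()) < 4 * 0.2 / np.sqrt(100)

    def test_fdr_in_unit_interval(self):
        table, _ = simulate_de_table(DESimParams(n_genes=300, n_targets=30, rng_seed=3))
        assert table["fdr"].between(0, 1).all()


class TestSimulateReporterCells:
    def test_noiseless_exact_factor(self):
        treated, control = simulate_reporter_cells(
            20, 1.0, 0.5, cv=0.0, rng_seed=0
        )
        rt = np.array([c.gfp_mean / c.rfp_mean for c in treated])
        rc = np.array([c.gfp_mean / c.rfp_mean for c in control])
        assert np.allclose(rt, 0.5) and np.allclose(rc, 1.0)

    def test_factor_one_identity(self):
        treated, control = simulate_reporter_cells(200, 1.0, 1.0, cv=0.1, rng_seed=1)
        rt = np.mean([c.gfp_mean / c.rfp_mean for c in treated])
        rc = np.mean([c.gfp_mean / c.rfp_mean for c in control])
        assert rt / rc == pytest.approx(1.0, abs=0.05)

    def test_invalid_factor_rejected(self):
        with pytest.raises(ValueError):
            simulate_reporter_cells(10, 1.0, 0.0, 0.1, 0)
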