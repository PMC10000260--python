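"""Synthetic-zygote simulator: determinism, calibration, error modes."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import truncnorm

from pnquant.detect import DetectorParams, detect_pronuclei, evaluate_recognition
from pnquant.focal import ZStack, select_clearest_plane
from pnquant.growth import fit_exponential
from pnquant.karyotype import analyze_pgt_string
from pnquant.simulate import (
    SimConfig,
    detections_from_frame,
    recognition_tables,
    render_zstack,
    simulate_cohort,
    simulate_detections,
    simulate_outcomes,
    simulate_patient_beta1s,
    simulate_trajectories,
)
from pnquant.track import track_embryo

CLEAN = dict(early_overcall_rate=0.0, overlap_miss_rate=0.0, vacuole_rate=0.0)


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        cfg = SimConfig(n_patients=6)
        a = simulate_cohort(cfg, seed=3)
        b = simulate_cohort(cfg, seed=3)
        pd.testing.assert_frame_equal(a["detections"], b["detections"])
        pd.testing.assert_frame_equal(a["outcomes"], b["outcomes"])

    def test_different_seed_differs(self):
        cfg = SimConfig(n_patients=6)
        a = simulate_cohort(cfg, seed=3)
        b = simulate_cohort(cfg, seed=4)
        assert not a["detections"].equals(b["detections"])

    def test_infeasible_config_rejected(self):
        with pytest.raises(ValueError, match="fade"):
            SimConfig(male_appear_h=(19.0, 21.0), fade_h=(20.0, 23.0))


class TestTrajectories:
    def test_noiseless_trajectories_exactly_exponential(self):
        cfg = SimConfig(n_patients=4, noise_sigma=0.0, **CLEAN)
        for emb in simulate_trajectories(cfg, seed=2):
            if emb.female is None:
                continue
            fit = fit_exponential(emb.female)
            assert fit.beta1 == pytest.approx(emb.beta1_female, rel=1e-9)
            assert fit.beta2 == pytest.approx(emb.beta2_female, rel=1e-9)

    def test_beta2_cohort_summary_recovers_truncated_normal(self):
        cfg = SimConfig(n_patients=100, noise_sigma=0.02)
        embryos = [e for e in simulate_trajectories(cfg, seed=4) if e.female]
        assert len(embryos) >= 400
        beta2 = np.array([fit_exponential(e.female).beta2 for e in embryos])
        a = (cfg.beta2_bounds[0] - cfg.beta2_mean) / cfg.beta2_sd
        b = (cfg.beta2_bounds[1] - cfg.beta2_mean) / cfg.beta2_sd
        mean_true, var_true = truncnorm.stats(
            a, b, loc=cfg.beta2_mean, scale=cfg.beta2_sd, moments="mv"
        )
        sd_true = float(np.sqrt(var_true))
        n = len(beta2)
        assert beta2.mean() == pytest.approx(float(mean_true), abs=4 * sd_true / np.sqrt(n))
        assert beta2.std(ddof=1) == pytest.approx(sd_true, abs=4 * sd_true / np.sqrt(2 * n))
        # and the nominal generator parameters at coarse precision
        assert beta2.mean() == pytest.approx(1.04, abs=0.005)
        # fitted values scatter around the truncated truth by noise
        assert beta2.min() >= 1.01 - 0.01 and beta2.max() <= 1.11 + 0.01

    def test_male_appears_earlier_and_larger_early(self):
        cfg = SimConfig(n_patients=20, noise_sigma=0.0, **CLEAN)
        embryos = [e for e in simulate_trajectories(cfg, seed=5) if e.female]
        assert all(e.t_male_appear_h < e.t_female_appear_h for e in embryos)
        first_larger = np.mean(
            [e.male.areas_um2[0] > e.female.areas_um2[0] for e in embryos]
        )
        assert first_larger > 0.9


class TestDetectionErrorModel:
    def test_zero_error_rates_perfect_recognition(self):
        cfg = SimConfig(n_patients=5, **CLEAN)
        embryos = simulate_trajectories(cfg, seed=5)
        det, ann, _ = simulate_detections(embryos, cfg, seed=6)
        auto, truth, _ = recognition_tables(det, ann)
        _, acc = evaluate_recognition(auto, truth)
        assert acc == 1.0

    def test_windowed_accuracies_ordered_and_overcalls_early(self):
        cfg = SimConfig(n_patients=40)
        embryos = simulate_trajectories(cfg, seed=7)
        det, ann, _ = simulate_detections(embryos, cfg, seed=8)
        auto, truth, times = recognition_tables(det, ann)
        _, acc_all = evaluate_recognition(auto, truth)
        _, acc_12 = evaluate_recognition(auto, truth, frame_times_h=times, window_from_h=12.0)
        _, acc_14 = evaluate_recognition(auto, truth, frame_times_h=times, window_from_h=14.0)
        assert acc_all < acc_12 < acc_14
        overcalls = [k for k in auto if auto[k] == 2 and truth[k] != 2]
        early_share = np.mean([times[k] < 12.0 for k in overcalls])
        assert early_share > 0.9

    def test_injected_swaps_recovered_exactly(self):
        cfg = SimConfig(n_patients=4, noise_sigma=0.0, **CLEAN)
        embryos = [e for e in simulate_trajectories(cfg, seed=9) if e.female]
        want = {embryos[0].embryo_id: {40, 45}, embryos[1].embryo_id: {38}}
        det, _, injected = simulate_detections(embryos, cfg, seed=10, swap_frames=want)
        by_embryo: dict[str, list] = {}
        for d in detections_from_frame(det, cfg.scale_um_per_px):
            by_embryo.setdefault(d.embryo_id, []).append(d)
        for emb in embryos[:2]:
            track, female, _ = track_embryo(by_embryo[emb.embryo_id])
            assert sorted(track.swap_events) == sorted(injected[emb.embryo_id])
            # final labels match truth: the female fit recovers female beta1
            fit = fit_exponential(female)
            assert fit.beta1 == pytest.approx(emb.beta1_female, rel=1e-9)

    def test_random_swaps_all_corrected(self):
        cfg = SimConfig(n_patients=10, noise_sigma=0.0, swap_rate=0.05, **CLEAN)
        embryos = [e for e in simulate_trajectories(cfg, seed=11) if e.female]
        det, _, injected = simulate_detections(embryos, cfg, seed=12)
        by_embryo: dict[str, list] = {}
        for d in detections_from_frame(det, cfg.scale_um_per_px):
            by_embryo.setdefault(d.embryo_id, []).append(d)
        for emb in embryos:
            track, _, _ = track_embryo(by_embryo[emb.embryo_id])
            assert sorted(track.swap_events) == sorted(injected[emb.embryo_id])


class TestOutcomes:
    def test_null_model_or_near_one(self):
        from pnquant.ranking import odds_ratio_woolf, rank_within_patient, top_vs_last_table

        cfg = SimConfig(n_patients=2000, outcome_gamma=0.0)
        cohort = simulate_patient_beta1s(cfg, seed=12)
        out = simulate_outcomes(cohort, cfg, seed=13)
        ranked = rank_within_patient(out, pool_after=8).rename(
            columns={"normal_group": "outcome"}
        )
        a, b, c, d = top_vs_last_table(ranked)
        res = odds_ratio_woolf(a, b, c, d)
        se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        assert abs(np.log(res.estimate)) < 3 * se

    def test_all_normal_distribution_parses_normal(self):
        cfg = SimConfig(n_patients=10, outcome_alpha=50.0,
                        mosaic_share_of_normal_group=0.0)
        cohort = simulate_patient_beta1s(cfg, seed=14)
        out = simulate_outcomes(cohort, cfg, seed=15)
        assert (out["category"] == "chromosome_normal").all()
        assert all(
            analyze_pgt_string(s).category == "chromosome_normal"
            for s in out["pgt_string"]
        )

    def test_synthesised_strings_classify_to_assigned_category(self):
        cfg = SimConfig(n_patients=60)
        cohort = simulate_patient_beta1s(cfg, seed=16)
        out = simulate_outcomes(cohort, cfg, seed=17)
        assert set(out["category"]) >= {"chromosome_normal", "sole_aneuploidy"}
        for s, cat in zip(out["pgt_string"], out["category"]):
            assert analyze_pgt_string(s).category == cat


@pytest.fixture(scope="module")
def embryo():
    cfg = SimConfig(n_patients=2, noise_sigma=0.0, **CLEAN)
    return cfg, [e for e in simulate_trajectories(cfg, seed=9) if e.female][0]


class TestRendering:
    def test_detector_recovers_rendered_areas(self, embryo):
        cfg, emb = embryo
        planes = render_zstack(emb, 16.0, cfg, seed=11, sharp_plane=4)
        _, img = select_clearest_plane(
            ZStack(emb.embryo_id, 16.0, planes, list(range(-75, 76, 15)))
        )
        dets = detect_pronuclei(
            img, DetectorParams(min_area_px=100),
            scale_um_per_px=cfg.render_scale_um_per_px,
        )
        assert len(dets) == 2
        truth = sorted(
            [emb.beta1_female * emb.beta2_female**16.0,
             emb.beta1_male * emb.beta2_male**16.0]
        )
        for got, want in zip(sorted(d.area_um2 for d in dets), truth):
            assert got == pytest.approx(want, rel=0.05)

    @pytest.mark.parametrize("sharp", [0, 4, 10])
    def test_focal_selection_finds_rendered_sharp_plane(self, embryo, sharp):
        cfg, emb = embryo
        planes = render_zstack(emb, 15.0, cfg, seed=20 + sharp, sharp_plane=sharp)
        stack = ZStack(emb.embryo_id, 15.0, planes, list(range(-75, 76, 15)))
        assert select_clearest_plane(stack)[0] == sharp

    def test_oversized_pn_rejected(self, embryo):
        cfg, emb = embryo
        import dataclasses

        huge = dataclasses.replace(emb, beta1_female=50000.0, female=None, male=None)
        with pytest.raises(ValueError, match="exceeds"):
            render_zstack(huge, 16.0, cfg, seed=1)
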