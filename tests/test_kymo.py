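"""Kymograph analysis: peaks, linking, MSD, diffusion fits, profiles, bleaching."""

import numpy as np
import pytest

from parbslide.imaging import OpticsConfig, ScanImage, render_kymograph
from parbslide.kymo import (
    Trajectory,
    compute_msd,
    detect_peaks,
    ensemble_D,
    extract_profile,
    fit_bleach_decay,
    fit_diffusion,
    is_immobile,
    link_tracks,
    quantify_region,
    track_kymograph,
    trim_parS_dwell,
)
from parbslide.simulate import ParticleRecord, SimConfig, TrajectorySet, condition_preset, simulate
from parbslide.substrate import build_substrate


def _brownian_track(rng, n=100, d=0.4, dt=0.025, x0=0.0):
    steps = rng.normal(0.0, np.sqrt(2 * d * dt), n - 1)
    x = np.concatenate([[x0], x0 + np.cumsum(steps)])
    return Trajectory(times=np.arange(n) * dt, positions_um=x, intensities=np.zeros(n))


class TestDetectPeaks:
    def test_flat_line_gives_no_peaks(self):
        pos, _ = detect_peaks(np.ones(50), threshold=2.0)
        assert len(pos) == 0

    def test_rendered_emitter_localized_within_half_pixel(self):
        smap = build_substrate("1x")
        cfg = condition_preset("apo", duration=10.0, seed=6, load_rate=5.0,
                               parS_unbind_rate=0.0, bleach_rate=0.0)
        ts = simulate(cfg, smap)
        kymo = render_kymograph(ts, OpticsConfig(), seed=7)
        true_px = smap.parS_sites[0].center * smap.rise_per_bp / 100.0
        errors = []
        for row in kymo.counts:
            pos, _ = detect_peaks(row, threshold=5.0)
            if len(pos) == 1:
                errors.append(abs(pos[0] - true_px))
        assert len(errors) > 300
        assert np.mean(errors) < 0.5

    def test_close_peaks_merged_keeping_brighter(self):
        line = np.zeros(30)
        line[10] = 8.0
        line[13] = 10.0
        pos, hgt = detect_peaks(line, threshold=2.0, min_separation=5.0)
        assert len(pos) == 1
        assert abs(pos[0] - 13) < 1.0


class TestLinkTracks:
    def test_persistent_peak_gives_one_full_track(self):
        peaks = [(np.array([12.0]), np.array([10.0]))] * 30
        tracks = link_tracks(peaks, max_jump_px=3.0, min_length=5)
        assert len(tracks) == 1
        assert len(tracks[0][0]) == 30

    def test_single_line_gap_splits_track_without_gap_closing(self):
        peaks = [(np.array([12.0]), np.array([10.0]))] * 10
        peaks[5] = (np.array([]), np.array([]))
        tracks = link_tracks(peaks, max_jump_px=3.0, min_length=3)
        assert len(tracks) == 2
        assert [len(t[0]) for t in tracks] == [5, 4]

    def test_two_separated_clamps_recovered_with_correct_identities(self, sub2x):
        rng = np.random.default_rng(12)
        rise = sub2x.rise_per_bp
        times = np.arange(0, 5.0 + 1e-9, 0.005)
        n = len(times)

        def brown(x0):
            steps = rng.normal(0, np.sqrt(2 * 0.4 * 0.005) * 1000 / rise, n - 1)
            x = np.concatenate([[x0], x0 + np.cumsum(steps)])
            # fold into the substrate so emitters stay in the imaged field
            length = float(sub2x.length)
            y = x % (2 * length)
            return np.where(y > length, 2 * length - y, y)

        truth = [
            ParticleRecord(0, 0.0, brown(5000.0), np.full(n, "clamp", dtype=object)),
            ParticleRecord(1, 0.0, brown(13000.0), np.full(n, "clamp", dtype=object)),
        ]
        ts = TrajectorySet(sub2x, SimConfig(duration=5.0, dt=0.005, seed=0), truth, times)
        kymo = render_kymograph(ts, OpticsConfig(), seed=9)
        tracks = track_kymograph(kymo, threshold=5.0, min_length=40)
        assert len(tracks) >= 2
        correct = total = 0
        for tr in tracks:
            i0 = int(round(tr.times[0] / 0.005))
            x0 = tr.positions_um[0] * 1000 / rise
            ref = min(truth, key=lambda p: abs(x0 - p.positions[i0]))
            for t, x in zip(tr.times, tr.positions_um):
                i = int(round(t / 0.005))
                total += 1
                correct += abs(x * 1000 / rise - ref.positions[i]) * rise / 1000 < 0.3
        assert correct / total >= 0.95


class TestMsd:
    def test_immobile_trajectory_has_zero_msd(self):
        tr = Trajectory(np.arange(50) * 0.025, np.full(50, 1.5), np.zeros(50))
        msd = compute_msd(tr)
        assert np.all(msd.msd == 0.0)

    def test_ballistic_trajectory_is_quadratic(self):
        v = 0.8
        t = np.arange(60) * 0.025
        tr = Trajectory(t, v * t, np.zeros(60))
        msd = compute_msd(tr)
        assert msd.msd == pytest.approx(v**2 * msd.lag_times**2)

    def test_matches_brute_force_double_loop(self, rng):
        for _ in range(100):
            n = int(rng.integers(13, 120))
            tr = _brownian_track(rng, n=n)
            msd = compute_msd(tr)
            x = tr.positions_um[: min(n, 101)]  # 2.5 s clip at 25 ms sampling
            for j, k in enumerate(range(1, len(msd.msd) + 1)):
                brute = np.mean([(x[i + k] - x[i]) ** 2 for i in range(len(x) - k)])
                assert msd.msd[j] == pytest.approx(brute, rel=1e-12)
                assert msd.pair_counts[j] == len(x) - k

    def test_clipped_to_first_2p5_seconds(self):
        tr = _brownian_track(np.random.default_rng(0), n=400)  # 10 s at 25 ms
        msd = compute_msd(tr)
        # 2.5 s -> 101 samples -> max lag 25
        assert len(msd.msd) == 25

    def test_too_short_track_rejected(self):
        tr = _brownian_track(np.random.default_rng(0), n=8)
        with pytest.raises(ValueError, match="too short"):
            compute_msd(tr)


class TestFitDiffusion:
    def test_exact_line_recovers_headline_value(self):
        t = np.arange(1, 13) * 0.025
        msd = compute_msd(
            Trajectory(np.arange(50) * 0.025, np.zeros(50), np.zeros(50))
        )
        msd.lag_times = t
        msd.msd = 2 * 0.41 * t + 0.001
        est = fit_diffusion(msd)
        assert est.D == pytest.approx(0.41, abs=1e-12)
        assert est.offset == pytest.approx(0.001, abs=1e-12)

    def test_constant_msd_gives_zero_d(self):
        msd = compute_msd(Trajectory(np.arange(60) * 0.025, np.zeros(60), np.zeros(60)))
        msd.msd = np.full_like(msd.msd, 0.02)
        est = fit_diffusion(msd)
        assert est.D == pytest.approx(0.0, abs=1e-12)
        assert est.offset == pytest.approx(0.02)

    def test_needs_three_points(self):
        msd = compute_msd(_brownian_track(np.random.default_rng(0), n=60))
        msd.lag_times, msd.msd = msd.lag_times[:2], msd.msd[:2]
        with pytest.raises(ValueError):
            fit_diffusion(msd, lag_window=(1, 2))

    def test_offset_positive_for_rendered_but_not_ground_truth(self):
        # localization noise appears as a positive intercept in rendered data
        smap = build_substrate("1x")
        cfg = condition_preset("apo", duration=10.0, seed=6, load_rate=5.0,
                               parS_unbind_rate=0.0, bleach_rate=0.0)
        ts = simulate(cfg, smap)
        kymo = render_kymograph(ts, OpticsConfig(), seed=7)
        track = track_kymograph(kymo, threshold=5.0, min_length=40)[0]
        rendered = fit_diffusion(compute_msd(track))
        assert rendered.offset > 0

        rng = np.random.default_rng(3)
        offsets = [fit_diffusion(compute_msd(_brownian_track(rng))).offset
                   for _ in range(200)]
        assert abs(np.mean(offsets)) < 0.005
        assert rendered.offset > np.mean(offsets)


class TestEnsemble:
    def test_identical_estimates_have_zero_sem(self):
        mean, sem, n = ensemble_D(np.array([0.4, 0.4, 0.4]))
        assert mean == pytest.approx(0.4)
        assert sem == pytest.approx(0.0, abs=1e-12)
        assert n == 3

    def test_two_value_arithmetic(self):
        mean, sem, n = ensemble_D(np.array([0.3, 0.5]))
        assert mean == pytest.approx(0.4)
        assert sem == pytest.approx(0.1)

    def test_sem_scales_inverse_sqrt_n(self, rng):
        d = rng.normal(0.4, 0.1, 177)
        _, sem_full, _ = ensemble_D(d)
        subs = [ensemble_D(rng.choice(d, 44, replace=False))[1] for _ in range(300)]
        ratio = np.mean(subs) / sem_full
        assert ratio == pytest.approx(np.sqrt(177 / 44), rel=0.15)

    def test_single_estimate_rejected(self):
        with pytest.raises(ValueError):
            ensemble_D(np.array([0.4]))


class TestMobilityClassification:
    def test_immobile_requires_low_d_and_pars_position(self, sub39):
        slow = fit_diffusion(compute_msd(
            Trajectory(np.arange(60) * 0.025, np.full(60, 1.0), np.zeros(60))))
        pars_um = sub39.parS_sites[0].center * sub39.rise_per_bp / 1000.0
        assert is_immobile(slow, pars_um, sub39)
        assert not is_immobile(slow, pars_um - 1.0, sub39)
        fast = fit_diffusion(compute_msd(_brownian_track(np.random.default_rng(0), d=0.4)))
        assert not is_immobile(fast, pars_um, sub39)

    def test_trim_pars_dwell(self):
        smap = build_substrate("tpm_1717")
        pars_um = smap.parS_sites[0].center * smap.rise_per_bp / 1000.0
        n = 40
        pos = np.concatenate(
            [np.full(10, pars_um), np.linspace(pars_um + 0.3, pars_um + 0.5, n - 10)]
        )
        tr = Trajectory(np.arange(n) * 0.025, pos, np.zeros(n))
        trimmed = trim_parS_dwell(tr, smap)
        assert len(trimmed) == n - 10
        stuck = Trajectory(np.arange(n) * 0.025, np.full(n, pars_um), np.zeros(n))
        assert trim_parS_dwell(stuck, smap) is None


class TestProfiles:
    def _uniform_scan(self, value=7):
        counts = np.full((11, 40), value, dtype=np.uint16)
        return ScanImage(counts=counts,
                         row_positions=(np.arange(11) - 5) * 100.0,
                         pixel_positions=np.arange(40) * 100.0,
                         t_start=0.0, optics=OpticsConfig(), axis_row=5)

    def test_uniform_image_flat_profile_and_unit_fold(self):
        prof = extract_profile(self._uniform_scan())
        assert np.ptp(prof.mean_counts) == 0
        a = quantify_region(prof, (0.5, 1.5))
        b = quantify_region(prof, (2.0, 3.0))
        assert a == b  # fold-enhancement 1

    def test_band_conservation(self):
        scan = self._uniform_scan()
        scan.counts = np.random.default_rng(0).poisson(7, scan.counts.shape).astype(np.uint16)
        prof = extract_profile(scan, band_width_nm=500.0)
        band = np.abs(scan.row_positions) <= 250.0
        assert prof.mean_counts.sum() * band.sum() == pytest.approx(
            scan.counts[band].sum()
        )

    def test_window_outside_field_rejected(self):
        prof = extract_profile(self._uniform_scan())
        with pytest.raises(ValueError, match="outside"):
            quantify_region(prof, (50.0, 60.0))

    def test_ctp_enhances_pars_region_and_populates_nsdna(self, sub39):
        from parbslide.imaging import render_scan
        from parbslide.simulate import occupancy_profile

        scans, profs, occs = {}, {}, {}
        for cond in ("CTP", "apo"):
            cfg = condition_preset(cond, duration=20.0, seed=9, bleach_rate=0.0,
                                   load_rate=0.5)
            ts = simulate(cfg, sub39)
            occs[cond] = occupancy_profile(ts, bin_bp=100)
            scans[cond] = render_scan(ts, t0=19.0, n_lines=15, seed=2)
            profs[cond] = extract_profile(scans[cond])
        ps = sub39.parS_sites
        rise_um = sub39.rise_per_bp / 1000.0
        pars_win = (ps[0].start * rise_um, ps[-1].end * rise_um)
        ns_win = (1.0, 2.5)  # nsDNA flank
        fold = (quantify_region(profs["CTP"], pars_win)
                / quantify_region(profs["apo"], pars_win))
        assert fold > 1.0
        ns_ctp = quantify_region(profs["CTP"], ns_win)
        ns_apo = quantify_region(profs["apo"], ns_win)
        assert ns_ctp > 3.0 * max(abs(ns_apo), 0.1)
        # cross-check against the ground-truth occupancy oracle
        edges, occ_apo = occs["apo"]
        centers = 0.5 * (edges[:-1] + edges[1:])
        ns_bins = (centers >= 1.0 / rise_um) & (centers <= 2.5 / rise_um)
        assert occ_apo[ns_bins].sum() == 0.0
        _, occ_ctp = occs["CTP"]
        assert occ_ctp[ns_bins].sum() > 0.0


def test_bleach_decay_fit_exact_on_synthetic():
    t = np.linspace(0, 30, 200)
    rate, amp, floor = fit_bleach_decay(t, 5.0 * np.exp(-0.25 * t) + 2.0)
    assert rate == pytest.approx(0.25, rel=1e-6)
    assert amp == pytest.approx(5.0, rel=1e-6)
    assert floor == pytest.approx(2.0, rel=1e-6)


def test_bleach_decay_recovered_from_rendered_kymograph(sub39):
    cfg = condition_preset("apo", duration=40.0, seed=4, load_rate=1.0,
                           parS_unbind_rate=0.0, bleach_rate=0.15,
                           illumination_start=5.0)
    ts = simulate(cfg, sub39)
    kymo = render_kymograph(ts, OpticsConfig(), seed=5)
    sel = kymo.line_times >= 5.0
    intensity = kymo.counts[sel].sum(axis=1) - 1.0 * kymo.counts.shape[1]
    rate, _, _ = fit_bleach_decay(kymo.line_times[sel] - 5.0, intensity)
    assert rate == pytest.approx(0.15, rel=0.25)
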