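"""STA computation, time course, SNR, polarity, selection and RF fitting."""

from dataclasses import replace

import numpy as np
import pytest

from retdecode.stimuli import StimulusMovie, generate_white_noise
from retdecode.synthetic_retina import (GroundTruthCell, SpikeTrain,
                                        inject_noise, simulate_cell)
from retdecode.receptive_fields import (CellRecord, classify_polarity,
                                        compute_snr, compute_sta,
                                        extract_time_course, fit_rf_ellipse,
                                        select_cells, TimeCourse)


class TestComputeSTA:
    def test_fixed_pattern_responder_recovers_pattern_exactly(self, perfect=None):
        from conftest import perfect_responder

        movie, train, pattern = perfect_responder(n_spikes=20)
        sta = compute_sta(train, movie)
        assert np.allclose(sta.kernel, pattern)
        assert sta.spike_count_used == 20
        assert sta.depth_frames == 24  # default window

    def test_random_spikes_converge_to_stimulus_mean(self):
        mv = generate_white_noise((8000, 6, 6), seed=0)
        rng = np.random.default_rng(1)
        train = SpikeTrain(np.sort(rng.uniform(1.0, mv.duration - 1e-3, 6000)), mv.duration)
        sta = compute_sta(train, mv)
        # per-voxel binomial error ~0.5/sqrt(N); allow 6 sigma for the max
        assert np.max(np.abs(sta.kernel - 0.5)) < 6 * 0.5 / np.sqrt(train.n_spikes)

    def test_linear_in_the_stimulus(self, wn_movie, on_train):
        sta = compute_sta(on_train, wn_movie)
        scaled = StimulusMovie(0.5 * wn_movie.frames + 0.25, wn_movie.frame_rate,
                               wn_movie.pixel_pitch)
        sta2 = compute_sta(on_train, scaled)
        assert np.allclose(sta2.kernel, 0.5 * sta.kernel + 0.25)

    def test_split_half_consistency(self):
        mv = generate_white_noise((24_000, 6, 6), seed=6)
        cell = GroundTruthCell(cell_id=0, center_um=(180.0, 180.0))
        train = simulate_cell(cell, mv, seed=7)
        assert train.n_spikes >= 5000
        half = train.n_spikes // 2
        a = compute_sta(SpikeTrain(train.times[:half], train.duration), mv)
        b = compute_sta(SpikeTrain(train.times[half:], train.duration), mv)
        r = np.corrcoef(a.kernel.ravel(), b.kernel.ravel())[0, 1]
        assert r > 0.8

    def test_no_usable_spikes_rejected(self, wn_movie):
        early = SpikeTrain(np.array([0.01]), wn_movie.duration)  # inside first window
        with pytest.raises(ValueError):
            compute_sta(early, wn_movie)

    def test_crop_box_inside_kernel(self, wn_movie, on_train):
        sta = compute_sta(on_train, wn_movie)
        (f0, f1), (y0, y1), (x0, x1) = sta.crop_box
        assert 0 <= f0 < f1 <= sta.depth_frames and f1 - f0 == 4
        assert 0 <= y0 < y1 <= 12 and y1 - y0 == 3
        assert 0 <= x0 < x1 <= 12 and x1 - x0 == 3
        assert sta.cropped().shape == (4, 3, 3)


class TestTimeCourse:
    def test_flat_sta_gives_zero_time_course(self):
        mv = generate_white_noise((200, 4, 4), seed=0)
        from retdecode.receptive_fields import STA, _peak_and_crop

        kernel = np.full((24, 4, 4), 0.5)
        peak, box = _peak_and_crop(kernel, 0.5)
        tc = extract_time_course(STA(kernel, 10, 0.5, peak, box))
        assert np.all(tc.values == 0.0)

    def test_on_cell_last_lobe_positive(self, wn_movie, on_train):
        tc = extract_time_course(compute_sta(on_train, wn_movie))
        assert tc.peak_value > 0
        assert classify_polarity(tc, "visual", "LE") == "ON"

    def test_off_cell_last_lobe_negative(self, wn_movie, on_cell):
        off = replace(on_cell, cell_id="off0", polarity="OFF")
        train = simulate_cell(off, wn_movie, seed=11)
        tc = extract_time_course(compute_sta(train, wn_movie))
        assert tc.peak_value < 0
        assert classify_polarity(tc, "visual", "LE") == "OFF"

    def test_electrical_polarity_inversion_for_healthy_retina(self, wn_movie, on_train):
        tc = extract_time_course(compute_sta(on_train, wn_movie))
        assert classify_polarity(tc, "electrical", "LE") == "OFF"
        # degenerate retina labels are reported as measured
        assert classify_polarity(tc, "electrical", "RCS") == "ON"

    def test_negated_time_course_flips_label(self, wn_movie, on_train):
        tc = extract_time_course(compute_sta(on_train, wn_movie))
        flipped = TimeCourse(-tc.values, tc.peak_lag, -tc.peak_value)
        assert {classify_polarity(tc), classify_polarity(flipped)} == {"ON", "OFF"}

    def test_flat_course_unclassified(self):
        tc = TimeCourse(np.zeros(24), 0, 0.0)
        assert classify_polarity(tc) == "unclassified"


class TestSNR:
    def test_scale_invariance(self, wn_movie, on_train):
        tc = extract_time_course(compute_sta(on_train, wn_movie))
        scaled = TimeCourse(3.0 * tc.values, tc.peak_lag, 3.0 * tc.peak_value)
        assert compute_snr(tc) == pytest.approx(compute_snr(scaled))

    def test_signal_cell_beats_threshold_noise_cell_does_not(self, wn_movie, on_train):
        snr_signal = compute_snr(extract_time_course(compute_sta(on_train, wn_movie)))
        assert snr_signal >= 3.0
        noisy = inject_noise(on_train, 1.0, seed=3)
        snrs = []
        for s in range(6):
            sub = inject_noise(on_train, 1.0, seed=10 + s)
            snrs.append(compute_snr(extract_time_course(compute_sta(sub, wn_movie))))
        assert np.median(snrs) < 3.0

    def test_zero_noise_gives_infinity(self):
        tc = TimeCourse(np.concatenate([np.zeros(20), [0, 0, 0, 1.0]]), 23, 1.0)
        assert compute_snr(tc) == np.inf

    def test_short_course_rejected(self):
        with pytest.raises(ValueError):
            compute_snr(TimeCourse(np.ones(5), 0, 1.0))


class TestSelectCells:
    def _records(self):
        return [
            CellRecord("a", snr=10.0, contamination=0.01),
            CellRecord("b", snr=2.9, contamination=0.01),
            CellRecord("c", snr=10.0, contamination=0.12),
            CellRecord("d", snr=3.0, contamination=0.10),
        ]

    def test_contamination_and_snr_filters(self):
        kept, audit = select_cells(self._records())
        assert [r.cell_id for r in kept] == ["a", "d"]
        failed = audit[~audit["kept"]]
        assert set(zip(failed["cell_id"], failed["criterion"])) == {
            ("b", "snr>=3"), ("c", "contamination<0.10")}

    def test_empty_input(self):
        kept, audit = select_cells([])
        assert kept == [] and audit.empty

    def test_idempotent(self):
        kept, _ = select_cells(self._records())
        again, _ = select_cells(kept)
        assert [r.cell_id for r in again] == [r.cell_id for r in kept]

    def test_healthy_retina_region_and_dual_response_flags(self):
        recs = [CellRecord("a", 10, 0.0, in_implant_region=True, dual_responsive=True),
                CellRecord("b", 10, 0.0, in_implant_region=False, dual_responsive=True),
                CellRecord("c", 10, 0.0, in_implant_region=True, dual_responsive=False)]
        kept, _ = select_cells(recs, require_in_implant=True,
                               require_dual_responsive=True)
        assert [r.cell_id for r in kept] == ["a"]


class TestRFEllipse:
    def test_isotropic_cell_recovered(self, wn_movie, on_cell, on_train):
        sta = compute_sta(on_train, wn_movie)
        fit = fit_rf_ellipse(sta)
        assert fit.converged
        # centre within 1 pixel of ground truth
        cy_px = on_cell.center_um[0] / wn_movie.pixel_pitch
        cx_px = on_cell.center_um[1] / wn_movie.pixel_pitch
        assert abs(fit.center[0] - cy_px) < 1.0
        assert abs(fit.center[1] - cx_px) < 1.0
        # near-unity axis ratio for an isotropic RF
        ratio = max(fit.sigma_y, fit.sigma_x) / min(fit.sigma_y, fit.sigma_x)
        assert ratio < 1.5
        # scale within 25 % of the DoG centre width
        sigma_px = on_cell.sigma_center_um / wn_movie.pixel_pitch
        assert min(fit.sigma_y, fit.sigma_x) < sigma_px * 1.6
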