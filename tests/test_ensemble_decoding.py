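"""Block matching, templates, trial simulation and orientation decoding."""

import numpy as np
import pytest

from retdecode.stimuli import ORIENTATIONS, generate_white_noise
from retdecode.synthetic_retina import (RetinaSpec, build_population,
                                        simulate_population)
from retdecode.receptive_fields import compute_sta
from retdecode.ensemble_decoding import (EnsembleDecoder, ResponseTemplate,
                                         build_templates, decode_accuracy,
                                         decode_trial, find_matching_blocks,
                                         input_strength, run_experiment,
                                         simulate_trial, sliding_strengths)


@pytest.fixture(scope="module")
def small_retina():
    """10-cell population with STAs and spike trains on a shared movie."""
    mv = generate_white_noise((4500, 12, 12), seed=20)
    cells = build_population(RetinaSpec(preset="LE", n_cells=10,
                                        field_shape=(12, 12), noise_ratio=0.0),
                             seed=21)
    trains = simulate_population(cells, mv, seed=22)
    kernels = [compute_sta(tr, mv).kernel - 0.5 for tr in trains]
    return mv, cells, trains, kernels


class TestInputStrength:
    def test_zero_kernel_gives_zero(self):
        w = np.zeros((24, 4, 4))
        block = np.random.default_rng(0).random((24, 4, 4))
        assert input_strength(w, block) == 0.0

    def test_linear_in_the_block(self):
        rng = np.random.default_rng(1)
        w = rng.normal(size=(4, 3, 3))
        block = rng.normal(size=(4, 3, 3))
        assert input_strength(w, 2.5 * block) == pytest.approx(
            2.5 * input_strength(w, block))

    def test_matched_block_is_maximal_at_unit_norm(self):
        rng = np.random.default_rng(2)
        w = rng.normal(size=(4, 3, 3))
        best = w / np.linalg.norm(w)
        for _ in range(20):
            other = rng.normal(size=(4, 3, 3))
            other /= np.linalg.norm(other)
            assert input_strength(w, other) <= input_strength(w, best) + 1e-12

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            input_strength(np.zeros((4, 3, 3)), np.zeros((4, 4, 4)))


class TestBlockMatching:
    def test_exact_member_ranks_first_with_zero_residual(self, small_retina):
        mv, _, _, kernels = small_retina
        w = kernels[0]
        strengths = sliding_strengths(mv, w)
        target = strengths[137]
        starts, resid = find_matching_blocks(mv, w, target, k=5)
        assert starts[0] == 137
        assert resid[0] == 0.0
        assert np.all(np.diff(resid) >= 0)

    def test_k_of_one_equals_exhaustive_scan(self):
        """Brute-force python scan over a 500-frame movie as the oracle."""
        mv = generate_white_noise((500, 6, 6), seed=3)
        rng = np.random.default_rng(4)
        w = rng.normal(size=(24, 6, 6))
        c = float(mv.frames.mean())
        target = 1.234
        best, best_r = None, np.inf
        for t in range(mv.n_frames - 24 + 1):
            s = float(np.vdot(w, mv.frames[t : t + 24] - c))
            if abs(s - target) < best_r:
                best, best_r = t, abs(s - target)
        starts, resid = find_matching_blocks(mv, w, target, k=1)
        assert starts[0] == best
        assert resid[0] == pytest.approx(best_r)

    def test_too_many_blocks_requested(self, small_retina):
        mv, _, _, kernels = small_retina
        with pytest.raises(ValueError):
            find_matching_blocks(mv, kernels[0], 0.0, k=mv.n_frames)

    def test_disjoint_blocks_do_not_overlap(self, small_retina):
        mv, _, _, kernels = small_retina
        starts, _ = find_matching_blocks(mv, kernels[0], 0.0, k=20, disjoint=True)
        s = np.sort(starts)
        assert np.all(np.diff(s) >= 24)


class TestTemplates:
    def test_six_bins_per_cell_and_nonnegative(self, small_retina):
        mv, _, trains, kernels = small_retina
        dec = EnsembleDecoder(kernels, trains, mv, k_blocks=100)
        templates = dec.templates_for(8)
        assert set(templates) == set(ORIENTATIONS)
        for t in templates.values():
            assert t.n_bins == 6
            assert t.rates.shape == (10 * 6,)
            assert np.all(t.rates >= 0)

    def test_identical_cells_produce_identical_rows(self, small_retina):
        mv, _, trains, kernels = small_retina
        dup = build_templates([kernels[0], kernels[0]], [trains[0], trains[0]],
                              mv, EnsembleDecoder(kernels, trains, mv).landolt_movies(8),
                              k=100)
        for t in dup.values():
            assert np.array_equal(t.rates[:6], t.rates[6:])

    def test_orientation_tuning_differs_across_templates(self, small_retina):
        mv, _, trains, kernels = small_retina
        dec = EnsembleDecoder(kernels, trains, mv, k_blocks=100)
        templates = dec.templates_for(10)
        mat = np.stack([templates[o].rates for o in ORIENTATIONS])
        assert np.std(mat, axis=0).max() > 0


class TestTrials:
    def test_zero_template_gives_silent_trial(self):
        t = ResponseTemplate("up", np.zeros(12), 2, 6)
        assert np.all(simulate_trial(t, 3, seed=0) == 0)

    def test_counts_scale_linearly_with_flashes(self):
        rates = np.full(60, 2.0)
        t = ResponseTemplate("up", rates, 10, 6)
        means = [np.mean([simulate_trial(t, f, seed=100 * f + i).mean()
                          for i in range(50)]) for f in (1, 4)]
        assert means[1] == pytest.approx(4 * means[0], rel=0.1)

    def test_poisson_variance_matches_mean(self):
        rates = np.full(200, 5.0)
        t = ResponseTemplate("up", rates, 200, 1)
        draws = np.stack([simulate_trial(t, 1, seed=i) for i in range(200)])
        assert np.mean(draws) == pytest.approx(5.0, rel=0.05)
        assert np.var(draws) == pytest.approx(5.0, rel=0.1)


class TestDecoding:
    def _tuned_templates(self, scale=10.0):
        rng = np.random.default_rng(7)
        return {o: ResponseTemplate(o, scale * rng.random(48), 8, 6)
                for o in ORIENTATIONS}

    def test_noiseless_self_match(self):
        templates = self._tuned_templates()
        for o in ORIENTATIONS:
            assert decode_trial(templates[o].rates, templates, seed=0) == o

    def test_identical_templates_decode_at_chance(self):
        rates = 3.0 + np.random.default_rng(0).random(24)
        templates = {o: ResponseTemplate(o, rates, 4, 6) for o in ORIENTATIONS}
        res = decode_accuracy(templates, n_trials=8000, seed=1)
        assert abs(res.accuracy - 0.25) < 3 * np.sqrt(0.25 * 0.75 / 8000)

    def test_scaling_all_templates_leaves_decisions_unchanged(self):
        templates = self._tuned_templates()
        trial = simulate_trial(templates["left"], 5, seed=3)
        scaled = {o: ResponseTemplate(o, 7.0 * t.rates, t.n_cells, t.n_bins)
                  for o, t in templates.items()}
        assert decode_trial(trial, templates, seed=4) == decode_trial(trial, scaled, seed=4)

    def test_strongly_tuned_population_saturates(self):
        templates = self._tuned_templates(scale=20.0)
        res = decode_accuracy(templates, n_trials=4000, n_flashes=1, seed=5)
        assert res.accuracy > 0.95


class TestExperiments:
    def test_uniform_orientation_sampling(self):
        rates = np.full(24, 3.0)
        templates = {o: ResponseTemplate(o, rates, 4, 6) for o in ORIENTATIONS}
        res = decode_accuracy(templates, n_trials=10_000, seed=2, keep_trials=True)
        freq = np.bincount(res.truths, minlength=4) / res.n_trials
        assert np.all(np.abs(freq - 0.25) < 3 * np.sqrt(0.25 * 0.75 / res.n_trials))

    def test_accuracy_nondecreasing_along_flash_axis(self, small_retina):
        mv, _, trains, kernels = small_retina
        dec = EnsembleDecoder(kernels, trains, mv, k_blocks=200)
        results = run_experiment(dec, "n_flashes", [1, 4, 16], n_trials=1500,
                                 seed=9, c_size=10)
        accs = [r.accuracy for r in results]
        slack = 3 * np.sqrt(0.25 / 1500)
        assert accs[1] >= accs[0] - slack
        assert accs[2] >= accs[1] - slack
        assert accs[2] > 0.25 + slack  # the population does carry signal

    def test_cell_count_axis_uses_ranked_subsets(self, small_retina):
        mv, _, trains, kernels = small_retina
        dec = EnsembleDecoder(kernels, trains, mv, k_blocks=100)
        results = run_experiment(dec, "n_cells", [2, 10], n_trials=800, seed=10,
                                 c_size=10)
        assert results[0].config["n_cells"] == 2
        assert results[1].config["n_cells"] == 10

    def test_empty_grid_rejected(self, small_retina):
        mv, _, trains, kernels = small_retina
        dec = EnsembleDecoder(kernels, trains, mv)
        with pytest.raises(ValueError):
            run_experiment(dec, "n_flashes", [], n_trials=10, seed=0)
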