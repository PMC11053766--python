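"""Trial generation, stimulus rendering, the blur-dependent observer, and blocks."""

import numpy as np
import pytest

from focalsim import (
    ORIENTATIONS,
    SLOAN_LETTERS,
    ConfigurationError,
    EyeModel,
    GazePointController,
    ObserverModel,
    TaskConfig,
    TunableLens,
    generate_trial,
    ideal_lens,
    make_office_scene,
    observe_and_respond,
    place_stimuli,
    run_block,
)
from focalsim.matching_task import ARCMIN_TO_RAD
from focalsim.scene_synthesis import screen_rect_px


class TestGenerateTrial:
    def test_deterministic_given_seed(self):
        assert generate_trial(42) == generate_trial(42)

    def test_exactly_eight_orientations_and_letters(self):
        assert len(ORIENTATIONS) == 8 and len(SLOAN_LETTERS) == 8
        rng = np.random.default_rng(0)
        seen_ori, seen_let = set(), set()
        for _ in range(500):
            t = generate_trial(rng)
            seen_ori.add(t.landolt_orientation)
            seen_let.add(t.sloan_letter)
        assert seen_ori == set(ORIENTATIONS) and seen_let == set(SLOAN_LETTERS)

    def test_table_covers_all_orientations_once_and_match_flag_is_consistent(self):
        rng = np.random.default_rng(1)
        for _ in range(300):
            t = generate_trial(rng)
            oris = [c[0] for c in t.table]
            lets = [c[1] for c in t.table]
            assert sorted(oris) == sorted(ORIENTATIONS)
            assert sorted(lets) == sorted(SLOAN_LETTERS)
            in_table = (t.landolt_orientation, t.sloan_letter) in t.table
            assert in_table == t.is_match

    def test_screen_assignment_is_a_permutation(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            t = generate_trial(rng)
            assert sorted((t.landolt_screen, t.sloan_screen, t.table_screen)) == [
                "far",
                "intermediate",
                "near",
            ]

    def test_randomization_frequencies_over_3000_trials(self):
        rng = np.random.default_rng(3)
        trials = [generate_trial(rng) for _ in range(3000)]
        for label in ("near", "intermediate", "far"):
            count = sum(t.table_screen == label for t in trials)
            bound = 3 * np.sqrt(3000 * (1 / 3) * (2 / 3))
            assert abs(count - 1000) <= bound
        match_fraction = np.mean([t.is_match for t in trials])
        assert abs(match_fraction - 0.5) <= 0.03


class TestPlaceStimuli:
    SCENE = make_office_scene(resolution=(640, 480))

    def _ink_mask(self, before, after):
        return np.any(before.rgb != after.rgb, axis=2)

    def _trial_with(self, **overrides):
        base = generate_trial(7)
        from dataclasses import replace

        return replace(base, **overrides)

    def test_rendered_gap_size_follows_pinhole_conversion(self):
        trial = self._trial_with(
            placements={"landolt": "center", "sloan": "center", "table": "center"}
        )
        out = place_stimuli(self.SCENE, trial)
        mask = self._ink_mask(self.SCENE, out)
        rect = screen_rect_px(self.SCENE.camera,
                              {s.label: s for s in self.SCENE.screens}[trial.landolt_screen])
        x0, x1, y0, y1 = rect
        sub = mask[y0 : y1 + 1, x0 : x1 + 1]
        ys, xs = np.nonzero(sub)
        ring_diameter = max(xs.max() - xs.min(), ys.max() - ys.min()) + 1
        gap_px = trial.gap_arcmin * ARCMIN_TO_RAD * self.SCENE.camera.f_px
        assert ring_diameter == pytest.approx(5 * gap_px, abs=2.0)

    def test_center_placement_centroid_within_one_pixel(self):
        trial = self._trial_with(
            placements={"landolt": "center", "sloan": "center", "table": "center"}
        )
        out = place_stimuli(self.SCENE, trial)
        screens = {s.label: s for s in self.SCENE.screens}
        for kind in ("landolt", "sloan"):
            label = getattr(trial, f"{kind}_screen")
            x0, x1, y0, y1 = screen_rect_px(self.SCENE.camera, screens[label])
            sub = self._ink_mask(self.SCENE, out)[y0 : y1 + 1, x0 : x1 + 1]
            ys, xs = np.nonzero(sub)
            bbox_cx = (xs.min() + xs.max()) / 2 + x0
            bbox_cy = (ys.min() + ys.max()) / 2 + y0
            assert abs(bbox_cx - (x0 + x1) / 2) <= 1.0
            assert abs(bbox_cy - (y0 + y1) / 2) <= 1.0

    def test_corner_placement_stays_inside_screen(self):
        rng = np.random.default_rng(5)
        screens = {s.label: s for s in self.SCENE.screens}
        for _ in range(20):
            trial = generate_trial(rng)
            out = place_stimuli(self.SCENE, trial, jitter_sd_frac=0.05, rng=rng)
            mask = self._ink_mask(self.SCENE, out)
            inside = np.zeros_like(mask)
            for s in self.SCENE.screens:
                x0, x1, y0, y1 = screen_rect_px(self.SCENE.camera, s)
                inside[y0 : y1 + 1, x0 : x1 + 1] = True
            assert not np.any(mask & ~inside)

    def test_oversized_stimulus_rejected(self):
        trial = self._trial_with(gap_arcmin=500.0)
        with pytest.raises(ConfigurationError):
            place_stimuli(self.SCENE, trial)


class TestObserver:
    def test_identification_probability_limits_and_monotonicity(self):
        obs = ObserverModel()
        assert obs.p_identify(0.0) == 1.0
        assert obs.p_identify(1e6) == pytest.approx(1 / 8, abs=1e-3)
        ratios = np.linspace(0.01, 20, 50)
        probs = [obs.p_identify(r) for r in ratios]
        assert all(b <= a + 1e-12 for a, b in zip(probs, probs[1:]))
        assert obs.p_identify(obs.threshold_ratio) == pytest.approx(1 / 8 + 7 / 16)

    def test_zero_blur_block_is_at_ceiling(self):
        obs = ObserverModel()
        rng = np.random.default_rng(0)
        records = [
            observe_and_respond(generate_trial(rng), obs, {"landolt": 0.0, "sloan": 0.0}, rng)
            for _ in range(2000)
        ]
        assert np.mean([r.correct for r in records]) == 1.0

    def test_saturating_blur_block_is_at_chance(self):
        obs = ObserverModel()
        rng = np.random.default_rng(1)
        records = [
            observe_and_respond(
                generate_trial(rng), obs, {"landolt": 1e6, "sloan": 1e6}, rng
            )
            for _ in range(2000)
        ]
        accuracy = np.mean([r.correct for r in records])
        assert abs(accuracy - 0.5) <= 0.03

    def test_block_accuracy_nonincreasing_in_blur_multiplier(self):
        obs = ObserverModel()
        accuracies = []
        for multiplier in (0.0, 5.0, 15.0, 100.0):
            rng = np.random.default_rng(9)  # paired seeds across multipliers
            records = [
                observe_and_respond(
                    generate_trial(rng),
                    obs,
                    {"landolt": multiplier, "sloan": multiplier},
                    rng,
                )
                for _ in range(1200)
            ]
            accuracies.append(np.mean([r.correct for r in records]))
        noise = 2 * np.sqrt(0.25 / 1200)
        assert all(b <= a + noise for a, b in zip(accuracies, accuracies[1:]))

    def test_response_reproducible_given_seed(self):
        obs = ObserverModel()
        trial = generate_trial(3)
        a = observe_and_respond(trial, obs, {"landolt": 5.0, "sloan": 5.0}, 17)
        b = observe_and_respond(trial, obs, {"landolt": 5.0, "sloan": 5.0}, 17)
        assert a == b

    def test_reaction_time_positive_and_grows_with_refocusses(self):
        obs = ObserverModel(rt_jitter_sigma=0.0)
        rng = np.random.default_rng(0)
        rts = {}
        for _ in range(200):
            t = generate_trial(rng)
            rec = observe_and_respond(t, obs, {"landolt": 0.0, "sloan": 0.0}, rng)
            assert rec.reaction_time_s > 0
            path = (t.landolt_screen, t.sloan_screen, t.table_screen)
            rts[path] = rec.reaction_time_s
        # a near<->far double shift costs more than a mid-far shuttle
        assert rts[("near", "far", "intermediate")] > rts[("intermediate", "far", "near")] - 1e-9

    def test_negative_blur_rejected(self):
        with pytest.raises(ValueError):
            observe_and_respond(generate_trial(0), ObserverModel(), {"landolt": -1.0, "sloan": 0.0}, 0)


class TestRunBlock:
    def test_ideal_autofocal_reaches_ceiling(self, presbyope):
        result = run_block(
            12, presbyope, controller_factory=lambda: GazePointController(), seed=5
        )
        assert result.accuracy == 1.0

    def test_uncorrected_presbyope_scores_below_ideal(self, presbyope):
        fixed = run_block(30, presbyope, lens=TunableLens(current_power_D=0.0), seed=6)
        ideal = run_block(
            30, presbyope, controller_factory=lambda: GazePointController(), seed=6
        )
        near_defocus = [r.defocus_D["near"] for r in fixed.records]
        assert np.allclose(near_defocus, 1 / 0.30, atol=1e-6)
        assert fixed.accuracy < ideal.accuracy

    def test_zero_trials_rejected(self, presbyope):
        with pytest.raises(ValueError):
            run_block(0, presbyope)

    def test_block_logs_written(self, presbyope, tmp_path):
        run_block(2, presbyope, controller_factory=lambda: GazePointController(),
                  seed=1, out_dir=tmp_path)
        names = sorted(p.name for p in tmp_path.iterdir())
        assert any(n.startswith("task_responses_") for n in names)
        assert any(n.startswith("tuning_") for n in names)
        assert any(n.startswith("gaze_") for n in names)
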