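"""Fourier blending, triangle extraction and play assembly."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from camokit import (
    RasterImage,
    ValidationError,
    assemble_play_exp1,
    build_exp1_stimuli,
    extract_triangle,
    fourier_blend,
    fourier_blend_equal4,
    max_radius,
    sample_radius,
    triangle_mask,
)
from camokit.errors import DimensionError
from camokit.stimuli import (
    StimulusSet,
    TriangleTarget,
    assemble_play_exp2,
    place_at_radius,
)
from scipy import stats

from conftest import random_image


class TestFourierBlend:
    def test_identity_weight_returns_first_image(self, rng):
        a = random_image(rng, image_id="a")
        b = random_image(rng, image_id="b")
        out = fourier_blend(a, b, 1.0)
        assert np.abs(out.image.pixels - a.pixels).max() < 1e-6
        assert out.weights == (1.0, 0.0)

    def test_idempotent_on_identical_inputs(self, rng):
        a = random_image(rng, image_id="a")
        a2 = RasterImage(a.pixels.copy(), image_id="a2")
        for w in (0.0, 0.25, 0.5, 0.9):
            out = fourier_blend(a, a2, w)
            assert np.abs(out.image.pixels - a.pixels).max() < 1e-6

    @settings(max_examples=15, derandomize=True, deadline=None)
    @given(
        w=st.floats(0.0, 1.0),
        seed=st.integers(0, 2**16),
    )
    def test_weight_symmetry(self, w, seed):
        r = np.random.default_rng(seed)
        a = random_image(r, 16, 16, "a")
        b = random_image(r, 16, 16, "b")
        ab = fourier_blend(a, b, w)
        ba = fourier_blend(b, a, 1.0 - w)
        assert np.abs(ab.image.pixels - ba.image.pixels).max() < 1e-9

    def test_single_coefficient_closed_form(self):
        """In-phase gratings of amplitude 1:3 blend at w=0.5 to amplitude 2."""
        x = np.arange(64)
        carrier = np.sin(2 * np.pi * x / 16)
        mk = lambda amp, iid: RasterImage(
            np.repeat(np.tile(0.5 + amp * carrier, (64, 1))[:, :, None], 3, axis=2),
            image_id=iid,
        )
        out = fourier_blend(mk(0.1, "a1"), mk(0.3, "a3"), 0.5)
        expected = 0.5 + 0.2 * carrier
        assert np.abs(out.image.pixels[0, :, 0] - expected).max() < 1e-6

    def test_amplitude_spectrum_is_convex_combination(self, rng):
        w = 0.3
        a = random_image(rng, 32, 32, "a", lo=0.3, hi=0.7)
        b = random_image(rng, 32, 32, "b", lo=0.3, hi=0.7)
        out = fourier_blend(a, b, w)
        assert out.clip_fraction == 0.0
        for c in range(3):
            amp = np.abs(np.fft.fft2(out.image.pixels[..., c]))
            want = w * np.abs(np.fft.fft2(a.pixels[..., c])) + (1 - w) * np.abs(
                np.fft.fft2(b.pixels[..., c])
            )
            assert np.allclose(amp, want, rtol=1e-9, atol=1e-9)

    def test_dimension_mismatch_raises(self, rng):
        with pytest.raises(ValidationError):
            fourier_blend(
                random_image(rng, 16, 16, "a"), random_image(rng, 16, 32, "b"), 0.5
            )

    def test_invalid_weight_raises(self, rng):
        a, b = random_image(rng, 8, 8, "a"), random_image(rng, 8, 8, "b")
        with pytest.raises(ValidationError):
            fourier_blend(a, b, 1.2)


class TestEqual4:
    def _four(self, rng):
        base = rng.random((32, 32, 3)) * 0.5 + 0.25
        return [RasterImage(base.copy(), image_id=f"s{i}") for i in range(4)]

    def test_identical_sources_pass_through_chain(self, rng):
        a, b, c, d = self._four(rng)
        g4 = fourier_blend_equal4(
            fourier_blend(a, b, 0.5), fourier_blend(c, d, 0.5)
        )
        assert np.abs(g4.image.pixels - a.pixels).max() < 1e-6

    def test_weights_bookkeeping(self, rng):
        a = random_image(rng, 16, 16, "a")
        b = random_image(rng, 16, 16, "b")
        c = random_image(rng, 16, 16, "c")
        d = random_image(rng, 16, 16, "d")
        g4 = fourier_blend_equal4(fourier_blend(a, b, 0.5), fourier_blend(c, d, 0.5))
        assert g4.weights == (0.25, 0.25, 0.25, 0.25)
        assert set(g4.source_ids) == {"a", "b", "c", "d"}

    def test_mean_luminance_tracks_source_means(self, rng):
        imgs = [random_image(rng, 32, 32, f"i{k}", lo=0.3, hi=0.7) for k in range(4)]
        g4 = fourier_blend_equal4(
            fourier_blend(imgs[0], imgs[1], 0.5),
            fourier_blend(imgs[2], imgs[3], 0.5),
        )
        assert g4.clip_fraction == 0.0
        want = np.mean([i.pixels.mean() for i in imgs])
        assert abs(g4.image.pixels.mean() - want) / want < 0.02

    def test_overlapping_sources_raise(self, rng):
        a = random_image(rng, 16, 16, "a")
        b = random_image(rng, 16, 16, "b")
        c = random_image(rng, 16, 16, "c")
        with pytest.raises(ValidationError):
            fourier_blend_equal4(
                fourier_blend(a, b, 0.5), fourier_blend(b, c, 0.5)
            )


class TestTriangle:
    def test_mask_geometry(self):
        m = triangle_mask()
        assert m.shape == (75, 150)
        assert m[0].sum() == 150  # base spans the top edge
        assert m[74].sum() == 2  # apex at bottom-center
        cols = np.flatnonzero(m[74])
        assert set(cols) == {74, 75}
        # left/right symmetric
        assert np.array_equal(m, m[:, ::-1])

    def test_patch_dimensions_and_sentinel(self, mini_bank, rng):
        src = fourier_blend(mini_bank[0], mini_bank[4], 0.5)
        t = extract_triangle(src, rng)
        assert t.patch.shape == (75, 150, 3)
        assert (t.patch[~t.mask] == 0.0).all()

    def test_anchor_forced_on_minimal_source(self, rng):
        img = RasterImage(rng.random((75, 150, 3)), image_id="min")
        src = fourier_blend(img, RasterImage(rng.random((75, 150, 3)), "m2"), 0.5)
        t = extract_triangle(src, rng)
        assert t.anchor == (0, 0)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_masked_pixels_match_source_at_anchor(self, mini_bank, seed):
        """Coordinate oracle: direct indexing of the source at the anchor."""
        r = np.random.default_rng(seed)
        src = fourier_blend(mini_bank[1], mini_bank[5], 0.5)
        t = extract_triangle(src, r)
        row, col = t.anchor
        window = src.image.pixels[row : row + 75, col : col + 150]
        assert np.array_equal(t.patch[t.mask], window[t.mask])
        assert 0 <= row <= src.image.height - 75
        assert 0 <= col <= src.image.width - 150

    def test_too_small_source_raises(self, rng):
        img = RasterImage(rng.random((74, 150, 3)), image_id="small")
        with pytest.raises(DimensionError):
            extract_triangle(fourier_blend(img, img, 0.5), rng)


class TestExp1Builder:
    def test_counts_and_conditions(self, mini_bank, rng):
        s = build_exp1_stimuli(mini_bank, 4, rng)
        assert len(s.blends) == 12 and len(s.targets) == 12
        by_cond = s.targets_by_condition()
        assert {k: len(v) for k, v in by_cond.items()} == {
            "25": 4,
            "50": 4,
            "75": 4,
        }
        cats = {img.image_id: img.category for img in mini_bank}
        for b in s.blends:
            a, bb = b.source_ids
            assert cats[a] != cats[bb]
        # weights per condition: proportion of background A
        for t in s.targets:
            blend = next(b for b in s.blends if b.blend_id == t.source_blend)
            assert blend.weights[0] == pytest.approx(int(t.condition) / 100)

    def test_deterministic_given_seed(self, mini_bank):
        s1 = build_exp1_stimuli(mini_bank, 3, np.random.default_rng(5))
        s2 = build_exp1_stimuli(mini_bank, 3, np.random.default_rng(5))
        assert [t.anchor for t in s1.targets] == [t.anchor for t in s2.targets]
        assert [b.blend_id for b in s1.blends] == [b.blend_id for b in s2.blends]
        assert all(
            np.array_equal(x.patch, y.patch)
            for x, y in zip(s1.targets, s2.targets)
        )

    def test_no_duplicate_pairs(self, mini_bank, rng):
        s = build_exp1_stimuli(mini_bank, 10, rng)
        keys = {frozenset((a, b)) for _, a, b in s.pairs}
        assert len(keys) == 10

    def test_too_many_pairs_raises(self, mini_bank, rng):
        with pytest.raises(ValidationError):
            build_exp1_stimuli(mini_bank, 10_000, rng)

    def test_single_category_raises(self, mini_bank, rng):
        one_cat = [i for i in mini_bank if i.category == "dark"]
        with pytest.raises(ValidationError):
            build_exp1_stimuli(one_cat, 2, rng)


class TestRadiusSampling:
    def test_cdf_is_quadratic(self, rng):
        screen = (1280, 800)
        r_max = max_radius(screen)
        draws = np.array([sample_radius(screen, rng) for _ in range(10_000)])
        assert draws.max() <= r_max
        ks = stats.kstest(draws, lambda r: (r / r_max) ** 2)
        assert ks.pvalue > 0.01

    def test_mean_is_two_thirds_of_max(self, rng):
        screen = (1280, 800)
        r_max = max_radius(screen)
        draws = np.array([sample_radius(screen, rng) for _ in range(10_000)])
        se = draws.std() / math.sqrt(len(draws))
        assert abs(draws.mean() - 2 / 3 * r_max) < 3 * se

    def test_placement_keeps_target_on_screen(self, rng):
        screen = (1280, 800)
        r_max = max_radius(screen)
        for _ in range(500):
            r = sample_radius(screen, rng)
            x, y = place_at_radius(screen, r, rng)
            assert 75.0 - 1e-9 <= x <= 1280 - 75.0 + 1e-9
            assert 37.5 - 1e-9 <= y <= 800 - 37.5 + 1e-9
            assert math.hypot(x - 640, y - 400) == pytest.approx(r, abs=1e-9)
        assert r_max == pytest.approx(math.hypot(565.0, 362.5))

    def test_degenerate_screen_raises(self, rng):
        with pytest.raises(ValidationError):
            sample_radius((150, 400), rng)


class TestAssembly:
    def test_exp1_play_structure(self, mini_bank, rng):
        s = build_exp1_stimuli(mini_bank, 6, rng)
        play = assemble_play_exp1(s, (1280, 800), rng, play_id="pp")
        assert len(play.trials) == 12
        conds = sorted(t.condition for t in play.trials)
        assert conds == ["25"] * 4 + ["50"] * 4 + ["75"] * 4
        by_target = {}
        for t in play.trials:
            by_target.setdefault(t.target_id, []).append(t)
            t.validate_radius((1280, 800))
        assert len(by_target) == 6
        for trials in by_target.values():
            assert len(trials) == 2
            assert abs(trials[0].radius - trials[1].radius) < 0.5
            # shown on both source backgrounds
            assert trials[0].background_id != trials[1].background_id

    def test_exp1_trial_indices_are_a_permutation(self, mini_bank, rng):
        s = build_exp1_stimuli(mini_bank, 6, rng)
        play = assemble_play_exp1(s, (1280, 800), rng)
        assert sorted(t.trial_index for t in play.trials) == list(range(1, 13))

    def test_exp2_play_structure(self, rng):
        s = _fake_exp2_stimuli()
        play = assemble_play_exp2(s, (1280, 800), rng, play_id="q")
        assert len(play.trials) == 36
        conds = sorted(t.condition for t in play.trials)
        assert conds == ["G2"] * 12 + ["G4"] * 12 + ["S"] * 12
        cats = {f"cat{i}": set() for i in range(4)}
        by_target = {}
        for t in play.trials:
            by_target.setdefault(t.target_id, []).append(t.background_id)
        assert len(by_target) == 9
        cat_of = {
            iid: c for c, ids in s.bank_categories.items() for iid in ids
        }
        for bgs in by_target.values():
            assert sorted(cat_of[b] for b in bgs) == sorted(s.bank_categories)


def _fake_exp2_stimuli():
    """Minimal stimulus-set stand-in with 4 targets per type (synthetic)."""
    mask = triangle_mask().copy()
    patch = np.zeros((75, 150, 3))
    targets = []
    for cond in ("S", "G2", "G4"):
        for i in range(4):
            targets.append(
                TriangleTarget(
                    patch=patch,
                    mask=mask,
                    source_blend=f"b_{cond}_{i}",
                    anchor=(0, i),
                    target_id=f"t_{cond}_{i}",
                    condition=cond,
                )
            )
    bank_categories = {
        f"cat{i}": tuple(f"img{i}_{j}" for j in range(5)) for i in range(4)
    }
    return StimulusSet(
        experiment=2,
        blends=[],
        targets=targets,
        target_backgrounds={t.target_id: () for t in targets},
        bank_categories=bank_categories,
    )
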