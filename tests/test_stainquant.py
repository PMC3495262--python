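"""Threshold calibration and stain area-fraction quantification."""

from dataclasses import replace

import numpy as np
import pytest

from arterymorph.errors import CalibrationLookupError, DegenerateInputError
from arterymorph.stainquant import (
    NOTHING_POSITIVE,
    area_fraction,
    batch_quantify,
    calibrate_threshold,
    collagen_fraction_psr,
    elastin_fraction_vvg,
)
from arterymorph.synthgen import (
    PhantomSpec,
    make_artery_phantom,
    make_negative_control,
    make_psr_pair,
)


def flat(values) -> tuple[np.ndarray, np.ndarray]:
    arr = np.asarray(values, dtype=np.uint8).reshape(1, -1)
    return arr, np.ones_like(arr, dtype=bool)


class TestCalibrateThreshold:
    def test_separated_spike_puts_threshold_at_spike(self, rng):
        control, cmask = flat(rng.integers(0, 51, size=4000))
        sample_vals = np.concatenate(
            [rng.integers(0, 51, size=4000), np.full(400, 200)]
        )
        sample, smask = flat(sample_vals)
        cal = calibrate_threshold(sample, smask, control, cmask)
        assert cal.threshold == 200

    def test_identical_sample_and_control_yield_sentinel(self, rng):
        vals = rng.integers(0, 51, size=4000)
        sample, smask = flat(vals)
        control, cmask = flat(vals)
        with pytest.warns(UserWarning, match="indistinguishable"):
            cal = calibrate_threshold(sample, smask, control, cmask)
        assert cal.threshold == NOTHING_POSITIVE
        assert cal.nothing_positive

    def test_translation_soundness(self, rng):
        control_vals = rng.integers(10, 61, size=4000)
        sample_vals = np.concatenate(
            [rng.integers(10, 61, size=4000), rng.integers(150, 181, size=500)]
        )
        base = calibrate_threshold(*flat(sample_vals), *flat(control_vals))
        shifted = calibrate_threshold(
            *flat(sample_vals + 30), *flat(control_vals + 30)
        )
        assert shifted.threshold == base.threshold + 30

    def test_stray_bright_pixels_do_not_set_threshold(self, rng):
        control_vals = rng.integers(0, 51, size=4000)
        sample_vals = np.concatenate(
            [rng.integers(0, 51, size=4000), np.full(400, 150), [254]]
        )
        cal = calibrate_threshold(*flat(sample_vals), *flat(control_vals))
        assert cal.threshold == 150

    def test_empty_mask_rejected(self, rng):
        sample, smask = flat(rng.integers(0, 51, size=100))
        with pytest.raises(DegenerateInputError):
            calibrate_threshold(sample, np.zeros_like(smask), sample, smask)

    def test_histograms_sum_to_mask_pixel_counts(self, phantom, default_spec):
        images, masks, _ = phantom
        control = make_negative_control(default_spec)
        cal = calibrate_threshold(
            images.channels["sma"], masks.wall,
            control.channels["sma"], masks.wall,
        )
        assert cal.sample_histogram.sum() == masks.wall.sum()
        assert cal.control_histogram.sum() == masks.wall.sum()


class TestAreaFraction:
    def test_zero_threshold_gives_fraction_one(self, phantom):
        images, masks, _ = phantom
        rec = area_fraction(images.channels["sma"], masks.wall, 0)
        assert rec.fraction == 1.0

    def test_sentinel_threshold_gives_fraction_zero(self, phantom):
        images, masks, _ = phantom
        rec = area_fraction(images.channels["sma"], masks.wall, NOTHING_POSITIVE)
        assert rec.fraction == 0.0

    def test_monotone_non_increasing_in_threshold(self, phantom):
        images, masks, _ = phantom
        fractions = [
            area_fraction(images.channels["sma"], masks.wall, t).fraction
            for t in range(0, 257, 16)
        ]
        assert all(a >= b for a, b in zip(fractions, fractions[1:]))

    def test_fraction_ratio_consistent_with_counts(self, phantom):
        images, masks, _ = phantom
        rec = area_fraction(images.channels["sma"], masks.wall, 120)
        assert rec.fraction == rec.positive_pixels / rec.wall_pixels
        assert 0.0 <= rec.fraction <= 1.0

    def test_empty_wall_rejected(self, phantom):
        images, masks, _ = phantom
        with pytest.raises(DegenerateInputError):
            area_fraction(images.channels["sma"], np.zeros_like(masks.wall), 100)


class TestCalibratedRecovery:
    def test_calibrated_fraction_recovers_painted_fraction(self):
        """Signal mean 180 on background 40 (SD 8): control-calibrated
        thresholds must recover the painted fraction within 0.02."""
        errors = []
        for seed in range(5):
            spec = PhantomSpec(seed=seed)
            images, masks, truth = make_artery_phantom(spec)
            control = make_negative_control(spec)
            cal = calibrate_threshold(
                images.channels["sma"], masks.wall,
                control.channels["sma"], masks.wall,
            )
            rec = area_fraction(images.channels["sma"], masks.wall, cal.threshold)
            errors.append(abs(rec.fraction - truth.fractions["sma"]))
        assert np.mean(errors) <= 0.02

    def test_control_fraction_at_own_threshold_near_zero(self, default_spec):
        images, masks, _ = make_artery_phantom(default_spec)
        control = make_negative_control(default_spec)
        cal = calibrate_threshold(
            images.channels["sma"], masks.wall,
            control.channels["sma"], masks.wall,
        )
        rec = area_fraction(control.channels["sma"], masks.wall, cal.threshold)
        assert rec.fraction <= 0.01


class TestElastinVvg:
    def test_blob_removal_monotone_in_blob_size(self, phantom):
        images, masks, _ = phantom
        f0 = elastin_fraction_vvg(images.channels["vvg"], masks.wall, 100, 0)
        f30 = elastin_fraction_vvg(images.channels["vvg"], masks.wall, 100, 30)
        assert f0.fraction >= f30.fraction

    def test_recovery_with_nuclei_removed(self):
        errors = []
        for seed in range(5):
            spec = PhantomSpec(seed=seed)  # elastin preset 0.479
            images, masks, truth = make_artery_phantom(spec)
            rec = elastin_fraction_vvg(
                images.channels["vvg"], masks.wall, 100, min_blob_size=16
            )
            errors.append(abs(rec.fraction - truth.fractions["elastin"]))
        assert np.mean(errors) <= 0.02

    def test_image_of_only_nuclei_blobs_gives_zero(self):
        img = np.full((60, 60), 200, dtype=np.uint8)
        wall = np.ones_like(img, dtype=bool)
        for y, x in [(10, 10), (30, 40), (50, 20)]:
            img[y - 2 : y + 3, x - 2 : x + 3] = 40
        rec = elastin_fraction_vvg(img, wall, 100, min_blob_size=40)
        assert rec.fraction == 0.0


class TestCollagenPsr:
    def test_all_black_polarized_gives_zero(self):
        spec = PhantomSpec(noise_sd=0.0)
        brightfield, polarized, masks, _ = make_psr_pair(spec)
        rec = collagen_fraction_psr(
            brightfield, np.zeros_like(polarized), masks.wall
        )
        assert rec.fraction == 0.0

    def test_recovery_of_painted_collagen(self):
        errors = []
        for seed in range(5):
            spec = PhantomSpec(seed=seed)  # collagen preset 0.128
            brightfield, polarized, masks, truth = make_psr_pair(spec)
            rec = collagen_fraction_psr(brightfield, polarized, masks.wall)
            errors.append(abs(rec.fraction - truth.fractions["collagen"]))
        assert np.mean(errors) <= 0.02

    def test_positive_set_is_subset_of_roi(self):
        spec = PhantomSpec(seed=2, noise_sd=0.0)
        brightfield, polarized, masks, _ = make_psr_pair(spec)
        bf = brightfield.astype(int)
        roi = (bf[..., 0] >= bf[..., 1] + 20) & (bf[..., 0] >= bf[..., 2] + 20)
        positive = roi & masks.wall & (polarized > 30)
        assert not (positive & ~roi).any()

    def test_unregistered_images_rejected(self):
        spec = PhantomSpec()
        brightfield, polarized, masks, _ = make_psr_pair(spec)
        with pytest.raises(ValueError, match="registered"):
            collagen_fraction_psr(brightfield, polarized[:-2], masks.wall)


class TestBatchQuantify:
    def _samples(self, n=3):
        out = []
        cals = {}
        for i in range(n):
            spec = PhantomSpec(seed=100 + i)
            images, masks, _ = make_artery_phantom(spec)
            control = make_negative_control(spec)
            out.append((f"img{i}", images, masks.wall))
            for stain in ("sma", "cd34"):
                cals[(images.batch_key[0], stain)] = calibrate_threshold(
                    images.channels[stain], masks.wall,
                    control.channels[stain], masks.wall,
                )
        return out, cals

    def test_three_images_two_stains_give_six_rows(self):
        samples, cals = self._samples()
        table = batch_quantify(samples, cals, stains=("sma", "cd34"))
        assert len(table) == 6

    def test_input_order_does_not_change_output(self):
        samples, cals = self._samples()
        a = batch_quantify(samples, cals, stains=("sma", "cd34"))
        b = batch_quantify(samples[::-1], cals, stains=("sma", "cd34"))
        assert a.equals(b)

    def test_missing_calibration_raises(self):
        samples, cals = self._samples()
        with pytest.raises(CalibrationLookupError):
            batch_quantify(samples, cals, stains=("sma", "mac387"))
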