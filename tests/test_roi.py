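"""Circular-ROI placement and the slice/ROI measurement operations."""

import numpy as np
import pytest

from adcresponse.errors import DomainError
from adcresponse.roi import (
    CircularROISpec,
    average_readers,
    measure_adc_roi,
    measure_adc_slice,
    n_rois_for_size,
    place_circular_rois,
)
from adcresponse.synthgen import ADCVolume, render_lesion_volume

from conftest import make_ground_truth
from oracles import disc_search_exhaustive


def flat_lesion(value=1000.0, shape=(21, 21, 5), radius=9):
    """Cylindrical lesion of constant value on a constant background."""
    vox = np.full(shape, 2000.0)
    mask = np.zeros(shape, dtype=bool)
    cx, cy = shape[0] // 2, shape[1] // 2
    xx, yy = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    disc = (xx - cx) ** 2 + (yy - cy) ** 2 <= radius**2
    for z in range(1, shape[2] - 1):
        mask[:, :, z] = disc
        vox[:, :, z][disc] = value
    return ADCVolume(vox, (1.5, 1.5, 5.0)), mask


class TestROICount:
    @pytest.mark.parametrize(
        "diameter_cm,expected",
        [(1.5, 1), (1.99, 1), (2.0, 2), (3.0, 2), (4.0, 2), (4.01, 3), (5.0, 3)],
    )
    def test_size_rule(self, diameter_cm, expected):
        assert n_rois_for_size(diameter_cm) == expected

    @pytest.mark.parametrize("bad", [0.0, -1.0, float("nan")])
    def test_invalid_diameter(self, bad):
        with pytest.raises(DomainError):
            n_rois_for_size(bad)


class TestPlacement:
    def test_uniform_field_tie_breaks_lexicographically(self):
        vol, mask = flat_lesion()
        specs = place_circular_rois(vol, mask, diameter_cm=1.5, radius_mm=5.0)
        assert len(specs) == 1
        oracle = disc_search_exhaustive(vol, mask, specs[0].slice_index, 5.0)
        assert oracle is not None
        assert specs[0].center == oracle[1]

    def test_low_adc_pocket_is_found(self):
        vol, mask = flat_lesion()
        vox = vol.voxels.copy()
        # implant a cold pocket off-center inside the lesion
        vox[6:10, 6:10, 2] = 500.0
        vol2 = ADCVolume(vox, vol.spacing_mm)
        specs = place_circular_rois(vol2, mask, diameter_cm=1.5, radius_mm=3.0)
        (spec,) = specs
        mean_oracle, center_oracle = disc_search_exhaustive(
            vol2, mask, spec.slice_index, 3.0
        )
        assert spec.center == center_oracle
        assert measure_adc_roi(vol2, specs) == pytest.approx(mean_oracle, rel=1e-12)

    def test_matches_exhaustive_search_on_rendered_lesion(self):
        gt = make_ground_truth(diameter_mm=30.0)
        vol, mask = render_lesion_volume(gt, "pre", noise_sd=60.0, seed=21)
        specs = place_circular_rois(vol, mask, diameter_cm=1.9, radius_mm=5.0)
        (spec,) = specs
        mean_oracle, center_oracle = disc_search_exhaustive(
            vol, mask, spec.slice_index, 5.0
        )
        got = float(np.mean(vol.voxels[:, :, spec.slice_index][_disc_bool(vol, spec)]))
        assert got == pytest.approx(mean_oracle, rel=1e-12)
        assert spec.center == center_oracle

    def test_large_lesion_gets_three_consecutive_slices(self):
        gt = make_ground_truth(diameter_mm=50.0)
        vol, mask = render_lesion_volume(gt, "pre", noise_sd=50.0, seed=8)
        specs = place_circular_rois(vol, mask, diameter_cm=5.0)
        assert len(specs) == 3
        idx = [s.slice_index for s in specs]
        assert idx == list(range(idx[0], idx[0] + 3))


def _disc_bool(vol, spec):
    from adcresponse.roi import _disc_footprint

    foot = _disc_footprint(spec.radius_mm, vol.spacing_mm[:2])
    rx, ry = (foot.shape[0] - 1) // 2, (foot.shape[1] - 1) // 2
    out = np.zeros(vol.voxels.shape[:2], dtype=bool)
    r, c = spec.center
    out[r - rx : r + rx + 1, c - ry : c + ry + 1] = foot
    return out


class TestMeasurement:
    def test_single_disc_over_constant_field(self):
        vol, mask = flat_lesion(value=1234.0)
        specs = place_circular_rois(vol, mask, 1.5, radius_mm=5.0)
        assert measure_adc_roi(vol, specs) == pytest.approx(1234.0)

    def test_mean_across_discs_is_unweighted(self):
        vol, mask = flat_lesion()
        vox = vol.voxels.copy()
        vox[:, :, 1][mask[:, :, 1]] = 1000.0
        vox[:, :, 2][mask[:, :, 2]] = 1400.0
        vol2 = ADCVolume(vox, vol.spacing_mm)
        specs = [
            CircularROISpec(1, (10, 10), 5.0),
            CircularROISpec(2, (10, 10), 5.0),
        ]
        assert measure_adc_roi(vol2, specs) == pytest.approx(1200.0)

    def test_three_discs_match_voxel_enumeration(self, rng):
        gt = make_ground_truth(diameter_mm=50.0)
        vol, mask = render_lesion_volume(gt, "pre", noise_sd=80.0, seed=13)
        specs = place_circular_rois(vol, mask, 5.0)
        expected = np.mean(
            [
                vol.voxels[:, :, s.slice_index][_disc_bool(vol, s)].mean()
                for s in specs
            ]
        )
        assert measure_adc_roi(vol, specs) == pytest.approx(float(expected), rel=1e-12)

    def test_slice_trace_uses_largest_area_slice(self):
        vol, mask = flat_lesion()
        m = mask.copy()
        m[:, :, 1] = False
        m[5:8, 5:8, 1] = True  # small patch: slice 2 keeps the largest area
        value, idx = measure_adc_slice(vol, m)
        expected = vol.voxels[:, :, 2][m[:, :, 2]].mean()
        assert idx == 2
        assert value == pytest.approx(float(expected))

    def test_slice_trace_ignores_out_of_mask_voxels(self):
        vol, mask = flat_lesion()
        v1, s1 = measure_adc_slice(vol, mask)
        vox = vol.voxels.copy()
        vox[~mask] = 99999.0
        v2, s2 = measure_adc_slice(ADCVolume(vox, vol.spacing_mm), mask)
        assert (v1, s1) == (v2, s2)

    def test_homogeneous_lesion_all_measurements_agree(self):
        vol, mask = flat_lesion(value=1111.0)
        specs = place_circular_rois(vol, mask, 1.5)
        roi = measure_adc_roi(vol, specs)
        sl, _ = measure_adc_slice(vol, mask)
        whole = vol.voxels[mask].mean()
        assert roi == pytest.approx(whole)
        assert sl == pytest.approx(whole)

    def test_constant_shift_moves_every_measurement_by_c(self):
        gt = make_ground_truth(diameter_mm=35.0)
        vol, mask = render_lesion_volume(gt, "pre", noise_sd=40.0, seed=3)
        c = 250.0
        shifted = ADCVolume(vol.voxels + c, vol.spacing_mm)
        specs = place_circular_rois(vol, mask, 3.5)
        specs_shift = place_circular_rois(shifted, mask, 3.5)
        assert [s.center for s in specs] == [s.center for s in specs_shift]
        assert measure_adc_roi(shifted, specs_shift) == pytest.approx(
            measure_adc_roi(vol, specs) + c, rel=1e-12
        )
        v0, _ = measure_adc_slice(vol, mask)
        v1, _ = measure_adc_slice(shifted, mask)
        assert v1 == pytest.approx(v0 + c, rel=1e-12)

    def test_reader_average(self):
        assert average_readers(1.0, 1.0) == 1.0
        assert average_readers(1.2, 1.4) == pytest.approx(1.3)
        assert average_readers(2.0, 5.0) == average_readers(5.0, 2.0)
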