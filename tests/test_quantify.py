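"""Gaussian spot fitting, signal integration, per-cell statistics, masks."""

import numpy as np
import pytest

from punctakit import (
    FittedSpot,
    ImageStack,
    LabelMask,
    count_per_cell,
    derive_background_mask,
    fit_spot,
    integrate_signal,
    new_call_table,
    on_cell_stats,
)
from punctakit.quantify import CellExpression, FWHM_FACTOR


def render_spot(shape, amplitude, center, sigma_xy, sigma_z, background=0.0):
    """Noiseless anisotropic Gaussian spot oracle image."""
    depth, h, w = shape
    zz, yy, xx = np.mgrid[0:depth, 0:h, 0:w].astype(float)
    x0, y0, z0 = center
    bump = amplitude * np.exp(
        -((xx - x0) ** 2 + (yy - y0) ** 2) / (2 * sigma_xy**2)
        - ((zz - z0) ** 2) / (2 * sigma_z**2)
    )
    return ImageStack(background + bump)


class TestFitSpot:
    def test_noiseless_parameter_recovery(self):
        stack = render_spot((9, 31, 31), 500.0, (15, 15, 4), 1.5, 1.2)
        spot = fit_spot(stack, (15, 15, 4))
        assert not spot.fallback
        assert abs(spot.amplitude - 500.0) / 500.0 < 0.05
        assert abs(spot.x0 - 15.0) < 0.1 and abs(spot.y0 - 15.0) < 0.1
        assert abs(spot.width_xy - 1.5) < 0.2
        assert abs(spot.z0 - 4.0) < 0.3

    def test_subpixel_center_recovered(self):
        stack = render_spot((9, 31, 31), 500.0, (15.4, 15.0, 4.0), 1.5, 1.2)
        spot = fit_spot(stack, (15, 15, 4))
        assert abs(spot.x0 - 15.4) < 0.15
        assert abs(spot.y0 - 15.0) < 0.15

    def test_flat_crop_falls_back_flagged(self):
        stack = ImageStack(np.full((5, 20, 20), 100.0))
        spot = fit_spot(stack, (10, 10, 2))
        assert spot.fallback
        assert spot.width_xy == pytest.approx(1.3)

    def test_maximum_outside_stack_rejected(self):
        stack = ImageStack(np.zeros((3, 10, 10)))
        with pytest.raises(ValueError):
            fit_spot(stack, (50, 2, 1))

    def test_recovery_degrades_monotonically_with_noise(self, rng):
        errors = []
        for noise_sd in (0.0, 20.0, 80.0):
            errs = []
            for i in range(10):
                stack = render_spot((9, 31, 31), 500.0, (15, 15, 4), 1.5, 1.2)
                noisy = np.clip(
                    stack.voxels + rng.normal(0, noise_sd, stack.voxels.shape),
                    0, None,
                )
                spot = fit_spot(ImageStack(noisy), (15, 15, 4))
                errs.append(abs(spot.amplitude - 500.0))
            errors.append(np.median(errs))
        assert errors[0] <= errors[1] <= errors[2]


class TestIntegrateSignal:
    def _oracle_sum(self, stack, center, rx, rz):
        depth, h, w = stack.voxels.shape
        zz, yy, xx = np.mgrid[0:depth, 0:h, 0:w].astype(float)
        x0, y0, z0 = center
        inside = (
            ((xx - x0) / rx) ** 2 + ((yy - y0) / rx) ** 2 + ((zz - z0) / rz) ** 2
        ) <= 1.0
        return stack.voxels[inside].sum()

    def test_zero_background_matches_direct_sum(self):
        stack = render_spot((9, 31, 31), 500.0, (15, 15, 4), 1.5, 1.2)
        spot = fit_spot(stack, (15, 15, 4))
        total = integrate_signal(stack, spot)
        oracle = self._oracle_sum(
            stack, (15, 15, 4), FWHM_FACTOR * 1.5, max(spot.z_extent / 2, 1)
        )
        assert abs(total - oracle) / oracle < 0.15

    def test_background_above_crop_gives_zero(self):
        stack = ImageStack(np.full((5, 20, 20), 50.0))
        spot = FittedSpot(x0=10, y0=10, z0=2, amplitude=10.0, width_xy=1.5,
                          z_extent=2.0, background=1000.0, source=(10, 10, 2))
        assert integrate_signal(stack, spot) == 0.0

    def test_linearity_in_amplitude(self):
        s1 = render_spot((9, 31, 31), 300.0, (15, 15, 4), 1.5, 1.2)
        s2 = render_spot((9, 31, 31), 600.0, (15, 15, 4), 1.5, 1.2)
        f1 = fit_spot(s1, (15, 15, 4))
        f2 = fit_spot(s2, (15, 15, 4))
        t1 = integrate_signal(s1, f1)
        t2 = integrate_signal(s2, f2)
        assert abs(t2 - 2 * t1) / (2 * t1) < 0.1


class TestCountPerCell:
    def _mask(self):
        lab = np.zeros((20, 20), dtype=np.int32)
        lab[2:8, 2:8] = 1
        lab[12:18, 12:18] = 2
        return LabelMask(lab)

    def test_counts_and_on_flags(self):
        calls = new_call_table(x=[3, 4, 5, 13], y=[3, 4, 5, 13],
                               z=[0, 0, 1, 0], intensity=[10] * 4)
        cells, background = count_per_cell(calls, self._mask(), cutoff=2)
        by_id = {c.cell_id: c for c in cells}
        assert by_id[1].spot_count == 3 and by_id[1].is_on
        assert by_id[2].spot_count == 1 and not by_id[2].is_on
        assert background == 0

    def test_label_zero_calls_excluded(self):
        calls = new_call_table(x=[0], y=[0], z=[0], intensity=[5])
        cells, background = count_per_cell(calls, self._mask())
        assert background == 1
        assert all(c.spot_count == 0 for c in cells)

    def test_empty_call_table_all_cells_off(self):
        cells, background = count_per_cell(new_call_table(), self._mask())
        assert len(cells) == 2
        assert all(c.spot_count == 0 and not c.is_on for c in cells)

    def test_conservation_of_calls(self, rng):
        n = 60
        calls = new_call_table(
            x=rng.integers(0, 20, n), y=rng.integers(0, 20, n),
            z=np.zeros(n, dtype=int), intensity=np.ones(n),
        )
        cells, background = count_per_cell(calls, self._mask())
        assert sum(c.spot_count for c in cells) + background == n

    def test_nuclear_counts(self):
        nuc = np.zeros((20, 20), dtype=np.int32)
        nuc[3:5, 3:5] = 1
        calls = new_call_table(x=[3, 6], y=[3, 6], z=[0, 0], intensity=[1, 1])
        cells, _ = count_per_cell(calls, self._mask(), nuclei=LabelMask(nuc))
        by_id = {c.cell_id: c for c in cells}
        assert by_id[1].spot_count == 2
        assert by_id[1].nuclear_count == 1


class TestOnCellStats:
    def _cells(self, counts, cutoff):
        return [
            CellExpression(cell_id=i + 1, spot_count=n, is_on=n >= cutoff,
                           cutoff=cutoff)
            for i, n in enumerate(counts)
        ]

    def test_proportion_and_mean_among_on(self):
        prop, mean_on = on_cell_stats(self._cells([7, 9, 2], cutoff=8))
        assert prop == pytest.approx(1 / 3)
        assert mean_on == pytest.approx(9.0)

    def test_no_on_cells_mean_absent(self):
        prop, mean_on = on_cell_stats(self._cells([1, 0, 3], cutoff=8))
        assert prop == 0.0
        assert mean_on is None

    def test_cutoff_boundary_inclusive(self):
        prop, _ = on_cell_stats(self._cells([8, 8], cutoff=8))
        assert prop == 1.0

    def test_empty_cell_list_rejected(self):
        with pytest.raises(ValueError):
            on_cell_stats([])


class TestBackgroundMask:
    def _trans_stack(self, rng, h=64, w=64, depth=10):
        """Cells fluctuate strongly over z; background barely at all."""
        v = np.full((depth, h, w), 500.0)
        v += rng.normal(0, 2.0, v.shape)  # quiet background
        cells = np.zeros((h, w), dtype=np.int32)
        cells[8:30, 8:30] = 1
        cells[36:58, 36:58] = 2
        in_cell = cells > 0
        v[:, in_cell] += rng.normal(0, 80.0, (depth, int(in_cell.sum())))
        return ImageStack(np.clip(v, 0, None)), LabelMask(cells), in_cell

    def test_covers_true_background(self, rng):
        stack, cells, in_cell = self._trans_stack(rng)
        mask = derive_background_mask(stack, cells)
        background_true = ~in_cell
        coverage = (mask & background_true).sum() / background_true.sum()
        assert coverage >= 0.95
        assert not (mask & in_cell).any()  # disjoint from cells

    def test_empty_cell_mask_covers_frame(self, rng):
        v = np.clip(500.0 + rng.normal(0, 2.0, (10, 48, 48)), 0, None)
        cells = LabelMask(np.zeros((48, 48), dtype=np.int32))
        mask = derive_background_mask(ImageStack(v), cells)
        assert mask.mean() >= 0.95

    def test_small_hole_filled(self, rng):
        stack, cells, in_cell = self._trans_stack(rng)
        # carve a 10-px "hot" hole in the background far from any cell
        v = stack.voxels.copy()
        v[:, 2:4, 50:55] += rng.normal(0, 300.0, (10, 2, 5))
        mask = derive_background_mask(ImageStack(np.clip(v, 0, None)), cells)
        assert mask[2:4, 50:55].all()

    def test_single_plane_rejected(self):
        stack = ImageStack(np.zeros((1, 32, 32)))
        cells = LabelMask(np.zeros((32, 32), dtype=np.int32))
        with pytest.raises(ValueError):
            derive_background_mask(stack, cells)
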