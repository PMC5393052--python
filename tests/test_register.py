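"""Histogram rendering, cross-correlation registration, QC, DDR classes."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.ndimage import binary_dilation

from telostorm import register
from telostorm.cluster import Cluster
from telostorm.register import (
    RegisterParams,
    classify_ddr,
    estimate_offset,
    qc_clusters,
    render_histogram,
    upsample_nearest,
)
from telostorm.simulate import WideFieldImage


def table_from(xy):
    xy = np.asarray(xy, float).reshape(-1, 2)
    return pd.DataFrame({"x_nm": xy[:, 0], "y_nm": xy[:, 1]})


class TestHistogram:
    def test_single_localization_single_bin(self):
        h = render_histogram(table_from([[0.0, 0.0]]), bin_nm=22.0)
        assert h.shape == (1, 1)
        assert h[0, 0] == 1.0

    def test_total_counts_conserved(self):
        rng = np.random.default_rng(0)
        t = table_from(rng.uniform(0, 5000, size=(1234, 2)))
        h = render_histogram(t, bin_nm=22.0, field_size_nm=(5000.0, 5000.0))
        assert h.sum() == 1234

    def test_boundary_point_goes_to_higher_bin(self):
        # x exactly at 2*22 nm belongs to bin index 2 under [k*b, (k+1)*b)
        h = render_histogram(table_from([[44.0, 0.0]]), bin_nm=22.0)
        assert h[0, 2] == 1.0
        assert h.sum() == 1.0


class TestOffset:
    def _self_pair(self, shift_bins=(0, 0)):
        """Histogram + a wide-field image that is the same content shifted."""
        rng = np.random.default_rng(1)
        xy = np.vstack([
            rng.normal((1000.0, 1500.0), 60.0, size=(300, 2)),
            rng.normal((3000.0, 2500.0), 60.0, size=(300, 2)),
        ])
        hist = render_histogram(table_from(xy), 22.0, (4400.0, 4400.0))
        wf_pixels = np.roll(hist, (shift_bins[1], shift_bins[0]), axis=(0, 1))
        wf = WideFieldImage(pixels=wf_pixels, pixel_size_nm=22.0)
        params = RegisterParams(hist_bin_nm=22.0, upsample_factor=1)
        return hist, wf, params

    def test_zero_shift_recovered(self):
        hist, wf, params = self._self_pair()
        assert estimate_offset(hist, wf, params) == (0.0, 0.0)

    def test_integer_bin_shift_recovered_exactly(self):
        # wide-field content moved +3 bins in x: adding +66 nm to localization
        # coordinates re-aligns them, which is the declared sign convention
        hist, wf, params = self._self_pair(shift_bins=(3, 0))
        assert estimate_offset(hist, wf, params) == (66.0, 0.0)

    def test_shift_in_both_axes(self):
        hist, wf, params = self._self_pair(shift_bins=(2, -3))
        assert estimate_offset(hist, wf, params) == (44.0, -66.0)

    def test_empty_histogram_rejected(self):
        wf = WideFieldImage(pixels=np.ones((4, 4)), pixel_size_nm=22.0)
        with pytest.raises(ValueError, match="empty"):
            estimate_offset(np.zeros((4, 4)), wf, RegisterParams(22.0, 1))

    def test_upsampling_preserves_counts_blockwise(self):
        img = np.arange(6.0).reshape(2, 3)
        up = upsample_nearest(img, 5)
        assert up.shape == (10, 15)
        assert up.sum() == pytest.approx(img.sum() * 25)

    def test_injected_channel_offset_recovered_within_one_bin(self, small_fov):
        # registration runs on drift-corrected, merged localizations: with the
        # stage drift still in the table the clusters are smeared and displaced
        from telostorm import pipeline as pl

        res = pl.process_fov(
            small_fov["table"],
            small_fov["frames_total"],
            small_fov["probe_widefield"],
            small_fov["ddr_widefield"],
        )
        dx, dy = res["offset_nm"]
        tx, ty = small_fov["truth"].channel_offset_nm
        assert abs(dx - tx) <= 22.0
        assert abs(dy - ty) <= 22.0


def _scene():
    """A diffraction-blurred wide-field with one locus, plus clusters on/off it."""
    from telostorm.simulate import render_widefield

    rng = np.random.default_rng(3)
    locus_xy = rng.normal((2000.0, 2000.0), 60.0, size=(200, 2))
    wf = render_widefield(
        [[2000.0, 2000.0]], [60.0], (4320.0, 4320.0),
        pixel_size_nm=108.0, psf_sigma_nm=130.0, poisson=False, background=10.0,
    )
    background_xy = rng.normal((3500.0, 800.0), 60.0, size=(200, 2))
    table = table_from(np.vstack([locus_xy, background_xy]))
    on_locus = Cluster(cluster_id=0, member_indices=np.arange(200))
    off_locus = Cluster(cluster_id=1, member_indices=np.arange(200, 400))
    return table, wf, on_locus, off_locus


class TestQc:
    def test_self_consistent_cluster_kept(self):
        table, wf, on_locus, _ = _scene()
        mask = np.ones_like(wf.pixels, dtype=bool)
        qc_clusters([on_locus], table, wf, (0.0, 0.0), nucleus_mask=mask)
        assert on_locus.qc_status == "kept"

    def test_background_cluster_rejected_for_locus_criterion(self):
        table, wf, _, off_locus = _scene()
        mask = np.ones_like(wf.pixels, dtype=bool)
        qc_clusters([off_locus], table, wf, (0.0, 0.0), nucleus_mask=mask)
        assert off_locus.qc_status == "rejected"
        assert off_locus.qc_reason == "not_on_locus"

    def test_cluster_outside_nucleus_rejected(self):
        table, wf, on_locus, _ = _scene()
        mask = np.zeros_like(wf.pixels, dtype=bool)  # nothing is nucleus
        qc_clusters([on_locus], table, wf, (0.0, 0.0), nucleus_mask=mask)
        assert on_locus.qc_status == "rejected"
        assert on_locus.qc_reason == "outside_nucleus"

    def test_missing_mask_warns_and_skips_criterion(self):
        table, wf, on_locus, _ = _scene()
        with pytest.warns(UserWarning, match="nucleus mask"):
            qc_clusters([on_locus], table, wf, (0.0, 0.0), nucleus_mask=None)
        assert on_locus.qc_status == "kept"


class TestDdr:
    def _ddr_image(self):
        pixels = np.zeros((40, 40))
        pixels[15:25, 15:25] = 500.0  # one bright DDR locus
        return WideFieldImage(pixels=pixels + 10.0, pixel_size_nm=108.0, channel="ddr")

    def test_cluster_inside_locus_is_complete(self):
        wf = self._ddr_image()
        table = table_from(np.full((60, 2), 20 * 108.0 + 50.0))
        c = Cluster(cluster_id=0, member_indices=np.arange(60))
        classify_ddr([c], table, wf, (0.0, 0.0))
        assert c.ddr_class == "complete"
        assert c.ddr_fraction == 1.0

    def test_cluster_outside_locus_is_none(self):
        wf = self._ddr_image()
        table = table_from(np.full((60, 2), 5 * 108.0))
        c = Cluster(cluster_id=0, member_indices=np.arange(60))
        classify_ddr([c], table, wf, (0.0, 0.0))
        assert c.ddr_class == "none"
        assert c.ddr_fraction == 0.0

    def test_straddling_cluster_is_partial(self):
        wf = self._ddr_image()
        xy = np.column_stack([
            np.linspace(10 * 108.0, 20 * 108.0, 50),
            np.full(50, 20 * 108.0),
        ])
        c = Cluster(cluster_id=0, member_indices=np.arange(50))
        classify_ddr([c], table_from(xy), wf, (0.0, 0.0))
        assert c.ddr_class == "partial"

    def test_monotone_under_mask_dilation(self):
        # growing the locus mask can only increase each overlap fraction
        wf = self._ddr_image()
        rng = np.random.default_rng(4)
        xy = rng.normal(20 * 108.0, 300.0, size=(200, 2))
        table = table_from(xy)
        order = {"none": 0, "partial": 1, "complete": 2}
        threshold = register.robust_locus_threshold(wf.pixels)
        c = Cluster(cluster_id=0, member_indices=np.arange(200))
        classify_ddr([c], table, wf, (0.0, 0.0), threshold=threshold)
        base = order[c.ddr_class]
        dilated = binary_dilation(wf.pixels > threshold, iterations=5)
        grown = WideFieldImage(
            pixels=np.where(dilated, 500.0, 0.0), pixel_size_nm=108.0, channel="ddr"
        )
        c2 = Cluster(cluster_id=0, member_indices=np.arange(200))
        classify_ddr([c2], table, grown, (0.0, 0.0), threshold=250.0)
        assert order[c2.ddr_class] >= base

    def test_label_recovery_on_simulation(self, small_fov):
        from telostorm import pipeline as pl

        res = pl.process_fov(
            small_fov["table"],
            small_fov["frames_total"],
            small_fov["probe_widefield"],
            small_fov["ddr_widefield"],
        )
        truth = small_fov["truth"]
        hits = total = 0
        for c, tid in zip(
            res["clusters"], res["metrics"]["true_cluster_id"], strict=True
        ):
            if c.qc_status != "kept" or tid < 0:
                continue
            detected_positive = c.ddr_class in ("partial", "complete")
            hits += detected_positive == (tid in truth.ddr_positive_indices)
            total += 1
        assert total >= 8
        assert hits / total >= 0.95
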