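"""Background correction, segmentation, features and filter banks."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from hemoflow import imaging
from hemoflow.imaging import (
    GreyMap,
    PHASE_QUALITY_FILTER,
    TRANSMISSION_QUALITY_FILTER,
    correct_background_phase,
    correct_background_transmission,
    counting_filter,
    extract_features,
    phase_quality_filter,
    phase_to_grey,
    segment,
    transmission_quality_filter,
)


def disc_mask(shape, cy, cx, r):
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2


class TestBackgroundCorrection:
    def test_frame_equals_background_gives_flat_offset(self):
        bg = np.full((10, 12), 500.0)
        out = correct_background_transmission(bg[None], bg)
        assert np.allclose(out, 500.0)

    def test_contrast_preserved(self):
        bg = np.full((10, 12), 500.0)
        frame = bg.copy()
        frame[4, 5] = 200.0
        out = correct_background_transmission(frame[None], bg)[0]
        assert out[4, 5] - np.median(out) == pytest.approx(-300.0)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            correct_background_transmission(np.zeros((1, 5, 5)), np.zeros((4, 4)))

    def test_phase_identical_frames_cancel(self):
        stack = np.tile(np.random.default_rng(0).normal(size=(6, 7)), (12, 1, 1))
        out = correct_background_phase(stack)
        assert np.allclose(out, 0.0)

    def test_phase_median_robust_to_transient(self):
        """A cell crossing 5 of the first 11 frames does not contaminate
        the median reference."""
        stack = np.zeros((12, 6, 6))
        stack[2:7, 3, 3] = 5.0  # transient in 5 of 11 reference frames
        out = correct_background_phase(stack, n_ref=11)
        assert out[11, 3, 3] == 0.0
        assert out[2, 3, 3] == 5.0

    def test_phase_nref_one_is_first_frame_subtraction(self):
        stack = np.arange(24, dtype=float).reshape(2, 3, 4)
        out = correct_background_phase(stack, n_ref=1)
        assert np.allclose(out[0], 0.0)
        assert np.allclose(out[1], stack[1] - stack[0])

    def test_phase_short_stack_rejected(self):
        with pytest.raises(ValueError):
            correct_background_phase(np.zeros((5, 4, 4)), n_ref=11)


class TestGreyConversion:
    def test_round_trip(self):
        gm = GreyMap(gain=37.5, offset=12.0)
        phase = np.linspace(0, 6, 25).reshape(5, 5)
        grey, gm_out = phase_to_grey(phase, gm)
        np.testing.assert_allclose(gm_out.to_phase(grey), phase, atol=1e-12)

    def test_zero_phase_maps_to_offset(self):
        grey, gm = phase_to_grey(np.zeros((3, 3)), GreyMap(gain=40.0, offset=7.0))
        assert np.allclose(grey, 7.0)

    def test_gain_scales_contrast(self):
        p = np.array([[0.0, 1.0]])
        g1, _ = phase_to_grey(p, GreyMap(gain=10.0, offset=5.0))
        g2, _ = phase_to_grey(p, GreyMap(gain=20.0, offset=5.0))
        assert (g2 - 5.0)[0, 1] == pytest.approx(2 * (g1 - 5.0)[0, 1])


class TestSegmentation:
    def test_blank_frame_no_labels(self):
        labels = segment(np.full((20, 20), 100.0), 50.0, "below")
        assert labels.max() == 0

    def test_two_disjoint_objects(self):
        frame = np.full((40, 40), 100.0)
        frame[disc_mask(frame.shape, 10, 10, 4)] = 10.0
        frame[disc_mask(frame.shape, 28, 28, 4)] = 10.0
        assert segment(frame, 50.0, "below").max() == 2

    def test_small_speckles_removed(self):
        frame = np.full((20, 20), 100.0)
        frame[3, 3] = 10.0  # single-pixel noise excursion
        assert segment(frame, 50.0, "below", min_size_px=4).max() == 0

    def test_rendered_cell_single_label(self, singlet_transmission):
        from hemoflow.pipeline import process_transmission_stack

        table, _ = process_transmission_stack(singlet_transmission)
        assert len(table) == 1


@pytest.fixture(scope="module")
def disc_features():
    frame = np.full((60, 60), 1000.0)
    frame[disc_mask(frame.shape, 30, 30, 10)] = 100.0
    labels = segment(frame, 500.0, "below")
    return extract_features(
        labels, transmission=frame, raw_transmission=frame,
        pixel_size_um=1.0, i0=1000.0,
    ).iloc[0]


class TestFeatures:

    def test_disc_is_round(self, disc_features):
        assert disc_features.aspect_ratio == pytest.approx(1.0, abs=0.05)
        assert disc_features.circularity == pytest.approx(1.0, abs=0.1)
        assert disc_features.radius_variance < 0.05

    def test_disc_area_and_diameter(self, disc_features):
        assert disc_features.area_um2 == pytest.approx(np.pi * 10**2, rel=0.03)
        assert disc_features.diameter_um == pytest.approx(20.0, rel=0.02)

    def test_constant_object_texture(self, disc_features):
        """A flat-intensity object has co-occurrence energy 1 and zero
        dissimilarity (a single occupied co-occurrence cell)."""
        assert disc_features.energy == pytest.approx(1.0)
        assert disc_features.dissimilarity == pytest.approx(0.0)

    def test_requires_a_modality(self):
        with pytest.raises(ValueError):
            extract_features(np.zeros((5, 5), dtype=int))

    def test_translation_invariance(self, geom, optics):
        """Shifting a cell by whole pixels leaves its features unchanged."""
        from conftest import make_placements
        from hemoflow.simulate import NoiseSpec, render_transmission
        from hemoflow.pipeline import process_transmission_stack

        ps = 0.344
        base = make_placements([(60.0, 50.0, 0.0, 2.78, 0.33)])
        shifted = make_placements([(60.0 + 13 * ps, 50.0 + 7 * ps, 0.0, 2.78, 0.33)])
        cols = ["area_um2", "diameter_um", "aspect_ratio", "circularity",
                "energy", "dissimilarity", "i_mean", "i_min", "radius_variance"]
        tables = []
        for placed in (base, shifted):
            stack = render_transmission(placed, optics, geom, n_frames=1,
                                        noise=NoiseSpec.none())
            tab, _ = process_transmission_stack(stack)
            tables.append(tab[cols].iloc[0])
        pd.testing.assert_series_equal(tables[0], tables[1], rtol=1e-9)


def quality_row(**overrides):
    row = {
        "aspect_ratio": 1.02, "area_um2": 24.0, "circularity": 0.95,
        "energy": 0.5, "mass_center_shift": 0.1, "grey_min": 5.0,
        "radius_variance": 0.05, "dissimilarity": 8.0, "sphericity": 0.99,
        "feret_um": 5.6, "diameter_um": 5.5,
    }
    row.update(overrides)
    return row


class TestQualityFilters:
    def test_passing_row_kept_both_banks(self):
        table = pd.DataFrame([quality_row()])
        assert len(transmission_quality_filter(table)) == 1
        assert len(phase_quality_filter(table)) == 1

    @pytest.mark.parametrize(
        "bank, bad",
        [
            (transmission_quality_filter, {"aspect_ratio": 1.2}),
            (transmission_quality_filter, {"energy": 0.1}),
            (transmission_quality_filter, {"grey_min": 100.0}),
            (phase_quality_filter, {"area_um2": 45.0}),
            (phase_quality_filter, {"dissimilarity": 1.0}),
            (phase_quality_filter, {"sphericity": 0.9}),
        ],
    )
    def test_single_violation_drops_row(self, bank, bad):
        table = pd.DataFrame([quality_row(**bad)])
        assert len(bank(table)) == 0

    def test_missing_column_is_configuration_error(self):
        with pytest.raises(KeyError):
            transmission_quality_filter(pd.DataFrame([{"aspect_ratio": 1.0}]))

    @given(st.lists(st.integers(0, 5), min_size=0, max_size=12, unique=True))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_pure_row_predicate(self, order):
        """Filters are order-independent and idempotent row predicates."""
        rows = [
            quality_row(),
            quality_row(aspect_ratio=1.3),
            quality_row(circularity=0.5),
            quality_row(energy=0.05),
            quality_row(grey_min=200.0),
            quality_row(radius_variance=2.0),
        ]
        table = pd.DataFrame([rows[i] for i in order]) if order else pd.DataFrame(
            columns=list(rows[0])
        )
        once = transmission_quality_filter(table)
        twice = transmission_quality_filter(once)
        pd.testing.assert_frame_equal(once, twice)
        assert set(once.index) == {
            i for i in once.index if TRANSMISSION_QUALITY_FILTER.mask(table)[i]
        }

    def test_defocused_cell_fails_phase_sphericity(self, geom, optics):
        """A cell 3 depths-of-focus off the focal plane loses its sphere
        chord profile and fails the sphericity gate."""
        from conftest import make_placements
        from hemoflow.simulate import NoiseSpec, render_phase
        from hemoflow.pipeline import process_phase_stack

        placed = make_placements([(88.0, 66.0, 3 * 1.26, 2.78, 0.33)])
        placed["frame"] = 11
        stack = render_phase(placed, optics, geom, n_frames=12, noise=NoiseSpec.none())
        table, _ = process_phase_stack(stack)
        assert len(table) == 1
        assert table["sphericity"].iloc[0] < 0.95
        assert len(phase_quality_filter(table)) == 0


class TestCountingFilter:
    def test_platelet_sized_objects_removed(self):
        table = pd.DataFrame([
            quality_row(area_um2=4.0, feret_um=2.3),
            quality_row(area_um2=25.0, feret_um=5.8),
        ])
        out = counting_filter(table)
        assert len(out) == 1
        assert out["area_um2"].iloc[0] == 25.0

    def test_on_locus_single_cell(self):
        """A circular object (area ≈ π (feret/2)²) counts once."""
        table = pd.DataFrame([quality_row(area_um2=25.0, feret_um=5.8)] * 12)
        out = counting_filter(table)
        assert (out["multiplicity"] == 1).all()

    def test_elongated_doublet_counts_twice(self):
        """A merged pair with twice the singlet area and an elongated
        footprint is assigned multiplicity 2."""
        rows = [quality_row(area_um2=24.0, feret_um=5.6) for _ in range(10)]
        rows.append(quality_row(area_um2=46.0, feret_um=11.0, aspect_ratio=1.9))
        out = counting_filter(pd.DataFrame(rows))
        assert out["multiplicity"].iloc[-1] == 2
        assert out["multiplicity"].iloc[0] == 1

    def test_eclipsed_pair_rescued_by_absorbance(self):
        """A compact on-locus object carrying twice the singlet
        integrated absorbance is counted as two cells."""
        rows = [quality_row(area_um2=24.0, feret_um=5.6, od_integral_um2=54.0)
                for _ in range(15)]
        rows.append(quality_row(area_um2=26.0, feret_um=5.9, od_integral_um2=107.0))
        out = counting_filter(pd.DataFrame(rows))
        assert out["multiplicity"].iloc[-1] == 2

    def test_empty_table(self):
        out = counting_filter(pd.DataFrame(columns=list(quality_row())))
        assert out.empty and "multiplicity" in out.columns
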