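"""Synthetic imager: populations, passage, forward models, file I/O."""

import numpy as np
import pandas as pd
import pytest

from hemoflow.geometry import ChannelGeometry, FlowConfig
from hemoflow.simulate import (
    NoiseSpec,
    PopulationParams,
    read_stack,
    render_phase,
    render_transmission,
    sample_population,
    simulate_passage,
    write_stack,
)

from conftest import make_placements


class TestPopulation:
    def test_empty(self):
        assert len(sample_population(0, seed=1)) == 0

    def test_deterministic_under_seed(self):
        a = sample_population(500, seed=42)
        b = sample_population(500, seed=42)
        pd.testing.assert_frame_equal(a, b)

    def test_moments_match_targets(self):
        """10,000 RBC volumes/cHB land within 3 SE of the configured
        normal-population targets (90 ± 13 fl, 33 ± 2.2 g/dL)."""
        pop = sample_population(10_000, PopulationParams(), seed=7)
        v = pop["volume_fl"].to_numpy()
        c = pop["chb_g_ml"].to_numpy() * 100.0
        assert v.mean() == pytest.approx(90.0, abs=3 * 13.0 / 100.0)
        assert v.std() == pytest.approx(13.0, abs=3 * 13.0 / np.sqrt(2e4))
        assert c.mean() == pytest.approx(33.0, abs=3 * 2.2 / 100.0)
        assert c.std() == pytest.approx(2.2, abs=3 * 2.2 / np.sqrt(2e4))

    def test_radius_volume_consistency(self):
        pop = sample_population(100, seed=3)
        np.testing.assert_allclose(
            pop["volume_fl"], 4 / 3 * np.pi * pop["radius_um"] ** 3, rtol=1e-12
        )

    def test_contaminant_sizes(self):
        params = PopulationParams(
            platelet_fraction=0.3, leukocyte_fraction=0.2, debris_fraction=0.1
        )
        pop = sample_population(2000, params, seed=11)
        plt_r = pop.loc[pop.kind == "platelet", "radius_um"]
        wbc_r = pop.loc[pop.kind == "leukocyte", "radius_um"]
        rbc_r = pop.loc[pop.kind == "rbc", "radius_um"]
        # platelets stay below the counting area filter's equivalent radius
        assert (np.pi * plt_r**2 < 9.5).all()
        assert wbc_r.min() > rbc_r.max()

    def test_rejects_negative_sd(self):
        with pytest.raises(ValueError):
            PopulationParams(volume_sd_fl=-1.0)


class TestPassage:
    def test_fast_cell_single_frame(self, geom, default_field):
        """A cell advancing more than l_FOV per frame appears at most once
        per transit."""
        fast_cfg = FlowConfig(n_frames=200)
        pop = sample_population(200, seed=5, duration_s=fast_cfg.duration)
        # place at mid-height center where u dt = 54 μm < l_FOV = 132 μm,
        # then shrink dt so the step exceeds l_FOV
        slow = simulate_passage(pop, default_field, geom, fast_cfg, "focused",
                                wf_um=150.0, seed=0)
        fast_flow = FlowConfig(frame_rate=20.0, n_frames=40)
        fast = simulate_passage(pop, default_field, geom, fast_flow, "focused",
                                wf_um=150.0, seed=0)
        per_cell = fast.groupby("cell_id").size()
        assert per_cell.max() <= 1
        assert slow.groupby("cell_id").size().max() >= 2

    def test_laminar_capture_multiplicity(self, geom, default_field):
        """Cells in the central FOV are captured on average
        l_FOV/(u dt) times (≈ 2.4 at 100 fps for the default rate)."""
        cfg = FlowConfig(n_frames=2000)
        pop = sample_population(3000, PopulationParams(z_sd_um=0.0), seed=9,
                                duration_s=cfg.duration)
        placed = simulate_passage(pop, default_field, geom, cfg, "laminar", seed=2)
        per_cell = placed.groupby("cell_id").size()
        u_center = default_field.u_max
        tau = geom.fov_length / (u_center * 1000.0 * cfg.dt)
        assert per_cell.mean() == pytest.approx(tau, rel=0.05)
        assert set(per_cell.unique()) <= {int(np.floor(tau)), int(np.ceil(tau))}

    def test_focused_spread_within_stream(self, geom, default_field):
        cfg = FlowConfig(n_frames=100)
        pop = sample_population(500, seed=4, duration_s=cfg.duration)
        placed = simulate_passage(pop, default_field, geom, cfg, "focused",
                                  wf_um=120.0, seed=1)
        lo = (geom.fov_width - 120.0) / 2.0
        assert placed["x_fov_um"].between(lo, lo + 120.0).all()

    def test_focused_requires_width(self, geom, default_field):
        pop = sample_population(5, seed=1)
        with pytest.raises(ValueError):
            simulate_passage(pop, default_field, geom, FlowConfig(), "focused")


class TestForwardModels:
    def test_empty_frame_uniform(self, geom, optics):
        stack = render_transmission(
            make_placements([]), optics, geom, n_frames=2,
            noise=NoiseSpec.none(), i0=30000.0,
        )
        assert (stack.frames == 30000).all()

    def test_beer_lambert_center_attenuation(self, geom, optics):
        """An in-focus cell with cHB = 0.3307 g/mL and d = 5 μm transmits
        I/I0 = 10^-3 at its center (eps c d / M = 3.0)."""
        chb = 0.3307
        placed = make_placements([(88.0, 66.0, 0.0, 2.5, chb)])
        stack = render_transmission(
            placed, optics, geom, n_frames=1, noise=NoiseSpec.none(), i0=30000.0
        )
        assert stack.frames.min() / 30000.0 == pytest.approx(1e-3, rel=0.05)

    def test_total_absorbance_scales_with_sphere_volume(self, geom, optics):
        """The absorbance image integrates to (per-μm absorbance) x
        (sphere volume), the analytic chord integral."""
        placed = make_placements([(60.0, 40.0, 0.0, 2.78, 0.33),
                                  (120.0, 90.0, 0.0, 2.2, 0.30)])
        stack = render_transmission(
            placed, optics, geom, n_frames=1, noise=NoiseSpec.none(), i0=30000.0
        )
        ps = stack.pixel_size_um
        od = -np.log10(stack.frames[0].astype(float) / 30000.0)
        total = od.sum() * ps**2
        expected = sum(
            optics.absorbance_per_um(row.chb_g_ml) * 4 / 3 * np.pi * row.radius_um**3
            for row in placed.itertuples()
        )
        assert total == pytest.approx(expected, rel=0.01)

    def test_phase_center_value(self, geom, optics):
        """cHB = 0.33 g/mL over a 5 μm chord at 530 nm retards the wave
        by ~2.99 rad."""
        placed = make_placements([(88.0, 66.0, 0.0, 2.5, 0.33)])
        stack = render_phase(placed, optics, geom, n_frames=1, noise=NoiseSpec.none())
        expected = 2 * np.pi / 0.530 * (0.001 + 0.1497 * 0.33) * 5.0
        assert stack.frames.max() == pytest.approx(expected, rel=0.01)

    def test_phase_zero_outside_cells(self, geom, optics):
        placed = make_placements([(88.0, 66.0, 0.0, 2.5, 0.33)])
        stack = render_phase(placed, optics, geom, n_frames=1, noise=NoiseSpec.none())
        assert stack.frames[0, 0, 0] == 0.0

    def test_zero_concentration_still_retards(self, geom, optics):
        """A hemoglobin-free sphere still carries the n_HB0 - n_m
        contrast, so its phase is small but nonzero."""
        placed = make_placements([(88.0, 66.0, 0.0, 2.5, 0.0)])
        stack = render_phase(placed, optics, geom, n_frames=1, noise=NoiseSpec.none())
        expected = 2 * np.pi / 0.530 * 0.001 * 5.0
        assert stack.frames.max() == pytest.approx(expected, rel=0.02)
        assert stack.frames.max() > 0

    def test_overlapping_phases_add(self, geom, optics):
        one = render_phase(make_placements([(88.0, 66.0, 0.0, 2.5, 0.33)]),
                           optics, geom, n_frames=1, noise=NoiseSpec.none())
        two = render_phase(
            make_placements([(88.0, 66.0, 0.0, 2.5, 0.33),
                             (88.0, 66.0, 0.0, 2.5, 0.33)]),
            optics, geom, n_frames=1, noise=NoiseSpec.none(),
        )
        np.testing.assert_allclose(two.frames, 2 * one.frames, atol=1e-5)

    def test_deterministic_under_seed(self, geom, optics, singlet_placement):
        a = render_transmission(singlet_placement, optics, geom, n_frames=1, seed=10)
        b = render_transmission(singlet_placement, optics, geom, n_frames=1, seed=10)
        np.testing.assert_array_equal(a.frames, b.frames)


class TestStackIO:
    def test_round_trip_bit_exact(self, tmp_path, geom, optics, singlet_placement):
        stack = render_transmission(singlet_placement, optics, geom, n_frames=3, seed=1)
        truth = pd.DataFrame({"cell_id": [0], "radius_um": [2.78]})
        path = tmp_path / "stack.tif"
        write_stack(stack, path, ground_truth=truth)
        back = read_stack(path, "transmission", stack.pixel_size_um)
        np.testing.assert_array_equal(back.frames, stack.frames)
        np.testing.assert_array_equal(back.background, stack.background)
        truth_back = pd.read_csv(str(path).replace(".tif", "_truth.csv"))
        pd.testing.assert_frame_equal(truth_back, truth)

    def test_phase_float_round_trip(self, tmp_path, geom, optics, singlet_placement):
        stack = render_phase(singlet_placement, optics, geom, n_frames=2,
                             noise=NoiseSpec.none())
        path = tmp_path / "phase.tif"
        write_stack(stack, path)
        back = read_stack(path, "phase", stack.pixel_size_um)
        np.testing.assert_array_equal(back.frames, stack.frames)
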