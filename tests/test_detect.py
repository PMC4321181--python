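"""Bead detection, cross-slice linking, sub-pixel centroids, assignment."""

import numpy as np
import pandas as pd
import pytest

from fibgold import detect
from fibgold.detect import Component, DetectionParams
from fibgold.detectability import DetectionGeometry
from fibgold.errors import AssignmentError, ConfigError
from fibgold.stack_io import LabelVolume, VoxelGrid
from fibgold.synth import SimulationConfig, render_stack


def _grid_placed_stack(dz, nz, seed, lateral=240, step=12):
    """Beads on a regular lateral grid with uniform random z: isolates the
    axial detectability law from lateral overlap."""
    shape = (nz, lateral, lateral)
    cfg = SimulationConfig(
        shape=shape, voxel_size=(dz, 5.0, 5.0),
        noise_sigma=0.0, gain_drift=0.0, offset_drift=0.0, jitter_max_px=0,
        seed=seed, detection_geometry=DetectionGeometry(20.0, dz, 0.0))
    labels = LabelVolume(np.full(shape, 2, np.int32), cfg.voxel_size)
    rng = np.random.default_rng(seed)
    ys, xs = np.meshgrid(np.arange(step, lateral - step, step) * 5.0,
                         np.arange(step, lateral - step, step) * 5.0)
    x, y = xs.ravel(), ys.ravel()
    z = rng.uniform(30.0, nz * dz - 30.0, size=x.size)
    truth = pd.DataFrame({"id": np.arange(x.size), "x_nm": x, "y_nm": y,
                          "z_nm": z, "compartment": 2})
    return render_stack((truth, labels), cfg), truth, labels


class TestDetect:
    def test_empty_stack_gives_no_components(self):
        grid = VoxelGrid(np.zeros((4, 16, 16), np.float32), (25, 5, 5))
        with pytest.warns(UserWarning, match="threshold"):
            components, _ = detect.detect(grid, DetectionParams(threshold=0.5))
        assert components == []

    def test_detected_fraction_matches_miss_model_at_25nm(self):
        """Noiseless beads at t=25, d=20: ~80% intersect an imaged plane."""
        stack, truth, labels = _grid_placed_stack(25.0, 100, seed=3)
        particles = detect.find_particles(
            stack, DetectionParams(threshold=0.27), labels=labels)
        frac = len(particles) / len(truth)
        se = np.sqrt(0.2 * 0.8 / len(truth))
        assert abs(frac - 0.80) < 3 * se + 0.02  # small deficit from tangent planes

    def test_mean_slice_span_matches_section_model_at_5nm(self):
        """Noiseless beads at t=5, d=20 span 4 consecutive sections on average."""
        stack, truth, labels = _grid_placed_stack(5.0, 220, seed=4)
        particles = detect.find_particles(
            stack, DetectionParams(threshold=0.27), labels=labels)
        assert len(particles) == len(truth)
        assert particles["n_slices"].mean() == pytest.approx(4.0, abs=0.06)

    def test_raising_threshold_never_adds_components(self):
        """On isolated (unimodal) bead spots the component count is a
        non-increasing function of the threshold."""
        stack, _, _ = _grid_placed_stack(25.0, 40, seed=5, lateral=120)
        counts = []
        for thr in np.linspace(0.3, 1.1, 9):
            components, _ = detect.detect(stack, DetectionParams(threshold=float(thr),
                                                                 min_voxels=1))
            counts.append(len(components))
        assert all(a >= b for a, b in zip(counts, counts[1:]))
        assert counts[0] > 0

    def test_detection_is_idempotent(self):
        """Re-detecting a stack containing only the detected components
        reproduces them exactly."""
        stack, _, _ = _grid_placed_stack(25.0, 40, seed=6, lateral=120)
        params = DetectionParams(threshold=0.27)
        components, thr = detect.detect(stack, params)
        replay = np.zeros_like(stack.data)
        for comp in components:
            replay[comp.indices] = comp.intensities
        again, _ = detect.detect(VoxelGrid(replay, stack.voxel_size), params)
        key = lambda c: tuple(map(tuple, np.sort(np.column_stack(c.indices), axis=0)))
        assert sorted(key(c) for c in components) == sorted(key(c) for c in again)

    def test_size_filters(self):
        data = np.zeros((3, 16, 16), np.float32)
        data[1, 2, 2] = 1.0                      # 1 voxel
        data[1, 8:10, 8:10] = 1.0                # 4 voxels
        grid = VoxelGrid(data, (25, 5, 5))
        components, _ = detect.detect(grid, DetectionParams(threshold=0.5,
                                                            min_voxels=2))
        assert len(components) == 1
        components, _ = detect.detect(grid, DetectionParams(threshold=0.5,
                                                            min_voxels=1, max_voxels=2))
        assert len(components) == 1

    def test_slice_gap_tolerance_bridges_dark_slice(self):
        data = np.zeros((5, 8, 8), np.float32)
        data[1, 4, 4] = 1.0
        data[3, 4, 4] = 1.0   # same lateral spot, slice 2 dark
        grid = VoxelGrid(data, (25, 5, 5))
        components, _ = detect.detect(grid, DetectionParams(threshold=0.5, min_voxels=1))
        assert len(components) == 2
        components, _ = detect.detect(grid, DetectionParams(
            threshold=0.5, min_voxels=1, slice_gap_tolerance=1))
        assert len(components) == 1


class TestSubpixelCentroid:
    grid = VoxelGrid(np.zeros((8, 8, 8), np.float32), (5.0, 5.0, 5.0))

    def test_single_voxel_is_its_centre(self):
        comp = Component((np.array([3]), np.array([2]), np.array([1])),
                         np.array([0.8]))
        x, y, z = detect.subpixel_centroid(comp, self.grid)
        assert (x, y, z) == (5.0, 10.0, 15.0)

    def test_weighted_two_voxel_interpolation(self):
        """Weights 1 and 3 on slices 3 and 4 (dz=5): z = 18.75 nm."""
        comp = Component((np.array([3, 4]), np.array([0, 0]), np.array([0, 0])),
                         np.array([1.0, 3.0]))
        _, _, z = detect.subpixel_centroid(comp, self.grid)
        assert z == pytest.approx(18.75)

    def test_zero_weights_fall_back_to_geometric_centroid(self):
        comp = Component((np.array([2, 4]), np.array([0, 0]), np.array([0, 0])),
                         np.array([0.1, 0.1]))
        with pytest.warns(UserWarning, match="geometric"):
            _, _, z = detect.subpixel_centroid(comp, self.grid, background=0.5)
        assert z == pytest.approx(15.0)


class TestAssignCompartment:
    labels = LabelVolume(
        np.concatenate([np.full((2, 4, 4), 2, np.int32),
                        np.full((2, 4, 4), 3, np.int32)]), (25.0, 5.0, 5.0))

    def test_inside_nucleolus(self):
        assert detect.assign_compartment((10.0, 10.0, 60.0), self.labels) == 3

    def test_boundary_goes_to_lower_voxel(self):
        # z = 37.5 nm is exactly between voxel 1 (label 2) and voxel 2 (label 3)
        assert detect.assign_compartment((10.0, 10.0, 37.5), self.labels) == 2

    def test_outside_grid_is_an_error(self):
        with pytest.raises(AssignmentError):
            detect.assign_compartment((10.0, 10.0, 500.0), self.labels)

    def test_majority_of_detections_get_their_true_compartment(self, clean_config):
        """Noise-free phantom away from boundaries: >= 95% of detections are
        assigned the compartment of their generating position."""
        from fibgold.synth import simulate

        cfg = clean_config.with_(densities={1: 30.0, 2: 150.0, 3: 100.0, 4: 0.0},
                                 seed=9)
        stack, truth = simulate(cfg)
        particles = detect.find_particles(stack, DetectionParams(threshold=0.6),
                                          labels=truth.label_volume)
        # match each detection to its nearest true position
        from scipy.spatial import cKDTree
        t_xyz = truth.positions[["x_nm", "y_nm", "z_nm"]].to_numpy()
        d_xyz = particles[["x_nm", "y_nm", "z_nm"]].to_numpy()
        dist, idx = cKDTree(t_xyz).query(d_xyz)
        ok = (particles["compartment"].to_numpy() ==
              truth.positions["compartment"].to_numpy()[idx])
        assert ok.mean() >= 0.95


def test_invalid_params_rejected():
    with pytest.raises(ConfigError):
        DetectionParams(min_voxels=0)
    with pytest.raises(ConfigError):
        DetectionParams(connectivity=10)
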