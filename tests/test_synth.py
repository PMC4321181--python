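"""Synthetic FIB/SEM generator: phantom geometry, Poisson placement,
surface-imaging rendering, and the injected instrument imperfections."""

import numpy as np
import pandas as pd
import pytest

from fibgold.errors import ConfigError
from fibgold.stack_io import LabelVolume
from fibgold.synth import (SimulationConfig, build_phantom, place_particles,
                           render_stack, simulate, slice_jitter)


class TestPhantom:
    def test_degenerate_nucleus_leaves_cytoplasm_only(self, clean_config):
        cfg = clean_config.with_(nucleus_diameter=0.0, nucleolus_diameter=0.0,
                                 heterochromatin_thickness=0.0)
        labels = build_phantom(cfg)
        assert set(np.unique(labels.labels)) <= {0, 1}

    def test_sphere_volume_matches_closed_form(self):
        """A 14 um nucleus voxelized at 50 nm recovers (4/3)*pi*7^3 within 2%."""
        cfg = SimulationConfig(
            shape=(300, 300, 300), voxel_size=(50.0, 50.0, 50.0),
            cell_semiaxes=(7450.0, 7450.0, 7450.0), nucleus_diameter=14000.0,
            nucleolus_diameter=0.0, heterochromatin_thickness=0.0,
            jitter_max_px=0, noise_sigma=0.0, seed=0)
        labels = build_phantom(cfg)
        voxel_um3 = 50.0 ** 3 * 1e-9
        measured = float(np.isin(labels.labels, (2, 3, 4)).sum()) * voxel_um3
        analytic = (np.pi / 6.0) * 14.0 ** 3
        assert measured == pytest.approx(analytic, rel=0.02)

    def test_phantom_is_deterministic(self, clean_config):
        a = build_phantom(clean_config)
        b = build_phantom(clean_config)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_nucleolus_must_fit_inside_nucleus(self, clean_config):
        with pytest.raises(ConfigError):
            build_phantom(clean_config.with_(nucleolus_diameter=500.0))

    def test_all_compartments_present(self, clean_phantom):
        assert set(np.unique(clean_phantom.labels)) == {0, 1, 2, 3, 4}


class TestPlacement:
    def test_zero_density_places_nothing(self, slab_labels):
        table = place_particles(slab_labels, {2: 0.0}, 1)
        assert len(table) == 0

    def test_poisson_count_moments(self):
        """Mean count over seeds matches lambda * V for the measured nuclear
        density (23.8 / um^3) in a 10 um^3 mask."""
        labels = LabelVolume(np.full((80, 64, 64), 2, np.int32), (50.0, 25.0, 25.0))
        volume = labels.labels.size * 50.0 * 25.0 * 25.0 * 1e-9
        assert volume == pytest.approx(10.24)
        lam = 23.8
        counts = [len(place_particles(labels, {2: lam}, seed)) for seed in range(200)]
        expected = lam * volume
        se = np.sqrt(expected / 200)
        assert abs(np.mean(counts) - expected) < 3 * se

    def test_positions_lie_inside_their_compartment(self, clean_phantom):
        table = place_particles(clean_phantom, {1: 50.0, 2: 200.0, 3: 100.0, 4: 50.0}, 7)
        grid = clean_phantom.as_grid()
        idx = grid.nm_to_index(table[["z_nm", "y_nm", "x_nm"]].to_numpy())
        at = clean_phantom.labels[idx[:, 0], idx[:, 1], idx[:, 2]]
        assert (at == table["compartment"].to_numpy()).all()

    def test_negative_density_rejected(self, slab_labels):
        with pytest.raises(ConfigError):
            place_particles(slab_labels, {2: -1.0}, 1)

    def test_missing_density_for_present_label_rejected(self, clean_phantom):
        with pytest.raises(ConfigError):
            place_particles(clean_phantom, {2: 1.0}, 1)


class TestRendering:
    def _one_particle(self, cfg, z_nm):
        labels = build_phantom(cfg)
        table = pd.DataFrame({"id": [0], "x_nm": [320.0], "y_nm": [320.0],
                              "z_nm": [z_nm], "compartment": [2]})
        return render_stack((table, labels), cfg)

    def test_visibility_window_matches_chord_model(self, clean_config):
        """d=20, t=5, p=0: a bead at z=50 renders contrast on planes 41..59 nm
        (tangent planes at 40/60 nm carry zero chord area); one centred
        between planes shows on exactly 4."""
        from fibgold.detectability import DetectionGeometry

        cfg = clean_config.with_(shape=(24, 128, 128), voxel_size=(5.0, 5.0, 5.0),
                                 cell_semiaxes=(400.0, 300.0, 300.0),
                                 nucleus_diameter=0.0, nucleolus_diameter=0.0,
                                 heterochromatin_thickness=0.0,
                                 detection_geometry=DetectionGeometry(20.0, 5.0, 0.0))
        stack = self._one_particle(cfg, 50.0)
        base = cfg.base_intensities[1]
        lit = {k for k in range(24) if stack.data[k].max() > base + 1e-4}
        assert lit == {9, 10, 11}  # interior planes; 8 and 12 are tangent-adjacent
        stack = self._one_particle(cfg, 52.5)
        lit = {k for k in range(24) if stack.data[k].max() > base + 1e-4}
        assert lit == {9, 10, 11, 12}

    def test_no_particles_gives_base_plus_noise_only(self, clean_config):
        empty = pd.DataFrame({"id": [], "x_nm": [], "y_nm": [], "z_nm": [],
                              "compartment": []})
        labels = build_phantom(clean_config)
        stack = render_stack((empty, labels), clean_config)
        lut = np.zeros(5, np.float32)
        for lab, g in clean_config.base_intensities.items():
            lut[lab] = g
        np.testing.assert_allclose(stack.data, lut[labels.labels], atol=1e-6)

    def test_simulation_is_deterministic(self, clean_config):
        cfg = clean_config.with_(noise_sigma=0.1, jitter_max_px=2,
                                 gain_drift=0.05, offset_drift=0.02,
                                 densities={1: 30.0, 2: 100.0, 3: 30.0, 4: 0.0})
        s1, t1 = simulate(cfg)
        s2, t2 = simulate(cfg)
        np.testing.assert_array_equal(s1.data, s2.data)
        pd.testing.assert_frame_equal(t1.positions, t2.positions)

    def test_injected_jitter_shows_up_as_cross_correlation_offset(self, clean_config):
        """Exhaustive 2D cross-correlation between consecutive slices peaks at
        the injected jitter offset."""
        cfg = clean_config.with_(shape=(20, 128, 128), voxel_size=(5.0, 5.0, 5.0),
                                 cell_semiaxes=(400.0, 300.0, 300.0),
                                 nucleus_diameter=300.0, nucleolus_diameter=100.0,
                                 nucleolus_offset=(0.0, 30.0, 30.0),
                                 heterochromatin_thickness=40.0,
                                 jitter_max_px=3, noise_sigma=0.0)
        stack, truth = simulate(cfg)
        jitter = slice_jitter(cfg)
        k = 7
        a = stack.data[k - 1] - stack.data[k - 1].mean()
        b = stack.data[k] - stack.data[k].mean()
        best, best_off = -np.inf, None
        for dy in range(-6, 7):
            for dx in range(-6, 7):
                shifted = np.roll(np.roll(b, -dy, axis=0), -dx, axis=1)
                score = float((a * shifted).sum())
                if score > best:
                    best, best_off = score, (dy, dx)
        expected = tuple((jitter[k] - jitter[k - 1]).tolist())
        assert best_off == expected

    def test_tem_like_polarity_inverts(self, clean_config):
        cfg = clean_config.with_(densities={1: 0.0, 2: 100.0, 3: 0.0, 4: 0.0})
        bright, _ = simulate(cfg)
        dark, _ = simulate(cfg, tem_like=True)
        # the dense nucleolus is bright internally, dark in the TEM-like view
        nol = build_phantom(cfg).labels == 3
        assert bright.data[nol].mean() > bright.data.mean()
        assert dark.data[nol].mean() < dark.data.mean()


def test_miss_and_span_laws_on_rendered_stacks():
    """Ground-truth beads intersecting no imaged plane converge to (t-d)/t = 20%
    for t=25, and the mean geometric span is d/t for t=5 (p = 0)."""
    from fibgold.detectability import DetectionGeometry, intersecting_planes

    rng = np.random.default_rng(5)
    z = rng.uniform(100.0, 900.0, size=20_000)
    geom = DetectionGeometry(20.0, 25.0, 0.0)
    missed = sum(len(intersecting_planes(zi, geom, dz=25.0)) == 0 for zi in z)
    se = np.sqrt(0.2 * 0.8 / z.size)
    assert abs(missed / z.size - 0.20) < 3 * se
    geom5 = DetectionGeometry(20.0, 5.0, 0.0)
    spans = [len(intersecting_planes(zi, geom5, dz=5.0)) for zi in z]
    assert np.mean(spans) == pytest.approx(4.0, abs=0.02)
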