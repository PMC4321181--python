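"""Densities, enrichment, detectability correction, molecule estimate."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fibgold import quantify
from fibgold.errors import ConfigError
from fibgold.quantify import CompartmentStats
from fibgold.reference import REFERENCE_COUNTS
from fibgold.stack_io import LabelVolume


class TestDensity:
    @pytest.mark.parametrize("n,v,rounded", [
        (196, 41.9, 4.7),      # cytoplasm, Fab probe
        (1913, 113.8, 16.8),   # cell total, Fab probe
        (0, 5.0, 0.0),
    ])
    def test_published_pairs(self, n, v, rounded):
        assert round(quantify.density(n, v), 1) == rounded

    def test_zero_volume_rejected(self):
        with pytest.raises(ConfigError):
            quantify.density(10, 0.0)

    @settings(deadline=None, max_examples=50)
    @given(st.integers(0, 10_000), st.floats(0.01, 1000.0))
    def test_stats_invariant_density_times_volume_is_count(self, n, v):
        s = CompartmentStats("x", n, v)
        assert s.density * s.volume_um3 == pytest.approx(n, rel=1e-9)


class TestEnrichment:
    def _stats(self, probe, name):
        n, v = REFERENCE_COUNTS[probe][name]
        return CompartmentStats(name, n, v)

    def test_nucleolar_depletion_is_3_2_fold(self):
        fold = quantify.fold_enrichment(self._stats("fab_us", "whole_nucleus"),
                                        self._stats("fab_us", "nucleoli"))
        assert round(fold, 1) == 3.2

    def test_identical_stats_give_unity(self):
        s = self._stats("fab_us", "cytoplasm")
        assert quantify.fold_enrichment(s, s) == pytest.approx(1.0)

    def test_nucleus_over_cytoplasm_from_table_is_5_1(self):
        """Direct division of the published Fab densities gives 5.1 (the
        prose rounds to 5.0)."""
        fold = quantify.fold_enrichment(self._stats("fab_us", "whole_nucleus"),
                                        self._stats("fab_us", "cytoplasm"))
        assert round(fold, 1) == 5.1

    def test_empty_reference_compartment_is_undefined(self):
        assert np.isnan(quantify.fold_enrichment(
            self._stats("fab_us", "cytoplasm"), CompartmentStats("empty", 0, 1.0)))


class TestNuclearFraction:
    def test_all_nuclear_is_100(self):
        table = [CompartmentStats("whole_nucleus", 50, 1.0),
                 CompartmentStats("total", 50, 2.0)]
        assert quantify.nuclear_fraction(table) == 100.0

    def test_published_fab_counts_give_89_8(self):
        """1717 / 1913 = 89.8% (the prose prints 84%, which is not derivable
        from the table's counts; the computed value is reported)."""
        table = [CompartmentStats("whole_nucleus", *REFERENCE_COUNTS["fab_us"]["whole_nucleus"]),
                 CompartmentStats("total", *REFERENCE_COUNTS["fab_us"]["total"])]
        assert round(quantify.nuclear_fraction(table), 1) == 89.8

    def test_no_nuclear_particles_is_zero(self):
        table = pd.DataFrame({"compartment": [1, 1, 1]})
        assert quantify.nuclear_fraction(table) == 0.0

    def test_zero_total_undefined(self):
        with pytest.raises(ConfigError):
            quantify.nuclear_fraction(pd.DataFrame({"compartment": []}))


class TestMoleculeEstimate:
    def test_sphere_volume_of_14_um_nucleus(self):
        v = quantify.sphere_volume(14.0)
        assert v == pytest.approx(1436.8, abs=0.1)
        assert quantify.round_sig(v, 2) == 1400.0

    def test_sphere_volume_small_cases(self):
        assert quantify.sphere_volume(2.0) == pytest.approx(np.pi / 6 * 8)
        assert quantify.sphere_volume(0.0) == 0.0

    def test_labelled_molecules_at_published_density(self):
        est = quantify.molecules_labelled(23.8, 1400.0)
        assert est == pytest.approx(33_320.0)
        assert quantify.round_sig(est, 2) == 33_000.0

    def test_estimate_sensitivity_to_volume_rounding(self):
        assert quantify.molecules_labelled(23.8, quantify.sphere_volume(14.0)) == \
            pytest.approx(23.8 * (np.pi / 6.0) * 14.0 ** 3)
        assert quantify.round_sig(quantify.molecules_labelled(
            23.8, quantify.sphere_volume(14.0)), 2) == 34_000.0

    def test_labelled_fraction(self):
        assert quantify.labelled_fraction(33_000, 330_000) == pytest.approx(10.0)
        assert quantify.labelled_fraction(0.0, 123.0) == 0.0
        with pytest.raises(ConfigError):
            quantify.labelled_fraction(1.0, 0.0)


class TestTableReconstruction:
    def test_recomputed_densities_match_printed_except_known_cell(self):
        """Every printed density cell is reproduced by N/V at 1 decimal,
        except the Fab whole-nucleus cell (23.9 recomputed vs 23.8 printed),
        which must be logged, not asserted."""
        with pytest.warns(UserWarning, match="whole_nucleus"):
            rows = quantify.reconstruct_reference_table("fab_us")
        by_name = {r.name: r for r in rows}
        assert by_name["cytoplasm"].density_rounded == 4.7
        assert by_name["nucleus_without_nucleoli"].density_rounded == 24.4
        assert by_name["nucleoli"].density_rounded == 7.5
        assert by_name["total"].density_rounded == 16.8
        assert by_name["whole_nucleus"].density_rounded == 23.9  # logged discrepancy

    def test_igg_column_reconstructs_cleanly(self):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("error")
            rows = quantify.reconstruct_reference_table("igg_us")
        by_name = {r.name: r for r in rows}
        assert by_name["whole_nucleus"].density_rounded == 9.3
        assert by_name["total"].density_rounded == 4.9

    @pytest.mark.parametrize("probe", ["fab_us", "igg_us"])
    def test_count_additivity(self, probe):
        ref = REFERENCE_COUNTS[probe]
        assert (ref["nucleus_without_nucleoli"][0] + ref["nucleoli"][0]
                == ref["whole_nucleus"][0])


class TestCompartmentTable:
    def test_counts_volumes_and_aggregates(self):
        labels = np.zeros((4, 6, 6), np.int32)
        labels[0] = 1          # cytoplasm: 36 voxels
        labels[1] = 2          # euchromatin
        labels[2] = 3          # nucleolus
        labels[3] = 4          # heterochromatin
        vol = LabelVolume(labels, (25.0, 5.0, 5.0))
        particles = pd.DataFrame({"compartment": [1, 1, 2, 3, 4, 4]})
        table = quantify.compartment_table(particles, vol)
        by_name = {s.name: s for s in table}
        assert by_name["cytoplasm"].n == 2
        assert by_name["whole_nucleus"].n == 4
        assert by_name["nucleus_without_nucleoli"].n == 3
        assert by_name["nucleoli"].n == 1
        assert by_name["total"].n == 6
        voxel = 625e-9 * 36
        assert by_name["whole_nucleus"].volume_um3 == pytest.approx(3 * voxel)

    def test_enrichment_report_consistency(self, geometry):
        labels = np.zeros((4, 6, 6), np.int32)
        labels[0], labels[1], labels[2], labels[3] = 1, 2, 3, 4
        vol = LabelVolume(labels, (25.0, 5.0, 5.0))
        particles = pd.DataFrame({"compartment": [1, 2, 2, 2, 3]})
        table = quantify.compartment_table(particles, vol)
        report = quantify.enrichment_report(table, geometry, assumed_total=330_000)
        assert report.miss_fraction == pytest.approx(0.2)
        assert report.corrected_counts["total"] == pytest.approx(5 / 0.8)
        assert report.nuclear_fraction_pct == pytest.approx(80.0)
        by_name = {s.name: s for s in table}
        assert report.molecules_labelled == pytest.approx(
            by_name["whole_nucleus"].density * quantify.sphere_volume(14.0))
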