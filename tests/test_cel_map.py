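"""CEL map assembly, local minima, rotamer comparison, export."""

import numpy as np
import pytest

from glycocel import cel_map, grid_enum as ge, pucker
from glycocel.cel_map import SliceBinning
from glycocel.energy_backends import ToyPuckerBackend, ToyWell
from glycocel.records import ConformerRecord


def ring_record(conf_id, name, energy, rotamer="R1"):
    ring = pucker.ideal_ring_geometry(name, 0.55)
    return ConformerRecord(
        conf_id=conf_id, symbols=list(ring.labels), coords=ring.coords,
        energy=energy, rotamer=rotamer,
    )


def toy_ensemble(wells, rotamer="R1", offsets=None, spec=None):
    be = ToyPuckerBackend(wells, rotamer_offsets=offsets or {})
    return ge.run_grid(None, be, spec=spec or ge.GridSpec(), rotamers=(rotamer,))


class TestBinning:
    def test_partition_exhaustive_and_disjoint(self):
        b = SliceBinning()
        cells = {(band, p) for band in range(b.n_bands) for p in range(b.phi_bins(band))}
        assert len(cells) == 38  # one cell per canonical conformer region
        for theta in np.linspace(0.0, 180.0, 73):
            for phi in np.linspace(0.0, 359.5, 48):
                assert b.cell_of(theta, phi) in cells

    def test_cell_labels_cover_all_38_conformers(self):
        b = SliceBinning()
        labels = {
            b.cell_label((band, p))
            for band in range(b.n_bands)
            for p in range(b.phi_bins(band))
        }
        assert labels == {r.name for r in pucker.canonical_conformers()}

    def test_poles_map_to_chairs(self):
        b = SliceBinning()
        assert b.cell_label(b.cell_of(0.0, None)) == "4C1"
        assert b.cell_label(b.cell_of(179.0, 123.0)) == "1C4"


class TestBuildMap:
    def test_minimum_cell_is_planted_well(self):
        recs = toy_ensemble([ToyWell(0.0, 0.0, 30.0)])
        m = cel_map.build_map(recs, "R1")
        assert m.binning.cell_label(m.min_cell()) == "4C1"

    def test_self_referenced_minimum_is_zero(self):
        recs = toy_ensemble([ToyWell(90.0, 270.0, 20.0)])
        m = cel_map.build_map(recs, "R1")
        assert m.min_energy() == pytest.approx(0.0, abs=1e-12)

    def test_single_conformer_single_cell(self):
        m = cel_map.build_map([ring_record(0, "4H3", 10.0)], "R1")
        assert len(m.cells) == 1
        assert m.min_energy() == 0.0

    def test_each_record_in_exactly_one_cell(self):
        recs = toy_ensemble([ToyWell(0.0, 0.0, 30.0)], spec=ge.GridSpec(-60, 60, 30))
        m = cel_map.build_map(recs, "R1")
        occupied = len(m.cells) + len(m.missing_cells)
        assert occupied == 38

    def test_empty_ensemble_rejected(self):
        with pytest.raises(ValueError):
            cel_map.build_map([], "R1")
        with pytest.raises(ValueError, match="rotamer"):
            cel_map.build_map([ring_record(0, "4C1", 0.0, rotamer="R2")], "R1")

    def test_records_missing_energy_skipped_and_counted(self):
        recs = [ring_record(0, "4C1", 0.0), ring_record(1, "1C4", None)]
        m = cel_map.build_map(recs, "R1")
        assert m.n_skipped == 1


class TestLocalMinima:
    def test_single_well_single_minimum(self):
        recs = toy_ensemble([ToyWell(0.0, 0.0, 30.0)])
        m = cel_map.build_map(recs, "R1")
        minima = cel_map.find_local_minima(m)
        assert len(minima) == 1
        assert m.binning.cell_label(minima[0][0]) == "4C1"

    def test_two_symmetric_wells_two_equal_minima(self):
        recs = toy_ensemble(
            [ToyWell(0.0, 0.0, 30.0, width=15.0), ToyWell(180.0, 0.0, 30.0, width=15.0)]
        )
        m = cel_map.build_map(recs, "R1")
        minima = cel_map.find_local_minima(m)
        labels = {m.binning.cell_label(c) for c, _ in minima[:2]}
        assert labels == {"4C1", "1C4"}
        e0, e1 = (m.relative_energy(c) for c, _ in minima[:2])
        assert e0 == pytest.approx(e1, abs=0.35)  # grid discretization only

    def test_flat_surface_every_cell_is_minimal(self):
        recs = toy_ensemble([])
        m = cel_map.build_map(recs, "R1")
        assert len(cel_map.find_local_minima(m)) == len(m.cells)


class TestCompareRotamers:
    def make_maps(self, e1, e2):
        m1 = cel_map.build_map([ring_record(0, "4C1", e1, "R1")], "R1", reference_energy=0.0)
        m2 = cel_map.build_map([ring_record(1, "4H3", e2, "R2")], "R2", reference_energy=0.0)
        return m1, m2

    def test_deeper_r1_is_lrp_favorable(self):
        m1, m2 = self.make_maps(0.0, 2.5 * cel_map.KCAL)
        cmp_ = cel_map.compare_rotamers(m1, m2, 0.5)
        assert cmp_.verdict == "LRP-favorable"
        assert cmp_.ddg_kcal == pytest.approx(-2.5, abs=1e-9)

    def test_equal_minima_indeterminate(self):
        m1, m2 = self.make_maps(1.0, 1.0)
        assert cel_map.compare_rotamers(m1, m2, 0.5).verdict == "indeterminate"

    def test_sign_reversal_unfavorable(self):
        m1, m2 = self.make_maps(3.0 * cel_map.KCAL, 0.0)
        assert cel_map.compare_rotamers(m1, m2, 0.5).verdict == "LRP-unfavorable"

    def test_inconsistent_reference_rejected(self):
        m1 = cel_map.build_map([ring_record(0, "4C1", 0.0, "R1")], "R1", reference_energy=0.0)
        m2 = cel_map.build_map([ring_record(1, "4C1", 0.0, "R2")], "R2", reference_energy=5.0)
        with pytest.raises(ValueError, match="common energy zero"):
            cel_map.compare_rotamers(m1, m2)


class TestExport:
    def test_csv_rows_equal_occupied_cells_and_bytes_stable(self, tmp_path):
        recs = toy_ensemble([ToyWell(0.0, 0.0, 30.0)], spec=ge.GridSpec(-60, 60, 30))
        m = cel_map.build_map(recs, "R1")
        png1, csv1 = cel_map.export_heatmap(m, str(tmp_path / "a"))
        _, csv2 = cel_map.export_heatmap(m, str(tmp_path / "b"))
        import pandas as pd

        df = pd.read_csv(csv1)
        assert len(df) == len(m.cells)
        assert df["delta_g_kj"].min() == pytest.approx(0.0, abs=1e-9)
        assert open(csv1, "rb").read() == open(csv2, "rb").read()
        assert (tmp_path / "a.png").stat().st_size > 0

    def test_default_contour_interval(self):
        recs = toy_ensemble([])
        m = cel_map.build_map(recs, "R1")
        assert m.contour_interval == 0.5  # kcal/mol


class TestCollapseDuplicates:
    def test_identical_structures_collapse(self):
        a = ring_record(0, "4C1", 1.0)
        b = ring_record(1, "4C1", 1.0)
        c = ring_record(2, "1C4", 1.0)
        kept = cel_map.collapse_duplicates([a, b, c])
        assert [r.conf_id for r in kept] == [0, 2]

    def test_energy_difference_prevents_collapse(self):
        a = ring_record(0, "4C1", 1.0)
        b = ring_record(1, "4C1", 3.0)
        assert len(cel_map.collapse_duplicates([a, b])) == 2


class TestParameterRecovery:
    """Planted toy minima are recovered end-to-end (grid -> map -> minima)."""

    @pytest.mark.parametrize(
        "names", [["4C1"], ["4C1", "1S5"], ["4C1", "1C4", "OS2"]],
        ids=lambda n: "+".join(n),
    )
    def test_planted_minima_recovered(self, names):
        wells = [
            ToyWell(
                pucker.conformer_by_name(n).theta_ref,
                pucker.conformer_by_name(n).phi_ref or 0.0,
                30.0,
                width=12.0,
            )
            for n in names
        ]
        recs = toy_ensemble(wells)
        m = cel_map.build_map(recs, "R1")
        minima = cel_map.find_local_minima(m)
        found = [m.binning.cell_label(c) for c, _ in minima]
        for n in names:
            assert n in found
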