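"""IR simulation stages: search, pruning, broadening, matching, assignment."""

import numpy as np
import pytest

from glycocel import ir_pipeline as ir
from glycocel.records import ConformerRecord


def stick(positions, intensities):
    return ir.Spectrum(np.asarray(positions, float), np.asarray(intensities, float))


def synthetic_trace(bands, amplitude=1.0):
    """Broadened trace with unit sticks at the given wavenumbers."""
    lines = stick(sorted(bands), [amplitude] * len(bands))
    return ir.broaden(lines, 20.0)


class TestSpectrumType:
    def test_invariants(self):
        with pytest.raises(ValueError, match="non-negative"):
            stick([1000.0], [-1.0])
        with pytest.raises(ValueError, match="increasing"):
            ir.Spectrum(np.array([2.0, 1.0]), np.array([0.0, 0.0]), "trace")

    def test_tsv_round_trip(self, tmp_path):
        tr = synthetic_trace([1600.0])
        path = tmp_path / "t.tsv"
        ir.write_spectrum_tsv(tr, path)
        back = ir.read_spectrum_tsv(path)
        assert back.kind == "trace"
        np.testing.assert_allclose(back.positions, tr.positions, atol=1e-4)
        np.testing.assert_allclose(back.intensities, tr.intensities, rtol=1e-6)


class TestConformerSearch:
    def test_seeded_and_reproducible(self, small_cation):
        cfg = ir.PipelineConfig(n_conformers=8, seed=5)
        a = ir.conformer_search(small_cation, cfg)
        b = ir.conformer_search(small_cation, cfg)
        assert len(a) == 8
        for ra, rb in zip(a, b):
            np.testing.assert_allclose(ra.coords, rb.coords, atol=1e-12)
            assert ra.energy == pytest.approx(rb.energy, abs=1e-9)

    def test_molecular_graph_preserved(self, small_cation):
        cfg = ir.PipelineConfig(n_conformers=4, seed=5)
        recs = ir.conformer_search(small_cation, cfg)
        symbols = sorted(recs[0].symbols)
        assert all(sorted(r.symbols) == symbols for r in recs)

    def test_bad_smiles_rejected(self):
        with pytest.raises(ValueError, match="SMILES"):
            ir.conformer_search("not_a_molecule(", ir.PipelineConfig(n_conformers=2))


class TestDiversitySelect:
    def fake_records(self, coords_list, energies):
        return [
            ConformerRecord(conf_id=i, symbols=["C"] * len(c), coords=np.asarray(c, float),
                            energy=e)
            for i, (c, e) in enumerate(zip(coords_list, energies))
        ]

    def test_below_cap_all_retained(self):
        rng = np.random.default_rng(3)
        recs = self.fake_records([rng.normal(size=(5, 3)) for _ in range(10)], range(10))
        assert len(ir.diversity_select(recs, ir.PipelineConfig(max_selected=40))) == 10

    def test_cap_respected(self):
        rng = np.random.default_rng(3)
        recs = self.fake_records([rng.normal(size=(5, 3)) for _ in range(30)], range(30))
        out = ir.diversity_select(recs, ir.PipelineConfig(max_selected=7))
        assert len(out) == 7

    def test_exact_duplicates_collapse(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=(5, 3))
        recs = self.fake_records([base, base.copy(), base + 5.0], [0.0, 1.0, 2.0])
        # +5 is a rigid translation: superposition makes it a duplicate too
        assert len(ir.diversity_select(recs)) == 1

    def test_lowest_energy_always_first_pick(self):
        rng = np.random.default_rng(4)
        recs = self.fake_records([rng.normal(size=(5, 3)) for _ in range(6)],
                                 [3.0, 1.0, 7.0, 0.5, 9.0, 2.0])
        out = ir.diversity_select(recs, ir.PipelineConfig(max_selected=2))
        assert any(r.conf_id == 3 for r in out)


class TestEnergyFilter:
    def recs(self, energies):
        return [ConformerRecord(conf_id=i, energy=e) for i, e in enumerate(energies)]

    def test_default_window(self):
        out = ir.filter_by_energy(self.recs([0.0, 30.0, 50.0]))
        assert [r.conf_id for r in out] == [0, 1]

    def test_pyranosyl_window(self):
        out = ir.filter_by_energy(self.recs([0.0, 70.0]), pyranosyl=True)
        assert len(out) == 2

    def test_minimum_always_retained(self):
        out = ir.filter_by_energy(self.recs([1234.5]))
        assert len(out) == 1

    def test_relative_not_absolute(self):
        out = ir.filter_by_energy(self.recs([1000.0, 1030.0, 1100.0]))
        assert [r.conf_id for r in out] == [0, 1]


class TestScaleAndBroaden:
    def test_default_scaling(self):
        out = ir.scale_frequencies(stick([1000.0], [2.0]))
        assert out.positions[0] == pytest.approx(975.0)
        assert out.intensities[0] == 2.0

    def test_identity_factor_and_order(self):
        lines = stick([800.0, 1200.0, 1600.0], [1.0, 2.0, 3.0])
        out = ir.scale_frequencies(lines, 1.0)
        np.testing.assert_allclose(out.positions, lines.positions)
        out = ir.scale_frequencies(lines, 0.975)
        assert np.all(np.diff(out.positions) > 0)

    def test_peak_at_line_position(self):
        tr = ir.broaden(stick([1234.0], [1.0]), 20.0)
        assert tr.positions[np.argmax(tr.intensities)] == pytest.approx(1234.0, abs=1.0)

    def test_unit_area_kernels_conserve_intensity(self):
        lines = stick([900.0, 1300.0, 1700.0], [1.0, 2.5, 0.5])
        tr = ir.broaden(lines, 20.0)
        area = np.trapezoid(tr.intensities, tr.positions)
        assert area == pytest.approx(lines.intensities.sum(), rel=1e-6)

    def test_linearity_for_coincident_lines(self):
        one = ir.broaden(stick([1500.0], [1.0]), 20.0)
        two = ir.broaden(stick([1500.0, 1500.0], [1.0, 1.0]), 20.0)
        np.testing.assert_allclose(two.intensities, 2.0 * one.intensities, rtol=1e-12)

    def test_fwhm_interpretation(self):
        tr = ir.broaden(stick([1275.0], [1.0]), 20.0, width_is_fwhm=True)
        half = tr.intensities.max() / 2.0
        above = tr.positions[tr.intensities >= half]
        assert above.max() - above.min() == pytest.approx(20.0, abs=1.5)


class TestEnsemble:
    def recs(self, energies):
        return [ConformerRecord(conf_id=i, gibbs=g) for i, g in enumerate(energies)]

    def test_single_record_is_identity(self):
        t = synthetic_trace([1600.0])
        out = ir.ensemble_spectrum(self.recs([0.0]), [t])
        np.testing.assert_allclose(out.intensities, t.intensities)

    def test_equal_energies_arithmetic_mean(self):
        a, b = synthetic_trace([1500.0]), synthetic_trace([1700.0])
        out = ir.ensemble_spectrum(self.recs([5.0, 5.0]), [a, b])
        np.testing.assert_allclose(
            out.intensities, 0.5 * (a.intensities + b.intensities), rtol=1e-12
        )

    def test_explicit_5050_equals_equal_energy_boltzmann(self):
        a, b = synthetic_trace([1500.0]), synthetic_trace([1700.0])
        boltz = ir.ensemble_spectrum(self.recs([1.0, 1.0]), [a, b])
        mixed = ir.ensemble_spectrum([], [a, b], fractions=[0.5, 0.5])
        np.testing.assert_allclose(boltz.intensities, mixed.intensities, rtol=1e-12)


class TestMatchScore:
    def test_self_similarity_is_one(self):
        t = synthetic_trace([1600.0, 1800.0])
        assert ir.match_score(t, t) == pytest.approx(1.0, abs=1e-12)

    def test_rescaled_copy_scores_one(self):
        t = synthetic_trace([1600.0, 1800.0])
        t10 = ir.Spectrum(t.positions, 10.0 * t.intensities, "trace")
        assert ir.match_score(t, t10) == pytest.approx(1.0, abs=1e-9)

    def test_disjoint_bands_near_zero(self):
        a = synthetic_trace([800.0])
        b = synthetic_trace([1700.0])
        assert ir.match_score(a, b) < 0.01

    def test_symmetry(self):
        a = synthetic_trace([1000.0, 1550.0])
        b = synthetic_trace([1050.0, 1500.0])
        assert ir.match_score(a, b) == pytest.approx(ir.match_score(b, a), abs=1e-12)

    def test_empty_overlap_rejected(self):
        a = synthetic_trace([1000.0])
        with pytest.raises(ValueError, match="overlap"):
            ir.match_score(a, a, range_=(2000.0, 2100.0))


class TestClassifyIonType:
    def test_oxocarbenium_signature(self):
        tr = synthetic_trace([1600.0, 1800.0])
        assert ir.classify_ion_type(tr).label == "oxocarbenium"

    def test_dioxolenium_signature(self):
        tr = synthetic_trace([1550.0, 1500.0])
        assert ir.classify_ion_type(tr).label == "dioxolenium"

    def test_ring_opened_signature(self):
        tr = synthetic_trace([1550.0, 1500.0, 1745.0])
        assert ir.classify_ion_type(tr).label == "ring-opened"

    def test_ambiguous_is_indeterminate(self):
        tr = synthetic_trace([1600.0, 1550.0, 1500.0, 1800.0])
        assert ir.classify_ion_type(tr).label == "mixed/indeterminate"

    def test_evidence_reports_positions(self):
        tr = synthetic_trace([1600.0, 1800.0])
        ev = ir.classify_ion_type(tr).evidence
        assert ev["oxocarbenium_stretch"]["present"]
        assert ev["oxocarbenium_stretch"]["position"] == pytest.approx(1600.0, abs=2.0)
        assert not ev["dioxolenium_stretch"]["present"]

    def test_weak_bands_ignored(self):
        lines = stick([1600.0, 1800.0, 1550.0], [1.0, 1.0, 0.01])
        tr = ir.broaden(lines, 20.0)
        assert ir.classify_ion_type(tr).label == "oxocarbenium"

    def test_trace_must_cover_windows(self):
        narrow = ir.Spectrum(np.arange(700.0, 1200.0), np.ones(500), "trace")
        with pytest.raises(ValueError, match="window"):
            ir.classify_ion_type(narrow)


class TestEndToEnd:
    def test_stage_monotonicity_and_determinism(self, small_cation):
        cfg = ir.PipelineConfig(n_conformers=30, max_selected=10, seed=9)
        r1 = ir.run_pipeline(small_cation, cfg)
        r2 = ir.run_pipeline(small_cation, cfg)
        s = r1["stages"]
        assert s["generated"] >= s["selected"] >= s["filtered"] >= 1
        np.testing.assert_allclose(
            r1["spectrum"].intensities, r2["spectrum"].intensities, rtol=1e-9
        )
        rel = [r.energy for r in r1["filtered"]]
        assert max(rel) - min(rel) <= cfg.energy_cutoff + 1e-9
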