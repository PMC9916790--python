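"""Generator correctness: planted signal, determinism, companion tables."""

import dataclasses

import numpy as np
import pytest

from thyromsi import msi_data as md
from thyromsi import synthetic_msi as synth
from thyromsi.errors import ConfigError

from conftest import noise_free_single_peptide_config


class TestSimulateDataset:
    def test_noise_free_cube_is_exactly_the_planted_gaussian(self):
        cfg = noise_free_single_peptide_config()
        ds, roi, _truth = synth.simulate_dataset(cfg)
        labels = roi.labels_for(ds)
        mz = ds.common_mz
        expected = 100.0 * np.exp(-0.5 * ((mz - 1505.83) / 0.3) ** 2)
        for label, (_, inten) in zip(labels, ds.spectra):
            if label == md.NIFTP:
                np.testing.assert_allclose(inten, expected, atol=1e-12)
            else:
                assert np.all(inten == 0.0)

    def test_apex_amplitude_is_the_configured_mean(self):
        cfg = noise_free_single_peptide_config()
        ds, roi, truth = synth.simulate_dataset(cfg)
        niftp_rows = np.flatnonzero(roi.labels_for(ds) == md.NIFTP)
        apex = max(ds.spectra[niftp_rows[0]][1])
        pep = cfg.peptide_panel[0]
        assert apex == pytest.approx(
            truth.expected_apex(pep, f"{md.NIFTP}:{md.RAS_MUTANT}"), rel=1e-12
        )

    def test_same_seed_gives_identical_files(self, tmp_path):
        cfg = synth.small_config(seed=11)
        for run in ("a", "b"):
            ds, _roi, _truth = synth.simulate_dataset(cfg)
            md.write_dataset(ds, str(tmp_path / f"{run}.txt"), "internal")
        assert (tmp_path / "a.txt").read_bytes() == (tmp_path / "b.txt").read_bytes()

    def test_region_means_match_configuration(self):
        """Monte-Carlo: empirical mean apex per profile within 3 SE of the
        configured mean (baseline off so the apex is pure peak + noise)."""
        cfg = dataclasses.replace(synth.default_config(seed=3), baseline=(0.0, 400.0))
        ds, _roi, truth = synth.simulate_dataset(cfg)
        matrix = ds.intensity_matrix()
        mz = ds.common_mz
        profiles = truth.pixel_profile.astype(str)
        for pep in (cfg.peptide_panel[0], cfg.peptide_panel[8], cfg.peptide_panel[12]):
            # sample at the snapped grid point: unbiased, unlike a window max
            idx = int(np.argmin(np.abs(mz - pep.theoretical_mz)))
            apex = matrix[:, idx]
            for key in np.unique(profiles):
                sample = apex[profiles == key]
                want = truth.expected_apex(pep, key)
                se = sample.std(ddof=1) / np.sqrt(len(sample))
                assert abs(sample.mean() - want) < 3 * se

    def test_overlapping_regions_rejected(self):
        cfg = noise_free_single_peptide_config()
        regions = (
            synth.RegionSpec(md.NIFTP, ("rect", 0, 0, 4, 9), nodule_id=1,
                             profile=synth.RAS_MUTANT),
            synth.RegionSpec(md.HP, ("rect", 4, 0, 6, 9)),
            synth.RegionSpec(md.THYP, ("rest",)),
        )
        with pytest.raises(ConfigError, match="overlap"):
            dataclasses.replace(cfg, regions=regions).validate()

    def test_peptide_outside_axis_rejected(self):
        cfg = noise_free_single_peptide_config()
        panel = (synth.PeptideSpec(2000.0, "PPIA", {"NIFTP:RAS_MUTANT": 1.0}),)
        with pytest.raises(ConfigError, match="outside axis"):
            dataclasses.replace(cfg, peptide_panel=panel).validate()


class TestGroundTruth:
    def test_differential_iff_configured_means_differ(self, default_sim):
        cfg, _ds, _roi, truth = default_sim
        status = truth.differential_status((md.NIFTP, md.HP))
        n_diff = sum(1 for s in status.values() if s != synth.NULL)
        assert n_diff == 8 and len(status) == 30
        assert status[1505.83] == synth.OVER       # PPIA up in NIFTP
        assert status[952.35] == synth.UNDER       # SFPQ down in NIFTP
        assert status[1198.70] == synth.NULL       # redistributed within NIFTP
        assert status[836.48] == synth.NULL        # parenchyma marker

    def test_population_auc_limits(self, default_sim):
        cfg, _ds, _roi, truth = default_sim
        ppia = next(p for p in cfg.peptide_panel if p.gene == "PPIA")
        null = next(p for p in cfg.peptide_panel if p.gene == "ALB")
        assert truth.population_auc(ppia, (md.NIFTP, md.HP)) > 0.99
        assert truth.population_auc(null, (md.NIFTP, md.HP)) == pytest.approx(0.5)

    def test_expected_calls_cover_all_nodules(self, default_sim):
        _cfg, _ds, _roi, truth = default_sim
        assert truth.expected_calls == {
            1: synth.RAS_LIKE, 2: synth.RAS_LIKE, 3: synth.RAS_LIKE,
            4: synth.RAS_LIKE, 5: synth.WT_LIKE, 6: synth.WT_LIKE,
            7: synth.WT_LIKE, 8: synth.WT_LIKE, 9: synth.MIXED,
        }


class TestIdTable:
    def test_zero_jitter_measured_equals_theoretical(self):
        cfg = dataclasses.replace(synth.small_config(), ppm_jitter=0.0)
        for row in synth.simulate_id_table(cfg):
            assert row.measured_mz == row.theoretical_mz

    def test_jitter_bound_holds(self):
        cfg = dataclasses.replace(synth.default_config(), ppm_jitter=50.0)
        rows = synth.simulate_id_table(cfg)
        errors = [
            abs(r.measured_mz - r.theoretical_mz) / r.theoretical_mz * 1e6
            for r in rows
        ]
        assert max(errors) <= 50.0

    def test_shared_mz_different_genes_flagged_non_unique(self):
        cfg = synth.small_config()
        panel = cfg.peptide_panel + (
            synth.PeptideSpec(815.39, "OTHERGENE", {"HP": 5.0}),
        )
        cfg = dataclasses.replace(cfg, peptide_panel=panel)
        rows = synth.simulate_id_table(cfg, include_extra_signature_peptides=False)
        flags = {r.gene: r.unique_for_protein for r in rows}
        assert flags["RBMX"] is False and flags["OTHERGENE"] is False
        assert flags["COL1A1"] is True

    def test_sequences_are_tryptic_like(self):
        rows = synth.simulate_id_table(synth.default_config())
        assert all(r.sequence[-1] in "KR" for r in rows)

    def test_reproducible(self):
        cfg = synth.default_config(seed=5)
        assert synth.simulate_id_table(cfg) == synth.simulate_id_table(cfg)


class TestInteractome:
    def test_common_core_in_every_bait(self):
        inter = synth.simulate_interactome(synth.default_config())
        for bait in ("NRAS", "HRAS"):
            assert set(synth.SIGNATURE_GENES) <= inter[bait]

    def test_panel_intersection_is_exactly_the_common_core(self):
        cfg = synth.default_config()
        inter = synth.simulate_interactome(cfg)
        panel = {p.gene for p in cfg.peptide_panel}
        both = inter["NRAS"] & inter["HRAS"]
        assert both & panel == set(synth.SIGNATURE_GENES)

    def test_round_trip(self, tmp_path):
        inter = synth.simulate_interactome(synth.small_config(), n_decoys=5)
        path = synth.write_interactome(inter, str(tmp_path / "intact.tsv"))
        assert synth.read_interactome(path) == inter

    def test_seeded_run_reproducible(self):
        cfg = synth.default_config(seed=9)
        assert synth.simulate_interactome(cfg) == synth.simulate_interactome(cfg)


class TestCohortFixture:
    def test_shape_and_patients(self):
        table = synth.fixture_table1()
        assert len(table) == 10
        assert table["patient_id"].nunique() == 9  # one bilateral patient

    def test_first_case_row(self):
        row = synth.fixture_table1().iloc[0]
        assert row["age"] == 65 and row["sex"] == "F"
        assert row["ras_status"] == "NRAS Q61R"

    def test_published_ages(self):
        ages = list(synth.fixture_table1()["age"])
        assert ages == [65, 52, 50, 41, 48, 61, 58, 53, 56, 56]
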