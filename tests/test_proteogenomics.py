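"""Interactome intersection, signature reduction, nodule calls, cohort stats."""

import numpy as np
import pytest

from thyromsi import identification as ident
from thyromsi import proteogenomics as pg
from thyromsi import synthetic_msi as synth
from thyromsi.errors import DataError, ParameterError
from thyromsi.msi_data import HP, NIFTP
from thyromsi.preprocess import FeatureMatrix


class TestInteractomeIntersection:
    def test_worked_example(self):
        common, _ = pg.interactome_intersection(
            {"PPIA", "ATP1A1", "X"},
            {"NRAS": {"PPIA", "ATP1A1"}, "HRAS": {"PPIA", "ATP1A1", "Y"}},
        )
        assert common == {"PPIA", "ATP1A1"}

    def test_disjoint_sets_empty(self):
        common, _ = pg.interactome_intersection({"A"}, {"NRAS": {"B"}, "HRAS": {"C"}})
        assert common == set()

    def test_single_bait_is_pairwise_intersection(self):
        common, _ = pg.interactome_intersection({"A", "B"}, {"NRAS": {"B", "C"}})
        assert common == {"B"}

    def test_venn_counts_are_exclusive_and_complete(self):
        identified = {"PPIA", "ATP1A1", "X"}
        inter = {"NRAS": {"PPIA", "ATP1A1"}, "HRAS": {"PPIA", "ATP1A1", "Y"}}
        _, venn = pg.interactome_intersection(identified, inter)
        universe = identified | inter["NRAS"] | inter["HRAS"]
        assert sum(venn.values()) == len(universe)
        assert venn["identified&NRAS&HRAS"] == 2   # PPIA, ATP1A1
        assert venn["identified"] == 1             # X
        assert venn["HRAS"] == 1                   # Y

    def test_empty_bait_set_rejected(self):
        with pytest.raises(DataError):
            pg.interactome_intersection({"A"}, {"NRAS": set()})


def match_for(mz, gene, ppm=5.0):
    pid = ident.PeptideID(
        sequence="SAMPLEK", gene=gene, protein=f"{gene}_HUMAN",
        measured_mz=mz, theoretical_mz=mz,
    )
    return ident.MatchResult(mz, [(pid, ppm)], gene)


class TestReduceSignature:
    def test_seven_peptides_collapse_to_four_genes(self):
        """The interactome fixture: 7 matched peptides over 4 common genes
        reduce to a one-signal-per-protein signature."""
        matches = [
            match_for(944.50, "BCAP31"), match_for(944.53, "BCAP31"),
            match_for(1002.40, "CANX"), match_for(1002.37, "CANX"),
            match_for(1505.83, "PPIA"),
            match_for(1584.90, "ATP1A1"), match_for(1584.95, "ATP1A1"),
        ]
        scores = {m.feature_mz: 0.9 for m in matches}
        scores[944.50] = 0.99
        sig = pg.reduce_signature(
            matches, set(synth.SIGNATURE_GENES), feature_scores=scores
        )
        assert len(sig.entries) == 4
        assert sorted(sig.genes) == sorted(synth.SIGNATURE_GENES)
        assert sig.mz_of("BCAP31") == 944.50  # the higher-AUC candidate
        assert sum(len(v) for v in sig.provenance.values()) == 7

    def test_equal_scores_tie_break_to_lower_mz(self):
        matches = [match_for(1002.40, "CANX"), match_for(1002.37, "CANX")]
        sig = pg.reduce_signature(
            matches, {"CANX"}, feature_scores={1002.40: 0.8, 1002.37: 0.8}
        )
        assert sig.mz_of("CANX") == 1002.37

    def test_lowest_ppm_rule(self):
        matches = [match_for(1002.40, "CANX", ppm=40.0),
                   match_for(1002.37, "CANX", ppm=2.0)]
        sig = pg.reduce_signature(matches, {"CANX"}, per_gene_rule="lowest_ppm")
        assert sig.mz_of("CANX") == 1002.37

    def test_empty_common_set_warns_and_returns_empty(self):
        with pytest.warns(UserWarning, match="empty"):
            sig = pg.reduce_signature(
                [match_for(1505.83, "PPIA")], set(), feature_scores={}
            )
        assert sig.entries == []

    def test_ambiguous_matches_excluded(self):
        ambiguous = ident.MatchResult(900.0, [], None)
        with pytest.warns(UserWarning, match="empty"):
            sig = pg.reduce_signature(
                [ambiguous], set(synth.SIGNATURE_GENES), feature_scores={}
            )
        assert sig.entries == []

    def test_duplicate_gene_entries_rejected(self):
        with pytest.raises(DataError):
            pg.Signature(entries=[(900.0, "PPIA"), (950.0, "PPIA")])


class TestClassifyNodules:
    def test_pixel_order_invariance(self, default_sim, feature_matrix):
        _cfg, _ds, roi, truth = default_sim
        sig = pg.Signature(
            entries=[(mz, g) for mz, g in zip(
                (944.50, 1002.40, 1505.83, 1584.90),
                ("BCAP31", "CANX", "PPIA", "ATP1A1"),
            )]
        )
        base = pg.classify_nodules(feature_matrix, sig, roi, seed=0)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(feature_matrix.pixel_index))
        shuffled = FeatureMatrix(
            feature_matrix.feature_mz,
            feature_matrix.values[perm],
            [feature_matrix.pixel_index[i] for i in perm],
        )
        again = pg.classify_nodules(shuffled, sig, roi, seed=0)
        assert {c.nodule_id: c.call for c in base} == {
            c.nodule_id: c.call for c in again
        }

    def test_seed_invariance_when_clusters_separated(self, default_sim, feature_matrix):
        _cfg, _ds, roi, truth = default_sim
        sig = pg.Signature(
            entries=[(944.50, "BCAP31"), (1002.40, "CANX"),
                     (1505.83, "PPIA"), (1584.90, "ATP1A1")]
        )
        calls = [
            {c.nodule_id: c.call
             for c in pg.classify_nodules(feature_matrix, sig, roi, seed=s)}
            for s in range(5)
        ]
        assert all(c == calls[0] for c in calls[1:])

    def test_degenerate_input_flagged_mixed(self):
        pixel_index = [(x, y) for y in range(4) for x in range(4)]
        values = np.ones((16, 1))
        fm = FeatureMatrix(np.array([1505.83]), values, pixel_index)
        labels = np.full((4, 4), NIFTP, dtype=object)
        nodules = np.repeat([1, 1, 2, 2], 4).reshape(4, 4)
        from thyromsi.msi_data import ROIMap

        roi = ROIMap(labels, nodules)
        sig = pg.Signature(entries=[(1505.83, "PPIA")])
        with pytest.warns(UserWarning, match="degenerate"):
            calls = pg.classify_nodules(fm, sig, roi)
        assert all(c.call == synth.MIXED for c in calls)

    def test_fewer_than_two_nodules_rejected(self):
        pixel_index = [(x, 0) for x in range(4)]
        fm = FeatureMatrix(np.array([1505.83]), np.ones((4, 1)), pixel_index)
        labels = np.full((1, 4), NIFTP, dtype=object)
        from thyromsi.msi_data import ROIMap

        roi = ROIMap(labels, np.ones((1, 4), dtype=int))
        sig = pg.Signature(entries=[(1505.83, "PPIA")])
        with pytest.raises(DataError, match="nodule"):
            pg.classify_nodules(fm, sig, roi)

    def test_cluster_fractions_sum_to_one(self, default_sim, feature_matrix):
        _cfg, _ds, roi, _truth = default_sim
        sig = pg.Signature(
            entries=[(944.50, "BCAP31"), (1002.40, "CANX"),
                     (1505.83, "PPIA"), (1584.90, "ATP1A1")]
        )
        for call in pg.classify_nodules(feature_matrix, sig, roi, seed=1):
            assert sum(call.cluster_fractions.values()) == pytest.approx(1.0)


class TestCohortSummary:
    def test_percentages_recomputed_from_counts(self):
        table = synth.fixture_table1()
        summary = pg.cohort_summary(table)
        assert summary["n_patients"] == 9 and summary["n_nodules"] == 10
        assert summary["percent_female"] == round(100 * 7 / 9)
        assert summary["percent_ras_mutant"] == round(100 * 6 / 10)

    def test_single_patient_sd_is_missing(self):
        single = synth.fixture_table1().iloc[[0]]
        summary = pg.cohort_summary(single)
        assert summary["sd_age"] is None

    def test_empty_table_rejected(self):
        with pytest.raises(DataError):
            pg.cohort_summary(synth.fixture_table1().iloc[0:0])
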