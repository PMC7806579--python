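"""Clustering, candidate ranking, confidence indexes and diagnostics."""

import math

import numpy as np
import pytest

from adductgraph.chem import PROTON_MASS, IonSpecies, monoisotopic_mass
from adductgraph.graph import build_graph
from adductgraph.io import Peak, Spectrum
from adductgraph.ranking import (
    CandidateRecord,
    annotate_spectrum,
    annotation_table,
    candidate_table,
    cluster_indexes,
    clusters,
    explain,
    heterodimer_scan,
    rank_candidates,
    singleton_table,
)


def _mini_graph(peak_defs, closure):
    spec = Spectrum([Peak(mz, i) for mz, i in peak_defs])
    return spec, build_graph(spec, closure)


class TestClusters:
    def test_edgeless_graph_gives_all_singletons(self, default_closure):
        spec, g = _mini_graph(
            [(100.0, 1.0), (205.0, 1.0), (310.0, 1.0), (415.0, 1.0), (520.0, 1.0)],
            default_closure,
        )
        parts = clusters(g)
        assert len(parts) == 5 and all(c.is_singleton for c in parts)

    def test_chained_relations_give_one_cluster(self, default_closure):
        M = 115.0633
        labels = ["[M+H]+", "[M+Na]+", "[M+K]+", "[2M+H]+"]
        spec, g = _mini_graph(
            [(IonSpecies.parse_label(l).ion_mz(M), 10.0) for l in labels],
            default_closure,
        )
        parts = clusters(g)
        assert len(parts) == 1 and len(parts[0]) == 4

    def test_cluster_ids_ordered_by_minimum_mz(self, lc_fixture_result):
        _, _, res = lc_fixture_result
        mins = [c.member_peaks[0].mz for c in res.clusters]
        assert mins == sorted(mins)
        assert [c.cluster_id for c in res.clusters] == list(range(len(res.clusters)))


class TestExplain:
    def test_proline_mini_example_connectivity(self, default_closure):
        spec, g = _mini_graph(
            [(116.0706, 1000.0), (154.0265, 300.0), (231.1339, 100.0)],
            default_closure,
        )
        (cluster,) = clusters(g)
        p116, p154, p231 = cluster.member_peaks
        tic, conn = explain(p116, cluster, g)
        assert conn == 2 and tic == pytest.approx(1400.0)
        tic231, conn231 = explain(p231, cluster, g)
        assert conn231 == 0 and tic231 == pytest.approx(100.0)

    def test_node_outside_cluster_rejected(self, default_closure):
        spec, g = _mini_graph([(100.0, 1.0), (300.0, 1.0)], default_closure)
        a, b = clusters(g)
        with pytest.raises(ValueError):
            explain(b.member_peaks[0], a, g)

    def test_identical_explained_sets_give_identical_tic(self, default_closure):
        # an ambiguous +-NH3 2-peak cluster explains the same set from both ends
        spec, g = _mini_graph([(173.0922, 500.0), (190.1187, 700.0)], default_closure)
        (cluster,) = clusters(g)
        a, b = cluster.member_peaks
        assert explain(a, cluster, g)[0] == explain(b, cluster, g)[0]


class TestRankCandidates:
    def test_two_peak_cluster_selects_protonated_form(self, default_closure):
        M = 180.0634
        spec, g = _mini_graph(
            [
                (IonSpecies.parse_label("[M+H]+").ion_mz(M), 100.0),
                (IonSpecies.parse_label("[M+Na]+").ion_mz(M), 900.0),
            ],
            default_closure,
        )
        (cluster,) = clusters(g)
        rec = rank_candidates(cluster, g)
        assert rec.candidate_mz == pytest.approx(M + PROTON_MASS, abs=1e-6)

    def test_singleton_cluster_is_not_ranked(self, default_closure):
        spec, g = _mini_graph([(100.0, 1.0), (300.0, 1.0)], default_closure)
        with pytest.raises(ValueError, match="singleton"):
            rank_candidates(clusters(g)[0], g)

    def test_candidate_explained_tic_is_maximal_in_cluster(self, fia_fixture_result):
        _, g, res = fia_fixture_result
        for rec in res.candidates:
            best_tic = rec.explained_tic
            for p in rec.cluster.member_peaks:
                assert explain(p, rec.cluster, g)[0] <= best_tic + 1e-9

    def test_synthetic_truth_recovered(self, default_closure):
        from adductgraph.filters import clean
        from adductgraph.simulate import random_mixture, simulate_spectrum

        cfg = random_mixture(42, n_compounds=3)
        spec, truth = simulate_spectrum(cfg)
        cleaned = clean(spec)
        res = annotate_spectrum(cleaned, build_graph(cleaned, default_closure))
        true_mh = sorted(
            p.mz for p, asg in truth.items() if any(l == "[M+H]+" for _, l in asg)
        )
        assert sorted(r.candidate_mz for r in res.candidates) == pytest.approx(true_mh)


class TestClusterIndexes:
    def test_thirteen_of_thirtythree_gives_ccc_39(self, fia_fixture_result):
        spec, _, res = fia_fixture_result
        big = max(res.clusters, key=len)
        cgc, cic, ccc = cluster_indexes(big, spec)
        assert cgc == 13
        assert round(ccc) == 39

    def test_whole_spectrum_cluster_covers_everything(self, default_closure):
        M = 115.0633
        labels = ["[M+H]+", "[M+Na]+", "[M+K]+"]
        spec, g = _mini_graph(
            [(IonSpecies.parse_label(l).ion_mz(M), 10.0) for l in labels],
            default_closure,
        )
        (cluster,) = clusters(g)
        _, cic, ccc = cluster_indexes(cluster, spec)
        assert cic == pytest.approx(100.0) and ccc == pytest.approx(100.0)

    def test_indexes_sum_to_100_over_all_clusters(self, lc_fixture_result):
        spec, _, res = lc_fixture_result
        cics, cccs = [], []
        for c in res.clusters:
            _, cic, ccc = cluster_indexes(c, spec)
            cics.append(cic)
            cccs.append(ccc)
        assert sum(cics) == pytest.approx(100.0)
        assert sum(cccs) == pytest.approx(100.0)

    def test_zero_tic_spectrum_rejected(self, default_closure):
        spec, g = _mini_graph([(100.0, 0.0), (300.0, 0.0)], default_closure)
        with pytest.raises(ValueError):
            cluster_indexes(clusters(g)[0], spec)


class TestTables:
    def test_lc_fixture_candidate_table_has_three_ranked_rows(self, lc_fixture_result):
        _, _, res = lc_fixture_result
        table = candidate_table([res])
        assert len(table) == 3
        assert set(table.columns) >= {
            "candidate_mz", "cgc", "cic_percent", "ccc_percent", "cluster_members",
        }
        assert len(singleton_table([res])) == 1

    def test_empty_batch_gives_empty_tables(self):
        assert candidate_table([]).empty
        assert annotation_table([]).empty
        assert singleton_table([]).empty

    def test_annotation_table_reports_signed_mmu(self, lc_fixture_result):
        _, _, res = lc_fixture_result
        table = annotation_table([res])
        row = table[
            (table.parent_mz == 116.0706) & (table.child_mz == 176.0100)
        ].iloc[0]
        assert row.label == "[M+Na+K-H]+"
        assert row.mass_error_mmu == pytest.approx(1.6, abs=0.1)


class TestHeterodimerScan:
    def _cand(self, mz):
        return CandidateRecord(
            candidate_mz=mz, explained_tic=0.0, connectivity=0, cgc=2,
            cic=0.0, ccc=0.0, cluster_id=0,
        )

    def test_creatinine_proline_dimer_flagged(self):
        mh_creatinine = monoisotopic_mass("C4H7N3O") + PROTON_MASS
        mh_proline = monoisotopic_mass("C5H9NO2") + PROTON_MASS
        spec = Spectrum(
            [Peak(mh_creatinine, 100.0), Peak(mh_proline, 100.0), Peak(229.1295, 5.0)]
        )
        flags = heterodimer_scan(
            spec, [self._cand(mh_creatinine), self._cand(mh_proline)], tol=0.010
        )
        assert len(flags) == 1
        assert flags[0].peak_mz == pytest.approx(229.1295)

    def test_creatine_homocitrulline_dimer_flagged(self):
        mh_creatine = monoisotopic_mass("C4H9N3O2") + PROTON_MASS
        mh_homocitrulline = monoisotopic_mass("C7H15N3O3") + PROTON_MASS
        spec = Spectrum(
            [Peak(mh_creatine, 50.0), Peak(mh_homocitrulline, 50.0), Peak(321.1881, 2.0)]
        )
        flags = heterodimer_scan(
            spec, [self._cand(mh_creatine), self._cand(mh_homocitrulline)], tol=0.010
        )
        assert [round(f.peak_mz, 4) for f in flags] == [321.1881]

    def test_no_candidate_pairs_gives_empty(self):
        spec = Spectrum([Peak(229.1295, 5.0)])
        assert heterodimer_scan(spec, [self._cand(116.0706)], tol=0.010) == []


class TestDocumentedFailureMode:
    def test_water_loss_twin_is_misread_as_fragment(self, default_closure):
        """A compound pair differing by exactly 18.0106 Da collapses into one
        cluster and the lighter [M+H]+ is annotated as a water loss — the
        documented wrong answer that only chromatography can fix."""
        m_creatine = monoisotopic_mass("C4H9N3O2")
        m_creatinine = monoisotopic_mass("C4H7N3O")
        assert m_creatine - m_creatinine == pytest.approx(18.0106, abs=5e-5)
        peaks = [
            (m_creatine + PROTON_MASS, 150000.0),
            (IonSpecies.parse_label("[M+K]+").ion_mz(m_creatine), 50000.0),
            (m_creatinine + PROTON_MASS, 90000.0),
            (IonSpecies.parse_label("[M+K]+").ion_mz(m_creatinine), 30000.0),
        ]
        spec, g = _mini_graph(peaks, default_closure)
        res = annotate_spectrum(spec, g)
        assert len(res.candidates) == 1  # both compounds in one cluster
        rec = res.candidates[0]
        assert rec.candidate_mz == pytest.approx(m_creatine + PROTON_MASS, abs=1e-6)
        table = annotation_table([res])
        misread = table[
            (table.parent_mz == round(m_creatine + PROTON_MASS, 4))
            & (table.child_mz == round(m_creatinine + PROTON_MASS, 4))
        ]
        assert list(misread.label) == ["[M+H-H2O]+"]
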