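"""Cohort annotation, joint clustering and group association."""

import numpy as np
import pandas as pd
import pytest

from tcrepspec.cohort import (
    Repertoire,
    annotate_cohort,
    group_cluster_association,
    joint_cluster_annotate,
    lookup_specific,
    specific_frequency,
)
from tcrepspec.epitope_db import build_epitope_db

from conftest import make_clonotype


@pytest.fixture
def small_db():
    run = [make_clonotype("CASSLGQGAEAFF", count=10),
           make_clonotype("CASSIRSTDTQYF", count=8)]
    return build_epitope_db([("HD1", "EPI-A", run)])


def _rep(ind, group, seqs):
    return Repertoire(ind, group, [make_clonotype(s, donor=ind) for s in seqs])


class TestLookup:
    def test_exact_match_found(self, small_db):
        rep = _rep("P1", "healthy", ["CASSLGQGAEAFF", "CWWWWWF"])
        hits = lookup_specific(rep, small_db, "EPI-A")
        assert [h.cdr3_aa for h in hits] == ["CASSLGQGAEAFF"]

    def test_one_mismatch_neighbour_not_found(self, small_db):
        rep = _rep("P1", "healthy", ["CASSLGQGAEAYF"])
        assert lookup_specific(rep, small_db, "EPI-A") == []

    def test_disjoint_repertoire_no_matches(self, small_db):
        rep = _rep("P1", "healthy", ["CWWWWWF", "CYYYYYF"])
        assert lookup_specific(rep, small_db, "EPI-A") == []


class TestRepertoireMerging:
    def test_multiple_samples_single_repertoire(self):
        s1 = [make_clonotype("CASSF", count=3), make_clonotype("CATSF", count=1)]
        s2 = [make_clonotype("CASSF", count=2), make_clonotype("CAWSF", count=1)]
        rep = Repertoire.from_samples("P1", "relapse", [s1, s2])
        assert rep.size == 3
        merged = {c.cdr3_aa: c.read_count for c in rep.clonotypes}
        assert merged["CASSF"] == 5  # counts summed across samples

    def test_size_counts_unique_cdr3s(self):
        s = [make_clonotype("CASSF", v="TRBV19"), make_clonotype("CASSF", v="TRBV28")]
        assert Repertoire.from_samples("P1", "healthy", [s]).size == 1


class TestAnnotate:
    def test_frequency_formula(self):
        assert specific_frequency(2, 931) == 0.215
        assert specific_frequency(0, 500) == 0.0
        with pytest.raises(ValueError):
            specific_frequency(1, 0)

    def test_lookup_only_counts_and_consistency(self, small_db):
        reps = [_rep("P1", "healthy", ["CASSLGQGAEAFF"] + [f"CA{a}AAF" for a in "GLTV"]),
                _rep("P2", "relapse", ["CWWWWWF"])]
        summary, identified = annotate_cohort(reps, small_db)
        s = summary.set_index("individual_id")
        assert s.loc["P1", "n_specific_EPI-A"] == 1
        assert s.loc["P1", "freq_specific_EPI-A"] == specific_frequency(1, 5)
        assert s.loc["P2", "n_specific_EPI-A"] == 0
        assert identified["EPI-A"]["P1"] == {"CASSLGQGAEAFF"}

    def test_union_rule_with_model(self, small_db):
        class FakeModel:
            epitope = "EPI-A"

            def predict_bpr(self, clonotypes, threshold=None):
                seqs = [c.cdr3_aa for c in clonotypes]
                return pd.DataFrame({
                    "cdr3_aa": seqs, "epitope": "EPI-A",
                    "score": 1.0, "bpr": 0.0,
                    "passes": [s.startswith("CASS") for s in seqs],
                })

        rep = _rep("P1", "complete remission",
                   ["CASSLGQGAEAFF", "CASSUNSEENF".replace("U", "V"), "CAAAAF"])
        summary, identified = annotate_cohort([rep], small_db, [FakeModel()])
        # union of look-up (1) and prediction (2, overlapping) = 2
        assert summary.loc[0, "n_specific_EPI-A"] == 2
        assert len(identified["EPI-A"]["P1"]) >= 1

    def test_unknown_group_warned_and_retained(self, small_db):
        rep = _rep("P1", "mystery", ["CAAAAF"])
        with pytest.warns(UserWarning, match="mystery"):
            summary, _ = annotate_cohort([rep], small_db)
        assert summary.loc[0, "group"] == "mystery"


class TestJointClustering:
    def test_planted_cluster_families_recovered(self, small_db):
        # two specific families (seed + 1-mut variants) and isolated noise
        fam_a = ["CASSLGQGAEAFF", "CASSLGQGAEAYF", "CASSLGQGAEAWF"]
        fam_b = ["CASSIRSTDTQYF", "CASSIRSTDTQYY".replace("YY", "AF")]
        reps = [
            _rep("P1", "complete remission", fam_a[:2] + ["CWWWWWWWWF"]),
            _rep("P2", "relapse", fam_a[2:] + fam_b + ["CYYYYYYYYF"]),
        ]
        identified = {"EPI-A": {"P1": {fam_a[0]}, "P2": {fam_b[0]}}}
        cg, table, dots = joint_cluster_annotate(reps, identified)
        assert len(table) == 2  # exactly the two planted families
        by_id = table.set_index("cluster_id")
        assert by_id.loc[min(fam_a), "size"] == 3
        # row sums over groups equal cluster size (no cross-group sharing here)
        groups = ["n_complete remission", "n_relapse"]
        assert (by_id[groups].sum(axis=1) == by_id["size"]).all()
        assert set(dots.columns) == {"cluster_id", "individual_id", "count", "group"}

    def test_identical_repertoires_pool_to_same_clusters(self):
        seqs = ["CASSF", "CASTF", "CAAAF"]
        reps = [_rep("P1", "healthy", seqs), _rep("P2", "relapse", seqs)]
        identified = {"E": {"P1": {"CASSF"}}}
        cg, table, _ = joint_cluster_annotate(reps, identified)
        assert cg.n_nodes == 3 and len(table) == 1

    def test_union_identified_at_least_lookup(self, small_db):
        # union rule at the summary level: adding a model can only grow counts
        rep = _rep("P1", "healthy", ["CASSLGQGAEAFF", "CAAAAF"])
        base, _ = annotate_cohort([rep], small_db)

        class PassNothing:
            epitope = "EPI-A"

            def predict_bpr(self, clonotypes, threshold=None):
                return pd.DataFrame({"cdr3_aa": [c.cdr3_aa for c in clonotypes],
                                     "epitope": "EPI-A", "score": 0.0,
                                     "bpr": 1.0, "passes": False})

        with_model, _ = annotate_cohort([rep], small_db, [PassNothing()])
        assert (with_model["n_specific_EPI-A"] >= base["n_specific_EPI-A"]).all()


class TestAssociation:
    def _table(self, rem, rel):
        return pd.DataFrame({
            "cluster_id": [f"c{i}" for i in range(len(rem))],
            "size": np.asarray(rem) + np.asarray(rel),
            "n_complete remission": rem,
            "n_relapse": rel,
        })

    def test_uniform_two_by_two_is_null(self):
        stat, dof, p, _ = group_cluster_association(self._table([10, 10], [10, 10]))
        assert stat == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_perfect_separation_hand_computed(self):
        # Pearson statistic for [[20,0],[0,20]]: all expected 10 -> 4*10 = 40
        stat, dof, p, _ = group_cluster_association(self._table([20, 0], [0, 20]))
        assert stat == pytest.approx(40.0) and dof == 1

    def test_published_composition_rows_reproduce_reported_p(self):
        # member counts of the seven annotated clusters, remission vs relapse
        stat, dof, p, _ = group_cluster_association(
            self._table([4, 4, 3, 6, 4, 1, 2], [13, 0, 0, 0, 2, 0, 1]))
        assert dof == 6
        assert stat == pytest.approx(18.9216, abs=1e-3)
        assert p == pytest.approx(0.0043, abs=5e-5)

    def test_zero_total_group_rejected(self):
        with pytest.raises(ValueError):
            group_cluster_association(self._table([5, 5], [0, 0]))

    def test_missing_group_column_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            group_cluster_association(
                self._table([1, 2], [3, 4]), groups=("healthy", "nope"))
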