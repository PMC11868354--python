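"""Database construction: disambiguation, dedup, publicity."""

import numpy as np
import pytest

from tcrepspec.epitope_db import (
    build_epitope_db,
    dedup_cdr3,
    disambiguate_cross_epitope,
    publicity,
)
from conftest import make_clonotype


class TestDisambiguation:
    @pytest.mark.parametrize("counts,expected", [
        ({"EPI-A": 500, "CTRL": 3}, "EPI-A"),      # ratio 166.7
        ({"EPI-A": 1000, "EPI-B": 10}, "EPI-A"),   # ratio exactly 100 assigns
        ({"EPI-A": 120, "EPI-B": 119}, None),      # ratio < 100 removes
        ({"EPI-A": 7, "EPI-B": 7}, None),          # tie -> ratio 1 -> remove
    ])
    def test_ratio_rule(self, counts, expected):
        assert disambiguate_cross_epitope(counts) == expected

    def test_three_epitopes_use_top_two_only(self):
        # top two decide; the third is ignored
        assert disambiguate_cross_epitope(
            {"A": 1000, "B": 10, "C": 1}) == "A"
        assert disambiguate_cross_epitope(
            {"A": 1000, "B": 11, "C": 1}) is None

    def test_single_epitope_is_a_caller_bypass(self):
        with pytest.raises(ValueError):
            disambiguate_cross_epitope({"A": 5})


class TestDedup:
    def test_highest_count_vj_retained(self):
        a = make_clonotype("CASSF", v="TRBV19", count=40)
        b = make_clonotype("CASSF", v="TRBV28", count=7)
        assert dedup_cdr3([b, a]) == [a]

    def test_single_record_identity(self):
        a = make_clonotype("CASSF")
        assert dedup_cdr3([a]) == [a]

    def test_tie_breaks_lexicographically(self):
        a = make_clonotype("CASSF", v="TRBV28", j="TRBJ1-1", count=5)
        b = make_clonotype("CASSF", v="TRBV19", j="TRBJ2-7", count=5)
        assert dedup_cdr3([a, b]) == [b]
        assert dedup_cdr3([b, a]) == [b]

    def test_preserves_unique_cdr3_set(self, rng):
        records = [
            make_clonotype(f"CASS{c1}{c2}F", v=f"TRBV{rng.integers(1, 30)}",
                           count=int(rng.integers(1, 50)))
            for c1 in "ASGL" for c2 in "ASGL" for _ in range(3)
        ]
        out = dedup_cdr3(records)
        assert {r.cdr3_aa for r in out} == {r.cdr3_aa for r in records}
        assert len(out) == len({r.cdr3_aa for r in records})


class TestBuild:
    def test_single_clean_run_is_dedup_of_run(self):
        run = [make_clonotype("CASSF", count=3), make_clonotype("CATSF", count=1)]
        db = build_epitope_db([("HD1", "EPI-A", run)])
        assert db.epitopes == ["EPI-A"]
        assert db.unique_cdr3s("EPI-A") == {"CASSF", "CATSF"}

    def test_promiscuous_clone_at_ratio_2_removed(self):
        runs = [
            ("HD1", "EPI-A", [make_clonotype("CASSF", count=200)]),
            ("HD1", "EPI-B", [make_clonotype("CASSF", count=100)]),
        ]
        db = build_epitope_db(runs)
        assert "CASSF" not in db.unique_cdr3s("EPI-A")
        assert "CASSF" not in db.unique_cdr3s("EPI-B")

    def test_control_epitope_disambiguates_but_is_excluded(self):
        runs = [
            ("HD1", "EPI-A", [make_clonotype("CASSF", count=50)]),
            ("HD1", "CTRL", [make_clonotype("CASSF", count=49),
                             make_clonotype("CATSF", count=9)]),
        ]
        db = build_epitope_db(runs, control_epitopes=["CTRL"])
        # ratio 50/49 < 100: removed from EPI-A even though rival is a control
        assert db.unique_cdr3s("EPI-A") == set()
        assert "CTRL" not in db.epitopes

    def test_replicate_runs_merge_with_summed_counts(self):
        runs = [
            ("HD1", "EPI-A", [make_clonotype("CASSF", count=60)]),
            ("HD1", "EPI-A", [make_clonotype("CASSF", count=40)]),
            ("HD1", "EPI-B", [make_clonotype("CASSF", count=1)]),
        ]
        db = build_epitope_db(runs)
        # 60+40 = 100 vs 1: ratio 100 assigns to EPI-A with the summed count
        (entry,) = db.entries["EPI-A"]
        assert entry.read_count == 100

    def test_no_cdr3_assigned_to_two_epitopes(self, rng):
        runs = []
        for d in range(4):
            for e in ("EPI-A", "EPI-B"):
                clones = [
                    make_clonotype(f"CAS{c}{d2}F", donor=f"HD{d}",
                                   count=int(rng.integers(1, 500)))
                    for c in "ASGLT" for d2 in "ASG"
                ]
                runs.append((f"HD{d}", e, clones))
        db = build_epitope_db(runs)
        seen = {}
        for e in db.epitopes:
            for cdr3 in db.unique_cdr3s(e):
                assert cdr3 not in seen, f"{cdr3} under {seen.get(cdr3)} and {e}"
                seen[cdr3] = e


class TestPublicity:
    def test_disjoint_donors_no_public(self):
        runs = [("HD1", "E", [make_clonotype("CASSF", donor="HD1")]),
                ("HD2", "E", [make_clonotype("CATSF", donor="HD2")])]
        db = build_epitope_db(runs)
        table, hist = publicity(db, "E")
        assert table.public.sum() == 0 and hist == {}

    def test_planted_three_of_five_donors_in_bin_three(self):
        runs = []
        for i in range(5):
            clones = [make_clonotype(f"CA{'ASGLT'[i]}AAF", donor=f"HD{i}")]
            if i < 3:
                clones.append(make_clonotype("CASSSHAREDF", donor=f"HD{i}"))
            runs.append((f"HD{i}", "E", clones))
        db = build_epitope_db(runs)
        _, hist = publicity(db, "E")
        assert hist == {3: 1}

    def test_publicity_on_cdr3_identity_only(self):
        # same CDR3, different V genes in two donors: still public
        runs = [("HD1", "E", [make_clonotype("CASSF", v="TRBV19", donor="HD1")]),
                ("HD2", "E", [make_clonotype("CASSF", v="TRBV28", donor="HD2")])]
        db = build_epitope_db(runs)
        table, _ = publicity(db, "E")
        assert list(table.n_donors) == [2]

    def test_sharing_probability_recovered(self, rng):
        """Public fraction matches the planted sharing rate within binomial error."""
        p_share, n_clones, n_donors = 0.2, 1500, 6
        alphabet = "ACDEFGHIKLMNPQRSTVWY"
        runs = {f"HD{i}": [] for i in range(n_donors)}
        for k in range(n_clones):
            seq = "C" + "".join(rng.choice(list(alphabet), size=10)) + f"F"
            d = int(rng.integers(n_donors))
            runs[f"HD{d}"].append(make_clonotype(seq, donor=f"HD{d}"))
            if rng.random() < p_share:
                other = int((d + 1 + rng.integers(n_donors - 1)) % n_donors)
                runs[f"HD{other}"].append(make_clonotype(seq, donor=f"HD{other}"))
        db = build_epitope_db([(d, "E", cl) for d, cl in runs.items()])
        table, _ = publicity(db, "E")
        frac = table.public.mean()
        se = np.sqrt(p_share * (1 - p_share) / n_clones)
        assert abs(frac - p_share) < 4 * se
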