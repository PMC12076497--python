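"""Task construction filters, support draws, and the paired benchmark."""

import numpy as np
import pandas as pd
import pytest

from fewshotmol import metrics as M
from fewshotmol import taskbench as tb
from fewshotmol.exceptions import (
    InsufficientTask,
    NoTasksSurvive,
    OneClassSupport,
)


def make_group(gid, n_act, n_inact, source_size=100, start=0):
    """Distinct valid alkane/alcohol SMILES per record."""
    recs = []
    for i in range(n_act):
        recs.append(
            tb.AssayRecord("C" * (i + start + 1), gid, 1, source_size)
        )
    for i in range(n_inact):
        recs.append(
            tb.AssayRecord("C" * (i + 1) + "O", gid, 0, source_size)
        )
    return recs


class TestBuildTaskDB:
    def test_filters_a_and_d_on_toy_table(self):
        records = (
            make_group("G1", 60, 60)  # survives
            + make_group("G2", 60, 10)  # fails d (too few inactives)
            + make_group("G3", 60, 60, source_size=150_000)  # fails a
        )
        db = tb.build_taskdb(records, mode="by_target")
        assert set(db.tasks) == {"G1"}
        assert db.provenance["removed_hts"] == 120
        assert db.provenance["removed_small_tasks"] == 1

    def test_conflicting_labels_removed(self):
        records = make_group("G1", 60, 60)
        # molecule "C" already present with label 1; add a contradicting record
        records.append(tb.AssayRecord("C", "G1", 0, 100))
        db = tb.build_taskdb(records, mode="by_target")
        mols, y = db.tasks["G1"]
        assert "C" not in mols
        # 121 records minus the two conflicting ones for molecule "C"
        assert len(y) == 119
        assert db.provenance["removed_conflict"] == 2

    def test_by_assay_min_counts_boundary(self):
        ok = make_group("A1", 30, 30)
        db = tb.build_taskdb(ok, mode="by_assay")
        assert set(db.tasks) == {"A1"}
        short = make_group("A2", 29, 30)
        with pytest.raises(NoTasksSurvive):
            tb.build_taskdb(short, mode="by_assay")

    def test_invalid_smiles_filter_runs_before_size_filter(self):
        """A task at exactly the class minimum drops out when one of its
        actives fails SMILES parsing — so filter c precedes filter d."""
        records = make_group("G1", 49, 50)
        records.append(tb.AssayRecord("C1=CC", "G1", 1, 100))  # invalid 50th active
        with pytest.raises(NoTasksSurvive):
            tb.build_taskdb(records, mode="by_target")
        # same table with a valid 50th active survives
        records[-1] = tb.AssayRecord("CC(C)CC(C)C", "G1", 1, 100)
        db = tb.build_taskdb(records, mode="by_target")
        assert set(db.tasks) == {"G1"}

    def test_molecules_canonicalized_and_deduplicated(self):
        records = make_group("G1", 50, 50)
        # non-canonical duplicate of an existing active, same label
        records.append(tb.AssayRecord("C(C)C", "G1", 1, 100))  # canonical CCC
        db = tb.build_taskdb(records, mode="by_target")
        mols, y = db.tasks["G1"]
        assert len(mols) == len(set(mols)) == 100


class TestDrawSupport:
    @pytest.fixture()
    def db(self):
        return tb.build_taskdb(make_group("G1", 60, 60), mode="by_target")

    @pytest.mark.parametrize(
        "size,ratio,expected",
        [
            (8, "1:7", (1, 7)),
            (8, "1:3", (2, 6)),
            (8, "1:1", (4, 4)),
            (16, "1:7", (2, 14)),
            (16, "1:3", (4, 12)),
            (16, "1:1", (8, 8)),
        ],
    )
    def test_exact_compositions(self, db, size, ratio, expected):
        draw = tb.draw_support(db, "G1", size, ratio, 0, seed=1)
        n_act = int(draw.support_labels.sum())
        assert (n_act, len(draw.support_labels) - n_act) == expected

    def test_query_set_is_full_remainder(self, db):
        draw = tb.draw_support(db, "G1", 8, "1:1", 0, seed=1)
        assert int(draw.query_labels.sum()) == 56
        assert len(draw.query_labels) == 112
        assert set(draw.support_smiles) & set(draw.query_smiles) == set()

    def test_deterministic_in_all_keys(self, db):
        a = tb.draw_support(db, "G1", 8, "1:7", 2, seed=9)
        b = tb.draw_support(db, "G1", 8, "1:7", 2, seed=9)
        assert a.support_smiles == b.support_smiles
        c = tb.draw_support(db, "G1", 8, "1:7", 1, seed=9)
        assert a.support_smiles != c.support_smiles

    def test_insufficient_task_raises(self):
        db = tb.build_taskdb(
            make_group("G1", 30, 30), mode="by_assay"
        )
        with pytest.raises(InsufficientTask):
            tb.draw_support(db, "G1", 64, "1:1", 0, seed=0)


class TestRFBaseline:
    def test_separable_support_scores_high(self, rng):
        sX = np.vstack([np.ones((4, 8)), np.zeros((4, 8))])
        sy = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        qX = np.vstack([np.ones((50, 8)), np.zeros((50, 8))])
        scores = tb.rf_baseline(sX, sy, qX, seed=0)
        qy = np.r_[np.ones(50), np.zeros(50)]
        assert M.auc(scores, qy) == 1.0
        assert scores[0] > 0.5

    def test_deterministic_given_seed(self, rng):
        sX = rng.normal(size=(8, 5))
        sy = np.array([1, 0, 1, 0, 1, 0, 1, 0])
        qX = rng.normal(size=(20, 5))
        np.testing.assert_array_equal(
            tb.rf_baseline(sX, sy, qX, seed=3), tb.rf_baseline(sX, sy, qX, seed=3)
        )

    def test_one_class_support_rejected(self, rng):
        with pytest.raises(OneClassSupport):
            tb.rf_baseline(rng.normal(size=(4, 3)), np.ones(4), rng.normal(size=(2, 3)))


class _IdentityFeaturizer:
    """Maps a SMILES 'C'*k (or with O/N suffix) to a tiny numeric vector."""

    def transform(self, smiles):
        rng = np.random.default_rng(abs(hash(smiles)) % 2**31)
        return rng.normal(size=8)


def _random_method(seed_offset=0):
    def method(sup_X, sup_y, qry_X, cell_seed):
        rng = np.random.default_rng(cell_seed + seed_offset)
        return rng.random(len(qry_X))

    return method


@pytest.fixture(scope="module")
def eval_db():
    records = []
    for g in range(6):
        records += make_group(f"G{g}", 20, 20, start=g)  # overlapping is fine
    return tb.build_taskdb(
        records, mode="by_target", min_active=15, min_inactive=15
    )


class TestEvaluate:
    @pytest.fixture()
    def db(self, eval_db):
        return eval_db

    def test_row_count_full_factorial(self, db):
        results, skips = tb.evaluate(
            db,
            {"a": _random_method(0), "b": _random_method(1)},
            _IdentityFeaturizer(),
            sizes=(8,),
            seed=4,
        )
        assert not skips
        assert len(results) == 6 * 1 * 3 * 3 * 2

    def test_paired_design_identical_supports(self, db):
        seen = {}

        def recorder(name):
            def method(sup_X, sup_y, qry_X, cell_seed):
                seen[name].append((sup_X.tobytes(), sup_y.tobytes()))
                return np.linspace(0, 1, len(qry_X))

            return method

        seen = {"m1": [], "m2": []}
        tb.evaluate(
            db,
            {"m1": recorder("m1"), "m2": recorder("m2")},
            _IdentityFeaturizer(),
            sizes=(8,),
            seed=4,
        )
        assert seen["m1"] == seen["m2"]

    def test_random_scores_give_chance_level_auc(self, db):
        results, _ = tb.evaluate(
            db,
            {"rand": _random_method(0)},
            _IdentityFeaturizer(),
            sizes=(8, 16),
            seed=11,
        )
        assert len(results) >= 100
        assert abs(results["auc"].median() - 0.5) < 0.05


class TestCompare:
    def _results(self, delta, n_tasks=10):
        rows = []
        rng = np.random.default_rng(0)
        for t in range(n_tasks):
            for k in range(3):
                base = rng.uniform(0.4, 0.9)
                for method, d in (("a", delta), ("b", 0.0)):
                    rows.append(
                        {
                            "task_id": f"T{t}",
                            "draw_index": k,
                            "method": method,
                            "support_size": 8,
                            "ratio": "1:1",
                            "auc": base + d,
                        }
                    )
        return pd.DataFrame(rows)

    def test_constant_shift_detected_with_exact_p(self):
        # 8 tasks x 3 draws = 24 pairs, inside the exact-distribution regime
        res = self._results(delta=0.1, n_tasks=8)
        rep = tb.compare(res, "auc", "a", "b")
        row = rep.iloc[0]
        assert row["significant"] and row["winner"] == "a"
        assert row["p_value"] == pytest.approx(2.0 / 2**24, rel=1e-9)

    def test_identical_methods_no_star(self):
        rep = tb.compare(self._results(delta=0.0), "auc", "a", "b")
        row = rep.iloc[0]
        assert not row["significant"]
        assert row["note"] == "AllZeroDifferences"

    def test_report_row_count(self):
        rep = tb.compare(self._results(delta=0.05), ["auc"], "a", "b")
        assert len(rep) == 1  # 1 size x 1 ratio x 1 metric
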