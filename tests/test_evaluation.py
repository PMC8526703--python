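"""Split rule, accuracy, confusion matrices, error frequency, similarity."""

import math

import numpy as np
import pandas as pd
import pytest

from netimg.evaluation import (
    ConfusionCounts,
    PredictionLog,
    accuracy,
    class_similarity,
    confusion_matrix,
    error_frequency,
    make_split,
    misjudged_similarity_table,
)


def _brca_like_metadata(n_normal=113, n_tumor=1095):
    rows = [
        {"sample_id": f"BRCA_n{i}", "cancer": "BRCA", "status": "normal"}
        for i in range(n_normal)
    ] + [
        {"sample_id": f"BRCA_t{i}", "cancer": "BRCA", "status": "tumor"}
        for i in range(n_tumor)
    ]
    return pd.DataFrame(rows)


class TestMakeSplit:
    def test_three_to_one_worked_example(self):
        """113 normals -> 57 training normals -> exactly 171 training tumors."""
        train, _ = make_split(_brca_like_metadata(), seed=0)
        normals = [s for s in train if "_n" in s]
        tumors = [s for s in train if "_t" in s]
        assert len(normals) == 57
        assert len(tumors) == 171

    def test_partition_is_exact_complement(self, toy_metadata):
        train, val = make_split(toy_metadata, seed=3)
        assert set(train) & set(val) == set()
        assert set(train) | set(val) == set(toy_metadata["sample_id"])

    def test_deterministic_given_seed(self, toy_metadata):
        assert make_split(toy_metadata, seed=5) == make_split(toy_metadata, seed=5)
        assert make_split(toy_metadata, seed=5) != make_split(toy_metadata, seed=6)

    def test_per_cancer_counts_follow_rule(self, toy_metadata):
        train, _ = make_split(toy_metadata, seed=1)
        for cancer, n_norm in (("CA", 4), ("CB", 5)):
            got_norm = sum(1 for s in train if s.startswith(f"{cancer}_n"))
            got_tum = sum(1 for s in train if s.startswith(f"{cancer}_t"))
            assert got_norm == math.ceil(n_norm / 2)
            assert got_tum == 3 * got_norm

    def test_too_few_tumors_names_cancer(self):
        meta = _brca_like_metadata(n_normal=10, n_tumor=8)
        with pytest.raises(ValueError, match="BRCA"):
            make_split(meta, seed=0)


class TestAccuracy:
    def test_direct_arithmetic(self):
        counts = ConfusionCounts(matrix=pd.DataFrame(), TP=50, TN=45, FP=3, FN=2)
        assert accuracy(counts) == pytest.approx(0.95)

    def test_perfect_counts(self):
        counts = ConfusionCounts(matrix=pd.DataFrame(), TP=7, TN=5, FP=0, FN=0)
        assert accuracy(counts) == 1.0

    def test_empty_rejected(self):
        counts = ConfusionCounts(matrix=pd.DataFrame(), TP=0, TN=0, FP=0, FN=0)
        with pytest.raises(ValueError):
            accuracy(counts)

    def test_matches_match_fraction_oracle(self, rng):
        labels = ["normal", "CA", "CB"]
        truth = rng.choice(labels, 200)
        pred = rng.choice(labels, 200)
        log = PredictionLog()
        log.append(0, [f"s{i}" for i in range(200)], truth, pred)
        counts = confusion_matrix(log, 0)
        expect = np.mean((truth != "normal") == (pred != "normal"))
        assert accuracy(counts) == pytest.approx(expect)


class TestConfusionMatrix:
    def test_all_correct_is_diagonal(self):
        log = PredictionLog()
        log.append(0, ["a", "b", "c"], ["CA", "CB", "normal"], ["CA", "CB", "normal"])
        counts = confusion_matrix(log, 0)
        m = counts.matrix
        assert (m.to_numpy() == np.diag(np.diag(m.to_numpy()))).all()
        assert counts.FP == counts.FN == 0

    def test_matches_bruteforce_tally(self, rng):
        labels = ["normal", "CA", "CB"]
        truth = rng.choice(labels, 10)
        pred = rng.choice(labels, 10)
        log = PredictionLog()
        log.append("e1", [f"s{i}" for i in range(10)], truth, pred)
        m = confusion_matrix(log, "e1").matrix
        for t in labels:
            for p in labels:
                assert m.loc[t, p] == sum(
                    1 for a, b in zip(truth, pred) if a == t and b == p
                )

    def test_binary_collapse_conserves_records(self, rng):
        labels = ["normal", "CA", "CB", "CC"]
        truth = rng.choice(labels, 57)
        pred = rng.choice(labels, 57)
        log = PredictionLog()
        log.append(0, [f"s{i}" for i in range(57)], truth, pred)
        counts = confusion_matrix(log, 0)
        assert counts.total == 57
        assert counts.matrix.to_numpy().sum() == 57
        # each matrix row sums to that true class's sample count
        for t in counts.matrix.index:
            assert counts.matrix.loc[t].sum() == (truth == t).sum()

    def test_unknown_experiment_rejected(self):
        log = PredictionLog()
        log.append(0, ["a"], ["CA"], ["CA"])
        with pytest.raises(ValueError, match="no records"):
            confusion_matrix(log, "nope")


class TestErrorFrequency:
    @staticmethod
    def _log_for(sample, outcomes):
        log = PredictionLog()
        for i, wrong in enumerate(outcomes):
            log.append(i, [sample], ["LUAD"], ["LUSC" if wrong else "LUAD"])
        return log

    def test_always_wrong_is_100_percent(self):
        log = self._log_for("s", [True] * 40)
        assert error_frequency(log, "s") == (40, 40, 100.0)

    def test_never_wrong_is_zero(self):
        log = self._log_for("s", [False] * 10)
        assert error_frequency(log, "s") == (10, 0, 0.0)

    def test_never_selected_is_na(self):
        log = self._log_for("s", [True])
        assert error_frequency(log, "other") == (0, 0, None)

    def test_matches_recount_over_many_experiments(self, rng):
        log = PredictionLog()
        samples = [f"s{i}" for i in range(12)]
        expect: dict[str, list[int]] = {s: [0, 0] for s in samples}
        for e in range(50):
            chosen = rng.choice(samples, 6, replace=False)
            wrong = rng.random(6) < 0.3
            log.append(e, chosen, ["CA"] * 6, np.where(wrong, "CB", "CA"))
            for s, w in zip(chosen, wrong):
                expect[s][0] += 1
                expect[s][1] += int(w)
        for s in samples:
            sel, mis, pct = error_frequency(log, s)
            assert (sel, mis) == tuple(expect[s])
            if sel:
                assert pct == pytest.approx(100 * expect[s][1] / expect[s][0])


class TestClassSimilarity:
    def test_identical_members_give_one(self, rng):
        v = pd.Series(rng.normal(size=20), index=[f"g{i}" for i in range(20)])
        cls = pd.DataFrame({"m1": v, "m2": v, "m3": v})
        assert class_similarity(v, cls) == pytest.approx(1.0)

    def test_anticorrelated_single_member(self, rng):
        v = pd.Series(rng.normal(size=20), index=[f"g{i}" for i in range(20)])
        cls = pd.DataFrame({"m1": -v})
        assert class_similarity(v, cls) == pytest.approx(-1.0)

    def test_self_excluded_from_own_class(self, rng):
        genes = [f"g{i}" for i in range(20)]
        v = pd.Series(rng.normal(size=20), index=genes)
        other = pd.Series(rng.normal(size=20), index=genes)
        cls = pd.DataFrame({"me": v, "other": other})
        with_self = class_similarity(v, cls)
        without = class_similarity(v, cls, exclude="me")
        assert without == pytest.approx(float(np.corrcoef(v, other)[0, 1]))
        assert with_self > without  # self-correlation of 1 inflates the mean

    def test_matches_direct_covariance_formula(self, rng):
        genes = [f"g{i}" for i in range(20)]
        v = pd.Series(rng.normal(size=20), index=genes)
        cls = pd.DataFrame(
            {f"m{j}": rng.normal(size=20) for j in range(3)}, index=genes
        )
        got = class_similarity(v, cls)
        rs = []
        for j in range(3):
            y = cls[f"m{j}"].to_numpy()
            x = v.to_numpy()
            r = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
                ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
            )
            rs.append(r)
        assert got == pytest.approx(np.mean(rs))

    def test_zero_variance_member_skipped(self, rng):
        genes = [f"g{i}" for i in range(20)]
        v = pd.Series(rng.normal(size=20), index=genes)
        good = pd.Series(rng.normal(size=20), index=genes)
        cls = pd.DataFrame({"flat": np.ones(20), "good": good}, index=genes)
        got = class_similarity(v, cls)
        assert got == pytest.approx(float(np.corrcoef(v, good)[0, 1]))


def test_misjudged_similarity_table_directional(rng):
    """Misjudged samples built to resemble the wrong class fall below the diagonal."""
    genes = [f"g{i}" for i in range(30)]
    base_a = rng.normal(5, 1, 30)
    base_b = base_a + rng.normal(0, 3, 30)  # distinct class profile
    cols = {}
    meta_rows = []
    for j in range(4):
        cols[f"A{j}"] = np.maximum(base_a + rng.normal(0, 0.3, 30), 0)
        meta_rows.append({"sample_id": f"A{j}", "cancer": "CA", "status": "tumor"})
        cols[f"B{j}"] = np.maximum(base_b + rng.normal(0, 0.3, 30), 0)
        meta_rows.append({"sample_id": f"B{j}", "cancer": "CB", "status": "tumor"})
    # the misjudged sample is truly labeled CA but drawn from CB's profile
    cols["odd"] = np.maximum(base_b + rng.normal(0, 0.3, 30), 0)
    meta_rows.append({"sample_id": "odd", "cancer": "CA", "status": "tumor"})
    expr = pd.DataFrame(cols, index=genes)
    meta = pd.DataFrame(meta_rows)
    log = PredictionLog()
    log.append(0, ["odd", "A0"], ["CA", "CA"], ["CB", "CA"])
    table = misjudged_similarity_table(log, expr, meta)
    assert list(table["sample_id"]) == ["odd"]
    row = table.iloc[0]
    assert row["r_predicted"] > row["r_truth"]
    assert row["error_pct"] == 100.0
    assert bool(row["high_error"])
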