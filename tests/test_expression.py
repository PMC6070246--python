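import numpy as np
import pandas as pd
import pytest

from lncpair.expression import (
    Comparison,
    DEResult,
    ExpressionMatrix,
    format_fold_change,
    group_means,
    import_de_table,
    is_expressed,
    partition_features,
    run_de,
    write_de_table,
    de_to_frame,
    de_from_frame,
)


def make_matrix(values, groups):
    n_features, n_samples = np.asarray(values).shape
    frame = pd.DataFrame(
        values,
        index=[f"f{i}" for i in range(n_features)],
        columns=[f"s{i}" for i in range(n_samples)],
    )
    return ExpressionMatrix(frame, {f"s{i}": g for i, g in enumerate(groups)})


class TestGroupMeans:
    def test_two_sample_group_mean(self):
        m = make_matrix([[2.0, 4.0]], ["A", "A"])
        assert group_means(m).loc["f0", "A"] == 3.0

    def test_all_zero_feature(self):
        m = make_matrix([[0.0, 0.0, 0.0]], ["A", "A", "B"])
        assert (group_means(m).loc["f0"] == 0).all()

    def test_matches_per_feature_loop(self):
        rng = np.random.default_rng(7)
        values = rng.gamma(2.0, 3.0, size=(20, 6))
        groups = ["A", "A", "B", "B", "C", "C"]
        m = make_matrix(values, groups)
        means = group_means(m)
        for i in range(20):
            for g in ("A", "B", "C"):
                cols = [j for j, lbl in enumerate(groups) if lbl == g]
                expected = sum(values[i, j] for j in cols) / len(cols)
                assert means.loc[f"f{i}", g] == pytest.approx(expected)


class TestPresenceFilter:
    @pytest.mark.parametrize(
        "means,expected",
        [
            ((0.2, 0.9, 0.4), False),
            ((0.2, 1.0, 0.4), True),  # boundary counts as expressed
            ((0.0, 37.29), True),
        ],
    )
    def test_expressed_iff_some_group_mean_reaches_one(self, means, expected):
        assert is_expressed(means) is expected

    def test_empty_means_rejected(self):
        with pytest.raises(ValueError):
            is_expressed([])


class TestRunDE:
    def comparison(self):
        return Comparison("AvB", "A", "B")

    def test_identical_groups_not_significant(self):
        m = make_matrix([[5.0, 5.0, 5.0, 5.0]], ["A", "A", "B", "B"])
        (r,) = run_de(m, self.comparison())
        assert r.log2fc == 0.0
        assert not r.significant
        assert r.direction == "none"
        assert r.p_value == 1.0

    def test_swapping_groups_negates_log2fc_and_keeps_p(self):
        rng = np.random.default_rng(11)
        m = make_matrix(rng.gamma(3, 2, size=(30, 6)), ["A"] * 3 + ["B"] * 3)
        forward = run_de(m, Comparison("f", "A", "B"))
        backward = run_de(m, Comparison("b", "B", "A"))
        for f, b in zip(forward, backward):
            assert f.log2fc == pytest.approx(-b.log2fc)
            assert f.p_value == pytest.approx(b.p_value)

    def test_detection_rate_monotone_in_effect_size(self):
        rng = np.random.default_rng(5)
        rates = []
        for effect in (0.0, 1.0, 2.0, 3.0):
            hits = 0
            n_features = 200
            base = 2.0 ** rng.normal(3.5, 1.0, size=n_features)
            control = base[:, None] * 2.0 ** rng.normal(0, 0.25, (n_features, 4))
            treated = (base[:, None] * 2.0 ** (effect + rng.normal(0, 0.25, (n_features, 4))))
            values = np.hstack([control, treated])
            m = make_matrix(values, ["A"] * 4 + ["B"] * 4)
            results = run_de(m, self.comparison())
            hits = sum(r.significant for r in results)
            rates.append(hits / n_features)
        assert rates == sorted(rates)
        assert rates[-1] > 0.95

    def test_planted_strong_effect_detected_up(self):
        rng = np.random.default_rng(2)
        detected = 0
        for _ in range(40):
            base = 8.0
            control = base * 2.0 ** rng.normal(0, 0.25, 4)
            treated = base * 2.0 ** (3.0 + rng.normal(0, 0.25, 4))
            m = make_matrix([np.concatenate([control, treated])], ["A"] * 4 + ["B"] * 4)
            (r,) = run_de(m, self.comparison())
            if r.significant and r.direction == "up":
                detected += 1
        assert detected >= 38  # >= 95% of seeds

    def test_single_sample_group_rejected(self):
        m = make_matrix([[1.0, 2.0, 3.0]], ["A", "B", "B"])
        with pytest.raises(ValueError, match="'A'"):
            run_de(m, self.comparison())

    def test_nan_rejected_at_construction(self):
        with pytest.raises(ValueError, match="NaN"):
            make_matrix([[1.0, np.nan]], ["A", "B"])

    def test_bh_adjustment_is_more_conservative(self):
        rng = np.random.default_rng(9)
        values = 2.0 ** rng.normal(3, 1, size=(300, 6))
        m = make_matrix(values, ["A"] * 3 + ["B"] * 3)
        raw = sum(r.significant for r in run_de(m, self.comparison(), adjust="none"))
        adj = sum(r.significant for r in run_de(m, self.comparison(), adjust="BH"))
        assert adj <= raw


class TestImportDE:
    def write_table(self, tmp_path, rows):
        frame = pd.DataFrame(rows, columns=["feature_id", "comparison", "log2fc", "p_value"])
        path = tmp_path / "de.tsv"
        frame.to_csv(path, sep="\t", index=False)
        return str(path)

    def test_significant_up_call(self, tmp_path):
        path = self.write_table(tmp_path, [("geneX", "c1", 2.0, 0.001)])
        (r,) = import_de_table(path, alpha=0.05)
        assert r.significant and r.direction == "up"

    def test_boundary_p_is_not_significant(self, tmp_path):
        path = self.write_table(tmp_path, [("geneX", "c1", 2.0, 0.05)])
        (r,) = import_de_table(path, alpha=0.05)
        assert not r.significant

    def test_missing_column_is_schema_error(self, tmp_path):
        frame = pd.DataFrame({"feature_id": ["x"], "p_value": [0.1]})
        path = tmp_path / "bad.tsv"
        frame.to_csv(path, sep="\t", index=False)
        with pytest.raises(ValueError, match="comparison"):
            import_de_table(str(path))

    def test_round_trip_through_writer(self, tmp_path):
        path = self.write_table(
            tmp_path,
            [("a", "c1", 1.0, 0.01), ("b", "c1", -2.0, 0.2), ("c", "c1", 0.5, 0.04)],
        )
        results = import_de_table(path)
        assert len(results) == 3
        out = tmp_path / "out.tsv"
        write_de_table(results, str(out))
        # means are NaN when absent from the source, so compare the called fields
        frame_trip = de_from_frame(de_to_frame(results))
        assert [(r.feature_id, r.log2fc, r.p_value, r.significant, r.direction)
                for r in frame_trip] == [
            (r.feature_id, r.log2fc, r.p_value, r.significant, r.direction)
            for r in results
        ]
        reread = import_de_table(str(out))
        assert [(r.feature_id, r.log2fc, r.p_value, r.significant) for r in reread] == [
            (r.feature_id, r.log2fc, r.p_value, r.significant) for r in results
        ]


def de(fid, comparison, log2fc, p, alpha=0.05):
    sig = p < alpha
    direction = "none" if not sig else ("up" if log2fc > 0 else "down")
    return DEResult(fid, comparison, 1.0, 1.0, log2fc, p, None, sig, direction)


class TestPartition:
    def test_example_partition_sizes(self):
        # 10 features: 4 below threshold, 2 significant somewhere
        values = np.full((10, 4), 5.0)
        values[:4] = 0.1
        m = make_matrix(values, ["A", "A", "B", "B"])
        results = [de("f4", "c1", 2.0, 0.001), de("f5", "c2", -1.0, 0.01)]
        p = partition_features(m, results)
        assert (len(p.not_expressed), len(p.stable), len(p.differential)) == (4, 4, 2)

    def test_empty_de_results(self):
        m = make_matrix(np.full((5, 2), 3.0), ["A", "B"])
        p = partition_features(m, [])
        assert p.differential == frozenset()
        assert p.stable == frozenset(m.feature_ids)

    def test_conservation_on_random_fixture(self):
        rng = np.random.default_rng(13)
        values = 2.0 ** rng.normal(0, 2, size=(50, 6))
        m = make_matrix(values, ["A"] * 3 + ["B"] * 3)
        results = [
            de(f"f{i}", "c1", rng.normal(), float(rng.uniform()))
            for i in range(50)
        ]
        p = partition_features(m, results)
        assert p.total == 50
        union = p.not_expressed | p.stable | p.differential
        assert union == set(m.feature_ids)

    def test_unknown_feature_in_de_results_rejected(self):
        m = make_matrix(np.full((2, 2), 3.0), ["A", "B"])
        with pytest.raises(ValueError, match="ghost"):
            partition_features(m, [de("ghost", "c1", 1.0, 0.01)])


class TestFoldChangeFormat:
    def test_decrease(self):
        fc = format_fold_change(4.0, 1.0)
        assert fc.kind == "percent_decrease"
        assert fc.label == "75% decrease"

    def test_increase(self):
        fc = format_fold_change(1.0, 2.0)
        assert fc.kind == "fold_increase"
        assert fc.label == "2.00"

    def test_total_abolition_reports_100_percent(self):
        fc = format_fold_change(5.0, 0.0)
        assert fc.label == "100% decrease"

    def test_negative_mean_rejected(self):
        with pytest.raises(ValueError):
            format_fold_change(-1.0, 2.0)
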