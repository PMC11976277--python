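import numpy as np
import pandas as pd
import pytest

import lipidsat as L
from conftest import make_lipid_table, make_normalized


class TestLoad:
    def test_fixture_round_trip(self, tmp_path):
        table, truth = L.generate_lipidome(L.SimConfig(seed=5))
        paths = L.write_fixtures(table, truth, tmp_path)
        loaded = L.load_table(paths["matrix"], paths["metadata"])
        pd.testing.assert_frame_equal(loaded.amounts, table.amounts)
        assert loaded.species == table.species
        assert (loaded.samples["is_blank"] == table.samples["is_blank"]).all()

    def test_sample_without_metadata_rejected(self, tmp_path):
        (tmp_path / "m.csv").write_text("species,s1,s2\nPC(16:0_18:1),1,2\n")
        (tmp_path / "meta.csv").write_text("sample_id,group\ns1,A\n")
        with pytest.raises(ValueError, match="s2"):
            L.load_table(tmp_path / "m.csv", tmp_path / "meta.csv")

    def test_unparseable_species_named(self, tmp_path):
        (tmp_path / "m.csv").write_text("species,s1\nPC(18:?),1\n")
        (tmp_path / "meta.csv").write_text("sample_id,group\ns1,A\n")
        with pytest.raises(L.LipidParseError, match="PC\\(18:\\?\\)"):
            L.load_table(tmp_path / "m.csv", tmp_path / "meta.csv")

    def test_duplicate_species_rejected(self, tmp_path):
        (tmp_path / "m.csv").write_text(
            "species,s1\nPC(16:0_18:1),1\nPC(16:0_18:1),2\n"
        )
        (tmp_path / "meta.csv").write_text("sample_id,group\ns1,A\n")
        with pytest.raises(ValueError, match="duplicate species"):
            L.load_table(tmp_path / "m.csv", tmp_path / "meta.csv")


class TestFilter:
    def test_toy_table_verdicts_match_hand_application(self, toy_filter_table):
        table, expected = toy_filter_table
        filtered, report = L.filter_species(table, L.FilterConfig())
        for name, (retained, criterion) in expected.items():
            row = report.verdicts.loc[name]
            assert row["retained"] == retained, name
            assert row["failed_criterion"] == criterion, name
        assert report.n_retained == sum(r for r, _ in expected.values())
        assert set(filtered.amounts.index) == {
            n for n, (r, _) in expected.items() if r
        }
        # blanks are gone from the filtered table
        assert not filtered.samples["is_blank"].any()

    def test_monotone_in_thresholds(self):
        table, _ = L.generate_lipidome(L.SimConfig(seed=11, dropout_max=0.5))
        counts = []
        for overall in (0.5, 0.7, 0.9):
            for group in (0.4, 0.6, 0.8):
                for fold in (1.0, 2.0, 4.0):
                    _, rep = L.filter_species(
                        table, L.FilterConfig(overall, group, fold)
                    )
                    counts.append(((overall, group, fold), rep.n_retained))
        by_cfg = dict(counts)
        for (o, g, f), n in counts:
            for o2, g2, f2 in by_cfg:
                if o2 >= o and g2 >= g and f2 >= f:
                    assert by_cfg[(o2, g2, f2)] <= n

    def test_no_blanks_passes_vacuously_with_warning(self):
        table = make_lipid_table(
            {"PC(16:0_18:1)": [1, 1, 1, 1]},
            [("s1", "A", None, None, False), ("s2", "A", None, None, False),
             ("s3", "B", None, None, False), ("s4", "B", None, None, False)],
        )
        with pytest.warns(UserWarning, match="blank"):
            _, report = L.filter_species(table)
        assert report.n_retained == 1

    def test_requires_nonblank_samples(self):
        table = make_lipid_table(
            {"PC(16:0_18:1)": [1.0]}, [("b1", None, None, None, True)]
        )
        with pytest.raises(ValueError, match="non-blank"):
            L.filter_species(table)


class TestImpute:
    def test_group_median_fills_missing(self):
        table = make_lipid_table(
            {"PC(16:0_18:1)": [1, 2, None, 4, 7, 7, 7, 7]},
            [("A1", "A", None, None, False), ("A2", "A", None, None, False),
             ("A3", "A", None, None, False), ("A4", "A", None, None, False),
             ("B1", "B", None, None, False), ("B2", "B", None, None, False),
             ("B3", "B", None, None, False), ("B4", "B", None, None, False)],
        )
        out = L.impute_missing(table)
        assert out.amounts.loc["PC(16:0_18:1)", "A3"] == 2  # median of 1,2,4
        assert (out.amounts.loc["PC(16:0_18:1)", ["B1", "B2", "B3", "B4"]] == 7).all()

    def test_idempotent_and_identity_when_complete(self):
        table, _ = L.generate_lipidome(L.SimConfig(seed=3))
        filtered, _ = L.filter_species(table)
        once = L.impute_missing(filtered)
        twice = L.impute_missing(once)
        pd.testing.assert_frame_equal(once.amounts, twice.amounts)
        complete, _ = L.generate_lipidome(L.SimConfig(seed=3, dropout_max=0.0))
        filtered_c, _ = L.filter_species(complete)
        pd.testing.assert_frame_equal(
            L.impute_missing(filtered_c).amounts, filtered_c.amounts
        )

    def test_fully_missing_group_stays_missing_with_warning(self):
        table = make_lipid_table(
            {"PC(16:0_18:1)": [None, None, 3, 5]},
            [("A1", "A", None, None, False), ("A2", "A", None, None, False),
             ("B1", "B", None, None, False), ("B2", "B", None, None, False)],
        )
        with pytest.warns(UserWarning, match="missing"):
            out = L.impute_missing(table)
        assert out.amounts.loc["PC(16:0_18:1)", ["A1", "A2"]].isna().all()


class TestNormalize:
    def test_equal_split_within_class(self):
        table = make_lipid_table(
            {"PC(16:0_18:1)": [2.0], "PC(18:0_20:4)": [2.0], "PE(16:0_18:1)": [6.0]},
            [("s1", "A", None, None, False)],
        )
        norm = L.normalize(table, mode="per_class")
        assert norm.values.loc["PC(16:0_18:1)", "s1"] == pytest.approx(0.5)
        assert norm.values.loc["PC(18:0_20:4)", "s1"] == pytest.approx(0.5)
        assert norm.values.loc["PE(16:0_18:1)", "s1"] == pytest.approx(1.0)

    @pytest.mark.parametrize("mode", ["total", "per_class"])
    def test_proportions_sum_to_one(self, mode):
        table, _ = L.generate_lipidome(L.SimConfig(seed=8))
        imputed = L.impute_missing(L.filter_species(table)[0])
        norm = L.normalize(imputed, mode=mode)
        if mode == "total":
            sums = norm.values.sum(axis=0)
            assert np.allclose(sums, 1.0, atol=1e-9)
        else:
            for _, block in norm.values.groupby(norm.class_codes.values):
                assert np.allclose(block.sum(axis=0), 1.0, atol=1e-9)

    def test_zero_mass_sample_named(self):
        table = make_lipid_table(
            {"PC(16:0_18:1)": [0.0, 1.0]},
            [("s1", "A", None, None, False), ("s2", "A", None, None, False)],
        )
        with pytest.raises(ValueError, match="s1"):
            L.normalize(table, mode="total")

    def test_unknown_mode_rejected(self):
        table = make_lipid_table(
            {"PC(16:0_18:1)": [1.0]}, [("s1", "A", None, None, False)]
        )
        with pytest.raises(ValueError, match="mode"):
            L.normalize(table, mode="zscore")


class TestCenter:
    def test_simple_ratio(self):
        norm = make_normalized(
            {"PC(16:0_18:1)": [0.2, 0.2, 0.1]},
            [("c1", "ctrl", "I1", None, False),
             ("c2", "ctrl", "I1", None, False),
             ("t1", "case", "I1", None, False)],
        )
        centered = L.center_to_control(norm, "ctrl")
        assert centered.values.loc["PC(16:0_18:1)", "t1"] == pytest.approx(0.5)
        assert centered.values.loc["PC(16:0_18:1)", "c1"] == pytest.approx(1.0)

    def test_control_means_become_one_per_induction(self):
        table, _ = L.generate_lipidome(
            L.SimConfig(
                seed=21,
                inductions=("I1", "I2"),
                batch_shifts={"I2": 3.0},
            )
        )
        res = L.preprocess(table, center_control="control")
        centered = res.centered
        for ind, sub in centered.samples.groupby("induction"):
            ctrl = sub.index[sub["group"] == "control"]
            means = centered.values[ctrl].mean(axis=1).dropna()
            assert np.allclose(means, 1.0, atol=1e-9)

    def test_removes_multiplicative_batch_effect_exactly_when_noise_free(self):
        cfg = L.SimConfig(
            seed=4,
            noise_sigma=0.0,
            dropout_max=0.0,
            depletion=0.5,
            inductions=("I1", "I2"),
            batch_shifts={"I2": 3.0},
        )
        table, _ = L.generate_lipidome(cfg)
        res = L.preprocess(table, center_control="control")
        vals = res.centered.values
        meta = res.centered.samples
        by_induction = {}
        for ind, sub in meta.groupby("induction"):
            case = sub.index[sub["group"] == "case"]
            by_induction[ind] = vals[case].mean(axis=1)
        ratios = pd.concat(by_induction, axis=1)
        assert np.allclose(ratios["I1"], ratios["I2"], rtol=1e-9)

    def test_induction_without_control_raises(self):
        norm = L.normalize(
            make_lipid_table(
                {"PC(16:0_18:1)": [1.0, 1.0]},
                [("s1", "ctrl", "I1", None, False),
                 ("s2", "case", "I2", None, False)],
            ),
            mode="total",
        )
        with pytest.raises(ValueError, match="I2"):
            L.center_to_control(norm, "ctrl")


def test_pipeline_driver_runs_in_order():
    table, _ = L.generate_lipidome(L.SimConfig(seed=13))
    res = L.preprocess(table, mode="per_class", center_control="control")
    assert res.report.n_retained == res.filtered.amounts.shape[0]
    assert not res.imputed.amounts.isna().any().any()
    assert res.final.centered
    assert res.final is res.centered


def test_explicit_zero_class_mass_is_an_error(toy_filter_table):
    # the toy table's TAG species carries observed zeros in some samples, so
    # per-class normalization must refuse rather than divide by zero
    table, _ = toy_filter_table
    filtered, _ = L.filter_species(table)
    with pytest.raises(ValueError, match="TAG"):
        L.normalize(L.impute_missing(filtered), mode="per_class")
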