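import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from starkit.errors import ParameterError, PlateError, UndefinedStatisticError
from starkit.plate import (
    PlateDataset,
    StandardCurve,
    anova_tukey,
    build_standard_curve,
    copy_correlation,
    correct_plate,
    fold_activation,
    map_inducer_to_activity,
    read_plate_csv,
    welch_ttest,
)


def make_plate(rows):
    return PlateDataset(frame=pd.DataFrame(rows))


def well(wid, role, od, gfp, rfp=0.0, rep=1, **labels):
    return {"well": wid, "role": role, "replicate": rep, "OD600": od,
            "FL_GFP": gfp, "FL_RFP": rfp, **labels}


@pytest.fixture
def hand_plate():
    # oracle plate: blank FL=100/OD=0.04; blank cells FL/OD (corrected) = 200;
    # sample FL=1100/OD=0.54 -> FL/OD = 1000/0.5 = 2000 -> final 1800
    return make_plate([
        well("A1", "media_blank", 0.04, 100.0),
        well("A2", "blank_cells", 0.54, 200.0),
        well("A3", "sample", 0.54, 1100.0),
    ])


class TestPlateDataset:
    def test_missing_control_role(self):
        with pytest.raises(PlateError, match="media_blank"):
            make_plate([well("A1", "blank_cells", 0.5, 100.0),
                        well("A2", "sample", 0.5, 100.0)])

    def test_unknown_role(self):
        with pytest.raises(PlateError, match="unknown roles"):
            make_plate([well("A1", "media_blank", 0.04, 100.0),
                        well("A2", "blank_cells", 0.5, 100.0),
                        well("A3", "mystery", 0.5, 100.0)])

    def test_nonfinite_values(self):
        with pytest.raises(PlateError, match="finite"):
            make_plate([well("A1", "media_blank", 0.04, 100.0),
                        well("A2", "blank_cells", 0.5, np.nan)])

    def test_csv_roundtrip(self, hand_plate, tmp_path):
        path = tmp_path / "plate.csv"
        hand_plate.to_csv(path)
        back = read_plate_csv(path)
        pd.testing.assert_frame_equal(back.frame, hand_plate.frame)


class TestCorrectPlate:
    def test_hand_arithmetic_oracle(self, hand_plate):
        corrected = correct_plate(hand_plate)
        row = corrected.samples().iloc[0]
        assert row["od_corr"] == pytest.approx(0.5)
        assert row["fl_corr_GFP"] == pytest.approx(1000.0)
        assert row["flod_GFP"] == pytest.approx(2000.0)
        assert row["flod_sub_GFP"] == pytest.approx(1800.0)
        assert corrected.autofluorescence["GFP"] == pytest.approx(200.0)

    def test_sample_equal_to_blank_is_flagged(self):
        plate = make_plate([
            well("A1", "media_blank", 0.04, 100.0),
            well("A2", "blank_cells", 0.54, 200.0),
            well("A3", "sample", 0.04, 100.0),  # identical to the blank
        ])
        with pytest.warns(UserWarning, match="flagged"):
            corrected = correct_plate(plate)
        row = corrected.frame[corrected.frame["well"] == "A3"].iloc[0]
        assert row["od_corr"] == pytest.approx(0.0)
        assert row["fl_corr_GFP"] == pytest.approx(0.0)
        assert bool(row["excluded"])
        assert np.isnan(row["flod_GFP"])
        assert corrected.samples().empty

    def test_negative_subtracted_values_retained(self):
        plate = make_plate([
            well("A1", "media_blank", 0.04, 100.0),
            well("A2", "blank_cells", 0.54, 200.0),
            well("A3", "sample", 0.54, 120.0),  # dimmer than blank cells
        ])
        corrected = correct_plate(plate)
        assert corrected.samples().iloc[0]["flod_sub_GFP"] < 0

    @given(st.floats(min_value=0.1, max_value=100.0, allow_nan=False))
    @settings(max_examples=30, deadline=None)
    def test_pipeline_linearity_in_fl(self, c):
        # scaling all raw FL (blanks included) by c scales final FL/OD by c
        def build(scale):
            return make_plate([
                well("A1", "media_blank", 0.04, 100.0 * scale),
                well("A2", "blank_cells", 0.54, 200.0 * scale),
                well("A3", "sample", 0.54, 1100.0 * scale),
            ])

        base = correct_plate(build(1.0)).samples().iloc[0]["flod_sub_GFP"]
        scaled = correct_plate(build(c)).samples().iloc[0]["flod_sub_GFP"]
        assert scaled == pytest.approx(c * base, rel=1e-9)


class TestFoldActivation:
    def test_identity(self):
        assert fold_activation([3.0, 5.0], [3.0, 5.0]) == 1.0

    def test_ratio_arithmetic(self):
        on = [4500.0, 4600.0, 4570.0, 4610.0]   # mean 4570
        off = [90.0, 110.0, 95.0, 105.0]        # mean 100
        assert fold_activation(on, off) == pytest.approx(45.7)

    def test_degenerate_off(self):
        with pytest.raises(UndefinedStatisticError):
            fold_activation([1.0], [0.0, 0.0])
        with pytest.raises(UndefinedStatisticError):
            fold_activation([], [1.0])


def control_plate(levels_values, reps=4, noise=0.0, rng=None):
    rows = [well("B1", "media_blank", 0.04, 0.0), well("B2", "blank_cells", 1.04, 0.0)]
    i = 0
    for conc, value in levels_values:
        for rep in range(1, reps + 1):
            jitter = 0.0 if rng is None else rng.normal(0, noise)
            rows.append(well(f"C{i}", "sample", 1.04, value + jitter, rep=rep,
                             inducer=conc))
            i += 1
    return make_plate(rows)


class TestStandardCurve:
    LEVELS = [(0.0, 100.0), (0.1, 400.0), (0.3, 1000.0), (1.0, 2000.0)]

    def test_knots_returned_exactly(self):
        curve = build_standard_curve(control_plate(self.LEVELS))
        for conc, value in self.LEVELS:
            assert curve.query(conc) == pytest.approx(value, rel=1e-12)

    def test_midpoint_linear_interpolation(self):
        curve = build_standard_curve(control_plate(self.LEVELS))
        # hand oracle: midway between knots -> arithmetic mean of knot values
        assert curve.query(0.05) == pytest.approx((100.0 + 400.0) / 2)
        assert curve.query(0.2) == pytest.approx((400.0 + 1000.0) / 2)

    def test_too_few_levels(self):
        with pytest.raises(PlateError):
            build_standard_curve(control_plate([(0.0, 10.0), (1.0, 20.0)]))

    def test_isotonic_adjustment_warns_and_monotone(self):
        levels = [(0.0, 100.0), (0.1, 500.0), (0.3, 450.0), (1.0, 2000.0)]
        with pytest.warns(UserWarning, match="isotonic"):
            curve = build_standard_curve(control_plate(levels))
        assert np.all(np.diff(curve.values) >= 0)
        # isotonic pooling of the two violating knots: (500+450)/2 = 475
        assert curve.query(0.1) == pytest.approx(475.0)
        assert curve.query(0.3) == pytest.approx(475.0)

    def test_inverse_idempotence_at_knots(self):
        curve = build_standard_curve(control_plate(self.LEVELS))
        for conc, value in self.LEVELS:
            assert curve.inverse(curve.query(conc)) == pytest.approx(conc, abs=1e-12)

    def test_activity_normalization(self):
        curve = build_standard_curve(control_plate(self.LEVELS))
        assert map_inducer_to_activity(curve, 1.0) == pytest.approx(1.0)
        assert map_inducer_to_activity(curve, 0.0) == pytest.approx(100.0 / 2000.0)
        mid = map_inducer_to_activity(curve, 0.2)
        assert 400.0 / 2000.0 < mid < 1000.0 / 2000.0

    def test_extrapolation_refused(self):
        curve = build_standard_curve(control_plate(self.LEVELS))
        with pytest.raises(ParameterError):
            curve.query(1.5)
        with pytest.raises(ParameterError):
            curve.query(-0.1)


class TestCopyCorrelation:
    def test_perfect_line(self):
        pts = [(n, 2.0 * n + 1.0) for n in (1, 2, 4, 6, 8) for _ in range(4)]
        res = copy_correlation(pts)
        assert res["r"] == pytest.approx(1.0)
        assert res["p"] < 1e-12
        assert res["df"] == 18

    def test_constant_column_error(self):
        with pytest.raises(UndefinedStatisticError):
            copy_correlation([(2, 1.0), (2, 2.0), (2, 3.0)])
        with pytest.raises(UndefinedStatisticError):
            copy_correlation([(1, 5.0), (2, 5.0), (4, 5.0)])

    def test_too_few_levels(self):
        with pytest.raises(UndefinedStatisticError):
            copy_correlation([(1, 1.0), (2, 2.0), (1, 1.1), (2, 2.1)])

    def test_brute_force_oracle_20_points(self, rng):
        copies = np.repeat([1, 2, 4, 6, 8], 4)
        y = 3.0 * copies + rng.normal(0, 2.0, size=20)
        res = copy_correlation(list(zip(copies, y)))
        xc = copies - copies.mean()
        yc = y - y.mean()
        r_bf = (xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum())
        assert res["r"] == pytest.approx(float(r_bf), rel=1e-12)
        assert res["df"] == 18
        # two-sided t-based p oracle
        from scipy import stats as sps
        t = r_bf * np.sqrt(18 / (1 - r_bf**2))
        assert res["p"] == pytest.approx(2 * sps.t.sf(abs(t), 18), rel=1e-6)


class TestWelch:
    def test_identical_groups(self):
        res = welch_ttest([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert res["t"] == 0.0
        assert res["p"] == pytest.approx(1.0)
        assert res["df_pooled"] == 6

    def test_hand_formula_oracle(self):
        a = np.array([10.0, 12.0, 9.0, 11.0])
        b = np.array([15.0, 14.0, 16.0, 17.0])
        va, vb = a.var(ddof=1), b.var(ddof=1)
        t = (a.mean() - b.mean()) / np.sqrt(va / 4 + vb / 4)
        df = (va / 4 + vb / 4) ** 2 / ((va / 4) ** 2 / 3 + (vb / 4) ** 2 / 3)
        res = welch_ttest(a, b)
        assert res["t"] == pytest.approx(float(t), rel=1e-12)
        assert res["df"] == pytest.approx(float(df), rel=1e-12)

    def test_monotone_in_shift(self):
        a = [1.0, 1.0, 1.0, 1.0001]
        prev = 0.0
        for shift in (0.5, 1.0, 2.0):
            t = abs(welch_ttest(a, [x + shift for x in a])["t"])
            assert t > prev
            prev = t

    def test_group_size(self):
        with pytest.raises(UndefinedStatisticError):
            welch_ttest([1.0], [1.0, 2.0])


class TestAnovaTukey:
    def make_data(self, cells):
        rows = []
        for (f1, f2), values in cells.items():
            for v in values:
                rows.append({"star50": f1, "copies": f2, "y": v})
        return pd.DataFrame(rows)

    def test_identical_groups_all_nonsignificant(self):
        vals = [1.0, 2.0, 3.0]
        data = self.make_data({(a, b): vals for a in ("+", "-") for b in ("x1", "x4")})
        res = anova_tukey(data, "y", ["star50", "copies"])
        assert np.all(res["anova"]["F"].dropna() < 1e-10)
        assert np.all(res["tukey"]["p-adj"] > 0.9)

    def test_shifted_cell_flagged(self):
        data = self.make_data({
            ("+", "x1"): [1.0, 1.1, 0.9],
            ("+", "x4"): [1.0, 1.2, 0.8],
            ("-", "x1"): [1.1, 0.9, 1.0],
            ("-", "x4"): [50.0, 51.0, 49.0],
        })
        res = anova_tukey(data, "y", ["star50", "copies"])
        tk = res["tukey"]
        involving = tk[(tk["group1"] == "-:x4") | (tk["group2"] == "-:x4")]
        others = tk[(tk["group1"] != "-:x4") & (tk["group2"] != "-:x4")]
        assert np.all(involving["p-adj"] < 0.001)
        assert np.all(others["p-adj"] > 0.05)

    def test_two_by_two_sums_of_squares_oracle(self):
        # balanced 2x2, r = 3 replicates: classic hand computation
        cells = {
            ("a1", "b1"): [2.0, 3.0, 4.0],
            ("a1", "b2"): [5.0, 6.0, 7.0],
            ("a2", "b1"): [4.0, 5.0, 6.0],
            ("a2", "b2"): [9.0, 10.0, 11.0],
        }
        data = self.make_data(cells)
        y = data["y"].to_numpy()
        grand = y.mean()
        means = {k: np.mean(v) for k, v in cells.items()}
        a_means = {a: np.mean([means[(a, b)] for b in ("b1", "b2")]) for a in ("a1", "a2")}
        b_means = {b: np.mean([means[(a, b)] for a in ("a1", "a2")]) for b in ("b1", "b2")}
        r = 3
        ss_a = 2 * r * sum((m - grand) ** 2 for m in a_means.values())
        ss_b = 2 * r * sum((m - grand) ** 2 for m in b_means.values())
        ss_ab = r * sum(
            (means[(a, b)] - a_means[a] - b_means[b] + grand) ** 2
            for a in ("a1", "a2") for b in ("b1", "b2")
        )
        ss_err = sum((v - means[k]) ** 2 for k, vs in cells.items() for v in vs)
        ms_err = ss_err / (12 - 4)
        res = anova_tukey(data, "y", ["star50", "copies"])
        table = res["anova"]
        assert table.loc["C(star50)", "F"] == pytest.approx(ss_a / 1 / ms_err, rel=1e-9)
        assert table.loc["C(copies)", "F"] == pytest.approx(ss_b / 1 / ms_err, rel=1e-9)
        assert table.loc["C(star50):C(copies)", "F"] == pytest.approx(ss_ab / 1 / ms_err, rel=1e-9)

    def test_cell_with_single_replicate(self):
        data = self.make_data({("a1", "b1"): [1.0, 2.0], ("a1", "b2"): [3.0]})
        with pytest.raises(UndefinedStatisticError):
            anova_tukey(data, "y", ["star50", "copies"])
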