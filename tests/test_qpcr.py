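import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mircohort import qpcr
from mircohort.qpcr import (
    CalibrationError,
    CtMatrix,
    DataError,
    ParseError,
    assay_cv,
    detection_filter,
    global_mean_normalize,
    normfinder_stability,
    parse_ct_table,
    relative_quantity,
    standard_curve_quantify,
    write_ct_table,
)

import oracles


# ---------------------------------------------------------------- parsing


class TestParseCtTable:
    def test_long_basic(self, tmp_path):
        p = tmp_path / "ct.tsv"
        rows = ["sample_id\tassay_id\tct"]
        for s in ("s1", "s2", "s3"):
            for a, v in (("a1", 24.0), ("a2", 30.0)):
                rows.append(f"{s}\t{a}\t{v}")
        p.write_text("\n".join(rows))
        m = parse_ct_table(p, dialect="long")
        assert m.ct.shape == (2, 3)
        assert m.ct.loc["a2", "s3"] == 30.0

    def test_undetermined_becomes_missing(self, tmp_path):
        p = tmp_path / "ct.tsv"
        p.write_text(
            "sample_id\tassay_id\tct\ns1\ta1\tUndetermined\ns1\ta2\t25\n"
        )
        m = parse_ct_table(p, dialect="long")
        assert np.isnan(m.ct.loc["a1", "s1"])
        assert m.ct.loc["a2", "s1"] == 25.0

    def test_wide_long_round_trip(self, tmp_path, small_ct_matrix):
        pw, pl = tmp_path / "w.tsv", tmp_path / "l.tsv"
        write_ct_table(small_ct_matrix, pw, dialect="wide")
        write_ct_table(small_ct_matrix, pl, dialect="long")
        mw = parse_ct_table(pw, dialect="wide")
        ml = parse_ct_table(pl, dialect="long")
        pd.testing.assert_frame_equal(mw.ct, ml.ct)
        pd.testing.assert_frame_equal(mw.ct, small_ct_matrix.ct)

    def test_duplicate_pair_rejected(self, tmp_path):
        p = tmp_path / "ct.tsv"
        p.write_text("sample_id\tassay_id\tct\ns1\ta1\t24\ns1\ta1\t25\n")
        with pytest.raises(DataError, match="duplicate"):
            parse_ct_table(p, dialect="long")

    def test_malformed_row_names_line(self, tmp_path):
        p = tmp_path / "ct.tsv"
        p.write_text("sample_id\tassay_id\tct\ns1\ta1\t24\ns2\ta1\n")
        with pytest.raises(ParseError, match="line 3"):
            parse_ct_table(p, dialect="long")

    def test_bad_ct_value_names_line(self, tmp_path):
        p = tmp_path / "ct.tsv"
        p.write_text("sample_id\tassay_id\tct\ns1\ta1\ttwenty\n")
        with pytest.raises(ParseError, match="line 2"):
            parse_ct_table(p, dialect="long")


class TestCtMatrixInvariants:
    def test_out_of_range_ct_rejected(self):
        with pytest.raises(DataError):
            CtMatrix(ct=pd.DataFrame([[55.0]], index=["a"], columns=["s"]))
        with pytest.raises(DataError):
            CtMatrix(ct=pd.DataFrame([[0.0]], index=["a"], columns=["s"]))

    def test_duplicate_ids_rejected(self):
        with pytest.raises(DataError):
            CtMatrix(ct=pd.DataFrame([[20.0], [21.0]], index=["a", "a"], columns=["s"]))


# ------------------------------------------------------- detection filter


class TestDetectionFilter:
    def _matrix(self, detected_counts, n_samples=10):
        rows = []
        for k in detected_counts:
            row = [25.0] * k + [np.nan] * (n_samples - k)
            rows.append(row)
        ct = pd.DataFrame(
            rows,
            index=[f"a{i}" for i in range(len(detected_counts))],
            columns=[f"s{j}" for j in range(n_samples)],
        )
        return CtMatrix(ct=ct)

    def test_single_low_assay_removed(self):
        m = self._matrix([5, 6, 7, 8, 1])
        out, rep = detection_filter(m, min_samples=2, min_fraction=0)
        assert rep.threshold == 2
        assert out.n_assays == 4
        assert rep.removed == ["a4"]
        assert rep.n_retained + rep.n_removed == rep.n_input

    def test_threshold_equal_to_n_samples(self):
        m = self._matrix([10, 9, 10])
        out, rep = detection_filter(m, min_samples=10, min_fraction=0)
        assert out.assay_ids == ["a0", "a2"]

    def test_stricter_of_absolute_and_relative(self):
        # 10 samples, min_fraction .5 -> 5 beats min_samples 2
        m = self._matrix([4, 5])
        _, rep = detection_filter(m, min_samples=2, min_fraction=0.5)
        assert rep.threshold == 5
        assert rep.retained == ["a1"]

    def test_ct_above_limit_counts_undetected(self):
        ct = pd.DataFrame(
            [[36.0, 36.5, 25.0], [25.0, 26.0, 27.0]],
            index=["a0", "a1"], columns=["s0", "s1", "s2"],
        )
        m = CtMatrix(ct=ct, detection_limit=35.0)
        _, rep = detection_filter(m, min_samples=2, min_fraction=0)
        assert rep.removed == ["a0"]

    def test_paper_style_accounting_303_of_750(self):
        from mircohort.simulate import make_detection_fixture

        m = make_detection_fixture(n_assays=750, n_samples=62, n_pass=303)
        out, rep = detection_filter(m, min_samples=10, min_fraction=0.15)
        assert rep.threshold == 10  # max(10, ceil(0.15*62)=10)
        assert rep.n_retained == 303
        assert rep.n_removed == 447
        assert out.n_assays == 303
        assert rep.pct_retained == 40.4

    def test_idempotent(self, rng):
        ct = np.where(rng.random((30, 12)) < 0.5, rng.uniform(20, 30, (30, 12)), np.nan)
        m = CtMatrix(ct=pd.DataFrame(
            ct, index=[f"a{i}" for i in range(30)], columns=[f"s{j}" for j in range(12)]
        ))
        once, rep1 = detection_filter(m, min_samples=4, min_fraction=0)
        twice, rep2 = detection_filter(once, min_samples=4, min_fraction=0)
        pd.testing.assert_frame_equal(once.ct, twice.ct)
        assert rep2.n_removed == 0

    def test_empty_matrix_errors(self):
        m = CtMatrix(ct=pd.DataFrame(dtype=float))
        with pytest.raises(DataError):
            detection_filter(m)


# ---------------------------------------------------------- normalization


class TestGlobalMeanNormalize:
    def test_shift_invariance(self, small_ct_matrix):
        nm = global_mean_normalize(small_ct_matrix)
        shifted_ct = small_ct_matrix.ct.copy()
        shifted_ct["S0"] = shifted_ct["S0"] + 3.7
        nm2 = global_mean_normalize(CtMatrix(ct=shifted_ct))
        pd.testing.assert_frame_equal(nm.dct, nm2.dct)

    def test_per_sample_centering(self, small_ct_matrix):
        nm = global_mean_normalize(small_ct_matrix)
        assert np.allclose(nm.dct.mean(axis=0), 0.0, atol=1e-9)

    def test_common_detected_basis(self):
        ct = pd.DataFrame(
            [[20.0, 21.0], [30.0, np.nan], [24.0, 25.0]],
            index=["a", "b", "c"], columns=["s1", "s2"],
        )
        nm = global_mean_normalize(CtMatrix(ct=ct), mean_basis="common_detected")
        # common set = {a, c}; offsets are their means
        assert nm.sample_offsets["s1"] == pytest.approx(22.0)
        assert nm.sample_offsets["s2"] == pytest.approx(23.0)

    def test_missing_cells_stay_missing(self):
        ct = pd.DataFrame(
            [[20.0, np.nan], [22.0, 25.0], [24.0, 27.0]],
            index=list("abc"), columns=["s1", "s2"],
        )
        nm = global_mean_normalize(CtMatrix(ct=ct))
        assert np.isnan(nm.dct.loc["a", "s2"])

    def test_sample_with_nothing_detected_errors(self):
        ct = pd.DataFrame(
            [[20.0, np.nan], [22.0, np.nan]], index=["a", "b"], columns=["s1", "s2"]
        )
        with pytest.raises(DataError, match="s2"):
            global_mean_normalize(CtMatrix(ct=ct))

    def test_sparse_planted_effect_small_bias(self, rng):
        # 1 of 100 assays carries a 2-fold (1 Ct) group shift; global-mean
        # normalization should dilute it by only ~1/100 cycle.
        n_a, n_s = 100, 40
        base = rng.uniform(20, 30, n_a)
        ct = base[:, None] + rng.normal(0, 0.02, (n_a, n_s))
        ct[0, 20:] -= 1.0  # planted 2-fold up in second half
        m = CtMatrix(ct=pd.DataFrame(
            ct, index=[f"a{i}" for i in range(n_a)], columns=[f"s{j}" for j in range(n_s)]
        ))
        nm = global_mean_normalize(m)
        est = nm.dct.iloc[0, :20].mean() - nm.dct.iloc[0, 20:].mean()
        assert abs(est - 1.0) < 0.03


class TestRelativeQuantity:
    def test_ddct_zero_gives_one(self):
        ct = pd.DataFrame([[25.0, 25.0, 25.0]] * 3, index=list("abc"),
                          columns=["r1", "r2", "x"])
        nm = global_mean_normalize(CtMatrix(ct=ct))
        em = relative_quantity(nm, ["r1", "r2"])
        assert np.allclose(em.rq.to_numpy(), 1.0)

    def test_plus_one_cycle_halves(self):
        dct = pd.DataFrame([[0.0, 1.0]], index=["a"], columns=["ref", "x"])
        from conftest import make_normalized

        em = relative_quantity(make_normalized(dct), ["ref"])
        assert em.rq.loc["a", "x"] == pytest.approx(0.5)

    def test_matches_elementwise_formula_oracle(self, rng):
        from conftest import make_normalized

        dct = pd.DataFrame(rng.normal(0, 2, (4, 6)),
                           index=list("abcd"), columns=[f"s{j}" for j in range(6)])
        refs = ["s0", "s1"]
        em = relative_quantity(make_normalized(dct), refs)
        for a in dct.index:
            ref_mean = (dct.loc[a, "s0"] + dct.loc[a, "s1"]) / 2
            for s in dct.columns:
                expected = 2.0 ** -(dct.loc[a, s] - ref_mean)
                assert em.rq.loc[a, s] == pytest.approx(expected, abs=1e-12)

    def test_reference_geometric_mean_is_one(self, rng):
        from conftest import make_normalized

        dct = pd.DataFrame(rng.normal(0, 1, (5, 8)),
                           index=list("abcde"), columns=[f"s{j}" for j in range(8)])
        em = relative_quantity(make_normalized(dct), ["s0", "s1", "s2"])
        geo = np.exp(np.log(em.rq[["s0", "s1", "s2"]]).mean(axis=1))
        assert np.allclose(geo, 1.0, atol=1e-9)

    def test_no_reference_data_warns(self):
        from conftest import make_normalized

        dct = pd.DataFrame([[np.nan, 1.0]], index=["a"], columns=["ref", "x"])
        with pytest.warns(UserWarning, match="no reference-group data"):
            em = relative_quantity(make_normalized(dct), ["ref"])
        assert em.rq.loc["a"].isna().all()

    def test_empty_reference_errors(self):
        from conftest import make_normalized

        with pytest.raises(ValueError):
            relative_quantity(make_normalized(pd.DataFrame([[0.0]])), [])


class TestAssayCv:
    def test_constant_rq_zero_cv(self):
        from conftest import make_expression

        em = make_expression(np.full((2, 5), 3.0))
        cv = assay_cv(em)
        assert np.allclose(cv, 0.0)

    def test_hand_oracle(self):
        from conftest import make_expression

        em = make_expression([[1.0, 1.0, 1.2]])
        vals = [1.0, 1.0, 1.2]
        mean = sum(vals) / 3
        sd = math.sqrt(sum((v - mean) ** 2 for v in vals) / 2)
        assert assay_cv(em).iloc[0] == pytest.approx(sd / mean, abs=1e-12)

    def test_low_noise_cohort_mostly_under_5pct(self, rng):
        # noise sd 0.05 cycles -> rq CV ~ ln(2)*0.05 = 3.5% < 5% for most assays
        n_a, n_s = 120, 30
        ct = rng.uniform(20, 30, n_a)[:, None] + rng.normal(0, 0.05, (n_a, n_s))
        m = CtMatrix(ct=pd.DataFrame(
            ct, index=[f"a{i}" for i in range(n_a)], columns=[f"s{j}" for j in range(n_s)]
        ))
        nm = global_mean_normalize(m)
        em = relative_quantity(nm, list(nm.sample_ids))
        cv = assay_cv(em)
        assert (cv < 0.05).mean() > 0.8

    def test_single_observation_gives_nan(self):
        from conftest import make_expression

        em = make_expression([[1.0, np.nan, np.nan]])
        assert np.isnan(assay_cv(em).iloc[0])

    def test_empty_subset_errors(self, small_expression):
        with pytest.raises(ValueError):
            assay_cv(small_expression, sample_subset=[])


# ----------------------------------------------------------- NormFinder


class TestNormfinderStability:
    def test_constant_matrix_stability_zero(self):
        ct = pd.DataFrame(
            np.tile([[24.0], [26.0], [28.0], [30.0]], (1, 6)),
            index=list("abcd"), columns=[f"s{j}" for j in range(6)],
        )
        labels = ["g1"] * 3 + ["g2"] * 3
        res = normfinder_stability(CtMatrix(ct=ct), labels)
        assert res.table["stability"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert (res.table["stability"] == 0).all()

    def test_brute_force_oracle_4x2x3(self, rng):
        y = rng.normal(25, 2, size=(4, 6))
        labels = ["g1"] * 3 + ["g2"] * 3
        df = pd.DataFrame(y, index=list("abcd"), columns=[f"s{j}" for j in range(6)])
        res = normfinder_stability(df, labels)
        expected = oracles.normfinder_bruteforce(y.tolist(), labels)
        for i, aid in enumerate(list("abcd")):
            assert res.table.loc[aid, "stability"] == pytest.approx(
                expected[i], abs=1e-9
            )

    def test_planted_stable_assay_ranked_first(self):
        hits = 0
        n_rep = 100
        for seed in range(n_rep):
            r = np.random.default_rng(seed)
            n_s = 24
            labels = ["g1"] * 8 + ["g2"] * 8 + ["g3"] * 8
            y = np.empty((21, n_s))
            y[0] = 25.0 + r.normal(0, 0.01, n_s)  # stable: no group effect
            for i in range(1, 21):
                # random per-group offsets (zero mean across assays) + noise
                offsets = np.repeat(r.normal(0, 0.5, 3), 8)
                y[i] = 25.0 + offsets + r.normal(0, 0.6, n_s)
            df = pd.DataFrame(y, index=[f"a{i}" for i in range(21)],
                              columns=[f"s{j}" for j in range(n_s)])
            res = normfinder_stability(df, labels)
            if res.best() == "a0":
                hits += 1
        assert hits >= 95

    def test_shift_invariance(self, rng):
        y = rng.normal(25, 1, size=(5, 8))
        labels = ["g1"] * 4 + ["g2"] * 4
        df = pd.DataFrame(y, index=list("abcde"), columns=[f"s{j}" for j in range(8)])
        res1 = normfinder_stability(df, labels)
        df2 = df.copy()
        df2["s0"] = df2["s0"] + 5.0  # shift one sample
        res2 = normfinder_stability(df2, labels)
        pd.testing.assert_series_equal(
            res1.table["stability"], res2.table["stability"], atol=1e-9, rtol=0
        )

    def test_missing_values_excluded_with_warning(self, rng):
        y = rng.normal(25, 1, size=(5, 8))
        y[2, 3] = np.nan
        df = pd.DataFrame(y, index=list("abcde"), columns=[f"s{j}" for j in range(8)])
        with pytest.warns(UserWarning, match="excluded"):
            res = normfinder_stability(df, ["g1"] * 4 + ["g2"] * 4)
        assert res.excluded == ["c"]
        assert "c" not in res.ranking

    def test_small_group_errors(self, rng):
        df = pd.DataFrame(rng.normal(25, 1, (4, 5)), index=list("abcd"),
                          columns=[f"s{j}" for j in range(5)])
        with pytest.raises(DataError, match="< 2 samples"):
            normfinder_stability(df, ["g1"] * 4 + ["g2"])

    def test_stability_non_negative_property(self, rng):
        for _ in range(20):
            y = rng.normal(25, rng.uniform(0.1, 3), size=(6, 10))
            df = pd.DataFrame(y, index=[f"a{i}" for i in range(6)],
                              columns=[f"s{j}" for j in range(10)])
            res = normfinder_stability(df, ["g1"] * 5 + ["g2"] * 5)
            assert (res.table["stability"] >= 0).all()
            assert (res.table["intra_var"] >= 0).all()
            assert (res.table["inter_var"] >= 0).all()
            assert res.table["stability"].is_monotonic_increasing


# --------------------------------------------------------- standard curve


class TestStandardCurve:
    def test_perfect_tenfold_series_efficiency_100pct(self):
        slope = -3.3219280948873623  # -1/log10(2): exact doubling
        standards = [(q, 35.0 + slope * q) for q in range(0, 5)]
        curve, _ = standard_curve_quantify(standards)
        assert curve.efficiency == pytest.approx(1.0, abs=1e-3)
        assert curve.r_squared == pytest.approx(1.0)

    def test_unknown_at_standard_ct_recovers_quantity(self):
        standards = [(0.0, 34.0), (1.0, 30.7), (2.0, 27.4), (3.0, 24.1)]
        curve, q = standard_curve_quantify(standards, unknowns=[30.7])
        assert q[0] == pytest.approx(10.0 ** 1.0, rel=1e-9)

    def test_noisy_fit_matches_lstsq_oracle(self, rng):
        logq = np.array([0.0, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0])
        ct = 33.0 - 3.3 * logq + rng.normal(0, 0.2, logq.size)
        curve, _ = standard_curve_quantify(list(zip(logq, ct)))
        slope, intercept = oracles.least_squares_line(logq, ct)
        assert curve.slope == pytest.approx(slope, abs=1e-10)
        assert curve.intercept == pytest.approx(intercept, abs=1e-10)

    def test_too_few_standards(self):
        with pytest.raises(CalibrationError):
            standard_curve_quantify([(0, 30), (1, 27)])

    def test_narrow_range(self):
        with pytest.raises(CalibrationError, match="span"):
            standard_curve_quantify([(0, 30), (0.5, 29), (1.0, 28)])

    def test_positive_slope_rejected(self):
        with pytest.raises(CalibrationError, match="slope"):
            standard_curve_quantify([(0, 20), (1, 25), (2, 30)])


# ------------------------------------------------------------- properties


@settings(max_examples=25, deadline=None)
@given(shift=st.floats(-5, 5), col=st.integers(0, 7))
def test_normalization_removes_any_sample_shift(shift, col):
    r = np.random.default_rng(7)
    ct = pd.DataFrame(25 + r.normal(0, 1, (5, 8)),
                      index=list("abcde"), columns=[f"s{j}" for j in range(8)])
    nm1 = global_mean_normalize(CtMatrix(ct=ct))
    ct2 = ct.copy()
    ct2.iloc[:, col] = ct2.iloc[:, col] + shift
    nm2 = global_mean_normalize(CtMatrix(ct=ct2))
    assert np.allclose(nm1.dct.to_numpy(), nm2.dct.to_numpy(), atol=1e-9)
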