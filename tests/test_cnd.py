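"""CND cutoff machinery: variance-ratio curves, cubic fits, sub-populations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from vinefert.cnd import (
    communal_cutoff,
    correlation_matrix,
    CutoffFit,
    cumulative_variance_function,
    diagnose_variable,
    fit_cubic,
    inflection_cutoff,
    optimum_range,
    select_diagnostic_tissue,
    select_high_subpop,
)
from vinefert.synthetic import generate_planted_window


def curve_oracle(values, fqi, m_min=3):
    """Spreadsheet-style enumeration of every split, independent of the library."""
    order = sorted(range(len(values)), key=lambda i: -fqi[i])
    v = [values[i] for i in order]
    x = [fqi[i] for i in order]
    n = len(v)

    def var(chunk):
        m = sum(chunk) / len(chunk)
        return sum((c - m) ** 2 for c in chunk) / (len(chunk) - 1)

    pts = []
    for j in range(m_min, n - m_min + 1):
        if x[j - 1] <= x[j]:
            continue  # tie: keep equal scores together
        pts.append((x[j - 1], var(v[:j]) / var(v[j:])))
    total = sum(r for _, r in pts)
    out, acc = [], 0.0
    for xx, r in pts:
        acc += r
        out.append((xx, 100.0 * acc / total))
    return out


class TestDiagnosticTissueSelection:
    def _table(self, spec):
        rows = []
        for (stage, tissue, el), values in spec.items():
            for i, v in enumerate(values):
                rows.append({"stage": stage, "tissue": tissue, "element": el,
                             "unit": i, "value": v})
        return pd.DataFrame(rows)

    def test_constant_series_has_zero_cv_and_wins(self):
        tab = self._table({
            ("FBS", "leaf", "N"): [10.0, 10.0, 10.0],
            ("VS", "leaf", "N"): [10.0, 12.0, 8.0],
        })
        choice, cv = select_diagnostic_tissue(tab)
        assert choice.loc["N", "stage"] == "FBS"
        assert cv.set_index(["stage", "tissue"]).loc[("FBS", "leaf"), "cv_pct"] == 0.0

    def test_cv_formula_matches_hand_arithmetic(self):
        # sample SD of {1,2,3} is 1, mean 2 -> CV 50%
        tab = self._table({("MS", "fruit", "K"): [1.0, 2.0, 3.0],
                           ("VS", "fruit", "K"): [5.0, 5.0, 5.1]})
        _, cv = select_diagnostic_tissue(tab)
        got = cv.set_index(["stage", "tissue"]).loc[("MS", "fruit"), "cv_pct"]
        assert got == pytest.approx(50.0)

    def test_low_noise_tissue_selected_across_seeds(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            spec = {}
            for tissue in ("fruit", "leaf", "petiole"):
                cv = 0.05 if tissue == "leaf" else 0.10
                spec[("VS", tissue, "Mg")] = 5.0 * (1 + cv * rng.normal(0, 1, 30))
            choice, _ = select_diagnostic_tissue(self._table(spec))
            hits += choice.loc["Mg", "tissue"] == "leaf"
        assert hits >= 19


class TestCumulativeVarianceFunction:
    def test_endpoint_is_exactly_100(self, rng):
        pts = cumulative_variance_function(rng.uniform(1, 9, 25), rng.uniform(0, 1, 25))
        assert pts["F"].iloc[-1] == pytest.approx(100.0, abs=1e-12)

    def test_monotone_non_decreasing(self, rng):
        for _ in range(10):
            pts = cumulative_variance_function(
                rng.uniform(1, 9, 30), rng.uniform(0, 1, 30)
            )
            assert (np.diff(pts["F"]) >= -1e-12).all()
            assert (np.diff(pts["X"]) <= 1e-12).all()

    def test_matches_brute_force_enumeration(self, rng):
        values = rng.uniform(2, 14, 10)
        fqi = rng.uniform(0, 1, 10)
        pts = cumulative_variance_function(values, fqi)
        want = curve_oracle(list(values), list(fqi))
        assert len(pts) == len(want)
        for (x, f), (_, row) in zip(want, pts.iterrows()):
            assert row["X"] == pytest.approx(x, abs=1e-10)
            assert row["F"] == pytest.approx(f, abs=1e-10)

    def test_ties_kept_together(self):
        fqi = np.array([0.9, 0.9, 0.9, 0.9, 0.5, 0.4, 0.3, 0.2, 0.1, 0.05])
        pts = cumulative_variance_function(np.arange(10.0) + 1, fqi)
        # no split inside the four-way tie at 0.9
        assert (pts["j"] >= 4).all()

    def test_too_few_units_is_error(self):
        with pytest.raises(ValueError, match="at least"):
            cumulative_variance_function(np.arange(6.0), np.linspace(0, 1, 6))

    def test_constant_fqi_is_error(self):
        with pytest.raises(ValueError, match="all equal"):
            cumulative_variance_function(np.arange(10.0), np.full(10, 0.5))


class TestCubicFitAndCutoff:
    def test_recovers_exact_cubic_coefficients(self):
        # coefficients of the published leaf-N curve used as a generator
        A, B, C, D = -61.412, 150.17, -191.27, 105.24
        X = np.linspace(0.05, 0.95, 40)
        F = A * X**3 + B * X**2 + C * X + D
        fit = fit_cubic(pd.DataFrame({"X": X, "F": F}), "gen")
        np.testing.assert_allclose(fit.coefficients, (A, B, C, D), atol=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.cutoff == pytest.approx(-B / (3 * A), abs=1e-9)

    def test_linear_points_flag_undefined_cutoff(self):
        X = np.linspace(0, 1, 20)
        with pytest.warns(UserWarning, match="cutoff undefined"):
            fit = fit_cubic(pd.DataFrame({"X": X, "F": 3 * X + 1}), "lin")
        assert fit.cutoff is None

    def test_noisy_cubic_coefficient_bias_small(self):
        A, B, C, D = -61.412, 150.17, -191.27, 105.24
        X = np.linspace(0.02, 0.98, 80)
        acc = np.zeros(4)
        n_rep = 200
        rng = np.random.default_rng(2024)
        for _ in range(n_rep):
            F = A * X**3 + B * X**2 + C * X + D + rng.normal(0, 1.0, len(X))
            fit = fit_cubic(pd.DataFrame({"X": X, "F": F}))
            acc += np.asarray(fit.coefficients)
        bias = acc / n_rep - np.array([A, B, C, D])
        assert np.all(np.abs(bias / np.array([A, B, C, D])) < 0.02)

    def test_rank_deficient_is_error(self):
        pts = pd.DataFrame({"X": [0.1, 0.1, 0.5, 0.5, 0.9], "F": [1, 1, 2, 2, 3]})
        with pytest.raises(ValueError, match="distinct"):
            fit_cubic(pts)

    @pytest.mark.parametrize(
        "A, B, expected",
        [
            (-61.412, 150.170, 0.8151),  # leaf N at full bloom
            (62.153, -96.819, 0.5193),  # soil Ca at germination
            (1.0, 0.0, 0.0),
        ],
    )
    def test_inflection_examples(self, A, B, expected):
        assert round(inflection_cutoff(A, B), 4) == expected

    def test_inflection_matches_numeric_root_of_second_derivative(self, rng):
        for _ in range(20):
            A, B = rng.uniform(-200, 200, 2)
            if abs(A) < 1e-3:
                continue
            root = np.roots([6 * A, 2 * B])[0]
            assert inflection_cutoff(A, B) == pytest.approx(root, abs=1e-10)

    def test_zero_leading_coefficient_is_error(self):
        with pytest.raises(ValueError):
            inflection_cutoff(0.0, 5.0)


class TestSubpopulationAndRanges:
    def test_published_subpop_fraction(self):
        fqi = pd.Series(np.concatenate([np.linspace(0.82, 1.0, 13),
                                        np.linspace(0.0, 0.80, 67)]))
        sel, frac = select_high_subpop(fqi, 0.8151)
        assert len(sel) == 13
        assert frac == pytest.approx(16.25)

    def test_zero_cutoff_selects_all(self):
        sel, frac = select_high_subpop(pd.Series([0.1, 0.5, 0.9]), 0.0)
        assert frac == 100.0

    def test_cutoff_above_max_is_error(self):
        with pytest.raises(ValueError, match="cutoff"):
            select_high_subpop(pd.Series([0.1, 0.5]), 0.9)

    def test_optimum_range_is_min_max(self, rng):
        vals = pd.Series([7.192, 9.0, 12.516])
        r = optimum_range(vals, "v", 0.8, n_total=80)
        assert (r.low, r.high) == (7.192, 12.516)
        random_vals = rng.uniform(0, 50, 17)
        r2 = optimum_range(random_vals)
        assert r2.low == min(random_vals) and r2.high == max(random_vals)

    def test_singleton_subset_is_error(self):
        with pytest.raises(ValueError, match=">=2"):
            optimum_range(pd.Series([1.0]))

    def test_range_shrinks_as_cutoff_rises(self, rng):
        values = pd.Series(rng.uniform(0, 20, 60))
        fqi = pd.Series(rng.uniform(0, 1, 60))
        widths = []
        for cut in (0.1, 0.3, 0.5, 0.7):
            sel, _ = select_high_subpop(fqi, cut)
            r = optimum_range(values.loc[sel.index])
            widths.append(r.high - r.low)
        assert all(a >= b - 1e-12 for a, b in zip(widths, widths[1:]))

    def test_communal_cutoff_is_max_of_plant_cutoffs(self):
        cuts = [0.8151, 0.6597, 0.5507, 0.3860, 0.4655]
        fits = [CutoffFit(f"v{i}", -1, 3 * c, 0, 0, 0.99, c, 70)
                for i, c in enumerate(cuts)]
        assert communal_cutoff(fits) == 0.8151
        assert communal_cutoff(fits[:1]) == 0.8151
        same = [CutoffFit("a", -1, 1, 0, 0, 1.0, 0.5, 70)] * 3
        assert communal_cutoff(same) == 0.5

    def test_no_defined_cutoffs_is_error(self):
        fits = [CutoffFit("a", 0.0, 1, 0, 0, 1.0, None, 70)]
        with pytest.raises(ValueError, match="no defined"):
            communal_cutoff(fits)


class TestEndToEndRecovery:
    def test_planted_window_recovered_single_seed(self):
        df, boundary, window = generate_planted_window(seed=11)
        fit, rng_est = diagnose_variable(
            df.set_index("unit")["value"], df.set_index("unit")["fqi_norm"], "v"
        )
        assert abs(fit.cutoff - boundary) < 0.1
        lo, hi = window
        overlap = max(0.0, min(rng_est.high, hi) - max(rng_est.low, lo))
        assert overlap >= 0.8 * (hi - lo)


class TestCorrelationMatrix:
    def test_perfect_linear_pair(self):
        x = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0]})
        y = pd.DataFrame({"b": [2.0, 4.0, 6.0, 8.0]})
        out = correlation_matrix(x, y)
        assert out["r"].iloc[0] == pytest.approx(1.0)
        assert out["sig"].iloc[0] == "***"

    def test_matches_hand_covariance_formula(self):
        xs = [1.0, 3.0, 2.0, 5.0, 4.0]
        ys = [2.0, 1.0, 4.0, 3.0, 5.0]
        mx, my = np.mean(xs), np.mean(ys)
        num = sum((a - mx) * (b - my) for a, b in zip(xs, ys))
        den = np.sqrt(sum((a - mx) ** 2 for a in xs) * sum((b - my) ** 2 for b in ys))
        out = correlation_matrix(pd.DataFrame({"x": xs}), pd.DataFrame({"y": ys}))
        assert out["r"].iloc[0] == pytest.approx(num / den, abs=1e-12)

    def test_type_one_error_rate_calibrated(self):
        # independent pairs at n=80: the 5% stars should fire ~5% of the time
        rng = np.random.default_rng(606)
        hits = 0
        n_sim = 1000
        for _ in range(n_sim):
            x = rng.normal(0, 1, 80)
            y = rng.normal(0, 1, 80)
            hits += stats.pearsonr(x, y)[1] < 0.05
        assert 0.03 <= hits / n_sim <= 0.07

    def test_zero_variance_pair_skipped(self):
        x = pd.DataFrame({"a": [1.0, 1.0, 1.0, 1.0]})
        y = pd.DataFrame({"b": [1.0, 2.0, 3.0, 4.0]})
        with pytest.warns(UserWarning, match="zero variance"):
            out = correlation_matrix(x, y)
        assert out.empty
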