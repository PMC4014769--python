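"""Power transforms and strain/time ANOVA against design-matrix oracles."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tcekin.anova import (
    DEFAULT_LAMBDA_GRID,
    anova_table,
    one_way_anova_per_time,
    power_transform,
    select_power_transform,
    two_way_anova,
)
from tcekin.data import DATASET_COLUMNS, ConcentrationDataset
from tcekin.params import ConfigurationError


def _dataset(strains, times, values, metabolite="TCA"):
    """Build a dataset from parallel label/value arrays."""
    rows = [
        ("s1", s, f"{s}-{i}", metabolite, float(t), float(v), False, 0.001)
        for i, (s, t, v) in enumerate(zip(strains, times, values))
    ]
    return ConcentrationDataset(pd.DataFrame(rows, columns=list(DATASET_COLUMNS)))


def sequential_ss_oracle(y, time_labels, strain_labels):
    """Brute-force sequential (Type I) sums of squares via least squares.

    Fits the nested design matrices [1], [1|time], [1|time|strain] and
    reads the SS decrements off the residual sums of squares.
    """
    y = np.asarray(y, dtype=float)

    def dummies(labels):
        levels = sorted(set(labels))[1:]
        return np.column_stack(
            [np.asarray([1.0 if l == lev else 0.0 for l in labels])
             for lev in levels]
        ) if levels else np.empty((len(labels), 0))

    def rss(X):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r)

    n = len(y)
    ones = np.ones((n, 1))
    X1 = np.column_stack([ones, dummies(time_labels)])
    X2 = np.column_stack([X1, dummies(strain_labels)])
    rss0, rss1, rss2 = rss(ones), rss(X1), rss(X2)
    ss_time = rss0 - rss1
    ss_strain = rss1 - rss2
    df_time = X1.shape[1] - 1
    df_strain = X2.shape[1] - X1.shape[1]
    df_resid = n - X2.shape[1]
    ms_resid = rss2 / df_resid if df_resid > 0 else float("nan")
    f_strain = (ss_strain / df_strain) / ms_resid if df_resid > 0 else float("nan")
    p_strain = stats.f.sf(f_strain, df_strain, df_resid) if df_resid > 0 else float("nan")
    return {
        "ss_total": rss0, "ss_time": ss_time, "ss_strain": ss_strain,
        "ss_resid": rss2, "F_strain": f_strain, "p_strain": p_strain,
        "partial_R2_strain": ss_strain / rss0,
    }


class TestPowerTransform:
    def test_quarter_power(self):
        assert power_transform([16.0], 0.25)[0] == pytest.approx(2.0)

    def test_identity_endpoint(self):
        y = np.array([0.3, 2.0, 7.0])
        assert np.allclose(power_transform(y, 1.0), y)

    def test_zero_endpoint_is_log(self):
        assert power_transform([math.e**3], 0.0)[0] == pytest.approx(3.0)

    def test_log_of_zero_rejected(self):
        with pytest.raises(ValueError):
            power_transform([0.0, 1.0], 0.0)

    def test_monotone(self, rng):
        y = np.sort(rng.uniform(0.01, 50, 100))
        for lam in DEFAULT_LAMBDA_GRID:
            assert np.all(np.diff(power_transform(y, lam)) > 0)


class TestSelectPowerTransform:
    def _normality_dataset(self, rng, power):
        """Values whose `power`-th root is normal, per metabolite."""
        rows = []
        for met in ("TCA", "DCA", "DCVG", "DCVC"):
            base = rng.normal(8.0, 1.0, 200)
            values = np.abs(base) ** (1.0 / power) if power else np.exp(base)
            for i, v in enumerate(values):
                rows.append(("s1", f"st{i % 10}", f"a{i}", met, 2.0, v, False,
                             1e-9))
        return ConcentrationDataset(
            pd.DataFrame(rows, columns=list(DATASET_COLUMNS))
        )

    def test_fourth_root_data_selects_quarter(self, rng):
        data = self._normality_dataset(rng, power=0.25)
        best, scores = select_power_transform(data, grid=(0.0, 0.25, 0.5, 1.0))
        assert best == 0.25
        assert set(scores["metabolite"]) == {"TCA", "DCA", "DCVG", "DCVC"}

    def test_normal_data_selects_identity(self, rng):
        data = self._normality_dataset(rng, power=1.0)
        best, _ = select_power_transform(data, grid=(0.0, 0.25, 0.5, 1.0))
        assert best == 1.0

    def test_single_point_grid(self, rng):
        data = self._normality_dataset(rng, power=1.0)
        best, _ = select_power_transform(data, grid=(0.5,))
        assert best == 0.5

    def test_empty_grid_rejected(self, rng):
        data = self._normality_dataset(rng, power=1.0)
        with pytest.raises(ConfigurationError):
            select_power_transform(data, grid=())


class TestOneWay:
    def test_pure_strain_separation_gives_unit_r2(self):
        data = _dataset(
            ["A", "A", "B", "B"], [2, 2, 2, 2], [1.0, 1.0, 5.0, 5.0]
        )
        res = one_way_anova_per_time(data, "TCA", 2.0, lam=1.0)
        assert res.partial_R2 == pytest.approx(1.0)

    def test_hand_computed_two_by_three_table(self):
        strains = ["A", "A", "A", "B", "B", "B"]
        values = [1.0, 2.0, 3.0, 4.0, 6.0, 8.0]
        data = _dataset(strains, [2] * 6, values)
        res = one_way_anova_per_time(data, "TCA", 2.0, lam=1.0)
        # hand sums of squares: means 2 and 6, grand mean 4
        ss_strain = 3 * (2 - 4) ** 2 + 3 * (6 - 4) ** 2  # 24
        ss_resid = (1 + 0 + 1) + (4 + 0 + 4)  # 10
        f_expected = (ss_strain / 1) / (ss_resid / 4)
        assert res.partial_R2 == pytest.approx(24 / 34, rel=1e-12)
        assert res.F_statistic == pytest.approx(f_expected, rel=1e-12)
        assert res.p_value == pytest.approx(
            stats.f.sf(f_expected, 1, 4), rel=1e-12
        )

    def test_null_r2_matches_expectation(self, rng):
        """Random strain labels: E[R^2] = (k-1)/(n-1) under the null."""
        n, k = 60, 6
        r2 = []
        for _ in range(300):
            labels = rng.permutation(np.repeat([f"s{i}" for i in range(k)],
                                               n // k))
            values = rng.lognormal(0, 0.5, n)
            data = _dataset(labels, [2] * n, values)
            r2.append(one_way_anova_per_time(data, "TCA", 2.0, lam=0.25)
                      .partial_R2)
        expected = (k - 1) / (n - 1)
        assert np.mean(r2) == pytest.approx(expected, abs=0.01)

    def test_saturated_design_flags_f_undefined(self):
        data = _dataset(["A", "B", "C"], [2, 2, 2], [1.0, 2.0, 3.0])
        res = one_way_anova_per_time(data, "TCA", 2.0, lam=1.0)
        assert res.partial_R2 == pytest.approx(1.0)
        assert math.isnan(res.F_statistic)


class TestTwoWay:
    def _random_table(self, rng, n_strains=4, n_times=3, unbalanced=True):
        rows_s, rows_t, values = [], [], []
        for s in range(n_strains):
            for t in range(n_times):
                n_rep = rng.integers(1, 4) if unbalanced else 2
                for _ in range(n_rep):
                    rows_s.append(f"s{s}")
                    rows_t.append(2.0 * (t + 1))
                    values.append(rng.lognormal(0.1 * s + 0.2 * t, 0.3))
        return rows_s, rows_t, values

    def test_matches_design_matrix_oracle_on_random_tables(self, rng):
        for _ in range(10):
            strains, times, values = self._random_table(rng)
            data = _dataset(strains, times, values)
            res = two_way_anova(data, "TCA", lam=0.25)
            y = power_transform(np.array(values), 0.25)
            oracle = sequential_ss_oracle(y, [str(t) for t in times], strains)
            assert res["strain"].partial_R2 == pytest.approx(
                oracle["partial_R2_strain"], abs=1e-10
            )
            assert res["strain"].F_statistic == pytest.approx(
                oracle["F_strain"], rel=1e-9
            )
            assert res["strain"].p_value == pytest.approx(
                oracle["p_strain"], rel=1e-9, abs=1e-12
            )

    def test_exact_decomposition_for_additive_noise_free_data(self):
        strains, times, values = [], [], []
        strain_effect = {"A": 1.0, "B": 2.0, "C": 4.0}
        time_effect = {2.0: 0.5, 8.0: 1.5}
        for s, se in strain_effect.items():
            for t, te in time_effect.items():
                strains.append(s)
                times.append(t)
                values.append(se + te)
        data = _dataset(strains, times, values)
        res = two_way_anova(data, "TCA", lam=1.0)
        assert res["strain"].partial_R2 + res["time"].partial_R2 == pytest.approx(
            1.0, abs=1e-9
        )

    def test_balanced_no_time_effect_sequential_equals_marginal(self, rng):
        strains, times, values = self._random_table(rng, unbalanced=False)
        # wipe out any time structure by regenerating values per strain only
        values = [rng.lognormal({"s0": 0, "s1": 0.4, "s2": 0.8, "s3": 1.2}[s],
                                0.2) for s in strains]
        y = power_transform(np.array(values), 0.25)
        seq = sequential_ss_oracle(y, [str(t) for t in times], strains)
        # marginal: strain entered first
        marginal = sequential_ss_oracle(y, strains, [str(t) for t in times])
        assert seq["ss_strain"] == pytest.approx(marginal["ss_time"], rel=1e-9)

    def test_sequential_ss_nonnegative_and_sum_to_total(self, rng):
        for _ in range(10):
            strains, times, values = self._random_table(rng)
            y = power_transform(np.array(values), 0.25)
            oracle = sequential_ss_oracle(y, [str(t) for t in times], strains)
            assert oracle["ss_time"] >= -1e-9
            assert oracle["ss_strain"] >= -1e-9
            total = oracle["ss_time"] + oracle["ss_strain"] + oracle["ss_resid"]
            assert total == pytest.approx(oracle["ss_total"], rel=1e-9)

    def test_affine_invariance_of_f_and_r2(self, rng):
        strains, times, values = self._random_table(rng)
        data = _dataset(strains, times, values)
        scaled = _dataset(strains, times, [7.0 * v for v in values])
        a = two_way_anova(data, "TCA", lam=1.0)
        b = two_way_anova(scaled, "TCA", lam=1.0)
        assert a["strain"].F_statistic == pytest.approx(
            b["strain"].F_statistic, rel=1e-9
        )
        assert a["strain"].partial_R2 == pytest.approx(
            b["strain"].partial_R2, rel=1e-9
        )


class TestTable:
    def test_table_shape_on_synthetic_study(self, default_study):
        data, _ = default_study
        table = anova_table(data, lam=0.25)
        assert set(table["metabolite"]) == {"TCA", "DCA", "DCVG", "DCVC"}
        # per-timepoint rows plus an overall row per metabolite
        for met in ("TCA", "DCA"):
            sub = table[table["metabolite"] == met]
            assert "All" in set(sub["time_hr"])
            assert len(sub) == 4
        all_rows = table[table["time_hr"] == "All"]
        assert np.all(all_rows["partial_R2"].to_numpy() >= 0)
        assert np.all(all_rows["partial_R2"].to_numpy() <= 1)
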