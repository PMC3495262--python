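"""ANOVA decomposition, Bonferroni correction, star codes, report assembly."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from arterymorph.errors import DesignError, JoinError
from arterymorph.stats_report import (
    bonferroni_adjust,
    build_report,
    star_code,
    two_way_anova,
)


def balanced_two_way_ss(values, a_levels, b_levels):
    """Textbook sum-of-squares decomposition for a balanced design.

    ``values[i, j]`` holds the replicate vector of cell (a_i, b_j).
    Independent of the statsmodels fitting route.
    """
    y = np.asarray(values, dtype=float)  # (a, b, n)
    a, b, n = y.shape
    grand = y.mean()
    mean_a = y.mean(axis=(1, 2))
    mean_b = y.mean(axis=(0, 2))
    mean_ab = y.mean(axis=2)
    ss_a = b * n * np.sum((mean_a - grand) ** 2)
    ss_b = a * n * np.sum((mean_b - grand) ** 2)
    ss_ab = n * np.sum(
        (mean_ab - mean_a[:, None] - mean_b[None, :] + grand) ** 2
    )
    ss_err = np.sum((y - mean_ab[:, :, None]) ** 2)
    return ss_a, ss_b, ss_ab, ss_err


def _unstack(y):
    a, b, n = y.shape
    values = y.ravel()
    fa = np.repeat(np.arange(a), b * n)
    fb = np.tile(np.repeat(np.arange(b), n), a)
    return values, fa, fb


class TestTwoWayAnova:
    def test_constant_data_gives_f_zero_p_one(self):
        y = np.full((2, 2, 3), 7.0)
        res = two_way_anova(*_unstack(y))
        for effect in ("a", "b", "a:b"):
            assert res.anova_table.loc[effect, "F"] == 0.0
            assert res.anova_table.loc[effect, "PR(>F)"] == 1.0

    def test_balanced_2x2_matches_hand_computed_sums_of_squares(self, rng):
        y = rng.normal(10.0, 2.0, size=(2, 2, 5))
        y[1] += 3.0  # main effect of A
        y[:, 1] += 1.5  # main effect of B
        y[1, 1] += 2.0  # interaction
        res = two_way_anova(*_unstack(y))
        ss_a, ss_b, ss_ab, ss_err = balanced_two_way_ss(y, 2, 2)
        table = res.anova_table
        assert table.loc["a", "sum_sq"] == pytest.approx(ss_a, rel=1e-10)
        assert table.loc["b", "sum_sq"] == pytest.approx(ss_b, rel=1e-10)
        assert table.loc["a:b", "sum_sq"] == pytest.approx(ss_ab, rel=1e-10)
        assert table.loc["Residual", "sum_sq"] == pytest.approx(ss_err, rel=1e-10)

    def test_balanced_sums_of_squares_are_additive(self, rng):
        y = rng.normal(0.0, 1.0, size=(3, 4, 4))
        res = two_way_anova(*_unstack(y))
        table = res.anova_table
        ss_total = np.sum((y - y.mean()) ** 2)
        parts = table.loc[["a", "b", "a:b", "Residual"], "sum_sq"].sum()
        assert parts == pytest.approx(ss_total, rel=1e-9)

    def test_single_level_factor_rejected(self):
        with pytest.raises(DesignError):
            two_way_anova(np.arange(6.0), np.zeros(6), np.arange(6) % 2)

    def test_repeated_measures_blocks_subject_variance(self, rng):
        # strong per-subject offsets: blocking must shrink the residual
        n_subj, doses = 6, 4
        offsets = rng.normal(0.0, 10.0, size=n_subj)
        dose_effect = np.linspace(0.0, 8.0, doses)
        y, fa, fb, subj = [], [], [], []
        for s in range(n_subj):
            cond = "NT" if s < 3 else "HT"
            for d in range(doses):
                y.append(offsets[s] + dose_effect[d] + rng.normal(0, 0.5))
                fa.append(cond)
                fb.append(d)
                subj.append(s)
        plain = two_way_anova(np.array(y), fa, fb)
        blocked = two_way_anova(np.array(y), fa, fb, repeated=True, subject=subj)
        assert (
            blocked.anova_table.loc["Residual", "sum_sq"]
            < 0.2 * plain.anova_table.loc["Residual", "sum_sq"]
        )

    def test_repeated_without_subject_rejected(self, rng):
        y = rng.normal(size=8)
        with pytest.raises(DesignError):
            two_way_anova(y, np.arange(8) % 2, np.arange(8) // 4, repeated=True)

    def test_unbalanced_design_flagged(self, rng):
        y = rng.normal(size=11)
        fa = ["x"] * 6 + ["y"] * 5
        fb = ([0] * 3 + [1] * 3) + ([0] * 2 + [1] * 3)
        res = two_way_anova(np.array(y), fa, fb)
        assert any("unbalanced" in f for f in res.flags)


class TestBonferroni:
    @pytest.mark.parametrize("p,k,expected", [(0.01, 5, 0.05), (0.5, 3, 1.0)])
    def test_adjustment(self, p, k, expected):
        assert bonferroni_adjust([p], k)[0] == pytest.approx(expected)

    @given(
        p=st.floats(0.0, 1.0),
        k=st.integers(1, 50),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_adjusted_at_least_raw_and_capped(self, p, k):
        adj = float(bonferroni_adjust([p], k)[0])
        assert adj >= p
        assert adj <= 1.0


class TestStarCode:
    @pytest.mark.parametrize(
        "p,expected",
        [
            (0.0005, "***"),
            (0.005, "**"),
            (0.03, "*"),
            (0.2, ""),
            # boundaries map to the weaker code (open intervals)
            (0.001, "**"),
            (0.01, "*"),
            (0.05, ""),
        ],
    )
    def test_thresholds(self, p, expected):
        assert star_code(p) == expected

    @given(p=st.floats(0.0, 1.0))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_step_function_consistency(self, p):
        stars = star_code(p)
        n = len(stars)
        thresholds = [0.05, 0.01, 0.001]
        if n > 0:
            assert p < thresholds[n - 1]
        if n < 3:
            assert p >= thresholds[n] if n < 3 and p < 1 else True

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            star_code(1.5)


class TestBuildReport:
    @staticmethod
    def _geometry():
        return pd.DataFrame(
            {
                "condition": ["NT", "NT", "HT", "HT"],
                "week": [0, 0, 8, 8],
                "animal": [0, 1, 0, 1],
                "thickness_um": [50.0, 52.0, 78.0, 80.0],
            }
        )

    @staticmethod
    def _nuclei():
        return pd.DataFrame(
            {
                "condition": ["NT", "NT", "HT", "HT"],
                "week": [0, 0, 8, 8],
                "animal": [0, 1, 0, 1],
                "density": [0.004, 0.0038, 0.0041, 0.0039],
            }
        )

    def test_missing_fraction_table_is_flagged_not_fatal(self):
        report = build_report(geometry=self._geometry(), nuclei=self._nuclei())
        assert any("fractions" in f for f in report.flags)
        sections = {m.split(".")[0] for m in report.long["measure"]}
        assert sections == {"geometry", "nuclei"}

    def test_every_animal_appears_once_per_measure(self):
        report = build_report(geometry=self._geometry(), nuclei=self._nuclei())
        counts = report.long.groupby(["measure", "condition", "week", "animal"]).size()
        assert (counts == 1).all()

    def test_duplicate_rows_rejected(self):
        dup = pd.concat([self._geometry()] * 2, ignore_index=True)
        with pytest.raises(JoinError):
            build_report(geometry=dup)

    def test_missing_key_column_rejected(self):
        bad = self._geometry().drop(columns="animal")
        with pytest.raises(JoinError):
            build_report(geometry=bad)

    def test_order_independence(self):
        shuffled = self._geometry().sample(frac=1.0, random_state=0)
        a = build_report(geometry=self._geometry())
        b = build_report(geometry=shuffled)
        assert a.long.equals(b.long)
        assert a.summary.equals(b.summary)

    def test_drop_conditions_removes_group(self):
        report = build_report(geometry=self._geometry(), drop_conditions=("HT",))
        assert set(report.long["condition"]) == {"NT"}
        assert any("dropped" in f for f in report.flags)

    def test_summary_mean_and_sem(self):
        report = build_report(geometry=self._geometry())
        row = report.summary[(report.summary.condition == "NT")].iloc[0]
        assert row["mean"] == pytest.approx(51.0)
        assert row["sem"] == pytest.approx(1.0)
        assert row["n"] == 2
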