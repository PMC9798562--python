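"""Statistics and report-rendering tests."""

import itertools
import re

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from angleguard.stats import (
    StatsError,
    StratifiedCounts,
    StratumCount,
    compare_continuous,
    format_p,
    frame_to_markdown,
    pearson_chisq,
    percentage,
    prevalence_table,
    reference_table2,
    render_table1,
    render_table2,
)


class TestPercentage:
    @pytest.mark.parametrize(
        "num, den, expected",
        [(78, 991, 7.9), (0, 100, 0.0), (9, 313, 2.9), (32, 579, 5.5), (46, 412, 11.2)],
    )
    def test_reference_values(self, num, den, expected):
        assert percentage(num, den) == expected

    def test_half_up_not_bankers(self):
        # 1/16 = 6.25% -> 6.3 under half-up (bankers' would give 6.2)
        assert percentage(1, 16) == 6.3
        assert percentage(1, 8) == 12.5

    def test_zero_denominator(self):
        assert percentage(0, 0) is None


class TestPearsonChisq:
    def test_independence_table(self):
        res = pearson_chisq([[10, 10], [10, 10]])
        assert res.statistic == 0.0
        assert res.p == 1.0

    def test_df_is_k_minus_1(self):
        assert pearson_chisq([[5, 6, 7], [8, 9, 10]]).df == 2

    @given(
        st.lists(
            st.tuples(st.integers(1, 200), st.integers(1, 200)),
            min_size=2,
            max_size=4,
        )
    )
    @settings(deadline=None, derandomize=True, max_examples=60)
    def test_matches_brute_force_expected_counts(self, cols):
        """Pearson statistic equals sum (O-E)^2 / E from first principles."""
        obs = np.array(cols, dtype=float).T  # 2 x k
        row = obs.sum(axis=1, keepdims=True)
        col = obs.sum(axis=0, keepdims=True)
        expected = row @ col / obs.sum()
        chi2 = float(((obs - expected) ** 2 / expected).sum())
        p = float(sps.chi2.sf(chi2, obs.shape[1] - 1))
        res = pearson_chisq(obs.astype(int))
        assert res.statistic == pytest.approx(chi2, rel=1e-10)
        assert res.p == pytest.approx(p, rel=1e-10, abs=1e-300)

    def test_degenerate_table(self):
        with pytest.raises(StatsError, match="degenerate-table"):
            pearson_chisq([[0, 0], [5, 5]])
        with pytest.raises(StatsError, match="degenerate-table"):
            pearson_chisq([[1, 2, 3]])


class TestCompareContinuous:
    def test_identical_samples_p_one(self):
        res = compare_continuous([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert res.p == pytest.approx(1.0)

    def test_separated_samples(self):
        x, y = [1.0, 2.0, 3.0], [1001.0, 1002.0, 1003.0]
        assert compare_continuous(x, y, policy="t").p < 0.05
        # the exact two-sided U test on 3-vs-3 bottoms out at 2/C(6,3) = 0.1:
        # complete separation attains that floor exactly
        assert compare_continuous(x, y, policy="mannwhitney").p == pytest.approx(0.1)

    def test_u_branch_matches_exhaustive_rank_enumeration(self):
        """Two-sided Mann-Whitney p on tiny samples equals the permutation
        distribution of U enumerated over all label assignments."""
        x, y = [1.2, 3.4, 5.6], [2.1, 7.8, 9.9]
        res = compare_continuous(x, y, policy="mannwhitney")
        pooled = x + y
        n1 = len(x)
        u_obs = sum(1 for xi in x for yi in y if xi > yi) + 0.5 * sum(
            1 for xi in x for yi in y if xi == yi
        )
        mu = len(x) * len(y) / 2
        count = total = 0
        for idx in itertools.combinations(range(len(pooled)), n1):
            gx = [pooled[i] for i in idx]
            gy = [pooled[i] for i in range(len(pooled)) if i not in idx]
            u = sum(1 for xi in gx for yi in gy if xi > yi) + 0.5 * sum(
                1 for xi in gx for yi in gy if xi == yi
            )
            total += 1
            if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
                count += 1
        assert res.p == pytest.approx(count / total, abs=1e-9)

    def test_normality_gate_routes_skewed_data_to_u(self, rng):
        x = np.exp(rng.normal(size=60) * 2.0)  # heavily skewed
        y = np.exp(rng.normal(size=60) * 2.0) * 3
        assert compare_continuous(x, y).name == "mann-whitney-u"
        a = rng.normal(10, 2, size=60)
        b = rng.normal(12, 2, size=60)
        assert compare_continuous(a, b).name == "student-t"

    def test_constant_sample_falls_back_to_u(self):
        res = compare_continuous([5.0] * 10, [5.0] * 10)
        assert res.name == "mann-whitney-u"
        assert res.p == pytest.approx(1.0)

    def test_symmetry(self, rng):
        x = rng.normal(0, 1, 30)
        y = rng.normal(1, 2, 25)
        assert compare_continuous(x, y).p == pytest.approx(compare_continuous(y, x).p)

    def test_insufficient_sample(self):
        with pytest.raises(StatsError, match="insufficient-sample"):
            compare_continuous([1.0, 2.0], [1.0, 2.0, 3.0])


_CELL_RE = re.compile(r"^(\d+)/(\d+) \((\d+\.\d)%\)$")


class TestPrevalenceTable:
    @given(st.lists(st.tuples(st.integers(0, 50), st.integers(1, 400)), min_size=8, max_size=8))
    @settings(deadline=None, derandomize=True, max_examples=30)
    def test_rendered_percentages_parse_back(self, draws):
        bands = ["40-49", "50-59", "60-69", "70+"]
        cells = []
        for i, (num, extra) in enumerate(draws):
            den = num + extra
            cells.append(StratumCount("male" if i < 4 else "female", bands[i % 4], num, den))
        table = prevalence_table(StratifiedCounts(cells))
        for cell in table.to_numpy().ravel():
            m = _CELL_RE.match(cell)
            assert m, cell
            num, den, pct = int(m.group(1)), int(m.group(2)), float(m.group(3))
            assert pct == percentage(num, den)

    def test_margins_are_cell_sums_by_default(self):
        cells = [
            StratumCount("male", "40-49", 1, 10),
            StratumCount("female", "40-49", 2, 20),
            StratumCount("male", "50-59", 3, 30),
            StratumCount("female", "50-59", 4, 40),
        ]
        table = prevalence_table(StratifiedCounts(cells))
        assert table.loc["Total", "Total"].startswith("10/100")
        assert table.loc["40-49", "Total"].startswith("3/30")
        assert table.loc["Total", "male"].startswith("4/40")

    def test_zero_denominator_renders_dash(self):
        cells = [StratumCount("male", "40-49", 0, 0)]
        table = prevalence_table(StratifiedCounts(cells))
        assert table.loc["40-49", "male"] == "-"

    def test_invalid_cell_rejected(self):
        with pytest.raises(ValueError):
            StratumCount("male", "40-49", 5, 4)


class TestRenderTables:
    def test_reference_grid_reproduces_printed_percentages(self):
        table = render_table2(reference_table2())
        assert table.loc["Total", "Total"].startswith("78/991 (7.9%)")
        assert table.loc["Total", "male"] == "32/579 (5.5%)"
        assert table.loc["Total", "female"] == "46/412 (11.2%)"
        assert table.loc["40-49", "Total"] == "9/313 (2.9%)"
        assert table.loc["40-49", "P value"] == "0.011"
        assert table.loc["50-59", "P value"] == "0.005"
        assert table.loc["60-69", "P value"] == "0.036"
        assert table.loc["Total", "P value"] == "0.001"
        assert table.loc["P value", "male"] == "< 0.001"
        assert table.loc["P value", "female"] == "0.004"

    def test_table1_shape(self, rng):
        import pandas as pd

        def frame(n, hrac):
            return pd.DataFrame(
                {
                    "age": rng.normal(61 if hrac else 55, 8, n),
                    "gender": rng.choice(["male", "female"], n),
                    "eye_configuration": rng.choice(
                        ["mixed", "bombe", "thick_peripheral"] if hrac else ["flat", "bowing"], n
                    ),
                }
            )

        t1 = render_table1(frame(78, True), frame(913, False))
        assert "Characteristic" in t1.columns
        assert (t1["Characteristic"] == "Male gender (%)").any()
        assert (t1["Characteristic"].str.startswith("Iris configuration")).sum() == 5

    def test_markdown_rendering_well_formed(self):
        md = frame_to_markdown(prevalence_table(reference_table2()), "Age, years")
        lines = md.strip().splitlines()
        assert lines[0].startswith("| Age, years |")
        assert all(line.count("|") == lines[0].count("|") for line in lines)

    def test_format_p_floor(self):
        assert format_p(0.0004) == "< 0.001"
        assert format_p(0.0106) == "0.011"
        assert format_p(0.584) == "0.584"
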