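"""Stratified prevalence tables and group comparisons.

Percentages are rendered half-up to one decimal; p-values to three decimals
with a "< 0.001" floor. The chi-square is uncorrected Pearson (no Yates
continuity correction): with the continuity correction the published
stratified significance levels are not reproduced, without it they are.
The continuous-comparison policy gates Student's t on Shapiro-Wilk
normality of both samples at alpha = 0.05, falling back to the
Mann-Whitney U test; the gate is overridable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .enums import AGE_BANDS, Gender
from .errors import AngleguardError

__all__ = [
    "StatsError",
    "StratumCount",
    "StratifiedCounts",
    "TestResult",
    "percentage",
    "format_percentage",
    "format_p",
    "prevalence_table",
    "pearson_chisq",
    "compare_continuous",
    "render_table1",
    "render_table2",
    "reference_table2",
    "frame_to_markdown",
    "write_report",
]

_GENDERS = (Gender.MALE.value, Gender.FEMALE.value)


class StatsError(AngleguardError):
    """Statistical routine failed (``degenerate-table``, ``insufficient-sample``)."""


@dataclass
class TestResult:
    name: str
    statistic: float
    p: float
    df: float | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.p <= 1:
            raise ValueError(f"p-value {self.p} outside [0, 1]")

    @property
    def p_text(self) -> str:
        return format_p(self.p)


@dataclass
class StratumCount:
    gender: str
    age_band: str
    numerator: int
    denominator: int

    def __post_init__(self) -> None:
        if not 0 <= self.numerator <= self.denominator:
            raise ValueError(
                f"stratum {self.gender}/{self.age_band}: numerator {self.numerator} "
                f"outside [0, denominator={self.denominator}]"
            )


@dataclass
class StratifiedCounts:
    """Gender-by-age-band numerators (cases) and denominators (eligible).

    Margins default to sums of the cells. They may also be supplied
    explicitly -- the intended use is transcribing a published table whose
    printed margins are to be honored verbatim; any mismatch with the cell
    sums is then the source's, not this container's.
    """

    cells: list[StratumCount]
    row_totals: dict[str, tuple[int, int]] | None = None
    col_totals: dict[str, tuple[int, int]] | None = None
    grand_total: tuple[int, int] | None = None

    def cell(self, gender: str, band: str) -> StratumCount | None:
        for c in self.cells:
            if c.gender == gender and c.age_band == band:
                return c
        return None

    def _sum(self, gender: str | None = None, band: str | None = None) -> tuple[int, int]:
        num = den = 0
        for c in self.cells:
            if (gender is None or c.gender == gender) and (band is None or c.age_band == band):
                num += c.numerator
                den += c.denominator
        return num, den

    def row_total(self, band: str) -> tuple[int, int]:
        if self.row_totals and band in self.row_totals:
            return self.row_totals[band]
        return self._sum(band=band)

    def col_total(self, gender: str) -> tuple[int, int]:
        if self.col_totals and gender in self.col_totals:
            return self.col_totals[gender]
        return self._sum(gender=gender)

    def total(self) -> tuple[int, int]:
        return self.grand_total if self.grand_total is not None else self._sum()

    @classmethod
    def from_summary(cls, summary: dict) -> "StratifiedCounts":
        """Build from a :func:`~angleguard.screening.run_screening` summary."""
        cells = [
            StratumCount(g, b, int(num), int(den))
            for (g, b), (num, den) in summary["by_stratum"].items()
            if den > 0
        ]
        return cls(cells=cells)


def percentage(numerator: int, denominator: int) -> float | None:
    """100*num/den rounded half-up to 1 decimal; ``None`` for an empty cell."""
    if denominator == 0:
        return None
    q = Decimal(100 * numerator) / Decimal(denominator)
    return float(q.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def format_percentage(numerator: int, denominator: int) -> str:
    p = percentage(numerator, denominator)
    return "-" if p is None else f"{p:.1f}%"


def format_p(p: float) -> str:
    return "< 0.001" if p < 0.001 else f"{p:.3f}"


def _fmt_cell(num: int, den: int) -> str:
    return "-" if den == 0 else f"{num}/{den} ({format_percentage(num, den)})"


def prevalence_table(counts: StratifiedCounts) -> pd.DataFrame:
    """Age-by-gender prevalence grid with margins.

    Rows are the decade bands plus ``Total``; columns the genders plus
    ``Total``; each cell is rendered ``num/den (pct%)`` with the percentage
    rounded half-up to one decimal. Empty cells render ``-``.
    """
    bands = [b for b in AGE_BANDS if any(c.age_band == b for c in counts.cells)]
    data = {}
    for gender in _GENDERS:
        col = []
        for band in bands:
            c = counts.cell(gender, band)
            col.append(_fmt_cell(c.numerator, c.denominator) if c else "-")
        col.append(_fmt_cell(*counts.col_total(gender)))
        data[gender] = col
    total_col = [_fmt_cell(*counts.row_total(b)) for b in bands]
    total_col.append(_fmt_cell(*counts.total()))
    data["Total"] = total_col
    return pd.DataFrame(data, index=bands + ["Total"])


def pearson_chisq(table) -> TestResult:
    """Uncorrected Pearson chi-square on a 2 x k contingency table."""
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] != 2 or obs.shape[1] < 2:
        raise StatsError("degenerate-table", f"expected a 2 x k table, got shape {obs.shape}")
    if np.any(obs < 0) or not np.allclose(obs, np.round(obs)):
        raise StatsError("degenerate-table", "counts must be nonnegative integers")
    if np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
        raise StatsError("degenerate-table", "a margin of the table is zero")
    chi2, p, dof, _ = sps.chi2_contingency(obs, correction=False)
    return TestResult(name="pearson-chi-square", statistic=float(chi2), p=float(p), df=dof)


def compare_continuous(x, y, policy: str = "auto") -> TestResult:
    """Two-group location comparison: Student's t or Mann-Whitney U.

    ``policy='auto'`` uses Student's t (pooled variance) when both samples
    pass Shapiro-Wilk normality at alpha = 0.05, otherwise the two-sided
    Mann-Whitney U test; ``'t'`` and ``'mannwhitney'`` force a branch.
    Constant samples fail the normality gate.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(y) < 3:
        raise StatsError("insufficient-sample", "need n >= 3 in both samples")
    if policy not in ("auto", "t", "mannwhitney"):
        raise ValueError(f"unknown policy {policy!r}")
    if policy == "auto":
        policy = "t" if _both_normal(x, y) else "mannwhitney"
    if policy == "t":
        res = sps.ttest_ind(x, y, equal_var=True)
        return TestResult(
            name="student-t",
            statistic=float(res.statistic),
            p=float(res.pvalue),
            df=len(x) + len(y) - 2,
        )
    res = sps.mannwhitneyu(x, y, alternative="two-sided")
    return TestResult(name="mann-whitney-u", statistic=float(res.statistic), p=float(res.pvalue))


def _both_normal(x: np.ndarray, y: np.ndarray, alpha: float = 0.05) -> bool:
    for sample in (x, y):
        if np.ptp(sample) == 0:
            return False
        try:
            if sps.shapiro(sample).pvalue <= alpha:
                return False
        except Exception:
            return False
    return True


# ---------------------------------------------------------------------------
# report rendering


def render_table2(counts: StratifiedCounts, with_tests: bool = True) -> pd.DataFrame:
    """Prevalence grid plus per-row and per-column gender/age tests.

    The per-row test is the 2 x 2 gender-by-case chi-square within the age
    band; the per-column test is the 2 x 4 age-by-case chi-square within
    the gender; both uncorrected Pearson on the *cell* counts. Untestable
    rows (a zero margin) render ``-``.
    """
    table = prevalence_table(counts)
    if not with_tests:
        return table
    bands = [b for b in table.index if b != "Total"]
    pvals = []
    for band in bands + ["Total"]:
        cols = []
        for gender in _GENDERS:
            if band == "Total":
                num, den = counts.col_total(gender)
            else:
                c = counts.cell(gender, band)
                if c is None:
                    cols = []
                    break
                num, den = c.numerator, c.denominator
            cols.append([num, den - num])
        try:
            pvals.append(format_p(pearson_chisq(np.array(cols).T).p) if cols else "-")
        except StatsError:
            pvals.append("-")
    table["P value"] = pvals
    row = {}
    for gender in _GENDERS:
        tab = []
        for band in bands:
            c = counts.cell(gender, band)
            if c is None:
                tab = []
                break
            tab.append([c.numerator, c.denominator - c.numerator])
        try:
            row[gender] = format_p(pearson_chisq(np.array(tab).T).p) if tab else "-"
        except StatsError:
            row[gender] = "-"
    tot = [
        [counts.row_total(b)[0], counts.row_total(b)[1] - counts.row_total(b)[0]]
        for b in bands
    ]
    try:
        row["Total"] = format_p(pearson_chisq(np.array(tot).T).p)
    except StatsError:
        row["Total"] = "-"
    row["P value"] = ""
    table.loc["P value"] = [row.get(c, "") for c in table.columns]
    return table


def reference_table2() -> StratifiedCounts:
    """The published age-by-gender HRAC distribution, transcribed verbatim.

    Cells and margins are the printed counts; note the source's internal
    inconsistency (male age-stratum denominators sum to 561, printed male
    total 579), which explicit margins preserve.
    """
    cells = [
        StratumCount("male", "40-49", 1, 165),
        StratumCount("male", "50-59", 6, 190),
        StratumCount("male", "60-69", 18, 186),
        StratumCount("male", "70+", 7, 20),
        StratumCount("female", "40-49", 8, 148),
        StratumCount("female", "50-59", 16, 150),
        StratumCount("female", "60-69", 18, 98),
        StratumCount("female", "70+", 4, 16),
    ]
    return StratifiedCounts(
        cells=cells,
        row_totals={"40-49": (9, 313), "50-59": (22, 340), "60-69": (36, 284), "70+": (11, 36)},
        col_totals={"male": (32, 579), "female": (46, 412)},
        grand_total=(78, 991),
    )


def render_table1(hrac: pd.DataFrame, non_hrac: pd.DataFrame) -> pd.DataFrame:
    """Characteristics and iris-configuration distribution by HRAC status.

    Expects per-participant frames with (any of the) columns ``age``,
    ``gender``, ``pva``, ``iop``, ``eye_configuration``. Continuous rows
    show mean +/- SD with the gated t / Mann-Whitney p; categorical rows
    show n (%) with the chi-square p.
    """
    rows: list[dict] = []

    def continuous(label: str, col: str) -> None:
        if col not in hrac.columns or col not in non_hrac.columns:
            return
        a, b = hrac[col].dropna(), non_hrac[col].dropna()
        try:
            p = format_p(compare_continuous(a, b).p)
        except StatsError:
            p = "-"
        rows.append(
            {
                "Characteristic": label,
                f"With HRAC (N = {len(hrac)})": f"{a.mean():.1f} ± {a.std(ddof=1):.1f}",
                f"Without HRAC (N = {len(non_hrac)})": f"{b.mean():.1f} ± {b.std(ddof=1):.1f}",
                "P value": p,
            }
        )

    continuous("Mean age, years (± standard deviation)", "age")
    if "gender" in hrac.columns:
        m1 = int((hrac["gender"] == "male").sum())
        m0 = int((non_hrac["gender"] == "male").sum())
        try:
            p = format_p(
                pearson_chisq([[m1, len(hrac) - m1], [m0, len(non_hrac) - m0]]).p
            )
        except StatsError:
            p = "-"
        rows.append(
            {
                "Characteristic": "Male gender (%)",
                f"With HRAC (N = {len(hrac)})": f"{m1} ({format_percentage(m1, len(hrac))})",
                f"Without HRAC (N = {len(non_hrac)})": f"{m0} ({format_percentage(m0, len(non_hrac))})",
                "P value": p,
            }
        )
    continuous("Mean presenting visual acuity (logMAR)", "pva_logmar")
    continuous("Mean IOP (mmHg)", "iop")

    if "eye_configuration" in hrac.columns:
        order = ["flat", "bowing", "bombe", "thick_peripheral", "mixed"]
        c1 = hrac["eye_configuration"].value_counts()
        c0 = non_hrac["eye_configuration"].value_counts()
        tab = [[int(c1.get(k, 0)) for k in order], [int(c0.get(k, 0)) for k in order]]
        try:
            p = format_p(pearson_chisq([[v for v in row] for row in tab]).p)
        except StatsError:
            p = "-"
        for i, k in enumerate(order):
            rows.append(
                {
                    "Characteristic": f"Iris configuration: {k}",
                    f"With HRAC (N = {len(hrac)})": f"{tab[0][i]} ({format_percentage(tab[0][i], len(hrac))})",
                    f"Without HRAC (N = {len(non_hrac)})": f"{tab[1][i]} ({format_percentage(tab[1][i], len(non_hrac))})",
                    "P value": p if i == 0 else "",
                }
            )
    return pd.DataFrame(rows)


def frame_to_markdown(df: pd.DataFrame, index_label: str = "") -> str:
    """Render a DataFrame as a GitHub-style pipe table (no extra deps)."""
    header = [index_label] + [str(c) for c in df.columns]
    lines = ["| " + " | ".join(header) + " |", "|" + "|".join("---" for _ in header) + "|"]
    for idx, row in df.iterrows():
        cells = [str(idx)] + [str(v) for v in row.tolist()]
        lines.append("| " + " | ".join(cells) + " |")
    return "\n".join(lines) + "\n"


def write_report(outdir, screening_result, counts: StratifiedCounts | None = None) -> dict:
    """Write table1/table2 (CSV + Markdown), the flow chart and test JSON.

    ``screening_result`` is a :class:`~angleguard.screening.ScreeningResult`;
    ``counts`` defaults to the stratified counts of its summary. Returns the
    paths written.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    res = screening_result.results
    graded = res[res["hrac"].notna()] if "hrac" in res.columns and len(res) else res
    if len(graded):
        t1 = render_table1(graded[graded["hrac"] == True], graded[graded["hrac"] == False])  # noqa: E712
        t1.to_csv(outdir / "table1.csv", index=False)
        (outdir / "table1.md").write_text(frame_to_markdown(t1.set_index("Characteristic"), "Characteristic"))
        paths["table1"] = outdir / "table1.csv"
    counts = counts or StratifiedCounts.from_summary(screening_result.summary)
    t2 = render_table2(counts)
    t2.to_csv(outdir / "table2.csv")
    (outdir / "table2.md").write_text(frame_to_markdown(t2, "Age, years"))
    paths["table2"] = outdir / "table2.csv"
    (outdir / "flowchart.txt").write_text(screening_result.accounting.flowchart() + "\n")
    paths["flowchart"] = outdir / "flowchart.txt"
    tests = {}
    m, f = counts.col_total("male"), counts.col_total("female")
    try:
        gender = pearson_chisq([[m[0], m[1] - m[0]], [f[0], f[1] - f[0]]])
        tests["hrac_by_gender"] = {
            "test": gender.name,
            "statistic": gender.statistic,
            "df": gender.df,
            "p": gender.p,
            "p_text": gender.p_text,
        }
    except StatsError:
        pass
    (outdir / "tests.json").write_text(json.dumps(tests, indent=2) + "\n")
    paths["tests"] = outdir / "tests.json"
    return paths
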