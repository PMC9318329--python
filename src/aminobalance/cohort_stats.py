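"""Distribution-aware summaries, two-group and paired tests, report tables.

Summaries follow the clinical-reporting convention: mean ± SD for normally
distributed variables, median (Q1; Q3) otherwise.  Normality defaults to a
Shapiro–Wilk test at α = 0.05, but the display choice for each panel analyte
can be pinned via a preset so that table layout does not depend on a
re-derived test (the preset mirrors the variables conventionally shown as
median (IQR): heavy-tailed analytes such as taurine, citrulline, tryptophan).

Derived comparison columns:

* proportional difference (%) = (HD central − control central)/control × 100,
  rounded half-away-from-zero to integer percent;
* HD:control ratio, shown with one decimal below 2 and as an integer above;
* intradialytic proportional change (%) = absolute change / predialysis × 100.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import quantification as quant
from . import reference_data as ref

__all__ = [
    "SummaryStat",
    "TestResult",
    "assess_distribution",
    "summarize",
    "proportional_difference",
    "group_ratio",
    "compare_groups",
    "compare_paired",
    "PRESET_SKEWED",
    "build_table",
]

# Analytes displayed as median (IQR), per compartment. "plasma" governs both
# the HD-vs-control and the pre-vs-post comparison; "losses" governs the
# daily-loss comparison (both arms share the row's display form).
PRESET_SKEWED: dict[str, frozenset[str]] = {
    "plasma": frozenset({"tryptophan", "citrulline", "glutamic acid", "proline", "taurine"}),
    "losses": frozenset(
        {"lysine", "phenylalanine", "threonine", "valine", "citrulline", "serine", "taurine"}
    ),
}

GROUP_ROWS = ["bcaa", "essential", "non-essential", "total"]


@dataclass
class SummaryStat:
    """Central value + dispersion with the distribution flag that chose them."""

    central: float
    dispersion: tuple[float, float] | float  # SD, or (Q1, Q3)
    dist_flag: str  # "normal" | "skewed" | "skewed-degenerate"
    n: int

    def display(self, fmt: str = "{:.0f}") -> str:
        if self.dist_flag == "normal":
            return f"{fmt.format(self.central)} ± {fmt.format(self.dispersion)}"
        q1, q3 = self.dispersion
        return f"{fmt.format(self.central)} ({fmt.format(q1)}; {fmt.format(q3)})"


@dataclass
class TestResult:
    test: str
    statistic: float
    p: float
    note: str | None = None


def assess_distribution(values, alpha: float = 0.05) -> str:
    """Classify a sample as "normal" or "skewed" (Shapiro–Wilk, p ≥ α ⇒ normal).

    A zero-variance sample is flagged "skewed-degenerate".  Requires n ≥ 3.
    """
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if x.size < 3:
        raise ValueError(f"need at least 3 observations to assess distribution, got {x.size}")
    if np.ptp(x) == 0:
        return "skewed-degenerate"
    _, p = stats.shapiro(x)
    return "normal" if p >= alpha else "skewed"


def summarize(values, dist_flag: str | None = None) -> SummaryStat:
    """Mean ± SD or median (Q1; Q3) per the distribution flag (auto if None)."""
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if x.size == 0:
        raise ValueError("cannot summarize an empty vector")
    if dist_flag is None:
        dist_flag = assess_distribution(x) if x.size >= 3 else "normal"
    if dist_flag == "normal":
        sd = float(np.std(x, ddof=1)) if x.size > 1 else 0.0
        return SummaryStat(float(np.mean(x)), sd, "normal", x.size)
    q1, q3 = np.percentile(x, [25, 75])
    return SummaryStat(float(np.median(x)), (float(q1), float(q3)), dist_flag, x.size)


def _round_half_away(x: float, decimals: int = 0) -> float:
    scale = 10.0**decimals
    return math.copysign(math.floor(abs(x) * scale + 0.5), x) / scale


def proportional_difference(stat_hd: float, stat_ctrl: float) -> int:
    """(HD − control)/control × 100, on the displayed central values, integer %."""
    if stat_ctrl <= 0:
        raise quant.DomainError("control central value must be > 0")
    return int(_round_half_away((stat_hd - stat_ctrl) / stat_ctrl * 100.0))


def group_ratio(stat_hd: float, stat_ctrl: float) -> float:
    """HD/control ratio with display rounding: 1 decimal below 2, integer above."""
    if stat_ctrl <= 0:
        raise quant.DomainError("control central value must be > 0")
    r = stat_hd / stat_ctrl
    return _round_half_away(r, 1) if r < 2 else _round_half_away(r, 0)


def rounded_proportional_change(absolute: float, pre: float) -> int:
    """Intradialytic proportional change, rounded to integer % for display."""
    return int(_round_half_away(quant.proportional_change(absolute, pre)))


# ---------------------------------------------------------------------------
# hypothesis-test dispatch

def _rank_sum(a: np.ndarray, b: np.ndarray) -> TestResult:
    # exact null distribution for small tie-free samples, else normal
    # approximation with continuity correction, ties mid-ranked
    pooled = np.concatenate([a, b])
    exact_ok = max(a.size, b.size) <= 25 and np.unique(pooled).size == pooled.size
    method = "exact" if exact_ok else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=True)
    return TestResult("wilcoxon-rank-sum", float(res.statistic), float(res.pvalue), note=method)


def compare_groups(
    a,
    b,
    dtype: str = "continuous",
    dist_flag: str | None = None,
    *,
    yates: bool = False,
) -> TestResult:
    """Two-group comparison with the conventional dispatch.

    continuous + normal → independent two-sample t-test (pooled variance);
    continuous + skewed → Wilcoxon rank-sum; nominal → chi-squared on the
    contingency table (Yates correction off by default).
    """
    if dtype == "nominal":
        a = np.asarray(a)
        b = np.asarray(b)
        if a.size == 0 or b.size == 0:
            raise ValueError("empty group")
        levels = np.union1d(a, b)
        table = np.array(
            [[np.sum(g == lv) for lv in levels] for g in (a, b)], dtype=float
        )
        chi2, p, _, _ = stats.chi2_contingency(table, correction=yates)
        return TestResult("chi-squared", float(chi2), float(p))
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size == 0 or b.size == 0:
        raise ValueError("empty group")
    if dist_flag is None:
        flags = {assess_distribution(a), assess_distribution(b)}
        dist_flag = "normal" if flags == {"normal"} else "skewed"
    if dist_flag == "normal":
        t, p = stats.ttest_ind(a, b, equal_var=True)
        return TestResult("t-test", float(t), float(p))
    return _rank_sum(a, b)


def compare_paired(pre, post, dist_flag: str | None = None) -> TestResult:
    """Paired comparison: paired t-test or Wilcoxon signed-rank on the differences.

    Pairwise complete cases only.  All-zero differences return the documented
    degenerate convention (statistic 0, p = 1).
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("pre and post must have equal length")
    keep = ~(np.isnan(pre) | np.isnan(post))
    d = post[keep] - pre[keep]
    if d.size == 0:
        raise ValueError("no complete pairs")
    if np.all(d == 0):
        return TestResult("wilcoxon-signed-rank", 0.0, 1.0, note="all differences zero")
    if dist_flag is None:
        dist_flag = assess_distribution(d) if d.size >= 3 else "normal"
    if dist_flag == "normal":
        if np.std(d, ddof=1) == 0:
            return TestResult("paired-t", float("inf"), 0.0, note="zero-variance differences")
        t, p = stats.ttest_rel(post[keep], pre[keep])
        return TestResult("paired-t", float(t), float(p))
    exact_ok = d.size <= 25 and np.unique(np.abs(d[d != 0])).size == np.count_nonzero(d)
    res = stats.wilcoxon(d, method="exact" if exact_ok else "approx")
    return TestResult("wilcoxon-signed-rank", float(res.statistic), float(res.pvalue))


# ---------------------------------------------------------------------------
# report tables

def _display_flag(analyte: str, compartment: str, values) -> str:
    preset = PRESET_SKEWED.get(compartment, frozenset())
    if analyte in preset:
        return "skewed"
    if analyte in ref.REGISTRY or analyte in GROUP_ROWS:
        return "normal"
    return assess_distribution(values) if len(values) >= 3 else "normal"


def _with_groups(wide: pd.DataFrame) -> pd.DataFrame:
    """Append BCAA/essential/non-essential/total sum columns to a wide panel frame."""
    out = wide.copy()
    sums = wide.apply(lambda row: quant.group_sums(row.dropna().to_dict()), axis=1)
    for g in GROUP_ROWS:
        out[g] = [s[g] for s in sums]
    return out


def _comparison_table(
    wide_hd: pd.DataFrame,
    wide_ctrl: pd.DataFrame,
    compartment: str,
    derived: str,
) -> pd.DataFrame:
    rows = []
    for analyte in list(wide_hd.columns):
        a = wide_hd[analyte].dropna().to_numpy()
        b = wide_ctrl[analyte].dropna().to_numpy()
        flag = _display_flag(analyte, compartment, np.concatenate([a, b]))
        s_hd = summarize(a, flag)
        s_ct = summarize(b, flag)
        test = compare_groups(a, b, "continuous", flag)
        row = {
            "analyte": analyte,
            "hd": s_hd.display(),
            "control": s_ct.display(),
            "hd_central": s_hd.central,
            "control_central": s_ct.central,
            "test": test.test,
            "p": test.p,
        }
        if derived == "proportional_difference":
            row["proportional_difference_pct"] = proportional_difference(
                s_hd.central, s_ct.central
            )
        else:
            row["ratio"] = group_ratio(s_hd.central, s_ct.central)
        rows.append(row)
    return pd.DataFrame(rows)


def build_table(cohort, table_id: int) -> pd.DataFrame:
    """Build one of the four report tables from a simulated/loaded cohort.

    1: baseline characteristics; 2: plasma concentrations (HD predialysis vs
    control) with proportional differences; 3: daily losses with HD:control
    ratios; 4: intradialytic pre/post changes.  ``cohort`` is a
    :class:`~aminobalance.io.CohortData`.
    """
    from .io import loss_wide, panel_wide  # local import to avoid cycle

    if table_id == 1:
        return _table1(cohort)
    if table_id == 2:
        hd = _with_groups(panel_wide(cohort, "hd", "plasma_pre"))
        ct = _with_groups(panel_wide(cohort, "control", "plasma"))
        return _comparison_table(hd, ct, "plasma", "proportional_difference")
    if table_id == 3:
        hd = _with_groups(loss_wide(cohort, "hd"))
        ct = _with_groups(loss_wide(cohort, "control"))
        return _comparison_table(hd, ct, "losses", "ratio")
    if table_id == 4:
        pre = _with_groups(panel_wide(cohort, "hd", "plasma_pre"))
        post = _with_groups(panel_wide(cohort, "hd", "plasma_post"))
        rows = []
        for analyte in pre.columns:
            a, b = pre[analyte].to_numpy(), post[analyte].to_numpy()
            flag = _display_flag(analyte, "plasma", a)
            s_pre, s_post = summarize(a, flag), summarize(b, flag)
            delta = b - a
            s_delta = summarize(delta, flag)
            test = compare_paired(a, b, flag)
            rows.append(
                {
                    "analyte": analyte,
                    "pre": s_pre.display(),
                    "post": s_post.display(),
                    "pre_central": s_pre.central,
                    "post_central": s_post.central,
                    "absolute_change": s_delta.central,
                    "proportional_change_pct": rounded_proportional_change(
                        s_delta.central, s_pre.central
                    ),
                    "test": test.test,
                    "p": test.p,
                }
            )
        return pd.DataFrame(rows)
    raise ValueError(f"unknown table id {table_id}")


def _table1(cohort) -> pd.DataFrame:
    subj = cohort.subjects
    hd = subj[subj.arm == "hd"]
    ct = subj[subj.arm == "control"]
    rows = []

    def cont(label, col, flag=None):
        a, b = hd[col].dropna(), ct[col].dropna() if col in ct else pd.Series(dtype=float)
        s = summarize(a, flag)
        row = {"variable": label, "hd": s.display("{:.1f}")}
        if len(b):
            row["control"] = summarize(b, flag).display("{:.1f}")
            row["p"] = compare_groups(a, b, "continuous", flag).p
        rows.append(row)

    def nom(label, col):
        a = hd[col].astype(int)
        row = {"variable": label, "hd": f"{a.sum()} ({100 * a.mean():.0f})"}
        if col in ct.columns and ct[col].notna().any():
            b = ct[col].astype(int)
            row["control"] = f"{b.sum()} ({100 * b.mean():.0f})"
            row["p"] = compare_groups(a, b, "nominal").p
        rows.append(row)

    cont("Age, years", "age", "normal")
    nom("Sex, n male (%)", "male")
    cont("Dialysis vintage, months", "vintage_months", "skewed")
    nom("Three sessions per week, n (%)", "thrice_weekly")
    cont("Dialysate volume, L", "v_dialysate", "normal")
    cont("Ultrafiltration volume, L", "uf_volume", "normal")
    cont("Kt/V", "ktv", "normal")
    nom("Residual diuresis, n (%)", "has_diuresis")
    cont("Hemoglobin, mmol/L", "hemoglobin", "normal")
    cont("Plasma albumin, g/L", "albumin", "normal")
    cont("Weight postdialysis, kg", "weight_post", "normal")
    cont("Height, m", "height", "normal")
    cont("BMI, kg/m2", "bmi", "normal")
    cont("Protein intake absolute, g/24 h", "protein_intake_g", "normal")
    cont("Protein intake per kg bodyweight, g/kg/24 h", "protein_intake_gkg", "normal")
    return pd.DataFrame(rows)
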