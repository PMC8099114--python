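"""Cohort-level time-lapse analysis: per-cell metric series and group statistics.

This orchestrates the per-nucleus metrics over whole cohorts: building CI or
normalized-GI time series per cell, paired pre/post tables, cumulative
distributions with low/medium/high bin fractions, and the standard two-way
(treatment x time) ANOVA with Sidak-corrected post-hoc comparisons. The unit
of analysis is the cell.

The ANOVA stage is deliberately standard and delegates to established
statistics routines. Because each cell is measured repeatedly over time, the
default is a mixed (split-plot) two-way ANOVA with the cell as subject —
treatment between subjects, time within — so the interaction test is
calibrated in the presence of cell-level random effects; ``blocked=False``
gives the plain pooled two-way ANOVA instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .circularity import CIBinScheme, SLICE_SCHEME, compute_ci
from .granularity import compute_gi, normalize_gi_series
from .preprocess import crop_roi

__all__ = [
    "CellTimeSeries",
    "GroupComparison",
    "CDFBins",
    "build_series",
    "series_to_long",
    "prepost_table",
    "cdf_and_bins",
    "anova_two_way",
]


@dataclass(frozen=True)
class CellTimeSeries:
    """Per-cell metric trajectory; failed time points are NaN with a QC flag."""

    cell_id: str
    group: str
    times: tuple[float, ...]
    values: tuple[float, ...]
    metric: str  # "ci" or "gi"
    qc_flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        t = np.asarray(self.times)
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if len(self.times) != len(self.values):
            raise ValueError("times and values must have equal length")
        if self.metric == "ci":
            vals = np.asarray(self.values, dtype=float)
            ok = np.isnan(vals) | ((vals >= 0) & (vals <= 1))
            if not np.all(ok):
                raise ValueError("CI values must lie in [0, 1]")


@dataclass(frozen=True)
class GroupComparison:
    """ANOVA table plus Sidak-adjusted pairwise post-hoc comparisons."""

    anova: pd.DataFrame  # columns: source, df1, df2, F, p
    posthoc: pd.DataFrame  # columns: time, group_a, group_b, t, p_raw, p_sidak

    def p_interaction(self) -> float:
        row = self.anova[self.anova["source"] == "interaction"]
        return float(row["p"].iloc[0])


@dataclass(frozen=True)
class CDFBins:
    """Empirical CDF of CI values plus bin fractions under a scheme."""

    x: np.ndarray  # sorted values
    cdf: np.ndarray  # P(CI <= x)
    bin_fractions: dict  # low/medium/high -> fraction (sums to 1)
    n_gap_flagged: int  # values in the scheme's unassigned band


def build_series(
    stacks_by_cell,
    groups: dict[str, str] | None = None,
    metric: str = "ci",
    roi_center: tuple[float, float] | None = None,
    roi_size: tuple[int, int] = (100, 100),
    **metric_kw,
) -> list[CellTimeSeries]:
    """Compute per-cell metric series over a cohort.

    ``stacks_by_cell`` maps cell_id to a time-ordered list of stacks (a
    simulated ``Cohort`` may be passed directly). Per-time-point failures
    (e.g. a degenerate label) are recorded as NaN with a QC flag instead of
    aborting the cohort; cells with no valid time point are dropped.
    """
    if hasattr(stacks_by_cell, "stacks") and hasattr(stacks_by_cell, "truth"):
        cohort = stacks_by_cell
        groups = cohort.truth.group_of()
        stacks_by_cell = cohort.stacks
    if metric not in ("ci", "gi"):
        raise ValueError("metric must be 'ci' or 'gi'")
    groups = groups or {}
    out: list[CellTimeSeries] = []
    for cell_id, stacks in stacks_by_cell.items():
        times, values, flags = [], [], []
        if roi_center is not None:
            stacks = [crop_roi(s, roi_center, roi_size) for s in stacks]
        if metric == "gi":
            gi_results, gi_times = [], []
            for stack in stacks:
                try:
                    gi_results.append(compute_gi(stack))
                    gi_times.append(stack.time)
                except (ValueError, RuntimeError) as err:
                    flags.append(f"t={stack.time}: {err}")
            if not gi_results:
                continue
            series = normalize_gi_series(gi_results, gi_times)
            times, values = list(series.times), list(series.gi_norm)
        else:
            for stack in stacks:
                try:
                    res = compute_ci(stack, **metric_kw)
                    values.append(res.ci)
                except (ValueError, RuntimeError) as err:
                    values.append(np.nan)
                    flags.append(f"t={stack.time}: {err}")
                times.append(stack.time)
            if np.all(np.isnan(values)):
                continue
        out.append(
            CellTimeSeries(
                cell_id=cell_id,
                group=groups.get(cell_id, "default"),
                times=tuple(times),
                values=tuple(values),
                metric=metric,
                qc_flags=tuple(flags),
            )
        )
    return out


def series_to_long(series: list[CellTimeSeries]) -> pd.DataFrame:
    """Tidy long-form table (cell, group, time, value), NaN rows dropped."""
    rows = [
        (s.cell_id, s.group, t, v)
        for s in series
        for t, v in zip(s.times, s.values)
        if np.isfinite(v)
    ]
    return pd.DataFrame(rows, columns=["cell", "group", "time", "value"])


def prepost_table(
    series: list[CellTimeSeries], t_pre: float, t_post: float
) -> tuple[pd.DataFrame, int]:
    """Per-cell (pre, post) value pairs by group.

    Cells missing either time point (absent or NaN) are excluded; the second
    return value counts them. Raises if no complete cell remains.
    """
    rows, n_excluded = [], 0
    for s in series:
        lookup = dict(zip(s.times, s.values))
        pre, post = lookup.get(t_pre, np.nan), lookup.get(t_post, np.nan)
        if np.isfinite(pre) and np.isfinite(post):
            rows.append((s.cell_id, s.group, pre, post))
        else:
            n_excluded += 1
    if not rows:
        raise ValueError("no cell has both the pre and post time point")
    return (
        pd.DataFrame(rows, columns=["cell", "group", "pre", "post"]),
        n_excluded,
    )


def cdf_and_bins(values, scheme: CIBinScheme = SLICE_SCHEME) -> CDFBins:
    """Empirical CDF and low/medium/high bin fractions of CI values."""
    vals = np.asarray(values, dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("no values to summarize")
    if np.any((vals < 0) | (vals > 1)):
        raise ValueError("CI values must lie in [0, 1]")
    x = np.sort(vals)
    cdf = np.arange(1, x.size + 1) / x.size
    fractions = {"low": 0.0, "medium": 0.0, "high": 0.0}
    n_gap = 0
    for v in vals:
        label, gap = scheme.classify(float(v))
        fractions[label] += 1.0 / vals.size
        n_gap += int(gap)
    return CDFBins(x=x, cdf=cdf, bin_fractions=fractions, n_gap_flagged=n_gap)


def anova_two_way(
    data: pd.DataFrame,
    dv: str = "value",
    between: str = "group",
    within: str = "time",
    subject: str = "cell",
    blocked: bool = True,
) -> GroupComparison:
    """Two-way (treatment x time) ANOVA with Sidak post-hoc comparisons.

    With ``blocked=True`` (default) a mixed split-plot ANOVA is fitted with
    the cell as subject (between-subject treatment factor, within-subject
    time factor); with ``blocked=False`` a plain pooled two-way ANOVA is
    fitted, matching a naive cell x time table. Post-hoc: Welch t-tests for
    all group pairs within each time level, Sidak-corrected over the whole
    family (``p_adj = 1 - (1 - p)^m``).
    """
    for col in (dv, between, within, subject):
        if col not in data.columns:
            raise ValueError(f"column {col!r} missing from data")
    groups = sorted(data[between].unique())
    times = sorted(data[within].unique())
    if len(groups) < 2 or len(times) < 2:
        raise ValueError("need at least two levels per factor")

    if blocked:
        import pingouin as pg

        aov = pg.mixed_anova(
            data=data, dv=dv, within=within, between=between, subject=subject
        )
        name_map = {between: "treatment", within: "time", "Interaction": "interaction"}
        p_col = "p_unc" if "p_unc" in aov.columns else "p-unc"
        table = pd.DataFrame(
            {
                "source": [name_map.get(s, s) for s in aov["Source"]],
                "df1": aov["DF1"].to_numpy(float),
                "df2": aov["DF2"].to_numpy(float),
                "F": aov["F"].to_numpy(float),
                "p": aov[p_col].to_numpy(float),
            }
        )
    else:
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        d = data.rename(columns={dv: "_y", between: "_g", within: "_t"})
        fit = smf.ols("_y ~ C(_g) * C(_t)", data=d).fit()
        aov = sm.stats.anova_lm(fit, typ=2)
        resid_df = float(aov.loc["Residual", "df"])
        rows = []
        for src, label in (
            ("C(_g)", "treatment"),
            ("C(_t)", "time"),
            ("C(_g):C(_t)", "interaction"),
        ):
            rows.append(
                (
                    label,
                    float(aov.loc[src, "df"]),
                    resid_df,
                    float(aov.loc[src, "F"]),
                    float(aov.loc[src, "PR(>F)"]),
                )
            )
        table = pd.DataFrame(rows, columns=["source", "df1", "df2", "F", "p"])

    # Sidak-corrected pairwise group comparisons within each time level
    pairs = [(a, b) for i, a in enumerate(groups) for b in groups[i + 1 :]]
    m = len(pairs) * len(times)
    ph_rows = []
    for t in times:
        at_t = data[data[within] == t]
        for a, b in pairs:
            xa = at_t.loc[at_t[between] == a, dv].to_numpy(float)
            xb = at_t.loc[at_t[between] == b, dv].to_numpy(float)
            tt = stats.ttest_ind(xa, xb, equal_var=False)
            p_sidak = 1.0 - (1.0 - tt.pvalue) ** m
            ph_rows.append((t, a, b, float(tt.statistic), float(tt.pvalue), float(p_sidak)))
    posthoc = pd.DataFrame(
        ph_rows, columns=["time", "group_a", "group_b", "t", "p_raw", "p_sidak"]
    )
    return GroupComparison(anova=table, posthoc=posthoc)
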