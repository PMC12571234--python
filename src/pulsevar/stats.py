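"""Phase-comparison statistics over the cohort's PRV metric tables.

The analysis mirrors the standard hemorrhage-study workflow: per-subject
percent changes between the 15-minute phases, then, for each metric, a
one-way ANOVA across the nine 5-minute groups (labels 5..45, three per
phase) at alpha = 0.05, Anderson-Darling normality assessment with q-q
coordinates, and Tukey's honestly-significant-difference test over all 36
group pairs to keep the family-wise error rate at 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupTable", "AnovaResult", "PairwiseResult", "NormalityResult",
    "percent_change", "anova_oneway", "tukey_hsd", "normality",
    "phase_report", "PhaseReport",
]


@dataclass
class GroupTable:
    """Per-group vectors of one metric across subjects.

    ``groups`` maps group label -> 1-D array of per-subject values; every
    group must have the same subject count and finite values.
    """

    metric: str
    groups: dict

    def __post_init__(self) -> None:
        if len(self.groups) < 2:
            raise ValueError("need at least 2 groups")
        sizes = set()
        clean = {}
        for label, vals in self.groups.items():
            arr = np.asarray(vals, dtype=float)
            if arr.ndim != 1 or arr.size < 2:
                raise ValueError(f"group {label} needs at least 2 values")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"group {label} contains non-finite values")
            clean[label] = arr
            sizes.add(arr.size)
        if len(sizes) != 1:
            raise ValueError(f"all groups must have the same size, got {sorted(sizes)}")
        self.groups = clean

    @property
    def labels(self) -> list:
        return sorted(self.groups)

    def arrays(self) -> list:
        return [self.groups[k] for k in self.labels]


@dataclass(frozen=True)
class AnovaResult:
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float


@dataclass(frozen=True)
class PairwiseResult:
    """Tukey-adjusted p-values for every ordered group pair."""

    labels: list
    p_values: pd.DataFrame   # symmetric label x label matrix
    significant: pd.DataFrame
    alpha: float = 0.05

    def pairs(self):
        """Yield (label_a, label_b, p, significant) for each unordered pair."""
        for i, a in enumerate(self.labels):
            for b in self.labels[i + 1:]:
                yield a, b, float(self.p_values.loc[a, b]), bool(self.significant.loc[a, b])


@dataclass(frozen=True)
class NormalityResult:
    a_squared: float
    reject_at_05: bool
    qq_theoretical: np.ndarray
    qq_ordered: np.ndarray


def percent_change(before: float, after: float) -> float:
    """Signed percent change 100 * (after - before) / before.

    Raises
    ------
    ValueError
        If ``before`` is zero.
    """
    if before == 0:
        raise ValueError("percent change undefined for before = 0")
    return 100.0 * (after - before) / before


def anova_oneway(table: GroupTable) -> AnovaResult:
    """Classical one-way ANOVA across the table's groups.

    The fully degenerate case (all values identical, zero between- and
    within-group variance) is defined as F = 0, p = 1.
    """
    arrays = table.arrays()
    k = len(arrays)
    n = sum(a.size for a in arrays)
    allv = np.concatenate(arrays)
    if np.ptp(allv) == 0:
        return AnovaResult(0.0, k - 1, n - k, 1.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant-input warnings handled above
        f, p = sps.f_oneway(*arrays)
    return AnovaResult(float(f), k - 1, n - k, float(p))


def tukey_hsd(table: GroupTable, alpha: float = 0.05) -> PairwiseResult:
    """Tukey HSD over every group pair, pooled within-group variance.

    Adjusted p-values come from the studentized range distribution; the
    significance flags hold the family-wise error rate at ``alpha``.
    """
    arrays = table.arrays()
    labels = table.labels
    res = sps.tukey_hsd(*arrays)
    p = pd.DataFrame(np.clip(res.pvalue, 0.0, 1.0), index=labels, columns=labels)
    sig = (p < alpha) & ~np.eye(len(labels), dtype=bool)
    return PairwiseResult(labels=labels, p_values=p,
                          significant=pd.DataFrame(sig, index=labels, columns=labels),
                          alpha=alpha)


def normality(values, alpha: float = 0.05) -> NormalityResult:
    """Anderson-Darling test (mean/variance estimated from the sample) plus
    q-q coordinates against the normal distribution.

    The decision interpolates the p-value of A^2 from the
    small-sample-adjusted tables and rejects when it falls below ``alpha``.

    Raises
    ------
    ValueError
        With fewer than 8 values.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 8:
        raise ValueError(f"normality test needs at least 8 values, got {v.size}")
    res = sps.anderson(v, dist="norm", method="interpolate")
    (osm, osr), _ = sps.probplot(v, dist="norm")
    return NormalityResult(a_squared=float(res.statistic),
                           reject_at_05=bool(res.pvalue < alpha),
                           qq_theoretical=osm, qq_ordered=osr)


@dataclass
class PhaseReport:
    """Full statistical report across metrics.

    percent_changes : tidy table (subject_id, metric, comparison, percent).
    anova : metric -> AnovaResult over the 5-minute groups.
    tukey : metric -> PairwiseResult (all 36 pairs under the default protocol).
    normality : metric -> NormalityResult on group-mean-centred residuals.
    summary : tidy table of significant hemorrhage-vs-baseline and
        hemorrhage-vs-recovery pairs per metric.
    dropped : metric -> count of NaN values excluded (undefined LF/HF).
    warnings : list of analysis warnings (missing windows etc.).
    """

    percent_changes: pd.DataFrame
    anova: dict
    tukey: dict
    normality: dict
    summary: pd.DataFrame
    dropped: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)


def _group_table(window_df: pd.DataFrame, metric: str) -> tuple[Optional[GroupTable], int]:
    """Build a GroupTable for one metric from the tidy window-metrics table.

    NaN values (undefined LF/HF) are excluded; to keep group sizes equal
    the affected subjects are dropped listwise for that metric.
    """
    sub = window_df[window_df["metric"] == metric]
    wide = sub.pivot_table(index="subject_id", columns="group_label",
                           values="value", aggfunc="first")
    # a window absent for some subject (truncated recording) removes that
    # group from the comparison; a NaN *value* (e.g. undefined LF/HF)
    # removes the subject listwise
    present = sub.pivot_table(index="subject_id", columns="group_label",
                              values="value", aggfunc="size")
    present = present.reindex_like(wide)
    complete_cols = present.notna().all(axis=0)
    wide = wide.loc[:, complete_cols]
    n_before = wide.shape[0]
    wide = wide.dropna(axis=0)
    dropped = n_before - wide.shape[0]
    if wide.shape[0] < 2 or wide.shape[1] < 2:
        return None, dropped
    groups = {label: wide[label].to_numpy() for label in wide.columns}
    return GroupTable(metric=metric, groups=groups), dropped


def phase_report(phase_df: pd.DataFrame, window_df: pd.DataFrame,
                 alpha: float = 0.05,
                 phase_order: tuple = ("baseline", "hemorrhage", "recovery")
                 ) -> PhaseReport:
    """Assemble the full phase-comparison report.

    Parameters
    ----------
    phase_df : DataFrame
        Tidy 15-minute phase metrics: subject_id, phase, metric, value.
    window_df : DataFrame
        Tidy 5-minute window metrics: subject_id, group_label, phase,
        metric, value.
    """
    warns: list = []
    metrics = sorted(window_df["metric"].unique())

    # per-subject percent changes between consecutive phases (15-min metrics)
    pc_rows = []
    for (sid, metric), grp in phase_df.groupby(["subject_id", "metric"]):
        by_phase = dict(zip(grp["phase"], grp["value"]))
        for a, b in zip(phase_order[:-1], phase_order[1:]):
            if a in by_phase and b in by_phase and np.isfinite(by_phase[a]) \
                    and np.isfinite(by_phase[b]) and by_phase[a] != 0:
                pc_rows.append({"subject_id": sid, "metric": metric,
                                "comparison": f"{a}_to_{b}",
                                "percent": percent_change(by_phase[a], by_phase[b])})
            else:
                warns.append(f"percent change {a}->{b} unavailable for "
                             f"{sid}/{metric}")
    pc = pd.DataFrame(pc_rows, columns=["subject_id", "metric", "comparison", "percent"])

    anova: dict = {}
    tukey: dict = {}
    norm: dict = {}
    dropped: dict = {}
    phase_of = dict(zip(window_df["group_label"], window_df["phase"]))
    summary_rows = []
    for metric in metrics:
        table, n_drop = _group_table(window_df, metric)
        if n_drop:
            dropped[metric] = n_drop
        if table is None:
            warns.append(f"metric {metric}: too few complete subjects for ANOVA")
            continue
        anova[metric] = anova_oneway(table)
        tukey[metric] = tukey_hsd(table, alpha=alpha)
        resid = np.concatenate([g - g.mean() for g in table.arrays()])
        try:
            norm[metric] = normality(resid, alpha=alpha)
        except ValueError as exc:
            warns.append(f"metric {metric}: {exc}")
        for a, b, p, sig in tukey[metric].pairs():
            if not sig:
                continue
            pa, pb = phase_of.get(a), phase_of.get(b)
            if {pa, pb} == {"baseline", "hemorrhage"} or {pa, pb} == {"hemorrhage", "recovery"}:
                hem = a if pa == "hemorrhage" else b
                other = b if hem == a else a
                summary_rows.append({"metric": metric, "hemorrhage_group": hem,
                                     "other_group": other,
                                     "other_phase": phase_of.get(other),
                                     "p_adjusted": p})
    if not anova:
        raise ValueError(
            "no metric could be analyzed (ANOVA needs at least 2 subjects "
            "with complete groups): " + "; ".join(warns)
        )
    summary = pd.DataFrame(summary_rows, columns=["metric", "hemorrhage_group",
                                                  "other_group", "other_phase",
                                                  "p_adjusted"])
    return PhaseReport(percent_changes=pc, anova=anova, tukey=tukey,
                       normality=norm, summary=summary, dropped=dropped,
                       warnings=warns)
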