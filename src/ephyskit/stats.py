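"""The cohort statistical battery and scalar derived measures.

Covers the full analysis toolchain of an aging/treatment animal study:
Grubbs single-outlier screening per group, one-way ANOVA with Tukey–Kramer
post-hoc comparisons, pooled-variance Student's t, two-way repeated-measures
(split-plot) ANOVA, Pearson correlation panels, radial-arm water-maze
3-trial block averaging, delayed-matching-to-place improvement (day-20 minus
day-23 escape latency), 2^−ΔΔCt relative qPCR quantification, and western
densitometry fold change.

Tables are plain pandas DataFrames with columns ``subject``, ``group``,
optionally a repeated factor (e.g. ``day``), and named numeric features.
All p values are two-sided at the conventional α = 0.05; no multiple-testing
correction is applied across correlation panels by default (a
Benjamini–Hochberg option exists).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import ValidationError

__all__ = [
    "AnovaResult",
    "TukeyResult",
    "TukeyPair",
    "CorrelationResult",
    "OutlierReport",
    "GroupOutlier",
    "RMAnovaResult",
    "grubbs_critical_value",
    "grubbs_screen",
    "one_way_anova",
    "tukey_hsd",
    "students_t",
    "rm_anova_two_way",
    "pearson_r",
    "correlation_panel",
    "rawm_blocks",
    "dmp_improvement",
    "ddct_fold_change",
    "densitometry_fold_change",
]

ALPHA = 0.05


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------

@dataclass
class AnovaResult:
    f: float
    df_between: int
    df_within: int
    p: float
    group_means: dict[str, float]
    group_sems: dict[str, float]
    group_ns: dict[str, int]


@dataclass(frozen=True)
class TukeyPair:
    group_a: str
    group_b: str
    mean_diff: float          # mean(a) − mean(b)
    q: float                  # studentized-range statistic
    p_adj: float


@dataclass
class TukeyResult:
    pairs: list[TukeyPair]

    def pair(self, a: str, b: str) -> TukeyPair:
        for p in self.pairs:
            if {p.group_a, p.group_b} == {a, b}:
                return p
        raise KeyError((a, b))


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    p: float


@dataclass(frozen=True)
class GroupOutlier:
    group: str
    n: int
    g: float | None           # Grubbs statistic (None if SD = 0)
    critical: float | None
    excluded_subject: str | None
    excluded_value: float | None


@dataclass
class OutlierReport:
    alpha: float
    groups: list[GroupOutlier]

    def excluded_subjects(self) -> list[str]:
        return [g.excluded_subject for g in self.groups
                if g.excluded_subject is not None]


@dataclass(frozen=True)
class FTest:
    f: float
    df1: int
    df2: int
    p: float


@dataclass
class RMAnovaResult:
    group: FTest         # between-subjects factor
    time: FTest          # within factor
    interaction: FTest


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _group_vectors(table: pd.DataFrame, feature: str
                   ) -> dict[str, np.ndarray]:
    if feature not in table.columns:
        raise ValidationError(f"feature: {feature!r} not in table")
    out: dict[str, np.ndarray] = {}
    for g, sub in table.groupby("group", sort=False):
        out[str(g)] = sub[feature].dropna().to_numpy(dtype=float)
    return out


# ---------------------------------------------------------------------------
# Grubbs outlier screening
# ---------------------------------------------------------------------------

def grubbs_critical_value(n: int, alpha: float = ALPHA) -> float:
    """Two-sided Grubbs critical value from the t-quantile formula:
    G_crit = ((N−1)/√N)·√(t²/(N−2+t²)), t the upper α/(2N) quantile at
    N−2 degrees of freedom."""
    t = sps.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return (n - 1) / np.sqrt(n) * np.sqrt(t * t / (n - 2 + t * t))


def grubbs_screen(data: pd.DataFrame | Mapping[str, Sequence[float]],
                  feature: str | None = None,
                  alpha: float = ALPHA) -> OutlierReport:
    """Single-pass two-sided Grubbs test per group; at most one exclusion
    per group, no iterative re-testing.

    ``data`` is either a table (needs ``feature``) or a mapping of group
    label → values.  Groups with zero spread get no exclusion and G = None.
    """
    import warnings

    if isinstance(data, pd.DataFrame):
        if feature is None:
            raise ValidationError("feature: required with a table input")
        groups = _group_vectors(data, feature)
        subjects = {str(g): sub["subject"].tolist()
                    for g, sub in data.groupby("group", sort=False)}
    else:
        groups = {k: np.asarray(v, dtype=float) for k, v in data.items()}
        subjects = {k: [f"{k}[{i}]" for i in range(len(v))]
                    for k, v in groups.items()}

    out: list[GroupOutlier] = []
    for label, x in groups.items():
        n = x.size
        if n < 3:
            raise ValidationError(f"group {label}: Grubbs needs n >= 3")
        sd = float(np.std(x, ddof=1))
        if sd == 0.0:
            warnings.warn(f"group {label}: zero spread, Grubbs undefined",
                          stacklevel=2)
            out.append(GroupOutlier(label, n, None, None, None, None))
            continue
        dev = np.abs(x - x.mean())
        i = int(np.argmax(dev))
        g = float(dev[i] / sd)
        crit = float(grubbs_critical_value(n, alpha))
        if g > crit:
            out.append(GroupOutlier(label, n, g, crit,
                                    subjects[label][i], float(x[i])))
        else:
            out.append(GroupOutlier(label, n, g, crit, None, None))
    return OutlierReport(alpha=alpha, groups=out)


def apply_outlier_screen(table: pd.DataFrame, feature: str,
                         alpha: float = ALPHA
                         ) -> tuple[pd.DataFrame, OutlierReport]:
    """Convenience: screen and drop the flagged subjects from the table."""
    report = grubbs_screen(table, feature, alpha)
    excluded = set(report.excluded_subjects())
    return table[~table["subject"].isin(excluded)].copy(), report


# ---------------------------------------------------------------------------
# ANOVA family
# ---------------------------------------------------------------------------

def one_way_anova(table: pd.DataFrame, feature: str) -> AnovaResult:
    """Classical one-way between-groups ANOVA (F from the between/within
    mean-square ratio), with per-group means and SEMs."""
    groups = _group_vectors(table, feature)
    if len(groups) < 2:
        raise ValidationError("groups: need >= 2 groups")
    for label, x in groups.items():
        if x.size < 2:
            raise ValidationError(f"group {label}: need n >= 2")
    vecs = list(groups.values())
    f, p = sps.f_oneway(*vecs)
    k = len(vecs)
    n_total = sum(v.size for v in vecs)
    if all(np.ptp(v) == 0 for v in vecs) and f != f:  # all-constant: F=0/0
        f, p = 0.0, 1.0
    return AnovaResult(
        f=float(f), df_between=k - 1, df_within=n_total - k, p=float(p),
        group_means={g: float(v.mean()) for g, v in groups.items()},
        group_sems={g: float(sps.sem(v)) for g, v in groups.items()},
        group_ns={g: int(v.size) for g, v in groups.items()},
    )


def tukey_hsd(table: pd.DataFrame, feature: str) -> TukeyResult:
    """Tukey–Kramer all-pairs comparison (unequal n allowed): studentized
    range q per pair with the pooled within-group error."""
    groups = _group_vectors(table, feature)
    if len(groups) < 2:
        raise ValidationError("groups: need >= 2 groups")
    for label, x in groups.items():
        if x.size < 2:
            raise ValidationError(f"group {label}: need n >= 2")
    labels = list(groups)
    vecs = [groups[g] for g in labels]
    k = len(vecs)
    n_total = sum(v.size for v in vecs)
    df_w = n_total - k
    msw = sum(((v - v.mean()) ** 2).sum() for v in vecs) / df_w
    res = sps.tukey_hsd(*vecs)
    pairs: list[TukeyPair] = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = float(vecs[i].mean() - vecs[j].mean())
            se_q = np.sqrt(msw / 2.0 * (1.0 / vecs[i].size
                                        + 1.0 / vecs[j].size))
            q = abs(diff) / se_q if se_q > 0 else 0.0
            pairs.append(TukeyPair(group_a=labels[i], group_b=labels[j],
                                   mean_diff=diff, q=float(q),
                                   p_adj=float(res.pvalue[i, j])))
    return TukeyResult(pairs=pairs)


def students_t(x: Sequence[float], y: Sequence[float]
               ) -> tuple[float, int, float]:
    """Two-sided pooled-variance Student's t-test; returns (t, df, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValidationError("samples: need n >= 2 in each")
    t, p = sps.ttest_ind(x, y, equal_var=True)
    if t != t and np.ptp(np.concatenate([x, y])) == 0:
        t, p = 0.0, 1.0
    return float(t), int(x.size + y.size - 2), float(p)


def rm_anova_two_way(table: pd.DataFrame, feature: str,
                     between: str = "group", within: str = "day"
                     ) -> RMAnovaResult:
    """Two-way repeated-measures (split-plot) ANOVA.

    The between-subjects factor is tested against the subject-within-group
    error; the within factor and the interaction against the residual.  The
    design must be complete (every subject at every within level); no
    sphericity correction is applied (a Greenhouse–Geisser option is
    available via ``pingouin`` directly).
    """
    import pingouin as pg

    for col in ("subject", between, within, feature):
        if col not in table.columns:
            raise ValidationError(f"table: missing column {col!r}")
    counts = table.groupby(["subject", within]).size()
    if (counts > 1).any():
        raise ValidationError("design: duplicate (subject, within) cells")
    levels = table[within].nunique()
    per_subject = table.groupby("subject")[within].nunique()
    missing = per_subject[per_subject < levels]
    if len(missing):
        raise ValidationError(
            f"design: incomplete; subjects missing within levels: "
            f"{sorted(missing.index.tolist())}")

    n_subj = table["subject"].nunique()
    n_grp = table[between].nunique()
    if np.ptp(table[feature].to_numpy(dtype=float)) == 0.0:
        # degenerate all-equal table: every mean square is zero
        df_s = n_subj - n_grp
        return RMAnovaResult(
            group=FTest(0.0, n_grp - 1, df_s, 1.0),
            time=FTest(0.0, levels - 1, df_s * (levels - 1), 1.0),
            interaction=FTest(0.0, (n_grp - 1) * (levels - 1),
                              df_s * (levels - 1), 1.0))

    aov = pg.mixed_anova(data=table, dv=feature, within=within,
                         subject="subject", between=between, correction=False)
    aov = aov.set_index("Source")
    deg = {src: (int(aov.loc[src, "DF1"]), int(aov.loc[src, "DF2"]))
           for src in aov.index}

    def ft(src: str) -> FTest:
        f = float(aov.loc[src, "F"])
        p = float(aov.loc[src, "p_unc"])
        if f != f:   # degenerate all-equal table: MS ratios 0/0
            f, p = 0.0, 1.0
        return FTest(f=f, df1=deg[src][0], df2=deg[src][1], p=p)

    return RMAnovaResult(group=ft(between), time=ft(within),
                         interaction=ft("Interaction"))


# ---------------------------------------------------------------------------
# correlations
# ---------------------------------------------------------------------------

def pearson_r(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Sample Pearson correlation with the two-sided t-transform p value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValidationError("samples: need equal length n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValidationError("samples: must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("samples: zero variance, r undefined")
    res = sps.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), n=int(x.size),
                             p=float(res.pvalue))


def correlation_panel(table: pd.DataFrame, response: str,
                      markers: Sequence[str],
                      adjust: str | None = None
                      ) -> list[tuple[str, CorrelationResult | str]]:
    """Correlate one response (e.g. maze errors) against a marker panel.

    Pairwise-complete observations per marker; unadjusted p values by
    default (``adjust='bh'`` applies Benjamini–Hochberg across the panel).
    A marker whose correlation is undefined (constant values) is reported
    with its error message; the rest of the panel is unaffected.
    """
    if response not in table.columns:
        raise ValidationError(f"response: {response!r} not in table")
    out: list[tuple[str, CorrelationResult | str]] = []
    for m in markers:
        if m not in table.columns:
            raise ValidationError(f"marker: {m!r} not in table")
        sub = table[[response, m]].dropna()
        try:
            out.append((m, pearson_r(sub[response], sub[m])))
        except ValidationError as e:
            out.append((m, str(e)))
    if adjust == "bh":
        idx = [i for i, (_, r) in enumerate(out)
               if isinstance(r, CorrelationResult)]
        ps = np.array([out[i][1].p for i in idx])
        order = np.argsort(ps)
        m = len(ps)
        adj = np.empty(m)
        prev = 1.0
        for rank_pos in range(m - 1, -1, -1):
            i = order[rank_pos]
            prev = min(prev, ps[i] * m / (rank_pos + 1))
            adj[i] = prev
        for j, i in enumerate(idx):
            r = out[i][1]
            out[i] = (out[i][0],
                      CorrelationResult(r=r.r, n=r.n, p=float(adj[j])))
    return out


# ---------------------------------------------------------------------------
# behavior aggregation
# ---------------------------------------------------------------------------

def rawm_blocks(trial_values: Sequence[float]) -> np.ndarray:
    """Average consecutive non-overlapping triples of trials into blocks
    (6 learning trials/day → 2 blocks; each memory test is one block)."""
    x = np.asarray(trial_values, dtype=float)
    if x.size == 0 or x.size % 3 != 0:
        raise ValidationError(
            f"trials: count {x.size} not divisible by 3")
    return x.reshape(-1, 3).mean(axis=1)


def dmp_improvement(latencies_by_day: Mapping[int, Sequence[float]],
                    start_day: int = 20, end_day: int = 23) -> float:
    """Escape-latency improvement: mean(day 20 trials) − mean(day 23 trials);
    positive values mean faster escape at the end."""
    for d in (start_day, end_day):
        if d not in latencies_by_day or len(latencies_by_day[d]) == 0:
            raise ValidationError(f"day {d}: missing latencies")
    return float(np.mean(np.asarray(latencies_by_day[start_day], dtype=float))
                 - np.mean(np.asarray(latencies_by_day[end_day], dtype=float)))


# ---------------------------------------------------------------------------
# molecular fold changes
# ---------------------------------------------------------------------------

def ddct_fold_change(table: pd.DataFrame, ct_target: str, ct_reference: str,
                     calibrator_group: str) -> pd.Series:
    """Relative expression by 2^−ΔΔCt.

    ΔCt = Ct(target) − Ct(reference) per sample; ΔΔCt subtracts the mean ΔCt
    of the calibrator group; fold = 2^−ΔΔCt.  Any plate-wide Ct shift cancels
    in ΔΔCt.
    """
    for col in (ct_target, ct_reference):
        if col not in table.columns:
            raise ValidationError(f"column: {col!r} not in table")
        if table[col].isna().any():
            bad = table.loc[table[col].isna(), "subject"].tolist()
            raise ValidationError(f"{col}: missing Ct for samples {bad}")
    dct = table[ct_target] - table[ct_reference]
    cal = dct[table["group"] == calibrator_group]
    if cal.empty:
        raise ValidationError(
            f"calibrator group {calibrator_group!r}: no samples")
    ddct = dct - cal.mean()
    return (2.0 ** (-ddct)).rename("fold_change")


def densitometry_fold_change(table: pd.DataFrame, band: str, loading: str,
                             reference_group: str) -> pd.Series:
    """Band intensity normalized to the loading control (e.g. β-actin),
    expressed relative to the reference (vehicle) group's mean ratio."""
    for col in (band, loading):
        if col not in table.columns:
            raise ValidationError(f"column: {col!r} not in table")
        if (table[col] <= 0).any() or table[col].isna().any():
            raise ValidationError(f"{col}: intensities must be positive")
    ratio = table[band] / table[loading]
    ref = ratio[table["group"] == reference_group]
    if ref.empty:
        raise ValidationError(
            f"reference group {reference_group!r}: no samples")
    return (ratio / ref.mean()).rename("fold_change")
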