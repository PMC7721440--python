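"""Independent brute-force implementations used as test oracles.

Everything here is deliberately naive — direct formulas, dense scans,
repeated central differences — and shares no code with the package paths it
checks.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps


def third_derivative_threshold(v: np.ndarray, dt: float, peak_idx: int,
                               window_ms: float = 2.0) -> float:
    """Voltage at the max of d3V/dt3 before the peak, by plain repeated
    central differences on the raw trace (no smoothing)."""
    d = v.copy()
    for _ in range(3):
        d = np.gradient(d, dt)
    i0 = max(peak_idx - int(round(window_ms / dt)), 1)
    hi = peak_idx - 3   # stencil of the triple difference spans ±3 samples
    k = i0 + int(np.argmax(d[i0:hi]))
    return float(v[k])


def half_width_scan(v: np.ndarray, dt: float, peak_idx: int,
                    level: float, upsample: int = 64) -> float:
    """Half-width by exhaustive crossing scan on a densely resampled trace."""
    lo = max(peak_idx - int(round(5.0 / dt)), 0)
    hi = min(peak_idx + int(round(10.0 / dt)), v.size)
    t = np.arange(lo, hi) * dt
    tf = np.linspace(t[0], t[-1], (hi - lo) * upsample)
    vf = np.interp(tf, t, v[lo:hi])
    above = vf >= level
    pk = int(np.argmax(vf))
    i = pk
    while i > 0 and above[i - 1]:
        i -= 1
    j = pk
    while j < above.size - 1 and above[j + 1]:
        j += 1
    return float(tf[j] - tf[i])


def ols_slope(x: np.ndarray, y: np.ndarray) -> float:
    """Least-squares slope by the normal equations."""
    X = np.column_stack([x, np.ones_like(x)])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    return float(beta[0])


def anova_oneway(groups: list[np.ndarray]) -> tuple[float, int, int, float]:
    """One-way ANOVA by explicit sums of squares."""
    all_x = np.concatenate(groups)
    grand = all_x.mean()
    ssb = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    dfb = len(groups) - 1
    dfw = all_x.size - len(groups)
    f = (ssb / dfb) / (ssw / dfw)
    return f, dfb, dfw, float(sps.f.sf(f, dfb, dfw))


def pooled_t(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided pooled-variance t by the textbook formula."""
    nx, ny = x.size, y.size
    sp2 = (((x - x.mean()) ** 2).sum() + ((y - y.mean()) ** 2).sum()) \
        / (nx + ny - 2)
    t = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / nx + 1 / ny))
    p = 2 * sps.t.sf(abs(t), nx + ny - 2)
    return float(t), float(p)


def pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r and the two-sided t-transform p, by direct formula."""
    xc, yc = x - x.mean(), y - y.mean()
    r = float((xc * yc).sum() / np.sqrt((xc ** 2).sum() * (yc ** 2).sum()))
    n = x.size
    t = r * np.sqrt((n - 2) / (1 - r ** 2))
    return r, float(2 * sps.t.sf(abs(t), n - 2))


def rm_anova_split_plot(table) -> dict[str, tuple[float, int, int, float]]:
    """Split-plot (one between, one within factor) ANOVA by explicit
    cell-mean sums of squares on a complete balanced-within design.

    Returns {factor: (F, df1, df2, p)} for 'group', 'time', 'interaction'.
    """
    subjects = sorted(table["subject"].unique())
    days = sorted(table["day"].unique())
    groups = sorted(table["group"].unique())
    n_s, n_d = len(subjects), len(days)

    y = table.set_index(["subject", "day"])["y"]
    grp_of = table.drop_duplicates("subject").set_index("subject")["group"]
    grand = y.mean()

    subj_mean = {s: np.mean([y[(s, d)] for d in days]) for s in subjects}
    day_mean = {d: np.mean([y[(s, d)] for s in subjects]) for d in days}
    grp_mean = {g: np.mean([subj_mean[s] for s in subjects
                            if grp_of[s] == g]) for g in groups}
    cell_mean = {(g, d): np.mean([y[(s, d)] for s in subjects
                                  if grp_of[s] == g])
                 for g in groups for d in days}

    n_per_group = {g: sum(grp_of[s] == g for s in subjects) for g in groups}
    ss_group = n_d * sum(n_per_group[g] * (grp_mean[g] - grand) ** 2
                         for g in groups)
    ss_subj = n_d * sum((subj_mean[s] - grp_of.map(grp_mean)[s]) ** 2
                        for s in subjects)
    ss_time = n_s * sum((day_mean[d] - grand) ** 2 for d in days)
    ss_int = sum(n_per_group[g] * (cell_mean[(g, d)] - grp_mean[g]
                                   - day_mean[d] + grand) ** 2
                 for g in groups for d in days)
    ss_tot = ((y - grand) ** 2).sum()
    ss_resid = ss_tot - ss_group - ss_subj - ss_time - ss_int

    df_group = len(groups) - 1
    df_subj = n_s - len(groups)
    df_time = n_d - 1
    df_int = df_group * df_time
    df_resid = df_subj * df_time

    def ftest(ss, df, ss_err, df_err):
        f = (ss / df) / (ss_err / df_err)
        return float(f), df, df_err, float(sps.f.sf(f, df, df_err))

    return {
        "group": ftest(ss_group, df_group, ss_subj, df_subj),
        "time": ftest(ss_time, df_time, ss_resid, df_resid),
        "interaction": ftest(ss_int, df_int, ss_resid, df_resid),
    }
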