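"""Inference layer: split-plot ANOVA, Ryan's stepwise post hoc, one-way
ANOVA, and paired t-tests with Holm's adjustment.

The central design is a mixed (split-plot) two-way repeated-measures ANOVA:
the conditioning paradigm is a between-subjects factor (each paradigm is a
distinct group of animals) and the test time point a within-subjects factor.
For the canonical 4-paradigm x 8-animal x 4-time-point design the degrees of
freedom are (3, 28) for paradigm, (3, 84) for time and (9, 84) for the
interaction.  Balanced, complete data are required; no sphericity correction
is applied by default (Greenhouse-Geisser is available as an option).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "mixed_anova", "oneway_anova", "rm_oneway_anova",
    "ryan_posthoc", "paired_t_holm", "PosthocResult",
]


def _f_p(ss_num, df_num, ss_den, df_den):
    """F and p with the all-equal degenerate case (0/0) guarded to F=0, p=1."""
    if ss_den == 0:
        return (0.0, 1.0) if ss_num == 0 else (np.inf, 0.0)
    f = (ss_num / df_num) / (ss_den / df_den)
    return float(f), float(sps.f.sf(f, df_num, df_den))


def mixed_anova(
    data: pd.DataFrame,
    dv: str = "value",
    subject: str = "animal",
    between: str = "paradigm",
    within: str = "time_point",
    gg_correction: bool = False,
) -> pd.DataFrame:
    """Split-plot (mixed) two-way repeated-measures ANOVA.

    Between-subjects effect tested against the subjects-within-groups stratum;
    the within effect and the interaction against the subject x within
    residual.  Requires a balanced complete design (every subject measured at
    every within level, equal group sizes); unbalanced data raise.

    Returns a table with one row per effect (``between``, ``within``,
    ``interaction``) plus the error strata and total, holding sums of
    squares, df, F and p.  With ``gg_correction`` the within and interaction
    p-values use Greenhouse-Geisser-adjusted df (reported in extra columns);
    the uncorrected rows are unchanged.
    """
    df = data[[subject, between, within, dv]].copy()
    if df[dv].isna().any():
        raise ValueError("missing values are not supported; the design must be complete")

    groups = sorted(df[between].unique())
    times = sorted(df[within].unique())
    subjects = sorted(df[subject].unique())
    g, t = len(groups), len(times)
    if g < 2 or t < 2:
        raise ValueError("need >= 2 levels for both factors")

    # subject -> group map must be a function; design must be complete/balanced
    subj_group = df.groupby(subject)[between].nunique()
    if (subj_group != 1).any():
        raise ValueError("each subject must belong to exactly one between-group")
    counts = df.groupby([subject, within])[dv].count().unstack(fill_value=0)
    if (counts.values != 1).any() or counts.shape != (len(subjects), t):
        raise ValueError("design is unbalanced: every subject needs exactly one "
                         "measurement at every within level")
    group_sizes = df.drop_duplicates(subject).groupby(between)[subject].count()
    if group_sizes.nunique() != 1:
        raise ValueError("design is unbalanced: group sizes differ")
    n = int(group_sizes.iloc[0])

    y = df.pivot_table(index=subject, columns=within, values=dv, sort=True)
    y = y.loc[subjects, times].to_numpy()
    subj_groups = df.drop_duplicates(subject).set_index(subject)[between].loc[subjects]
    group_of = subj_groups.to_numpy()

    gm = y.mean()
    group_means = np.array([y[group_of == grp].mean() for grp in groups])
    time_means = y.mean(axis=0)
    subj_means = y.mean(axis=1)
    cell_means = np.array([y[group_of == grp].mean(axis=0) for grp in groups])  # g x t

    ss_total = float(((y - gm) ** 2).sum())
    ss_between = float(n * t * ((group_means - gm) ** 2).sum())
    ss_subj = float(t * sum(
        ((subj_means[group_of == grp] - group_means[i]) ** 2).sum()
        for i, grp in enumerate(groups)
    ))
    ss_time = float(g * n * ((time_means - gm) ** 2).sum())
    ss_inter = float(n * (
        (cell_means - group_means[:, None] - time_means[None, :] + gm) ** 2
    ).sum())
    ss_resid = ss_total - ss_between - ss_subj - ss_time - ss_inter

    df_between, df_subj = g - 1, g * (n - 1)
    df_time, df_inter = t - 1, (g - 1) * (t - 1)
    df_resid = g * (n - 1) * (t - 1)

    f_b, p_b = _f_p(ss_between, df_between, ss_subj, df_subj)
    f_t, p_t = _f_p(ss_time, df_time, ss_resid, df_resid)
    f_i, p_i = _f_p(ss_inter, df_inter, ss_resid, df_resid)

    rows = [
        dict(effect=between, ss=ss_between, df_num=df_between, df_den=df_subj, F=f_b, p=p_b),
        dict(effect=within, ss=ss_time, df_num=df_time, df_den=df_resid, F=f_t, p=p_t),
        dict(effect="interaction", ss=ss_inter, df_num=df_inter, df_den=df_resid, F=f_i, p=p_i),
        dict(effect="subjects_within_groups", ss=ss_subj, df_num=df_subj,
             df_den=np.nan, F=np.nan, p=np.nan),
        dict(effect="residual", ss=ss_resid, df_num=df_resid, df_den=np.nan,
             F=np.nan, p=np.nan),
        dict(effect="total", ss=ss_total, df_num=g * n * t - 1, df_den=np.nan,
             F=np.nan, p=np.nan),
    ]
    table = pd.DataFrame(rows)

    if gg_correction:
        eps = _gg_epsilon(y, group_of, groups)
        table["gg_eps"] = np.nan
        table["p_gg"] = np.nan
        for eff, f, d1, d2 in ((within, f_t, df_time, df_resid),
                               ("interaction", f_i, df_inter, df_resid)):
            idx = table.index[table["effect"] == eff][0]
            table.loc[idx, "gg_eps"] = eps
            table.loc[idx, "p_gg"] = float(sps.f.sf(f, d1 * eps, d2 * eps)) if f > 0 else 1.0
    return table


def _gg_epsilon(y, group_of, groups):
    """Greenhouse-Geisser epsilon from the pooled within-group covariance."""
    t = y.shape[1]
    centered = np.vstack([y[group_of == grp] - y[group_of == grp].mean(axis=0)
                          for grp in groups])
    s = centered.T @ centered / max(len(centered) - len(groups), 1)
    mean_diag = np.trace(s) / t
    mean_all = s.mean()
    num = (t * (mean_diag - mean_all)) ** 2
    den = (t - 1) * ((s ** 2).sum() - 2 * t * (s.mean(axis=1) ** 2).sum()
                     + t * t * mean_all ** 2)
    if den <= 0:
        return 1.0
    return float(min(max(num / den, 1.0 / (t - 1)), 1.0))


def oneway_anova(groups) -> dict:
    """Classical one-way between-subjects ANOVA.

    Returns F, (df_between, df_within) and p for k groups with N total
    observations: df = (k - 1, N - k).
    """
    arrays = [np.asarray(grp, dtype=float) for grp in groups]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(a) < 2 for a in arrays):
        raise ValueError("every group needs at least 2 observations")
    k = len(arrays)
    n_total = sum(len(a) for a in arrays)
    if all(np.allclose(a, arrays[0][0]) for a in arrays):
        f, p = 0.0, 1.0
    else:
        f, p = sps.f_oneway(*arrays)
    return {"F": float(f), "df": (k - 1, n_total - k), "p": float(p)}


def rm_oneway_anova(y: np.ndarray) -> dict:
    """One-way repeated-measures ANOVA on a subjects x levels matrix.

    Returns the within-factor F, df, p, and the subject x level residual mean
    square and its df — the error term for post hoc comparisons among the
    level means.
    """
    y = np.asarray(y, dtype=float)
    n, t = y.shape
    if n < 2 or t < 2:
        raise ValueError("need >= 2 subjects and >= 2 levels")
    gm = y.mean()
    ss_time = float(n * ((y.mean(axis=0) - gm) ** 2).sum())
    ss_subj = float(t * ((y.mean(axis=1) - gm) ** 2).sum())
    ss_total = float(((y - gm) ** 2).sum())
    ss_resid = ss_total - ss_time - ss_subj
    df_time, df_resid = t - 1, (n - 1) * (t - 1)
    f, p = _f_p(ss_time, df_time, ss_resid, df_resid)
    return {
        "F": f, "df": (df_time, df_resid), "p": p,
        "ms_error": ss_resid / df_resid, "df_error": df_resid,
    }


@dataclass(frozen=True)
class PosthocResult:
    """Stepwise pairwise comparisons among level means."""

    table: pd.DataFrame  # level_i, level_j, mean_diff, t, span_r, nominal_level, p, significant
    alpha: float

    def significant_pairs(self) -> set:
        sig = self.table[self.table["significant"]]
        return {(a, b) for a, b in zip(sig["level_i"], sig["level_j"])}


def ryan_posthoc(
    level_means,
    n_per_level: int,
    ms_error: float,
    df_error: int,
    alpha: float = 0.05,
    labels=None,
    level_formula: str = "ryan",
) -> PosthocResult:
    """Ryan's stepwise multiple comparison among k level means.

    Means are ranked; a pair spanning ``r`` ordered means (out of ``k``) is
    tested two-sided at the nominal level ``alpha_r = 2*alpha / (k*(r-1))``
    (for k = 2 this degenerates to a single test at ``alpha``).  Stepwise
    closure applies: a pair is declared significant only if its own test
    rejects *and* every enclosing span was rejected, so no isolated rejection
    can sit inside a non-rejected span.

    ``level_formula="regw"`` swaps in the Ryan-Einot-Gabriel-Welsch nominal
    levels ``1 - (1-alpha)**(r/k)`` (with ``alpha`` itself for r >= k-1),
    keeping the same t statistics and closure.

    The t statistic for a pair uses the supplied error term:
    ``t = (m_i - m_j) / sqrt(ms_error * 2 / n)`` with ``df_error`` df —
    typically the within-group MS from a one-way ANOVA or the subject x level
    residual from a repeated-measures ANOVA.
    """
    means = np.asarray(level_means, dtype=float)
    k = len(means)
    if k < 2:
        raise ValueError("need at least 2 levels")
    if not (ms_error > 0):
        raise ValueError("ms_error must be positive")
    if n_per_level < 2:
        raise ValueError("n_per_level must be >= 2")
    if labels is None:
        labels = list(range(k))

    order = np.argsort(means)  # ascending rank in mean
    rank_of = np.empty(k, dtype=int)
    rank_of[order] = np.arange(k)
    se = np.sqrt(ms_error * 2.0 / n_per_level)

    def nominal(r: int) -> float:
        if level_formula == "ryan":
            return 2.0 * alpha / (k * (r - 1)) if r > 2 else 2.0 * alpha / k if k > 2 else alpha
        if level_formula == "regw":
            return alpha if r >= k - 1 else 1.0 - (1.0 - alpha) ** (r / k)
        raise ValueError(f"unknown level_formula {level_formula!r}")

    # evaluate every pair in rank space, largest spans first, applying closure
    raw: dict[tuple[int, int], dict] = {}
    for a, b in combinations(range(k), 2):  # a < b are ranks
        i, j = order[a], order[b]
        diff = means[i] - means[j]
        tstat = diff / se
        p = 2.0 * sps.t.sf(abs(tstat), df_error)
        r = b - a + 1
        raw[(a, b)] = dict(
            i=i, j=j, diff=diff, t=tstat, p=p, r=r, nominal=nominal(r),
            own_reject=p < nominal(r),
        )
    rejected: dict[tuple[int, int], bool] = {}
    for (a, b), rec in sorted(raw.items(), key=lambda kv: -kv[1]["r"]):
        enclosing_ok = all(
            rejected.get((a2, b2), False)
            for (a2, b2) in raw
            if a2 <= a and b2 >= b and (a2, b2) != (a, b)
        )
        rejected[(a, b)] = bool(rec["own_reject"] and enclosing_ok)

    rows = []
    for (a, b), rec in sorted(raw.items()):
        rows.append(dict(
            level_i=labels[rec["i"]], level_j=labels[rec["j"]],
            mean_diff=rec["diff"], t=rec["t"], span_r=rec["r"],
            nominal_level=rec["nominal"], p=rec["p"],
            significant=rejected[(a, b)],
        ))
    return PosthocResult(table=pd.DataFrame(rows), alpha=alpha)


def paired_t_holm(comparisons, labels=None) -> pd.DataFrame:
    """Two-sided paired t-tests with Holm's step-down adjustment.

    ``comparisons`` is a sequence of (x, y) paired arrays.  Identical pairs
    (zero difference everywhere) are reported as t = 0, p = 1 rather than an
    undefined statistic.  Adjusted p-values are monotone in the sorted raw
    p-values and capped at 1.
    """
    raws, ts, ns = [], [], []
    for x, y in comparisons:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.shape != y.shape or x.ndim != 1:
            raise ValueError("each comparison needs two equal-length 1-D arrays")
        if len(x) < 2:
            raise ValueError("each comparison needs at least 2 pairs")
        d = x - y
        if np.all(d == 0):
            t, p = 0.0, 1.0
        else:
            t, p = sps.ttest_rel(x, y)
        raws.append(float(p))
        ts.append(float(t))
        ns.append(len(x))
    _, adj, _, _ = multipletests(raws, method="holm")
    if labels is None:
        labels = [f"cmp{i}" for i in range(len(raws))]
    return pd.DataFrame({
        "comparison": labels, "n_pairs": ns, "t": ts,
        "p_raw": raws, "p_holm": adj.astype(float),
        "significant": adj < 0.05,
    })
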