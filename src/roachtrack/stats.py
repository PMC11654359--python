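"""Assumption-gated group comparisons and scoring-agreement statistics.

The comparison decision tree mirrors common practice for small behavioral
samples: Shapiro-Wilk normality per group and Levene's homogeneity of
variance are run first at the gate alpha; if either rejects, the analysis
branches to Kruskal-Wallis with pairwise Mann-Whitney U tests under
Benjamini-Hochberg FDR correction, otherwise to one-way (or mixed) ANOVA
with Tukey HSD or Dunnett post hocs. Agreement between manual and automated
zone scoring is expressed per cell as an absolute difference normalized by
session length (percent of video), summarized by its mean and a paired t
test.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GroupSample",
    "PairwiseResult",
    "ComparisonReport",
    "AgreementReport",
    "ConfusionRates",
    "gated_compare",
    "mann_whitney",
    "bh_adjust",
    "agreement",
    "confusion_metrics",
    "daily_trend",
]


@dataclass
class GroupSample:
    """One group's measurements (seconds in a zone, cm traveled, cm/s...)."""

    label: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.size < 1:
            raise ValueError(f"group {self.label!r} is empty")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"group {self.label!r} has non-finite values")

    @property
    def n(self) -> int:
        return int(self.values.size)


@dataclass
class PairwiseResult:
    pair: tuple[str, str]
    statistic: float
    p_raw: float
    p_adj: float
    method: str
    mean_diff: float  # mean(a) - mean(b)
    median_diff: float


@dataclass
class ComparisonReport:
    branch: str  # {parametric, nonparametric}
    gate_shapiro_p: dict[str, float]
    gate_levene_p: float
    omnibus_test: str
    omnibus_stat: float
    omnibus_p: float
    pairwise: list[PairwiseResult]
    alpha: float = 0.05

    def significant_pairs(self) -> list[PairwiseResult]:
        return [p for p in self.pairwise if p.p_adj < self.alpha]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "group_a": p.pair[0],
                "group_b": p.pair[1],
                "method": p.method,
                "statistic": p.statistic,
                "p_raw": p.p_raw,
                "p_adj": p.p_adj,
                "mean_diff": p.mean_diff,
                "median_diff": p.median_diff,
            }
            for p in self.pairwise
        ]
        df = pd.DataFrame(rows)
        df.insert(0, "branch", self.branch)
        df.insert(1, "omnibus_test", self.omnibus_test)
        df.insert(2, "omnibus_p", self.omnibus_p)
        return df


def mann_whitney(a, b) -> tuple[float, float]:
    """Mann-Whitney U (two-sided): U statistic of ``a`` and its p value.

    Uses the exact null distribution for small untied samples and the
    tie-corrected normal approximation otherwise, so that
    ``U_a + U_b = n_a * n_b`` always holds.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    has_ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    small = max(a.size, b.size) <= 8
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def mann_whitney_exact_enumeration(a, b) -> float:
    """Exhaustive-permutation two-sided p for the Mann-Whitney U test.

    Brute-force oracle: enumerates every assignment of the pooled ranks to
    group a. Only feasible for tiny samples; requires no ties.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    pooled = np.concatenate([a, b])
    n_a, n_b = a.size, b.size
    ranks = sps.rankdata(pooled)

    def u_of(idx: tuple[int, ...]) -> float:
        r = ranks[list(idx)].sum()
        return r - n_a * (n_a + 1) / 2

    u_obs = u_of(tuple(range(n_a)))
    mu = n_a * n_b / 2
    count = 0
    total = comb(n_a + n_b, n_a)
    for idx in itertools.combinations(range(n_a + n_b), n_a):
        if abs(u_of(idx) - mu) >= abs(u_obs - mu) - 1e-12:
            count += 1
    return count / total


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (input order preserved)."""
    p = np.asarray(pvals, dtype=np.float64)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p values must lie in [0, 1]")
    _, adj, _, _ = multipletests(p, method="fdr_bh")
    return adj


def _pairwise_nonparametric(
    samples: list[GroupSample],
) -> list[PairwiseResult]:
    pairs = list(itertools.combinations(samples, 2))
    raw = []
    stats_ = []
    for a, b in pairs:
        u, p = mann_whitney(a.values, b.values)
        stats_.append(u)
        raw.append(p)
    adj = bh_adjust(raw)
    return [
        PairwiseResult(
            pair=(a.label, b.label),
            statistic=float(u),
            p_raw=float(p),
            p_adj=float(q),
            method="Mann-Whitney",
            mean_diff=float(a.values.mean() - b.values.mean()),
            median_diff=float(np.median(a.values) - np.median(b.values)),
        )
        for (a, b), u, p, q in zip(pairs, stats_, raw, adj)
    ]


def _pairwise_tukey(samples: list[GroupSample]) -> list[PairwiseResult]:
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    values = np.concatenate([g.values for g in samples])
    labels = np.concatenate([[g.label] * g.n for g in samples])
    res = pairwise_tukeyhsd(values, labels)
    by_label = {g.label: g for g in samples}
    out = []
    for row in res.summary().data[1:]:
        a, b = str(row[0]), str(row[1])
        ga, gb = by_label[a], by_label[b]
        p = float(row[3])
        out.append(
            PairwiseResult(
                pair=(a, b),
                statistic=float(row[2]),  # mean difference b - a, per summary
                p_raw=p,  # Tukey p values are family-adjusted by construction
                p_adj=p,
                method="Tukey",
                mean_diff=float(ga.values.mean() - gb.values.mean()),
                median_diff=float(np.median(ga.values) - np.median(gb.values)),
            )
        )
    return out


def _pairwise_dunnett(
    samples: list[GroupSample], control: str
) -> list[PairwiseResult]:
    ctrl = next(g for g in samples if g.label == control)
    others = [g for g in samples if g.label != control]
    res = sps.dunnett(*[g.values for g in others], control=ctrl.values)
    out = []
    for g, stat, p in zip(others, np.atleast_1d(res.statistic),
                          np.atleast_1d(res.pvalue)):
        out.append(
            PairwiseResult(
                pair=(g.label, control),
                statistic=float(stat),
                p_raw=float(p),  # Dunnett p values are family-adjusted
                p_adj=float(p),
                method="Dunnett",
                mean_diff=float(g.values.mean() - ctrl.values.mean()),
                median_diff=float(np.median(g.values) - np.median(ctrl.values)),
            )
        )
    return out


def gated_compare(
    samples: list[GroupSample],
    paired_within: list[np.ndarray] | None = None,
    alpha: float = 0.05,
    posthoc: str = "tukey",
    control: str | None = None,
) -> ComparisonReport:
    """Assumption-gated omnibus + pairwise comparison of >= 2 groups.

    Shapiro-Wilk (per group) and Levene gates run at ``alpha``; any
    rejection selects the nonparametric branch (Kruskal-Wallis, pairwise
    Mann-Whitney, Benjamini-Hochberg). Otherwise a one-way ANOVA (or, when
    ``paired_within`` supplies a within-subject factor per group, a mixed
    ANOVA) runs with Tukey (all pairs) or Dunnett (vs ``control``) post hocs.
    """
    if len(samples) < 2:
        raise ValueError("need at least 2 groups")
    labels = [g.label for g in samples]
    if len(set(labels)) != len(labels):
        raise ValueError("group labels must be unique")
    for g in samples:
        if g.n < 3:
            raise ValueError(
                f"group {g.label!r} has n={g.n} < 3; gates are undefined"
            )
    if posthoc not in ("tukey", "dunnett"):
        raise ValueError(f"unknown posthoc {posthoc!r}")
    if posthoc == "dunnett" and control not in labels:
        raise ValueError("dunnett posthoc requires a control group label")

    shapiro_p: dict[str, float] = {}
    for g in samples:
        if np.ptp(g.values) == 0:
            # zero-range data: normality is untestable and clearly violated
            shapiro_p[g.label] = 0.0
        else:
            with np.errstate(all="ignore"):
                shapiro_p[g.label] = float(sps.shapiro(g.values).pvalue)
    levene_p = float(sps.levene(*[g.values for g in samples]).pvalue)
    nonparametric = (
        any(not (p >= alpha) for p in shapiro_p.values()) or levene_p < alpha
    )

    if nonparametric:
        stat, p = sps.kruskal(*[g.values for g in samples])
        pairwise = _pairwise_nonparametric(samples)
        omnibus = "Kruskal-Wallis"
    else:
        if paired_within is not None:
            stat, p = _mixed_anova(samples, paired_within)
            omnibus = "mixed ANOVA (between effect)"
        else:
            stat, p = sps.f_oneway(*[g.values for g in samples])
            stat, p = float(stat), float(p)
            omnibus = "one-way ANOVA"
        if posthoc == "dunnett":
            pairwise = _pairwise_dunnett(samples, control)  # type: ignore[arg-type]
        else:
            pairwise = _pairwise_tukey(samples)
    return ComparisonReport(
        branch="nonparametric" if nonparametric else "parametric",
        gate_shapiro_p=shapiro_p,
        gate_levene_p=levene_p,
        omnibus_test=omnibus,
        omnibus_stat=float(stat),
        omnibus_p=float(p),
        pairwise=pairwise,
        alpha=alpha,
    )


def _mixed_anova(
    samples: list[GroupSample], within_factor: list[np.ndarray]
) -> tuple[float, float]:
    """Between-group effect from a mixed ANOVA (delegated to pingouin)."""
    import pingouin as pg

    rows = []
    subject = 0
    for g, within in zip(samples, within_factor):
        within = np.asarray(within)
        if within.size != g.n:
            raise ValueError("within factor length must match group values")
        # subjects are value/within pairs grouped by repeated within levels
        levels = pd.unique(within)
        n_subj = g.n // len(levels)
        for si in range(n_subj):
            for li, lev in enumerate(levels):
                idx = li * n_subj + si
                rows.append(
                    {
                        "value": g.values[idx],
                        "group": g.label,
                        "within": lev,
                        "subject": f"{g.label}-{subject + si}",
                    }
                )
        subject += n_subj
    df = pd.DataFrame(rows)
    aov = pg.mixed_anova(
        data=df, dv="value", within="within", between="group", subject="subject"
    )
    row = aov[aov["Source"] == "group"].iloc[0]
    p_col = "p_unc" if "p_unc" in aov.columns else "p-unc"
    return float(row["F"]), float(row[p_col])


@dataclass
class AgreementReport:
    """Manual vs automated zone-scoring agreement, normalized by duration."""

    cells: pd.DataFrame  # columns: keys..., hand_s, machine_s, norm_diff_pct
    mean_abs_error_pct: float
    paired_t_stat: float
    paired_t_p: float
    duration_s: float

    def to_frame(self) -> pd.DataFrame:
        return self.cells.copy()


def agreement(
    hand: pd.DataFrame,
    machine: pd.DataFrame,
    duration_s: float = 120.0,
    keys: tuple[str, ...] = ("session", "quadrant"),
    value_col: str = "seconds",
) -> AgreementReport:
    """Compare manual and automated seconds-per-quadrant tables.

    Both tables must be tidy frames with the same ``keys`` columns and a
    ``seconds`` column. Each cell's absolute difference is divided by the
    session duration and expressed as percent of video length; a paired t
    test runs across the raw cell values.
    """
    for name, df in (("hand", hand), ("machine", machine)):
        missing = (set(keys) | {value_col}) - set(df.columns)
        if missing:
            raise ValueError(f"{name} table lacks columns {sorted(missing)}")
    h = hand.set_index(list(keys))[value_col].sort_index()
    m = machine.set_index(list(keys))[value_col].sort_index()
    only_h = h.index.difference(m.index)
    only_m = m.index.difference(h.index)
    if len(only_h) or len(only_m):
        raise ValueError(
            "tables do not share keys; "
            f"hand-only={list(only_h)}, machine-only={list(only_m)}"
        )
    if h.index.has_duplicates:
        raise ValueError("duplicate keys in tables")
    diff_pct = (h - m).abs() / duration_s * 100.0
    cells = pd.DataFrame(
        {
            "hand_s": h,
            "machine_s": m,
            "norm_diff_pct": diff_pct,
        }
    ).reset_index()
    if len(h) > 1 and not np.allclose(h, m):
        t_stat, t_p = sps.ttest_rel(h, m)
    else:
        t_stat, t_p = 0.0, 1.0
    return AgreementReport(
        cells=cells,
        mean_abs_error_pct=float(diff_pct.mean()),
        paired_t_stat=float(t_stat),
        paired_t_p=float(t_p),
        duration_s=float(duration_s),
    )


@dataclass(frozen=True)
class ConfusionRates:
    """Validation confusion rates, as percentages summing to ~100."""

    fp_pct: float
    fn_pct: float
    tp_pct: float
    tn_pct: float

    def __post_init__(self) -> None:
        for name, v in (("fp", self.fp_pct), ("fn", self.fn_pct),
                        ("tp", self.tp_pct), ("tn", self.tn_pct)):
            if not 0 <= v <= 100:
                raise ValueError(f"{name}_pct must lie in [0, 100]")
        total = self.fp_pct + self.fn_pct + self.tp_pct + self.tn_pct
        if abs(total - 100.0) > 0.5:
            raise ValueError(f"rates sum to {total}, expected ~100")


def confusion_metrics(rates: ConfusionRates) -> dict[str, float]:
    """Recall, precision and accuracy (percent, 1 decimal) from rates."""
    tp, fp, fn, tn = rates.tp_pct, rates.fp_pct, rates.fn_pct, rates.tn_pct
    if tp + fn == 0:
        raise ValueError("recall undefined: tp + fn = 0")
    if tp + fp == 0:
        raise ValueError("precision undefined: tp + fp = 0")
    recall = tp / (tp + fn) * 100.0
    precision = tp / (tp + fp) * 100.0
    accuracy = (tp + tn) / (tp + tn + fp + fn) * 100.0
    return {
        "recall_pct": round(recall, 1),
        "precision_pct": round(precision, 1),
        "accuracy_pct": round(accuracy, 1),
    }


def daily_trend(day_values) -> dict[str, float]:
    """OLS fit of value on day: slope, intercept and r-squared."""
    arr = np.asarray(day_values, dtype=np.float64)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValueError("need >= 2 (day, value) pairs")
    days, values = arr[:, 0], arr[:, 1]
    if len(np.unique(days)) < 2:
        raise ValueError("need at least 2 distinct days")
    res = sps.linregress(days, values)
    r2 = float(res.rvalue**2)
    if np.isnan(r2):  # constant response: zero slope explains nothing
        r2 = 0.0
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r_squared": r2,
    }
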