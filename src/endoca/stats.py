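"""Replication hierarchy and the study's statistical tests.

Metrics climb the design: cells are averaged within a recording (technical
replicate), technical replicates within an animal (biological replicate),
and the biological replicates carry the statistics. Peak amplitudes are
log-transformed for testing (paired t test, or two-way ANOVA with Tukey's
multiple comparisons) and the means back-transformed — the back-transformed
mean of positive data is its geometric mean. Raw-scale means ± SEM are
reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["ReplicateTable", "StatResult", "aggregate", "paired_t_log",
           "anova2_tukey", "ALPHA"]

#: Significance threshold used throughout.
ALPHA = 0.05


@dataclass
class ReplicateTable:
    """Per-technical-replicate and per-animal means for one metric.

    ``tech_rep_means`` has one row per (animal, condition, tech_rep);
    ``animal_means`` one row per (animal, condition). Both keep the column
    named after the metric.
    """

    metric: str
    tech_rep_means: pd.DataFrame
    animal_means: pd.DataFrame

    def arm(self, condition: str) -> pd.Series:
        df = self.animal_means
        sel = df[df["condition"] == condition]
        if sel.empty:
            raise KeyError(f"no animals for condition {condition!r}")
        return sel.set_index("animal")[self.metric]


@dataclass
class StatResult:
    test: str
    statistic: float
    df: float
    p_value: float
    geometric_means: dict[str, float] = field(default_factory=dict)
    raw_means: dict[str, float] = field(default_factory=dict)
    sem: dict[str, float] = field(default_factory=dict)
    n: dict[str, int] = field(default_factory=dict)
    contrasts: pd.DataFrame | None = None
    anova_table: pd.DataFrame | None = None

    def significant(self, alpha: float = ALPHA) -> bool:
        return self.p_value < alpha


def aggregate(cell_summaries: pd.DataFrame, metric: str = "peak_amp",
              exclude_nonresponders: bool = False) -> ReplicateTable:
    """Average a per-cell metric up the replication hierarchy.

    The per-technical-replicate value is the mean over cells; the
    per-animal value is the mean over that animal's technical replicates.
    ``exclude_nonresponders`` drops cells with ``responder == False``
    before averaging (off by default: every analysed cell contributes).

    Raises
    ------
    KeyError
        If the metric column is missing.
    ValueError
        If exclusion empties a (animal, condition, tech_rep) group.
    """
    if metric not in cell_summaries.columns:
        raise KeyError(f"metric {metric!r} not in summaries")
    df = cell_summaries
    if exclude_nonresponders:
        if "responder" not in df.columns:
            raise KeyError("summaries lack a responder column")
        df = df[df["responder"]]
    keys = ["animal", "condition", "tech_rep"]
    n_groups_before = cell_summaries.groupby(keys).ngroups
    tech = df.groupby(keys, as_index=False)[metric].mean()
    if tech.shape[0] != n_groups_before:
        raise ValueError("a technical replicate lost all its cells")
    animal = tech.groupby(["animal", "condition"], as_index=False)[metric].mean()
    return ReplicateTable(metric=metric, tech_rep_means=tech,
                          animal_means=animal)


def _pair(table: ReplicateTable, condition_a: str,
          condition_b: str) -> tuple[np.ndarray, np.ndarray]:
    a = table.arm(condition_a)
    b = table.arm(condition_b)
    animals = a.index.intersection(b.index)
    missing = a.index.symmetric_difference(b.index)
    if len(missing):
        raise ValueError(
            f"pairing requires every animal in both conditions; "
            f"unpaired animals: {sorted(missing)}")
    if len(animals) < 2:
        raise ValueError("paired test needs at least 2 animals")
    return a.loc[animals].to_numpy(), b.loc[animals].to_numpy()


def paired_t_log(table: ReplicateTable, condition_a: str,
                 condition_b: str) -> StatResult:
    """Paired t test on natural-log-transformed per-animal means.

    t = mean(d) / (sd(d) / sqrt(n)) on the log differences, df = n - 1,
    two-sided p from the t distribution. Reported test means are the
    back-transformed (geometric) means; raw-scale means ± SEM accompany
    them. Identical arms give t = 0, p = 1.

    Raises
    ------
    ValueError
        On any non-positive per-animal mean (log undefined: a data problem
        to be resolved upstream, not silently offset).
    """
    x, y = _pair(table, condition_a, condition_b)
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError(
            "non-positive per-animal mean: log transform undefined; "
            "consider exclude_nonresponders or inspect the data")
    d = np.log(y) - np.log(x)
    n = d.size
    sd = d.std(ddof=1)
    if sd == 0:
        t_stat = 0.0 if np.isclose(d.mean(), 0) else np.inf * np.sign(d.mean())
    else:
        t_stat = d.mean() / (sd / np.sqrt(n))
    p = 1.0 if sd == 0 and np.isclose(d.mean(), 0) else \
        2.0 * sps.t.sf(abs(t_stat), n - 1)

    def gmean(v):
        return float(np.exp(np.mean(np.log(v))))

    return StatResult(
        test="paired t (log scale)",
        statistic=float(t_stat), df=float(n - 1), p_value=float(p),
        geometric_means={condition_a: gmean(x), condition_b: gmean(y)},
        raw_means={condition_a: float(x.mean()), condition_b: float(y.mean())},
        sem={condition_a: float(x.std(ddof=1) / np.sqrt(n)),
             condition_b: float(y.std(ddof=1) / np.sqrt(n))},
        n={condition_a: n, condition_b: n},
    )


def anova2_tukey(data: pd.DataFrame, value: str, factor_a: str,
                 factor_b: str, log_transform: bool = True) -> StatResult:
    """Two-way ANOVA with interaction on (log) values, plus Tukey HSD over
    all cell-mean (factor-combination) contrasts.

    Raises
    ------
    ValueError
        If either factor has a single level.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    df = data[[value, factor_a, factor_b]].copy()
    for f in (factor_a, factor_b):
        if df[f].nunique() < 2:
            raise ValueError(f"factor {f!r} has a single level")
    if log_transform:
        if (df[value] <= 0).any():
            raise ValueError("non-positive values: log transform undefined")
        df["_y"] = np.log(df[value])
    else:
        df["_y"] = df[value]

    model = smf.ols(f"_y ~ C({factor_a}) * C({factor_b})", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)

    groups = df[factor_a].astype(str) + ":" + df[factor_b].astype(str)
    tukey = pairwise_tukeyhsd(df["_y"].to_numpy(), groups.to_numpy())
    from itertools import combinations
    pairs = list(combinations(tukey.groupsunique, 2))
    contrasts = pd.DataFrame({
        "group1": [p[0] for p in pairs],
        "group2": [p[1] for p in pairs],
        "meandiff": tukey.meandiffs,
        "p_adj": tukey.pvalues,
        "lower": tukey.confint[:, 0],
        "upper": tukey.confint[:, 1],
        "reject": tukey.reject,
    })

    inter = f"C({factor_a}):C({factor_b})"
    gmeans = {g: float(np.exp(v) if log_transform else v)
              for g, v in df.groupby(groups.rename("g"))["_y"].mean().items()}
    return StatResult(
        test="two-way ANOVA + Tukey HSD",
        statistic=float(table.loc[inter, "F"]),
        df=float(table.loc[inter, "df"]),
        p_value=float(table.loc[inter, "PR(>F)"]),
        geometric_means=gmeans,
        contrasts=contrasts,
        anova_table=table,
    )
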