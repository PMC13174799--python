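"""Group comparisons for morphometric tables.

Long-format tables (condition, unit id, metric, value) flow through a
single comparison path supporting three designs: unpaired two-tailed
t-test, one-way ANOVA with Fisher's protected LSD post-hoc (pairwise
pooled-MSE t-tests performed only when the omnibus p < 0.05), and the
two-sample Kolmogorov-Smirnov test for distributional shifts.

Fisher's protected LSD is implemented as stated in the source
procedure despite its weaker family-wise control than e.g. Tukey HSD.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from mitomorph.errors import ValidationError

__all__ = [
    "StatsResult",
    "compare_groups",
    "make_group_table",
    "significance_stars",
    "PLSD_GATE",
]

#: Omnibus significance gate for protected-LSD pairwise tests.
PLSD_GATE = 0.05

TABLE_COLUMNS = ["condition", "unit_id", "metric", "value"]


@dataclass
class StatsResult:
    """Outcome of one group comparison."""

    test: str
    statistic: float
    pvalue: float
    n_per_group: dict[str, int]
    posthoc: dict[tuple[str, str], float] | None = None
    protected: bool | None = None  # PLSD only: omnibus gate passed?
    degenerate: bool = False
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {
            "test": self.test,
            "statistic": self.statistic,
            "pvalue": self.pvalue,
            "n_per_group": self.n_per_group,
            "degenerate": self.degenerate,
            "stars": significance_stars(self.pvalue),
            "notes": self.notes,
        }
        if self.posthoc is not None:
            d["posthoc"] = {f"{a} vs {b}": p for (a, b), p in self.posthoc.items()}
        if self.protected is not None:
            d["protected"] = self.protected
        return d


def significance_stars(p: float) -> str:
    """Star convention: *p<0.05, **p<0.01, ***p<0.001, ****p<0.0001."""
    if not np.isfinite(p):
        return "n/a"
    for stars, cut in (("****", 1e-4), ("***", 1e-3), ("**", 1e-2), ("*", 0.05)):
        if p < cut:
            return stars
    return "ns"


def make_group_table(frames: dict[str, pd.DataFrame], metrics=None) -> pd.DataFrame:
    """Melt per-condition wide metric tables into one long table."""
    rows = []
    for condition, df in frames.items():
        value_cols = [c for c in df.columns if c != "id"]
        if metrics is not None:
            value_cols = [c for c in value_cols if c in metrics]
        melted = df.melt(
            id_vars=["id"], value_vars=value_cols,
            var_name="metric", value_name="value",
        ).rename(columns={"id": "unit_id"})
        melted.insert(0, "condition", condition)
        rows.append(melted)
    out = pd.concat(rows, ignore_index=True)[TABLE_COLUMNS]
    if not np.all(np.isfinite(out["value"])):
        raise ValidationError("group table values must be finite")
    return out


def _extract_groups(table: pd.DataFrame, metric: str) -> dict[str, np.ndarray]:
    missing = [c for c in TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"group table missing columns: {missing}")
    sub = table[table["metric"] == metric]
    if sub.empty:
        raise ValidationError(f"metric {metric!r} absent from table")
    groups = {
        str(cond): np.asarray(g["value"], dtype=float)
        for cond, g in sub.groupby("condition", sort=True)
    }
    if len(groups) < 2:
        raise ValidationError("comparisons need >= 2 conditions")
    for name, vals in groups.items():
        if len(vals) < 2:
            raise ValidationError(f"group {name!r} has fewer than 2 values")
    return groups


def _fisher_plsd(groups: dict[str, np.ndarray]) -> StatsResult:
    names = list(groups)
    arrays = [groups[n] for n in names]
    k = len(arrays)
    if k < 3:
        raise ValidationError("ANOVA + Fisher's PLSD requires >= 3 groups")
    ns = np.array([len(a) for a in arrays])
    N = int(ns.sum())
    means = np.array([a.mean() for a in arrays])
    grand = np.concatenate(arrays).mean()
    ss_between = float(np.sum(ns * (means - grand) ** 2))
    ss_within = float(sum(((a - a.mean()) ** 2).sum() for a in arrays))
    df_b, df_w = k - 1, N - k
    mse = ss_within / df_w
    result = StatsResult(
        test="anova_plsd",
        statistic=np.nan,
        pvalue=np.nan,
        n_per_group={n: int(len(groups[n])) for n in names},
    )
    if mse <= 0:
        result.degenerate = True
        result.notes.append("zero pooled within-group variance")
        return result
    F = (ss_between / df_b) / mse
    p = float(sps.f.sf(F, df_b, df_w))
    result.statistic, result.pvalue = float(F), p
    result.protected = p < PLSD_GATE
    if result.protected:
        posthoc = {}
        for i in range(k):
            for j in range(i + 1, k):
                se = np.sqrt(mse * (1.0 / ns[i] + 1.0 / ns[j]))
                t = (means[i] - means[j]) / se
                posthoc[(names[i], names[j])] = float(2.0 * sps.t.sf(abs(t), df_w))
        result.posthoc = posthoc
    else:
        result.notes.append(
            f"omnibus p >= {PLSD_GATE}: pairwise LSD comparisons withheld"
        )
    return result


def compare_groups(table: pd.DataFrame, metric: str, design: str) -> StatsResult:
    """Compare a metric across conditions under the chosen design.

    ``design``: "ttest" (exactly 2 groups, unpaired two-tailed),
    "anova_plsd" (>= 3 groups), or "ks" (exactly 2 groups).
    """
    groups = _extract_groups(table, metric)
    names = list(groups)
    if design == "anova_plsd":
        return _fisher_plsd(groups)
    if len(names) != 2:
        raise ValidationError(f"design {design!r} requires exactly 2 conditions")
    a, b = groups[names[0]], groups[names[1]]
    n_per = {names[0]: len(a), names[1]: len(b)}
    if design == "ttest":
        if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
            return StatsResult(
                "ttest", np.nan, np.nan, n_per, degenerate=True,
                notes=["zero pooled variance"],
            )
        t, p = sps.ttest_ind(a, b, equal_var=True)
        return StatsResult("ttest", float(t), float(p), n_per)
    if design == "ks":
        res = sps.ks_2samp(a, b)
        return StatsResult("ks", float(res.statistic), float(res.pvalue), n_per)
    raise ValidationError(f"unknown design {design!r}")
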