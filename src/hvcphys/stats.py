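"""Group comparison across developmental stages.

One-way ANOVA over the three stages followed by pairwise two-sample t tests
with Bonferroni correction (each p multiplied by the number of comparisons,
three, and capped at 1), plus mean +/- SEM summary tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .synth import FeaturePopulation

N_COMPARISONS = 3


@dataclass
class AnovaResult:
    f: float
    p: float
    flagged: bool = False
    message: str = ""


def _values(group) -> np.ndarray:
    if isinstance(group, FeaturePopulation):
        return np.asarray(group.values, dtype=float)
    return np.asarray(group, dtype=float)


def anova_oneway(groups) -> AnovaResult:
    """Classical one-way ANOVA over three groups."""
    arrays = [_values(g) for g in groups]
    if len(arrays) != 3:
        raise ValueError("expected exactly three groups")
    for a in arrays:
        if len(a) < 2:
            raise ValueError("each group needs at least two values")
    if all(np.ptp(a) == 0 for a in arrays):
        return AnovaResult(float("nan"), float("nan"), flagged=True,
                           message="zero within-group variance in all groups")
    f, p = sps.f_oneway(*arrays)
    return AnovaResult(float(f), float(p))


def bonferroni(p: float, m: int = N_COMPARISONS) -> float:
    """Multiply p by the number of comparisons; cap at 1."""
    return min(1.0, p * m)


PAIRS = (("subsong", "plastic"), ("subsong", "adult"), ("plastic", "adult"))


def bonferroni_pairwise(groups) -> dict[tuple[str, str], float]:
    """Pairwise two-sample t tests, Bonferroni-corrected (x3, capped at 1).

    Groups are given in stage order (subsong, plastic, adult).
    """
    arrays = [_values(g) for g in groups]
    if len(arrays) != 3:
        raise ValueError("expected exactly three groups")
    out = {}
    for (i, j), pair in zip(combinations(range(3), 2), PAIRS):
        if np.ptp(arrays[i]) == 0 and np.ptp(arrays[j]) == 0:
            p = 0.0 if arrays[i][0] != arrays[j][0] else 1.0
        else:
            p = float(sps.ttest_ind(arrays[i], arrays[j]).pvalue)
        out[pair] = bonferroni(p)
    return out


def sem(values) -> float:
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        return float("nan")
    return float(v.std(ddof=1) / np.sqrt(len(v)))


def summarize(table: pd.DataFrame) -> pd.DataFrame:
    """Per-feature, per-stage mean +/- SEM with corrected pairwise p values.

    ``table`` is tidy with columns 'feature', 'group', 'value'.  Output has
    one row per feature: mean and SEM per stage plus the three
    Bonferroni-corrected pairwise p values (NaN when a stage is missing or
    too small to test).
    """
    required = {"feature", "group", "value"}
    if not required.issubset(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    rows = []
    for feat, sub in table.groupby("feature", sort=False):
        row: dict = {"feature": feat}
        groups = []
        for stage in ("subsong", "plastic", "adult"):
            vals = sub.loc[sub["group"] == stage, "value"].to_numpy()
            row[f"{stage}_mean"] = float(np.mean(vals)) if len(vals) else float("nan")
            row[f"{stage}_sem"] = sem(vals)
            groups.append(vals)
        if all(len(g) >= 2 for g in groups):
            pvals = bonferroni_pairwise(groups)
            for (a, b), p in pvals.items():
                row[f"p_{a}_vs_{b}"] = p
        else:
            for a, b in PAIRS:
                row[f"p_{a}_vs_{b}"] = float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


def populations_to_table(pops: list[FeaturePopulation]) -> pd.DataFrame:
    """Tidy DataFrame (feature, group, value) from population records."""
    frames = [pd.DataFrame({"feature": p.feature, "group": p.group,
                            "value": p.values}) for p in pops]
    return pd.concat(frames, ignore_index=True)
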