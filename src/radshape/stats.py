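"""Descriptive and inferential statistics over cut-plane morphometrics.

Group descriptives (mean, SD, min, max) per gender/side/plane; a
Lilliefors-corrected Kolmogorov-Smirnov normality check; two-sample t-tests
for gender/side differences with a Bonferroni-corrected significance
threshold (0.05 / 4 parameters = 0.0125, conventionally printed as 0.013);
and one-way ANOVA across the three planes with Bonferroni post-hoc pairwise
comparisons.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors

from .classify import SpecimenRecord
from .sections import PLANE_LABELS

__all__ = [
    "PARAMETERS",
    "BONFERRONI_ALPHA",
    "BONFERRONI_ALPHA_PRINTED",
    "records_to_frame",
    "group_descriptives",
    "normality_check",
    "compare_gender_side",
    "compare_planes_anova",
    "TTestResult",
]

PARAMETERS = ("width", "depth", "perimeter", "area")

#: 0.05 corrected for the four morphometric parameters
BONFERRONI_ALPHA = 0.05 / len(PARAMETERS)
#: the threshold as conventionally printed (three decimals, half-up)
BONFERRONI_ALPHA_PRINTED = 0.013


def records_to_frame(records: list[SpecimenRecord]) -> pd.DataFrame:
    """Long-format table: one row per specimen x plane."""
    rows = []
    for r in records:
        for plane, m in r.morphometrics.items():
            rows.append({
                "id": r.specimen_id, "gender": r.gender, "side": r.side,
                "plane": plane, **m.as_dict(),
            })
    frame = pd.DataFrame(rows)
    if frame.empty:
        raise ValueError("records carry no morphometrics")
    frame["plane"] = pd.Categorical(frame["plane"], categories=PLANE_LABELS, ordered=True)
    return frame


def group_descriptives(
    records: list[SpecimenRecord] | pd.DataFrame,
    by: tuple[str, ...] = ("plane", "gender"),
) -> pd.DataFrame:
    """Mean/SD/min/max/n per group cell in a plane x parameter x group layout.

    Sample SD (ddof=1); a single-record cell reports SD 0 with its n=1 flag
    visible.  Empty cells simply do not appear (nothing is fabricated).
    """
    frame = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    for key in by:
        if key not in frame.columns:
            raise ValueError(f"unknown grouping factor {key!r}")
    grouped = frame.groupby(list(by), observed=True)
    out = []
    for keys, sub in grouped:
        keys = keys if isinstance(keys, tuple) else (keys,)
        row: dict = dict(zip(by, keys))
        row["n"] = len(sub)
        for param in PARAMETERS:
            vals = sub[param].to_numpy(float)
            row[f"{param}_mean"] = vals.mean()
            row[f"{param}_sd"] = vals.std(ddof=1) if len(vals) > 1 else 0.0
            row[f"{param}_min"] = vals.min()
            row[f"{param}_max"] = vals.max()
        out.append(row)
    return pd.DataFrame(out).set_index(list(by)).sort_index()


def normality_check(values: np.ndarray) -> tuple[float, float]:
    """Kolmogorov-Smirnov test against a normal with estimated parameters.

    Uses the Lilliefors correction: the plain KS null distribution is wrong
    (anti-conservative in the opposite direction) when mean and SD are fitted
    from the sample.  Returns ``(statistic, p)``.
    """
    vals = np.asarray(values, float)
    if len(vals) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(vals) == 0:
        raise ValueError("constant input has no distribution to test")
    stat, p = lilliefors(vals, dist="norm", pvalmethod="table")
    return float(stat), float(p)


@dataclass(frozen=True)
class TTestResult:
    statistic: float
    df: float
    pvalue: float
    group_means: tuple[float, float]
    group_labels: tuple[str, str]
    alpha: float

    @property
    def significant(self) -> bool:
        return self.pvalue < self.alpha

    @property
    def direction(self) -> str:
        a, b = self.group_labels
        if self.group_means[0] == self.group_means[1]:
            return f"{a} == {b}"
        return f"{a} > {b}" if self.group_means[0] > self.group_means[1] else f"{a} < {b}"


def compare_gender_side(
    records: list[SpecimenRecord] | pd.DataFrame,
    parameter: str,
    factor: str = "gender",
    plane: str | None = None,
    alpha: float = BONFERRONI_ALPHA,
    equal_var: bool = True,
) -> TTestResult:
    """Independent two-sample t-test for one parameter between two groups.

    Pooled-variance (Student) form by default; ``equal_var=False`` switches
    to Welch.  ``alpha`` defaults to the Bonferroni-corrected threshold.
    """
    frame = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    if parameter not in PARAMETERS:
        raise ValueError(f"unknown parameter {parameter!r}")
    if plane is not None:
        frame = frame[frame["plane"] == plane]
    labels = sorted(frame[factor].unique())
    if len(labels) != 2:
        raise ValueError(f"factor {factor!r} must have exactly two levels, got {labels}")
    a = frame.loc[frame[factor] == labels[0], parameter].to_numpy(float)
    b = frame.loc[frame[factor] == labels[1], parameter].to_numpy(float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two observations")
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    df = len(a) + len(b) - 2 if equal_var else float(res.df)
    return TTestResult(
        statistic=float(res.statistic), df=float(df), pvalue=float(res.pvalue),
        group_means=(float(a.mean()), float(b.mean())),
        group_labels=(str(labels[0]), str(labels[1])), alpha=alpha,
    )


def compare_planes_anova(
    records: list[SpecimenRecord] | pd.DataFrame,
    parameter: str,
    gender: str | None = None,
) -> dict:
    """One-way ANOVA of a parameter across the three planes + Bonferroni post hoc.

    Pairwise post-hoc p-values are raw two-sample t-test p-values multiplied
    by the number of comparisons (3), capped at 1.
    """
    frame = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    if parameter not in PARAMETERS:
        raise ValueError(f"unknown parameter {parameter!r}")
    if gender is not None:
        frame = frame[frame["gender"] == gender]
    groups = {}
    for plane in PLANE_LABELS:
        vals = frame.loc[frame["plane"] == plane, parameter].to_numpy(float)
        if len(vals) == 0:
            raise ValueError(f"missing plane {plane!r}")
        groups[plane] = vals
    f_stat, p = sps.f_oneway(*groups.values())
    posthoc = []
    pairs = list(combinations(PLANE_LABELS, 2))
    for a, b in pairs:
        t = sps.ttest_ind(groups[a], groups[b], equal_var=True)
        posthoc.append({
            "pair": f"{a}-{b}",
            "t": float(t.statistic),
            "p_raw": float(t.pvalue),
            "p_bonferroni": min(1.0, len(pairs) * float(t.pvalue)),
        })
    return {
        "parameter": parameter,
        "gender": gender,
        "F": float(f_stat),
        "p": float(p),
        "posthoc": pd.DataFrame(posthoc),
    }
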