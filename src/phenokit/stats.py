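"""Two-group per-day comparisons with Student's t-test and star annotation.

The comparison convention follows the figures of the source study: two-sided
Student's t-test (pooled variance by default, Welch by flag), error bars as
standard errors, and significance stars "*" for p < 0.05 and "**" for
p < 0.01 (strict inequalities).  No multiple-testing correction is applied;
output metadata says so explicitly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["ComparisonResult", "ttest_two_sample", "annotate", "daily_comparison"]

logger = logging.getLogger(__name__)

#: emitted in output metadata alongside any comparison table
NO_CORRECTION_NOTE = "p-values are per-day and uncorrected for multiple testing"


@dataclass
class ComparisonResult:
    day_index: float
    mean_control: float
    mean_salt: float
    se_control: float
    se_salt: float
    t: float
    p: float
    stars: str
    n_control: int
    n_salt: int


def ttest_two_sample(x, y, variant: str = "pooled") -> tuple[float, float]:
    """Two-sided two-sample t-test; returns (t, p).

    ``variant="pooled"`` is the classical equal-variance Student test;
    ``"welch"`` drops the equal-variance assumption.  Degenerate zero-variance
    inputs are resolved by convention: equal means give (0, 1), fully
    separated constant groups give (inf with the sign of the difference, 0).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 replicates")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in input")
    if variant not in ("pooled", "welch"):
        raise ValueError(f"unknown t-test variant {variant!r}")
    if np.var(x, ddof=1) == 0.0 and np.var(y, ddof=1) == 0.0:
        if np.mean(x) == np.mean(y):
            return 0.0, 1.0
        return float(np.sign(np.mean(x) - np.mean(y)) * np.inf), 0.0
    t, p = sps.ttest_ind(x, y, equal_var=(variant == "pooled"))
    return float(t), float(p)


def annotate(p: float) -> str:
    """Map a p-value to the study's star convention (strict thresholds)."""
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"p-value {p} outside [0, 1]")
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def _se(x: np.ndarray) -> float:
    if x.size < 2:
        return 0.0
    return float(np.std(x, ddof=1) / np.sqrt(x.size))


def daily_comparison(
    series: pd.DataFrame,
    variant: str = "pooled",
    groups: tuple[str, str] = ("control", "salt"),
) -> list[ComparisonResult]:
    """Per-day control-vs-salt comparison of a long ``day, group, value`` table.

    Days where either group is absent (or has fewer than 2 replicates) are
    skipped with a log entry, not reported as NaN.
    """
    out: list[ComparisonResult] = []
    gc, gs = groups
    for day, sub in series.groupby("day", sort=True):
        x = sub.loc[sub["group"] == gc, "value"].to_numpy(float)
        y = sub.loc[sub["group"] == gs, "value"].to_numpy(float)
        if x.size < 2 or y.size < 2:
            logger.info("day %s skipped: control n=%d, salt n=%d", day, x.size, y.size)
            continue
        t, p = ttest_two_sample(x, y, variant=variant)
        out.append(ComparisonResult(
            day_index=day,
            mean_control=float(np.mean(x)), mean_salt=float(np.mean(y)),
            se_control=_se(x), se_salt=_se(y),
            t=t, p=p, stars=annotate(p),
            n_control=int(x.size), n_salt=int(y.size),
        ))
    return out


def comparison_table(results: list[ComparisonResult]) -> pd.DataFrame:
    """Results as the CSV schema used by the CLI."""
    rows = [{
        "day": r.day_index,
        "mean_control": r.mean_control, "se_control": r.se_control,
        "mean_salt": r.mean_salt, "se_salt": r.se_salt,
        "t": r.t, "p": r.p, "stars": r.stars,
        "n_control": r.n_control, "n_salt": r.n_salt,
    } for r in results]
    return pd.DataFrame(rows, columns=[
        "day", "mean_control", "se_control", "mean_salt", "se_salt",
        "t", "p", "stars", "n_control", "n_salt"])
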