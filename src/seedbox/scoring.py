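"""Time standardization, final-day damage tables, condition-change
statistics and resistance banding.

Condition change for a variety is the within-replicate infested-minus-
control index difference, averaged over replicates (``delta_index``). The
proportional condition change (``relative_change``) divides that by the
susceptible check's delta; its reciprocal (``fold_better``) expresses how
many times better than the check a variety maintained condition. Both are
emitted because the ratio notation is ambiguous in common usage.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import pandas as pd

from .colorspace import ChannelMeans
from .errors import DomainError
from .indices import compute_index
from .synthetic import ScreeningExperiment

__all__ = [
    "ConditionChange",
    "standardize_time",
    "final_day_patch_values",
    "final_day_table",
    "condition_change",
    "classify_by_score",
    "weight_loss",
    "BANDS",
]

logger = logging.getLogger(__name__)

#: Standard Evaluation System bands on the 0-9 damage score.
BANDS = (
    (0, 3, "resistant"),
    (4, 6, "moderately resistant"),
    (7, 9, "susceptible"),
)


@dataclass(frozen=True)
class ConditionChange:
    variety: str
    treatment: str
    index_name: str
    delta_index: float
    relative_change: float | None
    fold_better: float | None


def _round_tenth_half_up(x: float) -> float:
    return math.floor(10.0 * x + 0.5 + 1e-9) / 10.0


def standardize_time(days: list[int] | tuple[int, ...] | int, duration: int) -> list[float] | float:
    """Map sampling days to day/duration rounded to the nearest 0.1 (half up).

    The final day always maps to 1.0. Accepts a single day or a sequence.
    """
    if not 1 <= duration:
        raise DomainError(f"duration {duration} must be >= 1")
    scalar = isinstance(days, int)
    seq = [days] if scalar else list(days)
    out = []
    for d in seq:
        if not 1 <= d <= duration:
            raise DomainError(f"day {d} outside [1, {duration}]")
        out.append(_round_tenth_half_up(d / duration))
    return out[0] if scalar else out


def _as_frame(exp: ScreeningExperiment | pd.DataFrame) -> pd.DataFrame:
    if isinstance(exp, pd.DataFrame):
        return exp
    return exp.to_frame()


def _pool_controls(df: pd.DataFrame) -> pd.DataFrame:
    """Relabel any control arm (``control``, ``control_bph``, ...) as the
    single pooled ``control`` treatment."""
    df = df.copy()
    is_ctrl = df["treatment"].astype(str).str.startswith("control")
    df.loc[is_ctrl, "treatment"] = "control"
    return df


def final_day_patch_values(exp: ScreeningExperiment | pd.DataFrame, index_name: str = "gli",
                           literal: bool = False) -> pd.DataFrame:
    """Per-patch final-day index values (one row per patch at proportional
    time 1.0), control arms pooled under the single label ``control``."""
    df = _as_frame(exp)
    final = df[df["proportionalTime"] == 1.0]
    if final.empty:
        raise DomainError("no observations at proportional time 1.0")
    final = _pool_controls(final)

    def _value(row: pd.Series) -> float | None:
        cm = ChannelMeans(row["meanR"], row["meanG"], row["meanB"], int(row["nPixels"]))
        return compute_index(index_name, cm, literal=literal)

    return final.assign(value=final.apply(_value, axis=1))


def final_day_table(exp: ScreeningExperiment | pd.DataFrame, index_name: str = "gli",
                    literal: bool = False) -> pd.DataFrame:
    """One row per (variety, treatment, replicate) at proportional time 1.0.

    The index value is computed from the patch channel means; control arms
    are pooled and check sub-replicates averaged within a replicate.
    Varieties missing from a replicate are simply absent, with a logged
    warning.
    """
    final = final_day_patch_values(exp, index_name=index_name, literal=literal)
    grouped = (
        final.groupby(["variety", "treatment", "replicate"], as_index=False)
        .agg(
            value=("value", "mean"),
            sesScore=("sesScore", "mean"),
            dryWeight=("dryWeight", "mean"),
            deadCount=("deadCount", "mean"),
        )
    )

    reps = sorted(grouped["replicate"].unique())
    for variety, sub in grouped.groupby("variety"):
        missing = set(reps) - set(sub["replicate"].unique())
        if missing:
            logger.warning("variety %s missing from replicate(s) %s", variety, sorted(missing))
    return grouped


def condition_change(
    table: pd.DataFrame,
    variety: str,
    check: str,
    treatment: str,
    index_name: str = "gli",
) -> ConditionChange:
    """Condition change of ``variety`` under ``treatment`` relative to the
    susceptible ``check``, from a :func:`final_day_table` frame.

    Deltas are computed per replicate (infested minus control within the
    replicate), then averaged; the ratio uses the averaged deltas. When the
    check's delta is exactly 0 the ratios are missing (with a warning); when
    the variety's delta is 0, ``relative_change`` is 0 and ``fold_better``
    is missing.
    """

    def _mean_delta(v: str) -> float:
        sub = table[table["variety"] == v]
        inf = sub[sub["treatment"] == treatment].set_index("replicate")["value"]
        ctl = sub[sub["treatment"] == "control"].set_index("replicate")["value"]
        common = inf.index.intersection(ctl.index)
        if len(common) == 0:
            raise DomainError(
                f"variety {v!r}: no replicate has both {treatment!r} and control values"
            )
        return float((inf.loc[common] - ctl.loc[common]).mean())

    delta_v = _mean_delta(variety)
    delta_check = _mean_delta(check)
    if delta_check == 0.0:
        logger.warning("check %s has zero condition change; ratios undefined", check)
        rel, fold = None, None
    elif delta_v == 0.0:
        rel, fold = 0.0, None
    else:
        rel = delta_v / delta_check
        fold = delta_check / delta_v
    return ConditionChange(variety, treatment, index_name, delta_v, rel, fold)


def classify_by_score(ses_score: int) -> str:
    """Resistance band for a 0-9 damage score (0-3 resistant, 4-6 moderately
    resistant, 7-9 susceptible)."""
    if not isinstance(ses_score, (int,)) or isinstance(ses_score, bool):
        raise DomainError(f"score must be an integer, got {ses_score!r}")
    for lo, hi, band in BANDS:
        if lo <= ses_score <= hi:
            return band
    raise DomainError(f"score {ses_score} outside [0, 9]")


def weight_loss(table: pd.DataFrame, variety: str, treatment: str) -> float | None:
    """Mean control dry weight minus mean infested dry weight, per replicate,
    averaged; missing (with a warning) when either arm is absent."""
    sub = table[table["variety"] == variety]
    inf = sub[sub["treatment"] == treatment].set_index("replicate")["dryWeight"]
    ctl = sub[sub["treatment"] == "control"].set_index("replicate")["dryWeight"]
    common = inf.index.intersection(ctl.index)
    if len(common) == 0 or inf.loc[common].isna().all() or ctl.loc[common].isna().all():
        logger.warning("variety %s: missing arm for weight loss under %s", variety, treatment)
        return None
    return float((ctl.loc[common] - inf.loc[common]).mean())
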