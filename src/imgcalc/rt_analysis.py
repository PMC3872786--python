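"""Lexical-decision reaction time analyses.

Covers trial-level preprocessing (accuracy-based subject exclusion,
absolute and z-based RT trimming), residual variance partitioning (how
much residual RT variance imageability explains before vs. after
partialling out the CONTEXT and EMOTIONALITY composites), the ±1z
CONTEXT × EMOTIONALITY category grids with covariate-adjusted mean RTs,
the proportional-sampling null imageability effect, and the
reliability-ceiling arithmetic for correlations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .modeling import fit_ols

TRIAL_COLUMNS = ["subject", "word", "is_word", "correct", "rt"]


@dataclass
class ExclusionReport:
    """Counts and percentages removed at each preprocessing step."""

    steps: list[dict] = field(default_factory=list)

    def add(self, step: str, removed: int, remaining: int, of: int) -> None:
        pct = 100.0 * removed / of if of else 0.0
        self.steps.append({"step": step, "removed": removed,
                           "remaining": remaining, "percent": round(pct, 2)})

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps)


def preprocess_trials(trials: pd.DataFrame, fast_cut: float = 400.0,
                      slow_cut: float = 4000.0, z_cut: float = 2.5,
                      accuracy_z: float = 2.5, two_sided_z: bool = True
                      ) -> tuple[pd.DataFrame, ExclusionReport]:
    """Standard lexical-decision trial cleaning, in a pinned order.

    1. drop subjects whose accuracy is more than ``accuracy_z`` SDs below
       the across-subject mean accuracy;
    2. drop error trials and non-word trials;
    3. drop trials faster than ``fast_cut`` ms;
    4. drop trials slower than ``slow_cut`` ms;
    5. drop trials beyond ``z_cut`` SDs of the remaining RT distribution
       (two-sided by default; ``two_sided_z=False`` trims the slow tail
       only).

    The order matters (each step's statistics are computed on what the
    previous steps left) and is part of the contract.
    """
    t = trials.copy()
    report = ExclusionReport()

    acc = t.groupby("subject")["correct"].mean()
    cutoff = acc.mean() - accuracy_z * acc.std(ddof=1) if len(acc) > 1 else -np.inf
    bad_subjects = set(acc.index[acc < cutoff])
    before = len(t)
    t = t[~t["subject"].isin(bad_subjects)]
    report.add("subject_accuracy", before - len(t), len(t), before)

    before = len(t)
    t = t[(t["is_word"].astype(bool)) & (t["correct"].astype(bool))]
    report.add("errors_and_nonwords", before - len(t), len(t), before)

    before = len(t)
    t = t[t["rt"] >= fast_cut]
    report.add("too_fast", before - len(t), len(t), before)

    before = len(t)
    t = t[t["rt"] <= slow_cut]
    report.add("too_slow", before - len(t), len(t), before)

    before = len(t)
    if len(t) > 1:
        mu, sd = t["rt"].mean(), t["rt"].std(ddof=1)
        if sd > 0:
            z = (t["rt"] - mu) / sd
            t = t[(z.abs() <= z_cut) if two_sided_z else (z <= z_cut)]
    report.add("z_trim", before - len(t), len(t), before)

    if t.empty:
        raise ValueError("no trials remain after preprocessing")
    return t.reset_index(drop=True), report


def by_item_rt(trials: pd.DataFrame) -> pd.DataFrame:
    """Mean correct-word RT per item (megastudy convention)."""
    t = trials[trials["is_word"].astype(bool) & trials["correct"].astype(bool)]
    out = t.groupby("word")["rt"].mean().rename("rt_ms").reset_index()
    return out


# ---------------------------------------------------------------------------
# residualization and variance partitioning


def residualize(y: pd.Series | np.ndarray, covariates: pd.DataFrame
                ) -> np.ndarray:
    """Residuals of y after OLS on the covariates (with intercept)."""
    model = fit_ols(covariates, y)
    yhat = model.predict(pd.DataFrame(covariates)).to_numpy()
    return np.asarray(y, dtype=float) - yhat


@dataclass
class PartitionReport:
    """Residual variance attributable to imageability, before/after.

    ``covariate_r2``: r² of the lexical covariates on RT.
    ``before``: r² of imageability on those residuals.
    ``after``: r² of imageability on residuals of covariates + CONTEXT +
    EMOTIONALITY + their interaction.  ``ratio`` = after / before.
    """

    covariate_r2: float
    before: float
    after: float
    ratio: float

    def as_dict(self) -> dict:
        return {"covariate_r2": self.covariate_r2, "before": self.before,
                "after": self.after, "ratio": self.ratio}


def variance_partition(rt: pd.Series | np.ndarray, covariates: pd.DataFrame,
                       imageability: pd.Series | np.ndarray,
                       context: pd.Series | np.ndarray,
                       emotionality: pd.Series | np.ndarray
                       ) -> PartitionReport:
    """How much residual RT variance does imageability explain, before and
    after partialling out CONTEXT, EMOTIONALITY and their interaction?"""
    rt = np.asarray(rt, dtype=float)
    covariates = pd.DataFrame(covariates).reset_index(drop=True)
    img = pd.DataFrame({"imageability": np.asarray(imageability, dtype=float)})
    ctx = np.asarray(context, dtype=float)
    emo = np.asarray(emotionality, dtype=float)

    base = fit_ols(covariates, rt)
    resid_before = rt - base.predict(covariates).to_numpy()
    before = fit_ols(img, resid_before).r2

    full_X = covariates.copy()
    full_X["context"] = ctx
    full_X["emotionality"] = emo
    full_X["context_x_emotionality"] = ctx * emo
    full = fit_ols(full_X, rt)
    resid_after = rt - full.predict(full_X).to_numpy()
    after = fit_ols(img, resid_after).r2

    ratio = after / before if before > 0 else math.nan
    return PartitionReport(covariate_r2=base.r2, before=before, after=after,
                           ratio=ratio)


# ---------------------------------------------------------------------------
# distribution analysis


def zcategorize(values: pd.Series | np.ndarray) -> np.ndarray:
    """Label each value low (z < −1), high (z > 1) or mid (in between).

    Boundary values (exactly ±1z) are mid: strict inequalities.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values to z-categorize")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("cannot z-categorize values with zero spread")
    z = (x - x.mean()) / sd
    labels = np.where(z > 1, "high", np.where(z < -1, "low", "mid"))
    return labels


LEVELS = ("low", "mid", "high")


def adjusted_rt(rt: pd.Series | np.ndarray, covariates: pd.DataFrame
                ) -> np.ndarray:
    """Covariate-adjusted RTs: residuals plus the grand mean, so values
    stay on the millisecond scale."""
    resid = residualize(rt, covariates)
    return resid + float(np.mean(np.asarray(rt, dtype=float)))


def category_grid(context_labels: np.ndarray, emotionality_labels: np.ndarray,
                  adjusted_rts: np.ndarray,
                  member: np.ndarray | None = None) -> pd.DataFrame:
    """3×3 CONTEXT × EMOTIONALITY cell summary for one word group.

    ``member`` restricts counts/proportions to a word group (e.g., the
    high-imageability words) while the grid structure covers all cells.
    Returns one row per (context, emotionality) cell with count,
    proportion (within the group), mean adjusted RT and its SE.  Empty
    cells keep count 0 and NaN RTs.
    """
    ctx = np.asarray(context_labels)
    emo = np.asarray(emotionality_labels)
    rtv = np.asarray(adjusted_rts, dtype=float)
    if member is None:
        member = np.ones(len(ctx), dtype=bool)
    member = np.asarray(member, dtype=bool)
    group_n = int(member.sum())

    rows = []
    for c in LEVELS:
        for e in LEVELS:
            in_cell = (ctx == c) & (emo == e) & member
            n = int(in_cell.sum())
            if n:
                m = float(rtv[in_cell].mean())
                se = float(rtv[in_cell].std(ddof=1) / math.sqrt(n)) if n > 1 else math.nan
            else:
                m = se = math.nan
            prop = n / group_n if group_n else math.nan
            rows.append((c, e, n, prop, m, se))
    return pd.DataFrame(
        rows, columns=["context", "emotionality", "count", "proportion",
                       "mean_rt", "se"])


def null_effect(cell_means: np.ndarray, high_props: np.ndarray,
                low_props: np.ndarray, tol: float = 1e-6) -> float:
    """Expected high-minus-low RT difference with no true imageability
    effect: each group draws from shared cell means in its own observed
    cell proportions.  Positive when the low group comes out slower."""
    m = np.asarray(cell_means, dtype=float)
    ph = np.asarray(high_props, dtype=float)
    pl = np.asarray(low_props, dtype=float)
    for name, p in (("high", ph), ("low", pl)):
        if abs(p.sum() - 1.0) > tol:
            raise ValueError(f"{name}-group proportions sum to {p.sum():.8f}, "
                             "not 1")
    return float(pl @ m - ph @ m)


# ---------------------------------------------------------------------------
# reliability-ceiling arithmetic


def equivalent_correlation(r1: float, n1: int, n2: int) -> float:
    """The correlation at sample size n2 with the same t statistic as r1
    at n1 (used to move a reliability estimate between sample sizes)."""
    if not abs(r1) < 1:
        raise ValueError("|r1| must be < 1")
    if n1 <= 2 or n2 <= 2:
        raise ValueError("need n > 2")
    t = r1 * math.sqrt(n1 - 2) / math.sqrt(1 - r1 * r1)
    return t / math.sqrt(n2 - 2 + t * t)


def variance_ratio(r2_model_percent: float, r2_ceiling_percent: float) -> float:
    """Model variance as a percentage of the reliability ceiling."""
    if r2_ceiling_percent == 0:
        raise ValueError("ceiling variance must be nonzero")
    return 100.0 * r2_model_percent / r2_ceiling_percent
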