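"""Cue/stimulus effects, extinction tests, reliability, cross-task
correlation, within-subject error bars and trajectory smoothing.

Effects are cell-mean contrasts on the 2 (cue) x 3 (intensity) design:
identical to GLM coefficients under a balanced design and robust to missing
cells.  Group inference uses Wilcoxon signed-rank tests; reliability is the
odd/even split-half correlation with the Spearman-Brown correction
2r/(1+r); within-subject error bars follow the Cousineau-Morey recipe.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import interpolate, stats

from .agnostic import wilcoxon_signed_rank
from .trialdata import TrialTable, split_odd_even

logger = logging.getLogger(__name__)

_RATING_COL = {"expectation": "expectation_rating", "perception": "perceptual_rating"}


def participant_effects(trials: pd.DataFrame, rating_kind: str = "perception") -> dict:
    """Cue, stimulus and interaction effects for one participant x task.

    cue_effect: mean over intensity levels of (high-cue cell mean - low-cue
    cell mean); stimulus_effect: mean over cues of (level 3 - level 1);
    interaction: cue effect at level 3 minus cue effect at level 1.  For
    expectation ratings the stimulus factor collapses (cue effect only,
    stimulus_effect/interaction NaN).  Missing required cells yield NaN.
    """
    col = _RATING_COL[rating_kind]
    g = trials.dropna(subset=[col])
    out = {
        "participant_id": trials["participant_id"].iloc[0] if len(trials) else None,
        "task": trials["task"].iloc[0] if len(trials) else None,
        "rating_kind": rating_kind,
        "cue_effect": np.nan,
        "stimulus_effect": np.nan,
        "interaction": np.nan,
    }
    if rating_kind == "expectation":
        means = g.groupby("cue_type")[col].mean()
        if {"low", "high"} <= set(means.index):
            out["cue_effect"] = float(means["high"] - means["low"])
        return out

    cells = g.groupby(["cue_type", "stimulus_level"])[col].mean()
    cells = cells.reindex(
        pd.MultiIndex.from_product([["low", "high"], [1, 2, 3]])
    )
    m = cells.to_numpy().reshape(2, 3)  # rows: low, high
    if not np.isnan(m).any():
        out["cue_effect"] = float((m[1] - m[0]).mean())
        out["stimulus_effect"] = float((m[:, 2] - m[:, 0]).mean())
        out["interaction"] = float((m[1, 2] - m[0, 2]) - (m[1, 0] - m[0, 0]))
    else:
        logger.info("participant_effects: empty design cell(s)")
    return out


def cohort_effects(table: TrialTable, rating_kind: str = "perception") -> pd.DataFrame:
    """One effect row per participant x task."""
    rows = [participant_effects(g, rating_kind) for _, _, g in table.subjects()]
    return pd.DataFrame(rows)


def cue_time_interaction(trials: pd.DataFrame, rating_kind: str = "perception") -> float:
    """Per-subject extinction test: the cue x time OLS coefficient.

    Regresses the rating on cue (+-1/2), chronological time scaled to
    [0, 1], their product, and centered stimulus level.  A negative
    coefficient means the cue effect shrinks across the experiment.
    """
    col = _RATING_COL[rating_kind]
    g = trials.dropna(subset=[col]).sort_values("trial_index")
    if len(g) < 8:
        return np.nan
    y = g[col].to_numpy(dtype=float)
    cue = np.where(g["cue_type"].to_numpy() == "high", 0.5, -0.5)
    t = np.linspace(0.0, 1.0, len(g))
    stim = g["stimulus_level"].to_numpy(dtype=float)
    cols = [np.ones_like(y), cue, t, cue * t]
    if np.ptp(stim) > 0:  # constant stimulus would be collinear with intercept
        cols.append(stim - stim.mean())
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        return np.nan
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return float(coef[3])


def cohort_cue_time_test(table: TrialTable, rating_kind: str = "perception"):
    """Cue x time slopes per subject plus the group signed-rank test."""
    slopes = np.array(
        [cue_time_interaction(g, rating_kind) for _, _, g in table.subjects()]
    )
    slopes = slopes[np.isfinite(slopes)]
    z, p = wilcoxon_signed_rank(slopes)
    return slopes, z, p


def spearman_brown(r_half: float) -> float:
    """Project a split-half correlation to full length: 2r / (1 + r)."""
    if r_half <= -1.0:
        raise ValueError("split-half correlation must exceed -1")
    return 2.0 * r_half / (1.0 + r_half)


def odd_even_reliability(
    table: TrialTable,
    effect_fn=None,
    rating_kind: str = "perception",
    effect: str = "cue_effect",
    min_participants: int = 10,
) -> float:
    """Split-half reliability of a per-participant effect.

    ``effect_fn(per_subject_trials) -> float`` defaults to the named column
    of :func:`participant_effects`.  Effects are computed on the odd-rank
    and even-rank halves separately, Pearson-correlated across participants,
    and Spearman-Brown corrected.
    """
    if effect_fn is None:
        effect_fn = lambda g: participant_effects(g, rating_kind)[effect]
    odd, even = split_odd_even(table)
    vals = {}
    for half, t in (("odd", odd), ("even", even)):
        for pid, task, g in t.subjects():
            vals.setdefault((pid, task), {})[half] = effect_fn(g)
    pairsd = {
        k: v for k, v in vals.items()
        if np.isfinite(v.get("odd", np.nan)) and np.isfinite(v.get("even", np.nan))
    }
    if len(pairsd) < min_participants:
        raise ValueError(
            f"need >= {min_participants} participants with both halves; got {len(pairsd)}"
        )
    o = np.array([v["odd"] for v in pairsd.values()])
    e = np.array([v["even"] for v in pairsd.values()])
    r = float(np.corrcoef(o, e)[0, 1])
    return spearman_brown(r)


def cross_task_correlation(
    effects_a: pd.Series, effects_b: pd.Series, min_overlap: int = 10
) -> tuple[float, float]:
    """Spearman correlation of a per-participant effect across two tasks.

    Inputs are indexed by participant_id; pairing is on the shared index.
    """
    joined = pd.concat([effects_a.rename("a"), effects_b.rename("b")], axis=1).dropna()
    if len(joined) < min_overlap:
        raise ValueError(f"need >= {min_overlap} overlapping participants; got {len(joined)}")
    rs, p = stats.spearmanr(joined["a"], joined["b"])
    return float(rs), float(p)


def cousineau_morey_sem(matrix) -> np.ndarray:
    """Within-subject SEM per condition (Cousineau-Morey).

    Each subject's row mean is removed and the grand mean added back; the
    per-condition SEM of the transformed scores is scaled by
    sqrt(C / (C - 1)) for C conditions.  Rows with any missing cell are
    dropped listwise (logged).
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[1] < 2:
        raise ValueError("need a subjects x conditions matrix with >= 2 conditions")
    keep = ~np.isnan(m).any(axis=1)
    if not keep.all():
        logger.info("cousineau_morey_sem: dropped %d incomplete rows", (~keep).sum())
    m = m[keep]
    n, C = m.shape
    centered = m - m.mean(axis=1, keepdims=True) + m.mean()
    sem = centered.std(axis=0, ddof=1) / np.sqrt(n)
    return sem * np.sqrt(C / (C - 1.0))


def smooth_trajectory(values, ranks=None, lam: float | None = None):
    """Cubic smoothing-spline fit of a rating trajectory over trial ranks.

    The smoothing parameter defaults to generalized cross-validation; the
    curve is evaluated at the observed ranks only (never extrapolated).
    With fewer than 8 points the raw values are returned unchanged (flagged
    in the second return value)."""
    y = np.asarray(values, dtype=float)
    x = np.arange(len(y), dtype=float) if ranks is None else np.asarray(ranks, dtype=float)
    ok = np.isfinite(y) & np.isfinite(x)
    if ok.sum() < 8:
        logger.info("smooth_trajectory: < 8 points; returning raw values")
        return y.copy(), False
    order = np.argsort(x[ok])
    xs, ys = x[ok][order], y[ok][order]
    spl = interpolate.make_smoothing_spline(xs, ys, lam=lam)
    fitted = np.full_like(y, np.nan)
    fitted[ok] = spl(x[ok])
    return fitted, True
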