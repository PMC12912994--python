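r"""Model-agnostic learning rates and confirmation-bias statistics.

The delta rule implies a per-trial learning rate
alpha = (E_{t+1}^cue - E_t^cue) / delta_t.  Rather than aggregating that
ratio (which explodes for small prediction errors), the learning rate in
each condition is estimated as the OLS slope of the expectation update on
the prediction error, over consecutive same-cue trial pairs within a
session.  Conditions are cue (low/high) x prediction-error valence
(appetitive delta < 0 / aversive delta > 0); congruent cells are
(low, appetitive) and (high, aversive).  A higher pooled congruent slope
than incongruent slope (alpha_c > alpha_i) is the confirmation-bias
signature.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .trialdata import MIN_TRIALS, TrialTable

logger = logging.getLogger(__name__)

CONDITIONS = ("low-appetitive", "low-aversive", "high-appetitive", "high-aversive")
CONGRUENT_CONDITIONS = ("low-appetitive", "high-aversive")


def build_update_pairs(trials: pd.DataFrame) -> pd.DataFrame:
    """Consecutive same-cue trial pairs within each session for one
    participant x task (chronological order required).

    Each pair carries delta = O_t - E_t and dE = E_{t+1} - E_t; zero-delta
    pairs are dropped (their valence is undefined and the implied update is
    zero).  Rows with a missing rating contribute no pair.
    """
    rows = []
    for (session, cue), g in trials.groupby(["session", "cue_type"], sort=False):
        g = g.sort_values("trial_index")
        E = g["expectation_rating"].to_numpy(dtype=float)
        O = g["perceptual_rating"].to_numpy(dtype=float)
        for t in range(len(g) - 1):
            if not (np.isfinite(E[t]) and np.isfinite(O[t]) and np.isfinite(E[t + 1])):
                continue
            delta = O[t] - E[t]
            if delta == 0:
                continue
            valence = "aversive" if delta > 0 else "appetitive"
            congruent = (cue == "high") == (delta > 0)
            rows.append(
                {
                    "participant_id": g["participant_id"].iloc[0],
                    "task": g["task"].iloc[0],
                    "session": session,
                    "cue_type": cue,
                    "E_t": E[t],
                    "O_t": O[t],
                    "E_next": E[t + 1],
                    "delta": delta,
                    "dE": E[t + 1] - E[t],
                    "congruent": congruent,
                    "condition": f"{cue}-{valence}",
                }
            )
    cols = ["participant_id", "task", "session", "cue_type", "E_t", "O_t",
            "E_next", "delta", "dE", "congruent", "condition"]
    return pd.DataFrame(rows, columns=cols)


def _slope(delta: np.ndarray, dE: np.ndarray, min_pairs: int = 3) -> float:
    """OLS slope of dE on delta with intercept; NaN if under-identified."""
    if len(delta) < min_pairs or np.ptp(delta) == 0:
        return np.nan
    X = np.column_stack([np.ones_like(delta), delta])
    coef, *_ = np.linalg.lstsq(X, dE, rcond=None)
    return float(coef[1])


def condition_slopes(pairs: pd.DataFrame, min_pairs: int = 3) -> pd.DataFrame:
    """Per participant x task: learning-rate slopes in the four cue x valence
    cells, pooled congruent (alpha_c) and incongruent (alpha_i) slopes, and
    the derived bias contrasts.  Cells with fewer than ``min_pairs`` pairs
    are reported missing, never fabricated."""
    rows = []
    for (pid, task), g in pairs.groupby(["participant_id", "task"], sort=True):
        row: dict = {"participant_id": pid, "task": task}
        for cond in CONDITIONS:
            sub = g[g["condition"] == cond]
            row[f"slope_{cond}"] = _slope(
                sub["delta"].to_numpy(), sub["dE"].to_numpy(), min_pairs
            )
            row[f"n_{cond}"] = len(sub)
        for label, mask in (("alpha_c", g["congruent"]), ("alpha_i", ~g["congruent"])):
            sub = g[mask]
            row[label] = _slope(sub["delta"].to_numpy(), sub["dE"].to_numpy(), min_pairs)
        row["bias"] = row["alpha_c"] - row["alpha_i"]
        row["low_cue_bias"] = row["slope_low-appetitive"] - row["slope_high-appetitive"]
        row["high_cue_bias"] = row["slope_high-aversive"] - row["slope_low-aversive"]
        rows.append(row)
    out = pd.DataFrame(rows)
    if len(out) and out["bias"].notna().any():
        med = out["bias"].median()
        mad = (out["bias"] - med).abs().median()
        out["bias_outlier"] = (out["bias"] - med).abs() > 3 * max(mad, 1e-12)
    elif len(out):
        out["bias_outlier"] = False
    return out


def wilcoxon_signed_rank(diffs) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test: returns (z, p).

    Zero differences are dropped (all-zero input returns z=0, p=1).  With at
    most 12 nonzero differences the exact permutation distribution of the
    positive-rank sum is enumerated; otherwise a normal approximation with
    tie correction and continuity correction is used.  The sign of z follows
    the sign of the rank sum relative to its null mean (positive when diffs
    are predominantly positive).
    """
    d = np.asarray(diffs, dtype=float)
    d = d[np.isfinite(d)]
    d = d[d != 0]
    n = len(d)
    if n == 0:
        logger.info("wilcoxon: all differences zero")
        return 0.0, 1.0
    ranks = stats.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    mu = n * (n + 1) / 4.0

    if n <= 12:
        # exact: distribution of the positive-rank sum over all sign flips
        totals = np.zeros(1)
        for r in ranks:
            totals = np.concatenate([totals, totals + r])
        p_ge = np.mean(totals >= w_pos - 1e-9)
        p_le = np.mean(totals <= w_pos + 1e-9)
        p = min(1.0, 2.0 * min(p_ge, p_le))
        # z reported on the same normal scale for comparability
        sigma2 = n * (n + 1) * (2 * n + 1) / 24.0
        _, counts = np.unique(ranks, return_counts=True)
        sigma2 -= (counts**3 - counts).sum() / 48.0
        z = 0.0 if sigma2 == 0 else (w_pos - mu) / math.sqrt(sigma2)
        return z, p

    sigma2 = n * (n + 1) * (2 * n + 1) / 24.0
    _, counts = np.unique(ranks, return_counts=True)
    sigma2 -= (counts**3 - counts).sum() / 48.0
    if sigma2 <= 0:
        return 0.0, 1.0
    cc = 0.5 * np.sign(w_pos - mu)  # continuity correction toward the mean
    z = (w_pos - mu - cc) / math.sqrt(sigma2)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(min(p, 1.0))


def paired_effect_size(diffs) -> float:
    """Cohen's d for paired differences: mean / population sd
    (NaN if sd == 0)."""
    d = np.asarray(diffs, dtype=float)
    d = d[np.isfinite(d)]
    sd = d.std(ddof=0) if len(d) > 1 else 0.0
    if sd == 0:
        logger.info("paired_effect_size: zero-variance differences")
        return np.nan
    return float(d.mean() / sd)


@dataclass
class BiasTests:
    """Group-level confirmation-bias tests over participants."""

    n: int
    alpha_c_mean: float
    alpha_i_mean: float
    bias_z: float
    bias_p: float
    bias_d: float
    low_cue_bias_z: float
    low_cue_bias_p: float
    high_cue_bias_z: float
    high_cue_bias_p: float
    symmetry_z: float
    symmetry_p: float


def bias_statistics(results: pd.DataFrame) -> BiasTests:
    """Signed-rank tests of the confirmation-bias contrasts across
    participants: alpha_c vs alpha_i, each cue-specific bias vs 0, and the
    low- vs high-cue bias symmetry test."""
    ok = results.dropna(subset=["alpha_c", "alpha_i"])
    if len(ok) < 6:
        raise ValueError(f"need >= 6 participants with both rates; got {len(ok)}")
    bias = (ok["alpha_c"] - ok["alpha_i"]).to_numpy()
    z_b, p_b = wilcoxon_signed_rank(bias)

    lcb = results["low_cue_bias"].dropna().to_numpy()
    hcb = results["high_cue_bias"].dropna().to_numpy()
    z_l, p_l = wilcoxon_signed_rank(lcb) if len(lcb) else (np.nan, np.nan)
    z_h, p_h = wilcoxon_signed_rank(hcb) if len(hcb) else (np.nan, np.nan)
    both = results.dropna(subset=["low_cue_bias", "high_cue_bias"])
    if len(both):
        z_s, p_s = wilcoxon_signed_rank(
            (both["low_cue_bias"] - both["high_cue_bias"]).to_numpy()
        )
    else:
        z_s, p_s = np.nan, np.nan
    return BiasTests(
        n=len(ok),
        alpha_c_mean=float(ok["alpha_c"].mean()),
        alpha_i_mean=float(ok["alpha_i"].mean()),
        bias_z=z_b,
        bias_p=p_b,
        bias_d=paired_effect_size(bias),
        low_cue_bias_z=z_l,
        low_cue_bias_p=p_l,
        high_cue_bias_z=z_h,
        high_cue_bias_p=p_h,
        symmetry_z=z_s,
        symmetry_p=p_s,
    )


def inclusion_filter(
    table: TrialTable, min_trials: int = MIN_TRIALS
) -> tuple[TrialTable, pd.DataFrame]:
    """Drop participant x task groups with fewer than ``min_trials`` trials
    (at least two runs' worth); returns the filtered table and a report of
    per-group counts with an ``included`` flag."""
    counts = (
        table.df.groupby(["participant_id", "task"]).size().rename("n_trials").reset_index()
    )
    counts["included"] = counts["n_trials"] >= min_trials
    keep = counts[counts["included"]][["participant_id", "task"]]
    df = table.df.merge(keep, on=["participant_id", "task"], how="inner")
    n_excluded = int((~counts["included"]).sum())
    if n_excluded:
        logger.info("inclusion_filter: excluded %d participant-task groups", n_excluded)
    return TrialTable(df.reset_index(drop=True), table.rating_scale_max, table.normalized), counts


def cohort_agnostic_rates(table: TrialTable) -> pd.DataFrame:
    """Convenience: inclusion filter, pair construction and condition slopes
    for a whole cohort (one row per participant x task)."""
    table, _ = inclusion_filter(table)
    frames = [build_update_pairs(g) for _, _, g in table.subjects()]
    pairs = pd.concat(frames, ignore_index=True) if frames else build_update_pairs(table.df)
    return condition_slopes(pairs)
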