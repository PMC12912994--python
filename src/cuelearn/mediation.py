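"""Two-level mediation: per-subject OLS paths with subject-level bootstrap.

Two analyses mirror the bidirectional expectation-perception loop:

* mediation 1, Cue -> Expectation -> Perception, controlling for the
  current stimulus level and the previous trial's perception, cue and
  expectation;
* mediation 2, Stimulus -> Perception -> next-trial Expectation,
  controlling for the current cue, current expectation, the previous
  trial's perception and the next trial's cue.

Per subject j, OLS gives a_j (X -> M), b_j and c'_j (M, X -> Y) and c_j
(X -> Y); the group indirect effect is the mean of products ab_j with a
percentile bootstrap over subjects for CIs and two-sided p-values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trialdata import TrialTable, normalize_ratings

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MediationSpec:
    """Column roles of one mediation analysis over a trial table."""

    label: str
    x: str
    m: str
    y: str
    covariates: tuple = field(default_factory=tuple)


#: Cue -> Expectation -> Perception
MEDIATION1 = MediationSpec(
    "mediation1",
    x="cue",
    m="expectation",
    y="perception",
    covariates=("stimulus", "prev_perception", "prev_cue", "prev_expectation"),
)
#: Stimulus -> Perception -> Next-trial Expectation
MEDIATION2 = MediationSpec(
    "mediation2",
    x="stimulus",
    m="perception",
    y="next_expectation",
    covariates=("cue", "expectation", "prev_perception", "next_cue"),
)


def _role_columns(g: pd.DataFrame) -> pd.DataFrame:
    """Trial-level variables with within-session lags/leads resolved.

    Cue is coded +-1/2 (high = +1/2), stimulus level is centered; lagged or
    led variables are NaN at session boundaries.
    """
    g = g.sort_values("trial_index")
    out = pd.DataFrame(index=g.index)
    out["session"] = g["session"].to_numpy()
    out["cue"] = np.where(g["cue_type"].to_numpy() == "high", 0.5, -0.5)
    stim = g["stimulus_level"].to_numpy(dtype=float)
    out["stimulus"] = stim - stim.mean()
    out["expectation"] = g["expectation_rating"].to_numpy(dtype=float)
    out["perception"] = g["perceptual_rating"].to_numpy(dtype=float)
    by_sess = out.groupby("session", sort=False)
    for col in ("cue", "expectation", "perception"):
        out[f"prev_{col}"] = by_sess[col].shift(1)
    for col in ("cue", "expectation"):
        out[f"next_{col}"] = by_sess[col].shift(-1)
    return out


def build_mediation_frames(
    table: TrialTable, spec: MediationSpec, min_rows: int = 10
) -> dict:
    """Per-subject regression frames (columns X, M, Y, covariates...).

    Rows whose lags/leads cross a session boundary, or with any missing
    variable, are dropped and counted; subjects with fewer than ``min_rows``
    usable rows are excluded (logged).
    """
    if not table.normalized:
        table = normalize_ratings(table)
    frames = {}
    needed = [spec.x, spec.m, spec.y, *spec.covariates]
    for pid, task, g in table.subjects():
        roles = _role_columns(g)
        frame = roles[needed].dropna()
        if len(frame) < min_rows:
            logger.info(
                "mediation %s: excluding %s/%s (%d usable rows)",
                spec.label, pid, task, len(frame),
            )
            continue
        frames[(pid, task)] = frame
    return frames


def _ols(y: np.ndarray, X: np.ndarray) -> np.ndarray | None:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        return None
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return coef


@dataclass
class MediationResult:
    """Subject-level paths and the bootstrap group summary."""

    label: str
    paths: pd.DataFrame  # per subject: a, b, c, c_prime, ab
    summary: pd.DataFrame  # per path: mean, ci_low, ci_high, p
    n_subjects: int
    n_boot: int


def _boot_summary(paths: pd.DataFrame, n_boot: int, rng: np.random.Generator) -> pd.DataFrame:
    vals = paths[["a", "b", "ab", "c", "c_prime"]].to_numpy()
    n = len(vals)
    idx = rng.integers(0, n, size=(n_boot, n))
    boot_means = vals[idx].mean(axis=1)  # n_boot x 5
    rows = []
    for k, name in enumerate(["a", "b", "ab", "c", "c_prime"]):
        bm = boot_means[:, k]
        p = 2.0 * min((bm <= 0).mean(), (bm >= 0).mean())
        p = min(1.0, max(p, 2.0 / n_boot))
        rows.append(
            {
                "path": name,
                "mean": float(vals[:, k].mean()),
                "ci_low": float(np.percentile(bm, 2.5)),
                "ci_high": float(np.percentile(bm, 97.5)),
                "p": float(p),
            }
        )
    return pd.DataFrame(rows)


def fit_two_level_mediation(
    frames: dict, spec: MediationSpec, n_boot: int = 10_000, seed: int = 0
) -> MediationResult:
    """Per-subject OLS mediation paths + percentile bootstrap over subjects."""
    if len(frames) < 10:
        raise ValueError(f"need >= 10 subjects; got {len(frames)}")
    rows = []
    n_singular = 0
    for (pid, task), f in sorted(frames.items()):
        X_cov = f[list(spec.covariates)].to_numpy() if spec.covariates else np.empty((len(f), 0))
        x = f[spec.x].to_numpy()
        m = f[spec.m].to_numpy()
        y = f[spec.y].to_numpy()
        ones = np.ones((len(f), 1))
        A = _ols(m, np.hstack([ones, x[:, None], X_cov]))
        B = _ols(y, np.hstack([ones, m[:, None], x[:, None], X_cov]))
        C = _ols(y, np.hstack([ones, x[:, None], X_cov]))
        if A is None or B is None or C is None:
            n_singular += 1
            continue
        a_j, b_j, cp_j, c_j = A[1], B[1], B[2], C[1]
        rows.append(
            {"participant_id": pid, "task": task, "a": a_j, "b": b_j,
             "c": c_j, "c_prime": cp_j, "ab": a_j * b_j}
        )
    if n_singular:
        logger.info("mediation %s: dropped %d singular subjects", spec.label, n_singular)
    paths = pd.DataFrame(rows)
    if len(paths) < 10:
        raise ValueError("fewer than 10 subjects with estimable paths")
    rng = np.random.default_rng(seed)
    summary = _boot_summary(paths, n_boot, rng)
    return MediationResult(spec.label, paths, summary, len(paths), n_boot)


def run_both_mediations(
    table: TrialTable, n_boot: int = 10_000, seed: int = 0
) -> dict:
    """Both mediation analyses, per task; returns {(label, task): result}."""
    out = {}
    for spec in (MEDIATION1, MEDIATION2):
        for task in sorted(table.df["task"].unique()):
            sub = TrialTable(
                table.df[table.df["task"] == task].reset_index(drop=True),
                table.rating_scale_max,
                table.normalized,
            )
            frames = build_mediation_frames(sub, spec)
            out[(spec.label, task)] = fit_two_level_mediation(
                frames, spec, n_boot=n_boot, seed=seed
            )
    return out
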